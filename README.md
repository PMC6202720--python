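# ontocolor

Tools for studying **ontogenic color change in antipredator defenses**
on phylogenies — built around the life cycle of swallowtail butterflies
(Papilionidae), whose caterpillars may masquerade as bird droppings,
blend into foliage (crypsis), or advertise toxicity with warning colors
(aposematism), and may switch strategy between early instars, late
instars, and the pupa.

The package is aimed at comparative biologists who have, per species
and lifestage, a photograph (or color palette) of the animal and its
visual background, a dated phylogeny, and host-plant ecology, and who
want to run the full chain from pixels to evolutionary inference:

1. **Contrast scoring** (`ontocolor.colorquant`) — reduce each image to
   a ranked palette (seeded k-means quantization), take the dominant
   color of animal and background (relative proportion > 25%), and
   compute the conspicuousness statistic
   `ΔRGB = |RGB_background − RGB_lifestage|` per channel. Apparent
   (masquerade, aposematism) and nonapparent (crypsis) species are
   compared on the first principal component of ΔRGB with a
   Mann–Whitney test; pupal background matching is checked per channel
   with Kruskal–Wallis.
2. **Strategy classification** — low contrast ⇒ crypsis; apparent with
   an all-white/gray (bird-dropping) palette ⇒ masquerade; apparent
   with chromatic secondary colors ⇒ aposematism.
3. **Ancestral reconstruction** (`ontocolor.mkmap`) — the Mk model of
   discrete character evolution: pruning likelihood with
   `P(t) = expm(Qt)`, ML rate estimation (ER/SYM/ARD), marginal
   ancestral state probabilities, stochastic character mapping (2,000
   sampled histories by default), and counts of independent origins of
   each strategy.
4. **Ecological predictors** (`ontocolor.phyloglm`) — phylogenetic
   logistic regression (penalized ML for a binary trait switching along
   the tree): apparency ~ visual background + range, plus the
   host-toxicity/vegetation correlation check.
5. **Synthetic data** (`ontocolor.synth`) — a seeded generator for
   trees, correlated host characters, host-driven defense states and
   strategy-consistent color scenes, with the generating truth recorded
   for recovery tests.

`ontocolor.pipeline.run_all` chains all stages and writes a JSON report;
the `ontocolor` command line exposes each step
(`simulate`, `extract-colors`, `score-contrast`, `classify`, `fit-mk`,
`ancestral`, `simmap`, `origins`, `phyloglm`, `run-all`, `validate`).

## Worked example

```python
from ontocolor import pipeline, synth

cfg = pipeline.RunConfig(synth_config=synth.SynthConfig(seed=1),
                         nsim=2000, seed=1)
report = pipeline.run_all(cfg)

print(report.apparency_tests["late"])
print(report.phyloglm_fit["z"])
print(report.predictor_correlation)
```

prints (63 synthetic species under the default study conditions):

```
{'W': 902.0, 'p': 8.29e-11, 'variance_explained': [0.816, 0.173, 0.011], 'n_apparent': 22, 'n_nonapparent': 41}
{'(Intercept)': -2.09, 'vegetation_sparse': 3.48, 'distribution_tropical': -0.96}
{'z': 4.185, 'p': 2.85e-05, 'r_squared': 0.924}
```

Reading: late-instar caterpillars classified apparent sit far from the
nonapparent ones on the PC1 contrast axis (Mann–Whitney W = 902,
p ≈ 1e-10, with PC1 carrying 82% of ΔRGB variance); sparse vegetation
strongly predicts an apparent defense (z = 3.48, p < 0.001) while
geographic range does not (z = −0.96); and the two host characters are
tightly correlated (R² = 0.92, phylogenetic regression z = 4.19), which
is why only one of them enters the regression. The pupal channels show
no pupa/background difference (all p > 0.05), and the pupal ancestral
reconstruction is 100% crypsis at every node — the immobile stage keeps
its ancestral camouflage while the mobile stages diversify.

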