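# Methods

`ontocolor` implements a comparative analysis of ontogenic color-defense
evolution: quantify how strongly each lifestage of a species contrasts
with its visual background, classify the defense strategy this implies,
reconstruct how strategies evolved on a phylogeny, and test ecological
predictors of the phenotype. This note records the models, the tunable
parameters, the numerical choices, and what the synthetic data do and
do not establish.

## Color quantification

**Palette extraction.** An image region (foreground animal or
background vegetation) is reduced to a ranked palette by seeded k-means
in raw RGB space over the distinct pixel colors, weighted by their
frequencies. Working on the weighted distinct colors makes the result
invariant to pixel order; clusters holding less than `min_proportion`
(default 1%) of the pixels are merged into the nearest surviving
centroid, and centroids are rounded to integer channels. Fully
transparent pixels (the background-separated part of a PNG) are
excluded. No perceptual color space is used: the whole analysis
operates on 0–255 channel values, so all thresholds below are in those
units.

**Dominant color and delta RGB.** The primary color of a region is its
largest-proportion palette entry, required to exceed the dominance
threshold (default 0.25); proportion ties break toward the
lexicographically smallest (r, g, b), for determinism. The contrast
statistic is the per-channel absolute difference between the dominant
colors of background and lifestage, `ΔRGB = (|ΔR|, |ΔG|, |ΔB|)`.
Absolute values are used because conspicuousness is a magnitude; a
signed version would conflate direction of contrast with its strength.

**Apparency test.** ΔRGB rows (one per species) are centered but not
rescaled — the three channels share a unit — and decomposed by PCA
(SVD). Component signs follow a fixed convention (largest-magnitude
loading positive) so scores are reproducible; rank statistics on PC1
are unaffected up to the W ↔ n₁n₂−W reflection. Apparent (aposematic or
masquerading) and nonapparent (cryptic) species are compared on PC1
with a two-sided Mann–Whitney test; the reported W is the U statistic
of the apparent group (the two-sample `wilcox.test` convention), exact
for small untied samples and tie-corrected normal otherwise.

**Pupal background matching.** Pupae are compared with their
backgrounds one channel at a time by a two-group Kruskal–Wallis test
(three tests, R/G/B). Two identical samples are a fully tied
configuration and are reported as (H = 0, p = 1). Raw p-values are
reported everywhere; no multiple-testing correction is applied across
lifestages or channels, and the report schema says so.

**Strategy classification.** A lifestage is nonapparent — hence cryptic
— when ‖ΔRGB‖₂ falls below the apparency threshold (default 60; roughly
a 35-point shift on each channel). An apparent lifestage is masquerade
when its whole palette looks like a bird dropping: every color either a
shade of white/gray (channel spread ≤ 30 and mean channel ≥ 100) or
within Euclidean distance 60 of a small reference palette of dropping
whites, grays and desiccated browns. Any other apparent palette carries
chromatic secondary colors (reds, yellows) and is classified
aposematism. The contrast threshold and gray tolerances are exposed in
the run configuration; the defaults accept RGB grays and whites while
rejecting warning hues, and the synthetic scenes are classified
perfectly under them.

## Ancestral reconstruction (Mk model)

A k-state defense character evolves along the rooted tree as a
continuous-time Markov chain with rate matrix Q. Three
parameterisations are available — ER (one shared rate, the default, and
the most parsimonious choice for a 3-state character on 63 tips), SYM,
and ARD. Transition probabilities are `P(t) = expm(Qt)`; ER uses the
closed form `e^{-kqt} I + (1 − e^{-kqt}) J/k`.

The likelihood is computed by Felsenstein pruning with per-node
rescaling. Rates are estimated by L-BFGS-B on log rates, started from
the best point of a coarse log-spaced one-rate grid and bounded in
[1e-8, 1e3] per unit branch length; a character with no observed
variation short-circuits to the zero-rate boundary with a warning.
Zero-length branches carry identity transition matrices, which is why
polytomies can be resolved arbitrarily into zero-length bifurcations
without changing the likelihood. The root prior is equal by default;
stationary and explicit priors are available (the choice is
consequential only when Q is strongly asymmetric).

Marginal ancestral probabilities come from the standard two-pass
(post-order then pre-order) algorithm; at a fast-rates limit non-root
nodes decouple to the stationary distribution while the root keeps its
prior. Stochastic character maps are drawn by sampling node states
pre-order from their exact conditionals and then filling each branch
with an endpoint-conditioned CTMC path by rejection: unconditional
forward simulation when the endpoints agree, first jump drawn from the
truncated exponential when they differ, capped at 10⁶ attempts per
branch (the cap is unreachable in practice at the rates this pipeline
fits). The default of 2,000 maps follows the point at which node-state
frequencies stabilise for this problem size.

**Origin counting.** An origin of a state is a segment boundary
entering it on any branch, plus the root when the root is sampled in
that state (a gain predating the clade; a flag disables root
counting). Note a genuine identifiability limit: under a *reversible*
equal-rates map, a single early gain followed by losses competes with k
independent gains, so the modal origin count across maps is an
estimator, not a readout of the true history. The recovery tests
therefore plant irreversible gains and sample maps under an
irreversible low-rate model (gain 0.1 per tree height, loss 0,
all-ancestral root prior), where the planted count is recovered
exactly; for reversible ER runs the tests only require the realized
gain count to fall inside the sampled origin-count distribution.

## Phylogenetic logistic regression (MPLE)

Apparency (apparent = 1) is modelled as a two-state Markov process
switching along the tree. The stationary probability of state 1 on the
branch above tip i is `logistic(x_i'β)`; an internal branch takes the
mean of its descendant tips' stationary probabilities, and the root
prior is the tree-wide mean. A single switching rate α (per unit branch
length) carries the phylogenetic signal: large α makes tips independent
logistic draws, small α makes close relatives nearly identical. The tip
likelihood is computed exactly by pruning (2-state transition
probabilities in closed form), and a Firth-type penalty
`½ log det(X'WX)` with `W = diag(μ(1−μ))` keeps estimates finite under
separation — maximum penalized likelihood (MPLE).

Estimation is joint L-BFGS-B over (β, log α), with α bounded in
[1e-7/T, 50/T] for tree height T and started at 1/T, β at 0. Standard
errors come from the observed information (numerical Hessian in β at
the optimum, α profiled); p-values are two-sided normal. On a star tree
the switching process contributes no correlation and the fit reduces to
ordinary Firth logistic regression (verified against an independent
Firth-scoring implementation). Under tree-structured null data the
slope test is close to nominal but only asymptotically calibrated; the
test suite documents ≤ 10% rejection at nominal 5%.

The three-level range variable (temperate / tropical / both) is coded
tropical-vs-not with "both" counted tropical by default; alternatives
are a matter of recoding the input column. The predictor-correlation
check regresses one binary host character on the other with the same
model and reports, alongside the slope z, the ordinary (non-
phylogenetic) squared Pearson correlation of the two tip vectors as a
descriptive quantity.

## Synthetic data

The generator emulates the structure of the study system so that every
stage has known truth:

* **Tree** — birth–death (birth 1.0, death 0.3 per lineage) conditioned
  on 63 extant tips, rescaled to height 1. The simulator stops at the
  63rd speciation, which would leave a zero-length cherry; terminal
  branches are extended by the waiting time to the next speciation,
  keeping the tree ultrametric with strictly positive tip branches.
* **Host characters** — toxicity evolves under a 2-state ER process
  (rate 0.5); the draw is conditioned on each class holding ≥ 15% of
  tips, since both host classes are richly represented in the real
  group and a monomorphic draw would leave the regression undefined.
  Vegetation density copies toxicity and flips per tip with probability
  `1 − √0.9 ≈ 0.051`, targeting the reported squared correlation of 0.9
  (mean concordance ≈ 0.95). The range label thresholds a Brownian
  latitude surrogate at its realized terciles into temperate / both /
  tropical.
* **Defense states** — toxic hosts give aposematic caterpillars;
  nontoxic hosts give masquerade early and crypsis late, each with
  probability 1 − ε (ε = 0.05). An exceptional tip takes the stage's
  otherwise-absent third strategy (cryptic early instars, masquerading
  late instars), mirroring the few deviant lineages observed in real
  swallowtails. Pupae are cryptic throughout.
* **Scenes** — green-dominated foliage backgrounds; cryptic foregrounds
  match the background dominant within ±10 per channel (‖ΔRGB‖ ≤ √3·10,
  below the apparency threshold by construction), masquerade
  foregrounds are whites/grays (spread ≤ 20, mean ≥ 150), aposematic
  foregrounds pair a dark base with a red or yellow secondary color.
  Dominant proportions always exceed 0.25.

Everything is deterministic given the config seed (independent child
seeds per stage). What the synthetic data do **not** emulate: real
photographs (lighting variation, shadows, continuous color gradients —
the scenes are two-color palettes), within-lineage phenotype variation,
model mismatch in the tree (the tree is known exactly), and defense
states that actually evolve along branches (they are host-driven at the
tips). Passing tests therefore establish the correctness and
calibration of the machinery under the stated generating conditions,
not the robustness of the biological conclusions to real-data noise.

## Problem sizes and tolerances

Exhaustive-enumeration checks of the pruning likelihood use 200 random
instances with ≤ 6 tips and ≤ 3 states at 1e-10 agreement.
Stochastic-map frequencies are compared with analytic marginals at
2,000 maps on a 20-tip tree, within 3 binomial standard errors per node
and state plus a 1/nsim discreteness floor. Rate recovery uses 50
replicates of 200-tip trees at q = 0.5 (median in [0.4, 0.6]).
Regression checks use 50 replicates each for slope-sign recovery and
null calibration on 100-tip trees, and 50 full-pipeline replicates at
the default study conditions with 50 maps per lifestage per replicate;
the library default stays at 2,000 maps. The acceptance script runs one
full default-condition pipeline at 2,000 maps.
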