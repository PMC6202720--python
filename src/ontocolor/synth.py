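"""Synthetic data with known ground truth for every pipeline stage.

Emulates the structure of the study system: a ~63-tip butterfly
phylogeny; a 3-state color-defense phenotype per lifestage driven by
host-plant ecology (toxic hosts favour aposematism, nontoxic ones
masquerade early and crypsis late, pupae are uniformly cryptic); two
strongly concordant binary host characters (toxicity and vegetation
density); a latitude-like distribution label; and per-species color
scenes whose palettes follow the strategy, so the contrast classifier
can recover the generating labels.

Every output is deterministic given the config seed, and every
generating event (true character histories, gain counts, exception
tips) is recorded for recovery tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .colorquant import ColorComposition, RGBColor, apparency_of
from .errors import InvalidInputError
from .mkmap import QMatrix, StochasticMap, index_tree, simulate_mk
from .phyloio import CharacterMatrix, HostPlantTable, write_tree

__all__ = [
    "SynthConfig",
    "SynthData",
    "gen_tree",
    "sim_host_traits",
    "sim_defense_states",
    "sim_gain_history",
    "gen_color_scene",
    "composition_to_pixels",
    "generate_dataset",
    "write_dataset",
]

LIFESTAGES = ("early", "late", "pupa")
DEFENSE_STATES = ("masquerade", "crypsis", "aposematism")


@dataclass
class SynthConfig:
    """Study-condition parameters of the generator.

    `n_tips` matches the 63 representative lineages of the study group;
    `host_correlation` is the target squared correlation between
    toxicity and vegetation density (0.9, as reported for the real host
    families); `epsilon` is the per-tip probability that a caterpillar
    deviates from its host-predicted defense (a few exceptional
    lineages exist in nature); `host_rate` is the ER switching rate of
    toxicity on the height-1 tree; `q_defense` is the Mk rate matrix
    used for unconditional phenotype simulations in recovery tests.
    """

    n_tips: int = 63
    birth_rate: float = 1.0
    death_rate: float = 0.3
    host_rate: float = 0.5
    host_correlation: float = 0.9
    epsilon: float = 0.05
    min_host_class_fraction: float = 0.15
    q_defense: QMatrix = field(default_factory=lambda: QMatrix.er(3, 0.5))
    seed: int = 0

    def __post_init__(self):
        if self.birth_rate <= self.death_rate:
            raise InvalidInputError("birth rate must exceed death rate")
        if not 0.0 <= self.host_correlation <= 1.0:
            raise InvalidInputError("host_correlation must be in [0, 1]")
        if not 0.0 <= self.epsilon < 1.0:
            raise InvalidInputError("epsilon must be in [0, 1)")


@dataclass
class SynthData:
    """A full synthetic dataset plus its generating ground truth."""

    tree: dendropy.Tree
    hosts: HostPlantTable
    defense: dict[str, CharacterMatrix]  # lifestage -> states
    scenes: dict[tuple[str, str, str], ColorComposition]
    truth: dict


def _subseed(seed: int, stream: int) -> int:
    """Independent child seed below 2**31."""
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


def gen_tree(config: SynthConfig, max_retries: int = 100) -> dendropy.Tree:
    """Birth-death tree conditioned on `n_tips`, rescaled to height 1."""
    import random as _random

    rng = _random.Random(_subseed(config.seed, 1))
    last_error = None
    for _ in range(max_retries):
        try:
            tree = treesim.birth_death_tree(
                birth_rate=config.birth_rate,
                death_rate=config.death_rate,
                num_extant_tips=config.n_tips,
                rng=rng,
            )
            break
        except Exception as exc:  # whole-tree extinction; retry
            last_error = exc
    else:
        raise InvalidInputError(f"tree simulation kept going extinct: {last_error}")
    tree.seed_node.edge.length = 0.0
    tree.is_rooted = True
    # the simulator stops exactly at the n-th speciation, leaving a
    # zero-length cherry; run the clock on to the next (unrealised)
    # speciation so every terminal branch is positive and the tree stays
    # ultrametric
    extra = rng.expovariate(config.n_tips * config.birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    height = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length:
            edge.length = edge.length / height
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(),
                                    key=lambda l: l.taxon.label)):
        leaf.taxon.label = f"sp{i+1:02d}"
    tree.resolve_polytomies()
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return tree


def sim_host_traits(tree, config: SynthConfig) -> tuple[HostPlantTable, dict]:
    """Simulate toxicity (2-state Mk), vegetation (noisy copy), range.

    Vegetation is copied from toxicity (toxic -> sparse) and flipped
    independently per tip with probability ``1 - sqrt(host_correlation)``
    so the squared tip correlation targets `host_correlation`.  The
    distribution label thresholds a Brownian latitude surrogate into
    temperate / tropical / both at its realized terciles.  Returns the
    table and a truth record (true toxicity history, gain count, flips).
    """
    idx = index_tree(tree)
    q_host = QMatrix.er(2, config.host_rate)
    tip_order = sorted(idx.tip_index)
    # both host classes are richly represented in the study group, so the
    # toxicity simulation is conditioned on each class holding at least
    # min_host_class_fraction of the tips
    floor = max(1, int(math.ceil(config.min_host_class_fraction * len(tip_order))))
    for attempt in range(200):
        history = simulate_mk(tree, q_host, root_prior="equal",
                              seed=_subseed(config.seed, 2 + 100 * attempt))
        toxic = {lab: int(history.node_states[idx.tip_index[lab]])
                 for lab in tip_order}
        n1 = sum(toxic.values())
        if floor <= n1 <= len(tip_order) - floor:
            break
    else:
        raise InvalidInputError("could not draw host classes above the floor")
    rng = np.random.default_rng(_subseed(config.seed, 3))
    flip_rate = 1.0 - math.sqrt(config.host_correlation)
    flips = {lab: bool(rng.random() < flip_rate) for lab in tip_order}
    veg = {lab: (1 - toxic[lab]) if flips[lab] else toxic[lab] for lab in tip_order}

    # Brownian latitude surrogate along the tree
    lat = np.zeros(idx.n)
    for i in idx.preorder:
        if idx.parent[i] >= 0:
            lat[i] = lat[idx.parent[i]] + rng.normal(0.0, math.sqrt(max(idx.blen[i], 1e-12)))
    tip_lat = {lab: lat[idx.tip_index[lab]] for lab in tip_order}
    lo, hi = np.quantile(list(tip_lat.values()), [1 / 3, 2 / 3])
    dist = {lab: ("temperate" if v < lo else "tropical" if v > hi else "both")
            for lab, v in tip_lat.items()}

    toxic_gains = _count_history_gains(history, target=1)
    table = pd.DataFrame({
        "family": ["Toxicaceae" if toxic[lab] else "Densifoliaceae" for lab in tip_order],
        "toxicity": ["toxic" if toxic[lab] else "nontoxic" for lab in tip_order],
        "vegetation": ["sparse" if veg[lab] else "dense" for lab in tip_order],
        "distribution": [dist[lab] for lab in tip_order],
    }, index=pd.Index(tip_order, name="species"))
    truth = {
        "toxicity_history": history,
        "toxic_gain_count": toxic_gains,
        "vegetation_flips": [lab for lab, f in flips.items() if f],
    }
    return HostPlantTable(table), truth


def _count_history_gains(history: StochasticMap, target: int) -> int:
    idx = history.index
    n = 1 if history.node_states[idx.root] == target else 0
    for seg in history.segments:
        for j in range(1, len(seg)):
            if seg[j][0] == target and seg[j - 1][0] != target:
                n += 1
    return n


def sim_defense_states(tree, hosts: HostPlantTable, config: SynthConfig,
                       ) -> tuple[dict[str, CharacterMatrix], dict]:
    """Host-driven defense phenotypes per lifestage.

    Toxic hosts give aposematic caterpillars; nontoxic hosts give
    masquerade at early instars and crypsis at late instars — each with
    probability 1 - epsilon.  An exceptional tip takes the stage's
    otherwise-absent third strategy (cryptic early instars, masquerading
    late instars), mirroring the handful of deviant lineages in real
    swallowtails.  Pupae are cryptic throughout.
    """
    rng = np.random.default_rng(_subseed(config.seed, 4))
    tip_order = hosts.species
    toxic = hosts.binary("toxicity", "toxic")
    rule = {"early": {1: "aposematism", 0: "masquerade"},
            "late": {1: "aposematism", 0: "crypsis"}}
    third = {"early": "crypsis", "late": "masquerade"}
    matrices: dict[str, CharacterMatrix] = {}
    exceptions: dict[str, list[str]] = {}
    for stage in ("early", "late"):
        labels = {}
        exceptions[stage] = []
        for lab in tip_order:
            expected = rule[stage][toxic[lab]]
            if rng.random() < config.epsilon:
                labels[lab] = third[stage]
                exceptions[stage].append(lab)
            else:
                labels[lab] = expected
        matrices[stage] = CharacterMatrix.from_labels(labels, DEFENSE_STATES)
    matrices["pupa"] = CharacterMatrix.from_labels(
        {lab: "crypsis" for lab in tip_order}, DEFENSE_STATES)
    truth = {"rule": rule, "exceptions": exceptions}
    return matrices, truth


def sim_gain_history(tree, n_gains: int, seed: int = 0, target_state: int = 2,
                     base_state: int = 0, k: int = 3,
                     max_attempts: int = 10000) -> StochasticMap:
    """Plant `n_gains` irreversible gains of `target_state` on the tree.

    Gain branches are sampled without ancestor/descendant overlap — and
    such that every gain branch's parent clade keeps at least one
    unaffected tip, so the tip pattern itself pins the origin count (two
    sibling gains would be indistinguishable from one gain on their
    parent).  The gain event sits at the midpoint of its branch and
    every node below it is in the target state.  Ground truth for
    origin-count recovery.
    """
    idx = index_tree(tree)
    rng = np.random.default_rng(seed)
    below: list[set[int]] = [set() for _ in range(idx.n)]
    for i in idx.postorder:
        for c in idx.children[i]:
            below[i] |= below[c] | {c}
    tips_below = [frozenset(j for j in (below[i] | {i}) if idx.is_tip[j])
                  for i in range(idx.n)]
    candidates = [i for i in range(idx.n)
                  if i != idx.root and idx.blen[i] > 0]

    def identifiable(selection):
        covered = set()
        for c in selection:
            covered |= tips_below[c]
        return all(not (tips_below[idx.parent[c]] <= covered)
                   for c in selection)

    chosen: list[int] = []
    for _ in range(max_attempts):
        if len(chosen) == n_gains:
            break
        cand = int(rng.choice(candidates))
        if any(cand == c or cand in below[c] or c in below[cand] for c in chosen):
            continue
        if not identifiable(chosen + [cand]):
            continue
        chosen.append(cand)
    if len(chosen) < n_gains:
        raise InvalidInputError(
            f"could not place {n_gains} non-nested gains on this tree")
    gained = set()
    for c in chosen:
        gained |= below[c] | {c}
    node_states = np.full(idx.n, base_state, dtype=int)
    node_states[list(gained)] = target_state
    segments: list[list[tuple[int, float]]] = [[] for _ in range(idx.n)]
    for i in range(idx.n):
        if idx.parent[i] < 0:
            continue
        t = idx.blen[i]
        if i in chosen:
            segments[i] = [(base_state, t / 2.0), (target_state, t / 2.0)]
        else:
            segments[i] = [(int(node_states[i]), t)]
    return StochasticMap(node_states=node_states, segments=segments,
                         index=idx, k=k)


# ---------------------------------------------------------------------------
# Color scenes
# ---------------------------------------------------------------------------

def _jitter(rng, base, spread, lo=0, hi=255):
    return tuple(int(np.clip(v + rng.integers(-spread, spread + 1), lo, hi))
                 for v in base)


def gen_color_scene(strategy: str, config: SynthConfig | None = None,
                    seed: int = 0) -> tuple[ColorComposition, ColorComposition]:
    """(foreground, background) palettes consistent with a strategy.

    Backgrounds are green-dominated foliage.  Crypsis foregrounds match
    the background dominant within +-10 per channel; masquerade
    foregrounds are whites/grays (channel spread <= 20, mean >= 150);
    aposematic foregrounds pair a dark base with red/yellow secondary
    colors.  Dominant proportions always exceed 0.25.
    """
    if strategy not in DEFENSE_STATES:
        raise InvalidInputError(f"unknown strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    bg_dom = _jitter(rng, (70, 130, 50), 25)
    bg_second = _jitter(rng, (100, 80, 40), 20)
    while bg_second == bg_dom:
        bg_second = _jitter(rng, (100, 80, 40), 20)
    background = ColorComposition.from_pairs([(RGBColor.of(*bg_dom), 0.65),
                                              (RGBColor.of(*bg_second), 0.35)])
    if strategy == "crypsis":
        fg_dom = _jitter(rng, bg_dom, 10)
        fg_second = _jitter(rng, bg_second, 10)
    elif strategy == "masquerade":
        base = int(rng.integers(180, 246))
        fg_dom = tuple(int(np.clip(base + d, 160, 255))
                       for d in rng.integers(-8, 9, size=3))
        g2 = int(rng.integers(160, 210))
        fg_second = tuple(int(np.clip(g2 + d, 150, 255))
                          for d in rng.integers(-8, 9, size=3))
    else:  # aposematism: dark base, warning secondary color
        fg_dom = _jitter(rng, (20, 18, 16), 12)
        warn = (210, 40, 30) if rng.random() < 0.5 else (235, 200, 30)
        fg_second = _jitter(rng, warn, 15)
    if fg_second == fg_dom:
        fg_second = tuple(int(np.clip(v + 3, 0, 255)) for v in fg_second)
    foreground = ColorComposition.from_pairs([(RGBColor.of(*fg_dom), 0.6),
                                              (RGBColor.of(*fg_second), 0.4)])
    return foreground, background


def composition_to_pixels(comp: ColorComposition, n_pixels: int = 400,
                          seed: int = 0) -> np.ndarray:
    """Render a palette to a shuffled (n, 3) pixel array with proportions
    matched as closely as integer counts allow."""
    rng = np.random.default_rng(seed)
    counts = np.array([int(round(p * n_pixels)) for _, p, _ in comp.entries])
    counts[0] += n_pixels - counts.sum()
    pixels = np.concatenate([
        np.tile(np.array(c, dtype=np.uint8), (cnt, 1))
        for (c, _, _), cnt in zip(comp.entries, counts) if cnt > 0
    ])
    rng.shuffle(pixels, axis=0)
    return pixels


# ---------------------------------------------------------------------------
# Whole datasets
# ---------------------------------------------------------------------------

def generate_dataset(config: SynthConfig | None = None) -> SynthData:
    """Tree + hosts + defense states + color scenes, fully seeded."""
    config = config or SynthConfig()
    tree = gen_tree(config)
    hosts, host_truth = sim_host_traits(tree, config)
    defense, defense_truth = sim_defense_states(tree, hosts, config)
    scenes: dict[tuple[str, str, str], ColorComposition] = {}
    scene_rng = np.random.default_rng(_subseed(config.seed, 5))
    for stage in LIFESTAGES:
        for sp in hosts.species:
            strategy = defense[stage].name_of(sp)
            fg, bg = gen_color_scene(strategy, config,
                                     seed=int(scene_rng.integers(2**31)))
            scenes[(sp, stage, "foreground")] = fg
            scenes[(sp, stage, "background")] = bg
    truth = {
        **host_truth,
        **defense_truth,
        "config": config,
    }
    return SynthData(tree=tree, hosts=hosts, defense=defense,
                     scenes=scenes, truth=truth)


def write_dataset(data: SynthData, outdir) -> None:
    """Write tree.nwk, traits.csv, hosts.csv, scenes.csv, truth.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tree.nwk").write_text(write_tree(data.tree))
    rows = []
    for stage in LIFESTAGES:
        for sp in data.hosts.species:
            rows.append({
                "species": sp,
                "lifestage": stage,
                "strategy": data.defense[stage].name_of(sp),
                "apparency": apparency_of(data.defense[stage].name_of(sp)),
            })
    pd.DataFrame(rows).to_csv(out / "traits.csv", index=False)
    data.hosts.table.to_csv(out / "hosts.csv")
    scene_rows = []
    for (sp, stage, role), comp in sorted(data.scenes.items()):
        for color, prop, _rank in comp.entries:
            scene_rows.append({"species": sp, "lifestage": stage, "role": role,
                               "r": color.r, "g": color.g, "b": color.b,
                               "proportion": prop})
    pd.DataFrame(scene_rows).to_csv(out / "scenes.csv", index=False)
    truth = {
        "toxic_gain_count": data.truth["toxic_gain_count"],
        "vegetation_flips": data.truth["vegetation_flips"],
        "exceptions": data.truth["exceptions"],
        "rule": data.truth["rule"],
        "seed": data.truth["config"].seed,
        "n_tips": data.truth["config"].n_tips,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
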