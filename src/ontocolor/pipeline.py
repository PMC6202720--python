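"""End-to-end analysis: contrast scoring -> classification -> ancestral
mapping -> phylogenetic regression.

`run_all` chains every stage on either file inputs (tree.nwk,
traits/hosts CSVs, a scenes palette table) or a freshly generated
synthetic dataset, and returns a machine-readable report whose every
number traces back to one library operation.  Raw p-values are reported
throughout; no multiple-testing correction is applied across lifestages
or channels, and the report schema says so.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import colorquant as cq
from . import mkmap, phyloglm, synth
from .errors import InsufficientDataError, InvalidInputError, OntocolorError
from .phyloio import CharacterMatrix, HostPlantTable, bind_traits, read_tree

__all__ = ["RunConfig", "AnalysisReport", "run_all", "validate_inputs"]

log = logging.getLogger("ontocolor")

SCHEMA_VERSION = "1.0"


@dataclass
class RunConfig:
    """Inputs, thresholds and sampling sizes for a full run.

    With no input paths, a synthetic dataset is generated from
    `synth_config` (defaulting to the study conditions).  Thresholds:
    `dominance_threshold` is the primary-color proportion rule (0.25),
    `apparency_threshold` the delta RGB norm separating apparent from
    nonapparent (60), `gray_tolerance` the channel spread for the
    white/gray masquerade rule (30).
    """

    tree_path: str | None = None
    traits_path: str | None = None
    hosts_path: str | None = None
    scenes_path: str | None = None
    synth_config: synth.SynthConfig | None = None
    dominance_threshold: float = 0.25
    apparency_threshold: float = 60.0
    gray_tolerance: float = 30.0
    nsim: int = 2000
    seed: int = 0
    outdir: str | None = None

    def config_hash(self) -> str:
        payload = {k: repr(v) for k, v in dataclasses.asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    def validate_thresholds(self) -> list[str]:
        problems = []
        if not 0.0 < self.dominance_threshold < 1.0:
            problems.append("dominance_threshold must be in (0, 1)")
        if not 0.0 <= self.apparency_threshold <= 255 * np.sqrt(3):
            problems.append("apparency_threshold outside [0, 441.7]")
        if not 0.0 <= self.gray_tolerance <= 255:
            problems.append("gray_tolerance outside [0, 255]")
        if self.nsim < 1:
            problems.append("nsim must be >= 1")
        return problems


@dataclass
class AnalysisReport:
    """Structured results of one full run."""

    contrast: pd.DataFrame = field(repr=False)  # species x lifestage deltas+labels
    apparency_tests: dict = field(default_factory=dict)
    pupa_match: dict = field(default_factory=dict)
    mk_fits: dict = field(default_factory=dict)
    ancestral: dict = field(default_factory=dict)
    origin_counts: dict = field(default_factory=dict)
    phyloglm_fit: dict = field(default_factory=dict)
    predictor_correlation: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "note": "raw p-values; no multiple-testing correction applied",
            "contrast": self.contrast.to_dict(orient="index"),
            "apparency_tests": self.apparency_tests,
            "pupa_match": self.pupa_match,
            "mk_fits": self.mk_fits,
            "ancestral": self.ancestral,
            "origin_counts": self.origin_counts,
            "phyloglm": self.phyloglm_fit,
            "predictor_correlation": self.predictor_correlation,
            "provenance": self.provenance,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True,
                          default=_jsonable, **kwargs)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _load_inputs(config: RunConfig):
    if config.tree_path is None:
        sc = config.synth_config or synth.SynthConfig(seed=config.seed)
        log.info("generating synthetic dataset (seed=%d)", sc.seed)
        data = synth.generate_dataset(sc)
        return data.tree, data.hosts, data.scenes, data.truth
    tree = read_tree(Path(config.tree_path).read_text())
    hosts = HostPlantTable(pd.read_csv(config.hosts_path, index_col="species"))
    scenes = cq.read_composition_table(config.scenes_path)
    return tree, hosts, scenes, None


def _score_stage(scenes, species, stage, config: RunConfig):
    """Delta RGB + classified strategy per species for one lifestage."""
    rows = {}
    for sp in species:
        fg = scenes[(sp, stage, "foreground")]
        bg = scenes[(sp, stage, "background")]
        fg_dom = cq.dominant_color(fg, config.dominance_threshold)
        bg_dom = cq.dominant_color(bg, config.dominance_threshold)
        delta = cq.delta_rgb(bg_dom, fg_dom)
        label = cq.classify_strategy(
            delta, fg,
            apparency_threshold=config.apparency_threshold,
            gray_tolerance=config.gray_tolerance)
        rows[sp] = {
            "lifestage": stage,
            "dr": delta.dr, "dg": delta.dg, "db": delta.db,
            "strategy": label.value, "apparency": label.apparency,
            "dominant_rgb": tuple(fg_dom.color), "background_rgb": tuple(bg_dom.color),
            "_delta": delta,
        }
    return rows


def run_all(config: RunConfig | None = None) -> AnalysisReport:
    """Execute the full pipeline; every stage error is surfaced with its
    stage name and partial results are kept in the report."""
    config = config or RunConfig()
    problems = config.validate_thresholds()
    if problems:
        raise InvalidInputError("; ".join(problems))
    tree, hosts, scenes, truth = _load_inputs(config)
    species = sorted({key[0] for key in scenes})
    report = AnalysisReport(contrast=pd.DataFrame())

    # --- stage 1: contrast scoring & classification -----------------------
    contrast_rows = []
    stage_scores = {}
    for stage in synth.LIFESTAGES:
        log.info("stage colorquant: %s", stage)
        scored = _score_stage(scenes, species, stage, config)
        stage_scores[stage] = scored
        for sp, row in scored.items():
            contrast_rows.append({"species": sp, **{k: v for k, v in row.items()
                                                    if not k.startswith("_")}})
    report.contrast = pd.DataFrame(contrast_rows)

    # --- stage 2: apparency statistics ------------------------------------
    for stage in ("early", "late"):
        scored = stage_scores[stage]
        deltas = {sp: row["_delta"] for sp, row in scored.items()}
        labels = {sp: row["apparency"] for sp, row in scored.items()}
        try:
            res = cq.apparency_test(deltas, labels)
            report.apparency_tests[stage] = {
                "W": res.w_statistic, "p": res.p_value,
                "variance_explained": res.variance_explained.tolist(),
                "n_apparent": sum(1 for v in labels.values() if v == cq.APPARENT),
                "n_nonapparent": sum(1 for v in labels.values() if v == cq.NONAPPARENT),
            }
        except (InsufficientDataError, OntocolorError) as exc:
            report.apparency_tests[stage] = {"error": f"{type(exc).__name__}: {exc}"}

    pupa = stage_scores["pupa"]
    pupa_colors = {sp: cq.RGBColor.of(*row["dominant_rgb"]) for sp, row in pupa.items()}
    back_colors = {sp: cq.RGBColor.of(*row["background_rgb"]) for sp, row in pupa.items()}
    report.pupa_match = {
        ch: {"statistic": stat, "p": p}
        for ch, (stat, p) in cq.pupa_match_test(pupa_colors, back_colors).items()
    }

    # --- stage 3: ancestral reconstruction per lifestage -------------------
    import warnings as _warnings
    state_names = list(synth.DEFENSE_STATES)
    for stage in synth.LIFESTAGES:
        log.info("stage mkmap: %s", stage)
        labels = {sp: stage_scores[stage][sp]["strategy"] for sp in species}
        matrix = CharacterMatrix.from_labels(labels, state_names)
        bind_traits(tree, matrix)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            fit = mkmap.fit_mk(tree, matrix, model_class="ER")
        report.mk_fits[stage] = {
            "model": "ER", "rate": float(fit.Q.matrix[0, 1]),
            "loglik": fit.loglik, "converged": fit.converged,
            "boundary": fit.boundary,
        }
        anc = mkmap.marginal_ancestral(tree, matrix, fit.Q)
        maps = mkmap.sample_maps(tree, matrix, fit.Q, nsim=config.nsim,
                                 seed=_stage_seed(config.seed, stage))
        summary = mkmap.node_state_summary(maps, state_names)
        internal = ~summary.index.is_tip
        report.ancestral[stage] = {
            "state_names": state_names,
            "marginal_internal": anc.probs[internal].tolist(),
            "simmap_internal": summary.probs[internal].tolist(),
            "root_marginal": anc.probs[anc.index.root].tolist(),
            "root_simmap": summary.probs[summary.index.root].tolist(),
        }
        report.origin_counts[stage] = {
            name: {
                "modal": (oc := mkmap.count_origins(maps, i)).modal_count,
                "mean": float(oc.counts.mean()),
                "distribution": {str(k): v for k, v in oc.distribution().items()},
            }
            for i, name in enumerate(state_names)
        }

    # --- stage 4: phylogenetic regression ----------------------------------
    log.info("stage phyloglm")
    late = {sp: 1 if stage_scores["late"][sp]["apparency"] == cq.APPARENT else 0
            for sp in species}
    veg = hosts.binary("vegetation", "sparse")
    dist = hosts.binary("distribution", "tropical")
    X = pd.DataFrame({"vegetation_sparse": veg, "distribution_tropical": dist})
    try:
        fit = phyloglm.fit_phyloglm(tree, late, X.loc[species])
        report.phyloglm_fit = {
            "formula": "apparency ~ vegetation + distribution",
            "coefficients": fit.coefficients.to_dict(),
            "std_errors": fit.std_errors.to_dict(),
            "z": fit.z_scores.to_dict(),
            "p": fit.p_values.to_dict(),
            "alpha": fit.alpha, "converged": fit.converged, "n": fit.n,
        }
    except OntocolorError as exc:
        report.phyloglm_fit = {"error": f"{type(exc).__name__}: {exc}"}
    try:
        tox = hosts.binary("toxicity", "toxic")
        z, p, r2 = phyloglm.predictor_correlation(tree, tox, veg)
        report.predictor_correlation = {"z": z, "p": p, "r_squared": r2}
    except OntocolorError as exc:
        report.predictor_correlation = {"error": f"{type(exc).__name__}: {exc}"}

    report.provenance = {
        "seed": config.seed,
        "nsim": config.nsim,
        "config_hash": config.config_hash(),
        "n_species": len(species),
        "synthetic": config.tree_path is None,
    }
    if truth is not None:
        report.provenance["true_toxic_gains"] = truth["toxic_gain_count"]

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json() + "\n")
        report.contrast.to_csv(out / "contrast.csv", index=False)
    return report


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def validate_inputs(config: RunConfig) -> list[str]:
    """Human-readable list of input problems (empty = valid)."""
    problems = config.validate_thresholds()
    try:
        tree, hosts, scenes, _ = _load_inputs(config)
    except Exception as exc:
        return problems + [f"inputs failed to load: {exc}"]
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    scene_species = {key[0] for key in scenes}
    missing = tips - scene_species
    extra = scene_species - tips
    if missing:
        problems.append(f"tree tips without scenes: {sorted(missing)}")
    if extra:
        problems.append(f"scene species not in tree: {sorted(extra)}")
    host_missing = tips - set(hosts.species)
    if host_missing:
        problems.append(f"tree tips without host data: {sorted(host_missing)}")
    for key, comp in scenes.items():
        total = sum(p for _, p, _ in comp.entries)
        if abs(total - 1.0) > 1e-6:
            problems.append(f"scene {key} proportions sum to {total:.4f}")
    return problems
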