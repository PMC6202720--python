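"""Color-defense quantification in raw RGB space.

A lifestage photograph (or a precomputed palette table) is reduced to a
ranked color composition; the dominant color of the animal and of its
visual background (relative proportion > 25%) give the per-channel
contrast statistic *delta RGB* = |background − lifestage|.  Apparent
(aposematic or masquerading) and nonapparent (cryptic) species are
compared on the first principal component of delta RGB with a
Mann–Whitney test; pupal background matching is checked per channel
with Kruskal–Wallis.  Strategies are classified from contrast magnitude
plus palette chromaticity (shades of white/gray, or a bird-dropping
reference palette, mark masquerade among apparent phenotypes).

All operations work on integer 0–255 channels; no perceptual color
space is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidInputError,
    NoDominantColorError,
)

__all__ = [
    "RGBColor",
    "ColorComposition",
    "DominantColor",
    "DeltaRGB",
    "ApparencyResult",
    "StrategyLabel",
    "STRATEGIES",
    "APPARENT",
    "NONAPPARENT",
    "BIRD_DROPPING_PALETTE",
    "extract_color_gamut",
    "load_image_pixels",
    "read_composition_table",
    "dominant_color",
    "delta_rgb",
    "apparency_test",
    "pupa_match_test",
    "classify_strategy",
    "apparency_of",
]

STRATEGIES = ("masquerade", "crypsis", "aposematism")
APPARENT = "apparent"
NONAPPARENT = "nonapparent"
_APPARENCY = {"masquerade": APPARENT, "aposematism": APPARENT, "crypsis": NONAPPARENT}

#: Whites, grays and desiccated browns of a bird dropping; used as the
#: secondary masquerade criterion for apparent phenotypes.
BIRD_DROPPING_PALETTE = (
    (250, 250, 245),
    (210, 208, 200),
    (165, 162, 155),
    (120, 115, 108),
)


class RGBColor(NamedTuple):
    """An 8-bit RGB triple."""

    r: int
    g: int
    b: int

    @classmethod
    def of(cls, r, g, b) -> "RGBColor":
        vals = (int(r), int(g), int(b))
        if any(not 0 <= v <= 255 for v in vals):
            raise InvalidInputError(f"channel outside [0, 255]: {vals}")
        return cls(*vals)


@dataclass(frozen=True)
class ColorComposition:
    """Ranked palette: (color, proportion, rank) with rank 1 = largest."""

    entries: tuple[tuple[RGBColor, float, int], ...]

    def __post_init__(self):
        props = [p for _, p, _ in self.entries]
        if not props:
            raise InvalidInputError("empty color composition")
        if abs(sum(props) - 1.0) > 1e-6:
            raise InvalidInputError(f"proportions sum to {sum(props)}, not 1")
        ranks = [r for _, _, r in self.entries]
        if ranks != list(range(1, len(ranks) + 1)):
            raise InvalidInputError("ranks must be 1..n in order")
        if any(props[i] < props[i + 1] - 1e-12 for i in range(len(props) - 1)):
            raise InvalidInputError("proportions must be non-increasing by rank")
        colors = [c for c, _, _ in self.entries]
        if len(set(colors)) != len(colors):
            raise InvalidInputError("duplicate colors in composition")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[RGBColor, float]]) -> "ColorComposition":
        """Build from (color, proportion) pairs, ranking by proportion
        (ties broken toward the lexicographically smaller color)."""
        ordered = sorted(pairs, key=lambda cp: (-cp[1], cp[0]))
        return cls(tuple((RGBColor.of(*c), float(p), i + 1)
                         for i, (c, p) in enumerate(ordered)))

    def colors(self) -> list[RGBColor]:
        return [c for c, _, _ in self.entries]


@dataclass(frozen=True)
class DominantColor:
    """The primary color of an image region (proportion above threshold)."""

    color: RGBColor
    proportion: float


@dataclass(frozen=True)
class DeltaRGB:
    """Per-channel absolute contrast between background and lifestage."""

    dr: int
    dg: int
    db: int

    def as_array(self) -> np.ndarray:
        return np.array([self.dr, self.dg, self.db], dtype=float)

    @property
    def norm(self) -> float:
        return float(math.sqrt(self.dr**2 + self.dg**2 + self.db**2))


@dataclass
class ApparencyResult:
    """PCA of delta RGB plus the rank test on PC1 between apparency groups.

    `w_statistic` follows the rank-sum convention of R's two-sample
    wilcox.test: the Mann–Whitney U statistic of the first (apparent)
    group.
    """

    pc_scores: pd.DataFrame  # species x (PC1, PC2, PC3)
    variance_explained: np.ndarray
    w_statistic: float
    p_value: float


@dataclass(frozen=True)
class StrategyLabel:
    """A color-defense strategy and its binary apparency collapse."""

    value: str
    apparency: str

    def __post_init__(self):
        if self.value not in STRATEGIES:
            raise InvalidInputError(f"unknown strategy {self.value!r}")
        if self.apparency != _APPARENCY[self.value]:
            raise InvalidInputError(
                f"{self.value} must be {_APPARENCY[self.value]}")

    @classmethod
    def of(cls, value: str) -> "StrategyLabel":
        return cls(value, _APPARENCY[value])


def apparency_of(strategy: str) -> str:
    """apparent for masquerade/aposematism, nonapparent for crypsis."""
    return _APPARENCY[strategy]


# ---------------------------------------------------------------------------
# Palette extraction
# ---------------------------------------------------------------------------

def _as_pixel_array(pixels) -> np.ndarray:
    arr = np.asarray(pixels, dtype=float)
    if arr.ndim == 3:
        arr = arr.reshape(-1, arr.shape[-1])
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] == 0:
        raise InvalidInputError("pixels must be a non-empty grid of RGB triples")
    if (arr < 0).any() or (arr > 255).any():
        raise InvalidInputError("pixel channels outside [0, 255]")
    return arr


def extract_color_gamut(pixels, max_colors: int = 8, seed: int = 0,
                        min_proportion: float = 0.01) -> ColorComposition:
    """Quantize an image's pixels into a ranked palette.

    Seeded k-means in RGB space over the distinct pixel colors (weighted
    by their frequencies, so the result is invariant to pixel order);
    clusters holding less than `min_proportion` of the pixels are merged
    into the nearest remaining centroid.  Centroids are rounded to
    integer channels.
    """
    if max_colors < 1:
        raise InvalidInputError("max_colors must be >= 1")
    arr = _as_pixel_array(pixels)
    n = arr.shape[0]
    colors, counts = np.unique(arr, axis=0, return_counts=True)
    weights = counts / n
    if len(colors) > max_colors:
        km = KMeans(n_clusters=max_colors, random_state=seed, n_init=10)
        labels = km.fit_predict(colors, sample_weight=counts)
        centers, props = [], []
        for c in range(max_colors):
            mask = labels == c
            if not mask.any():
                continue
            w = weights[mask]
            centers.append(np.average(colors[mask], axis=0, weights=w))
            props.append(w.sum())
        colors, weights = np.array(centers), np.array(props)
    # merge sub-threshold clusters into the nearest surviving centroid
    while len(colors) > 1 and weights.min() < min_proportion:
        i = int(np.argmin(weights))
        keep = np.arange(len(colors)) != i
        d = np.linalg.norm(colors[keep] - colors[i], axis=1)
        j = int(np.flatnonzero(keep)[np.argmin(d)])
        colors[j] = np.average(colors[[j, i]], axis=0,
                               weights=[weights[j], weights[i]])
        weights[j] += weights[i]
        colors, weights = colors[keep], weights[keep]
    merged: dict[RGBColor, float] = {}
    for c, w in zip(colors, weights):
        key = RGBColor.of(*np.clip(np.rint(c), 0, 255))
        merged[key] = merged.get(key, 0.0) + float(w)
    total = sum(merged.values())
    return ColorComposition.from_pairs((c, w / total) for c, w in merged.items())


def load_image_pixels(path) -> np.ndarray:
    """Read a PNG/JPEG as an (n, 3) uint8 pixel array.

    A fully transparent alpha channel masks out background-separated
    pixels; images with no opaque pixel are rejected.
    """
    from PIL import Image

    with Image.open(path) as im:
        im = im.convert("RGBA")
        data = np.asarray(im)
    opaque = data[..., 3] > 0
    if not opaque.any():
        raise InvalidInputError(f"no opaque pixels in {path}")
    return data[opaque][:, :3]


def read_composition_table(path_or_buf) -> dict[tuple[str, str, str], ColorComposition]:
    """Read per-scene palettes from CSV.

    Expected columns: species, lifestage, role (foreground|background),
    r, g, b, proportion.  Returns compositions keyed by
    (species, lifestage, role).
    """
    df = pd.read_csv(path_or_buf)
    required = {"species", "lifestage", "role", "r", "g", "b", "proportion"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"composition table missing columns {sorted(missing)}")
    out = {}
    for key, grp in df.groupby(["species", "lifestage", "role"], sort=True):
        pairs = [(RGBColor.of(row.r, row.g, row.b), row.proportion)
                 for row in grp.itertuples()]
        out[tuple(map(str, key))] = ColorComposition.from_pairs(pairs)
    return out


# ---------------------------------------------------------------------------
# Contrast scoring
# ---------------------------------------------------------------------------

def dominant_color(comp: ColorComposition, threshold: float = 0.25) -> DominantColor:
    """The primary color: highest proportion, which must exceed `threshold`.

    Proportion ties are broken toward the lexicographically smallest
    (r, g, b).  Raises :class:`NoDominantColorError` when nothing
    exceeds the threshold (the image cannot be scored).
    """
    best_color, best_prop = None, -1.0
    for color, prop, _ in comp.entries:
        if prop > best_prop + 1e-12 or (abs(prop - best_prop) <= 1e-12
                                        and color < best_color):
            best_color, best_prop = color, prop
    if best_prop <= threshold:
        raise NoDominantColorError(
            f"largest proportion {best_prop:.3f} does not exceed {threshold}")
    return DominantColor(color=best_color, proportion=best_prop)


def delta_rgb(background: DominantColor, lifestage: DominantColor) -> DeltaRGB:
    """Per-channel absolute difference of the two dominant colors."""
    b, f = background.color, lifestage.color
    return DeltaRGB(abs(b.r - f.r), abs(b.g - f.g), abs(b.b - f.b))


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def _pca_centered(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centered (unscaled) PCA via SVD with a deterministic sign convention:
    each component's largest-magnitude loading is positive."""
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    for j in range(vt.shape[0]):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    scores = u * s
    var = s**2
    return scores, var / var.sum()


def apparency_test(deltas: Mapping[str, DeltaRGB],
                   labels: Mapping[str, str]) -> ApparencyResult:
    """PCA on delta RGB and a Mann–Whitney test of PC1 between groups.

    Channels are centered but not rescaled (they share the 0–255 unit).
    The two-sided test compares apparent against nonapparent species;
    the reported W is the Mann–Whitney U of the apparent group (exact
    null distribution for small untied samples, tie-corrected normal
    approximation otherwise).
    """
    species = sorted(deltas)
    if set(species) != set(labels):
        raise InvalidInputError("deltas and labels must cover the same species")
    groups = {APPARENT: [], NONAPPARENT: []}
    for sp in species:
        lab = labels[sp]
        if lab not in groups:
            raise InvalidInputError(f"label {lab!r} is not apparent/nonapparent")
        groups[lab].append(sp)
    if min(len(g) for g in groups.values()) < 2:
        raise InsufficientDataError("need >= 2 species in each apparency group")
    x = np.array([deltas[sp].as_array() for sp in species])
    if np.allclose(x, x[0]):
        raise DegenerateInputError("delta RGB has zero variance across species")
    scores, var_ratio = _pca_centered(x)
    pc = pd.DataFrame(scores, index=species,
                      columns=[f"PC{j+1}" for j in range(scores.shape[1])])
    s1 = pc.loc[groups[APPARENT], "PC1"].to_numpy()
    s2 = pc.loc[groups[NONAPPARENT], "PC1"].to_numpy()
    res = stats.mannwhitneyu(s1, s2, alternative="two-sided", method="auto")
    return ApparencyResult(pc_scores=pc, variance_explained=var_ratio,
                           w_statistic=float(res.statistic),
                           p_value=float(res.pvalue))


def pupa_match_test(pupa_colors: Sequence[RGBColor] | Mapping[str, RGBColor],
                    background_colors: Sequence[RGBColor] | Mapping[str, RGBColor],
                    ) -> dict[str, tuple[float, float]]:
    """Kruskal–Wallis comparison of pupal vs background channel values.

    One two-group test per channel; returns {"R": (H, p), ...}.  Two
    identical samples are a fully tied configuration, reported as
    (0.0, 1.0).
    """
    if isinstance(pupa_colors, Mapping):
        if set(pupa_colors) != set(background_colors):
            raise InvalidInputError("pupa and background species differ")
        keys = sorted(pupa_colors)
        pupa = np.array([tuple(pupa_colors[k]) for k in keys], dtype=float)
        back = np.array([tuple(background_colors[k]) for k in keys], dtype=float)
    else:
        pupa = np.array([tuple(c) for c in pupa_colors], dtype=float)
        back = np.array([tuple(c) for c in background_colors], dtype=float)
        if pupa.shape != back.shape:
            raise InvalidInputError(
                f"sample sizes differ: {pupa.shape[0]} vs {back.shape[0]}")
    if pupa.size == 0:
        raise InvalidInputError("empty samples")
    out = {}
    for j, channel in enumerate("RGB"):
        a, b = pupa[:, j], back[:, j]
        if np.ptp(np.concatenate([a, b])) == 0.0:
            out[channel] = (0.0, 1.0)
            continue
        h, p = stats.kruskal(a, b)
        out[channel] = (float(h), float(p))
    return out


# ---------------------------------------------------------------------------
# Strategy classification
# ---------------------------------------------------------------------------

def _is_gray_white(color: RGBColor, gray_tolerance: float, min_mean: float) -> bool:
    spread = max(color) - min(color)
    return spread <= gray_tolerance and sum(color) / 3.0 >= min_mean


def _near_palette(color: RGBColor, palette, max_distance: float) -> bool:
    c = np.array(color, dtype=float)
    return any(np.linalg.norm(c - np.array(p, dtype=float)) <= max_distance
               for p in palette)


def classify_strategy(delta: DeltaRGB, lifestage_composition: ColorComposition,
                      apparency_threshold: float = 60.0,
                      gray_tolerance: float = 30.0,
                      gray_min_mean: float = 100.0,
                      reference_palette: Iterable[tuple[int, int, int]] = BIRD_DROPPING_PALETTE,
                      palette_distance: float = 60.0) -> StrategyLabel:
    """Assign masquerade / crypsis / aposematism from contrast and palette.

    Contrast below `apparency_threshold` (Euclidean norm of delta RGB)
    is nonapparent, hence crypsis.  An apparent phenotype whose palette
    shows only shades of white or gray — channel spread at most
    `gray_tolerance` with mean channel at least `gray_min_mean` — or
    colors within `palette_distance` of the bird-dropping reference
    palette is masquerade; any other apparent phenotype carries
    conspicuous secondary colors and is aposematism.
    """
    if delta.norm < apparency_threshold:
        return StrategyLabel.of("crypsis")
    palette = tuple(reference_palette)
    dropping_like = all(
        _is_gray_white(c, gray_tolerance, gray_min_mean)
        or _near_palette(c, palette, palette_distance)
        for c in lifestage_composition.colors())
    return StrategyLabel.of("masquerade" if dropping_like else "aposematism")
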