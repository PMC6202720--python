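"""Palette extraction, contrast scoring and the apparency statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ontocolor import colorquant as cq
from ontocolor.errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidInputError,
    NoDominantColorError,
)

rgb = st.tuples(st.integers(0, 255), st.integers(0, 255), st.integers(0, 255))


# ---------------------------------------------------------------------------
# extract_color_gamut
# ---------------------------------------------------------------------------

class TestExtractColorGamut:
    def test_single_color_image(self):
        pixels = np.zeros((10, 10, 3), dtype=np.uint8)
        comp = cq.extract_color_gamut(pixels, max_colors=5)
        assert comp.entries == ((cq.RGBColor(0, 0, 0), 1.0, 1),)

    def test_two_well_separated_clusters(self):
        pixels = np.array([[255, 0, 0]] * 60 + [[0, 0, 255]] * 40)
        comp = cq.extract_color_gamut(pixels, max_colors=2)
        assert comp.entries[0] == (cq.RGBColor(255, 0, 0), 0.6, 1)
        assert comp.entries[1] == (cq.RGBColor(0, 0, 255), 0.4, 2)

    def test_gaussian_mixture_proportions_recovered(self):
        # oracle: assign each pixel to the nearest generating centroid
        rng = np.random.default_rng(42)
        centroids = np.array([[220.0, 30, 30], [30, 200, 40], [40, 40, 230]])
        weights = [0.5, 0.3, 0.2]
        parts = [
            np.clip(rng.normal(centroids[i], 12.0, size=(int(2000 * w), 3)), 0, 255)
            for i, w in enumerate(weights)
        ]
        pixels = np.rint(np.vstack(parts))
        d = ((pixels[:, None, :] - centroids[None]) ** 2).sum(axis=2)
        oracle_props = np.bincount(d.argmin(axis=1), minlength=3) / len(pixels)
        comp = cq.extract_color_gamut(pixels, max_colors=3, seed=0)
        got = sorted((p for _, p, _ in comp.entries), reverse=True)
        want = sorted(oracle_props, reverse=True)
        assert np.allclose(got, want, atol=0.05)
        # recovered centroids sit near the generating ones
        rec = np.array([list(c) for c, _, _ in comp.entries], dtype=float)
        for c in centroids:
            assert np.linalg.norm(rec - c, axis=1).min() < 15

    def test_pixel_order_invariance(self):
        rng = np.random.default_rng(3)
        pixels = rng.integers(0, 256, size=(500, 3))
        comp1 = cq.extract_color_gamut(pixels, max_colors=4, seed=7)
        comp2 = cq.extract_color_gamut(pixels[rng.permutation(500)],
                                       max_colors=4, seed=7)
        assert comp1 == comp2

    @given(st.integers(1, 6), st.integers(0, 10))
    @settings(max_examples=20, deadline=None)
    def test_proportions_sum_to_one(self, max_colors, seed):
        rng = np.random.default_rng(seed)
        pixels = rng.integers(0, 256, size=(rng.integers(5, 200), 3))
        comp = cq.extract_color_gamut(pixels, max_colors=max_colors, seed=seed)
        assert len(comp.entries) <= max_colors
        assert abs(sum(p for _, p, _ in comp.entries) - 1.0) < 1e-6

    def test_empty_grid_rejected(self):
        with pytest.raises(InvalidInputError):
            cq.extract_color_gamut(np.empty((0, 3)))


# ---------------------------------------------------------------------------
# dominant_color / delta_rgb
# ---------------------------------------------------------------------------

class TestDominantColor:
    def test_unique_maximum(self):
        comp = cq.ColorComposition.from_pairs(
            [((255, 255, 255), 0.6), ((128, 128, 128), 0.3), ((0, 200, 0), 0.1)])
        dom = cq.dominant_color(comp)
        assert dom.color == cq.RGBColor(255, 255, 255)
        assert dom.proportion == 0.6

    def test_no_color_above_threshold(self):
        comp = cq.ColorComposition.from_pairs(
            [((i * 40, 0, 0), 0.2) for i in range(5)])
        with pytest.raises(NoDominantColorError):
            cq.dominant_color(comp)

    def test_tie_broken_lexicographically(self):
        comp = cq.ColorComposition.from_pairs(
            [((200, 0, 0), 0.4), ((10, 10, 10), 0.4), ((0, 0, 0), 0.2)])
        assert cq.dominant_color(comp).color == cq.RGBColor(10, 10, 10)


class TestDeltaRGB:
    @pytest.mark.parametrize("bg, fg, want", [
        ((255, 255, 255), (255, 255, 255), (0, 0, 0)),
        ((120, 200, 80), (30, 40, 50), (90, 160, 30)),
        ((0, 0, 0), (255, 255, 255), (255, 255, 255)),
    ])
    def test_examples(self, bg, fg, want):
        d = cq.delta_rgb(cq.DominantColor(cq.RGBColor.of(*bg), 0.5),
                         cq.DominantColor(cq.RGBColor.of(*fg), 0.5))
        assert (d.dr, d.dg, d.db) == want

    @given(rgb, rgb)
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_bounds(self, a, b):
        da = cq.DominantColor(cq.RGBColor.of(*a), 0.5)
        db_ = cq.DominantColor(cq.RGBColor.of(*b), 0.5)
        d1, d2 = cq.delta_rgb(da, db_), cq.delta_rgb(db_, da)
        assert (d1.dr, d1.dg, d1.db) == (d2.dr, d2.dg, d2.db)
        assert all(0 <= v <= 255 for v in (d1.dr, d1.dg, d1.db))
        if a == b:
            assert (d1.dr, d1.dg, d1.db) == (0, 0, 0)


# ---------------------------------------------------------------------------
# apparency_test
# ---------------------------------------------------------------------------

def _line_deltas(values):
    """Deltas varying on the red channel only, so PC1 tracks that channel."""
    return {f"s{i}": cq.DeltaRGB(int(v), 0, 0) for i, v in enumerate(values)}


class TestApparencyTest:
    def test_separated_groups_exact_w_and_p(self):
        deltas = _line_deltas([10, 20, 30, 40, 50, 60])
        labels = {f"s{i}": cq.APPARENT if i < 3 else cq.NONAPPARENT
                  for i in range(6)}
        res = cq.apparency_test(deltas, labels)
        # apparent group holds the three smallest PC1 scores: U1 = 0,
        # exact two-sided p = 2 * (1 / C(6,3)) = 0.1
        assert res.w_statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_variance_explained_sums_to_one(self):
        rng = np.random.default_rng(1)
        deltas = {f"s{i}": cq.DeltaRGB(*rng.integers(0, 256, 3)) for i in range(12)}
        labels = {f"s{i}": cq.APPARENT if i % 2 else cq.NONAPPARENT
                  for i in range(12)}
        res = cq.apparency_test(deltas, labels)
        assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(res.variance_explained) <= 1e-12).all()

    def test_pc_scores_invariant_to_species_order(self):
        rng = np.random.default_rng(5)
        vals = rng.integers(0, 256, (10, 3))
        deltas = {f"s{i}": cq.DeltaRGB(*v) for i, v in enumerate(vals)}
        labels = {f"s{i}": cq.APPARENT if i < 5 else cq.NONAPPARENT
                  for i in range(10)}
        r1 = cq.apparency_test(deltas, labels)
        shuffled = dict(reversed(list(deltas.items())))
        r2 = cq.apparency_test(shuffled, labels)
        assert np.allclose(r1.pc_scores.loc["s3"], r2.pc_scores.loc["s3"])
        assert r1.w_statistic == r2.w_statistic

    def test_degenerate_identical_rows(self):
        deltas = {f"s{i}": cq.DeltaRGB(7, 7, 7) for i in range(6)}
        labels = {f"s{i}": cq.APPARENT if i < 3 else cq.NONAPPARENT
                  for i in range(6)}
        with pytest.raises(DegenerateInputError):
            cq.apparency_test(deltas, labels)

    def test_small_group_rejected(self):
        deltas = _line_deltas([1, 2, 3, 4])
        labels = {"s0": cq.APPARENT, "s1": cq.NONAPPARENT,
                  "s2": cq.NONAPPARENT, "s3": cq.NONAPPARENT}
        with pytest.raises(InsufficientDataError):
            cq.apparency_test(deltas, labels)

    @given(st.integers(2, 8), st.integers(2, 8), st.integers(0, 500))
    @settings(max_examples=60, deadline=None)
    def test_w_matches_pair_count_oracle(self, n1, n2, seed):
        """W equals the brute-force count of (apparent, nonapparent)
        PC1 pairs won by the apparent group (ties at half weight)."""
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 40, n1 + n2)  # small range forces ties
        deltas = _line_deltas(vals)
        labels = {f"s{i}": cq.APPARENT if i < n1 else cq.NONAPPARENT
                  for i in range(n1 + n2)}
        try:
            res = cq.apparency_test(deltas, labels)
        except DegenerateInputError:
            return
        pc = res.pc_scores["PC1"]
        a = pc[[f"s{i}" for i in range(n1)]].to_numpy()
        b = pc[[f"s{i}" for i in range(n1, n1 + n2)]].to_numpy()
        wins = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        assert res.w_statistic == pytest.approx(wins)


# ---------------------------------------------------------------------------
# pupa_match_test
# ---------------------------------------------------------------------------

class TestPupaMatch:
    def test_identical_samples_fully_tied(self):
        colors = [cq.RGBColor(10 * i, 5 * i, 2 * i) for i in range(8)]
        res = cq.pupa_match_test(colors, colors)
        assert all(res[ch] == (0.0, 1.0) or res[ch][1] == pytest.approx(1.0)
                   for ch in "RGB")

    def test_extreme_separation_significant(self):
        pupa = [cq.RGBColor(0, 0, 0)] * 10
        back = [cq.RGBColor(255, 255, 255)] * 10
        res = cq.pupa_match_test(pupa, back)
        assert all(res[ch][1] < 0.01 for ch in "RGB")

    def test_null_calibration(self):
        """Groups from one distribution: each channel's p > 0.05 in
        >= 90% of replicates (nominal rate 95% per channel)."""
        rng = np.random.default_rng(2024)
        ok = {ch: 0 for ch in "RGB"}
        for _ in range(100):
            a = rng.integers(0, 256, (30, 3))
            b = rng.integers(0, 256, (30, 3))
            res = cq.pupa_match_test([cq.RGBColor.of(*c) for c in a],
                                     [cq.RGBColor.of(*c) for c in b])
            for ch in "RGB":
                ok[ch] += res[ch][1] > 0.05
        assert all(ok[ch] >= 90 for ch in "RGB")

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            cq.pupa_match_test([cq.RGBColor(0, 0, 0)] * 3,
                               [cq.RGBColor(0, 0, 0)] * 4)


# ---------------------------------------------------------------------------
# classify_strategy
# ---------------------------------------------------------------------------

class TestClassifyStrategy:
    def test_low_contrast_is_crypsis(self):
        comp = cq.ColorComposition.from_pairs([((200, 30, 30), 1.0)])
        label = cq.classify_strategy(cq.DeltaRGB(5, 3, 2), comp)
        assert label.value == "crypsis"
        assert label.apparency == cq.NONAPPARENT

    def test_apparent_gray_white_is_masquerade(self):
        comp = cq.ColorComposition.from_pairs(
            [((255, 255, 255), 0.6), ((128, 128, 128), 0.4)])
        label = cq.classify_strategy(cq.DeltaRGB(200, 180, 190), comp)
        assert label.value == "masquerade"
        assert label.apparency == cq.APPARENT

    def test_apparent_warning_colors_are_aposematism(self):
        comp = cq.ColorComposition.from_pairs(
            [((0, 0, 0), 0.5), ((220, 30, 30), 0.3), ((235, 200, 40), 0.2)])
        label = cq.classify_strategy(cq.DeltaRGB(150, 90, 120), comp)
        assert label.value == "aposematism"

    @given(st.integers(0, 255), st.integers(0, 255), st.integers(0, 255),
           st.lists(st.tuples(rgb), min_size=1, max_size=4))
    @settings(max_examples=100, deadline=None)
    def test_total_and_apparency_consistent(self, dr, dg, db, colors):
        uniq = list(dict.fromkeys(c[0] for c in colors))
        props = np.full(len(uniq), 1.0 / len(uniq))
        comp = cq.ColorComposition.from_pairs(zip(uniq, props))
        label = cq.classify_strategy(cq.DeltaRGB(dr, dg, db), comp)
        assert label.value in cq.STRATEGIES
        if label.value in ("masquerade", "aposematism"):
            assert label.apparency == cq.APPARENT
            assert cq.DeltaRGB(dr, dg, db).norm >= 60.0
        else:
            assert label.apparency == cq.NONAPPARENT

    def test_deterministic(self):
        comp = cq.ColorComposition.from_pairs([((90, 90, 90), 1.0)])
        d = cq.DeltaRGB(100, 100, 100)
        assert cq.classify_strategy(d, comp) == cq.classify_strategy(d, comp)


class TestStrategyLabel:
    def test_apparency_binding_enforced(self):
        with pytest.raises(InvalidInputError):
            cq.StrategyLabel("crypsis", cq.APPARENT)
        assert cq.StrategyLabel.of("masquerade").apparency == cq.APPARENT
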