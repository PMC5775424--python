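"""Cell mixture index: clustering, impurity curve, and its area-under-curve."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteomix.cell_mixture import (
    CMIConfig,
    GLICurve,
    LabeledPixelSet,
    PixelColor,
    Schedule,
    build_cluster_tree,
    cluster_impurity,
    cmi_approx,
    cmi_exact,
    cmi_from_pixels,
    compute_cmi,
    extract_labeled_pixels,
    gli,
    gli_curve,
    partition_at,
)
from osteomix.raster_core import EmptyForegroundError
from osteomix.synthetic import SceneSpec, generate_distribution_image
from conftest import make_mask
from oracles import brute_force_cmi, direct_gli, ward_partitions


def random_pixel_set(rng, n, spread=20.0):
    coords = set()
    while len(coords) < n:
        coords.add(tuple(np.round(rng.uniform(0, spread, 2), 3)))
    coords = np.array(sorted(coords))
    colors = rng.integers(0, 2, n).astype(np.int8)
    return LabeledPixelSet(coords, colors)


def labels_to_partition(labels):
    return {frozenset(np.flatnonzero(labels == k)) for k in np.unique(labels)}


class TestExtractLabeledPixels:
    def test_disjoint_masks_counted_per_channel(self, two_blob_masks):
        cyan, red = two_blob_masks
        px = extract_labeled_pixels(cyan, red)
        assert px.n == 50
        assert px.y_total == 25 and px.r_total == 25

    def test_overlap_counted_once_as_red(self):
        bits = np.zeros((4, 4), dtype=bool)
        bits[1, 1] = True
        px = extract_labeled_pixels(make_mask(bits), make_mask(bits))
        assert px.n == 1
        assert px.r_total == 1 and px.y_total == 0

    def test_overlap_rule_configurable(self):
        bits = np.zeros((4, 4), dtype=bool)
        bits[1, 1] = True
        px = extract_labeled_pixels(make_mask(bits), make_mask(bits),
                                    overlap_color=PixelColor.CYAN)
        assert px.y_total == 1

    def test_empty_masks_raise(self):
        empty = make_mask(np.zeros((4, 4)))
        with pytest.raises(EmptyForegroundError):
            extract_labeled_pixels(empty, empty)


class TestClusterTree:
    def test_nearest_pairs_merge_first(self):
        coords = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 10.0], [10.0, 11.0]])
        px = LabeledPixelSet(coords, np.zeros(4, dtype=np.int8))
        tree = build_cluster_tree(px)
        first_two = {frozenset(tree.merges[0, :2].astype(int)),
                     frozenset(tree.merges[1, :2].astype(int))}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_n_minus_one_merges(self, rng):
        px = random_pixel_set(rng, 9)
        assert build_cluster_tree(px).merges.shape[0] == 8

    def test_single_pixel_rejected(self):
        px = LabeledPixelSet(np.array([[0.0, 0.0]]), np.array([0], dtype=np.int8))
        with pytest.raises(ValueError):
            build_cluster_tree(px)

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_sequence_matches_brute_force_ward(self, seed):
        rng = np.random.default_rng(seed)
        px = random_pixel_set(rng, 8)
        tree = build_cluster_tree(px)
        oracle = ward_partitions(px.coords)
        for m in range(1, 9):
            got = labels_to_partition(partition_at(tree, m, px).labels)
            assert got == oracle[m], f"partition differs at m={m}"


class TestPartitionAt:
    def test_m1_single_cluster(self, rng):
        px = random_pixel_set(rng, 6)
        cs = partition_at(build_cluster_tree(px), 1, px)
        assert cs.m == 1 and cs.y_counts.sum() + cs.r_counts.sum() == 6

    def test_m_equals_n_all_singletons_zero_impurity(self, rng):
        px = random_pixel_set(rng, 7)
        cs = partition_at(build_cluster_tree(px), 7, px)
        assert len(np.unique(cs.labels)) == 7
        assert gli(cs) == 0.0

    def test_two_separated_blobs_cut_cleanly(self, two_blob_masks):
        cyan, red = two_blob_masks
        px = extract_labeled_pixels(cyan, red)
        cs = partition_at(build_cluster_tree(px), 2, px)
        # each blob one pure cluster
        assert sorted(zip(cs.y_counts, cs.r_counts)) == [(0, 25), (25, 0)]

    def test_out_of_range_m(self, rng):
        px = random_pixel_set(rng, 5)
        tree = build_cluster_tree(px)
        for m in (0, 6):
            with pytest.raises(ValueError):
                partition_at(tree, m, px)


class TestImpurityAndGLI:
    @pytest.mark.parametrize("y,r,expected", [
        (10, 10, 0.5),
        (7, 0, 0.0),
        (0, 7, 0.0),
        (3, 1, 0.375),
    ])
    def test_impurity_values(self, y, r, expected):
        assert cluster_impurity(y, r) == pytest.approx(expected, abs=1e-12)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            cluster_impurity(0, 0)

    @given(y=st.integers(0, 10**6), r=st.integers(0, 10**6))
    @settings(deadline=None, derandomize=True)
    def test_impurity_bounded_and_symmetric(self, y, r):
        if y + r == 0:
            return
        v = cluster_impurity(y, r)
        assert 0.0 <= v <= 0.5
        assert v == pytest.approx(cluster_impurity(r, y), abs=1e-15)

    def test_gli_hand_example(self):
        from osteomix.cell_mixture import ClusterSet
        cs = ClusterSet(2, np.array([0] * 4 + [1] * 4),
                        np.array([3, 0]), np.array([1, 4]))
        assert gli(cs) == pytest.approx(0.1875)

    def test_gli_pure_clusters_zero(self):
        from osteomix.cell_mixture import ClusterSet
        cs = ClusterSet(2, np.array([0, 0, 1, 1]),
                        np.array([2, 0]), np.array([0, 2]))
        assert gli(cs) == 0.0

    def test_gli_even_clusters_half(self):
        from osteomix.cell_mixture import ClusterSet
        cs = ClusterSet(3, np.arange(3).repeat(4),
                        np.array([2, 2, 2]), np.array([2, 2, 2]))
        assert gli(cs) == pytest.approx(0.5)


class TestGLICurve:
    def test_all_cyan_curve_identically_zero(self, rng):
        coords = random_pixel_set(rng, 12).coords
        px = LabeledPixelSet(coords, np.zeros(12, dtype=np.int8))
        curve = gli_curve(build_cluster_tree(px), px)
        assert (curve.values == 0).all()

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_m_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        px = random_pixel_set(rng, 30)
        tree = build_cluster_tree(px)
        curve = gli_curve(tree, px)
        for m in range(1, 31):
            part = labels_to_partition(partition_at(tree, m, px).labels)
            assert curve.value_at(m) == pytest.approx(
                direct_gli(part, px.colors), abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_non_increasing_bounded_terminal_zero(self, seed):
        rng = np.random.default_rng(seed)
        px = random_pixel_set(rng, rng.integers(5, 40))
        curve = gli_curve(build_cluster_tree(px), px)
        assert (np.diff(curve.values) <= 1e-12).all()
        assert (curve.values >= 0).all() and (curve.values <= 0.5).all()
        assert curve.values[-1] == 0.0

    def test_powers_schedule_subset(self, rng):
        px = random_pixel_set(rng, 20)
        tree = build_cluster_tree(px)
        full = gli_curve(tree, px, Schedule.FULL)
        pw = gli_curve(tree, px, Schedule.POWERS_OF_TWO)
        assert list(pw.ms) == [1, 2, 4, 8, 16]
        for m in pw.ms:
            assert pw.value_at(int(m)) == full.value_at(int(m))


class TestCMI:
    def test_telescoping_pinned_curve_gives_one(self):
        n = 137
        curve = GLICurve(np.arange(1, n + 1), np.full(n, 0.5), Schedule.FULL)
        assert cmi_exact(curve, n).cmi == pytest.approx(1.0, abs=1e-12)

    def test_approx_pinned_curve_gives_one(self):
        n = 137
        ms = 2 ** np.arange(8)  # 2^7 = 128 <= 137
        curve = GLICurve(ms, np.full(len(ms), 0.5), Schedule.POWERS_OF_TWO)
        res = cmi_approx(curve, n)
        assert res.cmi == pytest.approx(1.0, abs=1e-12)
        assert res.n_prime == 7

    def test_incomplete_curve_rejected(self):
        curve = GLICurve(np.arange(1, 5), np.zeros(4), Schedule.FULL)
        with pytest.raises(ValueError):
            cmi_exact(curve, 10)
        with pytest.raises(ValueError):
            cmi_approx(GLICurve(np.array([1, 2]), np.zeros(2),
                                Schedule.POWERS_OF_TWO), 10)

    def test_single_color_cmi_zero(self, rng):
        coords = random_pixel_set(rng, 16).coords
        px = LabeledPixelSet(coords, np.ones(16, dtype=np.int8))
        for method in ("exact", "approx"):
            assert cmi_from_pixels(px, method).cmi == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_chain_matches_brute_force_on_tiny_input(self, seed):
        rng = np.random.default_rng(100 + seed)
        px = random_pixel_set(rng, 8)
        oracle = brute_force_cmi(px.coords, px.colors)
        assert cmi_from_pixels(px, "exact").cmi == pytest.approx(
            oracle["cmi_exact"], abs=1e-10)
        assert cmi_from_pixels(px, "approx").cmi == pytest.approx(
            oracle["cmi_approx"], abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_color_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        px = random_pixel_set(rng, 24)
        swapped = LabeledPixelSet(px.coords, (1 - px.colors).astype(np.int8))
        for method in ("exact", "approx"):
            assert cmi_from_pixels(px, method).cmi == pytest.approx(
                cmi_from_pixels(swapped, method).cmi, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_cmi_in_unit_interval(self, seed):
        rng = np.random.default_rng(200 + seed)
        px = random_pixel_set(rng, rng.integers(4, 60))
        for method in ("exact", "approx"):
            assert 0.0 <= cmi_from_pixels(px, method).cmi <= 1.0


class TestComputeCMIPipeline:
    def test_colonies_score_below_interleaved(self):
        seg_cmis, mix_cmis = [], []
        for seed in range(3):
            for theta, acc in ((0.0, seg_cmis), (1.0, mix_cmis)):
                c, r, _ = generate_distribution_image(
                    SceneSpec(shape=(128, 128), theta=theta, n_cyan=12,
                              n_red=12, radius_mean_um=6, seed=seed))
                acc.append(compute_cmi(c, r).cmi)
        assert np.mean(seg_cmis) < np.mean(mix_cmis)

    def test_deterministic_given_seed_and_config(self):
        spec = SceneSpec(shape=(96, 96), n_cyan=8, n_red=8, seed=7)
        runs = []
        for _ in range(2):
            c, r, _ = generate_distribution_image(spec)
            runs.append(compute_cmi(c, r))
        assert runs[0].cmi == runs[1].cmi
        assert (runs[0].curve.values == runs[1].curve.values).all()

    def test_scale_quarter_vs_eighth_close(self):
        # cells of realistic size (~32 um across) so they stay resolved
        # at the coarser 1/8 grid
        c, r, _ = generate_distribution_image(
            SceneSpec(shape=(512, 512), theta=0.5, n_cyan=40, n_red=40,
                      radius_mean_um=16, radius_sd_um=3, seed=11))
        c4 = compute_cmi(c, r, CMIConfig(downscale_factor=1 / 4)).cmi
        c8 = compute_cmi(c, r, CMIConfig(downscale_factor=1 / 8)).cmi
        assert abs(c4 - c8) < 0.1

    def test_vanished_channel_names_itself(self):
        cyan = make_mask(np.zeros((64, 64)))
        red_bits = np.zeros((64, 64), dtype=bool)
        red_bits[10:20, 10:20] = True
        with pytest.raises(EmptyForegroundError, match="cyan"):
            compute_cmi(cyan, make_mask(red_bits))

    def test_reports_foreground_areas(self):
        c, r, gt = generate_distribution_image(
            SceneSpec(shape=(128, 128), n_cyan=6, n_red=6, noise_sigma=0.0,
                      bg_intensity=0.0, seed=3))
        res = compute_cmi(c, r)
        for chan in ("cyan", "red"):
            true = gt.area_um2[chan]
            assert res.areas_um2[f"{chan}_um2"] == pytest.approx(true, rel=0.05)
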