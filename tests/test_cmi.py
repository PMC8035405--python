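"""Cell mixture index: worked examples, brute-force oracle equivalence,
symmetry/invariance properties, subsampling, and the image-level driver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import naive_cmi, naive_ward_merges
from osteomix.containers import DataError
from osteomix.cmi import (
    CmiConfig,
    LabeledPointSet,
    cmi_for_image,
    compute_cmi,
    impurity_curve,
    points_from_tile,
    ward_merge_sequence,
)
from osteomix.preprocess import BinaryTile


def _points(coords, labels):
    return LabeledPointSet(coords=np.asarray(coords, float), labels=np.asarray(labels))


def _random_bichromatic(rng, n):
    coords = rng.random((n, 2)) * 100
    labels = np.zeros(n, dtype=int)
    labels[: n // 2 + 1] = 1
    rng.shuffle(labels)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    return _points(coords, labels)


class TestWardMergeSequence:
    def test_two_singletons_cost_is_half_squared_distance(self):
        ms = ward_merge_sequence(_points([[0, 0], [3, 4]], [0, 1]))
        assert len(ms.merges) == 1
        assert ms.merges[0].cost == pytest.approx(25 / 2)

    def test_quartet_merge_costs_hand_traced(self):
        ms = ward_merge_sequence(_points([[0, 0], [0, 1], [10, 0], [10, 1]], [0, 0, 1, 1]))
        costs = [m.cost for m in ms.merges]
        assert costs[:2] == pytest.approx([0.5, 0.5])
        assert costs[2] == pytest.approx(100.0)  # (2*2/4) * 10^2

    def test_costs_are_non_decreasing(self, rng):
        for _ in range(10):
            pts = _random_bichromatic(rng, 40)
            costs = [m.cost for m in ward_merge_sequence(pts).merges]
            assert np.all(np.diff(costs) >= -1e-9)

    def test_matches_naive_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 50))
            pts = _random_bichromatic(rng, n)
            mine = ward_merge_sequence(pts).merges
            oracle = naive_ward_merges(pts.coords)
            for m, (a, b, cost, size) in zip(mine, oracle):
                assert (m.a, m.b) == (a, b)
                assert m.cost == pytest.approx(cost, rel=1e-9)
                assert m.size == size

    def test_rejects_single_point(self):
        with pytest.raises(DataError):
            ward_merge_sequence(_points([[0, 0]], [0]))

    def test_labels_at_recovers_partitions(self, rng):
        pts = _random_bichromatic(rng, 20)
        ms = ward_merge_sequence(pts)
        for k in (1, 5, 20):
            labels = ms.labels_at(k)
            assert len(np.unique(labels)) == k


class TestImpurityCurve:
    def test_mixed_quartet_cluster_gini(self):
        # one cluster of 3 cyan + 1 red has Gini 1 - (0.75^2 + 0.25^2) = 0.375
        pts = _points([[0, 0], [0, 1], [1, 0], [50, 50]], [0, 0, 1, 0])
        ms = ward_merge_sequence(pts)
        curve = impurity_curve(pts, ms)
        # after 2 merges: a 3-point cluster (2 cyan + 1 red) and a far singleton
        gc = 1 - (2 / 3) ** 2 - (1 / 3) ** 2
        assert curve.y[2] == pytest.approx((3 / 4) * gc / curve.g_total)

    def test_endpoints(self, rng):
        pts = _random_bichromatic(rng, 30)
        curve = impurity_curve(pts, ward_merge_sequence(pts))
        assert curve.y[0] == 0.0
        assert curve.y[-1] == pytest.approx(1.0)
        assert curve.x[0] == 0.0 and curve.x[-1] == 1.0
        assert np.all((curve.y >= 0) & (curve.y <= 1))

    def test_balanced_colors_total_gini_is_half(self):
        pts = _points([[0, 0], [0, 1], [5, 0], [5, 1]], [0, 1, 0, 1])
        curve = impurity_curve(pts, ward_merge_sequence(pts))
        assert curve.g_total == pytest.approx(0.5)

    def test_single_color_rejected(self):
        pts = _points([[0, 0], [1, 1]], [0, 0])
        with pytest.raises(DataError):
            impurity_curve(pts, ward_merge_sequence(pts))


class TestWorkedExamples:
    def test_any_bichromatic_pair_scores_half(self, rng):
        for _ in range(10):
            coords = rng.random((2, 2)) * 50
            assert compute_cmi(_points(coords, [0, 1])).cmi == pytest.approx(0.5)

    def test_segregated_quartet(self):
        pts = _points([[0, 0], [0, 1], [10, 0], [10, 1]], [0, 0, 1, 1])
        assert compute_cmi(pts).cmi == pytest.approx(1 / 6)

    def test_interleaved_unit_square(self):
        pts = _points([[0, 0], [1, 1], [1, 0], [0, 1]], [0, 0, 1, 1])
        res = compute_cmi(pts)
        assert res.cmi == pytest.approx(2 / 3)
        np.testing.assert_allclose(res.curve.y, [0.0, 0.5, 1.0, 1.0])


class TestInvariances:
    def test_matches_naive_cmi_oracle(self, rng):
        for _ in range(8):
            n = int(rng.integers(4, 40))
            pts = _random_bichromatic(rng, n)
            assert compute_cmi(pts).cmi == pytest.approx(
                naive_cmi(pts.coords, pts.labels), rel=1e-9
            )

    def test_bounds(self, rng):
        for _ in range(30):
            pts = _random_bichromatic(rng, int(rng.integers(3, 50)))
            assert 0.0 <= compute_cmi(pts).cmi <= 1.0

    def test_label_swap_invariance(self, rng):
        for _ in range(10):
            pts = _random_bichromatic(rng, 25)
            swapped = _points(pts.coords, 1 - pts.labels)
            assert compute_cmi(pts).cmi == pytest.approx(compute_cmi(swapped).cmi)

    def test_rigid_motion_and_scale_invariance(self, rng):
        for _ in range(10):
            pts = _random_bichromatic(rng, 25)
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            moved = _points(pts.coords @ rot.T * 3.7 + [11.0, -4.0], pts.labels)
            assert compute_cmi(moved).cmi == pytest.approx(compute_cmi(pts).cmi, rel=1e-9)


class TestPointsFromTile:
    def _tile(self, n_cyan, n_red, shape=(100, 100)):
        c = np.zeros(shape, bool)
        r = np.zeros(shape, bool)
        c.ravel()[:n_cyan] = True
        r.ravel()[shape[0] * shape[1] - n_red :] = True
        return BinaryTile(cyan_mask=c, red_mask=r, tile_index=(0, 0), pass_ratio_filter=True)

    def test_no_subsample_below_cap(self):
        pts, sub = points_from_tile(self._tile(5, 5), cap=100)
        assert pts.n == 10 and pts.n_cyan == 5 and not sub

    def test_stratified_proportions(self):
        pts, sub = points_from_tile(self._tile(6000, 3000), cap=3000, seed=1)
        assert sub and pts.n == 3000
        assert abs(pts.n_cyan - 2000) <= 1
        assert abs(pts.n_red - 1000) <= 1

    def test_deterministic_given_seed(self):
        a, _ = points_from_tile(self._tile(500, 400), cap=300, seed=9)
        b, _ = points_from_tile(self._tile(500, 400), cap=300, seed=9)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.labels, b.labels)

    @pytest.mark.parametrize("n_cyan,n_red", [(0, 10), (10, 0), (1, 0)])
    def test_undefined_cmi_rejected(self, n_cyan, n_red):
        with pytest.raises(DataError):
            points_from_tile(self._tile(n_cyan, n_red))


class TestCmiForImage:
    def test_mixing_contrast_on_generator_scenes(self):
        from osteomix.experiments import experiment_scene_config
        from osteomix.synthetic import generate_field

        means = {}
        for lam in (0.0, 1.0):
            vals = []
            for seed in range(5):
                img, _ = generate_field(experiment_scene_config(lam, 10 + seed))
                table = cmi_for_image(img, CmiConfig(tile_grid=(2, 2), cap=250))
                vals.extend(table.loc[table["passed_filter"], "cmi"].dropna())
            means[lam] = np.mean(vals)
        assert means[1.0] > means[0.0]

    def test_all_one_color_yields_no_cmi(self):
        from osteomix.containers import TwoChannelImage

        rng = np.random.default_rng(0)
        cyan = rng.random((64, 64)) * 0.1
        cyan[10:30, 10:30] = 0.9
        red = rng.random((64, 64)) * 0.05  # no red objects
        with pytest.warns(UserWarning):
            table = cmi_for_image(
                TwoChannelImage(cyan, red), CmiConfig(tile_grid=(1, 1))
            )
        assert table["cmi"].isna().all()

    def test_cmi_within_bounds_per_tile(self, small_scene_config):
        from osteomix.synthetic import generate_field

        img, _ = generate_field(small_scene_config)
        table = cmi_for_image(img, CmiConfig(tile_grid=(2, 2), cap=300))
        analyzed = table[table["cmi"].notna()]
        assert len(analyzed) >= 1
        assert analyzed["cmi"].between(0, 1).all()
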