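"""Spot detection, dual-label matching, intensity contrasts, dropout."""

import numpy as np
import pandas as pd
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching
from scipy.spatial import cKDTree

from supraconnect import (
    MatchParams,
    PointSet,
    SpotParams,
    colabel_rate,
    detect_spots,
    dropout_curve,
    intensity_contrast,
    match_dual,
    simulate_nuclei_stack,
)
from supraconnect.synthetic_data import ImageStack


def hungarian_match_count(a: np.ndarray, b: np.ndarray, r: float) -> int:
    """Maximum-cardinality matching on the thresholded bipartite graph."""
    if len(a) == 0 or len(b) == 0:
        return 0
    pairs = cKDTree(a).query_ball_tree(cKDTree(b), r)
    rows, cols = [], []
    for i, js in enumerate(pairs):
        rows.extend([i] * len(js))
        cols.extend(js)
    if not rows:
        return 0
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(len(a), len(b)))
    return int((maximum_bipartite_matching(graph, perm_type="column") >= 0).sum())


class TestDetectSpots:
    def test_constant_image_yields_no_spots(self):
        stack = ImageStack(np.full((10, 20, 20), 37.0), (2.0, 2.0, 4.0))
        out = detect_spots(stack, SpotParams(intensity_threshold=1.0))
        assert len(out) == 0

    def test_missing_voxel_size_rejected(self):
        stack = ImageStack(np.zeros((5, 5, 5)), None)
        with pytest.raises(ValueError, match="voxel"):
            detect_spots(stack)

    def test_recovers_separated_blobs_within_one_voxel(self, rng):
        # 6 well-separated nuclei-sized blobs on a clean background
        truth = np.array(
            [[21.0, 21.0, 14.0], [61.0, 21.0, 30.0], [21.0, 61.0, 46.0],
             [61.0, 61.0, 14.0], [41.0, 41.0, 30.0], [75.0, 75.0, 46.0]]
        )
        ps = PointSet("a", "c", truth, intensity=np.full(6, 800.0))
        stack = simulate_nuclei_stack(
            ps, (44, 44, 16), voxel_size_um=(2.0, 2.0, 4.0),
            blob_sigma_um=(1.5, 3.0), background=100.0, noise_sd=1.0, seed=0,
        )
        out = detect_spots(stack, SpotParams(intensity_threshold=20.0))
        assert len(out) == 6
        d, _ = cKDTree(out.points).query(truth)
        assert np.all(d <= np.linalg.norm([2.0, 2.0, 4.0]))
        # peak intensities reflect the raw image (above background)
        assert np.all(out.intensity > 300)

    def test_blob_below_threshold_dropped(self):
        ps = PointSet("a", "c", [[21.0, 21.0, 14.0]], intensity=[50.0])
        stack = simulate_nuclei_stack(
            ps, (22, 22, 8), voxel_size_um=(2.0, 2.0, 4.0), background=100.0
        )
        strict = detect_spots(stack, SpotParams(intensity_threshold=100.0))
        lenient = detect_spots(stack, SpotParams(intensity_threshold=1.0))
        assert len(strict) == 0
        assert len(lenient) == 1


class TestMatchDual:
    def test_identical_points_pair_at_zero_distance(self):
        a = PointSet("a", "lumbar", [[10.0, 10.0, 10.0]])
        b = PointSet("a", "cervical", [[10.0, 10.0, 10.0]])
        m = match_dual(a, b)
        assert m.pairs == [(0, 0, 0.0)]

    def test_points_beyond_threshold_unmatched(self):
        a = PointSet("a", "lumbar", [[0.0, 0.0, 0.0]])
        b = PointSet("a", "cervical", [[10.0, 0.0, 0.0]])
        m = match_dual(a, b, MatchParams(max_distance_um=4.0))
        assert m.pairs == []
        assert list(m.unmatched_a) == [0] and list(m.unmatched_b) == [0]

    def test_greedy_prefers_closer_pair(self):
        a = PointSet("a", "lumbar", [[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        b = PointSet("a", "cervical", [[1.0, 0.0, 0.0]])
        m = match_dual(a, b)
        assert [(p[0], p[1]) for p in m.pairs] == [(0, 0)]
        assert list(m.unmatched_a) == [1]

    def test_partition_invariant(self, rng):
        a = PointSet("a", "lumbar", rng.uniform(0, 100, (80, 3)))
        b = PointSet("a", "cervical", rng.uniform(0, 100, (60, 3)))
        m = match_dual(a, b)
        assert len(m.pairs) + len(m.unmatched_a) == 80
        assert len(m.pairs) + len(m.unmatched_b) == 60
        assert len(m.pairs) <= min(80, 60)
        assert all(p[2] <= 4.0 for p in m.pairs)
        ia = [p[0] for p in m.pairs]
        ib = [p[1] for p in m.pairs]
        assert len(set(ia)) == len(ia) and len(set(ib)) == len(ib)

    def test_pair_count_monotone_in_threshold(self, rng):
        a = PointSet("a", "lumbar", rng.uniform(0, 60, (100, 3)))
        b = PointSet("a", "cervical", rng.uniform(0, 60, (100, 3)))
        counts = [
            len(match_dual(a, b, MatchParams(max_distance_um=r)).pairs)
            for r in (1.0, 2.0, 4.0, 8.0, 16.0)
        ]
        assert counts == sorted(counts)

    def test_anisotropic_metric_tolerates_axial_offset(self):
        a = PointSet("a", "lumbar", [[0.0, 0.0, 0.0]])
        b = PointSet("a", "cervical", [[0.0, 0.0, 6.0]])
        plain = match_dual(a, b, MatchParams(metric="euclidean"))
        scaled = match_dual(a, b, MatchParams(metric="anisotropic", z_scale=2.0))
        assert plain.pairs == []
        assert len(scaled.pairs) == 1

    def test_matches_hungarian_oracle_on_random_instances(self, rng):
        for _ in range(10):
            a = rng.uniform(0, [250, 250, 125], (200, 3))
            b = rng.uniform(0, [250, 250, 125], (200, 3))
            greedy = len(match_dual(PointSet("x", "l", a), PointSet("x", "c", b)).pairs)
            assert greedy == hungarian_match_count(a, b, 4.0)

    def test_disjoint_frames_warn(self, rng):
        a = PointSet("a", "lumbar", rng.uniform(0, 10, (20, 3)))
        b = PointSet("a", "cervical", rng.uniform(500, 510, (20, 3)))
        with pytest.warns(UserWarning, match="frame"):
            match_dual(a, b)


class TestColabelRate:
    def test_all_matched_rate_one(self):
        pts = np.array([[float(i), 0.0, 0.0] for i in range(0, 50, 10)])
        a = PointSet("a", "lumbar", pts)
        b = PointSet("a", "cervical", pts)
        m = match_dual(a, b)
        out = colabel_rate(m, a)
        assert out.loc[out["region"] == "overall", "rate"].iloc[0] == 1.0

    def test_none_matched_rate_zero(self):
        a = PointSet("a", "lumbar", [[0.0, 0.0, 0.0]])
        b = PointSet("a", "cervical", [[100.0, 0.0, 0.0]])
        out = colabel_rate(match_dual(a, b), a)
        assert out.loc[out["region"] == "overall", "rate"].iloc[0] == 0.0

    def test_per_region_rates_follow_assignment(self):
        pts = np.array([[float(10 * i), 0.0, 0.0] for i in range(4)])
        a = PointSet("a", "lumbar", pts)
        a.region = np.array([1, 1, 2, 2])
        b = PointSet("a", "cervical", pts[:2])  # only region-1 cells dual
        out = colabel_rate(match_dual(a, b), a).set_index("region")
        assert out.loc[1, "rate"] == 1.0
        assert out.loc[2, "rate"] == 0.0
        assert out.loc["overall", "rate"] == 0.5


class TestIntensityContrast:
    @staticmethod
    def build_sets(rng, n_dual=200, n_single=200, dimming=1.0, rho=0.0):
        # dual cells at shared coordinates; singles far away
        dual_xyz = rng.uniform(0, 2000, (n_dual, 3))
        lum_only = rng.uniform(3000, 5000, (n_single, 3))
        cerv_only = rng.uniform(6000, 8000, (n_single, 3))
        cov = [[0.25, rho * 0.25], [rho * 0.25, 0.25]]
        z = rng.multivariate_normal([6.0, 6.0], cov, size=n_dual)
        lum = PointSet(
            "a", "lumbar", np.vstack([dual_xyz, lum_only]),
            intensity=np.concatenate(
                [np.exp(z[:, 0]), np.exp(rng.normal(6.0, 0.5, n_single))]
            ),
        )
        cerv = PointSet(
            "a", "cervical", np.vstack([dual_xyz, cerv_only]),
            intensity=np.concatenate(
                [dimming * np.exp(z[:, 1]), np.exp(rng.normal(6.0, 0.5, n_single))]
            ),
        )
        return lum, cerv

    def test_null_distributions_give_nonsignificant_contrast(self, rng):
        lum, cerv = self.build_sets(rng, dimming=1.0)
        m = match_dual(lum, cerv)
        out = intensity_contrast(m, lum, cerv).set_index("channel")
        assert out.loc["cervical", "p_value"] > 0.01

    def test_dimming_halves_dual_cervical_median(self, rng):
        lum, cerv = self.build_sets(rng, dimming=0.5)
        m = match_dual(lum, cerv)
        out = intensity_contrast(m, lum, cerv).set_index("channel")
        ratio = out.loc["cervical", "median_dual"] / out.loc["cervical", "median_single"]
        # lognormal medians: dimming acts multiplicatively on the median
        assert ratio == pytest.approx(0.5, rel=0.15)
        assert out.loc["cervical", "p_value"] < 1e-6
        # lumbar channel unaffected
        assert out.loc["lumbar", "p_value"] > 0.001

    def test_coinjected_correlation_recovered(self, rng):
        lum, cerv = self.build_sets(rng, rho=0.6)
        m = match_dual(lum, cerv)
        out = intensity_contrast(m, lum, cerv, co_injected=True)
        r = out.attrs["dual_log_correlation"]
        z, half = np.arctanh(0.6), 1.96 / np.sqrt(200 - 3)
        assert np.tanh(z - half) < r < np.tanh(z + half)

    def test_tiny_group_flagged_undefined(self):
        a = PointSet("a", "lumbar", [[0.0, 0.0, 0.0]], intensity=[5.0])
        b = PointSet("a", "cervical", [[0.0, 0.0, 0.0]], intensity=[5.0])
        out = intensity_contrast(match_dual(a, b), a, b)
        assert out["undefined"].all()


class TestDropoutCurve:
    @staticmethod
    def dim_dual_sets(n_dual=50, n_bright=50):
        """All dual cells carry the dimmest cervical label."""
        dual_xyz = np.array([[10.0 * i, 0.0, 0.0] for i in range(n_dual)])
        far = np.array([[10.0 * i, 1000.0, 0.0] for i in range(n_bright)])
        lum = PointSet(
            "a", "lumbar",
            np.vstack([dual_xyz, dual_xyz + [0.0, 500.0, 0.0]]),
            intensity=np.ones(2 * n_dual),
        )
        cerv = PointSet(
            "a", "cervical", np.vstack([dual_xyz, far]),
            intensity=np.concatenate(
                [np.arange(1, n_dual + 1, dtype=float),         # dim duals
                 np.arange(100, 100 + n_bright, dtype=float)]   # bright singles
            ),
        )
        return lum, cerv

    def test_full_retention_is_identity(self):
        lum, cerv = self.dim_dual_sets()
        out = dropout_curve(lum, cerv, retain_fractions=[1.0]).iloc[0]
        assert out["dual_rate"] == 0.5
        assert out["relative_change_pct"] == 0.0

    def test_dim_duals_vanish_at_half_retention(self):
        lum, cerv = self.dim_dual_sets()
        out = dropout_curve(lum, cerv, retain_fractions=[1.0, 0.5]).set_index("fraction")
        assert out.loc[0.5, "dual_rate"] == 0.0
        assert out.loc[0.5, "relative_change_pct"] == -100.0

    def test_invalid_fraction_rejected(self):
        lum, cerv = self.dim_dual_sets(4, 4)
        with pytest.raises(ValueError, match="fraction"):
            dropout_curve(lum, cerv, retain_fractions=[0.0])

    def test_monotone_under_stochastic_dimming(self, small_cohort):
        a = small_cohort.animals[0]
        out = dropout_curve(
            a.pointsets["lumbar"], a.pointsets["cervical"],
            retain_fractions=[1.0, 0.8, 0.6, 0.4, 0.2],
        )
        rates = out.sort_values("fraction", ascending=False)["dual_rate"].to_numpy()
        assert np.all(np.diff(rates) <= 1e-12)
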