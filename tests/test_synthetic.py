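"""Generator correctness: atlas construction, count law, intensities, images."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from supraconnect import (
    CohortDesign,
    IntensityModel,
    PointSet,
    RegionSpec,
    build_toy_atlas,
    simulate_cohort,
    simulate_gfap_section,
    simulate_nuclei_stack,
)


class TestBuildToyAtlas:
    def test_labels_partition_and_mirror(self):
        volume, ontology = build_toy_atlas(4, (20, 20, 20), 25.0)
        assert set(np.unique(volume.labels)) == {0, 1, 2, 3, 4}
        # mirrored about the midline: x -> nx-1-x maps each region onto itself
        flipped = volume.labels[::-1, :, :]
        np.testing.assert_array_equal(volume.labels, flipped)
        # every region has voxels strictly on both sides of the midline
        for rid in (1, 2, 3, 4):
            xs = np.argwhere(volume.labels == rid)[:, 0]
            assert xs.min() < volume.midline <= xs.max()

    def test_ontology_partitions_leaves_into_summaries(self):
        _, ontology = build_toy_atlas(4, (20, 20, 20), 25.0)
        summaries = {ontology.collapse(leaf, "summary25") for leaf in ontology.leaves}
        assert len(ontology.leaves) == 4
        assert len(summaries) == 2
        for leaf in ontology.leaves:  # no leaf unassigned
            assert ontology.collapse(leaf, "summary25") in summaries

    def test_region_volumes_match_bruteforce_voxel_tally(self):
        volume, _ = build_toy_atlas(5, (18, 21, 16), 25.0)
        tally = volume.region_voxel_counts()
        brute = {}
        for v in volume.labels.ravel():
            brute[int(v)] = brute.get(int(v), 0) + 1
        assert tally == brute

    def test_too_small_shape_raises_sizing_error(self):
        with pytest.raises(ValueError, match="too small"):
            build_toy_atlas(8, (4, 6, 3), 25.0)


class TestDesignValidation:
    def test_unknown_region_in_severity_rejected(self):
        with pytest.raises(ValueError, match="unknown region"):
            CohortDesign(
                regions=[RegionSpec(1, 10.0, 0.1)],
                severity_sparing={"sev": {99: 0.5}},
            )

    def test_probability_ranges_enforced(self):
        with pytest.raises(ValueError, match="dual_probability"):
            RegionSpec(1, 10.0, 1.5)
        with pytest.raises(ValueError, match="sparing"):
            CohortDesign(
                regions=[RegionSpec(1, 10.0, 0.1)],
                severity_sparing={"sev": {1: 1.2}},
            )
        with pytest.raises(ValueError, match="dimming"):
            IntensityModel(dual_cervical_dimming=0.0)

    def test_design_region_missing_from_atlas_rejected(self, small_atlas):
        volume, ontology = small_atlas
        design = CohortDesign(regions=[RegionSpec(77, 10.0, 0.1)], n_animals=1)
        with pytest.raises(ValueError, match="77"):
            simulate_cohort(design, volume, ontology)


class TestSimulateCohort:
    def test_same_seed_gives_byte_identical_cohorts(self, small_design, small_atlas, tmp_path):
        volume, ontology = small_atlas
        d1 = tmp_path / "c1"
        d2 = tmp_path / "c2"
        simulate_cohort(small_design, volume, ontology).write(d1)
        simulate_cohort(small_design, volume, ontology).write(d2)
        files = sorted(p.name for p in d1.iterdir())
        assert files == sorted(p.name for p in d2.iterdir())
        for name in files:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_every_nucleus_lies_inside_its_region(self, small_cohort, small_atlas):
        volume, _ = small_atlas
        gt = small_cohort.ground_truth.per_region
        for animal in small_cohort.animals:
            ps = animal.pointsets["lumbar"]
            idx = np.floor(ps.points / 25.0).astype(int)
            labels = volume.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
            # counts per label match the recorded ground truth
            sub = gt[gt["animal"] == animal.animal_id]
            expect = dict(zip(sub["region"], sub["true_lumbar"]))
            got = {int(k): int(v) for k, v in zip(*np.unique(labels, return_counts=True))}
            for rid, n in expect.items():
                assert got.get(rid, 0) == n

    def test_full_sparing_equals_uninjured_means(self, small_atlas):
        volume, ontology = small_atlas
        design = CohortDesign(
            regions=[RegionSpec(1, 100.0, 0.2), RegionSpec(2, 50.0, 0.2)],
            severity_sparing={"sham": {1: 1.0, 2: 1.0}},
            n_animals=40,
            seed=5,
        )
        cohort = simulate_cohort(design, volume, ontology)
        gt = cohort.ground_truth.per_region
        means = gt.groupby(["condition", "region"])["true_lumbar"].mean().unstack()
        # same count law in both arms: means agree within 3 SE
        for rid, mean in ((1, 100.0), (2, 50.0)):
            se = np.sqrt((mean + mean**2 / design.dispersion) / 40)
            assert abs(means.loc["sham", rid] - mean) < 3 * se
            assert abs(means.loc["uninjured", rid] - mean) < 3 * se

    def test_mean_recovery_within_three_se(self, small_atlas):
        volume, ontology = small_atlas
        design = CohortDesign(
            regions=[RegionSpec(1, 200.0, 0.0)], n_animals=40, seed=7,
            dispersion=8.0,
        )
        cohort = simulate_cohort(design, volume, ontology)
        counts = cohort.ground_truth.per_region["true_lumbar"].to_numpy()
        se = np.sqrt((200 + 200**2 / 8.0) / 40)
        assert abs(counts.mean() - 200.0) < 3 * se

    def test_overdispersion_exceeds_poisson_and_vanishes_at_inf(self, small_atlas):
        volume, ontology = small_atlas
        out = {}
        for name, disp in (("nb", 4.0), ("poisson", np.inf)):
            design = CohortDesign(
                regions=[RegionSpec(1, 100.0, 0.0)], dispersion=disp,
                n_animals=200, seed=13,
            )
            c = simulate_cohort(design, volume, ontology)
            x = c.ground_truth.per_region["true_lumbar"].to_numpy()
            out[name] = x.var(ddof=1) / x.mean()
        assert out["nb"] > 2.0  # expected index ~ 1 + mean/size = 26
        assert 0.7 < out["poisson"] < 1.4

    def test_dual_log_intensities_correlate_as_designed(self, small_atlas):
        volume, ontology = small_atlas
        rho = 0.6
        design = CohortDesign(
            regions=[RegionSpec(1, 400.0, 0.9)],
            intensity_model=IntensityModel(correlation=rho, dual_cervical_dimming=1.0),
            n_animals=4, seed=3,
        )
        cohort = simulate_cohort(design, volume, ontology)
        logs_l, logs_c = [], []
        for a in cohort.animals:
            mask = cohort.ground_truth.dual_mask[a.animal_id]
            n_dual = mask.sum()
            logs_l.append(np.log(a.pointsets["lumbar"].intensity[mask]))
            # dual cervical cells come first in the cervical set per region
            logs_c.append(np.log(a.pointsets["cervical"].intensity[:n_dual]))
        r = np.corrcoef(np.concatenate(logs_l), np.concatenate(logs_c))[0, 1]
        n = sum(len(x) for x in logs_l)
        # Fisher-z 95% interval around the design correlation
        z = np.arctanh(rho)
        half = 1.96 / np.sqrt(n - 3)
        assert np.tanh(z - half) < r < np.tanh(z + half)

    def test_behavior_score_tracks_linked_region_sparing(self, small_atlas):
        from supraconnect.synthetic_data import BehaviorLink

        volume, ontology = small_atlas
        design = CohortDesign(
            regions=[RegionSpec(1, 100.0, 0.1), RegionSpec(2, 100.0, 0.1)],
            severity_sparing={
                "a": {1: 0.2, 2: 0.9}, "b": {1: 0.5, 2: 0.9}, "c": {1: 0.8, 2: 0.9},
            },
            behavior_link=BehaviorLink(region_ids=(1,), weights=(1.0,), noise_sd=0.3),
            n_animals=25, seed=21,
        )
        cohort = simulate_cohort(design, volume, ontology)
        gt = cohort.ground_truth.per_region
        bms = {a.animal_id: a.bms_score for a in cohort.animals}
        injured = gt[gt["condition"] != "uninjured"]
        linked = injured[injured["region"] == 1]
        rho_linked = sps.spearmanr(
            linked["realized_sparing"], [bms[a] for a in linked["animal"]]
        ).statistic
        assert rho_linked > 0.5
        # region 2 has constant sparing across arms: no association expected
        other = injured[injured["region"] == 2]
        rho_other = sps.spearmanr(
            other["realized_sparing"], [bms[a] for a in other["animal"]]
        ).statistic
        assert abs(rho_other) < 0.25

    def test_scores_clipped_to_bms_scale(self, small_cohort):
        for a in small_cohort.animals:
            assert 0.0 <= a.bms_score <= 9.0


class TestNucleiStack:
    def test_empty_pointset_gives_background_plus_noise(self):
        ps = PointSet("a", "lumbar", np.zeros((0, 3)))
        stack = simulate_nuclei_stack(ps, (10, 10, 5), background=50.0, noise_sd=2.0, seed=0)
        assert abs(stack.data.mean() - 50.0) < 1.0
        assert 1.0 < stack.data.std() < 3.0

    def test_single_blob_peaks_at_point_location(self):
        ps = PointSet("a", "lumbar", [[21.0, 25.0, 14.0]], intensity=[500.0])
        stack = simulate_nuclei_stack(
            ps, (20, 20, 10), voxel_size_um=(2.0, 2.0, 4.0), background=0.0, noise_sd=0.0
        )
        z, y, x = np.unravel_index(np.argmax(stack.data), stack.data.shape)
        assert (x, y, z) == (10, 12, 3)

    def test_integrated_intensity_matches_gaussian_integral(self):
        amp, sxy, sz = 300.0, 2.0, 4.0
        vx = vy = 1.0
        vz = 2.0
        ps = PointSet("a", "lumbar", [[30.0, 30.0, 30.0]], intensity=[amp])
        stack = simulate_nuclei_stack(
            ps, (60, 60, 30), voxel_size_um=(vx, vy, vz),
            blob_sigma_um=(sxy, sz), background=10.0, noise_sd=0.0,
        )
        integral = (stack.data - 10.0).sum() * vx * vy * vz
        expected = amp * (2 * np.pi) ** 1.5 * sxy * sxy * sz
        assert integral == pytest.approx(expected, rel=0.01)

    def test_out_of_bounds_point_rejected(self):
        ps = PointSet("a", "lumbar", [[1000.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="bounds"):
            simulate_nuclei_stack(ps, (10, 10, 10))

    def test_tiff_roundtrip(self, tmp_path):
        from supraconnect.synthetic_data import ImageStack

        ps = PointSet("a", "lumbar", [[10.0, 10.0, 10.0]], intensity=[100.0])
        stack = simulate_nuclei_stack(ps, (10, 10, 5), background=5.0)
        f = tmp_path / "stack.tiff"
        stack.write_tiff(f)
        back = ImageStack.read_tiff(f, stack.voxel_size_um)
        np.testing.assert_allclose(back.data, stack.data.astype(np.float32))


class TestGfapSection:
    @pytest.mark.parametrize(
        "spans,expected",
        [
            ([(0, 100)], 1.0),
            ([], 0.0),
            ([(10, 25), (60, 75)], 0.30),
        ],
    )
    def test_ground_truth_fraction(self, spans, expected):
        section = simulate_gfap_section(100, 60, spans)
        assert section.true_bridge_fraction == pytest.approx(expected)

    def test_overlapping_spans_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            simulate_gfap_section(100, 60, [(10, 30), (20, 40)])

    def test_span_outside_width_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            simulate_gfap_section(100, 60, [(90, 120)])
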