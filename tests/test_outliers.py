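"""Subject-level outlier mapping: z-maps, clusters, load scores, pipeline."""

import numpy as np
import pandas as pd
import pytest

from surfload.errors import IntegrityError, PipelineError
from surfload.mesh import SurfaceMesh, VertexMap, generate_icosphere
from surfload.outliers import (
    OutlierParams,
    compute_ratio_map,
    load_scores,
    normative_stats,
    run_outlier_pipeline,
    threshold_clusters,
    zmap,
)
from surfload.simulate import Cohort, SimConfig, simulate_cohort


def flood_fill_clusters(z, faces, thresh):
    """Brute-force oracle: connected suprathreshold components via face scan."""
    n = len(z)
    nbrs = [set() for _ in range(n)]
    for a, b, c in faces:
        for u, v in ((a, b), (b, c), (a, c)):
            nbrs[u].add(v)
            nbrs[v].add(u)
    found = []
    for sign, mask in (("high", z >= thresh), ("low", z <= -thresh)):
        seen = set()
        for start in np.flatnonzero(mask):
            if start in seen:
                continue
            comp, stack = set(), [start]
            while stack:
                u = stack.pop()
                if u in comp:
                    continue
                comp.add(u)
                stack.extend(v for v in nbrs[u] if mask[v] and v not in comp)
            seen |= comp
            found.append((sign, frozenset(int(v) for v in comp)))
    return set(found)


@pytest.fixture
def fan_mesh():
    # a path 0-1-2-3-4-5 of rim vertices closed through apex 6
    coords = np.array([[i, 0.0, 0.0] for i in range(6)] + [[2.5, 1.0, 0.0]])
    faces = np.array([[i, i + 1, 6] for i in range(5)])
    return SurfaceMesh(coords, faces)


class TestRatioMap:
    def test_identity_maps_give_ones(self):
        out = compute_ratio_map([2.0, 3.0, 4.0], [2.0, 3.0, 4.0])
        np.testing.assert_allclose(out.values, 1.0)

    def test_simple_division(self):
        np.testing.assert_allclose(
            compute_ratio_map([2.0, 3.0], [1.0, 2.0]).values, [2.0, 1.5])

    def test_nonpositive_t2w_flagged_missing(self):
        out = compute_ratio_map([1.0, 2.0, 3.0], [1.0, 0.0, -1.0])
        assert out.values[0] == 1.0
        assert np.isnan(out.values[1]) and np.isnan(out.values[2])

    def test_all_missing_is_pipeline_error(self):
        with pytest.raises(PipelineError):
            compute_ratio_map([1.0, 1.0], [0.0, -2.0])


class TestNormativeStats:
    def test_mean_and_sample_sd(self):
        maps = {"a": [10.0], "b": [12.0], "c": [14.0]}
        stats = normative_stats(maps)
        assert stats.mean_map.values[0] == pytest.approx(12.0)
        assert stats.sd_map.values[0] == pytest.approx(2.0)
        assert stats.n_reference == 3

    def test_leave_one_out(self):
        maps = {"a": [10.0], "b": [12.0], "c": [14.0], "d": [16.0]}
        stats = normative_stats(maps, exclude="a")
        assert stats.mean_map.values[0] == pytest.approx(14.0)
        assert stats.sd_map.values[0] == pytest.approx(2.0)
        assert stats.excluded_subject == "a"

    def test_too_few_after_exclusion(self):
        with pytest.raises(PipelineError):
            normative_stats({"a": [1.0], "b": [2.0]}, exclude="a")

    def test_zero_sd_flagged_with_warning(self):
        with pytest.warns(RuntimeWarning, match="zero reference SD"):
            stats = normative_stats({"a": [1.0], "b": [1.0], "c": [1.0]})
        assert np.isnan(stats.sd_map.values[0])


class TestZmap:
    def test_mean_map_scores_zero(self):
        stats = normative_stats({"a": [10.0], "b": [12.0], "c": [14.0]})
        assert zmap([12.0], stats).values[0] == pytest.approx(0.0)

    def test_two_sd_above(self):
        stats = normative_stats({"a": [10.0], "b": [12.0], "c": [14.0]})
        assert zmap([16.0], stats).values[0] == pytest.approx(2.0)

    def test_leave_one_out_value(self):
        stats = normative_stats({"a": [10.0], "b": [12.0], "c": [14.0]},
                                exclude="a")
        # (10 - 13) / sqrt(2)
        assert zmap([10.0], stats).values[0] == pytest.approx(-2.1213203, abs=1e-6)

    def test_mesh_mismatch(self):
        stats = normative_stats({"a": [1.0, 2.0], "b": [2.0, 3.0],
                                 "c": [3.0, 4.0]})
        with pytest.raises(IntegrityError):
            zmap([1.0], stats)


class TestThresholdClusters:
    def test_all_zero_gives_empty_list(self, fan_mesh):
        assert threshold_clusters(np.zeros(7), fan_mesh) == []

    def test_path_example_one_high_one_low(self, fan_mesh):
        z = np.array([0.0, 3.0, 3.0, 0.0, -3.0, 0.0, 0.0])
        clusters = threshold_clusters(z, fan_mesh, z_thresh=2.0, min_area=0.0)
        by_sign = {c.sign: set(c.vertex_set) for c in clusters}
        assert by_sign == {"high": {1, 2}, "low": {4}}

    def test_non_adjacent_vertices_stay_separate(self, fan_mesh):
        z = np.array([3.0, 0.0, 0.0, 3.0, 0.0, 0.0, 0.0])  # 0 and 3 not adjacent
        clusters = threshold_clusters(z, fan_mesh, min_area=0.0)
        assert len(clusters) == 2
        assert all(c.sign == "high" for c in clusters)

    def test_signs_never_merge_even_when_adjacent(self, fan_mesh):
        z = np.array([0.0, 2.5, -2.5, 0.0, 0.0, 0.0, 0.0])
        clusters = threshold_clusters(z, fan_mesh, min_area=0.0)
        assert {c.sign for c in clusters} == {"high", "low"}

    def test_min_area_discards_small_clusters(self, fan_mesh):
        z = np.array([0.0, 3.0, 3.0, 0.0, -3.0, 0.0, 0.0])
        assert threshold_clusters(z, fan_mesh, min_area=1e9) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_flood_fill_oracle(self, delaunay_factory, seed):
        rng = np.random.default_rng(seed)
        mesh = delaunay_factory(rng)
        z = rng.standard_normal(mesh.n_vertices) * 1.5
        clusters = threshold_clusters(z, mesh, z_thresh=2.0, min_area=0.0)
        ours = {(c.sign, frozenset(int(v) for v in c.vertex_set))
                for c in clusters}
        assert ours == flood_fill_clusters(z, mesh.faces, 2.0)

    def test_sorted_by_area_descending(self, fan_mesh):
        z = np.array([3.0, 0.0, 0.0, 3.0, 3.0, 0.0, 0.0])
        clusters = threshold_clusters(z, fan_mesh, min_area=0.0)
        areas = [c.area for c in clusters]
        assert areas == sorted(areas, reverse=True)


class TestLoadScores:
    def test_no_clusters_is_negative_status(self):
        ls = load_scores([], "s1")
        assert ls.hr_load == 0.0 and ls.lr_load == 0.0
        assert ls.hr_status == "HR-" and ls.lr_status == "LR-"

    def test_sums_by_sign(self, fan_mesh):
        z = np.array([0.0, 3.0, 3.0, 0.0, -3.0, 0.0, 0.0])
        clusters = threshold_clusters(z, fan_mesh, min_area=0.0, subject_id="s1")
        ls = load_scores(clusters, "s1")
        high = sum(c.area for c in clusters if c.sign == "high")
        low = sum(c.area for c in clusters if c.sign == "low")
        assert ls.hr_load == pytest.approx(high)
        assert ls.lr_load == pytest.approx(low)
        assert ls.hr_status == "HR+" and ls.lr_status == "LR+"


class TestPipeline:
    @pytest.fixture(scope="class")
    def small_cohort(self):
        mesh = generate_icosphere(2, 30.0)
        return simulate_cohort(SimConfig(seed=21, n_per_group=(5, 8),
                                         noise_fwhm=10.0), mesh)

    def test_small_reference_group_rejected(self):
        mesh = generate_icosphere(1, 10.0)
        cohort = simulate_cohort(SimConfig(seed=1, n_per_group=(3, 3)), mesh)
        with pytest.raises(PipelineError):
            run_outlier_pipeline(cohort)

    def test_subject_order_invariance(self, small_cohort):
        res_a = run_outlier_pipeline(small_cohort)
        shuffled = Cohort(
            subjects=small_cohort.subjects.sample(frac=1.0, random_state=0)
            .reset_index(drop=True),
            maps=small_cohort.maps, meshes=small_cohort.meshes,
        )
        res_b = run_outlier_pipeline(shuffled)
        a = res_a.loads.set_index("subject_id").sort_index()
        b = res_b.loads.set_index("subject_id").sort_index()
        pd.testing.assert_frame_equal(a, b)

    def test_loads_consistent_with_clusters(self, small_cohort):
        res = run_outlier_pipeline(small_cohort)
        for _, row in res.loads.iterrows():
            hr = sum(c.area for c in res.clusters
                     if c.subject_id == row["subject_id"] and c.sign == "high")
            assert row["hr_load"] == pytest.approx(hr)
            assert (row["hr_status"] == "HR+") == (row["hr_load"] > 0)

    def test_overlap_maps_bounded_by_group_size(self, small_cohort):
        res = run_outlier_pipeline(small_cohort)
        counts = res.overlap_maps[("ASD", "high")]["left"].values
        assert counts.min() >= 0
        assert counts.max() <= (small_cohort.subjects["group"] == "ASD").sum()

    def test_suprathreshold_partition_before_extent_filter(self, small_cohort):
        # every suprathreshold vertex belongs to exactly one cluster of its sign
        mesh = small_cohort.meshes["left"]
        res = run_outlier_pipeline(small_cohort, OutlierParams(min_area=0.0))
        sid = res.loads["subject_id"].iloc[0]
        mine = [c for c in res.clusters if c.subject_id == sid and c.sign == "high"]
        all_members = np.concatenate([c.vertex_set for c in mine]) if mine else []
        assert len(all_members) == len(set(all_members))
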