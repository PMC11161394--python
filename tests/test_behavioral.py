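"""Behavioral statistics: rank tests, t-tests, FDR, battery, group matching."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from surfload.behavioral import (
    bh_fdr,
    comparisons_frame,
    group_matching,
    mann_whitney_u,
    spearman_rho,
    subgroup_battery,
    two_sample_t,
)
from surfload.mesh import generate_icosphere
from surfload.outliers import OutlierParams, run_outlier_pipeline
from surfload.simulate import SimConfig, simulate_cohort


def mwu_enumeration_p(x, y):
    """Oracle: exact two-sided Mann-Whitney p by enumerating group labels."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    obs_u = sum(1 for xi in x for yj in y if xi > yj)  # tie-free inputs only
    mean_u = nx * len(y) / 2.0
    obs_dev = abs(obs_u - mean_u)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = sum(1 for xi in xs for yj in ys if xi > yj)
        count += abs(u - mean_u) >= obs_dev - 1e-12
        total += 1
    return count / total


def bh_oracle(p):
    """Hand implementation of the step-up adjustment."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestMannWhitney:
    def test_textbook_example(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_all_tied_warns(self):
        with pytest.warns(RuntimeWarning):
            _, p = mann_whitney_u([5.0, 5.0], [5.0, 5.0])
        assert p == 1.0

    @pytest.mark.parametrize("nx,ny,seed", [(2, 2, 0), (3, 4, 1), (4, 4, 2),
                                            (5, 3, 3), (6, 6, 4), (8, 7, 5)])
    def test_exact_p_equals_enumeration(self, nx, ny, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(np.arange(nx + ny, dtype=float))[:nx]
        y = np.setdiff1d(np.arange(nx + ny, dtype=float), x)
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(mwu_enumeration_p(x, y), abs=1e-12)

    def test_exact_and_asymptotic_agree_at_n10(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.5, 1, 10)
        _, p_exact = mann_whitney_u(x, y)
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        assert abs(p_exact - res.pvalue) < 0.02


class TestTwoSampleT:
    def test_identical_samples(self):
        t, df, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_student_hand_computation(self):
        # diff -3, pooled var 1, se = sqrt(2/3)
        t, df, p = two_sample_t([1, 2, 3], [4, 5, 6], variant="student")
        assert t == pytest.approx(-3.0 / np.sqrt(2 / 3), abs=1e-4)
        assert df == 4

    def test_welch_equals_student_for_balanced_equal_variance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.5, 3.5, 4.5, 5.5])  # same spread, same n
        tw, dfw, pw = two_sample_t(x, y, variant="welch")
        ts, dfs, ps = two_sample_t(x, y, variant="student")
        assert tw == pytest.approx(ts)
        assert dfw == pytest.approx(dfs)
        assert pw == pytest.approx(ps)

    def test_degenerate_equal_constants(self):
        t, df, p = two_sample_t([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == 1.0


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # sum d^2 = 4 -> rho = 1 - 24/60 = 0.6
        rho, _ = spearman_rho([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    def test_reversal_negates_rho(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        rho_fwd, _ = spearman_rho(x, y)
        rho_rev, _ = spearman_rho(x, -y)
        assert rho_rev == pytest.approx(-rho_fwd)

    def test_tie_free_formula(self):
        rng = np.random.default_rng(10)
        x = rng.permutation(10).astype(float)
        y = rng.permutation(10).astype(float)
        rho, _ = spearman_rho(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        d2 = ((rx - ry) ** 2).sum()
        assert rho == pytest.approx(1 - 6 * d2 / (10 * 99))

    def test_exact_permutation_p(self):
        rho, p = spearman_rho([1, 2, 3, 4, 5], [1, 3, 2, 5, 4], exact=True)
        assert 0 < p <= 1

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])


class TestBHFDR:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.04]),
                                   [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1,
                    max_size=30))
    def test_matches_hand_oracle_and_dominates_input(self, ps):
        q = bh_fdr(ps)
        np.testing.assert_allclose(q, bh_oracle(ps), atol=1e-12)
        assert (q >= np.asarray(ps) - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()

    def test_monotone_on_sorted_input(self):
        q = bh_fdr([0.001, 0.01, 0.02, 0.3, 0.9])
        assert (np.diff(q) >= -1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 0.0])


class TestSubgroupBattery:
    @pytest.fixture(scope="class")
    def cohort_and_loads(self):
        mesh = generate_icosphere(3, 30.0)
        cohort = simulate_cohort(SimConfig(seed=30, noise_fwhm=10.0), mesh)
        res = run_outlier_pipeline(cohort, OutlierParams(min_area=50.0))
        return cohort, res.loads

    def test_bookkeeping_both_arms(self, cohort_and_loads):
        cohort, loads = cohort_and_loads
        all_rows = []
        for arm in ("HR", "LR"):
            rows = subgroup_battery(loads, cohort.subjects, arm=arm)
            all_rows.extend(rows)
            t_rows = [r for r in rows if r.test == "welch_t"]
            assert len(t_rows) == 32  # 4 comparisons x 8 measures
            assert all(min(r.n) >= 2 for r in t_rows)
            assert all(r.p_fdr is not None and r.p_fdr >= r.p - 1e-12
                       for r in rows)
        frame = comparisons_frame(all_rows)
        assert len(frame) == len(all_rows)
        assert frame["p"].between(0, 1).all()

    def test_invariant_to_subject_order(self, cohort_and_loads):
        cohort, loads = cohort_and_loads
        rows_a = subgroup_battery(loads, cohort.subjects, arm="HR")
        shuffled = loads.sample(frac=1.0, random_state=1).reset_index(drop=True)
        rows_b = subgroup_battery(shuffled, cohort.subjects, arm="HR")
        pa = {(r.comparison, r.measure): r.p for r in rows_a}
        pb = {(r.comparison, r.measure): r.p for r in rows_b}
        assert pa.keys() == pb.keys()
        for k in pa:
            assert pa[k] == pytest.approx(pb[k], abs=1e-12)


class TestGroupMatching:
    def test_identical_groups_all_p_one(self):
        half = pd.DataFrame({
            "subject_id": [f"a{i}" for i in range(6)],
            "age": [50, 52, 54, 56, 58, 60.0],
            "pri": [100, 105, 110, 100, 105, 110.0],
            "sex": ["M", "M", "M", "F", "F", "F"],
        })
        both = pd.concat([half.assign(group="ASD"),
                          half.assign(group="TC",
                                      subject_id=[f"b{i}" for i in range(6)])])
        for r in group_matching(both):
            assert r.p == pytest.approx(1.0)

    def test_balanced_2x2_chi_square_zero(self):
        tab = pd.DataFrame({
            "group": ["ASD"] * 20 + ["TC"] * 20,
            "sex": (["M"] * 10 + ["F"] * 10) * 2,
            "age": np.r_[np.linspace(40, 70, 20), np.linspace(41, 69, 20)],
        })
        res = {r.measure: r for r in group_matching(tab)}
        assert res["sex"].test == "chi_square"
        assert res["sex"].statistic == pytest.approx(0.0)
        assert res["sex"].p == pytest.approx(1.0)

    def test_fisher_exact_matches_hypergeometric_enumeration(self):
        tab = pd.DataFrame({
            "group": ["ASD"] * 10 + ["TC"] * 10,
            "sex": ["M"] * 1 + ["F"] * 9 + ["M"] * 9 + ["F"] * 1,
            "age": np.r_[np.linspace(40, 70, 10), np.linspace(41, 69, 10)],
        })
        res = {r.measure: r for r in group_matching(tab)}
        assert res["sex"].test == "fisher"
        # two-sided Fisher p: sum of hypergeometric probabilities <= P(obs)
        rv = sps.hypergeom(20, 10, 10)
        p_obs = rv.pmf(1)
        p_oracle = sum(rv.pmf(k) for k in range(11) if rv.pmf(k) <= p_obs + 1e-12)
        assert res["sex"].p == pytest.approx(p_oracle, abs=1e-10)
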