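"""Subject-table statistics for outlier-load subgroup analyses.

Covers the whole behavioral arm: Mann-Whitney U comparisons of the
zero-inflated load distributions between diagnostic groups, the four planned
subgroup t-test contrasts per neuropsychological measure, Spearman
correlations of load with behavior inside the outlier-positive subgroups,
Benjamini-Hochberg false-discovery-rate adjustment, and Table-1-style
group-matching tests (t-test for continuous, chi-square/Fisher for
categorical variables).

Subgroups are defined by diagnosis crossed with outlier status: e.g. for the
high-ratio (HR) arm, ASD-HR+, ASD-HR-, TC-HR+, TC-HR-.  The planned
comparisons per measure are

    (i)   ASD-HR+ vs ASD-HR-   (outlier status within the diagnosis group)
    (ii)  ASD-HR+ vs TC-HR-    (diagnosis and outlier status combined)
    (iii) ASD-HR+ vs TC-HR+    (diagnosis within the outlier-positive)
    (iv)  TC-HR+  vs TC-HR-    (outlier status independent of diagnosis)

and the analogous set for the low-ratio (LR) arm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "mann_whitney_u",
    "two_sample_t",
    "spearman_rho",
    "bh_fdr",
    "subgroup_battery",
    "group_matching",
    "NEUROPSYCH_MEASURES",
]

NEUROPSYCH_MEASURES = (
    "FSIQ", "BRIEF_GEC", "TM_NS", "TM_LS", "TM_NLS", "VF_LF", "VF_CF", "VF_CS",
)

ADOS_MEASURES = ("ADOS_total", "ADOS_SA", "ADOS_RRB")


@dataclass
class ComparisonResult:
    """One row of a comparison table (a test of one measure on one contrast)."""

    comparison: str  # e.g. "ASD-HR+ vs TC-HR+"
    measure: str
    test: str  # welch_t | student_t | mann_whitney | spearman | chi_square | fisher
    statistic: float
    p: float
    n: tuple  # per-cell sample sizes (or total n for correlations)
    p_fdr: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n"] = "/".join(str(int(v)) for v in np.atleast_1d(self.n))
        return d


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[np.isfinite(x)]


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration when ``n_x * n_y <= 400`` and the data are
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.  Returns ``(U, p)`` where U counts pairs won by ``x``.
    """
    x, y = _clean(x), _clean(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both samples; p = 1",
                      RuntimeWarning, stacklevel=2)
        return float(len(x) * len(y) / 2.0), 1.0
    method = "exact" if (len(x) * len(y) <= 400 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def two_sample_t(x, y, variant: str = "welch") -> tuple[float, float, float]:
    """Two-sided two-sample t-test: ``(t, df, p)``.

    ``variant="welch"`` (default) uses the Welch-Satterthwaite df, robust to
    the unequal subgroup variances typical of these cells; ``"student"`` pools.
    """
    x, y = _clean(x), _clean(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(x) == 0 and np.var(y) == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    res = sps.ttest_ind(x, y, equal_var=(variant == "student"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def spearman_rho(x, y, exact: bool = False) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p.

    Rho is Pearson on (average) ranks.  The p-value uses the t approximation
    ``t = rho * sqrt((n-2) / (1-rho^2))``; with ``exact=True`` (n <= 8) the
    p is computed by full permutation enumeration of one variable's ranks.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input; Spearman rho undefined")
    rho = float(sps.spearmanr(x, y).statistic)
    if exact:
        if n > 8:
            raise ValueError("exact Spearman p only supported for n <= 8")
        from itertools import permutations

        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = total = 0
        for perm in permutations(range(n)):
            r = abs(np.corrcoef(rx, ry[list(perm)])[0, 1])
            count += r >= obs - 1e-12
            total += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, float(np.finfo(float).tiny)
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return rho, float(min(max(p, np.finfo(float).tiny), 1.0))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order kept)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


# ---------------------------------------------------------------------------
# Subgroup battery
# ---------------------------------------------------------------------------

def _subgroup_labels(table: pd.DataFrame, arm: str) -> pd.Series:
    status_col = {"HR": "hr_status", "LR": "lr_status"}[arm]
    return table["group"] + "-" + table[status_col]


def subgroup_battery(loads: pd.DataFrame, subjects: pd.DataFrame, arm: str = "HR",
                     variant: str = "welch", fdr_family: str = "arm",
                     measures: tuple[str, ...] = NEUROPSYCH_MEASURES,
                     ) -> list[ComparisonResult]:
    """The planned four-comparison battery for one outlier arm, FDR-adjusted.

    Runs, per measure, the four diagnosis-by-status t-tests plus, within each
    outlier-positive subgroup, the Spearman correlation of the arm's load
    score with the measure.  ADOS scores (present only for the diagnosis
    group) are compared within ASD only.  Missing scores are dropped pairwise
    with the per-cell n recorded.  ``fdr_family="arm"`` adjusts all rows of
    this battery together; ``"none"`` skips adjustment (for callers pooling
    arms into a single global family).
    """
    if arm not in ("HR", "LR"):
        raise ValueError("arm must be 'HR' or 'LR'")
    table = loads.merge(subjects, on="subject_id", suffixes=("", "_subj"))
    if "group" not in table.columns:
        raise ValueError("need a 'group' column")
    labels = _subgroup_labels(table, arm)
    load_col = {"HR": "hr_load", "LR": "lr_load"}[arm]
    pos, neg = f"{arm}+", f"{arm}-"
    pairs = [
        (f"ASD-{pos}", f"ASD-{neg}"),
        (f"ASD-{pos}", f"TC-{neg}"),
        (f"ASD-{pos}", f"TC-{pos}"),
        (f"TC-{pos}", f"TC-{neg}"),
    ]
    results: list[ComparisonResult] = []
    skipped: list[str] = []
    for measure in measures:
        if measure not in table.columns:
            continue
        within_asd_only = measure in ADOS_MEASURES
        for a, b in pairs:
            if within_asd_only and not (a.startswith("ASD") and b.startswith("ASD")):
                continue
            xa = _clean(table.loc[labels == a, measure])
            xb = _clean(table.loc[labels == b, measure])
            if len(xa) < 2 or len(xb) < 2:
                skipped.append(f"{a} vs {b} [{measure}]")
                continue
            t, df, p = two_sample_t(xa, xb, variant=variant)
            results.append(ComparisonResult(
                comparison=f"{a} vs {b}", measure=measure,
                test=f"{variant}_t", statistic=t, p=p, n=(len(xa), len(xb)),
            ))
        # load-behavior correlations within the outlier-positive subgroups
        if not within_asd_only:
            for grp in ("ASD", "TC"):
                cell = table.loc[labels == f"{grp}-{pos}", [load_col, measure]].dropna()
                if len(cell) < 4:
                    skipped.append(f"{grp}-{pos} correlation [{measure}]")
                    continue
                try:
                    rho, p = spearman_rho(cell[load_col], cell[measure])
                except ValueError:
                    skipped.append(f"{grp}-{pos} correlation [{measure}]")
                    continue
                results.append(ComparisonResult(
                    comparison=f"{grp}-{pos} load correlation", measure=measure,
                    test="spearman", statistic=rho, p=p, n=(len(cell),),
                ))
    if skipped:
        warnings.warn("skipped comparisons with undersized cells: "
                      + "; ".join(skipped), RuntimeWarning, stacklevel=2)
    if fdr_family == "arm" and results:
        q = bh_fdr([r.p for r in results])
        for r, qi in zip(results, q):
            r.p_fdr = float(qi)
    return results


def comparisons_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Long-format table of comparison results."""
    cols = ["comparison", "measure", "test", "statistic", "p", "n", "p_fdr"]
    return pd.DataFrame([r.to_dict() for r in results], columns=cols)


def battery_wide_table(results: list[ComparisonResult]) -> pd.DataFrame:
    """Pivot t-test rows to measures-by-comparisons of p-values (report layout)."""
    rows = [r for r in results if r.test.endswith("_t")]
    if not rows:
        return pd.DataFrame()
    tab = pd.DataFrame(
        {"measure": [r.measure for r in rows],
         "comparison": [r.comparison for r in rows],
         "p": [r.p for r in rows]}
    )
    return tab.pivot(index="measure", columns="comparison", values="p")


# ---------------------------------------------------------------------------
# Group matching (Table-1 style)
# ---------------------------------------------------------------------------

CONTINUOUS_MATCHING = ("age", "vci", "pri", "FSIQ", "tbv", "cnr")
CATEGORICAL_MATCHING = ("sex", "race", "ethnicity")


def group_matching(subjects: pd.DataFrame, group_col: str = "group",
                   variant: str = "welch") -> list[ComparisonResult]:
    """Between-group matching tests on demographics and covariates.

    Continuous variables use a two-sample t-test; categorical variables use
    the chi-square test of independence, switching to Fisher's exact test
    whenever any expected cell count is below 5 (2x2 tables only).
    """
    groups = sorted(subjects[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError("group matching needs exactly two groups")
    ga = subjects[subjects[group_col] == groups[0]]
    gb = subjects[subjects[group_col] == groups[1]]
    label = f"{groups[0]} vs {groups[1]}"
    out: list[ComparisonResult] = []
    for var in CONTINUOUS_MATCHING:
        if var not in subjects.columns:
            continue
        xa, xb = _clean(ga[var]), _clean(gb[var])
        if len(xa) < 2 or len(xb) < 2:
            continue
        t, df, p = two_sample_t(xa, xb, variant=variant)
        out.append(ComparisonResult(comparison=label, measure=var,
                                    test=f"{variant}_t", statistic=t, p=p,
                                    n=(len(xa), len(xb))))
    for var in CATEGORICAL_MATCHING:
        if var not in subjects.columns:
            continue
        tab = pd.crosstab(subjects[group_col], subjects[var])
        if tab.shape[0] != 2 or tab.shape[1] < 2:
            continue
        counts = tab.to_numpy()
        expected = sps.contingency.expected_freq(counts)
        sparse = (expected < 5).any() or (counts < 5).any()
        if sparse and counts.shape == (2, 2):
            odds, p = sps.fisher_exact(counts, alternative="two-sided")
            out.append(ComparisonResult(comparison=label, measure=var,
                                        test="fisher", statistic=float(odds),
                                        p=float(p), n=tuple(counts.sum(axis=1))))
        else:
            chi2, p, _, _ = sps.chi2_contingency(counts, correction=False)
            out.append(ComparisonResult(comparison=label, measure=var,
                                        test="chi_square", statistic=float(chi2),
                                        p=float(p), n=tuple(counts.sum(axis=1))))
    return out
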