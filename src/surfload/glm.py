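"""Vertex-wise general linear model with permutation-based FWE correction.

The model tests a group-by-age interaction (and main effects) on per-vertex
T1w/T2w ratio while controlling for nonverbal IQ (PRI), total brain volume
(TBV) and gray-white contrast-to-noise ratio (CNR).  Family-wise error over
vertices is controlled by the max-statistic permutation method under the
Freedman-Lane scheme: nuisance covariates are regressed out, the residualized
rows are permuted, the full model is refit, and the maximum |t| over vertices
is recorded per permutation.

Effect sizes for significant clusters are reported as the partial R^2 of the
term of interest for the cluster-mean response.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError, IntegrityError
from .mesh import SurfaceMesh, VertexMap
from .outliers import OutlierCluster, threshold_clusters

__all__ = [
    "DesignMatrix",
    "GLMResult",
    "ClusterEffect",
    "build_design",
    "fit_vertexwise",
    "permutation_fwe",
    "cluster_effect_size",
    "run_group_glm",
]

DEFAULT_TERMS = ("intercept", "group", "age", "group_x_age", "pri", "tbv", "cnr")


@dataclass
class DesignMatrix:
    """Subjects-by-terms design with named columns and the fitted subject ids."""

    matrix: np.ndarray
    columns: list[str]
    subject_ids: list[str]
    dropped_subjects: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def column_index(self, name: str) -> int:
        try:
            return self.columns.index(name)
        except ValueError:
            raise DesignError(f"term {name!r} not in design columns {self.columns}")

    def contrast(self, name: str) -> np.ndarray:
        c = np.zeros(self.p)
        c[self.column_index(name)] = 1.0
        return c


def build_design(subjects: pd.DataFrame,
                 terms: tuple[str, ...] = DEFAULT_TERMS) -> DesignMatrix:
    """Assemble the design matrix from a subject table.

    Age is centered at the sample mean (so the group main effect is evaluated
    at the mean age and the interaction column is interpretable).  Subjects
    with any missing covariate are dropped with their ids recorded.  Raises
    :class:`DesignError` on rank deficiency, naming the collinear columns, or
    when there are fewer than ``p + 2`` rows.
    """
    needed = {"group"} | {t for t in terms if t in ("pri", "tbv", "cnr", "age")}
    missing_cols = needed - set(subjects.columns)
    if missing_cols:
        raise DesignError(f"subject table lacks columns {sorted(missing_cols)}")
    covars = [t for t in terms if t not in ("intercept", "group", "group_x_age")]
    keep = subjects.dropna(subset=[c for c in covars if c in subjects.columns])
    dropped = sorted(set(subjects["subject_id"]) - set(keep["subject_id"]))
    n = len(keep)
    cols = {}
    group = (keep["group"] == "ASD").to_numpy(float)
    age_c = keep["age"].to_numpy(float) - keep["age"].to_numpy(float).mean() \
        if "age" in terms else None
    for t in terms:
        if t == "intercept":
            cols[t] = np.ones(n)
        elif t == "group":
            cols[t] = group
        elif t == "age":
            cols[t] = age_c
        elif t == "group_x_age":
            cols[t] = group * age_c
        else:
            cols[t] = keep[t].to_numpy(float)
    x = np.column_stack([cols[t] for t in terms])
    if n < x.shape[1] + 2:
        raise DesignError(f"{n} rows for {x.shape[1]} columns; need n >= p + 2")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the offending columns via QR pivoting on the normal matrix
        _, r = np.linalg.qr(x)
        bad = [terms[i] for i in range(x.shape[1])
               if abs(r[i, i]) < 1e-8 * max(1.0, abs(r[0, 0]))]
        raise DesignError(f"design is rank deficient; collinear columns: {bad}")
    return DesignMatrix(matrix=x, columns=list(terms),
                        subject_ids=list(keep["subject_id"]), dropped_subjects=dropped)


def _as_matrix(maps) -> np.ndarray:
    y = np.asarray(maps, dtype=np.float64)
    if y.ndim != 2:
        raise IntegrityError("maps must form an (n_subjects, n_vertices) array")
    return y


def fit_vertexwise(maps, design: DesignMatrix, contrast) -> dict:
    """Ordinary least squares at every vertex.

    Returns betas (p, V), the contrast t-statistics (V,), two-sided
    uncorrected p-values, residual df, and per-vertex sigma^2.  Vertices with
    zero residual variance get t = +/-inf and are flagged.
    """
    x = design.matrix
    y = _as_matrix(maps)
    if y.shape[0] != design.n:
        raise IntegrityError("one map per design row required")
    c = design.contrast(contrast) if isinstance(contrast, str) else np.asarray(
        contrast, float)
    if c.shape != (design.p,):
        raise DesignError("contrast length does not match design columns")
    pinv = np.linalg.pinv(x)
    beta = pinv @ y
    resid = y - x @ beta
    df = design.n - design.p
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(x.T @ x)
    c_var = float(c @ xtx_inv @ c)
    num = c @ beta
    denom = np.sqrt(c_var * sigma2)
    # residual variance at float rounding level counts as a perfect fit
    zero_var = sigma2 <= 1e-24 * ((y**2).mean(axis=0) + 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_var, np.sign(num) * np.inf, num / np.where(denom > 0, denom, 1.0))
    p_unc = 2.0 * sps.t.sf(np.abs(t), df)
    p_unc = np.where(zero_var, 0.0, p_unc)
    return {"beta": beta, "t": t, "p_uncorrected": p_unc, "df": df,
            "sigma2": sigma2, "zero_variance": zero_var}


def _freedman_lane_tmax(y, x, c, nuisance_idx, perms, t_obs=None):
    """Max |t| per row permutation, Freedman-Lane style.

    Also accumulates, per vertex, how many permutations reach the observed
    |t| at that vertex (the uncorrected permutation count) when ``t_obs`` is
    given.
    """
    n, p = x.shape
    z = x[:, nuisance_idx]
    if z.size:
        hz = z @ np.linalg.pinv(z)
        rz_y = y - hz @ y
    else:
        rz_y = y
    pinv = np.linalg.pinv(x)
    xtx_inv = np.linalg.inv(x.T @ x)
    c_var = float(c @ xtx_inv @ c)
    df = n - p
    tmax = np.empty(len(perms))
    exceed_vertex = None if t_obs is None else np.zeros(y.shape[1])
    abs_obs = None if t_obs is None else np.abs(t_obs)
    for k, perm in enumerate(perms):
        y_star = rz_y[np.asarray(perm)]
        beta = pinv @ y_star
        resid = y_star - x @ beta
        sigma2 = (resid**2).sum(axis=0) / df
        num = c @ beta
        with np.errstate(divide="ignore", invalid="ignore"):
            t = num / np.sqrt(c_var * sigma2)
        tmax[k] = np.nanmax(np.abs(t))
        if exceed_vertex is not None:
            exceed_vertex += np.abs(t) >= abs_obs
    return tmax, exceed_vertex


def permutation_fwe(maps, design: DesignMatrix, contrast, n_perm: int | str = 1000,
                    seed: int = 0) -> dict:
    """FWE-corrected p-values by max-|t| Freedman-Lane permutation.

    Nuisance columns are every design column outside the contrast (excluding
    the intercept-free handling: the contrast column itself is the term of
    interest).  ``n_perm="exhaustive"`` enumerates all row permutations
    (feasible for small n); otherwise ``n_perm`` random permutations are drawn
    and the corrected p is ``(1 + #{perm tmax >= observed |t|}) / (1 + n_perm)``,
    which always counts the identity.  Deterministic given ``seed``.
    """
    x = design.matrix
    y = _as_matrix(maps)
    c = design.contrast(contrast) if isinstance(contrast, str) else np.asarray(
        contrast, float)
    if c.shape != (design.p,):
        raise DesignError("contrast length does not match design columns")
    obs = fit_vertexwise(y, design, c)
    t_obs = obs["t"]
    nuisance_idx = [i for i in range(design.p) if c[i] == 0]
    n = design.n
    if n_perm == "exhaustive":
        perms = [np.asarray(p) for p in itertools.permutations(range(n))]
        tmax, exceed_v = _freedman_lane_tmax(y, x, c, nuisance_idx, perms, t_obs)
        p_fwe = np.array([(tmax >= abs(t)).mean() if np.isfinite(t) else 1.0 / len(perms)
                          for t in t_obs])
        p_perm = exceed_v / len(perms)  # identity is among the enumerated perms
        n_used = len(perms)
    else:
        n_perm = int(n_perm)
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100 (or 'exhaustive')")
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(n_perm)]
        tmax, exceed_v = _freedman_lane_tmax(y, x, c, nuisance_idx, perms, t_obs)
        exceed = (tmax[:, None] >= np.abs(t_obs)[None, :]).sum(axis=0)
        p_fwe = (1.0 + exceed) / (1.0 + n_perm)
        p_perm = (1.0 + exceed_v) / (1.0 + n_perm)
        n_used = n_perm
    p_fwe = np.minimum(p_fwe, 1.0)
    p_perm = np.minimum(p_perm, 1.0)
    return {**obs, "p_fwe": p_fwe, "p_perm": p_perm, "tmax_distribution": tmax,
            "n_perm": n_used, "seed": seed}


@dataclass
class ClusterEffect:
    """Partial R^2 of one model term for a cluster-mean response."""

    cluster_id: int
    term: str
    partial_r2: float
    n_vertices: int


def cluster_effect_size(vertex_set, maps, design: DesignMatrix, term: str,
                        mesh: SurfaceMesh | None = None,
                        cluster_id: int = 0) -> ClusterEffect:
    """Partial R^2 of ``term`` for the (area-weighted) cluster-mean response.

    ``(SSE_reduced - SSE_full) / SSE_reduced`` with the term dropped from the
    reduced model; the response is the mean of the map over the cluster,
    weighted by vertex areas when a mesh is supplied.
    """
    vs = np.asarray(vertex_set, dtype=int)
    if vs.size == 0:
        raise ValueError("cluster vertex set is empty")
    y_all = _as_matrix(maps)
    if mesh is not None:
        w = mesh.vertex_areas()[vs]
        y = (y_all[:, vs] * w).sum(axis=1) / w.sum()
    else:
        y = y_all[:, vs].mean(axis=1)
    x = design.matrix
    j = design.column_index(term)
    x_red = np.delete(x, j, axis=1)

    def sse(xm):
        beta, *_ = np.linalg.lstsq(xm, y, rcond=None)
        r = y - xm @ beta
        return float(r @ r)

    sse_full = sse(x)
    sse_red = sse(x_red)
    r2 = 0.0 if sse_red <= 0 else max(0.0, (sse_red - sse_full) / sse_red)
    return ClusterEffect(cluster_id=cluster_id, term=term, partial_r2=min(r2, 1.0),
                         n_vertices=int(vs.size))


@dataclass
class GLMResult:
    """Vertex-wise statistics plus significant-cluster summaries."""

    design: DesignMatrix
    contrast: str
    t_map: VertexMap
    p_uncorrected: VertexMap
    p_fwe: VertexMap
    clusters: list[OutlierCluster]
    cluster_effects: list[ClusterEffect]
    n_perm: int
    seed: int

    def clusters_frame(self) -> pd.DataFrame:
        rows = []
        for k, (c, e) in enumerate(zip(self.clusters, self.cluster_effects)):
            rows.append({
                "cluster_id": k, "hemisphere": c.hemisphere, "sign": c.sign,
                "area_mm2": c.area, "n_vertices": c.n_vertices,
                "peak_vertex": int(c.vertex_set[np.argmax(
                    np.abs(self.t_map.values[c.vertex_set]))]),
                "peak_abs_t": float(np.abs(self.t_map.values[c.vertex_set]).max()),
                "partial_r2": e.partial_r2,
            })
        cols = ["cluster_id", "hemisphere", "sign", "area_mm2", "n_vertices",
                "peak_vertex", "peak_abs_t", "partial_r2"]
        return pd.DataFrame(rows, columns=cols)


def run_group_glm(maps, mesh: SurfaceMesh, subjects: pd.DataFrame,
                  contrast: str = "group_x_age",
                  terms: tuple[str, ...] = DEFAULT_TERMS,
                  n_perm: int | str = 1000, seed: int = 0,
                  alpha: float = 0.05) -> GLMResult:
    """Fit the vertex-wise GLM, FWE-correct by permutation, summarise clusters.

    Reporting clusters are connected components of FWE-corrected p < alpha
    (signed by the local t direction); each gets a partial R^2 for the tested
    term from the cluster-mean response.
    """
    design = build_design(subjects, terms)
    y = _as_matrix(maps)
    # align map rows with retained design rows
    if y.shape[0] == len(subjects) and design.dropped_subjects:
        keep_idx = [i for i, sid in enumerate(subjects["subject_id"])
                    if sid in set(design.subject_ids)]
        y = y[keep_idx]
    res = permutation_fwe(y, design, contrast, n_perm=n_perm, seed=seed)
    sig = res["p_fwe"] < alpha
    signed = np.where(sig, np.sign(res["t"]) * 3.0, 0.0)  # pseudo-z for clustering
    clusters = threshold_clusters(signed, mesh, z_thresh=3.0, min_area=0.0,
                                  subject_id="group", hemisphere=mesh.hemisphere)
    effects = [
        cluster_effect_size(c.vertex_set, y, design, contrast, mesh=mesh,
                            cluster_id=k)
        for k, c in enumerate(clusters)
    ]
    return GLMResult(
        design=design, contrast=contrast, t_map=VertexMap(res["t"]),
        p_uncorrected=VertexMap(res["p_perm"]),
        p_fwe=VertexMap(res["p_fwe"]), clusters=clusters,
        cluster_effects=effects, n_perm=res["n_perm"], seed=seed,
    )
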