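"""Synthetic cohorts of cortical T1w/T2w-ratio surface maps with ground truth.

The generator emulates the statistical structure the downstream analyses
assume, for a two-group aging cohort (a diagnosis-positive "ASD" group and a
typical-comparison "TC" group, ages 40-70):

* a smooth per-hemisphere base ratio map shared by all subjects;
* spatially correlated Gaussian between-subject noise;
* a linear positive age effect on the ratio;
* sparse subject-specific high/low-ratio patches (Poisson counts, so a
  positive fraction of subjects carries none -- the zero-inflation that the
  load-score statistics must cope with);
* neuropsychological scores whose means are shifted in the diagnosis-positive
  subjects that carry at least one high patch, mirroring the subgroup
  structure the behavioral battery tests.

Every random draw flows from the single ``SimConfig.seed``; regenerating with
the same configuration reproduces the cohort exactly.  Injected patches are
returned as :class:`GroundTruthPatch` records so recovery can be scored.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import (
    SurfaceMesh,
    VertexMap,
    geodesic_distances,
    smoothing_operator,
    write_surface,
    write_vertex_map,
)

__all__ = [
    "SimConfig",
    "GroundTruthPatch",
    "Cohort",
    "simulate_noise_field",
    "inject_patch",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

#: neuropsychological measures carried by every cohort, with the mean/SD of
#: the unaffected base distribution each score is drawn from.  FSIQ follows
#: the comparison-group moments typical of recruited aging samples (~112/12.5),
#: BRIEF GEC is a T score (higher = more dysexecutive symptoms), the DKEFS
#: trail-making (TM) and verbal-fluency (VF) subscores are scaled scores.
PHENOTYPE_BASE: dict[str, tuple[float, float]] = {
    "FSIQ": (112.0, 12.5),
    "BRIEF_GEC": (50.0, 10.0),
    "TM_NS": (11.0, 3.0),
    "TM_LS": (11.0, 3.0),
    "TM_NLS": (11.0, 3.0),
    "VF_LF": (11.0, 3.0),
    "VF_CF": (11.0, 3.0),
    "VF_CS": (11.0, 3.0),
}

#: mean shift applied to affected subjects (diagnosis-positive carriers of at
#: least one high patch).  Signs follow the instruments: lower FSIQ/DKEFS is
#: worse, higher BRIEF is worse.  Magnitudes (about 1.2-1.8 base SDs) are in
#: the range implied by the strong subgroup separations the battery is
#: designed to detect.
PHENOTYPE_SHIFTS: dict[str, float] = {
    "FSIQ": -15.0,
    "BRIEF_GEC": 18.0,
    "TM_NS": -5.0,
    "TM_LS": -5.0,
    "TM_NLS": -5.0,
    "VF_LF": -5.0,
    "VF_CF": -5.0,
    "VF_CS": -5.0,
}


@dataclass
class SimConfig:
    """Knobs of the synthetic cohort.

    Group sizes, age range and the subgroup phenotype structure default to the
    study design the analyses target (30 diagnosis-positive / 36 comparison
    subjects, ages 40-70).  Patch rates default to values calibrated so the
    detected share of outlier-positive subjects reproduces the target design
    (about 64% HR+ and 33% LR+ after imperfect detection).  Ratio-map levels are unitless T1w/T2w.
    """

    seed: int = 0
    n_per_group: tuple[int, int] = (30, 36)  # (ASD, TC)
    age_range: tuple[float, float] = (40.0, 70.0)
    base_level: float = 1.5
    base_fluct_sd: float = 0.10
    base_fluct_fwhm: float = 40.0
    noise_sd: float = 0.05
    noise_fwhm: float = 25.0
    age_slope: float = 0.002  # ratio units per year
    patch_rate_high: float = 1.3   # expected high patches per subject
    patch_rate_low: float = 0.45
    patch_radius_range: tuple[float, float] = (10.0, 20.0)  # geodesic mm
    patch_amplitude_range: tuple[float, float] = (4.0, 6.0)  # in noise-SD units
    patch_taper_frac: float = 0.3
    phenotype_effects: dict[str, float] = field(
        default_factory=lambda: dict(PHENOTYPE_SHIFTS)
    )

    def validate(self) -> None:
        if any(n < 0 for n in self.n_per_group):
            raise ValueError("group sizes must be non-negative")
        if self.noise_sd < 0 or self.base_fluct_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.patch_rate_high < 0 or self.patch_rate_low < 0:
            raise ValueError("patch rates must be non-negative")
        if not (0 <= self.patch_taper_frac <= 1):
            raise ValueError("patch_taper_frac must be in [0, 1]")


@dataclass
class GroundTruthPatch:
    """An injected outlier patch: where it is and how big it truly is."""

    subject_id: str
    hemisphere: str
    seed_vertex: int
    radius: float  # geodesic mm
    amplitude: float  # ratio units, signed
    vertex_set: np.ndarray
    true_area: float  # mm^2

    @property
    def sign(self) -> str:
        return "high" if self.amplitude > 0 else "low"

    def to_json(self) -> dict:
        d = asdict(self)
        d["vertex_set"] = [int(v) for v in self.vertex_set]
        return d


@dataclass
class Cohort:
    """Subject table + per-subject per-hemisphere maps + ground truth."""

    subjects: pd.DataFrame
    maps: dict[str, dict[str, VertexMap]]  # subject_id -> hemisphere -> map
    meshes: dict[str, SurfaceMesh]
    ground_truth: list[GroundTruthPatch] = field(default_factory=list)

    @property
    def hemispheres(self) -> list[str]:
        return sorted(self.meshes)

    def map_matrix(self, hemisphere: str, subject_ids=None) -> np.ndarray:
        """Stack maps for one hemisphere into an (n_subjects, n_vertices) array."""
        ids = list(subject_ids) if subject_ids is not None else list(
            self.subjects["subject_id"]
        )
        return np.vstack([self.maps[s][hemisphere].values for s in ids])


def simulate_noise_field(mesh: SurfaceMesh, sd: float, fwhm: float, seed) -> VertexMap:
    """Smooth Gaussian field with per-vertex SD ``sd`` and correlation ``fwhm``.

    White noise is passed through the surface smoothing operator and
    renormalised by the operator's exact per-vertex row norms, so the marginal
    per-vertex variance is ``sd**2`` regardless of mesh resolution.
    ``seed`` may be an int or an existing :class:`numpy.random.Generator`.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sd == 0:
        # still consume one draw so field sequencing is stable across sd values
        rng.standard_normal(mesh.n_vertices)
        return VertexMap(np.zeros(mesh.n_vertices))
    w = rng.standard_normal(mesh.n_vertices)
    if fwhm <= 0:
        return VertexMap(sd * w)
    op = smoothing_operator(mesh, fwhm)
    norm_key = ("noise_norm", float(fwhm))
    row_norm = mesh._cache.get(norm_key)
    if row_norm is None:
        if isinstance(op, np.ndarray):
            row_norm = np.sqrt((op**2).sum(axis=1))
        else:  # sparse
            sq = op.copy()
            sq.data = sq.data**2
            row_norm = np.sqrt(np.asarray(sq.sum(axis=1)).ravel())
        row_norm[row_norm == 0] = 1.0
        mesh._cache[norm_key] = row_norm
    return VertexMap(sd * (op @ w) / row_norm)


def inject_patch(vmap, mesh: SurfaceMesh, seed_vertex: int, radius: float,
                 amplitude: float, taper_frac: float = 0.3,
                 subject_id: str = "", hemisphere: str = "none"
                 ) -> tuple[VertexMap, GroundTruthPatch]:
    """Add a geodesic-disk offset to a map and return the ground-truth record.

    The profile is flat at ``amplitude`` out to ``(1 - taper_frac) * radius``
    and falls to zero with a raised-cosine taper at ``radius`` (``taper_frac=0``
    gives a flat-topped disk).  Geodesic distance is graph shortest-path over
    mesh edges.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if not (0 <= seed_vertex < mesh.n_vertices):
        raise ValueError("seed_vertex out of range")
    vals = (vmap.values if isinstance(vmap, VertexMap) else np.asarray(vmap, float)).copy()
    d = geodesic_distances(mesh, seed_vertex, limit=radius * 1.001)
    inside = d < radius
    if inside.sum() <= 1:
        warnings.warn(
            "patch radius below the shortest incident edge; degenerates to the "
            "seed vertex", RuntimeWarning, stacklevel=2,
        )
    profile = np.zeros(mesh.n_vertices)
    flat_r = (1.0 - taper_frac) * radius
    din = d[inside]
    prof = np.ones(inside.sum())
    if taper_frac > 0:
        tail = din > flat_r
        prof[tail] = 0.5 * (1.0 + np.cos(np.pi * (din[tail] - flat_r)
                                         / (radius - flat_r)))
    profile[inside] = amplitude * prof
    vals = vals + profile
    if amplitude == 0:
        vertex_set = np.array([], dtype=int)
    else:
        vertex_set = np.flatnonzero(inside)
    true_area = float(mesh.vertex_areas()[vertex_set].sum())
    patch = GroundTruthPatch(
        subject_id=subject_id, hemisphere=hemisphere,
        seed_vertex=int(seed_vertex), radius=float(radius),
        amplitude=float(amplitude), vertex_set=vertex_set, true_area=true_area,
    )
    return VertexMap(vals), patch


def simulate_cohort(config: SimConfig, meshes: SurfaceMesh | dict[str, SurfaceMesh]
                    ) -> Cohort:
    """Draw a full cohort: demographics, phenotypes, maps and injected patches.

    Subject maps are ``base + age_slope * (age - mean age) + noise + patches``.
    Patch counts per subject and hemisphere arm are Poisson, so part of the
    cohort carries no patch at all.  Phenotype shifts are applied to
    diagnosis-positive (ASD) subjects carrying at least one high patch.
    """
    config.validate()
    if isinstance(meshes, SurfaceMesh):
        meshes = {"left": meshes}
    rng = np.random.default_rng(config.seed)
    n_asd, n_tc = config.n_per_group
    n = n_asd + n_tc
    groups = ["ASD"] * n_asd + ["TC"] * n_tc
    ids = [f"sub-{i:03d}" for i in range(n)]

    # --- demographics & covariates -------------------------------------
    lo, hi = config.age_range
    age = rng.uniform(lo, hi, n)
    sex = np.where(rng.random(n) < 0.77, "M", "F")
    pri = rng.normal(108.0, 16.0, n)
    vci = rng.normal(108.0, 18.0, n)
    tbv = rng.normal(1115.0, 100.0, n)  # cm^3
    cnr = rng.normal(1.48, 0.33, n)
    race = np.where(rng.random(n) < 0.87, "White", "non-White")
    ethnicity = np.where(rng.random(n) < 0.09, "Hispanic", "not Hispanic")

    # --- base maps (shared across subjects) ----------------------------
    base_maps = {
        h: config.base_level
        + simulate_noise_field(m, config.base_fluct_sd, config.base_fluct_fwhm,
                               rng).values
        for h, m in meshes.items()
    }
    mean_age = float(age.mean()) if n else 0.0

    # --- subject maps + patches ----------------------------------------
    maps: dict[str, dict[str, VertexMap]] = {}
    ground_truth: list[GroundTruthPatch] = []
    n_high = np.zeros(n, dtype=int)
    n_low = np.zeros(n, dtype=int)
    amp_lo, amp_hi = config.patch_amplitude_range
    rad_lo, rad_hi = config.patch_radius_range
    for i, sid in enumerate(ids):
        maps[sid] = {}
        for h, m in sorted(meshes.items()):
            vals = base_maps[h] + config.age_slope * (age[i] - mean_age)
            vals = vals + simulate_noise_field(m, config.noise_sd,
                                               config.noise_fwhm, rng).values
            k_high = rng.poisson(config.patch_rate_high)
            k_low = rng.poisson(config.patch_rate_low)
            vmap = VertexMap(vals)
            for sign, k in (("high", k_high), ("low", k_low)):
                for _ in range(k):
                    seed_v = int(rng.integers(m.n_vertices))
                    radius = float(rng.uniform(rad_lo, rad_hi))
                    amp = float(rng.uniform(amp_lo, amp_hi)) * config.noise_sd
                    if sign == "low":
                        amp = -amp
                    vmap, patch = inject_patch(
                        vmap, m, seed_v, radius, amp,
                        taper_frac=config.patch_taper_frac,
                        subject_id=sid, hemisphere=h,
                    )
                    ground_truth.append(patch)
            n_high[i] += k_high
            n_low[i] += k_low
            maps[sid][h] = vmap

    # --- phenotypes ------------------------------------------------------
    affected = (np.asarray(groups) == "ASD") & (n_high >= 1)
    pheno: dict[str, np.ndarray] = {}
    for name, (mu, sdev) in PHENOTYPE_BASE.items():
        vals = rng.normal(mu, sdev, n)
        shift = config.phenotype_effects.get(name, 0.0)
        vals = vals + np.where(affected, shift, 0.0)
        pheno[name] = np.round(vals, 1)
    # ADOS scores exist for the diagnosis-positive group only
    ados_total = np.where(np.asarray(groups) == "ASD",
                          np.round(rng.normal(14.0, 4.2, n), 0), np.nan)
    ados_sa = np.where(np.asarray(groups) == "ASD",
                       np.round(rng.normal(10.5, 3.8, n), 0), np.nan)
    ados_rrb = np.where(np.asarray(groups) == "ASD",
                        np.round(rng.normal(3.6, 1.8, n), 0), np.nan)

    subjects = pd.DataFrame(
        {
            "subject_id": ids,
            "group": groups,
            "age": np.round(age, 2),
            "sex": sex,
            "pri": np.round(pri, 1),
            "tbv": np.round(tbv, 1),
            "cnr": np.round(cnr, 3),
            **pheno,
            "ADOS_total": ados_total,
            "ADOS_SA": ados_sa,
            "ADOS_RRB": ados_rrb,
            "vci": np.round(vci, 1),
            "race": race,
            "ethnicity": ethnicity,
            "n_high_patches": n_high,
            "n_low_patches": n_low,
        }
    )
    return Cohort(subjects=subjects, maps=maps, meshes=dict(meshes),
                  ground_truth=ground_truth)


# ---------------------------------------------------------------------------
# On-disk layout
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir, map_format: str = "curv") -> None:
    """Write subjects.tsv, per-subject maps, meshes and ground_truth.json."""
    out = Path(outdir)
    (out / "maps").mkdir(parents=True, exist_ok=True)
    cohort.subjects.to_csv(out / "subjects.tsv", sep="\t", index=False)
    ext = {"curv": "curv", "gifti": "func.gii", "tsv": "tsv"}[map_format]
    for sid, by_hemi in cohort.maps.items():
        for h, vmap in by_hemi.items():
            write_vertex_map(out / "maps" / f"{sid}_hemi-{h}.{ext}", vmap)
    for h, mesh in cohort.meshes.items():
        write_surface(out / f"hemi-{h}.surf", mesh)
    gt = [p.to_json() for p in cohort.ground_truth]
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=1, sort_keys=True)


def read_cohort(indir) -> Cohort:
    """Load a cohort previously written by :func:`write_cohort`."""
    from .mesh import read_surface, read_vertex_map

    ind = Path(indir)
    subjects = pd.read_csv(ind / "subjects.tsv", sep="\t")
    meshes = {}
    for surf in sorted(ind.glob("hemi-*.surf")):
        h = surf.stem.split("hemi-")[1]
        meshes[h] = read_surface(surf, hemisphere=h)
    maps: dict[str, dict[str, VertexMap]] = {}
    for sid in subjects["subject_id"]:
        maps[sid] = {}
        for h in meshes:
            matches = sorted((ind / "maps").glob(f"{sid}_hemi-{h}.*"))
            if not matches:
                raise FileNotFoundError(f"missing map for {sid} hemisphere {h}")
            maps[sid][h] = read_vertex_map(matches[0], mesh=meshes[h])
    ground_truth = []
    gt_path = ind / "ground_truth.json"
    if gt_path.exists():
        with open(gt_path) as fh:
            for d in json.load(fh):
                d["vertex_set"] = np.asarray(d["vertex_set"], dtype=int)
                ground_truth.append(GroundTruthPatch(**d))
    return Cohort(subjects=subjects, maps=maps, meshes=meshes,
                  ground_truth=ground_truth)
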