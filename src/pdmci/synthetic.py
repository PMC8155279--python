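"""Seeded generators for every input modality of the analysis pipeline.

The generators emulate a two-center Parkinson's disease cohort with four
planted cognitive subtypes and optional structural effects, so that every
pipeline stage can be exercised and calibrated without patient data:

* ``gen_cohort`` inverts the level-I subtyping rules: it first chooses
  which domains to impair for each subject (respecting the planted
  subtype), then draws test z-scores from truncated normals so the
  impairment rule fires exactly as planted — failed tests from
  N(-2.2, 0.3) truncated at or below -1.65, passed tests from N(0, 0.8)
  truncated above -1.64 — and back-transforms them to raw scores through
  the normative table.  Re-classifying the output recovers the planted
  labels exactly.
* ``gen_meshes`` builds corresponded surface meshes on a frequency-10
  geodesic icosphere (10 f^2 + 2 = 1002 vertices), adds a smooth
  per-subject deformation field, couples overall size to a lognormal
  intracranial volume, applies a random rigid transform (removed later by
  Procrustes), and can plant an inward patch displacement in selected
  groups.
* ``gen_structure_volume`` draws a spatially smoothed Gaussian intensity
  field inside an ellipsoid mask; a planted kurtosis reduction blends the
  marginal toward a (light-tailed) uniform while preserving mean and SD.
* ``gen_tract_profiles`` produces smooth subject-level FA/MD curves
  (population baseline + low-frequency subject deviation + segment
  noise) with an optional level shift over a planted segment interval.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.ndimage import gaussian_filter

from .exceptions import ValidationError
from .subtyping import (DOMAINS, FRONTAL_DOMAINS, POSTERIOR_DOMAINS,
                        SUBTYPES)

__all__ = [
    "CohortSpec",
    "EffectSpec",
    "default_norms",
    "gen_cohort",
    "icosphere",
    "gen_meshes",
    "mesh_patch",
    "gen_structure_volume",
    "gen_texture_cohort",
    "gen_tract_profiles",
    "gen_streamlines",
]

# ---------------------------------------------------------------------------
# Normative battery
# ---------------------------------------------------------------------------

_NORM_ROWS = [
    # test_id, domain, norm_mean, norm_sd, higher_is_better
    ("digit_span_forward", "attention_wm", 8.5, 2.0, True),
    ("digit_span_backward", "attention_wm", 6.5, 1.8, True),
    ("sdmt", "attention_wm", 50.0, 10.0, True),
    ("tmt_b_time", "executive", 80.0, 30.0, False),
    ("stroop_interference_time", "executive", 55.0, 15.0, False),
    ("stroop_errors", "executive", 1.5, 2.5, False),
    ("phonemic_fluency", "executive", 15.5, 5.0, True),
    ("alternating_fluency", "executive", 15.0, 3.5, True),
    ("hvlt_total_recall", "memory", 26.0, 4.5, True),
    ("hvlt_delayed_recall", "memory", 9.5, 2.5, True),
    ("hvlt_retention", "memory", 90.0, 12.0, True),
    ("hvlt_recognition", "memory", 10.5, 1.3, True),
    ("jlo", "visuospatial", 13.0, 1.8, True),
    ("bnt", "language", 13.8, 1.3, True),
]


def default_norms() -> pd.DataFrame:
    """Normative table for the default synthetic battery.

    Five domains assessed by the usual clinical instruments (digit spans,
    SDMT, TMT-B, Stroop, fluencies, HVLT-R, JLO, BNT); means/SDs are
    field-plausible values for an elderly normative population.  Time and
    error scores are marked higher_is_better = False.
    """
    return pd.DataFrame(
        _NORM_ROWS,
        columns=["test_id", "domain", "norm_mean", "norm_sd",
                 "higher_is_better"],
    )


# ---------------------------------------------------------------------------
# Cohort specification
# ---------------------------------------------------------------------------

def _default_group_sizes():
    return {"PD-NC": 41, "PD-FS": 16, "PD-PC": 25, "PD-MS": 32}


def _default_impairment_probs():
    # Marginal per-domain impairment probabilities within each subtype,
    # matched to the reported impairment frequencies (executive 94% of
    # PD-FS, visuospatial 68% of PD-PC, executive+visuospatial co-impaired
    # in ~78% of PD-MS, encoding/storage deficits in ~32% of PD-PC and MS).
    return {
        "PD-NC": {},
        "PD-FS": {"attention_wm": 0.44, "executive": 0.94},
        "PD-PC": {"visuospatial": 0.68, "memory": 0.32, "language": 0.36},
        "PD-MS": {"attention_wm": 0.55, "executive": 0.92,
                  "visuospatial": 0.85, "memory": 0.31, "language": 0.30},
    }


def _default_covariate_params():
    # Per-group age/education means (SD), male fraction and center mix.
    return {
        "PD-NC": {"age": (63.27, 8.28), "education": (13.56, 4.01),
                  "p_male": 0.805, "p_center": 0.293},
        "PD-FS": {"age": (65.32, 9.48), "education": (14.81, 3.53),
                  "p_male": 0.9375, "p_center": 0.3125},
        "PD-PC": {"age": (64.64, 8.07), "education": (11.80, 2.75),
                  "p_male": 0.60, "p_center": 0.64},
        "PD-MS": {"age": (66.50, 7.78), "education": (10.25, 2.58),
                  "p_male": 0.53, "p_center": 0.6875},
    }


_ALLOWED_DOMAINS = {
    "PD-NC": frozenset(),
    "PD-FS": FRONTAL_DOMAINS,
    "PD-PC": POSTERIOR_DOMAINS,
    "PD-MS": FRONTAL_DOMAINS | POSTERIOR_DOMAINS,
}


@dataclass
class CohortSpec:
    """Planted composition of the synthetic cohort."""

    group_sizes: dict = field(default_factory=_default_group_sizes)
    impairment_probs: dict = field(default_factory=_default_impairment_probs)
    covariate_params: dict = field(default_factory=_default_covariate_params)
    #: chance that a memory-unimpaired subject shows a retrieval deficit
    #: (recall failed, recognition preserved) — does not affect the label.
    retrieval_deficit_prob: float = 0.10
    #: chance of one isolated failed test in an unimpaired multi-test domain.
    stray_failure_prob: float = 0.12
    seed: int = 20230

    def validate(self) -> "CohortSpec":
        for subtype, size in self.group_sizes.items():
            if subtype not in SUBTYPES:
                raise ValidationError(f"unknown subtype {subtype}")
            if size < 0:
                raise ValidationError("group sizes must be >= 0")
        for subtype, probs in self.impairment_probs.items():
            allowed = _ALLOWED_DOMAINS[subtype]
            for domain, p in probs.items():
                if domain not in DOMAINS:
                    raise ValidationError(f"unknown domain {domain}")
                if not 0 <= p <= 1:
                    raise ValidationError("probabilities must be in [0, 1]")
                if p > 0 and domain not in allowed:
                    raise ValidationError(
                        f"{subtype} may not impair {domain}: inconsistent "
                        "with the subtype truth table"
                    )
        return self


@dataclass
class EffectSpec:
    """A plantable group effect in one imaging modality.

    ``size`` is in units of within-group SD for texture/tract/volume
    effects and in millimeters of inward displacement for shape effects.
    For texture the size is the blend weight toward a light-tailed
    marginal (0 = none, 1 = fully uniform).
    """

    modality: str                       # texture | shape | tract | volume
    target: str                         # structure_id or tract_id
    affected_groups: tuple = ("PD-MS",)
    size: float = 0.0
    interval: tuple[int, int] | None = None   # tract segment interval
    patch_center: int = 0               # seed vertex of a mesh patch
    patch_size: int = 100               # number of patch vertices
    feature: str = "kurtosis"           # texture feature targeted

    def __post_init__(self):
        if self.modality not in {"texture", "shape", "tract", "volume"}:
            raise ValidationError(f"unknown modality {self.modality}")
        if self.size < 0:
            raise ValidationError("effect size must be >= 0")


# ---------------------------------------------------------------------------
# Cohort generation (scores + covariates + labels)
# ---------------------------------------------------------------------------

def _truncated(rng, mean, sd, lower=-np.inf, upper=np.inf, size=None):
    a = (lower - mean) / sd
    b = (upper - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                             random_state=rng)


def _failed_z(rng, size=None):
    return _truncated(rng, -2.2, 0.3, upper=-1.65, size=size)


def _passed_z(rng, size=None):
    return _truncated(rng, 0.0, 0.8, lower=-1.64, size=size)


def _draw_impaired_domains(rng, subtype, probs) -> set:
    """Bernoulli draw per domain, resampled until subtype-consistent."""
    allowed = _ALLOWED_DOMAINS[subtype]
    for _ in range(1000):
        impaired = {d for d in allowed if rng.random() < probs.get(d, 0.0)}
        frontal = impaired & FRONTAL_DOMAINS
        posterior = impaired & POSTERIOR_DOMAINS
        if subtype == "PD-NC" and not impaired:
            return impaired
        if subtype == "PD-FS" and frontal and not posterior:
            return impaired
        if subtype == "PD-PC" and posterior and not frontal:
            return impaired
        if subtype == "PD-MS" and frontal and posterior:
            return impaired
    # fall back to the modal pattern for the subtype
    if subtype == "PD-FS":
        return {"executive"}
    if subtype == "PD-PC":
        return {"visuospatial"}
    if subtype == "PD-MS":
        return {"executive", "visuospatial"}
    return set()


def gen_cohort(spec: CohortSpec | None = None, seed: int | None = None
               ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Generate (scores, covariates, planted subtype labels).

    Scores are raw test scores consistent with the normative table from
    :func:`default_norms`; re-running the classifier on them recovers the
    planted labels exactly (the z-score draws are truncated away from the
    -1.645 boundary on both sides).
    """
    spec = (spec or CohortSpec()).validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    norms = default_norms()
    by_domain = {
        d: norms.loc[norms["domain"] == d].to_dict("records") for d in DOMAINS
    }

    score_rows, cov_rows, labels = [], [], []
    sid = 0
    for subtype in SUBTYPES:
        n = spec.group_sizes.get(subtype, 0)
        probs = spec.impairment_probs.get(subtype, {})
        cov = spec.covariate_params[subtype]
        for _ in range(n):
            sid += 1
            subject = f"sub-{sid:03d}"
            impaired = _draw_impaired_domains(rng, subtype, probs)
            z: dict[str, float] = {}
            for domain in DOMAINS:
                tests = by_domain[domain]
                if domain == "memory":
                    z.update(_memory_z(rng, spec, impaired))
                    continue
                ids = [t["test_id"] for t in tests]
                if domain in impaired:
                    n_fail = 2 if len(ids) > 1 else 1
                    n_fail += sum(rng.random() < 0.3
                                  for _ in range(len(ids) - n_fail))
                    failing = set(
                        rng.choice(ids, size=min(n_fail, len(ids)),
                                   replace=False))
                else:
                    failing = set()
                    if (len(ids) > 1
                            and rng.random() < spec.stray_failure_prob):
                        failing = {str(rng.choice(ids))}
                for t in ids:
                    z[t] = float(_failed_z(rng)) if t in failing \
                        else float(_passed_z(rng))
            row = {"subject_id": subject}
            for rec in norms.itertuples(index=False):
                sign = 1.0 if rec.higher_is_better else -1.0
                row[rec.test_id] = (rec.norm_mean
                                    + sign * z[rec.test_id] * rec.norm_sd)
            score_rows.append(row)
            age_m, age_s = cov["age"]
            edu_m, edu_s = cov["education"]
            cov_rows.append({
                "subject_id": subject,
                "age": float(np.clip(rng.normal(age_m, age_s), 40, 90)),
                "sex": int(rng.random() < cov["p_male"]),
                "education": float(np.clip(rng.normal(edu_m, edu_s), 5, 22)),
                "center": int(rng.random() < cov["p_center"]),
            })
            labels.append(subtype)

    scores = pd.DataFrame(score_rows)
    covariates = pd.DataFrame(cov_rows)
    truth = pd.Series(labels, index=scores["subject_id"], name="subtype")
    return scores, covariates, truth


def _memory_z(rng, spec, impaired) -> dict[str, float]:
    """HVLT-R parameter z-scores honoring the planted memory status."""
    z = {}
    if "memory" in impaired:               # encoding/storage: both failed
        z["hvlt_delayed_recall"] = float(_failed_z(rng))
        z["hvlt_recognition"] = float(_failed_z(rng))
        for t in ("hvlt_total_recall", "hvlt_retention"):
            z[t] = float(_failed_z(rng)) if rng.random() < 0.7 \
                else float(_passed_z(rng))
    else:
        z["hvlt_recognition"] = float(_passed_z(rng))
        retrieval = rng.random() < spec.retrieval_deficit_prob
        z["hvlt_delayed_recall"] = float(_failed_z(rng)) if retrieval \
            else float(_passed_z(rng))
        z["hvlt_total_recall"] = float(_passed_z(rng))
        z["hvlt_retention"] = float(_passed_z(rng))
    return z


# ---------------------------------------------------------------------------
# Corresponded meshes (geodesic icosphere)
# ---------------------------------------------------------------------------

def icosphere(frequency: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Geodesic icosphere of the given frequency: 10 f^2 + 2 vertices.

    Each icosahedron face is subdivided into f^2 triangles on a
    barycentric lattice; shared edge/corner points are welded, and all
    vertices are projected to the unit sphere.
    """
    if frequency < 1:
        raise ValidationError("frequency must be >= 1")
    phi = (1 + np.sqrt(5)) / 2
    base = np.array([
        (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
        (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
        (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
    ], dtype=float)
    base /= np.linalg.norm(base[0])
    ico_faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]

    f = frequency
    index: dict[tuple, int] = {}
    verts: list[np.ndarray] = []
    faces: list[tuple[int, int, int]] = []

    def vid(point: np.ndarray) -> int:
        key = tuple(np.round(point, 9))
        if key not in index:
            index[key] = len(verts)
            verts.append(point)
        return index[key]

    for (a, b, c) in ico_faces:
        A, B, C = base[a], base[b], base[c]
        grid = {}
        for i in range(f + 1):
            for j in range(f + 1 - i):
                k = f - i - j
                grid[(i, j)] = vid((i * A + j * B + k * C) / f)
        for i in range(f):
            for j in range(f - i):
                v0, v1, v2 = grid[(i, j)], grid[(i + 1, j)], grid[(i, j + 1)]
                faces.append((v0, v1, v2))
                if j < f - i - 1:
                    faces.append((v1, grid[(i + 1, j + 1)], v2))

    V = np.array(verts)
    V /= np.linalg.norm(V, axis=1, keepdims=True)
    return V, np.array(faces, dtype=np.int64)


def mesh_patch(template: np.ndarray, center_vertex: int,
               n_vertices: int = 100) -> np.ndarray:
    """Indices of the n vertices nearest (Euclidean) to a seed vertex."""
    d = np.linalg.norm(template - template[center_vertex], axis=1)
    return np.argsort(d)[:n_vertices]


def _smooth_vertex_field(rng, adjacency, V, sd, n_smooth=3):
    """Spatially smooth random vertex displacements with unit-SD columns."""
    field = rng.standard_normal((V, 3))
    for _ in range(n_smooth):
        field = 0.5 * field + 0.5 * adjacency @ field
    field = (field - field.mean(axis=0)) / field.std(axis=0)
    return field * sd


def _adjacency_matrix(faces, V):
    from scipy import sparse
    rows = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2],
                           faces[:, 1], faces[:, 2], faces[:, 0]])
    cols = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0],
                           faces[:, 0], faces[:, 1], faces[:, 2]])
    A = sparse.coo_matrix((np.ones(rows.size), (rows, cols)),
                          shape=(V, V)).tocsr()
    A.data[:] = 1.0                      # dedupe to binary
    inv_deg = 1.0 / np.asarray(A.sum(axis=1)).ravel()
    return sparse.diags(inv_deg) @ A


def gen_meshes(labels, effect: EffectSpec | None = None,
               seed: int = 0, frequency: int = 10,
               radii=(12.0, 8.0, 6.0), noise_sd: float = 0.3,
               icv_mean: float = 1.5e6, icv_sigma: float = 0.08,
               rigid_jitter: bool = True,
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Corresponded per-subject meshes of one subcortical structure.

    Returns (vertices (m, V, 3) in mm, shared faces, icv (m,) in mm^3).
    The template is an ellipsoid sampled on a geodesic icosphere; each
    subject adds a smooth random deformation field (SD ``noise_sd`` mm
    per coordinate), scales with the cube root of its lognormal ICV, and
    (optionally) receives a random rigid transform.  A shape effect
    displaces a patch of vertices inward along the template normal by
    ``effect.size`` mm in the affected groups.
    """
    labels = np.asarray(labels)
    m = len(labels)
    rng = np.random.default_rng(seed)
    sphere, faces = icosphere(frequency)
    template = sphere * np.asarray(radii)
    V = template.shape[0]
    adjacency = _adjacency_matrix(faces, V)
    normals = template / np.linalg.norm(template, axis=1, keepdims=True)

    patch = None
    if effect is not None and effect.modality == "shape" and effect.size > 0:
        patch = mesh_patch(template, effect.patch_center, effect.patch_size)

    icv = icv_mean * np.exp(rng.normal(0.0, icv_sigma, size=m)
                            - icv_sigma**2 / 2)
    out = np.empty((m, V, 3))
    for i in range(m):
        v = template + _smooth_vertex_field(rng, adjacency, V, noise_sd)
        if patch is not None and labels[i] in effect.affected_groups:
            v[patch] -= effect.size * normals[patch]
        v *= (icv[i] / icv_mean) ** (1 / 3)
        if rigid_jitter:
            v = _random_rigid(rng, v)
        out[i] = v
    return out, faces, icv


def _random_rigid(rng, v):
    angle = rng.uniform(0, np.pi / 18)       # up to 10 degrees
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    t = rng.uniform(-5, 5, size=3)
    return v @ R.T + t


# ---------------------------------------------------------------------------
# Texture volumes
# ---------------------------------------------------------------------------

def gen_structure_volume(seed: int, shape=(24, 28, 22), radii=(9.0, 11.0, 8.0),
                         blend: float = 0.0, smooth_sigma: float = 1.2,
                         base_intensity: float = 100.0,
                         intensity_sd: float = 10.0,
                         mean_jitter: float = 2.0,
                         sd_jitter: float = 0.05,
                         structure_id: str = "structure"):
    """One subject's masked intensity volume with a controllable marginal.

    Intensities are a smoothed Gaussian random field standardized inside
    an ellipsoid mask.  ``blend`` in [0, 1] mixes the (approximately
    normal, kurtosis 3) marginal toward a light-tailed uniform marginal
    (kurtosis 1.8) through the rank-preserving map
    y = (1 - blend) z + blend sqrt(12) (Phi(z) - 1/2), then re-standardizes,
    so mean and SD are unchanged while kurtosis decreases with ``blend``.
    """
    from .texture import MaskedVolume

    if not 0 <= blend <= 1:
        raise ValidationError("blend must be in [0, 1]")
    rng = np.random.default_rng(seed)
    # subject-level global intensity offset/scale (scanner & tissue drift)
    subject_mean = base_intensity + rng.normal(0.0, mean_jitter)
    subject_sd = intensity_sd * np.exp(rng.normal(0.0, sd_jitter))
    grid = np.indices(shape).astype(float)
    center = (np.asarray(shape) - 1) / 2.0
    r = np.asarray(radii)
    mask = np.sum(((grid - center[:, None, None, None])
                   / r[:, None, None, None]) ** 2, axis=0) <= 1.0

    fieldv = gaussian_filter(rng.standard_normal(shape), smooth_sigma)
    z = (fieldv - fieldv[mask].mean()) / fieldv[mask].std()
    y = (1 - blend) * z + blend * np.sqrt(12.0) * (sps.norm.cdf(z) - 0.5)
    y = (y - y[mask].mean()) / y[mask].std()
    vol = subject_mean + subject_sd * y
    return MaskedVolume(intensities=vol, mask=mask,
                        structure_id=structure_id)


def gen_texture_cohort(labels, structures=("right_hippocampus",
                                           "left_caudate"),
                       effect: EffectSpec | None = None, seed: int = 0,
                       **volume_kwargs) -> pd.DataFrame:
    """Tidy texture-feature table for a cohort of synthetic volumes.

    A texture effect applies its blend weight (``effect.size``) to the
    target structure of subjects in the affected groups.  Columns:
    subject_id, structure_id, feature, value.
    """
    from .texture import texture_features

    labels = pd.Series(np.asarray(labels),
                       index=[f"sub-{i + 1:03d}" for i in range(len(labels))]
                       if not isinstance(labels, pd.Series) else labels.index)
    rng = np.random.default_rng(seed)
    rows = []
    for subject, grp in labels.items():
        for structure in structures:
            blend = 0.0
            if (effect is not None and effect.modality == "texture"
                    and structure == effect.target
                    and grp in effect.affected_groups):
                blend = effect.size
            vol = gen_structure_volume(
                seed=int(rng.integers(2**31)), blend=blend,
                structure_id=structure, **volume_kwargs)
            for feature, value in texture_features(vol).items():
                rows.append({"subject_id": subject, "structure_id": structure,
                             "feature": feature, "value": value})
    return pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# Tract profiles and streamlines
# ---------------------------------------------------------------------------

_METRIC_DEFAULTS = {
    # level/wobble set the population baseline curve; sd_within is the
    # nominal within-group SD and the unit of planted effect sizes.  The
    # within-subject variance splits into a subject offset (0.4 sd),
    # three low-frequency harmonics (~0.33 sd combined) and independent
    # segment noise (0.67 sd): segment noise dominates, so segment-wise
    # null p-values are only moderately dependent along the tract.
    "FA": dict(level=0.45, wobble=0.05, sd_within=0.03, lo=0.01, hi=0.99),
    "MD": dict(level=7.0e-4, wobble=0.8e-4, sd_within=0.5e-4,
               lo=3.0e-4, hi=1.2e-3),
}


def gen_tract_profiles(labels, metric: str = "FA", S: int = 100,
                       effect: EffectSpec | None = None, seed: int = 0,
                       ) -> np.ndarray:
    """Along-tract metric profiles (n_subjects, S) for one tract.

    Each subject's curve is a smooth population baseline plus a subject
    offset, a low-frequency random deviation and segment noise.  A tract
    effect shifts the affected groups by ``effect.size`` within-group SD
    over ``effect.interval`` (FA down, MD up).  FA stays in [0, 1].
    """
    if metric not in _METRIC_DEFAULTS:
        raise ValidationError("metric must be 'FA' or 'MD'")
    pars = _METRIC_DEFAULTS[metric]
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, S)
    baseline = (pars["level"] + pars["wobble"] * np.sin(np.pi * t)
                + 0.4 * pars["wobble"] * np.cos(3 * np.pi * t))
    out = np.empty((len(labels), S))
    sd = pars["sd_within"]
    for i, grp in enumerate(labels):
        offset = rng.normal(0.0, 0.4 * sd)
        lowfreq = sum(
            rng.normal(0.0, 0.27 * sd)
            * np.sin(k * np.pi * t + rng.uniform(0, 2 * np.pi))
            for k in (1, 2, 3)
        )
        curve = baseline + offset + lowfreq \
            + rng.normal(0.0, 0.67 * sd, size=S)
        if (effect is not None and effect.modality == "tract"
                and effect.size > 0 and effect.interval is not None
                and grp in effect.affected_groups):
            a, b = effect.interval
            shift = effect.size * pars["sd_within"]
            sign = -1.0 if metric == "FA" else 1.0
            curve[a:b + 1] += sign * shift
        out[i] = np.clip(curve, pars["lo"], pars["hi"])
    return out


def gen_streamlines(n_lines: int = 20, length: float = 80.0,
                    spacing: float = 1.0, jitter: float = 0.5,
                    seed: int = 0) -> list[np.ndarray]:
    """Nearly parallel streamlines along +x, for exercising the sampler."""
    rng = np.random.default_rng(seed)
    lines = []
    x = np.linspace(0.0, length, int(length / spacing) + 1)
    for _ in range(n_lines):
        y0, z0 = rng.uniform(-2, 2, size=2)
        y = y0 + rng.normal(0, jitter / 4, size=x.size).cumsum() * 0.05
        z = z0 + rng.normal(0, jitter / 4, size=x.size).cumsum() * 0.05
        lines.append(np.column_stack([x, y, z]))
    return lines
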