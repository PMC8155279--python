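"""End-to-end orchestration: subtype, then per-modality statistics.

``run_full_analysis`` drives the whole chain on a :class:`DataBundle`
(in memory, real or simulated): level-I subtyping, ICV-normalized
volumetry, vertex-wise shape statistics with deformation fields, texture
feature selection and group tests, along-tract cluster statistics with
post hocs, and partial Spearman brain–cognition correlations.  Subjects
missing a modality are dropped from that modality's analysis only; the
report is a JSON-serializable nested dict echoing the configuration, so
a run is reproducible from its own output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import io as pio
from . import shape_stats, subtyping, texture, tractometry
from .exceptions import PdmciError, ValidationError
from .stats_core import (bh_fdr, pairwise_posthoc, partial_spearman,
                         permutation_group_test)
from .synthetic import (CohortSpec, EffectSpec, default_norms, gen_cohort,
                        gen_meshes, gen_texture_cohort, gen_tract_profiles)

log = logging.getLogger("pdmci")

__all__ = ["RunConfig", "DataBundle", "simulate_bundle", "run_full_analysis"]


@dataclass
class RunConfig:
    n_perm: int = 10_000
    fdr_alpha: float = 0.05
    min_cluster: int = 5
    z_cutoff: float = -1.645
    n_levels: int = 32
    seed: int = 0
    shape_response: str = "xyz"

    def __post_init__(self):
        if not 0 < self.fdr_alpha < 1:
            raise ValidationError("fdr_alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValidationError("n_perm must be >= 100")


@dataclass
class DataBundle:
    """All pipeline inputs, keyed by subject_id per modality."""

    scores: pd.DataFrame
    norms: pd.DataFrame
    covariates: pd.DataFrame
    #: tidy (subject_id, structure_id, feature, value)
    texture_features: pd.DataFrame | None = None
    #: structure_id -> dict(subject_ids, vertices (m, V, 3), faces, icv (m,))
    meshes: dict = field(default_factory=dict)
    #: (tract_id, metric) -> dict(subject_ids, profiles (m, S))
    profiles: dict = field(default_factory=dict)


def simulate_bundle(spec: CohortSpec | None = None,
                    effects: list[EffectSpec] | None = None,
                    seed: int = 0,
                    mesh_structures=("right_hippocampus",),
                    texture_structures=("right_hippocampus", "left_caudate"),
                    tracts=(("right_ifof", "FA"), ("isthmus_pt", "MD")),
                    n_segments: int = 100) -> DataBundle:
    """Generate a full synthetic bundle (all modalities, planted truths)."""
    effects = effects or []
    spec = spec or CohortSpec(seed=seed)
    scores, covariates, labels = gen_cohort(spec, seed=seed)
    subject_ids = list(scores["subject_id"])

    bundle = DataBundle(scores=scores, norms=default_norms(),
                        covariates=covariates)

    tex_effect = next((e for e in effects if e.modality == "texture"), None)
    bundle.texture_features = gen_texture_cohort(
        pd.Series(labels.to_numpy(), index=subject_ids),
        structures=texture_structures, effect=tex_effect, seed=seed + 1)

    for s_idx, structure in enumerate(mesh_structures):
        eff = next((e for e in effects
                    if e.modality == "shape" and e.target == structure), None)
        verts, faces, icv = gen_meshes(labels.to_numpy(), effect=eff,
                                       seed=seed + 10 + s_idx)
        bundle.meshes[structure] = dict(subject_ids=subject_ids,
                                        vertices=verts, faces=faces, icv=icv)

    for t_idx, (tract_id, metric) in enumerate(tracts):
        eff = next((e for e in effects
                    if e.modality == "tract" and e.target == tract_id), None)
        profiles = gen_tract_profiles(labels.to_numpy(), metric=metric,
                                      S=n_segments, effect=eff,
                                      seed=seed + 100 + t_idx)
        bundle.profiles[(tract_id, metric)] = dict(subject_ids=subject_ids,
                                                   profiles=profiles)
    return bundle


def _aligned_covariates(covariates: pd.DataFrame, subject_ids) -> pd.DataFrame:
    cov = covariates.set_index("subject_id").loc[list(subject_ids)]
    return cov.reset_index()


def _stat_record(res) -> dict:
    return {"statistic": res.statistic, "p_raw": res.p_raw,
            "p_fdr": res.p_fdr, "label": res.label}


def run_full_analysis(bundle: DataBundle, config: RunConfig | None = None
                      ) -> dict:
    """Run every analysis stage and return the structured report."""
    config = config or RunConfig()
    report: dict = {"config": asdict(config), "stages": {}}

    # ---- 1. subtyping ----------------------------------------------------
    subtypes = subtyping.classify_table(bundle.scores, bundle.norms,
                                        cutoff=config.z_cutoff)
    subtypes["code"] = subtypes["subtype"].map(subtyping.SUBTYPE_CODES)
    counts = subtypes["subtype"].value_counts().reindex(
        subtyping.SUBTYPES, fill_value=0)
    domain_freq = {
        st: subtypes.loc[subtypes["subtype"] == st, list(subtyping.DOMAINS)]
        .mean().round(4).to_dict()
        for st in subtyping.SUBTYPES if (subtypes["subtype"] == st).any()
    }
    domain_z = subtyping.domain_z_summary(bundle.scores, bundle.norms)
    report["stages"]["subtyping"] = {
        "table": subtypes, "counts": counts.to_dict(),
        "impairment_frequencies": domain_freq,
    }
    label_of = subtypes.set_index("subject_id")["subtype"]
    code_of = subtypes.set_index("subject_id")["code"]

    # ---- 2 & 3. shape + volumetry ---------------------------------------
    shape_report, volumetry = {}, {}
    for structure, data in bundle.meshes.items():
        try:
            shape_report[structure], volumetry[structure] = _shape_stage(
                data, label_of, bundle.covariates, domain_z, config)
        except PdmciError as exc:          # keep going past a failed stage
            log.warning("shape stage failed for %s: %s", structure, exc)
            shape_report[structure] = {"error": str(exc)}
    report["stages"]["shape"] = shape_report
    report["stages"]["volumetry"] = volumetry

    # ---- 4. texture ------------------------------------------------------
    if bundle.texture_features is not None:
        report["stages"]["texture"] = _texture_stage(
            bundle.texture_features, label_of, code_of, bundle.covariates,
            domain_z, config)

    # ---- 5. tractometry --------------------------------------------------
    tract_report = {}
    for (tract_id, metric), data in bundle.profiles.items():
        tract_report[f"{tract_id}/{metric}"] = _tract_stage(
            tract_id, metric, data, label_of, bundle.covariates, domain_z,
            config)
    report["stages"]["tractometry"] = tract_report

    return report


def _shape_stage(data, label_of, covariates, domain_z, config):
    ids = [s for s in data["subject_ids"] if s in label_of.index]
    idx = [data["subject_ids"].index(s) for s in ids]
    verts = np.asarray(data["vertices"])[idx]
    icv = np.asarray(data["icv"])[idx]
    groups = label_of.loc[ids].to_numpy()
    cov = _aligned_covariates(covariates, ids)

    ref_icv = float(icv.mean())
    scaled = np.stack([
        shape_stats.icv_scale(verts[i], icv[i], ref_icv)
        for i in range(len(ids))
    ])
    aligned, template = shape_stats.procrustes_align(scaled)
    vmap = shape_stats.vertexwise_group_test(
        aligned, groups, cov, n_perm=config.n_perm, seed=config.seed,
        alpha=config.fdr_alpha, response=config.shape_response)

    fields = {}
    levels = [s for s in subtyping.SUBTYPES if s in set(groups)]
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            f = shape_stats.deformation_field(aligned, groups, a, b)
            fields[f"{a}/{b}"] = {
                "mean_magnitude_significant": float(
                    f.magnitude[vmap.significant].mean())
                if vmap.significant.size else 0.0,
            }

    distances = np.array([
        shape_stats.mean_distance_to_template(aligned[i], template)
        for i in range(len(ids))
    ])
    correlations = _correlate_with_cognition(
        pd.Series(distances, index=ids), domain_z, covariates)

    shape_rep = {
        "n_subjects": len(ids),
        "n_significant_vertices": int(vmap.significant.size),
        "significant_fraction": float(vmap.significant.size
                                      / vmap.p_fdr.size),
        "p_fdr_min": float(vmap.p_fdr.min()),
        "significant_vertices": vmap.significant,
        "deformation_fields": fields,
        "mean_distance_correlations": correlations,
    }

    volumes = np.array([
        pio.mesh_volume(verts[i], data["faces"]) for i in range(len(ids))
    ])
    normalized = volumes / icv
    omni = permutation_group_test(normalized, groups, cov,
                                  n_perm=config.n_perm, seed=config.seed)
    vol_rep = {"omnibus": _stat_record(omni)}
    if omni.p_raw < config.fdr_alpha:
        vol_rep["posthoc"] = [
            _stat_record(r) for r in pairwise_posthoc(
                normalized, groups, cov, n_perm=config.n_perm,
                seed=config.seed)
        ]
    return shape_rep, vol_rep


def _texture_stage(features, label_of, code_of, covariates, domain_z, config):
    ids = sorted(set(features["subject_id"]) & set(label_of.index))
    feats = features[features["subject_id"].isin(ids)]
    selection = texture.select_features(feats, code_of.loc[ids],
                                        alpha=config.fdr_alpha)
    selected = selection[selection["selected"]]

    wide = feats.pivot_table(index="subject_id", columns=["structure_id",
                                                          "feature"],
                             values="value").loc[ids]
    groups = label_of.loc[ids].to_numpy()
    cov = _aligned_covariates(covariates, ids)

    tests, correlations = [], {}
    for row in selected.itertuples(index=False):
        vals = wide[(row.structure_id, row.feature)].to_numpy(dtype=float)
        res = permutation_group_test(vals, groups, cov,
                                     n_perm=config.n_perm, seed=config.seed)
        tests.append({"structure_id": row.structure_id,
                      "feature": row.feature, **_stat_record(res)})
    if tests:
        adj = bh_fdr([t["p_raw"] for t in tests])
        for t, a in zip(tests, adj):
            t["p_fdr"] = float(a)
        for t in tests:
            if t["p_fdr"] < config.fdr_alpha:
                vals = wide[(t["structure_id"], t["feature"])] \
                    .to_numpy(dtype=float)
                t["posthoc"] = [
                    _stat_record(r) for r in pairwise_posthoc(
                        vals, groups, cov, n_perm=config.n_perm,
                        seed=config.seed)
                ]
                key = f"{t['structure_id']}/{t['feature']}"
                correlations[key] = _correlate_with_cognition(
                    wide[(t["structure_id"], t["feature"])], domain_z,
                    covariates)
    return {"selection": selection, "group_tests": tests,
            "correlations": correlations}


def _tract_stage(tract_id, metric, data, label_of, covariates, domain_z,
                 config):
    ids = [s for s in data["subject_ids"] if s in label_of.index]
    idx = [data["subject_ids"].index(s) for s in ids]
    profiles = np.asarray(data["profiles"])[idx]
    groups = label_of.loc[ids].to_numpy()
    cov = _aligned_covariates(covariates, ids)

    means = profiles.mean(axis=1)
    whole = permutation_group_test(means, groups, cov,
                                   n_perm=config.n_perm, seed=config.seed)

    stat, p_raw, p_fdr = tractometry.segmentwise_test(
        profiles, groups, cov, n_perm=config.n_perm, seed=config.seed)
    clusters = tractometry.significant_clusters(
        p_fdr < config.fdr_alpha, min_len=config.min_cluster)

    cluster_rows = []
    for c in clusters:
        cmeans = profiles[:, c.start:c.end + 1].mean(axis=1)
        row = {"tract_id": tract_id, "metric": metric,
               "start": c.start, "end": c.end, "k": c.size}
        for g in subtyping.SUBTYPES:
            sel = groups == g
            if sel.any():
                row[f"{g}_mean"] = float(cmeans[sel].mean())
                row[f"{g}_sd"] = float(cmeans[sel].std(ddof=1))
        row["posthoc"] = [
            _stat_record(r) for r in tractometry.cluster_posthoc(
                profiles, c, groups, cov, n_perm=config.n_perm,
                seed=config.seed)
        ]
        cluster_rows.append(row)

    correlations = _correlate_with_cognition(
        pd.Series(means, index=ids), domain_z, covariates)
    return {
        "n_subjects": len(ids),
        "whole_tract": _stat_record(whole),
        "n_significant_segments": int(np.sum(p_fdr < config.fdr_alpha)),
        "clusters": cluster_rows,
        "whole_tract_correlations": correlations,
    }


def _correlate_with_cognition(values: pd.Series, domain_z: pd.DataFrame,
                              covariates: pd.DataFrame) -> dict:
    """Partial Spearman of one MRI measure vs the five domain z-means.

    FDR is applied across the five domains (one family per measure).
    """
    dz = domain_z.set_index("subject_id")
    ids = [s for s in values.index if s in dz.index]
    cov = _aligned_covariates(covariates, ids)
    out, ps = {}, []
    for domain in subtyping.DOMAINS:
        pc = partial_spearman(values.loc[ids].to_numpy(dtype=float),
                              dz.loc[ids, domain].to_numpy(dtype=float), cov)
        out[domain] = {"rho": pc.rho, "p_raw": pc.p_raw, "n": pc.n}
        ps.append(pc.p_raw)
    for domain, a in zip(subtyping.DOMAINS, bh_fdr(ps)):
        out[domain]["p_fdr"] = float(a)
    return out
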