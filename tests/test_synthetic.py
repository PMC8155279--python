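"""Generator contracts: determinism, geometry, planted-truth round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pdmci.exceptions import ValidationError
from pdmci.subtyping import classify_table
from pdmci.synthetic import (CohortSpec, EffectSpec, default_norms,
                             gen_cohort, gen_meshes, gen_structure_volume,
                             gen_tract_profiles, icosphere, mesh_patch)


class TestGenCohort:
    def test_seeded_rerun_is_identical(self):
        a = gen_cohort(CohortSpec(seed=3))
        b = gen_cohort(CohortSpec(seed=3))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        pd.testing.assert_series_equal(a[2], b[2])

    def test_default_cohort_round_trip_exact(self):
        scores, cov, truth = gen_cohort(CohortSpec(seed=0))
        out = classify_table(scores, default_norms())
        assert (out.set_index("subject_id")["subtype"] == truth).all()
        assert truth.value_counts().to_dict() == {
            "PD-NC": 41, "PD-MS": 32, "PD-PC": 25, "PD-FS": 16}

    def test_zero_impairment_probabilities_give_all_normal(self):
        spec = CohortSpec(
            group_sizes={"PD-NC": 10},
            impairment_probs={"PD-NC": {}}, seed=1)
        scores, _, truth = gen_cohort(spec)
        assert (truth == "PD-NC").all()

    def test_inconsistent_spec_rejected(self):
        spec = CohortSpec(impairment_probs={
            "PD-FS": {"visuospatial": 0.5}})    # posterior domain in PD-FS
        with pytest.raises(ValidationError):
            gen_cohort(spec)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        n_nc=st.integers(0, 8), n_fs=st.integers(1, 8),
        n_pc=st.integers(1, 8), n_ms=st.integers(1, 8),
        p_att=st.floats(0, 1), p_vis=st.floats(0.1, 1),
        seed=st.integers(0, 2**20),
    )
    def test_round_trip_over_random_specs(self, n_nc, n_fs, n_pc, n_ms,
                                          p_att, p_vis, seed):
        """Any consistent spec must be recovered label-for-label."""
        spec = CohortSpec(
            group_sizes={"PD-NC": n_nc, "PD-FS": n_fs, "PD-PC": n_pc,
                         "PD-MS": n_ms},
            impairment_probs={
                "PD-NC": {},
                "PD-FS": {"attention_wm": p_att, "executive": 0.9},
                "PD-PC": {"visuospatial": p_vis, "memory": 0.3},
                "PD-MS": {"executive": 0.9, "visuospatial": p_vis},
            },
            seed=seed,
        )
        scores, _, truth = gen_cohort(spec)
        out = classify_table(scores, default_norms())
        assert (out.set_index("subject_id")["subtype"] == truth).all()


class TestIcosphere:
    @pytest.mark.parametrize("f", [1, 2, 4, 10])
    def test_vertex_and_face_counts(self, f):
        verts, faces = icosphere(f)
        assert verts.shape == (10 * f**2 + 2, 3)
        assert faces.shape == (20 * f**2, 3)

    def test_vertices_on_unit_sphere(self):
        verts, _ = icosphere(5)
        assert np.allclose(np.linalg.norm(verts, axis=1), 1.0)

    def test_faces_index_all_vertices(self):
        verts, faces = icosphere(3)
        assert set(faces.ravel()) == set(range(len(verts)))


class TestGenMeshes:
    def test_noise_free_cohort_is_the_template(self):
        labels = np.array(["PD-NC"] * 3)
        verts, faces, icv = gen_meshes(labels, seed=0, noise_sd=0.0,
                                       icv_sigma=0.0, rigid_jitter=False)
        assert np.allclose(verts[0], verts[1])
        assert np.allclose(verts[0], verts[2])

    def test_seeded_rerun_identical(self):
        labels = np.array(["PD-NC", "PD-MS"] * 3)
        a = gen_meshes(labels, seed=4)
        b = gen_meshes(labels, seed=4)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[2], b[2])

    def test_planted_patch_displaces_affected_group_inward(self):
        labels = np.array(["PD-NC"] * 6 + ["PD-MS"] * 6)
        eff = EffectSpec(modality="shape", target="s",
                         affected_groups=("PD-MS",), size=2.0)
        verts, faces, icv = gen_meshes(labels, effect=eff, seed=5,
                                       noise_sd=0.05, icv_sigma=0.0,
                                       rigid_jitter=False)
        template = icosphere(10)[0] * np.array([12.0, 8.0, 6.0])
        patch = mesh_patch(template, 0, 100)
        radii_nc = np.linalg.norm(verts[:6][:, patch], axis=2).mean()
        radii_ms = np.linalg.norm(verts[6:][:, patch], axis=2).mean()
        assert radii_nc - radii_ms > 1.0


class TestGenStructureVolume:
    def test_mask_matches_analytic_ellipsoid_volume(self):
        vol = gen_structure_volume(seed=0, shape=(40, 44, 38),
                                   radii=(15.0, 17.0, 14.0))
        analytic = 4 / 3 * np.pi * 15 * 17 * 14
        assert vol.mask.sum() == pytest.approx(analytic, rel=0.01)

    def test_blend_lowers_kurtosis_but_not_mean_sd(self):
        from pdmci.texture import first_order_features
        k0, k1 = [], []
        for seed in range(5):
            f0 = first_order_features(gen_structure_volume(seed=seed))
            f1 = first_order_features(gen_structure_volume(seed=seed,
                                                           blend=0.7))
            assert f1["mean"] == pytest.approx(f0["mean"], abs=1e-6)
            assert f1["sd"] == pytest.approx(f0["sd"], abs=1e-6)
            k0.append(f0["kurtosis"])
            k1.append(f1["kurtosis"])
        assert np.mean(k0) - np.mean(k1) > 0.5

    def test_invalid_blend_rejected(self):
        with pytest.raises(ValidationError):
            gen_structure_volume(seed=0, blend=1.5)


class TestGenTractProfiles:
    def test_fa_stays_in_unit_interval_even_with_huge_effect(self):
        labels = np.repeat(["PD-NC", "PD-MS"], 10)
        eff = EffectSpec(modality="tract", target="t",
                         affected_groups=("PD-MS",), size=50.0,
                         interval=(10, 40))
        prof = gen_tract_profiles(labels, effect=eff, seed=0)
        assert prof.min() >= 0.0 and prof.max() <= 1.0

    def test_md_magnitude_is_physiological(self):
        labels = np.repeat(["PD-NC"], 8)
        prof = gen_tract_profiles(labels, metric="MD", seed=1)
        assert prof.min() > 1e-4 and prof.max() < 2e-3

    def test_planted_interval_shifts_affected_group_only(self):
        labels = np.repeat(["PD-NC", "PD-PC"], 30)
        eff = EffectSpec(modality="tract", target="t",
                         affected_groups=("PD-PC",), size=2.0,
                         interval=(40, 54))
        prof = gen_tract_profiles(labels, effect=eff, seed=2)
        nc, pc = prof[:30], prof[30:]
        inside = slice(40, 55)
        outside = list(range(0, 40)) + list(range(55, 100))
        assert (nc[:, inside].mean() - pc[:, inside].mean()) > 0.04
        assert abs(nc[:, outside].mean() - pc[:, outside].mean()) < 0.02

    def test_seeded_rerun_identical(self):
        labels = np.repeat(["PD-NC"], 5)
        assert np.array_equal(gen_tract_profiles(labels, seed=3),
                              gen_tract_profiles(labels, seed=3))
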