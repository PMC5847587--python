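"""Artifact detection, interpolation, nuisance regression, CompCor PCA,
discrete-cosine high-pass, and the fixed preparation pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from devfmri.acquisition import AcquisitionParams, ConfigurationError
from devfmri.prep import (
    ArtifactMask,
    InputError,
    PrepOptions,
    composite_motion,
    detect_artifact_timepoints,
    highpass_filter,
    interpolate_artifacts,
    noise_components,
    prepare_roi_timecourses,
    regress_nuisance,
    subject_passes_exclusion,
)
from devfmri.rois import default_roi_table


class TestArtifactDetection:
    def test_motion_step_rule(self):
        mask = detect_artifact_timepoints(
            np.array([0.0, 2.5, 0.1]), np.ones(3)
        )
        assert list(mask.flagged_trs) == [2]

    def test_clean_run_has_no_flags(self):
        mask = detect_artifact_timepoints(np.zeros(20), np.ones(20))
        assert mask.n_flagged == 0

    def test_global_signal_excursion_flagged(self):
        gs = np.zeros(100)
        gs[40] = 5.0
        mask = detect_artifact_timepoints(np.zeros(100), gs)
        assert list(mask.flagged_trs) == [41]

    def test_length_mismatch_raises(self):
        with pytest.raises(InputError):
            detect_artifact_timepoints(np.zeros(5), np.zeros(6))


class TestExclusionRule:
    @pytest.mark.parametrize(
        "n_flagged,passes", [(56, False), (55, True), (0, True), (168, False)]
    )
    def test_one_third_boundary(self, acq, n_flagged, passes):
        flags = np.zeros(168, dtype=bool)
        flags[:n_flagged] = True
        assert subject_passes_exclusion(ArtifactMask(flags), acq) is passes


class TestInterpolation:
    def test_no_flags_is_identity(self, rng):
        tc = rng.normal(size=30)
        mask = ArtifactMask(np.zeros(30, dtype=bool))
        assert np.array_equal(interpolate_artifacts(tc, mask), tc)

    def test_equidistant_tie_takes_preceding(self):
        tc = np.array([1.0, 99.0, 3.0])
        mask = ArtifactMask(np.array([False, True, False]))
        assert interpolate_artifacts(tc, mask)[1] == 1.0

    def test_leading_flag_takes_first_unflagged(self):
        tc = np.array([99.0, 99.0, 5.0, 6.0])
        mask = ArtifactMask(np.array([True, True, False, False]))
        out = interpolate_artifacts(tc, mask)
        assert out[0] == 5.0 and out[1] == 5.0

    def test_trailing_flag_takes_last_unflagged(self):
        tc = np.array([1.0, 2.0, 99.0])
        mask = ArtifactMask(np.array([False, False, True]))
        assert interpolate_artifacts(tc, mask)[2] == 2.0

    def test_all_flagged_raises(self):
        with pytest.raises(InputError):
            interpolate_artifacts(
                np.ones(4), ArtifactMask(np.ones(4, dtype=bool))
            )

    @given(
        flags=st.lists(st.booleans(), min_size=5, max_size=40),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_idempotent_and_preserves_unflagged(self, flags, seed):
        flags = np.array(flags, dtype=bool)
        if flags.all():
            flags[0] = False
        tc = np.random.default_rng(seed).normal(size=len(flags))
        mask = ArtifactMask(flags)
        once = interpolate_artifacts(tc, mask)
        assert np.array_equal(once[~flags], tc[~flags])
        assert np.array_equal(interpolate_artifacts(once, mask), once)


class TestNuisanceRegression:
    def test_residual_matches_own_regressor(self, rng):
        reg = rng.normal(size=50)
        resid = regress_nuisance(3.0 * reg + 2.0, reg[:, None])
        assert np.abs(resid).max() < 1e-10

    def test_empty_set_mean_centers(self, rng):
        tc = rng.normal(size=50) + 10
        resid = regress_nuisance(tc, None)
        assert np.allclose(resid, tc - tc.mean())

    def test_matches_normal_equation_oracle(self, rng):
        n, k = 80, 6
        X = rng.normal(size=(n, k))
        tc = rng.normal(size=n)
        resid = regress_nuisance(tc, X)
        Xi = np.column_stack([np.ones(n), X])
        beta = np.linalg.solve(Xi.T @ Xi, Xi.T @ tc)
        assert np.allclose(resid, tc - Xi @ beta, atol=1e-10)

    def test_residuals_orthogonal_to_every_regressor(self, rng):
        X = rng.normal(size=(60, 4))
        resid = regress_nuisance(rng.normal(size=60), X)
        assert np.abs(X.T @ resid).max() < 1e-8

    def test_collinear_design_names_columns(self, rng):
        x = rng.normal(size=30)
        with pytest.raises(InputError, match="dup"):
            regress_nuisance(
                rng.normal(size=30),
                np.column_stack([x, 2 * x]),
                labels=["orig", "dup"],
            )


class TestNoiseComponents:
    def test_recovers_dominant_shared_series(self, rng):
        common = rng.normal(size=100)
        V = np.outer(rng.uniform(0.5, 2.0, size=30), common)
        V = V + 0.01 * rng.normal(size=V.shape)
        pcs = noise_components(V, 3)
        r = np.corrcoef(pcs[:, 0], common)[0, 1]
        assert abs(r) > 0.99

    def test_explained_variance_nonincreasing(self, rng):
        V = rng.normal(size=(40, 120))
        pcs = noise_components(V, 5)
        Xc = (V - V.mean(axis=1, keepdims=True)).T
        proj_var = [np.var(Xc.T @ pcs[:, j]) for j in range(5)]
        assert all(a >= b - 1e-12 for a, b in zip(proj_var, proj_var[1:]))

    def test_k_zero_gives_empty_set(self, rng):
        assert noise_components(rng.normal(size=(10, 20)), 0).shape == (20, 0)

    def test_k_above_rank_raises(self):
        V = np.outer(np.arange(1, 7), np.arange(20))  # rank 1 after centering
        with pytest.raises(InputError):
            noise_components(V, 3)


class TestHighpass:
    def test_constant_maps_to_zero(self, acq):
        out = highpass_filter(np.full(acq.n_volumes, 7.0), acq)
        assert np.abs(out).max() < 1e-10

    def test_passband_sine_preserved(self, acq):
        t = np.arange(acq.n_volumes) * acq.tr_seconds
        s = np.sin(2 * np.pi * t / 50.0)
        out = highpass_filter(s, acq)
        assert out.std() / s.std() == pytest.approx(1.0, abs=0.05)

    def test_stopband_sine_attenuated(self, acq):
        t = np.arange(acq.n_volumes) * acq.tr_seconds
        s = np.sin(2 * np.pi * t / 400.0)
        out = highpass_filter(s, acq)
        assert out.std() / s.std() < 0.10

    def test_cutoff_below_nyquist_raises(self, acq):
        with pytest.raises(ConfigurationError):
            highpass_filter(np.zeros(acq.n_volumes), acq, cutoff_s=3.0)

    def test_nan_input_rejected(self, acq):
        x = np.zeros(acq.n_volumes)
        x[5] = np.nan
        with pytest.raises(InputError):
            highpass_filter(x, acq)


class TestCompositeMotion:
    def test_first_tr_is_zero_and_steps_accumulate(self):
        trans = np.array([[0, 0, 0], [3, 4, 0], [3, 4, 0]], dtype=float)
        rot = np.zeros((3, 3))
        out = composite_motion(trans, rot)
        assert out[0] == 0.0
        assert out[1] == pytest.approx(5.0)
        assert out[2] == pytest.approx(0.0)

    def test_rotation_projected_at_head_radius(self):
        trans = np.zeros((2, 3))
        rot = np.array([[0, 0, 0], [0.01, 0, 0]])
        out = composite_motion(trans, rot, head_radius_mm=65.0)
        assert out[1] == pytest.approx(0.65)


class TestPreparePipeline:
    def test_trivial_input_equals_highpassed_input(self, acq, rng):
        roi_tab = default_roi_table()
        values = rng.normal(size=(len(roi_tab), acq.n_volumes))
        out = prepare_roi_timecourses(
            values, roi_tab, np.zeros(acq.n_volumes), acq
        )
        assert np.allclose(out.values, highpass_filter(values, acq))

    def test_m1_regression_removes_shared_signal(self, acq, rng):
        roi_tab = default_roi_table()
        m1sig = rng.normal(size=acq.n_volumes)
        scale = rng.uniform(0.5, 2.0, size=len(roi_tab))
        values = np.outer(scale, m1sig) + 0.001 * rng.normal(
            size=(len(roi_tab), acq.n_volumes)
        )
        out = prepare_roi_timecourses(
            values,
            roi_tab,
            np.zeros(acq.n_volumes),
            acq,
            options=PrepOptions(for_connectivity=True),
        )
        hp_m1 = highpass_filter(m1sig, acq)
        ok = ~out.mask.flags  # a few TRs may trip the global-signal rule
        for i, net in enumerate(roi_tab["network"]):
            if net in ("ToM", "Pain"):
                r = np.corrcoef(out.values[i, ok], hp_m1[ok])[0, 1]
                assert abs(r) < 0.05

    def test_flagged_trs_become_missing(self, acq, rng):
        roi_tab = default_roi_table()
        values = rng.normal(size=(len(roi_tab), acq.n_volumes))
        motion = np.zeros(acq.n_volumes)
        motion[20:30] = 3.0  # 10 artifact TRs
        out = prepare_roi_timecourses(values, roi_tab, motion, acq)
        assert out.mask.n_flagged == 10
        assert np.isnan(out.values).sum() == 10 * len(roi_tab)

    def test_voxel_order_invariance(self, acq, rng):
        roi_tab = default_roi_table()
        names = roi_tab["name"].tolist()
        labels = [n for n in names for _ in range(3)]
        values = rng.normal(size=(len(labels), acq.n_volumes))
        out1 = prepare_roi_timecourses(
            values, roi_tab, np.zeros(acq.n_volumes), acq, series_roi=labels
        )
        perm = rng.permutation(len(labels))
        out2 = prepare_roi_timecourses(
            values[perm],
            roi_tab,
            np.zeros(acq.n_volumes),
            acq,
            series_roi=[labels[i] for i in perm],
        )
        assert np.allclose(out1.values, out2.values)

    def test_empty_roi_raises(self, acq, rng):
        roi_tab = default_roi_table()
        labels = roi_tab["name"].tolist()[:-1]  # drop one ROI's only voxel
        values = rng.normal(size=(len(labels), acq.n_volumes))
        with pytest.raises(InputError, match="zero voxels"):
            prepare_roi_timecourses(
                values, roi_tab, np.zeros(acq.n_volumes), acq,
                series_roi=labels,
            )
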