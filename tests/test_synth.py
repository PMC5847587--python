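"""Synthetic cohort generator: determinism, structure, calibration nulls,
HRF timing, and the behavioral item model."""

import numpy as np
import pytest

from devfmri.acquisition import AcquisitionParams, ConfigurationError
from devfmri.connectivity import fisher_z_matrix, summarize_network_correlations
from devfmri.events import Event, EventSet
from devfmri.synth import (
    AgeLinear,
    BehaviorModel,
    CohortConfig,
    HrfParams,
    _normalized_regressor,
    hrf_kernel,
    simulate_behavior,
    simulate_cohort,
)


def null_config(**kw):
    """No coupling, no events, no shared structure: pure noise + spikes."""
    zero = AgeLinear(0.0, 0.0)
    defaults = dict(
        within_tom_z=zero,
        within_pain_z=zero,
        across_z=zero,
        amp_tom=zero,
        amp_pain=zero,
        global_sd=0.0,
        physio_roi_sd=0.0,
        bilateral_sd=0.0,
        m1_pair_sd=0.0,
        spike_rate_child=0.0,
        spike_rate_adult=0.0,
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestDeterminismAndShape:
    def test_same_seed_identical(self):
        cfg = CohortConfig(n_children=3, n_adults=2, seed=9)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        for ta, tb in zip(a.timecourses, b.timecourses):
            assert np.array_equal(ta.values, tb.values)
            assert np.array_equal(ta.mask.flags, tb.mask.flags)
        assert a.records_frame().equals(b.records_frame())

    def test_different_seed_differs(self):
        a = simulate_cohort(CohortConfig(n_children=2, n_adults=1, seed=1))
        b = simulate_cohort(CohortConfig(n_children=2, n_adults=1, seed=2))
        assert not np.array_equal(
            a.timecourses[0].values, b.timecourses[0].values
        )

    def test_matrix_dimensions(self, small_cohort):
        cfg = small_cohort.config
        for ts in small_cohort.timecourses:
            assert ts.values.shape == (len(cfg.roi_table), cfg.acq.n_volumes)

    def test_mask_marks_exactly_spiked_motion_trs(self, small_cohort):
        for ts in small_cohort.timecourses:
            motion = small_cohort.motion[ts.subject_id]
            assert np.array_equal(ts.mask.flags, motion > 2.0)
            rec = next(
                r
                for r in small_cohort.records
                if r.subject_id == ts.subject_id
            )
            assert rec.n_artifact_timepoints == ts.mask.n_flagged

    def test_degenerate_config_rejected(self):
        with pytest.raises(ConfigurationError):
            null_config(noise_sd=0.0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_cohort(CohortConfig(n_children=0, n_adults=0))


class TestCalibrationNull:
    def test_zero_coupling_gives_zero_mean_across_z(self):
        cfg = null_config(n_children=1000, n_adults=0, seed=11)
        cohort = simulate_cohort(cfg)
        zs = [
            summarize_network_correlations(
                fisher_z_matrix(ts), cfg.roi_table
            ).across_z
            for ts in cohort.timecourses
        ]
        assert abs(np.mean(zs)) < 0.02


class TestHrfTiming:
    def test_kernel_peaks_at_configured_lag(self):
        h = hrf_kernel(2.0, HrfParams(peak_s=5.0))
        peak_s = np.argmax(h) * 2.0
        assert abs(peak_s - 5.0) <= 2.0  # within one TR of the 5 s peak

    def test_event_regressor_lags_onset_by_hrf_peak(self):
        acq = AcquisitionParams()
        es = EventSet([Event("ToM", 60, 61)])
        reg = _normalized_regressor(es, "ToM", acq, HrfParams())
        peak_tr = np.argmax(reg) + 1
        hrf_peak_tr = 5.0 / acq.tr_seconds
        lag = peak_tr - 60
        assert abs(lag - hrf_peak_tr) <= 1.0


class TestBehaviorModel:
    def test_ability_saturation(self):
        hi = simulate_behavior([4.0], abilities=[np.inf], seed=0)[0]
        assert hi.tom_prop_correct == 1.0
        assert hi.fb_composite == 6
        assert hi.fb_group == "pass"
        lo = simulate_behavior([4.0], abilities=[-np.inf], seed=0)[0]
        assert lo.tom_prop_correct == 0.0
        assert lo.fb_composite == 0
        assert lo.fb_group == "fail"

    def test_age_tom_kendall_tau_recovered(self):
        from scipy.stats import kendalltau

        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ages = rng.uniform(3.0, 12.0, size=122)
            scores = simulate_behavior(ages, seed=seed + 1000)
            tau = kendalltau(
                ages, [s.tom_prop_correct for s in scores]
            ).statistic
            hits += tau > 0.3
        assert hits >= 19  # >= 95% of seeds

    def test_dccs_only_for_young_children(self):
        scores = simulate_behavior([4.0, 9.0], seed=3)
        assert scores[0].dccs_summary is not None
        assert scores[1].dccs_summary is None

    def test_negative_age_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_behavior([-1.0])


class TestGeneratorGroundTruth:
    def test_event_responses_grow_with_age(self):
        """Adult-defined peak responses in children rise with age (partial
        Spearman with motion covariate), as built into the amplitude model."""
        from devfmri.connectivity import partial_rank_correlation
        from devfmri.pipeline import prepare_cohort
        from devfmri.revcorr import (
            detect_events,
            group_mean_timecourse,
            network_timecourse,
            peak_response_table,
            rank_events,
        )

        cfg = CohortConfig(seed=5)
        cohort = simulate_cohort(cfg)
        prepared, _ = prepare_cohort(cohort)
        records = cohort.records_frame()
        adult_ids = set(
            records.loc[records.group == "adult", "subject_id"]
        )
        nts = [
            network_timecourse(p, cfg.roi_table, "ToM") for p in prepared
        ]
        adults = [x for x in nts if x.subject_id in adult_ids]
        events = rank_events(
            detect_events(adults), group_mean_timecourse(adults)
        )
        kids_nts = [x for x in nts if x.subject_id not in adult_ids]
        responses = (
            peak_response_table(kids_nts, events)
            .dropna()
            .groupby("subject_id")["response"]
            .mean()
            .reset_index()
            .merge(records, on="subject_id")
        )
        res = partial_rank_correlation(
            responses["age_years"],
            responses["response"],
            responses["n_artifact_timepoints"],
        )
        assert res.estimate > 0
        assert res.p < 0.05 / 19  # survives the 19-event Bonferroni level

    def test_age_independent_coupling_gives_null_age_trend(self):
        """With a constant across-network target the age trend vanishes."""
        from scipy.stats import spearmanr

        ps = []
        for seed in range(8):
            cfg = CohortConfig(
                n_children=122,
                n_adults=0,
                across_z=AgeLinear(-0.17, -0.17),
                within_tom_z=AgeLinear(0.48, 0.48),
                within_pain_z=AgeLinear(0.35, 0.35),
                amp_tom=AgeLinear(0.4, 0.4),
                amp_pain=AgeLinear(0.3, 0.3),
                seed=seed,
            )
            cohort = simulate_cohort(cfg)
            zs = [
                summarize_network_correlations(
                    fisher_z_matrix(ts), cfg.roi_table
                ).across_z
                for ts in cohort.timecourses
            ]
            ages = [r.age_years for r in cohort.records]
            ps.append(spearmanr(ages, zs).pvalue)
        assert np.mean(np.array(ps) < 0.05) <= 0.25


class TestRecordsFrame:
    def test_children_have_behavior_adults_do_not(self, small_cohort):
        df = small_cohort.records_frame()
        kids = df[df["group"] == "child"]
        adults = df[df["group"] == "adult"]
        assert kids["tom_prop_correct"].notna().all()
        assert adults["tom_prop_correct"].isna().all()

    def test_child_age_composition_bottom_heavy(self):
        cohort = simulate_cohort(CohortConfig(n_children=122, n_adults=0, seed=5))
        ages = [r.age_years for r in cohort.records]
        assert sum(a < 6.0 for a in ages) == 65
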