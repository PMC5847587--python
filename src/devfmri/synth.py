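"""Synthetic developmental fMRI cohorts with the statistical structure the
downstream analyses assume.

Each subject's ROI x TR matrix is a sum of

* a within-network shared latent per network (weight set by chronological
  age),
* one cross-network coupling latent whose signed loading moves the
  across-network correlation from ~+0.05 (Fisher z) at age 3 toward ~-0.17
  in adults,
* HRF-convolved responses to a shared movie-like event table, with
  amplitudes growing over development,
* extra shared signal for homologous bilateral ROI pairs, a small global
  signal, slow drifts, i.i.d. noise, and large spike artifacts that
  co-occur in the motion trace.

Calibration is analytic moment matching: per subject the latent loadings
are solved from target Fisher-z moments (linear in age between the age-3
and adult endpoints), after subtracting the variance contributed by the
event regressors and bilateral terms. Cross-network coupling and event
amplitude follow a *developmental age* (chronological age plus a
subject-level jitter), while within-network integration follows
chronological age; this makes functional maturity conditionally dependent
on the anti-correlation, not on within-network correlation, given age —
the structure the maturity analyses are designed to detect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .acquisition import AcquisitionParams, ConfigurationError, window_slice
from .behavior import BehaviorScores, score_tom_battery
from .events import EventSet, default_event_table, event_boxcar
from .prep import ArtifactMask, RoiTimecourseSet
from .rois import bilateral_pairs, default_roi_table, validate_roi_table

log = logging.getLogger(__name__)

ADULT_REFERENCE_AGE = 25.0
_MIN_AGE = 3.0


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma hemodynamic response (peak 5 s, undershoot 15 s)."""

    peak_s: float = 5.0
    undershoot_s: float = 15.0
    undershoot_ratio: float = 6.0
    length_s: float = 32.0


def hrf_kernel(tr_seconds: float, hrf: HrfParams = HrfParams()) -> np.ndarray:
    """HRF sampled on the TR grid, normalized to unit peak."""
    from scipy.stats import gamma

    t = np.arange(0.0, hrf.length_s + tr_seconds / 2, tr_seconds)
    h = gamma.pdf(t, hrf.peak_s + 1.0) - gamma.pdf(
        t, hrf.undershoot_s + 1.0
    ) / hrf.undershoot_ratio
    peak = h.max()
    if peak <= 0:
        raise ConfigurationError("degenerate HRF parameters")
    return h / peak


@dataclass(frozen=True)
class AgeLinear:
    """A quantity linear in age between its age-3 and adult values."""

    at_age3: float
    adult: float

    def __call__(self, age: float) -> float:
        a = np.clip(age, _MIN_AGE, ADULT_REFERENCE_AGE)
        frac = (a - _MIN_AGE) / (ADULT_REFERENCE_AGE - _MIN_AGE)
        return self.at_age3 + frac * (self.adult - self.at_age3)


@dataclass(frozen=True)
class BehaviorModel:
    """Logistic item-response model for the ToM battery.

    Latent ability is linear in developmental age; the 24 matched items span
    an ability range wide enough that the battery discriminates across ages
    3-12, and the six false-belief items sit near the 4-5-year ability level
    so pass/inconsistent/fail groups all occur.
    """

    ability_intercept: float = -2.4
    ability_slope: float = 0.4
    ability_noise_sd: float = 0.3
    tom_difficulty_range: tuple[float, float] = (-2.5, 2.5)
    fb_difficulty_range: tuple[float, float] = (-1.6, -0.6)
    control_p_correct: float = 0.98
    dccs_intercept: float = 1.2
    dccs_age_slope: float = 0.25
    dccs_noise_sd: float = 0.8
    dccs_max_age: float = 6.0


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the cohort generator; defaults are the study conditions.

    Target Fisher-z moments (`within_tom_z`, `within_pain_z`, `across_z`)
    give the age-3 and adult endpoints of the network correlation summaries
    the simulated data should reproduce after the full preparation pipeline.
    """

    acq: AcquisitionParams = field(default_factory=AcquisitionParams)
    n_children: int = 122
    n_adults: int = 33
    child_age_range: tuple[float, float] = (3.5, 12.0)
    adult_age_range: tuple[float, float] = (18.0, 39.0)
    roi_table: pd.DataFrame = field(default_factory=default_roi_table)
    event_table: EventSet | None = None  # None -> default_event_table(acq)
    within_tom_z: AgeLinear = AgeLinear(0.21, 0.48)
    within_pain_z: AgeLinear = AgeLinear(0.23, 0.35)
    across_z: AgeLinear = AgeLinear(0.05, -0.17)
    amp_tom: AgeLinear = AgeLinear(0.15, 0.60)
    amp_pain: AgeLinear = AgeLinear(0.12, 0.48)
    developmental_jitter_sd: float = 2.0
    hrf: HrfParams = HrfParams()
    bilateral_sd: float = 0.25
    m1_pair_sd: float = 0.55
    global_sd: float = 0.15
    physio_roi_sd: float = 0.08
    drift_sd: float = 0.4
    noise_sd: float = 1.0
    spike_rate_child: float = 10.5 / 168
    spike_rate_adult: float = 2.8 / 168
    spike_sd: float = 6.0
    n_noise_voxels: int = 50
    behavior: BehaviorModel = BehaviorModel()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "bilateral_sd", "m1_pair_sd", "global_sd", "physio_roi_sd",
            "drift_sd", "noise_sd", "spike_sd", "developmental_jitter_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("spike_rate_child", "spike_rate_adult"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for name in ("child_age_range", "adult_age_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigurationError(f"{name} must be a non-empty range")
        validate_roi_table(self.roi_table)
        shared = (
            abs(self.within_tom_z.adult)
            + abs(self.within_pain_z.adult)
            + abs(self.across_z.adult)
            + abs(self.amp_tom.adult)
            + abs(self.amp_pain.adult)
        )
        if self.noise_sd == 0 and shared == 0:
            raise ConfigurationError(
                "degenerate config: no noise and no shared signal/events"
            )

    def events(self) -> EventSet:
        return (
            self.event_table
            if self.event_table is not None
            else default_event_table(self.acq)
        )


@dataclass(frozen=True)
class SubjectRecord:
    """Metadata for one simulated participant.

    ``developmental_age`` is generator ground truth: the jittered age that
    drives cross-network coupling, event amplitudes, and behavior.
    """

    subject_id: str
    group: str  # child / adult
    age_years: float
    n_artifact_timepoints: int
    developmental_age: float
    behavior: BehaviorScores | None = None

    def __post_init__(self) -> None:
        if self.age_years <= 0:
            raise ConfigurationError("age_years must be positive")


@dataclass
class Cohort:
    """A simulated cohort: raw timecourses plus everything prep needs."""

    config: CohortConfig
    timecourses: list[RoiTimecourseSet]
    records: list[SubjectRecord]
    motion: dict[str, np.ndarray]
    noise_voxels: dict[str, np.ndarray]

    def records_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "subject_id": r.subject_id,
                "group": r.group,
                "age_years": r.age_years,
                "n_artifact_timepoints": r.n_artifact_timepoints,
                "developmental_age": r.developmental_age,
                "tom_prop_correct": np.nan,
                "fb_composite": np.nan,
                "fb_group": None,
                "dccs_summary": np.nan,
            }
            if r.behavior is not None:
                row.update(
                    tom_prop_correct=r.behavior.tom_prop_correct,
                    fb_composite=r.behavior.fb_composite,
                    fb_group=r.behavior.fb_group,
                    dccs_summary=(
                        np.nan
                        if r.behavior.dccs_summary is None
                        else r.behavior.dccs_summary
                    ),
                )
            rows.append(row)
        return pd.DataFrame(rows)


def _normalized_regressor(
    events: EventSet,
    network: str,
    acq: AcquisitionParams,
    hrf: HrfParams,
    amplitude_by_label: bool = True,
) -> np.ndarray:
    """HRF-convolved event response, z-scored over the analysis window.

    Per-event relative amplitudes decrease with the event's rank label
    (T01 strongest), so detected rankings are recoverable.
    """
    box = event_boxcar(events, network, acq)
    net_events = [e for e in events if e.network == network]
    if amplitude_by_label and net_events and all(
        e.label is not None for e in net_events
    ):
        n = len(net_events)
        for e in net_events:
            rank = int(e.label[1:]) - 1
            rel = 1.3 - 0.6 * (rank / max(n - 1, 1))
            box[np.array(list(e.trs)) - 1] = rel
    if not box.any():
        return np.zeros(acq.n_volumes)
    conv = np.convolve(box, hrf_kernel(acq.tr_seconds, hrf))[: acq.n_volumes]
    sl = window_slice(acq.analysis_window)
    mu, sd = conv[sl].mean(), conv[sl].std()
    if sd == 0:
        return np.zeros(acq.n_volumes)
    return (conv - mu) / sd


def _solve_loadings(
    cfg: CohortConfig,
    age: float,
    dev_age: float,
    rho_reg: float,
    frac_bilat: dict[str, float],
) -> dict[str, float]:
    """Latent loadings hitting the target z moments for one subject.

    With unit-variance noise plus the small shared extras (global, physio),
    a target pair correlation r needs shared variance v = r * s2 / (1 - r)
    where s2 is the non-shared variance. The within budget is then split
    into event response (amplitude from the developmental age), coupling
    latent (|cov| each side), bilateral share, and the within-network
    latent; negative leftovers are floored at a small positive value.
    """
    s2 = (
        cfg.noise_sd**2
        + cfg.global_sd**2
        + 4 * cfg.physio_roi_sd**2
    )
    out: dict[str, float] = {}
    r_tt = np.tanh(cfg.within_tom_z(age))
    r_pp = np.tanh(cfg.within_pain_z(age))
    r_tp = np.tanh(cfg.across_z(dev_age))
    v_t = r_tt * s2 / (1 - r_tt) if r_tt > 0 else 0.0
    v_p = r_pp * s2 / (1 - r_pp) if r_pp > 0 else 0.0
    cov_tp = r_tp * np.sqrt((v_t + s2) * (v_p + s2))
    a_t = cfg.amp_tom(dev_age)
    a_p = cfg.amp_pain(dev_age)
    cpl = cov_tp - a_t * a_p * rho_reg
    c = np.sqrt(abs(cpl))
    d = np.sign(cpl) * c
    w2_t = v_t - a_t**2 - abs(cpl) - frac_bilat["ToM"] * cfg.bilateral_sd**2
    w2_p = v_p - a_p**2 - abs(cpl) - frac_bilat["Pain"] * cfg.bilateral_sd**2
    for name, w2 in (("ToM", w2_t), ("Pain", w2_p)):
        if w2 < 0 and (v_t if name == "ToM" else v_p) > 0:
            log.warning(
                "within-%s budget negative (%.3f); flooring — event "
                "amplitudes large relative to the target correlations",
                name,
                w2,
            )
    out["w_tom"] = float(np.sqrt(max(w2_t, 0.0)))
    out["w_pain"] = float(np.sqrt(max(w2_p, 0.0)))
    out["c_tom"] = float(c)
    out["c_pain"] = float(d)
    out["amp_tom"] = float(a_t)
    out["amp_pain"] = float(a_p)
    return out


def simulate_behavior(
    ages,
    model: BehaviorModel | None = None,
    seed: int | np.random.Generator = 0,
    developmental_ages=None,
    abilities=None,
) -> list[BehaviorScores]:
    """Draw item-level battery outcomes for children of the given ages.

    Ability is linear in developmental age (defaults to chronological age)
    plus noise; ToM, false-belief and control items are independent
    Bernoulli draws given ability; the DCCS summary (0-3, under-6s only) is
    weakly age-correlated. ``abilities`` overrides the latent ability
    entirely (useful for saturation checks: +-inf gives ceiling/floor
    scores).
    """
    model = model or BehaviorModel()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ages = np.asarray(ages, dtype=float)
    if (ages <= 0).any():
        raise ConfigurationError("ages must be positive")
    dev = (
        ages
        if developmental_ages is None
        else np.asarray(developmental_ages, dtype=float)
    )
    tom_b = np.linspace(*model.tom_difficulty_range, 24)
    fb_b = np.linspace(*model.fb_difficulty_range, 6)
    out = []
    for age, d in zip(ages, dev):
        if abilities is not None:
            theta = float(abilities[len(out)])
        else:
            theta = (
                model.ability_intercept
                + model.ability_slope * d
                + rng.normal(0.0, model.ability_noise_sd)
            )
        with np.errstate(over="ignore"):
            p_tom = 1.0 / (1.0 + np.exp(-(theta - tom_b)))
            p_fb = 1.0 / (1.0 + np.exp(-(theta - fb_b)))
        tom_items = (rng.random(24) < p_tom).astype(int)
        fb_items = (rng.random(6) < p_fb).astype(int)
        ctrl = (rng.random(2) < model.control_p_correct).astype(int)
        dccs = None
        if age < model.dccs_max_age:
            dccs = float(
                np.clip(
                    np.round(
                        model.dccs_intercept
                        + model.dccs_age_slope * (age - 3.0)
                        + rng.normal(0.0, model.dccs_noise_sd)
                    ),
                    0,
                    3,
                )
            )
        out.append(
            score_tom_battery(
                tom_items, fb_items, ctrl, age_years=age, dccs_summary=dccs
            )
        )
    return out


def simulate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate a full cohort, reproducibly from ``config.seed``."""
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    acq = cfg.acq
    n_trs = acq.n_volumes
    roi_tab = cfg.roi_table
    names = roi_tab["name"].tolist()
    networks = roi_tab["network"].tolist()
    n_rois = len(names)
    events = cfg.events()

    reg = {
        "ToM": _normalized_regressor(events, "ToM", acq, cfg.hrf),
        "Pain": _normalized_regressor(events, "Pain", acq, cfg.hrf),
    }
    sl = window_slice(acq.analysis_window)
    if reg["ToM"][sl].std() > 0 and reg["Pain"][sl].std() > 0:
        rho_reg = float(np.corrcoef(reg["ToM"][sl], reg["Pain"][sl])[0, 1])
    else:
        rho_reg = 0.0

    pairs = bilateral_pairs(roi_tab)
    pair_index = {frozenset(p): k for k, p in enumerate(pairs)}
    roi_pair = [
        next((k for key, k in pair_index.items() if nm in key), None)
        for nm in names
    ]
    frac_bilat = {}
    for net in ("ToM", "Pain"):
        net_names = [n for n, w in zip(names, networks) if w == net]
        n_pairs_total = len(net_names) * (len(net_names) - 1) // 2
        n_bilat = sum(
            1 for p in pairs if p[0] in net_names and p[1] in net_names
        )
        frac_bilat[net] = n_bilat / n_pairs_total if n_pairs_total else 0.0

    # Cohort layout: children then adults. Child ages follow the study's
    # bottom-heavy composition: ~65/122 of children under six, the rest
    # spread over six-to-max (when the requested range brackets age six).
    lo, hi = cfg.child_age_range
    if lo < 6.0 < hi:
        n_young = int(round(cfg.n_children * 65.0 / 122.0))
        ages_child = np.sort(
            np.concatenate(
                [
                    rng.uniform(lo, 6.0, size=n_young),
                    rng.uniform(6.0, hi, size=cfg.n_children - n_young),
                ]
            )
        )
    else:
        ages_child = np.sort(rng.uniform(lo, hi, size=cfg.n_children))
    ages_adult = np.sort(rng.uniform(*cfg.adult_age_range, size=cfg.n_adults))
    subjects = [("child", a) for a in ages_child] + [
        ("adult", a) for a in ages_adult
    ]
    if not subjects:
        raise ConfigurationError("empty cohort: no children and no adults")

    t_lin = np.linspace(-0.5, 0.5, n_trs)
    drift_shapes = np.column_stack(
        [t_lin, np.cos(np.pi * np.arange(n_trs) / n_trs)]
    )
    baseline = 800.0 + 10.0 * np.arange(n_rois)

    timecourses, records = [], []
    motion_out: dict[str, np.ndarray] = {}
    voxels_out: dict[str, np.ndarray] = {}
    child_i = adult_i = 0
    dev_ages_children: list[float] = []

    for group, age in subjects:
        if group == "child":
            child_i += 1
            sid = f"child{child_i:03d}"
            dev_age = float(
                np.clip(
                    age + rng.normal(0.0, cfg.developmental_jitter_sd),
                    _MIN_AGE,
                    ADULT_REFERENCE_AGE,
                )
            )
            dev_ages_children.append(dev_age)
            spike_rate = cfg.spike_rate_child
            eff_age = age
        else:
            adult_i += 1
            sid = f"adult{adult_i:03d}"
            dev_age = ADULT_REFERENCE_AGE
            spike_rate = cfg.spike_rate_adult
            eff_age = ADULT_REFERENCE_AGE
        load = _solve_loadings(cfg, eff_age, dev_age, rho_reg, frac_bilat)

        u = {
            "ToM": rng.standard_normal(n_trs),
            "Pain": rng.standard_normal(n_trs),
        }
        coupling = rng.standard_normal(n_trs)
        glob = rng.standard_normal(n_trs)
        physio = rng.standard_normal((4, n_trs))
        pair_latents = rng.standard_normal((len(pairs), n_trs))
        physio_load = rng.normal(0.0, 1.0, size=(n_rois, 4))
        drift_coef = rng.normal(0.0, cfg.drift_sd, size=(n_rois, 2))

        X = np.empty((n_rois, n_trs))
        for i, (nm, net) in enumerate(zip(names, networks)):
            x = cfg.global_sd * glob + cfg.physio_roi_sd * (
                physio_load[i] @ physio
            )
            x = x + drift_coef[i] @ drift_shapes.T + baseline[i]
            if net in ("ToM", "Pain"):
                x = x + load[f"w_{net.lower()}"] * u[net]
                x = x + load[f"c_{net.lower()}"] * coupling
                x = x + load[f"amp_{net.lower()}"] * reg[net]
                if roi_pair[i] is not None:
                    x = x + cfg.bilateral_sd * pair_latents[roi_pair[i]]
            elif net == "M1":
                if roi_pair[i] is not None:
                    x = x + cfg.m1_pair_sd * pair_latents[roi_pair[i]]
            x = x + cfg.noise_sd * rng.standard_normal(n_trs)
            X[i] = x

        # Noise voxels share the global and physiological sources.
        vload = rng.normal(0.0, 0.4, size=(cfg.n_noise_voxels, 4))
        V = (
            vload @ physio
            + 0.5 * np.outer(np.ones(cfg.n_noise_voxels), glob)
            + rng.standard_normal((cfg.n_noise_voxels, n_trs))
        )

        n_spikes = rng.binomial(n_trs, spike_rate)
        spike_trs = np.sort(rng.choice(n_trs, size=n_spikes, replace=False))
        if n_spikes:
            X[:, spike_trs] += cfg.spike_sd * rng.standard_normal(
                (n_rois, n_spikes)
            )
            V[:, spike_trs] += cfg.spike_sd * rng.standard_normal(
                (cfg.n_noise_voxels, n_spikes)
            )
        motion = np.abs(rng.normal(0.0, 0.25, size=n_trs))
        motion[0] = 0.0
        motion[spike_trs] = 2.0 + np.abs(rng.normal(1.5, 1.0, size=n_spikes))

        flags = np.zeros(n_trs, dtype=bool)
        flags[spike_trs] = True
        timecourses.append(
            RoiTimecourseSet(
                subject_id=sid,
                values=X,
                roi_names=names,
                mask=ArtifactMask(flags),
                acq=acq,
            )
        )
        records.append(
            SubjectRecord(
                subject_id=sid,
                group=group,
                age_years=float(age),
                n_artifact_timepoints=int(n_spikes),
                developmental_age=dev_age,
            )
        )
        motion_out[sid] = motion
        voxels_out[sid] = V

    # Behavior for children, sharing the developmental-age latent.
    child_records = [r for r in records if r.group == "child"]
    if child_records:
        scores = simulate_behavior(
            [r.age_years for r in child_records],
            cfg.behavior,
            rng,
            developmental_ages=dev_ages_children,
        )
        scored = {
            r.subject_id: replace(r, behavior=s)
            for r, s in zip(child_records, scores)
        }
        records = [scored.get(r.subject_id, r) for r in records]

    return Cohort(
        config=cfg,
        timecourses=timecourses,
        records=records,
        motion=motion_out,
        noise_voxels=voxels_out,
    )
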