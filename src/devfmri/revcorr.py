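"""Reverse correlation: data-driven event discovery in network timecourses.

Each ROI timecourse is z-normalized over the analysis window and averaged
across the ROIs of a network, giving one network timecourse per subject.
Across a group of subjects, every analyzed TR is tested against baseline 0
with a one-tailed (positive) one-sample t-test; runs of two or more
consecutive significant TRs are events. Events are ranked by the group-mean
response at their peak TR and labeled accordingly (T01/P01 strongest).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .acquisition import window_slice
from .events import Event, EventSet
from .prep import InputError, RoiTimecourseSet

log = logging.getLogger(__name__)

_LABEL_PREFIX = {"ToM": "T", "Pain": "P"}


@dataclass(frozen=True)
class NetworkTimecourse:
    """One subject's averaged network timecourse (full-run indexing)."""

    subject_id: str
    network: str
    values: np.ndarray  # length n_volumes; NaN at masked TRs
    window: tuple[int, int]  # analyzed inclusive 1-based TR range

    @property
    def window_values(self) -> np.ndarray:
        return self.values[window_slice(self.window)]


def network_timecourse(
    roiset: RoiTimecourseSet,
    roi_table: pd.DataFrame,
    network: str,
    window: tuple[int, int] | None = None,
    zscore: bool = True,
) -> NetworkTimecourse:
    """Average a network's ROI timecourses into one series.

    With ``zscore`` each ROI is z-normalized over its non-missing window TRs
    before averaging (the reverse-correlation convention); without it the
    plain average is returned (the functional-maturity convention). Missing
    TRs propagate as missing.
    """
    window = window or roiset.acq.analysis_window
    sl = window_slice(window)
    vals = roiset.network_values(roi_table, network)[:, sl].astype(float)
    names = roi_table.loc[roi_table["network"] == network, "name"].tolist()
    out = np.full(roiset.acq.n_volumes, np.nan)
    rows = []
    for name, row in zip(names, vals):
        ok = np.isfinite(row)
        if ok.sum() < 2 or row[ok].std() == 0:
            raise InputError(
                f"ROI {name}: constant or empty timecourse in window"
            )
        if zscore:
            row = (row - row[ok].mean()) / row[ok].std()
        rows.append(row)
    out[sl] = np.mean(rows, axis=0)
    return NetworkTimecourse(
        subject_id=roiset.subject_id,
        network=network,
        values=out,
        window=window,
    )


def group_mean_timecourse(cohort: list[NetworkTimecourse]) -> np.ndarray:
    """Per-TR mean across subjects, ignoring missing values."""
    if not cohort:
        raise InputError("empty cohort")
    stacked = np.vstack([nt.values for nt in cohort])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN lead-in TRs
        return np.nanmean(stacked, axis=0)


def significant_timepoints(
    cohort: list[NetworkTimecourse], alpha: float = 0.05
) -> np.ndarray:
    """Boolean per-TR vector: group response significantly positive.

    TRs outside the common window are never significant; at each window TR
    subjects with a missing value are dropped from that TR's t-test (the
    test df varies by TR); an all-missing TR is non-significant and logged.
    """
    if len(cohort) < 3:
        raise InputError("need >= 3 subjects for the per-TR t-tests")
    windows = {nt.window for nt in cohort}
    if len(windows) > 1:
        raise InputError(f"subjects disagree on the analysis window: {windows}")
    (window,) = windows
    stacked = np.vstack([nt.values for nt in cohort])
    n_trs = stacked.shape[1]
    sig = np.zeros(n_trs, dtype=bool)
    lo, hi = window
    for t in range(lo - 1, hi):
        col = stacked[:, t]
        col = col[np.isfinite(col)]
        if col.size < 2:
            log.warning("TR %d: fewer than 2 usable subjects; skipped", t + 1)
            continue
        if col.std(ddof=1) == 0:
            sig[t] = col.mean() > 0
            continue
        res = stats.ttest_1samp(col, 0.0, alternative="greater")
        sig[t] = res.pvalue < alpha
    return sig


def events_from_significance(
    sig: np.ndarray, network: str, min_duration: int = 2
) -> list[Event]:
    """Runs of >= ``min_duration`` consecutive significant TRs."""
    events = []
    start = None
    for t, flag in enumerate(np.concatenate([sig, [False]])):
        if flag and start is None:
            start = t
        elif not flag and start is not None:
            if t - start >= min_duration:
                events.append(Event(network, start + 1, t))
            start = None
    return events


def detect_events(
    cohort: list[NetworkTimecourse], alpha: float = 0.05
) -> EventSet:
    """Group-level event discovery for one network's cohort."""
    networks = {nt.network for nt in cohort}
    if len(networks) != 1:
        raise InputError(f"cohort mixes networks: {networks}")
    (network,) = networks
    sig = significant_timepoints(cohort, alpha=alpha)
    evs = events_from_significance(sig, network)
    return EventSet(
        evs,
        source_group=f"detected(n={len(cohort)})",
        alpha=alpha,
    )


def rank_events(events: EventSet, group_mean: np.ndarray) -> EventSet:
    """Assign peak TRs and magnitude-rank labels.

    The peak is the TR with the highest group-mean value inside the event
    (earliest on ties); labels T01.../P01... are assigned per network by
    descending peak magnitude, earlier onset breaking ties. Relabeling an
    already-ranked set is idempotent.
    """
    ranked: list[Event] = []
    for net in sorted({e.network for e in events}):
        prefix = _LABEL_PREFIX.get(net, net[:1].upper())
        with_peaks = []
        for e in events:
            if e.network != net:
                continue
            seg = np.asarray(group_mean)[e.onset_tr - 1 : e.offset_tr]
            if not np.isfinite(seg).any():
                raise InputError(
                    f"event at TR {e.onset_tr}: group mean all-missing"
                )
            peak_off = int(np.nanargmax(seg))
            with_peaks.append(
                replace(
                    e,
                    peak_tr=e.onset_tr + peak_off,
                    peak_magnitude=float(seg[peak_off]),
                )
            )
        order = sorted(
            with_peaks, key=lambda e: (-e.peak_magnitude, e.onset_tr)
        )
        for rank, e in enumerate(order, start=1):
            ranked.append(replace(e, label=f"{prefix}{rank:02d}"))
    ranked.sort(key=lambda e: (e.onset_tr, e.network))
    return EventSet(
        ranked, source_group=events.source_group, alpha=events.alpha
    )


def peak_response(subject: NetworkTimecourse, event: Event) -> float:
    """The subject's network value at the event's peak TR (NaN if masked)."""
    if event.peak_tr is None:
        raise InputError(f"event {event.label}: no peak TR; rank events first")
    lo, hi = subject.window
    if not lo <= event.peak_tr <= hi:
        raise InputError(
            f"peak TR {event.peak_tr} outside subject window {subject.window}"
        )
    val = float(subject.values[event.peak_tr - 1])
    if np.isnan(val):
        log.info(
            "%s: peak TR %d masked; response missing",
            subject.subject_id,
            event.peak_tr,
        )
    return val


def peak_response_table(
    cohort: list[NetworkTimecourse], events: EventSet
) -> pd.DataFrame:
    """Long table of per-subject peak responses for each (ranked) event."""
    rows = []
    for nt in cohort:
        for e in events:
            if e.network != nt.network:
                continue
            rows.append(
                {
                    "subject_id": nt.subject_id,
                    "network": e.network,
                    "label": e.label,
                    "peak_tr": e.peak_tr,
                    "response": peak_response(nt, e),
                }
            )
    return pd.DataFrame(rows)
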