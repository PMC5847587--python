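"""Reverse-correlation event discovery on the adult group.

Averages z-normalized ROI timecourses into one ToM and one pain network
timecourse per adult, t-tests every analyzed TR against baseline, and
reports the runs of consecutive significant TRs as ranked events.
"""

from devfmri import (
    CohortConfig,
    PrepOptions,
    detect_events,
    network_timecourse,
    prepare_cohort,
    rank_events,
    simulate_cohort,
)
from devfmri.revcorr import group_mean_timecourse

config = CohortConfig(n_children=0, n_adults=33, seed=3)
cohort = simulate_cohort(config)
prepared, _ = prepare_cohort(cohort)

for network in ("ToM", "Pain"):
    nts = [network_timecourse(p, config.roi_table, network) for p in prepared]
    events = rank_events(detect_events(nts), group_mean_timecourse(nts))
    total = sum(events.durations())
    print(f"{network}: {len(events)} events, {total} event TRs")
    frame = events.to_frame(config.acq.tr_seconds)
    print(frame[["label", "onset_tr", "offset_tr", "peak_tr",
                 "peak_magnitude"]].sort_values("label").head(3)
          .to_string(index=False))
# Labels rank events by adult peak response (T01/P01 strongest); peak TRs
# lag the underlying event onsets by the hemodynamic delay.
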