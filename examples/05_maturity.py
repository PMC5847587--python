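"""Functional maturity: how adult-like is each child's network response?

Correlates every child's (non-normalized) network-average timecourse with
the adult template over TRs 11-168, then asks what predicts maturity:
the across-network anti-correlation, the within-network correlation, age,
or motion.
"""

from devfmri import (
    CohortConfig,
    PrepOptions,
    fisher_z_matrix,
    maturity_analysis,
    network_timecourse,
    prepare_cohort,
    simulate_cohort,
    summarize_network_correlations,
    timecourse_maturity,
)
from devfmri.connectivity import summaries_frame
from devfmri.maturity import adult_mean_timecourse, maturity_frame

config = CohortConfig(seed=4)  # 122 children + 33 adults
cohort = simulate_cohort(config)
prep_conn, _ = prepare_cohort(cohort, PrepOptions(for_connectivity=True))
prep_tc, _ = prepare_cohort(cohort)
records = cohort.records_frame()
adult_ids = set(records.loc[records.group == "adult", "subject_id"])

scores = []
for network in ("ToM", "Pain"):
    raw = [network_timecourse(p, config.roi_table, network, zscore=False)
           for p in prep_tc]
    template = adult_mean_timecourse(
        [x for x in raw if x.subject_id in adult_ids])
    scores += [timecourse_maturity(x, template)
               for x in raw if x.subject_id not in adult_ids]

mat = maturity_frame(scores)
print("mean child maturity r:",
      mat.groupby("network")["r"].mean().round(3).to_dict())

summaries = summaries_frame(
    [summarize_network_correlations(fisher_z_matrix(p), config.roi_table,
                                    subject_id=p.subject_id)
     for p in prep_conn])
res = maturity_analysis(mat, summaries, records)
sel = res[(res.contrast == "maturity_by_connectivity")
          & (res.term.isin(["across_z", "within_z"]))]
print(sel[["network", "term", "b", "t", "p"]].round(4).to_string(index=False))
# A negative across_z coefficient (with within_z, age and motion in the
# model) means children with more anti-correlated networks have more
# adult-like responses — the developmental signature this package tests.
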