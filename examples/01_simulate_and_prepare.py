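"""Simulate a small developmental cohort and run timecourse preparation.

Builds 20 children + 10 adults (168 volumes at TR 2 s, 16 ROIs), runs
artifact detection, interpolation, nuisance regression, and the 100 s
high-pass, and reports how much data survives scrubbing.
"""

import numpy as np

from devfmri import CohortConfig, PrepOptions, prepare_cohort, simulate_cohort

cohort = simulate_cohort(CohortConfig(n_children=20, n_adults=10, seed=0))
prepared, excluded = prepare_cohort(cohort, PrepOptions(for_connectivity=True))

print(f"simulated {len(cohort.timecourses)} subjects, "
      f"{len(prepared)} pass the 1/3-artifact exclusion, "
      f"{len(excluded)} excluded")
flagged = [p.mask.n_flagged for p in prepared]
print(f"artifact TRs per subject: median {int(np.median(flagged))}, "
      f"max {max(flagged)} of {cohort.config.acq.n_volumes}")
missing = np.isnan(prepared[0].values).sum(axis=1)
print(f"first subject: {prepared[0].mask.n_flagged} flagged TRs -> "
      f"{missing[0]} NaN entries per ROI after preparation")
# Each subject's matrix is ROI x TR; flagged TRs are NaN in every ROI, so
# downstream correlations use pairwise-complete timepoints only.
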