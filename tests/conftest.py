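import numpy as np
import pandas as pd
import pytest

from devfmri.acquisition import AcquisitionParams
from devfmri.connectivity import (
    fisher_z_matrix,
    summaries_frame,
    summarize_network_correlations,
)
from devfmri.pipeline import prepare_cohort
from devfmri.prep import ArtifactMask, PrepOptions, RoiTimecourseSet
from devfmri.rois import default_roi_table
from devfmri.synth import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def roi_tab():
    return default_roi_table()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_roiset(
    values: np.ndarray,
    acq: AcquisitionParams,
    roi_names=None,
    flags=None,
    subject_id="s01",
) -> RoiTimecourseSet:
    """Wrap a plain matrix as a RoiTimecourseSet for unit tests."""
    values = np.asarray(values, dtype=float)
    if roi_names is None:
        roi_names = [f"roi{i}" for i in range(values.shape[0])]
    if flags is None:
        flags = np.zeros(values.shape[1], dtype=bool)
    return RoiTimecourseSet(
        subject_id=subject_id,
        values=values,
        roi_names=list(roi_names),
        mask=ArtifactMask(flags),
        acq=acq,
    )


def cohort_summaries(config: CohortConfig):
    """Simulate, prepare (connectivity variant) and summarize one cohort."""
    cohort = simulate_cohort(config)
    prepared, _ = prepare_cohort(cohort, PrepOptions(for_connectivity=True))
    summaries = summaries_frame(
        [
            summarize_network_correlations(
                fisher_z_matrix(p), config.roi_table, subject_id=p.subject_id
            )
            for p in prepared
        ]
    )
    return cohort, summaries


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed cohort reused across read-only tests."""
    return simulate_cohort(CohortConfig(n_children=8, n_adults=5, seed=7))
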