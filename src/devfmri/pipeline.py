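"""End-to-end orchestration: simulate -> prep -> connectivity -> reverse
correlation -> overlap -> maturity -> behavior, with a reproducibility
manifest.

Every stochastic stage derives its seed from the run seed; two runs with
the same configuration produce byte-identical output files. Outputs are
CSV/JSON; TR indices in files are 1-based inclusive.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acquisition import AcquisitionParams, ConfigurationError
from .connectivity import (
    binned_mean_zmatrices,
    connectivity_analysis,
    fisher_z_matrix,
    summaries_frame,
    summarize_network_correlations,
)
from .behavior import behavioral_analysis
from .io import write_motion, write_timecourses
from .maturity import (
    adult_mean_timecourse,
    maturity_analysis,
    maturity_frame,
    timecourse_maturity,
)
from .overlap import overlap_pvalue
from .prep import (
    PrepOptions,
    RoiTimecourseSet,
    prepare_roi_timecourses,
    subject_passes_exclusion,
)
from .revcorr import (
    detect_events,
    group_mean_timecourse,
    network_timecourse,
    peak_response_table,
    rank_events,
)
from .synth import Cohort, CohortConfig, simulate_cohort

log = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate",
    "prep",
    "connectivity",
    "revcorr",
    "overlap",
    "maturity",
    "behavior",
)

# Bonferroni families used in reporting: 19 ToM+pain events, 7 ToM events,
# 5 child age bins.
DEFAULT_ALPHAS = {
    "per_tr": 0.05,
    "events_all": 0.05 / 19,
    "events_tom": 0.05 / 7,
    "age_bins": 0.05 / 5,
}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "devfmri_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    cohort: CohortConfig = field(default_factory=CohortConfig)
    alphas: dict = field(default_factory=lambda: dict(DEFAULT_ALPHAS))
    n_permutations: int = 1000

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        for name, a in self.alphas.items():
            if not 0 < a < 1:
                raise ConfigurationError(f"alpha {name}={a} outside (0, 1)")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_kwargs = raw.pop("cohort", {})
        acq_kwargs = cohort_kwargs.pop("acq", {})
        cohort = CohortConfig(
            acq=AcquisitionParams(**acq_kwargs), **cohort_kwargs
        )
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(cohort=cohort, **raw)


def _config_digest(config: RunConfig) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict("records")
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    fields = asdict(config)
    fields.pop("out_dir", None)  # where a run lands is not part of what it is
    payload = json.dumps(fields, default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def prepare_cohort(
    cohort: Cohort, options: PrepOptions = PrepOptions()
) -> tuple[list[RoiTimecourseSet], list[str]]:
    """Run the prep pipeline for every subject; returns the prepared sets
    for subjects passing the artifact-exclusion rule plus the excluded ids."""
    prepared, excluded = [], []
    for ts in cohort.timecourses:
        sid = ts.subject_id
        prep = prepare_roi_timecourses(
            ts.values,
            cohort.config.roi_table,
            cohort.motion[sid],
            ts.acq,
            noise_voxels=cohort.noise_voxels.get(sid),
            options=options,
            subject_id=sid,
        )
        if subject_passes_exclusion(prep.mask, ts.acq):
            prepared.append(prep)
        else:
            excluded.append(sid)
            log.info("%s excluded: %d artifact TRs", sid, prep.mask.n_flagged)
    return prepared, excluded


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig | None = None) -> Path:
    """Execute the configured stages into ``config.out_dir``.

    Upstream results a requested stage depends on are always computed (in
    memory, deterministically); the ``stages`` tuple only controls which
    output files are written. Returns the run directory.
    """
    config = config or RunConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    acq = config.cohort.acq
    roi_tab = config.cohort.roi_table
    written: list[str] = []

    cohort = simulate_cohort(replace(config.cohort, seed=config.seed))
    records = cohort.records_frame()
    if "simulate" in stages:
        write_timecourses(out / "timecourses.tsv", cohort.timecourses)
        write_motion(out / "motion.tsv", cohort.motion)
        _write_csv(records, out / "metadata.csv")
        _write_csv(roi_tab, out / "roi_table.csv")
        written += ["timecourses.tsv", "motion.tsv", "metadata.csv",
                    "roi_table.csv"]

    need_prep = stages & {
        "prep", "connectivity", "revcorr", "overlap", "maturity"
    }
    results: dict[str, object] = {}
    if need_prep:
        prepared_conn, excluded = prepare_cohort(
            cohort, PrepOptions(for_connectivity=True)
        )
        prepared_tc, _ = prepare_cohort(
            cohort, PrepOptions(for_connectivity=False)
        )
        if "prep" in stages:
            write_timecourses(
                out / "prepared_timecourses.tsv", prepared_tc
            )
            _write_csv(
                pd.DataFrame({"subject_id": excluded}),
                out / "excluded_subjects.csv",
            )
            written += ["prepared_timecourses.tsv", "excluded_subjects.csv"]

        if stages & {"connectivity", "maturity"}:
            zmats = {
                p.subject_id: fisher_z_matrix(p) for p in prepared_conn
            }
            summaries = summaries_frame(
                [
                    summarize_network_correlations(z, roi_tab, subject_id=s)
                    for s, z in zmats.items()
                ]
            )
            results["summaries"] = summaries
            if "connectivity" in stages:
                _write_csv(summaries, out / "network_summaries.csv")
                contrasts = connectivity_analysis(summaries, records)
                _write_csv(contrasts, out / "connectivity_contrasts.csv")
                written += ["network_summaries.csv",
                            "connectivity_contrasts.csv"]
                binned = binned_mean_zmatrices(zmats, records)
                for label, mat in binned.items():
                    name = f"zmatrix_{label}.csv"
                    mat.to_csv(out / name, float_format="%.10g")
                    written.append(name)

        if stages & {"revcorr", "overlap", "maturity"}:
            ids_adult = {
                r.subject_id for r in cohort.records if r.group == "adult"
            }
            nts = {
                net: [
                    network_timecourse(p, roi_tab, net)
                    for p in prepared_tc
                ]
                for net in ("ToM", "Pain")
            }
            adult_nts = {
                net: [nt for nt in nts[net] if nt.subject_id in ids_adult]
                for net in ("ToM", "Pain")
            }
            event_sets = {}
            for net in ("ToM", "Pain"):
                if len(adult_nts[net]) < 3:
                    raise ConfigurationError(
                        "reverse correlation needs >= 3 adults"
                    )
                detected = detect_events(
                    adult_nts[net], alpha=config.alphas["per_tr"]
                )
                event_sets[net] = rank_events(
                    detected, group_mean_timecourse(adult_nts[net])
                )
            results["events"] = event_sets
            if "revcorr" in stages:
                events_df = pd.concat(
                    [
                        es.to_frame(acq.tr_seconds)
                        for es in event_sets.values()
                    ],
                    ignore_index=True,
                )
                _write_csv(events_df, out / "events.csv")
                responses = pd.concat(
                    [
                        peak_response_table(nts[net], event_sets[net])
                        for net in ("ToM", "Pain")
                    ],
                    ignore_index=True,
                )
                _write_csv(responses, out / "peak_responses.csv")
                written += ["events.csv", "peak_responses.csv"]

            if "overlap" in stages:
                perm = overlap_pvalue(
                    event_sets["ToM"],
                    event_sets["Pain"],
                    total_len=acq.n_analyzed,
                    n=config.n_permutations,
                    seed=config.seed + 1,
                    start_tr=acq.analysis_window[0],
                )
                (out / "overlap.json").write_text(perm.to_json())
                written.append("overlap.json")

            if "maturity" in stages:
                scores = []
                for net in ("ToM", "Pain"):
                    raw_nts = [
                        network_timecourse(p, roi_tab, net, zscore=False)
                        for p in prepared_tc
                        if p.subject_id not in ids_adult
                    ]
                    adult_raw = [
                        network_timecourse(p, roi_tab, net, zscore=False)
                        for p in prepared_tc
                        if p.subject_id in ids_adult
                    ]
                    template = adult_mean_timecourse(adult_raw)
                    scores += [
                        timecourse_maturity(nt, template) for nt in raw_nts
                    ]
                mat = maturity_frame(scores)
                _write_csv(mat, out / "maturity.csv")
                written.append("maturity.csv")
                if "summaries" in results:
                    mat_res = maturity_analysis(
                        mat, results["summaries"], records
                    )
                    _write_csv(mat_res, out / "maturity_contrasts.csv")
                    written.append("maturity_contrasts.csv")

    if "behavior" in stages:
        kids = records[records["group"] == "child"]
        _write_csv(
            kids[
                ["subject_id", "age_years", "tom_prop_correct",
                 "fb_composite", "fb_group", "dccs_summary"]
            ],
            out / "behavior_scores.csv",
        )
        stats = behavioral_analysis(kids)
        _write_csv(stats, out / "behavior_stats.csv")
        written += ["behavior_scores.csv", "behavior_stats.csv"]

    manifest = {
        "package": "devfmri",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {"simulate": config.seed,
                        "overlap": config.seed + 1},
        "stages": sorted(stages),
        "config_sha256": _config_digest(config),
        "alphas": config.alphas,
        "files": sorted(written),
        "n_subjects": len(cohort.records),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
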