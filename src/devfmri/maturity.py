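"""Functional maturity: similarity of a child's network timecourse to the
adult average.

Maturity is the Pearson correlation, over the analysis window, between a
child's network-averaged timecourse (not z-normalized) and the mean adult
timecourse, computed over jointly non-missing TRs. The adult template is
the per-TR average of adults passing the artifact-exclusion rule; children
never contribute to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acquisition import window_slice
from .connectivity import ols_regression
from .prep import InputError
from .revcorr import NetworkTimecourse, group_mean_timecourse

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MaturityScore:
    subject_id: str
    network: str
    r: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise InputError(f"maturity r {self.r} outside [-1, 1]")


def adult_mean_timecourse(adults: list[NetworkTimecourse]) -> np.ndarray:
    """The adult template: per-TR mean over available (non-missing) values."""
    return group_mean_timecourse(adults)


def timecourse_maturity(
    child: NetworkTimecourse,
    adult_mean: np.ndarray,
    window: tuple[int, int] | None = None,
) -> MaturityScore:
    """Pearson r between a child timecourse and the adult template."""
    window = window or child.window
    sl = window_slice(window)
    x = np.asarray(child.values, dtype=float)[sl]
    y = np.asarray(adult_mean, dtype=float)[sl]
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise InputError(
            f"{child.subject_id}: fewer than 3 jointly non-missing TRs"
        )
    if x[ok].std() == 0 or y[ok].std() == 0:
        raise InputError("constant series; maturity undefined")
    r = float(np.corrcoef(x[ok], y[ok])[0, 1])
    return MaturityScore(
        subject_id=child.subject_id, network=child.network, r=r
    )


def maturity_frame(scores: list[MaturityScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"subject_id": s.subject_id, "network": s.network, "r": s.r}
         for s in scores]
    )


def maturity_analysis(
    scores: pd.DataFrame,
    summaries: pd.DataFrame,
    records: pd.DataFrame,
) -> pd.DataFrame:
    """The maturity regression battery (standardized OLS), per network:

    * maturity ~ across_z + within_z + age + motion,
    * within_z ~ maturity + age + motion,
    * maturity ~ age + ToM score + motion (ToM network),
    * maturity ~ FB pass-vs-fail + age + motion (3-5-year-olds).

    ``scores`` is the long (subject_id, network, r) table for children.
    Duplicate subject ids within a network are rejected.
    """
    required = {"subject_id", "network", "r"}
    if not required <= set(scores.columns):
        raise InputError(f"scores table needs columns {sorted(required)}")
    rows: list[dict] = []
    for network, sub in scores.groupby("network"):
        if sub["subject_id"].duplicated().any():
            dupes = sub.loc[
                sub["subject_id"].duplicated(), "subject_id"
            ].tolist()
            raise InputError(f"duplicate subject ids: {dupes}")
        within_col = (
            "within_tom_z" if network == "ToM" else "within_pain_z"
        )
        df = (
            sub.merge(summaries, on="subject_id", validate="one_to_one")
            .merge(records, on="subject_id", validate="one_to_one")
        )
        df = df[df["group"] == "child"]
        missing = [
            c
            for c in ("age_years", "n_artifact_timepoints", within_col,
                      "across_z")
            if c not in df.columns
        ]
        if missing:
            raise InputError(f"missing columns: {missing}")
        if len(df) < 5:
            log.info("%s: fewer than 5 children; maturity analysis skipped",
                     network)
            continue

        def reg(contrast, y, X, terms):
            res = ols_regression(df[y], X)
            for t in terms:
                b, tval, p = res.params[t]
                rows.append(
                    {
                        "network": network,
                        "contrast": contrast,
                        "term": t,
                        "b": b,
                        "t": tval,
                        "p": p,
                        "n": res.n,
                        "df": res.df_resid,
                    }
                )

        base = pd.DataFrame(
            {
                "across_z": df["across_z"],
                "within_z": df[within_col],
                "age": df["age_years"],
                "motion": df["n_artifact_timepoints"],
            }
        )
        reg("maturity_by_connectivity", "r", base,
            ["across_z", "within_z", "age", "motion"])
        reg(
            "within_by_maturity",
            within_col,
            pd.DataFrame(
                {
                    "maturity": df["r"],
                    "age": df["age_years"],
                    "motion": df["n_artifact_timepoints"],
                }
            ),
            ["maturity", "age", "motion"],
        )
        if network == "ToM" and "tom_prop_correct" in df.columns:
            kids = df.dropna(subset=["tom_prop_correct"])
            if len(kids) >= 5:
                res = ols_regression(
                    kids["r"],
                    pd.DataFrame(
                        {
                            "age": kids["age_years"],
                            "tom_score": kids["tom_prop_correct"],
                            "motion": kids["n_artifact_timepoints"],
                        }
                    ),
                )
                for t in ("age", "tom_score", "motion"):
                    b, tval, p = res.params[t]
                    rows.append(
                        {
                            "network": network,
                            "contrast": "maturity_by_age_tom",
                            "term": t,
                            "b": b,
                            "t": tval,
                            "p": p,
                            "n": res.n,
                            "df": res.df_resid,
                        }
                    )
        if "fb_group" in df.columns:
            fb = df[df["fb_group"].isin(["pass", "fail"])]
            if len(fb) >= 5 and fb["fb_group"].nunique() == 2:
                res = ols_regression(
                    fb["r"],
                    pd.DataFrame(
                        {
                            "fb_pass": (fb["fb_group"] == "pass").astype(float),
                            "age": fb["age_years"],
                            "motion": fb["n_artifact_timepoints"],
                        }
                    ),
                )
                for t in ("fb_pass", "age", "motion"):
                    b, tval, p = res.params[t]
                    rows.append(
                        {
                            "network": network,
                            "contrast": "maturity_by_fb_group",
                            "term": t,
                            "b": b,
                            "t": tval,
                            "p": p,
                            "n": res.n,
                            "df": res.df_resid,
                        }
                    )
    return pd.DataFrame(rows)
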