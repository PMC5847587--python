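"""Explicit theory-of-mind battery scoring and behavioral statistics.

Children answer 24 matched ToM items (14 prediction, 10 explanation), two
attention-control items, and six explicit false-belief items (4 prediction,
2 explanation). The battery score is the proportion correct of the 24
matched items; the false-belief composite is the count correct of the six
FB items, classified as pass (5-6), inconsistent (3-4) or fail (0-2).
Classification applies only to 3-5-year-olds; other ages are marked
``not_applicable``. The DCCS response-inhibition summary (0-3) is consumed
as given, not recomputed from trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import partial_rank_correlation
from .prep import InputError

log = logging.getLogger(__name__)

N_TOM_ITEMS = 24
N_FB_ITEMS = 6
N_CONTROL_ITEMS = 2
FB_AGE_RANGE = (3.0, 6.0)  # half-open [3, 6): the 3-5-year-olds

FB_GROUPS = ("pass", "inconsistent", "fail")


@dataclass(frozen=True)
class BehaviorScores:
    """One child's scored battery."""

    tom_items: tuple[int, ...]
    fb_items: tuple[int, ...]
    control_items: tuple[int, ...]
    tom_prop_correct: float
    fb_composite: int
    fb_group: str  # pass / inconsistent / fail / not_applicable
    dccs_summary: float | None = None


def classify_fb(fb_composite: int) -> str:
    """pass (5-6), inconsistent (3-4), fail (0-2)."""
    if not isinstance(fb_composite, (int, np.integer)):
        raise InputError("fb_composite must be an integer")
    if not 0 <= fb_composite <= 6:
        raise InputError(f"fb_composite {fb_composite} outside [0, 6]")
    if fb_composite >= 5:
        return "pass"
    if fb_composite >= 3:
        return "inconsistent"
    return "fail"


def _check_items(name: str, items, n: int) -> tuple[int, ...]:
    vals = list(items)
    if len(vals) != n:
        raise InputError(f"{name}: expected {n} items, got {len(vals)}")
    out = []
    for v in vals:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise InputError(f"{name}: missing item response")
        if v not in (0, 1, True, False):
            raise InputError(f"{name}: responses must be 0/1, got {v!r}")
        out.append(int(v))
    return tuple(out)


def score_tom_battery(
    tom_items,
    fb_items,
    control_items,
    age_years: float | None = None,
    dccs_summary: float | None = None,
) -> BehaviorScores:
    """Score one child's item responses.

    Control-item failures are logged as warnings (in practice all children
    pass them). The false-belief group is computed only when ``age_years``
    is within the 3-5-year range; otherwise it is ``not_applicable``.
    """
    tom = _check_items("tom_items", tom_items, N_TOM_ITEMS)
    fb = _check_items("fb_items", fb_items, N_FB_ITEMS)
    ctrl = _check_items("control_items", control_items, N_CONTROL_ITEMS)
    if sum(ctrl) < N_CONTROL_ITEMS:
        log.warning("control item(s) failed; check attentiveness")
    composite = int(sum(fb))
    if age_years is None or FB_AGE_RANGE[0] <= age_years < FB_AGE_RANGE[1]:
        group = classify_fb(composite)
    else:
        group = "not_applicable"
    if dccs_summary is not None and not 0 <= dccs_summary <= 3:
        raise InputError("dccs_summary must be in [0, 3]")
    return BehaviorScores(
        tom_items=tom,
        fb_items=fb,
        control_items=ctrl,
        tom_prop_correct=float(np.mean(tom)),
        fb_composite=composite,
        fb_group=group,
        dccs_summary=dccs_summary,
    )


def score_item_table(items: pd.DataFrame) -> pd.DataFrame:
    """Score an item-level table (tom_q1..tom_q24, fb_q1..fb_q6, ctrl_q1,
    ctrl_q2, optional dccs_summary and age_years, one row per subject)."""
    rows = []
    for _, r in items.iterrows():
        scores = score_tom_battery(
            [r[f"tom_q{i}"] for i in range(1, N_TOM_ITEMS + 1)],
            [r[f"fb_q{i}"] for i in range(1, N_FB_ITEMS + 1)],
            [r[f"ctrl_q{i}"] for i in range(1, N_CONTROL_ITEMS + 1)],
            age_years=r.get("age_years"),
            dccs_summary=(
                None if pd.isna(r.get("dccs_summary")) else r["dccs_summary"]
            ),
        )
        rows.append(
            {
                "subject_id": r.get("subject_id"),
                "tom_prop_correct": scores.tom_prop_correct,
                "fb_composite": scores.fb_composite,
                "fb_group": scores.fb_group,
                "dccs_summary": scores.dccs_summary,
            }
        )
    return pd.DataFrame(rows)


def behavioral_analysis(records: pd.DataFrame) -> pd.DataFrame:
    """The printed behavioral battery: age correlations (Kendall tau, given
    ties and non-normal scores), the ToM-DCCS partial tau controlling age,
    and false-belief-group contrasts on the battery score (group means,
    one-way ANOVA, Kruskal-Wallis, Tukey HSD via statsmodels).

    ``records`` needs subject_id, age_years, tom_prop_correct and optionally
    dccs_summary, fb_group. Tests with fewer than 5 usable subjects are
    skipped with a log message.
    """
    rows: list[dict] = []
    kids = records.dropna(subset=["age_years", "tom_prop_correct"])

    def add(contrast, method, term, estimate, statistic, df, p, n):
        rows.append(
            {
                "contrast": contrast,
                "method": method,
                "term": term,
                "estimate": estimate,
                "statistic": statistic,
                "df": df,
                "p": p,
                "n": n,
            }
        )

    if len(kids) >= 5:
        res = partial_rank_correlation(
            kids["age_years"], kids["tom_prop_correct"], method="kendall"
        )
        add("age_vs_tom", res.method, "age_years", res.estimate,
            res.statistic, res.df, res.p, res.n)
    else:
        log.info("age_vs_tom skipped: fewer than 5 usable subjects")

    if "dccs_summary" in records.columns:
        d = records.dropna(subset=["age_years", "dccs_summary"])
        if len(d) >= 5 and d["dccs_summary"].std() > 0:
            res = partial_rank_correlation(
                d["age_years"], d["dccs_summary"], method="kendall"
            )
            add("age_vs_dccs", res.method, "age_years", res.estimate,
                res.statistic, res.df, res.p, res.n)
            both = d.dropna(subset=["tom_prop_correct"])
            if len(both) >= 5:
                res = partial_rank_correlation(
                    both["tom_prop_correct"],
                    both["dccs_summary"],
                    both["age_years"],
                    method="kendall",
                )
                add("tom_vs_dccs_given_age", res.method, "dccs_summary",
                    res.estimate, res.statistic, res.df, res.p, res.n)
        else:
            log.info("DCCS tests skipped: constant or too few values")

    if "fb_group" in records.columns:
        fb = records[records["fb_group"].isin(FB_GROUPS)].dropna(
            subset=["tom_prop_correct"]
        )
        groups = [
            fb.loc[fb["fb_group"] == g, "tom_prop_correct"].to_numpy()
            for g in FB_GROUPS
        ]
        if all(len(g) >= 2 for g in groups) and len(fb) >= 5:
            for g, vals in zip(FB_GROUPS, groups):
                add(f"tom_by_fb_group", "group_mean", g, float(vals.mean()),
                    np.nan, len(vals) - 1, np.nan, len(vals))
            F, p = stats.f_oneway(*groups)
            add("tom_by_fb_group", "anova", "fb_group", np.nan, float(F),
                len(fb) - len(groups), float(p), len(fb))
            H, p = stats.kruskal(*groups)
            add("tom_by_fb_group", "kruskal_wallis", "fb_group", np.nan,
                float(H), len(groups) - 1, float(p), len(fb))
            try:
                from statsmodels.stats.multicomp import pairwise_tukeyhsd

                tk = pairwise_tukeyhsd(
                    fb["tom_prop_correct"].to_numpy(),
                    fb["fb_group"].to_numpy(),
                )
                names = tk.groupsunique
                i1, i2 = tk._multicomp.pairindices
                for g1, g2, diff, padj in zip(
                    i1, i2, tk.meandiffs, tk.pvalues
                ):
                    add("tom_by_fb_group", "tukey_hsd",
                        f"{names[g1]}-{names[g2]}", float(diff), np.nan,
                        np.nan, float(padj), len(fb))
            except Exception:  # pragma: no cover - Tukey is a convenience
                log.exception("Tukey HSD failed; omitting pairwise rows")
        else:
            log.info("FB-group contrasts skipped: groups too small")
    return pd.DataFrame(rows)
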