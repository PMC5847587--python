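"""Inter-region correlation analysis and its statistics.

Per subject, every ROI timecourse is correlated with every other over the
analysis window (pairwise-complete across NaN-ed artifact TRs) and Fisher
z-transformed. Network summaries average the z values over unordered
same-network pairs (within-ToM, within-Pain, and the non-bilateral variants
that drop homologous left/right pairs) and over all ToM x Pain pairs
(across-network).

Statistics offered here are the ones the developmental contrasts need:
partial rank correlations (Spearman or Kendall tau-b on rank residuals,
with motion or age as covariates) and OLS regression on a standardized
scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .acquisition import window_slice
from .prep import InputError, RoiTimecourseSet
from .rois import bilateral_pairs

log = logging.getLogger(__name__)

_R_CAP = 1.0 - 1e-15

SUMMARY_COLUMNS = [
    "subject_id",
    "within_tom_z",
    "within_pain_z",
    "across_z",
    "within_tom_nonbilateral_z",
    "within_pain_nonbilateral_z",
]


@dataclass(frozen=True)
class CorrelationSummary:
    """Per-subject within/across-network mean Fisher-z correlations."""

    subject_id: str
    within_tom_z: float
    within_pain_z: float
    across_z: float
    within_tom_nonbilateral_z: float
    within_pain_nonbilateral_z: float


@dataclass(frozen=True)
class StatResult:
    """A correlation-type test: estimate (r, r_s or r_k), statistic, df, p."""

    method: str
    estimate: float
    statistic: float
    df: int
    p: float
    n: int


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit: per-predictor (b, t, p) plus sample size and residual df."""

    params: dict[str, tuple[float, float, float]]
    n: int
    df_resid: int
    standardized: bool

    def b(self, term: str) -> float:
        return self.params[term][0]

    def t(self, term: str) -> float:
        return self.params[term][1]

    def p(self, term: str) -> float:
        return self.params[term][2]


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """atanh transform, capping |r| just below 1 (with a warning) so
    degenerate inputs stay finite."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > _R_CAP):
        log.warning("correlation at |r|=1 capped before Fisher transform")
    return np.arctanh(np.clip(r, -_R_CAP, _R_CAP))


def fisher_z_matrix(
    roiset: RoiTimecourseSet, min_trs: int = 3
) -> pd.DataFrame:
    """ROI x ROI matrix of Fisher-z correlations over the analysis window.

    Correlations use pairwise-complete TRs (both series non-missing); the
    diagonal is NaN. A constant timecourse raises, naming the ROI.
    """
    sl = window_slice(roiset.acq.analysis_window)
    vals = roiset.values[:, sl]
    names = roiset.roi_names
    n = len(names)
    z = np.full((n, n), np.nan)
    finite = np.isfinite(vals)
    for i in range(n):
        for j in range(i + 1, n):
            ok = finite[i] & finite[j]
            if ok.sum() < min_trs:
                raise InputError(
                    f"pair ({names[i]}, {names[j]}): fewer than {min_trs} "
                    "jointly non-missing TRs"
                )
            xi, xj = vals[i, ok], vals[j, ok]
            for name, s in ((names[i], xi), (names[j], xj)):
                if s.std() == 0:
                    raise InputError(
                        f"ROI {name}: constant timecourse, correlation "
                        "undefined"
                    )
            r = np.corrcoef(xi, xj)[0, 1]
            z[i, j] = z[j, i] = fisher_z(r)
    return pd.DataFrame(z, index=names, columns=names)


def _pair_mean(
    zmat: pd.DataFrame, rows: list[str], cols: list[str] | None = None
) -> float:
    if cols is None:  # unordered distinct same-network pairs
        vals = [
            zmat.loc[a, b]
            for i, a in enumerate(rows)
            for b in rows[i + 1 :]
        ]
    else:
        vals = [zmat.loc[a, b] for a in rows for b in cols]
    return float(np.mean(vals))


def summarize_network_correlations(
    zmat: pd.DataFrame,
    roi_table: pd.DataFrame,
    subject_id: str = "",
    exclude_bilateral: bool = False,
) -> CorrelationSummary:
    """Within-ToM / within-Pain / across-network mean Fisher-z values.

    Within means average over unordered distinct same-network pairs; the
    across mean covers all ToM x Pain pairs. The non-bilateral variants drop
    same-network pairs that are left/right homologues; with
    ``exclude_bilateral`` those variants are also reported as the main
    within values.
    """
    tom = roi_table.loc[roi_table["network"] == "ToM", "name"].tolist()
    pain = roi_table.loc[roi_table["network"] == "Pain", "name"].tolist()
    for net, names in (("ToM", tom), ("Pain", pain)):
        if len(names) < 2:
            raise InputError(f"network {net}: need >= 2 ROIs in roi_table")
    bilat = {frozenset(p) for p in bilateral_pairs(roi_table)}

    def nonbilateral(names: list[str]) -> float:
        vals = [
            zmat.loc[a, b]
            for i, a in enumerate(names)
            for b in names[i + 1 :]
            if frozenset((a, b)) not in bilat
        ]
        return float(np.mean(vals))

    within_tom = _pair_mean(zmat, tom)
    within_pain = _pair_mean(zmat, pain)
    nb_tom = nonbilateral(tom)
    nb_pain = nonbilateral(pain)
    return CorrelationSummary(
        subject_id=subject_id,
        within_tom_z=nb_tom if exclude_bilateral else within_tom,
        within_pain_z=nb_pain if exclude_bilateral else within_pain,
        across_z=_pair_mean(zmat, tom, pain),
        within_tom_nonbilateral_z=nb_tom,
        within_pain_nonbilateral_z=nb_pain,
    )


def _rank_residuals(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, int]:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if covariates is None or covariates.size == 0:
        return rx - rx.mean(), ry - ry.mean(), 0
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != len(x):
        C = C.T
    rc = np.column_stack(
        [np.ones(len(x))] + [stats.rankdata(C[:, j]) for j in range(C.shape[1])]
    )
    beta_x, *_ = np.linalg.lstsq(rc, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(rc, ry, rcond=None)
    return rx - rc @ beta_x, ry - rc @ beta_y, C.shape[1]


def partial_rank_correlation(
    x,
    y,
    covariates=None,
    method: str = "spearman",
) -> StatResult:
    """Rank correlation of x and y after residualizing on covariate ranks.

    ``spearman``: Pearson correlation of the rank residuals, t-test p with
    df = n - 2 - k. ``kendall``: tau-b of the rank residuals with the normal
    approximation p (ties expected in behavioral scores). With no
    covariates both reduce to the plain rank correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D and the same length")
    if np.isnan(x).any() or np.isnan(y).any() or (
        covariates is not None and np.isnan(np.asarray(covariates, float)).any()
    ):
        raise InputError("missing values not allowed; drop them first")
    n = len(x)
    if n < 5:
        raise InputError("need n >= 5")
    if x.std() == 0 or y.std() == 0:
        raise InputError("constant input to rank correlation")
    ex, ey, k = _rank_residuals(
        x, y, None if covariates is None else np.asarray(covariates, float)
    )
    df = n - 2 - k
    if method == "spearman":
        r = float(np.corrcoef(ex, ey)[0, 1])
        denom = max(1.0 - r * r, np.finfo(float).tiny)
        with np.errstate(over="ignore"):
            tstat = r * np.sqrt(df / denom)
        p = 2 * stats.t.sf(abs(tstat), df)
        return StatResult("partial_spearman", r, float(tstat), df, float(p), n)
    if method == "kendall":
        res = stats.kendalltau(ex, ey)
        return StatResult(
            "partial_kendall",
            float(res.statistic),
            float(res.statistic),
            df,
            float(res.pvalue),
            n,
        )
    raise InputError(f"unknown method {method!r}")


def ols_regression(
    response,
    predictors: pd.DataFrame,
    standardize: bool = True,
) -> RegressionResult:
    """OLS with intercept and two-sided t p-values.

    With ``standardize`` (the default) both the response and every predictor
    are z-scored first, so coefficients are on a standardized scale (the
    scale on which binary group effects of magnitude ~1 are reported);
    ``standardize=False`` gives raw-scale coefficients.
    """
    y = np.asarray(response, dtype=float)
    X = predictors.astype(float).copy()
    if len(y) != len(X):
        raise InputError("response and predictors length mismatch")
    if np.isnan(y).any() or X.isna().to_numpy().any():
        raise InputError("missing values in regression input")
    if standardize:
        sy = y.std(ddof=1)
        if sy == 0:
            raise InputError("constant response")
        y = (y - y.mean()) / sy
        for c in X.columns:
            s = X[c].std(ddof=1)
            if s == 0:
                raise InputError(f"constant predictor {c!r}")
            X[c] = (X[c] - X[c].mean()) / s
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        pairs = [
            (a, b)
            for a in corr.index
            for b in corr.columns
            if a < b and corr.loc[a, b] > 1 - 1e-10
        ]
        raise InputError(f"collinear predictors: {pairs or list(X.columns)}")
    fit = sm.OLS(y, design).fit()
    params = {
        name: (
            float(fit.params[name]),
            float(fit.tvalues[name]),
            float(fit.pvalues[name]),
        )
        for name in design.columns
    }
    return RegressionResult(
        params=params,
        n=len(y),
        df_resid=int(fit.df_resid),
        standardized=standardize,
    )


def summaries_frame(summaries: list[CorrelationSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries], columns=SUMMARY_COLUMNS)


def _result_row(**kw) -> dict:
    base = {
        "contrast": None,
        "measure": None,
        "method": None,
        "term": None,
        "estimate": np.nan,
        "statistic": np.nan,
        "df": np.nan,
        "p": np.nan,
        "n": np.nan,
    }
    base.update(kw)
    return base


def _regression_rows(
    contrast: str, measure: str, res: RegressionResult, terms: list[str]
) -> list[dict]:
    return [
        _result_row(
            contrast=contrast,
            measure=measure,
            method="ols_standardized" if res.standardized else "ols",
            term=t,
            estimate=res.b(t),
            statistic=res.t(t),
            df=res.df_resid,
            p=res.p(t),
            n=res.n,
        )
        for t in terms
    ]


def connectivity_analysis(
    summaries: pd.DataFrame,
    records: pd.DataFrame,
    measures: tuple[str, ...] = ("within_tom_z", "within_pain_z", "across_z"),
) -> pd.DataFrame:
    """The battery of developmental contrasts on the network summaries.

    Per measure: the child age trend (partial Spearman with motion as
    covariate), the child-vs-adult group regression (group + motion,
    standardized), the ToM-score relation among children (partial Kendall
    with motion; and a regression adding age), and the false-belief
    pass-vs-fail contrast among 3-5-year-olds (group + age + motion,
    optionally + DCCS).

    ``records`` needs columns subject_id, group, age_years,
    n_artifact_timepoints, and (for children) tom_prop_correct, fb_group,
    dccs_summary.
    """
    if summaries.empty or records.empty:
        raise InputError("empty cohort")
    df = summaries.merge(records, on="subject_id", validate="one_to_one")
    missing = [
        c
        for c in ("group", "age_years", "n_artifact_timepoints")
        if c not in df.columns
    ]
    if missing:
        raise InputError(f"records missing columns: {missing}")
    children = df[df["group"] == "child"]
    rows: list[dict] = []
    for m in measures:
        if len(children) >= 5:
            res = partial_rank_correlation(
                children["age_years"],
                children[m],
                children["n_artifact_timepoints"],
                method="spearman",
            )
            rows.append(
                _result_row(
                    contrast="age_trend",
                    measure=m,
                    method=res.method,
                    term="age_years",
                    estimate=res.estimate,
                    statistic=res.statistic,
                    df=res.df,
                    p=res.p,
                    n=res.n,
                )
            )
        if df["group"].nunique() == 2:
            X = pd.DataFrame(
                {
                    "is_child": (df["group"] == "child").astype(float),
                    "motion": df["n_artifact_timepoints"],
                }
            )
            res = ols_regression(df[m], X)
            rows += _regression_rows("group_child_vs_adult", m, res,
                                     ["is_child", "motion"])
        if "tom_prop_correct" in children.columns and len(children) >= 5:
            kids = children.dropna(subset=["tom_prop_correct"])
            res = partial_rank_correlation(
                kids["tom_prop_correct"],
                kids[m],
                kids["n_artifact_timepoints"],
                method="kendall",
            )
            rows.append(
                _result_row(
                    contrast="tom_score",
                    measure=m,
                    method=res.method,
                    term="tom_prop_correct",
                    estimate=res.estimate,
                    statistic=res.statistic,
                    df=res.df,
                    p=res.p,
                    n=res.n,
                )
            )
            X = pd.DataFrame(
                {
                    "tom_score": kids["tom_prop_correct"],
                    "age": kids["age_years"],
                    "motion": kids["n_artifact_timepoints"],
                }
            )
            res2 = ols_regression(kids[m], X)
            rows += _regression_rows("tom_score_regression", m, res2,
                                     ["tom_score", "age", "motion"])
        if "fb_group" in children.columns:
            fb = children[children["fb_group"].isin(["pass", "fail"])]
            if len(fb) >= 5 and fb["fb_group"].nunique() == 2:
                X = pd.DataFrame(
                    {
                        "fb_pass": (fb["fb_group"] == "pass").astype(float),
                        "age": fb["age_years"],
                        "motion": fb["n_artifact_timepoints"],
                    }
                )
                res = ols_regression(fb[m], X)
                rows += _regression_rows("fb_pass_vs_fail", m, res,
                                         ["fb_pass", "age", "motion"])
                if "dccs_summary" in fb.columns:
                    fbd = fb.dropna(subset=["dccs_summary"])
                    if len(fbd) >= 5 and fbd["dccs_summary"].std() > 0:
                        Xd = pd.DataFrame(
                            {
                                "fb_pass": (fbd["fb_group"] == "pass").astype(float),
                                "age": fbd["age_years"],
                                "motion": fbd["n_artifact_timepoints"],
                                "dccs": fbd["dccs_summary"],
                            }
                        )
                        resd = ols_regression(fbd[m], Xd)
                        rows += _regression_rows(
                            "fb_pass_vs_fail_dccs", m, resd,
                            ["fb_pass", "age", "motion", "dccs"],
                        )
    return pd.DataFrame(rows)


def binned_mean_zmatrices(
    zmats: dict[str, pd.DataFrame],
    records: pd.DataFrame,
    bins: tuple[tuple[str, float, float], ...] = (
        ("3yo", 3.0, 4.0),
        ("4yo", 4.0, 5.0),
        ("5yo", 5.0, 6.0),
        ("7yo", 6.0, 8.0),
        ("8-12yo", 8.0, 13.0),
    ),
) -> dict[str, pd.DataFrame]:
    """Mean z-matrix per reporting age bin (children) plus adults."""
    out: dict[str, pd.DataFrame] = {}
    rec = records.set_index("subject_id")
    for label, lo, hi in bins:
        ids = [
            s
            for s in zmats
            if s in rec.index
            and rec.loc[s, "group"] == "child"
            and lo <= rec.loc[s, "age_years"] < hi
        ]
        if ids:
            out[label] = sum(zmats[s] for s in ids) / len(ids)
    adult_ids = [
        s for s in zmats if s in rec.index and rec.loc[s, "group"] == "adult"
    ]
    if adult_ids:
        out["adult"] = sum(zmats[s] for s in adult_ids) / len(adult_ids)
    return out
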