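"""Timecourse preparation: from raw ROI/voxel series to analysis-ready data.

The fixed pipeline (:func:`prepare_roi_timecourses`) is

1. detect artifact timepoints (composite motion step > 2 mm, or global
   signal deviating > 3 s.d. from its mean),
2. nearest-neighbor interpolation over artifact TRs,
3. nuisance regression: one indicator regressor per artifact TR
   (scrub-style), five PCA noise components from a noise-voxel matrix
   (CompCor, computed on the interpolated data), and — for connectivity
   analyses only — the raw bilateral-M1 average timecourse,
4. discrete-cosine high-pass filter (100 s cutoff),
5. voxel averaging per ROI,
6. artifact TRs set to NaN.

Subjects with one third or more of their TRs flagged are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acquisition import AcquisitionParams, ConfigurationError

log = logging.getLogger(__name__)


class InputError(ValueError):
    """Inconsistent or degenerate analysis input."""


@dataclass(frozen=True)
class ArtifactMask:
    """Per-TR artifact flags for one subject's run."""

    flags: np.ndarray  # boolean, length n_volumes

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "flags", np.asarray(self.flags, dtype=bool).copy()
        )
        self.flags.setflags(write=False)

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())

    @property
    def flagged_trs(self) -> np.ndarray:
        """1-based TR indices of the flagged timepoints."""
        return np.flatnonzero(self.flags) + 1


@dataclass
class RoiTimecourseSet:
    """One subject's ROI x TR matrix with its artifact mask.

    ``values`` may contain NaN only at flagged TRs (after preparation).
    """

    subject_id: str
    values: np.ndarray  # (n_rois, n_volumes)
    roi_names: list[str]
    mask: ArtifactMask
    acq: AcquisitionParams

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputError("values must be a 2-D (roi x TR) matrix")
        n_rois, n_trs = self.values.shape
        if n_trs != self.acq.n_volumes:
            raise InputError(
                f"TR dimension {n_trs} != n_volumes {self.acq.n_volumes}"
            )
        if n_rois != len(self.roi_names):
            raise InputError("roi_names length mismatch with values")
        if len(self.mask.flags) != n_trs:
            raise InputError("mask length mismatch with values")
        bad = np.isnan(self.values).any(axis=0) & ~self.mask.flags
        if bad.any():
            raise InputError(
                f"missing values at unflagged TRs {np.flatnonzero(bad) + 1}"
            )

    def roi(self, name: str) -> np.ndarray:
        return self.values[self.roi_names.index(name)]

    def network_values(self, roi_table: pd.DataFrame, network: str) -> np.ndarray:
        names = roi_table.loc[roi_table["network"] == network, "name"]
        idx = [self.roi_names.index(n) for n in names]
        if not idx:
            raise InputError(f"no ROIs for network {network!r}")
        return self.values[idx]


@dataclass(frozen=True)
class PrepOptions:
    """Knobs of the preparation pipeline (defaults match the study design)."""

    for_connectivity: bool = False
    motion_threshold_mm: float = 2.0
    gs_sd_threshold: float = 3.0
    highpass_cutoff_s: float = 100.0
    n_noise_components: int = 5


def composite_motion(
    translations: np.ndarray,
    rotations_rad: np.ndarray,
    head_radius_mm: float = 65.0,
) -> np.ndarray:
    """Framewise composite motion from 6 rigid-body parameters.

    Euclidean norm of the translation deltas plus the rotation deltas
    projected to displacement at ``head_radius_mm``. Returns one value per
    TR; the first is 0 by definition.
    """
    t = np.asarray(translations, dtype=float)
    r = np.asarray(rotations_rad, dtype=float)
    if t.shape != r.shape or t.ndim != 2 or t.shape[1] != 3:
        raise InputError("translations and rotations must both be (n, 3)")
    dt = np.diff(t, axis=0)
    dr = np.diff(r, axis=0)
    step = np.linalg.norm(dt, axis=1) + head_radius_mm * np.linalg.norm(
        dr, axis=1
    )
    return np.concatenate([[0.0], step])


def detect_artifact_timepoints(
    composite_motion: np.ndarray,
    global_signal: np.ndarray,
    motion_threshold: float = 2.0,
    gs_sd_threshold: float = 3.0,
) -> ArtifactMask:
    """Flag TRs with a large motion step or a global-signal excursion.

    ``composite_motion`` is the per-TR composite displacement relative to the
    previous timepoint (first entry 0 by definition); a TR is flagged when it
    exceeds ``motion_threshold`` mm, or when the global signal deviates from
    its mean by more than ``gs_sd_threshold`` standard deviations.
    """
    motion = np.asarray(composite_motion, dtype=float)
    gs = np.asarray(global_signal, dtype=float)
    if motion.shape != gs.shape or motion.ndim != 1:
        raise InputError(
            f"series length mismatch: motion {motion.shape}, global {gs.shape}"
        )
    flags = motion > motion_threshold
    sd = gs.std()
    if sd > 0:
        flags = flags | (np.abs(gs - gs.mean()) > gs_sd_threshold * sd)
    return ArtifactMask(flags)


def subject_passes_exclusion(
    mask: ArtifactMask, acq: AcquisitionParams
) -> bool:
    """False when one third or more of the run's TRs are artifacts."""
    return mask.n_flagged < acq.n_volumes / 3


def interpolate_artifacts(tc: np.ndarray, mask: ArtifactMask) -> np.ndarray:
    """Replace flagged TRs with the nearest unflagged value.

    Equidistant neighbors tie-break to the *preceding* TR (deterministic and
    causal). Works on a 1-D series or a (series x TR) matrix; unflagged TRs
    are returned unchanged. Idempotent.
    """
    tc = np.asarray(tc, dtype=float)
    flags = mask.flags
    n = tc.shape[-1]
    if len(flags) != n:
        raise InputError("mask length mismatch with timecourse")
    good = np.flatnonzero(~flags)
    if good.size == 0:
        raise InputError("all TRs flagged; nothing to interpolate from")
    if good.size == n:
        return tc.copy()
    t = np.arange(n)
    # Nearest unflagged index; searchsorted('right') - 1 gives the preceding
    # good TR, favored on ties.
    pos = np.searchsorted(good, t, side="right") - 1
    prev = good[np.clip(pos, 0, good.size - 1)]
    nxt = good[np.clip(pos + 1, 0, good.size - 1)]
    nearest = np.where(
        (t - prev <= nxt - t) & (pos >= 0),
        prev,
        np.where(pos < 0, nxt, nxt),
    )
    out = tc.copy()
    out[..., flags] = tc[..., nearest[flags]]
    return out


def regress_nuisance(
    tc: np.ndarray,
    nuisance: np.ndarray | None,
    labels: list[str] | None = None,
) -> np.ndarray:
    """Residualize ``tc`` on the nuisance regressors plus an intercept.

    ``tc`` is 1-D (length n) or 2-D (series x n); ``nuisance`` is (n, k) or
    None/empty for intercept-only (mean centering). Residuals are exactly
    orthogonal to every regressor. Raises on a rank-deficient design, naming
    the collinear columns.
    """
    tc = np.asarray(tc, dtype=float)
    n = tc.shape[-1]
    if nuisance is None or (hasattr(nuisance, "size") and nuisance.size == 0):
        X = np.ones((n, 1))
        labels = ["intercept"]
    else:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n:
            if nuisance.shape[1] == n:
                nuisance = nuisance.T
            else:
                raise InputError("nuisance regressors must have length n_volumes")
        X = np.column_stack([np.ones(n), nuisance])
        labels = ["intercept"] + (
            labels
            if labels is not None
            else [f"nuisance_{i}" for i in range(nuisance.shape[1])]
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # Identify offending columns via incremental rank.
        bad, keep = [], np.ones((n, 0))
        for j in range(X.shape[1]):
            cand = np.column_stack([keep, X[:, j]])
            if np.linalg.matrix_rank(cand) > keep.shape[1]:
                keep = cand
            else:
                bad.append(labels[j])
        raise InputError(f"rank-deficient nuisance design; collinear: {bad}")
    beta, *_ = np.linalg.lstsq(X, tc.T if tc.ndim == 2 else tc, rcond=None)
    fitted = (X @ beta).T if tc.ndim == 2 else X @ beta
    return tc - fitted


def noise_components(noise_voxels: np.ndarray, k: int = 5) -> np.ndarray:
    """First ``k`` principal-component time series of a voxel x TR matrix.

    Each voxel series is mean-centered over time; components are ordered by
    decreasing explained variance and returned as a (n_volumes, k) matrix of
    unit-norm time series. ``k`` may not exceed the matrix rank.
    """
    V = np.asarray(noise_voxels, dtype=float)
    if V.ndim != 2:
        raise InputError("noise_voxels must be a 2-D voxel x TR matrix")
    if k == 0:
        return np.empty((V.shape[1], 0))
    if k < 0:
        raise InputError("k must be non-negative")
    if V.shape[0] < k:
        raise InputError(f"need at least {k} noise voxels, got {V.shape[0]}")
    Xc = (V - V.mean(axis=1, keepdims=True)).T  # TR x voxel, centered per voxel
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if k > rank:
        raise InputError(f"k={k} exceeds rank {rank} of the noise matrix")
    return U[:, :k]


def dct_basis(acq: AcquisitionParams, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift basis up to 1/cutoff Hz (excluding the constant)."""
    if cutoff_s <= 2 * acq.tr_seconds:
        raise ConfigurationError(
            f"high-pass cutoff {cutoff_s}s must exceed 2*TR "
            f"({2 * acq.tr_seconds}s)"
        )
    n = acq.n_volumes
    n_basis = int(np.floor(2.0 * n * acq.tr_seconds / cutoff_s))
    t = np.arange(n)
    cols = [
        np.cos(np.pi * (2 * t + 1) * j / (2.0 * n)) for j in range(1, n_basis + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n, 0))


def highpass_filter(
    tc: np.ndarray, acq: AcquisitionParams, cutoff_s: float = 100.0
) -> np.ndarray:
    """Remove fluctuations slower than ``cutoff_s`` (and the mean).

    Implemented as residualization against a discrete-cosine drift basis, so
    a constant input maps to zero and passband sines are preserved. Input
    must be free of missing values (filtering precedes masking).
    """
    tc = np.asarray(tc, dtype=float)
    if np.isnan(tc).any():
        raise InputError("highpass_filter input must not contain NaN")
    return regress_nuisance(tc, dct_basis(acq, cutoff_s))


def prepare_roi_timecourses(
    values: np.ndarray,
    roi_table: pd.DataFrame,
    motion: np.ndarray,
    acq: AcquisitionParams,
    noise_voxels: np.ndarray | None = None,
    series_roi: list[str] | None = None,
    options: PrepOptions = PrepOptions(),
    subject_id: str = "",
    mask: ArtifactMask | None = None,
) -> RoiTimecourseSet:
    """Run the full preparation pipeline for one subject.

    Parameters
    ----------
    values : (n_series, n_volumes) array
        Raw voxel or ROI timecourses. When ``series_roi`` is None, rows must
        correspond 1:1 (in order) to the rows of ``roi_table``; otherwise
        ``series_roi[i]`` names the ROI that row ``i``'s voxel belongs to.
    motion : array
        Per-TR composite motion step (mm relative to previous TR).
    noise_voxels : optional (n_voxels, n_volumes) array
        Noise-region voxels for the PCA noise regressors; without it no noise
        components are used.
    mask : optional ArtifactMask
        Precomputed artifact flags; detected from motion + global signal when
        omitted.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != acq.n_volumes:
        raise InputError("values must be (n_series, n_volumes)")
    roi_names = roi_table["name"].tolist()
    if series_roi is None:
        if values.shape[0] != len(roi_names):
            raise InputError(
                "without series_roi, values rows must match roi_table rows"
            )
        series_roi = roi_names
    empty = [r for r in roi_names if r not in series_roi]
    if empty:
        raise InputError(f"ROIs with zero voxels/series: {empty}")

    if mask is None:
        global_signal = values.mean(axis=0)
        mask = detect_artifact_timepoints(
            motion,
            global_signal,
            motion_threshold=options.motion_threshold_mm,
            gs_sd_threshold=options.gs_sd_threshold,
        )

    # 1) interpolate over artifacts
    interp = interpolate_artifacts(values, mask)

    # 2) nuisance regression
    regs, labels = [], []
    for tr0 in np.flatnonzero(mask.flags):
        ind = np.zeros(acq.n_volumes)
        ind[tr0] = 1.0
        regs.append(ind)
        labels.append(f"artifact_tr{tr0 + 1}")
    if noise_voxels is not None and options.n_noise_components > 0:
        nv = interpolate_artifacts(
            np.asarray(noise_voxels, dtype=float), mask
        )
        pcs = noise_components(nv, options.n_noise_components)
        for j in range(pcs.shape[1]):
            regs.append(pcs[:, j])
            labels.append(f"noise_pc{j + 1}")
    m1_rows: list[int] = []
    if options.for_connectivity:
        net_of = roi_table.set_index("name")["network"]
        m1_rows = [
            i for i, r in enumerate(series_roi) if net_of.loc[r] == "M1"
        ]
        if not m1_rows:
            log.warning(
                "%s: for_connectivity requested but no M1 ROIs present",
                subject_id,
            )
    nuisance = np.column_stack(regs) if regs else None
    if m1_rows:
        # The raw (interpolated) bilateral-M1 average is regressed from the
        # ToM/Pain timecourses only; M1's own rows keep the base nuisance
        # set (regressing M1 out of itself would leave degenerate series).
        m1_reg = interp[m1_rows].mean(axis=0)
        other = [i for i in range(interp.shape[0]) if i not in m1_rows]
        resid = np.empty_like(interp)
        resid[other] = regress_nuisance(
            interp[other],
            np.column_stack(regs + [m1_reg]),
            labels + ["bilateral_m1"],
        )
        resid[m1_rows] = regress_nuisance(interp[m1_rows], nuisance, labels)
    else:
        resid = regress_nuisance(interp, nuisance, labels)

    # 3) high-pass filter
    filtered = highpass_filter(resid, acq, options.highpass_cutoff_s)

    # 4) average voxels per ROI (order-invariant)
    out = np.empty((len(roi_names), acq.n_volumes))
    series_roi_arr = np.asarray(series_roi)
    for i, name in enumerate(roi_names):
        out[i] = filtered[series_roi_arr == name].mean(axis=0)

    # 5) NaN artifact TRs
    out[:, mask.flags] = np.nan
    return RoiTimecourseSet(
        subject_id=subject_id,
        values=out,
        roi_names=roi_names,
        mask=mask,
        acq=acq,
    )
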