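"""Motion censoring, temporal cleaning, parcellation, and concatenation.

The temporal pipeline mirrors a standard resting-state cleanup: framewise
displacement (FD) is computed from six rigid-body parameters, frames above an
FD threshold are censored, each unit's series is detrended (mean, linear,
quadratic) together with any confound regressors on the retained frames,
band-pass filtered (zero-phase) on the full frame grid with censored frames
linearly interpolated beforehand, and finally re-centered on the retained
frames.  Censored frames are dropped only when a statistic is extracted.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .datatypes import BoldRun, MotionTrace, Parcellation

logger = logging.getLogger(__name__)

__all__ = [
    "compute_fd",
    "censor_frames",
    "clean_timeseries",
    "parcellate",
    "volume_match",
    "concat_mean_centered",
    "DEFAULT_FD_THRESHOLD",
    "DEFAULT_BAND",
]

#: Censoring threshold on framewise displacement (mm).
DEFAULT_FD_THRESHOLD = 0.20
#: Band-pass edges in Hz.
DEFAULT_BAND = (0.01, 0.08)
#: Nominal head radius (mm) converting rotations to arc length.
DEFAULT_HEAD_RADIUS = 50.0


def compute_fd(motion: MotionTrace, head_radius: float = DEFAULT_HEAD_RADIUS) -> np.ndarray:
    """Framewise displacement (Power-style) in mm.

    FD[0] = 0 and FD[i] is the sum of absolute frame-to-frame differences of
    the three translations (mm) plus the three rotations converted to arc
    length at ``head_radius`` mm.
    """
    trans = motion.translations
    rot = motion.rotations
    if not (np.all(np.isfinite(trans)) and np.all(np.isfinite(rot))):
        raise ValueError("motion parameters contain non-finite values")
    if trans.shape[0] < 1:
        raise ValueError("motion trace must contain at least one frame")
    fd = np.zeros(trans.shape[0])
    if trans.shape[0] > 1:
        dt = np.abs(np.diff(trans, axis=0)).sum(axis=1)
        dr = np.abs(np.diff(rot, axis=0)).sum(axis=1) * head_radius
        fd[1:] = dt + dr
    return fd


def censor_frames(run: BoldRun, fd: np.ndarray, threshold: float = DEFAULT_FD_THRESHOLD) -> BoldRun:
    """Mark frames with FD above ``threshold`` as censored.

    The data matrix is untouched; only the logical mask changes.  Censoring is
    idempotent: re-censoring with the same trace changes nothing.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.shape[0] != run.n_frames:
        raise ValueError(f"fd length {fd.shape[0]} != frame count {run.n_frames}")
    mask = run.censor_mask & (fd <= threshold)
    n_removed = int(run.censor_mask.sum() - mask.sum())
    logger.info(
        "censor %s ses-%d %s run-%d: removed %d of %d frames (FD > %.3g mm)",
        run.subject, run.session, run.state, run.run, n_removed, run.n_frames, threshold,
    )
    return run.with_mask(mask)


def _drop_dependent_columns(X: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Greedily drop columns that do not increase the rank of X."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
    dropped = [j for j in range(X.shape[1]) if j not in keep]
    return X[:, keep], dropped


def clean_timeseries(
    run: BoldRun,
    confounds: np.ndarray | None = None,
    band: tuple[float, float] | None = DEFAULT_BAND,
    detrend_order: int = 2,
    filter_order: int = 3,
) -> BoldRun:
    """Detrend + confound-regress + band-pass one run.

    Polynomial trends (up to ``detrend_order``) and the confound columns are
    fitted by OLS on the *retained* frames only and removed from the full
    grid.  If ``band`` is given, censored frames of the residual series are
    linearly interpolated, a zero-phase Butterworth band-pass (order
    ``filter_order`` per direction) is applied over the full grid, and the
    result is re-centered on the retained frames.  Pass ``band=None`` to skip
    filtering, in which case the operation is an orthogonal projection
    (applying it twice equals applying it once).
    """
    T = run.n_frames
    mask = run.censor_mask
    if mask.sum() < 2:
        raise ValueError("need at least 2 retained frames to clean a run")
    t = np.linspace(-1.0, 1.0, T)
    cols = [t**k for k in range(detrend_order + 1)]
    if confounds is not None and np.size(confounds):
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] != T:
            raise ValueError("confound matrix must have one row per frame")
        cols.extend(confounds[:, j] for j in range(confounds.shape[1]))
    X = np.column_stack(cols)
    Xr = X[mask]
    if np.linalg.matrix_rank(Xr) < X.shape[1]:
        Xkept, dropped = _drop_dependent_columns(Xr)
        warnings.warn(
            f"confound matrix is rank deficient; dropped dependent columns {dropped}",
            RuntimeWarning,
            stacklevel=2,
        )
        X = X[:, [j for j in range(X.shape[1]) if j not in dropped]]
        Xr = Xkept
    beta, *_ = np.linalg.lstsq(Xr, run.data[mask], rcond=None)
    resid = run.data - X @ beta

    if band is not None:
        lo, hi = band
        fs = 1.0 / run.tr_seconds
        if not (0 < lo < hi < fs / 2):
            raise ValueError(f"band {band} invalid for sampling rate {fs:.4g} Hz")
        if not mask.all():
            idx = np.arange(T)
            good = idx[mask]
            for u in range(resid.shape[1]):
                resid[~mask, u] = np.interp(idx[~mask], good, resid[mask, u])
        sos = sps.butter(filter_order, [lo, hi], btype="bandpass", fs=fs, output="sos")
        resid = sps.sosfiltfilt(sos, resid, axis=0)

    resid = resid - resid[mask].mean(axis=0, keepdims=True)
    return run.with_data(resid)


def parcellate(run: BoldRun, parc: Parcellation) -> BoldRun:
    """Average member units within each parcel, per frame."""
    if run.n_units != parc.unit_to_parcel.shape[0]:
        raise ValueError(
            f"run has {run.n_units} units but parcellation maps {parc.unit_to_parcel.shape[0]}"
        )
    P = parc.n_parcels
    out = np.empty((run.n_frames, P))
    for p in range(1, P + 1):
        members = parc.unit_to_parcel == p
        out[:, p - 1] = run.data[:, members].mean(axis=1)
    new = run.with_data(out)
    new.unit_level = "parcel"
    return new


RunsBySession = Mapping[tuple, Sequence[BoldRun]]


def volume_match(
    runs_by_state: Mapping[str, RunsBySession],
    reference_state: str,
    floor: int = 50,
) -> tuple[int, dict[str, dict[tuple, list[BoldRun]]]]:
    """Equalize retained data quantity across states.

    The target is the global minimum, over subjects and sessions, of the
    retained-frame total of ``reference_state``.  Every (subject, session,
    state) run list is then truncated — by additional censoring — to exactly
    that many retained frames, keeping the earliest frames.
    """
    if reference_state not in runs_by_state:
        raise ValueError(f"reference state {reference_state!r} not present")
    ref_totals = [
        sum(r.n_retained for r in runs)
        for runs in runs_by_state[reference_state].values()
    ]
    if not ref_totals:
        raise ValueError("reference state has no runs")
    target = int(min(ref_totals))
    if target < floor:
        raise ValueError(
            f"volume-match target {target} frames is below the floor of {floor}"
        )
    out: dict[str, dict[tuple, list[BoldRun]]] = {}
    for state, sessions in runs_by_state.items():
        out[state] = {}
        for key, runs in sessions.items():
            kept = 0
            new_runs = []
            for r in runs:
                mask = r.censor_mask.copy()
                retained_idx = np.flatnonzero(mask)
                room = target - kept
                if room <= 0:
                    mask[:] = False
                elif retained_idx.size > room:
                    mask[retained_idx[room:]] = False
                kept += int(mask.sum())
                new_runs.append(r.with_mask(mask))
            out[state][key] = new_runs
    logger.info("volume match: truncated all states to %d retained frames", target)
    return target, out


def concat_mean_centered(runs: Sequence[BoldRun]) -> np.ndarray:
    """Per-run mean-centered retained frames, concatenated in list order."""
    if not runs:
        raise ValueError("no runs to concatenate")
    n_units = runs[0].n_units
    segments = []
    for r in runs:
        if r.n_units != n_units:
            raise ValueError("unit-count mismatch across runs")
        seg = r.retained()
        if seg.shape[0] == 0:
            continue
        segments.append(seg - seg.mean(axis=0, keepdims=True))
    if not segments:
        raise ValueError("all frames censored; nothing to concatenate")
    return np.vstack(segments)
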