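"""Finite-impulse-response task models.

An FIR basis makes no assumption about the hemodynamic response shape: each
condition gets one free regressor per post-stimulus time bin.  Designs are
accumulated on a microtime grid (default 0.1 s) so that bins narrower than the
frame interval contribute fractional coverage, then box-car averaged down to
the frame grid.  Condition-level parameter estimates (PEs) are uniform-weight
averages of a condition's bin betas (weight 1/n_bins each).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FIRBasis",
    "FIRDesign",
    "GLMFit",
    "default_fir_specs",
    "build_fir_design",
    "fit_glm",
    "average_contrast",
    "residualize",
    "aggregate_pes",
]


@dataclass(frozen=True)
class FIRBasis:
    """FIR basis for one condition: ``n_bins`` bins of ``bin_width`` seconds."""

    n_bins: int
    bin_width: float

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @property
    def window(self) -> float:
        """Modeled window length in seconds."""
        return self.n_bins * self.bin_width


def default_fir_specs() -> dict[str, dict[str, FIRBasis]]:
    """FIR bases for the three task designs (motor, language, memory).

    Motor conditions use 7 bins x 2.2 s (15.4 s window).  Language trial
    types use 8 bins x 1.5 s (12 s window), the two sustained block
    regressors one 121 s bin, and the block cues one 2.2 s bin.  Memory
    stimulus-by-repetition conditions use 8 bins x 1.5 s.
    """
    motor = {
        c: FIRBasis(7, 2.2)
        for c in ("left_hand", "right_hand", "left_foot", "right_foot", "tongue")
    }
    language: dict[str, FIRBasis] = {
        c: FIRBasis(8, 1.5) for c in ("coherent", "random", "noun", "verb")
    }
    language.update(
        {
            "coherence_sustained": FIRBasis(1, 121.0),
            "verbal_sustained": FIRBasis(1, 121.0),
            "cue_start": FIRBasis(1, 2.2),
            "cue_end": FIRBasis(1, 2.2),
        }
    )
    memory = {
        f"{stim}_rep{r}": FIRBasis(8, 1.5)
        for stim in ("face", "scene", "word")
        for r in (1, 2, 3)
    }
    return {"motor": motor, "language": language, "memory": memory}


@dataclass
class FIRDesign:
    """Frames x regressors FIR design with (condition, bin) column labels."""

    matrix: np.ndarray
    columns: list[tuple[str, int]]
    tr_seconds: float
    microtime_dt: float

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(c for c, _ in self.columns))

    def condition_columns(self, condition: str) -> list[int]:
        return [i for i, (c, _) in enumerate(self.columns) if c == condition]


def build_fir_design(
    events: pd.DataFrame,
    fir_spec: Mapping[str, FIRBasis],
    n_frames: int,
    tr_seconds: float,
    microtime_dt: float = 0.1,
) -> FIRDesign:
    """Accumulate FIR indicator columns for every condition present in events.

    Each event adds an indicator of 1 to bin ``b`` of its condition over the
    interval [onset + b*bin_width, onset + (b+1)*bin_width) on the microtime
    grid; columns are then averaged within each frame.  Overlapping events of
    the same condition sum.  Bins running past the end of the run are
    truncated (and logged).
    """
    if microtime_dt <= 0:
        raise ValueError("microtime_dt must be positive")
    run_len = n_frames * tr_seconds
    present = [c for c in fir_spec if c in set(events["trial_type"])]
    unknown = sorted(set(events["trial_type"]) - set(fir_spec))
    if unknown:
        raise ValueError(f"conditions without an FIR basis: {unknown}")
    for c in present:
        if fir_spec[c].bin_width < microtime_dt:
            raise ValueError(
                f"condition {c!r}: bin_width {fir_spec[c].bin_width} < microtime_dt"
            )

    n_micro = int(round(run_len / microtime_dt))
    mid = (np.arange(n_micro) + 0.5) * microtime_dt
    frame_of = np.minimum((mid / tr_seconds).astype(int), n_frames - 1)

    columns: list[tuple[str, int]] = []
    frame_cols: list[np.ndarray] = []
    counts = np.bincount(frame_of, minlength=n_frames)
    for cond in present:
        basis = fir_spec[cond]
        onsets = events.loc[events["trial_type"] == cond, "onset"].to_numpy(float)
        for b in range(basis.n_bins):
            micro = np.zeros(n_micro)
            for onset in onsets:
                start = onset + b * basis.bin_width
                end = start + basis.bin_width
                if start >= run_len:
                    logger.warning(
                        "event at %.2fs: bin %d of %s entirely beyond run end; dropped",
                        onset, b, cond,
                    )
                    continue
                if end > run_len:
                    logger.warning(
                        "event at %.2fs: bin %d of %s truncated at run end", onset, b, cond
                    )
                micro += (mid >= start) & (mid < end)
            col = np.bincount(frame_of, weights=micro, minlength=n_frames) / counts
            frame_cols.append(col)
            columns.append((cond, b))
    if not frame_cols:
        matrix = np.zeros((n_frames, 0))
    else:
        matrix = np.column_stack(frame_cols)
    return FIRDesign(matrix=matrix, columns=columns, tr_seconds=tr_seconds, microtime_dt=microtime_dt)


@dataclass
class GLMFit:
    """Per-unit OLS fit of a run against an FIR design (plus intercept)."""

    betas: np.ndarray  # regressors x units (intercept last)
    residuals: np.ndarray  # frames x units; NaN at censored frames
    columns: list[tuple[str, int]]  # includes ("intercept", 0) last
    aliased: list[int] = field(default_factory=list)

    def condition_betas(self, condition: str) -> np.ndarray:
        idx = [i for i, (c, _) in enumerate(self.columns) if c == condition]
        if not idx:
            raise KeyError(f"condition {condition!r} not in design")
        return self.betas[idx]


def fit_glm(
    series: np.ndarray,
    design: FIRDesign,
    censor_mask: np.ndarray | None = None,
) -> GLMFit:
    """OLS fit of every unit's series on the FIR design plus an intercept.

    Censored frames are excluded from the fit (row deletion); residuals at
    censored frames are set to NaN.  Rank-deficient designs fall back to the
    minimum-norm (pseudo-inverse) solution with aliased columns flagged.
    """
    series = np.asarray(series, dtype=float)
    T = series.shape[0]
    if design.matrix.shape[0] != T:
        raise ValueError("design and series frame counts differ")
    if censor_mask is None:
        censor_mask = np.ones(T, dtype=bool)
    censor_mask = np.asarray(censor_mask, dtype=bool)
    X = np.column_stack([design.matrix, np.ones(T)])
    columns = list(design.columns) + [("intercept", 0)]
    Xr = X[censor_mask]
    if Xr.shape[0] < X.shape[1] + 2:
        raise ValueError(
            f"{Xr.shape[0]} retained frames < regressors ({X.shape[1]}) + 2"
        )
    rank = np.linalg.matrix_rank(Xr)
    aliased: list[int] = []
    if rank < X.shape[1]:
        _, dropped = _aliased_columns(Xr)
        aliased = dropped
        logger.warning("design is rank deficient; aliased columns %s", dropped)
    beta, *_ = np.linalg.lstsq(Xr, series[censor_mask], rcond=None)
    resid = series - X @ beta
    resid[~censor_mask] = np.nan
    return GLMFit(betas=beta, residuals=resid, columns=columns, aliased=aliased)


def _aliased_columns(X: np.ndarray) -> tuple[list[int], list[int]]:
    keep: list[int] = []
    for j in range(X.shape[1]):
        if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
            keep.append(j)
    return keep, [j for j in range(X.shape[1]) if j not in keep]


def average_contrast(fit: GLMFit, condition: str) -> np.ndarray:
    """Condition PE per unit: uniform 1/n_bins weights over the bin betas."""
    b = fit.condition_betas(condition)
    return b.mean(axis=0)


def residualize(
    series: np.ndarray,
    design: FIRDesign,
    censor_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Residual series after removing the mean task-evoked response."""
    return fit_glm(series, design, censor_mask).residuals


def aggregate_pes(pe_table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Aggregate run-level PEs with unweighted means at each level.

    ``pe_table`` is long format with columns ``subject``, ``session``,
    ``run``, ``condition``, ``unit``, ``pe``.  Returns session-, subject-,
    task- (mean over conditions per subject) and group-level tables.  Missing
    runs are simply averaged over what is available.
    """
    required = {"subject", "session", "run", "condition", "unit", "pe"}
    missing = required - set(pe_table.columns)
    if missing:
        raise ValueError(f"pe_table missing columns {sorted(missing)}")
    session = (
        pe_table.groupby(["subject", "session", "condition", "unit"], sort=True)["pe"]
        .mean()
        .reset_index()
    )
    subject = (
        session.groupby(["subject", "condition", "unit"], sort=True)["pe"].mean().reset_index()
    )
    task = subject.groupby(["subject", "unit"], sort=True)["pe"].mean().reset_index()
    group = task.groupby("unit", sort=True)["pe"].mean().reset_index()
    return {"session": session, "subject": subject, "task": task, "group": group}
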