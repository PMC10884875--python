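"""Connectome construction and test-retest reliability statistics.

Two reliability measures are implemented:

* **FC-TRC** (functional-connectivity test-retest correlation): for each
  unit, the spatial Pearson correlation between that unit's connectivity row
  computed on two disjoint session halves (self-connection excluded).

* **Edge-wise ICC(2,1)**: a two-way random-effects, absolute-agreement,
  single-measurement intraclass correlation per connectome edge, with
  subjects as rows and the two halves as raters,

      ICC(2,1) = sigma_lambda^2 / (sigma_pi^2 + sigma_lambda^2 + sigma_eps^2)

  estimated from the ANOVA mean squares
  ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datatypes import BoldRun, Connectome, ReliabilityMap, SplitHalfPair
from .preprocess import concat_mean_centered

logger = logging.getLogger(__name__)

__all__ = [
    "pearson_connectome",
    "split_half",
    "fc_trc",
    "icc_2_1",
    "ICCResult",
    "edgewise_icc",
    "parcel_icc_map",
    "classify_icc",
    "delta_map",
    "group_summary",
    "ICC_BANDS",
]

#: ICC interpretation bands.  The printed upper edges (0.59, 0.74) leave gaps
#: that are closed deterministically: poor (-inf, 0.4], fair (0.4, 0.6),
#: good [0.6, 0.75), excellent [0.75, inf).
ICC_BANDS = {"poor": 0.4, "fair": 0.6, "good": 0.75}


def pearson_connectome(
    series: np.ndarray | BoldRun,
    unit_level: str = "parcel",
    provenance: dict | None = None,
) -> Connectome:
    """Pearson correlation matrix over (retained) frames.

    Zero-variance units get NaN in their row and column (logged), never a
    silent zero.  The diagonal is stored as 1.
    """
    if isinstance(series, BoldRun):
        unit_level = series.unit_level
        series = series.retained()
    series = np.asarray(series, dtype=float)
    T, P = series.shape
    if T < 3:
        raise ValueError(f"need at least 3 frames to correlate, got {T}")
    sd = series.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.corrcoef(series, rowvar=False)
    m = np.clip(m, -1.0, 1.0)
    if bad.size:
        logger.warning("%d zero-variance unit(s) set to missing: %s", bad.size, bad[:10])
        m[bad, :] = np.nan
        m[:, bad] = np.nan
    np.fill_diagonal(m, 1.0)
    prov = dict(provenance or {})
    prov.setdefault("n_frames", T)
    return Connectome(matrix=m, unit_level=unit_level, provenance=prov)


def split_half(
    session_series: Sequence[np.ndarray | Sequence[BoldRun]],
    split: tuple[Sequence[int], Sequence[int]] | None = None,
    unit_level: str = "parcel",
) -> SplitHalfPair:
    """Split sessions into two halves and build one connectome per half.

    ``session_series`` is ordered by session; each element is either a
    frames x units array of retained frames or a list of runs for that
    session.  The default split is first half / last half by session order
    (sessions 1-5 vs 6-10 for ten sessions); an odd session count requires an
    explicit ``split`` of 0-based session indices.
    """
    n = len(session_series)
    if n < 2:
        raise ValueError("need at least 2 sessions to split")
    if split is None:
        if n % 2:
            raise ValueError("odd session count: provide an explicit split")
        split = (tuple(range(n // 2)), tuple(range(n // 2, n)))
    a, b = (sorted(split[0]), sorted(split[1]))
    if set(a) & set(b) or set(a) | set(b) != set(range(n)):
        raise ValueError("split must be a disjoint, exhaustive partition of sessions")

    def half(idx: Sequence[int], label: str) -> Connectome:
        segments = []
        for i in idx:
            item = session_series[i]
            if isinstance(item, np.ndarray):
                seg = item - item.mean(axis=0, keepdims=True)
                segments.append(seg)
            else:
                segments.append(concat_mean_centered(list(item)))
        data = np.vstack(segments)
        return pearson_connectome(
            data, unit_level=unit_level,
            provenance={"sessions": [i + 1 for i in idx], "half": label},
        )

    return SplitHalfPair(first=half(a, "first"), second=half(b, "second"))


def fc_trc(pair: SplitHalfPair, state: str = "rest") -> ReliabilityMap:
    """Per-unit spatial correlation between the two half connectomes.

    Row ``u`` of each half, with the self-entry removed, is correlated across
    halves.  Units missing (NaN) in either half are excluded pairwise and the
    exclusion count is logged.
    """
    A, B = pair.first.matrix, pair.second.matrix
    P = A.shape[0]
    out = np.full(P, np.nan)
    n_excluded = 0
    for u in range(P):
        keep = np.ones(P, dtype=bool)
        keep[u] = False
        a, b = A[u, keep], B[u, keep]
        ok = np.isfinite(a) & np.isfinite(b)
        n_excluded += int((~ok).sum())
        if ok.sum() < 3:
            continue
        out[u] = _pearson(a[ok], b[ok])
    if n_excluded:
        logger.info("fc_trc: excluded %d missing row entries pairwise", n_excluded)
    return ReliabilityMap(values=out, state=state, level="subject", measure="fc_trc")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return np.nan
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


@dataclass
class ICCResult:
    """ICC(2,1) estimate with its variance components."""

    icc: float
    sigma_lambda2: float  # between-subject
    sigma_pi2: float  # between-half (rater)
    sigma_eps2: float  # residual
    negative: bool = False
    reason: str | None = None


def icc_2_1(table: np.ndarray) -> ICCResult:
    """Two-way random-effects, absolute-agreement, single-measurement ICC.

    ``table`` is subjects x raters (here raters are the two session halves).
    Negative estimates are reported as computed, flagged via ``negative``;
    variance components are truncated at zero.  A table with zero total
    variance yields a missing (NaN) ICC with a reason.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a subjects x raters table with >= 2 of each")
    n, k = x.shape
    grand = x.mean()
    sst = ((x - grand) ** 2).sum()
    if sst < 1e-15 * max(1.0, abs(grand)) ** 2:
        return ICCResult(np.nan, 0.0, 0.0, 0.0, reason="zero total variance")
    rows = x.mean(axis=1)
    cols = x.mean(axis=0)
    ssr = k * ((rows - grand) ** 2).sum()
    ssc = n * ((cols - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return ICCResult(
        icc=float(icc),
        sigma_lambda2=max((msr - mse) / k, 0.0),
        sigma_pi2=max((msc - mse) / n, 0.0),
        sigma_eps2=max(mse, 0.0),
        negative=bool(icc < 0),
    )


def edgewise_icc(pairs: Sequence[SplitHalfPair]) -> np.ndarray:
    """ICC(2,1) for every upper-triangle edge across subjects' half connectomes.

    ``pairs`` holds one SplitHalfPair per subject, all on the same parcel
    space.  Returns the per-edge ICC values in upper-triangle order.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 subjects for edge-wise ICC")
    P = pairs[0].first.n_units
    iu = np.triu_indices(P, k=1)
    first = np.stack([p.first.matrix[iu] for p in pairs])  # subjects x edges
    second = np.stack([p.second.matrix[iu] for p in pairs])
    n_edges = iu[0].size
    out = np.full(n_edges, np.nan)
    for e in range(n_edges):
        col = np.column_stack([first[:, e], second[:, e]])
        if not np.all(np.isfinite(col)):
            continue
        out[e] = icc_2_1(col).icc
    return out


def parcel_icc_map(edge_icc: np.ndarray, n_parcels: int) -> np.ndarray:
    """Aggregate edge ICCs to parcels: mean over each parcel's incident edges."""
    iu = np.triu_indices(n_parcels, k=1)
    out = np.full(n_parcels, np.nan)
    for p in range(n_parcels):
        incident = (iu[0] == p) | (iu[1] == p)
        vals = edge_icc[incident]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            out[p] = vals.mean()
    return out


def classify_icc(value: float) -> str | None:
    """Reliability band for an ICC value.

    Bands: poor (-inf, 0.4], fair (0.4, 0.6), good [0.6, 0.75),
    excellent [0.75, inf).  Values <= 0 are poor; missing input gives None.
    """
    if value is None or not np.isfinite(value):
        return None
    if value <= ICC_BANDS["poor"]:
        return "poor"
    if value < ICC_BANDS["fair"]:
        return "fair"
    if value < ICC_BANDS["good"]:
        return "good"
    return "excellent"


def delta_map(task_map: ReliabilityMap, rest_map: ReliabilityMap) -> ReliabilityMap:
    """Task-minus-rest reliability difference, unit-wise."""
    if task_map.values.shape != rest_map.values.shape:
        raise ValueError("unit-space mismatch between task and rest maps")
    return ReliabilityMap(
        values=task_map.values - rest_map.values,
        state=task_map.state,
        level=task_map.level,
        measure="delta_fc_trc",
    )


def group_summary(maps: Sequence[ReliabilityMap]) -> tuple[ReliabilityMap, ReliabilityMap]:
    """Across-subject mean and sample SD maps."""
    if len(maps) < 2:
        raise ValueError("need at least 2 subjects for a group summary")
    stack = np.stack([m.values for m in maps])
    mean = ReliabilityMap(np.nanmean(stack, axis=0), state=maps[0].state,
                          level="group", measure=maps[0].measure)
    sd = ReliabilityMap(np.nanstd(stack, axis=0, ddof=1), state=maps[0].state,
                        level="group", measure=maps[0].measure + "_sd")
    return mean, sd
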