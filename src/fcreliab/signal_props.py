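"""BOLD signal properties: tMean, tSD, tSNR, and task-minus-rest deltas.

All three measures are computed per unit over a run's retained frames and
then averaged with *unweighted* means up the hierarchy run -> session ->
subject -> group.  Averaging order matters and is the one asserted
throughout: per-run statistics are averaged, never pooled (e.g. tSNR is the
mean of per-run mean/SD ratios, not the ratio of averages).

tMean and tSNR are meaningful on the raw (pre-detrend) series only, since
cleaned series have per-unit means of ~0; tSD may be taken on either.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import BoldRun, SignalPropertyMap

logger = logging.getLogger(__name__)

__all__ = [
    "run_stat",
    "signal_table",
    "tmean_map",
    "tsd_map",
    "tsnr_map",
    "delta_signal",
]


def run_stat(run: BoldRun, measure: str) -> np.ndarray:
    """One run's per-unit tmean / tsd / tsnr over retained frames."""
    data = run.retained()
    if data.shape[0] < 2:
        raise ValueError("need at least 2 retained frames")
    if measure == "tmean":
        return data.mean(axis=0)
    if measure == "tsd":
        return data.std(axis=0, ddof=1)
    if measure == "tsnr":
        sd = data.std(axis=0, ddof=1)
        mean = data.mean(axis=0)
        out = np.full(run.n_units, np.nan)
        ok = sd > 0
        if not ok.all():
            logger.warning("tsnr: %d unit(s) with zero tSD set to missing", (~ok).sum())
        out[ok] = mean[ok] / sd[ok]
        return out
    raise ValueError(f"unknown measure {measure!r}")


def signal_table(runs: Sequence[BoldRun], measure: str) -> pd.DataFrame:
    """Run-level long table: one row per (subject, session, run, unit)."""
    rows = []
    for r in runs:
        vals = run_stat(r, measure)
        for u, v in enumerate(vals):
            rows.append((r.subject, r.session, r.run, u, v))
    return pd.DataFrame(rows, columns=["subject", "session", "run", "unit", "value"])


def _aggregate(table: pd.DataFrame, level: str) -> pd.DataFrame | pd.Series:
    session = table.groupby(["subject", "session", "unit"], sort=True)["value"].mean()
    if level == "session":
        return session
    subject = session.groupby(["subject", "unit"]).mean()
    if level == "subject":
        return subject
    if level == "group":
        return subject.groupby("unit").mean()
    raise ValueError(f"unknown level {level!r}")


def _map(runs: Sequence[BoldRun], measure: str, level: str, state: str | None) -> SignalPropertyMap:
    runs = list(runs)
    if not runs:
        raise ValueError("no runs")
    if state is None:
        states = {r.state for r in runs}
        if len(states) > 1:
            raise ValueError(f"runs span multiple states {states}; pass state explicitly")
        state = states.pop()
    agg = _aggregate(signal_table(runs, measure), level)
    if level == "group":
        values = agg.sort_index().to_numpy()
    else:
        # single-subject convenience: collapse if exactly one subject present
        subjects = agg.index.get_level_values("subject").unique()
        if len(subjects) != 1:
            raise ValueError(
                "multiple subjects at a non-group level; aggregate per subject "
                "or use signal_table directly"
            )
        values = agg.sort_index().to_numpy()
    return SignalPropertyMap(values=values, measure=measure, state=state, level=level)


def tmean_map(runs: Sequence[BoldRun], level: str = "subject",
              state: str | None = None) -> SignalPropertyMap:
    """Temporal mean per unit, averaged run -> session -> subject (-> group)."""
    return _map(runs, "tmean", level, state)


def tsd_map(runs: Sequence[BoldRun], level: str = "subject",
            state: str | None = None) -> SignalPropertyMap:
    """Temporal SD per unit (sample SD per run, then averaged)."""
    return _map(runs, "tsd", level, state)


def tsnr_map(runs: Sequence[BoldRun], level: str = "subject",
             state: str | None = None) -> SignalPropertyMap:
    """Temporal SNR: per-run mean/SD ratio, then averaged across runs."""
    return _map(runs, "tsnr", level, state)


def delta_signal(task: SignalPropertyMap, rest: SignalPropertyMap) -> SignalPropertyMap:
    """Task-minus-rest map for a matching measure on matching units."""
    if task.measure != rest.measure:
        raise ValueError(f"measure mismatch: {task.measure} vs {rest.measure}")
    if task.values.shape != rest.values.shape:
        raise ValueError("unit-space mismatch")
    return SignalPropertyMap(
        values=task.values - rest.values,
        measure=task.measure,
        state=task.state,
        level=task.level,
    )
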