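"""Recovery experiments: planted ground truth in, estimates out.

Each function simulates data with the synthetic generator at a stated
desk-scale problem size, runs the relevant slice of the analysis pipeline,
and returns the measured quantities together with the planted values.  They
back both the validation test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .datatypes import BoldRun, ReliabilityMap, SplitHalfPair
from .glm import build_fir_design, fit_glm
from .networks import (
    DEFAULT_DENSITIES,
    adjusted_rand,
    consensus_partition,
    density_threshold,
    detect_communities,
    reassign_excess,
)
from .preprocess import censor_frames, clean_timeseries, compute_fd, concat_mean_centered, volume_match
from .reliability import fc_trc, icc_2_1, pearson_connectome, split_half
from .signal_props import tsd_map
from .stats import fit_mixed_model
from .synth import (
    SyntheticSpec,
    build_ground_truth,
    default_fir_specs,
    simulate_edge_table,
    simulate_run,
)

__all__ = [
    "icc_recovery",
    "fc_trc_scan_length",
    "task_engagement_experiment",
    "mixed_model_recovery",
    "consensus_recovery",
]


def icc_recovery(seed: int, rhos=(0.2, 0.5, 0.8), n_subjects: int = 20,
                 n_edges: int = 500) -> dict[float, float]:
    """Mean edge ICC(2,1) for planted between/total variance ratios."""
    out = {}
    for k, rho in enumerate(rhos):
        table = simulate_edge_table(rho, n_subjects, n_edges, seed=seed + k)
        out[rho] = float(np.mean([icc_2_1(table[e]).icc for e in range(n_edges)]))
    return out


def fc_trc_scan_length(seed: int, lengths=(250, 1000, 4000), n_subjects: int = 6,
                       n_parcels: int = 60, n_networks: int = 6) -> dict[int, float]:
    """Group-mean FC-TRC at increasing retained scan lengths.

    Stationary rest data: each subject contributes two "sessions" of the
    longest length; shorter lengths reuse the leading frames, so the series
    differ only in data quantity.
    """
    max_len = max(lengths)
    spec = SyntheticSpec(
        n_subjects=n_subjects, n_sessions=2, n_parcels=n_parcels,
        n_networks=n_networks, frames_per_run={"rest": max_len},
        runs_per_state={"rest": 1}, seed=seed,
    )
    gt = build_ground_truth(spec)
    halves = []
    for subj in range(1, n_subjects + 1):
        sessions = [simulate_run(gt, subj, ses, "rest", spec)[0].data
                    for ses in (1, 2)]
        halves.append(sessions)
    out = {}
    for L in lengths:
        vals = []
        for sessions in halves:
            pair = split_half([s[:L] for s in sessions])
            vals.append(np.nanmean(fc_trc(pair).values))
        out[int(L)] = float(np.mean(vals))
    return out


def _preprocess_runs(runs, motions, fd_threshold=0.20, band=(0.01, 0.08)):
    censored, cleaned = [], []
    for run, motion in zip(runs, motions):
        c = censor_frames(run, motion.fd, fd_threshold)
        censored.append(c)
        cleaned.append(clean_timeseries(c, band=band))
    return censored, cleaned


def task_engagement_experiment(
    seed: int,
    n_subjects: int = 9,
    n_sessions: int = 4,
    n_parcels: int = 60,
    n_networks: int = 6,
    task: str = "motor",
) -> dict:
    """Evoked-task locality and task-regression effects on reliability.

    Simulates rest plus one task whose evoked response is confined to the
    planted engaged parcels, runs censoring / cleaning / volume matching /
    split-half reliability (with and without FIR task regression) and
    per-state tSD maps, and compares engaged vs non-engaged parcels.
    Returns group delta maps, engaged/non-engaged means, and one-sided
    Mann-Whitney p-values.
    """
    spec = SyntheticSpec(
        n_subjects=n_subjects, n_sessions=n_sessions, n_parcels=n_parcels,
        n_networks=n_networks,
        frames_per_run={"rest": 260, task: 160},
        runs_per_state={"rest": 1, task: 2},
        seed=seed,
    )
    gt = build_ground_truth(spec)
    engaged = gt.engaged_parcels[task] - 1
    others = np.setdiff1d(np.arange(n_parcels), engaged)
    fir = default_fir_specs()[task]

    delta_trc, delta_trc_resid, delta_tsd = [], [], []
    for subj in range(1, n_subjects + 1):
        raw_by_state: dict[str, dict[tuple, list[BoldRun]]] = {"rest": {}, task: {}}
        clean_by_state: dict[str, dict[tuple, list[BoldRun]]] = {"rest": {}, task: {}}
        events_for = {}
        for ses in range(1, n_sessions + 1):
            for state, n_runs in (("rest", 1), (task, 2)):
                runs, motions = [], []
                for r in range(1, n_runs + 1):
                    bold, events, motion = simulate_run(gt, subj, ses, state, spec, run=r)
                    runs.append(bold)
                    motions.append(motion)
                    events_for[(ses, state, r)] = events
                censored, cleaned = _preprocess_runs(runs, motions)
                raw_by_state[state][(subj, ses)] = censored
                clean_by_state[state][(subj, ses)] = cleaned
        _, raw_by_state = volume_match(raw_by_state, task)
        _, clean_by_state = volume_match(clean_by_state, task)

        def sessions_of(state, runs_map, regress=False):
            series = []
            for ses in range(1, n_sessions + 1):
                runs = runs_map[state][(subj, ses)]
                if regress:
                    out = []
                    for i, run in enumerate(runs, start=1):
                        ev = events_for[(ses, state, i)]
                        design = build_fir_design(ev, fir, run.n_frames, run.tr_seconds)
                        if run.n_retained < design.matrix.shape[1] + 3:
                            out.append(run)
                            continue
                        fit = fit_glm(run.data, design, run.censor_mask)
                        out.append(run.with_data(np.nan_to_num(fit.residuals, nan=0.0)))
                    runs = out
                series.append(concat_mean_centered(runs))
            return series

        rest_map = fc_trc(split_half(sessions_of("rest", clean_by_state))).values
        task_map = fc_trc(split_half(sessions_of(task, clean_by_state))).values
        task_map_resid = fc_trc(
            split_half(sessions_of(task, clean_by_state, regress=True))
        ).values
        delta_trc.append(task_map - rest_map)
        delta_trc_resid.append(task_map_resid - rest_map)

        rest_runs = [r for key in raw_by_state["rest"] for r in raw_by_state["rest"][key]
                     if r.n_retained >= 2]
        task_runs = [r for key in raw_by_state[task] for r in raw_by_state[task][key]
                     if r.n_retained >= 2]
        delta_tsd.append(
            tsd_map(task_runs, state=task).values - tsd_map(rest_runs).values
        )

    g_trc = np.mean(delta_trc, axis=0)
    g_trc_resid = np.mean(delta_trc_resid, axis=0)
    g_tsd = np.mean(delta_tsd, axis=0)

    def one_sided(delta):
        return float(sstats.mannwhitneyu(delta[engaged], delta[others],
                                         alternative="greater").pvalue)

    return {
        "engaged": engaged,
        "non_engaged": others,
        "delta_tsd": g_tsd,
        "delta_fc_trc": g_trc,
        "delta_fc_trc_residualized": g_trc_resid,
        "delta_tsd_engaged_mean": float(g_tsd[engaged].mean()),
        "delta_tsd_non_engaged_mean": float(g_tsd[others].mean()),
        "delta_tsd_p": one_sided(g_tsd),
        "delta_fc_trc_engaged_mean": float(g_trc[engaged].mean()),
        "delta_fc_trc_non_engaged_mean": float(g_trc[others].mean()),
        "delta_fc_trc_p": one_sided(g_trc),
        "regression_shift_engaged": float(
            g_trc_resid[engaged].mean() - g_trc[engaged].mean()
        ),
        "regression_shift_overall": float(g_trc_resid.mean() - g_trc.mean()),
    }


def mixed_model_recovery(
    seed: int,
    beta_tsd: float = 0.3,
    n_subjects: int = 9,
    n_parcels: int = 12,
    intercept_sd: float = 0.1,
    noise_sd: float = 0.05,
) -> dict:
    """Fit the attribution mixed model to data with known fixed effects.

    Reliability is generated as ``0.5 + beta_tsd * z(tSD) + subject intercept
    + noise`` over 4 states (rest + three tasks), with tMean and PE carrying
    no effect; the fit should recover ``beta_tsd`` and zeros elsewhere.
    """
    rng = np.random.default_rng(seed)
    states = ["rest", "motor", "language", "memory"]
    rows = []
    for p in range(1, n_parcels + 1):
        for s in range(n_subjects):
            for st in states:
                tmean = rng.normal(800, 50)
                tsd = rng.normal(15, 3)
                pe = 0.0 if st == "rest" else rng.normal(2, 1)
                rows.append([p, f"sub{s:02d}", st, 0.0, tmean, tsd, pe])
    df = pd.DataFrame(rows, columns=["parcel", "subject", "state", "reliability",
                                     "tmean", "tsd", "pe"])
    z_tsd = (df["tsd"] - df["tsd"].mean()) / df["tsd"].std(ddof=0)
    intercepts = {f"sub{s:02d}": rng.normal(0, intercept_sd) for s in range(n_subjects)}
    df["reliability"] = (0.5 + beta_tsd * z_tsd + df["subject"].map(intercepts)
                         + rng.normal(0, noise_sd, len(df)))
    mm = fit_mixed_model(df)
    means = mm.mean_betas()
    return {
        "beta_tsd": float(means["beta_tsd"]),
        "beta_tmean": float(means["beta_tmean"]),
        "beta_pe": float(means["beta_pe"]),
        "planted_beta_tsd": beta_tsd,
        "n_rows": len(df),
    }


def consensus_recovery(
    seed: int,
    n_subjects: int = 9,
    n_parcels: int = 170,
    n_networks: int = 17,
    frames: int = 600,
    densities=DEFAULT_DENSITIES,
    n_reps: int = 100,
    method: str = "infomap",
) -> dict:
    """Recover a planted network partition through the full consensus chain.

    Group rest connectome (mean of per-subject sample correlations) ->
    density thresholding -> community detection -> consensus -> excess
    reassignment, scored by adjusted Rand agreement with the planted
    partition.
    """
    spec = SyntheticSpec(
        n_subjects=n_subjects, n_sessions=1, n_parcels=n_parcels,
        n_networks=n_networks, frames_per_run={"rest": frames},
        runs_per_state={"rest": 1}, seed=seed,
    )
    gt = build_ground_truth(spec)
    conns = []
    for subj in range(1, n_subjects + 1):
        bold, _, _ = simulate_run(gt, subj, 1, "rest", spec)
        conns.append(pearson_connectome(bold.data).matrix)
    group = np.mean(conns, axis=0)
    partitions = [
        detect_communities(density_threshold(group, d), n_reps=n_reps,
                           seed=seed + i, method=method)
        for i, d in enumerate(densities)
    ]
    cons = consensus_partition(partitions, seed=seed, method=method, n_reps=10)
    neighbors = {p: [q for q in (p - 1, p + 1) if 0 <= q < n_parcels]
                 for p in range(n_parcels)}
    final = reassign_excess(cons.partition, n_networks, neighbors)
    return {
        "adjusted_rand": float(adjusted_rand(final.labels, gt.partition)),
        "n_communities": int(final.n_communities),
        "converged": bool(cons.converged),
        "n_parcels": n_parcels,
    }
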