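"""End-to-end pipeline: dataset -> censor -> clean -> match -> connectomes ->
reliability -> signal properties -> task GLMs -> networks -> association stats.

Every stage is a pure function of the dataset and the configuration, so a
rerun with the same config reproduces identical numbers.  The pipeline keeps
two parallel views of each run: the *raw* censored series (for tMean / tSD /
tSNR, whose absolute scale cleaning would destroy) and the *cleaned* series
(for connectomes, GLMs and reliability).
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .datatypes import BoldRun
from .glm import aggregate_pes, average_contrast, build_fir_design, fit_glm, residualize
from .io import PipelineConfig
from .networks import consensus_partition, density_threshold, detect_communities, reassign_excess
from .preprocess import censor_frames, clean_timeseries, compute_fd, concat_mean_centered, volume_match
from .reliability import (
    classify_icc,
    delta_map,
    edgewise_icc,
    fc_trc,
    group_summary,
    parcel_icc_map,
    pearson_connectome,
    split_half,
)
from .signal_props import delta_signal, tmean_map, tsd_map, tsnr_map
from .stats import fit_mixed_model, monotone_trend, parcelwise_ols
from .synth import default_fir_specs

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_dataset"]

STAGES = ("preprocess", "connectome", "reliability", "signal", "glm", "networks", "stats")


def load_dataset(dataset_dir) -> dict:
    """Load a simulated dataset tree (manifest + runs + events + motion)."""
    root = Path(dataset_dir)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    runs = []
    for entry in manifest["runs"]:
        bold = fio.read_timeseries(root / entry["bold"])
        events = fio.read_events(root / entry["events"])
        motion = fio.read_motion(root / entry["motion"])
        runs.append({"entry": entry, "bold": bold, "events": events, "motion": motion})
    gt = None
    gt_path = root / manifest.get("ground_truth", "")
    if gt_path.is_file():
        gt = dict(np.load(gt_path))
    return {"manifest": manifest, "runs": runs, "ground_truth": gt}


def _session_key(run: BoldRun) -> tuple:
    return (run.subject, run.session)


def run_pipeline(config: PipelineConfig, stages=STAGES) -> dict:
    """Run the requested stages (prerequisites included) and write outputs."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": {"fd_threshold": config.fd_threshold, "band": list(config.band),
                            "densities": list(config.densities), "seed": config.seed,
                            "gsr": config.gsr, "task_regress": config.task_regress},
                 "censoring": {}}
    ds = load_dataset(config.dataset_dir)
    result: dict = {"log": log, "outputs": []}

    # ---- preprocess: censor, clean, volume match -------------------------
    raw_by_state: dict[str, dict[tuple, list[BoldRun]]] = defaultdict(lambda: defaultdict(list))
    clean_by_state: dict[str, dict[tuple, list[BoldRun]]] = defaultdict(lambda: defaultdict(list))
    events_for: dict[tuple, pd.DataFrame] = {}
    for item in ds["runs"]:
        bold: BoldRun = item["bold"]
        motion = item["motion"]
        fd = motion.fd if motion.fd is not None else compute_fd(motion)
        censored = censor_frames(bold, fd, config.fd_threshold)
        log["censoring"][f"{bold.subject}_ses-{bold.session}_{bold.state}_run-{bold.run}"] = {
            "n_frames": int(bold.n_frames),
            "n_retained": int(censored.n_retained),
        }
        confounds = np.column_stack([motion.translations, motion.rotations])
        if config.gsr:
            gs = bold.data.mean(axis=1, keepdims=True)
            confounds = np.column_stack([confounds, gs])
        confounds = confounds[:, confounds.std(axis=0) > 0]  # flat channels carry nothing
        cleaned = clean_timeseries(censored, confounds=confounds, band=config.band)
        key = _session_key(bold)
        raw_by_state[bold.state][key].append(censored)
        clean_by_state[bold.state][key].append(cleaned)
        events_for[(bold.subject, bold.session, bold.state, bold.run)] = item["events"]

    states = sorted(raw_by_state)
    reference = config.reference_state if config.reference_state in states else states[0]
    target, raw_by_state = volume_match(raw_by_state, reference)
    _, clean_by_state = volume_match(clean_by_state, reference)
    # copy the matched masks onto the cleaned runs' raw twins is already done:
    # both views were matched with identical retained-frame sequences
    log["volume_match"] = {"reference_state": reference, "target_frames": target}
    if stages == ("preprocess",):
        return result

    subjects = sorted({key[0] for st in clean_by_state.values() for key in st})
    sessions = sorted({key[1] for st in clean_by_state.values() for key in st})
    n_units = next(iter(clean_by_state[states[0]].values()))[0].n_units

    # ---- task GLM: PEs and residualized runs -----------------------------
    fir_specs = default_fir_specs()
    pe_rows = []
    resid_by_state: dict[str, dict[tuple, list[BoldRun]]] = defaultdict(lambda: defaultdict(list))
    need_glm = config.task_regress or "glm" in stages or "stats" in stages
    if need_glm:
        for state in states:
            if state == "rest" or state not in fir_specs:
                continue
            for key in sorted(clean_by_state[state]):
                for run in clean_by_state[state][key]:
                    ev = events_for[(run.subject, run.session, state, run.run)]
                    if not len(ev):
                        resid_by_state[state][key].append(run)
                        continue
                    design = build_fir_design(ev, fir_specs[state], run.n_frames,
                                              run.tr_seconds)
                    if run.n_retained < design.matrix.shape[1] + 3:
                        # e.g. fully censored by volume matching: nothing to fit
                        logger.info("skipping GLM for %s ses-%d run-%d (%d retained frames)",
                                    run.subject, run.session, run.run, run.n_retained)
                        resid_by_state[state][key].append(run)
                        continue
                    fit = fit_glm(run.data, design, run.censor_mask)
                    for cond in design.conditions:
                        pe = average_contrast(fit, cond)
                        for u in range(n_units):
                            pe_rows.append((run.subject, run.session, run.run,
                                            f"{state}:{cond}", u, pe[u]))
                    resid = np.nan_to_num(fit.residuals, nan=0.0)
                    resid_by_state[state][key].append(run.with_data(resid))
    pe_levels = None
    subject_task_pe: dict[tuple, np.ndarray] = {}
    if pe_rows:
        pe_df = pd.DataFrame(pe_rows, columns=["subject", "session", "run",
                                               "condition", "unit", "pe"])
        for state in states:
            if state == "rest":
                continue
            sub_df = pe_df[pe_df["condition"].str.startswith(f"{state}:")]
            if not len(sub_df):
                continue
            levels = aggregate_pes(sub_df)
            for subj, grp in levels["task"].groupby("subject"):
                subject_task_pe[(subj, state)] = (
                    grp.sort_values("unit")["pe"].to_numpy()
                )
            fio.write_map(
                levels["group"].sort_values("unit")["pe"].to_numpy(),
                out_dir / f"group_pe_{state}.tsv",
            )
        pe_levels = pe_df

    # ---- connectomes & reliability ---------------------------------------
    def session_series(state, subj, runs_map):
        series = []
        for ses in sessions:
            key = (subj, ses)
            if key in runs_map[state]:
                series.append(concat_mean_centered(runs_map[state][key]))
        return series

    trc_maps: dict[tuple, np.ndarray] = {}
    trc_maps_resid: dict[tuple, np.ndarray] = {}
    rest_pairs = []
    for state in states:
        for subj in subjects:
            series = session_series(state, subj, clean_by_state)
            if len(series) < 2:
                continue
            pair = split_half(series)
            m = fc_trc(pair, state=state)
            trc_maps[(subj, state)] = m.values
            if state == "rest":
                rest_pairs.append(pair)
            if state in resid_by_state and resid_by_state[state]:
                rseries = session_series(state, subj, resid_by_state)
                rpair = split_half(rseries)
                trc_maps_resid[(subj, state)] = fc_trc(rpair, state=state).values

    from .datatypes import ReliabilityMap

    group_trc: dict[str, np.ndarray] = {}
    for state in states:
        maps = [ReliabilityMap(trc_maps[(s, state)], state=state)
                for s in subjects if (s, state) in trc_maps]
        if len(maps) >= 2:
            mean_map, sd_map = group_summary(maps)
            group_trc[state] = mean_map.values
            fio.write_map(mean_map.values, out_dir / f"group_fc_trc_{state}.tsv")
            fio.write_map(sd_map.values, out_dir / f"group_fc_trc_sd_{state}.tsv")
    for state in states:
        if state != "rest" and state in group_trc and "rest" in group_trc:
            delta = group_trc[state] - group_trc["rest"]
            fio.write_map(delta, out_dir / f"group_delta_fc_trc_{state}.tsv")

    # edge-wise ICC on the rest split-half connectomes
    icc_summary = {}
    if len(rest_pairs) >= 2:
        edge_icc = edgewise_icc(rest_pairs)
        pmap = parcel_icc_map(edge_icc, n_units)
        fio.write_map(pmap, out_dir / "parcel_icc_rest.tsv")
        finite = edge_icc[np.isfinite(edge_icc)]
        bands = pd.Series([classify_icc(v) for v in finite]).value_counts().to_dict()
        icc_summary = {"mean_edge_icc": float(finite.mean()), "bands": bands}
        log["icc"] = icc_summary

    # ---- signal properties ------------------------------------------------
    sig_group: dict[tuple, np.ndarray] = {}
    sig_subject: dict[tuple, dict[str, np.ndarray]] = {}
    for state in states:
        runs_flat = [r for key in sorted(raw_by_state[state])
                     for r in raw_by_state[state][key] if r.n_retained >= 2]
        if not runs_flat:
            continue
        for measure, fn in (("tmean", tmean_map), ("tsd", tsd_map), ("tsnr", tsnr_map)):
            gmap = fn(runs_flat, level="group", state=state)
            sig_group[(state, measure)] = gmap.values
            fio.write_map(gmap.values, out_dir / f"group_{measure}_{state}.tsv")
        for subj in subjects:
            srs = [r for key in sorted(raw_by_state[state]) if key[0] == subj
                   for r in raw_by_state[state][key] if r.n_retained >= 2]
            if srs:
                sig_subject[(subj, state)] = {
                    "tmean": tmean_map(srs, level="subject", state=state).values,
                    "tsd": tsd_map(srs, level="subject", state=state).values,
                }
    for state in states:
        if state == "rest":
            continue
        for measure in ("tmean", "tsd"):
            if (state, measure) in sig_group and ("rest", measure) in sig_group:
                fio.write_map(
                    sig_group[(state, measure)] - sig_group[("rest", measure)],
                    out_dir / f"group_delta_{measure}_{state}.tsv",
                )

    # ---- group networks ---------------------------------------------------
    assignment = None
    if "networks" in stages and "rest" in states:
        conns = []
        for subj in subjects:
            series = session_series("rest", subj, clean_by_state)
            if series:
                conns.append(pearson_connectome(np.vstack(series)).matrix)
        group_conn = np.mean(conns, axis=0)
        fio.write_matrix(group_conn, out_dir / "group_connectome_rest.tsv")
        partitions = [
            detect_communities(density_threshold(group_conn, d),
                               n_reps=config.community_reps,
                               seed=config.seed + i,
                               method=config.community_method)
            for i, d in enumerate(config.densities)
        ]
        cons = consensus_partition(partitions, seed=config.seed,
                                   method=config.community_method)
        neighbors = {p: [q for q in (p - 1, p + 1) if 0 <= q < n_units]
                     for p in range(n_units)}
        final = reassign_excess(cons.partition, config.max_networks, neighbors)
        assignment = final
        df = pd.DataFrame({
            "parcel": np.arange(1, n_units + 1),
            "network_id": final.labels,
            "network": [f"net{l:02d}" for l in final.labels],
        })
        df.to_csv(out_dir / "consensus_networks.tsv", sep="\t", index=False)
        fio.write_matrix(cons.probability, out_dir / "coassignment_probability.tsv")
        log["networks"] = {"n_communities": int(final.n_communities),
                           "converged": bool(cons.converged)}

    # ---- association statistics ------------------------------------------
    if "stats" in stages and "rest" in group_trc:
        stats_rows = []
        for measure in ("tmean", "tsd"):
            s = parcelwise_ols(sig_group[("rest", measure)], group_trc["rest"])
            stats_rows.append(("rest", measure, s.slope, s.r_squared, s.p_value,
                               s.standardized_beta, s.n))
        rho, p = monotone_trend(sig_group[("rest", "tsnr")], group_trc["rest"])
        log["tsnr_spearman"] = {"rho": rho, "p": p}
        pd.DataFrame(stats_rows, columns=["state", "predictor", "slope", "r_squared",
                                          "p_value", "standardized_beta", "n"]
                     ).to_csv(out_dir / "parcelwise_ols.tsv", sep="\t", index=False)

        # long table for the mixed model
        mm_rows = []
        for subj in subjects:
            for state in states:
                if (subj, state) not in trc_maps or (subj, state) not in sig_subject:
                    continue
                rel = trc_maps[(subj, state)]
                sig = sig_subject[(subj, state)]
                pe = subject_task_pe.get((subj, state), np.zeros(n_units))
                for u in range(n_units):
                    mm_rows.append((u + 1, subj, state, rel[u],
                                    sig["tmean"][u], sig["tsd"][u], pe[u]))
        mm_table = pd.DataFrame(mm_rows, columns=["parcel", "subject", "state",
                                                  "reliability", "tmean", "tsd", "pe"])
        mm_table.to_csv(out_dir / "mixed_model_table.tsv", sep="\t", index=False)
        if mm_table["subject"].nunique() >= 2 and mm_table["state"].nunique() >= 2:
            mm = fit_mixed_model(mm_table)
            mm.fixed_effects.to_csv(out_dir / "mixed_model_betas.tsv", sep="\t")
            log["mixed_model"] = {k: float(v) for k, v in mm.mean_betas().items()}

    result["outputs"] = sorted(str(p.name) for p in out_dir.iterdir())
    (out_dir / "pipeline_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    result["trc_maps"] = trc_maps
    result["trc_maps_residualized"] = trc_maps_resid
    result["group_trc"] = group_trc
    result["signal_group"] = sig_group
    result["assignment"] = assignment
    result["icc"] = icc_summary
    return result
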