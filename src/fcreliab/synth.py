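"""Synthetic multi-subject, multi-session, multi-state BOLD generator.

The generator emulates a densely sampled precision-fMRI design: a fixed
roster of subjects scanned over many sessions in one rest state and three
task states (motor, language, memory).  Each subject carries a stable,
network-structured parcel covariance (a block within/between-network
correlation matrix perturbed per subject); runs are draws of temporally
autocorrelated Gaussian noise through that covariance, scaled to per-parcel
temporal SD profiles and shifted to per-parcel mean intensities.  Task states
add a finite-impulse-response evoked component confined to the "engaged"
parcels, and motion traces carry baseline jitter plus occasional spikes that
trigger frame censoring downstream.

Every quantity a downstream stage estimates (network partition, edge-variance
components, engaged parcel sets, evoked amplitudes) is planted and recorded,
so recovery can be tested.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import BoldRun, MotionTrace
from .glm import FIRBasis, build_fir_design, default_fir_specs

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "TaskDesign",
    "default_task_designs",
    "build_ground_truth",
    "simulate_run",
    "simulate_dataset",
    "simulate_edge_table",
    "run_seed",
]

EVENT_COLUMNS = ["onset", "duration", "trial_type"]

#: Which planted network is engaged by each task state (1-based network id).
DEFAULT_ENGAGED_NETWORKS = {"motor": 1, "language": 2, "memory": 3}


def _bump(n_bins: int, peak: float) -> np.ndarray:
    """Smooth unimodal amplitude profile over FIR bins, peaking mid-window."""
    b = np.arange(1, n_bins + 1)
    return peak * np.sin(np.pi * b / (n_bins + 1))


@dataclass
class TaskDesign:
    """Event schedule plus per-bin evoked amplitudes for one task state."""

    task: str
    conditions: dict[str, FIRBasis]
    amplitudes: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for cond, basis in self.conditions.items():
            amp = np.asarray(self.amplitudes.get(cond, np.zeros(basis.n_bins)), dtype=float)
            if amp.shape != (basis.n_bins,):
                raise ValueError(f"amplitude profile for {cond!r} must have {basis.n_bins} bins")
            self.amplitudes[cond] = amp

    def make_events(self, n_frames: int, tr_seconds: float, rng: np.random.Generator,
                    run_index: int = 1) -> pd.DataFrame:
        run_len = n_frames * tr_seconds
        if self.task == "motor":
            return self._motor_events(run_len, rng)
        if self.task == "language":
            return self._language_events(run_len)
        if self.task == "memory":
            return self._memory_events(run_len, rng, run_index)
        raise ValueError(f"no schedule for task {self.task!r}")

    def _motor_events(self, run_len: float, rng: np.random.Generator) -> pd.DataFrame:
        # 2 blocks per movement condition, 15.4 s each, order shuffled per run
        conds = [c for c in self.conditions] * 2
        order = rng.permutation(len(conds))
        block = 15.4
        start, stop = 10.0, run_len - block - 2.0
        if stop <= start:
            raise ValueError("motor run too short for the block schedule")
        onsets = np.linspace(start, stop, len(conds))
        rows = [(onsets[i], block, conds[order[i]]) for i in range(len(conds))]
        return pd.DataFrame(rows, columns=EVENT_COLUMNS).sort_values("onset", ignore_index=True)

    def _language_events(self, run_len: float) -> pd.DataFrame:
        # two blocks each of the coherence and verbal tasks, 30 trials apiece,
        # 44 s fixation between blocks; deterministic schedule
        rows: list[tuple[float, float, str]] = []
        t = 10.0
        blocks = [("coherence", ("coherent", "random")), ("verbal", ("noun", "verb"))] * 2
        for kind, trial_types in blocks:
            rows.append((t, 2.2, "cue_start"))
            rows.append((t, 121.0, f"{kind}_sustained"))
            trial_t = t + 2.2 + 1.1
            for j in range(30):
                rows.append((trial_t, 0.5, trial_types[j % 2]))
                trial_t += 3.3
            rows.append((trial_t, 2.2, "cue_end"))
            t = trial_t + 2.2 + 44.0
        if t - 44.0 > run_len:
            raise ValueError("language run too short for the block schedule")
        return pd.DataFrame(rows, columns=EVENT_COLUMNS).sort_values("onset", ignore_index=True)

    def _memory_events(self, run_len: float, rng: np.random.Generator,
                       run_index: int) -> pd.DataFrame:
        stim = ("face", "scene", "word")[(run_index - 1) % 3]
        window = 12.0
        rows: list[tuple[float, float, str]] = []
        t = 10.0
        for rep in (1, 2, 3):
            for _ in range(24):
                if t + window > run_len:
                    break
                rows.append((t, 1.7, f"{stim}_rep{rep}"))
                t += 1.7 + rng.uniform(0.5, 4.9)  # jittered ISI
        return pd.DataFrame(rows, columns=EVENT_COLUMNS).sort_values("onset", ignore_index=True)


def default_task_designs(amplitude: float = 8.0) -> dict[str, TaskDesign]:
    """Task designs with the standard FIR bases and a common peak amplitude.

    ``amplitude`` (a.u.) is the peak evoked response added to engaged parcels;
    sustained and cue regressors get a quarter of it.
    """
    specs = default_fir_specs()
    designs = {}
    for task, conds in specs.items():
        amps = {}
        for cond, basis in conds.items():
            if basis.n_bins == 1:
                amps[cond] = np.array([amplitude / 4.0])
            else:
                amps[cond] = _bump(basis.n_bins, amplitude)
        designs[task] = TaskDesign(task=task, conditions=dict(conds), amplitudes=amps)
    return designs


@dataclass
class SyntheticSpec:
    """Full description of a synthetic multi-session dataset.

    Defaults mirror the emulated study design: 9 subjects x 10 sessions at
    TR 2.2 s with one 30-min rest run, two motor, two language and three
    memory runs per session.  The parcel count defaults to 170 parcels in 17
    networks (10 per network) as a desk-scale stand-in for a 1000-parcel
    atlas.
    """

    n_subjects: int = 9
    n_sessions: int = 10
    n_parcels: int = 170
    n_networks: int = 17
    frames_per_run: dict[str, int] = field(
        default_factory=lambda: {"rest": 818, "motor": 112, "language": 288, "memory": 150}
    )
    runs_per_state: dict[str, int] = field(
        default_factory=lambda: {"rest": 1, "motor": 2, "language": 2, "memory": 3}
    )
    tr_seconds: float = 2.2
    within_network_r: float = 0.4
    between_network_r: float = 0.08
    subject_edge_sd: float = 0.05
    parcel_mean_profile: np.ndarray | None = None  # a.u., default 600..1000
    parcel_sd_profile: np.ndarray | None = None  # a.u., default 5..30
    task_designs: dict[str, TaskDesign] | None = None
    engaged_parcels: dict[str, np.ndarray] | None = None  # 1-based labels
    engaged_networks: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ENGAGED_NETWORKS)
    )
    motion_spike_prob: float = 0.05
    ar1_coef: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parcels < self.n_networks:
            raise ValueError("need at least one parcel per network")
        if not -1 <= self.between_network_r <= self.within_network_r <= 1:
            raise ValueError("require -1 <= between_network_r <= within_network_r <= 1")
        if self.parcel_mean_profile is None:
            self.parcel_mean_profile = np.linspace(600.0, 1000.0, self.n_parcels)
        if self.parcel_sd_profile is None:
            self.parcel_sd_profile = np.linspace(5.0, 30.0, self.n_parcels)
        self.parcel_mean_profile = np.asarray(self.parcel_mean_profile, dtype=float)
        self.parcel_sd_profile = np.asarray(self.parcel_sd_profile, dtype=float)
        for name, prof in (("mean", self.parcel_mean_profile), ("sd", self.parcel_sd_profile)):
            if prof.shape != (self.n_parcels,):
                raise ValueError(f"parcel_{name}_profile must have n_parcels entries")
        if np.any(self.parcel_sd_profile <= 0):
            raise ValueError("parcel_sd_profile must be positive")
        if self.task_designs is None:
            self.task_designs = {
                t: d for t, d in default_task_designs().items() if t in self.runs_per_state
            }
        if self.engaged_parcels is not None:
            for state, parcels in self.engaged_parcels.items():
                parcels = np.asarray(parcels, dtype=int)
                if parcels.min(initial=1) < 1 or parcels.max(initial=1) > self.n_parcels:
                    raise ValueError(f"engaged parcels for {state!r} outside 1..n_parcels")
                self.engaged_parcels[state] = parcels
        if not 0 <= self.motion_spike_prob <= 1:
            raise ValueError("motion_spike_prob must be a probability")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must lie in [0, 1)")

    @property
    def states(self) -> list[str]:
        return list(self.runs_per_state)

    @property
    def task_states(self) -> list[str]:
        return [s for s in self.states if s != "rest"]


@dataclass
class GroundTruth:
    """Planted structure a downstream analysis should recover."""

    base_covariance: np.ndarray
    subject_covariances: list[np.ndarray]
    partition: np.ndarray  # parcel -> network id, 1..n_networks
    engaged_parcels: dict[str, np.ndarray]
    variance_components: dict[str, float]

    @property
    def n_parcels(self) -> int:
        return self.base_covariance.shape[0]


def _block_partition(n_parcels: int, n_networks: int) -> np.ndarray:
    return (np.arange(n_parcels) * n_networks) // n_parcels + 1


def _nearest_correlation(a: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues at ``eig_floor`` and rescale to a unit diagonal."""
    w, v = np.linalg.eigh((a + a.T) / 2.0)
    w = np.clip(w, eig_floor, None)
    a = (v * w) @ v.T
    d = np.sqrt(np.diag(a))
    a = a / np.outer(d, d)
    np.fill_diagonal(a, 1.0)
    return a


def build_ground_truth(spec: SyntheticSpec) -> GroundTruth:
    """Block network covariance plus per-subject perturbed covariances."""
    P, K = spec.n_parcels, spec.n_networks
    partition = _block_partition(P, K)
    base = np.full((P, P), spec.between_network_r)
    same = partition[:, None] == partition[None, :]
    base[same] = spec.within_network_r
    np.fill_diagonal(base, 1.0)
    w = np.linalg.eigvalsh(base)
    if w.min() <= 0:
        raise ValueError(
            f"target covariance is not positive definite (min eigenvalue {w.min():.3g}); "
            "between_network_r is too negative for this block count"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 101]))
    covs = []
    iu = np.triu_indices(P, k=1)
    for _ in range(spec.n_subjects):
        if spec.subject_edge_sd == 0:
            covs.append(base.copy())
            continue
        pert = np.zeros((P, P))
        pert[iu] = rng.normal(0.0, spec.subject_edge_sd, iu[0].size)
        pert = pert + pert.T
        covs.append(_nearest_correlation(base + pert))
    engaged = spec.engaged_parcels
    if engaged is None:
        engaged = {
            state: np.flatnonzero(partition == spec.engaged_networks[state]) + 1
            for state in spec.task_states
            if state in spec.engaged_networks
        }
    return GroundTruth(
        base_covariance=base,
        subject_covariances=covs,
        partition=partition,
        engaged_parcels=engaged,
        variance_components={
            "sigma_lambda2": float(spec.subject_edge_sd**2),
            "sigma_pi2": 0.0,
        },
    )


def run_seed(spec_seed: int, subject: int, session: int, state: str, run: int) -> int:
    """Stable per-run integer seed derived from the dataset seed and labels."""
    state_code = int.from_bytes(state.encode()[:4].ljust(4, b"\0"), "big")
    ss = np.random.SeedSequence([int(spec_seed), subject, session, state_code, run])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def simulate_run(
    gt: GroundTruth,
    subject: int,
    session: int,
    state: str,
    spec: SyntheticSpec,
    seed: int | None = None,
    run: int = 1,
) -> tuple[BoldRun, pd.DataFrame, MotionTrace]:
    """Simulate one run: BOLD matrix, BIDS-style events, and motion trace.

    The BOLD series is ``mean_profile + sd_profile * (AR(1) noise through the
    subject covariance factor)`` with the task-evoked FIR component added to
    engaged parcels only.  Identical arguments give bit-identical output.
    """
    if state not in spec.states:
        raise ValueError(f"unknown state {state!r}")
    if not 1 <= subject <= spec.n_subjects:
        raise ValueError(f"subject {subject} outside 1..{spec.n_subjects}")
    if seed is None:
        seed = run_seed(spec.seed, subject, session, state, run)
    rng = np.random.default_rng(seed)
    T = spec.frames_per_run[state]
    P = spec.n_parcels
    L = np.linalg.cholesky(gt.subject_covariances[subject - 1])

    z = rng.standard_normal((T, P))
    phi = spec.ar1_coef
    if phi > 0:
        x = np.empty_like(z)
        x[0] = z[0]
        c = np.sqrt(1.0 - phi**2)
        for t in range(1, T):
            x[t] = phi * x[t - 1] + c * z[t]
    else:
        x = z
    noise = x @ L.T
    data = spec.parcel_mean_profile + noise * spec.parcel_sd_profile

    if state == "rest":
        events = pd.DataFrame(columns=EVENT_COLUMNS).astype(
            {"onset": float, "duration": float, "trial_type": str}
        )
    else:
        design_spec = spec.task_designs[state]
        longest = max(b.window for b in design_spec.conditions.values())
        if T * spec.tr_seconds < longest:
            raise ValueError(
                f"run length {T * spec.tr_seconds:.1f}s shorter than the longest "
                f"FIR window ({longest:.1f}s)"
            )
        events = design_spec.make_events(T, spec.tr_seconds, rng, run_index=run)
        design = build_fir_design(events, design_spec.conditions, T, spec.tr_seconds)
        evoked = np.zeros(T)
        for i, (cond, b) in enumerate(design.columns):
            evoked += design.matrix[:, i] * design_spec.amplitudes[cond][b]
        engaged = gt.engaged_parcels.get(state, np.array([], dtype=int))
        if engaged.size:
            data[:, engaged - 1] += evoked[:, None]

    fd = np.abs(rng.normal(0.05, 0.02, T))
    spikes = rng.random(T) < spec.motion_spike_prob
    fd[spikes] += rng.uniform(0.25, 1.0, T)[spikes]
    fd[0] = 0.0
    # encode FD as alternating-sign x-translation steps so that recomputing
    # Power-style FD from the parameters recovers the planted trace exactly
    signs = np.where(np.arange(T) % 2 == 0, 1.0, -1.0)
    trans = np.zeros((T, 3))
    trans[:, 0] = np.cumsum(signs * fd)
    motion = MotionTrace(translations=trans, rotations=np.zeros((T, 3)), fd=fd)

    bold = BoldRun(
        data=data,
        tr_seconds=spec.tr_seconds,
        subject=f"sub-{subject:02d}",
        session=session,
        run=run,
        state=state,
        unit_level="parcel",
    )
    return bold, events, motion


def simulate_dataset(spec: SyntheticSpec, out_dir, overwrite: bool = False,
                     fmt: str = "npy") -> dict:
    """Write a full dataset tree (runs + events + motion + manifest) to disk."""
    from . import io as fio  # local import to avoid a cycle at import time
    from pathlib import Path
    import json

    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace it")
    out.mkdir(parents=True, exist_ok=True)

    gt = build_ground_truth(spec)
    gt_path = out / "ground_truth.npz"
    np.savez(
        gt_path,
        base_covariance=gt.base_covariance,
        subject_covariances=np.stack(gt.subject_covariances),
        partition=gt.partition,
        **{f"engaged_{k}": v for k, v in gt.engaged_parcels.items()},
    )

    entries = []
    for subject in range(1, spec.n_subjects + 1):
        for session in range(1, spec.n_sessions + 1):
            for state in spec.states:
                for run in range(1, spec.runs_per_state[state] + 1):
                    seed = run_seed(spec.seed, subject, session, state, run)
                    bold, events, motion = simulate_run(
                        gt, subject, session, state, spec, seed=seed, run=run
                    )
                    stem = (
                        f"sub-{subject:02d}/ses-{session:02d}/"
                        f"sub-{subject:02d}_ses-{session:02d}_task-{state}_run-{run:02d}"
                    )
                    (out / stem).parent.mkdir(parents=True, exist_ok=True)
                    run_path = fio.write_run(bold, out / f"{stem}_bold", fmt=fmt)
                    ev_path = out / f"{stem}_events.tsv"
                    fio.write_events(events, ev_path)
                    mo_path = out / f"{stem}_motion.tsv"
                    fio.write_motion(motion, mo_path)
                    entries.append(
                        {
                            "subject": subject,
                            "session": session,
                            "state": state,
                            "run": run,
                            "seed": seed,
                            "bold": str(run_path.relative_to(out)),
                            "events": str(ev_path.relative_to(out)),
                            "motion": str(mo_path.relative_to(out)),
                        }
                    )

    manifest = {
        "seed": int(spec.seed),
        "spec": _spec_to_jsonable(spec),
        "variance_components": gt.variance_components,
        "ground_truth": str(gt_path.relative_to(out)),
        "runs": entries,
    }
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _spec_to_jsonable(spec: SyntheticSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["parcel_mean_profile"] = spec.parcel_mean_profile.tolist()
    d["parcel_sd_profile"] = spec.parcel_sd_profile.tolist()
    d["task_designs"] = {
        t: {
            "conditions": {c: [b.n_bins, b.bin_width] for c, b in td.conditions.items()},
            "amplitudes": {c: a.tolist() for c, a in td.amplitudes.items()},
        }
        for t, td in spec.task_designs.items()
    }
    if spec.engaged_parcels is not None:
        d["engaged_parcels"] = {k: np.asarray(v).tolist() for k, v in spec.engaged_parcels.items()}
    return d


def simulate_edge_table(
    rho: float,
    n_subjects: int,
    n_edges: int,
    seed: int,
    total_variance: float = 1.0,
    mean: float = 0.3,
) -> np.ndarray:
    """Edge weights with a known between/total variance ratio.

    For each edge, subject true values are N(mean, rho * total_variance) and
    each half adds independent N(0, (1 - rho) * total_variance) measurement
    noise, so the population ICC(2,1) of every edge equals ``rho``.  Returns
    an (n_edges, n_subjects, 2) array.
    """
    if not 0 <= rho <= 1:
        raise ValueError("rho must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lam = rng.normal(mean, np.sqrt(rho * total_variance), (n_edges, n_subjects, 1))
    eps = rng.normal(0.0, np.sqrt((1.0 - rho) * total_variance), (n_edges, n_subjects, 2))
    return lam + eps
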