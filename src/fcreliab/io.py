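"""File formats: run matrices, events, motion, confounds, maps, config.

Run matrices travel either as delimited text (frames as rows, units as
columns, header row of unit ids) or as a binary ``.npy`` container; both
carry a JSON sidecar (``<stem>.json``) with tr_seconds, subject, session,
run, state, unit_level, and the censor mask.  Events and motion follow the
BIDS TSV dialect: tab-separated, ``n/a`` for missing values, onsets in
seconds from run start.  CIFTI dtseries/ptseries are read through nibabel
when available.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import BoldRun, MotionTrace

logger = logging.getLogger(__name__)

__all__ = [
    "write_run",
    "read_timeseries",
    "write_events",
    "read_events",
    "write_motion",
    "read_motion",
    "write_map",
    "read_map",
    "write_matrix",
    "read_matrix",
    "PipelineConfig",
]

NA = "n/a"


def _sidecar(run: BoldRun) -> dict:
    return {
        "tr_seconds": run.tr_seconds,
        "subject": run.subject,
        "session": run.session,
        "run": run.run,
        "state": run.state,
        "unit_level": run.unit_level,
        "censor_mask": run.censor_mask.astype(int).tolist(),
    }


def write_run(run: BoldRun, path, fmt: str = "npy") -> Path:
    """Write a run matrix plus JSON sidecar; returns the data path."""
    path = Path(path)
    if fmt == "npy":
        data_path = path.with_suffix(".npy")
        np.save(data_path, run.data)
    elif fmt == "tsv":
        data_path = path.with_suffix(".tsv")
        header = "\t".join(f"unit_{i + 1}" for i in range(run.n_units))
        np.savetxt(data_path, run.data, delimiter="\t", header=header, comments="")
    else:
        raise ValueError(f"unknown run format {fmt!r}")
    data_path.with_suffix(".json").write_text(json.dumps(_sidecar(run), indent=1))
    return data_path


REQUIRED_SIDECAR = ("tr_seconds", "subject", "session", "run", "state")


def read_timeseries(path) -> BoldRun:
    """Read a run from .tsv / .npy (+ sidecar) or CIFTI dtseries/ptseries."""
    path = Path(path)
    name = path.name
    if name.endswith(".dtseries.nii") or name.endswith(".ptseries.nii") or name.endswith(".nii"):
        return _read_cifti(path)
    if path.suffix == ".npy":
        data = np.load(path)
    elif path.suffix == ".tsv":
        data = _read_text_matrix(path, expect_header=True)
    else:
        raise ValueError(f"unrecognized time-series format: {path}")
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for f in REQUIRED_SIDECAR:
        if f not in meta:
            raise ValueError(f"sidecar {sidecar_path} missing field {f!r}")
    mask = meta.get("censor_mask")
    return BoldRun(
        data=data,
        tr_seconds=float(meta["tr_seconds"]),
        subject=str(meta["subject"]),
        session=int(meta["session"]),
        run=int(meta["run"]),
        state=str(meta["state"]),
        censor_mask=None if mask is None else np.asarray(mask, dtype=bool),
        unit_level=meta.get("unit_level", "parcel"),
    )


def _read_text_matrix(path: Path, expect_header: bool = False) -> np.ndarray:
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and expect_header:
                try:
                    [float(p) for p in parts]
                except ValueError:
                    width = len(parts)
                    continue  # header row
            if width is None:
                width = len(parts)
            elif len(parts) != width:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(parts)} fields, expected {width})"
                )
            rows.append([float(p) for p in parts])
    return np.asarray(rows, dtype=float)


def _read_cifti(path: Path) -> BoldRun:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    ax0 = img.header.get_axis(0)
    ax1 = img.header.get_axis(1)
    tr = float(getattr(ax0, "step", 1.0) or 1.0)
    unit_level = "parcel" if type(ax1).__name__ == "ParcelsAxis" else "dense"
    return BoldRun(
        data=data,
        tr_seconds=tr,
        subject="unknown",
        session=1,
        run=1,
        state="unknown",
        unit_level=unit_level,
    )


def write_events(events: pd.DataFrame, path) -> Path:
    path = Path(path)
    out = events.copy()
    out.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.6g")
    return path


def read_events(path) -> pd.DataFrame:
    """BIDS events TSV: columns onset, duration, trial_type; sorted by onset."""
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    for col in ("onset", "duration", "trial_type"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df["onset"] = df["onset"].astype(float)
    df["duration"] = pd.to_numeric(df["duration"], errors="coerce")
    if (df["onset"] < 0).any():
        raise ValueError(f"{path}: negative onset")
    if not df["onset"].is_monotonic_increasing:
        warnings.warn(f"{path}: onsets not sorted; sorting", RuntimeWarning, stacklevel=2)
        df = df.sort_values("onset", ignore_index=True)
    return df


MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def write_motion(motion: MotionTrace, path) -> Path:
    path = Path(path)
    data = {c: motion.translations[:, i] for i, c in enumerate(MOTION_COLUMNS[:3])}
    data.update({c: motion.rotations[:, i] for i, c in enumerate(MOTION_COLUMNS[3:])})
    if motion.fd is not None:
        data["fd"] = motion.fd
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.8g")
    return path


def read_motion(path) -> MotionTrace:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing and "fd" not in df.columns:
        raise ValueError(f"{path}: missing motion columns {missing} and no fd column")
    if missing:
        n = len(df)
        trans = np.zeros((n, 3))
        rot = np.zeros((n, 3))
    else:
        trans = df[MOTION_COLUMNS[:3]].to_numpy(float)
        rot = df[MOTION_COLUMNS[3:]].to_numpy(float)
    fd = df["fd"].to_numpy(float) if "fd" in df.columns else None
    return MotionTrace(translations=trans, rotations=rot, fd=fd)


def write_map(values: np.ndarray, path, unit_label: str = "unit") -> Path:
    """Two-column TSV map: unit id (1-based) and value."""
    path = Path(path)
    df = pd.DataFrame({unit_label: np.arange(1, np.size(values) + 1),
                       "value": np.asarray(values, dtype=float)})
    df.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.10g")
    return path


def read_map(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    return df["value"].to_numpy(float)


def write_matrix(matrix: np.ndarray, path, fmt: str = "tsv") -> Path:
    path = Path(path)
    if fmt == "tsv":
        np.savetxt(path, np.asarray(matrix, dtype=float), delimiter="\t", fmt="%.10g")
    elif fmt == "npy":
        np.save(path, np.asarray(matrix, dtype=float))
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")
    return path


def read_matrix(path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path)
    return _read_text_matrix(path)


@dataclass
class PipelineConfig:
    """All thresholds and paths driving the end-to-end pipeline.

    Values default to the study constants: FD threshold 0.20 mm, band-pass
    0.01-0.08 Hz, edge densities 2-5%, split halves = first/last half of the
    session list, global signal regression on.
    """

    dataset_dir: str = "dataset"
    output_dir: str = "outputs"
    fd_threshold: float = 0.20
    band: tuple[float, float] = (0.01, 0.08)
    densities: tuple[float, ...] = (0.02, 0.03, 0.04, 0.05)
    reference_state: str = "motor"
    gsr: bool = True
    task_regress: bool = True
    max_networks: int = 17
    community_method: str = "infomap"
    community_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fd_threshold <= 0:
            raise ValueError("fd_threshold must be positive")
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError("band must satisfy 0 < lo < hi")
        if any(not 0 < d <= 1 for d in self.densities):
            raise ValueError("densities must lie in (0, 1]")
        self.band = (float(lo), float(hi))
        self.densities = tuple(float(d) for d in self.densities)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        d["densities"] = list(self.densities)
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "band" in d:
            d["band"] = tuple(d["band"])
        if "densities" in d:
            d["densities"] = tuple(d["densities"])
        return cls(**d)
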