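"""Data model and file I/O for stance-slip training sessions.

A session is one participant's block of ten slip trials. Each trial bundles
surface EMG (8 channels: TA, GAS, VLAT, BFLH on the recovery and slipping
sides, 600 Hz), 3-D marker trajectories (120 Hz) and a harness load-cell
trace, all on a common clock. Files are plain CSV (UTF-8, '.' decimal, one
header row) plus a YAML session manifest; C3D ingestion is a non-goal.

Axis convention used throughout the package: x = anteroposterior (positive
anterior, i.e. the belt travel direction), y = mediolateral, z = vertical.
Readers must map input data into this frame.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Muscle",
    "Side",
    "MuscleChannel",
    "CANONICAL_CHANNELS",
    "CANONICAL_LABELS",
    "EmgTrial",
    "MarkerTrial",
    "LoadCellTrial",
    "TrialBundle",
    "Session",
    "PipelineConfig",
    "REQUIRED_MARKERS",
    "read_emg",
    "write_emg",
    "read_markers",
    "write_markers",
    "read_loadcell",
    "write_loadcell",
    "read_session",
    "write_session",
    "load_config",
]


class Muscle(str, enum.Enum):
    TA = "TA"        # tibialis anterior
    GAS = "GAS"      # medial gastrocnemius
    VLAT = "VLAT"    # vastus lateralis
    BFLH = "BFLH"    # biceps femoris long head


class Side(str, enum.Enum):
    RECOVERY = "R"   # stepping limb
    SLIPPING = "S"   # stance limb on the moving belt


@dataclass(frozen=True)
class MuscleChannel:
    muscle: Muscle
    side: Side

    @property
    def label(self) -> str:
        return f"{self.side.value}_{self.muscle.value}"

    @classmethod
    def from_label(cls, label: str) -> "MuscleChannel":
        side_code, _, muscle_code = label.partition("_")
        try:
            return cls(Muscle(muscle_code), Side(side_code))
        except ValueError as exc:
            raise ValueError(f"unrecognized EMG channel label {label!r}") from exc


#: Canonical channel order: recovery side first, then slipping side,
#: distal-to-proximal within side. All matrices in the package use this order.
CANONICAL_CHANNELS: tuple[MuscleChannel, ...] = tuple(
    MuscleChannel(m, s)
    for s in (Side.RECOVERY, Side.SLIPPING)
    for m in (Muscle.TA, Muscle.GAS, Muscle.VLAT, Muscle.BFLH)
)
CANONICAL_LABELS: tuple[str, ...] = tuple(c.label for c in CANONICAL_CHANNELS)

#: Markers every trial must provide (events, step geometry and BOS need them).
REQUIRED_MARKERS: tuple[str, ...] = (
    "belt",
    "L_heel", "R_heel",
    "L_toe", "R_toe",
    "L_shoulder", "R_shoulder",
    "L_hip", "R_hip",
)


@dataclass
class EmgTrial:
    """Raw or processed multi-channel EMG for one slip trial."""

    trial_id: str
    stage: str                      # "early", "late" or "other"
    channels: tuple[MuscleChannel, ...]
    signal: np.ndarray              # [8 x n_samples]
    rate_hz: float

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] != 8:
            raise ValueError(
                f"EMG signal must be 8 x n_samples, got {self.signal.shape}"
            )
        if self.signal.shape[1] < 2:
            raise ValueError("EMG trial needs at least 2 samples")
        if len(set(self.channels)) != 8:
            raise ValueError("EMG trial must carry 8 distinct (muscle, side) channels")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate_hz

    def replace(self, **kwargs) -> "EmgTrial":
        return dataclasses.replace(self, **kwargs)


@dataclass
class MarkerTrial:
    """3-D marker trajectories in metres, axes (AP, ML, vertical)."""

    marker_names: list[str]
    positions: np.ndarray           # [n_markers x n_frames x 3]
    rate_hz: float
    gap_report: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must be [n_markers x n_frames x 3]")
        if self.positions.shape[0] != len(self.marker_names):
            raise ValueError("marker_names length must match positions")
        if self.positions.shape[1] < 2:
            raise ValueError("marker trial needs at least 2 frames")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    def trajectory(self, name: str) -> np.ndarray:
        """[n_frames x 3] trajectory of one marker."""
        try:
            i = self.marker_names.index(name)
        except ValueError as exc:
            raise KeyError(f"marker {name!r} not present") from exc
        return self.positions[i]


@dataclass
class LoadCellTrial:
    """Harness load-cell force trace, baseline-subtracted, in newtons."""

    force: np.ndarray
    rate_hz: float
    body_weight_n: float

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        if self.force.ndim != 1:
            raise ValueError("force must be a vector")
        if np.any(self.force < 0):
            raise ValueError("force must be non-negative after baseline subtraction")
        if self.body_weight_n <= 0:
            raise ValueError("body_weight_n must be positive")


@dataclass
class TrialBundle:
    trial_id: str
    stage: str
    emg: EmgTrial
    markers: MarkerTrial
    loadcell: LoadCellTrial
    recovery_side: str = "right"    # limb that takes the compensatory step


@dataclass
class Session:
    """One participant's ten-trial slip-training block."""

    participant_id: str
    trials: list[TrialBundle]
    body_height_m: float
    body_weight_kg: float
    # trial index (0-based) -> stage; S1-S2 are early, S9-S10 late by default
    stage_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stage_map:
            n = len(self.trials)
            self.stage_map = {i: "other" for i in range(n)}
            for i in (0, 1):
                if i < n:
                    self.stage_map[i] = "early"
            for i in (n - 2, n - 1):
                if i >= 0:
                    self.stage_map[i] = "late"
        for i, t in enumerate(self.trials):
            t.stage = self.stage_map.get(i, "other")
            t.emg.stage = t.stage

    def stage_trials(self, stage: str) -> list[TrialBundle]:
        return [t for i, t in enumerate(self.trials) if self.stage_map.get(i) == stage]


# ---------------------------------------------------------------------------
# Pipeline configuration

def _percent_field(name: str, value: float, lo: float, hi: float) -> float:
    """Validate a percent-valued threshold; fractional look-alikes rejected."""
    value = float(value)
    if not (lo <= value <= hi):
        raise ValueError(
            f"config field {name}={value} out of range [{lo}, {hi}]; "
            f"percent thresholds must be given in percent, not as fractions"
        )
    return value


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters, defaulting to the study protocol.

    Thresholds that the protocol quotes in percent (VAF 90/75/5, onset 25,
    fall 30) are stored in percent; fraction-scale values are rejected to
    remove a silent x100 bug class.
    """

    emg_highpass_hz: float = 35.0
    emg_lowpass_hz: float = 40.0
    marker_lowpass_hz: float = 6.0
    event_lowpass_hz: float = 10.0
    bin_ms: float = 10.0
    window_pre_ms: float = 100.0
    window_post_ms: float = 100.0
    vaf_global_pct: float = 90.0
    vaf_muscle_pct: float = 75.0
    vaf_gain_pct: float = 5.0
    k_max_synergies: int = 8
    nnmf_restarts: int = 20
    nnmf_max_iter: int = 2000
    nnmf_tol: float = 1e-6
    cluster_k_min: int = 1
    cluster_k_max: int = 8
    kmeans_repeats: int = 100
    similarity_r: float = 0.83
    belt_velocity_thresh_mps: float = 0.05
    heel_velocity_thresh_mps: float = 0.05
    event_sustain_frames: int = 3
    onset_pct: float = 25.0
    fall_bw_pct: float = 30.0
    curve_points: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("emg_highpass_hz", "emg_lowpass_hz", "marker_lowpass_hz",
                     "bin_ms", "nnmf_tol", "similarity_r",
                     "belt_velocity_thresh_mps", "heel_velocity_thresh_mps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        self.vaf_global_pct = _percent_field("vaf_global_pct", self.vaf_global_pct, 50, 100)
        self.vaf_muscle_pct = _percent_field("vaf_muscle_pct", self.vaf_muscle_pct, 50, 100)
        self.vaf_gain_pct = _percent_field("vaf_gain_pct", self.vaf_gain_pct, 0.5, 50)
        self.onset_pct = _percent_field("onset_pct", self.onset_pct, 1, 99)
        self.fall_bw_pct = _percent_field("fall_bw_pct", self.fall_bw_pct, 1, 99)
        if not (1 <= self.k_max_synergies <= 8):
            raise ValueError("k_max_synergies must be in 1..8")
        if self.cluster_k_min < 1 or self.cluster_k_max < self.cluster_k_min:
            raise ValueError("invalid cluster k range")
        if self.curve_points < 2:
            raise ValueError("curve_points must be >= 2")


def load_config(path: Optional[str | Path] = None, **overrides) -> PipelineConfig:
    """Load a YAML config; unspecified fields take the protocol defaults."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(loaded)
    data.update(overrides)
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return PipelineConfig(**data)


# ---------------------------------------------------------------------------
# EMG files

def _infer_rate(time_s: np.ndarray, jitter_tol: float = 0.01) -> float:
    dt = np.diff(time_s)
    if np.any(dt <= 0):
        raise ValueError("time column must be strictly increasing")
    mean_dt = dt.mean()
    if np.max(np.abs(dt - mean_dt)) > jitter_tol * mean_dt:
        raise ValueError("non-uniform sampling: jitter exceeds 1% of the sample period")
    return 1.0 / mean_dt


def read_emg(path: str | Path, manifest_entry: Optional[dict] = None) -> EmgTrial:
    """Read one trial's EMG CSV into canonical channel order.

    The file has one header row of channel labels (R_TA ... S_BFLH) and an
    optional leading ``time`` column in seconds; without a time column the
    manifest's rate applies.
    """
    manifest_entry = manifest_entry or {}
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns)
    time_col = cols[0] if cols and cols[0].lower() in ("time", "time_s", "t") else None

    missing = [lab for lab in CANONICAL_LABELS if lab not in cols]
    if missing:
        raise ValueError(f"EMG file {path} missing channel(s): {', '.join(missing)}")

    rate = float(manifest_entry.get("emg_rate_hz", 600.0))
    if time_col is not None:
        inferred = _infer_rate(df[time_col].to_numpy())
        if "emg_rate_hz" in manifest_entry and abs(inferred - rate) > 1e-3 * rate:
            raise ValueError(
                f"inferred rate {inferred:.3f} Hz disagrees with manifest {rate} Hz"
            )
        rate = inferred

    signal = df[list(CANONICAL_LABELS)].to_numpy(dtype=float).T
    return EmgTrial(
        trial_id=str(manifest_entry.get("trial_id", Path(path).stem)),
        stage=str(manifest_entry.get("stage", "other")),
        channels=CANONICAL_CHANNELS,
        signal=signal,
        rate_hz=rate,
    )


def write_emg(trial: EmgTrial, path: str | Path, include_time: bool = True) -> None:
    row_of = {c.label: i for i, c in enumerate(trial.channels)}
    df = pd.DataFrame({lab: trial.signal[row_of[lab]] for lab in CANONICAL_LABELS})
    if include_time:
        df.insert(0, "time", trial.times)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Marker files

_GAP_INTERP_MAX = 5  # frames; longer gaps stay missing and are reported


def _fill_gaps(values: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Linearly interpolate interior gaps of <= _GAP_INTERP_MAX frames.

    Returns the filled array and a list of (start, length) for gaps left
    missing.
    """
    out = values.copy()
    n = len(values)
    isnan = np.isnan(values)
    long_gaps: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if not isnan[i]:
            i += 1
            continue
        j = i
        while j < n and isnan[j]:
            j += 1
        length = j - i
        interior = i > 0 and j < n
        if interior and length <= _GAP_INTERP_MAX:
            out[i:j] = np.interp(np.arange(i, j), [i - 1, j], [values[i - 1], values[j]])
        else:
            long_gaps.append((i, length))
        i = j
    return out, long_gaps


def read_markers(path: str | Path, rate_hz: float = 120.0) -> MarkerTrial:
    """Read a marker CSV with columns ``<name>_X/<name>_Y/<name>_Z``.

    Short gaps (<= 5 frames) are linearly interpolated; longer gaps are left
    missing and listed in ``gap_report``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns)
    if cols and cols[0].lower() in ("time", "time_s", "t"):
        rate_hz = _infer_rate(df[cols[0]].to_numpy())
        cols = cols[1:]

    names: list[str] = []
    for c in cols:
        if c.endswith("_X"):
            name = c[:-2]
            if f"{name}_Y" in cols and f"{name}_Z" in cols:
                names.append(name)
    missing = [m for m in REQUIRED_MARKERS if m not in names]
    if missing:
        raise ValueError(f"marker file {path} missing required marker(s): {', '.join(missing)}")

    n_frames = len(df)
    positions = np.empty((len(names), n_frames, 3))
    gap_report: dict[str, list[tuple[int, int]]] = {}
    for i, name in enumerate(names):
        for k, ax in enumerate("XYZ"):
            filled, gaps = _fill_gaps(df[f"{name}_{ax}"].to_numpy(dtype=float))
            positions[i, :, k] = filled
            if gaps and name not in gap_report:
                gap_report[name] = gaps
    for name, gaps in gap_report.items():
        n_missing = sum(g[1] for g in gaps)
        if n_missing > 0.10 * n_frames:
            raise ValueError(
                f"marker {name!r} has {n_missing}/{n_frames} frames missing after interpolation"
            )
    return MarkerTrial(names, positions, rate_hz, gap_report)


def write_markers(trial: MarkerTrial, path: str | Path, include_time: bool = True) -> None:
    data = {}
    if include_time:
        data["time"] = np.arange(trial.n_frames) / trial.rate_hz
    for i, name in enumerate(trial.marker_names):
        for k, ax in enumerate("XYZ"):
            data[f"{name}_{ax}"] = trial.positions[i, :, k]
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Load-cell files

def read_loadcell(path: str | Path, body_weight_n: float, rate_hz: float = 600.0) -> LoadCellTrial:
    df = pd.read_csv(path, float_precision="round_trip")
    if "force_n" not in df.columns:
        raise ValueError(f"load-cell file {path} missing 'force_n' column")
    cols = list(df.columns)
    if cols[0].lower() in ("time", "time_s", "t"):
        rate_hz = _infer_rate(df[cols[0]].to_numpy())
    return LoadCellTrial(df["force_n"].to_numpy(dtype=float), rate_hz, body_weight_n)


def write_loadcell(trial: LoadCellTrial, path: str | Path) -> None:
    df = pd.DataFrame({
        "time": np.arange(len(trial.force)) / trial.rate_hz,
        "force_n": trial.force,
    })
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Sessions

def write_session(session: Session, out_dir: str | Path) -> Path:
    """Write a session as per-trial CSVs plus a session.yaml manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "participant": session.participant_id,
        "body_height_m": float(session.body_height_m),
        "body_weight_kg": float(session.body_weight_kg),
        "stage_map": {int(k): v for k, v in session.stage_map.items()},
        "trials": [],
    }
    for i, bundle in enumerate(session.trials):
        tid = bundle.trial_id
        write_emg(bundle.emg, out / f"emg_{tid}.csv")
        write_markers(bundle.markers, out / f"markers_{tid}.csv")
        write_loadcell(bundle.loadcell, out / f"loadcell_{tid}.csv")
        manifest["trials"].append({
            "trial_id": tid,
            "index": i,
            "stage": bundle.stage,
            "recovery_side": bundle.recovery_side,
            "emg_rate_hz": float(bundle.emg.rate_hz),
            "marker_rate_hz": float(bundle.markers.rate_hz),
            "loadcell_rate_hz": float(bundle.loadcell.rate_hz),
        })
    (out / "session.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return out


def read_session(session_dir: str | Path) -> Session:
    """Read a session directory written by :func:`write_session`."""
    d = Path(session_dir)
    manifest_path = d / "session.yaml"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no session.yaml in {d}")
    manifest = yaml.safe_load(manifest_path.read_text())
    body_weight_kg = float(manifest["body_weight_kg"])
    body_weight_n = body_weight_kg * 9.81
    bundles = []
    for entry in manifest["trials"]:
        tid = entry["trial_id"]
        emg = read_emg(d / f"emg_{tid}.csv", entry)
        markers = read_markers(d / f"markers_{tid}.csv", entry.get("marker_rate_hz", 120.0))
        loadcell = read_loadcell(
            d / f"loadcell_{tid}.csv", body_weight_n, entry.get("loadcell_rate_hz", 600.0)
        )
        bundles.append(TrialBundle(
            trial_id=tid,
            stage=entry.get("stage", "other"),
            emg=emg,
            markers=markers,
            loadcell=loadcell,
            recovery_side=entry.get("recovery_side", "right"),
        ))
    stage_map = {int(k): v for k, v in manifest.get("stage_map", {}).items()}
    return Session(
        participant_id=str(manifest["participant"]),
        trials=bundles,
        body_height_m=float(manifest["body_height_m"]),
        body_weight_kg=body_weight_kg,
        stage_map=stage_map,
    )
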