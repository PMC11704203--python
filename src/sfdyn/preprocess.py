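"""Sensor ingestion, low-pass filtering, magnitude, phase segmentation.

Input recordings are tri-axial *free* acceleration (gravity already
subtracted on-device) sampled at ``fs`` Hz, stored as delimited text with
columns ``time_s, acc_x, acc_y, acc_z``. Phase annotations arrive as a
sidecar table (``phase, start_s, duration_s``) naming the five still-face
paradigm episodes in A-B-A-B-A order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

#: Canonical episode order of the still-face paradigm.
PHASES: tuple[str, ...] = ("Play", "SF1", "R1", "SF2", "R2")

#: Sensor placement labels.
SENSOR_LOCATIONS: tuple[str, ...] = (
    "torso",
    "wrist_left",
    "wrist_right",
    "ankle_left",
    "ankle_right",
)

#: Default episode duration in seconds.
PHASE_DURATION_S: float = 120.0


class RecordingValidationError(ValueError):
    """Raised when a recording or its phase annotations fail validation."""


@dataclass
class AccelRecording:
    """One sensor's tri-axial free-acceleration series.

    Parameters
    ----------
    sensor_location
        One of :data:`SENSOR_LOCATIONS`.
    fs
        Sampling rate in Hz.
    t
        Monotone time vector in seconds, shape ``(n,)``.
    xyz
        Free acceleration in m/s², shape ``(n, 3)``.
    phase_marks
        Ordered mapping phase name -> half-open sample interval
        ``(start_index, end_index)``.
    participant
        Optional participant identifier carried through to output tables.
    group
        Optional group label (e.g. ``term`` / ``preterm``).
    """

    sensor_location: str
    fs: float
    t: np.ndarray
    xyz: np.ndarray
    phase_marks: dict[str, tuple[int, int]] = field(default_factory=dict)
    participant: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.sensor_location not in SENSOR_LOCATIONS:
            raise RecordingValidationError(
                f"unknown sensor location {self.sensor_location!r}; "
                f"expected one of {SENSOR_LOCATIONS}"
            )
        if self.fs <= 0:
            raise RecordingValidationError(f"fs must be > 0, got {self.fs}")
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise RecordingValidationError(
                f"xyz must have shape (n, 3), got {self.xyz.shape}"
            )
        if len(self.t) != len(self.xyz):
            raise RecordingValidationError(
                f"time vector length {len(self.t)} != sample count {len(self.xyz)}"
            )
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise RecordingValidationError("time column is not strictly increasing")
        self._validate_phase_marks()

    def _validate_phase_marks(self) -> None:
        if not self.phase_marks:
            return
        n = len(self.t)
        prev_end = None
        prev_name = None
        order = [p for p in PHASES if p in self.phase_marks]
        if list(self.phase_marks) != order:
            raise RecordingValidationError(
                f"phases must appear in still-face order {PHASES}, "
                f"got {list(self.phase_marks)}"
            )
        for name, (start, end) in self.phase_marks.items():
            if not (0 <= start < end <= n):
                raise RecordingValidationError(
                    f"phase {name!r} interval [{start}, {end}) outside recording "
                    f"of length {n}"
                )
            if prev_end is not None and start < prev_end:
                raise RecordingValidationError(
                    f"phase {name!r} overlaps {prev_name!r}"
                )
            prev_end, prev_name = end, name

    @property
    def n(self) -> int:
        return len(self.t)


@dataclass
class MagnitudePhase:
    """Acceleration magnitude for one still-face phase.

    A complete 2-min phase at 100 Hz holds exactly 12,000 samples; shorter
    segments are flagged ``complete=False`` and excluded from entropy
    analysis downstream.
    """

    phase: str
    values: np.ndarray
    fs: float
    complete: bool = True
    participant: str = ""
    sensor_location: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.phase not in PHASES:
            raise RecordingValidationError(f"unknown phase {self.phase!r}")
        if np.any(self.values < 0):
            raise RecordingValidationError("magnitude values must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.values)


def read_phase_table(path: str | Path, fs: float) -> dict[str, tuple[int, int]]:
    """Read a phase annotation CSV (``phase, start_s[, duration_s]``).

    Missing ``duration_s`` defaults to 120 s. Intervals are half-open sample
    index ranges ``[round(start_s*fs), round((start_s+duration_s)*fs))``.
    """
    df = pd.read_csv(path)
    required = {"phase", "start_s"}
    if not required.issubset(df.columns):
        raise RecordingValidationError(
            f"phase table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    if "duration_s" not in df.columns:
        df["duration_s"] = PHASE_DURATION_S
    marks: dict[str, tuple[int, int]] = {}
    for row in df.itertuples(index=False):
        if row.phase not in PHASES:
            raise RecordingValidationError(f"unknown phase {row.phase!r} in phase table")
        start = int(round(row.start_s * fs))
        end = int(round((row.start_s + row.duration_s) * fs))
        marks[row.phase] = (start, end)
    # re-emit in canonical order; validation happens inside AccelRecording
    return {p: marks[p] for p in PHASES if p in marks}


def read_recording(
    path: str | Path,
    fs: float = 100.0,
    phase_table: str | Path | dict[str, tuple[int, int]] | None = None,
    sensor_location: str | None = None,
    participant: str = "",
    group: str = "",
) -> AccelRecording:
    """Read a delimited-text recording into a validated :class:`AccelRecording`.

    The file must contain columns ``time_s, acc_x, acc_y, acc_z`` (comma or
    tab separated). ``phase_table`` may be a sidecar CSV path or an explicit
    index mapping. ``sensor_location`` defaults to a label parsed from the
    file stem (last ``__``-separated token).
    """
    path = Path(path)
    try:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
        # round_trip parsing: values written at full precision come back exact
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except (OSError, pd.errors.ParserError, ValueError) as exc:
        raise RecordingValidationError(f"cannot parse {path}: {exc}") from exc
    required = ["time_s", "acc_x", "acc_y", "acc_z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RecordingValidationError(f"{path}: missing columns {missing}")
    bad = df[required].isna().any(axis=1)
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2)[:5]  # +2: header + 1-based
        raise RecordingValidationError(
            f"{path}: malformed/missing values at line(s) {lines.tolist()}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        gaps = np.diff(t) > 1.5 / fs
        if gaps.any():
            logger.warning("%s: %d gap(s) in the time base", path, int(gaps.sum()))
    if sensor_location is None:
        stem = path.stem
        sensor_location = stem.split("__")[-1] if "__" in stem else stem
    if isinstance(phase_table, (str, Path)):
        marks = read_phase_table(phase_table, fs)
    else:
        marks = dict(phase_table or {})
    return AccelRecording(
        sensor_location=sensor_location,
        fs=fs,
        t=t,
        xyz=df[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float),
        phase_marks=marks,
        participant=participant,
        group=group,
    )


def write_recording(rec: AccelRecording, path: str | Path) -> Path:
    """Write a recording back to the delimited-text format read_recording accepts."""
    path = Path(path)
    pd.DataFrame(
        {
            "time_s": rec.t,
            "acc_x": rec.xyz[:, 0],
            "acc_y": rec.xyz[:, 1],
            "acc_z": rec.xyz[:, 2],
        }
    ).to_csv(path, index=False, float_format="%.17g")  # exact round-trip
    return path


def lowpass_filter(
    rec: AccelRecording,
    cutoff: float = 20.0,
    order: int = 4,
    zero_phase: bool = True,
) -> AccelRecording:
    """Low-pass Butterworth filter each axis identically.

    Default is a 4th-order filter applied forward-backward (zero phase
    distortion — ordinal patterns are sensitive to phase warping), which
    squares the magnitude response.
    """
    nyq = rec.fs / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyq} Hz")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sos = signal.butter(order, cutoff, btype="low", fs=rec.fs, output="sos")
    if zero_phase:
        filtered = signal.sosfiltfilt(sos, rec.xyz, axis=0)
    else:
        filtered = signal.sosfilt(sos, rec.xyz, axis=0)
    return AccelRecording(
        sensor_location=rec.sensor_location,
        fs=rec.fs,
        t=rec.t,
        xyz=filtered,
        phase_marks=dict(rec.phase_marks),
        participant=rec.participant,
        group=rec.group,
    )


def acceleration_magnitude(rec: AccelRecording) -> np.ndarray:
    """Per-sample Euclidean norm of the tri-axial free acceleration."""
    return np.linalg.norm(rec.xyz, axis=1)


def segment_phases(
    mag: np.ndarray,
    rec: AccelRecording,
    min_fraction: float = 1.0,
) -> list[MagnitudePhase]:
    """Cut the magnitude series into one :class:`MagnitudePhase` per annotation.

    A phase whose interval holds fewer than ``min_fraction`` of the nominal
    ``round(120 * fs)`` samples is flagged incomplete (and excluded from
    entropy analysis downstream, with a warning).
    """
    mag = np.asarray(mag, dtype=float)
    if len(mag) != rec.n:
        raise ValueError(
            f"magnitude length {len(mag)} != recording length {rec.n}"
        )
    if not rec.phase_marks:
        raise RecordingValidationError("recording has no phase annotations")
    nominal = int(round(PHASE_DURATION_S * rec.fs))
    out: list[MagnitudePhase] = []
    for name, (start, end) in rec.phase_marks.items():
        seg = mag[start:end]
        complete = len(seg) >= min_fraction * nominal
        if not complete:
            warnings.warn(
                f"phase {name!r} has {len(seg)} samples (< {nominal}); "
                "flagged incomplete",
                stacklevel=2,
            )
        out.append(
            MagnitudePhase(
                phase=name,
                values=seg,
                fs=rec.fs,
                complete=complete,
                participant=rec.participant,
                sensor_location=rec.sensor_location,
                group=rec.group,
            )
        )
    return out


def trimmed_mean_acceleration(phase: MagnitudePhase) -> tuple[float, int]:
    """Mean magnitude after removing Tukey-fence outliers.

    Samples outside ``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]`` (quartiles by linear
    interpolation) are excluded. Returns ``(mean, n_excluded)``.
    """
    v = phase.values
    if v.size < 4:
        raise ValueError(f"need at least 4 samples, got {v.size}")
    q1, q3 = np.quantile(v, [0.25, 0.75])
    iqr = q3 - q1
    keep = (v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)
    return float(v[keep].mean()), int(v.size - keep.sum())
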