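"""End-to-end orchestration producing tidy result tables.

The motor pipeline runs filter -> magnitude -> phase segmentation ->
trimmed mean + multiscale PE -> overall and band complexity indices, one
row per (participant, sensor, phase[, scale/band]). The behaviour pipeline
runs chromatic RQA per (participant, phase). Statistical inference on the
tables is deliberately left to external tools.

Every output row carries the parameter fingerprint that produced it
(m, lag, max_scale, v_min, rounding rule, filter settings).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess as pp
from . import rqa as crqa
from .bands import DEFAULT_BANDS, BandSpec, band_scale_range, complexity_index
from .mpe import PEParams, improved_mpe

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_motor_pipeline",
    "run_behaviour_pipeline",
    "read_behaviour_codes",
]


@dataclass
class RunConfig:
    """Validated run parameters; serializable to YAML and echoed to output."""

    fs: float = 100.0
    cutoff_hz: float = 20.0
    filter_order: int = 4
    zero_phase: bool = True
    m: int = 4
    lag: int = 1
    max_scale: int = 50
    combine: str = "mean_pe"
    rounding: str = "half_up"
    v_min: int = 3
    loi_excluded: bool = True
    min_phase_fraction: float = 1.0
    seed: int = 0
    input_dir: str = ""
    phase_table: str = ""
    codes_csv: str = ""
    out_dir: str = ""

    def __post_init__(self) -> None:
        if self.cutoff_hz >= self.fs / 2:
            raise ValueError("cutoff must be below Nyquist")
        # delegate the remaining validation to the parameter owners
        PEParams(m=self.m, lag=self.lag, max_scale=self.max_scale, combine=self.combine)
        if self.rounding not in ("half_up", "floor", "ceil"):
            raise ValueError(f"unknown rounding {self.rounding!r}")
        if self.v_min < 1:
            raise ValueError("v_min must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @property
    def pe_params(self) -> PEParams:
        return PEParams(
            m=self.m, lag=self.lag, max_scale=self.max_scale, combine=self.combine
        )

    def fingerprint(self) -> dict:
        return {
            "m": self.m,
            "lag": self.lag,
            "max_scale": self.max_scale,
            "combine": self.combine,
            "rounding": self.rounding,
            "cutoff_hz": self.cutoff_hz,
            "filter_order": self.filter_order,
            "zero_phase": self.zero_phase,
        }


def _motor_rows_for_recording(
    rec: pp.AccelRecording,
    cfg: RunConfig,
    bands: tuple[BandSpec, ...],
) -> tuple[list[dict], list[dict]]:
    """Measure + per-scale PE rows for one recording."""
    filtered = pp.lowpass_filter(
        rec, cutoff=cfg.cutoff_hz, order=cfg.filter_order, zero_phase=cfg.zero_phase
    )
    mag = pp.acceleration_magnitude(filtered)
    phases = pp.segment_phases(mag, filtered, min_fraction=cfg.min_phase_fraction)
    fp = cfg.fingerprint()
    measure_rows: list[dict] = []
    pe_rows: list[dict] = []
    for ph in phases:
        key = {
            "participant": ph.participant,
            "group": ph.group,
            "sensor": ph.sensor_location,
            "phase": ph.phase,
        }
        mean_acc, n_excl = pp.trimmed_mean_acceleration(ph)
        row = {**key, "mean_acc": mean_acc, "n_excluded": n_excl, "n_samples": ph.n}
        if not ph.complete:
            logger.warning(
                "%s/%s/%s incomplete (%d samples); entropy skipped",
                ph.participant,
                ph.sensor_location,
                ph.phase,
                ph.n,
            )
            measure_rows.append({**row, **fp})
            continue
        curve = improved_mpe(ph.values, cfg.pe_params, meta=key)
        for s, pe, n_eff in zip(curve.scale, curve.pe, curve.n_eff):
            pe_rows.append(
                {**key, "scale": int(s), "pe": float(pe), "n_eff": int(n_eff), **fp}
            )
        row["ci_overall"] = complexity_index(curve, 1, cfg.max_scale).value
        for band in bands:
            lo, hi = band_scale_range(band, cfg.fs, cfg.max_scale, cfg.rounding)
            ci = complexity_index(curve, lo, hi, band=band.name)
            row[f"ci_{band.name}"] = ci.value
            row[f"scales_{band.name}"] = f"{lo}-{hi}"
        measure_rows.append({**row, **fp})
    return measure_rows, pe_rows


def run_motor_pipeline(
    recordings: list[pp.AccelRecording],
    cfg: RunConfig | None = None,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full motor analysis on in-memory recordings.

    Returns ``(measures, pe_curves)``: one row per participant/sensor/phase
    with trimmed mean and CIs, and the tidy per-scale PE table. Per-recording
    failures are isolated: the run continues and failures are summarized.
    """
    cfg = cfg or RunConfig()
    measure_rows: list[dict] = []
    pe_rows: list[dict] = []
    failures: list[str] = []
    for rec in recordings:
        try:
            m_rows, p_rows = _motor_rows_for_recording(rec, cfg, bands)
        except Exception as exc:  # noqa: BLE001 - isolate per-file failures
            failures.append(f"{rec.participant}/{rec.sensor_location}: {exc}")
            continue
        measure_rows.extend(m_rows)
        pe_rows.extend(p_rows)
    if failures:
        logger.warning("%d recording(s) failed: %s", len(failures), "; ".join(failures))
    measures = pd.DataFrame(measure_rows)
    pe_curves = pd.DataFrame(pe_rows)
    measures.attrs["failures"] = failures
    return measures, pe_curves


def load_recordings(
    input_dir: str | Path,
    phase_table: str | Path,
    fs: float = 100.0,
) -> list[pp.AccelRecording]:
    """Read every ``*.csv`` recording in a directory (sidecar phase table).

    File stems follow ``<participant>__<sensor>.csv``; missing or unreadable
    files are logged and skipped (the remaining sensors are kept).
    """
    input_dir = Path(input_dir)
    recs: list[pp.AccelRecording] = []
    paths = sorted(input_dir.glob("*.csv"))
    for path in paths:
        stem_parts = path.stem.split("__")
        participant = stem_parts[0] if len(stem_parts) > 1 else ""
        try:
            recs.append(
                pp.read_recording(
                    path, fs=fs, phase_table=phase_table, participant=participant
                )
            )
        except Exception as exc:  # noqa: BLE001
            logger.warning("skipping %s: %s", path.name, exc)
    return recs


def read_behaviour_codes(path: str | Path) -> list[crqa.BehaviourSequence]:
    """Read a behaviour-codes CSV (participant, phase, t_s, state).

    One sequence per (participant, phase), rows ordered by ``t_s``. Group
    labels are carried through when a ``group`` column is present.
    """
    df = pd.read_csv(path)
    required = {"participant", "phase", "t_s", "state"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"codes CSV missing columns {sorted(missing)}")
    sequences = []
    for (pid, phase), grp in df.groupby(["participant", "phase"], sort=True):
        grp = grp.sort_values("t_s")
        group = str(grp["group"].iloc[0]) if "group" in grp.columns else ""
        sequences.append(
            crqa.BehaviourSequence(
                states=grp["state"].to_numpy(dtype=object),
                phase=str(phase),
                participant=str(pid),
                group=group,
            )
        )
    return sequences


def run_behaviour_pipeline(
    sequences: list[crqa.BehaviourSequence],
    cfg: RunConfig | None = None,
    expected_length: int = crqa.SEQUENCE_LENGTH,
    length_tolerance: int = 0,
) -> pd.DataFrame:
    """Chromatic RQA per sequence: RR, LAM, TT, ENTb + total ER occupancy.

    Sequences whose length differs from ``expected_length`` by more than
    ``length_tolerance`` are excluded with a logged reason.
    """
    cfg = cfg or RunConfig()
    rows: list[dict] = []
    for seq in sequences:
        if abs(seq.T - expected_length) > length_tolerance:
            logger.warning(
                "excluding %s/%s: length %d != %d",
                seq.participant,
                seq.phase,
                seq.T,
                expected_length,
            )
            continue
        meas = crqa.rqa_measures(
            seq, v_min=cfg.v_min, loi_excluded=cfg.loi_excluded
        )
        er_occupancy = float(
            np.mean([s in crqa.ER_STATES for s in seq.states])
        )
        rows.append(
            {
                "participant": seq.participant,
                "group": seq.group,
                "phase": seq.phase,
                "rr": meas.rr,
                "lam": meas.lam,
                "tt": meas.tt,
                "entb": meas.entb,
                "er_occupancy": er_occupancy,
                "v_min": cfg.v_min,
                "loi_excluded": cfg.loi_excluded,
            }
        )
    return pd.DataFrame(rows)
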