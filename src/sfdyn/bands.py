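"""Complexity index and frequency-band <-> scale-factor mapping.

The complexity index (CI) is the sum of normalized permutation entropy
across a range of scale factors — the area under the multiscale entropy
curve. Scale factor ``s`` at sampling rate ``fs`` probes activity at the
equivalent frequency ``fs / s`` (scale 50 at 100 Hz -> 2 Hz), so a named
frequency band maps onto an inclusive scale-factor range and a band CI sums
only those scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mpe import MSECurve

__all__ = [
    "BandSpec",
    "ComplexityIndex",
    "DEFAULT_BANDS",
    "scale_for_frequency",
    "frequency_for_scale",
    "band_scale_range",
    "complexity_index",
    "band_table",
    "profile_edge_scales",
]


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with its edge frequencies in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ValueError(
                f"band {self.name!r}: need 0 < f_low < f_high, "
                f"got ({self.f_low}, {self.f_high})"
            )


#: EEG-style band edges, highest to lowest frequency.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("gamma", 30.0, 45.0),
    BandSpec("beta", 14.0, 30.0),
    BandSpec("alpha", 8.0, 13.5),
    BandSpec("theta", 4.5, 7.5),
    BandSpec("delta", 0.5, 4.0),
)


@dataclass
class ComplexityIndex:
    """Sum of normalized PE over an inclusive scale range."""

    value: float
    scales_used: tuple[int, int]
    band: str = "overall"
    meta: dict = field(default_factory=dict)

    @property
    def n_scales(self) -> int:
        return self.scales_used[1] - self.scales_used[0] + 1


def scale_for_frequency(
    f: float,
    fs: float = 100.0,
    max_scale: int = 50,
    rounding: str = "half_up",
) -> int:
    """Scale factor probing frequency ``f`` at sampling rate ``fs``.

    The mapping is ``fs / f`` rounded to an integer and clamped to
    ``[1, max_scale]``. ``rounding`` is one of ``half_up`` (default),
    ``floor``, ``ceil``; the choice moves band edges by at most one scale
    and is echoed into output metadata.
    """
    if f <= 0:
        raise ValueError(f"frequency must be positive, got {f}")
    raw = fs / f
    if rounding == "half_up":
        s = int(np.floor(raw + 0.5))
    elif rounding == "floor":
        s = int(np.floor(raw))
    elif rounding == "ceil":
        s = int(np.ceil(raw))
    else:
        raise ValueError(f"unknown rounding rule {rounding!r}")
    return max(1, min(s, max_scale))


def frequency_for_scale(scale: int, fs: float = 100.0) -> float:
    """Equivalent analysis frequency of a scale factor: ``fs / scale``.

    Scale 50 at 100 Hz probes 2 Hz activity (0.5 s between coarse-grained
    samples).
    """
    if scale < 1:
        raise ValueError(f"scale must be >= 1, got {scale}")
    return fs / scale


def band_scale_range(
    band: BandSpec,
    fs: float = 100.0,
    max_scale: int = 50,
    rounding: str = "half_up",
) -> tuple[int, int]:
    """Inclusive scale-factor range covered by a band.

    High frequency -> small scale, so ``scale_low`` comes from ``f_high``
    and ``scale_high`` from ``f_low`` (clamped at ``max_scale``; e.g. a
    0.5 Hz edge would need scale 200, unreachable with max_scale 50).
    """
    lo = scale_for_frequency(band.f_high, fs, max_scale, rounding)
    hi = scale_for_frequency(band.f_low, fs, max_scale, rounding)
    if lo > hi:
        raise ValueError(
            f"band {band.name!r} maps to an empty scale range ({lo} > {hi}) "
            f"at fs={fs}, max_scale={max_scale}"
        )
    return lo, hi


def profile_edge_scales(
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    fs: float = 100.0,
    max_scale: int = 50,
    rounding: str = "half_up",
) -> list[int]:
    """The distinct band-boundary scale factors for curve-profile analysis.

    Treating the bands as a contiguous spectrum, the boundaries are each
    band's upper-edge frequency plus the lowest band's lower edge — six
    frequencies for five bands — each mapped through
    :func:`scale_for_frequency`. With the defaults this yields
    ``[2, 3, 7, 13, 22, 50]``.
    """
    ordered = sorted(bands, key=lambda b: b.f_high, reverse=True)
    freqs = [b.f_high for b in ordered] + [ordered[-1].f_low]
    scales = {scale_for_frequency(f, fs, max_scale, rounding) for f in freqs}
    return sorted(scales)


def complexity_index(
    curve: MSECurve,
    scale_low: int = 1,
    scale_high: int = 50,
    band: str = "overall",
) -> ComplexityIndex:
    """Sum PE over the inclusive scale range ``[scale_low, scale_high]``."""
    wanted = np.arange(scale_low, scale_high + 1)
    present = np.isin(wanted, curve.scale)
    if not present.all():
        raise ValueError(
            f"curve is missing scales {wanted[~present].tolist()} "
            f"requested for band {band!r}"
        )
    mask = (curve.scale >= scale_low) & (curve.scale <= scale_high)
    return ComplexityIndex(
        value=float(curve.pe[mask].sum()),
        scales_used=(scale_low, scale_high),
        band=band,
        meta=dict(curve.meta),
    )


def band_table(
    curves: list[MSECurve],
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    fs: float = 100.0,
    max_scale: int = 50,
    rounding: str = "half_up",
) -> pd.DataFrame:
    """Tidy table of band CIs: one row per (curve meta, band)."""
    rows = []
    for curve in curves:
        for band in bands:
            lo, hi = band_scale_range(band, fs, max_scale, rounding)
            ci = complexity_index(curve, lo, hi, band=band.name)
            rows.append(
                {
                    **curve.meta,
                    "band": band.name,
                    "scale_low": lo,
                    "scale_high": hi,
                    "ci": ci.value,
                    "rounding": rounding,
                }
            )
    return pd.DataFrame(rows)
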