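"""Chromatic auto-recurrence quantification of categorical behaviour series.

A behaviour sequence is a 1 Hz categorical series over five emotional
self-regulation (ER) states plus ``none``. Recurrence is exact state
identity restricted to a target subset of states (the chromatic
restriction: ``none`` never recurs). From the T x T recurrence plot we
quantify:

- RR: percentage of possible points that are recurrent,
- LAM: percentage of recurrent points on vertical lines of length >= v_min,
- TT: mean length of those qualifying vertical lines (seconds at 1 Hz),
- ENTb: Shannon entropy (bits) of the size distribution of the rectangular
  block structures formed by pairs of same-state bouts.

The line of identity (LOI, the main diagonal) is excluded from RR/LAM/TT
counts by default, the usual auto-RQA convention. Blocks keep their full
a x b areas by default (``loi_in_blocks=True``) so that the block-area sum
equals the LOI-inclusive recurrent point count and equal-length bouts give
exactly one block size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ER_STATES",
    "NONE_STATE",
    "ALPHABET",
    "BehaviourSequence",
    "RecurrencePlot",
    "RQAMeasures",
    "build_recurrence_plot",
    "recurrence_rate",
    "vertical_lines",
    "laminarity",
    "trapping_time",
    "block_entropy",
    "rqa_measures",
]

#: The five emotional self-regulation behaviour states.
ER_STATES: tuple[str, ...] = (
    "oral_tactile",
    "object_distraction",
    "social_interactive",
    "motor_stimulatory",
    "distancing",
)
NONE_STATE: str = "none"
ALPHABET: tuple[str, ...] = ER_STATES + (NONE_STATE,)

#: Nominal length of one coded still-face phase (120 s at 1 Hz).
SEQUENCE_LENGTH: int = 120


@dataclass
class BehaviourSequence:
    """A categorical 1 Hz behaviour series for one still-face phase."""

    states: np.ndarray
    phase: str = "SF1"
    participant: str = ""
    group: str = ""
    alphabet: tuple[str, ...] = ALPHABET

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=object)
        unknown = sorted(set(self.states) - set(self.alphabet))
        if unknown:
            raise ValueError(
                f"unknown state label(s) {unknown}; alphabet is {self.alphabet}"
            )

    @property
    def T(self) -> int:
        return len(self.states)


@dataclass
class RecurrencePlot:
    """Boolean recurrence matrix plus the sequence it came from."""

    R: np.ndarray
    states: np.ndarray
    target_states: frozenset[str]
    loi_excluded: bool

    @property
    def T(self) -> int:
        return self.R.shape[0]

    @property
    def n_recurrent(self) -> int:
        return int(self.R.sum())


@dataclass
class RQAMeasures:
    """RR/LAM/TT/ENTb bundle for one sequence. Undefined values are NaN."""

    rr: float
    lam: float
    tt: float
    entb: float
    v_min: int = 3
    loi_excluded: bool = True
    meta: dict = field(default_factory=dict)


def build_recurrence_plot(
    seq: BehaviourSequence | np.ndarray,
    target_states: tuple[str, ...] | frozenset[str] = ER_STATES,
    loi_excluded: bool = True,
) -> RecurrencePlot:
    """Recurrence plot: R[i, j] iff states match and belong to the targets.

    ``none`` (or any non-target state) never recurs. With ``loi_excluded``
    the main diagonal is removed.
    """
    if not isinstance(seq, BehaviourSequence):
        seq = BehaviourSequence(states=np.asarray(seq, dtype=object))
    targets = frozenset(target_states)
    unknown = targets - set(seq.alphabet)
    if unknown:
        raise ValueError(f"target states {sorted(unknown)} not in alphabet")
    s = seq.states
    in_target = np.array([x in targets for x in s], dtype=bool)
    same = s[:, None] == s[None, :]
    R = same & in_target[:, None] & in_target[None, :]
    if loi_excluded:
        np.fill_diagonal(R, False)
    return RecurrencePlot(
        R=R, states=s, target_states=targets, loi_excluded=loi_excluded
    )


def recurrence_rate(rp: RecurrencePlot) -> float:
    """Percentage of possible plot points that are recurrent.

    The denominator is ``T^2 - T`` when the LOI is excluded, ``T^2``
    otherwise.
    """
    T = rp.T
    denom = T * T - T if rp.loi_excluded else T * T
    if denom <= 0:
        raise ValueError(f"recurrence rate undefined for T={T} with LOI excluded")
    return 100.0 * rp.n_recurrent / denom


def vertical_lines(rp: RecurrencePlot) -> list[int]:
    """Lengths of all maximal vertical runs of recurrent points.

    LOI gaps break runs when the LOI is excluded; runs truncated at the
    plot border count at their observed length.
    """
    T = rp.T
    # pad each column with False above and below; run boundaries are +1/-1
    padded = np.zeros((T + 2, T), dtype=np.int8)
    padded[1:-1, :] = rp.R
    d = np.diff(padded, axis=0)
    starts = np.argwhere(d == 1)
    ends = np.argwhere(d == -1)
    # argwhere returns row-major order, so starts/ends pair up per column
    order_s = np.lexsort((starts[:, 0], starts[:, 1]))
    order_e = np.lexsort((ends[:, 0], ends[:, 1]))
    lengths = ends[order_e, 0] - starts[order_s, 0]
    return lengths.tolist()


def laminarity(
    lines: list[int], total_recurrent: int, v_min: int = 3
) -> float:
    """Percentage of recurrent points on vertical lines of length >= v_min.

    Defined as 0 when there are no recurrent points.
    """
    if total_recurrent < 0:
        raise ValueError("total_recurrent must be nonnegative")
    if total_recurrent == 0:
        return 0.0
    laminar = sum(l for l in lines if l >= v_min)
    return 100.0 * laminar / total_recurrent


def trapping_time(lines: list[int], v_min: int = 3) -> float:
    """Mean length of vertical lines >= v_min, in seconds at 1 Hz.

    Returns NaN (missing, not zero) when no line qualifies, so downstream
    averaging is not biased.
    """
    qualifying = [l for l in lines if l >= v_min]
    if not qualifying:
        return math.nan
    return float(np.mean(qualifying))


def _bouts(states: np.ndarray, targets: frozenset[str]) -> list[tuple[str, int]]:
    """Maximal same-state runs restricted to target states: (state, length)."""
    bouts: list[tuple[str, int]] = []
    prev = None
    run = 0
    for x in states:
        if x == prev:
            run += 1
        else:
            if prev is not None and prev in targets:
                bouts.append((prev, run))
            prev, run = x, 1
    if prev is not None and prev in targets:
        bouts.append((prev, run))
    return bouts


def block_areas(rp: RecurrencePlot, loi_in_blocks: bool = True) -> list[int]:
    """Areas of the rectangular block structures in the plot.

    Each ordered pair of same-state target bouts of lengths ``a`` and ``b``
    contributes an ``a x b`` block (so symmetric partners are both counted
    and the areas sum to the recurrent point count). With
    ``loi_in_blocks=False`` the diagonal self-pair blocks lose their LOI
    points (area ``a^2 - a``); zero-area blocks are dropped.
    """
    bouts = _bouts(rp.states, rp.target_states)
    areas: list[int] = []
    for i, (si, a) in enumerate(bouts):
        for j, (sj, b) in enumerate(bouts):
            if si != sj:
                continue
            area = a * b
            if i == j and not loi_in_blocks and rp.loi_excluded:
                area -= a
            if area > 0:
                areas.append(area)
    return areas


def block_entropy(rp: RecurrencePlot, loi_in_blocks: bool = True) -> float:
    """Shannon entropy (bits) of the block-size distribution.

    One integer bin per distinct block area. NaN (missing) when the plot
    has no blocks.
    """
    areas = block_areas(rp, loi_in_blocks=loi_in_blocks)
    if not areas:
        return math.nan
    _, counts = np.unique(areas, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum() + 0.0)


def rqa_measures(
    seq: BehaviourSequence | np.ndarray,
    target_states: tuple[str, ...] | frozenset[str] = ER_STATES,
    v_min: int = 3,
    loi_excluded: bool = True,
    loi_in_blocks: bool = True,
) -> RQAMeasures:
    """All four chromatic-RQA measures for one behaviour sequence."""
    rp = build_recurrence_plot(seq, target_states, loi_excluded)
    lines = vertical_lines(rp)
    total = rp.n_recurrent
    meta = {}
    if isinstance(seq, BehaviourSequence):
        meta = {
            "participant": seq.participant,
            "group": seq.group,
            "phase": seq.phase,
        }
    return RQAMeasures(
        rr=recurrence_rate(rp),
        lam=laminarity(lines, total, v_min),
        tt=trapping_time(lines, v_min),
        entb=block_entropy(rp, loi_in_blocks=loi_in_blocks),
        v_min=v_min,
        loi_excluded=loi_excluded,
        meta=meta,
    )
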