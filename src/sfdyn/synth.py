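"""Synthetic cohort generation for both analysis arms.

Stands in for restricted-access cohort data: tri-axial acceleration phases
built from band-limited Gaussian noise with controllable per-band /
per-phase / per-group amplitudes, and 1 Hz categorical behaviour sequences
with controllable state occupancy and bout-length distributions.

This is a statistical stand-in, not a biomechanical simulation: signals
reproduce the spectral structure the analysis is sensitive to, nothing
more. Everything is deterministic given (scenario, seed); cohort members
get independent streams spawned from the scenario seed keyed by
(participant, sensor, phase) indices, so adding participants never
perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal
from scipy.special import ndtri

from .bands import DEFAULT_BANDS, BandSpec
from .preprocess import (
    PHASES,
    SENSOR_LOCATIONS,
    AccelRecording,
)
from .rqa import ALPHABET, ER_STATES, NONE_STATE, BehaviourSequence

__all__ = [
    "SignalScenario",
    "BehaviourScenario",
    "gen_accel_phase",
    "gen_cohort",
    "gen_behaviour_sequence",
]


@dataclass(frozen=True)
class SignalScenario:
    """Parameters for band-limited synthetic acceleration.

    ``band_amplitudes`` maps band name -> noise amplitude (m/s² SD before
    modulation); ``phase_effects`` / ``group_effects`` are multiplicative
    modulations per band (group effects optionally nested per sensor:
    ``{group: {sensor: {band: mult}}}`` or ``{group: {band: mult}}``).
    """

    fs: float = 100.0
    duration_s: float = 120.0
    band_amplitudes: dict = field(
        default_factory=lambda: {b.name: 1.0 for b in DEFAULT_BANDS}
    )
    phase_effects: dict = field(default_factory=dict)
    group_effects: dict = field(default_factory=dict)
    measurement_noise_sd: float = 0.05
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    filter_order: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.band_amplitudes.values()):
            raise ValueError("band amplitudes must be nonnegative")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s * fs must be integral")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass(frozen=True)
class BehaviourScenario:
    """Parameters for synthetic 1 Hz behaviour sequences.

    ``state_probs`` is a categorical distribution over the six-state
    alphabet; ``mean_bout_s`` is the expected bout duration, either a
    scalar or a per-state mapping; ``bout_dist`` is one of ``fixed``,
    ``geometric``, ``lognormal`` (sigma 0.5).
    """

    T: int = 120
    state_probs: dict = field(
        default_factory=lambda: {
            **{s: 0.1 for s in ER_STATES},
            NONE_STATE: 0.5,
        }
    )
    mean_bout_s: float | dict = 4.0
    bout_dist: str = "geometric"
    lognormal_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.state_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state probabilities must sum to 1, got {total}")
        unknown = sorted(set(self.state_probs) - set(ALPHABET))
        if unknown:
            raise ValueError(f"unknown states in state_probs: {unknown}")
        means = (
            self.mean_bout_s.values()
            if isinstance(self.mean_bout_s, dict)
            else [self.mean_bout_s]
        )
        if any(m < 1 for m in means):
            raise ValueError("mean_bout_s must be >= 1")
        if self.bout_dist not in ("fixed", "geometric", "lognormal"):
            raise ValueError(f"unknown bout_dist {self.bout_dist!r}")

    def mean_bout_for(self, state: str) -> float:
        if isinstance(self.mean_bout_s, dict):
            return float(self.mean_bout_s[state])
        return float(self.mean_bout_s)


def _effect(effects: dict, *keys: str) -> float:
    """Walk a (possibly nested) effect map; missing keys mean 1.0."""
    node = effects
    for key in keys:
        if not isinstance(node, dict):
            break
        if key not in node:
            # allow flat maps that skip intermediate levels (e.g. no sensor)
            continue
        node = node[key]
    return float(node) if isinstance(node, (int, float)) else 1.0


def _band_noise(
    rng: np.random.Generator,
    n: int,
    band: BandSpec,
    fs: float,
    order: int,
) -> np.ndarray:
    """Unit-variance white noise shaped into the band's frequency range."""
    white = rng.standard_normal(n)
    high = min(band.f_high, 0.999 * fs / 2)
    sos = signal.butter(order, [band.f_low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, white)


def _phase_rng(seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def gen_accel_phase(
    scn: SignalScenario,
    group: str = "term",
    phase: str = "SF1",
    sensor: str = "torso",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One phase of tri-axial acceleration, shape (n_samples, 3).

    Each axis is an independent sum over bands of band-limited Gaussian
    noise scaled by ``amplitude * phase_effect * group_effect``, plus white
    measurement noise.
    """
    if rng is None:
        rng = _phase_rng(
            scn.seed, 0, PHASES.index(phase), SENSOR_LOCATIONS.index(sensor)
        )
    n = scn.n_samples
    xyz = np.zeros((n, 3))
    for band in scn.bands:
        amp = scn.band_amplitudes.get(band.name, 0.0)
        amp *= _effect(scn.phase_effects, phase, band.name)
        amp *= _effect(scn.group_effects, group, sensor, band.name)
        if amp == 0.0:
            # keep the stream position independent of amplitude values
            rng.standard_normal(3 * n)
            continue
        for ax in range(3):
            xyz[:, ax] += amp * _band_noise(rng, n, band, scn.fs, scn.filter_order)
    if scn.measurement_noise_sd > 0:
        xyz += scn.measurement_noise_sd * rng.standard_normal((n, 3))
    return xyz


def gen_cohort(
    n_term: int,
    n_preterm: int,
    scn: SignalScenario,
    sensors: tuple[str, ...] = SENSOR_LOCATIONS,
) -> list[AccelRecording]:
    """Full A-B-A-B-A recordings for a two-group cohort.

    One recording per participant per sensor, phases contiguous, each of
    ``scn.duration_s`` seconds. Participant ids are ``term_01 ...`` /
    ``preterm_01 ...``; streams are deterministic per
    (participant index, sensor, phase, seed).
    """
    if n_term < 1 or n_preterm < 1:
        raise ValueError("need at least one participant per group")
    n = scn.n_samples
    recordings: list[AccelRecording] = []
    roster = [("term", i) for i in range(n_term)] + [
        ("preterm", i) for i in range(n_preterm)
    ]
    for group, idx in roster:
        pid = f"{group}_{idx + 1:02d}"
        pkey = (0 if group == "term" else 1, idx)
        for s_i, sensor in enumerate(sensors):
            chunks = []
            marks: dict[str, tuple[int, int]] = {}
            for p_i, phase in enumerate(PHASES):
                rng = _phase_rng(scn.seed, *pkey, s_i, p_i)
                chunks.append(gen_accel_phase(scn, group, phase, sensor, rng=rng))
                marks[phase] = (p_i * n, (p_i + 1) * n)
            xyz = np.concatenate(chunks, axis=0)
            t = np.arange(len(xyz)) / scn.fs
            recordings.append(
                AccelRecording(
                    sensor_location=sensor,
                    fs=scn.fs,
                    t=t,
                    xyz=xyz,
                    phase_marks=marks,
                    participant=pid,
                    group=group,
                )
            )
    return recordings


def gen_behaviour_sequence(
    scn: BehaviourScenario,
    phase: str = "SF1",
    participant: str = "",
    group: str = "",
    rng: np.random.Generator | None = None,
) -> BehaviourSequence:
    """Alternating-bout categorical sequence of exactly T samples.

    Repeatedly draw a state from ``state_probs`` and a bout length from
    ``bout_dist`` with that state's mean, append, truncate the final bout
    at T. Consecutive draws of the same ER state are separated by a one-
    second ``none`` gap so realized bout lengths track the drawn lengths
    (coded behaviour always has a visible transition between bouts).
    """
    if rng is None:
        rng = np.random.default_rng(scn.seed)
    states = list(scn.state_probs.keys())
    cum = np.cumsum([scn.state_probs[s] for s in states])
    out: list[str] = []
    while len(out) < scn.T:
        # inverse-CDF sampling throughout so scenarios sharing a seed are
        # coupled by common random numbers (bout lengths monotone in mean)
        state = states[int(np.searchsorted(cum, rng.random(), side="right"))]
        if out and state != NONE_STATE and out[-1] == state:
            out.append(NONE_STATE)
        mean = scn.mean_bout_for(state)
        u = rng.random()
        if scn.bout_dist == "fixed":
            length = int(round(mean))
        elif scn.bout_dist == "geometric":
            p = 1.0 / mean
            length = 1 + int(np.floor(np.log1p(-u) / np.log1p(-p))) if p < 1 else 1
        else:  # lognormal with given sigma, mean matched
            sigma = scn.lognormal_sigma
            mu = np.log(mean) - sigma**2 / 2
            length = max(1, int(round(np.exp(mu + sigma * ndtri(u)))))
        out.extend([state] * length)
    return BehaviourSequence(
        states=np.array(out[: scn.T], dtype=object),
        phase=phase,
        participant=participant,
        group=group,
    )


def scenario_to_dict(scn: SignalScenario | BehaviourScenario) -> dict:
    """Serialize a scenario for config echoing (YAML/JSON friendly)."""
    d = asdict(scn)
    if "bands" in d:
        d["bands"] = [
            {"name": b.name, "f_low": b.f_low, "f_high": b.f_high} for b in scn.bands
        ]
    return d
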