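# sfdyn

Two-level dynamic analysis of infant movement and behaviour during the
still-face paradigm:

- **Motor arm** — tri-axial wearable accelerometry (100 Hz, five sensor
  locations) is low-pass filtered (20 Hz Butterworth, zero-phase), reduced
  to per-sample acceleration magnitude, segmented into the five 2-minute
  paradigm phases (Play, SF1, R1, SF2, R2; 12,000 samples each), and
  summarized by an outlier-trimmed mean, improved multiscale permutation
  entropy over scale factors 1–50 (m=4, lag=1), and complexity indices —
  overall and within EEG-style frequency bands (gamma 30–45, beta 14–30,
  alpha 8–13.5, theta 4.5–7.5, delta 0.5–4 Hz) mapped to scale-factor
  ranges via `scale = round(fs / f)`.
- **Behaviour arm** — 1 Hz categorical sequences (120 s) over five
  emotional self-regulation states plus `none` are analysed with chromatic
  auto-recurrence quantification: recurrence rate (RR), laminarity (LAM,
  minimum laminar length 3 s), trapping time (TT) and block entropy (ENTb).
- **Synthetic data** — deterministic generators for both input kinds
  (band-limited noise cohorts with per-band/phase/group effects;
  bout-structured behaviour sequences), so every stage is testable without
  the restricted cohort data. These are statistical stand-ins reproducing
  the spectral/bout structure the analysis is sensitive to, not
  biomechanical simulations.

The pipeline emits tidy CSV tables (participant × sensor × phase ×
measure) intended for external statistics packages; no model fitting is
performed here.

## CLI

```sh
sfdyn simulate accel --n-term 2 --n-preterm 2 --seed 1 --out raw/
sfdyn preprocess --input raw/ --phases raw/phases.csv --cutoff 20 --fs 100 --out seg/
sfdyn mpe --in seg/ --m 4 --lag 1 --scales 50 --out pe.csv
sfdyn ci --in pe.csv --fs 100 --out ci.csv

sfdyn simulate behaviour --n 10 --seed 1 --out codes.csv
sfdyn rqa --in codes.csv --vmin 3 --exclude-loi --out rqa.csv

sfdyn run-all --config config.yaml   # both arms from a YAML RunConfig
```

Recording files are CSV with columns `time_s, acc_x, acc_y, acc_z` (free
acceleration, m/s²), one per `<participant>__<sensor>.csv`; phase
annotations are a sidecar CSV `phase, start_s, duration_s`. Behaviour
codes are CSV rows `participant, phase, t_s, state`.

## Notable conventions

- Butterworth order (4) and zero-phase application are configurable
  defaults; ordinal-pattern analysis is phase-sensitive, so forward-
  backward filtering is the default.
- Ordinal-pattern ties break by temporal order (stable argsort).
- Improved-MPE combines per-offset coarse-grainings by averaging the
  entropy values (`combine="mean_pe"`); a pooled-histogram variant is
  available (`combine="pooled"`).
- Frequency→scale rounding is half-up by default (`floor`/`ceil`
  available); the delta band's 0.5 Hz edge clamps to scale 50.
- The recurrence line of identity is excluded from RR/LAM/TT by default;
  ENTb blocks are ordered same-state bout pairs with full a×b areas, so
  block areas sum to the LOI-inclusive recurrent point count and
  equal-length bouts give ENTb = 0 exactly.
- TT and ENTb are reported as missing (NaN), never zero, when undefined.
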