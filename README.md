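# nirsbp

Analysis pipeline for studying how transient systemic blood-pressure
changes confound brain near-infrared spectroscopy (NIRS) recordings,
together with a seeded synthetic-session generator for end-to-end
parameter-recovery testing.

The pipeline implements:

- **`nirsbp.mbll`** — modified Beer–Lambert law conversion between
  two-wavelength optical-density changes and ΔO₂Hb/ΔHHb concentrations
  (µM), with an age-dependent differential pathlength factor
  `DPF(age) = a + b·age^c`. Extinction and DPF coefficient tables ship as
  cited, user-replaceable CSV files under `src/nirsbp/data/`.
- **`nirsbp.signalproc`** — zero-phase Butterworth low-pass filtering
  (1 Hz NIRS / 10 Hz pressure), degree-5 polynomial detrending, epoching
  (−0.5…12 s NIRS, −0.5…10 s pressure, half-open windows), pre-stimulus
  baseline correction, ±3 SD outlier-epoch rejection and condition
  averaging.
- **`nirsbp.pressure`** — peak-picking beat segmentation of the
  continuous finger-pressure waveform into per-beat systolic/diastolic/
  mean arterial pressure (MAP via true waveform average or the
  DBP + PP/3 estimate), resampled to a uniform grid.
- **`nirsbp.analyze`** — response amplitude/latency metrics (signed
  extremum over pre-stimulus baseline), one-sample and two-sample
  t-tests, the three planned contrasts with Bonferroni-corrected
  critical alpha (0.05/3 → 0.017), and point-wise NIRS-vs-MAP coupling
  regressions.
- **`nirsbp.synthgen`** — seeded synthetic sessions: a jittered 2×2
  factorial schedule (stimulus duration 1500/3000 ms × arm-raise
  movement, 15 trials per cell), a pulsatile pressure waveform with
  gamma-shaped arm-raise transients, and raw optical densities built by
  pushing ground-truth chromophore traces (gamma event-related
  responses, pressure-coupled changes, drift, pulsation, noise) through
  the forward optical model.
- **`nirsbp.pipeline`** — configuration, CSV I/O and orchestration.

All I/O is plain text (CSV/JSON); a fixed seed yields byte-identical
output directories.

## CLI

```bash
# simulate a synthetic session into out/session/
nirsbp simulate --out out --seed 1

# analyse a session given its three CSV inputs
nirsbp analyze --nirs out/session/nirs_raw.csv \
               --bp out/session/pressure.csv \
               --schedule out/session/schedule.csv \
               --modes deep=deep,shallow=shallow \
               --age 25 --out results

# simulate + analyse + injected-vs-recovered comparison
nirsbp full --out results --seed 1

# quick-look trace plots
nirsbp report --results results
```

Input schemas: `nirs_raw.csv` (`time_s`, then `<label>_od_w1`,
`<label>_od_w2` per channel), `pressure.csv` (`time_s,pressure_mmHg`),
`schedule.csv` (`onset_s,duration_ms,movement`). Results land in
`tables/` (`metrics.csv`, `stats.csv`, `regressions.csv`,
`rejections.csv`), `traces/` (condition-averaged mean ± SD time
courses), `provenance.json` and, for simulated runs, `recovery.json`.

A YAML/JSON config file mirroring `RunConfig`/`SimulationConfig` field
names can override any simulation or analysis parameter
(`--config cfg.yaml`); every analysis default is the reference value.

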