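"""Seeded synthetic sessions with known ground truth.

Generates the three ingredients of a session: a jittered factorial trial
schedule (two stimulus durations x movement/no-movement), a pulsatile
finger-pressure waveform whose per-beat baselines are modulated by a
gamma-shaped arm-raise transient on movement trials, and raw
two-wavelength optical densities produced by pushing ground-truth
chromophore traces (event-related responses, pressure-coupled volume
changes, drift, cardiac pulsation, white noise) through the forward
optical model.

Every stochastic draw is controlled by ``SimulationConfig.seed``; a fixed
config yields byte-identical CSV exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import truncnorm

from nirsbp import mbll
from nirsbp.mbll import (
    ChromophoreRecording,
    OpticalChannel,
    RawOpticalRecording,
)
from nirsbp.pressure import PressureRecording

__all__ = [
    "TrialSchedule",
    "SimulationConfig",
    "GroundTruth",
    "SessionData",
    "gamma_pulse",
    "make_schedule",
    "simulate_pressure",
    "map_deviation",
    "simulate_nirs",
    "simulate_session",
]

#: minimum inter-trial interval so that -0.5..12 s epochs can never overlap
MIN_ITI_S = 13.0
#: post-onset recording padding after the last trial (covers the 12 s epoch)
SESSION_TAIL_S = 13.0
DURATIONS_MS = (1500, 3000)
UPSTROKE_S = 0.08  # systolic upstroke duration of the beat template
DECAY_TAU_FRACTION = 0.3  # exponential decay constant, fraction of the period


@dataclass
class TrialSchedule:
    """Trial onsets with the two crossed experimental factors."""

    onsets_s: np.ndarray
    duration_ms: np.ndarray  # stimulus persistency, 1500 or 3000
    movement: np.ndarray  # True = arm-raise trial
    cue_lead_s: float = 1.0

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.duration_ms = np.asarray(self.duration_ms, dtype=int)
        self.movement = np.asarray(self.movement, dtype=bool)
        if not (
            self.onsets_s.size == self.duration_ms.size == self.movement.size
        ):
            raise ValueError("schedule columns must have equal length")
        if self.onsets_s.size and np.any(np.diff(self.onsets_s) <= 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.onsets_s.size

    def condition_labels(self) -> np.ndarray:
        return np.array(
            [
                f"{d}ms_{'move' if m else 'nomove'}"
                for d, m in zip(self.duration_ms, self.movement)
            ]
        )

    def cell_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.condition_labels(), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a synthetic session.

    Amplitude/peak-time dictionaries are keyed by chromophore
    (``"o2hb"``/``"hhb"``) then stimulus duration in ms. Coupling gains
    are in uM per mmHg of MAP deviation from baseline. Defaults mimic the
    published group-mean response magnitudes.
    """

    seed: int = 0
    n_per_condition: int = 15
    iti_mean_s: float = 19.2
    iti_sd_s: float = 2.9
    cue_lead_s: float = 1.0
    # cardiovascular baseline and arm-raise transient
    heart_rate_bpm: float = 70.0
    sbp_baseline_mmHg: float = 120.0
    dbp_baseline_mmHg: float = 80.0
    bp_transient_sbp_amplitude_mmHg: float = 7.8
    bp_transient_sbp_peak_s: float = 5.8
    bp_transient_dbp_amplitude_mmHg: float = 5.6
    bp_transient_dbp_peak_s: float = 5.1
    bp_transient_shape_k: float = 6.0
    # event-related haemodynamic response (deep channel only)
    hrf_amplitude_uM: dict = field(
        default_factory=lambda: {
            "o2hb": {1500: 0.26, 3000: 0.38},
            "hhb": {1500: -0.09, 3000: -0.11},
        }
    )
    hrf_peak_s: dict = field(
        default_factory=lambda: {
            "o2hb": {1500: 8.6, 3000: 10.4},
            "hhb": {1500: 7.4, 3000: 8.8},
        }
    )
    hrf_shape_k: float = 16.0
    # pressure-coupled volume/flow changes, uM per mmHg MAP deviation
    coupling_gain_shallow_o2hb: float = 0.066
    coupling_gain_shallow_hhb: float = 0.013
    coupling_gain_deep_o2hb: float = 0.06
    coupling_gain_deep_hhb: float = -0.008
    # nuisance components of the chromophore traces
    drift_poly_coeffs: tuple = (0.0, 0.3, -0.2, 0.1, 0.05, -0.08)
    pulsation_amp_uM: float = 0.05
    noise_sd_uM: float = 0.1
    # subject / instrument
    age_years: float = 25.0
    fs_nirs_hz: float = 50.0
    fs_bp_hz: float = 100.0
    wavelengths_nm: tuple = mbll.DEFAULT_WAVELENGTHS_NM
    deep_separation_cm: float = mbll.DEEP_SEPARATION_CM
    shallow_separation_cm: float = mbll.SHALLOW_SEPARATION_CM

    def __post_init__(self) -> None:
        nonneg = {
            "n_per_condition": self.n_per_condition,
            "iti_sd_s": self.iti_sd_s,
            "heart_rate_bpm": self.heart_rate_bpm,
            "bp_transient_sbp_amplitude_mmHg": self.bp_transient_sbp_amplitude_mmHg,
            "bp_transient_dbp_amplitude_mmHg": self.bp_transient_dbp_amplitude_mmHg,
            "pulsation_amp_uM": self.pulsation_amp_uM,
            "noise_sd_uM": self.noise_sd_uM,
            "age_years": self.age_years,
            "fs_nirs_hz": self.fs_nirs_hz,
            "fs_bp_hz": self.fs_bp_hz,
        }
        for name, v in nonneg.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n_per_condition < 1:
            raise ValueError("n_per_condition must be >= 1")
        if self.fs_bp_hz < 25:
            raise ValueError("fs_bp_hz must be >= 25")

    @property
    def iti_floor_s(self) -> float:
        return self.iti_mean_s - 2.0 * self.iti_sd_s

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("hrf_amplitude_uM", "hrf_peak_s"):
            if key in d:
                d[key] = {
                    chrom: {int(k): float(v) for k, v in per.items()}
                    for chrom, per in d[key].items()
                }
        for key in ("drift_poly_coeffs", "wavelengths_nm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Injected parameters of a synthetic session, for recovery testing."""

    bp_sbp_amplitude_mmHg: float = 0.0
    bp_sbp_peak_s: float = 0.0
    bp_dbp_amplitude_mmHg: float = 0.0
    bp_dbp_peak_s: float = 0.0
    bp_map_amplitude_mmHg: float = 0.0
    bp_map_peak_s: float = 0.0
    trials: list = field(default_factory=list)
    hrf_amplitude_uM: dict = field(default_factory=dict)
    hrf_peak_s: dict = field(default_factory=dict)
    coupling_gains: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def gamma_pulse(
    t_s: np.ndarray, peak_s: float, amplitude: float, shape_k: float
) -> np.ndarray:
    """Gamma-shaped pulse with value ``amplitude`` exactly at ``peak_s``.

    ``shape_k`` is the gamma shape parameter (k > 1); larger k gives a
    narrower pulse relative to its peak time. Zero for t <= 0.
    """
    if shape_k <= 1:
        raise ValueError("shape_k must be > 1")
    if peak_s <= 0:
        raise ValueError("peak_s must be > 0")
    t = np.asarray(t_s, dtype=float)
    theta = peak_s / (shape_k - 1.0)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = amplitude * (tp / peak_s) ** (shape_k - 1.0) * np.exp(
        -(tp - peak_s) / theta
    )
    return out


def make_schedule(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> TrialSchedule:
    """Randomized factorial schedule with truncated-normal jittered ITIs.

    The four condition cells (1500/3000 ms x movement/no-movement) each
    appear ``n_per_condition`` times in a seeded random order. ITIs are
    drawn from a normal distribution truncated below at
    ``iti_mean_s - 2*iti_sd_s`` (and never below 13.0 s, so the
    -0.5..12 s analysis epochs cannot overlap).
    """
    if config.iti_floor_s < MIN_ITI_S:
        raise ValueError(
            f"ITI truncation floor {config.iti_floor_s:.2f} s is below "
            f"{MIN_ITI_S} s: epochs could overlap"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)

    cells = [
        (dur, mov) for dur in DURATIONS_MS for mov in (False, True)
    ] * config.n_per_condition
    order = rng.permutation(len(cells))
    durations = np.array([cells[i][0] for i in order])
    movement = np.array([cells[i][1] for i in order])

    n = len(cells)
    a = (config.iti_floor_s - config.iti_mean_s) / config.iti_sd_s
    itis = truncnorm.rvs(
        a,
        np.inf,
        loc=config.iti_mean_s,
        scale=config.iti_sd_s,
        size=n,
        random_state=rng,
    )
    itis = np.maximum(itis, MIN_ITI_S)
    onsets = np.cumsum(itis)
    return TrialSchedule(onsets, durations, movement, cue_lead_s=config.cue_lead_s)


def session_duration_s(schedule: TrialSchedule) -> float:
    return float(schedule.onsets_s[-1]) + SESSION_TAIL_S


def _bp_deviation(
    schedule: TrialSchedule,
    config: SimulationConfig,
    t_s: np.ndarray,
    which: str,
) -> np.ndarray:
    """Sum of injected gamma transients for SBP or DBP, on any time grid."""
    if which == "sbp":
        amp = config.bp_transient_sbp_amplitude_mmHg
        peak = config.bp_transient_sbp_peak_s
    else:
        amp = config.bp_transient_dbp_amplitude_mmHg
        peak = config.bp_transient_dbp_peak_s
    dev = np.zeros_like(t_s, dtype=float)
    if amp == 0:
        return dev
    for onset, mov in zip(schedule.onsets_s, schedule.movement):
        if mov:
            dev += gamma_pulse(t_s - onset, peak, amp, config.bp_transient_shape_k)
    return dev


def map_deviation(
    schedule: TrialSchedule, config: SimulationConfig, t_s: np.ndarray
) -> np.ndarray:
    """Injected MAP deviation from baseline: ``dbp + (sbp - dbp)/3`` mix."""
    sbp = _bp_deviation(schedule, config, t_s, "sbp")
    dbp = _bp_deviation(schedule, config, t_s, "dbp")
    return dbp + (sbp - dbp) / 3.0


def _map_transient_extremum(config: SimulationConfig) -> tuple[float, float]:
    """Peak amplitude and latency of the single-trial MAP transient."""
    t = np.linspace(0.0, 4.0 * config.bp_transient_sbp_peak_s + 1.0, 20001)
    sbp = gamma_pulse(
        t,
        config.bp_transient_sbp_peak_s,
        config.bp_transient_sbp_amplitude_mmHg,
        config.bp_transient_shape_k,
    )
    dbp = gamma_pulse(
        t,
        config.bp_transient_dbp_peak_s,
        config.bp_transient_dbp_amplitude_mmHg,
        config.bp_transient_shape_k,
    )
    mix = dbp + (sbp - dbp) / 3.0
    i = int(np.argmax(mix))
    return float(mix[i]), float(t[i])


def beat_template_shape(phase_s: np.ndarray, period_s: float) -> np.ndarray:
    """Normalized 0..1 beat shape: raised-cosine upstroke, exponential decay.

    The maximum (1.0) sits exactly at ``phase = UPSTROKE_S``; the minimum
    (0.0) at phase 0. The decay constant scales with the period so the
    shape is rate-invariant.
    """
    phase = np.asarray(phase_s, dtype=float)
    tau = DECAY_TAU_FRACTION * period_s
    up = phase < UPSTROKE_S
    out = np.empty_like(phase)
    out[up] = 0.5 * (1.0 - np.cos(np.pi * phase[up] / UPSTROKE_S))
    out[~up] = np.exp(-(phase[~up] - UPSTROKE_S) / tau)
    return out


def simulate_pressure(
    schedule: TrialSchedule, config: SimulationConfig
) -> tuple[PressureRecording, GroundTruth]:
    """Continuous pulsatile pressure with arm-raise transients injected.

    One beat template per cardiac period; the per-beat systolic/diastolic
    baselines are modulated (movement trials only) by gamma-shaped
    transients peaking ``bp_transient_*_peak_s`` after stimulus onset.
    """
    fs = config.fs_bp_hz
    duration = session_duration_s(schedule)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    period = 60.0 / config.heart_rate_bpm

    beat_idx = np.floor(t / period).astype(int)
    phase = t - beat_idx * period
    n_beats = int(beat_idx[-1]) + 1
    # baselines sampled where each extremum occurs: SBP at the systolic
    # peak (upstroke end), DBP at the beat start
    peak_times = np.arange(n_beats) * period + UPSTROKE_S
    start_times = np.arange(n_beats) * period
    sbp_k = config.sbp_baseline_mmHg + _bp_deviation(schedule, config, peak_times, "sbp")
    dbp_k = config.dbp_baseline_mmHg + _bp_deviation(schedule, config, start_times, "dbp")

    shape = beat_template_shape(phase, period)
    p = dbp_k[beat_idx] + (sbp_k[beat_idx] - dbp_k[beat_idx]) * shape
    rec = PressureRecording(time_s=t, pressure_mmHg=p, fs_hz=fs)

    map_amp, map_peak = _map_transient_extremum(config)
    gt = GroundTruth(
        bp_sbp_amplitude_mmHg=config.bp_transient_sbp_amplitude_mmHg,
        bp_sbp_peak_s=config.bp_transient_sbp_peak_s,
        bp_dbp_amplitude_mmHg=config.bp_transient_dbp_amplitude_mmHg,
        bp_dbp_peak_s=config.bp_transient_dbp_peak_s,
        bp_map_amplitude_mmHg=map_amp,
        bp_map_peak_s=map_peak,
        trials=[
            {
                "trial": i,
                "onset_s": float(o),
                "movement": bool(m),
                "sbp_amplitude_mmHg": (
                    config.bp_transient_sbp_amplitude_mmHg if m else 0.0
                ),
                "dbp_amplitude_mmHg": (
                    config.bp_transient_dbp_amplitude_mmHg if m else 0.0
                ),
            }
            for i, (o, m) in enumerate(zip(schedule.onsets_s, schedule.movement))
        ],
    )
    return rec, gt


def simulate_nirs(
    schedule: TrialSchedule,
    map_dev: np.ndarray,
    config: SimulationConfig,
    mode: str,
    rng: np.random.Generator | None = None,
) -> tuple[RawOpticalRecording, ChromophoreRecording]:
    """Raw two-wavelength optical densities for one channel.

    Ground-truth chromophore traces are built first — deep mode: a
    per-trial gamma response (O2Hb positive, HHb negative, peak time
    increasing with stimulus duration) plus ``coupling_gain_deep_* x
    map_dev``; shallow mode: coupling only — then a slow polynomial drift,
    cardiac pulsation and white noise are added, and the result is pushed
    through the forward optical model. Returns both the raw recording and
    the noiseless-component ground-truth chromophores (responses +
    coupling only).

    ``map_dev`` must be the continuous MAP-minus-baseline series sampled
    at ``fs_nirs_hz`` over the whole session.
    """
    if mode not in ("deep", "shallow"):
        raise ValueError(f"mode must be 'deep' or 'shallow', got {mode!r}")
    if rng is None:
        rng = np.random.default_rng([config.seed, 0 if mode == "deep" else 1])

    map_dev = np.asarray(map_dev, dtype=float)
    n = map_dev.size
    fs = config.fs_nirs_hz
    t = np.arange(n) / fs

    o2hb = np.zeros(n)
    hhb = np.zeros(n)
    if mode == "deep":
        for onset, dur in zip(schedule.onsets_s, schedule.duration_ms):
            rel = t - onset
            for chrom, target in (("o2hb", o2hb), ("hhb", hhb)):
                amp = config.hrf_amplitude_uM[chrom][int(dur)]
                if amp == 0:
                    continue
                target += gamma_pulse(
                    rel, config.hrf_peak_s[chrom][int(dur)], amp, config.hrf_shape_k
                )
        o2hb += config.coupling_gain_deep_o2hb * map_dev
        hhb += config.coupling_gain_deep_hhb * map_dev
        sep = config.deep_separation_cm
    else:
        o2hb += config.coupling_gain_shallow_o2hb * map_dev
        hhb += config.coupling_gain_shallow_hhb * map_dev
        sep = config.shallow_separation_cm

    truth = ChromophoreRecording(
        time_s=t.copy(), o2hb={mode: o2hb.copy()}, hhb={mode: hhb.copy()}, fs_hz=fs
    )

    # nuisance components
    ts = np.linspace(-1.0, 1.0, n)
    drift = np.polynomial.polynomial.polyval(ts, np.asarray(config.drift_poly_coeffs))
    pulsation = config.pulsation_amp_uM * np.sin(
        2.0 * np.pi * (config.heart_rate_bpm / 60.0) * t
    )
    o2hb = o2hb + drift + pulsation + rng.normal(0.0, config.noise_sd_uM, n)
    hhb = hhb + 0.5 * drift - 0.3 * pulsation + rng.normal(
        0.0, config.noise_sd_uM, n
    )

    conc = ChromophoreRecording(
        time_s=t, o2hb={mode: o2hb}, hhb={mode: hhb}, fs_hz=fs
    )
    template = RawOpticalRecording(
        time_s=t,
        channels=[OpticalChannel(mode, sep, np.zeros((n, 2)), mode=mode)],
        wavelengths_nm=tuple(config.wavelengths_nm),
        age_years=config.age_years,
        fs_hz=fs,
    )
    raw = mbll.conc_to_od(conc, template)
    return raw, truth


@dataclass
class SessionData:
    """A fully simulated session with its ground truth."""

    config: SimulationConfig
    schedule: TrialSchedule
    pressure: PressureRecording
    nirs: RawOpticalRecording
    ground_truth: GroundTruth
    truth_conc: dict[str, ChromophoreRecording] = field(default_factory=dict)


def simulate_session(config: SimulationConfig) -> SessionData:
    """Simulate schedule, pressure and a deep + shallow NIRS channel pair."""
    rng = np.random.default_rng(config.seed)
    schedule = make_schedule(config, rng)
    prec, gt = simulate_pressure(schedule, config)

    n_nirs = int(round(session_duration_s(schedule) * config.fs_nirs_hz))
    t_nirs = np.arange(n_nirs) / config.fs_nirs_hz
    mdev = map_deviation(schedule, config, t_nirs)

    raw_deep, truth_deep = simulate_nirs(schedule, mdev, config, "deep")
    raw_shallow, truth_shallow = simulate_nirs(schedule, mdev, config, "shallow")
    nirs = RawOpticalRecording(
        time_s=t_nirs,
        channels=raw_deep.channels + raw_shallow.channels,
        wavelengths_nm=tuple(config.wavelengths_nm),
        age_years=config.age_years,
        fs_hz=config.fs_nirs_hz,
    )
    gt.hrf_amplitude_uM = config.hrf_amplitude_uM
    gt.hrf_peak_s = config.hrf_peak_s
    gt.coupling_gains = {
        "shallow_o2hb": config.coupling_gain_shallow_o2hb,
        "shallow_hhb": config.coupling_gain_shallow_hhb,
        "deep_o2hb": config.coupling_gain_deep_o2hb,
        "deep_hhb": config.coupling_gain_deep_hhb,
    }
    return SessionData(
        config=config,
        schedule=schedule,
        pressure=prec,
        nirs=nirs,
        ground_truth=gt,
        truth_conc={"deep": truth_deep, "shallow": truth_shallow},
    )
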