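"""End-to-end orchestration, configuration and plain-text I/O.

A run proceeds: simulate (or load) a session -> MBLL conversion -> NIRS
preprocessing and epoching -> beat extraction and pressure epoching ->
response metrics -> planned comparisons, one-sample tests and coupling
regressions -> a results bundle written as CSV tables plus a JSON
provenance block. All defaults follow the reference analysis parameters
(1 Hz / 10 Hz low-pass cutoffs, degree-5 detrend, -0.5..12 s and
-0.5..10 s epoch windows, +-3 SD rejection, alpha 0.05 over three planned
contrasts).

Outputs contain no timestamps or absolute paths, so a fixed seed yields
byte-identical results directories.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from nirsbp import analyze as _an
from nirsbp import mbll, pressure as _pr, signalproc as _sp, synthgen as _sg

__all__ = [
    "AnalysisParams",
    "RunConfig",
    "ResultsBundle",
    "run",
    "read_session",
    "write_session",
    "write_bundle",
]

log = logging.getLogger(__name__)

FLOAT_FMT = "%.9g"
POLARITY = {"o2hb": "max", "hhb": "min", "sbp": "max", "dbp": "max", "map": "max"}


@dataclass
class AnalysisParams:
    """Analysis-stage parameters; defaults are the reference values."""

    nirs_lowpass_hz: float = 1.0
    bp_lowpass_hz: float = 10.0
    detrend_degree: int = 5
    nirs_window_s: tuple = _sp.NIRS_WINDOW_S
    bp_window_s: tuple = _sp.PRESSURE_WINDOW_S
    baseline_s: tuple = _sp.BASELINE_WINDOW_S
    reject_k: float = 3.0
    map_method: str = "waveform_mean"
    beat_refractory_s: float = 0.3
    beat_prominence_mmHg: float = 5.0
    beat_interp: str = "cubic"
    family_alpha: float = 0.05
    paired_tests: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisParams":
        d = dict(d)
        for key in ("nirs_window_s", "bp_window_s", "baseline_s"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class RunConfig:
    """Top-level run configuration (``simulate`` | ``analyze`` | ``full``)."""

    mode: str = "full"
    seed: int = 0
    simulation: _sg.SimulationConfig = field(default_factory=_sg.SimulationConfig)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    # analyze-mode inputs
    nirs_path: str | None = None
    bp_path: str | None = None
    schedule_path: str | None = None
    age_years: float = 25.0
    channel_modes: dict = field(default_factory=dict)  # label -> deep|shallow
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze", "full"):
            raise ValueError(f"unknown run mode {self.mode!r}")
        # the run-level seed governs every stochastic stage
        self.simulation.seed = self.seed

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d:
            d["simulation"] = _sg.SimulationConfig.from_dict(d["simulation"])
        if "analysis" in d:
            d["analysis"] = AnalysisParams.from_dict(d["analysis"])
        cfg = cls(**d)
        if "seed" in d:
            cfg.simulation.seed = int(d["seed"])
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    def echo(self) -> dict:
        """Config echo for provenance — path fields stripped."""
        d = asdict(self)
        for key in ("nirs_path", "bp_path", "schedule_path"):
            d.pop(key, None)
        return d


@dataclass
class ResultsBundle:
    """In-memory results of one run."""

    metrics: pd.DataFrame
    stats: pd.DataFrame
    regressions: pd.DataFrame
    rejections: pd.DataFrame
    traces: dict[str, pd.DataFrame]
    provenance: dict
    recovery: dict | None = None


# ---------------------------------------------------------------------------
# session CSV / JSON I/O


def write_session(session: _sg.SessionData, outdir: str | Path) -> None:
    """Write schedule.csv, pressure.csv, nirs_raw.csv and ground_truth.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    sched = pd.DataFrame(
        {
            "onset_s": session.schedule.onsets_s,
            "duration_ms": session.schedule.duration_ms,
            "movement": session.schedule.movement.astype(int),
        }
    )
    sched.to_csv(out / "schedule.csv", index=False, float_format=FLOAT_FMT)

    bp = pd.DataFrame(
        {
            "time_s": session.pressure.time_s,
            "pressure_mmHg": session.pressure.pressure_mmHg,
        }
    )
    bp.to_csv(out / "pressure.csv", index=False, float_format=FLOAT_FMT)

    cols = {"time_s": session.nirs.time_s}
    for ch in session.nirs.channels:
        cols[f"{ch.label}_od_w1"] = ch.od[:, 0]
        cols[f"{ch.label}_od_w2"] = ch.od[:, 1]
    pd.DataFrame(cols).to_csv(out / "nirs_raw.csv", index=False, float_format=FLOAT_FMT)

    gt = session.ground_truth.to_dict()
    gt["channel_modes"] = {ch.label: ch.mode for ch in session.nirs.channels}
    (out / "ground_truth.json").write_text(
        json.dumps(gt, indent=2, sort_keys=True) + "\n"
    )


def _check_uniform(time_s: np.ndarray, name: str, tol: float = 1e-6) -> float:
    dt = np.diff(time_s)
    if dt.size == 0:
        raise ValueError(f"{name}: empty time axis")
    if np.any(np.abs(dt - dt[0]) > tol):
        bad = int(np.argmax(np.abs(dt - dt[0]) > tol)) + 1
        raise ValueError(f"{name}: non-uniform timestamps near row {bad + 1}")
    return 1.0 / float(np.mean(dt))


def _check_nan(df: pd.DataFrame, name: str) -> None:
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise ValueError(f"{name}: missing/NaN value at data row {row + 1}")


def read_session(
    nirs_path: str | Path,
    bp_path: str | Path,
    schedule_path: str | Path,
    age_years: float = 25.0,
    wavelengths_nm: tuple = mbll.DEFAULT_WAVELENGTHS_NM,
    channel_modes: dict | None = None,
) -> tuple[mbll.RawOpticalRecording, _pr.PressureRecording, _sg.TrialSchedule]:
    """Load and validate a session from the three CSV inputs.

    ``channel_modes`` maps channel labels (the ``<label>_od_w1`` column
    prefixes) to ``deep``/``shallow``; unlisted channels default to deep.
    """
    sched_df = pd.read_csv(schedule_path)
    _check_nan(sched_df, "schedule.csv")
    schedule = _sg.TrialSchedule(
        sched_df["onset_s"].to_numpy(),
        sched_df["duration_ms"].to_numpy(),
        sched_df["movement"].to_numpy().astype(bool),
    )
    if np.any(np.diff(schedule.onsets_s) <= 12.5):
        raise ValueError("schedule.csv: onsets closer than 12.5 s -> overlapping epochs")

    bp_df = pd.read_csv(bp_path)
    _check_nan(bp_df, "pressure.csv")
    fs_bp = _check_uniform(bp_df["time_s"].to_numpy(), "pressure.csv")
    prec = _pr.PressureRecording(
        bp_df["time_s"].to_numpy(), bp_df["pressure_mmHg"].to_numpy(), fs_bp
    )

    nirs_df = pd.read_csv(nirs_path)
    _check_nan(nirs_df, "nirs_raw.csv")
    t = nirs_df["time_s"].to_numpy()
    fs_nirs = _check_uniform(t, "nirs_raw.csv")
    labels = sorted(
        {c[: -len("_od_w1")] for c in nirs_df.columns if c.endswith("_od_w1")}
    )
    if not labels:
        raise ValueError("nirs_raw.csv: no '<label>_od_w1' columns found")
    channel_modes = channel_modes or {}
    channels = []
    for lab in labels:
        mode = channel_modes.get(lab, "deep")
        sep = (
            mbll.DEEP_SEPARATION_CM if mode == "deep" else mbll.SHALLOW_SEPARATION_CM
        )
        od = np.column_stack(
            [nirs_df[f"{lab}_od_w1"].to_numpy(), nirs_df[f"{lab}_od_w2"].to_numpy()]
        )
        channels.append(mbll.OpticalChannel(lab, sep, od, mode=mode))
    raw = mbll.RawOpticalRecording(
        time_s=t,
        channels=channels,
        wavelengths_nm=tuple(wavelengths_nm),
        age_years=age_years,
        fs_hz=fs_nirs,
    )
    return raw, prec, schedule


# ---------------------------------------------------------------------------
# analysis


def _pooled_cells(cell: str) -> list[str]:
    if cell == "move":
        return ["1500ms_move", "3000ms_move"]
    if cell == "nomove":
        return ["1500ms_nomove", "3000ms_nomove"]
    return [cell]


def _cell_mean(epochs: _sp.EpochSet, cell: str) -> tuple[np.ndarray, int]:
    sel = np.isin(epochs.conditions, _pooled_cells(cell)) & epochs.kept()
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"condition cell {cell!r} has no surviving epochs")
    return epochs.data[sel].mean(axis=0), n


def _preprocess_and_epoch(
    x: np.ndarray,
    fs: float,
    schedule: _sg.TrialSchedule,
    params: AnalysisParams,
    window: tuple,
    lowpass_hz: float | None,
    name: str,
    units: str,
) -> _sp.EpochSet:
    if lowpass_hz is not None:
        x = _sp.lowpass(x, fs, lowpass_hz)
    x = _sp.detrend_poly(x, fs, params.detrend_degree)
    eps = _sp.epoch(
        x,
        fs,
        schedule.onsets_s,
        schedule.condition_labels(),
        window_s=window,
        baseline_s=params.baseline_s,
        signal_name=name,
        units=units,
    )
    return _sp.reject_outliers(eps, params.reject_k)


def analyze_session(
    raw: mbll.RawOpticalRecording,
    prec: _pr.PressureRecording,
    schedule: _sg.TrialSchedule,
    params: AnalysisParams,
    provenance: dict | None = None,
) -> ResultsBundle:
    """Run the complete analysis chain on one session."""
    cells4 = ["1500ms_nomove", "3000ms_nomove", "1500ms_move", "3000ms_move"]
    all_cells = cells4 + ["nomove", "move"]
    epoch_sets: dict[str, _sp.EpochSet] = {}

    # --- NIRS branch
    conc = mbll.od_to_conc(raw)
    for ch in raw.channels:
        for chrom, series in (("o2hb", conc.o2hb[ch.label]), ("hhb", conc.hhb[ch.label])):
            name = f"{ch.label}_{chrom}"
            epoch_sets[name] = _preprocess_and_epoch(
                series,
                raw.fs_hz,
                schedule,
                params,
                params.nirs_window_s,
                params.nirs_lowpass_hz,
                name,
                "uM",
            )
            log.info(
                "%s: %d epochs, %d rejected",
                name,
                epoch_sets[name].n_trials,
                int(epoch_sets[name].rejected.sum()),
            )

    # --- pressure branch
    filt = _sp.lowpass(prec.pressure_mmHg, prec.fs_hz, params.bp_lowpass_hz)
    beats = _pr.detect_beats(
        _pr.PressureRecording(prec.time_s, filt, prec.fs_hz),
        refractory_s=params.beat_refractory_s,
        prominence_mmHg=params.beat_prominence_mmHg,
    )
    beats = _pr.map_from_beats(
        beats,
        _pr.PressureRecording(prec.time_s, filt, prec.fs_hz),
        method=params.map_method,
    )
    beats = _pr.beats_to_continuous(
        beats, raw.fs_hz, t_end_s=raw.time_s[-1] + 1.0 / raw.fs_hz,
        kind=params.beat_interp,
    )
    for key in ("sbp", "dbp", "map"):
        epoch_sets[key] = _preprocess_and_epoch(
            beats.series[key],
            raw.fs_hz,
            schedule,
            params,
            params.bp_window_s,
            None,  # beat series is already smooth; 10 Hz filter ran upstream
            key,
            "mmHg",
        )

    # --- per-cell metrics table
    metric_rows = []
    for name, eps in epoch_sets.items():
        chrom = name.split("_")[-1] if "_" in name else name
        pol = POLARITY.get(chrom, "auto")
        for cell in all_cells:
            mean_ep, n = _cell_mean(eps, cell)
            m = _an.response_metrics(mean_ep, eps.time_s, pol)
            metric_rows.append(
                {
                    "signal": name,
                    "condition": cell,
                    "amplitude": m.amplitude,
                    "latency_s": m.latency_s,
                    "n_epochs": n,
                }
            )
    metrics_df = pd.DataFrame(metric_rows)

    # --- per-trial metrics for the statistical layer
    per_trial = {
        name: _an.metrics_per_trial(
            eps, POLARITY.get(name.split("_")[-1] if "_" in name else name, "auto")
        )
        for name, eps in epoch_sets.items()
    }

    stat_rows = []

    def _add_stat(signal, contrast, measure, res, significant):
        stat_rows.append(
            {
                "signal": signal,
                "contrast": contrast,
                "measure": measure,
                "t": res.statistic,
                "df": res.df,
                "p": res.p,
                "significant": int(significant),
            }
        )

    # planned comparisons on every deep channel
    deep_labels = [ch.label for ch in raw.channels if ch.mode == "deep"]
    for lab in deep_labels:
        for chrom in ("o2hb", "hhb"):
            name = f"{lab}_{chrom}"
            pc = _an.planned_comparisons(
                per_trial[name], params.family_alpha, params.paired_tests
            )
            for entry in pc["tests"]:
                _add_stat(
                    name,
                    entry["contrast"],
                    entry["measure"],
                    entry["result"],
                    entry["significant"],
                )

    # one-sample tests: movement-trial response amplitudes vs zero
    shallow_labels = [ch.label for ch in raw.channels if ch.mode == "shallow"]
    onesample = ["sbp", "dbp", "map"] + [
        f"{lab}_{chrom}" for lab in shallow_labels for chrom in ("o2hb", "hhb")
    ]
    for name in onesample:
        amps = np.concatenate(
            [per_trial[name][c]["amplitude"] for c in _pooled_cells("move")]
        )
        res = _an.one_sample_t(amps, f"{name}:move amplitude vs 0")
        _add_stat(name, "move_vs_zero", "amplitude", res, res.p < 0.05)
    stats_df = pd.DataFrame(stat_rows)

    # --- coupling regressions (condition-averaged traces vs MAP)
    reg_rows = []
    w_common = (
        max(params.nirs_window_s[0], params.bp_window_s[0]),
        min(params.nirs_window_s[1], params.bp_window_s[1]),
    )
    for name, eps in epoch_sets.items():
        if name in ("sbp", "dbp", "map"):
            continue
        for cell in ("move", "nomove"):
            sig_mean, _ = _cell_mean(eps, cell)
            map_mean, _ = _cell_mean(epoch_sets["map"], cell)
            reg = _an.coupling_regression(
                sig_mean,
                eps.time_s,
                map_mean,
                epoch_sets["map"].time_s,
                common_window_s=w_common,
                label=f"{name}:{cell}",
            )
            reg_rows.append(
                {
                    "signal": name,
                    "condition": cell,
                    "slope": reg.slope,
                    "intercept": reg.intercept,
                    "r": reg.r,
                    "p": reg.p,
                    "n": reg.n,
                }
            )
    # systolic-vs-diastolic per-trial amplitude regression (movement trials,
    # paired on trials surviving rejection in both series)
    eps_s, eps_d = epoch_sets["sbp"], epoch_sets["dbp"]
    joint = (
        np.isin(eps_s.conditions, _pooled_cells("move"))
        & eps_s.kept()
        & eps_d.kept()
    )
    sbp_amp = np.array(
        [
            _an.response_metrics(row, eps_s.time_s, "max").amplitude
            for row in eps_s.data[joint]
        ]
    )
    dbp_amp = np.array(
        [
            _an.response_metrics(row, eps_d.time_s, "max").amplitude
            for row in eps_d.data[joint]
        ]
    )
    from scipy.stats import linregress

    fit = linregress(sbp_amp, dbp_amp)
    reg_rows.append(
        {
            "signal": "dbp_vs_sbp_amplitude",
            "condition": "move",
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "r": float(fit.rvalue),
            "p": float(fit.pvalue),
            "n": int(sbp_amp.size),
        }
    )
    reg_df = pd.DataFrame(reg_rows)

    # --- rejection audit log
    rej_rows = []
    for name, eps in epoch_sets.items():
        for i in range(eps.n_trials):
            rej_rows.append(
                {
                    "signal": name,
                    "trial": i,
                    "condition": eps.conditions[i],
                    "peak_abs_deviation": (
                        eps.rejection_stats[i] if eps.rejection_stats is not None else np.nan
                    ),
                    "rejected": int(eps.rejected[i]),
                }
            )
    rej_df = pd.DataFrame(rej_rows)

    # --- condition-averaged traces
    traces = {}
    for name, eps in epoch_sets.items():
        cols = {"time_s": eps.time_s}
        for cell in all_cells:
            sel = np.isin(eps.conditions, _pooled_cells(cell)) & eps.kept()
            block = eps.data[sel]
            cols[f"{cell}_mean"] = block.mean(axis=0)
            cols[f"{cell}_sd"] = block.std(axis=0)
        traces[name] = pd.DataFrame(cols)

    if provenance is None:
        provenance = {}
    provenance = dict(provenance)
    provenance["versions"] = _versions()
    return ResultsBundle(
        metrics=metrics_df,
        stats=stats_df,
        regressions=reg_df,
        rejections=rej_df,
        traces=traces,
        provenance=provenance,
    )


def _versions() -> dict:
    import scipy

    import nirsbp

    return {
        "nirsbp": nirsbp.__version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }


def _recovery_report(bundle: ResultsBundle, gt: _sg.GroundTruth) -> dict:
    """Injected-vs-recovered comparison for a simulated session."""
    m = bundle.metrics.set_index(["signal", "condition"])

    def get(sig, cell, col):
        return float(m.loc[(sig, cell), col])

    rec = {
        "map_amplitude": {
            "injected": gt.bp_map_amplitude_mmHg,
            "recovered": get("map", "move", "amplitude"),
        },
        "map_latency": {
            "injected": gt.bp_map_peak_s,
            "recovered": get("map", "move", "latency_s"),
        },
        "sbp_amplitude": {
            "injected": gt.bp_sbp_amplitude_mmHg,
            "recovered": get("sbp", "move", "amplitude"),
        },
        "deep_o2hb_latency_1500_nomove": {
            "injected": gt.hrf_peak_s["o2hb"][1500],
            "recovered": get("deep_o2hb", "1500ms_nomove", "latency_s"),
        },
        "deep_o2hb_latency_3000_nomove": {
            "injected": gt.hrf_peak_s["o2hb"][3000],
            "recovered": get("deep_o2hb", "3000ms_nomove", "latency_s"),
        },
        "deep_o2hb_amplitude_move": get("deep_o2hb", "move", "amplitude"),
        "deep_o2hb_amplitude_nomove": get("deep_o2hb", "nomove", "amplitude"),
    }
    return rec


def write_bundle(bundle: ResultsBundle, outdir: str | Path) -> None:
    out = Path(outdir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    bundle.metrics.to_csv(out / "tables" / "metrics.csv", index=False, float_format=FLOAT_FMT)
    bundle.stats.to_csv(out / "tables" / "stats.csv", index=False, float_format=FLOAT_FMT)
    bundle.regressions.to_csv(
        out / "tables" / "regressions.csv", index=False, float_format=FLOAT_FMT
    )
    bundle.rejections.to_csv(
        out / "tables" / "rejections.csv", index=False, float_format=FLOAT_FMT
    )
    for name, df in bundle.traces.items():
        df.to_csv(out / "traces" / f"{name}.csv", index=False, float_format=FLOAT_FMT)
    (out / "provenance.json").write_text(
        json.dumps(bundle.provenance, indent=2, sort_keys=True, default=str) + "\n"
    )
    if bundle.recovery is not None:
        (out / "recovery.json").write_text(
            json.dumps(bundle.recovery, indent=2, sort_keys=True) + "\n"
        )


def run(config: RunConfig, outdir: str | Path) -> ResultsBundle | None:
    """Execute a run and write its outputs under ``outdir``.

    ``simulate`` writes only the session CSVs; ``analyze`` reads a session
    from the configured paths and writes result tables; ``full`` does
    both and additionally writes an injected-vs-recovered report.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    if config.mode in ("simulate", "full"):
        config.simulation.seed = config.seed
        session = _sg.simulate_session(config.simulation)
        write_session(session, out / "session")
        log.info("simulated session: %d trials", session.schedule.n_trials)
        if config.mode == "simulate":
            return None
        raw, prec, schedule = session.nirs, session.pressure, session.schedule
        gt = session.ground_truth
    else:
        if not (config.nirs_path and config.bp_path and config.schedule_path):
            raise ValueError("analyze mode needs nirs_path, bp_path and schedule_path")
        raw, prec, schedule = read_session(
            config.nirs_path,
            config.bp_path,
            config.schedule_path,
            age_years=config.age_years,
            channel_modes=config.channel_modes,
        )
        gt = None

    bundle = analyze_session(
        raw, prec, schedule, config.analysis, provenance=config.echo()
    )
    if gt is not None:
        bundle.recovery = _recovery_report(bundle, gt)
    write_bundle(bundle, out)
    return bundle
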