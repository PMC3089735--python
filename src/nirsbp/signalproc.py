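"""Filtering, detrending, epoching, outlier rejection and averaging.

All operations act on uniformly sampled 1-D traces and are agnostic to
whether the trace is a chromophore concentration or a beat-derived
pressure series. Conventions: half-open epoch windows on the source
sampling grid, onset sample included at t = 0; timestamps in seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

__all__ = [
    "EpochSet",
    "lowpass",
    "detrend_poly",
    "epoch",
    "reject_outliers",
    "average_by_condition",
]

log = logging.getLogger(__name__)

NIRS_WINDOW_S = (-0.5, 12.0)
PRESSURE_WINDOW_S = (-0.5, 10.0)
BASELINE_WINDOW_S = (-0.5, 0.0)


def lowpass(x: np.ndarray, fs_hz: float, cutoff_hz: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter (applied forward-backward).

    DC gain is exactly 1; the effective magnitude response is the squared
    Butterworth magnitude, so a tone at frequency f is attenuated by
    ``1 / (1 + (f/cutoff)**(2*order))`` in amplitude.
    """
    x = np.asarray(x, dtype=float)
    if not 0 < cutoff_hz < fs_hz / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={fs_hz / 2} Hz)"
        )
    sos = _sig.butter(order, cutoff_hz, btype="low", fs=fs_hz, output="sos")
    return _sig.sosfiltfilt(sos, x)


def detrend_poly(x: np.ndarray, fs_hz: float, degree: int = 5) -> np.ndarray:
    """Subtract a least-squares polynomial of ``degree`` fitted to the trace.

    The fit spans the full trace; the abscissa is rescaled to [-1, 1] for
    numerical conditioning.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= degree + 1:
        raise ValueError(
            f"trace of {x.size} samples too short for degree-{degree} detrend"
        )
    t = np.linspace(-1.0, 1.0, x.size)
    fit = np.polynomial.Polynomial.fit(t, x, degree)
    return x - fit(t)


@dataclass
class EpochSet:
    """Time-locked, baseline-corrected epochs with a rejection mask.

    Attributes
    ----------
    data
        ``(n_trials, n_samples)`` baseline-corrected epoch matrix.
    time_s
        Time axis relative to stimulus onset, on the source sampling grid.
    conditions
        Per-trial condition labels.
    rejected
        Per-trial rejection mask (True = excluded from averages).
    dropped_trials
        Indices (into the original onset list) of trials whose window fell
        outside the recording and were excluded before epoching.
    """

    data: np.ndarray
    time_s: np.ndarray
    conditions: np.ndarray
    rejected: np.ndarray
    baseline_window_s: tuple[float, float] = BASELINE_WINDOW_S
    signal_name: str = ""
    units: str = ""
    dropped_trials: list[int] = field(default_factory=list)
    rejection_stats: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def kept(self) -> np.ndarray:
        return ~self.rejected


def epoch(
    x: np.ndarray,
    fs_hz: float,
    onsets_s: np.ndarray,
    conditions: np.ndarray | list | None = None,
    window_s: tuple[float, float] = NIRS_WINDOW_S,
    baseline_s: tuple[float, float] = BASELINE_WINDOW_S,
    signal_name: str = "",
    units: str = "",
) -> EpochSet:
    """Cut half-open windows ``[onset+w0, onset+w1)`` and baseline-correct.

    Each epoch's mean over ``baseline_s`` (relative to onset) is
    subtracted. Onsets whose window exceeds the recording bounds are
    excluded with a logged warning, not an error.
    """
    x = np.asarray(x, dtype=float)
    onsets = np.atleast_1d(np.asarray(onsets_s, dtype=float))
    if conditions is None:
        conditions = np.array([""] * onsets.size)
    conditions = np.asarray(conditions)

    w0, w1 = window_s
    n0 = int(round(w0 * fs_hz))
    n1 = int(round(w1 * fs_hz))
    rel = np.arange(n0, n1)
    time_axis = rel / fs_hz

    b0, b1 = baseline_s
    bmask = (time_axis >= b0) & (time_axis < b1)
    if not bmask.any():
        raise ValueError("baseline window contains no samples")

    rows, labels, dropped = [], [], []
    for i, onset in enumerate(onsets):
        centre = int(round(onset * fs_hz))
        idx = centre + rel
        if idx[0] < 0 or idx[-1] >= x.size:
            dropped.append(i)
            log.warning(
                "trial %d (onset %.2f s): window outside recording, excluded",
                i,
                onset,
            )
            continue
        ep = x[idx]
        rows.append(ep - ep[bmask].mean())
        labels.append(conditions[i])

    data = np.array(rows, dtype=float).reshape(len(rows), rel.size)
    return EpochSet(
        data=data,
        time_s=time_axis,
        conditions=np.asarray(labels),
        rejected=np.zeros(len(rows), dtype=bool),
        baseline_window_s=baseline_s,
        signal_name=signal_name,
        units=units,
        dropped_trials=dropped,
    )


def _peak_abs_deviation(data: np.ndarray) -> np.ndarray:
    # per-epoch statistic for outlier screening: peak |deviation| from the
    # (already subtracted) baseline, over the whole epoch window
    return np.max(np.abs(data), axis=1)


def reject_outliers(epochs: EpochSet, k: float = 3.0) -> EpochSet:
    """Mark epochs whose peak absolute deviation is outside mean +- k*SD.

    Statistics are pooled within each condition cell and computed in a
    single pass including the candidate epoch; if a cell's SD is zero
    nothing is rejected there. Returns a new :class:`EpochSet`; the
    per-epoch statistic is stored in ``rejection_stats`` for auditing.
    """
    if epochs.n_trials < 3:
        raise ValueError("need at least 3 epochs for outlier rejection")
    stats = _peak_abs_deviation(epochs.data)
    rejected = np.zeros(epochs.n_trials, dtype=bool)
    if np.isfinite(k):
        for cell in np.unique(epochs.conditions):
            sel = epochs.conditions == cell
            s = stats[sel]
            mu, sd = s.mean(), s.std()
            if sd == 0:
                continue
            rejected[sel] = np.abs(s - mu) > k * sd
    n_rej = int(rejected.sum())
    if n_rej:
        log.info("rejected %d/%d epochs (+-%g SD criterion)", n_rej, epochs.n_trials, k)
    return EpochSet(
        data=epochs.data,
        time_s=epochs.time_s,
        conditions=epochs.conditions,
        rejected=rejected,
        baseline_window_s=epochs.baseline_window_s,
        signal_name=epochs.signal_name,
        units=epochs.units,
        dropped_trials=list(epochs.dropped_trials),
        rejection_stats=stats,
    )


def average_by_condition(
    epochs: EpochSet,
    cells: list | None = None,
) -> dict:
    """Sample-wise mean and SD across surviving epochs, per condition cell.

    Returns ``{cell: (mean, sd, n)}``. SD is the population SD across
    epochs (zero for a single-epoch cell). An empty cell raises.
    """
    if cells is None:
        cells = list(np.unique(epochs.conditions))
    out = {}
    for cell in cells:
        sel = (epochs.conditions == cell) & epochs.kept()
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"condition cell {cell!r} has no surviving epochs")
        block = epochs.data[sel]
        out[cell] = (block.mean(axis=0), block.std(axis=0), n)
    return out
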