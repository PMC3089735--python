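"""Response metrics, planned comparisons and coupling regressions.

Amplitude/latency are measured on baseline-corrected epochs as the signed
extremum over the post-onset window and its time. The statistical layer
covers one-sample t-tests against zero, two-sample t-tests (unpaired
pooled-variance by default, paired available), the three-contrast planned
comparison family with Bonferroni-corrected critical alpha, and
point-wise linear regression between condition-averaged traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

from nirsbp.signalproc import EpochSet, average_by_condition

__all__ = [
    "ResponseMetrics",
    "StatResult",
    "RegressionResult",
    "response_metrics",
    "metrics_per_trial",
    "one_sample_t",
    "two_sample_t",
    "planned_comparisons",
    "coupling_regression",
    "PLANNED_CONTRASTS",
]

#: the three planned contrasts: (label, selector for group a, group b)
#: cells are "{duration}ms_{move|nomove}" strings
PLANNED_CONTRASTS = (
    ("nomove_1500_vs_3000", ("1500ms_nomove",), ("3000ms_nomove",)),
    ("move_1500_vs_3000", ("1500ms_move",), ("3000ms_move",)),
    ("move_vs_nomove", ("1500ms_move", "3000ms_move"), ("1500ms_nomove", "3000ms_nomove")),
)


@dataclass
class ResponseMetrics:
    """Signed extremum amplitude and its post-onset latency."""

    amplitude: float
    latency_s: float
    polarity: str  # "max" or "min"
    search_window_s: tuple[float, float]
    undefined_latency: bool = False


@dataclass
class StatResult:
    statistic: float
    df: float
    p: float
    mean_a: float
    sd_a: float
    mean_b: float | None
    sd_b: float | None
    label: str
    degenerate: bool = False  # zero-variance branch was taken

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    n: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("regression needs n >= 3")
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation {self.r} outside [-1, 1]")


def format_p(p: float) -> str:
    """Report-style p rendering: values below 0.001 become ``p < 0.001``."""
    return "p < 0.001" if p < 0.001 else f"p = {p:.3f}"


def response_metrics(
    mean_epoch: np.ndarray,
    time_s: np.ndarray,
    polarity: str = "auto",
) -> ResponseMetrics:
    """Extremum amplitude over pre-stimulus baseline and its latency.

    The search window is the strictly post-onset part of the epoch,
    ``(0, end]``. ``polarity='max'``/``'min'`` select the maximum or
    minimum; ``'auto'`` picks whichever has the larger magnitude. Ties are
    broken by the earliest time. A flat epoch yields amplitude 0 with the
    latency flagged undefined (NaN).
    """
    x = np.asarray(mean_epoch, dtype=float)
    t = np.asarray(time_s, dtype=float)
    post = t > 0
    if not post.any():
        raise ValueError("no post-onset samples in epoch")
    xs, ts = x[post], t[post]
    window = (float(ts[0]), float(ts[-1]))

    if polarity == "max":
        idx = int(np.argmax(xs))
    elif polarity == "min":
        idx = int(np.argmin(xs))
    elif polarity == "auto":
        imax, imin = int(np.argmax(xs)), int(np.argmin(xs))
        if abs(xs[imax]) > abs(xs[imin]):
            idx, polarity = imax, "max"
        elif abs(xs[imin]) > abs(xs[imax]):
            idx, polarity = imin, "min"
        else:  # tie -> earliest
            idx = min(imax, imin)
            polarity = "max" if idx == imax else "min"
    else:
        raise ValueError(f"polarity must be max/min/auto, got {polarity!r}")

    if np.all(xs == xs[0]) and xs[0] == 0.0:
        return ResponseMetrics(0.0, float("nan"), polarity, window, True)
    return ResponseMetrics(float(xs[idx]), float(ts[idx]), polarity, window)


def metrics_per_trial(epochs: EpochSet, polarity: str = "auto") -> dict:
    """Per-trial amplitude/latency arrays for each condition cell.

    Only non-rejected epochs contribute. Returns
    ``{cell: {"amplitude": arr, "latency": arr}}``; trials with undefined
    latency carry NaN there (drop before t-tests on latency).
    """
    out: dict = {}
    for cell in np.unique(epochs.conditions):
        sel = (epochs.conditions == cell) & epochs.kept()
        amps, lats = [], []
        for row in epochs.data[sel]:
            m = response_metrics(row, epochs.time_s, polarity)
            amps.append(m.amplitude)
            lats.append(m.latency_s)
        out[str(cell)] = {
            "amplitude": np.array(amps),
            "latency": np.array(lats),
        }
    return out


def _finite_t(values: np.ndarray, label: str) -> StatResult:
    """Zero-variance one-sample branch: report t = +-inf, p = 0, flagged."""
    mean = float(np.mean(values))
    t = math.inf if mean > 0 else (-math.inf if mean < 0 else 0.0)
    p = 0.0 if mean != 0 else 1.0
    return StatResult(t, len(values) - 1, p, mean, 0.0, None, None, label, True)


def one_sample_t(values: np.ndarray, label: str = "") -> StatResult:
    """Two-sided one-sample t-test of the mean against zero."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("one-sample t-test needs n >= 2")
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        return _finite_t(v, label)
    t, p = _st.ttest_1samp(v, 0.0)
    return StatResult(
        float(t), v.size - 1, float(p), float(v.mean()), sd, None, None, label
    )


def two_sample_t(
    a: np.ndarray, b: np.ndarray, paired: bool = False, label: str = ""
) -> StatResult:
    """Two-sided two-sample t-test.

    Unpaired uses the pooled-variance statistic with ``df = n1 + n2 - 2``;
    paired reduces to a one-sample test on the differences.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if paired:
        if a.size != b.size:
            raise ValueError("paired groups must have equal size")
        res = one_sample_t(a - b, label)
        return StatResult(
            res.statistic,
            res.df,
            res.p,
            float(a.mean()),
            float(np.std(a, ddof=1)),
            float(b.mean()),
            float(np.std(b, ddof=1)),
            label,
            res.degenerate,
        )
    sa, sb = np.std(a, ddof=1), np.std(b, ddof=1)
    if sa == 0.0 and sb == 0.0:
        diff = float(a.mean() - b.mean())
        t = math.inf if diff > 0 else (-math.inf if diff < 0 else 0.0)
        p = 0.0 if diff != 0 else 1.0
        return StatResult(
            t, a.size + b.size - 2, p, float(a.mean()), 0.0, float(b.mean()), 0.0,
            label, True,
        )
    t, p = _st.ttest_ind(a, b, equal_var=True)
    return StatResult(
        float(t),
        a.size + b.size - 2,
        float(p),
        float(a.mean()),
        float(sa),
        float(b.mean()),
        float(sb),
        label,
    )


def planned_comparisons(
    metrics_by_condition: dict,
    family_alpha: float = 0.05,
    paired: bool = False,
) -> dict:
    """The three planned contrasts, for amplitude and latency separately.

    ``metrics_by_condition`` maps each of the four cells to per-trial
    ``{"amplitude", "latency"}`` arrays (see :func:`metrics_per_trial`).
    The per-test critical alpha is ``family_alpha / 3``; it is rounded to
    3 decimals for display and used unrounded for the significance flags.

    Returns ``{"alpha_display", "alpha_exact", "tests": [...]}`` where
    each test entry carries the contrast label, the measure, the
    :class:`StatResult` and the flag.
    """
    required = {cells for _, ga, gb in PLANNED_CONTRASTS for cells in ga + gb}
    missing = sorted(required - set(metrics_by_condition))
    if missing:
        raise ValueError(f"missing condition cell(s): {', '.join(missing)}")

    alpha_exact = family_alpha / len(PLANNED_CONTRASTS)
    alpha_display = round(alpha_exact, 3)

    tests = []
    for label, group_a, group_b in PLANNED_CONTRASTS:
        for measure in ("amplitude", "latency"):
            va = np.concatenate(
                [metrics_by_condition[c][measure] for c in group_a]
            )
            vb = np.concatenate(
                [metrics_by_condition[c][measure] for c in group_b]
            )
            va = va[np.isfinite(va)]
            vb = vb[np.isfinite(vb)]
            res = two_sample_t(va, vb, paired=paired, label=f"{label}:{measure}")
            tests.append(
                {
                    "contrast": label,
                    "measure": measure,
                    "result": res,
                    "significant": bool(res.p < alpha_exact),
                }
            )
    return {
        "alpha_display": alpha_display,
        "alpha_exact": alpha_exact,
        "family_alpha": family_alpha,
        "tests": tests,
    }


def coupling_regression(
    signal_epoch: np.ndarray,
    signal_time_s: np.ndarray,
    map_epoch: np.ndarray,
    map_time_s: np.ndarray,
    common_window_s: tuple[float, float] | None = None,
    label: str = "",
) -> RegressionResult:
    """Point-wise linear regression of a condition-averaged trace on MAP.

    Both traces must share the sampling grid over the overlap of their
    windows (their sample times must coincide there); the regression runs
    across time points of that common window. Slope is in signal units
    per mmHg.
    """
    st = np.asarray(signal_time_s, dtype=float)
    mt = np.asarray(map_time_s, dtype=float)
    if common_window_s is None:
        common_window_s = (max(st[0], mt[0]), min(st[-1], mt[-1]))
    w0, w1 = common_window_s
    ssel = (st >= w0) & (st <= w1)
    msel = (mt >= w0) & (mt <= w1)
    ts, tm = st[ssel], mt[msel]
    n = min(ts.size, tm.size)
    ts, tm = ts[:n], tm[:n]
    if not np.allclose(ts, tm, atol=1e-9):
        raise ValueError("traces are not on a common sampling grid")
    y = np.asarray(signal_epoch, dtype=float)[ssel][:n]
    x = np.asarray(map_epoch, dtype=float)[msel][:n]
    if np.all(x == x[0]):
        raise ValueError("constant MAP regressor: correlation undefined")
    fit = _st.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        n=int(n),
        label=label,
    )


def group_one_sample_t(per_session_values: list[float], label: str = "") -> StatResult:
    """Across-session helper: one-sample t on one value per session/file."""
    return one_sample_t(np.asarray(per_session_values, dtype=float), label)
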