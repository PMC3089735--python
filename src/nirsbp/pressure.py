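"""Beat-to-beat pressure extraction from the continuous finger waveform.

The peak-picking stage segments the (already low-pass filtered) waveform
into beats delimited by diastolic troughs; each beat contributes one
systolic, one diastolic and one mean arterial pressure (MAP) value, which
can then be resampled to a uniform grid and analysed like any other
trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

__all__ = [
    "PressureRecording",
    "BeatSeries",
    "detect_beats",
    "map_from_beats",
    "beats_to_continuous",
]

log = logging.getLogger(__name__)

SANITY_RANGE_MMHG = (20.0, 300.0)
IBI_RANGE_S = (0.3, 2.0)
#: minimum fraction of the median beat length for an edge beat to count
#: as complete rather than partial
EDGE_BEAT_MIN_FRACTION = 0.75


@dataclass
class PressureRecording:
    """Uniformly sampled continuous arterial-pressure waveform (mmHg)."""

    time_s: np.ndarray
    pressure_mmHg: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.pressure_mmHg = np.asarray(self.pressure_mmHg, dtype=float)
        if self.time_s.shape != self.pressure_mmHg.shape:
            raise ValueError("time and pressure arrays must have equal length")
        lo, hi = SANITY_RANGE_MMHG
        bad = np.count_nonzero(
            (self.pressure_mmHg < lo) | (self.pressure_mmHg > hi)
        )
        if bad:
            log.warning(
                "%d pressure samples outside sanity range [%g, %g] mmHg",
                bad,
                lo,
                hi,
            )

    @property
    def duration_s(self) -> float:
        return self.pressure_mmHg.size / self.fs_hz


@dataclass
class BeatSeries:
    """Per-beat systolic/diastolic/MAP values plus optional uniform series."""

    systolic_time_s: np.ndarray
    sbp_mmHg: np.ndarray
    diastolic_time_s: np.ndarray
    dbp_mmHg: np.ndarray
    map_mmHg: np.ndarray | None = None
    # sample-index bounds [start, stop) of each beat in the source recording
    beat_bounds: np.ndarray | None = None
    grid_time_s: np.ndarray | None = None
    series: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_beats(self) -> int:
        return self.sbp_mmHg.size


def detect_beats(
    rec: PressureRecording,
    refractory_s: float = 0.3,
    prominence_mmHg: float = 5.0,
) -> BeatSeries:
    """Peak-picking beat segmentation.

    Systolic peaks are local maxima exceeding ``prominence_mmHg`` and
    separated by at least ``refractory_s``; the diastolic trough is the
    waveform minimum between consecutive systolic peaks. Beats are the
    trough-to-trough windows; the leading/trailing windows are kept only
    when long enough to be complete beats (partial edge beats dropped).
    """
    p = rec.pressure_mmHg
    fs = rec.fs_hz
    peaks, _ = find_peaks(
        p,
        distance=max(1, int(round(refractory_s * fs))),
        prominence=prominence_mmHg,
    )
    if peaks.size < 2:
        raise ValueError(
            f"peak picking found {peaks.size} systolic peak(s); need >= 2 "
            "(check prominence/refractory settings)"
        )

    troughs = np.array(
        [peaks[j] + int(np.argmin(p[peaks[j] : peaks[j + 1] + 1])) for j in range(peaks.size - 1)]
    )
    median_len = float(np.median(np.diff(troughs))) if troughs.size > 1 else float(
        peaks[1] - peaks[0]
    )

    bounds = [(troughs[j], troughs[j + 1]) for j in range(troughs.size - 1)]
    # edge windows count as beats only when essentially complete
    lead = (0, troughs[0])
    if lead[1] - lead[0] >= EDGE_BEAT_MIN_FRACTION * median_len and peaks[0] < troughs[0]:
        bounds.insert(0, lead)
    trail = (troughs[-1], p.size)
    if trail[1] - trail[0] >= EDGE_BEAT_MIN_FRACTION * median_len and peaks[-1] > troughs[-1]:
        bounds.append(trail)

    sys_t, sbp, dia_t, dbp = [], [], [], []
    for a, b in bounds:
        seg = p[a:b]
        imax = a + int(np.argmax(seg))
        imin = a + int(np.argmin(seg))
        sys_t.append(rec.time_s[imax])
        sbp.append(p[imax])
        dia_t.append(rec.time_s[imin])
        dbp.append(p[imin])

    sys_t = np.array(sys_t)
    ibi = np.diff(sys_t)
    lo, hi = IBI_RANGE_S
    n_bad = int(np.count_nonzero((ibi < lo) | (ibi > hi)))
    if n_bad:
        log.warning(
            "%d inter-beat intervals outside physiological range [%g, %g] s",
            n_bad,
            lo,
            hi,
        )
    log.info("detected %d beats", len(bounds))
    return BeatSeries(
        systolic_time_s=sys_t,
        sbp_mmHg=np.array(sbp),
        diastolic_time_s=np.array(dia_t),
        dbp_mmHg=np.array(dbp),
        beat_bounds=np.array(bounds, dtype=int),
    )


def map_from_beats(
    beats: BeatSeries,
    rec: PressureRecording | None = None,
    method: str = "waveform_mean",
) -> BeatSeries:
    """Fill per-beat MAP.

    ``waveform_mean``: time-average (trapezoidal) of the waveform over the
    beat's trough-to-trough window — requires ``rec``. ``onethird``: the
    classic ``DBP + (SBP - DBP)/3`` estimate.
    """
    if method == "onethird":
        beats.map_mmHg = beats.dbp_mmHg + (beats.sbp_mmHg - beats.dbp_mmHg) / 3.0
        return beats
    if method != "waveform_mean":
        raise ValueError(f"unknown MAP method {method!r}")
    if rec is None or beats.beat_bounds is None:
        raise ValueError("waveform_mean MAP needs the source recording and beat bounds")
    p = rec.pressure_mmHg
    maps = np.empty(beats.n_beats)
    for i, (a, b) in enumerate(beats.beat_bounds):
        seg = p[a:b]
        if seg.size < 2:
            maps[i] = seg.mean()
        else:
            maps[i] = np.trapezoid(seg) / (seg.size - 1)
    beats.map_mmHg = maps
    return beats


def _interp_series(t_nodes, v_nodes, grid, kind):
    if kind == "linear" or t_nodes.size < 3:
        out = np.interp(grid, t_nodes, v_nodes)
    elif kind == "cubic":
        spl = CubicSpline(t_nodes, v_nodes, bc_type="natural")
        out = spl(np.clip(grid, t_nodes[0], t_nodes[-1]))
    else:
        raise ValueError(f"unknown interpolation kind {kind!r}")
    # held constant beyond the first/last beat
    out[grid <= t_nodes[0]] = v_nodes[0]
    out[grid >= t_nodes[-1]] = v_nodes[-1]
    return out


def beats_to_continuous(
    beats: BeatSeries,
    fs_out_hz: float,
    t_end_s: float | None = None,
    kind: str = "cubic",
) -> BeatSeries:
    """Resample per-beat SBP/DBP/MAP onto a uniform grid.

    Values are interpolated between beats (natural cubic spline by
    default, which preserves smooth peak timing for latency estimation;
    ``kind='linear'`` is available) and held constant beyond the first and
    last beat. The grid spans ``[0, t_end_s)``; by default it ends just
    after the last beat.
    """
    if beats.n_beats < 2:
        raise ValueError("need at least 2 beats to build a continuous series")
    if t_end_s is None:
        t_end_s = float(beats.systolic_time_s[-1]) + 1.0 / fs_out_hz
    grid = np.arange(int(round(t_end_s * fs_out_hz))) / fs_out_hz
    beats.grid_time_s = grid
    beats.series["sbp"] = _interp_series(beats.systolic_time_s, beats.sbp_mmHg, grid, kind)
    beats.series["dbp"] = _interp_series(beats.diastolic_time_s, beats.dbp_mmHg, grid, kind)
    if beats.map_mmHg is not None:
        beats.series["map"] = _interp_series(
            beats.systolic_time_s, beats.map_mmHg, grid, kind
        )
    return beats
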