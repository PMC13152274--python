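"""Slow/fast decomposition and slow baseline-oscillation detection.

The dF/F trace is split into a slow component (centred 30 min moving
average, window shrinking at the edges) and a fast residual defined as
``input - slow``, so the decomposition reconstructs the input exactly.
Slow oscillations are local maxima of the slow trace passing three
criteria: minimum height (mean + 2 SD of a quiet clock-referenced window),
minimum peak distance (30 min, taller peak kept on conflict) and minimum
prominence (0.15 x the maximum of the animal's reference proestrous slow
trace).  Each retained peak is bounded by an onset and an offset trough;
trough-to-trough time is the oscillation duration, and the span from the
first onset trough to the last offset trough is the surge profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .baseline import CalciumTrace
from .io import ChannelSeries, seconds_since_start

logger = logging.getLogger(__name__)


@dataclass
class DeconvolvedTrace:
    """Slow (moving-average) and fast (residual) components of a trace."""

    times: np.ndarray
    slow: np.ndarray
    fast: np.ndarray
    meta: dict = field(default_factory=dict)
    window_min: float | None = None  # moving-average window used

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times)))

    def reconstruct(self) -> np.ndarray:
        return self.slow + self.fast


@dataclass
class Oscillation:
    """One slow baseline oscillation (peak with flanking troughs)."""

    peak_time: float
    peak_value: float
    onset_trough_time: float
    offset_trough_time: float
    duration_min: float
    amplitude: float  # peak value minus onset-trough value (dF/F %)
    prominence: float

    def __post_init__(self) -> None:
        if not (self.onset_trough_time < self.peak_time < self.offset_trough_time):
            raise ValueError("troughs must flank the peak")
        if self.duration_min <= 0:
            raise ValueError("duration must be positive")


@dataclass
class SurgeProfile:
    """Aggregate onset/offset/duration of a train of oscillations."""

    oscillations: list
    onset_s: float
    offset_s: float
    total_duration_hr: float
    count: int

    @property
    def defined(self) -> bool:
        return self.count > 0


@dataclass
class DetectionCriteria:
    """Peak-detection criteria for slow oscillations."""

    min_height: float
    min_prominence: float
    min_distance_min: float = 30.0
    quiet_window: tuple[str, str] = ("11:00", "13:00")
    trough_tolerance: float = 0.0
    trough_rule: str = "nearest"  # "nearest" | "argmin"

    def __post_init__(self) -> None:
        if self.min_distance_min <= 0:
            raise ValueError("min_distance must be positive")
        if self.min_prominence < 0:
            raise ValueError("min_prominence must be non-negative")


def moving_average(trace: CalciumTrace, window_min: float = 30.0) -> DeconvolvedTrace:
    """Centred moving mean with edge-shrinking window; fast = input - slow."""
    x = trace.dff
    dt = trace.dt
    w = int(round(window_min * 60.0 / dt))
    if w < 3:
        raise ValueError("moving-average window shorter than 3 samples")
    half = w // 2
    c = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(len(x))
    lo = np.maximum(0, i - half)
    hi = np.minimum(len(x), i + half + 1)
    slow = (c[hi] - c[lo]) / (hi - lo)
    return DeconvolvedTrace(trace.times, slow, x - slow, dict(trace.meta), window_min)


def quiet_window_indices(
    times: np.ndarray, meta: dict, quiet_window: tuple[str, str] = ("11:00", "13:00")
) -> np.ndarray:
    """Sample indices in the quiet clock window; first 2 hr if unanchored."""
    clock_start = meta.get("clock_start")
    if clock_start is None:
        logger.info("no clock anchor; using first 2 hr as quiet reference window")
        lo, hi = times[0], times[0] + 7200.0
    else:
        lo = seconds_since_start(quiet_window[0], clock_start)
        hi = lo + (
            (seconds_since_start(quiet_window[1], quiet_window[0])) or 7200.0
        )
    idx = np.nonzero((times >= lo) & (times < hi))[0]
    if len(idx) == 0:
        raise ValueError("quiet reference window does not overlap the recording")
    return idx


def build_criteria(
    trace: CalciumTrace,
    reference_trace: CalciumTrace | None = None,
    *,
    window_min: float = 30.0,
    min_distance_min: float = 30.0,
    prominence_frac: float = 0.15,
    quiet_window: tuple[str, str] = ("11:00", "13:00"),
    trough_rule: str = "nearest",
) -> DetectionCriteria:
    """Derive detection criteria from the recording and a reference trace.

    Height: mean + 2 SD of the slow trace in the quiet window of *this*
    recording.  Prominence: ``prominence_frac`` x maximum of the slow trace
    of the animal's reference proestrous recording (falls back to this
    recording with a logged warning if none is supplied).
    """
    dec = moving_average(trace, window_min)
    qi = quiet_window_indices(dec.times, trace.meta, quiet_window)
    q = dec.slow[qi]
    min_height = float(np.mean(q) + 2.0 * np.std(q))
    if reference_trace is None:
        logger.warning("no reference proestrous recording; prominence from own trace")
        ref_slow = dec.slow
    else:
        ref_slow = moving_average(reference_trace, window_min).slow
    min_prominence = float(max(0.0, prominence_frac * np.max(ref_slow)))
    return DetectionCriteria(
        min_height=min_height,
        min_prominence=min_prominence,
        min_distance_min=min_distance_min,
        quiet_window=quiet_window,
        trough_tolerance=float(2.0 * np.std(q)),
        trough_rule=trough_rule,
    )


def _is_neighbourhood_min(slow: np.ndarray, i: int, w: int) -> bool:
    lo = max(0, i - w)
    hi = min(len(slow), i + w + 1)
    return slow[i] <= slow[lo:hi].min()


def _nearest_trough(
    slow: np.ndarray, lo: int, hi: int, tol: float, rule: str, from_right: bool, w: int
) -> int:
    """Trough index in [lo, hi): walking away from the peak, the first
    sample that is within ``tol`` of the interval minimum *and* is a
    minimum of its +/- ``w``-sample neighbourhood (so wiggles riding on a
    slope do not qualify); nearest plain crossing of the tolerance level
    if no such sample exists."""
    seg = slow[lo:hi]
    if len(seg) == 0:
        return max(0, min(len(slow) - 1, lo if not from_right else hi - 1))
    if rule == "argmin":
        return lo + int(np.argmin(seg))
    m = seg.min()
    cand = np.nonzero(seg <= m + tol)[0] + lo
    order = cand[::-1] if from_right else cand
    for i in order:
        if _is_neighbourhood_min(slow, int(i), w):
            return int(i)
    return int(order[0])


def detect_oscillations(
    slow: ChannelSeries | DeconvolvedTrace, criteria: DetectionCriteria
) -> list[Oscillation]:
    """Detect slow oscillations on a 30 min moving-average trace.

    Peaks come from :func:`scipy.signal.find_peaks` with the height,
    distance (keep-taller) and prominence criteria.  For each retained
    peak the onset (offset) trough is searched between it and the
    previous (next) retained peak or the recording edge.  A plain
    interval argmin is ill-defined wherever the trace is flat at trough
    level (pre-surge stretches, gaps between separated oscillations), so
    by default the trough is the sample nearest the peak that sits within
    ``trough_tolerance`` of the interval minimum and is a minimum of its
    neighbourhood at the half-peak-spacing scale — in a shared V-shaped
    junction this is the junction minimum for both neighbours, and next
    to a flat stretch it is the oscillation foot.
    ``trough_rule="argmin"`` restores the plain argmin.
    """
    smooth_window_min = None
    if isinstance(slow, DeconvolvedTrace):
        times, y = slow.times, slow.slow
        smooth_window_min = slow.window_min
    else:
        times, y = slow.times, slow.values
    if len(y) < 3:
        return []
    dt = float(np.median(np.diff(times)))
    dist = max(1, int(round(criteria.min_distance_min * 60.0 / dt)))
    peaks, props = find_peaks(
        y,
        height=criteria.min_height,
        distance=dist,
        prominence=criteria.min_prominence if criteria.min_prominence > 0 else None,
    )
    w = max(1, dist // 2)  # nothing narrower than half the peak spacing matters
    out: list[Oscillation] = []
    for j, p in enumerate(peaks):
        lo = int(peaks[j - 1]) + 1 if j > 0 else 0
        hi = int(peaks[j + 1]) if j + 1 < len(peaks) else len(y)
        li = _nearest_trough(
            y, lo, p, criteria.trough_tolerance, criteria.trough_rule,
            from_right=True, w=w,
        )
        ri = _nearest_trough(
            y, p + 1, hi, criteria.trough_tolerance, criteria.trough_rule,
            from_right=False, w=w,
        )
        if smooth_window_min is not None and criteria.trough_rule != "argmin":
            # a centred moving average widens any event adjoining a flat
            # stretch by half the window on each side; undo the widening
            # where the trace is indeed flat beyond the trough
            shift = int(round(smooth_window_min * 60.0 / dt)) // 2
            margin = max(criteria.trough_tolerance, 0.02 * (y[p] - y[li]))
            jl = li - shift
            if shift > 0 and jl >= lo and y[jl] <= y[li] + margin:
                li = min(li + shift, p - 1)
            margin = max(criteria.trough_tolerance, 0.02 * (y[p] - y[ri]))
            jr = ri + shift
            if shift > 0 and jr < hi and y[jr] <= y[ri] + margin:
                ri = max(ri - shift, p + 1)
        prom = float(props["prominences"][j]) if "prominences" in props else float("nan")
        out.append(
            Oscillation(
                peak_time=float(times[p]),
                peak_value=float(y[p]),
                onset_trough_time=float(times[li]),
                offset_trough_time=float(times[ri]),
                duration_min=float(times[ri] - times[li]) / 60.0,
                amplitude=float(y[p] - y[li]),
                prominence=prom,
            )
        )
    return out


def surge_bounds(oscillations: Sequence[Oscillation]) -> SurgeProfile:
    """Onset (first onset trough) to offset (last offset trough) of a train."""
    osc = sorted(oscillations, key=lambda o: o.peak_time)
    if not osc:
        logger.info("no oscillations; surge bounds undefined")
        return SurgeProfile([], float("nan"), float("nan"), float("nan"), 0)
    onset = osc[0].onset_trough_time
    offset = osc[-1].offset_trough_time
    return SurgeProfile(list(osc), onset, offset, (offset - onset) / 3600.0, len(osc))


def compute_auc(trace: CalciumTrace) -> float:
    """Trapezoidal area under the dF/F curve (dF/F % x seconds)."""
    if len(trace.times) < 2:
        raise ValueError("need at least 2 samples for AUC")
    return float(np.trapezoid(trace.dff, trace.times))


def mean_profile(
    traces: Sequence[tuple[np.ndarray, np.ndarray]],
    grid: np.ndarray | None = None,
    n_grid: int = 500,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise mean and SEM of clock-aligned slow traces.

    Traces are (times, values) pairs resampled by linear interpolation to
    a common grid; outside a trace's own support its values are missing
    and the mean/SEM at that point use the traces that are available.
    """
    if not traces:
        raise ValueError("mean_profile needs at least one trace")
    if grid is None:
        lo = min(t[0] for t, _ in traces)
        hi = max(t[-1] for t, _ in traces)
        grid = np.linspace(lo, hi, n_grid)
    stack = np.full((len(traces), len(grid)), np.nan)
    for i, (t, v) in enumerate(traces):
        inside = (grid >= t[0]) & (grid <= t[-1])
        stack[i, inside] = np.interp(grid[inside], t, v)
    n = np.sum(np.isfinite(stack), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    return grid, mean, sem
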