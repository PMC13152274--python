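"""Detection of statistically significant fast calcium transients.

The residual (fast) trace is z-scored so its median is zero and its
standard deviation one, then thresholded at a grid of levels
k = 1, 1.2, ..., 4.  At each k, maximal runs of samples above +k are the
positive candidate transients (T_pos) and runs below -k the negative ones
(T_neg).  Negative-going excursions of a given duration can only be noise,
so for a candidate duration s the ratio ``n_neg / n_pos`` of counts of
candidates at least s samples long estimates the false-positive rate of
positive candidates of that duration; when the ratio is below 0.05 those
positive candidates are accepted.  A sample is significant if any (k, s)
combination accepts it, and maximal runs of the final mask are the
reported transients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_K_GRID = np.round(np.arange(1.0, 4.0 + 1e-9, 0.2), 10)


@dataclass
class ZTrace:
    """Median-centred, SD-scaled residual trace."""

    times: np.ndarray
    z: np.ndarray

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times)))


@dataclass
class Segment:
    """Maximal run of samples beyond a threshold (half-open indices)."""

    start_index: int
    end_index: int
    sign: str  # "+" or "-"
    threshold: float

    @property
    def size(self) -> int:
        return self.end_index - self.start_index


@dataclass
class Transient:
    """One significant positive transient."""

    start_time: float
    end_time: float
    duration_s: float
    amplitude: float  # max residual dF/F (%) within the event

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")


@dataclass
class TransientStats:
    """Per-recording transient summary (Hz, seconds, dF/F %)."""

    frequency_hz: float
    mean_duration_s: float
    mean_amplitude: float
    count: int = 0


def zscore_median(residual_times: np.ndarray, residual: np.ndarray) -> ZTrace:
    """z = (x - median(x)) / SD(x) over the full residual trace."""
    x = np.asarray(residual, dtype=float)
    sd = float(np.std(x))
    if sd == 0:
        raise ValueError("constant residual has no z-score")
    return ZTrace(np.asarray(residual_times, float), (x - np.median(x)) / sd)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, end) indices of maximal True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def threshold_segments(z: ZTrace, k: float, sign: str) -> list[Segment]:
    """Maximal runs with z > k (sign '+') or z < -k (sign '-')."""
    if k <= 0:
        raise ValueError("threshold must be positive")
    if sign not in ("+", "-"):
        raise ValueError("sign must be '+' or '-'")
    mask = z.z > k if sign == "+" else z.z < -k
    return [Segment(s, e, sign, k) for s, e in _runs(mask)]


def significance_mask(
    z: np.ndarray,
    k_grid: np.ndarray | None = None,
    fp_ratio: float = 0.05,
    size_comparison: str = "gte",
) -> np.ndarray:
    """Boolean mask of samples significant under any (k, s) combination.

    Candidate sizes s are the distinct observed positive-segment sizes
    (each candidate transient is assessed at its own duration).  With the
    default inclusive counting this is equivalent to sweeping every
    integer size: both the accepted set and n_pos are constant between
    consecutive observed positive sizes, and n_neg is smallest at the
    upper end of each such interval, so nothing is missed.
    ``size_comparison`` selects whether "sizes larger than s" counts a
    segment of exactly size s ("gte", default) or not ("gt"; a segment
    then never supports its own size).
    """
    if k_grid is None:
        k_grid = DEFAULT_K_GRID
    k_grid = np.asarray(k_grid, dtype=float)
    if len(k_grid) == 0 or np.any(np.diff(k_grid) <= 0):
        raise ValueError("k_grid must be non-empty and ascending")
    if size_comparison not in ("gte", "gt"):
        raise ValueError("size_comparison must be 'gte' or 'gt'")
    strict = size_comparison == "gt"
    mask = np.zeros(len(z), dtype=bool)
    for k in k_grid:
        pos = _runs(z > k)
        neg = _runs(z < -k)
        if not pos:
            continue
        pos_sizes = np.array([e - s for s, e in pos])
        neg_sizes = np.array([e - s for s, e in neg]) if neg else np.empty(0, int)
        for s in np.unique(pos_sizes):
            if strict:
                n_pos = int(np.sum(pos_sizes > s))
                n_neg = int(np.sum(neg_sizes > s))
            else:
                n_pos = int(np.sum(pos_sizes >= s))
                n_neg = int(np.sum(neg_sizes >= s))
            if n_pos > 0 and n_neg / n_pos < fp_ratio:
                for (a, b), sz in zip(pos, pos_sizes):
                    if (sz > s) if strict else (sz >= s):
                        mask[a:b] = True
    return mask


def detect_significant(
    z: ZTrace,
    k_grid: np.ndarray | None = None,
    fp_ratio: float = 0.05,
    *,
    residual: np.ndarray | None = None,
    size_comparison: str = "gte",
) -> tuple[np.ndarray, list[Transient]]:
    """Run the iterated-threshold procedure and merge accepted samples.

    Returns the significance mask and the transients (maximal runs of the
    mask).  Amplitudes are measured on ``residual`` (the dF/F residual
    before z-scoring) when given, so they are in dF/F %; otherwise on z.
    """
    mask = significance_mask(z.z, k_grid, fp_ratio, size_comparison)
    amp_src = z.z if residual is None else np.asarray(residual, float)
    dt = z.dt if len(z.times) > 1 else 1.0
    transients = [
        Transient(
            start_time=float(z.times[a]),
            end_time=float(z.times[b - 1] + dt),
            duration_s=float((b - a) * dt),
            amplitude=float(np.max(amp_src[a:b])),
        )
        for a, b in _runs(mask)
    ]
    return mask, transients


def transient_stats(transients: list[Transient], recording_duration_s: float) -> TransientStats:
    """Frequency (count / duration), mean duration and mean amplitude."""
    if recording_duration_s <= 0:
        raise ValueError("recording duration must be positive")
    n = len(transients)
    if n == 0:
        return TransientStats(0.0, float("nan"), float("nan"), 0)
    return TransientStats(
        frequency_hz=n / recording_duration_s,
        mean_duration_s=float(np.mean([t.duration_s for t in transients])),
        mean_amplitude=float(np.mean([t.amplitude for t in transients])),
        count=n,
    )


def detect_transients(
    times: np.ndarray,
    fast: np.ndarray,
    *,
    recorrect_window_s: float = 400.0,
    k_grid: np.ndarray | None = None,
    fp_ratio: float = 0.05,
    size_comparison: str = "gte",
) -> tuple[np.ndarray, list[Transient], TransientStats, np.ndarray]:
    """Full transient stage: 400 s re-correction, z-score, detect, summarise.

    Returns (mask, transients, stats, corrected residual).
    """
    from .baseline import correct_residual
    from .io import ChannelSeries

    resid = correct_residual(ChannelSeries(times, fast), window_s=recorrect_window_s)
    z = zscore_median(resid.times, resid.values)
    mask, transients = detect_significant(
        z, k_grid, fp_ratio, residual=resid.values, size_comparison=size_comparison
    )
    duration = float(times[-1] - times[0]) if len(times) > 1 else 0.0
    stats = transient_stats(transients, duration) if duration > 0 else TransientStats(
        0.0, float("nan"), float("nan"), 0
    )
    return mask, transients, stats, resid.values
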