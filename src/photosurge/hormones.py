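"""Alignment of sparse LH blood samples with the detected neural surge."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .deconvolve import SurgeProfile
from .io import LHSeries

logger = logging.getLogger(__name__)


@dataclass
class SurgeAlignment:
    """Timing of the LH peak relative to the first neural oscillation."""

    lh_peak_time_hr: float
    lh_peak_value: float
    first_oscillation_time_hr: float
    onset_to_lh_peak_lag_hr: float
    post_lh_activity_duration_hr: float | None = None
    negative_lag: bool = False


def lh_peak(series: LHSeries) -> tuple[float, float]:
    """Time (hr) and value of the maximum LH sample; earliest on ties.

    Sampling every 2-4 hr cannot support sub-sample peak estimation, so
    the peak is the raw sample argmax (no interpolation).
    """
    if len(series.values) == 0:
        raise ValueError("empty LH series")
    i = int(np.argmax(series.values))  # argmax returns the first maximum
    return float(series.times_hr[i]), float(series.values[i])


def lh_decline_time(series: LHSeries, decline_frac: float = 0.5) -> float | None:
    """First post-peak sample below ``decline_frac`` of the peak value."""
    i = int(np.argmax(series.values))
    thresh = decline_frac * series.values[i]
    after = np.nonzero(series.values[i + 1 :] < thresh)[0]
    if len(after) == 0:
        return None
    return float(series.times_hr[i + 1 + after[0]])


def align_surge(
    surge: SurgeProfile, lh: LHSeries, decline_frac: float = 0.5
) -> SurgeAlignment:
    """Lag from the first oscillation's onset trough to the LH peak (hours).

    Both series must share the same clock (hours since recording start).
    Negative lags (LH peak before neural onset) are allowed and flagged.
    When an LH decline time (first post-peak sample below half peak) is
    observable, the duration of neural activity continuing past it is also
    reported.
    """
    if surge.count < 1:
        raise ValueError("surge has no oscillations; alignment undefined")
    peak_t, peak_v = lh_peak(lh)
    onset_hr = surge.onset_s / 3600.0
    lag = peak_t - onset_hr
    if lag < 0:
        logger.warning("LH peak precedes neural onset (lag %.2f hr)", lag)
    decline = lh_decline_time(lh, decline_frac)
    post = None
    if decline is not None:
        post = surge.offset_s / 3600.0 - decline
    return SurgeAlignment(
        lh_peak_time_hr=peak_t,
        lh_peak_value=peak_v,
        first_oscillation_time_hr=onset_hr,
        onset_to_lh_peak_lag_hr=lag,
        post_lh_activity_duration_hr=post,
        negative_lag=lag < 0,
    )
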