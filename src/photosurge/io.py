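"""Reading, validation and preprocessing of dual-channel photometry data.

Recordings are acquired at 10 Hz in a scheduled mode (light on for 2 s,
off for 2 s) with a calcium-dependent 465 nm channel and a calcium-
independent 405 nm isosbestic channel.  This module collapses each 2 s
on-epoch to a single averaged point (one point per 4 s on/off period) and
subtracts the isosbestic channel to isolate calcium-dependent fluorescence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGES = (
    "metestrus",
    "diestrus",
    "proestrus",
    "estrus",
    "OVX",
    "OVX+E2",
    "OVX+E2+EB",
    "OVX+E2+EB-surge",
    "unknown",
)


def clock_to_hours(clock: str) -> float:
    """Convert an ``HH:MM`` wall-clock string to hours since midnight."""
    hh, mm = clock.split(":")
    return int(hh) + int(mm) / 60.0


def seconds_since_start(clock: str, clock_start: str) -> float:
    """Seconds from recording start to the *next* occurrence of ``clock``."""
    delta = (clock_to_hours(clock) - clock_to_hours(clock_start)) % 24.0
    return delta * 3600.0


@dataclass
class RawRecording:
    """Dual-channel scheduled-mode photometry recording.

    ``timestamps`` are seconds since recording start at the nominal 10 Hz
    acquisition rate (off-epoch samples may be absent).  ``clock_start``
    anchors the recording to wall-clock time for clock-relative logic
    (quiet reference window, lights-off).
    """

    timestamps: np.ndarray
    signal_465: np.ndarray
    signal_405: np.ndarray
    clock_start: str = "11:00"
    on_s: float = 2.0
    off_s: float = 2.0
    lights_on: str = "07:00"
    lights_off: str = "19:00"
    animal_id: str = "unknown"
    stage: str = "unknown"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.signal_465 = np.asarray(self.signal_465, dtype=float)
        self.signal_405 = np.asarray(self.signal_405, dtype=float)
        if self.timestamps.ndim != 1:
            raise ValueError("timestamps must be 1-D")
        if not (len(self.timestamps) == len(self.signal_465) == len(self.signal_405)):
            raise ValueError("channel lengths do not match timestamps")
        if len(self.timestamps) and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.on_s <= 0 or self.off_s < 0:
            raise ValueError("schedule durations must be positive")
        if not (np.all(np.isfinite(self.signal_465)) and np.all(np.isfinite(self.signal_405))):
            raise ValueError("fluorescence values must be finite")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")

    @property
    def meta(self) -> dict:
        return {
            "clock_start": self.clock_start,
            "lights_on": self.lights_on,
            "lights_off": self.lights_off,
            "animal_id": self.animal_id,
            "stage": self.stage,
        }


@dataclass
class ChannelSeries:
    """Uniformly spaced single-channel series (one point per on-epoch)."""

    times: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            raise ValueError("need at least 2 samples for a sampling interval")
        return float(np.median(np.diff(self.times)))


@dataclass
class LHSeries:
    """Sparse luteinizing-hormone samples from tail-tip bleeding (ng/mL)."""

    times_hr: np.ndarray
    values: np.ndarray
    assay_sensitivity: float = 0.07

    def __post_init__(self) -> None:
        self.times_hr = np.asarray(self.times_hr, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times_hr) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times_hr) > 1 and np.any(np.diff(self.times_hr) <= 0):
            raise ValueError("LH sample times must be increasing")
        if np.any(self.values < 0):
            raise ValueError("LH concentrations cannot be negative")
        n_below = int(np.sum(self.values < self.assay_sensitivity))
        if n_below:
            logger.warning(
                "%d LH sample(s) below assay sensitivity (%.2f ng/mL); retained",
                n_below,
                self.assay_sensitivity,
            )

    @property
    def below_sensitivity(self) -> np.ndarray:
        return self.values < self.assay_sensitivity


DEFAULT_COLUMNS = {"time": "time", "465": "465", "405": "405"}


def read_photometry(
    path,
    meta: Mapping | None = None,
    column_map: Mapping[str, str] | None = None,
) -> RawRecording:
    """Read a delimited-text photometry file into a :class:`RawRecording`.

    Rows with a non-finite value in either channel (the off-epoch sentinel
    rows written by the simulator, or hardware dropouts) are dropped with a
    logged count.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        raise ValueError(f"{path}: empty photometry file")
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    t = df[cols["time"]].to_numpy(dtype=float)
    s465 = df[cols["465"]].to_numpy(dtype=float)
    s405 = df[cols["405"]].to_numpy(dtype=float)
    keep = np.isfinite(s465) & np.isfinite(s405) & np.isfinite(t)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("%s: dropped %d row(s) with non-finite values", path, n_drop)
    t, s465, s405 = t[keep], s465[keep], s405[keep]
    if len(t) == 0:
        raise ValueError(f"{path}: no finite rows")
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time column is not strictly increasing")
    return RawRecording(t, s465, s405, **dict(meta or {}))


def save_recording(raw: RawRecording, path, include_off_epochs: bool = True) -> None:
    """Write a recording as CSV (columns time, 465, 405).

    With ``include_off_epochs`` the full nominal 10 Hz grid is written, with
    NaN sentinel rows for samples taken while the excitation light was off,
    mimicking scheduled-mode acquisition files; :func:`read_photometry`
    skips those rows on the way back in.
    """
    if include_off_epochs:
        fs = 10.0
        period = raw.on_s + raw.off_s
        t_full = np.arange(0.0, raw.timestamps[-1] + 1.0 / fs / 2, 1.0 / fs)
        s465 = np.full_like(t_full, np.nan)
        s405 = np.full_like(t_full, np.nan)
        idx = np.round(raw.timestamps * fs).astype(int)
        idx = np.clip(idx, 0, len(t_full) - 1)
        s465[idx] = raw.signal_465
        s405[idx] = raw.signal_405
        on = (t_full % period) < raw.on_s
        s465[~on] = np.nan
        s405[~on] = np.nan
        df = pd.DataFrame({"time": t_full, "465": s465, "405": s405})
    else:
        df = pd.DataFrame({"time": raw.timestamps, "465": raw.signal_465, "405": raw.signal_405})
    df.to_csv(path, index=False)


def downsample_scheduled(raw: RawRecording) -> tuple[ChannelSeries, ChannelSeries]:
    """Average each 2 s on-epoch into a single point per channel.

    Epochs are assigned by timestamp (half-open ``[start, start + on_s)``)
    rather than sample count, so dropped samples do not desynchronise the
    schedule.  The output point sits at the epoch centre (start + on_s/2);
    a partial trailing epoch is dropped.
    """
    period = raw.on_s + raw.off_s
    t = raw.timestamps
    if len(t) == 0:
        raise ValueError("empty recording")
    slack = 1.5 * float(np.median(np.diff(t))) if len(t) > 1 else raw.on_s / 10.0
    n_epochs = int(np.floor((t[-1] + 1e-9) / period)) + 1
    # complete on-epochs only: the on window must end at or before the last sample
    while n_epochs > 0 and (n_epochs - 1) * period + raw.on_s > t[-1] + slack:
        n_epochs -= 1
    if n_epochs < 1:
        raise ValueError("no complete on-epoch in recording")
    epoch = np.floor(t / period).astype(int)
    in_on = (t - epoch * period) < raw.on_s
    valid = in_on & (epoch < n_epochs)
    e = epoch[valid]
    sums465 = np.bincount(e, weights=raw.signal_465[valid], minlength=n_epochs)
    sums405 = np.bincount(e, weights=raw.signal_405[valid], minlength=n_epochs)
    counts = np.bincount(e, minlength=n_epochs)
    nonempty = counts > 0
    if not np.all(nonempty):
        logger.info("dropped %d empty on-epoch(s)", int((~nonempty).sum()))
    centres = np.arange(n_epochs) * period + raw.on_s / 2.0
    times = centres[nonempty]
    v465 = sums465[nonempty] / counts[nonempty]
    v405 = sums405[nonempty] / counts[nonempty]
    meta = raw.meta
    return ChannelSeries(times, v465, dict(meta)), ChannelSeries(times, v405, dict(meta))


def subtract_isosbestic(
    sig465: ChannelSeries, sig405: ChannelSeries, fit_scale: bool = False
) -> ChannelSeries:
    """Subtract the isosbestic 405 nm channel from the 465 nm channel.

    The default is plain pointwise subtraction.  ``fit_scale`` rescales the
    405 channel to the 465 channel by least squares first (non-default).
    """
    if len(sig465.times) != len(sig405.times) or not np.allclose(
        sig465.times, sig405.times
    ):
        raise ValueError("channel time grids do not match")
    ref = sig405.values
    if fit_scale:
        A = np.column_stack([ref, np.ones_like(ref)])
        coef, *_ = np.linalg.lstsq(A, sig465.values, rcond=None)
        ref = A @ coef
    return ChannelSeries(sig465.times, sig465.values - ref, dict(sig465.meta))


def read_lh(path, assay_sensitivity: float = 0.07) -> LHSeries:
    """Read a two-column (time_hr, lh_ng_ml) delimited text file."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time, LH)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    return LHSeries(t, v, assay_sensitivity=assay_sensitivity)


def save_channel(series: ChannelSeries, path, value_name: str = "value") -> None:
    pd.DataFrame({"time_s": series.times, value_name: series.values}).to_csv(
        path, index=False
    )


def read_channel(path, value_name: str | None = None, meta: Mapping | None = None) -> ChannelSeries:
    df = pd.read_csv(path)
    vcol = value_name or df.columns[1]
    return ChannelSeries(
        df["time_s"].to_numpy(float), df[vcol].to_numpy(float), dict(meta or {})
    )
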