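"""Photobleaching correction and dF/F conversion.

Long GCaMP recordings decay slowly as the fluorophore bleaches.  The decay
is modelled per overlapping window as a single exponential plus offset,
``F_fit(t) = a*exp(-t/tau) + c``, fitted with a redescending robust loss
(Cauchy) plus iterative positive-outlier clipping so that calcium events
— which deflect fluorescence upward only — do not drag the baseline.  Each window's fitted
curve is evaluated across the window and the overlapping evaluations are
cross-faded with triangular weights into one continuous baseline; this
keeps the stitched baseline faithful to curvature at the window scale,
which centre-point interpolation between windows cannot do when the decay
time constant is shorter than the window hop.

The same operation serves two stages of the pipeline: a 6 hr window for
the dF/F baseline and a 400 s window for re-flattening the residual trace
before transient detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .io import ChannelSeries

logger = logging.getLogger(__name__)


@dataclass
class BleachModel:
    """Stitched bleaching baseline for one series."""

    window_s: float
    overlap: float
    times: np.ndarray
    baseline: np.ndarray
    window_params: list = field(default_factory=list)  # (t0, params-or-None)

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window length must be positive")
        if not np.all(np.isfinite(self.baseline)):
            raise ValueError("stitched baseline must be finite")


@dataclass
class CalciumTrace:
    """dF/F (%) series with clock/stage metadata carried through."""

    times: np.ndarray
    dff: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if len(self.times) != len(self.dff):
            raise ValueError("times and dff must have equal length")
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dF/F must be finite")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times)))

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])


def _exp1(t, p):
    a, tau, c = p
    return a * np.exp(-t / tau) + c


def _exp2(t, p):
    a1, tau1, a2, tau2, c = p
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + c


def _centered_ma(x: np.ndarray, half: int) -> np.ndarray:
    """Centred moving mean with edge-shrinking window."""
    c = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(len(x))
    lo = np.maximum(0, i - half)
    hi = np.minimum(len(x), i + half + 1)
    return (c[hi] - c[lo]) / (hi - lo)


def _ma_gain(tau: float, width_s: float) -> float:
    """Gain of a width-``width_s`` moving average on exp(-t/tau): the
    averaged exponential stays in-family with amplitude scaled by
    (2 tau / W) sinh(W / 2 tau)."""
    x = width_s / (2.0 * tau)
    return float(np.sinh(x) / x)


def _fit_one_window(t, y, window_s, model, ma_width_s=0.0, clip_iters=2):
    """Robust exponential fit inside one window; None on failure.

    When ``ma_width_s`` > 0 the data have been pre-averaged with a moving
    mean of that width and the model amplitudes carry the corresponding
    analytic gain, so the returned parameters describe the *unsmoothed*
    exponential.
    """
    t0 = t[0]
    tl = t - t0
    span = max(y.max() - y.min(), 1e-12)
    scale = max(0.02 * span, 1e-9 * max(abs(y).max(), 1.0))
    gain = (lambda tau: _ma_gain(tau, ma_width_s)) if ma_width_s > 0 else (lambda tau: 1.0)
    if model == "double":
        p0 = [0.7 * (y[0] - y[-1]), window_s / 3.0, 0.3 * (y[0] - y[-1]), window_s, y[-1]]
        lo = [-10 * span, window_s / 50.0, -10 * span, window_s / 50.0, -np.inf]
        hi = [10 * span, 1e8, 10 * span, 1e8, np.inf]

        def fun(p, tl_, y_):
            a1, tau1, a2, tau2, c = p
            return (
                a1 * gain(tau1) * np.exp(-tl_ / tau1)
                + a2 * gain(tau2) * np.exp(-tl_ / tau2)
                + c
                - y_
            )

        kwargs = {}
    else:
        p0 = [y[0] - y[-1], window_s / 3.0, y[-1]]
        lo = [-10 * span, window_s / 50.0, -np.inf]
        hi = [10 * span, 1e8, np.inf]

        def fun(p, tl_, y_):
            a, tau, c = p
            return a * gain(tau) * np.exp(-tl_ / tau) + c - y_

        def jac(p, tl_):
            a, tau, _c = p
            e = np.exp(-tl_ / tau)
            g = gain(tau)
            if ma_width_s > 0:
                x = ma_width_s / (2.0 * tau)
                # d/dtau of sinh(x)/x with x = W/(2 tau)
                dg = (np.cosh(x) / x - np.sinh(x) / x**2) * (-ma_width_s / (2.0 * tau**2))
            else:
                dg = 0.0
            return np.column_stack(
                [g * e, a * (dg * e + g * tl_ / tau**2 * e), np.ones_like(tl_)]
            )

        kwargs = {"jac": jac}
    p0 = np.clip(p0, lo, hi)

    def solve(tl_s, y_s, start):
        def fun_s(p):
            return fun(p, tl_s, y_s)

        kw = {}
        if "jac" in kwargs:
            kw["jac"] = lambda p: kwargs["jac"](p, tl_s)
        return least_squares(
            fun_s, start, bounds=(lo, hi), loss="cauchy", f_scale=scale,
            xtol=1e-7, ftol=1e-7, max_nfev=200, **kw,
        )

    try:
        res = solve(tl, y, p0)
        # calcium events deflect fluorescence upward only, so the bleaching
        # baseline is a lower envelope: iteratively drop strong positive
        # outliers and refit
        for _ in range(clip_iters):
            r = -fun(res.x, tl, y)  # y minus model
            sigma = 1.4826 * np.median(np.abs(r - np.median(r)))
            if sigma <= 0:
                break
            keep = r < 2.5 * sigma
            if keep.sum() < max(8, 0.3 * len(y)) or keep.all():
                break
            res = solve(tl[keep], y[keep], res.x)
    except Exception:  # pragma: no cover - scipy failure path
        return None
    if not np.all(np.isfinite(res.x)):
        return None
    return res.x


def fit_window_exponential(
    series: ChannelSeries,
    window_s: float = 21600.0,
    overlap: float = 0.5,
    model: str = "single",
    presmooth_s: float = 0.0,
    clip_iters: int = 2,
) -> BleachModel:
    """Fit overlapping-window exponentials and stitch a continuous baseline.

    Windows of length ``window_s`` advance by ``window_s * (1 - overlap)``;
    a final window is pinned to the end of the series so every sample is
    covered.  Series shorter than two windows get a single global fit.
    Windows whose fit fails fall back to the window median (logged).

    ``presmooth_s`` > 0 pre-averages the series with a centred moving mean
    of that width before fitting; a moving average over one full period
    annihilates periodic structure (e.g. the ~90 min surge oscillations)
    while the averaged exponential stays in-family and its amplitude gain
    is corrected analytically, so the stitched baseline still describes
    the unsmoothed decay.  Samples whose averaging window is truncated at
    the series ends are excluded from the fits.
    """
    t = series.times
    y = series.values
    if len(t) == 0:
        raise ValueError("empty series")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")

    y_fit = y
    ma_width_s = 0.0
    edge_lo, edge_hi = t[0] - 1.0, t[-1] + 1.0
    if presmooth_s > 0 and len(t) > 4:
        dt = float(np.median(np.diff(t)))
        half = int(round(presmooth_s / 2.0 / dt))
        if half >= 1 and 2 * half + 1 < len(t):
            y_fit = _centered_ma(y, half)
            ma_width_s = (2 * half + 1) * dt
            edge_lo = t[0] + half * dt
            edge_hi = t[-1] - half * dt

    span = t[-1] - t[0]
    hop = window_s * (1.0 - overlap)
    if span <= window_s * (2.0 - overlap) or len(t) < 8:
        starts = [t[0]]
        window_s_eff = max(span, window_s)
    else:
        starts = list(np.arange(t[0], t[-1] - window_s + hop / 2, hop))
        if starts[-1] + window_s < t[-1] - 1e-9:
            starts.append(t[-1] - window_s)
        window_s_eff = window_s

    num = np.zeros_like(y)
    den = np.zeros_like(y)
    params = []
    half_w = window_s_eff / 2.0
    for t0 in starts:
        sel = (t >= t0 - 1e-9) & (t <= t0 + window_s_eff + 1e-9)
        fit_sel = sel & (t >= edge_lo) & (t <= edge_hi)
        if fit_sel.sum() < 4:
            fit_sel = sel
            use_ma = False
        else:
            use_ma = ma_width_s > 0
        src = y_fit if use_ma else y
        if sel.sum() < 4:
            # too few points for a 3-parameter fit: constant window
            p = None
        else:
            p = _fit_one_window(
                t[fit_sel], src[fit_sel], window_s_eff, model,
                ma_width_s if use_ma else 0.0, clip_iters,
            )
        if p is None:
            if sel.sum() >= 4:
                logger.warning("bleach fit failed in window at t0=%.0f s; using median", t0)
            fitted = np.full(sel.sum(), np.median(y[sel]))
        else:
            fun = _exp2 if model == "double" else _exp1
            fitted = fun(t[sel] - t[fit_sel][0], p)
        params.append((float(t0), None if p is None else np.asarray(p)))
        centre = t0 + half_w
        w = np.maximum(1e-3, 1.0 - np.abs(t[sel] - centre) / half_w)
        num[sel] += w * fitted
        den[sel] += w
    if np.any(den == 0):  # pragma: no cover - starts always tile the series
        raise RuntimeError("baseline windows failed to cover the series")
    return BleachModel(window_s, overlap, t.copy(), num / den, params)


def compute_dff(series: ChannelSeries, model: BleachModel) -> CalciumTrace:
    """Express fluorescence as percent change around the bleaching baseline:
    ``dF/F = (F - F_baseline) / F_baseline * 100``."""
    if len(model.baseline) != len(series.values):
        raise ValueError("baseline and series lengths differ")
    if np.any(model.baseline <= 0):
        raise ValueError(
            "non-positive baseline; bleach fit failed or input is pathological"
        )
    dff = (series.values - model.baseline) / model.baseline * 100.0
    return CalciumTrace(series.times, dff, dict(series.meta))


def correct_residual(series: ChannelSeries, window_s: float = 400.0) -> ChannelSeries:
    """Short-window exponential re-correction of a residual trace.

    Used before transient detection to flatten residual baseline drift at
    the few-hundred-second scale.  Unlike :func:`compute_dff` this is a
    subtraction (the residual is already in dF/F % units around zero).
    """
    model = fit_window_exponential(series, window_s=window_s, clip_iters=1)
    return ChannelSeries(series.times, series.values - model.baseline, dict(series.meta))
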