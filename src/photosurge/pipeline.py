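"""End-to-end orchestration: raw recording to per-recording summary.

The processing order is: down-sample the scheduled acquisition, subtract
the isosbestic channel, fit and remove the 6 hr-window bleaching
baseline, express as dF/F (%), compute the trapezoidal AUC, split into a
30 min moving-average slow trace plus fast residual, detect slow
oscillations and surge bounds on the slow trace, and detect significant
transients on the re-corrected fast residual.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import baseline as bl
from . import deconvolve as dc
from . import transients as tr
from .io import ChannelSeries, RawRecording, downsample_scheduled, save_channel, subtract_isosbestic

logger = logging.getLogger(__name__)


@dataclass
class BleachConfig:
    window_s: float = 21600.0
    overlap: float = 0.5
    model: str = "single"
    # optional pre-averaging width for the fit; averaging over one
    # oscillation period cancels periodic structure out of the bleaching
    # estimate, at the price of treating a sustained surge-length
    # elevation as baseline (off by default)
    presmooth_s: float = 0.0


@dataclass
class OscConfig:
    window_min: float = 30.0
    min_distance_min: float = 30.0
    prominence_frac: float = 0.15
    quiet_window: tuple[str, str] = ("11:00", "13:00")
    trough_rule: str = "nearest"


@dataclass
class TransConfig:
    window_s: float = 400.0
    k_min: float = 1.0
    k_max: float = 4.0
    k_step: float = 0.2
    fp_ratio: float = 0.05
    size_comparison: str = "gte"

    @property
    def k_grid(self) -> np.ndarray:
        return np.round(np.arange(self.k_min, self.k_max + 1e-9, self.k_step), 10)


@dataclass
class PipelineConfig:
    bleach: BleachConfig = field(default_factory=BleachConfig)
    osc: OscConfig = field(default_factory=OscConfig)
    trans: TransConfig = field(default_factory=TransConfig)
    subtract_fit_scale: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        cfg = cls()
        for section, obj in (("bleach", cfg.bleach), ("osc", cfg.osc), ("trans", cfg.trans)):
            for key, val in (d.get(section) or {}).items():
                if not hasattr(obj, key):
                    raise ValueError(f"unknown config key {section}.{key}")
                setattr(obj, key, tuple(val) if key == "quiet_window" else val)
        if "subtract_fit_scale" in d:
            cfg.subtract_fit_scale = bool(d["subtract_fit_scale"])
        return cfg

    def provenance(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class StageSummary:
    animal_id: str
    stage: str
    auc: float
    oscillation_count: int
    mean_oscillation_duration_min: float
    mean_oscillation_amplitude: float
    surge_total_duration_hr: float
    transient_frequency_hz: float
    transient_mean_duration_s: float
    transient_mean_amplitude: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(self)])


@dataclass
class PipelineResult:
    summary: StageSummary
    trace: bl.CalciumTrace
    deconvolved: dc.DeconvolvedTrace
    oscillations: list
    surge: dc.SurgeProfile
    transients: list
    transient_stats: tr.TransientStats
    transient_mask: np.ndarray
    residual: np.ndarray
    criteria: dc.DetectionCriteria
    provenance: dict


def preprocess(raw: RawRecording, config: PipelineConfig | None = None) -> bl.CalciumTrace:
    """Down-sample, subtract isosbestic, bleach-correct, express as dF/F."""
    config = config or PipelineConfig()
    s465, s405 = downsample_scheduled(raw)
    sig = subtract_isosbestic(s465, s405, fit_scale=config.subtract_fit_scale)
    model = bl.fit_window_exponential(
        sig, window_s=config.bleach.window_s, overlap=config.bleach.overlap,
        model=config.bleach.model, presmooth_s=config.bleach.presmooth_s,
    )
    return bl.compute_dff(sig, model)


def run_pipeline(
    raw: RawRecording,
    config: PipelineConfig | None = None,
    reference_trace: bl.CalciumTrace | None = None,
    outdir=None,
) -> PipelineResult:
    """Run the full analysis on one recording.

    ``reference_trace`` is the same animal's proestrous dF/F trace used
    for the prominence criterion; without it the recording's own trace is
    used (logged fallback).  Deterministic given inputs and config; when
    ``outdir`` is given, all intermediate artefacts and a provenance log
    are written there.
    """
    config = config or PipelineConfig()
    trace = preprocess(raw, config)
    auc = dc.compute_auc(trace)
    dec = dc.moving_average(trace, config.osc.window_min)
    criteria = dc.build_criteria(
        trace,
        reference_trace,
        window_min=config.osc.window_min,
        min_distance_min=config.osc.min_distance_min,
        prominence_frac=config.osc.prominence_frac,
        quiet_window=config.osc.quiet_window,
        trough_rule=config.osc.trough_rule,
    )
    oscillations = dc.detect_oscillations(dec, criteria)
    surge = dc.surge_bounds(oscillations)
    mask, transients, tstats, residual = tr.detect_transients(
        dec.times,
        dec.fast,
        recorrect_window_s=config.trans.window_s,
        k_grid=config.trans.k_grid,
        fp_ratio=config.trans.fp_ratio,
        size_comparison=config.trans.size_comparison,
    )
    summary = StageSummary(
        animal_id=raw.animal_id,
        stage=raw.stage,
        auc=auc,
        oscillation_count=surge.count,
        mean_oscillation_duration_min=(
            float(np.mean([o.duration_min for o in oscillations])) if oscillations else float("nan")
        ),
        mean_oscillation_amplitude=(
            float(np.mean([o.amplitude for o in oscillations])) if oscillations else float("nan")
        ),
        surge_total_duration_hr=surge.total_duration_hr,
        transient_frequency_hz=tstats.frequency_hz,
        transient_mean_duration_s=tstats.mean_duration_s,
        transient_mean_amplitude=tstats.mean_amplitude,
    )
    result = PipelineResult(
        summary=summary,
        trace=trace,
        deconvolved=dec,
        oscillations=oscillations,
        surge=surge,
        transients=transients,
        transient_stats=tstats,
        transient_mask=mask,
        residual=residual,
        criteria=criteria,
        provenance={
            "config": config.provenance(),
            "criteria": dataclasses.asdict(criteria),
            "animal_id": raw.animal_id,
            "stage": raw.stage,
        },
    )
    if outdir is not None:
        _export(result, Path(outdir))
    return result


def _export(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    save_channel(
        ChannelSeries(result.trace.times, result.trace.dff), outdir / "trace.csv", "dff_percent"
    )
    pd.DataFrame(
        {
            "time_s": result.deconvolved.times,
            "slow": result.deconvolved.slow,
            "fast": result.deconvolved.fast,
        }
    ).to_csv(outdir / "deconvolved.csv", index=False)
    pd.DataFrame(
        [
            {
                "peak_time_s": o.peak_time,
                "onset_s": o.onset_trough_time,
                "offset_s": o.offset_trough_time,
                "duration_min": o.duration_min,
                "amplitude": o.amplitude,
                "prominence": o.prominence,
            }
            for o in result.oscillations
        ]
    ).to_csv(outdir / "oscillations.csv", index=False)
    with open(outdir / "surge.json", "w") as fh:
        json.dump(
            {
                "onset_s": result.surge.onset_s,
                "offset_s": result.surge.offset_s,
                "total_duration_hr": result.surge.total_duration_hr,
                "count": result.surge.count,
            },
            fh,
            indent=1,
        )
    pd.DataFrame(
        [
            {
                "start_s": t.start_time,
                "end_s": t.end_time,
                "duration_s": t.duration_s,
                "amplitude_dff": t.amplitude,
            }
            for t in result.transients
        ]
    ).to_csv(outdir / "transients.csv", index=False)
    result.summary.to_frame().to_csv(outdir / "summary.csv", index=False)
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=1, default=str)


def overlay_cohorts(
    meanA: tuple[np.ndarray, np.ndarray],
    meanB: tuple[np.ndarray, np.ndarray],
    grid: np.ndarray | None = None,
    n_grid: int = 500,
) -> pd.DataFrame:
    """Clock-aligned two-cohort overlay table for plotting/export."""
    (ta, va), (tb, vb) = meanA, meanB
    lo, hi = max(ta[0], tb[0]), min(ta[-1], tb[-1])
    if lo >= hi:
        raise ValueError("cohort time ranges do not overlap")
    if grid is None:
        grid = np.linspace(lo, hi, n_grid)
    return pd.DataFrame(
        {"time_s": grid, "cohort_a": np.interp(grid, ta, va), "cohort_b": np.interp(grid, tb, vb)}
    )
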