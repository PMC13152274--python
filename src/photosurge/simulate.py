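"""Synthetic photometry generator with ground-truth annotations.

Generates 22 hr dual-channel scheduled-mode recordings whose statistical
structure matches what the analysis assumes: slow ~90 min raised-cosine
baseline oscillations forming a surge train on proestrus, fast ~10 s
difference-of-exponentials transients whose Poisson rate rises in the
oscillation up-state, a single-exponential bleaching carrier, additive
channel noise partly shared with the isosbestic channel, and a small
circadian bump an hour before lights-off.  Transients and oscillations
enter multiplicatively on the bleaching carrier (a fractional change of
fluorescence scales with fluorescence), so the dF/F formula is the
natural inverse of the generative model.

Every draw goes through a single ``numpy.random.Generator``, so a given
(parameters, seed) pair reproduces the recording bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import yaml

from .io import ChannelSeries, LHSeries, RawRecording, seconds_since_start


def _load_presets() -> dict:
    with resources.files("photosurge").joinpath("stages.yaml").open() as fh:
        return yaml.safe_load(fh)


_PRESETS = _load_presets()


def _draw(dist, rng: np.random.Generator):
    kind = dist["kind"]
    if kind == "poisson":
        return int(rng.poisson(dist["mean"]))
    if kind == "round_normal":
        v = rng.normal(dist["mean"], dist["sd"])
        return int(np.clip(round(v), dist["lo"], dist["hi"]))
    if kind == "trunc_normal":
        v = rng.normal(dist["mean"], dist["sd"])
        return float(np.clip(v, dist["lo"], dist["hi"]))
    raise ValueError(f"unknown distribution kind {kind!r}")


@dataclass
class StageParams:
    """Generator parameters for one hormonal condition."""

    n_oscillations: dict
    osc_duration_min: dict
    osc_amplitude: dict
    surge_onset_before_lights_off_hr: dict
    transient_amplitude: dict
    osc_gap_min: float = 0.0
    transient_rate_up_hz: float = 0.02
    transient_rate_down_hz: float = 0.003
    transient_rise_s: float = 1.0
    transient_decay_s: float = 4.0
    bleach_a: float = 100.0
    bleach_tau_s: float = 28800.0
    bleach_c: float = 150.0
    noise_sd: float = 2.5
    shared_noise_sd: float = 1.0
    iso_level: float = 8.0
    iso_noise_sd: float = 0.5
    prelightsoff_bump_amplitude: float = 0.0
    bump_duration_min: float = 90.0
    bump_lead_hr: float = 1.0
    stage: str = "unknown"

    @classmethod
    def preset(cls, stage: str) -> "StageParams":
        presets = _PRESETS
        if stage not in presets["stages"]:
            raise ValueError(
                f"unknown stage {stage!r}; available: {sorted(presets['stages'])}"
            )
        kwargs = dict(presets["shared"])
        kwargs.update(presets["stages"][stage])
        return cls(stage=stage, **kwargs)


@dataclass
class GroundTruth:
    """Injected events and nuisance parameters for one synthetic recording."""

    stage: str
    seed: int
    duration_s: float
    oscillations: list = field(default_factory=list)
    transients: list = field(default_factory=list)
    circadian_bump: dict | None = None
    bleach: dict = field(default_factory=dict)
    clock_start: str = "11:00"
    lights_off: str = "19:00"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @property
    def first_oscillation_onset_s(self) -> float | None:
        if not self.oscillations:
            return None
        return min(o["onset_s"] for o in self.oscillations)


def _raised_cosine(t: np.ndarray, onset: float, duration: float, amp: float) -> np.ndarray:
    """Smooth bump, zero outside [onset, onset + duration]."""
    phase = (t - onset) / duration
    out = np.zeros_like(t)
    inside = (phase >= 0) & (phase <= 1)
    out[inside] = amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase[inside]))
    return out


def _slow_component(t: np.ndarray, truth_osc: list, bump: dict | None) -> np.ndarray:
    m = np.zeros_like(t)
    for o in truth_osc:
        m += _raised_cosine(t, o["onset_s"], o["offset_s"] - o["onset_s"], o["amplitude"])
    if bump is not None:
        m += _raised_cosine(t, bump["onset_s"], bump["duration_s"], bump["amplitude"])
    return m


def _kernel(rise_s: float, decay_s: float, fs: float) -> tuple[np.ndarray, float]:
    """Peak-normalised difference-of-exponentials kernel and its duration
    above 10% of peak."""
    tk = np.arange(0.0, 8.0 * decay_s, 1.0 / fs)
    k = np.exp(-tk / decay_s) - np.exp(-tk / rise_s)
    k /= k.max()
    above = np.nonzero(k >= 0.1)[0]
    dur = (above[-1] - above[0] + 1) / fs
    return k, float(dur)


def draw_ground_truth(
    params: StageParams,
    duration_s: float,
    rng: np.random.Generator,
    clock_start: str = "11:00",
    lights_off: str = "19:00",
) -> GroundTruth:
    """Draw oscillation and transient events (no waveform rendering)."""
    truth = GroundTruth(
        stage=params.stage,
        seed=-1,
        duration_s=duration_s,
        clock_start=clock_start,
        lights_off=lights_off,
        bleach={"a": params.bleach_a, "tau_s": params.bleach_tau_s, "c": params.bleach_c},
    )
    lights_off_s = seconds_since_start(lights_off, clock_start)

    # --- slow oscillation train -------------------------------------------
    n_osc = _draw(params.n_oscillations, rng)
    onset = lights_off_s - _draw(params.surge_onset_before_lights_off_hr, rng) * 3600.0
    t_cursor = max(0.0, onset)
    for _ in range(n_osc):
        dur = _draw(params.osc_duration_min, rng) * 60.0
        if params.osc_gap_min > 0:
            gap = rng.exponential(params.osc_gap_min * 60.0)
        else:
            gap = 0.0
        if t_cursor + dur > duration_s - 1800.0:
            break
        amp = _draw(params.osc_amplitude, rng)
        truth.oscillations.append(
            {
                "onset_s": t_cursor,
                "peak_s": t_cursor + dur / 2.0,
                "offset_s": t_cursor + dur,
                "duration_min": dur / 60.0,
                "amplitude": amp,
            }
        )
        t_cursor += dur + gap

    # --- circadian pre-lights-off bump ------------------------------------
    if params.prelightsoff_bump_amplitude > 0:
        b_onset = lights_off_s - params.bump_lead_hr * 3600.0
        truth.circadian_bump = {
            "onset_s": b_onset,
            "duration_s": params.bump_duration_min * 60.0,
            "amplitude": params.prelightsoff_bump_amplitude,
        }

    # --- transients: inhomogeneous Poisson by thinning ---------------------
    rate_up, rate_dn = params.transient_rate_up_hz, params.transient_rate_down_hz
    rate_max = max(rate_up, rate_dn)
    if rate_max > 0:
        n_cand = rng.poisson(rate_max * duration_s)
        t_cand = np.sort(rng.uniform(0.0, duration_s, n_cand))
        env = _slow_component(t_cand, truth.oscillations, truth.circadian_bump)
        env_max = max((o["amplitude"] for o in truth.oscillations), default=0.0)
        env_norm = np.clip(env / env_max, 0.0, 1.0) if env_max > 0 else np.zeros_like(env)
        rate_t = rate_dn + (rate_up - rate_dn) * env_norm
        accept = rng.uniform(0.0, 1.0, n_cand) < rate_t / rate_max
        _, kern_dur = _kernel(params.transient_rise_s, params.transient_decay_s, 10.0)
        noise_au = np.hypot(params.noise_sd, params.iso_noise_sd)
        for t0 in t_cand[accept]:
            amp = _draw(params.transient_amplitude, rng)
            carrier = params.bleach_a * np.exp(-t0 / params.bleach_tau_s) + params.bleach_c
            truth.transients.append(
                {
                    "start_s": float(t0),
                    "end_s": float(t0 + kern_dur),
                    "amplitude": amp,
                    # effective noise SD (dF/F %) on the down-sampled trace at
                    # this point: private channel noise, averaged over the 20
                    # samples of an on-epoch, relative to the carrier
                    "noise_sd_dff": float(100.0 * noise_au / np.sqrt(20.0) / carrier),
                }
            )
    return truth


def render_recording(
    truth: GroundTruth,
    params: StageParams,
    rng: np.random.Generator,
    fs: float = 10.0,
    on_s: float = 2.0,
    off_s: float = 2.0,
) -> RawRecording:
    """Render channels for already-drawn ground truth (on-epoch samples only)."""
    t = np.arange(0.0, truth.duration_s, 1.0 / fs)
    m = _slow_component(t, truth.oscillations, truth.circadian_bump)
    kern, _ = _kernel(params.transient_rise_s, params.transient_decay_s, fs)
    for ev in truth.transients:
        i0 = int(round(ev["start_s"] * fs))
        i1 = min(len(t), i0 + len(kern))
        m[i0:i1] += ev["amplitude"] * kern[: i1 - i0]
    carrier = params.bleach_a * np.exp(-t / params.bleach_tau_s) + params.bleach_c
    shared = rng.normal(0.0, params.shared_noise_sd, len(t))
    own465 = rng.normal(0.0, params.noise_sd, len(t))
    own405 = rng.normal(0.0, params.iso_noise_sd, len(t))
    sig465 = carrier * (1.0 + m / 100.0) + shared + own465
    sig405 = params.iso_level + shared + own405
    on = (t % (on_s + off_s)) < on_s
    return RawRecording(
        timestamps=t[on],
        signal_465=sig465[on],
        signal_405=sig405[on],
        clock_start=truth.clock_start,
        on_s=on_s,
        off_s=off_s,
        lights_off=truth.lights_off,
        stage=params.stage if params.stage in (
            "metestrus", "diestrus", "proestrus", "estrus",
            "OVX", "OVX+E2", "OVX+E2+EB", "OVX+E2+EB-surge",
        ) else "unknown",
        animal_id=f"sim-{truth.seed}",
    )


def generate_recording(
    stage: str | StageParams = "proestrus",
    duration_hr: float = 22.0,
    seed: int = 0,
    clock_start: str = "11:00",
) -> tuple[RawRecording, GroundTruth]:
    """Generate one synthetic scheduled-mode recording with ground truth.

    ``stage`` is a preset label (e.g. ``"proestrus"``, ``"OVX"``) or an
    explicit :class:`StageParams`.  Identical (parameters, seed) pairs give
    bit-identical output.
    """
    if duration_hr <= 0:
        raise ValueError("duration must be positive")
    params = StageParams.preset(stage) if isinstance(stage, str) else stage
    rng = np.random.default_rng(seed)
    truth = draw_ground_truth(params, duration_hr * 3600.0, rng, clock_start)
    truth.seed = seed
    raw = render_recording(truth, params, rng)
    return raw, truth


def generate_lh(
    surge_truth: GroundTruth,
    lag_hr: float = 3.5,
    sampling_times_hr: np.ndarray | None = None,
    peak_ng_ml: float = 18.0,
    width_hr: float = 1.3,
    baseline_ng_ml: float = 0.3,
    assay_cv: float = 0.082,
    seed: int = 0,
) -> LHSeries:
    """Sample a Gaussian-bump LH surge tied to the first true oscillation.

    The profile peaks ``lag_hr`` hours after the onset of the first
    injected oscillation; samples carry multiplicative assay noise with
    the given coefficient of variation.
    """
    onset = surge_truth.first_oscillation_onset_s
    if onset is None:
        raise ValueError("ground truth contains no oscillations to anchor LH surge")
    if sampling_times_hr is None:
        sampling_times_hr = np.arange(1.0, 13.0, 2.0)
    sampling_times_hr = np.asarray(sampling_times_hr, dtype=float)
    if len(sampling_times_hr) == 0:
        raise ValueError("empty sampling times")
    if np.any(sampling_times_hr < 0) or np.any(
        sampling_times_hr > surge_truth.duration_s / 3600.0
    ):
        raise ValueError("sampling times outside the recording")
    rng = np.random.default_rng(seed)
    tp = onset / 3600.0 + lag_hr
    profile = baseline_ng_ml + (peak_ng_ml - baseline_ng_ml) * np.exp(
        -0.5 * ((sampling_times_hr - tp) / width_hr) ** 2
    )
    if assay_cv > 0:
        sigma = np.sqrt(np.log1p(assay_cv**2))
        profile = profile * rng.lognormal(-sigma**2 / 2.0, sigma, len(profile))
    return LHSeries(sampling_times_hr, profile)


def available_stages() -> list[str]:
    return sorted(_PRESETS["stages"])
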