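# Stage-dependent generator presets, version 1.
#
# Distributions: {kind: round_normal, mean, sd, lo, hi} draws a normal and
# rounds/clips to an integer count; {kind: poisson, mean} a Poisson count;
# {kind: trunc_normal, mean, sd, lo, hi} a clipped normal scalar.
#
# Oscillation durations/amplitudes and surge-onset timing follow the
# reported per-stage means, SEM-derived spreads and observed ranges for
# intact cycling and estrogen-replaced ovariectomized (OVX) mice.
# Transient rates are set so that the detected transient frequency lands
# at the reported per-stage scale (~0.01 Hz during surge-like activity,
# ~0.002-0.004 Hz otherwise); up/down rates implement the observed
# coupling of transient frequency to the oscillation up-state.
# The pre-lights-off circadian bump is present in all estrogen-exposed
# states, absent after OVX, and on proestrus is subsumed by the surge
# oscillation train rather than injected separately.

shared:
  transient_rise_s: 1.0        # difference-of-exponentials kernel rise
  transient_decay_s: 4.0       # decay; ~11 s above 10% of peak
  bleach_a: 100.0              # a.u., decaying part of the carrier
  bleach_tau_s: 28800.0        # 8 hr bleaching time constant
  bleach_c: 150.0              # a.u., non-bleaching offset
  noise_sd: 2.5                # a.u., private 465-channel noise at 10 Hz
  shared_noise_sd: 1.0         # a.u., movement noise common to both channels
  iso_level: 8.0               # a.u., flat isosbestic channel level
  iso_noise_sd: 0.5            # a.u., private 405-channel noise
  bump_duration_min: 90.0      # circadian pre-lights-off bump
  bump_lead_hr: 1.0            # bump onset precedes lights-off by 1 hr

stages:
  metestrus:
    n_oscillations: {kind: poisson, mean: 0.45}
    osc_duration_min: {kind: trunc_normal, mean: 88.6, sd: 15.0, lo: 40.0, hi: 170.0}
    osc_amplitude: {kind: trunc_normal, mean: 1.9, sd: 0.5, lo: 0.6, hi: 4.0}
    osc_gap_min: 0.0
    surge_onset_before_lights_off_hr: {kind: trunc_normal, mean: 3.7, sd: 0.5, lo: 1.6, hi: 5.3}
    transient_rate_up_hz: 0.003
    transient_rate_down_hz: 0.003
    transient_amplitude: {kind: trunc_normal, mean: 2.5, sd: 0.8, lo: 0.8, hi: 6.0}
    prelightsoff_bump_amplitude: 0.8
  diestrus:
    n_oscillations: {kind: poisson, mean: 0.4}
    osc_duration_min: {kind: trunc_normal, mean: 120.4, sd: 25.0, lo: 40.0, hi: 180.0}
    osc_amplitude: {kind: trunc_normal, mean: 1.1, sd: 0.4, lo: 0.4, hi: 3.0}
    osc_gap_min: 0.0
    surge_onset_before_lights_off_hr: {kind: trunc_normal, mean: 3.7, sd: 0.5, lo: 1.6, hi: 5.3}
    transient_rate_up_hz: 0.002
    transient_rate_down_hz: 0.002
    transient_amplitude: {kind: trunc_normal, mean: 2.2, sd: 0.7, lo: 0.8, hi: 6.0}
    prelightsoff_bump_amplitude: 0.8
  proestrus:
    n_oscillations: {kind: round_normal, mean: 8.4, sd: 0.9, lo: 5, hi: 11}
    osc_duration_min: {kind: trunc_normal, mean: 90.8, sd: 20.0, lo: 39.3, hi: 166.1}
    osc_amplitude: {kind: trunc_normal, mean: 7.2, sd: 1.5, lo: 3.0, hi: 12.0}
    osc_gap_min: 0.0
    surge_onset_before_lights_off_hr: {kind: trunc_normal, mean: 3.7, sd: 0.5, lo: 1.6, hi: 5.3}
    transient_rate_up_hz: 0.025
    transient_rate_down_hz: 0.003
    transient_amplitude: {kind: trunc_normal, mean: 4.0, sd: 1.2, lo: 1.0, hi: 9.0}
    prelightsoff_bump_amplitude: 0.0
  estrus:
    n_oscillations: {kind: poisson, mean: 0.5}
    osc_duration_min: {kind: trunc_normal, mean: 91.9, sd: 20.0, lo: 40.0, hi: 170.0}
    osc_amplitude: {kind: trunc_normal, mean: 1.5, sd: 0.5, lo: 0.5, hi: 3.5}
    osc_gap_min: 0.0
    surge_onset_before_lights_off_hr: {kind: trunc_normal, mean: 3.7, sd: 0.5, lo: 1.6, hi: 5.3}
    transient_rate_up_hz: 0.0025
    transient_rate_down_hz: 0.0025
    transient_amplitude: {kind: trunc_normal, mean: 2.4, sd: 0.7, lo: 0.8, hi: 6.0}
    prelightsoff_bump_amplitude: 0.8
  OVX:
    n_oscillations: {kind: poisson, mean: 0.0}
    osc_duration_min: {kind: trunc_normal, mean: 90.0, sd: 20.0, lo: 40.0, hi: 170.0}
    osc_amplitude: {kind: trunc_normal, mean: 1.0, sd: 0.3, lo: 0.3, hi: 2.0}
    osc_gap_min: 0.0
    surge_onset_before_lights_off_hr: {kind: trunc_normal, mean: 3.7, sd: 0.5, lo: 1.6, hi: 5.3}
    transient_rate_up_hz: 0.002
    transient_rate_down_hz: 0.002
    transient_amplitude: {kind: trunc_normal, mean: 2.30, sd: 0.6, lo: 0.8, hi: 6.0}
    prelightsoff_bump_amplitude: 0.0
  OVX+E2:
    n_oscillations: {kind: poisson, mean: 0.0}
    osc_duration_min: {kind: trunc_normal, mean: 90.0, sd: 20.0, lo: 40.0, hi: 170.0}
    osc_amplitude: {kind: trunc_normal, mean: 1.5, sd: 0.5, lo: 0.5, hi: 3.0}
    osc_gap_min: 0.0
    surge_onset_before_lights_off_hr: {kind: trunc_normal, mean: 3.7, sd: 0.5, lo: 1.6, hi: 5.3}
    transient_rate_up_hz: 0.0038
    transient_rate_down_hz: 0.0038
    transient_amplitude: {kind: trunc_normal, mean: 2.47, sd: 0.6, lo: 0.8, hi: 6.0}
    prelightsoff_bump_amplitude: 0.8
  OVX+E2+EB:
    n_oscillations: {kind: poisson, mean: 0.2}
    osc_duration_min: {kind: trunc_normal, mean: 90.0, sd: 20.0, lo: 40.0, hi: 170.0}
    osc_amplitude: {kind: trunc_normal, mean: 3.0, sd: 0.8, lo: 1.5, hi: 6.0}
    osc_gap_min: 0.0
    surge_onset_before_lights_off_hr: {kind: trunc_normal, mean: 3.7, sd: 0.5, lo: 1.6, hi: 5.3}
    transient_rate_up_hz: 0.0044
    transient_rate_down_hz: 0.0044
    transient_amplitude: {kind: trunc_normal, mean: 2.55, sd: 0.6, lo: 0.8, hi: 6.0}
    prelightsoff_bump_amplitude: 0.8
  OVX+E2+EB-surge:
    n_oscillations: {kind: round_normal, mean: 3.7, sd: 0.5, lo: 2, hi: 5}
    osc_duration_min: {kind: trunc_normal, mean: 88.6, sd: 20.0, lo: 59.7, hi: 169.3}
    osc_amplitude: {kind: trunc_normal, mean: 4.5, sd: 1.2, lo: 2.2, hi: 6.1}
    osc_gap_min: 35.0
    surge_onset_before_lights_off_hr: {kind: trunc_normal, mean: 3.7, sd: 0.5, lo: 1.6, hi: 5.3}
    transient_rate_up_hz: 0.06
    transient_rate_down_hz: 0.002
    transient_amplitude: {kind: trunc_normal, mean: 3.03, sd: 1.0, lo: 1.0, hi: 8.0}
    prelightsoff_bump_amplitude: 0.8
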