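# Methods

This note documents the models, parameter choices and numerical
decisions behind `photosurge`, and what the synthetic-data tests do and
do not establish about real recordings.

## Signal model

A recording is modelled as

```
F465(t) = B(t) · (1 + m(t)/100) + ε465(t) + εshared(t)
F405(t) = c405 + ε405(t) + εshared(t)
```

where `B(t) = a·exp(−t/τ) + c` is the bleaching carrier, `m(t)` the
neural modulation in dF/F percent (slow oscillations + fast transients),
and `εshared` movement noise common to both channels. Modulation enters
multiplicatively because a fractional change in indicator fluorescence
scales with the fluorescence itself; this makes the dF/F formula the
natural inverse of the generative model. Subtracting the isosbestic
channel cancels `εshared` and the constant `c405`; the analysis then
estimates `B` and reports `m`.

## Down-sampling

Scheduled acquisition (2 s light on, 2 s off at 10 Hz) is collapsed to
one point per on-epoch: the arithmetic mean of the samples whose
timestamps fall in the half-open on-window, placed at the epoch centre.
Epoch membership is computed from timestamps, not sample counts, so
dropped samples shift nothing. A trailing incomplete epoch is dropped.

## Bleach correction

`F_fit(t) = a·exp(−t/τ) + c` is fitted in overlapping windows (6 hr
long, 50% overlap, a final window pinned to the recording end), and each
window's curve is evaluated over its full support and cross-faded with
triangular weights into one continuous baseline. Blending fitted curves
rather than interpolating window-centre values keeps the baseline
faithful to curvature between centres, which matters when τ is of the
order of hours.

The fit uses the redescending Cauchy loss (`f_scale` = 2% of the window's
data span) plus up to two rounds of one-sided clipping: residuals more
than 2.5 robust SD *above* the fit are dropped and the window refitted.
Calcium events deflect fluorescence upward only, so the baseline is a
lower envelope; one-sided clipping encodes that. A bounded soft-L1 loss
proved insufficient here — a single 90 min oscillation occupying part of
a window could drag the fit to a tilted long-τ solution even on
noise-free input. τ is constrained to [window/50, 1e8] s; a failed or
non-finite fit falls back to the window median with a warning. A
double-exponential model is available behind `bleach.model = "double"`.

An optional pre-averaging mode (`presmooth_s`) first applies a centred
moving mean (e.g. one oscillation period, 5400 s) and fits the
analytically averaged model — the averaged exponential stays in-family
with amplitude gain `(2τ/W)·sinh(W/2τ)`, which the fit inverts. This
cancels zero-mean periodic structure exactly and is useful for
drift-dominated channels, but it converts a surge-length train of
non-negative oscillations into a sustained elevation that windows lying
entirely inside it cannot distinguish from carrier, so it is off by
default. This is a genuine identifiability limit of any window-length
baseline: elevation sustained for longer than a window is only separable
from carrier by shape assumptions.

The same windowed fit with a 400 s window re-flattens the fast residual
before transient detection (one clipping round; residuals there are
near zero-mean so the stage acts as a local detrender).

dF/F is `(F − F_baseline)/F_baseline × 100`, refused when the baseline
is not strictly positive (a failed fit, or input that is not
fluorescence-like).

## Deconvolution and oscillation detection

The slow trace is a centred moving mean (30 min default) whose window
shrinks at the edges; the fast trace is defined as `input − slow`, so the
decomposition is exact by construction. Detection criteria follow the
three-part rule: minimum height = mean + 2 SD of the slow trace in the
quiet clock window (11:00–13:00; the first 2 hr when no clock anchor is
present), minimum peak distance 30 min with the taller peak kept, and
minimum prominence = 0.15 × the maximum of the animal's proestrous
reference slow trace (falling back, with a warning, to the recording's
own maximum). Peak selection is `scipy.signal.find_peaks`, applying
height, then distance, then prominence — the order the brute-force
oracle in the test suite mirrors literally.

Troughs: for each retained peak the onset (offset) trough is searched
between it and the previous (next) retained peak or the recording edge.
A plain interval argmin is ill-posed wherever the trace is flat at
trough level — a pre-surge stretch sits at trough level for hours and
the argmin lands on an arbitrary noise minimum. The default rule takes
the sample nearest the peak that is (a) within a tolerance of the
interval minimum (tolerance = 2 SD of the quiet-window slow trace, the
same noise scale as the height criterion) and (b) a minimum of its
neighbourhood at the half-peak-spacing scale, so wiggles riding on a
flank do not qualify. In a V-shaped junction between abutting
oscillations this is the junction minimum for both neighbours; beside a
flat stretch it is the oscillation foot. Because a centred moving
average advances the apparent foot of any event adjoining a flat
baseline by half the smoothing window, flat-adjacent troughs are shifted
back by that amount (the flatness is verified before shifting; the plain
argmin remains available via `trough_rule="argmin"`).

Oscillation duration is trough-to-trough; amplitude is peak value minus
onset-trough value (the paper-style per-stage amplitudes; prominence is
also reported). Surge onset/offset are the first onset trough and last
offset trough; AUC is the trapezoidal integral of the full dF/F trace.

## Transient significance

The residual is z-scored so its median is 0 and its SD is 1 (plain SD of
the full trace). For each threshold k in 1, 1.2, …, 4 (16 values),
maximal runs above +k are positive candidates, runs below −k negative
ones. Negative-going excursions of a given duration can only be noise,
so `n_neg/n_pos` at candidate duration `s` estimates the false-positive
rate; positive candidates of duration ≥ s are accepted when the ratio is
below 0.05, and the final mask is the union over all (k, s). Candidate
sizes are the distinct observed positive-run sizes: with inclusive
counting both the accepted set and `n_pos` are constant between
consecutive observed sizes while `n_neg` is smallest at the upper end of
each interval, so the finite sweep is equivalent to trying every integer
size (the test suite verifies this bit-for-bit against a literal loop).
A strict variant (`size_comparison="gt"`, a run never supporting its own
size) is available; under it a lone unmatched excursion is never
significant, which is the main behavioural difference.

Transient amplitudes are measured on the residual dF/F trace before
z-scoring, so they are in dF/F percent; duration is the run length times
the sampling interval; per-recording stats are count/duration (Hz) and
means over events. Only positive transients are reported.

## Hormone alignment

The LH peak of a sparse series is the raw sample argmax (earliest on
ties) — 2–4 hr sampling cannot support sub-sample peak estimation. The
onset-to-peak lag is LH peak time minus the first oscillation's onset
trough; negative lags are allowed and flagged. "Decline in LH" is
operationalised as the first post-peak sample below 50% of the peak
(configurable); activity continuing past the decline is surge offset
minus that time.

## Synthetic generator

`generate_recording(stage, duration_hr=22, seed)` renders the model
above at 10 Hz with on-epoch samples only (the CSV writer can add NaN
sentinel rows for off-epochs, which the reader skips). Stage presets
live in `stages.yaml`; the defaults encode the reported study
conditions: proestrous oscillation durations ~N(90.8, 20) min truncated
to the observed 39.3–166.1 range, amplitudes ~N(7.2, 1.5) %dF/F,
oscillation count round(N(8.4, 0.9)) so that count × duration matches
the ~12.7 hr total surge span, surge onset ~N(3.7, 0.5) hr before
lights-off truncated to the observed 1.6–5.3 range, and OVX-regimen
transient frequencies/amplitudes at the reported per-condition values.
Oscillations are raised cosines laid back to back (sharing troughs);
the estrogen-replaced surge condition adds exponential gaps so its
fewer oscillations still span ~7 hr. Transients are difference-of-
exponentials kernels (rise 1 s, decay 4 s; ~11 s above 10% of peak)
whose Poisson rate switches with the oscillation envelope
(up-state-coupled, via thinning); proestrous rates give a detected
frequency of ~0.01 Hz. Channel noise is Gaussian at 10 Hz with a shared
component cancelled by subtraction; private noise gives ~0.3 %dF/F on
the down-sampled trace. A 90 min circadian bump starting 1 hr before
lights-off is present in estrogen-exposed states, absent after OVX, and
on proestrus is part of the surge train rather than a separate event;
its default amplitude (0.8%) sits below the proestrus-referenced
prominence threshold so it shapes mean profiles without inflating
oscillation counts on quiet days. Ground truth records every injected
event, including each transient's local effective noise SD in dF/F so
recovery tests can condition on signal-to-noise.

What the generator does not emulate: movement artefacts beyond shared
Gaussian noise, wavelength-dependent bleaching differences, inter-
oscillation interval structure beyond independent duration draws, or
state-dependent transient waveform changes. Passing recovery tests
therefore demonstrate the analysis is correct under its own model
assumptions at realistic SNR, not that those assumptions hold in vivo.

`generate_lh` ties a Gaussian LH profile (peak 18 ng/mL, SD 1.3 hr,
baseline 0.3 ng/mL, 8.2% multiplicative assay noise) to the first
injected oscillation with a configurable lag (default 3.5 hr).

## Statistical policy

Shapiro-Wilk per group plus an F-test (two groups) or Bartlett (more)
select the branch at α = 0.05; borderline cases fall to the
non-parametric side. Two paired groups: paired t or Wilcoxon. Three or
more: repeated-measures ANOVA with Greenhouse-Geisser correction
(pingouin) followed by Tukey on the within-subject error mean square
(studentized-range p with (n−1)(k−1) df), or Friedman (scipy) followed
by Dunn's multiple comparisons (within-subject rank z statistics,
Bonferroni-adjusted; no installed package provides Dunn, so it is
implemented here). On simulated 8 × 4 nulls the Friedman branch rejects
at ~4% for nominal 5%, inside the calibration band the test suite
checks.

## Problem sizes and tolerances

Validation uses 22 hr recordings at the effective 0.25 Hz (19 800
samples): 50 seeded proestrous recordings for parameter recovery, 100
seed-matched pairs for the stage contrast, 50 traces of ≤ 1 000 samples
for each brute-force oracle equivalence, and 1 000 replicates for the
type-I calibration. Decomposition and AUC identities are checked to
1e-12; the exponential-recovery bound is 1% pointwise; duration
recovery is required within 10% of the injected mean (typically ~5%);
transient recall/FDR bounds are 0.9/0.1 for events of ≥ 4 local noise
SD (typically ~0.99/0.02).

## Known limitations

- The 6 hr window baseline cannot separate carrier from elevation
  sustained longer than a window without shape assumptions (see above);
  the robust lower-envelope fit resolves this through the
  inter-oscillation troughs, which exist in surge-like data.
- Prominence referenced to the raw maximum of the reference trace makes
  detection sensitive to constant offsets in that reference (documented,
  tested behaviour).
- The LH lag is quantised by the blood-sampling interval.
- `mean_profile` aligns by clock time only; it does not warp for
  between-animal differences in surge onset.
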