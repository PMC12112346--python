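# Methods

`retinaosc` quantifies the pathological rhythmic activity that emerges in
degenerated retina — trains of large negative local-field-potential (LFP)
deflections at a genotype-specific fundamental frequency (~2 Hz in the RCS
rat, 3–6 Hz in the rd10 mouse), often with retinal-ganglion-cell spike
bursts phase-locked to the deflection troughs — and the degradation of
electrical stimulation efficiency that accompanies it.  This note documents
the analysis model, the parameter choices, and what the synthetic-data
generator does and does not emulate.

## Band separation

Raw multi-electrode-array (MEA) traces are split into an LFP view and a
spike-band view with zero-phase Butterworth filters (`scipy.signal`
second-order sections, applied forward–backward with odd-reflection padding
of three times the effective impulse length, ~3·fs/f_cutoff samples).  Two
probe profiles are built in:

| profile      | LFP             | spike band                    |
|--------------|-----------------|-------------------------------|
| PLANAR       | low-pass 50 Hz  | high-pass 200 Hz              |
| PENETRATING  | low-pass 100 Hz | band-pass 100–3000 Hz, order 6|

Only the penetrating band-pass order (6) is dictated by the recording
protocol the pipeline reproduces; the remaining filters use order 4, a
common default.  Cutoffs are the one-pass −3 dB points, so after the two
passes the cutoff sits at −6 dB; the tests assert both values against the
Butterworth closed form.  Zero-phase filtering matters here because
deflection trough *times* anchor the phase-locking analysis: any filter
delay would masquerade as a phase offset.

## Spectra and the fundamental

Amplitude spectra are computed on 10-s Hann-tapered segments (0.1 Hz
resolution), averaged across non-overlapping segments, restricted to
0–50 Hz, and max-normalized to 1 — normalization puts recordings of very
different oscillation amplitude on a common axis.  Peak frequencies are
refined by quadratic interpolation of the three bins around each local
maximum.

Because the deflection waveform is strongly non-sinusoidal, its spectrum
carries prominent 2nd/3rd harmonics and the tallest peak is not always the
fundamental.  `fundamental_frequency` therefore groups peaks into harmonic
families: every detected peak is tried as a candidate fundamental, peaks at
integer multiples (within 10% of the candidate, at most one peak per
harmonic index, index ≤ 4) join its family, and the family with the largest
summed amplitude wins; the reported fundamental is the amplitude-weighted
mean of `f_k/k` over members.  Two guards prevent octave errors: the
harmonic index is capped at 4 (the waveform carries little energy beyond the
3rd harmonic), and a candidate whose own amplitude is below 25% of its
family's largest peak is rejected — otherwise a small noise peak near half
the true fundamental can adopt the real peaks as its "harmonics" and win on
summed amplitude.

A channel is classified oscillatory when a fundamental exists and the peak
amplitude in 0.5–20 Hz exceeds 5× the median in-band amplitude.  The
threshold was fixed against the noise null (white-noise LFP spectra reach
max/median ≈ 2 after 6-segment averaging) so wild-type traces flag false in
≥ 95% of seeds; that property is tested.

## Negative deflections, windowed counts, bouts

Deflections are contiguous excursions below −3·σ_LFP lasting ≥ 20 ms,
timestamped at the trough; events closer than 100 ms are merged keeping the
deeper trough (capping the countable rate at 10 Hz, far above the ~2 Hz
phenomenon).  σ_LFP is a two-pass robust estimate: MAD/0.6745 on the whole
trace, provisional detection, then re-estimation with ±200 ms around each
provisional trough masked out, so the rhythm itself does not inflate its own
detection threshold.  Counts are reported per consecutive half-open 5-s
window (only complete windows; counts sum to the events in the covered
span).  Bouts are maximal runs of ≥ 3 events whose inter-event intervals
stay within a factor 2 of the run's median interval; the bout fundamental is
the reciprocal median interval.

## Spikes and phase locking

Spike detection is negative threshold crossing at −4·σ (MAD-based σ),
trough-timestamped within 1 ms of the crossing, 1-ms refractory, with
detection blanked for 2 ms after each stimulation pulse (covering the 0.8-ms
biphasic artifact plus settling).  Extracellular somatic spikes are
predominantly negative, hence the one-sided rule.  At 6σ spike amplitude the
detector achieves recall and precision ≥ 0.95 (tested); residual false
positives from Gaussian noise run at ~0.2/s under the default bandwidths,
which perturbs the stimulation-efficiency ratio by under 4%.

Spike phase is defined by the deflection troughs: phase 0 at each trough,
interpolated linearly between consecutive troughs — this avoids the phase
distortion a narrowband filter-Hilbert approach would introduce on such
non-sinusoidal waveforms.  Locking strength is the vector strength (modulus
of the mean unit phasor), flagged undefined below 10 spikes.  For Gaussian
phase jitter of σ cycles the expected vector strength is
`exp(−(2πσ)²/2)`; the implementation matches this closed form within 0.03
for σ ∈ {0.02, 0.05, 0.1, 0.2} (tested).  Note that on full multi-unit
trains the measured value is diluted by the unlocked tonic spikes: with 30%
of spikes in locked bursts at σ = 0.05 cycles, the expected train-level
vector strength is ≈ 0.3 × 0.95 ≈ 0.29.

## Stimulation efficiency and statistics

Efficiency is the per-stimulus spike-rate ratio: rate in the 0.4 s after the
pulse divided by the rate in the 8 s before it, pooled as mean ± SEM;
stimuli with a zero pre-window rate are excluded (logged).  Condition phases
(control / 500 µM GABA / washout) are compared pairwise with the two-sided
Mann–Whitney U test — exact null for small tie-free samples, tie-corrected
normal approximation otherwise — with the asterisk ladder
**** p ≤ 10⁻⁴, *** p ≤ 10⁻³, * p ≤ 0.05 (deliberately no ** rung), and no
multiple-comparison correction.  The elementary observation is the
per-stimulus ratio on each recording electrode.

## The synthetic generator

`synthetic.simulate_recording` / `simulate_stim_session` produce recordings
with the statistical structure the analysis assumes, plus full ground truth
(every injected deflection, bout interval, spike and evoked count).
Components, with defaults:

* **LFP noise**: Gaussian, low-passed at 100 Hz, σ = 20 µV.  **Instrument
  noise**: Gaussian, band-limited at 3 kHz (amplifier anti-aliasing),
  σ = 5 µV.
* **Deflections**: inverted Gaussians, 80 ms FWHM, −300 µV — unambiguous at
  the −3σ detection threshold (SNR 15) and harmonic-rich through the 3rd
  harmonic.  True LFP deflection amplitudes are not published for this
  preparation; these are calibration choices.
* **Bouts**: one bout per frame of length `bout_dur/duty_cycle`, uniformly
  placed within the frame, fixed duration `bout_dur` (2 s for RCS presets,
  30 s for rd10); within a bout, deflections repeat at the fundamental with
  3% cycle jitter.  Isolated deflections are placed one per `1/iso_rate`
  stratum, uniformly.  This *stratified* placement is deliberate: it keeps
  the waxing/waning phenomenology while making event totals over a 600-s
  recording near-deterministic, so the per-window mean count estimates the
  closed-form expectation `5·(f0·duty + iso_rate)` with a few percent
  sampling error.  A doubly-exponential renewal process (exponential gaps
  and durations) would give the sparsest preset a ~20% sampling SD at 600 s,
  swamping what the deflection detector is being validated against.
* **Spiking**: total tonic rate 5 Hz.  A target fraction (30%) is emitted as
  bursts locked to deflection troughs (Poisson burst size, jitter 0.05
  cycles); the locked rate is capped at 3 spikes per deflection and the
  Poisson background makes up the remainder, so the total rate is exactly
  `spike_rate_hz` — this keeps the efficiency expectation exact.  Spikes are
  rendered from a fixed 1-ms biphasic template (−60 µV trough).
* **Stimulation**: pulses every `isi_s` (must exceed the 8.4-s analysis
  span), each rendered as a smooth charge-balanced biphasic transient
  (500 µV, 0.8 ms — as the amplifier records it, with filter ringing
  confined to the pulse) plus Poisson(`evoked_mean`) evoked spikes uniform
  in (2 ms, 0.4 s].
* **GABA condition**: duty cycle and isolated-event rate to zero, tonic rate
  halved, evoked response unchanged; washout restores the baseline preset.
* **Depth**: penetrating-probe presets scale deflection amplitude linearly
  across channels (`depth_gain`), reproducing the growth of spectral peak
  prominence with recording depth.

Genotype/age presets (fundamental f0, bout duty cycle, isolated-event rate)
are calibrated so that `5·(f0·duty + iso_rate)` equals the published
per-window deflection counts — 0.6 / 1.9 / 3.25 / 3.9 per 5-s window for RCS
at 3 / 6 / 11 / 19 months (duty 0.02 / 0.15 / 0.285 / 0.35 with iso rate
0.08 Hz at f0 = 2 Hz) — and rd10 at f0 = 3.4 Hz, duty 0.8.  The
`RCS_M6_INTRA` preset models the intraretinal configuration: f0 = 1.98 Hz,
pronounced oscillation (duty 0.5, 4-s bouts), penetrating probe with a
0.4→1.0 depth gain.

The evoked-spike mean is calibrated from each preset's target efficiency
ratio R by inverting the estimator's actual expectation rather than the
naive `evoked = (R−1)·post_s·rate`: the mean of per-stimulus ratios exceeds
the ratio of mean rates by a Jensen factor `≈ 1 + Var(pre)/E(pre)²` (3–5%
here), where the pre-window count variance includes the burst and bout
clustering of locked spikes (compound-Poisson clusters for bouts shorter
than the window; an on/off Bernoulli mixture for bouts longer than it).
With this inversion, ground-truth mean ratios over 30 seeds center on the
targets within 1.5%.

Default sampling rate is 10 kHz (any fs ≥ 2.5× the 3-kHz band edge is
accepted); recording hardware of this class samples at 25 kHz, but 10 kHz
resolves everything the analysis uses at desk scale.

**What the generator does not emulate**: spatial correlation across
electrodes beyond the depth gain, electrode drift and line noise,
spike-waveform diversity (no units — the analysis is multi-unit by design),
slow non-stationarities of bout statistics, and any biophysics of the
oscillator.  Passing tests therefore validate the *analysis chain* against a
known statistical structure, not the biological claims themselves.

## Numerical and degenerate-input conventions

All intervals are half-open `[start, end)`; times in seconds, voltages in
µV.  Constant traces yield σ = 0 with a warning (no spikes, no deflections,
flat-flagged spectra classified non-oscillatory).  Ties in the Mann–Whitney
test fall back to the midrank normal approximation (the exact null assumes
no ties).  Merged deflections keep the deeper trough; bout runs restart
after any interval outside factor 2 of the running median.  All generator
randomness flows from a single `numpy.random.default_rng(seed)` per call —
identical arguments give bit-identical recordings, and pipeline reports are
reproducible from (config, seed).

## Problem sizes

The validation suite uses 600-s single-channel recordings for the
deflection-count calibration, 60-s recordings for fundamental-frequency and
GABA-reversibility checks (20 seeds × 3 phases), and 100-stimulus sessions
(~1000 s) for stimulation efficiency — sizes at which the stratified
generator's sampling error is small against the quantities' tolerances.

## Known limitations

* The deflection criterion (−3σ, 20 ms, 100 ms separation) is one reasonable
  operationalization; absolute counts on real data shift with these choices,
  which is why they are fixed, documented defaults.
* The oscillatory flag's SNR threshold is calibrated for the 0.5–20 Hz band
  and 10-s windows; very short recordings (< 30 s) give noisy
  classifications.
* Vector strength on multi-unit trains conflates locking strength with the
  locked fraction; interpreting it per unit requires spike sorting, which is
  out of scope.
* The Jensen correction in the efficiency calibration is second-order; for
  pre-windows with expected counts below ~10 the residual bias of the
  mean-of-ratios estimator grows and the calibration identity degrades.
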