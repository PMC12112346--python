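# retinaosc

Detection and quantification of pathological retinal oscillations in
multi-electrode-array (MEA) recordings.

In many models of retinitis pigmentosa, photoreceptor loss leaves the inner
retina generating abnormal rhythmic activity: large negative deflections of
the local field potential (LFP) recurring at a genotype-specific fundamental
frequency (~2 Hz in the RCS rat, 3–6 Hz in the rd10 mouse), with retinal
ganglion cell spike bursts phase-locked to the deflection troughs.  This
activity matters for vision-restoration strategies — it competes with, and
measurably lowers, the response to electrical stimulation.  `retinaosc` is a
reusable pipeline for quantifying that phenomenology, aimed at
electrophysiologists analyzing planar- or penetrating-MEA recordings of
explanted retina.

## What it computes

Per channel, from a raw voltage matrix (µV) with sampling rate:

- **Band separation** — zero-phase Butterworth cascades: LFP (low-pass
  50 Hz planar / 100 Hz penetrating) and spike band (high-pass 200 Hz
  planar / band-pass 100–3000 Hz order 6 penetrating).
- **Spectra** — max-normalized amplitude spectra (Hann, 10-s windows,
  segment-averaged) over 0–50 Hz, with peak detection.
- **Fundamental frequency** — harmonic-grouping estimator: peaks at integer
  multiples of a candidate `f₀` (within 10%, order ≤ 4) form a family, the
  family with the largest summed amplitude wins, so a tall 2nd harmonic is
  never mistaken for the fundamental.
- **Negative deflections** — excursions below −3·σ_LFP (robust two-pass MAD
  noise estimate) lasting ≥ 20 ms, counted in consecutive 5-s windows, and
  segmented into oscillation bouts (runs of ≥ 3 regularly spaced events);
  a channel is flagged *oscillatory* when its spectral peak exceeds 5× the
  median in-band amplitude.
- **Spike detection and phase locking** — threshold crossings at −4σ with
  1-ms refractory and stimulation-artifact blanking; spike phase
  interpolated between deflection troughs (troughs = phase 0); locking
  summarized as vector strength `|⟨e^{iφ}⟩|`.
- **Stimulation efficiency** — per-stimulus spike-rate ratio
  `rate[t, t+0.4 s) / rate[t−8 s, t)`, pooled as mean ± SEM, compared across
  pharmacology phases (control / GABA / washout) with the two-sided
  Mann–Whitney U test (stars: **** p ≤ 10⁻⁴, *** p ≤ 10⁻³, * p ≤ 0.05).

A calibrated synthetic-MEA generator (`retinaosc.synthetic`) provides
genotype/age presets (wild type, rd10, RCS at 3/6/11/19 months, an
intraretinal configuration), a GABA condition modifier, stimulation
sessions, and full ground truth for every injected event — it is the test
bed the pipeline is validated on, since recordings of this preparation are
not publicly deposited.

## Worked example

```python
from retinaosc import RunConfig, run_pipeline

report = run_pipeline(RunConfig(preset="RCS_M19", duration_s=60.0, seed=1))
row = report.channels.iloc[0]
print(f"fundamental    : {row.f0_hz:.2f} Hz")
print(f"oscillatory    : {bool(row.oscillatory)}")
print(f"deflections    : {int(row.n_deflections)} ({row.mean_count_per_window:.2f} per 5-s window)")
print(f"bouts          : {int(row.n_bouts)}")
print(f"vector strength: {row.vector_strength:.2f}")
```

prints

```
fundamental    : 1.93 Hz
oscillatory    : True
deflections    : 42 (3.50 per 5-s window)
bouts          : 10
vector strength: 0.25
```

The 19-month RCS preset oscillates at 2 Hz in short bouts; on this 60-s
realization the estimator reads the fundamental at 1.93 Hz, detects 42
negative deflections (3.50 per 5-s window, against the preset's calibrated
expectation of 3.9 — a single minute of a waxing/waning process), groups
them into 10 bouts, and flags the channel oscillatory.  The vector strength
of 0.25 is a multi-unit figure: ~30% of spikes are emitted as trough-locked
bursts, and the unlocked tonic spikes dilute the train-level locking
(0.3 × 0.95 ≈ 0.29 expected).

The same analysis is available from the shell:

```sh
retina-osc simulate --preset RCS_M19 --duration 600 --seed 1 --out rec.h5
retina-osc analyze  --input rec.h5 --out tables/
retina-osc compare  --preset RCS_M19 --duration 60 --seed 1 --out cmp/
retina-osc convert  --from container --to ascii rec.h5 rec.txt
```

`analyze` writes `spectra.csv`, `deflections.csv`, `bouts.csv`,
`efficiency.csv`, `comparisons.csv` and a config snapshot; `simulate` writes
the recording (HDF5 container or ASCII matrix) plus a `*_truth.csv` of every
injected event.

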