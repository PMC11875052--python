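# cortune

Analysis pipeline for sound-evoked calcium imaging of mouse auditory
cortex, built around the comparison of normal-hearing and hearing-loss
genotypes.  C57BL/6 mice homozygous for the recessive *ahl* variant of
*Cdh23* lose high-frequency hearing progressively from early adulthood;
congenic *Ahl+* littermates keep low thresholds.  This package implements
the full measurement chain used to quantify that phenotype in cortex —
widefield threshold detection, two-photon frequency tuning, pairwise
correlations, tonotopic area maps, and population decoding — together with
an in-silico model of the PCR + BsrI restriction-digest assay that
genotypes the *Cdh23* SNP, and a synthetic-session generator that implants
known tuning structure so every stage is verifiable without real
recordings.

It is aimed at systems-neuroscience groups running tone-grid imaging
experiments (widefield or two-photon) who want a tested, reproducible
reference implementation of these standard analyses.

## What it computes

Stimuli form a grid of F frequencies × A sound levels × R repeats
(default 4–64 kHz in octave steps, 30–90 dB SPL in 20 dB steps, 10
repeats); recordings are unmixed into trial tensors of shape
`unit × T × F × A × R`.

**Widefield thresholds.** Per trial, ΔF/F = (F − F₀)/F₀ with F₀ the mean
of the 1 s pre-onset frames.  Response amplitude is the mean ΔF/F 10–15
frames after onset; per condition, pixels at or above the 99th percentile
of the trial-averaged amplitude map are averaged.  Scanning levels in
ascending order, the detection threshold of a frequency is the first level
whose paired t test (response vs baseline, α = 0.05, uncorrected) rejects
with a positive mean difference, or the 110 dB SPL sentinel if none does.

**Two-photon tuning.** ROI traces are neuropil-corrected
(F = F_ROI − 0.7·F_NP), baselined with a rolling 10th percentile
(500-frame windows, 50-frame steps, linear interpolation) and normalized
to ΔF/F.  Each trial yields baseline, onset (frames 5–9 after tone onset)
and offset (frames 5–9 after tone offset) amplitudes.  A neuron is
sound-responsive when the phase factor of

    amp ~ C(phase) + C(freq) + C(level) + C(freq):C(level):C(phase)

is significant at α < 0.01 (partial F, Type II SS); post hoc one-sided
paired comparisons type it Onset / Offset / Onset-Offset.  Per-condition
significance uses paired onset-vs-baseline tests with Benjamini–Hochberg
FDR 0.2 per neuron.  Bandwidth is log₂(f_max/f_min) over the contiguous
significant frequencies at 70 dB SPL (multi-peaked neurons excluded);
best frequency (BF) is the argmax amplitude over significant conditions;
characteristic frequency (CF) is the argmax at the lowest significant
level.

**Correlations.** Signal correlations: Pearson r between trial-averaged
responses over the 30 frames after onset, per condition and pair, then
averaged (optionally conditioned on a frequency/level subset).  Noise
correlations: the same on repeat-by-repeat residuals after subtracting
condition means.

**Tonotopy.** A winner-take-all map: each 10 µm cell is assigned the CF
class with the largest Gaussian-weighted (σ = 60 µm) neuron support;
fractional areas are reported per CF band (e.g. ≤ 16 kHz vs ≥ 32 kHz).

**Decoding.** Trial features are per-neuron mean ΔF/F over 1 s after
onset.  Stratified 90/10 splits repeated 10 times cover every trial once;
per split, PCA components explaining ≥ 90 % of training variance feed a
pooled-covariance LDA that predicts the (frequency, level) class.  Chance
is 1/(F·A) = 5 %.

**Genotyping.** Exact-match in-silico PCR between the assay primers,
both-strand scan for the BsrI site (ACTGG, cutting 1 nt 3′ of the site),
fragment lengths, and the band-pattern call: {948} → *Ahl/Ahl*,
{284, 664} → *ahl/ahl*, all three → *Ahl/ahl*.  Synthetic allele
templates reproducing these sizes ship with the package.

## Worked example

Detect widefield thresholds on a synthetic 6-month hearing-loss cohort:

```python
import cortune as c

grid = c.default_widefield_grid()            # 4-64 kHz, 30-90 dB SPL, 10 repeats
pop = c.generate_ground_truth(600, "ahl_b6_6mo", grid, seed=1102)
noise = c.NoiseConfig(trace_sigma=1.0, drift_amplitude=0.05, seed=1202)
movie = c.synthesize_widefield(pop, grid, 32, noise)

tensor = c.unmix_trials(movie.movie, movie.log, grid)
profile = c.widefield_threshold_pipeline(tensor)
for f, t in zip(profile.frequencies_khz, profile.thresholds_db):
    print(f"{f:>4g} kHz: threshold {t:g} dB SPL")
```

prints

```
   4 kHz: threshold 50 dB SPL
   8 kHz: threshold 30 dB SPL
  16 kHz: threshold 50 dB SPL
  32 kHz: threshold 70 dB SPL
  64 kHz: threshold 110 dB SPL
```

— low-frequency hearing largely intact, 32 kHz elevated, and no
detectable 64 kHz response at any presented level (the 110 dB sentinel),
matching the thresholds implanted by the preset.

The numbered drivers under `analysis/` run the full study arc —
simulation, widefield thresholds, tuning, correlations, tonotopy,
decoding, genotyping — and write their tables under `results/`:

```sh
cd analysis && python 01_simulate.py && python 02_widefield_thresholds.py  # etc.
```

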