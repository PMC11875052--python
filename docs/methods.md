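# Methods

## Scope and design

The package implements a measurement chain for tone-grid calcium imaging
(widefield and two-photon) of mouse auditory cortex, plus an in-silico
RFLP genotyping model, organized as a library (`src/cortune/`) driven by
numbered analysis scripts (`analysis/`).  Every stage is validated
against a forward model (`cortune.synth`) that implants known tuning
structure; the tests therefore check parameter *recovery*, not merely
code paths.

## Stimulus model and trial tensors

The design is a complete grid: frequencies in octave steps (4–64 kHz),
sound levels in 20 dB steps (30–90 dB SPL), a fixed repeat count (10),
75-frame trial epochs, and tone onset placed so a full 1 s baseline
precedes it (frame 30 at the 30 Hz widefield rate, frame 15 at the 15 Hz
two-photon rate).  Frame indexing is 0-based; window specifications
"frames a–b after onset" include both endpoints.  Unmixing maps each
logged presentation to the epoch `[onset − onset_frame, … + 75)` and
fills slot (f, a, r) with the r-th presentation of that condition in
temporal order, erroring on incomplete or overfull conditions; it is a
bijection between log entries and tensor slots.

## Forward model (synthetic sessions)

Each simulated neuron carries a characteristic frequency (CF), a
threshold at CF, a V-shaped frequency-response area with threshold rising
linearly in octave distance from CF, a peak ΔF/F amplitude (log-normal,
median 0.5), a response type (onset 60 %, offset 10 %, onset-offset 15 %,
silent 15 %), and a baseline fluorescence (log-normal, median 100 a.u.).
The mean response to a tone is
`amplitude · min(1, (level − θ(f))/40 dB)` above threshold and 0 at or
below it (the boundary is exclusive).

Numerical choices, with reasons:

* **FRA slope 30 dB/octave.**  A shallow slope lets the sensitive tail of
  low-CF neurons respond at 32–64 kHz within one level step, which would
  erase any implanted high-frequency threshold elevation at the
  population level; 30 dB/oct preserves the hearing-loss phenotype while
  still producing bandwidths of 0–2 octaves at 70 dB SPL, the observed
  range.
* **Threshold quantization to {10, 30, 50, 70, 90, 110} dB SPL.**  The
  measurable grid is the presented level set plus the 110 sentinel,
  extended one step *below* the lowest presented level: with an exclusive
  response boundary, a neuron that responds at 30 dB SPL needs a
  threshold strictly below it.  Without the 10 dB rung no simulated
  neuron could ever be detected at the lowest presented level and the
  30 dB conditions would be undecodable.
* **Indicator kinetics rise 0.18 s / decay 1.5 s** (slow-indicator
  realism), double-exponential kernel normalized to unit peak.  Responses
  decay across trial boundaries (kernel truncated at 6 decay constants).
  This inter-trial bleed matters statistically: at non-responsive
  conditions the onset window sits slightly lower than the earlier
  baseline window, so the one-sided per-condition tests are not fooled by
  pure chance at FDR 0.2.  Hard truncation at trial end makes null
  p-values uniform and visibly degrades CF recovery.
* **Nuisance processes.**  Raw ROI trace
  `F = f0·(1 + ΔF/F)·drift(t) + 0.7·c_i·NP(t) + ε` with a shared low-pass
  neuropil process NP (2 s smoothing, 30 a.u. baseline), per-neuron
  coupling c_i ~ U(0.5, 1.5), sinusoidal drift (default 10 % amplitude,
  300 s period) and white noise (default SD 2 a.u.).  The matching
  neuropil trace is emitted so the analysis-side α = 0.7 subtraction is
  consequential and testable.
* **Widefield noise structure.**  Pixel signals are Gaussian-blurred
  (σ = 50 µm) sums of neuron ΔF/F.  Sensor noise is spatially smoothed
  (σ = 2 px) and a slow global ΔF/F fluctuation (SD 1 %, τ = 1 s) is
  shared by all pixels.  This mirrors real widefield recordings, where
  neighboring pixels are strongly correlated and hemodynamic/arousal
  common modes dominate.  It is not cosmetic: the 99th-percentile pixel
  selection conditions on the same data the paired test then uses, and
  with i.i.d. pixel noise that circularity cherry-picks positive noise
  across ~10³ independent pixels and produces spurious sub-threshold
  detections the method does not show on real data.
* **Tonotopy by construction.**  Preset CF-class probabilities double as
  tonotopic-axis span fractions: positions are uniform over the field and
  a neuron's CF class is the axis zone containing its x coordinate
  (±30 µm jitter).  Implanted neuron-mass fractions and implanted areal
  fractions therefore coincide, making areal recovery well-posed.

Genotype presets encode the cohorts' hearing phenotypes as per-class CF
probabilities and threshold means ± SDs (young hearing-loss mice: CF mass
0.86 at ≤ 16 kHz, 32/64 kHz thresholds 80 ± 30 / 80 ± 20 dB SPL;
protected congenic mice: uniform CF, 32 ± 5 / 34 ± 8 dB SPL; the aged
hearing-loss preset pushes high-frequency thresholds to the sentinel).
The published spreads are across-animal statistics; the presets reuse
them as across-neuron spread, a modeling choice rather than an empirical
claim.

What the simulator does **not** model: spiking or cochlear mechanics,
motion artifacts, photobleaching beyond multiplicative drift, vascular
occlusion, or inhibitory suppression.  Passing recovery tests therefore
show that the analysis correctly inverts this forward model at realistic
SNR — not that it is robust to every artifact of real data.

## Analysis stages

**Widefield.**  ΔF/F per trial against the mean of the 1 s pre-onset
window; response amplitude = mean over frames 10–15 post onset; per
condition, pixels at or above the 99th percentile of the trial-averaged
map are averaged, ties at the cutoff included (selection is per
condition; the scope is a design choice, not dictated by the method's
definition).  Threshold = first level, ascending, whose two-sided paired
t test rejects at α = 0.05 *and* whose mean response exceeds the mean
baseline — the directional gate keeps suppression from registering as
detection; the gate is part of threshold assignment, not of the test, so
the test's null rejection rate remains the nominal α.  Frequencies with
no qualifying level receive the 110 dB SPL sentinel.  Zero-variance
difference vectors yield NaN p-values and never count as rejections,
except that a constant nonzero difference in the tested direction is
treated as exact evidence (p = 0) — this makes noiseless recovery
deterministic.  Block-mean pooling implements spatial downsampling
(preserves ΔF/F scale).

**Preprocessing.**  Rolling-percentile baseline: 10th percentile on
500-frame windows advanced by 50 frames, anchors at window centers,
linear interpolation with edge extension; traces shorter than one window
fall back to a single global percentile.  Percentiles use linear
interpolation between order statistics (the numpy default).  A
nonpositive baseline aborts with the offending ROI named, since it
signals neuropil over-subtraction.

**Responsiveness.**  The omnibus criterion is the partial F test (Type II
sums of squares) for the phase factor in
`amp ~ C(phase) + C(freq) + C(level) + C(freq):C(level):C(phase)` at
trial-level observations.  With the three-way interaction present, the
full model spans the phase × freq × level cell means, so the test is
computed from three projections (freq+level; +phase; cell means) —
implemented with explicit design matrices so that tens of thousands of
neurons can be tested in one vectorized pass, and verified in the tests
to agree with a standard least-squares ANOVA to 8 significant digits.
Post hoc typing uses one-sided paired comparisons (onset > baseline,
offset > onset) BH-corrected over the comparisons made.  Per-condition
masks use one-sided paired onset-vs-baseline tests within trial (pairing
controls slow state drift), BH at FDR 0.2 across the 20 conditions of
each neuron.

**Tuning metrics.**  CF is defined at the lowest level with *any*
significant frequency; amplitude ties break toward the lower frequency so
outputs are deterministic.  Note the known fragility: at FDR 0.2 a
false-positive condition below a neuron's true threshold relocates the
CF-defining level; the inter-trial bleed of real (and simulated) calcium
signals suppresses most of these, which is why CF recovery is ≥ 90 % on
realistic sessions but would not be on data with independent
phase-amplitude noise.  Bandwidth is computed at 70 dB SPL (configurable)
and neurons with noncontiguous significant frequencies at that level are
excluded (multi-peaked).

**Correlations.**  The 30-frame post-onset window is treated as
authoritative for both estimators.  Zero-variance windows are excluded
pairwise (NaN-aware averaging) rather than propagating undefined values.

**Decoding.**  Splits are stratified by class so each of the 20 classes
appears in every training fold at 10 trials/class, and the 10 folds
partition the trials.  PCA is fit on training rows only; the component
count is the smallest reaching ≥ 90 % explained variance.  LDA uses the
classical pooled-covariance discriminant with uniform priors and no
shrinkage.  Decoding accuracy depends on population size through the
variance cutoff: weak low-level response dimensions only survive the 90 %
cut when enough neurons respond at 30 dB SPL, which is why the
high-SNR benchmark uses ~300 neurons (the per-animal scale of the study
cohorts, which report hundreds of sound-responsive neurons per field).

**Tonotopy.**  Per-neuron weight is an indicator (1 per neuron) by
default; amplitude weighting is available as an option.  Cell size 10 µm;
cells with total weight below that of a single neuron at 3σ are left
unassigned, reproducing unassigned regions where neurons are absent.

**Genotyping.**  Sequence matching is exact and case-insensitive; IUPAC
ambiguity codes are rejected.  BsrI is modeled as recognition ACTGG with
the top-strand cut 1 nt 3′ of the site (offset configurable); fragment
lengths use top-strand cut coordinates, and both strands are scanned.
All genomic coordinates are 0-based half-open.  The shipped templates are
synthetic stand-ins constructed to reproduce the diagnostic 948 and
284 + 664 bp patterns (regenerable with
`scripts/make_genotyping_fixtures.py`); running the assay on the real
locus requires a user-supplied sequence.

## Problem sizes and reproducibility

Synthetic benchmarks use one session per cohort at the study's own
scale: 200 trials of 75 frames, 150–400 neurons for two-photon analyses,
600 neurons and 32 × 32 pixels for widefield.  Statistical calibrations
use 20,000–50,000 replicates (paired-test null) and 10,000 neurons
(responsiveness null).  All stochastic steps take explicit integer seeds;
identical seeds give byte-identical sessions, decodings, and output
files, and every result directory carries a manifest with config, seed,
and package version.

## Known limitations

* Trials are assumed complete and artifact-free; no motion-artifact
  exclusion is implemented (none is specified for the source analyses).
* The per-condition FDR of 0.2 is liberal by design; CF and bandwidth for
  individual neurons inherit its false-discovery behavior (see above).
* Widefield detection near threshold is one level step conservative by
  construction (a threshold exactly at a presented level produces its
  first response one step higher).
* No image registration, ROI segmentation, areal parcellation (A1/A2/AAF)
  or audio synthesis; extraction-pipeline output is consumed, not
  produced.
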