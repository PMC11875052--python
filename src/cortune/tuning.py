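"""Sound-responsiveness classification and frequency tuning metrics.

Each neuron's trial is summarized by three phase amplitudes: baseline (mean
dF/F over the 1 s before the tone), onset (mean over frames 5-9 after tone
onset), and offset (mean over frames 5-9 after tone offset).  A neuron is
sound-responsive when the phase factor explains variance in the linear
model

    amp ~ C(phase) + C(freq) + C(level) + C(freq):C(level):C(phase)

at alpha < 0.01 (partial F test, Type II sums of squares).  Responsive
neurons are typed Onset / Offset / Onset-Offset from one-sided paired
post hoc comparisons (BH-corrected), and tuning is computed from onset
amplitudes only: per-condition significance masks (paired onset-vs-baseline
tests, BH FDR 0.2 per neuron), bandwidth log2(fmax/fmin) at a reference
level, best frequency (BF) and characteristic frequency (CF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import StimulusGrid, TrialTensor
from .stats import benjamini_hochberg, paired_ttest_pvalues

__all__ = [
    "PhaseAmplitudes",
    "TuningResult",
    "phase_amplitudes",
    "omnibus_phase_pvalues",
    "classify_neurons",
    "classify_neuron",
    "significant_conditions",
    "tuning_metrics",
    "population_summaries",
    "analyze_tuning",
]

ONSET_WINDOW = (5, 9)  # frames after tone onset, inclusive
OFFSET_WINDOW = (5, 9)  # frames after tone offset, inclusive

CLASSES = ("none", "onset", "offset", "onset_offset")


@dataclass
class PhaseAmplitudes:
    """Per-neuron per-trial phase scalars, each of shape (N, F, A, R)."""

    baseline: np.ndarray
    onset: np.ndarray
    offset: np.ndarray
    grid: StimulusGrid

    def __post_init__(self) -> None:
        shape = self.baseline.shape
        g = self.grid
        if shape[1:] != (g.n_frequencies, g.n_levels, g.n_repeats):
            raise ValueError("phase amplitude shape does not match grid")
        if self.onset.shape != shape or self.offset.shape != shape:
            raise ValueError("phase arrays must be congruent")

    @property
    def n_neurons(self) -> int:
        return self.baseline.shape[0]


def phase_amplitudes(dff: TrialTensor, grid: StimulusGrid | None = None) -> PhaseAmplitudes:
    """Extract baseline / onset / offset window means from a dF/F tensor."""
    grid = grid or dff.grid
    v = dff.values
    on = grid.onset_frame
    off = on + grid.tone_frames
    b = grid.baseline_frames
    if on - b < 0:
        raise ValueError("baseline window underflows the trial")
    if off + OFFSET_WINDOW[1] >= grid.trial_frames:
        raise ValueError("offset window overflows the trial")
    baseline = v[:, on - b : on].mean(axis=1)
    onset = v[:, on + ONSET_WINDOW[0] : on + ONSET_WINDOW[1] + 1].mean(axis=1)
    offset = v[:, off + OFFSET_WINDOW[0] : off + OFFSET_WINDOW[1] + 1].mean(axis=1)
    return PhaseAmplitudes(baseline=baseline, onset=onset, offset=offset, grid=grid)


def _design_matrices(grid: StimulusGrid) -> tuple[np.ndarray, np.ndarray, int]:
    """Orthonormal bases for the reduced (freq+level) and mid (+phase) models.

    Observations are stacked phase-major: for phase in (baseline, onset,
    offset), all (f, a, r) cells in C order.  Returns (Q_reduced, Q_mid,
    n_cells) where n_cells = 3 * F * A indexes the full cell-means model.
    """
    F, A, R = grid.n_frequencies, grid.n_levels, grid.n_repeats
    n = 3 * F * A * R
    phase = np.repeat(np.arange(3), F * A * R)
    freq = np.tile(np.repeat(np.arange(F), A * R), 3)
    level = np.tile(np.repeat(np.arange(A), R), 3 * F)

    def dummies(codes, k):
        return (codes[:, None] == np.arange(1, k)[None, :]).astype(float)

    x_red = np.column_stack([np.ones(n), dummies(freq, F), dummies(level, A)])
    x_mid = np.column_stack([x_red, dummies(phase, 3)])
    q_red, _ = np.linalg.qr(x_red)
    q_mid, _ = np.linalg.qr(x_mid)
    return q_red, q_mid, 3 * F * A


def omnibus_phase_pvalues(pa: PhaseAmplitudes) -> np.ndarray:
    """Partial F-test p-value for the phase factor, per neuron (vectorized).

    Type II sums of squares: the phase factor is tested against the model
    containing frequency and level (the terms not involving phase), with
    the error term taken from the full model.  With the three-way
    freq:level:phase interaction present alongside the main effects, the
    full model spans the (phase, freq, level) cell means, so its residual
    is the within-cell sum of squares.
    """
    g = pa.grid
    F, A, R = g.n_frequencies, g.n_levels, g.n_repeats
    if R < 2:
        raise ValueError("need >= 2 repeats per condition")
    n = 3 * F * A * R
    N = pa.n_neurons
    # (n_obs, N) with phase-major stacking matching _design_matrices
    y = np.concatenate(
        [pa.baseline.reshape(N, -1), pa.onset.reshape(N, -1), pa.offset.reshape(N, -1)], axis=1
    ).T

    q_red, q_mid, n_cells = _design_matrices(g)
    tot = (y**2).sum(axis=0)
    rss_red = tot - ((q_red.T @ y) ** 2).sum(axis=0)
    rss_mid = tot - ((q_mid.T @ y) ** 2).sum(axis=0)
    # full (cell-means) residual: within-cell sum of squares
    cells = y.T.reshape(N, n_cells, R)
    rss_full = ((cells - cells.mean(axis=2, keepdims=True)) ** 2).sum(axis=(1, 2))

    df_num = 2  # phase has 3 levels
    df_den = n - n_cells
    from scipy.stats import f as f_dist

    with np.errstate(invalid="ignore", divide="ignore"):
        f_stat = ((rss_red - rss_mid) / df_num) / (rss_full / df_den)
        p = f_dist.sf(f_stat, df_num, df_den)
    return np.asarray(p, dtype=float)


def classify_neurons(
    pa: PhaseAmplitudes, alpha_model: float = 0.01, q_posthoc: float = 0.05
) -> np.ndarray:
    """Response class per neuron: none / onset / offset / onset_offset.

    Neurons passing the omnibus phase test at ``alpha_model`` get one-sided
    paired post hoc comparisons (onset > baseline; offset > onset) across
    matched (f, a, r) trials, BH-corrected over the comparisons made.
    """
    p_omni = omnibus_phase_pvalues(pa)
    N = pa.n_neurons
    classes = np.array(["none"] * N, dtype=object)
    responsive = np.where(p_omni < alpha_model)[0]
    if responsive.size == 0:
        return classes

    flat = lambda a: a.reshape(N, -1)
    p_on = paired_ttest_pvalues(
        flat(pa.onset)[responsive], flat(pa.baseline)[responsive], axis=1, alternative="greater"
    )
    p_off = paired_ttest_pvalues(
        flat(pa.offset)[responsive], flat(pa.onset)[responsive], axis=1, alternative="greater"
    )
    for j, i in enumerate(responsive):
        pv = np.array([p_on[j], p_off[j]])
        pv = np.where(np.isnan(pv), 1.0, pv)
        reject, _ = benjamini_hochberg(pv, q_posthoc)
        if reject[0] and reject[1]:
            classes[i] = "onset_offset"
        elif reject[0]:
            classes[i] = "onset"
        elif reject[1]:
            classes[i] = "offset"
    return classes


def classify_neuron(
    baseline: np.ndarray,
    onset: np.ndarray,
    offset: np.ndarray,
    grid: StimulusGrid,
    alpha_model: float = 0.01,
) -> str:
    """Single-neuron convenience wrapper around :func:`classify_neurons`."""
    pa = PhaseAmplitudes(
        baseline=baseline[None], onset=onset[None], offset=offset[None], grid=grid
    )
    return str(classify_neurons(pa, alpha_model=alpha_model)[0])


def significant_conditions(pa: PhaseAmplitudes, q: float = 0.2) -> np.ndarray:
    """Per-neuron F x A mask of conditions with a significant onset response.

    Per condition, onset amplitudes are compared against the same trials'
    baselines (paired, one-sided greater); the F*A p-values of a neuron are
    BH-corrected at FDR ``q`` and the mask is true where rejected with a
    positive mean difference.  Returns (N, F, A) bool.
    """
    g = pa.grid
    if g.n_repeats < 2:
        raise ValueError("need >= 2 repeats per condition")
    p = paired_ttest_pvalues(pa.onset, pa.baseline, axis=-1, alternative="greater")
    diff = (pa.onset - pa.baseline).mean(axis=-1)
    N = pa.n_neurons
    mask = np.zeros((N, g.n_frequencies, g.n_levels), dtype=bool)
    for i in range(N):
        pv = np.where(np.isnan(p[i]), 1.0, p[i]).ravel()
        reject, _ = benjamini_hochberg(pv, q)
        mask[i] = reject.reshape(g.n_frequencies, g.n_levels) & (diff[i] > 0)
    return mask


@dataclass
class TuningResult:
    """Tuning metrics for a single neuron."""

    response_class: str
    mask: np.ndarray  # (F, A) significant conditions
    amplitudes: np.ndarray  # (F, A) mean onset amplitude
    best_frequency_khz: float | None
    characteristic_frequency_khz: float | None
    bandwidth_octaves: float | None
    bandwidth_excluded: bool  # noncontiguous response at the reference level
    reference_level_db: float


def tuning_metrics(
    amplitudes: np.ndarray,
    mask: np.ndarray,
    grid: StimulusGrid,
    reference_level_db: float = 70.0,
    response_class: str = "onset",
) -> TuningResult:
    """Bandwidth, best frequency, and characteristic frequency from a mask.

    * bandwidth: log2(fmax/fmin) over the significant frequencies at the
      reference level; a single frequency gives 0; a noncontiguous
      significant set (multiple peaks) flags the neuron as excluded.
    * BF: frequency of the maximum amplitude over all significant conditions.
    * CF: at the lowest level with any significant frequency, the frequency
      with the highest amplitude (amplitude ties break toward the lower
      frequency).
    * An empty mask yields explicit None metrics.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    F, A = grid.n_frequencies, grid.n_levels
    if amplitudes.shape != (F, A) or mask.shape != (F, A):
        raise ValueError("amplitudes and mask must be (F, A)")
    freqs = np.asarray(grid.frequencies_khz)

    bf = cf = None
    if mask.any():
        masked = np.where(mask, amplitudes, -np.inf)
        bi = np.unravel_index(np.argmax(masked), masked.shape)
        bf = float(freqs[bi[0]])
        lowest = int(np.argmax(mask.any(axis=0)))  # lowest level with any significance
        col = np.where(mask[:, lowest], amplitudes[:, lowest], -np.inf)
        cf = float(freqs[np.argmax(col)])  # argmax takes the first (lower) frequency on ties

    ri = grid.level_index(reference_level_db)
    sig = np.where(mask[:, ri])[0]
    bandwidth = None
    excluded = False
    if sig.size:
        if np.any(np.diff(sig) != 1):
            excluded = True  # multiple peaks
        else:
            bandwidth = float(np.log2(freqs[sig[-1]] / freqs[sig[0]]))
    return TuningResult(
        response_class=response_class,
        mask=mask,
        amplitudes=amplitudes,
        best_frequency_khz=bf,
        characteristic_frequency_khz=cf,
        bandwidth_octaves=bandwidth,
        bandwidth_excluded=excluded,
        reference_level_db=reference_level_db,
    )


def population_summaries(classes) -> dict[str, float]:
    """Responsive and offset-responding fractions of a class list.

    Offset and Onset-Offset neurons are grouped as offset-responding.
    """
    classes = list(classes)
    if not classes:
        raise ValueError("empty class list")
    n = len(classes)
    responsive = sum(c in ("onset", "offset", "onset_offset") for c in classes)
    offset = sum(c in ("offset", "onset_offset") for c in classes)
    return {"responsive_fraction": responsive / n, "offset_fraction": offset / n}


def analyze_tuning(
    dff: TrialTensor,
    positions_um: np.ndarray | None = None,
    alpha_model: float = 0.01,
    q_conditions: float = 0.2,
    reference_level_db: float = 70.0,
) -> pd.DataFrame:
    """Full per-neuron tuning table from a dF/F trial tensor.

    Classifies every neuron, and for Onset / Onset-Offset neurons computes
    the condition mask and tuning metrics from onset amplitudes.  Returns
    one row per neuron with class, BF, CF, bandwidth and exclusion flag.
    """
    grid = dff.grid
    pa = phase_amplitudes(dff, grid)
    classes = classify_neurons(pa, alpha_model=alpha_model)
    masks = significant_conditions(pa, q=q_conditions)
    cond_amp = pa.onset.mean(axis=-1)  # (N, F, A)

    rows = []
    for i in range(pa.n_neurons):
        cls = classes[i]
        row: dict = {"neuron": i, "response_class": cls}
        if positions_um is not None:
            row["x_um"], row["y_um"] = positions_um[i]
        if cls in ("onset", "onset_offset"):
            res = tuning_metrics(
                cond_amp[i], masks[i], grid,
                reference_level_db=reference_level_db, response_class=cls,
            )
            row.update(
                bf_khz=res.best_frequency_khz,
                cf_khz=res.characteristic_frequency_khz,
                bandwidth_oct=res.bandwidth_octaves,
                bandwidth_excluded=res.bandwidth_excluded,
                n_significant=int(masks[i].sum()),
            )
        else:
            row.update(
                bf_khz=None, cf_khz=None, bandwidth_oct=None,
                bandwidth_excluded=False, n_significant=0,
            )
        rows.append(row)
    return pd.DataFrame(rows)
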