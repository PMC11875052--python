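"""Widefield pipeline: dF/F, condition response maps, 99th-percentile pixel
traces, and per-frequency sound-evoked threshold detection.

The widefield recording is unmixed into a pixel trial tensor, normalized
per trial against the 1 s pre-onset baseline, and summarized per condition
by the mean dF/F in the window 10-15 frames after tone onset.  For each
condition only the brightest pixels (trial-averaged amplitude at or above
the 99th percentile) are averaged; the per-trial baseline and response
amplitudes of that averaged trace feed a paired t test (alpha = 0.05,
uncorrected), and the detection threshold of a frequency is the first
(lowest) level whose test rejects with a positive mean response, or the
110 dB SPL sentinel when no level does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import StimulusGrid, TrialTensor
from .stats import paired_ttest_pvalues

__all__ = [
    "ThresholdProfile",
    "WidefieldAmplitudes",
    "block_downsample",
    "widefield_dff",
    "condition_response_map",
    "top_percentile_trace",
    "detect_thresholds",
    "widefield_threshold_pipeline",
]

SENTINEL_DB = 110.0

RESPONSE_WINDOW = (10, 15)  # frames after onset, inclusive


def block_downsample(movie: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean pooling of an (ny, nx, T) movie by an integer factor.

    Mean pooling preserves the dF/F scale.  Trailing rows/columns that do
    not fill a block are dropped.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    ny, nx, t = movie.shape
    ny2, nx2 = ny // factor, nx // factor
    if ny2 == 0 or nx2 == 0:
        raise ValueError("movie smaller than one block")
    m = movie[: ny2 * factor, : nx2 * factor]
    return m.reshape(ny2, factor, nx2, factor, t).mean(axis=(1, 3))


def widefield_dff(tensor: TrialTensor) -> TrialTensor:
    """Per-pixel, per-trial dF/F against the mean of the 1 s pre-onset frames."""
    grid = tensor.grid
    b = grid.baseline_frames
    if grid.onset_frame < b:
        raise ValueError("onset_frame shorter than the baseline window")
    v = tensor.values
    f0 = v[:, grid.onset_frame - b : grid.onset_frame].mean(axis=1, keepdims=True)
    if np.any(f0 <= 0):
        raise ValueError("nonpositive baseline fluorescence: non-physical input")
    return TrialTensor(
        values=(v - f0) / f0, grid=grid, unit_kind=tensor.unit_kind, is_dff=True
    )


def condition_response_map(dff: TrialTensor, window: tuple[int, int] = RESPONSE_WINDOW) -> np.ndarray:
    """Trial-averaged response amplitude per unit per condition.

    Amplitude = mean dF/F over frames ``onset + window[0] .. onset +
    window[1]`` (inclusive), averaged over repeats.  Returns (units, F, A).
    """
    grid = dff.grid
    lo, hi = window
    if grid.onset_frame + hi >= grid.trial_frames:
        raise ValueError("response window out of trial bounds")
    w = dff.values[:, grid.onset_frame + lo : grid.onset_frame + hi + 1]
    return w.mean(axis=1).mean(axis=-1)


@dataclass
class WidefieldAmplitudes:
    """Per-trial scalars of the 99th-percentile pixel average, per condition."""

    baseline: np.ndarray  # (F, A, R)
    response: np.ndarray  # (F, A, R)
    mean_traces: np.ndarray  # (T, F, A) trial-averaged selected-pixel trace
    selected: np.ndarray  # (units, F, A) bool, pixels entering each average
    grid: StimulusGrid


def top_percentile_trace(
    dff: TrialTensor,
    maps: np.ndarray | None = None,
    q: float = 99.0,
    window: tuple[int, int] = RESPONSE_WINDOW,
) -> WidefieldAmplitudes:
    """Average the brightest pixels per condition and extract trial scalars.

    Pixels whose trial-averaged amplitude is at or above the q-th percentile
    of that condition's map are averaged (ties at the cutoff included).
    Selection is per condition.
    """
    if not (0 < q < 100):
        raise ValueError("percentile must lie in (0, 100)")
    grid = dff.grid
    if dff.n_units < 1:
        raise ValueError("need at least one pixel")
    if maps is None:
        maps = condition_response_map(dff, window=window)
    F, A, R, T = grid.n_frequencies, grid.n_levels, grid.n_repeats, grid.trial_frames
    lo, hi = window
    b = grid.baseline_frames

    baseline = np.empty((F, A, R))
    response = np.empty((F, A, R))
    mean_traces = np.empty((T, F, A))
    selected = np.zeros((dff.n_units, F, A), dtype=bool)
    for fi in range(F):
        for ai in range(A):
            cut = np.percentile(maps[:, fi, ai], q)
            sel = maps[:, fi, ai] >= cut
            selected[:, fi, ai] = sel
            trace = dff.values[sel, :, fi, ai].mean(axis=0)  # (T, R)
            mean_traces[:, fi, ai] = trace.mean(axis=-1)
            baseline[fi, ai] = trace[grid.onset_frame - b : grid.onset_frame].mean(axis=0)
            response[fi, ai] = trace[grid.onset_frame + lo : grid.onset_frame + hi + 1].mean(axis=0)
    return WidefieldAmplitudes(
        baseline=baseline, response=response, mean_traces=mean_traces,
        selected=selected, grid=grid,
    )


@dataclass
class ThresholdProfile:
    """Per-frequency detection thresholds with the underlying test results."""

    frequencies_khz: np.ndarray  # (F,)
    thresholds_db: np.ndarray  # (F,), in levels_db or the 110 sentinel
    pvalues: np.ndarray  # (F, A) paired-t p-values
    mean_amplitudes: np.ndarray  # (F, A) mean response - baseline difference
    levels_db: np.ndarray  # (A,)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fi, f in enumerate(self.frequencies_khz):
            row = {"freq_khz": f, "threshold_db": self.thresholds_db[fi]}
            for ai, a in enumerate(self.levels_db):
                row[f"p_{a:.0f}dB"] = self.pvalues[fi, ai]
                row[f"amp_{a:.0f}dB"] = self.mean_amplitudes[fi, ai]
            rows.append(row)
        return pd.DataFrame(rows)


def detect_thresholds(
    baseline: np.ndarray,
    response: np.ndarray,
    grid: StimulusGrid,
    alpha: float = 0.05,
) -> ThresholdProfile:
    """Scan levels in ascending order; first significant level is threshold.

    Per (frequency, level): two-sided paired t test of per-trial response vs
    baseline amplitudes, uncorrected.  A level counts toward threshold only
    if it rejects at ``alpha`` *and* its mean response exceeds the mean
    baseline (suppression never registers as detection).  The sentinel
    110 dB SPL marks frequencies with no detectable response at the highest
    presented level.
    """
    baseline = np.asarray(baseline, dtype=float)
    response = np.asarray(response, dtype=float)
    F, A, R = grid.n_frequencies, grid.n_levels, grid.n_repeats
    if baseline.shape != (F, A, R) or response.shape != (F, A, R):
        raise ValueError("amplitude arrays must be (F, A, R) and congruent")
    if R < 2:
        raise ValueError("need >= 2 paired trials per condition")

    pvals = paired_ttest_pvalues(response, baseline, axis=-1)
    diffs = (response - baseline).mean(axis=-1)
    thresholds = np.full(F, SENTINEL_DB)
    for fi in range(F):
        for ai in range(A):  # levels ascending
            p = pvals[fi, ai]
            if np.isfinite(p) and p < alpha and diffs[fi, ai] > 0:
                thresholds[fi] = grid.levels_db[ai]
                break
    return ThresholdProfile(
        frequencies_khz=np.asarray(grid.frequencies_khz),
        thresholds_db=thresholds,
        pvalues=pvals,
        mean_amplitudes=diffs,
        levels_db=np.asarray(grid.levels_db),
    )


def widefield_threshold_pipeline(
    raw: TrialTensor, q: float = 99.0, alpha: float = 0.05
) -> ThresholdProfile:
    """Raw pixel tensor -> dF/F -> maps -> top-percentile trace -> thresholds."""
    dff = widefield_dff(raw)
    amps = top_percentile_trace(dff, q=q)
    return detect_thresholds(amps.baseline, amps.response, raw.grid, alpha=alpha)
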