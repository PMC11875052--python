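"""Pairwise signal and noise correlations among sound-responsive neurons.

Signal correlations measure the similarity of trial-averaged tone
responses: per condition, the Pearson r between two neurons' averaged
dF/F over the 30 frames following tone onset, averaged over conditions and
then over pairs.  Noise correlations measure co-fluctuation independent of
the stimulus: condition means are subtracted from each repeat and the
Pearson r of the residual windows is computed repeat by repeat, then
averaged over pairs, conditions, and repeats.  Zero-variance windows are
excluded pairwise rather than producing undefined values.
"""

from __future__ import annotations

import numpy as np

from .grid import TrialTensor

__all__ = ["signal_correlations", "noise_correlations"]

WINDOW_FRAMES = 30


def _normalize_windows(w: np.ndarray) -> np.ndarray:
    """Center and unit-normalize along the time axis; NaN where variance is 0.

    Input (..., T_window); dot products of the outputs are Pearson r.
    """
    c = w - w.mean(axis=-1, keepdims=True)
    norm = np.sqrt((c**2).sum(axis=-1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = c / norm
    z[np.broadcast_to(norm == 0, z.shape)] = np.nan
    return z


def _pair_mean(r_by_cond: np.ndarray) -> tuple[np.ndarray, float]:
    """Average an (n, n, ...) stack of per-condition r matrices.

    Returns the per-pair mean matrix (NaN where every condition was
    degenerate) and the grand mean over unordered off-diagonal pairs.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        per_pair = np.nanmean(r_by_cond, axis=-1)
        n = per_pair.shape[0]
        iu = np.triu_indices(n, k=1)
        return per_pair, float(np.nanmean(per_pair[iu]))


def signal_correlations(
    dff: TrialTensor,
    responsive_ids: np.ndarray,
    window_frames: int = WINDOW_FRAMES,
    freq_subset=None,
    level_subset=None,
) -> tuple[np.ndarray, float]:
    """Per-pair and animal-mean signal correlation.

    ``freq_subset`` / ``level_subset`` restrict the conditions entering the
    average (e.g. the variant conditioned on low frequencies and higher
    sound levels).

    Returns ``(per_pair, animal_mean)`` with ``per_pair`` an (n, n) matrix.
    """
    grid = dff.grid
    ids = np.asarray(responsive_ids, dtype=int)
    if ids.size < 2:
        raise ValueError("need >= 2 responsive neurons")
    fsel = (
        np.arange(grid.n_frequencies)
        if freq_subset is None
        else np.array([grid.freq_index(f) for f in freq_subset])
    )
    asel = (
        np.arange(grid.n_levels)
        if level_subset is None
        else np.array([grid.level_index(a) for a in level_subset])
    )
    on = grid.onset_frame
    if on + window_frames > grid.trial_frames:
        raise ValueError("correlation window overflows the trial")

    # trial-average, cut the post-onset window, restrict conditions
    mean_resp = dff.values[ids][:, on : on + window_frames].mean(axis=-1)  # (n, W, F, A)
    mean_resp = mean_resp[:, :, fsel][:, :, :, asel]
    n, w = mean_resp.shape[:2]
    z = _normalize_windows(np.moveaxis(mean_resp, 1, -1))  # (n, Fs, As, W)
    z = z.reshape(n, -1, w)  # (n, n_cond, W)
    # per-condition correlation matrices via batched dot products
    r = np.einsum("icw,jcw->ijc", np.nan_to_num(z), np.nan_to_num(z))
    degenerate = np.isnan(z[:, :, 0])  # (n, n_cond)
    bad = degenerate[:, None, :] | degenerate[None, :, :]
    r = np.where(bad, np.nan, r)
    return _pair_mean(r)


def noise_correlations(
    dff: TrialTensor,
    responsive_ids: np.ndarray,
    window_frames: int = WINDOW_FRAMES,
) -> tuple[np.ndarray, float]:
    """Per-pair and animal-mean noise correlation.

    Residual = repeat - condition mean; Pearson r of residual post-onset
    windows per pair per condition per repeat, averaged over everything.
    """
    grid = dff.grid
    ids = np.asarray(responsive_ids, dtype=int)
    if ids.size < 2:
        raise ValueError("need >= 2 responsive neurons")
    if grid.n_repeats < 2:
        raise ValueError("need >= 2 repeats")
    on = grid.onset_frame
    if on + window_frames > grid.trial_frames:
        raise ValueError("correlation window overflows the trial")

    v = dff.values[ids][:, on : on + window_frames]  # (n, W, F, A, R)
    resid = v - v.mean(axis=-1, keepdims=True)
    n, w = resid.shape[:2]
    z = _normalize_windows(np.moveaxis(resid, 1, -1))  # (n, F, A, R, W)
    z = z.reshape(n, -1, w)  # (n, cond*repeat, W)
    r = np.einsum("icw,jcw->ijc", np.nan_to_num(z), np.nan_to_num(z))
    degenerate = np.isnan(z[:, :, 0])
    bad = degenerate[:, None, :] | degenerate[None, :, :]
    r = np.where(bad, np.nan, r)
    return _pair_mean(r)
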