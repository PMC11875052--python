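"""Two-photon ROI preprocessing: neuropil subtraction, rolling-percentile
baseline, and dF/F.

The extraction pipeline yields, for every region of interest (ROI), a raw
somatic trace and a surrounding-neuropil trace.  Preprocessing removes
neuropil contamination (``F = F_roi - alpha * F_np`` with alpha = 0.7),
estimates a slow baseline F0 as a rolling 10th percentile (500-frame
windows, 50-frame steps, linearly interpolated), and normalizes to
``dF/F = (F - F0) / F0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RoiSet",
    "subtract_neuropil",
    "rolling_percentile_baseline",
    "dff_trace",
    "preprocess_roiset",
]


@dataclass
class RoiSet:
    """ROI and neuropil traces with positions and curation flags."""

    roi_traces: np.ndarray  # (n_roi, n_frames), a.u.
    neuropil_traces: np.ndarray  # (n_roi, n_frames), a.u.
    positions_um: np.ndarray  # (n_roi, 2) as (x, y)
    cell_flags: np.ndarray  # (n_roi,) bool or probability
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.roi_traces = np.atleast_2d(np.asarray(self.roi_traces, dtype=float))
        self.neuropil_traces = np.atleast_2d(np.asarray(self.neuropil_traces, dtype=float))
        self.positions_um = np.asarray(self.positions_um, dtype=float).reshape(-1, 2)
        self.cell_flags = np.asarray(self.cell_flags)
        n = self.roi_traces.shape[0]
        if self.neuropil_traces.shape != self.roi_traces.shape:
            raise ValueError("roi and neuropil trace arrays must be congruent")
        if len(self.positions_um) != n or len(self.cell_flags) != n:
            raise ValueError("positions / cell flags length mismatch")
        if not np.all(np.isfinite(self.positions_um)):
            raise ValueError("positions must be finite")

    @property
    def n_rois(self) -> int:
        return self.roi_traces.shape[0]


def subtract_neuropil(f_roi: np.ndarray, f_np: np.ndarray, alpha: float = 0.7) -> np.ndarray:
    """``F = F_roi - alpha * F_np``, elementwise."""
    f_roi = np.asarray(f_roi, dtype=float)
    f_np = np.asarray(f_np, dtype=float)
    if f_roi.shape != f_np.shape:
        raise ValueError(f"shape mismatch: {f_roi.shape} vs {f_np.shape}")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    return f_roi - alpha * f_np


def rolling_percentile_baseline(
    f: np.ndarray, window: int = 500, step: int = 50, pct: float = 10.0
) -> np.ndarray:
    """Slow baseline F0: rolling percentile with linear interpolation.

    The percentile is computed on windows of ``window`` frames advanced by
    ``step`` frames; anchor points sit at window centers, and the anchors are
    linearly interpolated (edge-extended) back to full length.  Traces
    shorter than one window fall back to a single global percentile.
    """
    f = np.asarray(f, dtype=float)
    squeeze = f.ndim == 1
    f = np.atleast_2d(f)
    n = f.shape[1]
    if n == 0:
        raise ValueError("empty trace")
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")

    if n < window:
        f0 = np.percentile(f, pct, axis=1, keepdims=True) * np.ones((1, n))
    else:
        starts = np.arange(0, n - window + 1, step)
        centers = starts + (window - 1) / 2.0
        # (n_roi, n_windows, window) view, percentile over the last axis
        win = np.lib.stride_tricks.sliding_window_view(f, window, axis=1)[:, ::step, :]
        anchors = np.percentile(win, pct, axis=2)
        frames = np.arange(n)
        f0 = np.empty_like(f)
        for i in range(f.shape[0]):
            f0[i] = np.interp(frames, centers, anchors[i])
    return f0[0] if squeeze else f0


def dff_trace(f: np.ndarray, f0: np.ndarray) -> np.ndarray:
    """``dF/F = (F - F0) / F0``; F0 must be positive everywhere.

    A nonpositive baseline signals over-subtraction of neuropil (or
    non-physical input) and raises with the offending ROI index.
    """
    f = np.asarray(f, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    if f.shape != f0.shape:
        raise ValueError("F and F0 must be congruent")
    bad = np.where(np.any(np.atleast_2d(f0) <= 0, axis=1))[0]
    if bad.size:
        raise ValueError(
            f"nonpositive baseline for ROI(s) {bad.tolist()[:10]}: "
            "check neuropil subtraction"
        )
    return (f - f0) / f0


def preprocess_roiset(
    rois: RoiSet,
    alpha: float = 0.7,
    window: int = 500,
    step: int = 50,
    pct: float = 10.0,
) -> np.ndarray:
    """Full preprocessing chain: neuropil subtraction -> F0 -> dF/F."""
    f = subtract_neuropil(rois.roi_traces, rois.neuropil_traces, alpha=alpha)
    f0 = rolling_percentile_baseline(f, window=window, step=step, pct=pct)
    return dff_trace(f, f0)
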