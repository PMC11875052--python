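"""Winner-take-all characteristic-frequency area maps.

The imaging field is gridded into small cells; each CF class contributes a
Gaussian-weighted (sigma = 60 um) sum over its neurons to every cell, and
the class with the largest weight claims the cell.  Cells with negligible
total weight (no neurons within ~3 sigma) stay unassigned, and fractional
areas are computed over assigned cells only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CFAreaMap", "cf_area_map", "fractional_area"]

DEFAULT_SIGMA_UM = 60.0
DEFAULT_CELL_UM = 10.0


@dataclass
class CFAreaMap:
    """Gridded winner-take-all CF assignment."""

    assigned_khz: np.ndarray  # (ny, nx) CF in kHz, NaN where unassigned
    total_weight: np.ndarray  # (ny, nx) summed Gaussian weight
    classes_khz: np.ndarray  # sorted distinct CF classes
    cell_um: float
    sigma_um: float
    origin_um: tuple[float, float]

    @property
    def n_assigned(self) -> int:
        return int(np.isfinite(self.assigned_khz).sum())


def cf_area_map(
    positions_um: np.ndarray,
    cf_khz: np.ndarray,
    sigma_um: float = DEFAULT_SIGMA_UM,
    cell_um: float = DEFAULT_CELL_UM,
    min_weight: float | None = None,
    weights: np.ndarray | None = None,
    extent_um: tuple[float, float, float, float] | None = None,
) -> CFAreaMap:
    """Winner-take-all CF assignment on a spatial grid.

    For each grid cell and CF class, ``weight = sum_neurons exp(-d^2 / (2
    sigma^2))`` over the class's neurons (each neuron counts 1 unless
    ``weights`` supplies per-neuron amplitudes); the argmax class is
    assigned.  Cells whose total weight falls below ``min_weight`` (default:
    the weight of a single neuron at 3 sigma) are left unassigned.

    ``extent_um`` fixes the mapped rectangle (x0, x1, y0, y1); by default it
    hugs the neuron bounding box.
    """
    positions = np.asarray(positions_um, dtype=float).reshape(-1, 2)
    cf = np.asarray(cf_khz, dtype=float)
    keep = np.isfinite(cf)
    positions, cf = positions[keep], cf[keep]
    if weights is not None:
        weights = np.asarray(weights, dtype=float)[keep]
    if cf.size == 0:
        raise ValueError("no neurons with a defined CF")

    if extent_um is None:
        x0, x1 = positions[:, 0].min(), positions[:, 0].max()
        y0, y1 = positions[:, 1].min(), positions[:, 1].max()
    else:
        x0, x1, y0, y1 = extent_um
    nx = max(int(np.ceil((x1 - x0) / cell_um)), 1)
    ny = max(int(np.ceil((y1 - y0) / cell_um)), 1)
    cx = x0 + (np.arange(nx) + 0.5) * cell_um
    cy = y0 + (np.arange(ny) + 0.5) * cell_um
    gx, gy = np.meshgrid(cx, cy)

    classes = np.unique(cf)
    w_by_class = np.zeros((len(classes), ny, nx))
    for ci, c in enumerate(classes):
        sel = cf == c
        d2 = (gx[..., None] - positions[sel, 0]) ** 2 + (gy[..., None] - positions[sel, 1]) ** 2
        contrib = np.exp(-d2 / (2 * sigma_um**2))
        if weights is not None:
            contrib = contrib * weights[sel]
        w_by_class[ci] = contrib.sum(axis=-1)

    total = w_by_class.sum(axis=0)
    if min_weight is None:
        min_weight = float(np.exp(-9.0 / 2.0))  # single neuron at 3 sigma
    winner = np.argmax(w_by_class, axis=0)
    assigned = classes[winner].astype(float)
    assigned[total < min_weight] = np.nan
    return CFAreaMap(
        assigned_khz=assigned,
        total_weight=total,
        classes_khz=classes,
        cell_um=cell_um,
        sigma_um=sigma_um,
        origin_um=(float(x0), float(y0)),
    )


def fractional_area(area_map: CFAreaMap, bins: dict | None = None) -> dict[str, float]:
    """Fraction of assigned map area per CF bin.

    Default bins are the low/high split used for hearing-loss phenotyping
    (<= 16 kHz vs >= 32 kHz) plus a per-frequency breakdown; fractions are
    over assigned cells and sum to 1 within each bin family.
    """
    assigned = area_map.assigned_khz
    valid = np.isfinite(assigned)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("fully unassigned map")
    vals = assigned[valid]
    out: dict[str, float] = {}
    if bins is None:
        out["le_16khz"] = float((vals <= 16.0).sum() / n)
        out["ge_32khz"] = float((vals >= 32.0).sum() / n)
        for c in area_map.classes_khz:
            out[f"{c:g}khz"] = float((vals == c).sum() / n)
    else:
        for name, (lo, hi) in bins.items():
            out[name] = float(((vals >= lo) & (vals <= hi)).sum() / n)
    return out
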