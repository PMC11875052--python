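"""Readers and writers for the formats the pipeline touches.

The two-photon side consumes the extraction-pipeline directory layout
(per-array ``F.npy``, ``Fneu.npy``, ``iscell.npy``, ``stat.npy``,
``ops.npy``); the simulator emits the same layout so synthetic sessions
exercise the real ingestion path.  Trial tensors persist as HDF5 with the
grid serialized as attributes; result tables are CSV with fixed column
order plus a JSON manifest recording config, seed, and package version.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .grid import StimulusGrid, StimulusLog, TrialTensor
from .preproc import RoiSet

__all__ = [
    "write_extraction_dir",
    "read_extraction_dir",
    "save_tensor_h5",
    "load_tensor_h5",
    "load_movie",
    "write_results",
]

logger = logging.getLogger("cortune")

DEFAULT_MICRON_PER_PIXEL = 1.0


def write_extraction_dir(
    path,
    roi_traces: np.ndarray,
    neuropil_traces: np.ndarray,
    positions_um: np.ndarray,
    frame_rate_hz: float,
    cell_probs: np.ndarray | None = None,
    micron_per_pixel: float = DEFAULT_MICRON_PER_PIXEL,
) -> Path:
    """Write traces in the extraction-pipeline layout the reader consumes."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    roi_traces = np.asarray(roi_traces, dtype=float)
    n = roi_traces.shape[0]
    np.save(path / "F.npy", roi_traces)
    np.save(path / "Fneu.npy", np.asarray(neuropil_traces, dtype=float))
    if cell_probs is None:
        cell_probs = np.ones(n)
    iscell = np.column_stack([(np.asarray(cell_probs) > 0.5).astype(float), cell_probs])
    np.save(path / "iscell.npy", iscell)
    pos_px = np.asarray(positions_um, dtype=float) / micron_per_pixel
    stat = np.array([{"med": (float(y), float(x))} for x, y in pos_px], dtype=object)
    np.save(path / "stat.npy", stat, allow_pickle=True)
    ops = {"fs": float(frame_rate_hz), "micron_per_pixel": float(micron_per_pixel)}
    np.save(path / "ops.npy", np.array(ops, dtype=object), allow_pickle=True)
    return path


def read_extraction_dir(
    path,
    cell_threshold: float = 0.5,
    default_micron_per_pixel: float = DEFAULT_MICRON_PER_PIXEL,
) -> RoiSet:
    """Load an extraction directory into a curated :class:`RoiSet`.

    ROIs are filtered by the cell flag at ``cell_threshold``; centroid
    positions are converted to micrometers using the pixel size in the
    metadata, falling back (with a warning) to ``default_micron_per_pixel``
    when absent.
    """
    path = Path(path)
    for name in ("F.npy", "Fneu.npy", "iscell.npy", "stat.npy", "ops.npy"):
        if not (path / name).exists():
            raise FileNotFoundError(f"extraction directory missing {name}: {path}")
    f = np.load(path / "F.npy")
    fneu = np.load(path / "Fneu.npy")
    iscell = np.load(path / "iscell.npy")
    stat = np.load(path / "stat.npy", allow_pickle=True)
    ops = np.load(path / "ops.npy", allow_pickle=True).item()
    if f.shape != fneu.shape or len(iscell) != len(f) or len(stat) != len(f):
        raise ValueError("extraction arrays have mismatched lengths")

    mpp = ops.get("micron_per_pixel")
    if mpp is None:
        warnings.warn(
            f"no pixel-size metadata in {path}; assuming "
            f"{default_micron_per_pixel} um/px"
        )
        mpp = default_micron_per_pixel
    keep = iscell[:, 1] > cell_threshold if iscell.ndim == 2 else iscell.astype(bool)
    positions = np.array([(s["med"][1] * mpp, s["med"][0] * mpp) for s in stat])
    logger.info("read %d ROIs (%d pass cell flag) from %s", len(f), int(keep.sum()), path)
    return RoiSet(
        roi_traces=f[keep],
        neuropil_traces=fneu[keep],
        positions_um=positions[keep],
        cell_flags=np.ones(int(keep.sum()), dtype=bool),
        frame_rate_hz=float(ops["fs"]),
    )


def save_tensor_h5(path, tensor: TrialTensor) -> None:
    """Persist a trial tensor with named dimensions and grid attributes."""
    with h5py.File(path, "w") as fh:
        d = fh.create_dataset("values", data=tensor.values)
        d.attrs["dims"] = "unit,time,frequency,level,repeat"
        fh.attrs["unit_kind"] = tensor.unit_kind
        fh.attrs["is_dff"] = tensor.is_dff
        fh.attrs["grid"] = json.dumps(tensor.grid.to_dict())


def load_tensor_h5(path) -> TrialTensor:
    with h5py.File(path, "r") as fh:
        grid = StimulusGrid.from_dict(json.loads(fh.attrs["grid"]))
        return TrialTensor(
            values=fh["values"][...],
            grid=grid,
            unit_kind=str(fh.attrs["unit_kind"]),
            is_dff=bool(fh.attrs["is_dff"]),
        )


def load_movie(path, dataset: str = "movie") -> np.ndarray:
    """Load a widefield movie from TIFF ((T, Y, X) -> (Y, X, T)) or HDF5."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        stack = tifffile.imread(path)
        return np.moveaxis(stack, 0, -1)
    with h5py.File(path, "r") as fh:
        return fh[dataset][...]


def write_results(results: dict, out_dir, config: dict | None = None, seed: int | None = None) -> list[Path]:
    """Write result tables/objects with a reproducibility manifest.

    ``results`` maps names to DataFrames (written as CSV with fixed column
    order) or JSON-serializable objects (written with sorted keys).  The
    manifest records the config, the seed, and the package version so every
    run is reproducible from its outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, obj in sorted(results.items()):
        if isinstance(obj, pd.DataFrame):
            p = out_dir / f"{name}.csv"
            obj.to_csv(p, index=False)
        else:
            p = out_dir / f"{name}.json"
            with open(p, "w") as fh:
                json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        written.append(p)
    from . import __version__

    manifest = {
        "package": "cortune",
        "version": __version__,
        "seed": seed,
        "config": config or {},
        "files": [p.name for p in written],
    }
    mp = out_dir / "manifest.json"
    with open(mp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    written.append(mp)
    return written


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
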