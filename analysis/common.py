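"""Shared plumbing for the analysis drivers.

Synthetic sessions are cached under scratch/sessions/ (bulky arrays); the
drivers write only tables and summaries under results/.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

import cortune as c
from cortune import io as cio

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "sessions"
RESULTS = ROOT / "results"

# the study cohorts compared throughout: young hearing-loss (ahl) B6 mice,
# congenic Ahl+ B6 littermate-equivalents, and the aged ahl time point
PRESETS_2P = ("ahl_b6_2p5mo", "ahl_plus_b6")
PRESETS_WF = ("ahl_b6_2p5mo", "ahl_plus_b6", "ahl_b6_6mo")

N_NEURONS = 400
BASE_SEED = 1000
NOISE = dict(trace_sigma=1.0, drift_amplitude=0.05)


def session_dir(preset: str) -> Path:
    return SCRATCH / preset


def simulate_twophoton(preset: str, overwrite: bool = False) -> Path:
    """Synthesize one two-photon session and emit the extraction layout."""
    out = session_dir(preset)
    if (out / "F.npy").exists() and not overwrite:
        return out
    grid = c.default_twophoton_grid()
    seed = BASE_SEED + list(c.synth.PRESETS).index(preset)  # stable per preset
    pop = c.generate_ground_truth(N_NEURONS, preset, grid, seed=seed)
    noise = c.NoiseConfig(seed=seed + 500, **NOISE)
    sess = c.synthesize_session(pop, grid, noise)
    cio.write_extraction_dir(
        out, sess.roi_traces, sess.neuropil_traces, sess.positions_um, grid.frame_rate_hz
    )
    sess.log.to_csv(out / "stimulus_log.csv")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(
            {"preset": preset, "seed": seed, "grid": grid.to_dict(),
             "neurons": pop.to_records()},
            fh, indent=2,
        )
    return out


def load_dff_tensor(preset: str):
    """Ingest a cached session through the real extraction-reading path."""
    path = simulate_twophoton(preset)
    grid = c.default_twophoton_grid()
    rois = cio.read_extraction_dir(path)
    dff = c.preprocess_roiset(rois)
    log = c.StimulusLog.from_csv(path / "stimulus_log.csv")
    tensor = c.unmix_trials(dff, log, grid)
    tensor.is_dff = True
    return tensor, rois, json.loads((path / "ground_truth.json").read_text())
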