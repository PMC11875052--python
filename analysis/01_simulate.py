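"""Synthesize the study's imaging sessions with known ground truth.

Generates one two-photon session per cohort preset (400 neurons, 5
frequencies x 4 levels x 10 repeats at 15 Hz) in the extraction-pipeline
layout, plus the stimulus log and a ground-truth sidecar for the recovery
analyses that follow.
"""

import json

import numpy as np

from common import PRESETS_2P, simulate_twophoton


def main():
    for preset in PRESETS_2P:
        path = simulate_twophoton(preset, overwrite=False)
        truth = json.loads((path / "ground_truth.json").read_text())
        cfs = np.array([n["cf_khz"] for n in truth["neurons"]])
        thr = np.array([n["threshold_db"] for n in truth["neurons"]])
        print(f"{preset}: {len(cfs)} neurons -> {path}")
        print(f"  implanted CF mass <= 16 kHz: {np.mean(cfs <= 16):.2f}")
        print(f"  median implanted threshold at CF: {np.median(thr):.0f} dB SPL")


if __name__ == "__main__":
    main()
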