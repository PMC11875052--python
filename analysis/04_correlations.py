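"""Signal and noise correlations among sound-responsive neurons.

Computes, per cohort: the mean pairwise signal correlation (trial-averaged
responses, 30-frame post-onset windows, averaged over conditions and
pairs), the mean noise correlation (repeat-by-repeat residuals), and the
signal correlation conditioned on low frequencies (4-16 kHz) at higher
sound levels (70/90 dB SPL) - the regime where hearing-loss reorganization
concentrates responses and correlations rise.
"""

import json

import numpy as np
import pandas as pd

import cortune as c
from common import PRESETS_2P, RESULTS, load_dff_tensor


def main():
    RESULTS.mkdir(exist_ok=True)
    out = {}
    for preset in PRESETS_2P:
        tensor, rois, _ = load_dff_tensor(preset)
        tab = c.analyze_tuning(tensor, rois.positions_um)
        ids = tab[tab.response_class != "none"].neuron.to_numpy()
        _, sig = c.signal_correlations(tensor, ids)
        _, noise = c.noise_correlations(tensor, ids)
        _, sig_low = c.signal_correlations(
            tensor, ids, freq_subset=[4, 8, 16], level_subset=[70, 90]
        )
        out[preset] = {
            "n_responsive": int(len(ids)),
            "signal_correlation": sig,
            "noise_correlation": noise,
            "signal_correlation_low_freq_high_level": sig_low,
        }
        print(f"{preset}: signal r={sig:.3f}, noise r={noise:.3f}, "
              f"conditioned signal r={sig_low:.3f} ({len(ids)} neurons)")
    with open(RESULTS / "correlations.json", "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)


if __name__ == "__main__":
    main()
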