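"""Per-neuron responsiveness and tuning across cohorts.

Reads each simulated session back through the extraction-directory path,
preprocesses (neuropil subtraction, rolling 10th-percentile baseline,
dF/F), classifies responsiveness with the phase linear model, and computes
per-neuron condition masks, bandwidth, best and characteristic frequency.
The ahl cohort's CF distribution should pile onto <= 16 kHz.
"""

import numpy as np
import pandas as pd

import cortune as c
from common import PRESETS_2P, RESULTS, load_dff_tensor


def main():
    RESULTS.mkdir(exist_ok=True)
    summaries = {}
    for preset in PRESETS_2P:
        tensor, rois, truth = load_dff_tensor(preset)
        tab = c.analyze_tuning(tensor, rois.positions_um)
        tab.to_csv(RESULTS / f"tuning_{preset}.csv", index=False)
        pop = c.population_summaries(tab.response_class)
        withcf = tab[tab.cf_khz.notna()]
        cf_true = np.array([n["cf_khz"] for n in truth["neurons"]])
        cf_rec = withcf.cf_khz.to_numpy()
        match = np.mean(cf_rec == cf_true[withcf.neuron.to_numpy()])
        summaries[preset] = {
            **pop,
            "n_neurons": len(tab),
            "n_with_cf": int(len(withcf)),
            "cf_mass_le_16khz": float(np.mean(cf_rec <= 16)),
            "cf_recovery_vs_implanted": float(match),
            "median_bandwidth_oct": float(withcf.bandwidth_oct.dropna().median()),
        }
        print(f"{preset}: responsive {pop['responsive_fraction']:.2f}, "
              f"offset {pop['offset_fraction']:.2f}, "
              f"CF<=16 kHz {summaries[preset]['cf_mass_le_16khz']:.2f}, "
              f"CF recovery {match:.2f}")
    pd.Series(summaries).to_json(RESULTS / "tuning_summary.json", indent=2)


if __name__ == "__main__":
    main()
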