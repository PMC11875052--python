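"""Winner-take-all characteristic-frequency maps and fractional areas.

Builds the Gaussian-weighted (sigma = 60 um) winner-take-all CF map from
each cohort's recovered neuron positions and CFs, and reports the
fraction of assigned cortical area per CF band.  In the ahl cohort most
of the map should belong to <= 16 kHz.
"""

import json

import numpy as np
import pandas as pd

import cortune as c
from common import PRESETS_2P, RESULTS


def main():
    out = {}
    for preset in PRESETS_2P:
        tab = pd.read_csv(RESULTS / f"tuning_{preset}.csv")
        sel = tab[tab.cf_khz.notna()]
        amap = c.cf_area_map(
            sel[["x_um", "y_um"]].to_numpy(), sel.cf_khz.to_numpy(),
            extent_um=(0, 1000, 0, 1000),
        )
        fa = c.fractional_area(amap)
        out[preset] = {
            "n_neurons": int(len(sel)),
            "assigned_cells": amap.n_assigned,
            **{k: round(v, 4) for k, v in fa.items()},
        }
        print(f"{preset}: area <=16 kHz {fa['le_16khz']:.2f}, "
              f">=32 kHz {fa['ge_32khz']:.2f} "
              f"({amap.n_assigned} of {amap.assigned_khz.size} cells assigned)")
    with open(RESULTS / "fractional_area.json", "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)


if __name__ == "__main__":
    main()
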