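"""Population decoding of tone frequency and sound level.

Per cohort: trial features are per-neuron mean dF/F over the 1 s after
tone onset; stratified 90/10 splits repeated 10 times; per split, PCA
components explaining >= 90% of training variance feed a linear
discriminant classifier.  Chance is 1/20 = 5%.  The ahl cohort should
lose accuracy specifically at high frequencies and low sound levels.
"""

import json

import numpy as np
import pandas as pd

import cortune as c
from common import PRESETS_2P, RESULTS, load_dff_tensor

SEED = 0


def main():
    grid = c.default_twophoton_grid()
    out = {"chance": c.chance_level(grid)}
    for preset in PRESETS_2P:
        tensor, _, _ = load_dff_tensor(preset)
        X, y = c.trial_feature_matrix(tensor)
        res = c.decode_pca_lda(X, y, seed=SEED)
        conf = pd.DataFrame(res.confusion)
        conf.to_csv(RESULTS / f"confusion_{preset}.csv", index=False)
        per_class = res.per_class_accuracy.reshape(grid.n_frequencies, grid.n_levels)
        out[preset] = {
            "accuracy": res.accuracy,
            "per_frequency_accuracy": {
                f"{f:g}khz": float(per_class[fi].mean())
                for fi, f in enumerate(grid.frequencies_khz)
            },
            "per_level_accuracy": {
                f"{a:g}db": float(per_class[:, ai].mean())
                for ai, a in enumerate(grid.levels_db)
            },
            "pca_components_per_fold": res.n_components.tolist(),
        }
        print(f"{preset}: accuracy {res.accuracy:.2f} (chance {out['chance']:.2f})")
        print("  by frequency:", {k: round(v, 2) for k, v in out[preset]["per_frequency_accuracy"].items()})
    with open(RESULTS / "decoding.json", "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)


if __name__ == "__main__":
    main()
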