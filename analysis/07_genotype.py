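"""In-silico Cdh23 genotyping of the packaged allele templates.

Runs the PCR + BsrI digest model on the synthetic ahl and Ahl+ templates
and on their heterozygous combination, reproducing the diagnostic band
patterns: 284 + 664 bp (ahl/ahl), 948 bp (Ahl/Ahl), all three (Ahl/ahl).
"""

import json

from cortune import genotyping as geno
from common import RESULTS


def main():
    RESULTS.mkdir(exist_ok=True)
    calls = {}
    fragments = {}
    for allele in ("ahl", "ahl_plus"):
        amp = geno.insilico_pcr(geno.load_fixture_template(allele))
        frags = geno.digest_fragments(amp, geno.find_cut_sites(amp))
        fragments[allele] = frags
        res = geno.call_genotype(frags)
        calls[f"{allele}_homozygote"] = {"bands": res.fragments_bp, "call": res.call}
    het = sorted(set(fragments["ahl"]) | set(fragments["ahl_plus"]))
    res = geno.call_genotype(het)
    calls["heterozygote"] = {"bands": res.fragments_bp, "call": res.call}
    for name, r in calls.items():
        print(f"{name}: bands {r['bands']} bp -> {r['call']}")
    with open(RESULTS / "genotype_calls.json", "w") as fh:
        json.dump(calls, fh, indent=2, sort_keys=True)


if __name__ == "__main__":
    main()
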