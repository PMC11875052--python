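"""Regenerate the synthetic Cdh23-like allele templates.

The templates are constructed sequences (not the real locus): primers and
the SNP-dependent BsrI site are placed so the assay reproduces the
diagnostic 948 / 284+664 bp fragment pattern, then all unintended motif
and primer occurrences are scrubbed.  Deterministic; the repository
already ships the outputs under src/cortune/data/."""
import numpy as np
FWD = "GTGCTGTTGGGCCTCCTTGC"
REV = "GGGGTGGACCATGATCTATTTTGT"
from Bio.Seq import Seq
REV_RC = str(Seq(REV).reverse_complement())
FLANK = 120
AMP = 948
SITE_POS = FLANK + 278  # ACTGG here -> cut at amplicon coord 284
SNP_POS = SITE_POS + 4

def protected(i):
    return (FLANK <= i < FLANK + len(FWD)) or (FLANK + AMP - len(REV_RC) <= i < FLANK + AMP) or (SITE_POS <= i < SITE_POS + 5)

def violations(s, allow_site_at=None):
    bad = []
    for motif in ("ACTGG", "CCAGT"):
        i = s.find(motif)
        while i != -1:
            if not (motif == "ACTGG" and i == allow_site_at):
                bad.append((i, len(motif)))
            i = s.find(motif, i + 1)
    for motif in (FWD, REV_RC):
        pos = []
        i = s.find(motif)
        while i != -1:
            pos.append(i); i = s.find(motif, i + 1)
        assert len(pos) >= 1
        for p in pos[1:]:
            bad.append((p, len(motif)))
    return bad

rng = np.random.default_rng(20250929)
bases = np.array(list("ACGT"))
n = 2 * FLANK + AMP
seq = list(rng.choice(bases, size=n))
seq[FLANK:FLANK+len(FWD)] = list(FWD)
seq[FLANK+AMP-len(REV_RC):FLANK+AMP] = list(REV_RC)
seq[SITE_POS:SITE_POS+5] = list("ACTGG")
for _ in range(10000):
    s = "".join(seq)
    bad = violations(s, allow_site_at=SITE_POS)
    if not bad:
        break
    i0, ln = bad[0]
    cand = [j for j in range(i0, i0 + ln) if not protected(j)]
    j = int(rng.choice(cand))
    seq[j] = str(rng.choice([b for b in "ACGT" if b != seq[j]]))
else:
    raise SystemExit("failed to scrub")
ahl = "".join(seq)
plus = list(ahl); plus[SNP_POS] = "A"  # ACTGG -> ACTGA, site ablated
ahl_plus = "".join(plus)
assert not violations(ahl_plus)  # no site allowed at all

from cortune import genotyping as g
amp_ahl = g.insilico_pcr(ahl)
amp_plus = g.insilico_pcr(ahl_plus)
assert len(amp_ahl) == 948 and len(amp_plus) == 948, (len(amp_ahl), len(amp_plus))
fa = g.digest_fragments(amp_ahl, g.find_cut_sites(amp_ahl))
fp = g.digest_fragments(amp_plus, g.find_cut_sites(amp_plus))
assert sorted(fa) == [284, 664], fa
assert fp == [948], fp
assert g.call_genotype(fa).call == "ahl/ahl"
assert g.call_genotype(fp).call == "Ahl/Ahl"
assert g.call_genotype(sorted(set(fa) | set(fp))).call == "Ahl/ahl"

def write(path, name, desc, s):
    with open(path, "w") as fh:
        fh.write(f">{name} {desc}\n")
        for i in range(0, len(s), 70):
            fh.write(s[i:i+70] + "\n")

write("src/cortune/data/cdh23_synthetic_ahl.fasta",
      "cdh23_synthetic_ahl",
      "synthetic stand-in for the Cdh23 exon-9 ahl allele (BsrI site present; not the real locus)", ahl)
write("src/cortune/data/cdh23_synthetic_ahl_plus.fasta",
      "cdh23_synthetic_ahl_plus",
      "synthetic stand-in for the Cdh23 exon-9 Ahl+ allele (BsrI site ablated at the SNP; not the real locus)", ahl_plus)
print("ok; fragments:", fa, fp)
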