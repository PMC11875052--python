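"""In-silico model of the Cdh23 PCR + BsrI digest genotyping assay.

The age-related hearing-loss (ahl) variant of Cdh23 carried by C57BL/6
mice creates a BsrI restriction site inside a ~950 bp amplicon; the
protective Ahl+ allele lacks it.  The assay is modeled in three steps:
exact-match PCR between the published primers, a both-strand scan for the
BsrI recognition sequence (modeled as ACTGG cutting the top strand 1 nt
3' of the site), and fragment-length computation.  Band patterns map to
genotype calls:

    {948}            -> Ahl/Ahl   (uncut)
    {284, 664}       -> ahl/ahl   (both alleles cut)
    {284, 664, 948}  -> Ahl/ahl   (heterozygote)

Sequence matching is exact and case-insensitive; IUPAC ambiguity codes are
rejected.  Genomic coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from Bio.Seq import Seq
from Bio import SeqIO

__all__ = [
    "FWD_PRIMER",
    "REV_PRIMER",
    "BSRI_RECOGNITION",
    "DigestModel",
    "GenotypeCall",
    "insilico_pcr",
    "find_cut_sites",
    "digest_fragments",
    "call_genotype",
    "genotype_template",
    "load_fixture_template",
]

FWD_PRIMER = "GTGCTGTTGGGCCTCCTTGC"
REV_PRIMER = "GGGGTGGACCATGATCTATTTTGT"
BSRI_RECOGNITION = "ACTGG"
BSRI_TOP_OFFSET = 1  # cut 1 nt 3' of the recognition sequence, top strand

EXPECTED_UNCUT_BP = 948
EXPECTED_CUT_BP = (284, 664)

_VALID = set("ACGT")


def _clean(seq: str, what: str = "sequence") -> str:
    s = str(seq).upper().replace("\n", "").replace(" ", "")
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")
    return s


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


@dataclass
class DigestModel:
    """A resolved assay: template, primers, enzyme, and amplicon coordinates."""

    template: str
    fwd_primer: str
    rev_primer: str
    amplicon_start: int  # 0-based, half-open on the template
    amplicon_end: int
    recognition: str = BSRI_RECOGNITION
    top_offset: int = BSRI_TOP_OFFSET

    @property
    def amplicon(self) -> str:
        return self.template[self.amplicon_start : self.amplicon_end]


@dataclass
class GenotypeCall:
    fragments_bp: list[int]
    call: str  # "Ahl/Ahl" | "Ahl/ahl" | "ahl/ahl" | "indeterminate"


def insilico_pcr(template: str, fwd_primer: str = FWD_PRIMER, rev_primer: str = REV_PRIMER) -> str:
    """Amplicon from the forward primer through the reverse primer site.

    The forward primer must match the top strand exactly once; the reverse
    primer must match the bottom strand (i.e. its reverse complement appears
    on the top strand) exactly once, downstream of the forward match.  The
    amplicon includes both primer sequences.
    """
    t = _clean(template, "template")
    fwd = _clean(fwd_primer, "forward primer")
    rev = _clean(rev_primer, "reverse primer")
    rev_rc = str(Seq(rev).reverse_complement())

    fwd_hits = _find_all(t, fwd)
    rev_hits = _find_all(t, rev_rc)
    if len(fwd_hits) == 0:
        raise ValueError("forward primer not found in template")
    if len(fwd_hits) > 1:
        raise ValueError("forward primer matches multiple loci: ambiguous amplification")
    if len(rev_hits) == 0:
        raise ValueError("reverse primer not found in template")
    if len(rev_hits) > 1:
        raise ValueError("reverse primer matches multiple loci: ambiguous amplification")
    start = fwd_hits[0]
    end = rev_hits[0] + len(rev_rc)
    if end <= start:
        raise ValueError("reverse primer site lies upstream of the forward primer")
    return t[start:end]


def find_cut_sites(
    seq: str, recognition: str = BSRI_RECOGNITION, top_offset: int = BSRI_TOP_OFFSET
) -> list[int]:
    """Top-strand cut coordinates for recognition sites on either strand.

    A forward site at p cuts at ``p + len(recognition) + top_offset``; a
    reverse-strand site (reverse complement of the recognition sequence at
    q on the top strand) cuts at the mirrored position ``q - top_offset``.
    Returns sorted, deduplicated coordinates (no cut -> empty list).
    """
    s = _clean(seq)
    rec = _clean(recognition, "recognition sequence")
    rec_rc = str(Seq(rec).reverse_complement())
    cuts = {p + len(rec) + top_offset for p in _find_all(s, rec)}
    cuts |= {q - top_offset for q in _find_all(s, rec_rc)}
    return sorted(cuts)


def digest_fragments(amplicon: str, cut_positions) -> list[int]:
    """Fragment lengths between cuts; lengths always sum to amplicon length."""
    n = len(_clean(amplicon, "amplicon"))
    cuts = sorted(set(int(c) for c in cut_positions))
    for c in cuts:
        if not (0 < c < n):
            raise ValueError(f"cut position {c} not strictly inside the amplicon (length {n})")
    edges = [0] + cuts + [n]
    return [edges[i + 1] - edges[i] for i in range(len(edges) - 1)]


def call_genotype(band_lengths, tolerance_bp: int = 20) -> GenotypeCall:
    """Band-pattern -> genotype call within a size tolerance.

    {~948} -> Ahl/Ahl; {~284, ~664} -> ahl/ahl; all three -> Ahl/ahl;
    anything else -> indeterminate.
    """
    bands = sorted(int(b) for b in band_lengths)
    if not bands:
        raise ValueError("empty band list")

    def matches(pattern):
        if len(bands) != len(pattern):
            return False
        return all(abs(b - p) <= tolerance_bp for b, p in zip(bands, sorted(pattern)))

    if matches([EXPECTED_UNCUT_BP]):
        call = "Ahl/Ahl"
    elif matches(list(EXPECTED_CUT_BP)):
        call = "ahl/ahl"
    elif matches(list(EXPECTED_CUT_BP) + [EXPECTED_UNCUT_BP]):
        call = "Ahl/ahl"
    else:
        call = "indeterminate"
    return GenotypeCall(fragments_bp=bands, call=call)


def genotype_template(template: str, fwd_primer: str = FWD_PRIMER, rev_primer: str = REV_PRIMER) -> GenotypeCall:
    """Full assay on one allele template: PCR -> digest -> call.

    A homozygote is the same allele twice, so a single-template call of
    {948} reads Ahl/Ahl and {284, 664} reads ahl/ahl; heterozygotes are
    called by pooling the fragment sets of both allele templates.
    """
    amplicon = insilico_pcr(template, fwd_primer, rev_primer)
    cuts = find_cut_sites(amplicon)
    fragments = digest_fragments(amplicon, cuts)
    return call_genotype(fragments)


def load_fixture_template(allele: str) -> str:
    """Synthetic allele template shipped with the package.

    These are constructed sequences (not the real Cdh23 locus) whose primer
    placement and SNP-dependent BsrI site reproduce the published 948 /
    284+664 fragment pattern.  ``allele`` is "ahl" or "ahl_plus".
    """
    names = {"ahl": "cdh23_synthetic_ahl.fasta", "ahl_plus": "cdh23_synthetic_ahl_plus.fasta"}
    if allele not in names:
        raise ValueError(f"unknown allele {allele!r}; expected one of {sorted(names)}")
    path = resources.files("cortune.data").joinpath(names[allele])
    with path.open() as fh:
        record = next(SeqIO.parse(fh, "fasta"))
    return str(record.seq)
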