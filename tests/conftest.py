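"""Shared fixtures: tiny gene models, hand-built reads, brute-force oracles."""

from __future__ import annotations

import pytest
from Bio.Seq import Seq

from revertscan.reads import AlignedRead
from revertscan.refmodel import GeneModel
from revertscan.variants import SeqVariant

# A 60-bp, 20-codon single-exon CDS occupying the whole slice: ATG + 18
# stop-free sense codons + TAA. Written out explicitly so tests can do
# plain string surgery on it.
TOY60_CDS = (
    "ATG" "GCT" "GAA" "TTC" "GGA" "CAT" "ATC" "AAA" "CTG" "ATG"
    "AAC" "CCA" "CAG" "AGA" "AGC" "ACC" "GTT" "TGG" "TAC" "TAA"
)
assert len(TOY60_CDS) == 60


@pytest.fixture(scope="session")
def toy60() -> GeneModel:
    """Minimal plus-strand model: CDS == slice, 20 codons."""
    return GeneModel(
        gene_symbol="TOY60",
        contig="chrT",
        strand="+",
        seq_start=1,
        ref_seq=TOY60_CDS,
        cds_intervals=((1, 60),),
    )


@pytest.fixture(scope="session")
def toy60_minus() -> GeneModel:
    """The same protein encoded on the minus strand."""
    return GeneModel(
        gene_symbol="TOY60M",
        contig="chrT",
        strand="-",
        seq_start=1,
        ref_seq=str(Seq(TOY60_CDS).reverse_complement()),
        cds_intervals=((1, 60),),
    )


def sv(pos: int, ref: str, alt: str, contig: str = "chrT", **kw) -> SeqVariant:
    return SeqVariant(contig, pos, ref, alt, **kw)


def make_read(pos: int, seq: str, cigar: str | None = None, qname: str = "r", contig: str = "chrT") -> AlignedRead:
    return AlignedRead(qname=qname, contig=contig, pos=pos,
                       cigar=cigar or f"{len(seq)}M", seq=seq)


# ---------------------------------------------------------------------------
# Brute-force translation oracle (string surgery, no package machinery)
# ---------------------------------------------------------------------------

def surgery(seq: str, variants) -> str:
    """Apply VCF-style variants to a 1-based sequence by direct string edits,
    right to left."""
    s = seq
    for v in sorted(variants, key=lambda v: v.pos, reverse=True):
        i = v.pos - 1
        assert s[i : i + len(v.ref)] == v.ref
        s = s[:i] + v.alt + s[i + len(v.ref):]
    return s


def brute_force_functional(cds: str) -> bool:
    """Translate a whole-slice CDS string: functional iff in frame, the
    final codon is a stop, and no earlier codon is a stop."""
    if len(cds) % 3 != 0:
        return False
    aa = str(Seq(cds).translate())
    return aa.endswith("*") and "*" not in aa[:-1]
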