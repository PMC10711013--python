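"""Variant records, normalization, multi-caller consensus and germline subtraction.

Small somatic variants from several callers are reduced to a single
normalized key space (left-aligned, parsimonious, VCF-anchored) so that the
same indel reported with different right-shifted representations merges into
one record. Consensus keeps variants seen by at least ``min_callers``
independent callers; tumour-only analyses run with ``min_callers=1``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .errors import ContractError, ReferenceMismatchError
from .reads import AlignedRead

__all__ = [
    "SeqVariant",
    "parse_caller_vcf",
    "normalize_variant",
    "consensus_merge",
    "subtract_germline",
    "recount_from_reads",
]

_DNA = set("ACGT")


@dataclass(frozen=True)
class SeqVariant:
    """A normalized small variant with caller provenance and read counts.

    ``vaf`` is derived: ``alt_count / depth`` when depth is positive, and
    ``None`` (undefined) when there is no coverage information — zero
    spanning reads is deliberately distinct from an observed VAF of 0.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    callers: frozenset = frozenset()
    alt_count: int | None = None
    depth: int | None = None
    origin: str = "unknown"

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ContractError(f"empty REF/ALT at {self.contig}:{self.pos}")
        if self.ref == self.alt:
            raise ContractError(f"REF == ALT at {self.contig}:{self.pos}")
        if (set(self.ref) | set(self.alt)) - _DNA:
            raise ContractError(f"non-ACGT allele at {self.contig}:{self.pos}")
        if self.alt_count is not None and self.depth is not None:
            if not 0 <= self.alt_count <= self.depth:
                raise ContractError(
                    f"alt_count {self.alt_count} outside [0, depth={self.depth}] at {self.contig}:{self.pos}"
                )
        object.__setattr__(self, "callers", frozenset(self.callers))

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def vaf(self) -> float | None:
        if self.depth and self.alt_count is not None:
            return self.alt_count / self.depth
        return None

    @property
    def net_length(self) -> int:
        """len(alt) - len(ref): negative for deletions, positive for insertions."""
        return len(self.alt) - len(self.ref)

    @property
    def end(self) -> int:
        """1-based inclusive end of the reference footprint."""
        return self.pos + len(self.ref) - 1

    def is_parsimonious(self) -> bool:
        r, a = self.ref, self.alt
        if len(r) > 1 and len(a) > 1 and r[-1] == a[-1]:
            return False
        if len(r) > 1 and len(a) > 1 and r[0] == a[0]:
            return False
        return True

    def replace(self, **kw) -> "SeqVariant":
        return dataclasses.replace(self, **kw)

    def __str__(self) -> str:  # compact for logs
        return f"{self.contig}:{self.pos}:{self.ref}>{self.alt}"


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------

def parse_caller_vcf(path: str | Path, caller_id: str) -> list[SeqVariant]:
    """Read one caller's VCF into SeqVariants (one per ALT allele).

    Multiallelic records are split; AD/DP are taken from the first sample
    when present and tolerated as absent otherwise.
    """
    out: list[SeqVariant] = []
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ContractError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        for rec in vf:
            alts = rec.alts or ()
            depth, ads = _record_counts(rec)
            for i, alt in enumerate(alts):
                if alt is None or set(alt) - _DNA or set(rec.ref) - _DNA:
                    continue  # symbolic/spanning alleles are out of scope
                alt_count = ads[i] if ads is not None and i < len(ads) else None
                out.append(
                    SeqVariant(
                        contig=rec.contig,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        callers=frozenset({caller_id}),
                        alt_count=alt_count,
                        depth=depth,
                    )
                )
    return out


def _record_counts(rec) -> tuple[int | None, tuple[int, ...] | None]:
    if rec.samples:
        smp = rec.samples[0]
        ad = smp.get("AD")
        dp = smp.get("DP")
        if ad is not None and all(x is not None for x in ad):
            alt_ads = tuple(int(x) for x in ad[1:])
            depth = int(dp) if dp is not None else int(sum(int(x) for x in ad))
            return depth, alt_ads
        if dp is not None:
            return int(dp), None
    dp = rec.info.get("DP") if "DP" in rec.header.info else None
    return (int(dp) if dp is not None else None), None


# ---------------------------------------------------------------------------
# Normalization (left-align + parsimony)
# ---------------------------------------------------------------------------

def normalize_variant(reference, v: SeqVariant) -> SeqVariant:
    """Return the left-aligned, parsimonious representation of ``v``.

    ``reference`` is any object exposing ``base_at(pos)`` and
    ``seq_start``/``seq_end`` (a :class:`~revertscan.refmodel.GeneModel`
    qualifies). Idempotent: all right-shifted representations of one indel
    collapse onto the same key. Raises ReferenceMismatchError when the REF
    field disagrees with the reference sequence.
    """
    observed = "".join(reference.base_at(p) for p in range(v.pos, v.end + 1))
    if observed != v.ref:
        raise ReferenceMismatchError(
            f"REF mismatch at {v.contig}:{v.pos}: reference has {observed}, record says {v.ref}"
        )
    pos, ref, alt = v.pos, v.ref, v.alt
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            continue
        if (len(ref) == 1) != (len(alt) == 1) and ref[-1] == alt[-1] and pos > reference.seq_start:
            # anchored indel: roll the shared trailing base leftwards
            b = reference.base_at(pos - 1)
            pos -= 1
            ref, alt = b + ref[:-1], b + alt[:-1]
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise ContractError(f"variant {v} normalizes to a no-op")
    return v.replace(pos=pos, ref=ref, alt=alt)


# ---------------------------------------------------------------------------
# Consensus and germline subtraction
# ---------------------------------------------------------------------------

def consensus_merge(
    caller_lists: Sequence[Sequence[SeqVariant]],
    min_callers: int = 2,
    caller_priority: Sequence[str] | None = None,
) -> list[SeqVariant]:
    """Merge per-caller variant lists by identity key.

    A variant is retained iff it was reported by at least ``min_callers``
    callers; caller sets are unioned. Read counts are taken from the first
    caller in ``caller_priority`` (default: encounter order) that reported
    counts for the variant. Input must be normalized; a non-parsimonious
    record raises ContractError.
    """
    if min_callers < 1:
        raise ContractError("min_callers must be >= 1")
    by_key: dict[tuple, dict[str, SeqVariant]] = {}
    order: list[tuple] = []
    for lst in caller_lists:
        for v in lst:
            if not v.is_parsimonious():
                raise ContractError(f"unnormalized variant in consensus input: {v}")
            if not v.callers:
                raise ContractError(f"variant without caller provenance: {v}")
            if v.key not in by_key:
                by_key[v.key] = {}
                order.append(v.key)
            for c in v.callers:
                by_key[v.key][c] = v
    merged: list[SeqVariant] = []
    for key in sorted(order):
        per_caller = by_key[key]
        if len(per_caller) < min_callers:
            continue
        prio = list(caller_priority) if caller_priority else sorted(per_caller)
        counted = next(
            (per_caller[c] for c in prio if c in per_caller and per_caller[c].depth is not None),
            next(iter(per_caller.values())),
        )
        merged.append(
            counted.replace(callers=frozenset(per_caller))
        )
    return merged


def subtract_germline(tumour: Sequence[SeqVariant], germline: Sequence[SeqVariant]) -> list[SeqVariant]:
    """Somatic = tumour variants absent from the matched germline.

    Tumour variants whose key is present in the germline are excluded from
    the returned list (they would be tagged ``origin=germline``); the rest
    are tagged ``origin=somatic``. Known pathogenic germline lesions are
    re-injected downstream by explicit configuration, never recovered here.
    """
    germ_keys = {g.key for g in germline}
    return [v.replace(origin="somatic") for v in tumour if v.key not in germ_keys]


# ---------------------------------------------------------------------------
# Read-level recounting
# ---------------------------------------------------------------------------

def recount_from_reads(v: SeqVariant, reads: Iterable[AlignedRead]) -> SeqVariant:
    """Recompute alt_count/depth by direct inspection of aligned reads.

    Depth counts reads that align over the variant's anchor base with at
    least ``max(len(ref), len(alt)) + 1`` query bases remaining from it.
    That fixed query budget fully determines the carried allele (it covers
    the whole reference footprint on a reference read, and the whole
    alternate allele plus the downstream junction base on an indel read)
    and, crucially, makes the eligibility probability of a uniformly
    started read identical for both alleles — counting instead over the
    reference footprint would over-sample deletion reads (whose reference
    span is longer) and under-sample insertion reads. Alt support counts
    eligible reads whose aligned bases over the footprint equal the ALT
    allele exactly. Zero eligible reads leaves the VAF undefined rather
    than zero.
    """
    start, end = v.pos, v.end
    budget = max(len(v.ref), len(v.alt)) + 1
    depth = 0
    alt_count = 0
    for r in reads:
        if r.contig != v.contig:
            continue
        q0 = r.query_offset_at(start)
        if q0 is None or len(r.seq) - q0 < budget:
            continue
        depth += 1
        if r.allele_at(start, end) == v.alt:
            alt_count += 1
    return v.replace(alt_count=alt_count, depth=depth)


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

def write_vcf(
    variants: Sequence[SeqVariant],
    path: str | Path,
    contig: str,
    contig_length: int,
    extra_info: dict | None = None,
) -> None:
    """Write variants to an uncompressed VCF 4.2 with CALLERS/ORIGIN tags."""
    header = pysam.VariantHeader()
    header.add_line("##source=revertscan")
    header.contigs.add(contig, length=contig_length)
    header.info.add("CALLERS", ".", "String", "Callers reporting this variant")
    header.info.add("ORIGIN", "1", "String", "germline/somatic/unknown")
    header.info.add("MECH", "1", "String", "Reversion mechanism label")
    header.info.add("TVAF", "1", "Float", "True simulated variant allele fraction")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    header.formats.add("DP", "1", "Integer", "Read depth")
    header.add_sample("SAMPLE")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda x: (x.pos, x.ref, x.alt)):
            rec = out.new_record(contig=contig, start=v.pos - 1, alleles=(v.ref, v.alt))
            if v.callers:
                rec.info["CALLERS"] = ",".join(sorted(v.callers))
            rec.info["ORIGIN"] = v.origin
            if extra_info and v.key in extra_info:
                for k, val in extra_info[v.key].items():
                    rec.info[k] = val
            if v.depth is not None:
                rec.samples["SAMPLE"]["DP"] = v.depth
                if v.alt_count is not None:
                    rec.samples["SAMPLE"]["AD"] = (v.depth - v.alt_count, v.alt_count)
            out.write(rec)
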