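"""Reversion-mutation detection: candidate enumeration, mechanism
classification, read-backed cis phasing and confidence tiering.

A reversion is a secondary somatic event that restores an open reading
frame (or the reference sequence itself) on the haplotype carrying a
pathogenic primary lesion. Three mechanisms are distinguished:

``back_mutation``
    the secondary event exactly restores the reference allele at the
    lesion; expressed here as the inverse record of the primary
    (``pos=primary.pos, ref=primary.alt, alt=primary.ref``), since a fully
    reverted haplotype is indistinguishable from reference by
    reference-based calling.
``frame_restoring_indel``
    a separate indel whose net length together with the primary is a
    multiple of 3 and whose combined haplotype translates without a
    premature stop.
``spanning_deletion``
    an in-frame deletion whose reference footprint removes the lesion
    entirely (in reference space its own net length is a multiple of 3).

Phase is confirmed when primary and secondary alternate alleles co-occur
on the same sequencing reads; spanning deletions and back-mutations are
implicitly cis because the event physically contains or replaces the
lesion. Calls phased in trans are negative controls, never reversions.

Confidence tiers follow the read-support rule used for manual review of
targeted-panel reversions: high for > 10 supporting reads or > 5% VAF,
moderate for 6-10 reads, low for 2-5 reads, rejected below 2.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ContractError
from .refmodel import GeneModel, apply_variants, translate_haplotype
from .reads import AlignedRead
from .variants import SeqVariant, recount_from_reads

logger = logging.getLogger(__name__)

__all__ = [
    "PrimaryLesion",
    "ReversionCall",
    "BACK_MUTATION",
    "FRAME_RESTORING_INDEL",
    "SPANNING_DELETION",
    "NOT_REVERSION",
    "enumerate_candidates",
    "classify_mechanism",
    "check_cis_phase",
    "assign_confidence",
    "call_reversions",
]

BACK_MUTATION = "back_mutation"
FRAME_RESTORING_INDEL = "frame_restoring_indel"
SPANNING_DELETION = "spanning_deletion"
NOT_REVERSION = "not_reversion"

CIS_CONFIRMED = "cis_confirmed"
IMPLICIT_CIS = "implicit_cis"
UNKNOWN = "unknown"
TRANS = "trans"

TIER_HIGH = "high"
TIER_MODERATE = "moderate"
TIER_LOW = "low"
TIER_REJECTED = "rejected"


@dataclass(frozen=True)
class PrimaryLesion:
    """The known pathogenic lesion whose reversion is being sought."""

    gene: str
    variant: SeqVariant
    origin: str = "unknown"  # germline / somatic / unknown
    hgvs_c: str = ""
    hgvs_p: str = ""


@dataclass(frozen=True)
class ReversionCall:
    primary: PrimaryLesion
    secondary_events: tuple[SeqVariant, ...]
    mechanism: str
    phase: str
    shared_reads: int
    vaf: float | None
    tier: str

    @property
    def reported(self) -> bool:
        return self.phase != TRANS and self.tier != TIER_REJECTED


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------

def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def is_inverse(primary: SeqVariant, candidate: SeqVariant) -> bool:
    """True when applying the candidate to the mutant allele restores the
    exact reference sequence at the lesion."""
    return (
        candidate.pos == primary.pos
        and candidate.ref == primary.alt
        and candidate.alt == primary.ref
    )


def enumerate_candidates(
    primary: PrimaryLesion,
    somatic: Sequence[SeqVariant],
    window: int = 200,
    model: GeneModel | None = None,
) -> list[SeqVariant]:
    """Somatic variants near the lesion that could participate in a reversion.

    Keeps variants on the lesion's contig within ``window`` bp of the
    lesion, plus any deletion whose reference footprint overlaps the lesion
    regardless of distance. The primary itself is excluded.
    """
    if window <= 0:
        raise ContractError("window must be positive")
    p = primary.variant
    out: list[SeqVariant] = []
    for v in somatic:
        if v.contig != p.contig or v.key == p.key:
            continue
        if model is not None and not (model.seq_start <= v.pos <= model.seq_end):
            continue
        near = abs(v.pos - p.pos) <= window
        spanning = v.net_length < 0 and _overlaps(v.pos, v.end, p.pos, p.end)
        if near or spanning or is_inverse(p, v):
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# Mechanism classification
# ---------------------------------------------------------------------------

def _events_for(primary: SeqVariant, candidate: SeqVariant, mechanism: str) -> list[SeqVariant]:
    """Variants to apply to the reference to rebuild the reverted haplotype."""
    if mechanism == BACK_MUTATION:
        return []  # fully reverted haplotype == reference
    if mechanism == SPANNING_DELETION:
        return [candidate]  # the deletion supersedes the lesion
    return [primary, candidate]


def classify_mechanism(
    primary: PrimaryLesion,
    candidate: SeqVariant,
    model: GeneModel,
) -> str:
    """Decide whether ``candidate`` reverts ``primary`` and by what mechanism.

    The final arbiter for indel mechanisms is the translation oracle: the
    reconstructed haplotype must reach the canonical stop in frame with no
    premature stop codon. A candidate overlapping but not containing the
    lesion is an unphaseable allele conflict, never a reversion.
    """
    p = primary.variant
    if is_inverse(p, candidate):
        return BACK_MUTATION
    contains = candidate.pos <= p.pos and candidate.end >= p.end
    if candidate.net_length < 0 and contains:
        if candidate.net_length % 3 != 0:
            return NOT_REVERSION
        prot = translate_haplotype(model, apply_variants(model, [candidate]))
        return SPANNING_DELETION if prot.functional else NOT_REVERSION
    if _overlaps(candidate.pos, candidate.end, p.pos, p.end):
        logger.info("unphaseable allele conflict between %s and %s", p, candidate)
        return NOT_REVERSION
    if (p.net_length + candidate.net_length) % 3 != 0:
        return NOT_REVERSION
    # restoration only means something if the primary alone truncates the protein
    if translate_haplotype(model, apply_variants(model, [p])).functional:
        return NOT_REVERSION
    prot = translate_haplotype(model, apply_variants(model, [p, candidate]))
    return FRAME_RESTORING_INDEL if prot.functional else NOT_REVERSION


# ---------------------------------------------------------------------------
# Read-backed phasing
# ---------------------------------------------------------------------------

def _read_supports(read: AlignedRead, v: SeqVariant) -> bool:
    need_end = v.end + 1 if v.net_length > 0 else v.end
    return read.spans(v.pos, need_end) and read.allele_at(v.pos, v.end) == v.alt


def check_cis_phase(
    primary: PrimaryLesion,
    candidate: SeqVariant,
    reads: Iterable[AlignedRead] | None,
    min_shared: int = 2,
    mechanism: str | None = None,
) -> tuple[str, int]:
    """Count reads carrying both alternate alleles and assign a phase.

    Returns ``(phase, shared_reads)``. Spanning deletions and back-mutations
    are implicitly cis; their support is the candidate-allele read count
    (caller-provided for back-mutations, whose reads match the reference).
    When no read spans both loci, phasing is impossible and the phase is
    ``unknown``.
    """
    p = primary.variant
    if mechanism == BACK_MUTATION:
        return IMPLICIT_CIS, int(candidate.alt_count or 0)
    if mechanism == SPANNING_DELETION:
        if reads is None:
            return IMPLICIT_CIS, int(candidate.alt_count or 0)
        counted = recount_from_reads(candidate, reads)
        return IMPLICIT_CIS, int(counted.alt_count or 0)
    if reads is None:
        return UNKNOWN, 0
    shared = 0
    p_only = 0
    c_only = 0
    n_spanning = 0
    lo = min(p.pos, candidate.pos)
    hi = max(p.end + (1 if p.net_length > 0 else 0), candidate.end + (1 if candidate.net_length > 0 else 0))
    for r in reads:
        if r.contig != p.contig or not r.spans(lo, hi):
            continue
        n_spanning += 1
        has_p = _read_supports(r, p)
        has_c = _read_supports(r, candidate)
        if has_p and has_c:
            shared += 1
        elif has_p:
            p_only += 1
        elif has_c:
            c_only += 1
    if n_spanning == 0:
        logger.info("no read spans both %s and %s: phasing impossible", p, candidate)
        return UNKNOWN, 0
    if shared >= min_shared:
        return CIS_CONFIRMED, shared
    if shared == 0 and p_only >= min_shared and c_only >= min_shared:
        return TRANS, 0
    return UNKNOWN, shared


# ---------------------------------------------------------------------------
# Confidence tiers
# ---------------------------------------------------------------------------

def assign_confidence(support: int, vaf: float | None) -> str:
    """Tier a reversion by supporting reads and VAF.

    The VAF clause is evaluated first (> 5% is high confidence regardless
    of read count); with an undefined VAF the reads-only boundaries apply:
    > 10 high, 6-10 moderate, 2-5 low, < 2 rejected.
    """
    if support < 0:
        raise ContractError(f"negative read support: {support}")
    if vaf is not None and not 0 <= vaf <= 1:
        raise ContractError(f"VAF outside [0,1]: {vaf}")
    if vaf is not None and vaf > 0.05:
        return TIER_HIGH
    if support > 10:
        return TIER_HIGH
    if support >= 6:
        return TIER_MODERATE
    if support >= 2:
        return TIER_LOW
    return TIER_REJECTED


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def call_reversions(
    primary: PrimaryLesion,
    somatic: Sequence[SeqVariant],
    reads: Sequence[AlignedRead] | None,
    model: GeneModel,
    window: int = 200,
    min_shared: int = 2,
    allow_compound: bool = True,
    audit_log: list | None = None,
) -> list[ReversionCall]:
    """Full reversion screen for one primary lesion.

    Composes enumerate -> classify -> phase -> recount -> tier. Calls phased
    in trans or tiered ``rejected`` are excluded from the returned list but
    appended to ``audit_log`` when one is supplied. Candidate pairs of
    indels jointly restoring the frame (compound reversions) are considered
    up to size 2.
    """
    cands = enumerate_candidates(primary, somatic, window=window, model=model)
    calls: list[ReversionCall] = []
    singles_not_reversion: list[SeqVariant] = []
    for cand in cands:
        mech = classify_mechanism(primary, cand, model)
        if mech == NOT_REVERSION:
            singles_not_reversion.append(cand)
            continue
        phase, shared = check_cis_phase(primary, cand, reads, min_shared=min_shared, mechanism=mech)
        measured = cand
        if reads is not None and mech not in (BACK_MUTATION,):
            measured = recount_from_reads(cand, reads)
        vaf = measured.vaf
        tier = assign_confidence(shared, vaf)
        calls.append(
            ReversionCall(
                primary=primary,
                secondary_events=(cand,),
                mechanism=mech,
                phase=phase,
                shared_reads=shared,
                vaf=vaf,
                tier=tier,
            )
        )
    if allow_compound:
        calls.extend(
            _compound_calls(primary, singles_not_reversion, reads, model, min_shared)
        )
    reported = [c for c in calls if c.reported]
    if audit_log is not None:
        audit_log.extend(calls)
    return reported


def _compound_calls(
    primary: PrimaryLesion,
    leftovers: Sequence[SeqVariant],
    reads: Sequence[AlignedRead] | None,
    model: GeneModel,
    min_shared: int,
) -> list[ReversionCall]:
    """Pairs of secondary indels that jointly restore the frame."""
    p = primary.variant
    indels = [v for v in leftovers if v.net_length != 0 and not _overlaps(v.pos, v.end, p.pos, p.end)]
    out: list[ReversionCall] = []
    for a, b in itertools.combinations(indels, 2):
        if _overlaps(a.pos, a.end, b.pos, b.end):
            continue
        if (p.net_length + a.net_length + b.net_length) % 3 != 0:
            continue
        try:
            prot = translate_haplotype(model, apply_variants(model, [p, a, b]))
        except Exception:
            continue
        if not prot.functional:
            continue
        phases = [check_cis_phase(primary, c, reads, min_shared=min_shared) for c in (a, b)]
        if any(ph == TRANS for ph, _ in phases):
            phase, shared = TRANS, 0
        elif all(ph == CIS_CONFIRMED for ph, _ in phases):
            phase, shared = CIS_CONFIRMED, min(s for _, s in phases)
        else:
            phase, shared = UNKNOWN, min(s for _, s in phases)
        vafs = []
        for c in (a, b):
            m = recount_from_reads(c, reads) if reads is not None else c
            if m.vaf is not None:
                vafs.append(m.vaf)
        vaf = min(vafs) if vafs else None
        tier = assign_confidence(shared, vaf)
        out.append(
            ReversionCall(
                primary=primary,
                secondary_events=(a, b),
                mechanism=FRAME_RESTORING_INDEL,
                phase=phase,
                shared_reads=shared,
                vaf=vaf,
                tier=tier,
            )
        )
    return out
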