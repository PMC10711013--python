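"""Synthetic targeted-panel cohort generator with full ground truth.

Emulates the data regime of a tumour-only / matched targeted capture panel:
~500X median coverage, tumour purity 0.25-0.85, subclonal reversion events
at allele fractions from below 1% up to ~17%, and a per-base substitution
error around 0.1-1%. Reads are single-end with exact alignments (the
generating haplotype is known, so CIGARs are correct by construction): the
downstream phasing logic needs read co-occurrence, not mapping realism.

Every implanted event carries its true allele fraction
(purity x CCF x allele dosage, dosage 0.5 for a heterozygous site), so each
downstream stage can be scored against truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from Bio.Seq import Seq

from .errors import ConfigError
from .refmodel import GeneModel, Haplotype, apply_variants, translate_haplotype
from .reads import AlignedRead, write_sam
from .reversion import BACK_MUTATION, FRAME_RESTORING_INDEL, SPANNING_DELETION
from .variants import SeqVariant, normalize_variant, write_vcf

__all__ = [
    "ReversionSpec",
    "SimPatientConfig",
    "TruthEvent",
    "SimTruth",
    "toy_gene_model",
    "default_primary",
    "make_reversion_variant",
    "build_haplotype_mixture",
    "simulate_reads",
    "simulate_caller_vcfs",
    "simulate_germline_vcf",
    "simulate_patient",
    "SimPatient",
    "MixtureComponent",
    "plan_events",
    "write_truth",
    "read_truth",
    "default_cohort_configs",
    "write_patient_bundle",
    "simulate_cohort",
]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in _STOPS]


# ---------------------------------------------------------------------------
# Toy reference models
# ---------------------------------------------------------------------------

def toy_gene_model(
    n_codons: int = 160,
    seed: int = 7,
    strand: str = "+",
    contig: str = "chrT",
    gene: str = "TOYGENE",
    flank: int = 60,
) -> GeneModel:
    """Build a single-exon gene model with a stop-free random CDS.

    The CDS is ``ATG`` + random sense codons + ``TAA``; flanking sequence is
    random. For minus-strand models the designed CDS is stored as its
    reverse complement on the plus strand, mirroring how a minus-strand
    gene (e.g. BRCA1) sits in a genomic reference.
    """
    rng = np.random.default_rng(seed)
    if n_codons < 4:
        raise ConfigError("n_codons must be >= 4")
    body = "".join(rng.choice(_SENSE_CODONS) for _ in range(n_codons - 2))
    cds = "ATG" + body + "TAA"
    if strand == "-":
        cds_on_plus = str(Seq(cds).reverse_complement())
    else:
        cds_on_plus = cds
    left = "".join(rng.choice(_BASES, size=flank))
    right = "".join(rng.choice(_BASES, size=flank))
    ref_seq = left + cds_on_plus + right
    cds_start = flank + 1
    cds_end = flank + len(cds)
    return GeneModel(
        gene_symbol=gene,
        contig=contig,
        strand=strand,
        seq_start=1,
        ref_seq=ref_seq,
        cds_intervals=((cds_start, cds_end),),
    )


def default_primary(model: GeneModel, del_len: int = 5, codon_offset: int = 40) -> SeqVariant:
    """A pathogenic frameshift deletion mid-CDS, verified truncating.

    Emulates a hotspot-style small deletion (the archetype being the 5-bp
    BRCA1 exon-11 deletion). Scans codon-aligned positions until the
    frameshift provably truncates the protein.
    """
    cds_pos = model.cds_positions()
    for shift in range(0, len(cds_pos) // 3 - codon_offset - 10):
        start = cds_pos[3 * (codon_offset + shift)]
        anchor = start - 1
        if anchor < model.seq_start or start + del_len - 1 > model.seq_end:
            continue
        ref = model.slice(anchor, start + del_len - 1)
        v = normalize_variant(model, SeqVariant(model.contig, anchor, ref, ref[0]))
        prot = translate_haplotype(model, apply_variants(model, [v]))
        if prot.premature_stop:
            return v
    raise ConfigError("could not place a truncating primary deletion in this model")


# ---------------------------------------------------------------------------
# Patient configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReversionSpec:
    """One implanted secondary event: mechanism, cancer-cell fraction and
    (for negative controls) trans placement on the wild-type haplotype."""

    mechanism: str
    ccf: float
    in_trans: bool = False

    def __post_init__(self) -> None:
        if self.mechanism not in (BACK_MUTATION, FRAME_RESTORING_INDEL, SPANNING_DELETION):
            raise ConfigError(f"unknown reversion mechanism: {self.mechanism}")
        if not 0 < self.ccf <= 1:
            raise ConfigError(f"CCF must be in (0,1], got {self.ccf}")


@dataclass(frozen=True)
class SimPatientConfig:
    patient_id: str
    primary_lesion: SeqVariant
    primary_origin: str = "germline"  # germline or somatic
    purity: float = 0.6
    depth: float = 500.0
    read_length: int = 100
    error_rate: float = 0.001
    reversion_events: tuple[ReversionSpec, ...] = ()
    tp53_vaf_target: float | None = 0.63
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise ConfigError(f"purity must be in (0,1], got {self.purity}")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        if not 0 <= self.error_rate <= 0.05:
            raise ConfigError(f"error_rate must be in [0,0.05], got {self.error_rate}")
        if self.primary_origin not in ("germline", "somatic"):
            raise ConfigError(f"primary_origin must be germline or somatic: {self.primary_origin}")
        object.__setattr__(self, "reversion_events", tuple(self.reversion_events))
        cis_total = sum(e.ccf for e in self.reversion_events if not e.in_trans)
        trans_total = sum(e.ccf for e in self.reversion_events if e.in_trans)
        if cis_total > 1 or trans_total > 1:
            raise ConfigError("CCFs imply a negative wild-type fraction")


@dataclass(frozen=True)
class TruthEvent:
    variant: SeqVariant
    mechanism: str
    true_vaf: float
    ccf: float
    in_trans: bool = False


@dataclass(frozen=True)
class SimTruth:
    patient_id: str
    primary: SeqVariant
    primary_origin: str
    purity: float
    events: tuple[TruthEvent, ...]
    tp53_vaf_target: float | None = None


# ---------------------------------------------------------------------------
# Event construction
# ---------------------------------------------------------------------------

def make_reversion_variant(
    model: GeneModel,
    primary: SeqVariant,
    mechanism: str,
    rng: np.random.Generator,
    window: int = 90,
    span_sizes: Sequence[int] = (21, 15, 27, 12, 9, 18, 24, 30),
    min_offset: int = 6,
) -> SeqVariant:
    """Construct a secondary variant realising ``mechanism`` for ``primary``.

    Placement is searched deterministically (given the RNG state) and every
    returned event is verified against the translation oracle.
    """
    if mechanism == BACK_MUTATION:
        return SeqVariant(primary.contig, primary.pos, primary.alt, primary.ref)
    if mechanism == FRAME_RESTORING_INDEL:
        k = (-primary.net_length) % 3
        for d in range(min_offset, window):
            pos = primary.end + d
            if pos + 4 > model.seq_end:
                break
            if k > 0:
                ins = "".join(rng.choice(_BASES, size=k))
                cand = SeqVariant(model.contig, pos, model.base_at(pos), model.base_at(pos) + ins)
            else:
                ref = model.slice(pos, pos + 3)
                cand = SeqVariant(model.contig, pos, ref, ref[0])
            cand = normalize_variant(model, cand)
            if cand.pos <= primary.end:
                continue
            try:
                prot = translate_haplotype(model, apply_variants(model, [primary, cand]))
            except Exception:
                continue
            if prot.functional:
                return cand
        raise ConfigError("no frame-restoring indel placement found near primary")
    if mechanism == SPANNING_DELETION:
        for L in span_sizes:
            if L <= primary.end - primary.pos + 1:
                continue
            max_left = L - (primary.end - primary.pos + 1)
            for left in range(1, max_left + 1):
                s = primary.pos - left
                anchor = s - 1
                if anchor < model.seq_start or s + L - 1 > model.seq_end:
                    continue
                ref = model.slice(anchor, s + L - 1)
                cand = normalize_variant(model, SeqVariant(model.contig, anchor, ref, ref[0]))
                if not (cand.pos <= primary.pos and cand.end >= primary.end):
                    continue
                try:
                    prot = translate_haplotype(model, apply_variants(model, [cand]))
                except Exception:
                    continue
                if prot.functional:
                    return cand
        raise ConfigError("no in-frame spanning deletion placement found")
    raise ConfigError(f"unknown mechanism: {mechanism}")


# ---------------------------------------------------------------------------
# Haplotype mixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureComponent:
    label: str
    haplotype: Haplotype
    weight: float


def build_haplotype_mixture(
    cfg: SimPatientConfig,
    model: GeneModel,
    events: Sequence[TruthEvent],
) -> list[MixtureComponent]:
    """Allele-level haplotype weights for the tumour/normal cell mixture.

    The sample is a pool of alleles: each cell contributes two. A germline
    heterozygous lesion is carried by normal cells as well; a somatic one
    is confined to tumour cells. A reversion at cancer-cell fraction f
    converts weight purity x 0.5 x f of the lesion haplotype into the
    reverted haplotype (or of the wild-type haplotype, for trans controls).
    """
    p = cfg.purity
    cis = [e for e in events if not e.in_trans]
    trans = [e for e in events if e.in_trans]
    cis_f = sum(e.ccf for e in cis)
    trans_f = sum(e.ccf for e in trans)
    if cfg.primary_origin == "germline":
        lesion_w = (1 - p) * 0.5 + p * 0.5 * (1 - cis_f)
    else:
        lesion_w = p * 0.5 * (1 - cis_f)
    ref_w = 1.0 - lesion_w - p * 0.5 * (cis_f + trans_f)
    if ref_w < -1e-9 or lesion_w < -1e-9:
        raise ConfigError("CCFs imply a negative haplotype fraction")
    comps = [
        MixtureComponent("ref", apply_variants(model, []), max(ref_w, 0.0)),
        MixtureComponent("lesion", apply_variants(model, [cfg.primary_lesion]), max(lesion_w, 0.0)),
    ]
    for i, e in enumerate(events):
        if e.mechanism == BACK_MUTATION:
            hap = apply_variants(model, [])
        elif e.mechanism == SPANNING_DELETION or e.in_trans:
            hap = apply_variants(model, [e.variant])
        else:
            hap = apply_variants(model, [cfg.primary_lesion, e.variant])
        comps.append(MixtureComponent(f"event{i}", hap, p * 0.5 * e.ccf))
    total = sum(c.weight for c in comps)
    return [dataclasses.replace(c, weight=c.weight / total) for c in comps]


def plan_events(
    cfg: SimPatientConfig, model: GeneModel, rng: np.random.Generator
) -> list[TruthEvent]:
    """Materialise the configured reversion specs into concrete variants.

    Distinct events of the same mechanism are pushed to distinct loci so a
    patient can carry several unique reversions.
    """
    out: list[TruthEvent] = []
    sizes = (21, 15, 27, 12, 9, 18, 24, 30)
    used: set[tuple] = set()
    for spec in cfg.reversion_events:
        v = None
        for attempt in range(8):
            v = make_reversion_variant(
                model,
                cfg.primary_lesion,
                spec.mechanism,
                rng,
                min_offset=6 + 9 * attempt,
                span_sizes=sizes[attempt:] + sizes[:attempt],
            )
            if v.key not in used or spec.mechanism == BACK_MUTATION:
                break
        used.add(v.key)
        out.append(
            TruthEvent(
                variant=v,
                mechanism=spec.mechanism,
                true_vaf=cfg.purity * 0.5 * spec.ccf,
                ccf=spec.ccf,
                in_trans=spec.in_trans,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _hap_blocks(hap: Haplotype) -> list[tuple[str, int, int, int]]:
    """Compress haplotype segments into (kind, hap_start, length, ref_start)
    blocks, kind 'M' (reference-anchored run) or 'I' (inserted bases)."""
    blocks: list[tuple[str, int, int, int]] = []
    segs = hap.segments
    i = 0
    while i < len(segs):
        j = i
        if segs[i].is_ref:
            while (
                j + 1 < len(segs)
                and segs[j + 1].is_ref
                and segs[j + 1].anchor == segs[j].anchor + 1
            ):
                j += 1
            blocks.append(("M", i, j - i + 1, segs[i].anchor))
        else:
            while j + 1 < len(segs) and not segs[j + 1].is_ref:
                j += 1
            blocks.append(("I", i, j - i + 1, -1))
        i = j + 1
    return blocks


def _read_alignment(blocks, start: int, length: int) -> tuple[int, str]:
    """Reference position (1-based) and CIGAR for a read covering haplotype
    offsets [start, start+length)."""
    ops: list[tuple[str, int]] = []
    ref_pos = None
    expected_ref = None
    end = start + length
    for kind, hs, ln, rs in blocks:
        he = hs + ln
        if he <= start or hs >= end:
            continue
        a, b = max(hs, start), min(he, end)
        n = b - a
        if kind == "M":
            block_ref = rs + (a - hs)
            if ref_pos is None:
                ref_pos = block_ref
            elif block_ref > expected_ref:
                ops.append(("D", block_ref - expected_ref))
            ops.append(("M", n))
            expected_ref = block_ref + n
        else:
            if ref_pos is not None:
                ops.append(("I", n))
            # leading inserted bases would need soft-clipping; start positions
            # are adjusted onto M blocks so this branch stays anchored
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    cigar = "".join(f"{n}{op}" for op, n in merged)
    return ref_pos, cigar


def simulate_reads(
    mixture: Sequence[MixtureComponent],
    cfg: SimPatientConfig,
    model: GeneModel,
    rng: np.random.Generator | None = None,
) -> tuple[list[AlignedRead], dict]:
    """Draw single-end reads haplotype-proportionally with uniform starts.

    Substitution errors are applied at ``cfg.error_rate``; alignments are
    exact by construction. Start positions are uniform over the whole
    slice with reads truncated at its right edge, which makes the expected
    per-base depth equal ``cfg.depth`` away from the left edge. Returns the
    reads plus an expected-pileup summary (read count, expected interior
    depth, haplotype weights).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    L = cfg.read_length
    slice_len = len(model.ref_seq)
    if L >= slice_len:
        raise ConfigError("read_length must be shorter than the reference slice")
    n_reads = int(round(cfg.depth * slice_len / L))
    weights = np.array([c.weight for c in mixture])
    weights = weights / weights.sum()
    seqs = [c.haplotype.sequence for c in mixture]
    blocks = [_hap_blocks(c.haplotype) for c in mixture]
    choices = rng.choice(len(mixture), size=n_reads, p=weights)
    reads: list[AlignedRead] = []
    for i, hi in enumerate(choices):
        S = seqs[hi]
        s = int(rng.integers(0, len(S) - 1))
        s = _snap_to_match(blocks[hi], s, len(S) - 2)
        n = min(L, len(S) - s)
        seq = list(S[s : s + n])
        k = rng.binomial(n, cfg.error_rate)
        if k:
            for idx in rng.choice(n, size=k, replace=False):
                cur = seq[idx]
                seq[idx] = str(rng.choice([b for b in "ACGT" if b != cur]))
        pos, cigar = _read_alignment(blocks[hi], s, n)
        reads.append(
            AlignedRead(
                qname=f"{cfg.patient_id}_r{i}",
                contig=model.contig,
                pos=pos,
                cigar=cigar,
                seq="".join(seq),
            )
        )
    summary = {
        "n_reads": n_reads,
        "expected_depth": cfg.depth,
        "haplotype_weights": {c.label: c.weight for c in mixture},
    }
    return reads, summary


def _snap_to_match(blocks, s: int, max_start: int) -> int:
    """Shift a start offset forward onto a reference-anchored block."""
    for kind, hs, ln, _ in blocks:
        if hs <= s < hs + ln:
            if kind == "M":
                return s
            nxt = min(hs + ln, max_start)
            return nxt
    return max(0, min(s, max_start))


# ---------------------------------------------------------------------------
# Pseudo-callers
# ---------------------------------------------------------------------------

def simulate_caller_vcfs(
    truth: SimTruth,
    cfg: SimPatientConfig,
    n_callers: int = 4,
    sensitivity: float = 0.9,
    fp_rate: float = 2.0,
    model: GeneModel | None = None,
    seed: int | None = None,
    caller_ids: Sequence[str] | None = None,
) -> dict[str, list[SeqVariant]]:
    """Emulate independent variant callers over the simulated truth.

    Each pseudo-caller reports each true variant with probability
    ``sensitivity`` (counts drawn from the binomial sampling model at the
    event's true allele fraction) and adds Poisson-distributed false
    positive SNVs at low VAF. Deterministic under a fixed seed.
    """
    if n_callers < 1:
        raise ConfigError("n_callers must be >= 1")
    if not 0 <= sensitivity <= 1:
        raise ConfigError(f"sensitivity must be in [0,1], got {sensitivity}")
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    ids = list(caller_ids) if caller_ids else [f"caller{i+1}" for i in range(n_callers)]
    truth_records: list[tuple[SeqVariant, float]] = []
    primary_vaf = 0.5 if cfg.primary_origin == "germline" else cfg.purity * 0.5
    cis_loss = cfg.purity * 0.5 * sum(e.ccf for e in truth.events if not e.in_trans)
    truth_records.append((truth.primary, max(primary_vaf - cis_loss, 0.01)))
    for e in truth.events:
        truth_records.append((e.variant, e.true_vaf))
    if truth.tp53_vaf_target is not None:
        truth_records.append(
            (SeqVariant("TP53", 1000, "C", "T"), truth.tp53_vaf_target)
        )
    occupied = {(v.contig, p) for v, _ in truth_records for p in range(v.pos, v.end + 1)}
    out: dict[str, list[SeqVariant]] = {}
    for cid in ids:
        calls: list[SeqVariant] = []
        for v, tvaf in truth_records:
            if rng.random() > sensitivity:
                continue
            dp = max(int(rng.poisson(cfg.depth)), 1)
            ad = int(rng.binomial(dp, min(tvaf, 1.0)))
            if ad == 0:
                continue
            calls.append(v.replace(callers=frozenset({cid}), alt_count=ad, depth=dp))
        n_fp = int(rng.poisson(fp_rate))
        for _ in range(n_fp):
            if model is None:
                break
            for _try in range(20):
                pos = int(rng.integers(model.seq_start, model.seq_end + 1))
                if (model.contig, pos) in occupied:
                    continue
                ref = model.base_at(pos)
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                dp = max(int(rng.poisson(cfg.depth)), 1)
                ad = 2 + int(rng.binomial(dp, 0.004))
                calls.append(
                    SeqVariant(model.contig, pos, ref, alt, callers=frozenset({cid}), alt_count=ad, depth=dp)
                )
                break
        out[cid] = calls
    return out


def simulate_germline_vcf(
    cfg: SimPatientConfig,
    truth: SimTruth,
    model: GeneModel,
    n_snps: int = 3,
    seed: int | None = None,
) -> list[SeqVariant]:
    """Matched-normal calls: the germline lesion (when germline) plus a few
    heterozygous SNPs that also appear in the tumour callers' output."""
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    out: list[SeqVariant] = []
    if cfg.primary_origin == "germline":
        dp = max(int(rng.poisson(cfg.depth)), 1)
        ad = int(rng.binomial(dp, 0.5))
        out.append(truth.primary.replace(callers=frozenset({"germline"}), alt_count=max(ad, 1), depth=dp, origin="germline"))
    occupied = {p for v in [truth.primary] + [e.variant for e in truth.events] for p in range(v.pos - 1, v.end + 2)}
    placed = 0
    while placed < n_snps:
        pos = int(rng.integers(model.seq_start, model.seq_end + 1))
        if pos in occupied:
            continue
        ref = model.base_at(pos)
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        dp = max(int(rng.poisson(cfg.depth)), 1)
        ad = int(rng.binomial(dp, 0.5))
        out.append(SeqVariant(model.contig, pos, ref, alt, callers=frozenset({"germline"}), alt_count=max(ad, 1), depth=dp, origin="germline"))
        occupied.add(pos)
        placed += 1
    return out


# ---------------------------------------------------------------------------
# Patient bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimPatient:
    cfg: SimPatientConfig
    model: GeneModel
    truth: SimTruth
    mixture: tuple[MixtureComponent, ...]
    reads: tuple[AlignedRead, ...]
    pileup_summary: dict


def simulate_patient(cfg: SimPatientConfig, model: GeneModel | None = None) -> SimPatient:
    """Generate one patient end to end: events, mixture, reads, truth."""
    if model is None:
        model = toy_gene_model()
    rng = np.random.default_rng(cfg.seed)
    events = plan_events(cfg, model, rng)
    mixture = build_haplotype_mixture(cfg, model, events)
    reads, summary = simulate_reads(mixture, cfg, model, rng)
    truth = SimTruth(
        patient_id=cfg.patient_id,
        primary=cfg.primary_lesion,
        primary_origin=cfg.primary_origin,
        purity=cfg.purity,
        events=tuple(events),
        tp53_vaf_target=cfg.tp53_vaf_target,
    )
    return SimPatient(cfg, model, truth, tuple(mixture), tuple(reads), summary)


# ---------------------------------------------------------------------------
# Truth I/O
# ---------------------------------------------------------------------------

def write_truth(truth: SimTruth, outdir: str | Path, model: GeneModel) -> None:
    """Emit the truth as a VCF (with mechanism/true-VAF INFO tags) plus a
    JSON document; the two agree record for record and round-trip."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    extra = {
        e.variant.key: {"MECH": e.mechanism, "TVAF": round(e.true_vaf, 6)}
        for e in truth.events
    }
    write_vcf(
        [e.variant for e in truth.events],
        outdir / f"{truth.patient_id}.truth.vcf",
        contig=model.contig,
        contig_length=len(model.ref_seq),
        extra_info=extra,
    )
    doc = {
        "patient_id": truth.patient_id,
        "primary": _v_to_dict(truth.primary),
        "primary_origin": truth.primary_origin,
        "purity": truth.purity,
        "tp53_vaf_target": truth.tp53_vaf_target,
        "events": [
            {
                "variant": _v_to_dict(e.variant),
                "mechanism": e.mechanism,
                "true_vaf": e.true_vaf,
                "ccf": e.ccf,
                "in_trans": e.in_trans,
            }
            for e in truth.events
        ],
    }
    (outdir / f"{truth.patient_id}.truth.json").write_text(json.dumps(doc, indent=2, sort_keys=True))


def read_truth(path: str | Path) -> SimTruth:
    doc = json.loads(Path(path).read_text())
    return SimTruth(
        patient_id=doc["patient_id"],
        primary=_v_from_dict(doc["primary"]),
        primary_origin=doc["primary_origin"],
        purity=doc["purity"],
        tp53_vaf_target=doc.get("tp53_vaf_target"),
        events=tuple(
            TruthEvent(
                variant=_v_from_dict(e["variant"]),
                mechanism=e["mechanism"],
                true_vaf=e["true_vaf"],
                ccf=e["ccf"],
                in_trans=e["in_trans"],
            )
            for e in doc["events"]
        ),
    )


def _v_to_dict(v: SeqVariant) -> dict:
    return {"contig": v.contig, "pos": v.pos, "ref": v.ref, "alt": v.alt}


def _v_from_dict(d: dict) -> SeqVariant:
    return SeqVariant(d["contig"], d["pos"], d["ref"], d["alt"])


# ---------------------------------------------------------------------------
# Cohort-level generation and file bundles
# ---------------------------------------------------------------------------

_MECH_CYCLE = (FRAME_RESTORING_INDEL, SPANNING_DELETION, BACK_MUTATION)


def default_cohort_configs(
    n_patients: int,
    seed: int,
    depth: float = 500.0,
    read_length: int = 100,
    error_rate: float = 0.001,
    purity_range: tuple[float, float] = (0.25, 0.85),
    vaf_range: tuple[float, float] = (0.005, 0.17),
    reversion_fraction: float = 1.0,
    trans_control_fraction: float = 0.0,
    model: GeneModel | None = None,
) -> list[SimPatientConfig]:
    """Draw per-patient configs bracketing the study's observed regime.

    Purity is uniform over 0.25-0.85; implanted reversion CCFs are chosen
    so true allele fractions span ~0.5%-17%; mechanisms cycle through the
    three classes. ``trans_control_fraction`` of patients additionally get
    a trans-placed negative-control event.
    """
    if model is None:
        model = toy_gene_model()
    rng = np.random.default_rng(seed)
    primary = default_primary(model)
    cfgs: list[SimPatientConfig] = []
    for i in range(n_patients):
        purity = float(rng.uniform(*purity_range))
        events: list[ReversionSpec] = []
        if rng.random() < reversion_fraction:
            mech = _MECH_CYCLE[i % len(_MECH_CYCLE)]
            target_vaf = float(rng.uniform(*vaf_range))
            ccf = min(target_vaf / (purity * 0.5), 1.0)
            events.append(ReversionSpec(mechanism=mech, ccf=ccf))
        if rng.random() < trans_control_fraction:
            target_vaf = float(rng.uniform(0.02, 0.1))
            ccf = min(target_vaf / (purity * 0.5), 1.0)
            events.append(ReversionSpec(mechanism=FRAME_RESTORING_INDEL, ccf=ccf, in_trans=True))
        cfgs.append(
            SimPatientConfig(
                patient_id=f"SIM{i:04d}",
                primary_lesion=primary,
                primary_origin="germline" if i % 4 else "somatic",
                purity=purity,
                depth=depth,
                read_length=read_length,
                error_rate=error_rate,
                reversion_events=tuple(events),
                tp53_vaf_target=float(np.clip(rng.normal(0.63, 0.2), 0.05, 0.95)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return cfgs


def write_patient_bundle(
    patient: SimPatient,
    outdir: str | Path,
    n_callers: int = 4,
    sensitivity: float = 0.95,
    fp_rate: float = 2.0,
) -> dict:
    """Write one patient's SAM, truth, per-caller tumour VCFs, germline VCF
    and lesion/model configs; returns the paths."""
    from .pipeline import write_primary_lesion  # local import avoids a cycle
    from .reversion import PrimaryLesion

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = patient.model
    pid = patient.cfg.patient_id
    paths: dict = {"patient_id": pid}
    sam = outdir / f"{pid}.reads.sam"
    write_sam(patient.reads, sam, model.contig, len(model.ref_seq))
    paths["sam"] = sam
    write_truth(patient.truth, outdir, model)
    paths["truth_json"] = outdir / f"{pid}.truth.json"
    callers = simulate_caller_vcfs(
        patient.truth, patient.cfg, n_callers=n_callers, sensitivity=sensitivity,
        fp_rate=fp_rate, model=model,
    )
    paths["tumour_vcfs"] = []
    for cid, calls in callers.items():
        p = outdir / f"{pid}.tumour.{cid}.vcf"
        _write_caller_vcf(calls, p, model)
        paths["tumour_vcfs"].append(p)
    germ = simulate_germline_vcf(patient.cfg, patient.truth, model)
    gpath = outdir / f"{pid}.germline.vcf"
    _write_caller_vcf(germ, gpath, model)
    paths["germline_vcf"] = gpath
    model_path = outdir / f"{pid}.model.yaml"
    from .refmodel import write_gene_model

    write_gene_model(model, model_path)
    paths["model"] = model_path
    lesion_path = outdir / f"{pid}.lesion.yaml"
    write_primary_lesion(
        PrimaryLesion(gene=model.gene_symbol, variant=patient.cfg.primary_lesion,
                      origin=patient.cfg.primary_origin),
        lesion_path,
    )
    paths["lesion"] = lesion_path
    return paths


def _write_caller_vcf(calls: Sequence[SeqVariant], path: Path, model: GeneModel) -> None:
    # records may sit on auxiliary contigs (e.g. the TP53 marker site)
    import pysam

    header = pysam.VariantHeader()
    header.add_line("##source=revertscan-sim")
    header.contigs.add(model.contig, length=len(model.ref_seq))
    header.contigs.add("TP53", length=100000)
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    header.formats.add("DP", "1", "Integer", "Read depth")
    header.add_sample("SAMPLE")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(calls, key=lambda x: (x.contig, x.pos, x.ref, x.alt)):
            rec = out.new_record(contig=v.contig, start=v.pos - 1, alleles=(v.ref, v.alt))
            if v.depth is not None:
                rec.samples["SAMPLE"]["DP"] = v.depth
                if v.alt_count is not None:
                    rec.samples["SAMPLE"]["AD"] = (v.depth - v.alt_count, v.alt_count)
            out.write(rec)


def simulate_cohort(
    n_patients: int,
    seed: int,
    outdir: str | Path | None = None,
    model: GeneModel | None = None,
    **cohort_kwargs,
) -> list[SimPatient]:
    """Generate a cohort; when ``outdir`` is given, write file bundles."""
    if model is None:
        model = toy_gene_model()
    cfgs = default_cohort_configs(n_patients, seed, model=model, **cohort_kwargs)
    patients = [simulate_patient(cfg, model) for cfg in cfgs]
    if outdir is not None:
        for p in patients:
            write_patient_bundle(p, outdir)
    return patients
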