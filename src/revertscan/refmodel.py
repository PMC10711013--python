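"""Gene models, haplotype construction and CDS translation.

This module is the coordinate and translation authority for the package:
every reversion decision is ultimately checked by rebuilding the mutant
haplotype and translating its coding sequence.

Conventions
-----------
External coordinates are 1-based inclusive (VCF/SAM style); internal offsets
are 0-based. Minus-strand genes store the genomic plus-strand sequence and
translate on the reverse complement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio.Seq import Seq

from .errors import ConfigError, ModelError, ReferenceMismatchError, VariantConflictError

__all__ = [
    "GeneModel",
    "Haplotype",
    "ProteinResult",
    "load_gene_model",
    "apply_variants",
    "translate_haplotype",
]

_DNA = set("ACGT")


@dataclass(frozen=True)
class GeneModel:
    """A reference contig slice with CDS structure.

    Parameters
    ----------
    gene_symbol : str
        HGNC-style gene name (e.g. ``BRCA1``).
    contig : str
        Contig/chromosome name the slice was taken from.
    strand : str
        ``'+'`` or ``'-'``. Minus-strand genes translate the reverse
        complement of the stored plus-strand sequence.
    seq_start : int
        1-based genomic position of ``ref_seq[0]``.
    ref_seq : str
        Uppercase plus-strand reference sequence of the slice.
    cds_intervals : tuple
        Ordered ``(start, end)`` 1-based inclusive genomic intervals.
    """

    gene_symbol: str
    contig: str
    strand: str
    seq_start: int
    ref_seq: str
    cds_intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cds_intervals", tuple(tuple(iv) for iv in self.cds_intervals))
        self._validate()

    # -- validation -------------------------------------------------------
    def _validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise ConfigError(f"strand must be '+' or '-', got {self.strand!r}")
        if set(self.ref_seq) - _DNA:
            bad = sorted(set(self.ref_seq) - _DNA)
            raise ModelError(f"ref_seq contains non-ACGT characters: {bad}")
        lo, hi = self.seq_start, self.seq_end
        prev_end = None
        total = 0
        for s, e in self.cds_intervals:
            if s > e:
                raise ModelError(f"CDS interval ({s},{e}) has start > end")
            if s < lo or e > hi:
                raise ModelError(f"CDS interval ({s},{e}) outside slice [{lo},{hi}]")
            if prev_end is not None and s <= prev_end:
                raise ModelError(f"CDS intervals unsorted or overlapping at ({s},{e})")
            prev_end = e
            total += e - s + 1
        if not self.cds_intervals:
            raise ModelError("at least one CDS interval required")
        if total % 3 != 0:
            raise ModelError(f"total CDS length {total} not divisible by 3")
        aa = self._translate_cds(self.cds_sequence())
        if "*" in aa[:-1]:
            raise ModelError("reference CDS contains an internal stop codon")
        if not aa.endswith("*"):
            raise ModelError("reference CDS does not end in a stop codon")

    # -- basic accessors --------------------------------------------------
    @property
    def seq_end(self) -> int:
        """1-based genomic position of the last stored reference base."""
        return self.seq_start + len(self.ref_seq) - 1

    @property
    def canonical_stop(self) -> int:
        """Genomic position of the last CDS base in translation order."""
        if self.strand == "+":
            return self.cds_intervals[-1][1]
        return self.cds_intervals[0][0]

    @property
    def cds_start(self) -> int:
        """Genomic position of the first translated base."""
        if self.strand == "+":
            return self.cds_intervals[0][0]
        return self.cds_intervals[-1][1]

    def cds_positions(self) -> list[int]:
        """All CDS genomic positions in ascending genomic order."""
        out: list[int] = []
        for s, e in self.cds_intervals:
            out.extend(range(s, e + 1))
        return out

    def base_at(self, pos: int) -> str:
        """Reference base at 1-based genomic position ``pos``."""
        if not self.seq_start <= pos <= self.seq_end:
            raise ReferenceMismatchError(f"position {pos} outside slice [{self.seq_start},{self.seq_end}]")
        return self.ref_seq[pos - self.seq_start]

    def slice(self, start: int, end: int) -> str:
        """Reference bases for the 1-based inclusive interval [start, end]."""
        if start > end:
            raise ValueError("start > end")
        if not (self.seq_start <= start and end <= self.seq_end):
            raise ReferenceMismatchError(f"interval [{start},{end}] outside slice")
        return self.ref_seq[start - self.seq_start : end - self.seq_start + 1]

    def cds_sequence(self) -> str:
        """Plus-strand concatenation of the CDS intervals."""
        return "".join(self.slice(s, e) for s, e in self.cds_intervals)

    def _translate_cds(self, plus_strand_cds: str) -> str:
        seq = plus_strand_cds
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        n = len(seq) - len(seq) % 3
        return str(Seq(seq[:n]).translate())


# ---------------------------------------------------------------------------
# Haplotypes
# ---------------------------------------------------------------------------

@dataclass
class _Seg:
    """One haplotype base: genomic anchor, base, whether it is a retained
    reference position (False for inserted bases)."""

    anchor: int
    base: str
    is_ref: bool


@dataclass
class Haplotype:
    """A sequence derived from a :class:`GeneModel` by applying variants."""

    model: GeneModel
    segments: list[_Seg] = field(repr=False)
    applied: tuple = ()

    @property
    def sequence(self) -> str:
        return "".join(s.base for s in self.segments)

    @property
    def coord_map(self) -> dict[int, int]:
        """Genomic position -> 0-based haplotype offset for retained
        reference positions. Deleted positions are absent."""
        return {s.anchor: i for i, s in enumerate(self.segments) if s.is_ref}


def _footprint(v) -> tuple[int, int]:
    return v.pos, v.pos + len(v.ref) - 1


def apply_variants(model: GeneModel, variants: Sequence) -> Haplotype:
    """Apply an ordered set of non-overlapping variants to the reference.

    Variants are applied right-to-left in genomic order so earlier edits do
    not shift later coordinates. Raises :class:`VariantConflictError` if two
    footprints overlap and :class:`ReferenceMismatchError` if a REF field
    disagrees with the model sequence.
    """
    segs = [_Seg(model.seq_start + i, b, True) for i, b in enumerate(model.ref_seq)]
    ordered = sorted(variants, key=lambda v: v.pos)
    for a, b in zip(ordered, ordered[1:]):
        if _footprint(a)[1] >= _footprint(b)[0]:
            raise VariantConflictError(
                f"overlapping variants: {a.pos}:{a.ref}>{a.alt} and {b.pos}:{b.ref}>{b.alt}"
            )
    for v in sorted(ordered, key=lambda v: v.pos, reverse=True):
        lo, hi = _footprint(v)
        if lo < model.seq_start or hi > model.seq_end:
            raise ReferenceMismatchError(f"variant {v.pos}:{v.ref}>{v.alt} outside model slice")
        idx = lo - model.seq_start
        observed = "".join(s.base for s in segs[idx : idx + len(v.ref)])
        if observed != v.ref:
            raise ReferenceMismatchError(
                f"REF mismatch at {v.pos}: expected {observed}, variant says {v.ref}"
            )
        k = min(len(v.ref), len(v.alt))
        repl = [_Seg(v.pos + i, v.alt[i], True) for i in range(k)]
        repl += [_Seg(v.pos + k - 1, c, False) for c in v.alt[k:]]
        segs[idx : idx + len(v.ref)] = repl
    return Haplotype(model=model, segments=segs, applied=tuple(variants))


@dataclass(frozen=True)
class ProteinResult:
    """Outcome of translating a haplotype's CDS.

    ``stop_offset`` is the codon index of the first stop (``None`` when no
    stop is reached). ``premature_stop`` is true iff that index precedes the
    canonical stop codon. A haplotype whose CDS start was deleted reports
    ``premature_stop=True`` with ``stop_offset=0`` by convention.
    """

    aa_sequence: str
    premature_stop: bool
    stop_offset: int | None
    frame_intact_at_canonical_stop: bool

    @property
    def functional(self) -> bool:
        """No premature stop and the canonical stop is reached in frame."""
        return (not self.premature_stop) and self.frame_intact_at_canonical_stop


def translate_haplotype(model: GeneModel, hap: Haplotype) -> ProteinResult:
    """Translate the CDS of a haplotype codon by codon.

    Inserted bases belong to the CDS when their anchor position is a CDS
    position; deleted CDS positions simply vanish, shifting the frame.
    """
    cds_pos = set(model.cds_positions())
    if model.cds_start not in hap.coord_map:
        return ProteinResult("", True, 0, False)
    bases = [s.base for s in hap.segments if s.anchor in cds_pos]
    seq = "".join(bases)
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    n_full = len(seq) - len(seq) % 3
    aa = str(Seq(seq[:n_full]).translate()) if n_full else ""
    in_frame = len(seq) % 3 == 0
    canonical_idx = len(seq) // 3 - 1 if in_frame else None
    first_stop = aa.find("*")
    stop_offset = first_stop if first_stop >= 0 else None
    if stop_offset is None:
        premature = False
    elif not in_frame:
        premature = True
    else:
        premature = stop_offset < canonical_idx
    frame_ok = in_frame and stop_offset is not None and stop_offset == canonical_idx
    shown = aa[: stop_offset + 1] if stop_offset is not None else aa
    return ProteinResult(shown, premature, stop_offset, frame_ok)


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

_REQUIRED = ("gene", "contig", "strand", "seq_start", "cds_intervals")


def load_gene_model(config_path: str | Path) -> GeneModel:
    """Load and validate a gene model from a YAML/JSON config.

    The config carries ``gene``, ``contig``, ``strand``, ``seq_start``,
    ``cds_intervals`` and either an inline ``ref_seq`` or a ``fasta`` path
    (the whole record, or a slice named by ``contig``).
    """
    path = Path(config_path)
    if not path.exists():
        raise ConfigError(f"gene-model config not found: {path}")
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError("gene-model config must be a mapping")
    for key in _REQUIRED:
        if key not in cfg:
            raise ConfigError(f"gene-model config missing required field: {key}")
    if "ref_seq" in cfg:
        ref_seq = str(cfg["ref_seq"]).upper()
    elif "fasta" in cfg:
        ref_seq = _read_fasta_record(Path(cfg["fasta"]), str(cfg["contig"]))
    else:
        raise ConfigError("gene-model config missing required field: ref_seq (or fasta)")
    try:
        return GeneModel(
            gene_symbol=str(cfg["gene"]),
            contig=str(cfg["contig"]),
            strand=str(cfg["strand"]),
            seq_start=int(cfg["seq_start"]),
            ref_seq=ref_seq,
            cds_intervals=tuple((int(s), int(e)) for s, e in cfg["cds_intervals"]),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"gene-model config field malformed: {exc}") from exc


def _read_fasta_record(path: Path, name: str) -> str:
    from Bio import SeqIO

    if not path.exists():
        raise ConfigError(f"fasta not found: {path}")
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id == name:
            return str(rec.seq).upper()
    raise ConfigError(f"fasta record {name!r} not found in {path}")


def write_gene_model(model: GeneModel, path: str | Path) -> None:
    """Serialise a gene model to YAML (round-trips with load_gene_model)."""
    cfg = {
        "gene": model.gene_symbol,
        "contig": model.contig,
        "strand": model.strand,
        "seq_start": model.seq_start,
        "ref_seq": model.ref_seq,
        "cds_intervals": [list(iv) for iv in model.cds_intervals],
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
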