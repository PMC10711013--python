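"""Lightweight aligned-read records and SAM I/O.

Phasing and allele recounting only need aligned base strings and CIGARs, so
reads are held in memory as small records; :mod:`pysam` handles the SAM
files at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pysam

__all__ = ["AlignedRead", "read_sam", "write_sam"]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
# ops consuming (query, reference)
_CONSUMES = {
    "M": (True, True), "=": (True, True), "X": (True, True),
    "I": (True, False), "S": (True, False),
    "D": (False, True), "N": (False, True),
    "H": (False, False), "P": (False, False),
}


@dataclass(frozen=True)
class AlignedRead:
    """A single-end aligned read.

    ``pos`` is the 1-based leftmost reference position of the alignment.
    """

    qname: str
    contig: str
    pos: int
    cigar: str
    seq: str

    @property
    def reference_end(self) -> int:
        """1-based inclusive rightmost reference position covered."""
        end = self.pos - 1
        for n, op in _CIGAR_RE.findall(self.cigar):
            if _CONSUMES[op][1]:
                end += int(n)
        return end

    def spans(self, start: int, end: int) -> bool:
        """True if the alignment covers the whole interval [start, end]."""
        return self.pos <= start and self.reference_end >= end

    def query_offset_at(self, pos: int) -> int | None:
        """Query index of the base aligned to reference position ``pos``
        (None if the position is deleted or outside the alignment)."""
        rpos = self.pos
        qpos = 0
        for n_str, op in _CIGAR_RE.findall(self.cigar):
            n = int(n_str)
            cq, cr = _CONSUMES[op]
            if cq and cr:
                if rpos <= pos < rpos + n:
                    return qpos + (pos - rpos)
                rpos += n
                qpos += n
            elif cq:
                qpos += n
            elif cr:
                if rpos <= pos < rpos + n:
                    return None
                rpos += n
        return None

    def allele_at(self, start: int, end: int) -> str:
        """Aligned query bases over reference interval [start, end].

        Deleted reference positions contribute nothing; inserted bases are
        attributed to the reference base immediately 5' of them, so an
        anchored-indel allele (VCF style) compares directly against the
        returned string. The caller is responsible for checking
        :meth:`spans` first.
        """
        out: list[str] = []
        rpos = self.pos
        qpos = 0
        for n_str, op in _CIGAR_RE.findall(self.cigar):
            n = int(n_str)
            cq, cr = _CONSUMES[op]
            if cq and cr:
                for i in range(n):
                    if start <= rpos <= end:
                        out.append(self.seq[qpos])
                    rpos += 1
                    qpos += 1
            elif cq:
                if op == "I" and start <= rpos - 1 <= end:
                    out.append(self.seq[qpos : qpos + n])
                qpos += n
            elif cr:
                rpos += n
        return "".join(out)


def write_sam(reads: Iterable[AlignedRead], path: str | Path, contig: str, contig_length: int) -> None:
    """Write reads to a (text) SAM file with a minimal @SQ header."""
    header = {"HD": {"VN": "1.6", "SO": "unsorted"}, "SQ": [{"SN": contig, "LN": contig_length}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in reads:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r.qname
            a.query_sequence = r.seq
            a.flag = 0
            a.reference_id = 0
            a.reference_start = r.pos - 1
            a.mapping_quality = 60
            a.cigarstring = r.cigar
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
            fh.write(a)


def read_sam(path: str | Path) -> list[AlignedRead]:
    """Load aligned, mapped reads from a SAM/BAM file."""
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            out.append(
                AlignedRead(
                    qname=a.query_name,
                    contig=a.reference_name,
                    pos=a.reference_start + 1,
                    cigar=a.cigarstring,
                    seq=a.query_sequence,
                )
            )
    return out
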