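"""Shared I/O and CIGAR arithmetic.

Internal coordinates are 0-based half-open everywhere; the 1-based SAM
convention is converted at the parse/write boundary.  Query coordinates of a
:class:`ContigAlignment` (``query_start``/``query_end``) are always expressed
on the *forward* strand of the contig, with hard-clipped bases counted, so a
fragment pair of one contig orders consistently regardless of strand.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import pysam

# CIGAR op classes (SAM spec)
QUERY_OPS = frozenset("MIS=X")  # consume query
REF_OPS = frozenset("MDN=X")  # consume reference
CLIP_OPS = frozenset("SH")
VALID_OPS = frozenset("MIDNSHP=X")

_PYSAM_OPS = "MIDNSHP=XB"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CigarOp:
    """A single CIGAR operation."""

    code: str
    length: int

    def __post_init__(self) -> None:
        if self.code not in VALID_OPS:
            raise ValueError(f"invalid CIGAR op code {self.code!r}")
        if self.length < 1:
            raise ValueError(f"CIGAR op length must be >= 1, got {self.length}")

    def __str__(self) -> str:
        return f"{self.length}{self.code}"


def parse_cigar(cigar: str) -> tuple[CigarOp, ...]:
    """Parse a CIGAR string into ops; '*' yields an empty tuple."""
    if cigar == "*":
        return ()
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if not num:
                raise ValueError(f"malformed CIGAR {cigar!r}")
            ops.append(CigarOp(ch, int(num)))
            num = ""
    if num:
        raise ValueError(f"malformed CIGAR {cigar!r}: trailing digits")
    return tuple(ops)


def cigar_str(ops: Sequence[CigarOp]) -> str:
    return "".join(str(op) for op in ops) if ops else "*"


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence over {A, C, G, T, N} (case kept as read)."""

    name: str
    seq: str


@dataclass
class ContigAlignment:
    """One mapped fragment of an assembly contig.

    ``cigar`` and ``seq`` are stored in alignment (record) orientation, as in
    the SAM record; ``seq`` excludes hard-clipped bases and is ``None`` when
    the record carried ``*``.  ``query_start``/``query_end`` are forward-strand
    contig coordinates with clips excluded from the interval but counted
    toward ``contig_length``.
    """

    contig_id: str
    ref_name: str
    ref_start: int
    ref_end: int
    strand: str
    mapq: int
    cigar: tuple[CigarOp, ...]
    query_start: int
    query_end: int
    contig_length: int
    seq: str | None = None
    is_supplementary: bool = False

    @property
    def lead_clip(self) -> int:
        """Total leading S+H clip in record orientation."""
        n = 0
        for op in self.cigar:
            if op.code in CLIP_OPS:
                n += op.length
            else:
                break
        return n

    @property
    def lead_hard_clip(self) -> int:
        return self.cigar[0].length if self.cigar and self.cigar[0].code == "H" else 0

    def aligned_query_span(self) -> int:
        return sum(op.length for op in self.cigar if op.code in QUERY_OPS - CLIP_OPS)

    def query_seq_slice(self, q0: int, q1: int) -> str | None:
        """Bases for record-orientation query interval [q0, q1).

        Coordinates count from the start of the record-orientation contig
        (hard clips included).  Returns None when SEQ is absent or the slice
        runs into hard-clipped bases.
        """
        if self.seq is None:
            return None
        h = self.lead_hard_clip
        s0, s1 = q0 - h, q1 - h
        if s0 < 0 or s1 > len(self.seq):
            return None
        return self.seq[s0:s1]


def _check_alphabet(seq: str, lineno: int, path: str) -> None:
    bad = set(seq.upper()) - set("ACGTN")
    if bad:
        raise ValueError(
            f"{path}:{lineno}: illegal character(s) {sorted(bad)} in sequence"
        )


def read_fasta(path: str, validate: bool = True) -> list[GenomeSequence]:
    """Read a FASTA file into GenomeSequence records, in file order.

    Headers are truncated at the first whitespace.  Malformed headers or
    non-ACGTN characters raise ValueError naming the line number.
    """
    records: list[GenomeSequence] = []
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append(GenomeSequence(name, "".join(chunks)))
                header = line[1:].strip()
                if not header:
                    raise ValueError(f"{path}:{lineno}: empty FASTA header")
                name = header.split()[0]
                chunks = []
            else:
                if name is None:
                    raise ValueError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                if validate:
                    _check_alphabet(line, lineno, path)
                chunks.append(line)
    if name is not None:
        records.append(GenomeSequence(name, "".join(chunks)))
    return records


def write_fasta(records: Iterable[GenomeSequence], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")
            if not rec.seq:
                pass  # header-only record for empty sequence


def read_fasta_dict(path: str, validate: bool = True) -> dict[str, str]:
    return {rec.name: rec.seq for rec in read_fasta(path, validate=validate)}


def _record_to_alignment(rec: pysam.AlignedSegment) -> ContigAlignment | None:
    if rec.is_unmapped:
        return None
    if rec.cigartuples is None:
        warnings.warn(f"record {rec.query_name}: no CIGAR, skipped")
        return None
    ops = tuple(CigarOp(_PYSAM_OPS[c], ln) for c, ln in rec.cigartuples)
    lead = 0
    for op in ops:
        if op.code in CLIP_OPS:
            lead += op.length
        else:
            break
    trail = 0
    for op in reversed(ops):
        if op.code in CLIP_OPS:
            trail += op.length
        else:
            break
    q_span = sum(op.length for op in ops if op.code in QUERY_OPS - CLIP_OPS)
    r_span = sum(op.length for op in ops if op.code in REF_OPS)
    contig_length = lead + q_span + trail
    seq = rec.query_sequence
    if seq is not None:
        soft = sum(op.length for op in ops if op.code == "S")
        if len(seq) != q_span + soft:
            warnings.warn(
                f"record {rec.query_name}: SEQ length {len(seq)} inconsistent "
                f"with CIGAR (expected {q_span + soft}), record rejected"
            )
            return None
    strand = "-" if rec.is_reverse else "+"
    if strand == "+":
        q0, q1 = lead, lead + q_span
    else:
        q0, q1 = trail, trail + q_span
    return ContigAlignment(
        contig_id=rec.query_name,
        ref_name=rec.reference_name,
        ref_start=rec.reference_start,
        ref_end=rec.reference_start + r_span,
        strand=strand,
        mapq=rec.mapping_quality,
        cigar=ops,
        query_start=q0,
        query_end=q1,
        contig_length=contig_length,
        seq=seq,
        is_supplementary=rec.is_supplementary,
    )


def parse_contig_alignments(
    sam_path: str, include_secondary: bool = False
) -> list[ContigAlignment]:
    """Parse mapped records of a SAM/BAM file into ContigAlignments.

    Secondary alignments are excluded by default (supplementary records are
    kept, since split contigs are emitted as primary + supplementary pairs);
    unmapped and CIGAR-less records are skipped.
    """
    alns: list[ContigAlignment] = []
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
            for rec in fh:
                if rec.is_secondary and not include_secondary:
                    continue
                aln = _record_to_alignment(rec)
                if aln is not None:
                    alns.append(aln)
    finally:
        pysam.set_verbosity(save)
    return alns


def write_contig_alignments(
    alns: Sequence[ContigAlignment],
    sam_path: str,
    reference_lengths: dict[str, int],
) -> None:
    """Write alignments back to SAM (inverse of :func:`parse_contig_alignments`)."""
    names = list(reference_lengths)
    header = pysam.AlignmentHeader.from_references(
        names, [reference_lengths[n] for n in names]
    )
    with pysam.AlignmentFile(sam_path, "w", header=header) as out:
        for aln in alns:
            rec = pysam.AlignedSegment(header)
            rec.query_name = aln.contig_id
            rec.reference_name = aln.ref_name
            rec.reference_start = aln.ref_start
            rec.mapping_quality = aln.mapq
            rec.cigarstring = cigar_str(aln.cigar)
            rec.query_sequence = aln.seq
            flag = 0
            if aln.strand == "-":
                flag |= 16
            if aln.is_supplementary:
                flag |= 2048
            rec.flag = flag
            out.write(rec)


def cigar_walk(aln: ContigAlignment) -> Iterator[tuple[CigarOp, int, int]]:
    """Yield each CIGAR op with the (ref, query) coordinates where it begins.

    Coordinates are in alignment (record) orientation: the reference
    coordinate starts at ``ref_start`` and the query coordinate at the
    leading-clip length, so for forward-strand alignments the walk ends at
    ``(ref_end, query_end)``.  Clip ops advance the query coordinate.
    """
    ref = aln.ref_start
    query = 0
    for op in aln.cigar:
        yield op, ref, query
        if op.code in REF_OPS:
            ref += op.length
        if op.code in QUERY_OPS or op.code == "H":
            query += op.length


def write_bed(
    intervals: Iterable[tuple[str, int, int] | tuple[str, int, int, str]],
    path: str,
) -> None:
    """Write 0-based half-open intervals as BED (optional 4th name column)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path: str) -> list[tuple[str, int, int, str | None]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            name = parts[3] if len(parts) > 3 else None
            out.append((parts[0], int(parts[1]), int(parts[2]), name))
    return out
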