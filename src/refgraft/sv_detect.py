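"""Insertion and deletion discovery from contig-to-reference alignments.

Two complementary detectors are implemented:

* INTRA — events contained inside a single continuous alignment, read
  directly off the CIGAR (``I`` ops for insertions, ``D`` ops for deletions).
* INTER — events spanning a split mapping: a pair of query-consecutive
  fragments of one contig.  The contig sequence between the fragments is the
  candidate insertion; the uncovered reference span between them (adjusted by
  the contig-side gap/overlap) is the candidate deletion.

Calls below 100 bp are discarded, as are calls from alignments with mapping
quality 0.  Crowded candidates (several insertion points within 1 kb) are
removed wholesale by :func:`proximity_filter`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from refgraft.alignment_io import (
    ContigAlignment,
    cigar_walk,
    revcomp,
)

DEFAULT_MIN_LEN = 100
DEFAULT_ADJACENCY_FRAC = 0.2
DEFAULT_PROXIMITY_RADIUS = 1000
DEFAULT_DEL_MAX_FRAC = 0.2
DEFAULT_DEL_MIN_CONTIG = 100_000


@dataclass
class InsertionCall:
    """A candidate long insertion relative to the reference."""

    ref_name: str
    ref_pos: int  # 0-based base index before which the insertion sits
    length: int
    sequence: str
    method: str  # INTRA | INTER
    contig_id: str
    split_distance: int = 0  # signed ref gap between fragments (INTER)
    mapq: int = 0
    id: str | None = None


@dataclass
class DeletionCall:
    ref_name: str
    ref_start: int
    ref_end: int
    del_len: int
    method: str
    contig_id: str
    rlen: int = 0  # unmapped reference span (INTER)
    contig_gap: int = 0  # signed: positive = contig gap, negative = overlap
    id: str | None = None


@dataclass
class FragmentPair:
    """Two query-consecutive mapped fragments of one contig.

    ``left``/``right`` are ordered by forward-strand query coordinates;
    ``clip_len`` is the signed contig span between them (negative when the
    fragments overlap on the contig); ``ref_gap`` is the signed reference
    distance between the reference-leftmost fragment's end and the other
    fragment's start.
    """

    left: ContigAlignment
    right: ContigAlignment
    clip_len: int
    ref_gap: int

    @property
    def insertion_point(self) -> int:
        """Reference coordinate at which the clipped sequence belongs."""
        a, b = self.left, self.right
        ref_left = a if a.ref_start <= b.ref_start else b
        return ref_left.ref_end

    @property
    def min_mapq(self) -> int:
        return min(self.left.mapq, self.right.mapq)


def build_fragment_pairs(alns: Iterable[ContigAlignment]) -> list[FragmentPair]:
    """Pair query-consecutive fragments of each split-mapped contig.

    Only pairs on the same reference and strand are returned; no fragment of
    the contig maps between the two in query coordinates.
    """
    by_contig: dict[str, list[ContigAlignment]] = {}
    for aln in alns:
        by_contig.setdefault(aln.contig_id, []).append(aln)
    pairs: list[FragmentPair] = []
    for frags in by_contig.values():
        if len(frags) < 2:
            continue
        frags.sort(key=lambda a: (a.query_start, a.query_end))
        for a, b in zip(frags, frags[1:]):
            if a.ref_name != b.ref_name or a.strand != b.strand:
                continue
            clip_len = b.query_start - a.query_end
            if a.strand == "+":
                ref_gap = b.ref_start - a.ref_end
            else:
                # query-later fragment sits ref-leftward on '-' strand
                ref_gap = a.ref_start - b.ref_end
            pairs.append(FragmentPair(a, b, clip_len, ref_gap))
    return pairs


def _intra_sequence(
    aln: ContigAlignment,
    q0: int,
    q1: int,
    contigs: Mapping[str, str] | None,
) -> str | None:
    seq = aln.query_seq_slice(q0, q1)
    if seq is not None:
        return seq
    if contigs is not None and aln.contig_id in contigs:
        contig = contigs[aln.contig_id]
        if aln.strand == "+":
            return contig[q0:q1]
        # q0/q1 are record-orientation offsets; map to forward strand
        L = aln.contig_length
        return revcomp(contig[L - q1 : L - q0])
    return None


def detect_ins_intra(
    alns: Iterable[ContigAlignment],
    min_len: int = DEFAULT_MIN_LEN,
    contigs: Mapping[str, str] | None = None,
) -> list[InsertionCall]:
    """Insertions from CIGAR I ops >= min_len in alignments with mapq > 0."""
    calls: list[InsertionCall] = []
    missing: set[str] = set()
    for aln in alns:
        if aln.mapq <= 0:
            continue
        for op, ref_pos, q_pos in cigar_walk(aln):
            if op.code != "I" or op.length < min_len:
                continue
            seq = _intra_sequence(aln, q_pos, q_pos + op.length, contigs)
            if seq is None:
                missing.add(aln.contig_id)
                continue
            calls.append(
                InsertionCall(
                    ref_name=aln.ref_name,
                    ref_pos=ref_pos,
                    length=op.length,
                    sequence=seq,
                    method="INTRA",
                    contig_id=aln.contig_id,
                    split_distance=0,
                    mapq=aln.mapq,
                )
            )
    if missing:
        raise ValueError(
            "insertion sequence unavailable (SAM lacks SEQ and no contig FASTA "
            "supplied) for contigs: " + ", ".join(sorted(missing))
        )
    return calls


def _clipped_sequence(
    pair: FragmentPair, contigs: Mapping[str, str] | None
) -> str | None:
    """Forward-strand contig bases between the fragments, in ref orientation."""
    a = pair.left
    q0, q1 = a.query_end, pair.right.query_start
    if contigs is not None and a.contig_id in contigs:
        fwd = contigs[a.contig_id][q0:q1]
        return fwd if a.strand == "+" else revcomp(fwd)
    # fall back to soft-clipped bases of either record
    L = a.contig_length
    for frag in (pair.left, pair.right):
        if frag.strand == "+":
            r0, r1 = q0, q1
        else:
            r0, r1 = L - q1, L - q0
        seq = frag.query_seq_slice(r0, r1)
        if seq is not None:
            return seq
    return None


def detect_ins_inter(
    alns: Iterable[ContigAlignment],
    min_len: int = DEFAULT_MIN_LEN,
    adjacency_frac: float = DEFAULT_ADJACENCY_FRAC,
    contigs: Mapping[str, str] | None = None,
) -> list[InsertionCall]:
    """Insertions from split mappings.

    A fragment pair yields a call when both fragments have mapq > 0, the
    clipped contig span is >= min_len, and the fragments map adjacently:
    |ref_gap| < adjacency_frac * clip_len.  The absolute value admits
    overlapping fragments (negative split distance), which the reference
    grafting stage resolves by trimming the duplicated reference sequence.
    """
    calls: list[InsertionCall] = []
    missing: set[str] = set()
    for pair in build_fragment_pairs(alns):
        if pair.min_mapq <= 0:
            continue
        if pair.clip_len < min_len:
            continue
        if abs(pair.ref_gap) >= adjacency_frac * pair.clip_len:
            continue
        seq = _clipped_sequence(pair, contigs)
        if seq is None:
            missing.add(pair.left.contig_id)
            continue
        calls.append(
            InsertionCall(
                ref_name=pair.left.ref_name,
                ref_pos=pair.insertion_point,
                length=pair.clip_len,
                sequence=seq,
                method="INTER",
                contig_id=pair.left.contig_id,
                split_distance=pair.ref_gap,
                mapq=pair.min_mapq,
            )
        )
    if missing:
        raise ValueError(
            "clipped sequence unavailable (hard-clipped records and no contig "
            "FASTA supplied) for contigs: " + ", ".join(sorted(missing))
        )
    return calls


def proximity_filter(
    calls: Sequence[InsertionCall], radius: int = DEFAULT_PROXIMITY_RADIUS
) -> list[InsertionCall]:
    """Remove every call within ``radius`` bp of another call.

    Removal is transitive (single-linkage): a chain of calls each within
    radius of the next is removed as a whole.  Survivors are returned sorted
    by (ref_name, ref_pos).
    """
    ordered = sorted(calls, key=lambda c: (c.ref_name, c.ref_pos, c.length))
    keep: list[InsertionCall] = []
    cluster: list[InsertionCall] = []
    prev: InsertionCall | None = None
    for call in ordered:
        if (
            prev is not None
            and call.ref_name == prev.ref_name
            and call.ref_pos - prev.ref_pos <= radius
        ):
            cluster.append(call)
        else:
            if len(cluster) == 1:
                keep.append(cluster[0])
            cluster = [call]
        prev = call
    if len(cluster) == 1:
        keep.append(cluster[0])
    return keep


def detect_del_intra(
    alns: Iterable[ContigAlignment], min_len: int = DEFAULT_MIN_LEN
) -> list[DeletionCall]:
    """Deletions from CIGAR D ops >= min_len in alignments with mapq > 0."""
    calls: list[DeletionCall] = []
    for aln in alns:
        if aln.mapq <= 0:
            continue
        for op, ref_pos, _ in cigar_walk(aln):
            if op.code == "D" and op.length >= min_len:
                calls.append(
                    DeletionCall(
                        ref_name=aln.ref_name,
                        ref_start=ref_pos,
                        ref_end=ref_pos + op.length,
                        del_len=op.length,
                        method="INTRA",
                        contig_id=aln.contig_id,
                    )
                )
    return calls


def detect_del_inter(
    alns: Iterable[ContigAlignment],
    min_len: int = DEFAULT_MIN_LEN,
    max_frac: float = DEFAULT_DEL_MAX_FRAC,
    min_contig: int = DEFAULT_DEL_MIN_CONTIG,
) -> list[DeletionCall]:
    """Deletions from split mappings of long contigs.

    The unmapped reference span between the fragments (rlen) is adjusted by
    the contig-side relationship: no contig gap -> del_len = rlen; contig
    overlap o -> del_len = rlen - o; contig gap g -> del_len = rlen + g.
    Only contigs longer than ``min_contig`` are considered and calls longer
    than ``max_frac`` of the contig are discarded.
    """
    calls: list[DeletionCall] = []
    for pair in build_fragment_pairs(alns):
        if pair.min_mapq <= 0:
            continue
        if pair.left.contig_length <= min_contig:
            continue
        rlen = pair.ref_gap
        if rlen <= 0:  # fragments must map at some distance on the reference
            continue
        del_len = rlen + pair.clip_len
        if del_len < min_len or del_len >= max_frac * pair.left.contig_length:
            continue
        start = pair.insertion_point
        calls.append(
            DeletionCall(
                ref_name=pair.left.ref_name,
                ref_start=start,
                ref_end=start + rlen,
                del_len=del_len,
                method="INTER",
                contig_id=pair.left.contig_id,
                rlen=rlen,
                contig_gap=pair.clip_len,
            )
        )
    return calls


def assign_ids(
    calls: Sequence[InsertionCall], prefix: str = "INS"
) -> list[InsertionCall]:
    """Assign serial ids in genome order after all filtering."""
    ordered = sorted(calls, key=lambda c: (c.ref_name, c.ref_pos, c.length))
    return [replace(c, id=f"{prefix}{i}") for i, c in enumerate(ordered, 1)]


def validate_against_prototype(
    calls: Sequence[InsertionCall],
    prototype_alignments: Sequence[ContigAlignment],
    insertion_intervals: Mapping[str, tuple[str, int, int]],
    prototype_sequences: Mapping[str, str] | None = None,
) -> list[InsertionCall]:
    """Keep calls whose integrated interval realigns identically.

    ``insertion_intervals`` maps call id -> (ref_name, start, end) in the
    prototype (augmented) reference, as emitted by the grafting stage.  A call
    survives iff at least one realigned contig covers its interval with pure
    match ops and — when both the record SEQ and the prototype sequence are
    available — base-identical sequence.  Uncovered intervals count as
    unsupported and are removed.
    """
    by_ref: dict[str, list[ContigAlignment]] = {}
    for aln in prototype_alignments:
        by_ref.setdefault(aln.ref_name, []).append(aln)

    kept: list[InsertionCall] = []
    for call in calls:
        if call.id is None or call.id not in insertion_intervals:
            raise KeyError(f"no prototype interval recorded for call {call.id!r}")
        ref_name, start, end = insertion_intervals[call.id]
        proto_seq = (
            prototype_sequences.get(ref_name) if prototype_sequences else None
        )
        if any(
            _covers_identically(aln, start, end, proto_seq)
            for aln in by_ref.get(ref_name, [])
        ):
            kept.append(call)
    return kept


def _covers_identically(
    aln: ContigAlignment, start: int, end: int, proto_seq: str | None
) -> bool:
    if aln.ref_start > start or aln.ref_end < end:
        return False
    for op, ref_pos, q_pos in cigar_walk(aln):
        op_ref_end = ref_pos + (op.length if op.code in "MDN=X" else 0)
        if op_ref_end <= start:
            continue
        if ref_pos >= end:
            break
        # op intersects the interval
        if op.code in "DNX":
            return False
        if op.code == "I":
            if start < ref_pos < end:  # insertion strictly inside
                return False
            continue
        if op.code in "M=":
            if op.code == "M" and proto_seq is not None and aln.seq is not None:
                lo = max(ref_pos, start)
                hi = min(op_ref_end, end)
                q_lo = q_pos + (lo - ref_pos)
                frag = aln.query_seq_slice(q_lo, q_lo + (hi - lo))
                if frag is None:
                    return False
                if frag.upper() != proto_seq[lo:hi].upper():
                    return False
    return True


def write_insertion_table(calls: Sequence[InsertionCall], path: str) -> None:
    cols = "id\tchrom\tpos\tlength\tmethod\tsplit_distance\tmapq\n"
    with open(path, "w") as fh:
        fh.write(cols)
        for c in calls:
            fh.write(
                f"{c.id}\t{c.ref_name}\t{c.ref_pos}\t{c.length}\t{c.method}\t"
                f"{c.split_distance}\t{c.mapq}\n"
            )


def write_insertion_fasta(calls: Sequence[InsertionCall], path: str) -> None:
    from refgraft.alignment_io import GenomeSequence, write_fasta

    write_fasta(
        [GenomeSequence(c.id or f"{c.ref_name}:{c.ref_pos}", c.sequence) for c in calls],
        path,
    )


def write_deletion_bed(calls: Sequence[DeletionCall], path: str) -> None:
    from refgraft.alignment_io import write_bed

    write_bed(
        [
            (c.ref_name, c.ref_start, c.ref_start + c.del_len, c.method)
            for c in sorted(calls, key=lambda c: (c.ref_name, c.ref_start))
        ],
        path,
    )
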