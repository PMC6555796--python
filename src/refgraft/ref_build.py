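"""Grafting insertion calls into a reference genome.

Three integration cases follow from the split-contig distance ``d`` of an
INTER call (INTRA calls behave like ``d = 0``):

* ``d = 0`` — the fragments are exactly adjacent: the insertion sequence is
  spliced in at the insertion point, deleting nothing.
* ``d > 0`` — the fragments leave a reference gap of ``d`` bases: that gap is
  replaced by the insertion sequence.
* ``d < 0`` — the fragments overlap ``|d|`` reference bases: the overlapped
  reference segment is replaced by overlap + insertion + overlap, so both
  fragment ends retain their shared flank.

Besides the augmented FASTA the module emits a monotone liftover chain
(UCSC chain format) and builds the decoy contig: all insertion sequences
concatenated with a 20-N spacer after each, so that reads originating from
the novel sequence align there instead of mismapping.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from refgraft.alignment_io import GenomeSequence
from refgraft.sv_detect import InsertionCall

DEFAULT_SPACER = 20


@dataclass(frozen=True)
class IntegrationEdit:
    """One splice: delete ``delete_len`` reference bases at ``ref_pos``, insert ``insert_seq``."""

    ref_name: str
    ref_pos: int
    delete_len: int
    insert_seq: str
    source_id: str


@dataclass
class LiftoverChain:
    """Monotone block map from source to augmented (destination) coordinates.

    ``blocks[ref]`` is an ordered list of (src_start, src_end, dst_start,
    dst_end) spans of unedited sequence; ``insertion_intervals`` maps each
    source call id to the destination interval its inserted sequence occupies.
    """

    src_sizes: dict[str, int]
    dst_sizes: dict[str, int]
    blocks: dict[str, list[tuple[int, int, int, int]]]
    insertion_intervals: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def lift(self, ref_name: str, pos: int) -> int | None:
        """Map an unedited source position to destination; None if deleted."""
        blks = self.blocks.get(ref_name, [])
        i = bisect_right(blks, pos, key=lambda b: b[0]) - 1
        if i < 0:
            return None
        s0, s1, d0, _ = blks[i]
        if s0 <= pos < s1:
            return d0 + (pos - s0)
        return None

    def lift_back(self, ref_name: str, pos: int) -> int | None:
        """Map a destination position back to source; None inside inserted sequence."""
        blks = self.blocks.get(ref_name, [])
        i = bisect_right(blks, pos, key=lambda b: b[2]) - 1
        if i < 0:
            return None
        s0, _, d0, d1 = blks[i]
        if d0 <= pos < d1:
            return s0 + (pos - d0)
        return None

    def write_chain(self, path: str) -> None:
        """Emit the map in UCSC chain format (source = target, dst = query)."""
        with open(path, "w") as fh:
            for i, (ref, blks) in enumerate(self.blocks.items(), 1):
                if not blks:
                    continue
                s_size, d_size = self.src_sizes[ref], self.dst_sizes[ref]
                s0, d0 = blks[0][0], blks[0][2]
                s_end, d_end = blks[-1][1], blks[-1][3]
                fh.write(
                    f"chain 0 {ref} {s_size} + {s0} {s_end} "
                    f"{ref} {d_size} + {d0} {d_end} {i}\n"
                )
                for (a0, a1, b0, b1), nxt in zip(blks, blks[1:] + [None]):
                    size = a1 - a0
                    if nxt is None:
                        fh.write(f"{size}\n")
                    else:
                        dt = nxt[0] - a1  # skipped in source (deleted)
                        dq = nxt[2] - b1  # skipped in destination (inserted)
                        fh.write(f"{size}\t{dt}\t{dq}\n")
                fh.write("\n")


@dataclass
class DecoyBuild:
    insertion_ids: list[str]
    spacer_len: int
    offsets: dict[str, tuple[int, int]]
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def build_integration_plan(
    calls: Sequence[InsertionCall],
    reference: Mapping[str, str],
) -> list[IntegrationEdit]:
    """Turn insertion calls into non-overlapping splice edits.

    Overlapping edits keep the earlier call (by id order); later conflicting
    calls are dropped with a warning.  This does not arise after proximity
    filtering but is resolved deterministically anyway.
    """
    edits: list[IntegrationEdit] = []
    for call in calls:
        cid = call.id or f"{call.ref_name}:{call.ref_pos}"
        d = call.split_distance if call.method == "INTER" else 0
        if d == 0:
            edit = IntegrationEdit(call.ref_name, call.ref_pos, 0, call.sequence, cid)
        elif d > 0:
            edit = IntegrationEdit(call.ref_name, call.ref_pos, d, call.sequence, cid)
        else:
            o = -d
            start = call.ref_pos - o
            if start < 0:
                raise ValueError(f"call {cid}: overlap extends past chromosome start")
            overlap = reference[call.ref_name][start : call.ref_pos]
            edit = IntegrationEdit(
                call.ref_name, start, o, overlap + call.sequence + overlap, cid
            )
        edits.append(edit)

    edits.sort(key=lambda e: (e.ref_name, e.ref_pos))
    accepted: list[IntegrationEdit] = []
    for edit in edits:
        prev = accepted[-1] if accepted and accepted[-1].ref_name == edit.ref_name else None
        if prev is not None and edit.ref_pos < prev.ref_pos + prev.delete_len:
            warnings.warn(
                f"edit {edit.source_id} overlaps {prev.source_id}; dropped"
            )
            continue
        accepted.append(edit)
    return accepted


def apply_integration(
    reference: Mapping[str, str],
    plan: Sequence[IntegrationEdit],
) -> tuple[dict[str, str], LiftoverChain]:
    """Apply splice edits and return (augmented genome, liftover chain).

    Edits are applied right-to-left per chromosome so stored positions stay
    valid; the chain maps every unedited base bijectively and records the
    destination interval of each inserted sequence.
    """
    by_ref: dict[str, list[IntegrationEdit]] = {}
    for edit in plan:
        if edit.ref_name not in reference:
            raise KeyError(f"edit on unknown chromosome {edit.ref_name!r}")
        if edit.ref_pos + edit.delete_len > len(reference[edit.ref_name]):
            raise ValueError(
                f"edit {edit.source_id} extends past end of {edit.ref_name}"
            )
        by_ref.setdefault(edit.ref_name, []).append(edit)

    out: dict[str, str] = {}
    chain = LiftoverChain(
        src_sizes={n: len(s) for n, s in reference.items()},
        dst_sizes={},
        blocks={},
    )
    for ref_name, seq in reference.items():
        edits = sorted(by_ref.get(ref_name, []), key=lambda e: e.ref_pos)
        pieces: list[str] = []
        blocks: list[tuple[int, int, int, int]] = []
        src_cursor = 0
        dst_cursor = 0
        for edit in edits:
            if edit.ref_pos > src_cursor:
                span = edit.ref_pos - src_cursor
                pieces.append(seq[src_cursor : edit.ref_pos])
                blocks.append(
                    (src_cursor, edit.ref_pos, dst_cursor, dst_cursor + span)
                )
                dst_cursor += span
            pieces.append(edit.insert_seq)
            chain.insertion_intervals[edit.source_id] = (
                ref_name,
                dst_cursor,
                dst_cursor + len(edit.insert_seq),
            )
            dst_cursor += len(edit.insert_seq)
            src_cursor = edit.ref_pos + edit.delete_len
        if src_cursor < len(seq) or not blocks:
            span = len(seq) - src_cursor
            pieces.append(seq[src_cursor:])
            blocks.append((src_cursor, len(seq), dst_cursor, dst_cursor + span))
            dst_cursor += span
        out[ref_name] = "".join(pieces)
        chain.blocks[ref_name] = blocks
        chain.dst_sizes[ref_name] = dst_cursor
        assert dst_cursor == len(out[ref_name])
    return out, chain


def build_decoy(
    calls: Sequence[InsertionCall],
    spacer: int = DEFAULT_SPACER,
    name: str = "decoy",
) -> DecoyBuild:
    """Concatenate insertion sequences with an N-spacer after each.

    k insertions of total length L yield a decoy of length L + k * spacer,
    containing exactly k runs of ``spacer`` Ns (insertion sequences are
    N-free by construction).
    """
    if not calls:
        warnings.warn("building decoy from an empty call set")
    pieces: list[str] = []
    offsets: dict[str, tuple[int, int]] = {}
    ids: list[str] = []
    cursor = 0
    pad = "N" * spacer
    for call in calls:
        cid = call.id or f"{call.ref_name}:{call.ref_pos}"
        ids.append(cid)
        offsets[cid] = (cursor, cursor + call.length)
        pieces.append(call.sequence)
        pieces.append(pad)
        cursor += call.length + spacer
    return DecoyBuild(ids, spacer, offsets, "".join(pieces))


def decoy_fasta(decoy: DecoyBuild, name: str = "decoy") -> GenomeSequence:
    return GenomeSequence(name, decoy.sequence)


def select_release_set(
    calls: Sequence[InsertionCall],
    genotype_matrix,
    min_carriers: int,
    other_assembly_hits: Iterable[str] | None = None,
) -> tuple[list[InsertionCall], list[InsertionCall]]:
    """Select calls for public release.

    ``genotype_matrix`` is a samples x insertion-ids frame of called summed
    copy numbers (NaN = missing).  A call goes into the reference set iff its
    carrier count (samples with called copy >= 1) reaches ``min_carriers``;
    it goes into the decoy set iff it meets the carrier criterion OR appears
    in ``other_assembly_hits`` (ids found in external assemblies).

    Returns (reference_set, decoy_set).
    """
    import pandas as pd

    ids = {c.id for c in calls}
    unknown = [c for c in genotype_matrix.columns if c not in ids]
    if unknown:
        raise KeyError(f"genotype matrix contains unknown insertion ids: {unknown}")
    hits = set(other_assembly_hits or ())
    carriers = (genotype_matrix >= 1).sum(axis=0)
    ref_set: list[InsertionCall] = []
    decoy_set: list[InsertionCall] = []
    for call in calls:
        n = int(carriers.get(call.id, 0))
        if n >= min_carriers:
            ref_set.append(call)
            decoy_set.append(call)
        elif call.id in hits:
            decoy_set.append(call)
    return ref_set, decoy_set


def majorize_insertion_sequences(
    calls: Sequence[InsertionCall],
    site_frequencies: Mapping[str, Sequence[tuple[int, str, str, float]]],
) -> list[InsertionCall]:
    """Replace assembled bases by the population-major allele.

    ``site_frequencies[call_id]`` lists (offset, assembled_base, alt_base,
    alt_frequency) within the insertion.  A base is swapped only when the
    alternative allele is in strict majority (frequency > 0.5), so a rare
    variant private to the assembled individual is anonymised away.
    """
    out: list[InsertionCall] = []
    for call in calls:
        sites = site_frequencies.get(call.id or "", [])
        if not sites:
            out.append(call)
            continue
        seq = list(call.sequence)
        for offset, ref_base, alt_base, freq in sites:
            if not 0 <= offset < len(seq):
                raise IndexError(
                    f"site offset {offset} out of range for call {call.id} "
                    f"(length {len(seq)})"
                )
            if freq > 0.5:
                seq[offset] = alt_base
        out.append(replace(call, sequence="".join(seq)))
    return out
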