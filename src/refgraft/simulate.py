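"""Synthetic data with known truth for every pipeline stage.

The generator emulates the study design end to end: a random reference
genome, planted insertions/deletions with population allele frequencies,
contig alignments split around each event (INTRA CIGAR records and INTER
fragment pairs with configurable split distance), and per-individual window
coverage whose insertion-level normalised depth follows the genotyping
model Normal(a + b * S, 1/c) with multinomial haploid copies.

Insertion lengths are drawn from a two-mode log-normal mixture centred near
the Alu (~300 bp) and LINE (~6 kb) repeat lengths, matching the bimodal
length spectrum such insertions show in real assemblies.

All randomness flows from a single seed: each stage derives its own child
generator from :func:`stage_rng`, so stages can be re-run independently and
reproduce bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from refgraft.alignment_io import CigarOp, ContigAlignment

BASES = np.array(list("ACGT"))

_STAGES = ("reference", "variants", "deletions", "contigs", "coverage", "values")


@dataclass
class SimConfig:
    """Study conditions for the synthetic pipeline.

    Defaults reflect the desk-scale re-creation of the study: a 2-Mb genome,
    40 insertions of 100 bp-10 kb with Alu/LINE-like length modes, allele
    frequencies spread over (0.05, 0.95), and a coverage model with unit
    per-copy slope (a=0, b=1) and depth noise sd 0.2 (c=25).
    """

    seed: int
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000}
    )
    n_insertions: int = 40
    n_deletions: int = 0
    min_spacing: int = 2000
    length_range: tuple[int, int] = (100, 10_000)
    alu_mode: float = 300.0
    line_mode: float = 6000.0
    alu_weight: float = 0.6
    freq_range: tuple[float, float] = (0.05, 0.95)
    n_individuals: int = 200
    gc_target: float = 0.5
    # coverage model; a > 0 reflects the stray-read background every locus
    # keeps even in non-carriers (zero-depth windows are not alignable, so
    # a = 0 would leave null genotypes with no usable coverage value)
    cov_a: float = 0.1
    cov_b: float = 1.0
    cov_c: float = 25.0
    base_depth: float = 40.0
    gc_bias_amp: float = 0.3
    gc_bias_center: float = 0.45
    gc_bias_width: float = 0.1
    # contig simulation
    contig_flank: int = 500
    del_contig_flank: int = 51_000
    mapq: int = 60


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage child generator from the run seed."""
    idx = _STAGES.index(stage)
    child = np.random.SeedSequence(seed).spawn(len(_STAGES))[idx]
    return np.random.default_rng(child)


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def sim_reference(config: SimConfig) -> dict[str, str]:
    """Random reference genome with the configured GC content."""
    rng = stage_rng(config.seed, "reference")
    out = {}
    for name, length in config.chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length")
        out[name] = random_sequence(rng, length, config.gc_target)
    return out


def _draw_lengths(rng: np.random.Generator, config: SimConfig, n: int) -> np.ndarray:
    """Two-mode log-normal mixture clipped to the configured range."""
    is_alu = rng.random(n) < config.alu_weight
    mu = np.where(is_alu, np.log(config.alu_mode), np.log(config.line_mode))
    sigma = np.where(is_alu, 0.15, 0.4)
    lengths = np.exp(rng.normal(mu, sigma))
    lo, hi = config.length_range
    return np.clip(np.round(lengths), lo, hi).astype(int)


def _draw_sites(
    rng: np.random.Generator,
    config: SimConfig,
    n: int,
    margin: int,
    allow_close: bool = False,
) -> list[tuple[str, int]]:
    refs = list(config.chrom_lengths)
    weights = np.array([config.chrom_lengths[r] for r in refs], dtype=float)
    weights /= weights.sum()
    sites: list[tuple[str, int]] = []
    for _ in range(20 * n):
        if len(sites) == n:
            break
        ref = refs[rng.choice(len(refs), p=weights)]
        L = config.chrom_lengths[ref]
        if L <= 2 * margin:
            continue
        pos = int(rng.integers(margin, L - margin))
        if not allow_close and any(
            r == ref and abs(p - pos) < config.min_spacing for r, p in sites
        ):
            continue
        sites.append((ref, pos))
    if len(sites) < n:
        raise ValueError(
            f"could not place {n} sites with spacing {config.min_spacing}; "
            "genome too small (pass allow_close=True to relax)"
        )
    return sorted(sites)


def plant_variants(
    reference: Mapping[str, str],
    config: SimConfig,
    allow_close: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant insertions and draw per-individual genotypes.

    Returns (truth, genotypes): ``truth`` has one row per insertion
    (id, chrom, pos, length, sequence, freq, method, ref_gap) where method
    cycles through INTRA and the three INTER split-distance cases so every
    detection path is exercised; ``genotypes`` is individuals x insertion
    ids of summed copy numbers drawn Binomial(2, freq).
    """
    rng = stage_rng(config.seed, "variants")
    sites = _draw_sites(
        rng, config, config.n_insertions, config.contig_flank + 50, allow_close
    )
    lengths = _draw_lengths(rng, config, config.n_insertions)
    lo, hi = config.freq_range
    freqs = rng.uniform(lo, hi, config.n_insertions)
    modes = ["INTRA", ("INTER", 0), ("INTER", 1), ("INTER", -1)]
    rows = []
    for i, ((ref, pos), L, f) in enumerate(zip(sites, lengths, freqs)):
        mode = modes[i % len(modes)]
        if mode == "INTRA":
            method, gap = "INTRA", 0
        else:
            method = "INTER"
            g = max(1, int(0.1 * L))  # strictly below the 0.2 adjacency bound
            gap = mode[1] * min(g, 30 if L >= 300 else g)
        rows.append(
            {
                "id": f"SIM{i + 1}",
                "chrom": ref,
                "pos": pos,
                "length": int(L),
                "sequence": random_sequence(rng, int(L), config.gc_target),
                "freq": float(f),
                "method": method,
                "ref_gap": int(gap),
            }
        )
    truth = pd.DataFrame(rows)
    samples = [f"S{j + 1:04d}" for j in range(config.n_individuals)]
    geno = pd.DataFrame(
        rng.binomial(2, truth["freq"].to_numpy()[None, :], (len(samples), len(truth))),
        index=samples,
        columns=truth["id"],
    )
    return truth, geno


def plant_deletions(
    reference: Mapping[str, str], config: SimConfig
) -> pd.DataFrame:
    """Truth table of planted deletions cycling INTRA and the three INTER cases.

    INTER cases carry a contig-side gap/overlap so all three del_len
    computations (rlen, rlen - overlap, rlen + gap) are exercised.
    """
    rng = stage_rng(config.seed, "deletions")
    margin = config.del_contig_flank + config.length_range[1] + 50
    sites = _draw_sites(rng, config, config.n_deletions, margin)
    lengths = _draw_lengths(rng, config, config.n_deletions)
    cases = [("INTRA", 0), ("INTER", 0), ("INTER", 1), ("INTER", -1)]
    rows = []
    for i, ((ref, pos), L) in enumerate(zip(sites, lengths)):
        method, sign = cases[i % len(cases)]
        contig_gap = 0
        if method == "INTER" and sign:
            contig_gap = sign * max(1, int(0.2 * L))
        rows.append(
            {
                "id": f"DEL{i + 1}",
                "chrom": ref,
                "start": pos,
                "del_len": int(L),
                "method": method,
                "contig_gap": int(contig_gap),
            }
        )
    return pd.DataFrame(rows)


def sim_contig_alignments(
    truth: pd.DataFrame,
    reference: Mapping[str, str],
    config: SimConfig,
    deletions: pd.DataFrame | None = None,
) -> tuple[list[ContigAlignment], dict[str, str]]:
    """Contig alignments over a carrier haplotype of every planted event.

    Each insertion yields either one INTRA record (CIGAR ... I ...) or an
    INTER primary+supplementary fragment pair with the configured split
    distance and the correct clipped sequence; each deletion yields a
    D-op record or a long-contig fragment pair with the configured
    contig-side gap/overlap.  Returns (alignments, contig sequences).
    """
    f = config.contig_flank
    alns: list[ContigAlignment] = []
    contigs: dict[str, str] = {}
    for row in truth.itertuples():
        ref_seq = reference[row.chrom]
        p, L, ins = row.pos, row.length, row.sequence
        cid = f"ctg_{row.id}"
        if row.method == "INTRA":
            contig = ref_seq[p - f : p] + ins + ref_seq[p : p + f]
            contigs[cid] = contig
            alns.append(
                ContigAlignment(
                    contig_id=cid,
                    ref_name=row.chrom,
                    ref_start=p - f,
                    ref_end=p + f,
                    strand="+",
                    mapq=config.mapq,
                    cigar=(CigarOp("M", f), CigarOp("I", L), CigarOp("M", f)),
                    query_start=0,
                    query_end=2 * f + L,
                    contig_length=2 * f + L,
                    seq=contig,
                )
            )
        else:
            g = row.ref_gap
            contig = ref_seq[p - f : p] + ins + ref_seq[p + g : p + g + f]
            contigs[cid] = contig
            alns.append(
                ContigAlignment(
                    contig_id=cid,
                    ref_name=row.chrom,
                    ref_start=p - f,
                    ref_end=p,
                    strand="+",
                    mapq=config.mapq,
                    cigar=(CigarOp("M", f), CigarOp("S", L + f)),
                    query_start=0,
                    query_end=f,
                    contig_length=2 * f + L,
                    seq=contig,
                )
            )
            alns.append(
                ContigAlignment(
                    contig_id=cid,
                    ref_name=row.chrom,
                    ref_start=p + g,
                    ref_end=p + g + f,
                    strand="+",
                    mapq=config.mapq,
                    cigar=(CigarOp("H", f + L), CigarOp("M", f)),
                    query_start=f + L,
                    query_end=2 * f + L,
                    contig_length=2 * f + L,
                    seq=None,
                    is_supplementary=True,
                )
            )
    if deletions is not None:
        F = config.del_contig_flank
        for row in deletions.itertuples():
            cid = f"ctg_{row.id}"
            p, D = row.start, row.del_len
            if row.method == "INTRA":
                alns.append(
                    ContigAlignment(
                        contig_id=cid,
                        ref_name=row.chrom,
                        ref_start=p - F,
                        ref_end=p + D + F,
                        strand="+",
                        mapq=config.mapq,
                        cigar=(CigarOp("M", F), CigarOp("D", D), CigarOp("M", F)),
                        query_start=0,
                        query_end=2 * F,
                        contig_length=2 * F,
                        seq=None,
                    )
                )
            else:
                cg = row.contig_gap
                rlen = D - cg  # so that del_len = rlen + contig_gap
                clen = 2 * F + cg
                alns.append(
                    ContigAlignment(
                        contig_id=cid,
                        ref_name=row.chrom,
                        ref_start=p - F,
                        ref_end=p,
                        strand="+",
                        mapq=config.mapq,
                        cigar=(CigarOp("M", F), CigarOp("H", F + cg))
                        if F + cg > 0
                        else (CigarOp("M", F),),
                        query_start=0,
                        query_end=F,
                        contig_length=clen,
                        seq=None,
                    )
                )
                alns.append(
                    ContigAlignment(
                        contig_id=cid,
                        ref_name=row.chrom,
                        ref_start=p + rlen,
                        ref_end=p + rlen + F,
                        strand="+",
                        mapq=config.mapq,
                        cigar=(CigarOp("H", F + cg), CigarOp("M", F)),
                        query_start=F + cg,
                        query_end=clen,
                        contig_length=clen,
                        seq=None,
                        is_supplementary=True,
                    )
                )
    return alns, contigs


def gc_bias_multiplier(gc: np.ndarray, config: SimConfig) -> np.ndarray:
    """Smooth unimodal depth multiplier peaking near 45% GC."""
    return 1.0 + config.gc_bias_amp * np.exp(
        -((np.asarray(gc) - config.gc_bias_center) ** 2)
        / (2 * config.gc_bias_width**2)
    )


def sim_coverage(
    genotypes: pd.DataFrame,
    insertion_intervals: Mapping[str, tuple[str, int, int]],
    augmented_reference: Mapping[str, str],
    config: SimConfig,
    width: int = 50,
    lowq_windows: Mapping[str, Sequence[int]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-individual window count tables over the augmented reference.

    Background windows are Poisson around base_depth times the GC-bias
    multiplier (normalised depth ~1, i.e. the two background copies).  For
    each insertion, the sample-level mean normalised depth is drawn
    Normal(a + b * S, 1/c) and spread over the insertion's windows with
    zero-mean jitter, then converted back to raw counts through the same
    GC-bias curve.  ``lowq_windows`` optionally marks (ref, window-start)
    pairs whose reads are flagged low-quality, to exercise the alignable
    rule.  Returns {sample: DataFrame(ref_name, start, total_count,
    lowq_count)}.
    """
    from refgraft.coverage_genotype import FLANK  # same GC flank convention

    rng = stage_rng(config.seed, "coverage")
    # precompute per-window expected depth
    win_meta: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ref, seq in augmented_reference.items():
        n_win = max(1, -(-len(seq) // width))
        starts = np.arange(n_win) * width
        arr = np.frombuffer(seq.upper().encode(), np.uint8)
        is_gc = np.concatenate([[0], np.cumsum((arr == ord("G")) | (arr == ord("C")))])
        f0 = np.clip(starts - FLANK, 0, len(seq))
        f1 = np.clip(starts + FLANK, 0, len(seq))
        gc = (is_gc[f1] - is_gc[f0]) / np.maximum(f1 - f0, 1)
        win_meta[ref] = (starts, config.base_depth * gc_bias_multiplier(gc, config))

    ins_windows: dict[str, tuple[str, np.ndarray]] = {}
    for ins_id, (ref, start, end) in insertion_intervals.items():
        starts = win_meta[ref][0]
        mask = (starts >= start) & (starts + width <= end)
        ins_windows[ins_id] = (ref, np.where(mask)[0])

    sd = 1.0 / np.sqrt(config.cov_c)
    out: dict[str, pd.DataFrame] = {}
    for sample in genotypes.index:
        per_ref: dict[str, np.ndarray] = {}
        for ref, (starts, expected) in win_meta.items():
            per_ref[ref] = rng.poisson(expected).astype(float)
        for ins_id, (ref, idx) in ins_windows.items():
            S = int(genotypes.loc[sample, ins_id])
            x = rng.normal(config.cov_a + config.cov_b * S, sd)
            jitter = rng.normal(0, 0.05, len(idx))
            jitter -= jitter.mean() if len(idx) else 0.0
            vals = (x + jitter) * win_meta[ref][1][idx]
            per_ref[ref][idx] = np.clip(np.round(vals), 0, None)
        frames = []
        for ref, counts in per_ref.items():
            starts = win_meta[ref][0]
            low = np.zeros_like(counts)
            if lowq_windows:
                for w in lowq_windows.get(ref, ()):
                    i = w // width
                    if i < len(low):
                        low[i] = counts[i]  # all reads low quality
            frames.append(
                pd.DataFrame(
                    {
                        "ref_name": ref,
                        "start": starts,
                        "total_count": counts.astype(int),
                        "lowq_count": low.astype(int),
                    }
                )
            )
        out[sample] = pd.concat(frames, ignore_index=True)
    return out


def sim_insertion_coverage_values(
    a: float,
    b: float,
    c: float,
    freq: float,
    n: int,
    rng: np.random.Generator,
    A: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (x, S) directly from the genotyping model for one insertion.

    Haploid copies are Bernoulli(freq) per chromosome (biallelic insertion),
    S is their sum, and x ~ Normal(a + b * S, 1/c).
    """
    S = rng.binomial(A, freq, n)
    x = rng.normal(a + b * S, 1.0 / np.sqrt(c), n)
    return x, S
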