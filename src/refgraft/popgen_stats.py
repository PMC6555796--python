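"""Population-genetic and sequence-level characterisation of insertions.

Covers: biallelic-site selection from the genotype matrix, per-population
allele frequencies, hierarchical clustering of populations by L1 distance of
frequencies, the discovery-probability integral P(2n, q_min) over an
allele-frequency spectrum, repeat-class enrichment against a random-placement
null, GC/dinucleotide-entropy sequence statistics, distance binning against a
variant catalog, and SNV counting inside insertion regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

DEFAULT_MIN_CALL_RATE = 0.95
DEFAULT_N_NULL = 1000
QUADRATURE_POINTS = 20001


# ---------------------------------------------------------------------------
# Genotype-matrix summaries
# ---------------------------------------------------------------------------


def select_biallelic(
    calls_matrix: pd.DataFrame,
    anchor_sample: str,
    min_unique_reads: int,
    unique_read_counts: Mapping[str, int] | None = None,
    min_rate: float = DEFAULT_MIN_CALL_RATE,
) -> list[str]:
    """Insertion ids behaving as simple biallelic presence/absence alleles.

    ``calls_matrix`` is samples x insertion-ids of called summed copy numbers
    (NaN = missing).  An insertion passes iff strictly more than ``min_rate``
    of samples have a called copy number in {0, 1, 2}, the anchor sample
    (the assembled individual) carries it (call 1 or 2), and at least
    ``min_unique_reads`` uniquely-mapped reads support it.
    """
    if anchor_sample not in calls_matrix.index:
        raise KeyError(f"anchor sample {anchor_sample!r} not in genotype matrix")
    n = len(calls_matrix.index)
    passed: list[str] = []
    for ins_id in calls_matrix.columns:
        col = calls_matrix[ins_id]
        ok = col.isin([0, 1, 2]).sum()
        if ok / n <= min_rate:
            continue
        anchor = col.loc[anchor_sample]
        if not (anchor == 1 or anchor == 2):
            continue
        if unique_read_counts is not None:
            if unique_read_counts.get(ins_id, 0) < min_unique_reads:
                continue
        passed.append(ins_id)
    return passed


@dataclass
class AlleleFrequencyRecord:
    insertion_id: str
    population: str
    alt_freq: float  # NaN when nothing called
    call_rate: float
    n_null: int
    n_het: int
    n_hom: int
    n_missing: int


def allele_frequencies(
    calls_matrix: pd.DataFrame,
    population_labels: Mapping[str, str],
) -> list[AlleleFrequencyRecord]:
    """Per-population alternative-allele frequencies of biallelic insertions.

    alt_freq = (het + 2*hom) / (2 * called) among diploid samples with a
    called genotype in {0, 1, 2}; genotypes outside {0, 1, 2} count as
    missing for this summary.
    """
    pops = pd.Series(population_labels)
    records: list[AlleleFrequencyRecord] = []
    for ins_id in calls_matrix.columns:
        col = calls_matrix[ins_id]
        for pop in pops.unique():
            samples = pops.index[pops == pop]
            sub = col.loc[samples]
            n = len(sub)
            n0 = int((sub == 0).sum())
            n1 = int((sub == 1).sum())
            n2 = int((sub == 2).sum())
            called = n0 + n1 + n2
            freq = (n1 + 2 * n2) / (2 * called) if called else float("nan")
            records.append(
                AlleleFrequencyRecord(
                    ins_id, pop, freq, called / n if n else 0.0,
                    n0, n1, n2, n - called,
                )
            )
    return records


def frequency_table(records: Sequence[AlleleFrequencyRecord]) -> pd.DataFrame:
    """Populations x insertions matrix of alt allele frequencies."""
    df = pd.DataFrame(
        [(r.population, r.insertion_id, r.alt_freq) for r in records],
        columns=["population", "insertion_id", "alt_freq"],
    )
    return df.pivot(index="population", columns="insertion_id", values="alt_freq")


def cluster_populations(freq_table: pd.DataFrame, method: str = "average"):
    """Hierarchical clustering of populations by L1 frequency distance.

    Returns (linkage_matrix, leaf_order) with dissimilarity = sum of absolute
    allele-frequency differences across insertions.
    """
    if len(freq_table.index) < 2:
        raise ValueError("need at least 2 populations to cluster")
    if freq_table.isna().any().any():
        raise ValueError("frequency table contains missing cells")
    dist = pdist(freq_table.to_numpy(), metric="cityblock")
    Z = linkage(dist, method=method)
    order = [freq_table.index[i] for i in leaves_list(Z)]
    return Z, order


def dendrogram_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    n = len(labels)

    def height(i: int) -> float:
        return 0.0 if i < n else float(Z[i - n, 2])

    def render(i: int) -> str:
        if i < n:
            return str(labels[i])
        l, r = int(Z[i - n, 0]), int(Z[i - n, 1])
        h = height(i)
        return (
            f"({render(l)}:{h - height(l):.6g},{render(r)}:{h - height(r):.6g})"
        )

    return render(2 * n - 2) + ";"


# ---------------------------------------------------------------------------
# Discovery-rate model
# ---------------------------------------------------------------------------


@dataclass
class FrequencySpectrumModel:
    """Allele-frequency spectrum F(q) used by the discovery-rate integral.

    ``kind`` is "neutral" (F(q) proportional to 1/q, the standard-neutral
    site-frequency spectrum) or "tabulated" (grid interpolation of an
    externally supplied spectrum, e.g. from a fitted demographic model).
    """

    kind: str = "neutral"
    grid_q: np.ndarray | None = None
    grid_F: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind == "tabulated":
            q = np.asarray(self.grid_q, dtype=float)
            F = np.asarray(self.grid_F, dtype=float)
            if np.any(np.diff(q) <= 0):
                raise ValueError("tabulated q grid must be strictly increasing")
            if np.any(F < 0):
                raise ValueError("F(q) must be non-negative")
            self.grid_q, self.grid_F = q, F
        elif self.kind != "neutral":
            raise ValueError(f"unknown spectrum kind {self.kind!r}")

    def density(self, q: np.ndarray) -> np.ndarray:
        if self.kind == "neutral":
            return 1.0 / q
        return np.interp(q, self.grid_q, self.grid_F)

    @classmethod
    def from_tsv(cls, path: str) -> "FrequencySpectrumModel":
        df = pd.read_csv(path, sep="\t")
        return cls("tabulated", df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


def discovery_rate(
    model: FrequencySpectrumModel,
    two_n: int,
    q_min: float,
    n_points: int = QUADRATURE_POINTS,
) -> float:
    """Probability that a polymorphic site with MAF >= q_min is sampled.

    P(2n, q_min) = int_{q_min}^{1-q_min} {1 - (1-q)^{2n}} F(q) dq
                   / int_{q_min}^{1-q_min} F(q) dq
    evaluated by composite trapezoid on a log-spaced grid (F can be steep
    near q_min).
    """
    if not 0 < q_min < 0.5:
        raise ValueError("q_min must be in (0, 0.5)")
    if two_n < 1:
        raise ValueError("two_n must be >= 1")
    q = np.exp(np.linspace(np.log(q_min), np.log(1.0 - q_min), n_points))
    F = model.density(q)
    sampled = 1.0 - (1.0 - q) ** two_n
    denom = np.trapezoid(F, q)
    if denom <= 0:
        raise ValueError("spectrum integrates to zero over the range")
    return float(np.trapezoid(sampled * F, q) / denom)


def incremental_discovery_gain(
    model: FrequencySpectrumModel, n_ref: int, q_min: float
) -> float:
    """Discovery-rate gain from adding one individual to the assembly panel."""
    return discovery_rate(model, 2 * (n_ref + 1), q_min) - discovery_rate(
        model, 2 * n_ref, q_min
    )


# ---------------------------------------------------------------------------
# Annotation statistics
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    repeat_class: str
    observed_count: int
    q025: float
    q25: float
    q50: float
    q75: float
    q975: float
    enriched: bool


def _count_by_class(
    intervals: Sequence[tuple[str, int, int]],
    trees: Mapping[str, IntervalTree],
    classes: Sequence[str],
) -> dict[str, int]:
    counts = {c: 0 for c in classes}
    for ref, start, end in intervals:
        tree = trees.get(ref)
        if tree is None:
            continue
        for hit in tree.overlap(start, end):
            counts[hit.data] += 1
    return counts


def repeat_enrichment(
    insertions: Sequence[tuple[str, int, int]],
    annotation: Sequence[tuple[str, int, int, str]],
    genome_lengths: Mapping[str, int],
    n_null: int = DEFAULT_N_NULL,
    seed: int = 0,
    quantile: float = 0.975,
) -> list[EnrichmentResult]:
    """Repeat-class enrichment of insertion intervals vs random placement.

    The observed statistic counts, per class, annotation records overlapping
    any insertion interval (a multiply-annotated insertion contributes once
    per overlapping record).  The null redraws the placement of the same
    length multiset uniformly over the genome (chromosomes weighted by
    length, placements truncated to fit) ``n_null`` times.  A class is
    enriched when the observed count exceeds the ``quantile`` null quantile.
    """
    classes = sorted({rec[3] for rec in annotation})
    trees: dict[str, IntervalTree] = {}
    for ref, start, end, cls in annotation:
        trees.setdefault(ref, IntervalTree()).addi(start, end, cls)

    observed = _count_by_class(insertions, trees, classes)

    rng = np.random.default_rng(seed)
    refs = list(genome_lengths)
    lengths = np.array([genome_lengths[r] for r in refs], dtype=float)
    weights = lengths / lengths.sum()
    ins_lengths = [end - start for _, start, end in insertions]

    null_counts = {c: np.empty(n_null, dtype=int) for c in classes}
    for it in range(n_null):
        placements = []
        ref_idx = rng.choice(len(refs), size=len(ins_lengths), p=weights)
        starts = rng.random(len(ins_lengths))
        for L, ri, u in zip(ins_lengths, ref_idx, starts):
            ref = refs[ri]
            span = genome_lengths[ref] - L
            if span <= 0:
                s = 0
            else:
                s = int(u * span)
            placements.append((ref, s, s + L))
        cnt = _count_by_class(placements, trees, classes)
        for c in classes:
            null_counts[c][it] = cnt[c]

    results = []
    for c in classes:
        nc = null_counts[c]
        qs = np.quantile(nc, [0.025, 0.25, 0.5, 0.75, quantile])
        results.append(
            EnrichmentResult(
                c,
                observed[c],
                float(qs[0]),
                float(qs[1]),
                float(qs[2]),
                float(qs[3]),
                float(qs[4]),
                observed[c] > qs[4],
            )
        )
    return results


def gc_entropy(sequence: str) -> tuple[float, float]:
    """GC ratio and entropy (bits) of overlapping dinucleotide frequencies.

    GC ratio is (G+C)/length over the full sequence; the entropy is taken
    over the 16 A/C/G/T dinucleotide patterns in overlapping windows,
    skipping dinucleotides containing any other character.  Range [0, 4].
    """
    if len(sequence) < 2:
        raise ValueError("sequence must be at least 2 bases")
    s = sequence.upper()
    gc = (s.count("G") + s.count("C")) / len(s)
    counts: dict[str, int] = {}
    for i in range(len(s) - 1):
        di = s[i : i + 2]
        if di[0] in "ACGT" and di[1] in "ACGT":
            counts[di] = counts.get(di, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return gc, 0.0
    p = np.array(list(counts.values()), dtype=float) / total
    entropy = float(-(p * np.log2(p)).sum())
    return gc, entropy


DISTANCE_BIN_EDGES = (100, 1_000, 10_000, 100_000, 1_000_000, 10_000_000)
DISTANCE_BIN_LABELS = ("<100", "<1K", "<10K", "<100K", "<1M", "<10M")


def distance_bins(
    insertions: Sequence[tuple[str, int]],
    catalog_positions: Mapping[str, Sequence[int]],
) -> tuple[pd.Series, pd.Series]:
    """Bin distances from insertions to the nearest catalog position.

    Returns (exclusive, cumulative) counts per bin; insertions on
    chromosomes with no catalog entries fall in "NA".  Exclusive counts
    assign each insertion to its smallest qualifying bin.
    """
    sorted_pos = {r: np.sort(np.asarray(p)) for r, p in catalog_positions.items()}
    labels = list(DISTANCE_BIN_LABELS) + ["NA"]
    exclusive = pd.Series(0, index=labels, dtype=int)
    for ref, pos in insertions:
        cat = sorted_pos.get(ref)
        if cat is None or len(cat) == 0:
            exclusive["NA"] += 1
            continue
        i = np.searchsorted(cat, pos)
        d = min(
            abs(pos - cat[i - 1]) if i > 0 else np.inf,
            abs(cat[i] - pos) if i < len(cat) else np.inf,
        )
        for edge, label in zip(DISTANCE_BIN_EDGES, DISTANCE_BIN_LABELS):
            if d < edge:
                exclusive[label] += 1
                break
        else:
            exclusive["NA"] += 1
    cumulative = exclusive.copy()
    running = 0
    for label in DISTANCE_BIN_LABELS:
        running += exclusive[label]
        cumulative[label] = running
    return exclusive, cumulative


def variants_in_regions(
    vcf_path: str, regions: Sequence[tuple[str, int, int]]
) -> tuple[int, pd.Series]:
    """Count VCF records whose position falls in any region.

    Regions are 0-based half-open; VCF POS is 1-based.  Returns the total
    and per-region counts (indexed "chrom:start-end").
    """
    trees: dict[str, IntervalTree] = {}
    keys = []
    for ref, start, end in regions:
        key = f"{ref}:{start}-{end}"
        keys.append(key)
        trees.setdefault(ref, IntervalTree()).addi(start, end, key)
    per_region = pd.Series(0, index=keys, dtype=int)
    total = 0
    with open(vcf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{vcf_path}:{lineno}: malformed VCF line")
            try:
                pos = int(parts[1]) - 1
            except ValueError as exc:
                raise ValueError(
                    f"{vcf_path}:{lineno}: non-integer POS {parts[1]!r}"
                ) from exc
            tree = trees.get(parts[0])
            if tree is None:
                continue
            hits = tree.overlap(pos, pos + 1)
            if hits:
                total += 1
                for hit in hits:
                    per_region[hit.data] += 1
    return total, per_region
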