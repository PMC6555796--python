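# Methods

## Detection from contig alignments

A de-novo assembly aligned to a reference exposes a long insertion in one of
two ways. Either the aligner threads the whole contig through as one record
and the inserted bases appear as a CIGAR `I` operation (the *INTRA* route),
or it splits the contig into two mapped fragments and the insertion is the
contig sequence between them (the *INTER* route). For INTER, the two
fragments of one contig must be consecutive in contig coordinates, on the
same reference and strand, with both mapping qualities above 0, and map
*adjacently*: the signed reference gap between them (`split_distance`) must
satisfy |gap| < 0.2 × clipped-sequence length. The absolute value matters —
aligners also emit fragment pairs that overlap on the reference (negative
gap), and those carry real insertions whose flanks share sequence.

Deletions mirror the logic with `D` operations and, for INTER, the unmapped
reference span `rlen` between fragments of a long contig (> 100 kb),
corrected by the contig-side relationship: no contig gap → del_len = rlen;
contig overlap o → rlen − o; contig gap g → rlen + g. INTER deletion calls
longer than 0.2 × contig length are discarded as likely misjoins.

Both call sets drop events < 100 bp. Insertion candidates within 1000 bp of
one another are all removed; removal chains transitively (single linkage), a
deliberately conservative reading of "remove all nearby calls" since the
alternative (pairwise-only) is ambiguous about chains. A final verification
step regrafts the candidates into the reference, realigns the contigs, and
keeps only calls whose integrated interval is covered by a realignment with
pure match operations and identical bases; an uncovered interval counts as
unsupported.

Coordinates are 0-based half-open everywhere internally; SAM's 1-based
convention is converted at the I/O boundary. Query coordinates of alignment
fragments are expressed on the forward strand of the contig with
hard-clipped bases counted, so INTER pairing works identically for soft- and
hard-clipped supplementary records (the clipped sequence is then taken from
the contig FASTA when the record lacks SEQ).

## Reference grafting

Each verified call becomes a splice edit. With split distance d: d = 0 (and
all INTRA calls) inserts the sequence at the point; d > 0 replaces the
d-base reference gap; d < 0 replaces the |d|-base overlapped segment with
overlap + insertion + overlap, preserving both fragment ends' flanks. Edits
are applied right-to-left per chromosome so stored positions stay valid, and
the augmented length obeys dst = src + Σ(|insert| − deleted) exactly. A
block liftover chain (UCSC chain format) maps every unedited base
bijectively and records each insertion's destination interval. Overlapping
edits cannot survive the 1-kb proximity filter, but if constructed manually
the earlier call (by id) wins, deterministically.

The decoy contig concatenates the insertion sequences with a 20-N spacer
*after each* insertion (including the last): k insertions of total length L
give a decoy of L + 20k bases with exactly k N-runs. Per-insertion offsets
are emitted so either spacer convention is recoverable downstream.

## Window depth and GC normalisation

Reads are binned into 50-bp windows by midpoint. A window is *alignable*
when it has coverage and reads with mapq ≤ 1 are at most 40% of it — the
bound is inclusive at exactly 40%, and an empty window is not alignable
(nothing attests to its mappability). GC content is measured over a 400-bp
flank starting 200 bp upstream of the window start. Alignable windows are
grouped into 2%-wide GC bins; each bin's *standard coverage* is the 10%
truncated mean (10% of windows trimmed from each tail — the usual
trimmed-mean convention), valid only when ≥ 100 windows remain after
trimming and the mean is positive. Normalised coverage is raw count divided
by the standard of the window's bin; windows in invalid bins are dropped.
The pipeline is therefore invariant to overall sequencing depth (scaling all
counts cancels).

A sample's coverage value for an insertion is the mean normalised coverage
of alignable windows *fully contained* in the insertion interval
(boundary-straddling windows are excluded; they mix flank and insertion
signal). The value is invalidated when those windows cover < 50 bp or < 30%
of the insertion.

## The copy-number model

For one insertion across n samples, the normalised coverage is modelled as
x ~ Normal(a + b·S, c⁻¹) with S the sum over the sample's A chromosomes
(2 for autosomes, 0–2 for sex chromosomes) of iid haploid copy numbers
z ~ Multinomial(θ₀…θ_M), M = 10. Hyperparameters: a ~ Normal(0, λₐ = 8),
log b ~ Normal(0, λ_b = 16), c ~ Gamma(shape λ_c = 1, rate 1),
θ ~ Dirichlet(λ_θ = 1); λₐ and λ_b are read as prior variances. `a`
absorbs the stray-read background present even in non-carriers; `b` is the
depth added per haploid copy (≈ 1 when the GC standard reflects the two
background copies).

Fitting is MAP-EM. The E-step computes each sample's posterior over S (the
A-fold convolution of θ times the Normal likelihood, in log space). The
M-step updates blocks in turn: (a, b) by penalised weighted least squares —
a closed form for a given b, a bounded line search on log b — then c in
closed form with its Gamma prior, then θ from expected haploid category
counts, using the exchangeable decomposition
E[#{j: zⱼ = k} | S] = A·θ_k·θ_{S−k}/p_A(S) for diploids, plus Dirichlet
pseudo-counts. Each block update ascends the penalised objective, so the
objective trace is non-decreasing (asserted in tests).

Two numerical choices matter:

* **θ initialisation.** The three restarts fix a ∈ {0, 0.4, 0.8}, b = 1,
  c = 1. θ starts from a nearest-component assignment of the data under the
  restart's (a, b) (each sample's rounded S split evenly into haploid
  copies, plus a 0.5 pseudo-count). A uniform θ start leaves the first
  posteriors prior-dominated — at c = 1 the components overlap almost
  completely — and the first slope update then collapses b toward a
  halved-slope local optimum on every restart.
* **b warm-up.** For the same reason, b is held at its restart value for the
  first 25 iterations while a, c and θ adapt (an ECM schedule; monotonicity
  is unaffected). Once c has sharpened, the line search on log b converges
  onto the data slope.

Convergence is declared at a relative objective change < 1e-8 (500-iteration
cap); the precision is capped at c ≤ 1e6 (variance floor 1e-6) to prevent
collapse onto a single point. The restart with the best penalised objective
wins, and the estimate is *accepted* when |a| ≤ 0.75 and 0.6 ≤ b ≤ 1.4.
Selection precedes the band check deliberately: an out-of-band truth (say a
real offset of 0.9) typically has an in-band mirror solution with all copy
numbers shifted by one; preferring accepted restarts would silently return
that distorted model, whereas flagging the locus excludes it honestly.

Copy numbers are called per sample when the posterior of S exceeds 0.8
(strictly), otherwise left missing; samples with invalid coverage are never
called; A = 0 yields S = 0 deterministically. A fitted model can be applied
without refitting to samples from other cohorts (different depth is handled
by the per-cohort GC standard), summarising presence as 0 / ≥1 / not
determined.

## Population statistics

An insertion is treated as *biallelic* when strictly more than 95% of panel
samples have a called copy number in {0, 1, 2}, the assembled individual
carries it (call 1 or 2 — its absence would contradict the assembly), and a
caller-supplied minimum of uniquely mapped supporting reads is met (no
universal default exists; it depends on depth and read length, so it is a
required parameter). Alternative-allele frequencies are (het + 2·hom) /
(2·called) per population; populations are clustered hierarchically on the
L1 distance between frequency vectors with average linkage (the distance is
the principled choice here; linkage is exposed as a parameter).

The discovery-rate integral P(2n, q_min) = ∫{1−(1−q)²ⁿ}F(q)dq / ∫F(q)dq is
evaluated by composite trapezoid on a log-spaced grid of 20,001 points
between q_min and 1−q_min — F(q) ∝ 1/q is steep near q_min, and halving the
step changes P by < 1e-6. The built-in spectrum is the standard-neutral
F(q) = 1/q; a tabulated spectrum from a fitted demographic model can be
loaded from TSV. With 2n = 20 the integral exceeds 99.9% for q_min ≥ 0.3
regardless of spectrum shape, since (1−q)²⁰ ≤ 0.7²⁰ ≈ 8·10⁻⁴ on the range.

Repeat enrichment compares per-class counts of annotation records
overlapping the insertion intervals (multiply-annotated insertions count
once per record) against 1000 seeded random placements of the same length
multiset, chromosomes weighted by length; a class is enriched when the
observed count exceeds the 97.5% null quantile (a 1.5×IQR notch rule is
available as an alternative). Sequence complexity is summarised by GC
fraction and the entropy of overlapping dinucleotide frequencies (0–4 bits;
dinucleotides containing non-ACGT characters are skipped).

## The simulator

The generator emulates the study design at desk scale: a uniform-composition
random genome (default one 2-Mb chromosome, GC 0.5), 40 planted insertions
with a two-mode log-normal length mixture (modes near 300 bp and 6 kb,
weights 0.6/0.4, clipped to 100 bp–10 kb) mirroring the Alu/LINE bimodality
of real insertion catalogues, allele frequencies uniform on (0.05, 0.95),
and 200 individuals with Binomial(2, freq) genotypes. Planted sites keep
≥ 2 kb spacing so the proximity filter is exercised deliberately, not by
accident. Contigs are synthesised around each event — INTRA CIGARs and INTER
fragment pairs cycling split distances 0 / + / − (magnitude strictly below
the 0.2 adjacency bound) — with exact clipped sequences, and deletion
contigs (> 100 kb) cycle the three contig-side cases.

Coverage simulation draws background windows Poisson around depth 40 times a
smooth unimodal GC-bias multiplier (peak 1.3× at 45% GC, width 0.1), giving
the GC standardisation real structure to remove. Each sample × insertion
mean is drawn from the genotyping model (defaults a = 0.1, b = 1, c = 25,
i.e. noise sd 0.2) and spread over the insertion's windows with zero-mean
jitter before being converted back to raw counts through the same bias
curve. The offset default is positive because zero-depth windows are not
alignable: a = 0 would leave non-carriers with no valid coverage value,
whereas real loci always collect some stray reads. All stages derive
independent child generators from the single run seed.

What the simulator does *not* emulate — and hence what passing tests do not
show about real data: alignment artefacts (chimeric splits, mapq decay in
repeats), assembly errors, reference N-gaps, GC-dependent *fragment* bias
coupling adjacent windows, population structure in genotypes, and
multi-allelic or segmentally duplicated loci. Detection recovery of 100% on
simulated contigs validates the arithmetic of the detectors, not aligner
behaviour.

## Problem sizes

The test suite and the acceptance script run the detection stage on a 2-Mb
genome with 60 planted events, the genotyper on 50 insertions × 500 samples,
and the end-to-end depth pipeline on a 250-kb genome × 200 samples — sizes
chosen so the full suite completes in a few minutes on one core while every
code path (all split-distance and deletion cases, both detection routes,
GC-bin validity edges, EM restarts) is exercised.

## Known limitations

* INTER pairing considers query-consecutive fragment pairs only; a contig
  split into three parts across one locus yields two pairs, not a joint
  call.
* The verification realignment demands exact identity over the integrated
  interval; a single polishing error in a contig removes the call (matching
  the conservative intent, but lossy).
* The copy-number model assumes one shared (a, b, c) per insertion across
  samples; cohort-specific depth biases beyond GC are not modelled — apply
  per-cohort normalisation before mixing cohorts.
* With A = 2 and flat θ the S-posterior can be multimodal; calls rely on the
  0.8 threshold rather than interval estimates.
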