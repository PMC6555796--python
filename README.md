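# refgraft

Long insertions (≥ 100 bp) are largely invisible to short-read resequencing:
reads from sequence missing in the reference either fail to map or mismap
onto similar regions. A de-novo assembly of one individual, aligned back to
the reference, exposes those insertions — and once they are grafted into the
reference, ordinary short-read panels can genotype them population-wide by
read depth.

`refgraft` implements that pipeline for researchers building
population-augmented references:

1. **Detection** (`sv_detect`) — insertions and deletions from
   contig-to-reference alignments, by two routes: *INTRA* (CIGAR `I`/`D`
   operations inside one continuous alignment) and *INTER* (a pair of
   split-mapped fragments of one contig; the unaligned contig sequence
   between them is the candidate insertion). Calls < 100 bp or with mapping
   quality 0 are dropped; candidates crowding within 1 kb of each other are
   removed wholesale.
2. **Grafting** (`ref_build`) — insertion calls are spliced into the
   reference according to their split distance *d* (insert at the point for
   *d* = 0; replace the reference gap for *d* > 0; duplicate the overlap on
   both ends for *d* < 0), with a liftover chain and a decoy contig (all
   insertion sequences concatenated with 20-N spacers).
3. **Genotyping** (`coverage_genotype`) — per-sample read depth in 50-bp
   windows, GC-bias correction by a per-2%-GC-bin standard (10% truncated
   mean), and a per-insertion mixture model

   > xₙ ~ Normal(a + b·Sₙ, c⁻¹),  Sₙ = Σⱼ zₙⱼ,  zₙⱼ ~ Multinomial(θ₀…θ_M)

   fitted by MAP-EM (priors a ~ N(0, λₐ), log b ~ N(0, λ_b), c ~ Gamma(λ_c),
   θ ~ Dirichlet(λ_θ)). Copy numbers are called when the posterior of Sₙ
   exceeds 0.8.
4. **Population analysis** (`popgen_stats`) — biallelic-site selection,
   per-population allele frequencies, L1-distance population clustering, the
   discovery-probability integral
   P(2n, q_min) = ∫ {1−(1−q)²ⁿ} F(q) dq ⁄ ∫ F(q) dq,
   repeat-class enrichment against a random-placement null, and sequence
   statistics (GC, dinucleotide entropy).
5. **Simulation** (`simulate`) — seeded synthetic genomes, planted variants,
   contig alignments and coverage matrices with known truth, so the whole
   pipeline is testable without external data.

## Worked example

`examples/` contains one narrative script per capability. Running
`python examples/03_genotype_copy_numbers.py` fits the copy-number model to
500 simulated diploid samples of one insertion (allele frequency 0.35, depth
noise sd 0.2) and prints:

```
true  a=0.10 b=1.00 sd=0.20
fit   a=0.103 b=0.987 sd=0.214 accepted=True (band |a|<=0.75, 0.6<=b<=1.4)
theta (haploid copy probabilities): [0.657 0.343 0.   ] ...

called 97.8% of samples at posterior > 0.8; 99.4% match the simulated genotypes
```

`a` is the stray-read background depth at the locus, `b` the depth added per
haploid copy, and θ the haploid copy-number distribution (here: 0.343 ≈ the
planted allele frequency). Samples whose coverage falls between the cluster
centres stay uncalled rather than being guessed — 97.8% of samples clear the
0.8 posterior bar and 99.4% of those match the simulated truth.

A thin CLI mirrors the library (`refgraft detect-sv`, `build-ref`,
`build-decoy`, `genotype`, `popstats`, `discovery-rate`, `enrich`,
`simulate`, `annotate`); every run writes a `manifest.json` recording
parameters and input checksums.

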