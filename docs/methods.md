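# Methods

## The model

`chromdiv` simulates a single chromosome in a diploid Wright–Fisher
population and asks how the chromosome's mean recombination rate shapes
nucleotide diversity (π) within a population and sequence divergence (d)
between populations that split from it. Because meiosis requires at least
one crossover per chromosome, smaller chromosomes have higher per-bp
recombination rates; the simulations hold chromosome length fixed (1 Mb)
and sweep the mean recombination rate across nine multipliers
(0.33r–3r, r = 10⁻⁸ per bp per generation), which stands in for an
~9-fold range of chromosome sizes. A variable-length mode
(`build_chromosome` with lengths other than 1 Mb) is provided for the
converse design: length varies, gene density is held constant.

Model components:

* **Reproduction.** Non-overlapping generations; each of N offspring draws
  two parents independently with probability proportional to fitness
  (selfing allowed). Fitness is multiplicative across loci:
  (1+s) per homozygous and (1+hs) per heterozygous non-neutral locus,
  h = 0.5 everywhere (all non-neutral mutations codominant), floored at 0.
* **Genome.** 1-Mb chromosome carrying nine 20.5-kb coding genes separated
  by 94.5-kb intergenic spacers (18.45% coding). Mutations follow an
  infinite-sites model on the integer coordinate grid; a recurrent hit at
  an occupied position creates an independent allele record (probability
  negligible at these rates).
* **Mutation.** Uniform rate μ = 5.7×10⁻⁹/bp/generation (mouse germline
  estimate). Intergenic mutations are always neutral. Coding mutations are
  neutral : deleterious : beneficial at 0.3 : 1 : 0.0005; non-neutral
  magnitudes are Gamma(shape 0.3, mean 1.5625×10⁻²) with the sign set by
  the class. Deleterious and beneficial draws share one gamma law because a
  single mean and shape parameterise the DFE.
* **Recombination.** Crossover count per meiosis ~ Poisson(r·multiplier·L),
  breakpoints uniform. Non-crossover gene conversion initiates at one third
  of the local crossover rate (so the multiplier applies to gene conversion
  too — the rate is defined relative to r) and copies a tract from the
  homologue; tract lengths are geometric with mean 440 bp extending
  unidirectionally from the initiation point (a fixed 440-bp tract is
  available via a flag). A conversion tract is implemented as a pair of
  source toggles, i.e. a complex double crossover.
* **Demography.** The ancestral population (Ne ∈ {10,000; 40,000; 160,000})
  burns in for 20·Ne generations from a monomorphic start — long enough for
  coalescence-scale equilibration of diversity — then splits into two
  daughters of 0.5·Ne (mild bottleneck) or 0.1·Ne (severe), founders drawn
  without replacement and disjoint, no migration afterwards. 30 diploids
  are sampled at burn-in end; post split, one random haploid genome per
  daughter is sampled immediately after the split (generation 1) and every
  `output_interval` generations.
* **Statistics.** π is the unbiased pairwise estimator
  Σ 2p̂(1−p̂)·n/(n−1)/L over the 60 sampled haplotypes, reported
  chromosome-wide and restricted to coding/intergenic partitions
  (length-weighted parts recompose exactly). d is the proportion of
  unmatched bases between the two haploid genomes, counting segregating
  differences and each population's fixed substitutions (the substitution
  ledger); shared ancestral substitutions cancel. In neutral runs
  E[π] = θ = 4Neμ and E[d(T)] = 4Neμ + 2Tμ, both used as closed-form
  oracles.

## Rescaling

Forward simulation at Ne = 10,000+ is not affordable, so the canonical
population-genetic rescaling is applied: Ne → Ne/λ, μ → μλ, r → rλ with
λ = 25, preserving θ = 4Neμ and ρ = 4Ner (the scaled parameter table keeps
the DFE mean at 1.5625×10⁻², the primary convention of the study design).
Scaled generations are the unit of every schedule quantity (burn-in,
output interval, horizon).

For the large replicate grids (nine multipliers × ≥10 replicates, twice)
an **additional diffusion-preserving factor** is applied on top of ×25 via
`sim_config.diffusion_rescale`: the extra factor also multiplies the DFE
mean so that Ne·s is preserved along with θ and ρ. With all three compound
parameters fixed, the sampling distribution of π and d is invariant up to
O(s) and O(1/Ne) corrections. Problem sizes used by the shipped tests and
the acceptance script:

| computation | extra factor | scaled Ne | burn-in | replicates |
|---|---|---|---|---|
| π-vs-recombination grids, acceptance script (± gene conversion) | 2 | 200 | 4,000 | 10 |
| π-vs-recombination grids, shipped tests (± gene conversion)     | 4 | 100 | 2,000 | 10 |
| Δπ across ancestral Ne (10k / 40k arms, tests) | 4 / 8 | 100 / 200 | 2,000 / 4,000 | 10 / 8 |
| split/divergence property runs (tests)         | 4 | 100 | 2,000 | 12 |

These sizes are the package's own choice of problem scale; the full ×25
conditions (scaled Ne 400–6,400, 8,000–128,000-generation burn-ins,
30 replicates) remain available through the same API, and the engine is
exact at any scale. The largest grid point (scaled Ne 6,400 with a
128,000-generation burn-in across 12,800 haplotypes) is a cluster-scale
computation; the shipped suite checks the increase of Δπ with Ne on the
two smallest populations instead of the largest population's endpoint.

## Numerical and design choices

* **Engine.** The population is a dense uint8 haplotype × mutation
  incidence matrix advanced by a numba kernel; columns are unordered, and
  meiosis resolves breakpoint parity only at columns where the two parental
  haplotypes differ (≈π·L sites, an order of magnitude fewer than
  segregating columns). Lost columns are dropped and fixed columns moved to
  the substitution ledger every 4 generations; removing a fixed column
  multiplies every individual's fitness by the same constant, so selection
  probabilities are unchanged. A readable single-generation reference path
  (`fitness`, `gametogenesis`, `advance_generation`) implements the same
  model and is cross-checked against the kernel statistically.
* **Fitness underflow.** Log-space accumulation with a −10³⁰⁰ sentinel for
  non-positive factors; an all-zero fitness vector raises an extinction
  error rather than silently renormalising.
* **Seeding.** One master seed per run expands through
  `numpy.random.SeedSequence` spawning into independent kernel and sampling
  streams, so every replicate is reproducible in isolation and a scenario
  re-run is byte-identical.
* **Chromosome layout.** 9×20.5 kb + 8×94.5 kb = 940.5 kb; the 59.5-kb
  remainder of the 1-Mb chromosome is split evenly between the two ends as
  intergenic sequence. Other lengths hold round(9·L/1 Mb) genes; when the
  printed spacer width cannot fit (long chromosomes whose rounded gene
  count overshoots), gene size and count are kept exact and internal
  spacers shrink uniformly. Coding fraction stays within one gene-length of
  0.1845 for any supported length.
* **Coordinates.** 0-based half-open everywhere internally; VCF export
  converts to 1-based, phased `GT` per haplotype pair, INFO carrying the
  selection coefficient and region class.
* **Regression conventions.** "Variance in π explained by recombination"
  is replicate-level OLS of π on the multiplier with adjusted
  R² = 1−(1−R²)(n−1)/(n−2); a mean-level mode (`on_means=True`) is provided
  because either design is defensible. The ANOVA across multiplier classes
  is one-way fixed-effects with replicates as observations. Δ statistics
  are replicate means of extreme-high minus extreme-low classes.
* **Alignment pipeline.** "Longer than 10 kb" is strict (> 10,000 bp).
  Percent *similarity* (not identity) feeds 1 − s/100 so N-to-N matches do
  not masquerade as identity. Overlapping alignments are not deduplicated;
  overlap surfaces as a QC flag (`total_aligned_bp > size_bp`). Sex
  chromosomes are excluded by a configurable name list
  ({chrX, chrY, X, Y} by default). The btab column mapping is pinned in
  `alignment_divergence.py` (query id in column 0, reference id in column
  5, reference coordinates 8–9, percent identity/similarity 10–11,
  alignment length 12) since btab layouts vary across aligner versions.

## What the synthetic data does and does not emulate

The synthetic alignment generator reproduces only the *statistical*
structure of chromosome-level alignment summaries: a log-linear
size–divergence law with tunable slope, intercept and noise, emitted as
alignment rows whose length-weighted similarity equals the drawn
divergence exactly. It contains no sequence, no rearrangements, no
alignment gaps or repeat-driven artefacts, and no reference-bias effects —
so passing the pipeline tests shows the bookkeeping (parsing, filtering,
weighting, regression) is correct, not that any particular genome pair
follows the law. Likewise, the simulated chromosome omits introns (coding
genes are solid selected blocks), assumes uniform recombination and
mutation along the chromosome and through time, and ignores crossover
mutagenesis; simulated π/d contrasts therefore isolate the
recombination–selection interplay rather than reproduce any species'
genomic landscape.

## Known limitations

* In this engine, enabling gene conversion (initiation at one third of the
  local crossover rate, 440-bp mean tracts) leaves both mean π and the
  variance in π explained by recombination essentially unchanged at the
  smallest population size — the grids with and without gene conversion
  yield statistically indistinguishable regressions. Tract-level transfer
  is verified directly by a behavioral test, so this is a property of the
  parameter regime (gene conversion adds ~r/3 of effective recombination
  over sub-kb tracts), not of the implementation.

* Stochastic acceptance quantities (adjusted R² of π on recombination rate
  measured from ≥10 replicates) carry seed-to-seed spreads of several
  percentage points; the shipped tests therefore assert bootstrap
  confidence intervals rather than point equality.
* The engine's memory and time scale as (haplotypes × segregating sites);
  scaled Ne beyond a few thousand belongs on a cluster, not a desk.
* No migration, no sex chromosomes, no tree-sequence recording, and d is
  estimated from a single haploid pair per replicate per time point (as the
  sampling design specifies), which dominates the variance of Δd at short
  horizons.
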