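"""Forward-time Wright-Fisher engine with selection, recombination, gene
conversion and split/bottleneck demography.

Two execution paths share one model:

* a readable reference path (:func:`fitness`, :func:`gametogenesis`,
  :func:`advance_generation`) that operates one generation at a time and is
  used for small-population oracle tests, and
* a numba fast path (:func:`run_generations`) that advances a population
  many generations at once and powers :func:`run_scenario` and the
  replicate grids.

Populations store haplotypes as rows of a dense 0/1 incidence matrix over
currently segregating mutations (infinite-sites on an integer coordinate
grid; a recurrent hit at an occupied position creates an independent allele
record).  Mutations fixed in a population are moved to its substitution
ledger: invisible to within-population diversity, but counted by the
divergence estimator.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .sim_config import (
    ChromosomeMap,
    ScaledParameters,
    mutation_class_probabilities,
    draw_mutation_effect,
)

__all__ = [
    "Mutation",
    "Population",
    "DemographySchedule",
    "SampleSnapshot",
    "HaploidSample",
    "ScenarioResult",
    "fitness",
    "gametogenesis",
    "advance_generation",
    "run_generations",
    "split_population",
    "sample_snapshot",
    "sample_haploid",
    "run_scenario",
    "ancestral_diversity_grid",
    "write_vcf",
]

DOMINANCE = 0.5  # all non-neutral mutations are codominant


@dataclass(frozen=True)
class Mutation:
    """One mutation in a run's registry."""

    id: int
    position_bp: int
    selection_coefficient: float
    origin_generation: int = 0


class Population:
    """A diploid Wright-Fisher population as a haplotype x mutation matrix.

    ``H[2*i]`` and ``H[2*i + 1]`` are the two haplotypes of individual
    ``i``.  Only the first ``n_sites`` columns are live.
    """

    def __init__(self, label: str, n_diploids: int, capacity: int = 1024, sub_capacity: int = 4096):
        if n_diploids < 1:
            raise ValueError("population must hold at least one diploid")
        self.label = label
        self.N = int(n_diploids)
        self.H = np.zeros((2 * self.N, capacity), dtype=np.uint8)
        self._scratch = np.zeros_like(self.H)
        self.positions = np.zeros(capacity, dtype=np.int64)
        self.sel_coeffs = np.zeros(capacity, dtype=np.float64)
        self.mut_ids = np.zeros(capacity, dtype=np.int64)
        self.n_sites = 0
        self.sub_positions = np.zeros(sub_capacity, dtype=np.int64)
        self.sub_sel_coeffs = np.zeros(sub_capacity, dtype=np.float64)
        self.sub_ids = np.zeros(sub_capacity, dtype=np.int64)
        self.n_subs = 0
        self.generation = 0
        self.next_mutation_id = 0

    # -- views ---------------------------------------------------------
    @property
    def n_haplotypes(self) -> int:
        return 2 * self.N

    def genotype_matrix(self) -> np.ndarray:
        """Live (2N, n_sites) incidence matrix (a view)."""
        return self.H[:, : self.n_sites]

    def site_positions(self) -> np.ndarray:
        return self.positions[: self.n_sites]

    def site_sel_coeffs(self) -> np.ndarray:
        return self.sel_coeffs[: self.n_sites]

    def site_ids(self) -> np.ndarray:
        return self.mut_ids[: self.n_sites]

    def substitution_ids(self) -> np.ndarray:
        return self.sub_ids[: self.n_subs]

    def substitution_positions(self) -> np.ndarray:
        return self.sub_positions[: self.n_subs]

    def haplotype_mutation_ids(self, hap_index: int) -> np.ndarray:
        """Ids of segregating derived alleles carried by one haplotype."""
        mask = self.H[hap_index, : self.n_sites] == 1
        return self.mut_ids[: self.n_sites][mask]

    # -- state management ------------------------------------------------
    def _grow_sites(self, min_capacity: int | None = None) -> None:
        cap = self.H.shape[1]
        new_cap = max(2 * cap, min_capacity or 0)
        for name in ("H", "_scratch"):
            old = getattr(self, name)
            new = np.zeros((old.shape[0], new_cap), dtype=np.uint8)
            new[:, : self.n_sites] = old[:, : self.n_sites]
            setattr(self, name, new)
        for name in ("positions", "mut_ids"):
            old = getattr(self, name)
            new = np.zeros(new_cap, dtype=old.dtype)
            new[: self.n_sites] = old[: self.n_sites]
            setattr(self, name, new)
        old = self.sel_coeffs
        new = np.zeros(new_cap, dtype=np.float64)
        new[: self.n_sites] = old[: self.n_sites]
        self.sel_coeffs = new

    def _grow_subs(self) -> None:
        cap = self.sub_positions.shape[0]
        for name in ("sub_positions", "sub_ids"):
            old = getattr(self, name)
            new = np.zeros(2 * cap, dtype=old.dtype)
            new[: self.n_subs] = old[: self.n_subs]
            setattr(self, name, new)
        old = self.sub_sel_coeffs
        new = np.zeros(2 * cap, dtype=np.float64)
        new[: self.n_subs] = old[: self.n_subs]
        self.sub_sel_coeffs = new

    def add_mutation_column(self, hap_index: int, position: int, s: float) -> int:
        """Append a new derived allele carried by a single haplotype."""
        if self.n_sites >= self.H.shape[1]:
            self._grow_sites()
        c = self.n_sites
        self.H[:, c] = 0
        self._scratch[:, c] = 0
        self.H[hap_index, c] = 1
        self.positions[c] = position
        self.sel_coeffs[c] = s
        self.mut_ids[c] = self.next_mutation_id
        self.next_mutation_id += 1
        self.n_sites += 1
        return c

    def compact(self) -> None:
        """Drop lost columns; move fixed columns to the substitution ledger."""
        if self.n_sites == 0:
            return
        counts = self.genotype_matrix().sum(axis=0)
        fixed = counts == self.n_haplotypes
        n_fixed = int(fixed.sum())
        while self.n_subs + n_fixed > self.sub_positions.shape[0]:
            self._grow_subs()
        if n_fixed:
            sl = slice(self.n_subs, self.n_subs + n_fixed)
            self.sub_positions[sl] = self.site_positions()[fixed]
            self.sub_sel_coeffs[sl] = self.site_sel_coeffs()[fixed]
            self.sub_ids[sl] = self.site_ids()[fixed]
            self.n_subs += n_fixed
        keep = (counts > 0) & ~fixed
        nk = int(keep.sum())
        self.H[:, :nk] = self.H[:, : self.n_sites][:, keep]
        self.positions[:nk] = self.site_positions()[keep]
        self.sel_coeffs[:nk] = self.site_sel_coeffs()[keep]
        self.mut_ids[:nk] = self.site_ids()[keep]
        self.n_sites = nk

    def copy(self, label: str | None = None, individuals: np.ndarray | None = None) -> "Population":
        """Deep copy, optionally restricted to a subset of individuals."""
        if individuals is None:
            individuals = np.arange(self.N)
        individuals = np.asarray(individuals, dtype=np.int64)
        out = Population(
            label or self.label,
            individuals.size,
            capacity=self.H.shape[1],
            sub_capacity=self.sub_positions.shape[0],
        )
        rows = np.empty(2 * individuals.size, dtype=np.int64)
        rows[0::2] = 2 * individuals
        rows[1::2] = 2 * individuals + 1
        out.H[:, : self.n_sites] = self.H[rows, : self.n_sites]
        out.positions[: self.n_sites] = self.site_positions()
        out.sel_coeffs[: self.n_sites] = self.site_sel_coeffs()
        out.mut_ids[: self.n_sites] = self.site_ids()
        out.n_sites = self.n_sites
        out.sub_positions[: self.n_subs] = self.substitution_positions()
        out.sub_sel_coeffs[: self.n_subs] = self.sub_sel_coeffs[: self.n_subs]
        out.sub_ids[: self.n_subs] = self.substitution_ids()
        out.n_subs = self.n_subs
        out.generation = self.generation
        out.next_mutation_id = self.next_mutation_id
        return out


# ---------------------------------------------------------------------------
# reference-path operations
# ---------------------------------------------------------------------------

def fitness(pop: Population) -> np.ndarray:
    """Multiplicative codominant fitness for every individual.

    ``w_i = prod_loci (1+s)`` for homozygous and ``(1 + s/2)`` for
    heterozygous non-neutral loci, floored at zero.
    """
    sel = np.flatnonzero(pop.site_sel_coeffs() != 0.0)
    w = np.ones(pop.N, dtype=np.float64)
    if sel.size == 0:
        return w
    s = pop.site_sel_coeffs()[sel]
    G = pop.H[0::2, : pop.n_sites][:, sel].astype(np.int64) + pop.H[1::2, : pop.n_sites][:, sel]
    het = np.maximum(1.0 + DOMINANCE * s, 0.0)
    hom = np.maximum(1.0 + s, 0.0)
    # large finite sentinel instead of -inf keeps the matmul NaN-free;
    # exp underflows these weights to exactly zero
    with np.errstate(divide="ignore"):
        lhet = np.where(het > 0, np.log(het), -1e300)
        lhom = np.where(hom > 0, np.log(hom), -1e300)
    lw = (G == 1) @ lhet + (G == 2) @ lhom
    with np.errstate(under="ignore"):
        return np.exp(lw)


def _meiosis_events(chrom: ChromosomeMap, rng: np.random.Generator, fixed_tract: bool = False) -> np.ndarray:
    """Source-toggle breakpoints for one meiosis (crossovers + GC tracts)."""
    L = chrom.length_bp
    kx = rng.poisson(chrom.per_bp_recombination_rate * L)
    events = list(rng.integers(0, L, size=kx))
    gc_rate = chrom.per_bp_gene_conversion_initiation_rate
    if gc_rate > 0:
        for _ in range(rng.poisson(gc_rate * L)):
            start = int(rng.integers(0, L))
            tract = (
                int(chrom.gene_conversion_tract_len_bp)
                if fixed_tract
                else int(rng.geometric(1.0 / chrom.gene_conversion_tract_len_bp))
            )
            events.extend((start, start + tract))
    return np.asarray(events, dtype=np.int64)


def gametogenesis(
    pop: Population,
    parent_index: int,
    chrom: ChromosomeMap,
    params: ScaledParameters,
    rng: np.random.Generator,
    fixed_gc_tract: bool = False,
) -> tuple[np.ndarray, list[Mutation]]:
    """Form one gamete from a parent: recombination, gene conversion, mutation.

    Returns the gamete's incidence vector over the population's current
    ``n_sites`` columns plus the list of de novo :class:`Mutation` records
    (not yet registered as columns — :func:`advance_generation` does that
    for the offspring generation).
    """
    if not (0 <= parent_index < pop.N):
        raise ValueError("parent index out of range")
    h0 = 2 * parent_index + int(rng.random() < 0.5)
    h1 = 2 * parent_index + (1 - (h0 - 2 * parent_index))
    events = _meiosis_events(chrom, rng, fixed_gc_tract)
    posns = pop.site_positions()
    if events.size == 0:
        gamete = pop.H[h0, : pop.n_sites].copy()
    else:
        parity = (events[None, :] <= posns[:, None]).sum(axis=1) % 2
        gamete = np.where(parity == 0, pop.H[h0, : pop.n_sites], pop.H[h1, : pop.n_sites]).astype(np.uint8)
    new: list[Mutation] = []
    for _ in range(rng.poisson(params.mutation_rate_per_bp_per_gen * chrom.length_bp)):
        mp = int(rng.integers(0, chrom.length_bp))
        eff = draw_mutation_effect(rng, mp, chrom, params)
        new.append(Mutation(-1, mp, eff.selection_coefficient, pop.generation + 1))
    return gamete, new


def advance_generation(
    pop: Population,
    chrom: ChromosomeMap,
    params: ScaledParameters,
    rng: np.random.Generator,
    return_parents: bool = False,
):
    """One Wright-Fisher generation, in place (reference path).

    Each of the N offspring draws two parents independently with
    probability proportional to fitness (selfing allowed); each parent
    contributes one recombinant, possibly mutated gamete.
    """
    w = fitness(pop) if params.selection_enabled else np.ones(pop.N)
    wtot = w.sum()
    if wtot <= 0:
        raise RuntimeError(f"population {pop.label} extinct: all fitness weights are zero")
    probs = w / wtot
    n_haps = pop.n_haplotypes
    parents = rng.choice(pop.N, size=n_haps, p=probs)
    gametes = np.empty((n_haps, pop.n_sites), dtype=np.uint8)
    pending: list[tuple[int, Mutation]] = []
    for j in range(n_haps):
        gamete, new = gametogenesis(pop, int(parents[j]), chrom, params, rng)
        gametes[j] = gamete
        pending.extend((j, m) for m in new)
    pop.H[:, : pop.n_sites] = gametes
    for j, m in pending:
        pop.add_mutation_column(j, m.position_bp, m.selection_coefficient)
    pop.generation += 1
    pop.compact()
    if return_parents:
        return parents
    return None


# ---------------------------------------------------------------------------
# fast path
# ---------------------------------------------------------------------------

def _kernel_seed(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def run_generations(
    pop: Population,
    chrom: ChromosomeMap,
    params: ScaledParameters,
    n_generations: int,
    seed: int | np.random.SeedSequence,
    compact_every: int = 4,
    fixed_gc_tract: bool = False,
) -> None:
    """Advance ``pop`` by ``n_generations`` using the numba kernel.

    Deterministic given the seed.  Capacity is grown transparently when the
    segregating-site or substitution buffers fill up.
    """
    if n_generations < 0:
        raise ValueError("n_generations must be non-negative")
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    p_neu, p_del, _ = mutation_class_probabilities(params)
    mu_L = params.mutation_rate_per_bp_per_gen * chrom.length_bp
    # pre-size the column buffer near its working set to avoid regrowth
    need = int(
        4.2 * params.theta * chrom.length_bp * (np.log(pop.n_haplotypes) + 1.0)
        + compact_every * mu_L * pop.n_haplotypes
        + 256
    )
    if pop.H.shape[1] < need:
        pop._grow_sites(min_capacity=need)
    remaining = n_generations
    while remaining > 0:
        # spawn a fresh child per kernel invocation so resumed epochs
        # (after buffer growth) continue with an independent stream
        ks = _kernel_seed(seq.spawn(1)[0])
        (pop.n_sites, pop.n_subs, pop.next_mutation_id, gens_done, status) = _kernels.run_epoch(
            pop.H,
            pop._scratch,
            pop.positions,
            pop.sel_coeffs,
            pop.mut_ids,
            pop.n_sites,
            chrom.length_bp,
            chrom.per_bp_recombination_rate * chrom.length_bp,
            chrom.per_bp_gene_conversion_initiation_rate * chrom.length_bp,
            float(chrom.gene_conversion_tract_len_bp),
            bool(fixed_gc_tract),
            mu_L,
            chrom.coding_starts,
            chrom.coding_ends,
            p_neu,
            p_del,
            params.dfe_shape_alpha,
            params.dfe_mean_abs_s / params.dfe_shape_alpha,
            params.selection_enabled,
            pop.sub_positions,
            pop.sub_sel_coeffs,
            pop.sub_ids,
            pop.n_subs,
            pop.next_mutation_id,
            remaining,
            compact_every,
            ks,
        )
        pop.generation += gens_done
        remaining -= gens_done
        if status == _kernels.STATUS_OK:
            break
        if status == _kernels.STATUS_GROW_SITES:
            pop._grow_sites()
        elif status == _kernels.STATUS_GROW_SUBS:
            pop._grow_subs()
        elif status == _kernels.STATUS_EXTINCT:
            raise RuntimeError(f"population {pop.label} extinct: all fitness weights are zero")


# ---------------------------------------------------------------------------
# demography and sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DemographySchedule:
    """Burn-in, split and output schedule for one scenario.

    ``sampling_generations`` are measured from the split; the first entry
    is 1 (one generation after the split) followed by multiples of the
    output interval.  Gene flow between the daughters is always zero.
    """

    burn_in_generations: int
    bottleneck_fraction: float
    sampling_generations: tuple[int, ...]
    no_migration: bool = True

    def __post_init__(self) -> None:
        gens = self.sampling_generations
        if any(b <= a for a, b in zip(gens, gens[1:])):
            raise ValueError("sampling generations must be strictly increasing")
        if not self.no_migration:
            raise ValueError("migration between daughter populations is not modelled")

    @classmethod
    def from_parameters(
        cls, params: ScaledParameters, max_generations: int | None = None
    ) -> "DemographySchedule":
        horizon = max_generations if max_generations is not None else params.max_generations_post_split
        interval = params.output_interval_generations
        gens = [1] + [t for t in range(interval, horizon + 1, interval)]
        return cls(
            burn_in_generations=params.burn_in_generations,
            bottleneck_fraction=params.bottleneck_fraction,
            sampling_generations=tuple(gens),
        )


def split_population(
    pop: Population, bottleneck_fraction: float, rng: np.random.Generator
) -> tuple[Population, Population]:
    """Split an ancestral population into two isolated daughters.

    Each daughter receives ``floor(fraction * N)`` founders drawn without
    replacement; the two founder sets are disjoint, so fractions above 0.5
    are rejected.
    """
    if not (0.0 < bottleneck_fraction <= 0.5):
        raise ValueError("bottleneck fraction must lie in (0, 0.5]: founders must be disjoint")
    n_d = int(bottleneck_fraction * pop.N)
    if n_d < 1:
        raise ValueError("bottleneck leaves a daughter population without founders")
    perm = rng.permutation(pop.N)
    pop.compact()
    pop1 = pop.copy(label="pop_1", individuals=np.sort(perm[:n_d]))
    pop2 = pop.copy(label="pop_2", individuals=np.sort(perm[n_d : 2 * n_d]))
    for daughter in (pop1, pop2):
        daughter.compact()
    return pop1, pop2


@dataclass(frozen=True)
class SampleSnapshot:
    """Genotypes of sampled diploids at one time point."""

    label: str
    generation: int
    genotypes: np.ndarray  # (2k, S) uint8, phased haplotype rows
    positions: np.ndarray  # (S,) 0-based bp
    sel_coeffs: np.ndarray  # (S,)
    mut_ids: np.ndarray  # (S,)
    coding: np.ndarray  # (S,) bool
    chromosome_length: int

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0] // 2


@dataclass(frozen=True)
class HaploidSample:
    """One haploid genome: segregating derived alleles + fixed substitutions."""

    ids: np.ndarray
    positions: np.ndarray
    sub_ids: np.ndarray
    sub_positions: np.ndarray
    chromosome_length: int


def sample_snapshot(
    pop: Population, n_individuals: int, chrom: ChromosomeMap, rng: np.random.Generator
) -> SampleSnapshot:
    """Sample diploids without replacement and keep their segregating sites."""
    if n_individuals > pop.N:
        raise ValueError("cannot sample more individuals than the population holds")
    chosen = np.sort(rng.choice(pop.N, size=n_individuals, replace=False))
    rows = np.empty(2 * n_individuals, dtype=np.int64)
    rows[0::2] = 2 * chosen
    rows[1::2] = 2 * chosen + 1
    G = pop.H[rows, : pop.n_sites]
    seg = np.flatnonzero((G.sum(axis=0) > 0) & (G.sum(axis=0) < 2 * n_individuals))
    order = seg[np.argsort(pop.site_positions()[seg], kind="stable")]
    positions = pop.site_positions()[order].copy()
    return SampleSnapshot(
        label=pop.label,
        generation=pop.generation,
        genotypes=np.ascontiguousarray(G[:, order]),
        positions=positions,
        sel_coeffs=pop.site_sel_coeffs()[order].copy(),
        mut_ids=pop.site_ids()[order].copy(),
        coding=chrom.is_coding(positions),
        chromosome_length=chrom.length_bp,
    )


def sample_haploid(pop: Population, chrom: ChromosomeMap, rng: np.random.Generator) -> HaploidSample:
    """Sample one haploid genome (carried alleles plus the fixation ledger)."""
    row = int(rng.integers(0, pop.n_haplotypes))
    mask = pop.H[row, : pop.n_sites] == 1
    return HaploidSample(
        ids=pop.site_ids()[mask].copy(),
        positions=pop.site_positions()[mask].copy(),
        sub_ids=pop.substitution_ids().copy(),
        sub_positions=pop.substitution_positions().copy(),
        chromosome_length=chrom.length_bp,
    )


@dataclass(frozen=True)
class DivergenceSample:
    """A pair of haploid genomes, one from each daughter population."""

    generation_post_split: int
    haploid_1: HaploidSample
    haploid_2: HaploidSample


@dataclass(frozen=True)
class ScenarioResult:
    """All samples emitted by one simulation replicate."""

    ancestral_snapshot: SampleSnapshot
    divergence_samples: tuple[DivergenceSample, ...]
    multiplier: float
    seed: int


def run_scenario(
    params: ScaledParameters,
    chrom: ChromosomeMap,
    schedule: DemographySchedule,
    seed: int,
    sample_size: int | None = None,
) -> ScenarioResult:
    """Run one replicate: burn-in, ancestral sample, split, divergence series.

    Deterministic given ``seed``.  The ancestral sample holds
    ``sample_size`` diploids (default: the configured 30) taken at burn-in
    end; at each post-split sampling generation one random haploid genome
    per daughter population is recorded for the divergence estimator.
    """
    root = np.random.SeedSequence(seed)
    kernel_seq, sampling_seq = root.spawn(2)
    rng = np.random.default_rng(sampling_seq)
    k = sample_size if sample_size is not None else params.sample_size_individuals

    pop = Population("pop_A", params.ancestral_Ne_diploids)
    run_generations(pop, chrom, params, schedule.burn_in_generations, kernel_seq.spawn(1)[0])
    snapshot = sample_snapshot(pop, k, chrom, rng)

    pop1, pop2 = split_population(pop, schedule.bottleneck_fraction, rng)
    samples = []
    elapsed = 0
    for t in schedule.sampling_generations:
        step = t - elapsed
        run_generations(pop1, chrom, params, step, kernel_seq.spawn(1)[0])
        run_generations(pop2, chrom, params, step, kernel_seq.spawn(1)[0])
        elapsed = t
        samples.append(
            DivergenceSample(
                generation_post_split=t,
                haploid_1=sample_haploid(pop1, chrom, rng),
                haploid_2=sample_haploid(pop2, chrom, rng),
            )
        )
    return ScenarioResult(
        ancestral_snapshot=snapshot,
        divergence_samples=tuple(samples),
        multiplier=chrom.recombination_multiplier,
        seed=seed,
    )


def ancestral_diversity_grid(
    params: ScaledParameters,
    multipliers=None,
    n_replicates: int | None = None,
    seed: int = 0,
    chromosome_length: int = 1_000_000,
    sample_size: int | None = None,
):
    """Burn in the ancestral population across the multiplier grid.

    Runs ``n_replicates`` independent replicates for every recombination
    multiplier, samples diploids at burn-in end and returns a tidy
    DataFrame with one row per (multiplier, replicate, region) holding pi.
    This is the work behind the pi-versus-recombination regressions.
    """
    import pandas as pd

    from .popgen_stats import snapshot_diversity

    mults = tuple(multipliers) if multipliers is not None else params.recombination_multipliers
    n_rep = n_replicates if n_replicates is not None else params.n_replicates
    root = np.random.SeedSequence(seed)
    rows = []
    for mult in mults:
        chrom = build_grid_chromosome(chromosome_length, mult, params)
        for rep in range(n_rep):
            rep_seq = np.random.SeedSequence(entropy=root.entropy, spawn_key=(hash_mult(mult), rep))
            kernel_seq, sampling_seq = rep_seq.spawn(2)
            pop = Population("pop_A", params.ancestral_Ne_diploids)
            run_generations(pop, chrom, params, params.burn_in_generations, kernel_seq)
            rng = np.random.default_rng(sampling_seq)
            snap = sample_snapshot(pop, sample_size or params.sample_size_individuals, chrom, rng)
            pis = snapshot_diversity(snap, chrom)
            for region, value in pis.items():
                rows.append(
                    {
                        "multiplier": mult,
                        "replicate": rep,
                        "region": region,
                        "statistic": "pi",
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


def build_grid_chromosome(length_bp: int, multiplier: float, params: ScaledParameters) -> ChromosomeMap:
    from .sim_config import build_chromosome

    return build_chromosome(length_bp, multiplier, params)


def hash_mult(multiplier: float) -> int:
    """Stable non-negative key for a multiplier, used in seed spawning."""
    return int(round(multiplier * 1000))


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

def write_vcf(snapshot: SampleSnapshot, path: str | os.PathLike, contig: str = "chr1") -> None:
    """Write a snapshot's segregating sites as a phased VCF 4.2 file.

    One record per site segregating in the sample, positions converted to
    1-based, GT phased as haplotype_1|haplotype_2, INFO carrying the
    selection coefficient ``S`` and the region class ``RC``.
    """
    if snapshot.genotypes.shape[0] < 2:
        raise ValueError("snapshot must hold at least one diploid sample")
    n = snapshot.n_individuals
    names = [f"ind{i}" for i in range(n)]
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={snapshot.chromosome_length}>",
        '##INFO=<ID=S,Number=1,Type=Float,Description="Selection coefficient">',
        '##INFO=<ID=RC,Number=1,Type=String,Description="Region class (coding|intergenic)">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names),
    ]
    G = snapshot.genotypes
    for j in range(snapshot.positions.size):
        info = f"S={snapshot.sel_coeffs[j]:.6g};RC={'coding' if snapshot.coding[j] else 'intergenic'}"
        gts = "\t".join(f"{G[2 * i, j]}|{G[2 * i + 1, j]}" for i in range(n))
        lines.append(
            f"{contig}\t{snapshot.positions[j] + 1}\t{snapshot.mut_ids[j]}\tA\tT\t.\tPASS\t{info}\tGT\t{gts}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
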