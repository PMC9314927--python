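"""Simulation parameters, population-genetic scaling, and chromosome architecture.

The simulated system is a single chromosome evolving in a diploid
Wright-Fisher population.  A parameter set describes the mutation rate, the
mean per-bp recombination rate (one crossover per chromosome per meiosis on
average for the 1-Mb reference chromosome at multiplier 1), a non-crossover
gene-conversion rate expressed as a fraction of the crossover rate, a gamma
distribution of fitness effects for coding mutations, and the demography of
an ancestral population that splits into two bottlenecked daughters.

To make forward simulation affordable the classical population-genetic
rescaling is applied: Ne -> Ne/lambda, mu -> mu*lambda, r -> r*lambda, which
preserves the population-scaled compound parameters theta = 4*Ne*mu and
rho = 4*Ne*r that control diversity and linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "RawParameters",
    "ScaledParameters",
    "ChromosomeMap",
    "MutationEffect",
    "DEFAULT_MULTIPLIERS",
    "default_parameters",
    "scale_parameters",
    "build_chromosome",
    "draw_mutation_effect",
    "mutation_class_probabilities",
]

#: The nine recombination-rate multipliers spanning 0.33r-3r, mirroring the
#: ~9-fold spread of mean recombination rate implied by mammalian chromosome
#: size variation.
DEFAULT_MULTIPLIERS: tuple[float, ...] = (0.33, 0.4, 0.5, 0.66, 1.0, 1.5, 2.0, 2.5, 3.0)

GENE_LENGTH_BP = 20_500
SPACER_LENGTH_BP = 94_500
REFERENCE_LENGTH_BP = 1_000_000
REFERENCE_GENE_COUNT = 9


@dataclass(frozen=True)
class RawParameters:
    """Unscaled simulation parameters (per-generation, per-bp rates).

    Defaults are the study conditions: mouse germline mutation rate, one
    crossover per 1-Mb chromosome on average, Drosophila-calibrated gene
    conversion (rate r/3, 440-bp tracts), and a gamma DFE with mean
    |s| = 15.625e-3 and shape 0.3 for coding mutations that are
    neutral/deleterious/beneficial at relative frequencies 0.3/1/0.0005.
    """

    mutation_rate_per_bp_per_gen: float = 5.7e-9
    mean_recombination_rate_per_bp_per_gen: float = 1.0e-8
    gene_conversion_rate_rel_r: float = 1.0 / 3.0
    gene_conversion_tract_len_bp: float = 440.0
    dfe_mean_abs_s: float = 15.625e-3
    dfe_shape_alpha: float = 0.3
    rel_freq_neutral: float = 0.3
    rel_freq_deleterious: float = 1.0
    rel_freq_beneficial: float = 0.0005
    ancestral_Ne_diploids: int = 10_000
    bottleneck_fraction: float = 0.5
    recombination_multipliers: tuple[float, ...] = DEFAULT_MULTIPLIERS
    selection_mode: str = "with_selection"
    gene_conversion_enabled: bool = False
    burn_in_multiple: int = 20
    n_replicates: int = 30
    sample_size_individuals: int = 30
    output_interval_generations: int = 250_000
    max_generations_post_split: int = 10_000_000

    def __post_init__(self) -> None:
        rates = (
            self.mutation_rate_per_bp_per_gen,
            self.mean_recombination_rate_per_bp_per_gen,
            self.gene_conversion_rate_rel_r,
            self.gene_conversion_tract_len_bp,
            self.dfe_mean_abs_s,
            self.dfe_shape_alpha,
        )
        if any(x < 0 for x in rates):
            raise ValueError("rates and DFE parameters must be non-negative")
        freqs = (self.rel_freq_neutral, self.rel_freq_deleterious, self.rel_freq_beneficial)
        if any(f <= 0 for f in freqs):
            raise ValueError("relative mutation-class frequencies must be positive")
        if self.rel_freq_deleterious < self.rel_freq_beneficial:
            raise ValueError("deleterious mutations cannot be rarer than beneficial ones")
        if self.ancestral_Ne_diploids < 1:
            raise ValueError("ancestral Ne must be a positive number of diploids")
        if not (0.0 < self.bottleneck_fraction <= 0.5):
            raise ValueError(
                "bottleneck_fraction must lie in (0, 0.5]: daughter founders are "
                "drawn without replacement from the ancestor"
            )
        if any(m <= 0 for m in self.recombination_multipliers):
            raise ValueError("recombination multipliers must be positive")
        if self.selection_mode not in ("neutral", "with_selection"):
            raise ValueError("selection_mode must be 'neutral' or 'with_selection'")


@dataclass(frozen=True)
class ScaledParameters:
    """A :class:`RawParameters` set after rescaling by ``scaling_factor``.

    Carries the same fields with Ne divided and mu/r multiplied by the
    factor.  ``theta`` and ``rho`` are invariant under the rescaling; the
    burn-in length is ``burn_in_multiple * Ne`` scaled generations.
    """

    mutation_rate_per_bp_per_gen: float
    mean_recombination_rate_per_bp_per_gen: float
    gene_conversion_rate_rel_r: float
    gene_conversion_tract_len_bp: float
    dfe_mean_abs_s: float
    dfe_shape_alpha: float
    rel_freq_neutral: float
    rel_freq_deleterious: float
    rel_freq_beneficial: float
    ancestral_Ne_diploids: int
    bottleneck_fraction: float
    recombination_multipliers: tuple[float, ...]
    selection_mode: str
    gene_conversion_enabled: bool
    burn_in_multiple: int
    n_replicates: int
    sample_size_individuals: int
    output_interval_generations: int
    max_generations_post_split: int
    scaling_factor: int = 1

    @property
    def theta(self) -> float:
        """Population-scaled mutation rate 4*Ne*mu per bp."""
        return 4.0 * self.ancestral_Ne_diploids * self.mutation_rate_per_bp_per_gen

    @property
    def rho(self) -> float:
        """Population-scaled recombination rate 4*Ne*r per bp."""
        return 4.0 * self.ancestral_Ne_diploids * self.mean_recombination_rate_per_bp_per_gen

    @property
    def burn_in_generations(self) -> int:
        return self.burn_in_multiple * self.ancestral_Ne_diploids

    @property
    def drift_effect_size(self) -> float:
        """Per-generation sampling effect of drift, 1/(2*Ne)."""
        return 1.0 / (2.0 * self.ancestral_Ne_diploids)

    @property
    def selection_enabled(self) -> bool:
        return self.selection_mode == "with_selection"


def default_parameters(**overrides) -> RawParameters:
    """The study's baseline parameter set, with keyword overrides."""
    return RawParameters(**overrides)


def scale_parameters(raw: RawParameters, scaling_factor: int) -> ScaledParameters:
    """Rescale a raw parameter set by an integer factor lambda.

    Ne -> Ne/lambda, mu -> mu*lambda, r -> r*lambda.  theta = 4*Ne*mu and
    rho = 4*Ne*r are preserved exactly.  Selection coefficients, the
    gene-conversion tract length and the relative gene-conversion rate are
    dimensionless relative quantities and are left untouched.

    Raises
    ------
    ValueError
        If ``Ne / scaling_factor`` is not a whole number of diploids.
    """
    if scaling_factor < 1 or int(scaling_factor) != scaling_factor:
        raise ValueError("scaling factor must be a positive integer")
    scaling_factor = int(scaling_factor)
    ne, lam = raw.ancestral_Ne_diploids, scaling_factor
    if ne % lam != 0:
        raise ValueError(
            f"ancestral Ne={ne} is not divisible by scaling factor lambda={lam}; "
            "the scaled population must contain an integral number of diploids"
        )
    return ScaledParameters(
        mutation_rate_per_bp_per_gen=raw.mutation_rate_per_bp_per_gen * lam,
        mean_recombination_rate_per_bp_per_gen=raw.mean_recombination_rate_per_bp_per_gen * lam,
        gene_conversion_rate_rel_r=raw.gene_conversion_rate_rel_r,
        gene_conversion_tract_len_bp=raw.gene_conversion_tract_len_bp,
        dfe_mean_abs_s=raw.dfe_mean_abs_s,
        dfe_shape_alpha=raw.dfe_shape_alpha,
        rel_freq_neutral=raw.rel_freq_neutral,
        rel_freq_deleterious=raw.rel_freq_deleterious,
        rel_freq_beneficial=raw.rel_freq_beneficial,
        ancestral_Ne_diploids=ne // lam,
        bottleneck_fraction=raw.bottleneck_fraction,
        recombination_multipliers=tuple(raw.recombination_multipliers),
        selection_mode=raw.selection_mode,
        gene_conversion_enabled=raw.gene_conversion_enabled,
        burn_in_multiple=raw.burn_in_multiple,
        n_replicates=raw.n_replicates,
        sample_size_individuals=raw.sample_size_individuals,
        output_interval_generations=raw.output_interval_generations,
        max_generations_post_split=raw.max_generations_post_split,
        scaling_factor=lam,
    )


def unscale_parameters(scaled: ScaledParameters) -> RawParameters:
    """Inverse of :func:`scale_parameters` (exact round-trip)."""
    lam = scaled.scaling_factor
    return RawParameters(
        mutation_rate_per_bp_per_gen=scaled.mutation_rate_per_bp_per_gen / lam,
        mean_recombination_rate_per_bp_per_gen=scaled.mean_recombination_rate_per_bp_per_gen / lam,
        gene_conversion_rate_rel_r=scaled.gene_conversion_rate_rel_r,
        gene_conversion_tract_len_bp=scaled.gene_conversion_tract_len_bp,
        dfe_mean_abs_s=scaled.dfe_mean_abs_s,
        dfe_shape_alpha=scaled.dfe_shape_alpha,
        rel_freq_neutral=scaled.rel_freq_neutral,
        rel_freq_deleterious=scaled.rel_freq_deleterious,
        rel_freq_beneficial=scaled.rel_freq_beneficial,
        ancestral_Ne_diploids=scaled.ancestral_Ne_diploids * lam,
        bottleneck_fraction=scaled.bottleneck_fraction,
        recombination_multipliers=tuple(scaled.recombination_multipliers),
        selection_mode=scaled.selection_mode,
        gene_conversion_enabled=scaled.gene_conversion_enabled,
        burn_in_multiple=scaled.burn_in_multiple,
        n_replicates=scaled.n_replicates,
        sample_size_individuals=scaled.sample_size_individuals,
        output_interval_generations=scaled.output_interval_generations,
        max_generations_post_split=scaled.max_generations_post_split,
    )


def diffusion_rescale(raw: RawParameters, extra_factor: int) -> ScaledParameters:
    """Apply the canonical x25 rescale plus an extra diffusion-preserving factor.

    The x25 rescale follows the primary convention (s untouched).  The
    additional factor also multiplies the DFE mean so the population-scaled
    selection strength Ne*s is preserved along with theta and rho; with all
    three compound parameters fixed, diversity patterns are invariant up to
    O(s) and O(1/Ne) corrections.  Used to shrink replicate grids to a
    practical problem size.
    """
    if extra_factor < 1 or int(extra_factor) != extra_factor:
        raise ValueError("extra_factor must be a positive integer")
    extra = int(extra_factor)
    boosted = replace(raw, dfe_mean_abs_s=raw.dfe_mean_abs_s * extra)
    return scale_parameters(boosted, 25 * extra)


@dataclass(frozen=True)
class ChromosomeMap:
    """Coding/intergenic layout and per-bp meiotic rates for one chromosome.

    Coding intervals are 0-based half-open ``[start, end)``, sorted and
    disjoint.  ``per_bp_recombination_rate`` already includes the
    chromosome's recombination multiplier; the gene-conversion initiation
    rate is one third of it (the multiplier applies to gene conversion too,
    since that rate is defined relative to r).
    """

    length_bp: int
    coding_starts: np.ndarray
    coding_ends: np.ndarray
    per_bp_recombination_rate: float
    per_bp_gene_conversion_initiation_rate: float
    gene_conversion_tract_len_bp: float
    recombination_multiplier: float = 1.0

    def __post_init__(self) -> None:
        starts = np.asarray(self.coding_starts, dtype=np.int64)
        ends = np.asarray(self.coding_ends, dtype=np.int64)
        object.__setattr__(self, "coding_starts", starts)
        object.__setattr__(self, "coding_ends", ends)
        if starts.shape != ends.shape:
            raise ValueError("coding interval start/end arrays differ in length")
        if starts.size:
            if np.any(ends <= starts):
                raise ValueError("coding intervals must be non-empty half-open intervals")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError("coding intervals must be sorted and disjoint")
            if starts[0] < 0 or ends[-1] > self.length_bp:
                raise ValueError("coding intervals must lie within the chromosome")

    @property
    def n_genes(self) -> int:
        return int(self.coding_starts.size)

    @property
    def coding_length_bp(self) -> int:
        return int(np.sum(self.coding_ends - self.coding_starts))

    @property
    def intergenic_length_bp(self) -> int:
        return self.length_bp - self.coding_length_bp

    @property
    def coding_fraction(self) -> float:
        return self.coding_length_bp / self.length_bp

    def is_coding(self, positions) -> np.ndarray:
        """Vectorised membership test for 0-based positions."""
        pos = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        if self.coding_starts.size == 0:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(self.coding_starts, pos, side="right") - 1
        inside = idx >= 0
        idx = np.clip(idx, 0, None)
        return inside & (pos < self.coding_ends[idx])


def build_chromosome(
    length_bp: int,
    r_multiplier: float,
    params: ScaledParameters | RawParameters,
) -> ChromosomeMap:
    """Lay out coding genes and intergenic spacers on a chromosome.

    The 1-Mb reference chromosome holds nine 20.5-kb coding genes separated
    by 94.5-kb intergenic spacers; other lengths hold
    ``round(9 * length / 1 Mb)`` genes so the coding fraction stays at the
    reference value of 0.1845 up to one gene's rounding.  Any leftover
    intergenic sequence is split evenly between the two chromosome ends;
    when the printed spacer width cannot fit (long chromosomes whose rounded
    gene count slightly overshoots), the gene size and count are kept exact
    and the internal spacers are narrowed uniformly instead.
    """
    if length_bp <= 0:
        raise ValueError("chromosome length must be positive")
    if r_multiplier <= 0:
        raise ValueError("recombination multiplier must be positive")
    n_genes = round(REFERENCE_GENE_COUNT * length_bp / REFERENCE_LENGTH_BP)
    if n_genes < 1 or length_bp < GENE_LENGTH_BP:
        raise ValueError(
            f"chromosome of {length_bp} bp is too short to hold one "
            f"{GENE_LENGTH_BP}-bp coding gene"
        )
    core = n_genes * GENE_LENGTH_BP + (n_genes - 1) * SPACER_LENGTH_BP
    if core <= length_bp:
        spacer = SPACER_LENGTH_BP
        leftover = length_bp - core
        left_pad = leftover // 2
    else:
        # keep genes exact, shrink internal spacers uniformly
        if n_genes * GENE_LENGTH_BP > length_bp:
            raise ValueError(
                f"chromosome of {length_bp} bp cannot hold {n_genes} coding genes"
            )
        spacer = (length_bp - n_genes * GENE_LENGTH_BP) // max(n_genes - 1, 1)
        used = n_genes * GENE_LENGTH_BP + (n_genes - 1) * spacer
        left_pad = (length_bp - used) // 2
    starts = left_pad + np.arange(n_genes, dtype=np.int64) * (GENE_LENGTH_BP + spacer)
    ends = starts + GENE_LENGTH_BP
    r = params.mean_recombination_rate_per_bp_per_gen * r_multiplier
    gc = r * params.gene_conversion_rate_rel_r if params.gene_conversion_enabled else 0.0
    return ChromosomeMap(
        length_bp=int(length_bp),
        coding_starts=starts,
        coding_ends=ends,
        per_bp_recombination_rate=r,
        per_bp_gene_conversion_initiation_rate=gc,
        gene_conversion_tract_len_bp=params.gene_conversion_tract_len_bp,
        recombination_multiplier=float(r_multiplier),
    )


NEUTRAL = "neutral"
DELETERIOUS = "deleterious"
BENEFICIAL = "beneficial"
INTERGENIC_NEUTRAL = "intergenic_neutral"


@dataclass(frozen=True)
class MutationEffect:
    """Fitness effect of a single mutation.

    All non-neutral mutations are codominant (h = 0.5); neutral mutations
    carry s = 0 exactly.
    """

    selection_coefficient: float
    dominance: float
    mutation_class: str

    def __post_init__(self) -> None:
        s, cls = self.selection_coefficient, self.mutation_class
        if cls in (NEUTRAL, INTERGENIC_NEUTRAL) and s != 0.0:
            raise ValueError("neutral mutations must have s = 0")
        if cls == DELETERIOUS and s >= 0.0:
            raise ValueError("deleterious mutations must have s < 0")
        if cls == BENEFICIAL and s <= 0.0:
            raise ValueError("beneficial mutations must have s > 0")


def mutation_class_probabilities(params: RawParameters | ScaledParameters) -> tuple[float, float, float]:
    """(neutral, deleterious, beneficial) probabilities for a coding mutation."""
    total = params.rel_freq_neutral + params.rel_freq_deleterious + params.rel_freq_beneficial
    return (
        params.rel_freq_neutral / total,
        params.rel_freq_deleterious / total,
        params.rel_freq_beneficial / total,
    )


def draw_mutation_effect(
    rng: np.random.Generator,
    position: int,
    chrom: ChromosomeMap,
    params: ScaledParameters,
) -> MutationEffect:
    """Draw the fitness effect of a new mutation at ``position``.

    Intergenic mutations are always neutral.  In the selection model a
    coding mutation is neutral/deleterious/beneficial with probabilities
    proportional to the configured relative frequencies, and non-neutral
    magnitudes follow Gamma(shape alpha, mean |s|) with the sign set by the
    class.  In the neutral model every mutation has s = 0.
    """
    if not (0 <= position < chrom.length_bp):
        raise ValueError(f"position {position} outside chromosome [0, {chrom.length_bp})")
    if not bool(chrom.is_coding(position)[0]):
        return MutationEffect(0.0, 0.5, INTERGENIC_NEUTRAL)
    if not params.selection_enabled:
        return MutationEffect(0.0, 0.5, NEUTRAL)
    p_neu, p_del, _ = mutation_class_probabilities(params)
    u = rng.random()
    if u < p_neu:
        return MutationEffect(0.0, 0.5, NEUTRAL)
    scale = params.dfe_mean_abs_s / params.dfe_shape_alpha
    mag = rng.gamma(params.dfe_shape_alpha, scale)
    # gamma draws of magnitude zero are measure-zero but guard the class invariant
    mag = max(mag, np.finfo(float).tiny)
    if u < p_neu + p_del:
        return MutationEffect(-mag, 0.5, DELETERIOUS)
    return MutationEffect(mag, 0.5, BENEFICIAL)
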