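"""Diversity and divergence statistics over simulator output.

pi is the unbiased average pairwise nucleotide diversity per bp
(sum over sites of ``2 p (1-p) n/(n-1)`` divided by the region length,
equivalent to averaging mismatches over all haplotype pairs).  d is the
proportion of unmatched bases between two haploid genomes drawn from
diverging populations, counting both segregating differences and the
populations' fixed substitutions.  Delta-pi / Delta-d contrast the highest-
and lowest-recombination chromosomes; the regression and ANOVA helpers wrap
statsmodels/scipy with the conventions used throughout the package
(adjusted R-squared, fixed-effects one-way ANOVA over multiplier classes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .sim_config import ChromosomeMap
from .wf_engine import HaploidSample, SampleSnapshot

__all__ = [
    "nucleotide_diversity",
    "snapshot_diversity",
    "divergence",
    "divergence_by_region",
    "delta_stat",
    "variance_explained",
    "anova_across_classes",
    "decay_series",
    "RegressionResult",
]

REGION_CHROMOSOME = "chromosome"
REGION_CODING = "coding"
REGION_INTERGENIC = "intergenic"


def _region_lengths(chrom: ChromosomeMap) -> dict[str, int]:
    return {
        REGION_CHROMOSOME: chrom.length_bp,
        REGION_CODING: chrom.coding_length_bp,
        REGION_INTERGENIC: chrom.intergenic_length_bp,
    }


def nucleotide_diversity(
    haplotypes: np.ndarray,
    length_bp: int,
    positions: np.ndarray | None = None,
    site_mask: np.ndarray | None = None,
) -> float:
    """Unbiased pairwise nucleotide diversity per bp.

    Parameters
    ----------
    haplotypes:
        (n, S) 0/1 matrix of sampled haplotypes (n >= 2).
    length_bp:
        Length of the region the diversity is averaged over (monomorphic
        sites contribute zeros implicitly).
    positions, site_mask:
        Optional restriction to a subset of sites; ``site_mask`` selects
        the columns belonging to the region of interest.
    """
    H = np.asarray(haplotypes)
    n = H.shape[0]
    if n < 2:
        raise ValueError("need at least two haplotypes to measure diversity")
    if length_bp <= 0:
        raise ValueError("region length must be positive")
    if site_mask is not None:
        H = H[:, np.asarray(site_mask, dtype=bool)]
    if H.shape[1] == 0:
        return 0.0
    p = H.sum(axis=0) / n
    per_site = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    return float(per_site.sum() / length_bp)


def snapshot_diversity(snapshot: SampleSnapshot, chrom: ChromosomeMap) -> dict[str, float]:
    """pi across the chromosome, coding genes only, and intergenic areas only."""
    lengths = _region_lengths(chrom)
    coding = snapshot.coding
    return {
        REGION_CHROMOSOME: nucleotide_diversity(snapshot.genotypes, lengths[REGION_CHROMOSOME]),
        REGION_CODING: nucleotide_diversity(
            snapshot.genotypes, lengths[REGION_CODING], site_mask=coding
        ),
        REGION_INTERGENIC: nucleotide_diversity(
            snapshot.genotypes, lengths[REGION_INTERGENIC], site_mask=~coding
        ),
    }


def _all_ids(h: HaploidSample) -> np.ndarray:
    return np.concatenate([h.ids, h.sub_ids])


def divergence(hap_x: HaploidSample, hap_y: HaploidSample, length_bp: int | None = None) -> float:
    """Proportion of unmatched bases between two haploid genomes.

    Counts the symmetric difference of derived-allele identities carried by
    the two genomes, including each source population's substitution
    ledger (ancestral substitutions shared by both ledgers cancel).
    """
    if hap_x.chromosome_length != hap_y.chromosome_length:
        raise ValueError("haploid genomes come from chromosomes of different lengths")
    L = length_bp if length_bp is not None else hap_x.chromosome_length
    diff = np.setxor1d(_all_ids(hap_x), _all_ids(hap_y), assume_unique=False)
    return diff.size / L


def divergence_by_region(
    hap_x: HaploidSample, hap_y: HaploidSample, chrom: ChromosomeMap
) -> dict[str, float]:
    """d across the chromosome and within coding/intergenic partitions."""
    if hap_x.chromosome_length != hap_y.chromosome_length:
        raise ValueError("haploid genomes come from chromosomes of different lengths")
    ids = np.concatenate([_all_ids(hap_x), _all_ids(hap_y)])
    pos = np.concatenate(
        [hap_x.positions, hap_x.sub_positions, hap_y.positions, hap_y.sub_positions]
    )
    order = np.argsort(ids, kind="stable")
    ids, pos = ids[order], pos[order]
    uniq, counts = np.unique(ids, return_counts=True)
    first = np.searchsorted(ids, uniq[counts == 1])
    diff_pos = pos[first]
    coding = chrom.is_coding(diff_pos) if diff_pos.size else np.zeros(0, dtype=bool)
    lengths = _region_lengths(chrom)
    return {
        REGION_CHROMOSOME: diff_pos.size / lengths[REGION_CHROMOSOME],
        REGION_CODING: int(coding.sum()) / lengths[REGION_CODING],
        REGION_INTERGENIC: int((~coding).sum()) / lengths[REGION_INTERGENIC],
    }


# ---------------------------------------------------------------------------
# tidy-table statistics
# ---------------------------------------------------------------------------

def delta_stat(
    records: pd.DataFrame,
    statistic: str,
    generation: int | None = None,
    value_col: str = "value",
) -> float:
    """Replicate-mean difference between the extreme recombination classes.

    ``stat(max multiplier) - stat(min multiplier)``, averaged over
    replicates, for rows matching ``statistic`` (and ``generation`` when
    the table carries one).
    """
    df = records[records["statistic"] == statistic]
    if generation is not None and "generation" in df.columns:
        df = df[df["generation"] == generation]
    if "region" in df.columns:
        df = df[df["region"] == REGION_CHROMOSOME]
    if df.empty:
        raise ValueError(f"no rows for statistic {statistic!r}")
    mults = df["multiplier"].unique()
    hi, lo = mults.max(), mults.min()
    if hi == lo:
        raise ValueError("both extreme recombination classes must be present")
    hi_vals = df.loc[df["multiplier"] == hi, value_col]
    lo_vals = df.loc[df["multiplier"] == lo, value_col]
    if hi_vals.empty or lo_vals.empty:
        raise ValueError("missing replicates in an extreme recombination class")
    return float(hi_vals.mean() - lo_vals.mean())


@dataclass(frozen=True)
class RegressionResult:
    """OLS summary: slope, intercept, adjusted R-squared, slope p-value, n."""

    slope: float
    intercept: float
    r_squared_adj: float
    r_squared: float
    p_value: float
    n: int


def variance_explained(x, y, on_means: bool = False) -> RegressionResult:
    """OLS of a statistic on the recombination rate (or any predictor).

    ``on_means=True`` first averages y within each distinct x (mean-level
    regression); the default regresses replicate-level observations.
    Adjusted R-squared follows ``1 - (1-R2)(n-1)/(n-2)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have matching shapes")
    if on_means:
        df = pd.DataFrame({"x": x, "y": y}).groupby("x", as_index=False)["y"].mean()
        x, y = df["x"].to_numpy(), df["y"].to_numpy()
    if np.unique(x).size < 3:
        raise ValueError("need at least three distinct predictor values")
    if x.size <= 2:
        raise ValueError("need more than two observations")
    if np.allclose(x.var(), 0):
        raise ValueError("zero variance in the predictor")
    if np.ptp(y) == 0:
        # constant response: R2 is 0 by definition (statsmodels yields 0/0)
        n = x.size
        return RegressionResult(
            slope=0.0,
            intercept=float(y[0]),
            r_squared_adj=1.0 - (n - 1) / (n - 2),
            r_squared=0.0,
            p_value=1.0,
            n=int(n),
        )
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared_adj=float(model.rsquared_adj),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=int(x.size),
    )


def anova_across_classes(groups) -> tuple[float, float]:
    """One-way fixed-effects ANOVA across recombination classes.

    ``groups`` is either a mapping/sequence of per-class value arrays or a
    DataFrame with ``multiplier`` and ``value`` columns.  Returns (F, p).
    """
    if isinstance(groups, pd.DataFrame):
        arrays = [g["value"].to_numpy() for _, g in groups.groupby("multiplier")]
    elif isinstance(groups, dict):
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("ANOVA needs at least two classes with two values each")
    if all(np.ptp(a) == 0 for a in arrays) and np.ptp(np.concatenate(arrays)) == 0:
        return 0.0, 1.0
    f, p = scipy.stats.f_oneway(*arrays)
    return float(f), float(p)


def decay_series(records: pd.DataFrame, statistic: str = "d") -> pd.DataFrame:
    """Delta-d(t) per scenario plus the first generation where it turns negative.

    Expects one row per (multiplier, replicate, generation) with the
    statistic's value; returns one row per generation with the
    replicate-mean extreme-class difference and a ``sign_change`` flag on
    the first negative entry.
    """
    df = records[records["statistic"] == statistic]
    if df["generation"].nunique() < 2:
        raise ValueError("need at least two sampling generations")
    rows = []
    for gen, sub in df.groupby("generation"):
        rows.append({"generation": gen, "delta": delta_stat(sub, statistic)})
    out = pd.DataFrame(rows).sort_values("generation").reset_index(drop=True)
    negative = out.index[out["delta"] < 0]
    out["sign_change"] = False
    if negative.size:
        out.loc[negative[0], "sign_change"] = True
    return out


def first_negative_generation(series: pd.DataFrame) -> int | None:
    """Generation of the first sign change in a :func:`decay_series` table."""
    hit = series.loc[series["sign_change"], "generation"]
    return int(hit.iloc[0]) if hit.size else None
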