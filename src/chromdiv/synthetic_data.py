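"""Synthetic inputs for every stage of the pipeline — no downloads needed.

Three generators:

* alignment tables whose per-chromosome divergence follows a controllable
  log-linear law in chromosome size (the statistical structure of real
  whole-genome-alignment summaries, without any sequence content),
* drift-only binomial allele-frequency trajectories (closed-form oracle
  for the Wright-Fisher engine), and
* haploid genome pairs with an exact number of mismatches (oracle for the
  divergence estimator).

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment_divergence import COLUMNS
from .wf_engine import HaploidSample

__all__ = [
    "SyntheticAlignmentSpec",
    "generate_alignment_table",
    "generate_drift_fixture",
    "generate_haplotype_pair",
]


@dataclass(frozen=True)
class SyntheticAlignmentSpec:
    """Recipe for a synthetic whole-genome-alignment table.

    Chromosome sizes are log-uniform over ``size_range_bp`` (default a
    mammalian 20-250 Mb span); each chromosome's expected divergence is
    ``intercept + slope * log10(size)`` plus Gaussian noise, clamped to
    [0, 1].  Emitted alignment rows are constructed so their
    length-weighted similarity reproduces the drawn divergence exactly.
    """

    n_chromosomes: int = 20
    size_range_bp: tuple[int, int] = (20_000_000, 250_000_000)
    intercept: float = 0.20
    slope: float = -0.02
    noise_sd: float = 0.0
    alignments_per_chromosome: int = 25
    alignment_length_range_bp: tuple[int, int] = (15_000, 2_000_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        lo, hi = self.size_range_bp
        if lo <= 0 or hi < lo:
            raise ValueError("invalid chromosome size range")
        if self.noise_sd < 0:
            raise ValueError("noise SD cannot be negative")
        if self.alignments_per_chromosome < 1:
            raise ValueError("need at least one alignment per chromosome")
        lo_d = self.intercept + self.slope * np.log10(self.size_range_bp[0])
        hi_d = self.intercept + self.slope * np.log10(self.size_range_bp[1])
        if max(lo_d, hi_d) < 0.0 or min(lo_d, hi_d) > 1.0:
            raise ValueError(
                "expected divergence lies outside [0, 1] over the whole size range; "
                "adjust intercept/slope"
            )


def generate_alignment_table(
    spec: SyntheticAlignmentSpec,
    alignment_path: str | os.PathLike | None = None,
    sizes_path: str | os.PathLike | None = None,
) -> pd.DataFrame:
    """Draw chromosomes and emit a coords-tsv table + size table + truth.

    Returns the per-chromosome truth table (name, size, true d).  When
    paths are given the alignment rows and sizes are written as the same
    tab-separated dialects the parser reads.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.size_range_bp
    sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_chromosomes)).astype(np.int64)
    sizes = np.sort(sizes)[::-1]
    names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    true_d = spec.intercept + spec.slope * np.log10(sizes)
    if spec.noise_sd > 0:
        true_d = true_d + rng.normal(0.0, spec.noise_sd, size=sizes.size)
    true_d = np.clip(true_d, 0.0, 1.0)

    rows = []
    for name, size, d in zip(names, sizes, true_d):
        k = spec.alignments_per_chromosome
        llo, lhi = spec.alignment_length_range_bp
        lengths = rng.integers(llo, lhi + 1, size=k)
        target = 100.0 * (1.0 - d)
        # per-row similarities scatter around the target but are reweighted
        # so the length-weighted mean equals the target exactly
        sims = np.clip(target + rng.normal(0.0, 0.5, size=k), 0.0, 100.0)
        current = float(lengths @ sims / lengths.sum())
        sims = np.clip(sims + (target - current), 0.0, 100.0)
        current = float(lengths @ sims / lengths.sum())
        if abs(current - target) > 1e-9:
            sims = np.full(k, target)
        start = 1
        for ln, sim in zip(lengths, sims):
            ref_start = int(min(start, max(size - ln, 1)))
            rows.append(
                {
                    "ref_chromosome": name,
                    "query_chromosome": f"q_{name}",
                    "ref_start": ref_start,
                    "ref_end": int(ref_start + ln - 1),
                    "alignment_length_bp": int(ln),
                    "percent_identity": float(sim),
                    "percent_similarity": float(sim),
                }
            )
            start = ref_start + int(ln) + 1
    table = pd.DataFrame(rows, columns=COLUMNS)
    truth = pd.DataFrame({"chromosome": names, "size_bp": sizes, "true_d": true_d})
    if alignment_path is not None:
        table.to_csv(alignment_path, sep="\t", index=False)
    if sizes_path is not None:
        truth[["chromosome", "size_bp"]].to_csv(sizes_path, sep="\t", index=False, header=False)
    truth.attrs["alignments"] = table
    return truth


def generate_drift_fixture(
    N: int, p0: float, T: int, replicates: int, seed: int = 0
) -> np.ndarray:
    """Binomial Wright-Fisher allele-frequency trajectories, drift only.

    Returns an array of shape (replicates, T+1) with frequencies in a
    diploid population of N individuals (2N allele copies), starting at
    ``p0``.  Closed-form oracle: E[H_t] = H_0 (1 - 1/2N)^t and the
    fixation probability equals p0.
    """
    if not (0.0 < p0 <= 1.0):
        raise ValueError("initial frequency must lie in (0, 1]")
    if N < 1 or T < 0 or replicates < 1:
        raise ValueError("N, T and replicates must be positive")
    rng = np.random.default_rng(seed)
    two_n = 2 * N
    traj = np.empty((replicates, T + 1), dtype=np.float64)
    p = np.full(replicates, p0)
    traj[:, 0] = p
    for t in range(1, T + 1):
        p = rng.binomial(two_n, p) / two_n
        traj[:, t] = p
    return traj


def generate_haplotype_pair(
    L: int, n_differences: int, seed: int = 0
) -> tuple[HaploidSample, HaploidSample]:
    """Two haploid genomes differing at exactly ``n_differences`` positions.

    Shared background alleles are placed on both genomes; the differences
    are split between private alleles of each genome, so the pair
    exercises both sides of the symmetric difference in the divergence
    estimator.
    """
    if n_differences > L:
        raise ValueError("cannot place more differences than positions")
    rng = np.random.default_rng(seed)
    n_shared = int(rng.integers(0, max(L // 1000, 2)))
    pos = rng.choice(L, size=n_differences + n_shared, replace=False).astype(np.int64)
    shared_pos, diff_pos = pos[:n_shared], pos[n_shared:]
    ids = np.arange(n_differences + n_shared, dtype=np.int64)
    shared_ids, diff_ids = ids[:n_shared], ids[n_shared:]
    k = n_differences // 2
    hap_x = HaploidSample(
        ids=np.concatenate([shared_ids, diff_ids[:k]]),
        positions=np.concatenate([shared_pos, diff_pos[:k]]),
        sub_ids=np.empty(0, dtype=np.int64),
        sub_positions=np.empty(0, dtype=np.int64),
        chromosome_length=L,
    )
    hap_y = HaploidSample(
        ids=np.concatenate([shared_ids, diff_ids[k:]]),
        positions=np.concatenate([shared_pos, diff_pos[k:]]),
        sub_ids=np.empty(0, dtype=np.int64),
        sub_positions=np.empty(0, dtype=np.int64),
        chromosome_length=L,
    )
    return hap_x, hap_y
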