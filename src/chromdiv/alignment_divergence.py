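"""Chromosome-level divergence from whole-genome-alignment coordinate tables.

The empirical pipeline: parse a tab-delimited alignment table (a MUMmer
``show-coords`` btab-style dialect or a headered TSV), keep autosomal
alignments longer than 10 kb, summarise each chromosome's divergence as the
alignment-length-weighted mean of ``1 - percent_similarity/100``, and
regress that divergence on log10 chromosome size.  Percent *similarity* is
used rather than percent identity so N-to-N matches do not inflate the
apparent identity.

Alignments should come from a global filtering of the aligner output (for
MUMmer: ``nucmer --maxgap 2000 --mincluster 1000`` followed by
``delta-filter -g``); running the aligner is outside this package's scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popgen_stats import RegressionResult, variance_explained

__all__ = [
    "COLUMNS",
    "DEFAULT_SEX_CHROMOSOMES",
    "parse_alignment_table",
    "read_chromosome_sizes",
    "filter_alignments",
    "chromosome_divergence",
    "size_divergence_regression",
]

#: Canonical record columns used throughout the pipeline.
COLUMNS = [
    "ref_chromosome",
    "query_chromosome",
    "ref_start",
    "ref_end",
    "alignment_length_bp",
    "percent_identity",
    "percent_similarity",
]

#: btab column indices (0-based) in the pinned show-coords -B dialect:
#: 0 query id, 5 reference id, 6-7 query start/end, 8-9 reference start/end,
#: 10 percent identity, 11 percent similarity, 12 alignment length.
_BTAB_MAP = {
    "query_chromosome": 0,
    "ref_chromosome": 5,
    "ref_start": 8,
    "ref_end": 9,
    "percent_identity": 10,
    "percent_similarity": 11,
    "alignment_length_bp": 12,
}

DEFAULT_SEX_CHROMOSOMES = ("chrX", "chrY", "X", "Y")


def _coerce_row(fields: list[str], dialect: str) -> dict:
    if dialect == "btab":
        if len(fields) < 13:
            raise ValueError("btab rows need at least 13 columns")
        raw = {k: fields[i] for k, i in _BTAB_MAP.items()}
    else:
        raw = dict(zip(COLUMNS, fields))
    rec = {
        "ref_chromosome": str(raw["ref_chromosome"]),
        "query_chromosome": str(raw["query_chromosome"]),
        "ref_start": int(raw["ref_start"]),
        "ref_end": int(raw["ref_end"]),
        "alignment_length_bp": int(raw["alignment_length_bp"]),
        "percent_identity": float(raw["percent_identity"]),
        "percent_similarity": float(raw["percent_similarity"]),
    }
    if rec["alignment_length_bp"] <= 0:
        raise ValueError("alignment length must be positive")
    for key in ("percent_identity", "percent_similarity"):
        if not (0.0 <= rec[key] <= 100.0):
            raise ValueError(f"{key} outside [0, 100]")
    # reference coordinates are 1-based inclusive; allow indel slack between
    # span and alignment length but reject grossly inconsistent rows
    span = abs(rec["ref_end"] - rec["ref_start"]) + 1
    if span > 3 * rec["alignment_length_bp"] or rec["alignment_length_bp"] > 3 * span:
        raise ValueError("reference span inconsistent with alignment length")
    return rec


def parse_alignment_table(path, dialect: str = "coords-tsv", on_malformed: str = "warn") -> pd.DataFrame:
    """Read an alignment coordinate table into canonical records.

    ``dialect`` is ``"coords-tsv"`` (headered TSV with the canonical column
    names) or ``"btab"`` (headerless show-coords -B layout).  Malformed
    rows are reported with their line numbers and either skipped with a
    warning (default) or raised (``on_malformed="raise"``).
    """
    if dialect not in ("btab", "coords-tsv"):
        raise ValueError(f"unknown alignment-table dialect {dialect!r}")
    if on_malformed not in ("warn", "raise"):
        raise ValueError("on_malformed must be 'warn' or 'raise'")
    records, problems = [], []
    with open(path) as fh:
        lines = fh.readlines()
    start = 0
    if dialect == "coords-tsv":
        if not lines:
            raise ValueError(f"{path}: empty alignment table")
        header = lines[0].rstrip("\n").split("\t")
        if header[: len(COLUMNS)] != COLUMNS:
            raise ValueError(
                f"{path}: coords-tsv header must start with columns {COLUMNS}"
            )
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        try:
            records.append(_coerce_row(line.split("\t"), dialect))
        except (ValueError, KeyError) as exc:
            problems.append(f"line {lineno}: {exc}")
    if not records and not problems:
        raise ValueError(f"{path}: empty alignment table")
    if problems:
        msg = f"{path}: rejected {len(problems)} malformed row(s): " + "; ".join(problems)
        if on_malformed == "raise":
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    return pd.DataFrame(records, columns=COLUMNS)


def read_chromosome_sizes(path) -> pd.Series:
    """Read a two-column ``name TAB size_bp`` table into a Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chromosome", "size_bp"], comment="#")
    if (df["size_bp"] <= 0).any():
        raise ValueError("chromosome sizes must be positive")
    return df.set_index("chromosome")["size_bp"]


def filter_alignments(
    records: pd.DataFrame,
    min_length_bp: int = 10_000,
    sex_chromosomes=DEFAULT_SEX_CHROMOSOMES,
) -> pd.DataFrame:
    """Keep autosomal alignments strictly longer than ``min_length_bp``.

    Sex chromosomes are removed by name on either side of the alignment
    (they experience a different mix of evolutionary forces than
    autosomes).  Idempotent.
    """
    if min_length_bp < 0:
        raise ValueError("minimum alignment length cannot be negative")
    sex = set(sex_chromosomes or ())
    keep = records["alignment_length_bp"] > min_length_bp
    if sex:
        keep &= ~records["ref_chromosome"].isin(sex)
        keep &= ~records["query_chromosome"].isin(sex)
    return records.loc[keep].reset_index(drop=True)


def chromosome_divergence(
    records: pd.DataFrame,
    chromosome_sizes: pd.Series | dict,
    by: str = "ref_chromosome",
) -> pd.DataFrame:
    """Length-weighted mean divergence per (reference) chromosome.

    ``weighted_mean_d = 1 - (sum length*similarity / sum length) / 100``.
    Chromosomes present in the size table but with no retained alignments
    are emitted with a missing d and a warning; overlap between alignments
    is not deduplicated but surfaces as ``total_aligned_bp > size_bp``
    (``overlap_flag``).
    """
    sizes = pd.Series(chromosome_sizes, name="size_bp")
    missing = set(records[by]) - set(sizes.index)
    if missing:
        raise ValueError(f"alignment records on chromosomes absent from the size table: {sorted(missing)}")
    rows = []
    grouped = dict(tuple(records.groupby(by)))
    for chrom, size in sizes.items():
        sub = grouped.get(chrom)
        if sub is None or sub.empty:
            warnings.warn(f"chromosome {chrom}: no retained alignments, divergence undefined", stacklevel=2)
            rows.append(
                {
                    "chromosome": chrom,
                    "size_bp": int(size),
                    "weighted_mean_d": np.nan,
                    "total_aligned_bp": 0,
                    "n_alignments": 0,
                    "overlap_flag": False,
                }
            )
            continue
        w = sub["alignment_length_bp"].to_numpy(dtype=float)
        sim = sub["percent_similarity"].to_numpy(dtype=float)
        total = int(w.sum())
        d = 1.0 - (w @ sim) / w.sum() / 100.0
        rows.append(
            {
                "chromosome": chrom,
                "size_bp": int(size),
                "weighted_mean_d": d,
                "total_aligned_bp": total,
                "n_alignments": int(len(sub)),
                "overlap_flag": total > size,
            }
        )
    return pd.DataFrame(rows)


def size_divergence_regression(per_chromosome: pd.DataFrame) -> RegressionResult:
    """OLS of weighted mean d on log10 chromosome size.

    A negative slope is the canonical pattern: smaller chromosomes, with
    higher per-bp recombination, diverge more.  Chromosomes with missing d
    are dropped; at least three are required.
    """
    df = per_chromosome.dropna(subset=["weighted_mean_d"])
    if len(df) < 3:
        raise ValueError("need at least three chromosomes with defined divergence")
    x = np.log10(df["size_bp"].to_numpy(dtype=float))
    y = df["weighted_mean_d"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        # statsmodels is degenerate on a constant response; R2 is zero by definition
        return RegressionResult(
            slope=0.0, intercept=float(y[0]), r_squared_adj=0.0, r_squared=0.0, p_value=1.0, n=len(df)
        )
    return variance_explained(x, y)
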