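"""GC content, GC homogeneity, the K diversity statistic, and statistical tests.

Percent scale (0-100) is used in every public return value; fractions are
internal only.  Species-level GC is the unweighted mean over distinct alleles
(copy counts are ignored), mirroring analysis of distinct variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alphabet import GAP_CHARS
from .io_seqstruct import SeqStructRecord, SpeciesMatrix
from .structure import StructurePartition


@dataclass
class GCReport:
    """Per-species GC summary over total / paired / unpaired columns."""

    species: str
    gc_total: float
    gc_paired: float
    gc_unpaired: float
    sd_paired: float
    sd_unpaired: float
    n_alleles: int


@dataclass
class DiversityStat:
    """Average number of pairwise nucleotide differences within a species."""

    species: str
    K: float


def _per_allele_gc(rec: SeqStructRecord, columns: Sequence[int]) -> float | None:
    """GC percent of one allele over selected columns, or None if no countable base."""
    bases = [rec.sequence[c] for c in columns if rec.sequence[c] not in GAP_CHARS]
    if not bases:
        return None
    gc = sum(b in "GC" for b in bases)
    return 100.0 * gc / len(bases)


def _gc_values(
    records: Sequence[SeqStructRecord], columns: Sequence[int] | None
) -> list[float]:
    if not records:
        raise ValueError("no records")
    if columns is None:
        columns = range(len(records[0]))
    columns = list(columns)
    if not columns:
        raise ValueError("empty column selection")
    vals = [_per_allele_gc(r, columns) for r in records]
    vals = [v for v in vals if v is not None]
    if not vals:
        raise ValueError("no countable bases in the selected columns")
    return vals


def gc_content(
    records: Sequence[SeqStructRecord], columns: Sequence[int] | None = None
) -> float:
    """Unweighted mean per-allele GC percent over the selected columns.

    Gaps and N are excluded from both numerator and denominator; alleles with
    no countable base in the selection are dropped (error if all are).
    """
    return float(np.mean(_gc_values(records, columns)))


def gc_homogeneity(
    records: Sequence[SeqStructRecord], columns: Sequence[int] | None = None
) -> float:
    """Sample standard deviation (n-1 denominator) of per-allele GC percents."""
    if len(records) < 2:
        raise ValueError("gc_homogeneity needs >= 2 records")
    return float(np.std(_gc_values(records, columns), ddof=1))


def avg_nucleotide_differences(records: Sequence[SeqStructRecord]) -> float:
    """K: mean pairwise count of differing, mutually gap-free positions.

    Positions where either allele has a gap or N are excluded per pair
    (pairwise deletion).  Alleles enter unweighted; copy counts are ignored.
    """
    if len(records) < 2:
        raise ValueError("K needs >= 2 records")
    total = 0
    npairs = 0
    for a, b in combinations(records, 2):
        diff = sum(
            1
            for x, y in zip(a.sequence, b.sequence)
            if x not in GAP_CHARS and y not in GAP_CHARS and x != y
        )
        total += diff
        npairs += 1
    return total / npairs


def spearman_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; two-sided p.

    The p-value uses the t approximation.  Constant input vectors have no
    defined rank correlation and raise ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def shapiro_wilk(x: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test; annotates GC distributions."""
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.all(x == x[0]):
        raise ValueError("Shapiro-Wilk undefined for constant data")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def base_frequency_profile(records: Sequence[SeqStructRecord]) -> pd.DataFrame:
    """Per-column relative frequencies of A, C, G, U plus gap fraction.

    A/C/G/U frequencies are normalized over non-gap bases (rows sum to 1
    wherever a column has any base); the ``gap`` column is the fraction of
    gap/N characters.  This table stands in for a sequence-logo rendering.
    """
    if not records:
        raise ValueError("no records")
    ncols = len(records[0])
    counts = np.zeros((ncols, 4))
    gaps = np.zeros(ncols)
    idx = {"A": 0, "C": 1, "G": 2, "U": 3}
    for rec in records:
        for c, b in enumerate(rec.sequence):
            if b in GAP_CHARS:
                gaps[c] += 1
            else:
                counts[c, idx[b]] += 1
    denom = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(denom > 0, counts / denom, 0.0)
    df = pd.DataFrame(freqs, columns=["A", "C", "G", "U"])
    df.insert(0, "column", np.arange(1, ncols + 1))
    df["gap"] = gaps / len(records)
    return df


def gc_report(matrix: SpeciesMatrix, partition: StructurePartition) -> GCReport:
    """Assemble the per-species GC summary over the structure partition."""
    paired_cols = [c for ij in partition.paired for c in ij]
    records = matrix.records
    n = len(records)
    return GCReport(
        species=matrix.species_name,
        gc_total=gc_content(records),
        gc_paired=gc_content(records, paired_cols),
        gc_unpaired=gc_content(records, partition.unpaired),
        sd_paired=gc_homogeneity(records, paired_cols) if n >= 2 else 0.0,
        sd_unpaired=gc_homogeneity(records, partition.unpaired) if n >= 2 else 0.0,
        n_alleles=n,
    )
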