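"""Cancer cell fraction estimation and clonality statistics.

The CCF of a variant is the fraction of tumor cells that carry it, corrected
for tumor purity, local total copy number and mutation multiplicity:

    ccf = vaf * (purity * CN_t + 2 * (1 - purity)) / (purity * m)

with integer multiplicity m obtained by rounding the purity/copy-number
corrected allele count and clamping to [1, CN_t]. Variants are classified
clonal (ccf >= 0.75), subclonal (ccf <= 0.5, inclusive by default; the
strict "< 0.5" convention used in some human analyses is available via
``subclonal_inclusive=False``) or intermediate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .variants import VariantCall

__all__ = [
    "CopyNumberSegment",
    "CCFVariant",
    "NeoantigenCandidate",
    "IthIndex",
    "CCFComparison",
    "compute_ccf",
    "classify_clonality",
    "stratified_burden",
    "ith_index",
    "ccf_density",
    "compare_ccf_distributions",
    "prioritize_neoantigens",
]

CLONAL_CCF_MIN = 0.75
SUBCLONAL_CCF_MAX = 0.5


@dataclass(frozen=True)
class CopyNumberSegment:
    """Allele-specific copy-number segment (half-open, 0-based coordinates)."""

    chrom: str
    start: int
    end: int
    total_cn: int
    minor_cn: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")
        if not 0 <= self.minor_cn <= self.total_cn:
            raise ValueError("require total_cn >= minor_cn >= 0")

    def covers(self, chrom: str, pos: int) -> bool:
        """Whether the segment covers the 1-based variant position."""
        return chrom == self.chrom and self.start <= pos - 1 < self.end


@dataclass(frozen=True)
class CCFVariant:
    variant: VariantCall
    multiplicity: int
    ccf: float
    ccf_raw: float
    clonality: str
    neoantigen: bool = False
    expressed: Optional[bool] = None


def classify_clonality(ccf: float, subclonal_inclusive: bool = True) -> str:
    """Partition CCF into clonal / intermediate / subclonal classes."""
    if ccf < 0:
        raise ValueError(f"ccf must be non-negative, got {ccf}")
    if ccf >= CLONAL_CCF_MIN:
        return "clonal"
    subclonal = ccf <= SUBCLONAL_CCF_MAX if subclonal_inclusive else ccf < SUBCLONAL_CCF_MAX
    return "subclonal" if subclonal else "intermediate"


def compute_ccf(
    variant: VariantCall,
    purity: float,
    segment: CopyNumberSegment,
    subclonal_inclusive: bool = True,
) -> CCFVariant:
    """Purity/copy-number corrected CCF of a single variant.

    The raw estimate is retained in ``ccf_raw``; ``ccf`` is capped at 1.0
    (binomial read noise routinely produces super-unity raw values for
    truly clonal variants).
    """
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if not segment.covers(variant.chrom, variant.pos):
        raise ValueError(f"variant {variant.key} not covered by segment {segment}")
    if variant.vaf is None:
        raise ValueError(f"variant {variant.key} has no VAF")
    denom_cn = purity * segment.total_cn + 2.0 * (1.0 - purity)
    mult = int(round(variant.vaf / purity * denom_cn))
    mult = min(max(mult, 1), segment.total_cn)
    ccf_raw = variant.vaf * denom_cn / (purity * mult)
    return CCFVariant(
        variant=variant,
        multiplicity=mult,
        ccf=min(ccf_raw, 1.0),
        ccf_raw=ccf_raw,
        clonality=classify_clonality(min(ccf_raw, 1.0), subclonal_inclusive),
        neoantigen=variant.neoantigen,
    )


def stratified_burden(
    ccf_variants: Iterable[CCFVariant],
    territory_mb: float,
    neoantigens_only: bool = False,
) -> dict[str, float]:
    """Clonal, subclonal and total mutations (or neoantigens) per Mb.

    Intermediate-CCF variants count toward the total but neither stratum.
    """
    if territory_mb <= 0:
        raise ValueError("territory_mb must be positive")
    counts = {"clonal": 0, "subclonal": 0, "total": 0}
    for cv in ccf_variants:
        if neoantigens_only and not cv.neoantigen:
            continue
        counts["total"] += 1
        if cv.clonality in ("clonal", "subclonal"):
            counts[cv.clonality] += 1
    return {k: n / territory_mb for k, n in counts.items()}


@dataclass(frozen=True)
class IthIndex:
    """Subclonal-to-clonal neoantigen ratio; undefined when no clonal
    neoantigens are present (flagged, not infinite)."""

    value: float
    n_subclonal: int
    n_clonal: int
    defined: bool


def ith_index(neoantigen_ccf_variants: Iterable[CCFVariant]) -> IthIndex:
    n_sub = n_clonal = 0
    for cv in neoantigen_ccf_variants:
        if cv.clonality == "subclonal":
            n_sub += 1
        elif cv.clonality == "clonal":
            n_clonal += 1
    if n_clonal == 0:
        return IthIndex(math.nan, n_sub, 0, defined=False)
    return IthIndex(n_sub / n_clonal, n_sub, n_clonal, defined=True)


def ccf_density(
    ccfs: Sequence[float],
    bandwidth: Optional[float] = None,
    gridsize: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density estimate of a CCF distribution on [0, 1].

    ``bandwidth`` is the KDE bandwidth factor (Scott's rule when None).
    """
    ccfs = np.asarray(ccfs, dtype=float)
    if ccfs.size < 2:
        raise ValueError("need at least two CCF values for a density estimate")
    kde = stats.gaussian_kde(ccfs, bw_method=bandwidth)
    grid = np.linspace(0.0, 1.0, gridsize)
    return grid, kde(grid)


@dataclass(frozen=True)
class CCFComparison:
    statistic: float
    pvalue: float
    median_a: float
    median_b: float


def compare_ccf_distributions(
    a: Sequence[float], b: Sequence[float]
) -> CCFComparison:
    """Two-sided Kolmogorov-Smirnov comparison of two CCF samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both CCF samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided")
    return CCFComparison(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
    )


@dataclass(frozen=True)
class NeoantigenCandidate:
    peptide: str
    affinity_nm: float
    allele: Optional[str] = None


def prioritize_neoantigens(
    per_snv_candidates: Mapping[str, Sequence[NeoantigenCandidate]],
    affinity_max_nm: float = 500.0,
) -> dict[str, NeoantigenCandidate]:
    """One neoantigen per SNV: candidates with predicted binding affinity
    above ``affinity_max_nm`` (default 500 nM) are discarded, then the
    strongest binder (lowest nM) is kept, ties broken by lexicographic
    peptide."""
    chosen: dict[str, NeoantigenCandidate] = {}
    for snv, candidates in per_snv_candidates.items():
        eligible = [c for c in candidates if c.affinity_nm <= affinity_max_nm]
        if eligible:
            chosen[snv] = min(eligible, key=lambda c: (c.affinity_nm, c.peptide))
    return chosen
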