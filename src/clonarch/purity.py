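"""Coverage- and edit-fraction-based tumor purity estimators.

Three estimators for engineered mouse tumors:

* ``purity_from_floxed_coverage`` -- in models where Cre excises a floxed
  allele in every tumor cell, sequencing coverage over the floxed exons drops
  in proportion to purity. With R = median(flanking depth) / median(floxed
  depth) computed in the tumor and in matched normals, complete biallelic
  recombination in tumor cells gives floxed coverage proportional to
  (1 - purity), hence purity = 1 - R_normal / R_tumor.
* ``knockout_efficiency`` -- same coverage-ratio logic for a conditional
  knockout exon, with the observed dropout adjusted by tumor purity.
* ``purity_from_edit_fraction`` -- at a CRISPR cut site whose disruption is
  prerequisite for tumorigenesis, every tumor cell carries non-wild-type
  alleles, so the non-reference read fraction estimates purity directly.

Medians, not means, are used at every aggregation step.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "ExonCoverage",
    "FloxPurityResult",
    "purity_from_floxed_coverage",
    "knockout_efficiency",
    "purity_from_edit_fraction",
]


@dataclass(frozen=True)
class ExonCoverage:
    """Median sequencing depth over one exon in one sample."""

    sample_id: str
    exon_id: str
    gene: str
    region_class: str  # "floxed" | "flanking" | "target_exon"
    median_depth: float
    chrom: Optional[str] = None
    start: Optional[int] = None  # 0-based half-open, for BED serialization
    end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.median_depth < 0:
            raise ValueError("depth must be non-negative")


@dataclass(frozen=True)
class FloxPurityResult:
    purity: float
    ratio_tumor: float
    ratio_normal: float
    complete_dropout: bool


def _class_median(exons: Iterable[ExonCoverage], region_class: str) -> float:
    depths = [e.median_depth for e in exons if e.region_class == region_class]
    if not depths:
        raise ValueError(f"no exons of class {region_class!r}")
    return float(median(depths))


def purity_from_floxed_coverage(
    tumor: Sequence[ExonCoverage],
    normals: Sequence[Sequence[ExonCoverage]],
    floxed_class: str = "floxed",
    flanking_class: str = "flanking",
) -> FloxPurityResult:
    """Tumor purity from coverage dropout over Cre-excised (floxed) exons.

    R_t = median(flanking)/median(floxed) in the tumor; R_n is the median of
    the same ratio across matched normals. Assuming complete recombination
    in all tumor cells and none in normal cells, purity = 1 - R_n / R_t,
    clipped to [0, 1]. Zero floxed coverage in the tumor is reported as
    purity 1.0 with a complete-dropout flag.
    """
    if not normals:
        raise ValueError("at least one normal sample is required")
    flank_t = _class_median(tumor, flanking_class)
    flox_t = _class_median(tumor, floxed_class)
    ratio_n = float(
        median(
            _class_median(n, flanking_class) / _class_median(n, floxed_class)
            for n in normals
        )
    )
    if flox_t == 0:
        return FloxPurityResult(1.0, float("inf"), ratio_n, complete_dropout=True)
    ratio_t = flank_t / flox_t
    purity = float(np.clip(1.0 - ratio_n / ratio_t, 0.0, 1.0))
    return FloxPurityResult(purity, ratio_t, ratio_n, complete_dropout=False)


def knockout_efficiency(
    tumor: Sequence[ExonCoverage],
    normals: Sequence[Sequence[ExonCoverage]],
    purity: float,
    target_class: str = "floxed",
    surrounding_class: str = "flanking",
) -> float:
    """Fraction of tumor cells with the conditional exon excised.

    rho is the tumor's target/surrounding coverage ratio normalized by the
    median of the same ratio in normals; with coverage at the target exon
    proportional to 1 - purity * efficiency, the efficiency estimate is
    (1 - rho) / purity, clipped to [0, 1].
    """
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if not normals:
        raise ValueError("at least one normal sample is required")
    ratio_t = _class_median(tumor, target_class) / _class_median(tumor, surrounding_class)
    ratio_n = float(
        median(
            _class_median(n, target_class) / _class_median(n, surrounding_class)
            for n in normals
        )
    )
    rho = ratio_t / ratio_n
    return float(np.clip((1.0 - rho) / purity, 0.0, 1.0))


def purity_from_edit_fraction(non_wt_count: int, total_count: int) -> float:
    """Purity as the non-wild-type allele fraction at an sgRNA cut site.

    Assumes every tumor cell carries biallelic loss-of-function edits at the
    locus (disruption is prerequisite for tumorigenesis), so the non-reference
    read fraction equals the tumor-cell fraction.
    """
    if total_count <= 0:
        raise ValueError("no coverage at the cut site")
    if not 0 <= non_wt_count <= total_count:
        raise ValueError("non_wt_count outside [0, total_count]")
    return non_wt_count / total_count
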