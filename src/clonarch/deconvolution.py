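"""Clone deconvolution from targeted deep amplicon sequencing.

Mixed tumors seeded from a defined set of clones are deconvolved using
clone-private SNVs as genetic barcodes. Per-target background PCR/sequencing
error is estimated from truly clonal control samples and subtracted; tumor
purity is estimated from SNVs common to all clones; and the fraction of each
clone is

    fraction = median(private alt frequencies - background, floored at 0)
               * ploidy / purity

(for the tetraploid lines of the original design each private SNV is at
1/(4n), hence the factor 4). Clone diversity is summarized by the
Gini-Simpson index D = 1 - sum(p_i^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .ccf import CopyNumberSegment
from .variants import PileupRead, VariantCall

__all__ = [
    "COMMON",
    "AmpliconTarget",
    "AmpliconPanel",
    "AmpliconPileup",
    "CloneEstimate",
    "PurityEstimate",
    "select_private_snvs",
    "qc_exclude_targets",
    "estimate_background",
    "estimate_purity_common",
    "estimate_clone_fractions",
    "simpson_diversity",
]

#: Owning-clone sentinel for SNVs shared by every clone.
COMMON = "COMMON"


@dataclass(frozen=True)
class AmpliconTarget:
    target_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    clone: str  # owning clone id, or COMMON


@dataclass(frozen=True)
class AmpliconPanel:
    """Clone-defining SNV targets: private SNVs (one owning clone each) plus
    common SNVs present in all clones."""

    targets: tuple[AmpliconTarget, ...]
    clones: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(self.targets))
        object.__setattr__(self, "clones", tuple(self.clones))
        known = set(self.clones) | {COMMON}
        for t in self.targets:
            if t.clone not in known:
                raise ValueError(f"target {t.target_id} references unknown clone {t.clone!r}")

    @property
    def private_targets(self) -> tuple[AmpliconTarget, ...]:
        return tuple(t for t in self.targets if t.clone != COMMON)

    @property
    def common_targets(self) -> tuple[AmpliconTarget, ...]:
        return tuple(t for t in self.targets if t.clone == COMMON)

    def targets_for(self, clone: str) -> tuple[AmpliconTarget, ...]:
        return tuple(t for t in self.targets if t.clone == clone)

    def without(self, target_ids: Iterable[str]) -> "AmpliconPanel":
        drop = set(target_ids)
        return AmpliconPanel(
            targets=tuple(t for t in self.targets if t.target_id not in drop),
            clones=self.clones,
        )


@dataclass(frozen=True)
class AmpliconPileup:
    """Base counts at one target in one sample (from a min-BQ filtered pileup)."""

    sample_id: str
    target_id: str
    ref_count: int
    alt_count: int
    other_alt_count: int = 0
    min_bq: int = 30

    def __post_init__(self) -> None:
        if min(self.ref_count, self.alt_count, self.other_alt_count) < 0:
            raise ValueError("pileup counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count + self.other_alt_count

    @property
    def alt_fraction(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0


@dataclass(frozen=True)
class PurityEstimate:
    value: float  # clipped to (0, 1]
    raw: float


@dataclass(frozen=True)
class CloneEstimate:
    sample_id: str
    fractions: Mapping[str, float]  # raw, not renormalized
    percentages: Mapping[str, float]
    present: Mapping[str, bool]
    purity_estimate: Optional[PurityEstimate]
    simpson_d: float
    excluded_targets: tuple[tuple[str, str], ...] = ()
    undefined_clones: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Panel construction
# ---------------------------------------------------------------------------


def select_private_snvs(
    clone_call_sets: Mapping[str, Sequence[VariantCall]],
    other_sample_pileups: Mapping[str, Mapping[tuple[str, int, str, str], Sequence[PileupRead]]],
    segments: Sequence[CopyNumberSegment],
    neutral_total_cn: int = 4,
    bq_min: int = 20,
    mq_min: int = 30,
) -> list[AmpliconTarget]:
    """Candidate clone-private SNVs for an amplicon panel.

    A candidate must be called in exactly one clone, lie in a copy-number
    neutral segment (``total_cn == neutral_total_cn``), and show complete
    absence of qualifying alternative reads (base quality > bq_min, mapping
    quality > mq_min, exclusive thresholds) in every other sample's pileup.
    Clones without candidates are reported via a warning, not an error.
    """
    calls_by_key: dict[tuple, set[str]] = {}
    variant_by_key: dict[tuple, VariantCall] = {}
    for clone, calls in clone_call_sets.items():
        for v in calls:
            if v.variant_class != "SNV":
                continue
            calls_by_key.setdefault(v.key, set()).add(clone)
            variant_by_key.setdefault(v.key, v)

    def cn_neutral(v: VariantCall) -> bool:
        return any(
            s.covers(v.chrom, v.pos) and s.total_cn == neutral_total_cn for s in segments
        )

    candidates = []
    per_clone_counts: dict[str, int] = {c: 0 for c in clone_call_sets}
    for key, owners in sorted(calls_by_key.items()):
        if len(owners) != 1:
            continue
        (owner,) = owners
        v = variant_by_key[key]
        if not cn_neutral(v):
            continue
        contaminated = False
        for sample, pileups in other_sample_pileups.items():
            if sample == owner:
                continue
            for read in pileups.get(key, ()):
                if (
                    read.base == v.alt
                    and read.base_quality > bq_min
                    and read.mapping_quality > mq_min
                ):
                    contaminated = True
                    break
            if contaminated:
                break
        if contaminated:
            continue
        per_clone_counts[owner] += 1
        candidates.append(
            AmpliconTarget(
                target_id=f"{owner}_{per_clone_counts[owner]}",
                chrom=v.chrom,
                pos=v.pos,
                ref=v.ref,
                alt=v.alt,
                clone=owner,
            )
        )
    for clone, n in per_clone_counts.items():
        if n == 0:
            warnings.warn(f"no private-SNV candidates found for clone {clone}")
    return candidates


def qc_exclude_targets(
    panel: AmpliconPanel,
    equal_mix_control_pileups: Mapping[str, AmpliconPileup],
) -> tuple[AmpliconPanel, list[tuple[str, str]]]:
    """Exclude targets not cleanly supported in the equal-mixture control.

    In a control containing all clones in equal proportion every target must
    be supported by more alt reads than reads carrying any other alternative
    allele; failing targets are excluded (with the observed counts logged in
    the reason), mirroring the handling of a noisy target.
    """
    exclusions: list[tuple[str, str]] = []
    for t in panel.targets:
        pile = equal_mix_control_pileups.get(t.target_id)
        if pile is None:
            raise ValueError(f"equal-mixture control pileup missing for target {t.target_id}")
        if pile.alt_count <= pile.other_alt_count:
            exclusions.append(
                (t.target_id, f"alt {pile.alt_count} <= other-alt {pile.other_alt_count} in control")
            )
    return panel.without(t for t, _ in exclusions), exclusions


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------


def estimate_background(
    panel: AmpliconPanel,
    clonal_control_samples: Mapping[str, tuple[str, Mapping[str, AmpliconPileup]]],
) -> dict[str, float]:
    """Per-target background error from truly clonal control samples.

    ``clonal_control_samples`` maps sample id to (dominant clone, pileups by
    target id). For each private target the background is the median alt
    frequency across controls whose dominant clone is not the target's owner
    (in such samples any alt signal is PCR/sequencing error). Targets with
    no eligible control get background 0 with a warning; common targets get 0.
    """
    backgrounds: dict[str, float] = {}
    for t in panel.targets:
        if t.clone == COMMON:
            backgrounds[t.target_id] = 0.0
            continue
        freqs = [
            pileups[t.target_id].alt_fraction
            for _, (dominant, pileups) in sorted(clonal_control_samples.items())
            if dominant != t.clone and t.target_id in pileups
        ]
        if not freqs:
            warnings.warn(f"no clonal controls of other clones for target {t.target_id}; background 0")
            backgrounds[t.target_id] = 0.0
        else:
            backgrounds[t.target_id] = float(median(freqs))
    return backgrounds


def estimate_purity_common(
    sample_pileups: Mapping[str, AmpliconPileup],
    panel: AmpliconPanel,
    expected_fraction: float = 0.25,
) -> PurityEstimate:
    """Tumor purity from common SNVs: median observed/expected alt fraction.

    ``expected_fraction`` is the alt fraction of a fully clonal single-copy
    SNV in a pure sample, 1/ploidy (0.25 for tetraploid lines).
    """
    ratios = [
        sample_pileups[t.target_id].alt_fraction / expected_fraction
        for t in panel.common_targets
        if t.target_id in sample_pileups and sample_pileups[t.target_id].depth > 0
    ]
    if not ratios:
        raise ValueError("no covered common targets; cannot estimate purity")
    raw = float(median(ratios))
    return PurityEstimate(value=float(np.clip(raw, np.finfo(float).tiny, 1.0)), raw=raw)


def estimate_clone_fractions(
    sample_pileups: Mapping[str, AmpliconPileup],
    panel: AmpliconPanel,
    backgrounds: Mapping[str, float],
    purity: float,
    ploidy: int = 4,
    detection_threshold: float = 0.01,
    normalize: bool = False,
) -> CloneEstimate:
    """Per-clone fractions in one sample from private-SNV alt frequencies.

    For each clone the fraction is the median over its private targets of the
    background-subtracted alt frequency (floored at 0), times ploidy, divided
    by purity. Fractions are reported raw (their sum is free to deviate from
    1, making estimator bias visible); optional renormalization to sum 1 is
    off by default. Clones at or above ``detection_threshold`` (default 1%)
    are flagged present; the Simpson index is computed over detected clones
    renormalized to sum 1.
    """
    if purity <= 0:
        raise ValueError("purity must be positive")
    sample_ids = {p.sample_id for p in sample_pileups.values()}
    sample_id = sample_ids.pop() if len(sample_ids) == 1 else "?"
    fractions: dict[str, float] = {}
    undefined: list[str] = []
    for clone in panel.clones:
        freqs = []
        for t in panel.targets_for(clone):
            pile = sample_pileups.get(t.target_id)
            if pile is None or pile.depth == 0:
                continue
            adj = max(pile.alt_fraction - backgrounds.get(t.target_id, 0.0), 0.0)
            freqs.append(adj)
        if not freqs:
            undefined.append(clone)
            fractions[clone] = float("nan")
        else:
            fractions[clone] = float(median(freqs)) * ploidy / purity
    if normalize:
        total = sum(f for f in fractions.values() if np.isfinite(f))
        if total > 0:
            fractions = {
                c: (f / total if np.isfinite(f) else f) for c, f in fractions.items()
            }
    present = {
        c: bool(np.isfinite(f) and f >= detection_threshold) for c, f in fractions.items()
    }
    detected = [fractions[c] for c in panel.clones if present[c]]
    simpson = simpson_diversity(detected) if detected else 0.0
    return CloneEstimate(
        sample_id=sample_id,
        fractions=fractions,
        percentages={c: f * 100.0 for c, f in fractions.items()},
        present=present,
        purity_estimate=None,
        simpson_d=simpson,
        undefined_clones=tuple(undefined),
    )


def simpson_diversity(proportions: Sequence[float]) -> float:
    """Gini-Simpson diversity D = 1 - sum(p_i^2) over renormalized proportions.

    0 for a monoclonal sample; 1 - 1/k for an equal k-clone mixture.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    total = p.sum()
    if total == 0:
        raise ValueError("all proportions are zero")
    p = p / total
    return float(1.0 - np.sum(p**2))
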