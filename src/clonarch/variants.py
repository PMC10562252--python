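"""Somatic variant integration, filtering and summary statistics.

This module integrates call sets from several somatic callers into a single
consensus set, applies cohort-level germline-leakage filters (dbSNP positions,
recurrence across animals and across tumors of one animal), annotates
microsatellite context around each variant, and computes burden and spectrum
summaries (mutations per Mb, indel size spectrum, 96-channel substitution
spectrum).

Coordinates are 1-based inclusive for variants (VCF convention).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "VariantCall",
    "MicrosatelliteAnnotation",
    "MutationSpectrum",
    "PileupRead",
    "ExpressedCheck",
    "SPECTRUM_CHANNELS",
    "merge_caller_calls",
    "apply_cohort_filters",
    "annotate_microsatellites",
    "find_microsatellite",
    "burden_per_mb",
    "indel_size_spectrum",
    "expressed_variant_check",
    "build_96_spectrum",
]

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: COSMIC-style channel labels, e.g. "A[C>A]A", ordered by substitution,
#: then 5' base, then 3' base.
SPECTRUM_CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_TYPES
    for five in _BASES
    for three in _BASES
)

_CHANNEL_INDEX = {label: i for i, label in enumerate(SPECTRUM_CHANNELS)}


@dataclass(frozen=True)
class MicrosatelliteAnnotation:
    """Tandem repeat overlapping a variant locus.

    ``motif`` is the repeat unit as observed at the start of the repeat
    region; ``repeat_count`` is the number of (possibly imperfect) unit
    copies; ``score`` is the repeat score under the scoring scheme of
    :func:`find_microsatellite`.
    """

    motif: str
    repeat_count: int
    score: int
    region_start: int  # window coordinate, 0-based
    region_length: int


@dataclass(frozen=True)
class VariantCall:
    """One somatic SNV or indel with caller provenance and read support."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    sample_id: str
    animal_id: Optional[str] = None
    alt_depth: Optional[int] = None
    total_depth: Optional[int] = None
    vaf: Optional[float] = None
    callers: frozenset[str] = frozenset()
    in_dbsnp: bool = False
    microsatellite: Optional[MicrosatelliteAnnotation] = None
    neoantigen: bool = False
    variant_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.alt_depth is not None and self.total_depth is not None:
            if not 0 <= self.alt_depth <= self.total_depth:
                raise ValueError(
                    f"alt_depth {self.alt_depth} outside [0, {self.total_depth}]"
                )
            if self.total_depth > 0:
                implied = self.alt_depth / self.total_depth
                if self.vaf is None:
                    object.__setattr__(self, "vaf", implied)
                elif abs(self.vaf - implied) >= 1e-6:
                    raise ValueError(
                        f"vaf {self.vaf} inconsistent with AD/DP {implied:.6f}"
                    )
        if not isinstance(self.callers, frozenset):
            object.__setattr__(self, "callers", frozenset(self.callers))

    @property
    def variant_class(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "SNV"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def is_indel(self) -> bool:
        return self.variant_class != "SNV"

    @property
    def indel_size(self) -> int:
        """Signed indel size (insertions positive, deletions negative); 0 for SNVs."""
        return len(self.alt) - len(self.ref)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


# ---------------------------------------------------------------------------
# Consensus merging and cohort filters
# ---------------------------------------------------------------------------


def merge_caller_calls(
    per_caller_sets: Mapping[str, Iterable[VariantCall]],
    anchor_caller: str = "mutect2",
) -> list[VariantCall]:
    """Integrate per-caller call sets into a consensus set.

    SNVs are retained iff called by the anchor caller and at least one other
    caller; indels are retained iff called by at least two callers (the
    anchor is not required). No VAF filter is applied. The output records
    the union of callers supporting each variant.
    """
    if anchor_caller not in per_caller_sets:
        raise ValueError(
            f"anchor caller {anchor_caller!r} absent from input map "
            f"(callers: {sorted(per_caller_sets)})"
        )
    grouped: dict[tuple, dict[str, VariantCall]] = defaultdict(dict)
    for caller in sorted(per_caller_sets):
        for v in per_caller_sets[caller]:
            grouped[(v.sample_id,) + v.key][caller] = v
    out = []
    for gkey in sorted(grouped):
        by_caller = grouped[gkey]
        callers = frozenset(by_caller)
        rep = by_caller.get(anchor_caller, by_caller[min(by_caller)])
        if rep.variant_class == "SNV":
            keep = anchor_caller in callers and len(callers) >= 2
        else:
            keep = len(callers) >= 2
        if keep:
            out.append(replace(rep, callers=callers))
    return out


def apply_cohort_filters(
    variants: Iterable[VariantCall],
    dbsnp_positions: set[tuple[str, int]] = frozenset(),
) -> list[VariantCall]:
    """Apply dbSNP-position and cross-tumor recurrence filters.

    Removes variants at known dbSNP positions, variants observed in tumors of
    two or more animals, and variants observed in at least 50% (inclusive) of
    tumors from the same animal.  The per-animal tumor census is taken from
    the input table itself, and the per-animal recurrence filter is skipped
    for animals contributing a single tumor (it targets germline leakage,
    which is undetectable with one tumor).  The result is independent of
    the order in which the filters are stated, and idempotent.
    """
    variants = list(variants)
    for v in variants:
        if v.animal_id is None:
            raise ValueError(f"variant {v.key} missing animal_id annotation")

    samples_per_animal: dict[str, set[str]] = defaultdict(set)
    for v in variants:
        samples_per_animal[v.animal_id].add(v.sample_id)

    animals_with_key: dict[tuple, set[str]] = defaultdict(set)
    samples_with_key: dict[tuple[tuple, str], set[str]] = defaultdict(set)
    for v in variants:
        animals_with_key[v.key].add(v.animal_id)
        samples_with_key[(v.key, v.animal_id)].add(v.sample_id)

    out = []
    for v in variants:
        if (v.chrom, v.pos) in dbsnp_positions or v.in_dbsnp:
            continue
        if len(animals_with_key[v.key]) >= 2:
            continue
        n_tumors = len(samples_per_animal[v.animal_id])
        if n_tumors >= 2:
            n_hit = len(samples_with_key[(v.key, v.animal_id)])
            if n_hit / n_tumors >= 0.5:
                continue
        out.append(v)
    return out


# ---------------------------------------------------------------------------
# Microsatellite annotation
# ---------------------------------------------------------------------------
#
# A repeat of motif length m covering window interval [a, b) (b - a >= 2m) is
# scored against the period-m self-alignment: position x in [a+m, b) matches
# when window[x] == window[x-m].  The score is
#
#     score = m + sum over x in [a+m, b) of (+1 if match else -penalty)
#
# so a perfect repeat of length L scores L.  A repeat is annotated when it
# overlaps the variant span and (i) score >= min_score, (ii) it contains a
# perfect stretch (seed) of at least seed_length nt, and (iii) it comprises
# at least min_repeats unit copies (floor((b-a)/m)).


def _weights(window: str, m: int, penalty: int) -> list[int]:
    return [
        1 if window[x] == window[x - m] and window[x] in _BASES else -penalty
        for x in range(m, len(window))
    ]


def find_microsatellite(
    window: str,
    span_start: int,
    span_end: int,
    *,
    min_score: int = 8,
    seed_length: int = 8,
    min_repeats: int = 2,
    mismatch_penalty: int = 1,
    max_motif: int = 6,
) -> Optional[MicrosatelliteAnnotation]:
    """Best-scoring tandem repeat (motif length 1..max_motif) overlapping
    ``[span_start, span_end)`` in ``window``, or None.

    Ties are broken by higher score, then shorter motif, then longer region,
    then leftmost start. The search is a seed-and-extend over maximal perfect
    runs, which is exact for this scoring scheme: any scoring interval can be
    extended over the full perfect run it contains without losing score.
    """
    window = window.upper()
    n = len(window)
    best = None  # (score, length, -m, -i) maximized
    for m in range(1, max_motif + 1):
        if n < 2 * m:
            continue
        w = _weights(window, m, mismatch_penalty)
        nw = len(w)
        seed_run = max(1, seed_length - m)
        # prefix sums P[t] = sum(w[:t])
        P = np.concatenate([[0], np.cumsum(w)])
        # suffix argmax of P over j in [t, nw]
        suff_best_j = np.empty(nw + 1, dtype=int)
        bj = nw
        for t in range(nw, -1, -1):
            if P[t] > P[bj]:  # strict: keep the largest maximizing j (longest region)
                bj = t
            suff_best_j[t] = bj
        # maximal runs of matches (w == 1)
        runs = []
        t = 0
        while t < nw:
            if w[t] == 1:
                s = t
                while t < nw and w[t] == 1:
                    t += 1
                if t - s >= seed_run:
                    runs.append((s, t))
            else:
                t += 1
        for rs, re in runs:
            i_max = min(rs, span_end - 1)
            if i_max < 0:
                continue
            j_floor = max(re, span_start - m + 1)
            for i in range(0, i_max + 1):
                jlo = max(j_floor, i + (min_repeats - 1) * m)
                if jlo > nw:
                    continue
                j = int(suff_best_j[jlo])
                score = m + int(P[j] - P[i])
                if score < min_score:
                    continue
                length = j + m - i
                cand = (score, -m, length, -i)
                if best is None or cand > best[0]:
                    best = (cand, i, j, m)
    if best is None:
        return None
    _, i, j, m = best
    return MicrosatelliteAnnotation(
        motif=window[i : i + m],
        repeat_count=(j + m - i) // m,
        score=m + int(np.sum(_weights(window, m, mismatch_penalty)[i:j])),
        region_start=i,
        region_length=j + m - i,
    )


def annotate_microsatellites(
    variants: Iterable[VariantCall],
    reference: Mapping[str, str],
    flank: int = 30,
    **scan_kwargs,
) -> list[VariantCall]:
    """Annotate each variant with the best tandem repeat overlapping its locus.

    ``reference`` maps chromosome name to sequence. A flank of at least 20 nt
    on each side of the variant span must be available.
    """
    out = []
    for v in variants:
        seq = reference[v.chrom]
        start0 = v.pos - 1
        span_len = len(v.ref)
        lo = start0 - flank
        hi = start0 + span_len + flank
        if lo < 0 or hi > len(seq) or flank < 20:
            raise ValueError(
                f"insufficient reference flank for {v.key} (need >= 20 nt each side)"
            )
        ann = find_microsatellite(seq[lo:hi], flank, flank + span_len, **scan_kwargs)
        out.append(replace(v, microsatellite=ann))
    return out


# ---------------------------------------------------------------------------
# Burden and spectra
# ---------------------------------------------------------------------------


def burden_per_mb(
    variants: Iterable[VariantCall],
    territory_mb: float,
    classes: Optional[Sequence[str]] = None,
) -> float:
    """Mutations per Mb of captured territory, optionally restricted to
    variant classes ("SNV", "insertion", "deletion", or "indel")."""
    if territory_mb <= 0:
        raise ValueError("territory_mb must be positive")
    if classes is not None:
        wanted = set(classes)
        if "indel" in wanted:
            wanted |= {"insertion", "deletion"}
        n = sum(1 for v in variants if v.variant_class in wanted)
    else:
        n = sum(1 for _ in variants)
    return n / territory_mb


def indel_size_spectrum(variants: Iterable[VariantCall], clip: int = 10):
    """Indel size counts on -clip..+clip nt (deletions negative).

    Sizes beyond the range are clipped into the terminal bins so the bin sum
    equals the number of indels. SNVs are ignored. Returns a pandas Series.
    """
    import pandas as pd

    index = list(range(-clip, clip + 1))
    counts = pd.Series(0, index=index, dtype=int)
    for v in variants:
        size = v.indel_size
        if size == 0:
            continue
        counts[int(np.clip(size, -clip, clip))] += 1
    return counts


@dataclass(frozen=True)
class PileupRead:
    """One read observation at a locus, as extracted from an alignment pileup."""

    base: str
    mapping_quality: int
    base_quality: int
    is_duplicate: bool = False


@dataclass(frozen=True)
class ExpressedCheck:
    alt_depth: int
    total_depth: int
    vaf: Optional[float]
    no_coverage: bool


def expressed_variant_check(
    variant: VariantCall,
    rna_pileup: Sequence[PileupRead],
    mq_min: int = 255,
    bq_min: int = 20,
) -> ExpressedCheck:
    """Expressed VAF of a variant from an RNA pileup.

    Only non-duplicate reads with mapping quality >= ``mq_min`` (default 255,
    the STAR unique-mapper convention) and base quality >= ``bq_min`` are
    counted. If no read passes, the site is flagged ``no_coverage`` rather
    than reported as VAF 0.
    """
    passing = [
        r
        for r in rna_pileup
        if not r.is_duplicate and r.mapping_quality >= mq_min and r.base_quality >= bq_min
    ]
    if not passing:
        return ExpressedCheck(0, 0, None, no_coverage=True)
    alt = sum(1 for r in passing if r.base == variant.alt)
    return ExpressedCheck(alt, len(passing), alt / len(passing), no_coverage=False)


@dataclass
class MutationSpectrum:
    """96-channel trinucleotide substitution spectrum (pyrimidine convention)."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros(96, dtype=float))
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have 96 channels")
        if np.any(self.counts < 0):
            raise ValueError("spectrum counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def as_series(self):
        import pandas as pd

        return pd.Series(self.counts, index=list(SPECTRUM_CHANNELS))

    def __getitem__(self, channel: str) -> float:
        return float(self.counts[_CHANNEL_INDEX[channel]])


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def build_96_spectrum(
    snvs: Iterable[VariantCall],
    reference: Mapping[str, str] | Callable[[str, int], str],
) -> MutationSpectrum:
    """Classify SNVs by substitution and flanking 5'/3' bases.

    ``reference`` is either a chrom -> sequence mapping or a callable
    ``(chrom, pos) -> trinucleotide`` returning the reference 3-mer centered
    on the (1-based) position. Purine-reference substitutions are
    reverse-complemented into the pyrimidine convention. Variants with an
    ambiguous (non-ACGT) context are skipped and counted in ``n_skipped``.
    """
    spectrum = MutationSpectrum()
    for v in snvs:
        if v.variant_class != "SNV":
            continue
        if callable(reference):
            tri = reference(v.chrom, v.pos).upper()
        else:
            seq = reference[v.chrom]
            tri = seq[v.pos - 2 : v.pos + 1].upper()
        if len(tri) != 3 or any(b not in _BASES for b in tri):
            spectrum.n_skipped += 1
            continue
        ref, alt = v.ref.upper(), v.alt.upper()
        if tri[1] != ref:
            spectrum.n_skipped += 1
            continue
        if ref in "AG":
            tri = _revcomp(tri)
            ref = _revcomp(ref)
            alt = _revcomp(alt)
        label = f"{tri[0]}[{ref}>{alt}]{tri[2]}"
        idx = _CHANNEL_INDEX.get(label)
        if idx is None:
            spectrum.n_skipped += 1
            continue
        spectrum.counts[idx] += 1
    return spectrum
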