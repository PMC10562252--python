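"""Synthetic tumor generator.

Generates ground-truth tumors and the observations every downstream stage
consumes: a star-with-trunk clone tree with truncal and clone-private
mutations, neutral subclonal frequency spectra drawn by inverse transform
from the cumulative model M(f) = mu/beta (1/f - 1/f_max), binomial read
sampling at stated coverage/purity/copy number, targeted-amplicon counts
with additive background error, floxed-allele coverage dropout proportional
to purity, per-caller call sets with configurable sensitivity and false
positives, and immunoediting as CCF-dependent depletion of
neoantigen-bearing variants.

All randomness flows through explicit integer seeds; there is no global RNG
state, and every observable is reproducible bit-for-bit from (parameters,
seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .deconvolution import COMMON, AmpliconPanel, AmpliconPileup, AmpliconTarget
from .purity import ExonCoverage
from .signatures import SignatureSet
from .variants import _BASES, SPECTRUM_CHANNELS, MutationSpectrum, VariantCall

__all__ = [
    "SyntheticTruth",
    "VariantTruth",
    "SimulatedReadObservation",
    "simulate_clone_tree",
    "simulate_neutral_vafs",
    "neutral_vaf_cdf",
    "expected_vaf",
    "simulate_reads",
    "single_clone_truth",
    "equal_mix_truth",
    "panel_from_truth",
    "simulate_amplicon_counts",
    "simulate_coverage_track",
    "simulate_reference",
    "make_variant_calls",
    "simulate_caller_outputs",
    "apply_immunoediting",
    "make_signature_set",
    "simulate_spectrum_from_signatures",
]


@dataclass(frozen=True)
class VariantTruth:
    """Ground truth for one simulated variant."""

    variant_id: str
    clones: frozenset[str]
    ccf: float
    multiplicity: int = 1
    neoantigen: bool = False


@dataclass(frozen=True)
class SyntheticTruth:
    """Full ground-truth record for one simulated tumor."""

    clone_ids: tuple[str, ...]
    clone_proportions: np.ndarray  # fractions of tumor cells, sum to 1
    purity: float
    ploidy: int
    variant_truth: tuple[VariantTruth, ...]
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "clone_ids", tuple(self.clone_ids))
        props = np.asarray(self.clone_proportions, dtype=float)
        object.__setattr__(self, "clone_proportions", props)
        object.__setattr__(self, "variant_truth", tuple(self.variant_truth))
        if len(props) != len(self.clone_ids):
            raise ValueError("one proportion per clone required")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"clone proportions must sum to 1, got {props.sum()}")
        if not 0 < self.purity <= 1:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.ploidy < 1:
            raise ValueError("ploidy must be a positive integer")
        prop = dict(zip(self.clone_ids, props))
        for vt in self.variant_truth:
            implied = sum(prop[c] for c in vt.clones)
            if abs(implied - vt.ccf) > 1e-9:
                raise ValueError(
                    f"variant {vt.variant_id}: ccf {vt.ccf} != summed clone proportions {implied}"
                )

    def proportion_of(self, clone: str) -> float:
        return float(self.clone_proportions[self.clone_ids.index(clone)])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SyntheticTruth)
            and self.clone_ids == other.clone_ids
            and np.array_equal(self.clone_proportions, other.clone_proportions)
            and (self.purity, self.ploidy, self.seed) == (other.purity, other.ploidy, other.seed)
            and self.variant_truth == other.variant_truth
        )


@dataclass(frozen=True)
class SimulatedReadObservation:
    variant_id: str
    alt_depth: int
    total_depth: int
    sample_id: str

    def __post_init__(self) -> None:
        if not 0 <= self.alt_depth <= self.total_depth:
            raise ValueError("require 0 <= alt_depth <= total_depth")


def simulate_clone_tree(
    k_clones: int,
    n_private: int,
    n_truncal: int,
    seed: int,
    proportions: Optional[Sequence[float]] = None,
    purity: float = 1.0,
    ploidy: int = 2,
    neoantigen_fraction: float = 0.0,
) -> SyntheticTruth:
    """Star-with-trunk clone tree: ``n_truncal`` variants carried by every
    clone (CCF 1) plus ``n_private`` variants private to each clone (CCF
    equal to that clone's proportion).

    Clone proportions are drawn from a symmetric Dirichlet(1) unless
    supplied. A ``neoantigen_fraction`` of variants is flagged as
    neoantigen-bearing (Bernoulli per variant).
    """
    if k_clones < 1:
        raise ValueError("k_clones must be >= 1")
    if n_private < 0 or n_truncal < 0:
        raise ValueError("variant counts must be non-negative")
    rng = np.random.default_rng(seed)
    clone_ids = tuple(f"C{i + 1}" for i in range(k_clones))
    if proportions is None:
        props = rng.dirichlet(np.ones(k_clones))
    else:
        props = np.asarray(proportions, dtype=float)
    props = props / props.sum()
    all_clones = frozenset(clone_ids)
    variants = []
    for i in range(n_truncal):
        variants.append(
            VariantTruth(
                variant_id=f"T{i + 1:04d}",
                clones=all_clones,
                ccf=1.0,
                neoantigen=bool(rng.random() < neoantigen_fraction),
            )
        )
    for c, clone in enumerate(clone_ids):
        for i in range(n_private):
            variants.append(
                VariantTruth(
                    variant_id=f"{clone}_P{i + 1:04d}",
                    clones=frozenset({clone}),
                    ccf=float(props[c]),
                    neoantigen=bool(rng.random() < neoantigen_fraction),
                )
            )
    return SyntheticTruth(
        clone_ids=clone_ids,
        clone_proportions=props,
        purity=purity,
        ploidy=ploidy,
        variant_truth=tuple(variants),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Neutral frequency spectrum
# ---------------------------------------------------------------------------


def neutral_vaf_cdf(f, f_min: float, f_max: float):
    """Analytic CDF of a neutral-model frequency draw on [f_min, f_max]."""
    f = np.asarray(f, dtype=float)
    span = 1.0 / f_min - 1.0 / f_max
    cdf = 1.0 - (1.0 / f - 1.0 / f_max) / span
    return np.clip(cdf, 0.0, 1.0)


def simulate_neutral_vafs(
    mu_over_beta: float, f_min: float, f_max: float, seed: int
) -> np.ndarray:
    """Subclonal frequencies under neutral growth, by inverse transform.

    The number of draws is round(mu/beta * (1/f_min - 1/f_max)), the total
    mutation count the model predicts in the window; each draw is
    f = 1 / (1/f_max + u * (1/f_min - 1/f_max)) with u uniform on (0, 1).
    """
    if mu_over_beta <= 0:
        raise ValueError("mu_over_beta must be positive")
    if not 0 < f_min < f_max <= 1:
        raise ValueError(f"require 0 < f_min < f_max <= 1, got [{f_min}, {f_max}]")
    span = 1.0 / f_min - 1.0 / f_max
    n = int(round(mu_over_beta * span))
    u = np.random.default_rng(seed).random(n)
    return 1.0 / (1.0 / f_max + u * span)


# ---------------------------------------------------------------------------
# Read-level sampling
# ---------------------------------------------------------------------------


def expected_vaf(ccf: float, purity: float, total_cn: int, multiplicity: int = 1) -> float:
    """Expected allele frequency of a variant at the given CCF, purity,
    tumor copy number and multiplicity (normal cells contribute 2 copies)."""
    return ccf * purity * multiplicity / (purity * total_cn + (1.0 - purity) * 2.0)


def simulate_reads(
    truth: SyntheticTruth,
    coverage: float,
    seed: int,
    sample_id: str = "S1",
) -> list[SimulatedReadObservation]:
    """Poisson total depth and binomial alt depth for every true variant."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for vt in truth.variant_truth:
        dp = int(rng.poisson(coverage))
        evaf = expected_vaf(vt.ccf, truth.purity, truth.ploidy, vt.multiplicity)
        alt = int(rng.binomial(dp, evaf)) if dp > 0 else 0
        out.append(SimulatedReadObservation(vt.variant_id, alt, dp, sample_id))
    return out


# ---------------------------------------------------------------------------
# Amplicon panel and counts
# ---------------------------------------------------------------------------


def single_clone_truth(truth: SyntheticTruth, clone: str) -> SyntheticTruth:
    """A pure outgrowth of one clone (e.g. a clonal metastasis control):
    same clone universe, proportions one-hot, purity 1, no variant list."""
    props = np.array([1.0 if c == clone else 0.0 for c in truth.clone_ids])
    if props.sum() == 0:
        raise ValueError(f"unknown clone {clone!r}")
    return replace(truth, clone_proportions=props, purity=1.0, variant_truth=())


def equal_mix_truth(truth: SyntheticTruth) -> SyntheticTruth:
    """The equal-proportion mixture control of all clones at purity 1."""
    k = len(truth.clone_ids)
    return replace(
        truth, clone_proportions=np.full(k, 1.0 / k), purity=1.0, variant_truth=()
    )


def panel_from_truth(
    truth: SyntheticTruth,
    n_private_per_clone: int = 4,
    n_common: int = 4,
    seed: int = 0,
) -> AmpliconPanel:
    """Design an amplicon panel from ground truth: the first ``n_common``
    truncal variants as common targets and ``n_private_per_clone`` private
    variants per clone, with synthetic coordinates."""
    rng = np.random.default_rng(seed)
    targets = []
    truncal = [vt for vt in truth.variant_truth if vt.clones == frozenset(truth.clone_ids)]
    if len(truncal) < n_common:
        raise ValueError("not enough truncal variants for the requested common targets")
    pos = 1000
    for i, vt in enumerate(truncal[:n_common]):
        targets.append(
            AmpliconTarget(f"COMMON_{i + 1}", "ampli_ref", pos, "A", "G", COMMON)
        )
        pos += 500
    for clone in truth.clone_ids:
        private = [vt for vt in truth.variant_truth if vt.clones == frozenset({clone})]
        if len(private) < n_private_per_clone:
            raise ValueError(f"not enough private variants for clone {clone}")
        chosen = rng.choice(len(private), size=n_private_per_clone, replace=False)
        for i in sorted(chosen):
            targets.append(
                AmpliconTarget(
                    f"{clone}_{i + 1}", "ampli_ref", pos, "A", "G", clone
                )
            )
            pos += 500
    return AmpliconPanel(targets=tuple(targets), clones=truth.clone_ids)


def simulate_amplicon_counts(
    truth: SyntheticTruth,
    panel: AmpliconPanel,
    depth: int,
    bg_error: float,
    seed: int,
    sample_id: str = "S1",
) -> dict[str, AmpliconPileup]:
    """Targeted amplicon counts for one sample.

    The expected alt fraction at a private target is the owning clone's
    proportion times purity over ploidy, plus an additive background error;
    common targets sit at purity/ploidy plus background. Total depth is
    Poisson around ``depth``; alt and other-alt reads are binomial.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0 <= bg_error < 0.01:
        raise ValueError("bg_error must be in [0, 0.01)")
    unknown = {t.clone for t in panel.targets} - set(truth.clone_ids) - {COMMON}
    if unknown:
        raise ValueError(f"panel references unknown clones: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    pileups = {}
    for t in panel.targets:
        if t.clone == COMMON:
            frac = truth.purity / truth.ploidy + bg_error
        else:
            frac = truth.proportion_of(t.clone) * truth.purity / truth.ploidy + bg_error
        dp = int(rng.poisson(depth))
        alt = int(rng.binomial(dp, min(frac, 1.0))) if dp else 0
        other = int(rng.binomial(dp - alt, bg_error)) if dp - alt > 0 else 0
        pileups[t.target_id] = AmpliconPileup(
            sample_id=sample_id,
            target_id=t.target_id,
            ref_count=dp - alt - other,
            alt_count=alt,
            other_alt_count=other,
        )
    return pileups


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------


def _noisy(rng: np.random.Generator, mean: float, cv: float) -> float:
    # lognormal multiplicative noise with unit mean and the given CV
    if cv <= 0 or mean == 0:
        return mean
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(mean * rng.lognormal(-0.5 * sigma * sigma, sigma))


def simulate_coverage_track(
    purity: float,
    base_depth: float,
    floxed_exons: Sequence[str],
    flanking_exons: Sequence[str],
    noise_cv: float,
    seed: int,
    knockout_efficiency: float = 0.0,
    target_exons: Sequence[str] = (),
) -> list[ExonCoverage]:
    """Per-exon depth for a tumor and its matched normal.

    Floxed exons are excised in every tumor cell, so tumor depth there is
    base_depth * (1 - purity); flanking exons stay at base_depth; optional
    conditional-knockout target exons drop to
    base_depth * (1 - purity * knockout_efficiency). The matched normal is
    flat at base_depth. Depths carry multiplicative lognormal noise with the
    given coefficient of variation.
    """
    if not 0 <= purity <= 1:
        raise ValueError("purity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    start = 0
    specs = (
        [("floxed", e, base_depth * (1.0 - purity)) for e in floxed_exons]
        + [("flanking", e, base_depth) for e in flanking_exons]
        + [
            ("target_exon", e, base_depth * (1.0 - purity * knockout_efficiency))
            for e in target_exons
        ]
    )
    for region_class, exon, tumor_mean in specs:
        for sample, mean in (("tumor", tumor_mean), ("normal", base_depth)):
            rows.append(
                ExonCoverage(
                    sample_id=sample,
                    exon_id=str(exon),
                    gene="synthetic",
                    region_class=region_class,
                    median_depth=_noisy(rng, mean, noise_cv),
                    chrom="cov_ref",
                    start=start,
                    end=start + 200,
                )
            )
        start += 400
    return rows


# ---------------------------------------------------------------------------
# Reference sequence and caller outputs
# ---------------------------------------------------------------------------


def simulate_reference(contig_lengths: Mapping[str, int], seed: int) -> dict[str, str]:
    """Random reference sequences (uniform ACGT) for variant placement."""
    rng = np.random.default_rng(seed)
    return {
        chrom: "".join(rng.choice(list(_BASES), size=length))
        for chrom, length in contig_lengths.items()
    }


def make_variant_calls(
    truth: SyntheticTruth,
    reference: Mapping[str, str],
    coverage: float,
    seed: int,
    sample_id: str = "S1",
    animal_id: str = "A1",
    indel_fraction: float = 0.15,
) -> list[VariantCall]:
    """Place true variants at unique reference positions and attach sampled
    read depths. A fraction of variants are 1-3 nt indels; the rest SNVs."""
    rng = np.random.default_rng(seed)
    reads = {
        r.variant_id: r for r in simulate_reads(truth, coverage, seed + 1, sample_id)
    }
    contigs = sorted(reference)
    occupied: set[tuple[str, int]] = set()
    calls = []
    for vt in truth.variant_truth:
        chrom = contigs[int(rng.integers(len(contigs)))]
        seq = reference[chrom]
        while True:
            pos = int(rng.integers(31, len(seq) - 35)) + 1  # leave flank for context
            if (chrom, pos) not in occupied:
                occupied.add((chrom, pos))
                break
        ref_base = seq[pos - 1]
        if rng.random() < indel_fraction:
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                ref, alt = ref_base, ref_base + "".join(rng.choice(list(_BASES), size=size))
            else:
                ref, alt = seq[pos - 1 : pos + size], ref_base
        else:
            ref = ref_base
            alt = rng.choice([b for b in _BASES if b != ref_base])
        obs = reads[vt.variant_id]
        dp = max(obs.total_depth, 1)
        calls.append(
            VariantCall(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=str(alt),
                sample_id=sample_id,
                animal_id=animal_id,
                alt_depth=min(obs.alt_depth, dp),
                total_depth=dp,
                neoantigen=vt.neoantigen,
                variant_id=vt.variant_id,
            )
        )
    return calls


def simulate_caller_outputs(
    true_variants: Sequence[VariantCall],
    caller_sensitivities: Mapping[str, float],
    fp_rate: float,
    seed: int,
    territory_mb: float = 50.0,
    fp_contig: str = "fp_ref",
) -> dict[str, list[VariantCall]]:
    """Per-caller call sets: each caller independently detects each true
    variant with its sensitivity and adds Poisson false positives (rate per
    Mb of territory) private to itself."""
    for caller, s in caller_sensitivities.items():
        if not 0 <= s <= 1:
            raise ValueError(f"sensitivity for {caller} outside [0, 1]")
    rng = np.random.default_rng(seed)
    out: dict[str, list[VariantCall]] = {}
    fp_pos = 10_000_000  # disjoint coordinate block so FPs never collide with truth
    for caller in sorted(caller_sensitivities):
        sens = caller_sensitivities[caller]
        calls = [
            replace(v, callers=frozenset({caller}))
            for v in true_variants
            if rng.random() < sens
        ]
        n_fp = int(rng.poisson(fp_rate * territory_mb))
        sample = true_variants[0].sample_id if true_variants else "S1"
        animal = true_variants[0].animal_id if true_variants else "A1"
        for _ in range(n_fp):
            fp_pos += int(rng.integers(1, 1000))
            ref, alt = rng.choice(list(_BASES), size=2, replace=False)
            calls.append(
                VariantCall(
                    chrom=fp_contig,
                    pos=fp_pos,
                    ref=str(ref),
                    alt=str(alt),
                    sample_id=sample,
                    animal_id=animal,
                    alt_depth=5,
                    total_depth=100,
                    callers=frozenset({caller}),
                )
            )
        out[caller] = calls
    return out


# ---------------------------------------------------------------------------
# Immunoediting
# ---------------------------------------------------------------------------


def apply_immunoediting(truth: SyntheticTruth, strength: float, seed: int) -> SyntheticTruth:
    """Deplete neoantigen-bearing variants with probability 1 - exp(-strength * CCF).

    Models immunosurveillance pruning clonal neoantigens: high-CCF
    neoantigens are far more likely to be removed than subclonal ones.
    Strength 0 is the identity map.
    """
    if strength < 0:
        raise ValueError("strength must be non-negative")
    if strength == 0:
        return truth
    rng = np.random.default_rng(seed)
    kept = tuple(
        vt
        for vt in truth.variant_truth
        if not (vt.neoantigen and rng.random() < 1.0 - math.exp(-strength * vt.ccf))
    )
    return replace(truth, variant_truth=kept)


# ---------------------------------------------------------------------------
# Synthetic signature catalogues and spectra
# ---------------------------------------------------------------------------


def make_signature_set(
    k: int, seed: int, names: Optional[Sequence[str]] = None, alpha: float = 0.08
) -> SignatureSet:
    """Random sparse signature catalogue (Dirichlet columns).

    A small ``alpha`` concentrates each signature on a few channels, giving
    nearly orthogonal signatures as in curated catalogues.
    """
    rng = np.random.default_rng(seed)
    matrix = rng.dirichlet(np.full(96, alpha), size=k).T
    if names is None:
        names = tuple(f"SYN{i + 1}" for i in range(k))
    return SignatureSet(names=tuple(names), matrix=matrix)


def simulate_spectrum_from_signatures(
    weight_fractions: Sequence[float],
    signatures: SignatureSet,
    n_mutations: int,
    seed: int,
) -> MutationSpectrum:
    """Poisson-sampled spectrum from a signature mixture with the given
    weight fractions and expected total mutation count."""
    frac = np.asarray(weight_fractions, dtype=float)
    if frac.shape != (len(signatures.names),):
        raise ValueError("one weight per signature required")
    frac = frac / frac.sum()
    expected = n_mutations * (signatures.matrix @ frac)
    counts = np.random.default_rng(seed).poisson(expected).astype(float)
    return MutationSpectrum(counts=counts)
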