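# Methods

This note documents the models implemented in `clonarch`, the assumptions
behind them, the parameters that matter, and the choices made where the
design was genuinely open. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Consensus variant integration and cohort filters

Somatic SNVs are retained when called by the anchor caller (default
`mutect2`) plus at least one other caller; indels when called by at least
two callers, anchor not required. No VAF filter is applied. The anchor is a
parameter rather than a constant so synthetic caller sets can exercise the
rule. Cohort-level filters then remove (i) variants at supplied dbSNP
positions, (ii) variants observed in two or more animals, and (iii)
variants observed in at least 50% (inclusive boundary) of the tumors of one
animal. Both recurrence filters target germline leakage and sample
cross-contamination; they are set-based, hence order-invariant and
idempotent. The per-animal tumor census is derived from the variant table
itself, so a tumor contributing zero variants is invisible to the census —
callers of `apply_cohort_filters` on sparse tables should be aware of this.
Animals with a single tumor skip filter (iii): 1/1 = 100% would otherwise
delete every private variant, and the filter's target (germline leakage)
cannot be distinguished with one tumor.

Restriction to exonic territory is treated as data (an optional BED
intersect before filtering), not algorithm.

## Microsatellite annotation

The scanner finds tandem repeats of motif length 1–6 overlapping a variant
locus. A repeat region of length `L` starting with one motif copy is scored
against the period-`m` self-alignment: each position matching the base `m`
earlier scores +1, each mismatch −`penalty`, plus `m` for the leading copy
— so a perfect repeat of length `L` scores `L`. A repeat is annotated when
score ≥ 8, it contains a perfect stretch of ≥ 8 nt (the seed), and it spans
≥ 2 unit copies; ties go to higher score, then shorter motif, then longer
region, then leftmost start. Defaults mirror the four published scoring
parameters of SciRoKo-style SSR searches (minimum score 8, seed length 8,
repeats 2, mismatch penalty 1); the exact mismatch bookkeeping of that tool
is not published, so edge-case imperfect repeats may differ, which is why
the implementation is verified against an exhaustive interval-enumeration
oracle (identical scoring definition, independent search) on random
windows rather than against the external tool.

The production scanner is a seed-and-extend search over maximal perfect
runs with prefix-sum–optimal extension. This is exact for the scoring
scheme above: any qualifying interval can be extended over the full perfect
run it contains without score loss, so optimizing extensions around each
run enumerates all optima.

## CCF estimation and clonality

For VAF `v`, purity `ρ`, tumor total copy number `n_t` (normal cells
contribute 2 copies) the multiplicity is
`m = clamp(round(v/ρ · (ρ n_t + 2(1−ρ))), 1, n_t)` and
`CCF = v (ρ n_t + 2(1−ρ)) / (ρ m)`. This is the standard
purity/copy-number-corrected estimator with rounded integer multiplicity,
adopted in place of a Bayesian multiplicity model; the downstream
clonality statistics depend only on a calibrated CCF, and recovery on
simulated reads (≥95% correct clonal/subclonal classification at 200×,
mean |error| < 0.05) is the calibration criterion. Raw CCF above 1 —
routine for clonal variants under binomial noise — is capped at 1.0 for
classification but preserved (`ccf_raw`) for QC. Within a fixed
multiplicity class the estimator is monotone in VAF; at multiplicity
transitions it steps down by construction.

Clonality classes: clonal CCF ≥ 0.75, subclonal CCF ≤ 0.5 (inclusive
default), intermediate otherwise. The strict `< 0.5` subclonal boundary
used in some human analyses is available via `subclonal_inclusive=False`;
the two conventions differ only at exactly 0.5. Stratified burden divides
class counts by captured territory (Mb); intermediate variants count in
the total but neither stratum. The ITH index is the subclonal:clonal
neoantigen count ratio and is flagged undefined (NaN, `defined=False`) —
not infinite — when no clonal neoantigen exists.

CCF densities use a Gaussian KDE on a fixed 512-point grid over [0, 1]
with Scott's-rule bandwidth by default; both are logged in results for
reproducibility. Mass within ~1 bandwidth of the boundaries leaks outside
the unit interval, so the grid integral is only ≈1 (the tests allow 0.01).
Distribution comparisons use the two-sided two-sample Kolmogorov–Smirnov
test with SciPy's exact/asymptotic switching.

Neoantigen prioritization keeps, per SNV, the strongest binder (lowest
median predicted affinity in nM) among candidates at ≤ 500 nM, with a
deterministic lexicographic-peptide tie-break. Binding prediction itself is
out of scope; candidates arrive annotated.

## Neutral-evolution test

The cumulative count of subclonal mutations at purity-corrected frequency
`f = VAF/ρ` or above is fitted to `M(f) = μ/β (1/f − 1/f_max)` by
least squares on `x = 1/f − 1/f_max` without intercept (the model pins
`M(f_max) = 0`). R² is the uncentered coefficient of determination,
reported descriptively; no neutrality p-value is produced. The default fit
window `f ∈ [0.12, 0.24]` follows the established cumulative-spectrum
procedure and is configurable; whether indels enter M(f) is likewise left
to the caller (they do if their VAFs are supplied).

A single window at μ/β = 50 contains ≈ 200 mutations, giving the slope
estimator a sampling error of roughly 3% (unbiased); calibration is
therefore assessed on the mean over seeded replicates, with single fits
checked for linearity (R² ≥ 0.98) and for the direction of the contrast
against a two-clone selected mixture.

## Amplicon clone deconvolution

Clone-private SNVs are selected as: clonal in exactly one clone, inside a
copy-number-neutral segment (default total CN 4, matching tetraploid
lines), and with complete absence of alt reads (BQ > 20, MQ > 30,
exclusive) in all other samples. Targets whose alt reads do not exceed all
other alternative alleles in the equal-mixture control are excluded
(logged with counts). Background per target is the median alt frequency
across clonal controls dominated by *other* clones; background-subtracted
frequencies are floored at 0 because frequencies are physical proportions.
Purity is the median observed/expected frequency ratio over common SNVs
(expected = 1/ploidy; common SNVs are not background-subtracted, which
biases purity upward by ≈ ploidy × background — ~1% at the default 0.2%
background — a second-order effect on clone fractions). Clone fraction =
median(adjusted private frequencies) × ploidy / purity.

Raw fractions are *not* renormalized to sum to 1 by default so estimator
bias stays visible; optional renormalization is available. Clones at ≥ 1%
(the reporting threshold for presence) are flagged present, and the
Gini–Simpson index `D = 1 − Σ p²` is computed over detected clones
renormalized to sum 1. The Gini–Simpson form is used (an equal 8-mix
scores 0.875, monoclonal 0) since the plain Σp² variant would reverse the
diversity direction. The estimator works on frequencies, so it is
invariant to per-target depth differences; UMI consensus collapsing is an
upstream concern and the estimator consumes consensus or raw counts
identically.

## Purity estimators

*Floxed-coverage purity* assumes complete biallelic Cre recombination in
tumor cells and none in normal cells, so floxed-exon coverage scales with
(1 − purity). With R = median(flanking exon depths)/median(floxed exon
depths), purity = 1 − R_normal/R_tumor, clipped to [0, 1]. The inversion
from the recombination assumption to this formula is this package's own
derivation; intermediate ratios are reported alongside the estimate. Zero
floxed coverage returns purity 1.0 with a complete-dropout flag. Medians
(never means) are used at every aggregation, and the normals' reference
ratio is the median of per-normal pooled-median ratios (per-exon-then-
median is a second-order variant). *Knockout efficiency* applies the same
ratio logic to a conditional exon and divides the observed dropout by
purity. *Edit-fraction purity* is the non-wild-type read fraction at an
sgRNA cut site whose disruption is prerequisite for tumorigenesis
(biallelic-edit, diploid assumption).

## Signature refitting

Spectra are refit in counts space by non-negative least squares
(`scipy.optimize.nnls`); the observed spectrum is not normalized before
fitting, so weights are mutation counts and fractions are derived. Cosine
similarity of observed vs reconstructed spectrum is the goodness of fit.
Signature groups (MMR deficiency: SBS6/14/15/21/26/44; POLE:
SBS10a/10b/28/17b) can be collapsed into summed contributions; ungrouped
signatures pass through. The catalogue is a pluggable 96 × k TSV — tests
and the demo pipeline use synthetic sparse-Dirichlet catalogues so no
external download is needed. Exome-vs-genome trinucleotide renormalization
is deliberately not applied. Note the information floor: with N mutations
and k well-separated signatures the L1 fraction error cannot beat the
multinomial sampling noise ≈ Σ√(p_i(1−p_i)/N), which is why noised-recovery
checks use two-signature mixtures at N = 1000 and assess the mean over
seeds.

## Synthetic-tumor generator

The generator produces the statistical structure the estimators assume —
and only that:

- **Clone tree**: star-with-trunk (truncal mutations in all clones,
  private mutations in one); proportions default to a symmetric
  Dirichlet(1) so unequal mixtures are covered even though the original
  experimental mixtures were equal by design. Deeper topologies are out of
  scope.
- **Neutral frequencies**: inverse-transform draws from the M(f) model;
  the draw count is the model-implied mutation count
  `round(μ/β (1/f_min − 1/f_max))`.
- **Reads**: per-variant depth ~ Poisson(coverage), alt reads ~
  Binomial(depth, VAF) with VAF = CCF·ρ·m/(ρ·n_t + 2(1−ρ)). No
  sequence-context error model, no mapping artifacts.
- **Amplicon counts**: expected alt fraction = clone proportion × ρ /
  ploidy (+ additive background error, symmetric across targets by
  default); depth ~ Poisson, counts binomial; other-alt reads are drawn at
  the background rate so the QC-exclusion rule can be exercised. Amplicon
  depth is a free parameter (default 10,000×).
- **Coverage tracks**: floxed exons at base × (1 − purity), flanking at
  base, optional knockout exons at base × (1 − purity × efficiency);
  multiplicative lognormal noise with user CV (mean-one parameterization),
  chosen to match exome-capture overdispersion.
- **Caller outputs**: independent per-caller Bernoulli detection plus
  Poisson false positives private to each caller, placed on a disjoint
  contig so they never collide with true variants.
- **Immunoediting**: each neoantigen-flagged variant is removed with
  probability 1 − exp(−strength × CCF); strength 0 is the identity map.

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); no global RNG state exists, and every
observable is reproducible bit for bit from (parameters, seed).

What the generator does *not* emulate — alignment and calling artifacts,
copy-number heterogeneity along the genome, overdispersed (non-binomial)
allele counts, clone phylogenies deeper than one level, expression-level
neoantigen filtering — bounds what passing tests show: they demonstrate
correctness and calibration of the estimators under their stated sampling
assumptions, not robustness to real-data artifacts.

### Immunoediting contrast design

The clonality contrast compares, per seed, an immunoedited arm against an
unedited arm, each an *independent* synthetic tumor (12 subclones, ~500
neoantigen-bearing variants in expectation, a lognormal tumor-level burden
multiplier with CV 0.6 emulating the order-of-magnitude burden spread seen
across hypermutated tumors). Independent arms are the faithful analogue of
treatment-group comparisons across different animals. Under the
exponential depletion model editing at strength 2 removes ~86% of clonal
but only ~10–25% of low-CCF neoantigens, so across 20 seed pairs the
clonal burden is systematically lower in the edited arm (sign test,
α = 0.01) while the small subclonal depletion stays within between-tumor
variability and the subclonal sign test stays non-significant at the same
level. A paired same-tumor design would instead detect the subclonal
depletion — the model removes subclonal neoantigens at a nonzero rate —
and was therefore not used for this directional check.

## Pipeline and problem sizes

`run_pipeline` wires the stages deterministically from a flat key=value
config whose only required key is `seed`; the manifest records the config
hash, seeds and per-stage record counts so every filter's discard
accounting is auditable. Default problem sizes (6 clones, ~220 variants,
200× exome coverage, 10,000× amplicon depth, 2,000-mutation spectra, 20
seed pairs for the contrast) were chosen as the smallest sizes at which
the recovery tolerances above are comfortably identifiable; all are
config-exposed.

## Known limitations

- The CCF multiplicity model is a rounding heuristic; dedicated subclonal
  deconvolution (PyClone-class) problems are out of scope.
- The microsatellite scorer matches the four published parameters but is
  not guaranteed to reproduce SciRoKo's behavior on imperfect repeats.
- The uncentered R² of the through-origin neutral fit is generous for
  monotone cumulative data; it is a descriptive statistic, not a test.
- The floxed-coverage purity estimator degrades as purity → 0 (the signal
  is a ratio shift of size purity/(1 − purity)).
- Clone-fraction estimates for clones below ~2× background/(ploidy/ρ) are
  dominated by the background-subtraction floor and should be interpreted
  via the presence threshold rather than their point values.
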