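# clonarch

Clonal-architecture statistics for hypermutated (mismatch-repair-deficient)
tumors: consensus somatic-variant filtering, cancer-cell-fraction (CCF) and
clonality statistics, neutral-evolution testing, mutational-signature
refitting, targeted-amplicon clone deconvolution with diversity indices, and
coverage-based tumor purity estimators — together with a synthetic-tumor
generator so that every stage can be exercised, calibrated and tested
without sequencing data.

It is aimed at cancer-genomics analysts working with multi-caller somatic
call sets from engineered mouse models (or comparable human cohorts) who
need per-variant clonality annotations and per-sample clonal-architecture
summaries such as clonal/subclonal mutation burden, intratumor-heterogeneity
(ITH) index and clone diversity.

## Models and statistics

**CCF estimation.** For a variant with allele frequency `v` in a sample of
purity `ρ` at a locus with tumor copy number `n_t`, the mutation
multiplicity is `m = clamp(round(v/ρ · (ρ·n_t + 2(1−ρ))), 1, n_t)` and

```
CCF = v · (ρ·n_t + 2(1−ρ)) / (ρ · m)
```

Variants are classified clonal (CCF ≥ 0.75), subclonal (CCF ≤ 0.5; a strict
`< 0.5` boundary is available) or intermediate. The ITH index is the
subclonal:clonal neoantigen count ratio.

**Neutral evolution.** Under neutral growth the cumulative count of
subclonal mutations above purity-corrected frequency `f` follows
`M(f) = μ/β (1/f − 1/f_max)` (Williams model); `M(f)` is fitted against
`1/f` without intercept, the slope estimating the mutation rate per
effective division `μ/β` and the through-origin R² quantifying linearity.

**Clone deconvolution.** Mixed tumors seeded from known clones are
deconvolved from deep amplicon counts over clone-private SNVs: per-target
background error (median alt frequency in clonal controls of *other*
clones) is subtracted, purity is the median observed/expected frequency
ratio of SNVs common to all clones, and each clone's fraction is
`median(private frequencies − background) × ploidy / purity` (×4 for
tetraploid lines, where a single-copy SNV sits at 1/(4n)). Diversity is the
Gini–Simpson index `D = 1 − Σ p_i²`.

**Purity estimators.** (i) Coverage dropout over Cre-excised (floxed) exons:
with R = flanking/floxed median-coverage ratio, purity = 1 − R_normal/R_tumor;
(ii) conditional-knockout efficiency = (1 − ρ)/purity from the same ratio
logic; (iii) non-wild-type allele fraction at a CRISPR cut site whose
disruption is prerequisite for tumorigenesis.

**Signatures.** 96-channel trinucleotide spectra are refit on a signature
catalogue by non-negative least squares in counts space; goodness of fit is
the cosine similarity of observed and reconstructed spectra, and signature
groups (e.g. the MMR-deficiency signatures SBS6/14/15/21/26/44) can be
collapsed for reporting.

## Worked example

Deconvolve a simulated 8-clone mixture (purity 0.8, tetraploid, 10,000×
amplicon depth, 0.2% background error) from 4 private SNVs per clone and 4
common SNVs:

```python
from clonarch import simulate as sim
from clonarch.deconvolution import (qc_exclude_targets, estimate_background,
    estimate_purity_common, estimate_clone_fractions, simpson_diversity)
from clonarch.simulate import equal_mix_truth, single_clone_truth

truth = sim.simulate_clone_tree(8, 8, 8, seed=11, purity=0.8, ploidy=4)
panel = sim.panel_from_truth(truth, n_private_per_clone=4, n_common=4, seed=12)
tumor = sim.simulate_amplicon_counts(truth, panel, depth=10_000,
                                     bg_error=0.002, seed=13, sample_id="tumor")
mix = sim.simulate_amplicon_counts(equal_mix_truth(truth), panel, 10_000, 0.002, 14, "mix")
controls = {f"met_{c}": (c, sim.simulate_amplicon_counts(
                single_clone_truth(truth, c), panel, 10_000, 0.002, 15 + i, f"met_{c}"))
            for i, c in enumerate(truth.clone_ids)}

panel_qc, excluded = qc_exclude_targets(panel, mix)
backgrounds = estimate_background(panel_qc, controls)
purity = estimate_purity_common(tumor, panel_qc, expected_fraction=0.25)
est = estimate_clone_fractions(tumor, panel_qc, backgrounds, purity.value, ploidy=4)
```

Output:

```
estimated purity: 0.791  (truth 0.800)
C1: estimated  4.18%   true  3.76%
C2: estimated  8.30%   true  8.82%
C3: estimated 19.29%   true 18.39%
C4: estimated  0.78%   true  0.75%
C5: estimated  2.13%   true  1.91%
C6: estimated 61.37%   true 62.11%
C7: estimated  0.86%   true  1.17%
C8: estimated  3.12%   true  3.09%
Simpson D: estimated 0.562, true 0.570
```

Every clone fraction is recovered to well within one percentage point after
background subtraction and purity normalization, and the Simpson diversity
of the estimated composition matches the truth to < 0.01.

The same stages are available from the shell: `clonarch run --config
run.cfg --out outdir` drives the full pipeline (simulate → consensus filter
→ CCF → neutrality/deconvolution/signatures → summary), and per-stage
subcommands (`clonarch variants merge`, `clonarch ccf annotate`, `clonarch
neutrality fit`, `clonarch deconv estimate`, `clonarch purity flox`,
`clonarch signatures fit`, …) work standalone. See `docs/methods.md` for
the modeling details and parameter defaults.

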