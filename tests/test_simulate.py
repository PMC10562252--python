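"""Synthetic tumor generator: ground-truth construction, sampling models,
reproducibility."""

import numpy as np
import pytest
from scipy import stats

from clonarch import simulate as sim
from clonarch.deconvolution import COMMON
from clonarch.variants import merge_caller_calls


class TestCloneTree:
    def test_single_clone_all_truncal(self):
        truth = sim.simulate_clone_tree(1, 0, 10, seed=1)
        assert len(truth.variant_truth) == 10
        assert all(vt.ccf == 1.0 for vt in truth.variant_truth)

    def test_equal_eight_clone_mixture(self):
        truth = sim.simulate_clone_tree(8, 4, 4, seed=1, proportions=[0.125] * 8)
        private = [vt for vt in truth.variant_truth if len(vt.clones) == 1]
        assert len(private) == 32
        assert all(vt.ccf == pytest.approx(0.125) for vt in private)

    def test_supplied_proportions_define_private_ccfs(self):
        truth = sim.simulate_clone_tree(3, 1, 0, seed=1, proportions=[0.5, 0.3, 0.2])
        ccfs = sorted(vt.ccf for vt in truth.variant_truth)
        assert ccfs == pytest.approx([0.2, 0.3, 0.5])

    def test_dirichlet_proportions_sum_to_one(self):
        truth = sim.simulate_clone_tree(5, 2, 2, seed=3)
        assert truth.clone_proportions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_clone_tree(0, 1, 1, seed=1)

    def test_truth_invariant_ccf_equals_summed_proportions(self):
        truth = sim.simulate_clone_tree(4, 3, 3, seed=9)
        prop = dict(zip(truth.clone_ids, truth.clone_proportions))
        for vt in truth.variant_truth:
            assert vt.ccf == pytest.approx(sum(prop[c] for c in vt.clones), abs=1e-12)


class TestNeutralVafs:
    def test_draw_count_follows_model(self):
        # mu/beta * (1/f_min - 1/f_max) = 10 * (10 - 4) = 60
        assert sim.simulate_neutral_vafs(10, 0.1, 0.25, seed=1).size == 60

    def test_draws_within_window(self):
        f = sim.simulate_neutral_vafs(30, 0.05, 0.4, seed=2)
        assert f.min() >= 0.05 and f.max() <= 0.4

    def test_inverse_cdf_construction_is_exactly_linear(self):
        # deterministic quantiles reproduce M(f) linear in 1/f with the stated slope
        from clonarch.neutrality import fit_neutral_model

        mu_over_beta, f_min, f_max = 10.0, 0.1, 0.25
        span = 1 / f_min - 1 / f_max
        n = 60
        u = (np.arange(n) + 1) / n
        f = 1.0 / (1 / f_max + u * span)
        m_f = np.arange(1, n + 1)  # by construction f is descending in u
        fit = fit_neutral_model(1.0 / f, m_f.astype(float), f_max=f_max)
        assert fit.slope == pytest.approx(mu_over_beta, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_empirical_cdf_converges_to_analytic(self):
        mu_for_10k = 10_000 / (1 / 0.05 - 1 / 0.5)
        f = sim.simulate_neutral_vafs(mu_for_10k, 0.05, 0.5, seed=4)
        # 10,000 frequencies; KS distance to the analytic CDF < 0.02
        assert f.size == 10_000
        d = stats.kstest(f, lambda x: sim.neutral_vaf_cdf(x, 0.05, 0.5)).statistic
        assert d < 0.02

    def test_monte_carlo_slope_recovery(self):
        # mu/beta = 50: the mean fitted slope over replicates is within 5%
        from clonarch.neutrality import fit_neutral

        slopes = [
            fit_neutral(sim.simulate_neutral_vafs(50, 0.12, 0.24, seed=s), 1.0, 0.12, 0.24).slope
            for s in range(30)
        ]
        assert np.mean(slopes) == pytest.approx(50, rel=0.05)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_neutral_vafs(10, 0.3, 0.2, seed=1)


class TestReads:
    @pytest.mark.parametrize(
        "ccf,purity,cn,mult,expected",
        [
            (1.0, 1.0, 2, 1, 0.5),
            (1.0, 1.0, 4, 1, 0.25),  # tetraploid: fully clonal SNV sits at 1/4
            (0.5, 0.5, 2, 1, 0.125),
        ],
    )
    def test_expected_vaf(self, ccf, purity, cn, mult, expected):
        assert sim.expected_vaf(ccf, purity, cn, mult) == pytest.approx(expected)

    def test_reads_reproducible_and_bounded(self):
        truth = sim.simulate_clone_tree(3, 10, 10, seed=5)
        a = sim.simulate_reads(truth, 100, seed=6)
        b = sim.simulate_reads(truth, 100, seed=6)
        assert a == b
        assert all(0 <= r.alt_depth <= r.total_depth for r in a)

    def test_mean_alt_fraction_tracks_expected_vaf(self):
        truth = sim.simulate_clone_tree(1, 0, 400, seed=7, purity=0.8, ploidy=2)
        reads = sim.simulate_reads(truth, 200, seed=8)
        vafs = [r.alt_depth / r.total_depth for r in reads if r.total_depth]
        assert np.mean(vafs) == pytest.approx(sim.expected_vaf(1.0, 0.8, 2), abs=0.01)


class TestAmpliconCounts:
    @pytest.fixture
    def truth(self):
        return sim.simulate_clone_tree(
            8, 8, 8, seed=11, proportions=[0.125] * 8, purity=0.8, ploidy=4
        )

    def test_expected_private_fraction(self, truth):
        panel = sim.panel_from_truth(truth, 4, 4, seed=12)
        piles = sim.simulate_amplicon_counts(truth, panel, 200_000, 0.0, seed=13)
        fr = [
            piles[t.target_id].alt_count / piles[t.target_id].depth
            for t in panel.private_targets
        ]
        # 0.125 * 0.8 / 4 = 0.025
        assert np.mean(fr) == pytest.approx(0.025, abs=0.001)

    def test_common_fraction_is_purity_over_ploidy(self, truth):
        panel = sim.panel_from_truth(truth, 4, 4, seed=12)
        piles = sim.simulate_amplicon_counts(truth, panel, 200_000, 0.0, seed=14)
        fr = [
            piles[t.target_id].alt_count / piles[t.target_id].depth
            for t in panel.common_targets
        ]
        assert np.mean(fr) == pytest.approx(0.8 / 4, abs=0.003)

    def test_private_fraction_conservation(self, truth):
        # summed expected private alt fractions equal purity/ploidy
        total = sum(
            truth.proportion_of(c) * truth.purity / truth.ploidy for c in truth.clone_ids
        )
        assert total == pytest.approx(truth.purity / truth.ploidy)

    def test_unknown_clone_in_panel_rejected(self, truth):
        from clonarch.deconvolution import AmpliconPanel, AmpliconTarget

        panel = AmpliconPanel(
            targets=(AmpliconTarget("x", "c", 1, "A", "G", "ghost"),),
            clones=("ghost",),
        )
        with pytest.raises(ValueError):
            sim.simulate_amplicon_counts(truth, panel, 100, 0.0, seed=1)


class TestCoverageTrack:
    def test_floxed_dropout_proportional_to_purity(self):
        cov = sim.simulate_coverage_track(0.5, 100, ["f1"], ["k1"], 0.0, seed=1)
        tumor_flox = next(
            e for e in cov if e.sample_id == "tumor" and e.region_class == "floxed"
        )
        assert tumor_flox.median_depth == pytest.approx(50.0)

    def test_purity_zero_tumor_matches_normal(self):
        cov = sim.simulate_coverage_track(0.0, 80, ["f1", "f2"], ["k1"], 0.0, seed=2)
        by_exon = {}
        for e in cov:
            by_exon.setdefault(e.exon_id, {})[e.sample_id] = e.median_depth
        for depths in by_exon.values():
            assert depths["tumor"] == pytest.approx(depths["normal"])

    def test_reproducible(self):
        a = sim.simulate_coverage_track(0.7, 100, ["f"], ["k"], 0.1, seed=3)
        b = sim.simulate_coverage_track(0.7, 100, ["f"], ["k"], 0.1, seed=3)
        assert a == b


class TestCallerOutputs:
    @pytest.fixture
    def true_calls(self):
        truth = sim.simulate_clone_tree(2, 5, 5, seed=21)
        ref = sim.simulate_reference({"chr1": 20_000}, seed=22)
        return sim.make_variant_calls(truth, ref, 100, seed=23)

    def test_perfect_callers_reproduce_truth_through_consensus(self, true_calls):
        sets = sim.simulate_caller_outputs(
            true_calls, {"mutect2": 1.0, "strelka2": 1.0}, fp_rate=0.0, seed=24
        )
        merged = merge_caller_calls(sets)
        assert {v.key for v in merged} == {v.key for v in true_calls}

    def test_single_caller_yields_empty_snv_consensus(self, true_calls):
        snvs = [v for v in true_calls if v.variant_class == "SNV"]
        sets = sim.simulate_caller_outputs(snvs, {"mutect2": 1.0}, fp_rate=0.0, seed=25)
        assert merge_caller_calls(sets) == []

    def test_private_false_positives_removed_by_consensus(self, true_calls):
        sets = sim.simulate_caller_outputs(
            true_calls,
            {"mutect2": 1.0, "strelka2": 1.0, "vardict": 1.0},
            fp_rate=2.0,
            seed=26,
        )
        assert any(v.chrom == "fp_ref" for calls in sets.values() for v in calls)
        merged = merge_caller_calls(sets)
        assert all(v.chrom != "fp_ref" for v in merged)


class TestImmunoediting:
    def test_strength_zero_is_identity(self):
        truth = sim.simulate_clone_tree(4, 5, 5, seed=31, neoantigen_fraction=0.5)
        assert sim.apply_immunoediting(truth, 0.0, seed=32) == truth

    def test_infinite_strength_removes_all_clonal_neoantigens(self):
        truth = sim.simulate_clone_tree(2, 5, 20, seed=33, neoantigen_fraction=1.0)
        edited = sim.apply_immunoediting(truth, 1e9, seed=34)
        assert all(vt.ccf < 1.0 for vt in edited.variant_truth)

    def test_non_neoantigens_never_removed(self):
        truth = sim.simulate_clone_tree(2, 5, 20, seed=35, neoantigen_fraction=0.0)
        assert sim.apply_immunoediting(truth, 10.0, seed=36) == truth

    def test_editing_lowers_surviving_neoantigen_ccf(self):
        truth = sim.simulate_clone_tree(12, 25, 200, seed=37, neoantigen_fraction=1.0)
        edited = sim.apply_immunoediting(truth, 2.0, seed=38)
        med_before = np.median([vt.ccf for vt in truth.variant_truth])
        med_after = np.median([vt.ccf for vt in edited.variant_truth])
        assert med_after < med_before
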