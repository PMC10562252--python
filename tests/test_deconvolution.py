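"""Amplicon-based clone deconvolution: panel QC, background, purity and
clone-fraction estimation, Simpson diversity."""

import warnings

import numpy as np
import pytest

from clonarch.ccf import CopyNumberSegment
from clonarch.deconvolution import (
    COMMON,
    AmpliconPanel,
    AmpliconPileup,
    AmpliconTarget,
    estimate_background,
    estimate_clone_fractions,
    estimate_purity_common,
    qc_exclude_targets,
    select_private_snvs,
    simpson_diversity,
)
from clonarch.variants import PileupRead
from conftest import snv


def _pile(target_id, alt, depth, other=0, sample="S1"):
    return AmpliconPileup(sample, target_id, depth - alt - other, alt, other)


def _panel(clones=("M1", "M2"), n_private=2, n_common=2):
    targets = [
        AmpliconTarget(f"COMMON_{i}", "amp", 100 * i, "A", "G", COMMON)
        for i in range(1, n_common + 1)
    ]
    for c in clones:
        targets += [
            AmpliconTarget(f"{c}_{i}", "amp", hash((c, i)) % 10_000 + 1, "A", "G", c)
            for i in range(1, n_private + 1)
        ]
    return AmpliconPanel(targets=tuple(targets), clones=tuple(clones))


class TestPanel:
    def test_unknown_clone_rejected(self):
        with pytest.raises(ValueError, match="unknown clone"):
            AmpliconPanel(
                targets=(AmpliconTarget("x", "amp", 1, "A", "G", "ghost"),), clones=("M1",)
            )

    def test_private_and_common_partition(self):
        panel = _panel()
        assert len(panel.private_targets) == 4
        assert len(panel.common_targets) == 2


class TestQcExcludeTargets:
    def test_clean_target_kept_noisy_excluded(self):
        panel = _panel()
        controls = {t.target_id: _pile(t.target_id, 120, 1000, other=3) for t in panel.targets}
        controls["M1_2"] = _pile("M1_2", 8, 1000, other=15)
        qc_panel, exclusions = qc_exclude_targets(panel, controls)
        assert [t for t, _ in exclusions] == ["M1_2"]
        assert "M1_2" not in {t.target_id for t in qc_panel.targets}

    def test_all_pass_panel_unchanged(self):
        panel = _panel()
        controls = {t.target_id: _pile(t.target_id, 100, 1000) for t in panel.targets}
        qc_panel, exclusions = qc_exclude_targets(panel, controls)
        assert exclusions == [] and qc_panel.targets == panel.targets

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            qc_exclude_targets(_panel(), {})


class TestEstimateBackground:
    def test_median_of_other_clone_controls(self):
        panel = _panel()
        controls = {}
        for name, freq in (("metA", 0.001), ("metB", 0.003), ("metC", 0.002)):
            controls[name] = (
                "M2",
                {t.target_id: _pile(t.target_id, int(freq * 100_000), 100_000) for t in panel.targets},
            )
        bg = estimate_background(panel, controls)
        assert bg["M1_1"] == pytest.approx(0.002)
        # controls are all dominated by M2, so M2 targets have no eligible control
        assert bg["M2_1"] == 0.0

    def test_single_control_used_directly(self):
        panel = _panel()
        controls = {
            "met": ("M2", {t.target_id: _pile(t.target_id, 30, 10_000) for t in panel.targets})
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bg = estimate_background(panel, controls)
        assert bg["M1_1"] == pytest.approx(0.003)

    def test_binomial_background_recovery(self):
        # true background 0.002 at depth 50,000: estimates within +-0.0005
        rng = np.random.default_rng(17)
        panel = _panel(clones=("M1", "M2", "M3", "M4"))
        controls = {}
        for clone in ("M2", "M3", "M4"):
            piles = {
                t.target_id: _pile(t.target_id, int(rng.binomial(50_000, 0.002)), 50_000)
                for t in panel.targets
            }
            controls[f"met_{clone}"] = (clone, piles)
        bg = estimate_background(panel, controls)
        for t_id in ("M1_1", "M1_2"):
            assert bg[t_id] == pytest.approx(0.002, abs=0.0005)


class TestEstimatePurity:
    def test_median_observed_over_expected(self):
        panel = _panel(n_common=4)
        fracs = [0.20, 0.20, 0.21, 0.19]
        piles = {
            f"COMMON_{i}": _pile(f"COMMON_{i}", int(f * 10_000), 10_000)
            for i, f in enumerate(fracs, start=1)
        }
        est = estimate_purity_common(piles, panel, expected_fraction=0.25)
        assert est.value == pytest.approx(0.8)

    def test_fully_pure_sample(self):
        panel = _panel(n_common=2)
        piles = {f"COMMON_{i}": _pile(f"COMMON_{i}", 2500, 10_000) for i in (1, 2)}
        assert estimate_purity_common(piles, panel, 0.25).value == pytest.approx(1.0)

    def test_binomial_purity_recovery(self):
        rng = np.random.default_rng(23)
        panel = _panel(n_common=4)
        piles = {
            f"COMMON_{i}": _pile(f"COMMON_{i}", int(rng.binomial(20_000, 0.6 * 0.25)), 20_000)
            for i in (1, 2, 3, 4)
        }
        assert estimate_purity_common(piles, panel, 0.25).value == pytest.approx(0.6, abs=0.02)

    def test_no_covered_common_targets_rejected(self):
        with pytest.raises(ValueError):
            estimate_purity_common({}, _panel(), 0.25)


class TestEstimateCloneFractions:
    def test_stated_formula(self):
        # median private freq 0.05, bg 0, ploidy 4, purity 0.8 -> 25%
        panel = _panel(clones=("M1",), n_private=4, n_common=0)
        freqs = [0.050, 0.052, 0.048, 0.050]
        piles = {
            f"M1_{i}": _pile(f"M1_{i}", int(f * 100_000), 100_000)
            for i, f in enumerate(freqs, start=1)
        }
        est = estimate_clone_fractions(piles, panel, {}, purity=0.8, ploidy=4)
        assert est.percentages["M1"] == pytest.approx(25.0, abs=0.1)

    def test_zero_background_purity_one_exact(self):
        panel = _panel(clones=("M1", "M2"), n_private=2, n_common=0)
        piles = {
            "M1_1": _pile("M1_1", 600, 10_000),
            "M1_2": _pile("M1_2", 640, 10_000),
            "M2_1": _pile("M2_1", 100, 10_000),
            "M2_2": _pile("M2_2", 120, 10_000),
        }
        est = estimate_clone_fractions(piles, panel, {}, purity=1.0, ploidy=4)
        assert est.fractions["M1"] == pytest.approx(4 * 0.062)
        assert est.fractions["M2"] == pytest.approx(4 * 0.011)

    def test_depth_invariance(self):
        panel = _panel(clones=("M1",), n_private=2, n_common=0)
        shallow = {"M1_1": _pile("M1_1", 50, 1000), "M1_2": _pile("M1_2", 60, 1000)}
        deep = {"M1_1": _pile("M1_1", 500, 10_000), "M1_2": _pile("M1_2", 600, 10_000)}
        a = estimate_clone_fractions(shallow, panel, {}, 1.0, 4)
        b = estimate_clone_fractions(deep, panel, {}, 1.0, 4)
        assert a.fractions["M1"] == pytest.approx(b.fractions["M1"])

    def test_background_subtraction_floors_at_zero(self):
        panel = _panel(clones=("M1",), n_private=1, n_common=0)
        piles = {"M1_1": _pile("M1_1", 10, 10_000)}
        est = estimate_clone_fractions(piles, panel, {"M1_1": 0.01}, 1.0, 4)
        assert est.fractions["M1"] == 0.0

    def test_clone_without_targets_flagged_undefined(self):
        panel = _panel(clones=("M1", "M2"), n_private=1, n_common=0)
        piles = {"M1_1": _pile("M1_1", 500, 10_000)}
        est = estimate_clone_fractions(piles, panel, {}, 1.0, 4)
        assert "M2" in est.undefined_clones
        assert np.isnan(est.fractions["M2"])

    def test_presence_threshold(self):
        panel = _panel(clones=("M1", "M2"), n_private=1, n_common=0)
        piles = {
            "M1_1": _pile("M1_1", 500, 10_000),
            "M2_1": _pile("M2_1", 10, 10_000),
        }
        est = estimate_clone_fractions(piles, panel, {}, 1.0, 4)
        assert est.present["M1"] and not est.present["M2"]


class TestSimpsonDiversity:
    def test_equal_eight_clones(self):
        assert simpson_diversity([0.125] * 8) == pytest.approx(0.875)

    def test_single_clone(self):
        assert simpson_diversity([1.0]) == 0.0

    def test_two_equal(self):
        assert simpson_diversity([0.5, 0.5]) == pytest.approx(0.5)

    def test_renormalizes_inputs(self):
        assert simpson_diversity([2.0, 2.0]) == pytest.approx(0.5)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            simpson_diversity([0.0, 0.0])


class TestSelectPrivateSnvs:
    SEGMENTS = [CopyNumberSegment("chr1", 0, 10_000, total_cn=4, minor_cn=2)]
    GAIN = [CopyNumberSegment("chr1", 0, 10_000, total_cn=6, minor_cn=2)]

    def _calls(self):
        return {
            "M1": [snv(pos=100, sample="M1")],
            "M2": [snv(pos=200, ref="C", alt="G", sample="M2")],
        }

    def test_clean_private_snv_eligible(self):
        cands = select_private_snvs(self._calls(), {"M1": {}, "M2": {}}, self.SEGMENTS)
        assert {c.clone for c in cands} == {"M1", "M2"}

    def test_single_qualifying_alt_read_elsewhere_disqualifies(self):
        pileups = {
            "M2": {("chr1", 100, "C", "T"): [PileupRead("T", 40, 25)]},
            "M1": {},
        }
        cands = select_private_snvs(self._calls(), pileups, self.SEGMENTS)
        assert {c.clone for c in cands} == {"M2"}

    def test_low_quality_alt_read_tolerated(self):
        pileups = {
            "M2": {("chr1", 100, "C", "T"): [PileupRead("T", 40, 15), PileupRead("T", 10, 35)]},
            "M1": {},
        }
        cands = select_private_snvs(self._calls(), pileups, self.SEGMENTS)
        assert {c.clone for c in cands} == {"M1", "M2"}

    def test_copy_number_gain_ineligible(self):
        cands = select_private_snvs(self._calls(), {"M1": {}, "M2": {}}, self.GAIN)
        assert cands == []

    def test_shared_snv_ineligible(self):
        shared = snv(pos=300)
        calls = {"M1": [shared], "M2": [shared]}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cands = select_private_snvs(calls, {"M1": {}, "M2": {}}, self.SEGMENTS)
        assert cands == []
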