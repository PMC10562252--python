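"""End-to-end pipeline: simulate -> consensus filter -> CCF -> neutrality /
deconvolution / signatures -> summary, with a flat-text run configuration,
a manifest recording seeds, parameter hashes and per-stage record counts,
and bundled fixture presets for the test suite.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional

import numpy as np

from . import ccf as ccf_mod
from . import deconvolution as deconv_mod
from . import io as io_mod
from . import neutrality as neut_mod
from . import signatures as sig_mod
from . import simulate as sim_mod
from . import variants as var_mod

__all__ = [
    "RunConfig",
    "run_pipeline",
    "make_fixture",
    "neoantigen_cohort",
    "immunoediting_contrast",
    "FIXTURE_PRESETS",
]


@dataclass
class RunConfig:
    """Flat key/value configuration driving every pipeline stage.

    ``seed`` has no default: every stochastic stage must be explicitly
    seeded. The config round-trips losslessly through ``to_text`` /
    ``from_text``.
    """

    seed: int
    k_clones: int = 6
    n_private: int = 30
    n_truncal: int = 40
    purity: float = 0.8
    ploidy: int = 2
    coverage: float = 200.0
    territory_mb: float = 30.0
    neoantigen_fraction: float = 0.3
    indel_fraction: float = 0.15
    fp_per_mb: float = 0.5
    anchor_caller: str = "mutect2"
    caller_sensitivities: str = "mutect2:0.95,muse:0.90,vardict:0.90,strelka2:0.90"
    f_min: float = 0.12
    f_max: float = 0.24
    subclonal_inclusive: bool = True
    detection_threshold: float = 0.01
    amplicon_depth: int = 10000
    amplicon_bg: float = 0.002
    n_private_targets: int = 4
    n_common_targets: int = 4
    n_signatures: int = 6
    spectrum_mutations: int = 2000

    def sensitivities(self) -> dict[str, float]:
        out = {}
        for item in self.caller_sensitivities.split(","):
            caller, s = item.split(":")
            out[caller.strip()] = float(s)
        return out

    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        raw: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        kwargs = {}
        for f in fields(cls):
            if f.name not in raw:
                continue
            value = raw.pop(f.name)
            if f.type in ("int", int):
                kwargs[f.name] = int(value)
            elif f.type in ("float", float):
                kwargs[f.name] = float(value)
            elif f.type in ("bool", bool):
                kwargs[f.name] = value.lower() in ("1", "true", "yes")
            else:
                kwargs[f.name] = value
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.from_text(Path(path).read_text())

    def to_file(self, path) -> None:
        Path(path).write_text(self.to_text())


_one_hot_truth = sim_mod.single_clone_truth
_equal_mix_truth = sim_mod.equal_mix_truth


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run every stage deterministically from the config; returns the manifest.

    Writes per-stage tables (truth, consensus VCF, CCF table, neutrality
    curve, clone estimates) plus ``summary.json`` and ``manifest.json`` into
    ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    counts: dict[str, int] = {}

    # --- simulate ---------------------------------------------------------
    truth = sim_mod.simulate_clone_tree(
        config.k_clones,
        config.n_private,
        config.n_truncal,
        seed=seed,
        purity=config.purity,
        ploidy=config.ploidy,
        neoantigen_fraction=config.neoantigen_fraction,
    )
    io_mod.write_truth_tsv(truth, out / "truth.tsv")
    io_mod.write_params_json(truth, out / "truth_params.json")
    counts["truth_variants"] = len(truth.variant_truth)

    reference = sim_mod.simulate_reference({"chr1": 200_000, "chr2": 200_000}, seed + 1)
    true_calls = sim_mod.make_variant_calls(
        truth,
        reference,
        coverage=config.coverage,
        seed=seed + 2,
        indel_fraction=config.indel_fraction,
    )

    # --- consensus and filters -------------------------------------------
    per_caller = sim_mod.simulate_caller_outputs(
        true_calls,
        config.sensitivities(),
        fp_rate=config.fp_per_mb,
        seed=seed + 3,
        territory_mb=config.territory_mb,
    )
    counts.update({f"calls_{c}": len(v) for c, v in per_caller.items()})
    consensus = var_mod.merge_caller_calls(per_caller, anchor_caller=config.anchor_caller)
    counts["consensus"] = len(consensus)
    filtered = var_mod.apply_cohort_filters(consensus)
    counts["post_cohort_filters"] = len(filtered)
    io_mod.write_vcf(filtered, out / "consensus.vcf")

    # --- CCF --------------------------------------------------------------
    segments = [
        ccf_mod.CopyNumberSegment(chrom, 0, len(seq), total_cn=config.ploidy, minor_cn=config.ploidy // 2)
        for chrom, seq in reference.items()
    ]

    def segment_for(v):
        for s in segments:
            if s.covers(v.chrom, v.pos):
                return s
        return None

    ccf_variants = []
    for v in filtered:
        seg = segment_for(v)
        if seg is None or not v.total_depth:
            continue
        ccf_variants.append(
            ccf_mod.compute_ccf(v, config.purity, seg, config.subclonal_inclusive)
        )
    counts["ccf_variants"] = len(ccf_variants)
    io_mod.ccf_variants_to_frame(ccf_variants).to_csv(out / "ccf.tsv", sep="\t", index=False)

    burden = ccf_mod.stratified_burden(ccf_variants, config.territory_mb)
    neo = [cv for cv in ccf_variants if cv.neoantigen]
    neo_burden = ccf_mod.stratified_burden(ccf_variants, config.territory_mb, neoantigens_only=True)
    ith = ccf_mod.ith_index(neo)
    median_ccf = float(np.median([cv.ccf for cv in ccf_variants])) if ccf_variants else math.nan

    # --- neutrality -------------------------------------------------------
    vafs = [cv.variant.vaf for cv in ccf_variants if cv.variant.vaf is not None]
    try:
        fit = neut_mod.fit_neutral(vafs, config.purity, config.f_min, config.f_max)
        neut_summary = {
            "slope": fit.slope,
            "r_squared": fit.r_squared,
            "n_subclonal": fit.n_subclonal,
            "f_min": fit.f_min,
            "f_max": fit.f_max,
        }
        np.savetxt(
            out / "neutrality_curve.tsv",
            np.column_stack([fit.inv_f_grid, fit.m_f]),
            delimiter="\t",
            header="inv_f\tm_f",
            comments="",
        )
        counts["neutrality_points"] = len(fit.m_f)
    except ValueError:
        neut_summary = None
        counts["neutrality_points"] = 0

    # --- deconvolution ----------------------------------------------------
    panel = sim_mod.panel_from_truth(
        truth, config.n_private_targets, config.n_common_targets, seed + 4
    )
    tumor_piles = sim_mod.simulate_amplicon_counts(
        truth, panel, config.amplicon_depth, config.amplicon_bg, seed + 5, "tumor"
    )
    mix_piles = sim_mod.simulate_amplicon_counts(
        _equal_mix_truth(truth), panel, config.amplicon_depth, config.amplicon_bg, seed + 6, "mix"
    )
    controls = {}
    for i, clone in enumerate(truth.clone_ids):
        controls[f"met_{clone}"] = (
            clone,
            sim_mod.simulate_amplicon_counts(
                _one_hot_truth(truth, clone), panel, config.amplicon_depth,
                config.amplicon_bg, seed + 7 + i, f"met_{clone}",
            ),
        )
    panel_qc, exclusions = deconv_mod.qc_exclude_targets(panel, mix_piles)
    backgrounds = deconv_mod.estimate_background(panel_qc, controls)
    purity_est = deconv_mod.estimate_purity_common(
        tumor_piles, panel_qc, expected_fraction=1.0 / truth.ploidy
    )
    estimate = deconv_mod.estimate_clone_fractions(
        tumor_piles,
        panel_qc,
        backgrounds,
        purity=purity_est.value,
        ploidy=truth.ploidy,
        detection_threshold=config.detection_threshold,
    )
    counts["panel_targets"] = len(panel_qc.targets)
    counts["panel_excluded"] = len(exclusions)
    import pandas as pd

    pd.DataFrame(
        [
            {
                "clone": c,
                "true_fraction": truth.proportion_of(c),
                "estimated_fraction": estimate.fractions[c],
                "present": estimate.present[c],
            }
            for c in truth.clone_ids
        ]
    ).to_csv(out / "clone_estimates.tsv", sep="\t", index=False)

    # --- signatures -------------------------------------------------------
    catalogue = sim_mod.make_signature_set(config.n_signatures, seed + 20)
    rng = np.random.default_rng(seed + 21)
    true_fracs = rng.dirichlet(np.ones(config.n_signatures))
    spectrum = sim_mod.simulate_spectrum_from_signatures(
        true_fracs, catalogue, config.spectrum_mutations, seed + 22
    )
    sig_fit = sig_mod.fit_signatures(spectrum, catalogue)
    sig_l1 = float(
        np.abs(np.array([sig_fit.fractions[n] for n in catalogue.names]) - true_fracs).sum()
    )
    counts["spectrum_mutations"] = int(spectrum.total)

    summary = {
        "burden_per_mb": burden,
        "neoantigen_burden_per_mb": neo_burden,
        "ith_index": None if not ith.defined else ith.value,
        "median_ccf": median_ccf,
        "neutrality": neut_summary,
        "deconvolution": {
            "purity_estimate": purity_est.value,
            "fractions": {c: estimate.fractions[c] for c in truth.clone_ids},
            "simpson_d": estimate.simpson_d,
            "excluded_targets": [t for t, _ in exclusions],
        },
        "signatures": {
            "cosine": sig_fit.cosine,
            "l1_fraction_error": sig_l1,
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    config_text = config.to_text()
    manifest = {
        "config": config_text,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": seed,
        "record_counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# Cohort helpers (immunoediting contrast)
# ---------------------------------------------------------------------------


def neoantigen_cohort(
    seed: int,
    k_clones: int = 12,
    base_truncal: int = 200,
    base_private: int = 25,
    burden_cv: float = 0.6,
) -> sim_mod.SyntheticTruth:
    """One tumor's worth of neoantigen-bearing variants.

    Star-with-trunk tree with many small subclones (Dirichlet proportions,
    mean 1/k) and a truncal trunk. The per-tumor mutation burden carries a
    lognormal tumor-level multiplier (CV ``burden_cv``), emulating the large
    between-animal spread of mutational burden in hypermutated cohorts.
    """
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + burden_cv**2))
    factor = float(rng.lognormal(-0.5 * sigma * sigma, sigma))
    return sim_mod.simulate_clone_tree(
        k_clones,
        n_private=max(1, round(base_private * factor)),
        n_truncal=max(1, round(base_truncal * factor)),
        seed=seed + 1,
        neoantigen_fraction=1.0,
    )


def _truth_burden(truth: sim_mod.SyntheticTruth, subclonal_inclusive: bool = True) -> dict:
    ccfs = [vt.ccf for vt in truth.variant_truth if vt.neoantigen]
    return {
        "clonal": sum(c >= ccf_mod.CLONAL_CCF_MIN for c in ccfs),
        "subclonal": sum(
            (c <= ccf_mod.SUBCLONAL_CCF_MAX if subclonal_inclusive else c < ccf_mod.SUBCLONAL_CCF_MAX)
            for c in ccfs
        ),
        "ccfs": ccfs,
    }


def immunoediting_contrast(n_seeds: int, strength: float, seed: int) -> list[dict]:
    """Per-seed paired cohorts: an unedited arm and an independently
    simulated, immunoedited arm, with clonal/subclonal neoantigen counts.

    The two arms of each pair are independent tumors (as treatment arms in
    an animal study are different animals), so tumor-level burden
    variability enters the comparison.
    """
    records = []
    for i in range(n_seeds):
        unedited = neoantigen_cohort(seed + 1000 * i)
        edited_base = neoantigen_cohort(seed + 1000 * i + 500)
        edited = sim_mod.apply_immunoediting(edited_base, strength, seed + 1000 * i + 999)
        rec_u = _truth_burden(unedited)
        rec_e = _truth_burden(edited)
        records.append(
            {
                "seed_index": i,
                "unedited_clonal": rec_u["clonal"],
                "unedited_subclonal": rec_u["subclonal"],
                "edited_clonal": rec_e["clonal"],
                "edited_subclonal": rec_e["subclonal"],
                "unedited_ccfs": rec_u["ccfs"],
                "edited_ccfs": rec_e["ccfs"],
            }
        )
    return records


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

FIXTURE_PRESETS = ("equal8", "edited_vs_depleted", "neutral_vs_selected")


def make_fixture(name: str, out_dir, seed: int = 20230914) -> dict:
    """Write a bundled small dataset plus an expectations file.

    Presets: ``equal8`` (8-clone equal mixture with amplicon counts),
    ``neutral_vs_selected`` (neutral vs two-clone frequency cohorts) and
    ``edited_vs_depleted`` (paired immunoedited/unedited cohorts).
    Returns the expectations dict that is also written as JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if name == "equal8":
        truth = sim_mod.simulate_clone_tree(
            8, 8, 8, seed=seed, proportions=np.full(8, 0.125), purity=0.8, ploidy=4
        )
        panel = sim_mod.panel_from_truth(truth, 4, 4, seed + 1)
        tumor = sim_mod.simulate_amplicon_counts(truth, panel, 10000, 0.002, seed + 2, "tumor")
        mix = sim_mod.simulate_amplicon_counts(
            _equal_mix_truth(truth), panel, 10000, 0.002, seed + 3, "mix"
        )
        control_piles = []
        control_map = {}
        for i, clone in enumerate(truth.clone_ids):
            piles = sim_mod.simulate_amplicon_counts(
                _one_hot_truth(truth, clone), panel, 10000, 0.002, seed + 4 + i, f"met_{clone}"
            )
            control_piles.extend(piles.values())
            control_map[f"met_{clone}"] = clone
        io_mod.write_truth_tsv(truth, out / "truth.tsv")
        io_mod.write_params_json(truth, out / "truth_params.json")
        io_mod.write_panel_tsv(panel, out / "panel.tsv")
        io_mod.write_pileups_tsv(
            list(tumor.values()) + list(mix.values()) + control_piles, out / "pileups.tsv"
        )
        expectations = {
            "clone_fractions": {c: 0.125 for c in truth.clone_ids},
            "purity": 0.8,
            "ploidy": 4,
            "simpson_d": 0.875,
            "equal_mix_sample": "mix",
            "tumor_sample": "tumor",
            "controls": control_map,
        }
    elif name == "neutral_vs_selected":
        mu_over_beta = 50.0
        f_min, f_max = 0.12, 0.24
        neutral = sim_mod.simulate_neutral_vafs(mu_over_beta, f_min, f_max, seed)
        rng = np.random.default_rng(seed + 1)
        n_half = neutral.size // 2
        selected = np.concatenate(
            [
                sim_mod.simulate_neutral_vafs(mu_over_beta / 2, f_min, f_max, seed + 2),
                rng.normal(0.2, 0.004, size=n_half),  # strong subclone cluster
            ]
        )
        np.savetxt(out / "neutral_vafs.tsv", neutral, header="vaf", comments="")
        np.savetxt(out / "selected_vafs.tsv", selected, header="vaf", comments="")
        expectations = {
            "mu_over_beta": mu_over_beta,
            "f_min": f_min,
            "f_max": f_max,
            "purity": 1.0,
            "direction": "neutral r_squared exceeds selected r_squared",
        }
    elif name == "edited_vs_depleted":
        records = immunoediting_contrast(n_seeds=20, strength=2.0, seed=seed)
        import pandas as pd

        pd.DataFrame(
            [{k: v for k, v in r.items() if not k.endswith("ccfs")} for r in records]
        ).to_csv(out / "cohort_burdens.tsv", sep="\t", index=False)
        expectations = {
            "strength": 2.0,
            "n_seeds": 20,
            "direction": "clonal neoantigen burden lower in edited arm; subclonal not significantly different",
        }
    else:
        raise ValueError(f"unknown fixture preset {name!r}; choose from {FIXTURE_PRESETS}")
    (out / "expectations.json").write_text(json.dumps(expectations, indent=2, sort_keys=True) + "\n")
    return expectations
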