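"""Readers and writers for the package's on-disk formats.

Variant call sets round-trip through minimal VCF 4.2 (CHROM/POS/REF/ALT with
AD/DP sample fields and INFO tags for the caller set, dbSNP membership,
microsatellite annotation and neoantigen flag). Tabular data (ground truth,
amplicon panels and pileups, copy-number segments, exon coverage) round-trip
through TSV; coverage tracks additionally serialize as BED with a depth
column. Simulation parameters are written as a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .ccf import CCFVariant, CopyNumberSegment
from .deconvolution import AmpliconPanel, AmpliconPileup, AmpliconTarget
from .purity import ExonCoverage
from .simulate import SyntheticTruth, VariantTruth
from .variants import MicrosatelliteAnnotation, VariantCall

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_truth_tsv",
    "read_truth_tsv",
    "write_params_json",
    "write_panel_tsv",
    "read_panel_tsv",
    "write_pileups_tsv",
    "read_pileups_tsv",
    "write_segments_tsv",
    "read_segments_tsv",
    "write_coverage_bed",
    "read_coverage_bed",
    "write_coverage_tsv",
    "read_coverage_tsv",
    "ccf_variants_to_frame",
    "read_fasta",
]

_VCF_HEADER_LINES = [
    ('INFO', 'CALLERS', '.', 'String', 'Callers supporting the variant'),
    ('INFO', 'DBSNP', '0', 'Flag', 'Position overlaps a known dbSNP site'),
    ('INFO', 'NEO', '0', 'Flag', 'Variant is annotated as neoantigen-bearing'),
    ('INFO', 'MS_MOTIF', '1', 'String', 'Microsatellite motif at the locus'),
    ('INFO', 'MS_REPEATS', '1', 'Integer', 'Microsatellite repeat count'),
    ('INFO', 'MS_SCORE', '1', 'Integer', 'Microsatellite repeat score'),
    ('INFO', 'ANIMAL', '1', 'String', 'Animal of origin'),
    ('INFO', 'VID', '1', 'String', 'Simulation variant identifier'),
    ('FORMAT', 'AD', 'R', 'Integer', 'Allelic depths (ref, alt)'),
    ('FORMAT', 'DP', '1', 'Integer', 'Total read depth'),
]


def write_vcf(variants: Sequence[VariantCall], path, sample_id: Optional[str] = None) -> None:
    """Write a single-sample VCF. All variants must share one sample."""
    samples = {v.sample_id for v in variants}
    if sample_id is None:
        if len(samples) > 1:
            raise ValueError(f"variants span multiple samples {sorted(samples)}; write per sample")
        sample_id = samples.pop() if samples else "SAMPLE"
    header = pysam.VariantHeader()
    for kind, name, number, vtype, desc in _VCF_HEADER_LINES:
        header.add_meta(
            kind,
            items=[("ID", name), ("Number", number), ("Type", vtype), ("Description", desc)],
        )
    for chrom in sorted({v.chrom for v in variants}):
        header.contigs.add(chrom)
    header.add_sample(sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            rec = vcf.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            if v.callers:
                rec.info["CALLERS"] = ",".join(sorted(v.callers))
            if v.in_dbsnp:
                rec.info["DBSNP"] = True
            if v.neoantigen:
                rec.info["NEO"] = True
            if v.microsatellite is not None:
                rec.info["MS_MOTIF"] = v.microsatellite.motif
                rec.info["MS_REPEATS"] = v.microsatellite.repeat_count
                rec.info["MS_SCORE"] = v.microsatellite.score
            if v.animal_id is not None:
                rec.info["ANIMAL"] = v.animal_id
            if v.variant_id is not None:
                rec.info["VID"] = v.variant_id
            if v.total_depth is not None and v.alt_depth is not None:
                rec.samples[sample_id]["AD"] = (v.total_depth - v.alt_depth, v.alt_depth)
                rec.samples[sample_id]["DP"] = v.total_depth
            vcf.write(rec)


def read_vcf(path) -> list[VariantCall]:
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_id = vcf.header.samples[0] if len(vcf.header.samples) else "SAMPLE"
        for rec in vcf:
            info = rec.info
            callers = info.get("CALLERS")
            if callers:
                callers = frozenset(",".join(callers).split(",") if isinstance(callers, tuple) else str(callers).split(","))
            else:
                callers = frozenset()
            ms = None
            if "MS_MOTIF" in info:
                ms = MicrosatelliteAnnotation(
                    motif=str(info["MS_MOTIF"]),
                    repeat_count=int(info["MS_REPEATS"]),
                    score=int(info.get("MS_SCORE", 0)),
                    region_start=0,
                    region_length=0,
                )
            ad = dp = None
            if len(rec.samples):
                fmt = rec.samples[sample_id]
                if fmt.get("AD") is not None:
                    ad = fmt["AD"][1]
                if fmt.get("DP") is not None:
                    dp = fmt["DP"]
            out.append(
                VariantCall(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    sample_id=sample_id,
                    animal_id=str(info["ANIMAL"]) if "ANIMAL" in info else None,
                    alt_depth=ad,
                    total_depth=dp,
                    callers=callers,
                    in_dbsnp=bool(info.get("DBSNP", False)),
                    neoantigen=bool(info.get("NEO", False)),
                    microsatellite=ms,
                    variant_id=str(info["VID"]) if "VID" in info else None,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


def write_truth_tsv(truth: SyntheticTruth, path) -> None:
    rows = [
        {
            "variant_id": vt.variant_id,
            "clones": ";".join(sorted(vt.clones)),
            "ccf": repr(vt.ccf),  # repr round-trips bit-exactly

            "multiplicity": vt.multiplicity,
            "neoantigen": int(vt.neoantigen),
        }
        for vt in truth.variant_truth
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_params_json(truth: SyntheticTruth, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "clone_ids": list(truth.clone_ids),
                "clone_proportions": [float(p) for p in truth.clone_proportions],
                "purity": truth.purity,
                "ploidy": truth.ploidy,
                "seed": truth.seed,
                "n_variants": len(truth.variant_truth),
            },
            indent=2,
        )
        + "\n"
    )


def read_truth_tsv(tsv_path, params_path) -> SyntheticTruth:
    params = json.loads(Path(params_path).read_text())
    df = pd.read_csv(tsv_path, sep="\t", float_precision="round_trip")
    variants = tuple(
        VariantTruth(
            variant_id=str(r.variant_id),
            clones=frozenset(str(r.clones).split(";")),
            ccf=float(r.ccf),
            multiplicity=int(r.multiplicity),
            neoantigen=bool(r.neoantigen),
        )
        for r in df.itertuples()
    )
    return SyntheticTruth(
        clone_ids=tuple(params["clone_ids"]),
        clone_proportions=np.asarray(params["clone_proportions"]),
        purity=params["purity"],
        ploidy=params["ploidy"],
        variant_truth=variants,
        seed=params["seed"],
    )


# ---------------------------------------------------------------------------
# Amplicon panel and pileups
# ---------------------------------------------------------------------------


def write_panel_tsv(panel: AmpliconPanel, path) -> None:
    pd.DataFrame(
        [
            {
                "target_id": t.target_id,
                "chrom": t.chrom,
                "pos": t.pos,
                "ref": t.ref,
                "alt": t.alt,
                "clone": t.clone,
            }
            for t in panel.targets
        ]
    ).to_csv(path, sep="\t", index=False)


def read_panel_tsv(path) -> AmpliconPanel:
    df = pd.read_csv(path, sep="\t")
    targets = tuple(
        AmpliconTarget(str(r.target_id), str(r.chrom), int(r.pos), str(r.ref), str(r.alt), str(r.clone))
        for r in df.itertuples()
    )
    clones = tuple(dict.fromkeys(t.clone for t in targets if t.clone != "COMMON"))
    return AmpliconPanel(targets=targets, clones=clones)


def write_pileups_tsv(pileups: Iterable[AmpliconPileup], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": p.sample_id,
                "target_id": p.target_id,
                "ref_count": p.ref_count,
                "alt_count": p.alt_count,
                "other_alt_count": p.other_alt_count,
                "min_bq": p.min_bq,
            }
            for p in pileups
        ]
    ).to_csv(path, sep="\t", index=False)


def read_pileups_tsv(path) -> dict[str, dict[str, AmpliconPileup]]:
    """Returns pileups nested as sample_id -> target_id -> AmpliconPileup."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, AmpliconPileup]] = {}
    for r in df.itertuples():
        p = AmpliconPileup(
            sample_id=str(r.sample_id),
            target_id=str(r.target_id),
            ref_count=int(r.ref_count),
            alt_count=int(r.alt_count),
            other_alt_count=int(r.other_alt_count),
            min_bq=int(r.min_bq),
        )
        out.setdefault(p.sample_id, {})[p.target_id] = p
    return out


# ---------------------------------------------------------------------------
# Segments, coverage, CCF tables
# ---------------------------------------------------------------------------


def write_segments_tsv(segments: Iterable[CopyNumberSegment], path) -> None:
    pd.DataFrame(
        [
            {"chrom": s.chrom, "start": s.start, "end": s.end, "total_cn": s.total_cn, "minor_cn": s.minor_cn}
            for s in segments
        ]
    ).to_csv(path, sep="\t", index=False)


def read_segments_tsv(path) -> list[CopyNumberSegment]:
    df = pd.read_csv(path, sep="\t")
    return [
        CopyNumberSegment(str(r.chrom), int(r.start), int(r.end), int(r.total_cn), int(r.minor_cn))
        for r in df.itertuples()
    ]


def write_coverage_tsv(coverage: Iterable[ExonCoverage], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": e.sample_id,
                "gene": e.gene,
                "exon_id": e.exon_id,
                "region_class": e.region_class,
                "median_depth": e.median_depth,
            }
            for e in coverage
        ]
    ).to_csv(path, sep="\t", index=False)


def read_coverage_tsv(path) -> list[ExonCoverage]:
    df = pd.read_csv(path, sep="\t")
    return [
        ExonCoverage(
            sample_id=str(r.sample_id),
            exon_id=str(r.exon_id),
            gene=str(r.gene),
            region_class=str(r.region_class),
            median_depth=float(r.median_depth),
        )
        for r in df.itertuples()
    ]


def write_coverage_bed(coverage: Iterable[ExonCoverage], path) -> None:
    """BED with a depth column: chrom, start, end, name, depth. The name
    packs sample/gene/exon/class so the record round-trips."""
    with open(path, "w") as fh:
        for e in coverage:
            if e.chrom is None:
                raise ValueError(f"exon {e.exon_id} has no coordinates; use the TSV writer")
            name = f"{e.sample_id}|{e.gene}|{e.exon_id}|{e.region_class}"
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{name}\t{e.median_depth:.4f}\n")


def read_coverage_bed(path) -> list[ExonCoverage]:
    out = []
    with open(path) as fh:
        for line in fh:
            chrom, start, end, name, depth = line.rstrip("\n").split("\t")
            sample, gene, exon, region_class = name.split("|")
            out.append(
                ExonCoverage(
                    sample_id=sample,
                    exon_id=exon,
                    gene=gene,
                    region_class=region_class,
                    median_depth=float(depth),
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                )
            )
    return out


def ccf_variants_to_frame(ccf_variants: Sequence[CCFVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": cv.variant.chrom,
                "pos": cv.variant.pos,
                "ref": cv.variant.ref,
                "alt": cv.variant.alt,
                "sample_id": cv.variant.sample_id,
                "vaf": cv.variant.vaf,
                "multiplicity": cv.multiplicity,
                "ccf": cv.ccf,
                "ccf_raw": cv.ccf_raw,
                "clonality": cv.clonality,
                "neoantigen": int(cv.neoantigen),
            }
            for cv in ccf_variants
        ]
    )


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file into a chrom -> sequence dict (creates a .fai index)."""
    with pysam.FastaFile(str(path)) as fa:
        return {name: fa.fetch(name) for name in fa.references}
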