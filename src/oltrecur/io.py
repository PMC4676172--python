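"""Readers and writers for the pipeline's file formats.

Tab-separated tables for variants, genotype panels, binned coverage,
counts and clinical data; a minimal VCF 4.2 (AD/DP) per patient; BED for
segments and region catalogs (0-based half-open); JSON for ground truth
and reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .simulate import Cohort, SimulationConfig

VARIANT_COLUMNS = [
    "patient", "specimen", "chrom", "pos", "ref", "alt",
    "ref_reads", "alt_reads", "gene", "effect",
]
PANEL_COLUMNS = [
    "patient", "specimen", "chrom", "pos", "ref", "alt",
    "genotype", "depth", "alt_reads",
]


def read_variant_table(path: str | Path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    t["gene"] = t.get("gene", "").fillna("") if "gene" in t else ""
    return t


def read_genotype_panel(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})


def read_coverage(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3+ with optional name/score columns mapped to state/n_bins."""
    names = ["chrom", "start", "end", "state", "n_bins", "mean_log2"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path: str | Path, extra: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra or [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_vcf(
    variants: pd.DataFrame, path: str | Path, contigs: dict[str, int]
) -> None:
    """Minimal multi-sample VCF 4.2 with AD/DP genotype fields.

    One record per (chrom, pos, ref, alt); the specimens present in the
    table become the sample columns.
    """
    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">')
    specimens = list(pd.unique(variants["specimen"]))
    for s in specimens:
        header.add_sample(s)
    v = variants.sort_values(["chrom", "pos", "ref", "alt"], kind="stable")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for (chrom, pos, ref, alt), grp in v.groupby(
            ["chrom", "pos", "ref", "alt"], sort=False
        ):
            rec = out.new_record(contig=chrom, start=int(pos) - 1, alleles=(ref, alt))
            for _, row in grp.iterrows():
                smp = rec.samples[row["specimen"]]
                smp["AD"] = (int(row["ref_reads"]), int(row["alt_reads"]))
                smp["DP"] = int(row["ref_reads"] + row["alt_reads"])
            out.write(rec)


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Emit every cohort input file plus the ground-truth record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = cohort.config

    (outdir / "config.json").write_text(cfg.to_json())
    (outdir / "truth.json").write_text(cohort.truth.to_json())
    cohort.panels[PANEL_COLUMNS].to_csv(outdir / "genotypes.tsv", sep="\t", index=False)
    cohort.variants[VARIANT_COLUMNS].to_csv(outdir / "variants.tsv", sep="\t", index=False)
    contigs = {c: cfg.chrom_length for c in cfg.chrom_names}
    for patient in cfg.sequenced_patients:
        sub = cohort.variants[cohort.variants["patient"] == patient]
        write_vcf(sub, outdir / f"{patient}.vcf", contigs)
    for (patient, specimen), cov in cohort.coverage.items():
        cov.to_csv(outdir / f"coverage_{patient}_{specimen}.tsv", sep="\t", index=False)
    cohort.counts.to_csv(outdir / "counts.tsv", sep="\t")
    cohort.sample_sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    write_bed(cohort.gene_model.assign(name=cohort.gene_model["gene"]),
              outdir / "genes.bed", extra=["name"])
    cohort.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    return outdir


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="list")
        if isinstance(o, pd.Series):
            return o.to_dict()
        if hasattr(o, "__dataclass_fields__"):
            return {k: getattr(o, k) for k in o.__dataclass_fields__}
        return str(o)

    Path(path).write_text(json.dumps(obj, indent=1, default=default))
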