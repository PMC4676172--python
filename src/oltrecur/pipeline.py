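"""End-to-end cohort analysis.

Chains the analysis modules the way the study design dictates: somatic
calling with donor-difference masking per sequenced patient, tumor-origin
and contamination estimation, copy-number segmentation and cross-patient
region discovery, the recurrent-versus-non-recurrent expression contrast,
deleted-region x under-expression candidate integration, and per-candidate
survival models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chimerism, cnv, expression, survival, variants
from .simulate import Cohort, genome_bins


@dataclass
class PatientReport:
    patient: str
    pt_calls: pd.DataFrame
    rt_calls: pd.DataFrame
    partition: variants.SharedUniquePartition
    origin: chimerism.CRResult
    contamination: chimerism.ContaminationEstimate | None
    spectrum_pt: pd.Series
    nonsilent_silent_pt: variants.NonsilentSilentRatio
    segments_pt: pd.DataFrame
    segments_rt: pd.DataFrame


@dataclass
class CohortAnalysis:
    patients: dict[str, PatientReport]
    region_catalog: pd.DataFrame
    shared_del_genes: pd.DataFrame
    size_factors: pd.Series
    folds: pd.DataFrame
    contrast: pd.DataFrame
    underexpressed: list[str]
    candidates: list[str]
    gene_survival: dict[str, dict] = field(default_factory=dict)


def analyze_patient(
    cohort: Cohort,
    patient: str,
    call_params: variants.SomaticCallParams | None = None,
    cn_exclude_log2: float = 0.1,
) -> PatientReport:
    """Run the per-patient variant/contamination/CNV arm of the pipeline."""
    cfg = cohort.config
    pt = cohort.patient_variants(patient, "P_T")
    rt = cohort.patient_variants(patient, "R_T")
    pb = cohort.patient_variants(patient, "P_B")
    nat = cohort.patient_variants(patient, "P_NAT")
    pb_panel = cohort.patient_panel(patient, "P_B")
    rnat_panel = cohort.patient_panel(patient, "R_NAT")
    rt_panel = cohort.patient_panel(patient, "R_T")

    pt_calls = variants.call_somatic(pt, pb, call_params, nat=nat)
    rt_calls = variants.call_somatic(rt, pb, call_params)
    rt_calls = variants.mask_donor_differences(rt_calls, rnat_panel, pb_panel)
    partition = variants.partition_shared_unique(pt_calls, rt_calls)
    callable_bases = cfg.n_chroms * cfg.chrom_length
    origin = chimerism.clonal_relationship(pt_calls, rt_calls, callable_bases)

    # copy number: tumor against its own adjacent normal
    track_pt = cnv.bin_log2_ratios(
        cohort.coverage[(patient, "P_T")], cohort.coverage[(patient, "P_NAT")]
    )
    track_rt = cnv.bin_log2_ratios(
        cohort.coverage[(patient, "R_T")], cohort.coverage[(patient, "R_NAT")]
    )
    seg_pt = cnv.call_states(cnv.segment_binary(track_pt), cfg.purity_pt)
    seg_rt_raw = cnv.segment_binary(track_rt)

    # loci inside CN-aberrant recurrent-tumor segments violate the
    # two-copies-per-cell mixture model and are excluded from the MLE
    excluded = seg_rt_raw[np.abs(seg_rt_raw["mean_log2"]) > cn_exclude_log2]
    germ = chimerism.estimate_contamination_germline(
        rt_panel, pb_panel, rnat_panel, excluded_regions=excluded, eps=cfg.seq_error
    )
    som = chimerism.estimate_contamination_somatic(
        partition.shared, cfg.purity_pt, excluded_regions=excluded
    )
    try:
        contamination = chimerism.combine_contamination(germ, som)
    except ValueError:
        contamination = None

    alpha_hat = 0.0
    if germ.estimable:
        alpha_hat = germ.alpha
    elif som.estimable:
        alpha_hat = som.alpha
    purity_rt_eff = float(np.clip((1.0 - alpha_hat) * cfg.purity_rt, 0.05, 1.0))
    seg_rt = cnv.call_states(seg_rt_raw, purity_rt_eff)

    return PatientReport(
        patient=patient,
        pt_calls=pt_calls,
        rt_calls=rt_calls,
        partition=partition,
        origin=origin,
        contamination=contamination,
        spectrum_pt=variants.substitution_spectrum(pt_calls),
        nonsilent_silent_pt=variants.nonsilent_silent_ratio(pt_calls),
        segments_pt=seg_pt,
        segments_rt=seg_rt,
    )


def analyze_cohort(
    cohort: Cohort,
    k_of_n: int = 3,
    covariates: tuple[str, ...] = ("hbv", "grade", "age_lt_cut", "male"),
    age_cut: float = 49.0,
    call_params: variants.SomaticCallParams | None = None,
) -> CohortAnalysis:
    """Full pipeline on a synthetic cohort.

    Survival models (median-cut log-rank, uni- and multivariate Cox) are
    fitted for every integrated candidate gene on the per-patient fold
    changes against the cohort's recurrence times.
    """
    cfg = cohort.config
    reports = {
        p: analyze_patient(cohort, p, call_params) for p in cfg.sequenced_patients
    }

    bins = genome_bins(cfg)
    catalog = cnv.cross_patient_regions(
        {p: (r.segments_pt, r.segments_rt) for p, r in reports.items()},
        bins,
        k=k_of_n,
    )
    shared_del = catalog[catalog["category"] == "shared-del"]
    if len(shared_del):
        shared_del_genes = cnv.genes_in_regions(shared_del, cohort.gene_model)
    else:
        shared_del_genes = pd.DataFrame(
            columns=["category", "region_chrom", "region_start", "region_end",
                     "gene", "chrom", "start", "end"]
        )

    counts = cohort.counts.loc[(cohort.counts > 0).any(axis=1)]
    size_factors = expression.estimate_size_factors(counts)
    folds = expression.per_patient_fold_changes(counts, size_factors, cohort.sample_sheet)
    labels = (
        cohort.sample_sheet.drop_duplicates("patient")
        .set_index("patient")["recurrent"]
    )
    contrast = expression.group_contrast(folds, labels)
    under = expression.underexpressed_genes(contrast)

    if len(shared_del_genes) and len(under):
        candidates = survival.candidate_integration(shared_del_genes, under)
    else:
        candidates = []

    clin = cohort.clinical.set_index("patient").copy()
    clin["age_lt_cut"] = (clin["age"] < age_cut).astype(int)
    gene_survival: dict[str, dict] = {}
    for gene in candidates:
        vals = folds.loc[gene].reindex(clin.index)
        d = survival.dichotomize_median(vals)
        lr = survival.logrank_test(
            clin["time"].to_numpy(), clin["event"].to_numpy(), d.labels.to_numpy()
        )
        low = (d.labels == "low").astype(float)
        uni = survival.cox_fit(
            clin["time"].to_numpy(), clin["event"].to_numpy(),
            pd.DataFrame({"low": low}), grouping=d,
        )
        multi_X = pd.DataFrame({"low": low}).join(clin[list(covariates)].astype(float))
        try:
            multi = survival.cox_fit(
                clin["time"].to_numpy(), clin["event"].to_numpy(), multi_X, grouping=d
            )
        except ValueError:  # a constant covariate in a small cohort
            multi = None
        gene_survival[gene] = {"dichotomy": d, "logrank": lr, "cox_uni": uni, "cox_multi": multi}

    return CohortAnalysis(
        patients=reports,
        region_catalog=catalog,
        shared_del_genes=shared_del_genes,
        size_factors=size_factors,
        folds=folds,
        contrast=contrast,
        underexpressed=under,
        candidates=candidates,
        gene_survival=gene_survival,
    )
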