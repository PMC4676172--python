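"""Somatic/germline variant classification and summary statistics.

Operates on per-specimen variant tables — records of
``(chrom, pos, ref, alt, ref_reads, alt_reads, gene, effect)`` — and on
germline genotype panels with 0/1/2 alt-allele dosages.  Variant identity
is the ``(chrom, pos, ref, alt)`` key throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import NONSILENT_CLASSES, SPECTRUM_CLASSES, VARIANT_KEY, _COMPLEMENT


@dataclass
class SomaticCallParams:
    """Thresholds of the tumor/normal somatic filter cascade."""

    min_vaf: float = 0.05
    min_alt: int = 4
    max_normal_vaf: float = 0.01
    min_depth: int = 20
    max_nat_vaf: float = 0.05  # secondary exclusion on the adjacent normal


@dataclass
class IdentityReport:
    concordance: float
    n_loci: int
    same_individual: bool
    threshold: float


def _with_vaf(table: pd.DataFrame) -> pd.DataFrame:
    t = table.copy()
    depth = t["ref_reads"] + t["alt_reads"]
    t["depth"] = depth
    t["vaf"] = np.where(depth > 0, t["alt_reads"] / np.where(depth > 0, depth, 1), np.nan)
    return t


def check_identity(
    panel_a: pd.DataFrame,
    panel_b: pd.DataFrame,
    min_depth: int = 20,
    threshold: float = 0.95,
    min_loci: int = 50,
) -> IdentityReport:
    """Genotype concordance between two germline panels.

    Concordance is the fraction of co-covered loci (depth >= ``min_depth``
    in both panels) with identical genotype dosage; two panels are called
    the same individual iff concordance >= ``threshold``.
    """
    m = panel_a.merge(panel_b, on=VARIANT_KEY, suffixes=("_a", "_b"))
    m = m[(m["depth_a"] >= min_depth) & (m["depth_b"] >= min_depth)]
    m = m[(m["genotype_a"] >= 0) & (m["genotype_b"] >= 0)]
    if len(m) < min_loci:
        raise ValueError(
            f"only {len(m)} co-covered loci pass depth {min_depth}; need >= {min_loci}"
        )
    conc = float((m["genotype_a"] == m["genotype_b"]).mean())
    return IdentityReport(conc, len(m), conc >= threshold, threshold)


def call_somatic(
    tumor: pd.DataFrame,
    matched_normal: pd.DataFrame,
    params: SomaticCallParams | None = None,
    nat: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tumor/normal somatic variant calling by a fixed filter cascade.

    A variant is somatic iff tumor VAF >= ``min_vaf``, tumor alt reads >=
    ``min_alt``, matched-normal VAF <= ``max_normal_vaf`` and both depths >=
    ``min_depth``.  When an adjacent-normal table ``nat`` is supplied,
    variants present there above ``max_nat_vaf`` are additionally excluded.

    Returns the somatic call set: one row per passing variant with tumor
    VAF/depth and any gene/effect annotation carried on the tumor table.
    """
    if params is None:
        params = SomaticCallParams()
    if len(tumor) == 0 or len(matched_normal) == 0:
        raise ValueError("empty variant table")
    t = _with_vaf(tumor)
    n = _with_vaf(matched_normal)[VARIANT_KEY + ["depth", "vaf"]]
    m = t.merge(n, on=VARIANT_KEY, suffixes=("", "_normal"))
    keep = (
        (m["vaf"] >= params.min_vaf)
        & (m["alt_reads"] >= params.min_alt)
        & (m["vaf_normal"] <= params.max_normal_vaf)
        & (m["depth"] >= params.min_depth)
        & (m["depth_normal"] >= params.min_depth)
    )
    calls = m.loc[keep].reset_index(drop=True)
    if nat is not None and len(nat):
        a = _with_vaf(nat)[VARIANT_KEY + ["vaf"]].rename(columns={"vaf": "vaf_nat"})
        calls = calls.merge(a, on=VARIANT_KEY, how="left")
        calls = calls[~(calls["vaf_nat"] > params.max_nat_vaf)].reset_index(drop=True)
        calls = calls.drop(columns=["vaf_nat"])
    cols = [c for c in calls.columns if not c.endswith("_normal")]
    return calls[cols]


def mask_donor_differences(
    r_t_calls: pd.DataFrame,
    r_nat_panel: pd.DataFrame,
    p_b_panel: pd.DataFrame,
) -> pd.DataFrame:
    """Drop recurrent-tumor calls at loci where donor and recipient differ.

    Any call whose locus shows a donor (R_NAT) genotype different from the
    recipient (P_B) genotype is removed — those sites reflect
    donor/recipient germline differences leaking through the mixed biopsy,
    not somatic mutation.  Loci absent from both panels are retained with a
    ``donor_check_missing`` flag.  Output is always a subset of the input.
    """
    donor = r_nat_panel[VARIANT_KEY + ["genotype"]].rename(columns={"genotype": "g_donor"})
    recip = p_b_panel[VARIANT_KEY + ["genotype"]].rename(columns={"genotype": "g_recipient"})
    m = r_t_calls.merge(donor, on=VARIANT_KEY, how="left").merge(
        recip, on=VARIANT_KEY, how="left"
    )
    covered = m["g_donor"].notna() & m["g_recipient"].notna()
    differs = covered & (m["g_donor"] != m["g_recipient"])
    out = m.loc[~differs].copy()
    out["donor_check_missing"] = out["g_donor"].isna() & out["g_recipient"].isna()
    return out.drop(columns=["g_donor", "g_recipient"]).reset_index(drop=True)


@dataclass
class SharedUniquePartition:
    """Shared / primary-unique / recurrent-unique partition of somatic calls."""

    shared: pd.DataFrame  # carries vaf_pt and vaf_rt
    pt_unique: pd.DataFrame
    rt_unique: pd.DataFrame
    mean_vaf_shared_pct: float
    mean_vaf_pt_unique_pct: float
    welch_p: float  # NaN (flagged) when a compared group has < 2 variants
    degenerate: bool


def partition_shared_unique(
    p_t: pd.DataFrame, r_t: pd.DataFrame
) -> SharedUniquePartition:
    """Partition P_T and R_T somatic calls by variant-key equality.

    Reports the mean VAF (percent) of shared versus P_T-unique variants and
    a Welch two-sample t-test p-value for their difference.
    """
    if len(p_t) == 0:
        raise ValueError("empty P_T call set")
    pt = _with_vaf(p_t) if "vaf" not in p_t else p_t
    rt = _with_vaf(r_t) if "vaf" not in r_t else r_t
    m = pt.merge(
        rt[VARIANT_KEY + ["vaf"]], on=VARIANT_KEY, how="outer",
        suffixes=("_pt", "_rt"), indicator=True,
    )
    shared = m[m["_merge"] == "both"].drop(columns="_merge").reset_index(drop=True)
    pt_unique = m[m["_merge"] == "left_only"].drop(columns="_merge").reset_index(drop=True)
    rt_unique = m[m["_merge"] == "right_only"].drop(columns="_merge").reset_index(drop=True)

    v_sh = shared["vaf_pt"].dropna().to_numpy() * 100.0
    v_un = pt_unique["vaf_pt"].dropna().to_numpy() * 100.0
    degenerate = len(v_sh) < 2 or len(v_un) < 2
    if degenerate:
        p = float("nan")
    else:
        p = float(stats.ttest_ind(v_sh, v_un, equal_var=False).pvalue)
    return SharedUniquePartition(
        shared=shared,
        pt_unique=pt_unique,
        rt_unique=rt_unique,
        mean_vaf_shared_pct=float(np.mean(v_sh)) if len(v_sh) else float("nan"),
        mean_vaf_pt_unique_pct=float(np.mean(v_un)) if len(v_un) else float("nan"),
        welch_p=p,
        degenerate=degenerate,
    )


def is_snv(table: pd.DataFrame) -> pd.Series:
    return (table["ref"].str.len() == 1) & (table["alt"].str.len() == 1)


def substitution_spectrum(calls: pd.DataFrame) -> pd.Series:
    """Proportions over the 6 strand-collapsed substitution classes.

    Purine-reference substitutions are collapsed onto their
    reverse-complement pyrimidine representation (G>A counts as C>T, etc.).
    Indels are excluded; raises on an SNV-free call set.
    """
    snv = calls.loc[is_snv(calls), ["ref", "alt"]]
    if len(snv) == 0:
        raise ValueError("no SNVs in call set")
    ref = snv["ref"].to_numpy()
    alt = snv["alt"].to_numpy()
    flip = np.isin(ref, ("G", "A"))
    ref = np.where(flip, [ _COMPLEMENT[b] for b in ref ], ref)
    alt = np.where(flip, [ _COMPLEMENT[b] for b in alt ], alt)
    labels = np.char.add(np.char.add(ref.astype("U1"), ">"), alt.astype("U1"))
    counts = pd.Series(labels).value_counts()
    out = pd.Series(0.0, index=list(SPECTRUM_CLASSES))
    out.update(counts / counts.sum())
    return out


@dataclass
class NonsilentSilentRatio:
    ratio: float  # inf when no silent variants
    n_nonsilent: int
    n_silent: int
    infinite: bool


def nonsilent_silent_ratio(calls: pd.DataFrame) -> NonsilentSilentRatio:
    """(nonsynonymous + stop-gain + stop-loss + frameshift) / silent."""
    eff = calls["effect"]
    n_non = int(eff.isin(NONSILENT_CLASSES).sum())
    n_sil = int((eff == "silent").sum())
    if n_sil == 0:
        return NonsilentSilentRatio(float("inf"), n_non, n_sil, True)
    return NonsilentSilentRatio(n_non / n_sil, n_non, n_sil, False)
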