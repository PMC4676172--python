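"""Tumor-origin testing and donor-cell contamination estimation.

After liver transplantation a recurrent tumor biopsy is a mixture of
recipient-derived tumor cells and donor-derived normal liver.  Two
questions follow:

* **origin** — does the recurrent tumor share a clonal origin with the
  recipient's primary tumor?  Answered by a clonal-relationship (CR)
  statistic over the two somatic variant sets: the Jaccard index with a
  Poisson null for the number of variants shared by chance.
* **contamination** — what fraction ``alpha`` of the biopsy's cells are
  donor-derived?  Estimated two independent ways: a binomial maximum
  likelihood over germline SNPs where recipient and donor genotypes differ
  (informative loci), and the dilution of shared clonal somatic VAFs
  between primary and recurrent tumor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import xlogy

from .simulate import VARIANT_KEY


@dataclass
class CRResult:
    cr_value: float
    n_shared: int
    n_union: int
    expected_shared_by_chance: float
    p_value: float
    origin_call: str  # "recipient" | "not-established"


def clonal_relationship(
    p_t: pd.DataFrame,
    r_t: pd.DataFrame,
    callable_bases: int,
    p_threshold: float = 1e-6,
    cr_threshold: float = 0.05,
) -> CRResult:
    """Clonal-relationship value between two somatic call sets.

    ``cr = |intersection| / |union|`` over ``(chrom, pos, ref, alt)`` keys.
    Under independent mutation the number of shared variants is
    approximately Poisson with mean ``|P| * |R| / callable_bases``; the
    reported p-value is the upper tail ``P(X >= observed)``.  The origin is
    called ``recipient`` iff ``p <= p_threshold`` and ``cr >= cr_threshold``.
    """
    if len(p_t) == 0 or len(r_t) == 0:
        raise ValueError("empty somatic call set")
    if callable_bases <= 0:
        raise ValueError("callable_bases must be > 0")
    keys_p = set(map(tuple, p_t[VARIANT_KEY].itertuples(index=False)))
    keys_r = set(map(tuple, r_t[VARIANT_KEY].itertuples(index=False)))
    if callable_bases < max(len(keys_p), len(keys_r)):
        raise ValueError("callable_bases smaller than a call set")
    inter = len(keys_p & keys_r)
    union = len(keys_p | keys_r)
    cr = inter / union
    expected = len(keys_p) * len(keys_r) / callable_bases
    p = float(stats.poisson.sf(inter - 1, expected)) if inter > 0 else 1.0
    call = "recipient" if (p <= p_threshold and cr >= cr_threshold) else "not-established"
    return CRResult(cr, inter, union, expected, p, call)


# ---------------------------------------------------------------------------
# germline-SNP maximum-likelihood estimator
# ---------------------------------------------------------------------------


@dataclass
class AlphaEstimate:
    alpha: float | None
    ci_low: float | None
    ci_high: float | None
    n_loci: int
    method: str
    estimable: bool
    reason: str = ""


def _germline_loglik(
    alpha: np.ndarray, g_r: np.ndarray, g_d: np.ndarray, alt: np.ndarray,
    ref: np.ndarray, eps: float,
) -> np.ndarray:
    """Binomial log-likelihood of alpha over informative loci (vectorized).

    Expected alt fraction at locus i: ``f_i = ((1-a) g_R + a g_D) / 2``,
    folded through the symmetric error rate, ``f' = eps + f (1 - 2 eps)``.
    """
    a = np.atleast_1d(np.asarray(alpha, dtype=float))[:, None]
    f = ((1.0 - a) * g_r[None, :] + a * g_d[None, :]) / 2.0
    fo = eps + f * (1.0 - 2.0 * eps)
    ll = xlogy(alt[None, :], fo) + xlogy(ref[None, :], 1.0 - fo)
    return ll.sum(axis=1)


def estimate_contamination_germline(
    r_t_counts: pd.DataFrame,
    p_b: pd.DataFrame,
    r_nat: pd.DataFrame,
    excluded_regions: pd.DataFrame | None = None,
    eps: float = 1e-3,
    min_depth: int = 20,
    min_informative: int = 30,
    grid_step: float = 0.001,
) -> AlphaEstimate:
    """Donor-contamination MLE from informative germline SNPs.

    Informative loci have recipient genotype (P_B) different from donor
    genotype (R_NAT), depth >= ``min_depth`` in the recurrent-tumor counts,
    and lie outside any excluded copy-number-aberrant segment (the mixture
    model assumes two copies per cell).  The likelihood is maximized on a
    grid of step ``grid_step`` with local bounded refinement; the 95% CI is
    the profile-likelihood interval ``{a : logL(a) >= logL_max - 1.92}``.
    """
    recip = p_b[VARIANT_KEY + ["genotype"]].rename(columns={"genotype": "g_r"})
    donor = r_nat[VARIANT_KEY + ["genotype"]].rename(columns={"genotype": "g_d"})
    m = r_t_counts.merge(recip, on=VARIANT_KEY).merge(donor, on=VARIANT_KEY)
    m = m[(m["g_r"] >= 0) & (m["g_d"] >= 0) & (m["g_r"] != m["g_d"])]
    m = m[m["depth"] >= min_depth]
    if excluded_regions is not None and len(excluded_regions):
        drop = np.zeros(len(m), dtype=bool)
        p0 = m["pos"].to_numpy() - 1
        for _, seg in excluded_regions.iterrows():
            drop |= (
                (m["chrom"].to_numpy() == seg["chrom"])
                & (p0 >= seg["start"])
                & (p0 < seg["end"])
            )
        m = m[~drop]
    n = len(m)
    if n == 0:
        return AlphaEstimate(None, None, None, 0, "germline", False,
                             "no informative loci (donor and recipient genotypes agree)")
    if n < min_informative:
        return AlphaEstimate(None, None, None, n, "germline", False,
                             f"only {n} informative loci; need >= {min_informative}")

    g_r = m["g_r"].to_numpy(dtype=float)
    g_d = m["g_d"].to_numpy(dtype=float)
    alt = m["alt_reads"].to_numpy(dtype=float)
    ref = (m["depth"] - m["alt_reads"]).to_numpy(dtype=float)

    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    ll = _germline_loglik(grid, g_r, g_d, alt, ref, eps)
    i = int(np.argmax(ll))

    lo = max(0.0, grid[i] - grid_step)
    hi = min(1.0, grid[i] + grid_step)
    res = optimize.minimize_scalar(
        lambda a: -_germline_loglik(a, g_r, g_d, alt, ref, eps)[0],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-9},
    )
    candidates = np.array([0.0, 1.0, grid[i], float(res.x)])
    cand_ll = _germline_loglik(candidates, g_r, g_d, alt, ref, eps)
    best = int(np.argmax(cand_ll))
    alpha_hat = float(candidates[best])
    ll_max = float(cand_ll[best])

    # profile-likelihood CI on the grid, refined by linear interpolation
    thr = ll_max - 1.92
    ok = ll >= thr
    if not ok.any():  # maximum between grid points; fall back to the point
        ci_lo = ci_hi = alpha_hat
    else:
        j_lo, j_hi = int(np.argmax(ok)), int(len(ok) - 1 - np.argmax(ok[::-1]))
        ci_lo, ci_hi = grid[j_lo], grid[j_hi]
        if j_lo > 0:
            a0, a1, l0, l1 = grid[j_lo - 1], grid[j_lo], ll[j_lo - 1], ll[j_lo]
            ci_lo = a0 + (thr - l0) / (l1 - l0) * (a1 - a0)
        if j_hi < len(grid) - 1:
            a0, a1, l0, l1 = grid[j_hi], grid[j_hi + 1], ll[j_hi], ll[j_hi + 1]
            ci_hi = a0 + (thr - l0) / (l1 - l0) * (a1 - a0)
    return AlphaEstimate(
        alpha_hat, float(np.clip(ci_lo, 0, 1)), float(np.clip(ci_hi, 0, 1)),
        n, "germline", True,
    )


# ---------------------------------------------------------------------------
# somatic dilution estimator
# ---------------------------------------------------------------------------


def estimate_contamination_somatic(
    shared: pd.DataFrame,
    purity_pt: float,
    clonal_factor: float = 0.8,
    min_clonal: int = 10,
    n_boot: int = 1000,
    seed: int = 0,
    excluded_regions: pd.DataFrame | None = None,
) -> AlphaEstimate:
    """Donor contamination from the dilution of shared clonal somatic VAFs.

    Under equal primary/recurrent tumor purity a shared clonal variant's
    recurrent-tumor VAF is ``(1 - alpha)`` times its primary-tumor VAF, so
    ``alpha = 1 - median(VAF_RT / VAF_PT)`` over clonal shared variants
    (``VAF_PT >= clonal_factor * purity_pt / 2``, copy-number-neutral loci
    only).  The 95% CI comes from a seeded percentile bootstrap over loci.
    """
    if not (0 < purity_pt <= 1):
        raise ValueError("purity must lie in (0, 1]")
    s = shared
    if excluded_regions is not None and len(excluded_regions):
        keep = np.ones(len(s), dtype=bool)
        p0 = s["pos"].to_numpy() - 1
        for _, seg in excluded_regions.iterrows():
            keep &= ~(
                (s["chrom"].to_numpy() == seg["chrom"])
                & (p0 >= seg["start"])
                & (p0 < seg["end"])
            )
        s = s[keep]
    clonal = s[s["vaf_pt"] >= clonal_factor * purity_pt / 2.0]
    clonal = clonal[clonal["vaf_pt"] > 0]
    n = len(clonal)
    if n < min_clonal:
        return AlphaEstimate(None, None, None, n, "somatic", False,
                             f"only {n} clonal shared variants; need >= {min_clonal}")
    ratio = (clonal["vaf_rt"] / clonal["vaf_pt"]).to_numpy()
    alpha_hat = float(np.clip(1.0 - np.median(ratio), 0.0, 1.0))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = np.clip(1.0 - np.median(ratio[idx], axis=1), 0.0, 1.0)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return AlphaEstimate(alpha_hat, float(lo), float(hi), n, "somatic", True)


@dataclass
class ContaminationEstimate:
    germline: AlphaEstimate | None
    somatic: AlphaEstimate | None
    combined_low: float
    combined_high: float

    def as_percent_range(self) -> str:
        lo = round(self.combined_low * 100)
        hi = round(self.combined_high * 100)
        return f"{lo} %" if lo == hi else f"{lo}–{hi} %"


def combine_contamination(
    germline: AlphaEstimate | None, somatic: AlphaEstimate | None
) -> ContaminationEstimate:
    """Combine the two estimators into a reporting range.

    The combined range is the min/max envelope of the available point
    estimates; with a single estimator it collapses to a point.  Raises
    when neither estimator succeeded.
    """
    points = [
        e.alpha
        for e in (germline, somatic)
        if e is not None and e.estimable and e.alpha is not None
    ]
    if not points:
        raise ValueError("neither contamination estimator produced an estimate")
    return ContaminationEstimate(germline, somatic, min(points), max(points))
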