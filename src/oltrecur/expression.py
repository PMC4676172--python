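"""Count normalization and negative-binomial differential expression.

Median-of-ratios size factors, within-patient tumor/normal log2 fold
changes, a sum-conditioned NB exact test for single tumor/normal pairs
(dispersion borrowed from a method-of-moments trend fitted on a
pseudo-replicate group), and a recurrent-versus-non-recurrent group
contrast on the per-patient fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    For genes expressed in every sample, each count is divided by the
    gene's geometric mean across samples; the sample's factor is the median
    of those ratios.  Raises when no gene is expressed in all samples.
    """
    k = counts.to_numpy(dtype=float)
    expressed = (k > 0).all(axis=1)
    if not expressed.any():
        raise ValueError("no gene with nonzero count in all samples")
    logk = np.log(k[expressed])
    log_gm = logk.mean(axis=1, keepdims=True)
    # median taken on the ratio scale (not of the log ratios): with an even
    # number of genes the two differ slightly
    factors = np.median(np.exp(logk - log_gm), axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def per_patient_fold_changes(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    sample_sheet: pd.DataFrame,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """log2 fold change of normalized P_T over matched P_NAT per patient.

    ``F_gp = log2((K_PT/s_PT + c) / (K_PNAT/s_PNAT + c))``.  Raises when a
    patient lacks either mate sample.
    """
    folds = {}
    for patient, grp in sample_sheet.groupby("patient", sort=False):
        roles = dict(zip(grp["role"], grp["sample"]))
        if "P_T" not in roles or "P_NAT" not in roles:
            raise ValueError(f"patient {patient} lacks a matched P_T/P_NAT pair")
        t = counts[roles["P_T"]] / size_factors[roles["P_T"]]
        n = counts[roles["P_NAT"]] / size_factors[roles["P_NAT"]]
        folds[patient] = np.log2((t + pseudocount) / (n + pseudocount))
    return pd.DataFrame(folds)


@dataclass
class DispersionTrend:
    """NB dispersion trend ``phi(mu) = a0 + a1 / mu`` (floored at 1e-8)."""

    a0: float
    a1: float
    floor: float = 1e-8

    def __call__(self, mu: np.ndarray | float) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        with np.errstate(divide="ignore"):
            phi = self.a0 + self.a1 / np.where(mu > 0, mu, np.inf)
        return np.maximum(phi, self.floor)


def fit_dispersion_trend(
    counts: pd.DataFrame, group: list[str], size_factors: pd.Series | None = None
) -> DispersionTrend:
    """Method-of-moments dispersion trend from a pseudo-replicate group.

    Per-gene dispersions ``(s^2 - mu) / mu^2`` of the size-factor-normalized
    counts across the group are regressed on ``1/mu`` by least squares.
    Needs >= 2 samples.
    """
    if len(group) < 2:
        raise ValueError("need >= 2 samples to estimate dispersion")
    sub = counts[group]
    if size_factors is None:
        size_factors = estimate_size_factors(sub)
    norm = sub.to_numpy(dtype=float) / size_factors[group].to_numpy()[None, :]
    mu = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    keep = mu > 0
    mu, var = mu[keep], var[keep]
    phi = (var - mu) / mu**2
    X = np.column_stack([np.ones_like(mu), 1.0 / mu])
    coef, *_ = np.linalg.lstsq(X, phi, rcond=None)
    return DispersionTrend(float(coef[0]), float(coef[1]))


def _nb_logpmf(k: np.ndarray, mean: float, phi: float) -> np.ndarray:
    r = 1.0 / phi
    return stats.nbinom.logpmf(k, r, r / (r + mean))


def nb_pair_test(
    k_a: np.ndarray,
    k_b: np.ndarray,
    s_a: float,
    s_b: float,
    trend: DispersionTrend,
    genes: pd.Index | None = None,
    fold_threshold: float = 1.0,
    p_threshold: float = 0.01,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Sum-conditioned NB exact test between one tumor/normal sample pair.

    For each gene, given the observed total ``T = k_A + k_B``, the common
    mean is estimated as the average normalized count and the dispersion is
    read off the trend; the two-sided p-value is the total probability of
    all splits of ``T`` no more likely than the observed one under the two
    independent NB marginals, renormalized over all splits.  A zero total
    yields p = 1 by convention.  A gene passes at ``p < p_threshold`` and
    ``|log2 fold| > fold_threshold``.
    """
    k_a = np.asarray(k_a, dtype=int)
    k_b = np.asarray(k_b, dtype=int)
    if genes is None:
        genes = pd.RangeIndex(len(k_a))
    pvals = np.ones(len(k_a))
    for g in range(len(k_a)):
        total = int(k_a[g] + k_b[g])
        if total == 0:
            continue
        mu = (k_a[g] / s_a + k_b[g] / s_b) / 2.0
        phi = float(trend(mu))
        a = np.arange(total + 1)
        logp = _nb_logpmf(a, mu * s_a, phi) + _nb_logpmf(total - a, mu * s_b, phi)
        obs = logp[k_a[g]]
        num = np.logaddexp.reduce(logp[logp <= obs + 1e-10])
        den = np.logaddexp.reduce(logp)
        pvals[g] = min(1.0, float(np.exp(num - den)))
    effect = np.log2((k_a / s_a + pseudocount) / (k_b / s_b + pseudocount))
    out = pd.DataFrame(
        {
            "effect": effect,
            "pvalue": pvals,
            "pass": (pvals < p_threshold) & (np.abs(effect) > fold_threshold),
            "direction": np.where(effect < 0, "down", "up"),
        },
        index=genes,
    )
    return out


def group_contrast(
    folds: pd.DataFrame,
    labels: pd.Series | dict[str, int],
    effect_threshold: float = 1.0,
    p_threshold: float = 0.01,
    method: str = "welch",
) -> pd.DataFrame:
    """Recurrent-versus-non-recurrent contrast on per-patient fold changes.

    Per gene, the per-patient log2 folds of recurrent patients are compared
    against non-recurrent patients (Welch t by default, Mann-Whitney as an
    alternative).  A gene passes at ``|effect| >= effect_threshold`` (log2
    units, i.e. a 2-fold difference at the default) and raw
    ``p < p_threshold``; no multiplicity adjustment is applied.  The
    under-expressed subset is ``pass & effect < 0``.
    """
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    labels = labels.reindex(folds.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some patients")
    rec = folds.loc[:, labels.astype(bool).to_numpy()].to_numpy()
    non = folds.loc[:, ~labels.astype(bool).to_numpy()].to_numpy()
    if rec.shape[1] < 2 or non.shape[1] < 2:
        raise ValueError("need >= 2 patients per group")
    effect = rec.mean(axis=1) - non.mean(axis=1)
    degenerate = (rec.std(axis=1) == 0) & (non.std(axis=1) == 0)
    if method == "welch":
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(rec, non, axis=1, equal_var=False)
        p = np.asarray(res.pvalue)
    elif method == "mannwhitney":
        p = np.array(
            [stats.mannwhitneyu(r, n_, alternative="two-sided").pvalue
             for r, n_ in zip(rec, non)]
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    p = np.where(degenerate & (effect == 0), 1.0, p)
    p = np.where(degenerate & (effect != 0), 0.0, p)
    passed = (np.abs(effect) >= effect_threshold) & (p < p_threshold)
    return pd.DataFrame(
        {
            "effect": effect,
            "pvalue": p,
            "pass": passed,
            "direction": np.where(effect < 0, "down", "up"),
            "degenerate": degenerate,
        },
        index=folds.index,
    )


def underexpressed_genes(contrast: pd.DataFrame) -> list[str]:
    """Genes passing the contrast with a negative effect."""
    sel = contrast[(contrast["pass"]) & (contrast["effect"] < 0)]
    return list(sel.index)
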