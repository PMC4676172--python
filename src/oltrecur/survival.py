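"""Prognostic survival screening.

Expression dichotomization (median cut, or reference mean minus k standard
deviations), Kaplan-Meier product-limit curves, the two-group log-rank
test, Cox proportional-hazards regression with Efron tie handling, and the
candidate-gene integration / region-wide specificity screen built on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# dichotomization
# ---------------------------------------------------------------------------


@dataclass
class Dichotomy:
    labels: pd.Series  # "low" / "high"
    cut: float
    rule: str
    n_low: int
    n_high: int
    degenerate: bool


def dichotomize_median(values: pd.Series) -> Dichotomy:
    """Cut at the median; the median value itself goes to the low group.

    With an odd number of distinct values the low group therefore has
    ``(n + 1) / 2`` members (e.g. an 11/10 split of 21 patients).
    """
    values = pd.Series(values)
    if len(values) < 4:
        raise ValueError("need >= 4 values to dichotomize")
    cut = float(values.median())
    labels = pd.Series(np.where(values <= cut, "low", "high"), index=values.index)
    n_low = int((labels == "low").sum())
    n_high = len(labels) - n_low
    return Dichotomy(labels, cut, "median", n_low, n_high, n_low == 0 or n_high == 0)


def dichotomize_reference_sd(
    values: pd.Series, reference: pd.Series, k_sd: float = 2.0
) -> Dichotomy:
    """Cut at ``mean(reference) - k_sd * sd(reference)``; low iff below cut.

    The reference is a normal-tissue distribution of the same measure;
    needs >= 10 reference values with nonzero variance.
    """
    values = pd.Series(values)
    reference = pd.Series(reference)
    if len(reference) < 10:
        raise ValueError("need >= 10 reference values")
    sd = float(reference.std(ddof=1))
    if sd == 0:
        raise ValueError("reference distribution has zero variance")
    cut = float(reference.mean()) - k_sd * sd
    labels = pd.Series(np.where(values < cut, "low", "high"), index=values.index)
    n_low = int((labels == "low").sum())
    n_high = len(labels) - n_low
    return Dichotomy(labels, cut, f"mean-{k_sd:g}sd", n_low, n_high, n_low == 0 or n_high == 0)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    times: np.ndarray  # distinct event times
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    median: float | None  # smallest t with S(t) <= 0.5; None if never reached


def _km_one(times: np.ndarray, events: np.ndarray) -> KMCurve:
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq = np.unique(t[e == 1])
    n_at_risk, n_events, surv = [], [], []
    s = 1.0
    for u in uniq:
        n = int((t >= u).sum())
        d = int(((t == u) & (e == 1)).sum())
        s *= 1.0 - d / n
        n_at_risk.append(n)
        n_events.append(d)
        surv.append(s)
    surv_arr = np.array(surv)
    median = None
    reached = np.nonzero(surv_arr <= 0.5)[0]
    if reached.size:
        median = float(uniq[reached[0]])
    return KMCurve(uniq, np.array(n_at_risk), np.array(n_events), surv_arr, median)


def km_fit(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray | None = None
) -> dict[str, KMCurve]:
    """Product-limit survival estimate, optionally per group."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValueError("negative times")
    if groups is None:
        return {"all": _km_one(times, events)}
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        sel = groups == g
        if not sel.any():
            raise ValueError(f"empty group {g!r}")
        out[str(g)] = _km_one(times[sel], events[sel])
    return out


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    n_events: int


def logrank_test(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray
) -> LogRankResult:
    """Two-group log-rank test (1 df chi-square).

    Observed-minus-expected events in group 1 with the hypergeometric
    variance, summed over distinct event times.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    if events.sum() < 1:
        raise ValueError("no events")
    g1 = groups == labels[0]
    o_minus_e = 0.0
    var = 0.0
    for u in np.unique(times[events == 1]):
        at_risk = times >= u
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(((times == u) & (events == 1)).sum())
        d1 = int(((times == u) & (events == 1) & g1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return LogRankResult(0.0, 1.0, int(events.sum()))
    chi2 = o_minus_e**2 / var
    return LogRankResult(float(chi2), float(stats.chi2.sf(chi2, 1)), int(events.sum()))


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)
# ---------------------------------------------------------------------------


@dataclass
class SurvivalModelResult:
    summary: pd.DataFrame  # per covariate: beta, hr, se, ci_low, ci_high, p
    loglik: float
    null_loglik: float
    lrt_stat: float
    lrt_p: float
    n: int
    n_events: int
    n_iter: int
    converged: bool
    monotone_likelihood: bool
    grouping: Dichotomy | None = None

    @property
    def hr(self) -> float:
        """Hazard ratio of the first covariate (the grouping coefficient)."""
        return float(self.summary["hr"].iloc[0])

    @property
    def p(self) -> float:
        return float(self.summary["p"].iloc[0])


def _efron_ll_grad_info(
    beta: np.ndarray, t: np.ndarray, e: np.ndarray, X: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Efron partial log-likelihood, gradient and information at ``beta``.

    Inputs must be sorted ascending by time.  Risk-set sums are accumulated
    from the largest time downward.
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    theta = np.exp(eta)
    # tie-group boundaries (equal times)
    boundaries = [0] + [i for i in range(1, n) if t[i] != t[i - 1]] + [n]
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    S0, S1, S2 = 0.0, np.zeros(p), np.zeros((p, p))
    for gi in range(len(boundaries) - 2, -1, -1):
        a, b = boundaries[gi], boundaries[gi + 1]
        th = theta[a:b]
        x = X[a:b]
        S0 += th.sum()
        S1 += th @ x
        S2 += (th[:, None] * x).T @ x
        ev = e[a:b] == 1
        d = int(ev.sum())
        if d == 0:
            continue
        thD = th[ev]
        xD = x[ev]
        s0d = thD.sum()
        s1d = thD @ xD
        s2d = (thD[:, None] * xD).T @ xD
        ll += eta[a:b][ev].sum()
        grad += xD.sum(axis=0)
        for l in range(d):
            frac = l / d
            phi = S0 - frac * s0d
            u = S1 - frac * s1d
            M = S2 - frac * s2d
            ll -= np.log(phi)
            grad -= u / phi
            info += M / phi - np.outer(u, u) / phi**2
    return float(ll), grad, info


def cox_fit(
    times: np.ndarray,
    events: np.ndarray,
    covariates: pd.DataFrame | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
    separation_beta: float = 12.0,
    grouping: Dichotomy | None = None,
) -> SurvivalModelResult:
    """Cox proportional-hazards fit by Newton-Raphson with Efron ties.

    Converges when the partial log-likelihood changes by less than ``tol``;
    steps are halved when an update decreases the likelihood.  A coefficient
    drifting beyond ``separation_beta`` in absolute value marks monotone
    likelihood (separation); the fit is reported with the flag set rather
    than suppressed.  Reports per-covariate hazard ratios with Wald 95% CIs
    and p-values, plus a likelihood-ratio test against the null model.
    """
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        raise ValueError("need >= 1 event")
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"constant covariate {name!r}")
    order = np.argsort(times, kind="stable")
    t, e, Xs = times[order], events[order], X[order]
    # center covariates for numerical stability; beta is unaffected
    centers = Xs.mean(axis=0)
    Xc = Xs - centers

    beta = np.zeros(X.shape[1])
    ll, grad, info = _efron_ll_grad_info(beta, t, e, Xc)
    null_ll = ll
    converged = False
    monotone = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            delta = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.solve(info + 1e-8 * np.eye(len(beta)), grad)
        step = 1.0
        for _ in range(30):
            beta_new = beta + step * delta
            ll_new, grad_new, info_new = _efron_ll_grad_info(beta_new, t, e, Xc)
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        change = ll_new - ll
        beta, ll, grad, info = beta_new, ll_new, grad_new, info_new
        if np.abs(beta).max() > separation_beta:
            monotone = True
            break
        if abs(change) < tol:
            converged = True
            break

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(beta), np.nan)
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    summary = pd.DataFrame(
        {
            "beta": beta,
            "hr": np.exp(beta),
            "se": se,
            "ci_low": np.exp(np.clip(beta - 1.96 * se, -700.0, 700.0)),
            "ci_high": np.exp(np.clip(beta + 1.96 * se, -700.0, 700.0)),
            "p": pvals,
        },
        index=pd.Index(names, name="covariate"),
    )
    lrt = max(0.0, 2.0 * (ll - null_ll))
    lrt_p = float(stats.chi2.sf(lrt, len(beta)))
    return SurvivalModelResult(
        summary=summary,
        loglik=float(ll),
        null_loglik=float(null_ll),
        lrt_stat=float(lrt),
        lrt_p=lrt_p,
        n=len(t),
        n_events=int(e.sum()),
        n_iter=it,
        converged=converged,
        monotone_likelihood=monotone,
        grouping=grouping,
    )


# ---------------------------------------------------------------------------
# candidate integration and region screen
# ---------------------------------------------------------------------------


def candidate_integration(
    region_genes: pd.DataFrame, underexpressed: set[str] | list[str]
) -> list[str]:
    """Intersect deleted-region genes with the under-expressed gene set.

    ``region_genes`` is a gene table with ``gene``, ``chrom`` and ``start``
    columns (the output of the CNV gene-overlap step); the result is the
    intersection ordered by genomic position.  An empty intersection is a
    valid (empty) candidate list.
    """
    if len(region_genes) == 0 or len(underexpressed) == 0:
        raise ValueError("both gene sets must be non-empty")
    under = set(underexpressed)
    hit = region_genes[region_genes["gene"].isin(under)]
    hit = hit.drop_duplicates("gene").sort_values(["chrom", "start", "gene"], kind="stable")
    return list(hit["gene"])


def region_survival_screen(
    values: pd.DataFrame,
    genes: list[str],
    clinical: pd.DataFrame,
    reference: pd.DataFrame,
    covariates: list[str],
    k_sd: float = 2.0,
    balance_threshold: float = 0.05,
) -> pd.DataFrame:
    """Multivariate Cox screen over every gene in a region.

    Per gene the patients are dichotomized by the reference mean minus
    ``k_sd`` SD rule, a multivariate Cox model (group + configured clinical
    covariates) is fitted, and genes are ranked by ascending grouping
    coefficient p-value.  Genes whose minority group holds less than
    ``balance_threshold`` of the patients are flagged as unbalanced; genes
    with a degenerate (single-group) cut are skipped.

    ``values`` and ``reference`` are gene x sample tables; ``clinical`` is
    indexed like the columns of ``values`` and carries ``time``, ``event``
    and the covariate columns.
    """
    rows = []
    for gene in genes:
        if gene not in values.index or gene not in reference.index:
            continue
        d = dichotomize_reference_sd(values.loc[gene], reference.loc[gene], k_sd)
        if d.degenerate:
            rows.append(
                {"gene": gene, "hr": np.nan, "p": np.nan,
                 "low_fraction": d.n_low / (d.n_low + d.n_high),
                 "unbalanced": True, "degenerate": True, "monotone_likelihood": False}
            )
            continue
        cov = clinical.loc[values.columns, covariates].astype(float).copy()
        cov.insert(0, "low", (d.labels == "low").astype(float).to_numpy())
        fit = cox_fit(
            clinical.loc[values.columns, "time"].to_numpy(),
            clinical.loc[values.columns, "event"].to_numpy(),
            cov,
            grouping=d,
        )
        frac_low = d.n_low / (d.n_low + d.n_high)
        rows.append(
            {
                "gene": gene,
                "hr": fit.hr,
                "p": fit.p,
                "low_fraction": frac_low,
                "unbalanced": min(frac_low, 1 - frac_low) < balance_threshold,
                "degenerate": False,
                "monotone_likelihood": fit.monotone_likelihood,
            }
        )
    if not rows:
        raise ValueError("no gene passed dichotomization")
    out = pd.DataFrame(rows).sort_values("p", kind="stable", na_position="last")
    return out.reset_index(drop=True)
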