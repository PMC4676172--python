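"""Dichotomization, KM, log-rank, Efron Cox and the survival screens.

lifelines serves purely as an independent cross-check oracle for the
product-limit estimator, the log-rank statistic and the Cox fit.
"""

import numpy as np
import pandas as pd
import pytest

from oltrecur.survival import (
    candidate_integration,
    cox_fit,
    dichotomize_median,
    dichotomize_reference_sd,
    km_fit,
    logrank_test,
    region_survival_screen,
)

from oracles import efron_partial_loglik, km_survival_no_censoring


# -- dichotomization ----------------------------------------------------------


def test_median_split_of_21_distinct_values_is_11_10(rng):
    vals = pd.Series(rng.permutation(np.linspace(-2, 2, 21)))
    d = dichotomize_median(vals)
    assert (d.n_low, d.n_high) == (11, 10)
    assert (vals[d.labels == "low"] <= d.cut).all()


def test_median_split_even_n():
    d = dichotomize_median(pd.Series([1.0, 2.0, 3.0, 4.0]))
    assert d.cut == 2.5
    assert sorted(d.labels[d.labels == "low"].index) == [0, 1]


def test_median_split_degenerate_and_precondition():
    d = dichotomize_median(pd.Series([2.0] * 6))
    assert d.degenerate and d.n_high == 0
    with pytest.raises(ValueError):
        dichotomize_median(pd.Series([1.0, 2.0, 3.0]))


def test_reference_sd_cut():
    ref = pd.Series(np.concatenate([np.full(120, 9.0), np.full(119, 11.0)]))
    # mean 10, sd ~1.002: cut ~8; 7.9 is low, 8.1 is high
    d = dichotomize_reference_sd(pd.Series([7.9, 8.1]), ref)
    assert d.labels.tolist() == ["low", "high"]


def test_reference_sd_degenerate_and_counts(rng):
    ref = pd.Series(rng.normal(10, 1, 239))
    vals = pd.Series(rng.normal(10, 2, 100))
    d = dichotomize_reference_sd(vals, ref)
    cut = ref.mean() - 2 * ref.std(ddof=1)
    assert d.n_low == int((vals < cut).sum())  # brute-force threshold count
    high_only = dichotomize_reference_sd(pd.Series([50.0, 60.0]), ref)
    assert high_only.degenerate and high_only.n_low == 0
    with pytest.raises(ValueError):
        dichotomize_reference_sd(vals, pd.Series(np.full(20, 1.0)))
    with pytest.raises(ValueError):
        dichotomize_reference_sd(vals, ref.iloc[:5])


# -- Kaplan-Meier -------------------------------------------------------------


def test_km_no_events_is_flat():
    curves = km_fit(np.array([5.0, 8.0, 9.0]), np.array([0, 0, 0]))
    km = curves["all"]
    assert km.survival.size == 0 and km.median is None


def test_km_hand_product_limit():
    km = km_fit(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))["all"]
    assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
    assert km.median == 2.0


def test_km_equals_empirical_survival_without_censoring(rng):
    t = rng.exponential(10, 200).round(1)
    km = km_fit(t, np.ones(200, int))["all"]
    ecdf = km_survival_no_censoring(t)
    for u, s in zip(km.times, km.survival):
        assert s == pytest.approx(ecdf[float(u)], abs=1e-12)


def test_km_censoring_toy_matches_lifelines(rng):
    from lifelines import KaplanMeierFitter

    t = rng.exponential(12, 80)
    e = (rng.random(80) < 0.5).astype(int)
    km = km_fit(t, e)["all"]
    fitter = KaplanMeierFitter().fit(t, e)
    for u, s in zip(km.times, km.survival):
        assert s == pytest.approx(fitter.predict(u), abs=1e-9)


def test_km_monotone_and_groups(rng):
    t = rng.exponential(10, 100)
    e = (rng.random(100) < 0.7).astype(int)
    g = rng.integers(0, 2, 100)
    curves = km_fit(t, e, g)
    for km in curves.values():
        assert (np.diff(km.survival) <= 1e-12).all()
        assert km.survival.size == 0 or km.survival[0] <= 1.0
    with pytest.raises(ValueError):
        km_fit(np.array([-1.0]), np.array([1]))


# -- log-rank ------------------------------------------------------------------


def test_logrank_identical_groups():
    t = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
    e = np.array([1, 1, 0, 1, 1, 1, 0, 1])
    g = np.repeat([0, 1], 4)
    res = logrank_test(t, e, g)
    assert res.statistic == pytest.approx(0.0) and res.p_value == pytest.approx(1.0)


def test_logrank_six_subject_toy_hand_computed():
    """O-E and hypergeometric variance accumulated by hand."""
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    e = np.array([1, 1, 1, 1, 0, 1])
    g = np.array([0, 1, 0, 1, 0, 1])
    o_minus_e, var = 0.0, 0.0
    for u in [1.0, 2.0, 3.0, 4.0, 6.0]:
        risk = t >= u
        n, n1 = risk.sum(), (risk & (g == 0)).sum()
        d1 = int(((t == u) & (e == 1) & (g == 0)).sum())
        o_minus_e += d1 - n1 / n
        if n > 1:  # single subject at risk contributes no variance
            var += (n1 / n) * (1 - n1 / n) * (n - 1) / (n - 1)
    from scipy.stats import chi2

    res = logrank_test(t, e, g)
    assert res.statistic == pytest.approx(o_minus_e**2 / var)
    assert res.p_value == pytest.approx(chi2.sf(o_minus_e**2 / var, 1))


def test_logrank_matches_lifelines(rng):
    from lifelines.statistics import logrank_test as ll_logrank

    t = rng.exponential(10, 120)
    g = rng.integers(0, 2, 120)
    t[g == 1] *= 0.6
    e = (t < 12).astype(int)
    t = np.minimum(t, 12)
    ours = logrank_test(t, e, g)
    theirs = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
    assert ours.statistic == pytest.approx(theirs.test_statistic, rel=1e-9)
    assert ours.p_value == pytest.approx(theirs.p_value, rel=1e-9)


def test_logrank_label_swap_invariance(rng):
    t = rng.exponential(10, 60)
    e = (rng.random(60) < 0.8).astype(int)
    g = rng.integers(0, 2, 60)
    a = logrank_test(t, e, g)
    b = logrank_test(t, e, 1 - g)
    assert a.statistic == pytest.approx(b.statistic)


def test_logrank_preconditions():
    with pytest.raises(ValueError):
        logrank_test(np.array([1.0, 2.0]), np.array([1, 1]), np.array([0, 0]))
    with pytest.raises(ValueError):
        logrank_test(np.array([1.0, 2.0]), np.array([0, 0]), np.array([0, 1]))


# -- Cox ------------------------------------------------------------------------


def test_cox_partial_likelihood_beats_grid_oracle(rng):
    """On n <= 8 instances the fitted beta maximizes the Efron partial
    likelihood over a dense grid, ties included."""
    cases = [
        (np.array([2.0, 3, 3, 5, 6, 7, 8, 9]), np.array([1, 1, 1, 0, 1, 1, 0, 1]),
         np.array([1.0, 0, 1, 0, 1, 0, 0, 1])),
        (np.array([1.0, 1, 2, 2, 3, 4]), np.array([1, 1, 1, 1, 1, 0]),
         np.array([0.0, 1, 0, 1, 1, 0])),
    ]
    grid = np.arange(-5.0, 5.0 + 1e-9, 1e-4)
    for t, e, x in cases:
        fit = cox_fit(t, e, x - x.mean())
        ll_grid = efron_partial_loglik(grid, t, e, x - x.mean())
        beta_star = grid[np.argmax(ll_grid)]
        ll_hat = efron_partial_loglik(fit.summary["beta"].to_numpy(), t, e, x - x.mean())[0]
        assert ll_hat >= ll_grid.max() - 1e-6
        assert abs(fit.summary["beta"].iloc[0] - beta_star) <= 2e-4


def test_cox_matches_lifelines(rng):
    from lifelines import CoxPHFitter

    n = 150
    x = np.column_stack([rng.integers(0, 2, n), rng.normal(0, 1, n), rng.integers(1, 4, n)])
    beta_true = np.array([0.8, -0.4, 0.3])
    t = rng.exponential(np.exp(-(x @ beta_true)) * 10).round(1)  # rounding forces ties
    e = (t < 15).astype(int)
    t = np.minimum(t, 15)
    ours = cox_fit(t, e, pd.DataFrame(x, columns=["a", "b", "c"]))
    df = pd.DataFrame(x, columns=["a", "b", "c"]).assign(time=t, event=e)
    theirs = CoxPHFitter().fit(df, "time", "event")
    assert np.allclose(ours.summary["beta"], theirs.params_, atol=1e-4)
    assert np.allclose(ours.summary["se"], theirs.standard_errors_, atol=1e-4)
    assert ours.loglik == pytest.approx(theirs.log_likelihood_, rel=1e-6)


def test_cox_null_recovery(rng):
    """Independent covariate at n=2000: |beta| <= 0.05, HR ~= 1."""
    n = 2000
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(10, n)
    e = (t < 20).astype(int)
    fit = cox_fit(np.minimum(t, 20), e, x)
    assert abs(fit.summary["beta"].iloc[0]) <= 0.05
    assert fit.converged and not fit.monotone_likelihood


def test_cox_wald_ci_coverage_at_hr_7():
    """CI covers log 7 in >= 90% of 50 seeds at n = 200/arm."""
    covered = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        x = np.repeat([0.0, 1.0], 200)
        t = rng.exponential(np.where(x == 1, 1 / 7.0, 1.0) * 30, 400)
        e = (t < 40).astype(int)
        fit = cox_fit(np.minimum(t, 40), e, x)
        lo, hi = fit.summary["ci_low"].iloc[0], fit.summary["ci_high"].iloc[0]
        covered += lo <= 7.0 <= hi
    assert covered >= 45


def test_cox_separation_flagged():
    t = np.array([1.0, 2, 3, 10, 11, 12])
    e = np.ones(6, int)
    x = np.array([1.0, 1, 1, 0, 0, 0])  # perfect separation
    fit = cox_fit(t, e, x)
    assert fit.monotone_likelihood


def test_cox_preconditions():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    with pytest.raises(ValueError, match="constant"):
        cox_fit(t, np.array([1, 1, 0, 1]), np.ones(4))
    with pytest.raises(ValueError, match="event"):
        cox_fit(t, np.zeros(4, int), np.array([0.0, 1, 0, 1]))


def test_cox_lrt_against_null(rng):
    n = 300
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(np.where(x == 1, 5.0, 15.0), n)
    e = (t < 25).astype(int)
    fit = cox_fit(np.minimum(t, 25), e, x)
    assert fit.lrt_stat > 0 and fit.lrt_p < 1e-6
    assert fit.loglik >= fit.null_loglik


# -- integration and screen ------------------------------------------------------


def _region_genes(names_positions):
    return pd.DataFrame(
        [{"gene": g, "chrom": c, "start": s, "end": s + 1000}
         for g, c, s in names_positions]
    )


def test_candidate_integration_orders_by_position():
    rg = _region_genes([("C", "chr4", 500), ("A", "chr4", 9000), ("B", "chr4", 100)])
    assert candidate_integration(rg, {"A", "B", "C", "D"}) == ["B", "C", "A"]
    assert candidate_integration(rg, {"Z"}) == []
    with pytest.raises(ValueError):
        candidate_integration(rg.iloc[:0], {"A"})


def _screen_inputs(seed, n_genes=50, n_pat=200, hr=2.5):
    rng = np.random.default_rng(seed)
    patients = [f"p{i}" for i in range(n_pat)]
    genes = [f"g{i}" for i in range(n_genes + 1)]
    ref = pd.DataFrame(rng.normal(10, 1, (n_genes + 1, 100)), index=genes)
    vals = pd.DataFrame(rng.normal(10, 1, (n_genes + 1, n_pat)), index=genes, columns=patients)
    low = rng.random(n_pat) < 0.3
    vals.loc["g0", low] = rng.normal(6.5, 0.3, low.sum())  # planted prognostic gene
    haz = 0.05 * np.where(low, hr, 1.0)
    t = rng.exponential(1 / haz)
    e = (t <= 20).astype(int)
    clinical = pd.DataFrame(
        {
            "time": np.minimum(t, 20),
            "event": e,
            "sex": rng.integers(0, 2, n_pat).astype(float),
            "age": rng.normal(55, 8, n_pat),
        },
        index=pd.Index(patients, name="patient"),
    )
    return vals, genes, clinical, ref


def test_screen_single_gene_region():
    vals, genes, clinical, ref = _screen_inputs(0, n_genes=0)
    table = region_survival_screen(vals, ["g0"], clinical, ref, ["sex", "age"])
    assert len(table) == 1 and table.iloc[0]["gene"] == "g0"
    assert table.iloc[0]["p"] < 0.01


def test_screen_ranks_planted_gene_top3():
    """Planted prognostic gene among 50 nulls ranks top 3 in >= 16/20 seeds."""
    hits = 0
    for seed in range(20):
        vals, genes, clinical, ref = _screen_inputs(100 + seed)
        table = region_survival_screen(vals, genes, clinical, ref, ["sex", "age"])
        hits += "g0" in set(table["gene"].iloc[:3])
    assert hits >= 16


def test_screen_balance_flag():
    rng = np.random.default_rng(1)
    genes = ["g0"]
    ref = pd.DataFrame(rng.normal(10, 1, (1, 100)), index=genes)
    cut = ref.loc["g0"].mean() - 2 * ref.loc["g0"].std(ddof=1)
    patients = [f"p{i}" for i in range(100)]
    v = np.full(100, 10.0)
    v[:3] = cut - 1  # 3% low group
    vals = pd.DataFrame([v], index=genes, columns=patients)
    t = rng.exponential(10, 100)
    clinical = pd.DataFrame(
        {"time": np.minimum(t, 15), "event": (t < 15).astype(int),
         "sex": rng.integers(0, 2, 100).astype(float)},
        index=pd.Index(patients, name="patient"),
    )
    table = region_survival_screen(vals, genes, clinical, ref, ["sex"])
    assert bool(table.iloc[0]["unbalanced"])
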