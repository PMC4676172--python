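"""Copy-number binning, segmentation, state calling, region logic."""

import numpy as np
import pandas as pd
import pytest

from oltrecur.cnv import (
    CN_STATES,
    bin_log2_ratios,
    call_states,
    cross_patient_regions,
    genes_in_regions,
    segment_binary,
    state_means,
)

from oracles import best_two_breakpoints


def _cov(depths, chrom="chr1", bin_size=1000):
    n = len(depths)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * bin_size,
            "end": (np.arange(n) + 1) * bin_size,
            "depth": depths,
        }
    )


def _track(values, chrom="chr1"):
    t = _cov(np.full(len(values), 100), chrom=chrom)
    t = t.rename(columns={"depth": "tumor_depth"})
    t["normal_depth"] = 100
    t["log2_ratio"] = values
    return t


# -- log2 ratios ---------------------------------------------------------------


def test_log2_identical_tracks_are_zero():
    cov = _cov(np.full(50, 120))
    track = bin_log2_ratios(cov, cov.copy())
    assert np.allclose(track["log2_ratio"], 0.0)


def test_log2_global_doubling_cancels():
    """Library-size normalization removes a uniform scaling of one library."""
    rng = np.random.default_rng(0)
    d = rng.poisson(150, 80)
    track = bin_log2_ratios(_cov(2 * d), _cov(d))
    assert np.allclose(track["log2_ratio"], 0.0, atol=1e-12)


def test_log2_mismatched_grids_raise():
    with pytest.raises(ValueError, match="grids"):
        bin_log2_ratios(_cov(np.full(10, 100)), _cov(np.full(10, 100), chrom="chr2"))


def test_log2_planted_deletion_near_minus_one(rng):
    """Hemizygous deletion at purity 1, depth 200: mean L within 0.1 of -1."""
    n = 200
    tumor = np.where(np.arange(n) < 60, rng.poisson(100, n), rng.poisson(200, n))
    normal = rng.poisson(200, n)
    track = bin_log2_ratios(_cov(tumor), _cov(normal))
    # normalization shifts the whole track; compare the deletion against the
    # neutral baseline
    inside = track["log2_ratio"][:60].mean() - track["log2_ratio"][60:].mean()
    assert abs(inside - (-1.0)) < 0.1


# -- segmentation ----------------------------------------------------------------


def test_constant_track_yields_single_segment_per_chromosome(rng):
    vals = np.concatenate([np.zeros(40), np.zeros(30)])
    t1 = _track(rng.normal(0, 0.1, 50), chrom="chr1")
    t2 = _track(rng.normal(0, 0.1, 40), chrom="chr2")
    segs = segment_binary(pd.concat([t1, t2], ignore_index=True))
    assert len(segs) == 2
    assert segs["n_bins"].tolist() == [50, 40]


def test_segmentation_finds_planted_step(rng):
    """Step 0 -> -1 at bin 50 of 100, noise sd 0.2: breakpoint within +-2."""
    x = np.concatenate([rng.normal(0, 0.2, 50), rng.normal(-1, 0.2, 50)])
    segs = segment_binary(_track(x))
    assert len(segs) == 2
    breakpoint_bin = segs.iloc[0]["end"] // 1000
    assert abs(breakpoint_bin - 50) <= 2


def test_segmentation_matches_exhaustive_split_oracle(rng):
    """On a 60-bin two-breakpoint track the recursion finds the same
    segmentation as exhaustive search over all split pairs."""
    for seed in range(5):
        r = np.random.default_rng(seed)
        x = np.concatenate(
            [r.normal(0, 0.15, 20), r.normal(-1.2, 0.15, 22), r.normal(0, 0.15, 18)]
        )
        segs = segment_binary(_track(x))
        i, j = best_two_breakpoints(x, 5)
        assert len(segs) == 3
        assert segs.iloc[0]["end"] // 1000 == i
        assert segs.iloc[1]["end"] // 1000 == j


def test_segmentation_tiles_territory(rng):
    x = rng.normal(0, 0.3, 120) + np.repeat([0, -0.8, 0.4], 40)
    segs = segment_binary(_track(x))
    assert segs["n_bins"].sum() == 120
    assert segs.iloc[0]["start"] == 0 and segs.iloc[-1]["end"] == 120_000
    assert (segs["end"].to_numpy()[:-1] == segs["start"].to_numpy()[1:]).all()


def test_segmentation_requires_enough_bins():
    with pytest.raises(ValueError, match="bins"):
        segment_binary(_track(np.zeros(8)))


def test_segmentation_example_depth_100():
    """Planted breakpoints recovered within +-2 bins at depth 100."""
    from oltrecur.simulate import SimulationConfig, simulate_coverage_bins, _streams

    cfg = SimulationConfig(seed=2, depth_mean=100.0, purity_pt=0.8)
    streams = _streams(cfg)
    patient = cfg.planted_patients[0]
    cov_t = simulate_coverage_bins(cfg, patient, "P_T", 0.0, streams["coverage"])
    cov_n = simulate_coverage_bins(cfg, patient, "P_NAT", 0.0, streams["coverage"])
    segs = segment_binary(bin_log2_ratios(cov_t, cov_n))
    chrom, start, end = cfg.planted_region
    del_segs = segs[(segs["chrom"] == chrom) & (segs["mean_log2"] < -0.3)]
    assert len(del_segs) == 1
    assert abs(del_segs.iloc[0]["start"] - start) <= 2 * cfg.bin_size
    assert abs(del_segs.iloc[0]["end"] - end) <= 2 * cfg.bin_size


# -- state calling ----------------------------------------------------------------


def _segs(means, chrom="chr1"):
    n = len(means)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * 10_000,
            "end": (np.arange(n) + 1) * 10_000,
            "mean_log2": means,
            "n_bins": 10,
            "state": None,
        }
    )


def test_state_calls_at_exact_model_means():
    out = call_states(_segs([-1.0, 0.58, 0.0]), purity=1.0)
    assert out["state"].tolist() == ["hemi-del", "hemi-amp", "neutral"]


def test_state_calls_match_nearest_mean_oracle(rng):
    means = rng.uniform(-3, 1.5, 200)
    purity = 0.7
    out = call_states(_segs(means), purity)
    model = state_means(purity)
    for l, s in zip(means, out["state"]):
        best = min(CN_STATES, key=lambda st: (abs(l - model[st]), abs(model[st])))
        assert s == best


def test_state_tie_breaks_toward_neutral():
    model = state_means(1.0)
    mid = (model["neutral"] + model["hemi-amp"]) / 2
    out = call_states(_segs([mid]), 1.0)
    assert out["state"].iloc[0] == "neutral"


def test_state_purity_monotonicity():
    """For fixed L < 0, increasing purity never flips hemi-del to homo-del.

    Under the nearest-mean rule the homozygous-deletion mean falls away
    from the hemizygous mean as purity rises, so a hemizygous call can only
    deepen when purity *decreases* (a given shift implies a larger
    underlying loss in an impurer biopsy), never when it increases.
    """
    for l in np.linspace(-2.5, -0.05, 40):
        prev = None
        for purity in np.linspace(0.1, 1.0, 19):
            state = call_states(_segs([l]), purity)["state"].iloc[0]
            if prev == "hemi-del":
                assert state != "homo-del"
            prev = state


def test_state_requires_positive_purity():
    with pytest.raises(ValueError):
        call_states(_segs([0.0]), 0.0)


# -- cross-patient regions ---------------------------------------------------------


def _bin_grid(n=30, chrom="chr1"):
    return pd.DataFrame(
        {"chrom": chrom, "start": np.arange(n) * 1000, "end": (np.arange(n) + 1) * 1000}
    )


def _tiling(states, chrom="chr1"):
    """One segment per run of equal states over the 30-bin grid."""
    rows, start = [], 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            rows.append(
                {"chrom": chrom, "start": start * 1000, "end": i * 1000,
                 "mean_log2": 0.0, "n_bins": i - start, "state": states[start]}
            )
            start = i
    return pd.DataFrame(rows)


def test_shared_deletion_in_three_of_four_patients():
    n = 30
    deleted = ["neutral"] * 10 + ["hemi-del"] * 11 + ["neutral"] * 9
    neutral = ["neutral"] * n
    per_patient = {
        "P1": (_tiling(deleted), _tiling(deleted)),
        "P2": (_tiling(deleted), _tiling(deleted)),
        "P3": (_tiling(deleted), _tiling(deleted)),
        "P4": (_tiling(neutral), _tiling(neutral)),
    }
    cat = cross_patient_regions(per_patient, _bin_grid(n), k=3)
    assert len(cat) == 1
    row = cat.iloc[0]
    assert row["category"] == "shared-del"
    assert (row["start"], row["end"]) == (10_000, 21_000)


def test_region_absent_below_vote_threshold():
    n = 30
    deleted = ["hemi-del"] * n
    neutral = ["neutral"] * n
    per_patient = {
        "P1": (_tiling(deleted), _tiling(deleted)),
        "P2": (_tiling(deleted), _tiling(deleted)),
        "P3": (_tiling(neutral), _tiling(neutral)),
        "P4": (_tiling(neutral), _tiling(neutral)),
    }
    assert len(cross_patient_regions(per_patient, _bin_grid(n), k=3)) == 0


def test_all_neutral_cohort_yields_empty_catalog():
    n = 30
    neutral = ["neutral"] * n
    per_patient = {f"P{i}": (_tiling(neutral), _tiling(neutral)) for i in range(4)}
    assert len(cross_patient_regions(per_patient, _bin_grid(n), k=3)) == 0


def test_region_logic_matches_per_bin_vote_oracle(rng):
    """Random state grids: catalog equals a brute-force per-bin vote count."""
    n, k = 40, 2
    states = list(CN_STATES)
    per_patient = {}
    raw = {}
    for p in range(3):
        pt = [states[i] for i in rng.integers(0, 5, n)]
        rt = [states[i] for i in rng.integers(0, 5, n)]
        per_patient[f"P{p}"] = (_tiling(pt), _tiling(rt))
        raw[f"P{p}"] = (pt, rt)
    cat = cross_patient_regions(per_patient, _bin_grid(n), k=k)

    def bin_cat(pt, rt):
        amp = {"hemi-amp", "homo-amp"}
        dele = {"hemi-del", "homo-del"}
        return {
            "shared-amp": pt in amp and rt in amp,
            "shared-del": pt in dele and rt in dele,
            "P-only-amp": pt in amp and rt not in amp,
            "P-only-del": pt in dele and rt not in dele,
            "R-only-amp": rt in amp and pt not in amp,
            "R-only-del": rt in dele and pt not in dele,
        }

    qualifying = set()
    for b in range(n):
        for c in bin_cat("neutral", "neutral"):
            votes = sum(bin_cat(pt[b], rt[b])[c] for pt, rt in raw.values())
            if votes >= k:
                qualifying.add((c, b))
    from_catalog = set()
    for _, row in cat.iterrows():
        for b in range(row["start"] // 1000, row["end"] // 1000):
            from_catalog.add((row["category"], b))
    assert from_catalog == qualifying


def test_cross_patient_needs_k_patients():
    with pytest.raises(ValueError):
        cross_patient_regions({"P1": (_tiling(["neutral"] * 5), _tiling(["neutral"] * 5))},
                              _bin_grid(5), k=3)


# -- gene overlap -----------------------------------------------------------------


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def test_gene_overlap_conventions():
    regions = pd.DataFrame(
        [{"category": "shared-del", "chrom": "chr1", "start": 1000, "end": 2000}]
    )
    genes = _genes(
        [
            ("INSIDE", "chr1", 1200, 1800),
            ("ABUT", "chr1", 2000, 2500),      # half-open: zero overlap
            ("SPAN", "chr1", 500, 1001),       # 1 bp overlap counts
            ("OTHER", "chr2", 1200, 1800),
        ]
    )
    hit = genes_in_regions(regions, genes)
    assert set(hit["gene"]) == {"INSIDE", "SPAN"}


def test_gene_overlap_matches_all_pairs_oracle(rng):
    regions = pd.DataFrame(
        [
            {"category": "c", "chrom": f"chr{c}", "start": int(s), "end": int(s + l)}
            for c, s, l in zip(
                rng.integers(1, 3, 15), rng.integers(0, 9000, 15), rng.integers(100, 3000, 15)
            )
        ]
    )
    genes = _genes(
        [
            (f"G{i}", f"chr{c}", int(s), int(s + l))
            for i, (c, s, l) in enumerate(
                zip(rng.integers(1, 3, 60), rng.integers(0, 9000, 60), rng.integers(50, 2000, 60))
            )
        ]
    )
    hit = set(map(tuple, genes_in_regions(regions, genes)[["gene", "region_start"]].itertuples(index=False)))
    oracle = set()
    for _, reg in regions.iterrows():
        for _, g in genes.iterrows():
            if g["chrom"] == reg["chrom"] and g["start"] < reg["end"] and g["end"] > reg["start"]:
                oracle.add((g["gene"], reg["start"]))
    assert hit == oracle


def test_gene_overlap_rejects_empty_or_duplicate_model():
    regions = pd.DataFrame([{"category": "c", "chrom": "chr1", "start": 0, "end": 10}])
    with pytest.raises(ValueError):
        genes_in_regions(regions, _genes([]))
    dup = _genes([("A", "chr1", 0, 5), ("A", "chr1", 6, 9)])
    with pytest.raises(ValueError):
        genes_in_regions(regions, dup)
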