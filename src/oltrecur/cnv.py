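"""Copy-number analysis from binned coverage.

Log2 tumor/normal depth ratios per bin, recursive binary segmentation,
five-state purity-aware calling (homozygous/hemizygous deletion, neutral,
hemizygous/homozygous amplification), and discovery of regions shared or
unique across patients.  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

CN_STATES = ("homo-del", "hemi-del", "neutral", "hemi-amp", "homo-amp")
AMP_STATES = frozenset({"hemi-amp", "homo-amp"})
DEL_STATES = frozenset({"hemi-del", "homo-del"})

REGION_CATEGORIES = (
    "shared-amp",
    "shared-del",
    "P-only-amp",
    "P-only-del",
    "R-only-amp",
    "R-only-del",
)


def bin_log2_ratios(
    tumor_cov: pd.DataFrame, normal_cov: pd.DataFrame, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Library-size-normalized log2 depth ratio per bin.

    Both depth vectors are rescaled to a common library size (the mean of
    the two totals) so a global scaling of either library cancels; the
    pseudocount is applied on that count scale to keep zero-depth bins
    finite.  Requires identical bin grids.
    """
    for c in ("chrom", "start", "end"):
        if not tumor_cov[c].reset_index(drop=True).equals(
            normal_cov[c].reset_index(drop=True)
        ):
            raise ValueError("tumor and normal bin grids differ")
    t = tumor_cov["depth"].to_numpy(dtype=float)
    n = normal_cov["depth"].to_numpy(dtype=float)
    s_t, s_n = t.sum(), n.sum()
    if s_t <= 0 or s_n <= 0:
        raise ValueError("zero total depth")
    s_bar = (s_t + s_n) / 2.0
    t_norm = t * s_bar / s_t
    n_norm = n * s_bar / s_n
    out = tumor_cov[["chrom", "start", "end"]].copy()
    out["tumor_depth"] = t
    out["normal_depth"] = n
    out["log2_ratio"] = np.log2((t_norm + pseudocount) / (n_norm + pseudocount))
    return out


def _best_split(x: np.ndarray, min_bins: int) -> tuple[int, float] | None:
    """Interior split maximizing the two-sample t statistic; (index, p)."""
    n = len(x)
    if n < 2 * min_bins:
        return None
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    total, total_sq = csum[-1], csq[-1]
    k = np.arange(min_bins, n - min_bins + 1)  # left segment sizes
    s1, q1 = csum[k - 1], csq[k - 1]
    s2, q2 = total - s1, total_sq - q1
    n1, n2 = k, n - k
    m1, m2 = s1 / n1, s2 / n2
    ss = (q1 - n1 * m1**2) + (q2 - n2 * m2**2)
    var = ss / (n - 2)
    denom = np.sqrt(var * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(m1 - m2) / denom
    t = np.where(denom > 0, t, np.where(m1 != m2, np.inf, 0.0))
    j = int(np.argmax(t))
    t_best = t[j]
    if not np.isfinite(t_best):
        p = 0.0 if t_best > 0 else 1.0
    else:
        p = float(2.0 * stats.t.sf(t_best, n - 2))
    return int(k[j]), p


def segment_binary(
    track: pd.DataFrame, min_seg_bins: int = 5, alpha_split: float = 0.001
) -> pd.DataFrame:
    """Recursive binary segmentation of the log2-ratio track.

    Within each chromosome the split maximizing the pooled two-sample t
    statistic is accepted iff its p-value (t distribution, n-2 df) is below
    ``alpha_split`` and both sides keep >= ``min_seg_bins`` bins; accepted
    sides are split recursively.  Segments tile the binned territory.
    """
    segments = []
    for chrom, sub in track.groupby("chrom", sort=False):
        x = sub["log2_ratio"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if len(x) < 2 * min_seg_bins:
            raise ValueError(
                f"{chrom}: {len(x)} bins < 2 * min_seg_bins ({2 * min_seg_bins})"
            )
        stack = [(0, len(x))]
        pieces = []
        while stack:
            a, b = stack.pop()
            found = _best_split(x[a:b], min_seg_bins)
            if found is not None:
                k, p = found
                if p < alpha_split:
                    stack.append((a, a + k))
                    stack.append((a + k, b))
                    continue
            pieces.append((a, b))
        for a, b in sorted(pieces):
            segments.append(
                {
                    "chrom": chrom,
                    "start": int(starts[a]),
                    "end": int(ends[b - 1]),
                    "mean_log2": float(x[a:b].mean()),
                    "n_bins": b - a,
                    "state": None,
                }
            )
    return pd.DataFrame(segments)


def state_means(purity: float, homo_del_floor: float = 0.05) -> dict[str, float]:
    """Expected log2 ratio of each CN state at tumor-cell fraction ``purity``."""
    if not (0 < purity <= 1):
        raise ValueError("purity must lie in (0, 1]")
    return {
        "homo-del": float(np.log2(max(1.0 - purity, homo_del_floor))),
        "hemi-del": float(np.log2(1.0 - purity / 2.0)),
        "neutral": 0.0,
        "hemi-amp": float(np.log2(1.0 + purity / 2.0)),
        "homo-amp": float(np.log2(1.0 + purity)),
    }


def call_states(segments: pd.DataFrame, purity: float) -> pd.DataFrame:
    """Assign each segment the CN state with the nearest model mean.

    Ties break toward neutral (more precisely: toward the state nearer the
    neutral mean).
    """
    means = state_means(purity)
    order = sorted(CN_STATES, key=lambda s: abs(means[s]))  # neutral-first tie-break
    out = segments.copy()
    states = []
    for l in out["mean_log2"].to_numpy():
        d = {s: abs(l - means[s]) for s in order}
        states.append(min(order, key=lambda s: d[s]))
    out["state"] = states
    return out


def _states_per_bin(segments: pd.DataFrame, bins: pd.DataFrame) -> np.ndarray:
    """Map a segment tiling onto the bin grid."""
    state = np.array(["neutral"] * len(bins), dtype=object)
    chrom = bins["chrom"].to_numpy()
    start = bins["start"].to_numpy()
    for _, seg in segments.iterrows():
        sel = (chrom == seg["chrom"]) & (start >= seg["start"]) & (start < seg["end"])
        state[sel] = seg["state"]
    return state


def _bin_categories(pt_state: np.ndarray, rt_state: np.ndarray) -> dict[str, np.ndarray]:
    p_amp = np.isin(pt_state, list(AMP_STATES))
    p_del = np.isin(pt_state, list(DEL_STATES))
    r_amp = np.isin(rt_state, list(AMP_STATES))
    r_del = np.isin(rt_state, list(DEL_STATES))
    return {
        "shared-amp": p_amp & r_amp,
        "shared-del": p_del & r_del,
        "P-only-amp": p_amp & ~r_amp,
        "P-only-del": p_del & ~r_del,
        "R-only-amp": r_amp & ~p_amp,
        "R-only-del": r_del & ~p_del,
    }


def cross_patient_regions(
    per_patient: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    bins: pd.DataFrame,
    k: int = 3,
) -> pd.DataFrame:
    """Regions with a CN category recurrent in >= k patients.

    ``per_patient`` maps patient -> (primary-tumor segments, recurrent-tumor
    segments), both state-called on the common ``bins`` grid.  Per bin and
    patient the category follows from the (P_T, R_T) state pair; a bin
    enters the catalog under a category iff at least ``k`` patients share
    it, and adjacent qualifying bins merge into regions.
    """
    if len(per_patient) < k:
        raise ValueError(f"need >= k={k} patients, got {len(per_patient)}")
    votes = {c: np.zeros(len(bins), dtype=int) for c in REGION_CATEGORIES}
    for patient, (seg_pt, seg_rt) in per_patient.items():
        cats = _bin_categories(
            _states_per_bin(seg_pt, bins), _states_per_bin(seg_rt, bins)
        )
        for c in REGION_CATEGORIES:
            votes[c] += cats[c]
    chrom = bins["chrom"].to_numpy()
    start = bins["start"].to_numpy()
    end = bins["end"].to_numpy()
    rows = []
    for c in REGION_CATEGORIES:
        qual = votes[c] >= k
        i = 0
        while i < len(qual):
            if qual[i]:
                j = i
                while (
                    j + 1 < len(qual)
                    and qual[j + 1]
                    and chrom[j + 1] == chrom[i]
                    and start[j + 1] == end[j]
                ):
                    j += 1
                rows.append(
                    {
                        "category": c,
                        "chrom": chrom[i],
                        "start": int(start[i]),
                        "end": int(end[j]),
                        "n_bins": j - i + 1,
                        "max_votes": int(votes[c][i : j + 1].max()),
                    }
                )
                i = j + 1
            else:
                i += 1
    return pd.DataFrame(
        rows, columns=["category", "chrom", "start", "end", "n_bins", "max_votes"]
    )


def genes_in_regions(regions: pd.DataFrame, gene_model: pd.DataFrame) -> pd.DataFrame:
    """Genes overlapping catalog regions by >= 1 bp (half-open intervals)."""
    if len(gene_model) == 0:
        raise ValueError("empty gene model")
    if gene_model["gene"].duplicated().any():
        raise ValueError("gene model symbols must be unique")
    rows = []
    for _, reg in regions.iterrows():
        hit = gene_model[
            (gene_model["chrom"] == reg["chrom"])
            & (gene_model["start"] < reg["end"])
            & (gene_model["end"] > reg["start"])
        ]
        for _, g in hit.iterrows():
            rows.append(
                {
                    "category": reg.get("category", ""),
                    "region_chrom": reg["chrom"],
                    "region_start": reg["start"],
                    "region_end": reg["end"],
                    "gene": g["gene"],
                    "chrom": g["chrom"],
                    "start": g["start"],
                    "end": g["end"],
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "category", "region_chrom", "region_start", "region_end",
            "gene", "chrom", "start", "end",
        ],
    )
    return out.sort_values(["chrom", "start", "gene"], kind="stable").reset_index(drop=True)
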