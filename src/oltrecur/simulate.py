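"""Synthetic post-transplant liver-cancer cohort generator.

Emulates the specimen structure of a transplant-recurrence study: every
patient contributes a primary tumor (``P_T``) and its adjacent normal tissue
(``P_NAT``); a subset of the patients who recur after orthotopic liver
transplantation additionally contribute the recurrent tumor (``R_T``), donor
liver adjacent normal tissue (``R_NAT``) and recipient blood (``P_B``).

The generator produces every input the downstream analysis modules consume —
germline genotype panels in Hardy-Weinberg equilibrium, clonal somatic
variants with binomial read sampling, recurrent tumors modelled as
recipient-tumor / donor-normal cell mixtures with a known contamination
fraction ``alpha``, binned sequencing coverage carrying a planted hemizygous
deletion, negative-binomial expression counts with a planted under-expressed
gene, and proportional-hazards recurrence times — together with a
:class:`TruthRecord` of everything it planted.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SPECIMEN_ROLES = ("P_T", "P_NAT", "R_T", "R_NAT", "P_B")

EFFECT_CLASSES = (
    "nonsynonymous",
    "stop-gain",
    "stop-loss",
    "frameshift",
    "silent",
    "noncoding",
)
NONSILENT_CLASSES = frozenset({"nonsynonymous", "stop-gain", "stop-loss", "frameshift"})

#: strand-collapsed substitution classes (pyrimidine reference representation)
SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults emulate a 21-patient transplant cohort in which 9 patients
    recur within the follow-up horizon and 4 of the recurrent patients have
    the full five-specimen set sequenced.

    Parameters
    ----------
    alpha
        Donor-cell contamination fraction of each sequenced patient's
        recurrent-tumor biopsy; a scalar is broadcast to all sequenced
        patients.  The per-patient defaults span the regimes of interest:
        heavy, light and intermediate contamination plus one uncontaminated
        biopsy.
    clone_fractions
        Cancer-cell fraction of each tumor clone, each in (0, 1]; clones may
        be nested, so the fractions need not sum to 1.
    shared_clone_fraction
        Fraction of primary clones that persist in the recurrent tumor
        (largest clones are retained first).
    planted_region
        ``(chrom, start, end)`` half-open interval carrying a hemizygous
        deletion shared by P_T and R_T in ``planted_in_k`` of the sequenced
        patients.
    planted_gene_log2fc
        log2 effect applied to the planted gene's P_T expression mean in
        recurrent patients only.
    hazard_ratio
        True recurrence hazard ratio of the planted low-expression group
        versus the rest.
    """

    # cohort structure
    n_patients: int = 21
    n_recurrent: int = 9
    n_sequenced: int = 4
    # genome model
    n_chroms: int = 4
    chrom_length: int = 100_000_000
    bin_size: int = 1_000_000
    # germline panel
    panel_size: int = 2000
    maf_range: tuple[float, float] = (0.1, 0.5)
    # somatic architecture
    n_somatic_per_clone: int = 100
    clone_fractions: tuple[float, ...] = (0.9, 0.1)
    shared_clone_fraction: float = 0.5
    private_clone_fractions: tuple[float, ...] = (0.1,)
    alpha: float | tuple[float, ...] = (0.80, 0.06, 0.55, 0.0)
    purity_pt: float = 0.8
    purity_rt: float = 0.8
    # sequencing model
    depth_mean: float = 300.0
    seq_error: float = 1e-3
    substitution_weights: tuple[float, ...] = (0.08, 0.06, 0.38, 0.16, 0.28, 0.04)
    effect_weights: tuple[float, ...] = (0.58, 0.05, 0.01, 0.06, 0.25, 0.05)
    # copy number
    planted_region: tuple[str, int, int] = ("chr4", 40_000_000, 70_000_000)
    planted_in_k: int = 3
    # expression
    n_genes: int = 200
    nb_dispersion: float = 0.1
    base_mean: float = 300.0
    base_log_sd: float = 1.0
    library_size_range: tuple[float, float] = (0.7, 1.3)
    planted_gene_log2fc: float = -1.5
    # survival
    hazard_ratio: float = 7.0
    baseline_hazard: float = 0.02
    censor_time: float = 24.0
    hbv_freq: float = 0.8
    male_freq: float = 0.95
    age_mean: float = 51.0
    age_sd: float = 8.0
    grade_probs: tuple[float, ...] = (0.25, 0.5, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_recurrent <= self.n_patients):
            raise ValueError("need 0 < n_recurrent <= n_patients")
        if not (0 < self.n_sequenced <= self.n_recurrent):
            raise ValueError("need 0 < n_sequenced <= n_recurrent")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("MAF range must lie within (0, 0.5]")
        if self.panel_size < 1:
            raise ValueError("panel_size must be >= 1")
        # clone fractions are cancer-cell fractions; clones may be nested
        # (a subclone inside a parental clone), so only each fraction is
        # bounded by 1, not their sum
        for cf in self.clone_fractions + self.private_clone_fractions:
            if not (0 < cf <= 1):
                raise ValueError("clone fractions must lie in (0, 1]")
        for a in self.alphas:
            if not (0 <= a <= 1):
                raise ValueError("alpha must lie in [0, 1]")
        for p in (self.purity_pt, self.purity_rt):
            if not (0 < p <= 1):
                raise ValueError("purity must lie in (0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if not (0 <= self.seq_error < 0.5):
            raise ValueError("seq_error must lie in [0, 0.5)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if self.censor_time < 0:
            raise ValueError("censor_time must be >= 0")
        if not (0 < self.planted_in_k <= self.n_sequenced):
            raise ValueError("planted_in_k must lie in (0, n_sequenced]")

    # -- derived structure -------------------------------------------------

    @property
    def alphas(self) -> tuple[float, ...]:
        a = self.alpha
        if np.isscalar(a):
            return tuple(float(a) for _ in range(self.n_sequenced))
        a = tuple(float(x) for x in a)
        if len(a) < self.n_sequenced:
            raise ValueError("alpha sequence shorter than n_sequenced")
        return a[: self.n_sequenced]

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_chroms))

    @property
    def patients(self) -> tuple[str, ...]:
        return tuple(f"HCC{i + 1:02d}" for i in range(self.n_patients))

    @property
    def recurrent_patients(self) -> tuple[str, ...]:
        return self.patients[: self.n_recurrent]

    @property
    def sequenced_patients(self) -> tuple[str, ...]:
        return self.patients[: self.n_sequenced]

    @property
    def planted_patients(self) -> tuple[str, ...]:
        """Sequenced patients carrying the planted shared deletion.

        The ``planted_in_k`` least-contaminated biopsies carry it: a deletion
        planted under heavy donor contamination is diluted to a log-ratio
        shift too small to be identifiable at the default depth, which would
        make the ground truth unrecoverable by construction rather than by
        failure of the method.
        """
        order = sorted(range(self.n_sequenced), key=lambda i: (self.alphas[i], i))
        chosen = sorted(order[: self.planted_in_k])
        return tuple(self.sequenced_patients[i] for i in chosen)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, default=list)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        raw = json.loads(text)
        fields = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in raw.items():
            if k not in fields:
                raise ValueError(f"unknown config key {k!r}")
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


@dataclass
class TruthRecord:
    """Ground truth for everything the generator planted."""

    alphas: dict[str, float]
    clones: pd.DataFrame  # patient, chrom, pos, ref, alt, clone, cell_fraction, in_rt, in_region, retained
    planted_region: tuple[str, int, int]
    planted_patients: tuple[str, ...]
    planted_gene: str
    planted_gene_log2fc: float
    low_group: tuple[str, ...]
    hazard_ratio: float
    baseline_hazard: float

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["clones"] = self.clones.to_dict(orient="list")
        return json.dumps(d, indent=1, default=list)


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------


def _streams(config: SimulationConfig) -> dict[str, np.random.Generator]:
    names = (
        "genes",
        "germline",
        "somatic",
        "mixture",
        "coverage",
        "counts",
        "clinical",
        "reads",
    )
    children = np.random.SeedSequence(config.seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _hwe_genotypes(maf: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw (n, loci) genotype dosages from Hardy-Weinberg proportions."""
    return rng.binomial(2, maf[None, :], size=(n, maf.size)).astype(np.int64)


def _observed_fraction(f: np.ndarray, eps: float) -> np.ndarray:
    """Fold the symmetric per-base error rate into an expected alt fraction."""
    return eps + np.asarray(f, dtype=float) * (1.0 - 2.0 * eps)


def _in_region(chrom: np.ndarray, pos: np.ndarray, region: tuple[str, int, int]) -> np.ndarray:
    """1-based positions against a 0-based half-open region."""
    c, start, end = region
    p0 = np.asarray(pos) - 1
    return (np.asarray(chrom) == c) & (p0 >= start) & (p0 < end)


def _sample_reads(
    f: np.ndarray,
    copy_ratio: np.ndarray | float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson depth scaled by local copy ratio, binomial alt reads."""
    f = np.asarray(f, dtype=float)
    lam = config.depth_mean * np.broadcast_to(np.asarray(copy_ratio, dtype=float), f.shape)
    depth = rng.poisson(lam)
    alt = rng.binomial(depth, _observed_fraction(f, config.seq_error))
    return depth, alt


# ---------------------------------------------------------------------------
# gene model
# ---------------------------------------------------------------------------


def make_gene_model(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Place ``n_genes`` genes uniformly on the synthetic genome.

    Returns a 0-based half-open interval table (gene, chrom, start, end),
    sorted by position, with at least one gene inside the planted region.
    """
    chroms = rng.choice(config.chrom_names, size=config.n_genes)
    length = rng.integers(20_000, 200_000, size=config.n_genes)
    start = rng.integers(0, config.chrom_length - length)
    genes = pd.DataFrame(
        {
            "gene": [f"G{i + 1:04d}" for i in range(config.n_genes)],
            "chrom": chroms,
            "start": start,
            "end": start + length,
        }
    )
    rc, rs, re = config.planted_region
    inside = (genes["chrom"] == rc) & (genes["start"] >= rs) & (genes["end"] <= re)
    if not inside.any():
        # force one gene into the region centre so a planted gene exists
        mid = (rs + re) // 2
        genes.loc[genes.index[0], ["chrom", "start", "end"]] = (rc, mid, mid + 50_000)
    genes = genes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return genes


def planted_gene_id(config: SimulationConfig, gene_model: pd.DataFrame) -> str:
    """The region gene nearest the planted-region centre."""
    rc, rs, re = config.planted_region
    inside = gene_model[
        (gene_model["chrom"] == rc)
        & (gene_model["start"] >= rs)
        & (gene_model["end"] <= re)
    ]
    centre = (rs + re) / 2
    mid = (inside["start"] + inside["end"]) / 2
    return str(inside.loc[(mid - centre).abs().idxmin(), "gene"])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def simulate_germlines(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict[str, dict[str, np.ndarray]]]:
    """Draw recipient and donor germlines for every sequenced patient.

    Returns
    -------
    loci : DataFrame
        Panel loci (chrom, pos, ref, alt, maf), sorted, unique positions.
    genotypes : dict
        ``genotypes[patient]["recipient"|"donor"]`` is the 0/1/2 alt-allele
        dosage vector over the panel loci.  Genotypes are drawn per locus
        from Hardy-Weinberg proportions at the locus MAF, independently for
        every individual.
    """
    if rng is None:
        rng = _streams(config)["germline"]
    chroms = rng.choice(config.chrom_names, size=config.panel_size)
    pos = rng.integers(1, config.chrom_length + 1, size=config.panel_size)
    ref_idx = rng.integers(0, 4, size=config.panel_size)
    alt_idx = (ref_idx + rng.integers(1, 4, size=config.panel_size)) % 4
    bases = np.array(list("ACGT"))
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=config.panel_size)
    loci = pd.DataFrame(
        {"chrom": chroms, "pos": pos, "ref": bases[ref_idx], "alt": bases[alt_idx], "maf": maf}
    )
    loci = (
        loci.drop_duplicates(["chrom", "pos"])
        .sort_values(["chrom", "pos"], kind="stable")
        .reset_index(drop=True)
    )
    maf = loci["maf"].to_numpy()
    genotypes: dict[str, dict[str, np.ndarray]] = {}
    for patient in config.sequenced_patients:
        genotypes[patient] = {
            "recipient": _hwe_genotypes(maf, 1, rng)[0],
            "donor": _hwe_genotypes(maf, 1, rng)[0],
        }
    return loci, genotypes


def genotype_panel(
    loci: pd.DataFrame,
    dosage: np.ndarray,
    patient: str,
    specimen: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    expected_fraction: np.ndarray | None = None,
) -> pd.DataFrame:
    """Emit a genotype panel with sampled read counts for one specimen.

    ``expected_fraction`` overrides the default dosage/2 alt fraction (used
    for the mixed recurrent-tumor specimen, where no genotype call is made
    and the dosage column is set to -1).
    """
    if expected_fraction is None:
        f = dosage / 2.0
        geno = dosage
    else:
        f = np.asarray(expected_fraction, dtype=float)
        geno = np.full(len(loci), -1, dtype=np.int64)
    depth, alt = _sample_reads(f, 1.0, config, rng)
    return pd.DataFrame(
        {
            "patient": patient,
            "specimen": specimen,
            "chrom": loci["chrom"].to_numpy(),
            "pos": loci["pos"].to_numpy(),
            "ref": loci["ref"].to_numpy(),
            "alt": loci["alt"].to_numpy(),
            "genotype": geno,
            "depth": depth,
            "alt_reads": alt,
        }
    )


def _draw_somatic_sites(
    config: SimulationConfig,
    n: int,
    rng: np.random.Generator,
    gene_model: pd.DataFrame | None,
) -> pd.DataFrame:
    """Random somatic sites with substitution class, effect and gene."""
    chroms = rng.choice(config.chrom_names, size=n)
    pos = rng.integers(1, config.chrom_length + 1, size=n)
    cls = rng.choice(
        SPECTRUM_CLASSES, size=n, p=np.asarray(config.substitution_weights) / sum(config.substitution_weights)
    )
    effect = rng.choice(
        EFFECT_CLASSES, size=n, p=np.asarray(config.effect_weights) / sum(config.effect_weights)
    )
    flip = rng.random(n) < 0.5  # report on the purine strand half the time
    ref = np.array([c[0] for c in cls])
    alt = np.array([c[2] for c in cls])
    ref = np.where(flip, [ _COMPLEMENT[b] for b in ref ], ref)
    alt = np.where(flip, [ _COMPLEMENT[b] for b in alt ], alt)
    # frameshift variants are emitted as 1-bp insertions (type flag via allele length)
    ins = effect == "frameshift"
    extra = rng.choice(list("ACGT"), size=n)
    alt = np.where(ins, np.char.add(ref.astype("U2"), extra), alt)
    out = pd.DataFrame({"chrom": chroms, "pos": pos, "ref": ref, "alt": alt, "effect": effect})
    out["gene"] = ""
    if gene_model is not None:
        for _, g in gene_model.iterrows():
            hit = (out["chrom"] == g["chrom"]) & (out["pos"] - 1 >= g["start"]) & (out["pos"] - 1 < g["end"])
            out.loc[hit, "gene"] = g["gene"]
    return out


def _somatic_fraction(
    cf: np.ndarray,
    purity: float,
    in_region: np.ndarray,
    retained: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected VAF and local copy-ratio for somatic variants.

    CN-neutral heterozygous model outside the planted region; inside a
    hemizygous deletion the mutated allele sits on the retained haplotype
    with probability 1/2 (``retained``), and both the allele fraction and
    the local depth scale with the reduced copy number.  ``purity`` is the
    tumor-cell fraction of the biopsy.
    """
    pi = purity
    total = np.where(in_region, 2.0 - pi, 2.0)
    altcopies = np.where(in_region, pi * cf * retained, pi * cf)
    f = altcopies / total
    return f, total / 2.0


def simulate_tumor_variants(
    config: SimulationConfig,
    patient: str,
    recipient_dosage: np.ndarray,
    loci: pd.DataFrame,
    rng: np.random.Generator,
    gene_model: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the primary-tumor variant table plus germline backgrounds.

    Every somatic variant belongs to exactly one clone with cell fraction
    ``clone_fractions[j]``; its expected primary-tumor VAF is
    ``purity_pt * cf / 2`` at CN-neutral sites, with copy-number-aware
    adjustment inside the planted deletion for planted patients.  ``P_NAT``
    and ``P_B`` carry only germline variants (somatic sites drop to the
    sequencing-error floor).

    Returns ``(variant_table, truth)`` where ``truth`` records the clone
    assignment of every somatic variant.
    """
    if any(not (0 < cf <= 1) for cf in config.clone_fractions):
        raise ValueError("clone fractions must lie in (0, 1]")
    n_clones = len(config.clone_fractions)
    n = n_clones * config.n_somatic_per_clone
    sites = _draw_somatic_sites(config, n, rng, gene_model)
    clone = np.repeat(np.arange(n_clones), config.n_somatic_per_clone)
    cf = np.asarray(config.clone_fractions)[clone]
    planted = patient in config.planted_patients
    in_reg = _in_region(sites["chrom"].to_numpy(), sites["pos"].to_numpy(), config.planted_region) & planted
    retained = (rng.random(n) < 0.5).astype(float)

    f_pt, ratio_pt = _somatic_fraction(cf, config.purity_pt, in_reg, retained)

    rows = []
    for specimen, f, ratio in (
        ("P_T", f_pt, ratio_pt),
        ("P_NAT", np.zeros(n), 1.0),
        ("P_B", np.zeros(n), 1.0),
    ):
        depth, alt = _sample_reads(f, ratio, config, rng)
        rows.append(
            pd.DataFrame(
                {
                    "patient": patient,
                    "specimen": specimen,
                    "chrom": sites["chrom"],
                    "pos": sites["pos"],
                    "ref": sites["ref"],
                    "alt": sites["alt"],
                    "ref_reads": depth - alt,
                    "alt_reads": alt,
                    "gene": sites["gene"],
                    "effect": sites["effect"],
                }
            )
        )

    # germline variant background at panel loci carrying an alt allele
    carrier = recipient_dosage > 0
    gl = loci.loc[carrier, ["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    f_gl = recipient_dosage[carrier] / 2.0
    for specimen in ("P_T", "P_NAT", "P_B"):
        depth, alt = _sample_reads(f_gl, 1.0, config, rng)
        rows.append(
            pd.DataFrame(
                {
                    "patient": patient,
                    "specimen": specimen,
                    "chrom": gl["chrom"],
                    "pos": gl["pos"],
                    "ref": gl["ref"],
                    "alt": gl["alt"],
                    "ref_reads": depth - alt,
                    "alt_reads": alt,
                    "gene": "",
                    "effect": "noncoding",
                }
            )
        )

    table = pd.concat(rows, ignore_index=True)
    table = table.drop_duplicates(["specimen"] + VARIANT_KEY).reset_index(drop=True)
    truth = pd.DataFrame(
        {
            "patient": patient,
            "chrom": sites["chrom"],
            "pos": sites["pos"],
            "ref": sites["ref"],
            "alt": sites["alt"],
            "clone": clone,
            "cell_fraction": cf,
            "in_region": in_reg,
            "retained": retained.astype(bool),
            "in_rt": False,
        }
    )
    return table, truth


def shared_clone_ids(config: SimulationConfig) -> tuple[int, ...]:
    """Primary clones retained in the recurrent tumor (largest first)."""
    n_clones = len(config.clone_fractions)
    n_keep = max(1, int(round(config.shared_clone_fraction * n_clones)))
    order = sorted(range(n_clones), key=lambda j: (-config.clone_fractions[j], j))
    return tuple(sorted(order[:n_keep]))


def simulate_recurrent_mixture(
    config: SimulationConfig,
    patient: str,
    alpha: float,
    primary_truth: pd.DataFrame,
    recipient_dosage: np.ndarray,
    donor_dosage: np.ndarray,
    loci: pd.DataFrame,
    rng: np.random.Generator,
    gene_model: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the recurrent tumor as a recipient-tumor / donor-normal mixture.

    A fraction ``alpha`` of the biopsy's cells are donor normal cells
    carrying the donor germline; the remaining ``1 - alpha`` are recipient
    cells of which ``purity_rt`` are tumor cells carrying the retained
    primary clones (plus any new private clones).  At a germline SNP the
    expected alt fraction is ``((1 - alpha) g_R + alpha g_D) / 2``.

    Returns ``(variant_table, panels, truth)`` where ``variant_table``
    stacks R_T and R_NAT records, ``panels`` stacks the R_T allele-count
    panel and the R_NAT genotype panel, and ``truth`` is ``primary_truth``
    with ``in_rt`` updated plus rows for private recurrent clones.
    """
    if not (0 <= alpha <= 1):
        raise ValueError("alpha must lie in [0, 1]")
    planted = patient in config.planted_patients
    keep = shared_clone_ids(config)
    truth = primary_truth.copy()
    truth["in_rt"] = truth["clone"].isin(keep)

    # private clones new to the recurrent tumor
    n_priv = len(config.private_clone_fractions) * config.n_somatic_per_clone
    priv_sites = _draw_somatic_sites(config, n_priv, rng, gene_model)
    priv_clone = np.repeat(
        np.arange(len(config.private_clone_fractions)) + len(config.clone_fractions),
        config.n_somatic_per_clone,
    )
    priv_cf = np.asarray(config.private_clone_fractions)[
        priv_clone - len(config.clone_fractions)
    ]
    priv_reg = (
        _in_region(priv_sites["chrom"].to_numpy(), priv_sites["pos"].to_numpy(), config.planted_region)
        & planted
    )
    priv_ret = (rng.random(n_priv) < 0.5).astype(float)

    shared_mask = truth["in_rt"].to_numpy()
    pi_eff = (1.0 - alpha) * config.purity_rt  # tumor-cell fraction of the biopsy

    def rt_fraction(cf, in_reg, retained):
        total = np.where(in_reg, 2.0 - pi_eff, 2.0)
        return pi_eff * cf * np.where(in_reg, retained, 1.0) / total, total / 2.0

    rows = []
    # shared somatic variants as seen in R_T
    sh = truth.loc[shared_mask]
    f_sh, ratio_sh = rt_fraction(
        sh["cell_fraction"].to_numpy(), sh["in_region"].to_numpy(), sh["retained"].to_numpy().astype(float)
    )
    # unique-to-primary somatic sites are still covered in R_T (error floor)
    un = truth.loc[~shared_mask]
    for sites_df, f, ratio in (
        (sh, f_sh, ratio_sh),
        (un, np.zeros(len(un)), np.where(un["in_region"].to_numpy() & planted, (2.0 - pi_eff) / 2.0, 1.0)),
        (
            priv_sites.assign(cell_fraction=priv_cf),
            rt_fraction(priv_cf, priv_reg, priv_ret)[0],
            rt_fraction(priv_cf, priv_reg, priv_ret)[1],
        ),
    ):
        depth, alt = _sample_reads(f, ratio, config, rng)
        rows.append(
            pd.DataFrame(
                {
                    "patient": patient,
                    "specimen": "R_T",
                    "chrom": sites_df["chrom"].to_numpy(),
                    "pos": sites_df["pos"].to_numpy(),
                    "ref": sites_df["ref"].to_numpy(),
                    "alt": sites_df["alt"].to_numpy(),
                    "ref_reads": depth - alt,
                    "alt_reads": alt,
                    "gene": sites_df["gene"].to_numpy() if "gene" in sites_df else "",
                    "effect": sites_df["effect"].to_numpy() if "effect" in sites_df else "noncoding",
                }
            )
        )

    # germline background in R_T: mixture of recipient and donor dosages
    mix_f = ((1.0 - alpha) * recipient_dosage + alpha * donor_dosage) / 2.0
    carrier = (recipient_dosage > 0) | (donor_dosage > 0)
    gl = loci.loc[carrier, ["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    depth, alt = _sample_reads(mix_f[carrier], 1.0, config, rng)
    rows.append(
        pd.DataFrame(
            {
                "patient": patient,
                "specimen": "R_T",
                "chrom": gl["chrom"],
                "pos": gl["pos"],
                "ref": gl["ref"],
                "alt": gl["alt"],
                "ref_reads": depth - alt,
                "alt_reads": alt,
                "gene": "",
                "effect": "noncoding",
            }
        )
    )
    # R_NAT: pure donor germline
    d_carrier = donor_dosage > 0
    gl_d = loci.loc[d_carrier, ["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    depth, alt = _sample_reads(donor_dosage[d_carrier] / 2.0, 1.0, config, rng)
    rows.append(
        pd.DataFrame(
            {
                "patient": patient,
                "specimen": "R_NAT",
                "chrom": gl_d["chrom"],
                "pos": gl_d["pos"],
                "ref": gl_d["ref"],
                "alt": gl_d["alt"],
                "ref_reads": depth - alt,
                "alt_reads": alt,
                "gene": "",
                "effect": "noncoding",
            }
        )
    )
    table = pd.concat(rows, ignore_index=True)
    table = table.drop_duplicates(["specimen"] + VARIANT_KEY).reset_index(drop=True)

    panels = pd.concat(
        [
            genotype_panel(loci, donor_dosage, patient, "R_NAT", config, rng),
            genotype_panel(
                loci, recipient_dosage, patient, "R_T", config, rng, expected_fraction=mix_f
            ),
        ],
        ignore_index=True,
    )

    priv_truth = pd.DataFrame(
        {
            "patient": patient,
            "chrom": priv_sites["chrom"],
            "pos": priv_sites["pos"],
            "ref": priv_sites["ref"],
            "alt": priv_sites["alt"],
            "clone": priv_clone,
            "cell_fraction": priv_cf,
            "in_region": priv_reg,
            "retained": priv_ret.astype(bool),
            "in_rt": True,
        }
    )
    truth = pd.concat([truth, priv_truth], ignore_index=True)
    return table, panels, truth


def genome_bins(config: SimulationConfig) -> pd.DataFrame:
    """The 0-based half-open bin grid of the synthetic genome."""
    per = config.chrom_length // config.bin_size
    chrom = np.repeat(config.chrom_names, per)
    start = np.tile(np.arange(per) * config.bin_size, config.n_chroms)
    return pd.DataFrame({"chrom": chrom, "start": start, "end": start + config.bin_size})


def simulate_coverage_bins(
    config: SimulationConfig,
    patient: str,
    specimen: str,
    alpha: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Binned coverage with Poisson depth scaled by the local copy ratio.

    Tumor specimens of planted patients carry the hemizygous deletion over
    the planted region; the depth ratio there is ``(2 - pi) / 2`` with
    ``pi`` the biopsy's tumor-cell fraction (``purity_pt`` for P_T,
    ``(1 - alpha) * purity_rt`` for R_T).  Normal specimens are flat.
    """
    bins = genome_bins(config)
    ratio = np.ones(len(bins))
    planted = patient in config.planted_patients
    if planted and specimen in ("P_T", "R_T"):
        pi = config.purity_pt if specimen == "P_T" else (1.0 - alpha) * config.purity_rt
        c, s, e = config.planted_region
        sel = (bins["chrom"] == c) & (bins["start"] >= s) & (bins["end"] <= e)
        ratio[sel.to_numpy()] = (2.0 - pi) / 2.0
    bins = bins.copy()
    bins["depth"] = rng.poisson(config.depth_mean * ratio)
    return bins


def simulate_counts_matrix(
    config: SimulationConfig,
    rng: np.random.Generator,
    gene_model: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial expression counts for P_T / P_NAT of every patient.

    Counts are NB with gene base mean ``mu_g`` (log-normal across genes),
    per-sample library-size factor, and dispersion ``phi`` (``variance =
    mu + phi mu^2``); ``nb_dispersion == 0`` degenerates to Poisson.  The
    planted gene's P_T mean is multiplied by ``2**planted_gene_log2fc`` in
    recurrent patients only.

    Returns ``(counts, sample_sheet, gene_model)``; counts has genes as rows
    and samples as columns.
    """
    if gene_model is None:
        gene_model = make_gene_model(config, rng)
    planted = planted_gene_id(config, gene_model)
    genes = gene_model["gene"].to_numpy()
    mu = np.exp(rng.normal(np.log(config.base_mean), config.base_log_sd, size=len(genes)))

    samples, patients, roles = [], [], []
    for p in config.patients:
        for role in ("P_T", "P_NAT"):
            samples.append(f"{p}_{role}")
            patients.append(p)
            roles.append(role)
    lo, hi = config.library_size_range
    libsize = rng.uniform(lo, hi, size=len(samples))

    mean = mu[:, None] * libsize[None, :]
    planted_idx = int(np.flatnonzero(genes == planted)[0])
    eff = 2.0 ** config.planted_gene_log2fc
    for j, (p, role) in enumerate(zip(patients, roles)):
        if role == "P_T" and p in config.recurrent_patients:
            mean[planted_idx, j] *= eff

    if config.nb_dispersion == 0:
        counts = rng.poisson(mean)
    else:
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mean))
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)
    sheet = pd.DataFrame(
        {
            "sample": samples,
            "patient": patients,
            "role": roles,
            "recurrent": [int(p in config.recurrent_patients) for p in patients],
        }
    )
    return counts_df, sheet, gene_model


def simulate_clinical_survival(
    config: SimulationConfig,
    low_group: Sequence[bool] | Mapping[str, bool],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Recurrence times under a two-group proportional-hazards model.

    Times are exponential with hazard ``h0 * HR**I(low)`` and are
    administratively censored at ``censor_time``.  Covariates (HBV carrier
    status, tumor grade, age, gender) are drawn from the configured marginal
    frequencies, independent of outcome.
    """
    patients = config.patients
    if isinstance(low_group, Mapping):
        low = np.array([bool(low_group[p]) for p in patients])
    else:
        low = np.asarray(low_group, dtype=bool)
        if low.size != len(patients):
            raise ValueError("low_group length must equal n_patients")
    hazard = config.baseline_hazard * np.where(low, config.hazard_ratio, 1.0)
    t = rng.exponential(1.0 / hazard)
    event = (t <= config.censor_time).astype(int)
    time = np.minimum(t, config.censor_time)
    return _clinical_frame(config, patients, time, event, low, rng)


def _clinical_frame(config, patients, time, event, low, rng) -> pd.DataFrame:
    grade = rng.choice(
        np.arange(1, len(config.grade_probs) + 1),
        size=len(patients),
        p=np.asarray(config.grade_probs) / sum(config.grade_probs),
    )
    return pd.DataFrame(
        {
            "patient": patients,
            "time": time,
            "event": event,
            "low": np.asarray(low, dtype=int),
            "hbv": (rng.random(len(patients)) < config.hbv_freq).astype(int),
            "grade": grade,
            "age": np.round(rng.normal(config.age_mean, config.age_sd, size=len(patients))),
            "male": (rng.random(len(patients)) < config.male_freq).astype(int),
        }
    )


def simulate_cohort_clinical(
    config: SimulationConfig,
    low_group: Sequence[bool],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Clinical table for the retrospective cohort design.

    The cohort is defined by observed outcome within the follow-up window:
    the ``n_recurrent`` recurrent patients have recurrence times drawn from
    the proportional-hazards model *conditional on falling inside the
    window* (inverse-CDF sampling of the truncated exponential), while
    tumor-free patients are administratively censored at the horizon.  This
    reproduces the fixed events/censored split that defines the design;
    :func:`simulate_clinical_survival` is the unconditional counterpart.
    """
    patients = config.patients
    low = np.asarray(low_group, dtype=bool)
    recur = np.array([p in config.recurrent_patients for p in patients])
    hazard = config.baseline_hazard * np.where(low, config.hazard_ratio, 1.0)
    u = rng.random(len(patients))
    with np.errstate(divide="ignore"):
        trunc = 1.0 - np.exp(-hazard * config.censor_time)
        t_cond = -np.log1p(-u * trunc) / hazard
    time = np.where(recur, t_cond, config.censor_time)
    event = recur.astype(int)
    return _clinical_frame(config, patients, time, event, low, rng)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """Everything the synthetic generator emits, plus ground truth."""

    config: SimulationConfig
    loci: pd.DataFrame
    germlines: dict[str, dict[str, np.ndarray]]
    panels: pd.DataFrame  # P_B, R_NAT, R_T genotype/allele-count panels
    variants: pd.DataFrame  # all specimens, all sequenced patients
    coverage: dict[tuple[str, str], pd.DataFrame]  # (patient, specimen) -> bins
    counts: pd.DataFrame
    sample_sheet: pd.DataFrame
    gene_model: pd.DataFrame
    clinical: pd.DataFrame
    truth: TruthRecord

    def patient_variants(self, patient: str, specimen: str) -> pd.DataFrame:
        v = self.variants
        return v[(v["patient"] == patient) & (v["specimen"] == specimen)].reset_index(drop=True)

    def patient_panel(self, patient: str, specimen: str) -> pd.DataFrame:
        p = self.panels
        return p[(p["patient"] == patient) & (p["specimen"] == specimen)].reset_index(drop=True)


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate the full synthetic cohort for one configuration/seed."""
    streams = _streams(config)
    gene_model = make_gene_model(config, streams["genes"])
    loci, germlines = simulate_germlines(config, streams["germline"])

    panels, variant_tables, truths = [], [], []
    coverage: dict[tuple[str, str], pd.DataFrame] = {}
    for i, patient in enumerate(config.sequenced_patients):
        alpha = config.alphas[i]
        g_r = germlines[patient]["recipient"]
        g_d = germlines[patient]["donor"]
        panels.append(genotype_panel(loci, g_r, patient, "P_B", config, streams["reads"]))
        pt_table, pt_truth = simulate_tumor_variants(
            config, patient, g_r, loci, streams["somatic"], gene_model
        )
        rt_table, rt_panels, truth = simulate_recurrent_mixture(
            config, patient, alpha, pt_truth, g_r, g_d, loci, streams["mixture"], gene_model
        )
        variant_tables += [pt_table, rt_table]
        panels.append(rt_panels)
        truths.append(truth)
        for specimen in ("P_T", "P_NAT", "R_T", "R_NAT"):
            coverage[(patient, specimen)] = simulate_coverage_bins(
                config, patient, specimen, alpha, streams["coverage"]
            )

    counts, sheet, gene_model = simulate_counts_matrix(config, streams["counts"], gene_model)
    low_group = [p in config.recurrent_patients for p in config.patients]
    clinical = simulate_cohort_clinical(config, low_group, streams["clinical"])
    clinical["recurrent"] = [int(p in config.recurrent_patients) for p in config.patients]

    truth = TruthRecord(
        alphas={p: config.alphas[i] for i, p in enumerate(config.sequenced_patients)},
        clones=pd.concat(truths, ignore_index=True),
        planted_region=config.planted_region,
        planted_patients=config.planted_patients,
        planted_gene=planted_gene_id(config, gene_model),
        planted_gene_log2fc=config.planted_gene_log2fc,
        low_group=tuple(config.recurrent_patients),
        hazard_ratio=config.hazard_ratio,
        baseline_hazard=config.baseline_hazard,
    )
    return Cohort(
        config=config,
        loci=loci,
        germlines=germlines,
        panels=pd.concat(panels, ignore_index=True),
        variants=pd.concat(variant_tables, ignore_index=True),
        coverage=coverage,
        counts=counts,
        sample_sheet=sheet,
        gene_model=gene_model,
        clinical=clinical,
        truth=truth,
    )
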