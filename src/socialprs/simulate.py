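"""Synthetic cohort generator: genotypes, GWAS summary statistics, phenotypes.

Emulates the statistical structure of a two-cohort polygenic study of social
behaviour without any restricted data:

* LD-blocked biallelic genotype dosages with dizygotic twin pairs and
  singleton representatives of monozygotic pairs (one panel per cohort);
* case-control disorder GWAS summary statistics under a normal-mixture
  (spike-and-slab) effect model with configurable SNP-heritability,
  polygenicity and discovery sample size;
* longitudinal, skewed 0-10 count phenotypes whose true per-measure
  polygenic effect follows a linear moderator model in median assessment
  age, reporter (parent/teacher) and trait (low prosociality / peer
  problems), with a cohort-level random offset.

All generators are pure functions of ``(spec, seed)``: one global seed is
expanded into per-component substreams so components can be regenerated
independently yet reproducibly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "DesignCell",
    "SimulationSpec",
    "GenotypePanel",
    "default_design",
    "generate_genotypes",
    "generate_sumstats",
    "generate_phenotypes",
]

PARENT, TEACHER = "parent", "teacher"
LOW_PROSOCIALITY, PEER_PROBLEMS = "low_prosociality", "peer_problems"
SCORE_MAX = 10

# substream indices for SeedSequence expansion
_STREAM_GENO, _STREAM_SUMSTATS, _STREAM_PHENO, _STREAM_COHORT = 0, 1, 2, 3


@dataclass(frozen=True)
class DesignCell:
    """One longitudinal measurement occasion: cohort x age x reporter x trait.

    ``mean_score`` is the target marginal mean of the 0-10 count score in
    that cell; the generator moment-matches the cell intercept to it.
    """

    cohort: str
    age_years: float
    reporter: str
    trait: str
    mean_score: float

    def __post_init__(self) -> None:
        if self.reporter not in (PARENT, TEACHER):
            raise ValueError(f"invalid field 'reporter': {self.reporter!r}")
        if self.trait not in (LOW_PROSOCIALITY, PEER_PROBLEMS):
            raise ValueError(f"invalid field 'trait': {self.trait!r}")
        if not 0 < self.mean_score <= SCORE_MAX:
            raise ValueError(f"invalid field 'mean_score': {self.mean_score}")


def default_design() -> list[DesignCell]:
    """The 29-measure two-cohort design grid (14 discovery + 15 follow-up).

    Median assessment ages and cell means mirror the descriptive moments of
    the SDQ low-prosociality (reverse-coded prosocial) and peer-problem
    subscales in a UK birth cohort ("alspac"-style, parent reports at
    ~7-17 y plus teacher reports at ~8/11 y) and a twin cohort
    ("teds"-style, parent reports at ~4-16 y plus teacher reports at
    ~7-12 y; no 16 y peer-problem wave).
    """
    a, t = "alspac", "teds"
    lp, pp = LOW_PROSOCIALITY, PEER_PROBLEMS
    cells = [
        # discovery cohort: parent-reported
        DesignCell(a, 6.79, PARENT, lp, 1.82),
        DesignCell(a, 9.65, PARENT, lp, 1.66),
        DesignCell(a, 11.72, PARENT, lp, 1.65),
        DesignCell(a, 13.16, PARENT, lp, 2.76),
        DesignCell(a, 16.84, PARENT, lp, 1.97),
        DesignCell(a, 6.79, PARENT, pp, 1.02),
        DesignCell(a, 9.65, PARENT, pp, 1.10),
        DesignCell(a, 11.72, PARENT, pp, 1.10),
        DesignCell(a, 13.16, PARENT, pp, 1.19),
        DesignCell(a, 16.84, PARENT, pp, 1.11),
        # discovery cohort: teacher-reported
        DesignCell(a, 8.33, TEACHER, lp, 2.21),
        DesignCell(a, 11.16, TEACHER, lp, 2.06),
        DesignCell(a, 8.33, TEACHER, pp, 1.13),
        DesignCell(a, 11.16, TEACHER, pp, 1.20),
        # twin cohort: parent-reported
        DesignCell(t, 4.04, PARENT, lp, 2.60),
        DesignCell(t, 7.06, PARENT, lp, 1.84),
        DesignCell(t, 9.01, PARENT, lp, 2.71),
        DesignCell(t, 11.25, PARENT, lp, 1.46),
        DesignCell(t, 16.31, PARENT, lp, 1.74),
        DesignCell(t, 4.04, PARENT, pp, 1.52),
        DesignCell(t, 7.06, PARENT, pp, 1.01),
        DesignCell(t, 9.01, PARENT, pp, 1.11),
        DesignCell(t, 11.25, PARENT, pp, 1.11),
        # twin cohort: teacher-reported
        DesignCell(t, 7.20, TEACHER, lp, 2.68),
        DesignCell(t, 9.03, TEACHER, lp, 2.44),
        DesignCell(t, 11.50, TEACHER, lp, 1.99),
        DesignCell(t, 7.20, TEACHER, pp, 1.07),
        DesignCell(t, 9.03, TEACHER, pp, 0.85),
        DesignCell(t, 11.51, TEACHER, pp, 1.04),
    ]
    return cells


@dataclass
class SimulationSpec:
    """Parameters of the synthetic study.

    Attributes
    ----------
    n_individuals : int
        Unrelated singletons per panel.
    n_dz_pairs : int
        Dizygotic twin pairs (both members emitted, sharing a family id).
    n_mz_singletons : int
        Monozygotic pairs represented by a single emitted member.
    n_variants, block_size : int
        Biallelic variants, grouped into exchangeable-LD blocks of
        ``block_size`` consecutive variants.
    within_block_r : float
        Target pairwise dosage correlation inside a block (0 across blocks).
    maf_range : (float, float)
        Per-variant minor-allele frequencies are drawn uniformly here.
    h2_disorder : float
        SNP-heritability of the discovery disorder on its analysed scale.
    pi0 : float
        Proportion of variants with exactly zero true effect.
    n_cases, n_controls : int
        Discovery GWAS sample.
    trait_disorder_cov : float
        Genetic covariance between the disorder and the latent social trait
        (used by the power module; bookkeeping parameter here).
    theta_true : (float, float, float, float)
        Moderator model for the per-measure polygenic effect beta_cell =
        theta0 + theta_age*(age-4) + theta_reporter*[teacher] +
        theta_trait*[peer problems].
    cohort_sigma : float
        SD of the cohort-level random offset added to beta_cell.
    person_sigma : float
        SD of a person-level log-scale latent shared across all of a
        sample's measures; induces the cross-measure phenotypic
        correlation real SDQ subscales show (0 disables it).
    nb_dispersion : float
        Negative-binomial size parameter k (variance mu + mu^2/k).
    design : list[DesignCell]
        Measurement grid; defaults to the 29-cell two-cohort grid.
    seed : int
        Global seed; expanded into per-component substreams.
    """

    n_individuals: int = 2000
    n_dz_pairs: int = 500
    n_mz_singletons: int = 200
    n_variants: int = 2000
    block_size: int = 10
    within_block_r: float = 0.8
    maf_range: tuple[float, float] = (0.1, 0.5)
    h2_disorder: float = 0.22
    pi0: float = 0.9
    n_cases: int = 20000
    n_controls: int = 35000
    trait_disorder_cov: float = 0.05
    theta_true: tuple[float, float, float, float] = (0.0, 0.0025, 0.044, 0.03)
    cohort_sigma: float = 0.005
    person_sigma: float = 0.5
    nb_dispersion: float = 3.0
    design: list[DesignCell] = field(default_factory=default_design)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_individuals", "n_dz_pairs", "n_mz_singletons",
                     "n_variants", "block_size", "n_cases", "n_controls"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"invalid field '{name}': {v!r}")
        if self.n_individuals + self.n_dz_pairs + self.n_mz_singletons <= 0:
            raise ValueError("invalid field 'n_individuals': no samples requested")
        if self.n_variants <= 0:
            raise ValueError(f"invalid field 'n_variants': {self.n_variants}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"invalid field 'maf_range': {self.maf_range}")
        if not 0 <= self.within_block_r < 1:
            raise ValueError(f"invalid field 'within_block_r': {self.within_block_r}")
        if not 0 <= self.h2_disorder <= 1:
            raise ValueError(f"invalid field 'h2_disorder': {self.h2_disorder}")
        if not 0 <= self.pi0 <= 1:
            raise ValueError(f"invalid field 'pi0': {self.pi0}")
        if self.pi0 >= 1 and self.h2_disorder > 0:
            raise ValueError("invalid field 'pi0': pi0 = 1 with h2_disorder > 0")
        if self.nb_dispersion <= 0:
            raise ValueError(f"invalid field 'nb_dispersion': {self.nb_dispersion}")
        if self.cohort_sigma < 0:
            raise ValueError(f"invalid field 'cohort_sigma': {self.cohort_sigma}")
        if self.person_sigma < 0:
            raise ValueError(f"invalid field 'person_sigma': {self.person_sigma}")
        if len(self.theta_true) != 4:
            raise ValueError(f"invalid field 'theta_true': {self.theta_true}")
        seen = set()
        for c in self.design:
            key = (c.cohort, c.age_years, c.reporter, c.trait)
            if key in seen:
                raise ValueError(f"invalid field 'design': duplicate cell {key}")
            seen.add(key)

    def cohorts(self) -> list[str]:
        out: list[str] = []
        for c in self.design:
            if c.cohort not in out:
                out.append(c.cohort)
        return out

    def replace(self, **kw) -> "SimulationSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class GenotypePanel:
    """Dosage matrix plus sample metadata and variant records.

    ``dosages`` is samples x variants with values in [0, 2] (allele counts
    of the recorded effect allele). ``variants`` has columns
    snp/chr/pos/a1/a2/frq (a1 = counted allele, 1-based positions).
    ``samples`` has sample_id/family_id/zygosity/sex plus PC and batch
    covariates; zygosity is one of {unrelated, dz, mz_singleton}.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_index(self, ids) -> np.ndarray:
        lookup = pd.Index(self.variants["snp"])
        idx = lookup.get_indexer(ids)
        if (idx < 0).any():
            missing = np.asarray(ids)[idx < 0][:3]
            raise KeyError(f"variants absent from panel: {list(missing)}")
        return idx


def _draw_mafs(rng: np.random.Generator, spec: SimulationSpec) -> np.ndarray:
    """Allele frequencies: one value per LD block, shared by its variants.

    Sharing the frequency within a block keeps the copula's latent-to-dosage
    correlation attenuation uniform across block pairs, so the calibrated
    latent correlation reproduces ``within_block_r`` at the dosage level.
    """
    n_blocks = -(-spec.n_variants // spec.block_size)
    per_block = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=n_blocks)
    return np.repeat(per_block, spec.block_size)[:spec.n_variants]


@lru_cache(maxsize=4096)
def _latent_rho_for_dosage_r(target_r: float, maf: float) -> float:
    """Latent Gaussian correlation giving dosage correlation ``target_r``.

    Thresholding a bivariate normal at t = Phi^-1(f) attenuates the latent
    correlation rho to the indicator (phi) correlation
    (Phi2(t, t; rho) - f^2) / (f (1-f)); invert numerically.
    """
    if target_r <= 0:
        return 0.0
    t = stats.norm.ppf(maf)
    denom = maf * (1.0 - maf)

    def phi_corr(rho: float) -> float:
        p11 = stats.multivariate_normal.cdf(
            [t, t], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        )
        return (p11 - maf * maf) / denom

    hi = 1.0 - 1e-9
    if phi_corr(hi) <= target_r:
        return hi
    return brentq(lambda r: phi_corr(r) - target_r, 0.0, hi, xtol=1e-6)


def _haplotypes(rng: np.random.Generator, n_hap: int, mafs: np.ndarray,
                blocks: np.ndarray, rho_by_block: dict[int, float]) -> np.ndarray:
    """Draw n_hap haplotypes under the blockwise Gaussian copula."""
    m = mafs.size
    z = rng.standard_normal((n_hap, m))
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        rho = rho_by_block[int(b)]
        if rho > 0:
            u = rng.standard_normal(n_hap)
            z[:, idx] = np.sqrt(rho) * u[:, None] + np.sqrt(1 - rho) * z[:, idx]
    thresh = stats.norm.ppf(mafs)
    return (z < thresh).astype(np.int8)


def generate_genotypes(spec: SimulationSpec) -> GenotypePanel:
    """Generate an LD-blocked dosage panel with twin family structure.

    Unrelated singletons and MZ-pair representatives are drawn as
    independent haplotype pairs. Each DZ pair descends from four simulated
    parental haplotypes; each child inherits one maternal and one paternal
    haplotype segment per LD block, chosen independently, so co-twins share
    half their additive genetic values in expectation while within-block LD
    is preserved.
    """
    spec.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(_STREAM_GENO,))
    )
    m = spec.n_variants
    blocks = np.arange(m) // spec.block_size
    mafs = _draw_mafs(rng, spec)

    rho_by_block = {}
    for b in np.unique(blocks):
        maf = round(float(mafs[blocks == b][0]), 4)
        rho_by_block[int(b)] = _latent_rho_for_dosage_r(spec.within_block_r, maf)

    n_single = spec.n_individuals + spec.n_mz_singletons
    dos_single = (
        _haplotypes(rng, n_single, mafs, blocks, rho_by_block)
        + _haplotypes(rng, n_single, mafs, blocks, rho_by_block)
    ).astype(np.float64)

    # DZ pairs: blockwise transmission from 4 parental haplotypes
    n_fam = spec.n_dz_pairs
    dz_rows = []
    if n_fam > 0:
        hapm1 = _haplotypes(rng, n_fam, mafs, blocks, rho_by_block)
        hapm2 = _haplotypes(rng, n_fam, mafs, blocks, rho_by_block)
        happ1 = _haplotypes(rng, n_fam, mafs, blocks, rho_by_block)
        happ2 = _haplotypes(rng, n_fam, mafs, blocks, rho_by_block)
        n_blocks = int(blocks.max()) + 1
        for child in range(2):
            pick_m = rng.integers(0, 2, size=(n_fam, n_blocks))[:, blocks]
            pick_p = rng.integers(0, 2, size=(n_fam, n_blocks))[:, blocks]
            mat = np.where(pick_m == 0, hapm1, hapm2)
            pat = np.where(pick_p == 0, happ1, happ2)
            dz_rows.append((mat + pat).astype(np.float64))

    parts, sample_ids, family_ids, zygosity = [], [], [], []
    for i in range(spec.n_individuals):
        sample_ids.append(f"S{i:06d}")
        family_ids.append(f"F_S{i:06d}")
        zygosity.append("unrelated")
    for i in range(spec.n_mz_singletons):
        sample_ids.append(f"M{i:06d}")
        family_ids.append(f"F_M{i:06d}")
        zygosity.append("mz_singleton")
    parts.append(dos_single)
    if n_fam > 0:
        inter = np.empty((2 * n_fam, m))
        inter[0::2] = dz_rows[0]
        inter[1::2] = dz_rows[1]
        parts.append(inter)
        for f in range(n_fam):
            for k in range(2):
                sample_ids.append(f"D{f:06d}_{k}")
                family_ids.append(f"F_D{f:06d}")
                zygosity.append("dz")

    dosages = np.vstack(parts)
    n = dosages.shape[0]

    variants = pd.DataFrame({
        "snp": [f"rs{i + 1}" for i in range(m)],
        "chr": np.ones(m, dtype=int),
        "pos": 1 + 5000 * np.arange(m, dtype=int),
        "a1": "A",
        "a2": "G",
        "frq": mafs,
    })
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "family_id": family_ids,
        "zygosity": zygosity,
        "sex": rng.integers(0, 2, size=n),
        "batch": rng.integers(0, 2, size=n),
    })
    for k in range(10):
        samples[f"PC{k + 1}"] = rng.standard_normal(n)
    return GenotypePanel(dosages=dosages, variants=variants, samples=samples)


def generate_sumstats(
    spec: SimulationSpec, true_effects_out: bool = False
):
    """Simulate discovery-GWAS summary statistics for the disorder.

    A fraction ``pi0`` of variants is exactly null; the rest carry
    standardized-scale effects b ~ N(0, h2 / (m (1-pi0))), converted to the
    per-allele scale by 1/sqrt(2 f (1-f)). The reported effect adds Wald
    noise with the SE implied by the case-control sample size, and the
    p-value is the two-sided Wald test.

    Returns the summary table (columns SNP CHR BP A1 A2 BETA SE P FRQ as a
    DataFrame with lowercase names snp/chr/pos/a1/a2/beta/se/p/frq), plus
    the standardized-scale true effect vector when ``true_effects_out``.
    """
    spec.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(_STREAM_SUMSTATS,))
    )
    geno_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(_STREAM_GENO,))
    )
    m = spec.n_variants
    # replay the genotype stream's first draw so frequencies match the panel
    mafs = _draw_mafs(geno_rng, spec)

    n_nonnull = m - int(round(spec.pi0 * m))
    b_std = np.zeros(m)
    if n_nonnull > 0 and spec.h2_disorder > 0:
        idx = rng.choice(m, size=n_nonnull, replace=False)
        b_std[idx] = rng.normal(0.0, np.sqrt(spec.h2_disorder / n_nonnull),
                                size=n_nonnull)
    per_allele = b_std / np.sqrt(2 * mafs * (1 - mafs))

    n = spec.n_cases + spec.n_controls
    v = spec.n_cases / n
    se = 1.0 / np.sqrt(n * v * (1 - v) * 2 * mafs * (1 - mafs))
    beta_hat = per_allele + rng.normal(0.0, se)
    z = beta_hat / se
    p = 2 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    table = pd.DataFrame({
        "snp": [f"rs{i + 1}" for i in range(m)],
        "chr": np.ones(m, dtype=int),
        "pos": 1 + 5000 * np.arange(m, dtype=int),
        "a1": "A",
        "a2": "G",
        "beta": beta_hat,
        "se": se,
        "p": p,
        "frq": mafs,
    })
    if true_effects_out:
        return table, b_std
    return table


@lru_cache(maxsize=4096)
def _matched_intercept(target_mean: float, eta_sd: float, k_disp: float) -> float:
    """Intercept a with E[min(Y, 10)] = target_mean for the truncated draw.

    Y | eta ~ NB(mean e^(a+eta), size k) with eta ~ N(0, eta_sd^2);
    E[min(Y, 10)] = sum_{c=0..9} P(Y > c), evaluated by Gauss-Hermite
    quadrature over eta, and inverted for a by bracketing.
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(21)
    weights = weights / weights.sum()

    def trunc_mean(a: float) -> float:
        mu = np.exp(a + eta_sd * nodes)
        pnb = k_disp / (mu + k_disp)
        sf = np.array([stats.nbinom.sf(c, k_disp, pnb) for c in range(SCORE_MAX)])
        return float((sf.sum(axis=0) * weights).sum())

    naive = np.log(target_mean) - eta_sd ** 2 / 2.0
    return brentq(lambda a: trunc_mean(a) - target_mean, naive - 0.5,
                  naive + 2.0, xtol=1e-8)


def cell_effect(spec: SimulationSpec, cell: DesignCell,
                cohort_offset: float = 0.0) -> float:
    """True polygenic effect beta_cell under the moderator model."""
    t0, t_age, t_rep, t_trait = spec.theta_true
    return (t0
            + t_age * (cell.age_years - 4.0)
            + t_rep * (cell.reporter == TEACHER)
            + t_trait * (cell.trait == PEER_PROBLEMS)
            + cohort_offset)


def cohort_offsets(spec: SimulationSpec) -> dict[str, float]:
    """Cohort-level random offsets, drawn once per spec from a fixed substream."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(_STREAM_COHORT,))
    )
    return {c: float(rng.normal(0.0, spec.cohort_sigma)) for c in spec.cohorts()}


def generate_phenotypes(
    panel: GenotypePanel,
    true_effects: np.ndarray,
    spec: SimulationSpec,
    cohort: str,
) -> pd.DataFrame:
    """Draw the longitudinal count-score table for one cohort's panel.

    For every design cell of ``cohort``, every panel sample receives a score
    y ~ NegBin(mean = exp(a_cell + beta_cell * G_std), size = nb_dispersion),
    truncated at 10, where G_std is the sample's standardized true genetic
    value (standardized dosages times the standardized-scale true effects)
    and a_cell is moment-matched so the cell mean hits the design target
    (E exp(beta G) = exp(beta^2/2) for standard-normal G).

    Returns a long-format DataFrame with columns sample_id, family_id,
    cohort, median_age_years, reporter, trait, score, sex, batch, PC1..PC10.
    """
    spec.validate()
    true_effects = np.asarray(true_effects, dtype=float)
    if true_effects.shape[0] != panel.n_variants:
        raise ValueError("panel and true effects are not aligned on variants")
    cells = [c for c in spec.design if c.cohort == cohort]
    if not cells:
        raise ValueError(f"design has no cells for cohort {cohort!r}")

    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(_STREAM_PHENO,))
    )
    offs = cohort_offsets(spec)[cohort]

    f = panel.variants["frq"].to_numpy()
    x_std = (panel.dosages - 2 * f) / np.sqrt(2 * f * (1 - f))
    g = x_std @ true_effects
    sd = g.std()
    g_std = (g - g.mean()) / sd if sd > 0 else np.zeros_like(g)

    frames = []
    covar_cols = ["sex", "batch"] + [f"PC{k + 1}" for k in range(10)]
    k_disp = spec.nb_dispersion
    person = rng.normal(0.0, spec.person_sigma, size=panel.n_samples)
    for cell in cells:
        beta = cell_effect(spec, cell, offs)
        eta_sd = np.sqrt(beta ** 2 + spec.person_sigma ** 2)
        a = _matched_intercept(cell.mean_score, eta_sd, k_disp)
        mu = np.exp(a + beta * g_std + person)
        lam = rng.gamma(shape=k_disp, scale=mu / k_disp)
        y = np.minimum(rng.poisson(lam), SCORE_MAX)
        df = pd.DataFrame({
            "sample_id": panel.samples["sample_id"],
            "family_id": panel.samples["family_id"],
            "cohort": cell.cohort,
            "median_age_years": cell.age_years,
            "reporter": cell.reporter,
            "trait": cell.trait,
            "score": y.astype(int),
        })
        for c in covar_cols:
            df[c] = panel.samples[c].to_numpy()
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
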