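"""Per-measure association of social-behaviour counts with polygenic scores.

Untransformed 0-10 count scores are regressed on one or more Z-standardised
PRS with a log-link negative-binomial likelihood (statsmodels joint ML over
coefficients and dispersion), optionally with a family-level Gaussian
random intercept integrated by adaptive Gauss-Hermite quadrature (twin
cohorts). beta is the change in log counts of the social score per 1 SD
of PRS. Predictive ability is summarised by delta-McFadden's R^2 against
an intercept-plus-dispersion-only null on the same rows; replication-style
one-sided p-values are derived from the two-sided Wald test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from socialprs._nbglmm import fit_nbglmm
from socialprs.prs import PRSProfile

__all__ = ["AssocEffect", "NBFit", "fit_nb", "delta_mcfadden", "one_sided_p",
           "aic_nb_vs_poisson"]


@dataclass
class AssocEffect:
    """One univariate (or cross-disorder-adjusted) PRS association effect."""

    beta: float
    se: float
    z: float
    p_two_sided: float
    delta_mcfadden_r2: float
    n_samples: int
    dispersion: float           # NB2 alpha (var = mu + alpha mu^2)
    disorder: str
    cohort: str = ""
    median_age_years: float = np.nan
    reporter: str = ""
    trait: str = ""
    p_t: float = np.nan
    adjusted: bool = False
    converged: bool = True

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "disorder", "cohort", "median_age_years", "reporter", "trait",
            "p_t", "adjusted", "beta", "se", "z", "p_two_sided",
            "delta_mcfadden_r2", "n_samples", "dispersion", "converged")}


@dataclass
class NBFit:
    """Light container for one fitted count model (for nested comparisons)."""

    llf: float
    ll_null: float
    params: pd.Series
    nobs: int
    row_key: int                # hash of the analysed row index
    alpha: float
    converged: bool
    bse: pd.Series = field(default_factory=pd.Series)

    @property
    def mcfadden_r2(self) -> float:
        return 1.0 - self.llf / self.ll_null


def _check_outcome(y: np.ndarray) -> None:
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("outcome must be non-negative integers")


def _design(df: pd.DataFrame, cols: list[str]) -> np.ndarray:
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in cols])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"collinearity in design columns {cols}: "
                         f"rank {rank} < {X.shape[1]}")
    return X


def _fit_one(df: pd.DataFrame, cols: list[str], family_random: bool,
             ll_null: float | None = None) -> NBFit:
    y = df["score"].to_numpy(float)
    X = _design(df, cols)
    names = ["const"] + cols
    row_key = int(pd.util.hash_pandas_object(df.index).sum())
    if family_random:
        res = fit_nbglmm(y, X, df["family_id"].to_numpy())
        params = pd.Series(res.params, index=names)
        bse = pd.Series(res.bse, index=names)
        llf, alpha, conv = res.llf, res.alpha, res.converged
    else:
        mod = sm.NegativeBinomial(y, X)
        try:
            res = mod.fit(disp=0, maxiter=200, method="newton", tol=1e-10)
            if not res.mle_retvals["converged"]:
                raise ValueError
        except Exception:
            res = mod.fit(disp=0, maxiter=500, gtol=1e-9)
        params = pd.Series(res.params[:len(names)], index=names)
        bse = pd.Series(res.bse[:len(names)], index=names)
        llf, alpha, conv = res.llf, float(res.params[-1]), res.mle_retvals["converged"]
    if ll_null is None:
        if cols:
            null = _fit_one(df, [], family_random)
            ll_null = null.llf
        else:
            ll_null = llf
    return NBFit(llf=llf, ll_null=ll_null, params=params, nobs=len(df),
                 row_key=row_key, alpha=alpha, converged=conv, bse=bse)


def fit_nb(
    pheno_cell: pd.DataFrame,
    prs: PRSProfile | list[PRSProfile],
    covariates: list[str],
    family_random: bool = False,
    p_t: float = np.nan,
) -> list[AssocEffect]:
    """Fit the count model for one measurement cell; one effect per PRS.

    ``pheno_cell`` is a single (cohort, age, reporter, trait) slice of the
    long phenotype table. Passing several profiles produces the
    cross-disorder-adjusted fit (all PRS entered jointly; each effect's
    delta-McFadden's R^2 compares the joint model with the model dropping
    that PRS). Covariates are complete-case; with ``family_random`` a
    family-level Gaussian random intercept is integrated by adaptive
    quadrature. Non-convergence is flagged on the result, never silent.
    """
    profiles = [prs] if isinstance(prs, PRSProfile) else list(prs)
    cell = pheno_cell.dropna(subset=["score"] + covariates).copy()
    _check_outcome(cell["score"].to_numpy(float))
    for prof in profiles:
        zmap = pd.Series(prof.z, index=prof.sample_ids)
        cell[f"PRS_{prof.disorder}"] = zmap.reindex(cell["sample_id"]).to_numpy()
    cell = cell.dropna(subset=[f"PRS_{p.disorder}" for p in profiles])
    prs_cols = [f"PRS_{p.disorder}" for p in profiles]

    null = _fit_one(cell, [], family_random)
    full = _fit_one(cell, prs_cols + covariates, family_random,
                    ll_null=null.llf)
    labels = _cell_labels(cell)
    out = []
    for prof, col in zip(profiles, prs_cols):
        reduced_cols = [c for c in prs_cols if c != col] + covariates
        reduced = _fit_one(cell, reduced_cols, family_random, ll_null=null.llf)
        beta = float(full.params[col])
        se = float(full.bse[col])
        z = beta / se
        p2 = float(2 * stats.norm.sf(abs(z)))
        d_r2 = delta_mcfadden(full, reduced)
        out.append(AssocEffect(
            beta=beta, se=se, z=z, p_two_sided=p2, delta_mcfadden_r2=d_r2,
            n_samples=full.nobs, dispersion=full.alpha,
            disorder=prof.disorder, p_t=prof.p_t if np.isnan(p_t) else p_t,
            adjusted=len(profiles) > 1, converged=full.converged, **labels))
    return out


def _cell_labels(cell: pd.DataFrame) -> dict:
    labels = {}
    for key, out in [("cohort", "cohort"), ("median_age_years", "median_age_years"),
                     ("reporter", "reporter"), ("trait", "trait")]:
        if key in cell.columns:
            vals = cell[key].unique()
            labels[out] = vals[0] if len(vals) == 1 else vals[0]
    return labels


def delta_mcfadden(fit_with: NBFit, fit_without: NBFit) -> float:
    """Difference of McFadden pseudo-R^2 between two nested fits.

    Both fits must be on identical rows and share the intercept-plus-
    dispersion-only null likelihood; returns
    (1 - ll_with/ll_null) - (1 - ll_without/ll_null) >= 0 up to tolerance.
    """
    if fit_with.row_key != fit_without.row_key or fit_with.nobs != fit_without.nobs:
        raise ValueError("fits are not on identical rows")
    if abs(fit_with.ll_null - fit_without.ll_null) > 1e-6 * abs(fit_with.ll_null):
        raise ValueError("fits do not share the same null likelihood")
    return (1.0 - fit_with.llf / fit_with.ll_null) - \
           (1.0 - fit_without.llf / fit_without.ll_null)


def one_sided_p(effect: AssocEffect, reference_sign: int) -> float:
    """Replication-style one-sided p against a reference direction.

    p_one = p_two/2 when the estimate's sign matches the reference sign,
    1 - p_two/2 otherwise; an exactly-zero estimate gives 0.5.
    """
    if reference_sign == 0:
        raise ValueError("reference sign must be +1 or -1")
    if effect.beta == 0:
        return 0.5
    if np.sign(effect.beta) == np.sign(reference_sign):
        return effect.p_two_sided / 2.0
    return 1.0 - effect.p_two_sided / 2.0


def aic_nb_vs_poisson(df: pd.DataFrame, cols: list[str]) -> dict[str, float]:
    """AIC comparison utility (model choice is fixed to NB; this only reports)."""
    y = df["score"].to_numpy(float)
    _check_outcome(y)
    X = _design(df, cols)
    nb = sm.NegativeBinomial(y, X).fit(disp=0, maxiter=200)
    po = sm.Poisson(y, X).fit(disp=0, maxiter=200)
    return {"aic_negbin": float(nb.aic), "aic_poisson": float(po.aic)}
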