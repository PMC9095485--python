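"""Mixed-effects meta-regression of labelled PRS effects across cohorts.

Stage 2 of the pipeline: the per-measure association effects beta (one per
cohort x age x reporter x trait at the representative threshold) are
combined in the marginal model

    beta ~ N(X theta, V + tau2_cohort Z Z' + tau2_effect I)

where X holds the moderators (age centred at 4 years, teacher-report and
peer-problem indicators, optional cohort fixed effects), Z indicates the
cohort of each effect (the "nested within cohort" random structure), and V
is a composite variance-covariance matrix: block-diagonal by cohort with
cov(beta_i, beta_j) = r_ij SE_i SE_j, r_ij the phenotypic correlation
between the two measures — the same construction used for correlated
phylogenetic histories. Variance components are estimated by REML for
reported coefficients and ML for likelihood-ratio model pruning; residual
heterogeneity is summarised by Cochran's Q and moderator explanatory power
by R^2 = 1 - tau2(model)/tau2(null), the ratio of explained to total
variance in the univariate effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

__all__ = ["EffectTable", "MetaModel", "build_composite_v", "fit_meta",
           "lrt_select", "residual_q", "pseudo_r2", "predict_effects",
           "measure_label"]

AGE_CENTER = 4.0
MODERATORS = ("age", "reporter", "trait", "cohort")
_LOG_TAU2_FLOOR = -30.0


def measure_label(age_years: float, reporter: str, trait: str) -> str:
    return f"{age_years}y_{reporter}_{trait}"


@dataclass
class EffectTable:
    """Labelled univariate effects plus per-cohort phenotype correlations.

    ``data`` needs columns beta, se, cohort, median_age_years, reporter,
    trait. ``corr`` maps cohort -> DataFrame of phenotypic correlations
    indexed by measure labels (see ``measure_label``).
    """

    data: pd.DataFrame
    corr: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"beta", "se", "cohort", "median_age_years",
                    "reporter", "trait"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"effect table missing columns: {sorted(missing)}")
        if (self.data["se"] <= 0).any():
            raise ValueError("all effect SEs must be positive")
        self.data = self.data.reset_index(drop=True)

    def labels(self) -> list[str]:
        return [measure_label(a, r, t) for a, r, t in zip(
            self.data["median_age_years"], self.data["reporter"],
            self.data["trait"])]


def build_composite_v(effects: EffectTable) -> np.ndarray:
    """Composite variance-covariance matrix over effect rows.

    Within a cohort cov(beta_i, beta_j) = r_ij SE_i SE_j with r_ij the
    phenotypic correlation between the two measures; zero across cohorts
    (disjoint samples); diagonal SE^2. If numerical noise pushes the
    smallest eigenvalue below -1e-10 the matrix is projected to the
    nearest PSD matrix (eigenvalue clipping, original diagonal restored).
    """
    df = effects.data
    n = len(df)
    se = df["se"].to_numpy()
    labels = effects.labels()
    V = np.diag(se ** 2)
    for i in range(n):
        for j in range(i + 1, n):
            if df["cohort"].iat[i] != df["cohort"].iat[j]:
                continue
            cohort = df["cohort"].iat[i]
            cm = effects.corr.get(cohort)
            r = 0.0
            if cm is not None:
                li, lj = labels[i], labels[j]
                if li not in cm.index or lj not in cm.columns:
                    raise KeyError(
                        f"missing phenotypic correlation for pair ({li}, {lj})"
                        f" in cohort {cohort}")
                r = float(cm.loc[li, lj])
            V[i, j] = V[j, i] = r * se[i] * se[j]
    lam = np.linalg.eigvalsh(V)
    if lam.min() < -1e-10:
        w, Q = np.linalg.eigh(V)
        V = (Q * np.clip(w, 1e-12, None)) @ Q.T
        d = np.sqrt(se ** 2 / np.diag(V))
        V = V * np.outer(d, d)
    return V


def _design(df: pd.DataFrame, moderators: tuple[str, ...],
            cohort_levels: list[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    if "age" in moderators:
        cols.append(df["median_age_years"].to_numpy(float) - AGE_CENTER)
        names.append("age_c4")
    if "reporter" in moderators:
        cols.append((df["reporter"] == "teacher").to_numpy(float))
        names.append("reporter_teacher")
    if "trait" in moderators:
        cols.append((df["trait"] == "peer_problems").to_numpy(float))
        names.append("trait_peer_problems")
    if "cohort" in moderators:
        unseen = set(df["cohort"]) - set(cohort_levels)
        if unseen:
            raise ValueError(f"cohort level unseen in training: {sorted(unseen)}")
        for lev in cohort_levels[1:]:
            cols.append((df["cohort"] == lev).to_numpy(float))
            names.append(f"cohort_{lev}")
    X = np.column_stack(cols)
    return X, names


@dataclass
class MetaModel:
    """Fitted mixed-effects meta-regression."""

    theta: pd.Series
    se: pd.Series
    zval: pd.Series
    pval: pd.Series
    vcov_fixed: np.ndarray
    tau2_cohort: float
    tau2_effect: float
    ll_reml: float
    ll_ml: float
    method: str
    moderators: tuple[str, ...]
    random: tuple[str, ...]
    cohort_levels: list[str]
    X: np.ndarray
    y: np.ndarray
    V: np.ndarray
    cohort_codes: np.ndarray
    converged: bool

    @property
    def n_effects(self) -> int:
        return len(self.y)

    @property
    def tau2_total(self) -> float:
        return self.tau2_cohort + self.tau2_effect

    def loglik(self, method: str | None = None) -> float:
        return self.ll_ml if (method or self.method) == "ML" else self.ll_reml


def _sigma(V: np.ndarray, tau2: np.ndarray, C: np.ndarray,
           random: tuple[str, ...]) -> np.ndarray:
    S = V.copy()
    k = 0
    if "cohort" in random:
        S = S + tau2[k] * C
        k += 1
    if "effect" in random:
        S = S + tau2[k] * np.eye(len(V))
    return S


def _gls(X, y, S):
    c = cho_factor(S)
    Si_X = cho_solve(c, X)
    Si_y = cho_solve(c, y)
    XtSiX = X.T @ Si_X
    theta = np.linalg.solve(XtSiX, X.T @ Si_y)
    cov = np.linalg.inv(XtSiX)
    r = y - X @ theta
    quad = float(r @ cho_solve(c, r))
    logdet = 2 * np.log(np.diag(c[0])).sum()
    sign, logdet_xsx = np.linalg.slogdet(XtSiX)
    return theta, cov, quad, logdet, logdet_xsx


def _loglik(X, y, S, restricted: bool) -> float:
    n, p = X.shape
    _, _, quad, logdet, logdet_xsx = _gls(X, y, S)
    if restricted:
        return -0.5 * ((n - p) * np.log(2 * np.pi) + logdet + logdet_xsx + quad)
    return -0.5 * (n * np.log(2 * np.pi) + logdet + quad)


def fit_meta(
    effects: EffectTable,
    V: np.ndarray,
    moderators: tuple[str, ...] = ("age", "reporter", "trait", "cohort"),
    method: str = "REML",
    random: tuple[str, ...] = ("cohort", "effect"),
) -> MetaModel:
    """Fit theta and variance components for the marginal model.

    ``moderators`` is any subset of {age, reporter, trait, cohort} (the
    intercept is always included); ``random`` selects the variance
    components (cohort-level, effect-level). Variance components are
    optimised by bounded quasi-Newton on the log scale with multi-starts
    at ~0 and a method-of-moments value; theta is the GLS solution at the
    optimum. REML for reported estimates, ML for likelihood-ratio tests.
    """
    if method not in ("REML", "ML"):
        raise ValueError(f"method must be REML or ML: {method}")
    bad = set(moderators) - set(MODERATORS)
    if bad:
        raise ValueError(f"unknown moderators: {sorted(bad)}")
    df = effects.data
    y = df["beta"].to_numpy(float)
    cohort_levels = list(dict.fromkeys(df["cohort"]))
    codes = np.array([cohort_levels.index(c) for c in df["cohort"]])
    X, names = _design(df, moderators, cohort_levels)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(f"rank-deficient moderator design: columns {names}")
    if n <= p:
        raise ValueError(f"too few effects ({n}) for {p} coefficients")
    C = (codes[:, None] == codes[None, :]).astype(float)
    random = tuple(r for r in random if r in ("cohort", "effect"))
    if "cohort" in random and len(cohort_levels) < 2 and "effect" in random:
        # single cohort: the two components are nearly aliased; keep effect
        random = ("effect",)
    k = len(random)

    restricted = method == "REML"

    def nll(log_tau2):
        S = _sigma(V, np.exp(log_tau2), C, random)
        try:
            return -_loglik(X, y, S, restricted)
        except np.linalg.LinAlgError:
            return 1e10

    if k == 0:
        tau2 = np.zeros(0)
        converged = True
    else:
        # method-of-moments scale for starts: excess variance of y over V
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        mom = max(float(resid.var() - np.diag(V).mean()), 1e-6)
        starts = [np.full(k, _LOG_TAU2_FLOOR + 1), np.full(k, np.log(mom)),
                  np.full(k, np.log(mom) - 2)]
        best = None
        for s0 in starts:
            res = minimize(nll, s0, method="L-BFGS-B",
                           bounds=[(_LOG_TAU2_FLOOR, 5.0)] * k,
                           options={"maxiter": 500, "ftol": 1e-13})
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        tau2 = np.exp(best.x)
        tau2 = np.where(best.x <= _LOG_TAU2_FLOOR + 1e-6, 0.0, tau2)
        converged = bool(best.success)
    S = _sigma(V, tau2, C, random)
    theta, cov, _, _, _ = _gls(X, y, S)
    se = np.sqrt(np.diag(cov))
    z = theta / se
    pv = 2 * stats.norm.sf(np.abs(z))
    t2c = float(tau2[random.index("cohort")]) if "cohort" in random else 0.0
    t2e = float(tau2[random.index("effect")]) if "effect" in random else 0.0
    return MetaModel(
        theta=pd.Series(theta, index=names),
        se=pd.Series(se, index=names),
        zval=pd.Series(z, index=names),
        pval=pd.Series(pv, index=names),
        vcov_fixed=cov,
        tau2_cohort=t2c, tau2_effect=t2e,
        ll_reml=_loglik(X, y, S, True), ll_ml=_loglik(X, y, S, False),
        method=method, moderators=tuple(moderators), random=random,
        cohort_levels=cohort_levels, X=X, y=y, V=V, cohort_codes=codes,
        converged=converged)


def residual_q(model: MetaModel) -> tuple[float, int, float]:
    """Cochran's Q for residual heterogeneity beyond the moderators.

    Weighted residual sum of squares under the fixed-effect weights
    implied by V (no random components), referred to chi-square with
    df = n_effects - n_coefficients.
    """
    n, p = model.X.shape
    df = n - p
    if df <= 0:
        raise ValueError(f"Q undefined: {n} effects, {p} coefficients")
    theta_w, _, quad, _, _ = _gls(model.X, model.y, model.V)
    q = float(quad)
    return q, df, float(stats.chi2.sf(q, df))


def pseudo_r2(model: MetaModel, null_model: MetaModel) -> float:
    """Ratio of explained to total variance in the univariate effects.

    1 - tau2_total(model) / tau2_total(null_model), floored at 0 and
    capped at 1. The null model's moderators must nest inside the model's.
    """
    if not set(null_model.moderators) <= set(model.moderators):
        raise ValueError("null model moderators are not nested in the model's")
    if null_model.n_effects != model.n_effects:
        raise ValueError("models were fitted to different effect sets")
    t_null = null_model.tau2_total
    if t_null <= 0:
        return 0.0
    return float(np.clip(1.0 - model.tau2_total / t_null, 0.0, 1.0))


def lrt_select(
    effects: EffectTable,
    V: np.ndarray,
    full_moderators: tuple[str, ...] = ("age", "reporter", "trait", "cohort"),
    alpha: float = 0.05,
    retention_delta_r2: float | None = None,
    random: tuple[str, ...] = ("cohort", "effect"),
) -> tuple[MetaModel, list[dict]]:
    """Backward elimination of moderators by ML likelihood-ratio tests.

    Repeatedly drops the single moderator whose removal has the largest
    LRT p-value while that p exceeds ``alpha`` (ties: drop the term with
    the smaller |Z|), then refits the final model by REML. The trace
    records every candidate test. With ``retention_delta_r2`` set, a
    moderator whose removal would reduce the model R^2 (vs the
    intercept-only null) by more than that amount is retained even when
    its LRT p exceeds alpha.
    """
    current = tuple(full_moderators)
    trace: list[dict] = []
    null_reml = fit_meta(effects, V, (), "REML", random)

    def model_r2(mods: tuple[str, ...]) -> float:
        if not mods:
            return 0.0
        return pseudo_r2(fit_meta(effects, V, mods, "REML", random), null_reml)

    while current:
        full_ml = fit_meta(effects, V, current, "ML", random)
        candidates = []
        for mod in current:
            reduced = tuple(m for m in current if m != mod)
            red_ml = fit_meta(effects, V, reduced, "ML", random)
            df_diff = full_ml.X.shape[1] - red_ml.X.shape[1]
            lrt = max(2 * (full_ml.ll_ml - red_ml.ll_ml), 0.0)
            # zero-column moderators (e.g. cohort with one level) are no-ops
            p = 1.0 if df_diff == 0 else float(stats.chi2.sf(lrt, df_diff))
            absz = _moderator_absz(full_ml, mod)
            candidates.append({"step": len(trace), "moderator": mod,
                               "lrt": lrt, "df": df_diff, "p": p,
                               "abs_z": absz})
        trace.extend(candidates)
        droppable = [c for c in candidates if c["p"] > alpha]
        if retention_delta_r2 is not None and droppable:
            r2_full = model_r2(current)
            kept = []
            for c in droppable:
                reduced = tuple(m for m in current if m != c["moderator"])
                if r2_full - model_r2(reduced) > retention_delta_r2:
                    c["retained_by_delta_r2"] = True
                else:
                    kept.append(c)
            droppable = kept
        if not droppable:
            break
        drop = max(droppable, key=lambda c: (c["p"], -c["abs_z"]))
        current = tuple(m for m in current if m != drop["moderator"])
        drop["dropped"] = True
    final = fit_meta(effects, V, current, "REML", random)
    return final, trace


def _moderator_absz(model: MetaModel, moderator: str) -> float:
    prefix = {"age": "age_c4", "reporter": "reporter_teacher",
              "trait": "trait_peer_problems", "cohort": "cohort_"}[moderator]
    zs = [abs(z) for name, z in model.zval.items() if name.startswith(prefix)]
    return max(zs) if zs else 0.0


def predict_effects(model: MetaModel, grid: pd.DataFrame,
                    include_random: bool = False,
                    level: float = 0.95) -> pd.DataFrame:
    """Predicted moderator-profile effects beta-hat with CIs.

    ``grid`` has columns cohort, median_age_years, reporter, trait. With
    ``include_random`` the cohort-level empirical-Bayes offset is added and
    its conditional variance widens the interval. Factor levels unseen in
    training raise an error.
    """
    bad_rep = set(grid["reporter"]) - {"parent", "teacher"}
    bad_trait = set(grid["trait"]) - {"low_prosociality", "peer_problems"}
    if bad_rep or bad_trait:
        raise ValueError(f"factor level unseen in training: "
                         f"{sorted(bad_rep | bad_trait)}")
    Xg, _ = _design(grid, model.moderators, model.cohort_levels)
    pred = Xg @ model.theta.to_numpy()
    var = np.einsum("ij,jk,ik->i", Xg, model.vcov_fixed, Xg)
    if include_random and model.tau2_cohort > 0:
        S = _sigma(model.V, np.array(
            [model.tau2_cohort, model.tau2_effect][:len(model.random)]),
            (model.cohort_codes[:, None] == model.cohort_codes[None, :]
             ).astype(float), model.random)
        r = model.y - model.X @ model.theta.to_numpy()
        Si_r = np.linalg.solve(S, r)
        for lev in set(grid["cohort"]):
            if lev not in model.cohort_levels:
                raise ValueError(f"cohort level unseen in training: {lev}")
        offsets, offset_var = {}, {}
        for li, lev in enumerate(model.cohort_levels):
            zc = (model.cohort_codes == li).astype(float)
            offsets[lev] = model.tau2_cohort * float(zc @ Si_r)
            offset_var[lev] = model.tau2_cohort - model.tau2_cohort ** 2 * float(
                zc @ np.linalg.solve(S, zc))
        pred = pred + np.array([offsets[c] for c in grid["cohort"]])
        var = var + np.array([max(offset_var[c], 0.0) for c in grid["cohort"]])
    zcrit = stats.norm.ppf(0.5 + level / 2)
    se = np.sqrt(var)
    out = grid.copy()
    out["beta_hat"] = pred
    out["se"] = se
    out["ci_low"] = pred - zcrit * se
    out["ci_high"] = pred + zcrit * se
    return out
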