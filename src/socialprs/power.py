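"""Analytic PRS power and trait-disorder genetic covariance estimation.

Normal-mixture ("spike and slab") polygenic model over m independent
post-clumping markers: a fraction 1-pi0 carries standardized discovery
effects beta_j ~ N(0, h2_d / (m (1-pi0))), jointly normal with the target
trait's effects gamma_j through the genetic covariance cov_gt; estimated
discovery effects add sampling noise with variance 1/n_discovery. A
marker enters the score when its discovery p-value passes p_t, i.e.
|beta_hat_j| > c = z_{1-p_t/2} / sqrt(n_d). Closed-form truncated-normal
moments then give the expected squared correlation between score and
target trait, the noncentrality parameter of the association test at
n_target, and its power. A binary discovery trait is handled on the
liability scale (prevalence + case fraction) via the standard
observed-scale conversion.

The same model is simulated exactly (effects drawn marker-wise, the score
x trait sample correlation drawn from its Wishart distribution) for
Monte-Carlo validation, and is inverted to estimate cov_gt from observed
association effects across thresholds by profile likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.optimize import brentq, minimize_scalar

__all__ = ["PolygenicModelSpec", "expected_r2_and_power",
           "simulate_power", "estimate_covariance"]


@dataclass(frozen=True)
class PolygenicModelSpec:
    """Parameters of the two-trait polygenic model.

    m: independent markers after clumping; pi0: null proportion;
    h2_discovery: discovery-trait SNP-h2 (liability scale when
    ``prevalence`` is set); cov_gt: genetic covariance between disorder
    and target trait; h2_target: target-trait genetic variance (total
    target variance is 1, so residual variance is 1 - h2_target);
    n_cases/n_controls: discovery sample; n_target: target sample;
    p_t: selection threshold; alpha: test level; prevalence: disorder
    population prevalence (None = continuous discovery trait).
    """

    m: int = 1000
    pi0: float = 0.9
    h2_discovery: float = 0.22
    cov_gt: float = 0.05
    h2_target: float = 0.1
    n_cases: int = 20000
    n_controls: int = 20000
    n_target: int = 5000
    p_t: float = 0.1
    alpha: float = 0.05
    prevalence: float | None = None

    def validate(self) -> None:
        if not 0 <= self.pi0 < 1:
            raise ValueError(f"pi0 outside [0,1): {self.pi0}")
        for name in ("h2_discovery", "h2_target"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} outside [0,1]: {v}")
        if min(self.m, self.n_cases + self.n_controls, self.n_target) <= 0:
            raise ValueError("sample sizes and m must be positive")
        if not 0 < self.p_t <= 1:
            raise ValueError(f"p_t outside (0,1]: {self.p_t}")
        bound = np.sqrt(self.h2_obs * self.h2_target)
        if abs(self.cov_gt) > bound + 1e-12:
            raise ValueError(
                f"infeasible covariance |{self.cov_gt}| > "
                f"sqrt(h2_discovery * h2_target) = {bound:.4g}")

    @property
    def n_discovery(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def h2_obs(self) -> float:
        """Discovery h2 on the analysed (observed) scale."""
        if self.prevalence is None:
            return self.h2_discovery
        K = self.prevalence
        v = self.n_cases / self.n_discovery
        z = stats.norm.pdf(stats.norm.ppf(K))
        # inverse of the liability-scale transformation for ascertained samples
        return self.h2_discovery * z ** 2 * v * (1 - v) / (K ** 2 * (1 - K) ** 2)


def _truncated_second_moment(s2: float, c: float) -> float:
    """E[X^2 ; |X| > c] for X ~ N(0, s2)."""
    if s2 <= 0:
        return 0.0
    a = c / np.sqrt(s2)
    return s2 * 2.0 * (a * stats.norm.pdf(a) + stats.norm.sf(a))


def _model_moments(spec: PolygenicModelSpec) -> tuple[float, float, float]:
    """(A, VarS, c): score-trait covariance, score variance, selection cutoff."""
    m1 = spec.m * (1 - spec.pi0)
    m0 = spec.m - m1
    nd = spec.n_discovery
    sd2 = spec.h2_obs / m1 if m1 > 0 else 0.0
    s1sq = sd2 + 1.0 / nd
    s0sq = 1.0 / nd
    c = stats.norm.ppf(1 - spec.p_t / 2) / np.sqrt(nd)
    e1 = _truncated_second_moment(s1sq, c)
    e0 = _truncated_second_moment(s0sq, c)
    # E[gamma | beta_hat] = (cov_per_marker / s1sq) beta_hat for non-nulls
    A = (spec.cov_gt / s1sq) * e1 if m1 > 0 else 0.0
    var_s = m1 * e1 + m0 * e0
    return A, var_s, c


def expected_r2_and_power(spec: PolygenicModelSpec
                          ) -> tuple[float, float, float]:
    """Expected target-sample R^2 of the score, test NCP, and power.

    R^2 = cov(S, y)^2 / (var(S) var(y)) with var(y) = 1;
    NCP = n_target R^2 / (1 - R^2); power is the upper tail of the
    noncentral chi-square(1, NCP) at the ``alpha`` critical value.
    """
    spec.validate()
    A, var_s, _ = _model_moments(spec)
    r2 = 0.0 if var_s <= 0 else (A ** 2) / var_s
    r2 = min(r2, 1 - 1e-12)
    ncp = spec.n_target * r2 / (1 - r2)
    crit = stats.chi2.ppf(1 - spec.alpha, 1)
    power = float(stats.ncx2.sf(crit, 1, ncp)) if ncp > 0 else spec.alpha
    return float(r2), float(ncp), power


def simulate_power(spec: PolygenicModelSpec, n_reps: int = 1000,
                   seed: int = 0) -> float:
    """Monte-Carlo power under the same model (independent of the
    closed-form route).

    Each replicate draws marker effects and their noisy estimates, forms
    the selected score's true covariance with the target trait, and then
    draws the target-sample correlation test exactly from the bivariate
    sample-covariance (Wishart) distribution.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    m1 = int(round(spec.m * (1 - spec.pi0)))
    m0 = spec.m - m1
    nd = spec.n_discovery
    sd2 = spec.h2_obs / m1 if m1 > 0 else 0.0
    sg2 = spec.h2_target / m1 if m1 > 0 else 0.0
    cov_pm = spec.cov_gt / m1 if m1 > 0 else 0.0
    c = stats.norm.ppf(1 - spec.p_t / 2) / np.sqrt(nd)
    n = spec.n_target
    tcrit = stats.t.ppf(1 - spec.alpha / 2, n - 2)
    rej = 0
    for _ in range(n_reps):
        if m1 > 0 and sd2 > 0:
            cov = np.array([[sd2, cov_pm], [cov_pm, sg2]])
            bg = rng.multivariate_normal([0, 0], cov, size=m1,
                                         check_valid="ignore")
            beta, gamma = bg[:, 0], bg[:, 1]
        else:
            beta = np.zeros(m1)
            gamma = np.zeros(m1)
        bhat1 = beta + rng.normal(0, 1 / np.sqrt(nd), m1)
        bhat0 = rng.normal(0, 1 / np.sqrt(nd), m0)
        sel1 = np.abs(bhat1) > c
        sel0 = np.abs(bhat0) > c
        var_s = float((bhat1[sel1] ** 2).sum() + (bhat0[sel0] ** 2).sum())
        if var_s <= 0:
            continue
        cov_sy = float((bhat1[sel1] * gamma[sel1]).sum())
        sigma = np.array([[var_s, cov_sy], [cov_sy, 1.0]])
        W = stats.wishart.rvs(df=n - 1, scale=sigma / (n - 1), random_state=rng)
        r = W[0, 1] / np.sqrt(W[0, 0] * W[1, 1])
        tstat = r * np.sqrt((n - 2) / (1 - r ** 2))
        if abs(tstat) > tcrit:
            rej += 1
    return rej / n_reps


def expected_effect(spec: PolygenicModelSpec) -> float:
    """Model-implied standardized effect of the score on the target trait.

    The expected regression coefficient of the standardized target trait
    on the Z-standardised score equals the score-trait correlation
    sign(cov_gt) * sqrt(R^2).
    """
    r2, _, _ = expected_r2_and_power(spec)
    return float(np.sign(spec.cov_gt) * np.sqrt(r2))


def estimate_covariance(observed: list[tuple[float, float, float]],
                        spec: PolygenicModelSpec
                        ) -> tuple[float, tuple[float, float]]:
    """ML trait-disorder covariance from effects observed across thresholds.

    ``observed`` is a list of (p_t, beta, se) triples of standardized
    association effects; ``spec`` supplies the remaining model parameters
    (its cov_gt is ignored). Gaussian likelihood around the model-implied
    effect per threshold; the 95% CI is the chi-square(1) profile. A
    degenerate estimate at 0 is allowed.
    """
    if len(observed) < 1:
        raise ValueError("need at least one observed effect to estimate "
                         "one free parameter")
    spec.validate()
    bound = np.sqrt(spec.h2_obs * spec.h2_target) * (1 - 1e-9)

    def nll(cov: float) -> float:
        tot = 0.0
        for p_t, b, se in observed:
            pred = expected_effect(replace(spec, cov_gt=cov, p_t=p_t))
            tot += ((b - pred) / se) ** 2
        return 0.5 * tot

    res = minimize_scalar(nll, bounds=(-bound, bound), method="bounded",
                          options={"xatol": 1e-8})
    est = float(res.x)
    ll0 = res.fun
    crit = stats.chi2.ppf(0.95, 1) / 2

    def edge(lo: float, hi: float) -> float:
        f = lambda c: nll(c) - ll0 - crit
        if f(hi) < 0:
            return hi
        return brentq(f, lo, hi, xtol=1e-6)

    ci_hi = edge(est, bound)
    f_lo = lambda c: nll(c) - ll0 - crit
    ci_lo = -bound if f_lo(-bound) < 0 else brentq(f_lo, -bound, est, xtol=1e-6)
    return est, (float(ci_lo), float(ci_hi))
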