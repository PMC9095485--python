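"""Effective number of independent tests and study-wide thresholds.

Interrelated phenotypes inflate a Bonferroni correction; the effective
number of independent variables M_eff is estimated from the eigenvalue
spectrum of their correlation matrix (Li-Ji estimator by default, Nyholt's
variance-based estimator behind a flag) and the significance threshold is
alpha / (M_eff x number of score sets), doubled for one-sided tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["effective_tests", "threshold", "phenotype_correlation"]


def effective_tests(corr: np.ndarray, method: str = "li-ji") -> float:
    """Effective number of independent variables from a correlation matrix.

    ``li-ji``: M_eff = sum_i [ 1(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ].
    ``nyholt``: M_eff = 1 + (M - 1) (1 - var(lambda)/M).
    The matrix must be symmetric with unit diagonal and eigenvalues
    >= -1e-8; the result lies in [1, M] and is conventionally reported
    rounded to an integer.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    lam = np.linalg.eigvalsh(corr)
    if lam.min() < -1e-8:
        raise ValueError(f"matrix is not positive semidefinite "
                         f"(min eigenvalue {lam.min():.3g})")
    lam = np.clip(lam, 0.0, None)
    m = corr.shape[0]
    if method == "li-ji":
        # the floor makes the estimator discontinuous at integer eigenvalues;
        # round away eigensolver noise so exact-integer spectra land exactly
        lam_r = np.round(lam, 9)
        meff = float(np.sum((lam_r >= 1).astype(float)
                            + (lam_r - np.floor(lam_r))))
    elif method == "nyholt":
        meff = 1.0 + (m - 1) * (1.0 - np.var(lam, ddof=1) / m)
    else:
        raise ValueError(f"unknown method: {method}")
    return float(np.clip(meff, 1.0, m))


def threshold(alpha: float, m_eff: float, n_score_sets: int,
              sided: str = "two") -> float:
    """Multiple-testing-corrected significance threshold.

    Two-sided: alpha / (m_eff * n_score_sets); one-sided: the burden is
    relaxed to (2 alpha) / (m_eff * n_score_sets), with ``alpha`` the
    nominal two-sided level. Reported to 2 significant figures
    (e.g. 0.05/(10 x 5) = 0.001; one-sided 0.1/(12 x 5) = 0.0017).
    """
    if m_eff < 1:
        raise ValueError(f"m_eff must be >= 1, got {m_eff}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha outside (0,1): {alpha}")
    if n_score_sets < 1:
        raise ValueError(f"n_score_sets must be >= 1, got {n_score_sets}")
    numer = {"two": alpha, "one": 2 * alpha}[sided]
    t = numer / (round(m_eff) * n_score_sets)
    return float(f"{t:.1e}")  # 2 significant figures


def phenotype_correlation(pheno: pd.DataFrame, method: str = "spearman"
                          ) -> tuple[np.ndarray, list[str]]:
    """Pairwise-complete correlation matrix of the wide phenotype table.

    The long table is pivoted to one column per
    (age, reporter, trait) measure; SDQ-style scores are skewed counts, so
    Spearman is the default.
    """
    wide = pheno.pivot_table(
        index="sample_id",
        columns=["median_age_years", "reporter", "trait"],
        values="score")
    labels = ["{}y_{}_{}".format(*c) for c in wide.columns]
    corr = wide.corr(method=method, min_periods=2).to_numpy()
    np.fill_diagonal(corr, 1.0)
    return corr, labels
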