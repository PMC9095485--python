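"""PRSet-style pathway polygenic-score screen.

For a fixed baseline threshold (P_T <= 0.1 by convention), each gene set's
score is the baseline clumped score restricted to variants inside the
set's gene intervals (+/- flank); the association is refitted with the
identical regression specification, and a pathway passes the screen when
its association is at least as strong as the baseline's and the baseline
itself clears the study-wide gate: p_pathway <= p_baseline <= gate.
Variants are not re-clumped per set, so every pathway score is a nested
subset of the baseline score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from socialprs.association import fit_nb
from socialprs.prs import (ClumpConfig, PathwayAnnotation, pathway_subset,
                           score)
from socialprs.simulate import GenotypePanel

logger = logging.getLogger(__name__)

__all__ = ["PathwayResult", "run_pathway_screen", "screen_decision"]


@dataclass
class PathwayResult:
    set_name: str
    n_variants: int
    beta: float
    se: float
    p: float
    baseline_beta: float
    baseline_se: float
    baseline_p: float
    passes_screen: bool

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def screen_decision(p_pathway: float, p_baseline: float,
                    gate: float = 0.001) -> bool:
    """The screen is a pure function of the two p-values and the gate."""
    return p_pathway <= p_baseline <= gate


def run_pathway_screen(
    panel: GenotypePanel,
    sumstats: pd.DataFrame,
    clumped: list[str],
    annotation: PathwayAnnotation,
    sets: list[str] | None,
    pheno_cell: pd.DataFrame,
    covariates: list[str],
    baseline_p_t: float = 0.1,
    gate: float = 0.001,
    family_random: bool = False,
    disorder: str = "disorder",
) -> list[PathwayResult]:
    """Screen gene sets for association at least as strong as baseline.

    One result per non-empty set (sets with zero overlapping variants are
    skipped with a log entry); the regression specification (outcome cell,
    covariates, random-intercept flag) is identical to the baseline fit.
    """
    if len(pheno_cell) == 0:
        raise ValueError("phenotype cell is empty")
    base_profile = score(panel, sumstats, clumped, baseline_p_t,
                         disorder=disorder)
    base = fit_nb(pheno_cell, base_profile, covariates,
                  family_random=family_random)[0]
    results = []
    for name in (sets if sets is not None else annotation.sets):
        subset = pathway_subset(clumped, panel.variants, annotation, name)
        if not subset:
            logger.info("skipped %s: no overlapping variants", name)
            continue
        try:
            prof = score(panel, sumstats, subset, baseline_p_t,
                         disorder=disorder, pathway=name)
        except ValueError as exc:
            logger.info("skipped %s: %s", name, exc)
            continue
        eff = fit_nb(pheno_cell, prof, covariates,
                     family_random=family_random)[0]
        results.append(PathwayResult(
            set_name=name, n_variants=prof.n_variants,
            beta=eff.beta, se=eff.se, p=eff.p_two_sided,
            baseline_beta=base.beta, baseline_se=base.se,
            baseline_p=base.p_two_sided,
            passes_screen=screen_decision(eff.p_two_sided,
                                          base.p_two_sided, gate)))
    results.sort(key=lambda r: r.p)
    return results
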