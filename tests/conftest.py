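import warnings

import numpy as np
import pandas as pd
import pytest

from socialprs.simulate import (SimulationSpec, generate_genotypes,
                                generate_phenotypes, generate_sumstats)

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def small_spec():
    return SimulationSpec(n_individuals=800, n_dz_pairs=0, n_mz_singletons=0,
                          n_variants=300, seed=101)


@pytest.fixture(scope="session")
def small_panel(small_spec):
    return generate_genotypes(small_spec)


@pytest.fixture(scope="session")
def small_sumstats(small_spec):
    table, true_b = generate_sumstats(small_spec, true_effects_out=True)
    return table, true_b


@pytest.fixture(scope="session")
def small_pheno(small_panel, small_sumstats, small_spec):
    table, true_b = small_sumstats
    return generate_phenotypes(small_panel, true_b, small_spec, "alspac")


def nb_draw(rng, mu, size_param):
    """Reference NB sampler (gamma-Poisson mixture)."""
    lam = rng.gamma(size_param, np.asarray(mu) / size_param)
    return rng.poisson(lam)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_cell(y, extra=None):
    """Wrap an outcome vector as a minimal single-cell phenotype table."""
    n = len(y)
    df = pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)],
        "family_id": [f"F{i}" for i in range(n)],
        "cohort": "alspac",
        "median_age_years": 7.0,
        "reporter": "parent",
        "trait": "low_prosociality",
        "score": np.asarray(y, dtype=int),
    })
    if extra is not None:
        for k, v in extra.items():
            df[k] = v
    return df


def make_profile(z, disorder="d1", p_t=0.1, ids=None):
    from socialprs.prs import PRSProfile

    z = np.asarray(z, dtype=float)
    if ids is None:
        ids = [f"S{i}" for i in range(len(z))]
    return PRSProfile(sample_ids=list(ids), raw=z.copy(), z=z,
                      disorder=disorder, p_t=p_t, n_variants=1)
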