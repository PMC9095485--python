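"""Meta-regression: composite V construction, GLS/REML estimation against
matrix and grid oracles and against R's metafor, LRT pruning, Q, R^2,
prediction."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import cho_factor, cho_solve

from socialprs.meta import (EffectTable, build_composite_v, fit_meta,
                            lrt_select, measure_label, predict_effects,
                            pseudo_r2, residual_q)
from socialprs.simulate import SimulationSpec, cell_effect, default_design


def simulate_effects(theta, se=0.012, seed=0, rho=0.0, tau_extra=0.0,
                     cohorts=("alspac", "teds")):
    """29-row effect table from the moderator model, optional correlated
    within-cohort noise and extra heterogeneity."""
    rng = np.random.default_rng(seed)
    spec = SimulationSpec(theta_true=tuple(theta), cohort_sigma=0.0)
    cells = [c for c in default_design() if c.cohort in cohorts]
    rows, corr = [], {}
    for cohort in dict.fromkeys(c.cohort for c in cells):
        sub = [c for c in cells if c.cohort == cohort]
        k = len(sub)
        C = np.full((k, k), rho)
        np.fill_diagonal(C, 1.0)
        L = np.linalg.cholesky(C)
        noise = (L @ rng.standard_normal(k)) * se
        extra = rng.normal(0, tau_extra, k) if tau_extra else np.zeros(k)
        labels = [measure_label(c.age_years, c.reporter, c.trait)
                  for c in sub]
        corr[cohort] = pd.DataFrame(C, index=labels, columns=labels)
        for c, nz, ex in zip(sub, noise, extra):
            rows.append(dict(beta=cell_effect(spec, c) + nz + ex, se=se,
                             cohort=c.cohort, median_age_years=c.age_years,
                             reporter=c.reporter, trait=c.trait))
    return EffectTable(pd.DataFrame(rows), corr=corr)


class TestCompositeV:
    def test_zero_correlation_gives_diagonal(self):
        et = simulate_effects((0, 0, 0, 0), rho=0.0)
        V = build_composite_v(et)
        assert np.allclose(V, np.diag(np.diag(V)))
        np.testing.assert_allclose(np.diag(V), et.data["se"] ** 2)

    def test_unit_correlation_gives_se_product(self):
        et = simulate_effects((0, 0, 0, 0), rho=0.0)
        for c in et.corr.values():
            c.iloc[0, 1] = c.iloc[1, 0] = 1.0
        V = build_composite_v(et)
        i = 0
        assert V[i, i + 1] == pytest.approx(
            et.data["se"].iloc[i] * et.data["se"].iloc[i + 1])

    def test_three_effect_hand_computation(self):
        labels = ["7.0y_parent_low_prosociality", "7.0y_parent_peer_problems",
                  "8.0y_teacher_low_prosociality"]
        df = pd.DataFrame(dict(
            beta=[0.1, 0.2, 0.3], se=[0.01, 0.02, 0.03], cohort="c1",
            median_age_years=[7.0, 7.0, 8.0],
            reporter=["parent", "parent", "teacher"],
            trait=["low_prosociality", "peer_problems", "low_prosociality"]))
        C = pd.DataFrame([[1.0, 0.5, 0.2], [0.5, 1.0, 0.1],
                          [0.2, 0.1, 1.0]], index=labels, columns=labels)
        V = build_composite_v(EffectTable(df, corr={"c1": C}))
        expect = np.array([
            [1e-4, 0.5 * 0.01 * 0.02, 0.2 * 0.01 * 0.03],
            [0.5 * 0.01 * 0.02, 4e-4, 0.1 * 0.02 * 0.03],
            [0.2 * 0.01 * 0.03, 0.1 * 0.02 * 0.03, 9e-4]])
        np.testing.assert_allclose(V, expect, atol=1e-15)
        assert np.linalg.eigvalsh(V).min() > 0

    def test_cross_cohort_covariance_is_zero(self):
        et = simulate_effects((0, 0, 0, 0), rho=0.4)
        V = build_composite_v(et)
        coh = et.data["cohort"].to_numpy()
        cross = V[np.not_equal.outer(coh, coh)]
        assert np.all(cross == 0)

    def test_missing_pair_named(self):
        et = simulate_effects((0, 0, 0, 0), rho=0.3, cohorts=("alspac",))
        et.corr["alspac"] = et.corr["alspac"].iloc[1:, 1:]
        with pytest.raises(KeyError, match="missing phenotypic correlation"):
            build_composite_v(et)


def gls_oracle(X, y, S):
    """Direct matrix-formula GLS."""
    Si = np.linalg.inv(S)
    cov = np.linalg.inv(X.T @ Si @ X)
    return cov @ X.T @ Si @ y, cov


class TestFitMeta:
    def test_fixed_effect_limit_is_ivw_mean(self):
        # no moderators, diagonal V, variance components absent
        et = simulate_effects((0.05, 0, 0, 0), rho=0.0, seed=3)
        V = build_composite_v(et)
        m = fit_meta(et, V, moderators=(), random=())
        w = 1 / et.data["se"] ** 2
        ivw = np.sum(w * et.data["beta"]) / np.sum(w)
        assert m.theta["intercept"] == pytest.approx(ivw, abs=1e-12)

    def test_gls_matches_matrix_oracle_at_fixed_components(self):
        et = simulate_effects((0.02, 0.003, 0.04, 0.03), rho=0.3, seed=4)
        V = build_composite_v(et)
        m = fit_meta(et, V, random=())
        theta_o, cov_o = gls_oracle(m.X, m.y, V)
        np.testing.assert_allclose(m.theta.to_numpy(), theta_o, atol=1e-10)
        np.testing.assert_allclose(m.vcov_fixed, cov_o, atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_reml_optimum_matches_grid_search(self, seed):
        et = simulate_effects((0.02, 0.003, 0.04, 0.03), rho=0.2,
                              tau_extra=0.01, seed=seed)
        V = build_composite_v(et)
        m = fit_meta(et, V, random=("effect",))
        # 1-D brute-force profile over the effect-level component
        grid = np.linspace(0, 4e-4, 161)
        from socialprs.meta import _loglik
        lls = [_loglik(m.X, m.y, V + t * np.eye(len(m.y)), True)
               for t in grid]
        t_grid = grid[int(np.argmax(lls))]
        assert abs(m.tau2_effect - t_grid) <= (grid[1] - grid[0])

    def test_matches_metafor_reference(self, tmp_path):
        # single cohort, diagonal V: standard random-effects meta-regression
        rng = np.random.default_rng(7)
        n = 14
        age = rng.uniform(4, 17, n)
        rep = rng.integers(0, 2, n)
        tr = rng.integers(0, 2, n)
        beta = (0.01 + 0.002 * (age - 4) + 0.03 * rep + 0.02 * tr
                + rng.normal(0, 0.015, n))
        se = rng.uniform(0.008, 0.02, n)
        df = pd.DataFrame(dict(
            beta=beta, se=se, cohort="c1", median_age_years=age,
            reporter=np.where(rep == 1, "teacher", "parent"),
            trait=np.where(tr == 1, "peer_problems", "low_prosociality")))
        m = fit_meta(EffectTable(df), np.diag(se ** 2),
                     ("age", "reporter", "trait"), "REML", random=("effect",))
        fix = tmp_path / "meta_fix.tsv"
        df.to_csv(fix, sep="\t", index=False)
        rscript = tmp_path / "check.R"
        rscript.write_text(f"""
library(metafor)
d <- read.delim('{fix}')
d$age_c <- d$median_age_years - 4
d$rep <- as.integer(d$reporter == 'teacher')
d$tr <- as.integer(d$trait == 'peer_problems')
m <- rma(yi = beta, sei = se, mods = ~ age_c + rep + tr, data = d,
         method = 'REML', control = list(threshold = 1e-10))
cat(coef(m), m$se, m$tau2, sep = '\\n')
""")
        out = subprocess.run(["Rscript", str(rscript)], capture_output=True,
                             text=True, timeout=180)
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.split()]
        np.testing.assert_allclose(m.theta.to_numpy(), vals[:4], atol=1e-6)
        np.testing.assert_allclose(m.se.to_numpy(), vals[4:8], atol=1e-6)
        assert abs(m.tau2_effect - vals[8]) < 1e-6

    def test_invariant_to_age_recentring_and_order(self):
        et = simulate_effects((0.02, 0.003, 0.04, 0.03), rho=0.2, seed=9)
        V = build_composite_v(et)
        m1 = fit_meta(et, V, ("age", "reporter", "trait"))
        m2 = fit_meta(et, V, ("trait", "age", "reporter"))
        assert m1.theta["age_c4"] == pytest.approx(m2.theta["age_c4"],
                                                   rel=1e-9)
        shifted = EffectTable(
            et.data.assign(median_age_years=et.data["median_age_years"] + 3),
            corr=et.corr)
        m3 = fit_meta(shifted, V, ("age", "reporter", "trait"))
        assert m3.theta["age_c4"] == pytest.approx(m1.theta["age_c4"],
                                                   rel=1e-6)
        # ages shifted +3 with the centre fixed: intercept absorbs -3*theta_age
        assert m3.theta["intercept"] == pytest.approx(
            m1.theta["intercept"] - 3 * m1.theta["age_c4"], abs=1e-6)

    def test_rank_deficient_design_reported(self):
        et = simulate_effects((0, 0, 0, 0), cohorts=("alspac",), seed=1)
        df = et.data.copy()
        df["median_age_years"] = 7.0  # age constant -> aliased with intercept
        with pytest.raises(ValueError, match="rank"):
            fit_meta(EffectTable(df, corr=et.corr),
                     np.diag(df["se"] ** 2), ("age",))


class TestSelection:
    def test_strong_moderator_always_retained(self):
        for seed in range(5):
            et = simulate_effects((0.0, 0, 0, 0.05), se=0.01, seed=seed)
            V = build_composite_v(et)
            model, _ = lrt_select(et, V)
            assert "trait" in model.moderators

    def test_all_null_reduces_to_intercept_only(self):
        keep = 0
        for seed in range(20):
            et = simulate_effects((0.0, 0, 0, 0), se=0.01, seed=100 + seed)
            model, _ = lrt_select(et, build_composite_v(et))
            keep += bool(model.moderators)
        assert keep <= 5  # each of 4 nulls retained ~5% of the time

    def test_trace_records_candidates(self):
        et = simulate_effects((0.0, 0.003, 0.04, 0.03), seed=12)
        model, trace = lrt_select(et, build_composite_v(et))
        assert all({"moderator", "lrt", "df", "p"} <= set(t) for t in trace)
        assert any(t.get("dropped") for t in trace)  # cohort should drop


class TestQAndR2:
    def test_perfect_fit_gives_zero_q(self):
        et = simulate_effects((0.02, 0.003, 0.04, 0.03), seed=12)
        spec = SimulationSpec(theta_true=(0.02, 0.003, 0.04, 0.03),
                              cohort_sigma=0.0)
        exact = [cell_effect(spec, c) for c in default_design()]
        df = et.data.copy()
        df["beta"] = exact
        m = fit_meta(EffectTable(df, corr=et.corr), np.eye(len(df)),
                     ("age", "reporter", "trait"), random=())
        q, dfq, p = residual_q(m)
        assert q == pytest.approx(0.0, abs=1e-18)
        assert p == pytest.approx(1.0)

    def test_df_boundary_error(self):
        et = simulate_effects((0, 0, 0, 0), cohorts=("alspac",), seed=13)
        df = et.data.iloc[:5].reset_index(drop=True)
        m = fit_meta(EffectTable(df, corr=et.corr),
                     np.diag(df["se"] ** 2), ("age",))
        m.X = np.eye(5)  # saturated design: df = n - p = 0
        with pytest.raises(ValueError, match="Q undefined"):
            residual_q(m)

    def test_r2_zero_for_self_and_one_in_explained_limit(self):
        et = simulate_effects((0.0, 0.004, 0.05, 0.04), se=0.005, seed=14)
        V = build_composite_v(et)
        null = fit_meta(et, V, ())
        full = fit_meta(et, V, ("age", "reporter", "trait"))
        assert pseudo_r2(null, null) == 0.0
        assert pseudo_r2(full, null) > 0.9  # moderators explain heterogeneity

    def test_non_nested_rejected(self):
        et = simulate_effects((0, 0.003, 0.04, 0.03), seed=15)
        V = build_composite_v(et)
        a = fit_meta(et, V, ("age",))
        b = fit_meta(et, V, ("trait",))
        with pytest.raises(ValueError, match="nested"):
            pseudo_r2(a, b)


class TestPredict:
    @pytest.fixture
    def model(self):
        et = simulate_effects((0.01, 0.003, 0.04, 0.03), seed=16)
        return fit_meta(et, build_composite_v(et),
                        ("age", "reporter", "trait"))

    def test_reference_cell_equals_intercept(self, model):
        grid = pd.DataFrame([dict(cohort="alspac", median_age_years=4.0,
                                  reporter="parent",
                                  trait="low_prosociality")])
        out = predict_effects(model, grid)
        assert out["beta_hat"].iloc[0] == pytest.approx(
            model.theta["intercept"], abs=1e-14)

    def test_trait_contrast_equals_theta(self, model):
        grid = pd.DataFrame([
            dict(cohort="alspac", median_age_years=9.0, reporter="parent",
                 trait="low_prosociality"),
            dict(cohort="alspac", median_age_years=9.0, reporter="parent",
                 trait="peer_problems")])
        out = predict_effects(model, grid)
        diff = out["beta_hat"].iloc[1] - out["beta_hat"].iloc[0]
        assert diff == pytest.approx(model.theta["trait_peer_problems"],
                                     abs=1e-14)

    def test_ci_narrowest_near_design_centroid(self):
        for seed in range(10):
            et = simulate_effects((0.01, 0.003, 0.04, 0.03), seed=20 + seed)
            m = fit_meta(et, build_composite_v(et), ("age",))
            centroid = et.data["median_age_years"].mean()
            grid = pd.DataFrame([
                dict(cohort="alspac", median_age_years=a, reporter="parent",
                     trait="low_prosociality")
                for a in (centroid, 1.0, 25.0)])
            out = predict_effects(m, grid)
            w = out["ci_high"] - out["ci_low"]
            assert w.iloc[0] <= w.iloc[1] and w.iloc[0] <= w.iloc[2]

    def test_unseen_factor_level_rejected(self, model):
        grid = pd.DataFrame([dict(cohort="alspac", median_age_years=4.0,
                                  reporter="self", trait="low_prosociality")])
        with pytest.raises(ValueError, match="unseen"):
            predict_effects(model, grid)
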