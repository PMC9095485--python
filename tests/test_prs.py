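"""C+T engine: parsing/validation, allele harmonization, greedy clumping
against a brute-force oracle, scoring, pathway subsetting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from socialprs.io import write_sumstats
from socialprs.prs import (ClumpConfig, PathwayAnnotation, harmonize,
                           ld_clump, parse_sumstats, pathway_subset, score)
from socialprs.simulate import GenotypePanel

from conftest import make_profile


def toy_panel(dosages, chrom=None, pos=None, a1="A", a2="G"):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame({
        "snp": [f"rs{i + 1}" for i in range(m)],
        "chr": chrom if chrom is not None else np.ones(m, dtype=int),
        "pos": pos if pos is not None else 1 + 1000 * np.arange(m),
        "a1": a1, "a2": a2,
        "frq": dosages.mean(axis=0) / 2,
    })
    samples = pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)],
        "family_id": [f"F{i}" for i in range(n)],
        "zygosity": "unrelated",
        "sex": 0, "batch": 0,
    })
    for k in range(10):
        samples[f"PC{k + 1}"] = 0.0
    return GenotypePanel(dosages=dosages, variants=variants, samples=samples)


def toy_sumstats(m, beta=None, p=None, a1="A", a2="G", pos=None):
    return pd.DataFrame({
        "snp": [f"rs{i + 1}" for i in range(m)],
        "chr": np.ones(m, dtype=int),
        "pos": pos if pos is not None else 1 + 1000 * np.arange(m),
        "a1": a1, "a2": a2,
        "beta": beta if beta is not None else np.full(m, 0.1),
        "se": np.full(m, 0.01),
        "p": p if p is not None else np.full(m, 0.01),
        "frq": np.full(m, 0.3),
    })


class TestParse:
    def test_round_trip(self, tmp_path, small_sumstats):
        table, _ = small_sumstats
        path = tmp_path / "ss.tsv"
        write_sumstats(table, path)
        back = parse_sumstats(path)
        assert len(back) == len(table)
        np.testing.assert_allclose(back["beta"], table["beta"], rtol=1e-12)

    def test_odds_ratio_one_becomes_zero_effect(self, tmp_path):
        df = toy_sumstats(3).drop(columns=["beta"])
        df["or"] = 1.0
        df = df.rename(columns={"snp": "SNP", "pos": "BP"})
        path = tmp_path / "or.tsv"
        df.to_csv(path, sep="\t", index=False)
        out = parse_sumstats(path)
        assert (out["beta"] == 0.0).all()

    def test_malformed_p_row_rejected_and_logged(self, tmp_path, caplog):
        df = toy_sumstats(100)
        df.loc[42, "p"] = 0.0
        path = tmp_path / "bad.tsv"
        df.to_csv(path, sep="\t", index=False)
        with caplog.at_level("WARNING"):
            out = parse_sumstats(path)
        assert len(out) == 99
        assert "rs43" in caplog.text and "p-value" in caplog.text

    def test_missing_column_is_hard_error(self, tmp_path):
        df = toy_sumstats(5).drop(columns=["se"])
        path = tmp_path / "nose.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="SE"):
            parse_sumstats(path)

    def test_non_acgt_allele_rejected(self, tmp_path):
        df = toy_sumstats(10)
        df.loc[3, "a1"] = "I"
        path = tmp_path / "indel.tsv"
        df.to_csv(path, sep="\t", index=False)
        assert len(parse_sumstats(path)) == 9


class TestHarmonize:
    def test_allele_swap_flips_sign(self):
        panel = toy_panel(np.random.default_rng(0).integers(0, 3, (20, 1)),
                          a1="A", a2="G")
        ss = toy_sumstats(1, beta=[0.1], a1="G", a2="A")
        out = harmonize(ss, panel)
        assert out["beta"].iloc[0] == pytest.approx(-0.1)
        assert out["a1"].iloc[0] == "A"

    def test_identical_alleles_unchanged(self):
        panel = toy_panel(np.random.default_rng(0).integers(0, 3, (20, 2)))
        ss = toy_sumstats(2, beta=[0.1, -0.2])
        out = harmonize(ss, panel)
        np.testing.assert_allclose(out["beta"], [0.1, -0.2])

    def test_constructed_mixture_counts(self):
        # 1000 variants: 100 swapped, 50 ambiguous, rest aligned
        rng = np.random.default_rng(1)
        m = 1000
        panel = toy_panel(rng.integers(0, 3, (10, m)))
        ss = toy_sumstats(m, beta=np.full(m, 0.1))
        swap = rng.choice(m, 150, replace=False)
        amb = swap[100:]
        swap = swap[:100]
        ss.loc[swap, ["a1", "a2"]] = ["G", "A"]
        ss.loc[amb, ["a1", "a2"]] = ["C", "G"]
        out = harmonize(ss, panel, drop_ambiguous=True)
        assert len(out) == 950
        assert (out["beta"] < 0).sum() == 100

    def test_idempotent(self, small_panel, small_sumstats):
        table, _ = small_sumstats
        once = harmonize(table, small_panel)
        twice = harmonize(once, small_panel)
        pd.testing.assert_frame_equal(once, twice)

    def test_zero_overlap_is_error(self, small_panel):
        ss = toy_sumstats(3)
        ss["snp"] = ["zz1", "zz2", "zz3"]
        with pytest.raises(ValueError, match="overlap"):
            harmonize(ss, small_panel)


def brute_force_clump(sumstats, r2mat, cfg):
    """Reference clumping that re-scans all pairs every round."""
    df = sumstats.copy().reset_index(drop=True)
    alive = set(df.index)
    picked = []
    while alive:
        sub = df.loc[sorted(alive)]
        best = sub.sort_values(["p", "pos", "snp"], kind="mergesort").index[0]
        picked.append(df.loc[best, "snp"])
        alive.discard(best)
        for j in list(alive):
            same_chr = df.loc[j, "chr"] == df.loc[best, "chr"]
            near = abs(df.loc[j, "pos"] - df.loc[best, "pos"]) \
                <= cfg.window_kb * 1000
            if same_chr and near and r2mat[best, j] >= cfg.r2_threshold:
                alive.discard(j)
    order = {s: (df.set_index("snp").loc[s, "chr"],
                 df.set_index("snp").loc[s, "pos"]) for s in picked}
    return sorted(picked, key=lambda s: order[s])


class TestClump:
    def test_independent_variants_all_kept(self):
        rng = np.random.default_rng(2)
        panel = toy_panel(rng.integers(0, 3, (500, 8)))
        ss = toy_sumstats(8, p=rng.uniform(0.001, 0.5, 8))
        assert len(ld_clump(ss, panel, ClumpConfig(r2_threshold=0.9))) == 8

    def test_perfect_ld_keeps_best_p(self):
        rng = np.random.default_rng(3)
        col = rng.integers(0, 3, (100, 1)).astype(float)
        panel = toy_panel(np.hstack([col, col]))
        ss = toy_sumstats(2, p=[1e-8, 1e-4])
        assert ld_clump(ss, panel) == ["rs1"]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 300, 10
        base = rng.integers(0, 3, (n, m)).astype(float)
        # plant correlated pairs
        for j in range(0, m - 1, 3):
            mask = rng.random(n) < 0.8
            base[mask, j + 1] = base[mask, j]
        panel = toy_panel(base)
        ss = toy_sumstats(m, p=rng.uniform(1e-6, 0.9, m))
        cfg = ClumpConfig(r2_threshold=0.3, window_kb=5)
        d = panel.dosages
        r2mat = np.corrcoef(d.T) ** 2
        assert ld_clump(ss, panel, cfg) == brute_force_clump(ss, r2mat, cfg)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_to_row_order(self, seed):
        rng = np.random.default_rng(seed)
        panel = toy_panel(rng.integers(0, 3, (100, 12)).astype(float))
        # duplicate p-values to exercise the tie-break
        ss = toy_sumstats(12, p=rng.choice([1e-4, 1e-3, 0.01], 12))
        shuffled = ss.sample(frac=1, random_state=seed)
        assert ld_clump(ss, panel) == ld_clump(shuffled, panel)


class TestScore:
    def test_standardized_mean_zero_sd_one(self, small_panel,
                                           small_sumstats):
        table, _ = small_sumstats
        ss = harmonize(table, small_panel)
        clumped = ld_clump(ss, small_panel)
        prof = score(small_panel, ss, clumped, 0.5)
        assert abs(prof.z.mean()) < 1e-8
        assert abs(prof.z.std() - 1) < 1e-8

    def test_constant_score_rejected(self):
        panel = toy_panel(np.full((10, 2), 2.0))
        ss = toy_sumstats(2)
        with pytest.raises(ValueError, match="zero variance"):
            score(panel, ss, ["rs1", "rs2"], 1.0)

    def test_no_passing_variant_names_threshold(self, small_panel,
                                                small_sumstats):
        table, _ = small_sumstats
        ss = harmonize(table, small_panel)
        ss["p"] = 0.5
        with pytest.raises(ValueError, match="1e-09"):
            score(small_panel, ss, list(ss["snp"][:5]), 1e-9)

    def test_single_variant_score_is_standardized_dosage(self):
        dos = np.array([[0.0], [1.0], [2.0], [1.0], [0.0]])
        panel = toy_panel(dos)
        ss = toy_sumstats(1, beta=[-0.3])
        prof = score(panel, ss, ["rs1"], 1.0)
        d = dos[:, 0]
        expect = -(d - d.mean()) / d.std()  # sign of the effect
        np.testing.assert_allclose(prof.z, expect, atol=1e-12)

    def test_threshold_nesting(self, small_panel, small_sumstats):
        table, _ = small_sumstats
        ss = harmonize(table, small_panel)
        clumped = ld_clump(ss, small_panel)
        sizes = [score(small_panel, ss, clumped, pt).n_variants
                 for pt in (0.05, 0.2, 0.999)]
        assert sizes == sorted(sizes)

    def test_missing_dosages_mean_imputed(self):
        dos = np.array([[0.0, 1], [1, 1], [2, 1], [np.nan, 1], [2, 1]])
        panel = toy_panel(np.nan_to_num(dos))
        panel.dosages = dos  # re-inject the missing value
        ss = toy_sumstats(2, beta=[1.0, 0.5])
        prof = score(panel, ss, ["rs1", "rs2"], 1.0)
        filled = dos.copy()
        filled[3, 0] = np.nanmean(dos[:, 0])
        np.testing.assert_allclose(prof.raw, filled @ [1.0, 0.5])


class TestPathwaySubset:
    @pytest.fixture
    def annotation(self):
        # 0-based half-open gene intervals on chromosome 1
        genes = {"G1": (1, 0, 5_000), "G2": (1, 8_000, 9_000),
                 "G3": (2, 0, 100_000)}
        sets = {"all_span": ["G1", "G2", "G3"], "tiny": ["G2"],
                "off_chrom": ["G3"], "empty_genes": []}
        return PathwayAnnotation(genes=genes, sets=sets, flank_kb=1.0)

    def test_spanning_set_returns_input(self, annotation):
        variants = toy_sumstats(5, pos=[1, 1000, 3000, 5500, 8500])
        clumped = list(variants["snp"])
        got = pathway_subset(clumped, variants, annotation, "all_span")
        assert got == clumped

    def test_disjoint_set_empty(self, annotation):
        variants = toy_sumstats(3, pos=[20_000, 30_000, 40_000])
        assert pathway_subset(list(variants["snp"]), variants, annotation,
                              "tiny") == []

    def test_hand_checked_flank_arithmetic(self, annotation):
        # G2 covers 0-based [8000,9000) +/- 1kb flank -> [7000, 10000)
        # 1-based positions 7001..10000 inclusive are inside
        variants = toy_sumstats(6, pos=[6_999, 7_000, 7_001, 9_999,
                                        10_000, 10_001])
        got = pathway_subset(list(variants["snp"]), variants, annotation,
                             "tiny")
        assert got == ["rs3", "rs4", "rs5"]

    def test_unknown_set_errors(self, annotation):
        with pytest.raises(KeyError, match="nope"):
            pathway_subset([], toy_sumstats(1), annotation, "nope")
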