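"""C+T polygenic scoring: parse, harmonize, clump, threshold, score.

Summary statistics are held as pandas DataFrames with columns
``snp chr pos a1 a2 beta se p frq`` (a1 = effect allele, beta = log-odds).
Scores are built by greedy LD clumping (ascending p-value, dosage-r^2
pruning within a window) followed by p-value thresholding, and are
Z-standardised over the scored samples. Pathway scores restrict the
clumped variants to those inside a gene set's intervals (+/- flank).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from socialprs.simulate import GenotypePanel

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["snp", "chr", "pos", "a1", "a2", "se", "p", "frq"]
VALID_ALLELES = {"A", "C", "G", "T"}
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

#: nine variant-selection thresholds spanning 0.001 <= P_T < 1
DEFAULT_P_THRESHOLDS = (0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.3, 0.5,
                        1.0 - 1e-9)
#: representative threshold used for reporting and stage-2 input
REPRESENTATIVE_P_T = 0.1


@dataclass(frozen=True)
class ClumpConfig:
    """Greedy clumping parameters: prune r^2 >= threshold within window_kb."""

    r2_threshold: float = 0.1
    window_kb: float = 250.0

    def __post_init__(self) -> None:
        if not 0 < self.r2_threshold <= 1:
            raise ValueError(f"r2_threshold outside (0,1]: {self.r2_threshold}")
        if self.window_kb <= 0:
            raise ValueError(f"window_kb must be positive: {self.window_kb}")


@dataclass
class PRSProfile:
    """Per-sample raw and Z-standardised polygenic score with provenance."""

    sample_ids: list[str]
    raw: np.ndarray
    z: np.ndarray
    disorder: str
    p_t: float
    n_variants: int
    clump: ClumpConfig = field(default_factory=ClumpConfig)
    pathway: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids,
                             "raw": self.raw, "z": self.z})


@dataclass
class PathwayAnnotation:
    """Gene intervals (0-based half-open) plus named gene sets and a flank."""

    genes: dict[str, tuple[int, int, int]]
    sets: dict[str, list[str]]
    flank_kb: float = 10.0


def parse_sumstats(path) -> pd.DataFrame:
    """Read and validate a GWAS summary-statistics TSV.

    Accepts either a BETA (log-odds) or an OR column (log-transformed on
    read). Rows failing validation (non-ACGT alleles, SE <= 0, p outside
    (0,1], OR <= 0) are dropped and each rejection logged with its reason;
    a missing required column is a hard error naming the column.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    df = df.rename(columns={"bp": "pos"})
    if "beta" not in df.columns and "or" in df.columns:
        bad = df["or"] <= 0
        for snp in df.loc[bad, "snp"]:
            logger.warning("rejected %s: non-positive OR", snp)
        df = df[~bad].copy()
        df["beta"] = np.log(df["or"].astype(float))
    for col in REQUIRED_COLUMNS + ["beta"]:
        if col not in df.columns:
            raise ValueError(f"missing required column: {col.upper()}")

    keep = np.ones(len(df), dtype=bool)
    a1 = df["a1"].astype(str).str.upper()
    a2 = df["a2"].astype(str).str.upper()
    for mask, reason in [
        (~(a1.isin(VALID_ALLELES) & a2.isin(VALID_ALLELES)), "non-ACGT allele"),
        (~(df["se"] > 0), "non-positive SE"),
        (~((df["p"] > 0) & (df["p"] <= 1)), "p-value outside (0,1]"),
    ]:
        for snp in df.loc[keep & mask, "snp"]:
            logger.warning("rejected %s: %s", snp, reason)
        keep &= ~mask.to_numpy()
    df = df[keep].copy()
    df["a1"], df["a2"] = a1[keep], a2[keep]
    if df["snp"].duplicated().any():
        dups = df.loc[df["snp"].duplicated(), "snp"].unique()[:3]
        raise ValueError(f"duplicate variant IDs: {list(dups)}")
    return df.reset_index(drop=True)


def harmonize(sumstats: pd.DataFrame, panel: GenotypePanel,
              drop_ambiguous: bool = True) -> pd.DataFrame:
    """Align summary-statistic effect alleles to the panel's counted allele.

    Variants whose alleles are swapped relative to the panel have their
    effect sign flipped (and frequency complemented); strand-ambiguous
    (A/T, C/G) variants are dropped when ``drop_ambiguous``; variants with
    irreconcilable alleles are dropped with a log entry. Output is the
    intersection with the panel, in panel variant order. Idempotent.
    """
    pv = panel.variants.set_index("snp")
    common = [s for s in pv.index if s in set(sumstats["snp"])]
    if not common:
        raise ValueError("no overlapping variants between sumstats and panel")
    ss = sumstats.set_index("snp").loc[common]

    out_rows = []
    n_flip = n_amb = n_mismatch = 0
    for snp in common:
        row = ss.loc[snp]
        p_a1, p_a2 = pv.at[snp, "a1"], pv.at[snp, "a2"]
        s_a1, s_a2 = row["a1"], row["a2"]
        if drop_ambiguous and (s_a1, s_a2) in AMBIGUOUS_PAIRS:
            n_amb += 1
            continue
        rec = row.to_dict()
        rec["snp"] = snp
        if (s_a1, s_a2) == (p_a1, p_a2):
            pass
        elif (s_a1, s_a2) == (p_a2, p_a1):
            rec["beta"] = -row["beta"]
            rec["a1"], rec["a2"] = p_a1, p_a2
            rec["frq"] = 1.0 - row["frq"]
            n_flip += 1
        else:
            n_mismatch += 1
            logger.warning("dropped %s: alleles %s/%s vs panel %s/%s",
                           snp, s_a1, s_a2, p_a1, p_a2)
            continue
        rec["chr"], rec["pos"] = pv.at[snp, "chr"], pv.at[snp, "pos"]
        out_rows.append(rec)
    logger.info("harmonize: %d kept, %d sign flips, %d ambiguous dropped, "
                "%d mismatched dropped", len(out_rows), n_flip, n_amb, n_mismatch)
    if not out_rows:
        raise ValueError("no overlapping variants after allele harmonization")
    cols = ["snp", "chr", "pos", "a1", "a2", "beta", "se", "p", "frq"]
    return pd.DataFrame(out_rows)[cols].reset_index(drop=True)


def _dosage_r2(panel: GenotypePanel, i: int, others: np.ndarray) -> np.ndarray:
    x = panel.dosages[:, i]
    y = panel.dosages[:, others]
    xc = x - x.mean()
    yc = y - y.mean(axis=0)
    denom = np.sqrt((xc @ xc) * (yc * yc).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc @ yc) / denom, 0.0)
    return r ** 2


def ld_clump(sumstats: pd.DataFrame, panel: GenotypePanel,
             cfg: ClumpConfig = ClumpConfig()) -> list[str]:
    """Greedy LD clumping; returns index-variant IDs sorted by position.

    The best remaining variant by ascending p-value (ties: smaller
    position, then ID) becomes an index; all remaining variants on the
    same chromosome within ``window_kb`` whose dosage r^2 with it is >=
    ``r2_threshold`` are removed; repeat until exhausted.
    """
    ss = sumstats.sort_values(["p", "pos", "snp"], kind="mergesort")
    order = panel.variant_index(ss["snp"])
    chrom = ss["chr"].to_numpy()
    pos = ss["pos"].to_numpy()
    window = cfg.window_kb * 1000.0

    alive = np.ones(len(ss), dtype=bool)
    index_ids: list[tuple[int, int, str]] = []
    snps = ss["snp"].to_numpy()
    for k in range(len(ss)):
        if not alive[k]:
            continue
        alive[k] = False
        index_ids.append((int(chrom[k]), int(pos[k]), snps[k]))
        cand = np.flatnonzero(alive
                              & (chrom == chrom[k])
                              & (np.abs(pos - pos[k]) <= window))
        if cand.size:
            r2 = _dosage_r2(panel, int(order[k]), order[cand])
            alive[cand[r2 >= cfg.r2_threshold]] = False
    index_ids.sort()
    return [snp for _, _, snp in index_ids]


def score(panel: GenotypePanel, sumstats: pd.DataFrame, clumped: list[str],
          p_t: float, disorder: str = "disorder",
          clump: ClumpConfig = ClumpConfig(),
          pathway: str | None = None) -> PRSProfile:
    """Weighted allelic score over clumped variants passing the threshold.

    raw_i = sum_j dosage_ij * beta_j over clumped variants with p_j <= p_t;
    missing dosages are mean-imputed per variant; the Z score standardises
    raw over all scored samples (an all-equal score is an error).
    """
    ss = sumstats.set_index("snp").loc[clumped]
    sel = ss[ss["p"] <= p_t]
    if len(sel) == 0:
        raise ValueError(f"no variant passes threshold p_t={p_t}")
    idx = panel.variant_index(sel.index)
    dos = panel.dosages[:, idx].astype(float)
    if np.isnan(dos).any():
        col_mean = np.nanmean(dos, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(dos))
        dos[nan_r, nan_c] = col_mean[nan_c]
    raw = dos @ sel["beta"].to_numpy()
    sd = raw.std()
    if sd < 1e-12:
        raise ValueError("zero variance: polygenic score is constant across samples")
    z = (raw - raw.mean()) / sd
    return PRSProfile(sample_ids=panel.samples["sample_id"].tolist(),
                      raw=raw, z=z, disorder=disorder, p_t=p_t,
                      n_variants=len(sel), clump=clump, pathway=pathway)


def pathway_subset(clumped: list[str], variants: pd.DataFrame,
                   annotation: PathwayAnnotation, set_name: str) -> list[str]:
    """Clumped variants falling inside any member gene's interval +/- flank.

    ``variants`` supplies snp/chr/pos (1-based positions); gene intervals
    are 0-based half-open. The result preserves the input order and may be
    empty.
    """
    if set_name not in annotation.sets:
        raise KeyError(f"unknown gene set: {set_name}")
    flank = annotation.flank_kb * 1000.0
    intervals = []
    for gene in annotation.sets[set_name]:
        if gene in annotation.genes:
            c, s, e = annotation.genes[gene]
            intervals.append((c, max(0, s - flank), e + flank))
    vt = variants.set_index("snp")
    out = []
    for snp in clumped:
        c, p0 = int(vt.at[snp, "chr"]), int(vt.at[snp, "pos"]) - 1
        if any(c == ci and si <= p0 < ei for ci, si, ei in intervals):
            out.append(snp)
    return out
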