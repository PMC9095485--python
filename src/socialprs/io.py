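"""Readers/writers for the pipeline's on-disk formats.

Genotype panels travel as VCF (GT:DS per sample) plus a sample-metadata
TSV; GWAS summary statistics as a tab-delimited table with header
``SNP CHR BP A1 A2 BETA SE P FRQ``; phenotypes as long-format TSV; gene
intervals as BED (0-based half-open on disk and in memory); gene sets as
GMT. Coordinates are 1-based in VCF/GWAS files.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from socialprs.simulate import GenotypePanel

SUMSTAT_HEADER = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "FRQ"]
_COLMAP = dict(zip(SUMSTAT_HEADER, ["snp", "chr", "pos", "a1", "a2",
                                    "beta", "se", "p", "frq"]))


def write_sumstats(table: pd.DataFrame, path: str | os.PathLike) -> None:
    out = table.rename(columns={v: k for k, v in _COLMAP.items()})
    out[SUMSTAT_HEADER].to_csv(path, sep="\t", index=False)


def read_sumstats_raw(path: str | os.PathLike) -> pd.DataFrame:
    """Read a GWAS TSV without validation (see prs.parse_sumstats)."""
    df = pd.read_csv(path, sep="\t")
    return df


def write_phenotypes(pheno: pd.DataFrame, path: str | os.PathLike) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_panel(panel: GenotypePanel, vcf_path: str | os.PathLike,
                meta_path: str | os.PathLike) -> None:
    """Write dosages as a VCF with GT:DS fields plus a sample-metadata TSV.

    GT is the rounded dosage (0/0, 0/1, 1/1); DS carries the exact value.
    """
    samples = panel.samples["sample_id"].tolist()
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description='
                 '"Dosage of ALT allele">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        gt_codes = np.array(["0/0", "0/1", "1/1"])
        for j, rec in panel.variants.iterrows():
            ds = panel.dosages[:, j]
            gt = gt_codes[np.clip(np.rint(ds).astype(int), 0, 2)]
            fields = [f"{g}:{d:.3f}" for g, d in zip(gt, ds)]
            # ALT is the counted (effect) allele a1, REF the other allele
            fh.write(f"{rec['chr']}\t{rec['pos']}\t{rec['snp']}\t{rec['a2']}\t"
                     f"{rec['a1']}\t.\tPASS\t.\tGT:DS\t" + "\t".join(fields) + "\n")
    panel.samples.to_csv(meta_path, sep="\t", index=False)


def read_panel(vcf_path: str | os.PathLike,
               meta_path: str | os.PathLike) -> GenotypePanel:
    """Read a GT:DS VCF and sample metadata back into a GenotypePanel."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    sample_ids = vcf.samples
    rows, dosage_cols = [], []
    for v in vcf:
        ds = v.format("DS")
        if ds is None:  # fall back to GT allele counts
            col = np.array([sum(g[:2]) for g in v.genotypes], dtype=float)
        else:
            col = np.asarray(ds, dtype=float).ravel()
        dosage_cols.append(col)
        rows.append({"snp": v.ID, "chr": int(v.CHROM), "pos": v.POS,
                     "a1": v.ALT[0], "a2": v.REF,
                     "frq": float(col.mean() / 2.0)})
    variants = pd.DataFrame(rows)
    dosages = np.column_stack(dosage_cols)
    samples = pd.read_csv(meta_path, sep="\t")
    if list(samples["sample_id"]) != list(sample_ids):
        samples = samples.set_index("sample_id").loc[sample_ids].reset_index()
    return GenotypePanel(dosages=dosages, variants=variants, samples=samples)


def read_bed_genes(path: str | os.PathLike) -> dict[str, tuple[int, int, int]]:
    """BED file of gene intervals -> {gene: (chrom, start, end)}, 0-based half-open."""
    genes: dict[str, tuple[int, int, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            chrom, start, end, name = line.split("\t")[:4]
            genes[name] = (int(chrom.removeprefix("chr")), int(start), int(end))
    return genes


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """GMT gene sets -> {set name: [genes]} (description column ignored)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate gene-set name: {name}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


def load_simulation_spec(path: str | os.PathLike):
    """Read a SimulationSpec from a YAML file mapping 1:1 onto its fields.

    ``design`` entries are mappings with cohort/age_years/reporter/trait/
    mean_score; ``maf_range`` and ``theta_true`` may be YAML lists.
    """
    import yaml

    from socialprs.simulate import DesignCell, SimulationSpec

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "design" in data:
        data["design"] = [DesignCell(**cell) for cell in data["design"]]
    for key in ("maf_range", "theta_true"):
        if key in data:
            data[key] = tuple(data[key])
    spec = SimulationSpec(**data)
    spec.validate()
    return spec


def write_effects(effects, path: str | os.PathLike) -> None:
    """Tidy effect table (one row per disorder x measure x threshold x adjustment)."""
    pd.DataFrame([e.to_dict() for e in effects]).to_csv(path, sep="\t", index=False)


def read_effects(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
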