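"""Readers for the standard interchange formats.

Summary statistics, phenotype tables, BED gene intervals and GMT gene
sets are line-oriented text; malformed lines are reported with their line
number. Genotypes come from VCF via cyvcf2 (DS dosages used verbatim when
present, otherwise ALT-allele counts from GT; missing calls become NaN).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from pathprs.containers import GenotypeData

__all__ = ["read_sumstats", "read_vcf", "read_pheno", "read_bed", "read_gmt",
           "FormatError"]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


def _require_nonempty(path) -> None:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise FormatError(f"{path}: file is empty")


#: default column map for summary statistics; override for other dialects
SUMSTATS_MAP = {"SNP": "SNP", "CHR": "CHR", "BP": "BP",
                "A1": "A1", "A2": "A2", "BETA": "BETA", "P": "P"}


def read_sumstats(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read base GWAS summary statistics (tab-separated, with header)."""
    _require_nonempty(path)
    cmap = dict(SUMSTATS_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype={cmap["CHR"]: str})
    missing = [v for v in cmap.values() if v not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    df = df.rename(columns={v: k for k, v in cmap.items()})
    bad = df.index[~df["P"].between(0, 1) | df["P"].isna() | df["BETA"].isna()]
    if len(bad):
        # +2: header line plus 1-based numbering
        lines = [int(i) + 2 for i in bad[:5]]
        raise FormatError(f"{path}: invalid BETA/P on line(s) {lines}")
    if (df["P"] <= 0).any():
        df["P"] = df["P"].clip(lower=1e-300)
    df["A1"] = df["A1"].str.upper()
    df["A2"] = df["A2"].str.upper()
    return df


def read_vcf(path) -> GenotypeData:
    """Read genotypes from VCF; DS field preferred, GT fallback."""
    _require_nonempty(path)
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF contains no samples")
    rows, dosage_rows = [], []
    has_ds = None
    for var in vcf:
        if has_ds is None:
            try:
                var.format("DS")
                has_ds = var.format("DS") is not None
            except KeyError:
                has_ds = False
        if has_ds:
            ds = var.format("DS")
            d = np.asarray(ds, dtype=np.float32).reshape(-1)
        else:
            # gts012: 0/1/2 = ALT count, 3 = missing
            g = np.asarray(var.gt_types, dtype=np.float32)
            d = np.where(g == 3, np.nan, g)
        dosage_rows.append(d)
        rows.append(
            {
                "SNP": var.ID if var.ID else f"{var.CHROM}:{var.POS}",
                "CHR": str(var.CHROM),
                "BP": int(var.POS),
                "REF": var.REF.upper(),
                "ALT": var.ALT[0].upper() if var.ALT else ".",
            }
        )
    if not rows:
        raise FormatError(f"{path}: VCF contains no variant records")
    dosages = np.vstack(dosage_rows).T  # individuals x variants
    return GenotypeData(dosages=dosages, variants=pd.DataFrame(rows), samples=samples)


def read_pheno(path) -> pd.DataFrame:
    """Read the phenotype/covariate table (IID, STATUS, SEX, BMI, AGE...)."""
    _require_nonempty(path)
    df = pd.read_csv(path, sep="\t")
    required = {"IID", "STATUS"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    if df["IID"].duplicated().any():
        dups = df["IID"][df["IID"].duplicated()].unique()[:5]
        raise FormatError(f"{path}: duplicate individual IDs {list(dups)}")
    if not df["STATUS"].isin([0, 1]).all():
        bad = [int(i) + 2 for i in df.index[~df["STATUS"].isin([0, 1])][:5]]
        raise FormatError(f"{path}: STATUS not in {{0,1}} on line(s) {bad}")
    df["IID"] = df["IID"].astype(str)
    return df


def read_bed(path) -> pd.DataFrame:
    """Read BED3+name gene intervals (0-based half-open)."""
    _require_nonempty(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 BED columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start or start < 0:
                raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            rows.append({"CHR": parts[0], "START": start, "END": end, "GENE": parts[3]})
    if not rows:
        raise FormatError(f"{path}: no gene intervals found")
    return pd.DataFrame(rows)


def read_gmt(path) -> dict[str, list[str]]:
    """Read GMT gene sets: name, description, then member genes."""
    _require_nonempty(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description "
                                  f"and at least one gene")
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            genes = [g for g in parts[2:] if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets[name] = genes
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return sets
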