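"""Readers and writers for the plain-text formats used across the pipeline.

Expression matrices are genes x samples TSV; gene sets travel as GMT;
clonotypes as AIRR-style rearrangement TSV; mutations as a MAF-like TSV;
sample metadata, neoantigen candidates and survival tables as plain TSV.
All round-trip losslessly at the printed precision.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

AIRR_COLUMNS = ["sample_id", "cdr3_aa", "v_call", "j_call", "duplicate_count"]
SHEET_COLUMNS = ["sample", "patient", "region", "timepoint", "tissue", "purity"]


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples abundance TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError("duplicate gene identifiers in expression matrix")
    if df.columns.has_duplicates:
        raise ValueError("duplicate sample identifiers in expression matrix")
    if (df.to_numpy() < 0).any():
        raise ValueError("abundances must be non-negative")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file into ``{set name: member genes}``."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        name, _desc, *genes = parts
        genes = [g for g in genes if g]
        if not genes:
            raise ValueError(f"empty gene set {name!r}")
        sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    missing = set(SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["sample"].duplicated().any():
        raise ValueError("duplicate samples in sheet")
    bad = ~sheet["timepoint"].isin(["pre", "post", "untreated"])
    if bad.any():
        raise ValueError(f"unknown timepoints: {sorted(sheet.loc[bad, 'timepoint'].unique())}")
    tumor = sheet["tissue"] == "tumor"
    if sheet.loc[tumor, "purity"].isna().any():
        raise ValueError("tumor samples must carry a purity value")
    return sheet.set_index("sample")


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.reset_index().to_csv(path, sep="\t", index=False)


def read_clonotypes(path) -> pd.DataFrame:
    """Read an AIRR-style rearrangement TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = set(AIRR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"rearrangement table missing columns: {sorted(missing)}")
    if (df["duplicate_count"] < 1).any():
        raise ValueError("clonotype counts must be >= 1")
    return df


def write_clonotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=AIRR_COLUMNS)


def read_mutations(path) -> pd.DataFrame:
    """Read a MAF-like mutation TSV (patient, sample, gene, mutation_id)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"patient", "sample", "gene", "mutation_id"} - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    return df


def write_mutations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_neoantigens(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"patient", "mutation_id", "peptide", "hla_allele", "percent_rank"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"neoantigen table missing columns: {sorted(missing)}")
    return df


def write_neoantigens(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"subject", "time", "event", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    return df


def write_survival(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
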