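"""Readers and writers for the flat-text formats the pipeline exchanges.

All tables are tab-delimited. Coordinates are 1-based and inclusive, the
convention used throughout the package (documented in the README). Matrices
(beta values, detection p-values, control-probe intensities) are stored with
probes as rows and a header row of sample ids.
"""

from __future__ import annotations

import pandas as pd

MANIFEST_COLUMNS = ["probe_id", "chrom", "pos", "is_sex_chrom", "is_masked"]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def read_manifest(path) -> pd.DataFrame:
    """Read a CpG manifest (probe_id, chrom, pos, is_sex_chrom, is_masked)."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    df["is_sex_chrom"] = df["is_sex_chrom"].astype(bool)
    df["is_masked"] = df["is_masked"].astype(bool)
    if df["probe_id"].duplicated().any():
        raise ValueError("manifest probe_ids are not unique")
    return df[MANIFEST_COLUMNS]


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)


def read_genes(path) -> pd.DataFrame:
    """Read gene models (gene_id, chrom, start, end, strand; 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    if (df["start"] > df["end"]).any():
        raise ValueError("gene start must be <= end")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    return df[GENE_COLUMNS]


def write_genes(genes: pd.DataFrame, path) -> None:
    genes[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def gene_tss(genes: pd.DataFrame) -> pd.Series:
    """Transcription start site: start on '+' strand, end on '-' strand."""
    return genes["start"].where(genes["strand"] == "+", genes["end"])


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT file into an ordered name -> gene-id-set mapping."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line: {line!r}")
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate pathway name in GMT: {name}")
            sets[name] = {g for g in fields[2:] if g}
    return sets


def write_gmt(pathway_db: dict[str, set[str]], path, descriptions=None) -> None:
    with open(path, "w") as fh:
        for name, genes in pathway_db.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_matrix(path) -> pd.DataFrame:
    """Read a probe x sample matrix with probe ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path, float_format="%.6g") -> None:
    matrix.to_csv(path, sep="\t", float_format=float_format)


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def write_covariates(covariates: pd.DataFrame, path) -> None:
    covariates.to_csv(path, sep="\t", index=False, float_format="%.6g")
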