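"""TSV readers and writers for the pipeline's data contracts.

Empty cells denote absent measurements (NaN), never zeros.  Set-valued
columns (GO terms, Pfam domains, localization terms) are ``;``-separated.
"""

from __future__ import annotations

import pandas as pd

from .classify import AnnotationCatalog, FLAG_COLUMNS
from .interactome import ProteinQuantTable, WholeProteomeTable
from .localization import LocalizationDB, aggregate_entries

__all__ = [
    "read_quant_tsv",
    "write_quant_tsv",
    "read_whole_proteome_tsv",
    "write_whole_proteome_tsv",
    "read_catalog_tsv",
    "write_catalog_tsv",
    "read_vocabulary_tsv",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_localization_tsv",
    "write_localization_tsv",
    "read_gene_list",
    "write_gene_list",
]


def read_quant_tsv(path, method: str) -> ProteinQuantTable:
    df = pd.read_csv(path, sep="\t")
    if "method" in df.columns:
        df = df[df["method"] == method].drop(columns="method").reset_index(drop=True)
    return ProteinQuantTable(method=method, data=df)


def write_quant_tsv(table: ProteinQuantTable, path) -> None:
    out = table.data.copy()
    out.insert(1, "method", table.method)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_whole_proteome_tsv(path) -> WholeProteomeTable:
    return WholeProteomeTable(pd.read_csv(path, sep="\t"))


def write_whole_proteome_tsv(table: WholeProteomeTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _split_terms(value) -> set[str]:
    if pd.isna(value) or value == "":
        return set()
    return {t for t in str(value).split(";") if t}


def read_catalog_tsv(path) -> AnnotationCatalog:
    """Read a full catalog TSV with precomputed boolean flag columns."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    df["go_terms"] = df["go_terms"].map(_split_terms)
    df["pfam_domains"] = df["pfam_domains"].map(_split_terms)
    for col in FLAG_COLUMNS:
        df[col] = df[col].astype(bool)
    return AnnotationCatalog(df)


def write_catalog_tsv(catalog: AnnotationCatalog, path) -> None:
    out = catalog.data.copy()
    out["go_terms"] = out["go_terms"].map(lambda s: ";".join(sorted(s)))
    out["pfam_domains"] = out["pfam_domains"].map(lambda s: ";".join(sorted(s)))
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_vocabulary_tsv(path, column: str = None) -> set[str]:
    """Read a one-column vocabulary TSV (RBD domains, GO term lists)."""
    df = pd.read_csv(path, sep="\t")
    col = column or df.columns[0]
    return set(df[col].astype(str))


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_localization_tsv(path) -> LocalizationDB:
    df = pd.read_csv(path, sep="\t")
    return aggregate_entries(df)


def write_localization_tsv(db: LocalizationDB, path) -> None:
    db.to_frame().to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")
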