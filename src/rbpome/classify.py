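"""RBP classification and annotation-term enrichment.

Called proteins are sorted into a three-way cascade — *known* RBPs (carry an
RNA-binding domain from a curated Pfam-based catalog, or the RNA-binding GO
molecular function), *inferred* RBPs (no direct annotation, but a mammalian
mRNA-interactome/census ortholog or an RNA-related GO term), and *new* RBPs
(no prior RNA-binding evidence at all).  GO-term and Pfam-domain enrichment
of a foreground gene set against an expressed-gene background uses one-sided
Fisher exact tests with Benjamini-Hochberg (GO) or Bonferroni (domains)
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationCatalog",
    "classify_rbp",
    "classify_all",
    "domain_enrichment",
    "go_enrichment",
    "fisher_enrichment_p",
]

CLASS_LABELS = ("known", "inferred", "new")

FLAG_COLUMNS = [
    "go_rna_binding",
    "go_rna_related",
    "has_rbd",
    "ortholog_interactome",
    "census_member",
    "is_tf",
    "is_ribosomal",
]


@dataclass
class AnnotationCatalog:
    """Per-gene annotations driving classification and enrichment.

    ``data`` is indexed by gene_id with columns ``go_terms`` and
    ``pfam_domains`` (Python sets) plus the boolean flag columns
    ``go_rna_binding, go_rna_related, has_rbd, ortholog_interactome,
    census_member, is_tf, is_ribosomal``.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in FLAG_COLUMNS + ["go_terms", "pfam_domains"] if c not in self.data.columns]
        if missing:
            raise ValueError(f"catalog missing columns: {missing}")
        bad = self.data.index[self.data["has_rbd"] & (self.data["pfam_domains"].map(len) == 0)]
        if len(bad):
            raise ValueError(f"has_rbd set but no Pfam domains for: {list(bad[:5])}")

    @classmethod
    def from_annotations(
        cls,
        table: pd.DataFrame,
        rbd_domains: set[str],
        rna_binding_go: set[str],
        rna_related_go: set[str],
    ) -> "AnnotationCatalog":
        """Derive flags from raw annotation sets and controlled vocabularies.

        ``table`` is indexed by gene_id with set-valued ``go_terms`` and
        ``pfam_domains`` columns; flags absent from the table are computed
        from the vocabularies (RBD domain list, RNA-binding GO list,
        RNA-related GO list) and defaulted to False otherwise.
        """
        df = table.copy()
        df["has_rbd"] = df["pfam_domains"].map(lambda s: bool(s & rbd_domains))
        df["go_rna_binding"] = df["go_terms"].map(lambda s: bool(s & rna_binding_go))
        df["go_rna_related"] = df["go_terms"].map(lambda s: bool(s & rna_related_go))
        for col in ("ortholog_interactome", "census_member", "is_tf", "is_ribosomal"):
            if col not in df.columns:
                df[col] = False
        return cls(df)

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.data.index


def classify_rbp(gene_id: str, catalog: AnnotationCatalog) -> str:
    """Classify one gene through the known / inferred / new cascade."""
    if gene_id not in catalog:
        raise KeyError(f"gene {gene_id!r} not in annotation catalog")
    row = catalog.data.loc[gene_id]
    if row["has_rbd"] or row["go_rna_binding"]:
        return "known"
    if row["ortholog_interactome"] or row["census_member"] or row["go_rna_related"]:
        return "inferred"
    return "new"


def classify_all(gene_ids, catalog: AnnotationCatalog) -> pd.Series:
    """Classify every gene; returns a Series gene_id -> label."""
    df = catalog.data
    missing = [g for g in gene_ids if g not in df.index]
    if missing:
        raise KeyError(f"genes not in catalog: {missing[:5]}")
    sub = df.loc[list(gene_ids)]
    known = sub["has_rbd"] | sub["go_rna_binding"]
    inferred = ~known & (sub["ortholog_interactome"] | sub["census_member"] | sub["go_rna_related"])
    labels = np.where(known, "known", np.where(inferred, "inferred", "new"))
    return pd.Series(labels, index=sub.index, name="class_label")


def fisher_enrichment_p(a: int, b: int, c: int, d: int, two_sided: bool = False) -> float:
    """Fisher exact P for a 2x2 table, enrichment-sided by default.

    Table layout: (a) foreground with the term, (b) foreground without,
    (c) background-only with, (d) background-only without.
    """
    alternative = "two-sided" if two_sided else "greater"
    return float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


def _term_enrichment(
    foreground: set[str],
    background: set[str],
    memberships: pd.Series,
    correction: str,
    two_sided: bool,
) -> pd.DataFrame:
    """Shared 2x2 machinery for GO-term and Pfam-domain enrichment.

    ``memberships`` maps gene_id -> set of terms.  Terms with zero
    background count are never tested (undefined contingency).
    """
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        raise ValueError("foreground must be a subset of background")
    bg_only = bg - fg

    fg_counts: dict[str, int] = {}
    bg_counts: dict[str, int] = {}
    for gene in bg:
        terms = memberships.get(gene, set())
        for t in terms:
            bg_counts[t] = bg_counts.get(t, 0) + 1
            if gene in fg:
                fg_counts[t] = fg_counts.get(t, 0) + 1

    n_fg, n_bg = len(fg), len(bg)
    rows = []
    for term in sorted(bg_counts):
        k_bg = bg_counts[term]
        a = fg_counts.get(term, 0)
        b = n_fg - a
        c = k_bg - a  # background-only carriers
        d = (n_bg - n_fg) - c
        p = fisher_enrichment_p(a, b, c, d, two_sided=two_sided)
        fold = (a / n_fg) / (k_bg / n_bg) if n_fg else np.nan
        recovery = a / k_bg
        rows.append((term, a, b, c, d, fold, recovery, p))

    df = pd.DataFrame(
        rows,
        columns=["term_or_domain", "a", "b", "c", "d", "fold", "recovery_pct", "p"],
    )
    if len(df):
        df["p_adj"] = multipletests(df["p"].to_numpy(), method=correction)[1]
    else:
        df["p_adj"] = pd.Series(dtype=float)
    return df.sort_values("p", kind="stable").reset_index(drop=True)


def domain_enrichment(
    foreground: set[str],
    background: set[str],
    catalog: AnnotationCatalog,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Pfam-domain enrichment, Fisher exact + Bonferroni across domains."""
    return _term_enrichment(
        foreground, background, catalog.data["pfam_domains"], "bonferroni", two_sided
    )


def go_enrichment(
    foreground: set[str],
    background: set[str],
    catalog: AnnotationCatalog,
    two_sided: bool = False,
) -> pd.DataFrame:
    """GO-term enrichment, Fisher exact + Benjamini-Hochberg across terms.

    Adds a ``neg_log10_p_adj`` column matching the usual heat-map scale.
    """
    df = _term_enrichment(
        foreground, background, catalog.data["go_terms"], "fdr_bh", two_sided
    )
    with np.errstate(divide="ignore"):
        df["neg_log10_p_adj"] = -np.log10(df["p_adj"])
    return df
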