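"""Resampling-based enrichment of embryonic transcript-localization terms.

A localization database (Fly-FISH-like) annotates each gene, per embryonic
stage window (stages 1-3, before cellularization; stages 4-5, syncytial and
cellular blastoderm), with a set of controlled localization terms, one of
which — "ubiquitous" — marks unlocalized transcripts.  Over-representation
of a term in a gene subset is measured as observed/expected fold change
against the whole database and an empirical P from random same-size subsets
drawn without replacement; odds ratios compare two subsets directly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "STAGE_WINDOWS",
    "UBIQUITOUS",
    "LocalizationDB",
    "aggregate_entries",
    "term_enrichment",
    "restricted_fraction",
    "subset_odds_ratio",
]

STAGE_WINDOWS = ("stages_1-3", "stages_4-5")
UBIQUITOUS = "ubiquitous"


@dataclass
class LocalizationDB:
    """gene -> stage window -> set of localization terms.

    Backed by a nested dict; every gene has at least one annotated window.
    """

    entries: dict[str, dict[str, frozenset[str]]] = field(repr=False)

    def __post_init__(self) -> None:
        for gene, windows in self.entries.items():
            if not windows:
                raise ValueError(f"gene {gene!r} has no annotated window")
            for w in windows:
                if w not in STAGE_WINDOWS:
                    raise ValueError(f"unknown stage window {w!r} for gene {gene!r}")

    @property
    def genes(self) -> list[str]:
        return sorted(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries

    def terms(self, gene: str, window: str) -> frozenset[str]:
        return self.entries.get(gene, {}).get(window, frozenset())

    def carriers(self, term: str, window: str) -> set[str]:
        return {g for g, w in self.entries.items() if term in w.get(window, frozenset())}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, w, ";".join(sorted(terms)))
            for g in self.genes
            for w, terms in sorted(self.entries[g].items())
        ]
        return pd.DataFrame(rows, columns=["gene_id", "stage_window", "terms"])


def aggregate_entries(records: pd.DataFrame) -> LocalizationDB:
    """Aggregate raw (gene_id, stage_window, terms) records into a DB.

    Genes with multiple records for the same window get the union of their
    term sets; aggregation is idempotent.  ``terms`` may be a set or a
    ``;``-separated string.
    """
    entries: dict[str, dict[str, set[str]]] = {}
    for _, row in records.iterrows():
        window = row["stage_window"]
        if window not in STAGE_WINDOWS:
            raise ValueError(f"unknown stage window label {window!r}")
        terms = row["terms"]
        if isinstance(terms, str):
            terms = {t for t in terms.split(";") if t}
        entries.setdefault(row["gene_id"], {}).setdefault(window, set()).update(terms)
    frozen = {
        g: {w: frozenset(t) for w, t in windows.items()} for g, windows in entries.items()
    }
    return LocalizationDB(frozen)


def _carrier_matrix(db: LocalizationDB) -> tuple[list[str], list[tuple[str, str]], np.ndarray]:
    """Bool matrix genes x (window, term) over terms present in the DB."""
    genes = db.genes
    keys: list[tuple[str, str]] = sorted(
        {
            (w, t)
            for g in genes
            for w, terms in db.entries[g].items()
            for t in terms
        }
    )
    idx = {k: j for j, k in enumerate(keys)}
    mat = np.zeros((len(genes), len(keys)), dtype=bool)
    for i, g in enumerate(genes):
        for w, terms in db.entries[g].items():
            for t in terms:
                mat[i, idx[(w, t)]] = True
    return genes, keys, mat


def _resolve_subset(subset, db: LocalizationDB) -> list[str]:
    subset = set(subset)
    present = sorted(subset & set(db.entries))
    dropped = len(subset) - len(present)
    if dropped:
        logger.info("%d subset genes absent from localization DB; dropped", dropped)
    return present


def term_enrichment(
    subset,
    db: LocalizationDB,
    n_samples: int = 1000,
    seed=None,
) -> pd.DataFrame:
    """Fold change and empirical P for every (term, window) in the DB.

    observed: subset genes carrying the term in the window;
    expected: |subset| x database carrier frequency;
    p_emp: add-one-corrected fraction of ``n_samples`` random subsets
    (drawn uniformly without replacement from the DB at the same size)
    whose carrier count reaches the observed count.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not set(subset) <= set(db.entries):
        stray = sorted(set(subset) - set(db.entries))
        if len(stray) == len(set(subset)):
            raise ValueError("subset shares no genes with the localization DB")
        logger.info("%d subset genes absent from DB; dropped: %s...", len(stray), stray[:3])
    genes, keys, mat = _carrier_matrix(db)
    gene_pos = {g: i for i, g in enumerate(genes)}
    sub_idx = [gene_pos[g] for g in sorted(set(subset) & set(db.entries))]
    k = len(sub_idx)
    n = len(genes)
    if k == 0:
        raise ValueError("empty subset after intersecting with DB")

    observed = mat[sub_idx].sum(axis=0)
    db_counts = mat.sum(axis=0)
    expected = k * db_counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(expected > 0, observed / expected, np.nan)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(keys), dtype=np.int64)
    for _ in range(n_samples):
        draw = rng.choice(n, size=k, replace=False)
        exceed += mat[draw].sum(axis=0) >= observed
    p_emp = (exceed + 1) / (n_samples + 1)

    return pd.DataFrame(
        {
            "term": [t for _, t in keys],
            "window": [w for w, _ in keys],
            "observed": observed,
            "expected": expected,
            "fold": fold,
            "p_emp": p_emp,
            "n_samples": n_samples,
        }
    )


def restricted_fraction(subset, db: LocalizationDB, window: str) -> tuple[int, float]:
    """Count and fraction of subset genes spatially restricted in a window.

    A gene counts as restricted when it carries at least one term other
    than "ubiquitous" in that window; the fraction is over subset genes
    present in the DB.
    """
    if window not in STAGE_WINDOWS:
        raise ValueError(f"unknown stage window {window!r}")
    present = _resolve_subset(subset, db)
    count = sum(1 for g in present if db.terms(g, window) - {UBIQUITOUS})
    frac = count / len(present) if present else 0.0
    return count, frac


def subset_odds_ratio(
    subset_a, subset_b, term: str, window: str, db: LocalizationDB
) -> float:
    """Sample odds ratio of term carriage in subset A vs subset B.

    2x2 cells: (carriers in A, non-carriers in A, carriers in B,
    non-carriers in B); Haldane-Anscombe +0.5 applied to every cell when
    any cell is zero, so the ratio is always finite.
    """
    a_genes = _resolve_subset(subset_a, db)
    b_genes = _resolve_subset(subset_b, db)
    carriers = db.carriers(term, window)
    ca = sum(1 for g in a_genes if g in carriers)
    cb = sum(1 for g in b_genes if g in carriers)
    na, nb = len(a_genes) - ca, len(b_genes) - cb
    cells = [ca, na, cb, nb]
    if set(subset_a) == set(subset_b):
        return 1.0
    if 0 in cells:
        cells = [x + 0.5 for x in cells]
    ca, na, cb, nb = cells
    return (ca * nb) / (na * cb) if na * cb else math.inf
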