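"""Enrichment calling from oligo(dT)-capture proteomics.

UV-crosslinked (CL) embryo lysates pulled down with oligo(dT) beads retain
proteins covalently bound to poly(A)+ RNA; the matched non-crosslinked (noCL)
pull-down measures background sticking.  A protein is called RNA-bound in one
crosslinking method when it is confidently identified (enough unique peptides)
and its CL intensity dominates its noCL intensity.  Calls from the two
crosslinking methods (254-nm conventional CL and 4SU/365-nm PAR-CL) are then
intersected into the high-confidence mRNA-bound proteome ("mRBPome") and
proteins are graded by their pull-down vs whole-embryo iBAQ abundance ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProteinQuantTable",
    "WholeProteomeTable",
    "RbpCallResult",
    "EnrichmentClass",
    "call_enriched",
    "combine_methods",
    "enrichment_class",
    "classify_enrichment_all",
]

METHODS = ("cCL", "PAR-CL")

QUANT_COLUMNS = [
    "protein_id",
    "intensity_cl",
    "intensity_noncl",
    "unique_peptides_cl",
    "ibaq_pulldown",
]


@dataclass
class ProteinQuantTable:
    """Per-protein MS quantification for one crosslinking method.

    ``data`` holds one row per protein with columns ``protein_id``,
    ``intensity_cl``, ``intensity_noncl``, ``unique_peptides_cl`` and
    ``ibaq_pulldown``.  Missing measurements are NaN: an undetected protein
    has no intensity, never a zero (MS detection semantics).
    """

    method: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        missing = [c for c in QUANT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"quant table missing columns: {missing}")
        if self.data["protein_id"].duplicated().any():
            dup = self.data.loc[self.data["protein_id"].duplicated(), "protein_id"]
            raise ValueError(f"duplicate protein_id in {self.method} table: {list(dup[:5])}")
        for col in ("intensity_cl", "intensity_noncl", "ibaq_pulldown"):
            vals = self.data[col].to_numpy(dtype=float)
            if np.any(vals[~np.isnan(vals)] < 0):
                raise ValueError(f"negative values in {col}")

    @property
    def protein_ids(self) -> pd.Index:
        return pd.Index(self.data["protein_id"])


@dataclass
class WholeProteomeTable:
    """Whole-embryo reference proteome: ``protein_id`` -> ``ibaq_whole``."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        for col in ("protein_id", "ibaq_whole"):
            if col not in self.data.columns:
                raise ValueError(f"whole-proteome table missing column {col!r}")
        if self.data["protein_id"].duplicated().any():
            raise ValueError("duplicate protein_id in whole-proteome table")

    def ibaq(self, protein_id: str) -> float:
        row = self.data.loc[self.data["protein_id"] == protein_id, "ibaq_whole"]
        if row.empty:
            return math.nan
        return float(row.iloc[0])


@dataclass
class RbpCallResult:
    """Per-method enriched sets combined by set logic.

    ``mrbpome`` is the intersection (called by both methods), ``union_set``
    the union, ``unique_set`` the symmetric difference.
    """

    per_method_sets: dict[str, frozenset[str]]
    mrbpome: frozenset[str]
    union_set: frozenset[str]
    unique_set: frozenset[str]


@dataclass
class EnrichmentClass:
    protein_id: str
    mean_ibaq_ratio: float  # NaN when undetermined
    class_label: str  # high | middle | low | undetermined


def call_enriched(
    table: ProteinQuantTable,
    fold_threshold: float = 10.0,
    min_peptides: int = 2,
    pseudocount: float | None = None,
) -> set[str]:
    """Call proteins enriched in the crosslinked pull-down.

    A protein passes when it has at least ``min_peptides`` unique peptides in
    the CL sample and either (a) its CL/noCL intensity ratio is strictly
    greater than ``fold_threshold``, or (b) it was detected in CL while
    absent (or zero) in noCL — absence from the non-crosslinked control is
    treated as the strongest enrichment evidence.

    ``pseudocount``, if given, switches convention (b) off: the ratio is
    computed as ``intensity_cl / (intensity_noncl + pseudocount)`` with
    missing noCL treated as zero, so every CL-detected protein gets a finite
    ratio.
    """
    if fold_threshold <= 0:
        raise ValueError("fold_threshold must be positive")
    if min_peptides < 0:
        raise ValueError("min_peptides must be non-negative")

    df = table.data
    cl = df["intensity_cl"].to_numpy(dtype=float)
    noncl = df["intensity_noncl"].to_numpy(dtype=float)
    pep = df["unique_peptides_cl"].fillna(0).to_numpy(dtype=float)

    detected_cl = ~np.isnan(cl) & (cl > 0)
    enough_pep = pep >= min_peptides

    if pseudocount is not None:
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        ratio = cl / (np.nan_to_num(noncl, nan=0.0) + pseudocount)
        passes_ratio = detected_cl & (ratio > fold_threshold)
    else:
        absent_noncl = np.isnan(noncl) | (noncl == 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = cl / noncl
        passes_ratio = detected_cl & (absent_noncl | (ratio > fold_threshold))

    mask = enough_pep & passes_ratio
    return set(df.loc[mask, "protein_id"])


def combine_methods(set_a: set[str], set_b: set[str]) -> RbpCallResult:
    """Combine two per-method call sets into mRBPome / union / unique sets."""
    a, b = frozenset(set_a), frozenset(set_b)
    inter = a & b
    union = a | b
    result = RbpCallResult(
        per_method_sets={"cCL": a, "PAR-CL": b},
        mrbpome=inter,
        union_set=union,
        unique_set=union - inter,
    )
    # inclusion-exclusion sanity
    assert len(result.union_set) == len(a) + len(b) - len(inter)
    assert not (result.unique_set & result.mrbpome)
    return result


def _ibaq_ratio(table: ProteinQuantTable, whole: WholeProteomeTable, protein_id: str) -> float:
    row = table.data.loc[table.data["protein_id"] == protein_id]
    if row.empty:
        return math.nan
    num = float(row["ibaq_pulldown"].iloc[0])
    den = whole.ibaq(protein_id)
    if math.isnan(num) or math.isnan(den) or den == 0:
        return math.nan
    return num / den


def _label(ratio: float) -> str:
    if math.isnan(ratio):
        return "undetermined"
    if ratio > 10:
        return "high"
    if ratio >= 1:
        return "middle"
    return "low"


def enrichment_class(
    protein_id: str,
    tables: list[ProteinQuantTable] | tuple[ProteinQuantTable, ...],
    whole: WholeProteomeTable,
    mean: str = "arithmetic",
) -> EnrichmentClass:
    """Grade a protein by its mean pull-down/whole iBAQ abundance ratio.

    The per-method ratio ibaq_pulldown/ibaq_whole is computed for each
    crosslinking method where both values exist and averaged (arithmetic by
    default, geometric optional).  Classes: high (>10-fold), middle (1 to
    10-fold, closed interval), low (<1-fold); a protein never detected in the
    whole-embryo proteome is "undetermined".
    """
    if mean not in ("arithmetic", "geometric"):
        raise ValueError("mean must be 'arithmetic' or 'geometric'")
    present = any(
        protein_id in set(t.data["protein_id"]) for t in tables
    )
    if not present:
        raise KeyError(f"protein {protein_id!r} absent from every pull-down table")
    ratios = [_ibaq_ratio(t, whole, protein_id) for t in tables]
    ratios = [r for r in ratios if not math.isnan(r)]
    if not ratios:
        mean_ratio = math.nan
    elif mean == "arithmetic":
        mean_ratio = float(np.mean(ratios))
    else:
        mean_ratio = float(np.exp(np.mean(np.log(ratios))))
    return EnrichmentClass(protein_id, mean_ratio, _label(mean_ratio))


def classify_enrichment_all(
    protein_ids,
    tables,
    whole: WholeProteomeTable,
    mean: str = "arithmetic",
) -> pd.DataFrame:
    """Vector wrapper over :func:`enrichment_class`; one row per protein."""
    rows = []
    for pid in protein_ids:
        ec = enrichment_class(pid, tables, whole, mean=mean)
        rows.append((ec.protein_id, ec.mean_ibaq_ratio, ec.class_label))
    return pd.DataFrame(rows, columns=["protein_id", "mean_ibaq_ratio", "class_label"])
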