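"""Physicochemical sequence features: isoelectric point and composition.

RNA-binding proteomes skew basic (RNA is a polyanion) and are enriched for
arginine, lysine and glycine.  The pI here is the pH at which the
Henderson-Hasselbalch net charge over all ionizable side chains plus the two
termini crosses zero, solved by bisection; the pKa set is a configurable
table (EMBOSS values by default) since pI is only used comparatively.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "EMBOSS_PKA",
    "STANDARD_AA",
    "net_charge",
    "isoelectric_point",
    "aa_composition",
    "feature_table",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

# side-chain and terminal pKa values (EMBOSS defaults)
EMBOSS_PKA = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}

_BASIC = ("Nterm", "H", "K", "R")
_ACIDIC = ("Cterm", "C", "D", "E", "Y")


def _validate(seq: str) -> str:
    if not seq:
        raise ValueError("empty protein sequence")
    if not seq.isupper():
        raise ValueError("sequence must be uppercase one-letter codes")
    bad = set(seq) - STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residues in sequence: {sorted(bad)}")
    return seq


def net_charge(seq: str, ph: float, pka_table: dict[str, float] = EMBOSS_PKA) -> float:
    """Net charge of a sequence at a given pH.

    Positive groups contribute 1/(1+10^(pH-pKa)), negative groups
    -1/(1+10^(pKa-pH)); residue counts weight the side chains, the termini
    count once each.
    """
    _validate(seq)
    counts = {aa: seq.count(aa) for aa in set(seq)}
    charge = 0.0
    for group in _BASIC:
        n = 1 if group == "Nterm" else counts.get(group, 0)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - pka_table[group]))
    for group in _ACIDIC:
        n = 1 if group == "Cterm" else counts.get(group, 0)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka_table[group] - ph))
    return charge


def isoelectric_point(
    seq: str,
    pka_table: dict[str, float] = EMBOSS_PKA,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> float:
    """pH in [0, 14] at which the net charge crosses zero, by bisection.

    The charge is strictly decreasing in pH, positive at pH 0 (protonated
    N-terminus) and negative at pH 14 (deprotonated C-terminus), so a root
    always exists; iteration stops when |charge| < ``tol``.
    """
    _validate(seq)
    lo, hi = 0.0, 14.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        q = net_charge(seq, mid, pka_table)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def aa_composition(seq: str) -> pd.Series:
    """Per-residue fractions plus the combined R+K+G fraction.

    Returns a Series over the 20 standard residues (keys ``frac_<aa>``)
    and ``frac_RKG``; the 20 per-residue fractions sum to 1.
    """
    _validate(seq)
    n = len(seq)
    fracs = {f"frac_{aa}": seq.count(aa) / n for aa in sorted(STANDARD_AA)}
    fracs["frac_RKG"] = fracs["frac_R"] + fracs["frac_K"] + fracs["frac_G"]
    return pd.Series(fracs)


def feature_table(
    sequences: dict[str, str],
    pka_table: dict[str, float] = EMBOSS_PKA,
) -> pd.DataFrame:
    """pI and composition summary for a set of sequences.

    Output columns match the TSV contract: ``gene_id, pI, frac_R, frac_K,
    frac_G, frac_RKG``.
    """
    rows = []
    for gene_id, seq in sequences.items():
        comp = aa_composition(seq)
        rows.append(
            (
                gene_id,
                isoelectric_point(seq, pka_table),
                comp["frac_R"],
                comp["frac_K"],
                comp["frac_G"],
                comp["frac_RKG"],
            )
        )
    return pd.DataFrame(rows, columns=["gene_id", "pI", "frac_R", "frac_K", "frac_G", "frac_RKG"])
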