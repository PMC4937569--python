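"""Synthetic inputs with the statistical structure the analysis assumes.

Four generators emulate, respectively: (1) oligo(dT)-capture MS experiments
— log-normal intensities, true RBPs enriched in the crosslinked sample with
a shared-latent correlation between the two crosslinking methods,
contaminants at crosslink/no-crosslink parity, per-table detection dropout;
(2) annotation catalogs constructed so the classification cascade
reproduces requested class counts exactly; (3) developmental expression
matrices with planted cluster prototypes and single-stage spike genes; and
(4) localization databases with multinomial term assignment and an optional
planted enriched subset.  Every generator is deterministic given its
config: same config + seed means bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import AnnotationCatalog
from .interactome import ProteinQuantTable, WholeProteomeTable
from .localization import STAGE_WINDOWS, UBIQUITOUS, LocalizationDB

__all__ = [
    "MsSimConfig",
    "ExprSimConfig",
    "LocSimConfig",
    "MsExperiment",
    "generate_ms_experiment",
    "generate_annotations",
    "generate_dev_expression",
    "generate_localization_db",
]


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class MsSimConfig:
    """Parameters of the simulated oligo(dT)-capture MS experiment.

    Intensities are log-normal: ``log_intensity_mean``/``sd`` set the
    natural-log baseline (defaults give MS-typical 1e8-1e10 raw
    intensities).  True RBPs gain a log-scale crosslink enrichment drawn
    around ``rbp_log_ratio_mean`` (default ln 50, i.e. ~50-fold CL over
    noCL) shared between methods with correlation ``method_correlation``
    (default 0.77, the observed between-method agreement).  Contaminants
    and background proteins sit at CL~noCL parity.  ``detection_dropout``
    drops a protein from a given table; a dropped noCL measurement leaves
    an absent (NaN) record, never a zero.
    """

    n_proteins: int = 2000
    frac_true_rbp: float = 0.25
    frac_contaminant: float = 0.05
    log_intensity_mean: float = 21.0
    log_intensity_sd: float = 1.5
    rbp_log_ratio_mean: float = math.log(50.0)
    rbp_log_ratio_sd: float = 0.5
    detection_dropout: float = 0.05
    method_correlation: float = 0.77
    peptide_rate: float = 5.0
    measurement_noise_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        _check_fraction("frac_true_rbp", self.frac_true_rbp)
        _check_fraction("frac_contaminant", self.frac_contaminant)
        _check_fraction("detection_dropout", self.detection_dropout)
        _check_fraction("method_correlation", self.method_correlation)
        if self.frac_true_rbp + self.frac_contaminant > 1.0:
            raise ValueError("frac_true_rbp + frac_contaminant must not exceed 1")
        for name in ("log_intensity_sd", "rbp_log_ratio_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.peptide_rate < 1:
            raise ValueError("peptide_rate must be >= 1")


@dataclass
class MsExperiment:
    """Simulated experiment: two pull-down tables, whole-embryo iBAQ, truth."""

    tables: dict[str, ProteinQuantTable]
    whole: WholeProteomeTable
    truth: pd.DataFrame = field(repr=False)  # protein_id, label in {rbp, contaminant, background}


def generate_ms_experiment(config: MsSimConfig) -> MsExperiment:
    """Simulate cCL and PAR-CL pull-down tables plus the whole-embryo proteome."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    n_rbp = int(round(config.frac_true_rbp * n))
    n_cont = int(round(config.frac_contaminant * n))

    ids = np.array([f"P{i:05d}" for i in range(n)])
    labels = np.array(["background"] * n, dtype=object)
    order = rng.permutation(n)
    labels[order[:n_rbp]] = "rbp"
    labels[order[n_rbp : n_rbp + n_cont]] = "contaminant"
    is_rbp = labels == "rbp"

    baseline = rng.normal(config.log_intensity_mean, config.log_intensity_sd, size=n)

    # shared latent + method-specific component reproduces the between-method
    # enrichment correlation with a single parameter
    rho = config.method_correlation
    z_shared = rng.normal(size=n)
    tables: dict[str, ProteinQuantTable] = {}
    for method in ("cCL", "PAR-CL"):
        z_method = rng.normal(size=n)
        enrich = np.zeros(n)
        enrich[is_rbp] = config.rbp_log_ratio_mean + config.rbp_log_ratio_sd * (
            math.sqrt(rho) * z_shared[is_rbp] + math.sqrt(1.0 - rho) * z_method[is_rbp]
        )
        noise_cl = rng.normal(0.0, config.measurement_noise_sd, size=n)
        noise_noncl = rng.normal(0.0, config.measurement_noise_sd, size=n)
        intensity_cl = np.exp(baseline + enrich + noise_cl)
        intensity_noncl = np.exp(baseline + noise_noncl)
        peptides = 1 + rng.poisson(config.peptide_rate - 1.0, size=n)
        ibaq_noise = rng.normal(0.0, config.measurement_noise_sd, size=n)
        ibaq_pulldown = np.exp(baseline + enrich + ibaq_noise) / 50.0

        detected = rng.random(n) >= config.detection_dropout
        noncl_detected = detected & (rng.random(n) >= config.detection_dropout)
        df = pd.DataFrame(
            {
                "protein_id": ids,
                "intensity_cl": intensity_cl,
                "intensity_noncl": np.where(noncl_detected, intensity_noncl, np.nan),
                "unique_peptides_cl": peptides,
                "ibaq_pulldown": ibaq_pulldown,
            }
        )
        tables[method] = ProteinQuantTable(method=method, data=df.loc[detected].reset_index(drop=True))

    ibaq_whole = np.exp(baseline + rng.normal(0.0, config.measurement_noise_sd, size=n)) / 50.0
    whole_detected = rng.random(n) >= config.detection_dropout
    whole = WholeProteomeTable(
        pd.DataFrame({"protein_id": ids, "ibaq_whole": ibaq_whole}).loc[whole_detected].reset_index(drop=True)
    )
    truth = pd.DataFrame({"protein_id": ids, "label": labels})
    return MsExperiment(tables=tables, whole=whole, truth=truth)


# vocabularies for constructive annotation catalogs; RBD and RNA-binding GO
# lists mimic a curated census vocabulary, generic pools avoid collisions
_RBD_DOMAINS = ("RRM_1", "KH_1", "DEAD", "LSm", "zf-CCCH", "PAZ", "Piwi")
_GENERIC_DOMAINS = ("WD40", "Pkinase", "Ank_2", "EGF", "HEAT", "TPR_1")
_GO_RNA_BINDING = "GO:0003723"
_GO_RNA_RELATED = ("GO:0006396", "GO:0008380", "GO:0006417")
_GO_GENERIC = ("GO:0005515", "GO:0016301", "GO:0005524", "GO:0003677")


def generate_annotations(
    gene_ids,
    class_counts: tuple[int, int, int, int],
    rbd_within_known: int,
    go_within_rbd: int = 0,
    seed: int = 0,
) -> AnnotationCatalog:
    """Build a catalog in which the cascade reproduces requested class sizes.

    ``class_counts`` is (known, inferred_homolog, inferred_go, new) and must
    sum to ``len(gene_ids)``.  Of the known genes, ``rbd_within_known``
    carry an RNA-binding domain (``go_within_rbd`` of those also carry the
    RNA-binding GO term) and the remainder carry the RNA-binding GO term
    only.  Homolog-inferred genes get mammalian interactome/census ortholog
    flags, GO-inferred genes get RNA-related GO terms, new genes get only
    generic annotation.  Gene order is shuffled under ``seed``.
    """
    gene_ids = list(gene_ids)
    n_known, n_homolog, n_go, n_new = class_counts
    counts = (n_known, n_homolog, n_go, n_new)
    if any(c < 0 for c in counts):
        raise ValueError("class counts must be non-negative")
    if sum(counts) != len(gene_ids):
        raise ValueError(
            f"class counts sum to {sum(counts)} but {len(gene_ids)} genes given"
        )
    if not 0 <= rbd_within_known <= n_known:
        raise ValueError("rbd_within_known must be between 0 and the known count")
    if not 0 <= go_within_rbd <= rbd_within_known:
        raise ValueError("go_within_rbd must be between 0 and rbd_within_known")

    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(gene_ids)))
    shuffled = [gene_ids[i] for i in order]

    rows = {}
    pos = 0

    def take(k):
        nonlocal pos
        chunk = shuffled[pos : pos + k]
        pos += k
        return chunk

    def base_row():
        return {
            "go_terms": {str(rng.choice(_GO_GENERIC))},
            "pfam_domains": {str(rng.choice(_GENERIC_DOMAINS))},
            "go_rna_binding": False,
            "go_rna_related": False,
            "has_rbd": False,
            "ortholog_interactome": False,
            "census_member": False,
            "is_tf": False,
            "is_ribosomal": False,
        }

    known_genes = take(n_known)
    for i, g in enumerate(known_genes):
        row = base_row()
        if i < rbd_within_known:
            row["has_rbd"] = True
            row["pfam_domains"].add(str(rng.choice(_RBD_DOMAINS)))
            if i < go_within_rbd:
                row["go_rna_binding"] = True
                row["go_terms"].add(_GO_RNA_BINDING)
        else:
            row["go_rna_binding"] = True
            row["go_terms"].add(_GO_RNA_BINDING)
        rows[g] = row
    for g in take(n_homolog):
        row = base_row()
        # either interactome ortholog, census member, or both
        which = rng.integers(0, 3)
        row["ortholog_interactome"] = which in (0, 2)
        row["census_member"] = which in (1, 2)
        rows[g] = row
    for g in take(n_go):
        row = base_row()
        row["go_rna_related"] = True
        row["go_terms"].add(str(rng.choice(_GO_RNA_RELATED)))
        rows[g] = row
    for g in take(n_new):
        rows[g] = base_row()

    df = pd.DataFrame.from_dict(rows, orient="index").loc[gene_ids]
    df.index.name = "gene_id"
    return AnnotationCatalog(df)


@dataclass
class ExprSimConfig:
    """Parameters of the simulated developmental expression matrix.

    Default prototypes are six staggered temporal waves over twelve 2-h
    embryonic windows (0-24 h), peaking successively at amplitude 50 FPKM —
    condensed, timely resolved clusters.  ``frac_specific`` genes instead
    get a single-stage spike (one stage at ``spike_fpkm``, the rest 0) for
    specificity-score testing.
    """

    n_genes: int = 1200
    n_stages: int = 12
    n_clusters: int = 6
    prototype_profiles: list | None = None
    noise_sd: float = 5.0
    frac_specific: float = 0.0
    spike_fpkm: float = 200.0
    seed: int = 0

    def resolved_prototypes(self) -> np.ndarray:
        if self.prototype_profiles is not None:
            protos = np.asarray(self.prototype_profiles, dtype=float)
        else:
            stages = np.arange(self.n_stages)
            peaks = (np.arange(self.n_clusters) + 0.5) * self.n_stages / self.n_clusters
            width = self.n_stages / (1.5 * self.n_clusters)
            protos = 50.0 * np.exp(-0.5 * ((stages[None, :] - peaks[:, None]) / width) ** 2)
        if protos.shape != (self.n_clusters, self.n_stages):
            raise ValueError(
                f"prototypes must be {self.n_clusters} x {self.n_stages}, got {protos.shape}"
            )
        if np.any(protos < 0):
            raise ValueError("prototype FPKM profiles must be non-negative")
        return protos

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        _check_fraction("frac_specific", self.frac_specific)
        self.resolved_prototypes()


def generate_dev_expression(config: ExprSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a genes x stages FPKM matrix with known cluster structure.

    Returns the matrix and a truth table (gene_id, cluster, is_specific):
    spike genes carry cluster = -1.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    protos = config.resolved_prototypes()
    n = config.n_genes
    n_specific = int(round(config.frac_specific * n))

    clusters = rng.integers(0, config.n_clusters, size=n)
    specific = np.zeros(n, dtype=bool)
    specific[rng.permutation(n)[:n_specific]] = True
    clusters[specific] = -1

    fpkm = protos[np.where(specific, 0, clusters)].astype(float)
    fpkm += rng.normal(0.0, config.noise_sd, size=fpkm.shape) if config.noise_sd else 0.0
    fpkm = np.clip(fpkm, 0.0, None)
    spike_stage = rng.integers(0, config.n_stages, size=n)
    for i in np.flatnonzero(specific):
        fpkm[i] = 0.0
        fpkm[i, spike_stage[i]] = config.spike_fpkm

    gene_ids = [f"G{i:05d}" for i in range(n)]
    stages = [f"stage_{j:02d}" for j in range(config.n_stages)]
    matrix = pd.DataFrame(fpkm, index=pd.Index(gene_ids, name="gene_id"), columns=stages)
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "cluster": clusters, "is_specific": specific}
    )
    return matrix, truth


@dataclass
class LocSimConfig:
    """Parameters of the simulated localization database.

    Defaults mirror the scale of an embryonic in situ database: 4767
    annotated genes, a mostly-ubiquitous early window (stages 1-3) and a
    more restricted later window (stages 4-5).  A planted subset has its
    ``planted_term`` probability multiplied by ``planted_fold`` in both
    windows (other terms rescaled), giving constructive enrichment truth.
    """

    n_genes: int = 4767
    term_vocabulary: tuple = (
        UBIQUITOUS,
        "posterior",
        "anterior",
        "pole_plasm",
        "dorsal",
        "ventral",
        "apical",
    )
    term_probs: dict | None = None
    planted_subset_size: int = 0
    planted_term: str = "posterior"
    planted_fold: float = 1.0
    seed: int = 0

    def resolved_probs(self) -> dict[str, np.ndarray]:
        if self.term_probs is not None:
            probs = {w: np.asarray(p, dtype=float) for w, p in self.term_probs.items()}
        else:
            k = len(self.term_vocabulary) - 1
            probs = {
                STAGE_WINDOWS[0]: np.array([0.88] + [0.12 / k] * k),
                STAGE_WINDOWS[1]: np.array([0.58] + [0.42 / k] * k),
            }
        for w, p in probs.items():
            if w not in STAGE_WINDOWS:
                raise ValueError(f"unknown stage window {w!r}")
            if len(p) != len(self.term_vocabulary):
                raise ValueError("term_probs length must match vocabulary")
            if not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
                raise ValueError(f"term probabilities for {w!r} must sum to 1")
        return probs

    def validate(self) -> None:
        if UBIQUITOUS not in self.term_vocabulary:
            raise ValueError(f"vocabulary must include {UBIQUITOUS!r}")
        if self.planted_subset_size and self.planted_term not in self.term_vocabulary:
            raise ValueError("planted_term must be in the vocabulary")
        if self.planted_fold < 1.0:
            raise ValueError("planted_fold must be >= 1")
        if not 0 <= self.planted_subset_size <= self.n_genes:
            raise ValueError("planted_subset_size out of range")
        self.resolved_probs()


def _plant(probs: np.ndarray, term_idx: int, fold: float) -> np.ndarray:
    boosted = probs.copy()
    target = min(fold * probs[term_idx], 0.95)
    rest = 1.0 - target
    others = np.delete(np.arange(len(probs)), term_idx)
    boosted[others] = probs[others] * rest / probs[others].sum()
    boosted[term_idx] = target
    return boosted


def generate_localization_db(config: LocSimConfig) -> tuple[LocalizationDB, list[str]]:
    """Simulate a localization DB; returns the DB and the planted subset ids."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    probs = config.resolved_probs()
    vocab = list(config.term_vocabulary)
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    planted = set(rng.permutation(config.n_genes)[: config.planted_subset_size])

    entries: dict[str, dict[str, frozenset[str]]] = {}
    term_idx = vocab.index(config.planted_term) if config.planted_subset_size else 0
    for i, gene in enumerate(gene_ids):
        windows = {}
        for w in STAGE_WINDOWS:
            if w not in probs:
                continue
            p = probs[w]
            if i in planted and config.planted_fold > 1.0:
                p = _plant(p, term_idx, config.planted_fold)
            term = vocab[rng.choice(len(vocab), p=p)]
            windows[w] = frozenset({term})
        entries[gene] = windows
    db = LocalizationDB(entries)
    return db, [gene_ids[i] for i in sorted(planted)]
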