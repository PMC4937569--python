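"""Temporal expression dynamics: fuzzy clustering and stage specificity.

Developmental FPKM profiles are z-scored genewise on FPKM+1 (optionally
log2(FPKM+1)) and clustered with fuzzy c-means, whose soft memberships suit
the gradual maternal-to-zygotic handover better than hard k-means.  Cluster
over-representation of a protein set is tested in two Fisher steps —
proteome vs transcriptome first, then mRBPome vs proteome — so that the MS
detection bias toward highly expressed genes is absorbed by the first step.
The Developmental Stage Specificity Score (DSSS) measures how far a gene's
expression deviates from uniformity across N stages:

    DSSS = H_max - H_obs = log2(N) + sum_i p_i log2 p_i,   p_i = x_i / sum x,

with x_i = FPKM_i + 1; it is 0 for flat expression and approaches log2(N)
for a single-stage spike.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_random_state
from statsmodels.stats.multitest import multipletests

from .classify import fisher_enrichment_p

logger = logging.getLogger(__name__)

__all__ = [
    "zscore_profiles",
    "FuzzyCMeans",
    "fuzzy_cmeans",
    "hard_assign",
    "dsss_profile",
    "dsss_table",
    "DsssResult",
    "stage_specific_genes",
    "cluster_enrichment_two_step",
]


def zscore_profiles(
    matrix: pd.DataFrame, log2: bool = False, ddof: int = 1
) -> tuple[pd.DataFrame, pd.Index]:
    """Genewise z-score transform of FPKM+1 profiles.

    Each row of ``matrix`` (genes x stages, FPKM) is shifted by +1,
    optionally log2-transformed, then centred and scaled by its sample
    (n-1) standard deviation.  Zero-variance rows cannot be standardized;
    they are excluded from the output and returned separately.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two stages to z-score profiles")
    vals = matrix.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("negative FPKM values")
    x = vals + 1.0
    if log2:
        x = np.log2(x)
    sd = x.std(axis=1, ddof=ddof)
    keep = sd > 0
    excluded = matrix.index[~keep]
    if len(excluded):
        logger.info("excluding %d zero-variance profiles from clustering", len(excluded))
    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns), excluded


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy c-means clustering (Bezdek alternating optimization).

    Soft memberships u_ik in [0,1] with rows summing to 1 are updated as
    ``u_ik = 1 / sum_j (d_ik/d_jk)^(2/(m-1))`` (Euclidean distance d) and
    centers as the u^m-weighted means; iteration stops when the largest
    center displacement drops below ``tol``.  The objective
    ``J = sum_ik u_ik^m d_ik^2`` is non-increasing across iterations and is
    checked every run.  A point coinciding with several centers splits its
    membership equally among them.

    Parameters
    ----------
    n_clusters : number of clusters c (>= 2).
    m : fuzzifier (> 1); m -> 1 approaches hard k-means.  Default 1.23,
        a hardness suited to condensed temporal expression clusters.
    tol : convergence threshold on the max center displacement.
    max_iter : iteration cap per restart.
    n_init : random restarts; the solution with the lowest objective wins.
    random_state : seed; initial centers are distinct data rows.

    Attributes
    ----------
    cluster_centers_ : (n_clusters, n_features) center profiles.
    membership_ : (n_samples, n_clusters) membership matrix.
    labels_ : hard assignment (argmax membership, ties to lowest index).
    objective_ : final value of J.
    n_iter_ : iterations used by the winning restart.
    converged_ : whether the winning restart met ``tol``.
    """

    def __init__(
        self,
        n_clusters: int = 6,
        m: float = 1.23,
        tol: float = 1e-6,
        max_iter: int = 1000,
        n_init: int = 5,
        random_state=None,
    ):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.random_state = random_state

    def _memberships(self, d2: np.ndarray) -> np.ndarray:
        """Membership update from squared distances (n_samples, c)."""
        exp = 1.0 / (self.m - 1.0)
        zero = d2 <= 0.0
        any_zero = zero.any(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = d2 ** (-exp)
            u = t / t.sum(axis=1, keepdims=True)
        if any_zero.any():
            # coincident with >=1 center: split equally among the coincident ones
            u[any_zero] = 0.0
            z = zero[any_zero]
            u[any_zero] = z / z.sum(axis=1, keepdims=True)
        return u

    def _single_fit(self, X: np.ndarray, rng) -> tuple:
        n, _ = X.shape
        c = self.n_clusters
        # distinct data rows as initial centers
        uniq = np.unique(X, axis=0)
        if len(uniq) < c:
            raise ValueError(f"need >= {c} distinct rows, got {len(uniq)}")
        centers = uniq[rng.choice(len(uniq), size=c, replace=False)].copy()
        prev_obj = np.inf
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            d2 = cdist(X, centers, metric="sqeuclidean")
            u = self._memberships(d2)
            um = u**self.m
            obj = float((um * d2).sum())
            if obj > prev_obj * (1 + 1e-9) + 1e-12:
                raise AssertionError(
                    f"fuzzy c-means objective increased: {prev_obj} -> {obj}"
                )
            prev_obj = obj
            new_centers = (um.T @ X) / um.sum(axis=0)[:, None]
            shift = np.abs(new_centers - centers).max()
            centers = new_centers
            if shift < self.tol:
                converged = True
                break
        d2 = cdist(X, centers, metric="sqeuclidean")
        u = self._memberships(d2)
        obj = float((u**self.m * d2).sum())
        return centers, u, obj, n_iter, converged

    def fit(self, X, y=None):
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        X = check_array(X, dtype=float)
        rng = check_random_state(self.random_state)
        best = None
        for _ in range(self.n_init):
            result = self._single_fit(X, rng)
            if best is None or result[2] < best[2]:
                best = result
        centers, u, obj, n_iter, converged = best
        self.cluster_centers_ = centers
        self.membership_ = u
        self.labels_ = np.argmax(u, axis=1)
        self.objective_ = obj
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X, dtype=float)
        d2 = cdist(X, self.cluster_centers_, metric="sqeuclidean")
        return np.argmax(self._memberships(d2), axis=1)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def fuzzy_cmeans(
    matrix: pd.DataFrame,
    c: int = 6,
    m: float = 1.23,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed=None,
    n_init: int = 5,
) -> FuzzyCMeans:
    """Fit :class:`FuzzyCMeans` on a standardized genes x stages matrix."""
    est = FuzzyCMeans(
        n_clusters=c, m=m, tol=tol, max_iter=max_iter, n_init=n_init, random_state=seed
    )
    return est.fit(matrix.to_numpy(dtype=float))


def hard_assign(model: FuzzyCMeans, index: pd.Index | None = None) -> pd.Series:
    """Hard cluster assignment: argmax membership, ties to the lowest index."""
    check_is_fitted(model)
    labels = np.argmax(model.membership_, axis=1)
    return pd.Series(labels, index=index, name="cluster")


@dataclass
class DsssResult:
    gene_id: str
    N: int
    p_i: np.ndarray
    H_obs: float
    H_max: float
    dsss: float


def dsss_profile(fpkm, gene_id: str = "") -> DsssResult:
    """DSSS of one expression profile over N developmental stages."""
    x = np.asarray(fpkm, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("profile must be 1-D with at least two stages")
    if np.any(x < 0):
        raise ValueError("negative FPKM values")
    n = len(x)
    x = x + 1.0
    p = x / x.sum()
    h_obs = float(-(p * np.log2(p)).sum())
    h_max = math.log2(n)
    return DsssResult(gene_id, n, p, h_obs, h_max, h_max - h_obs)


def dsss_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Vectorized DSSS over a genes x stages FPKM matrix."""
    vals = matrix.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("negative FPKM values")
    n = vals.shape[1]
    if n < 2:
        raise ValueError("need at least two stages")
    x = vals + 1.0
    p = x / x.sum(axis=1, keepdims=True)
    h_obs = -(p * np.log2(p)).sum(axis=1)
    h_max = math.log2(n)
    return pd.DataFrame(
        {"N": n, "H_obs": h_obs, "H_max": h_max, "dsss": h_max - h_obs},
        index=matrix.index,
    )


def stage_specific_genes(
    dsss: pd.DataFrame, threshold: float = 1.0
) -> tuple[pd.Index, float]:
    """Genes scoring at or above the DSSS threshold, plus their fraction."""
    hits = dsss.index[dsss["dsss"] >= threshold]
    frac = len(hits) / len(dsss) if len(dsss) else 0.0
    return hits, frac


def _step_fisher(universe: set, cluster: set, marked: set) -> tuple:
    """2x2 of (in cluster) x (marked) over a universe; enrichment-sided."""
    a = len(cluster & marked)
    b = len(marked) - a
    c = len(cluster) - a
    d = len(universe) - len(marked) - c
    p = fisher_enrichment_p(a, b, c, d)
    if b * c > 0:
        odds = (a * d) / (b * c)
    else:
        odds = math.inf if a * d > 0 else math.nan
    return a, b, c, d, p, odds


def cluster_enrichment_two_step(
    assignment: pd.Series,
    transcriptome_genes: set[str],
    proteome_genes: set[str],
    mrbpome_genes: set[str],
) -> pd.DataFrame:
    """Two-step Fisher cluster enrichment.

    Step 1 tests, per cluster over the transcriptome, whether
    proteome-detected genes are over-represented; step 2 repeats the test
    over the proteome with mRBPome membership, so the abundance bias of MS
    detection is factored out before asking where RNA-bound proteins sit.
    P-values are BH-adjusted across clusters within each step.  Genes
    violating mrbpome <= proteome <= transcriptome are reported and dropped.
    """
    transcriptome = set(transcriptome_genes)
    proteome = set(proteome_genes)
    mrbpome = set(mrbpome_genes)
    stray_p = proteome - transcriptome
    stray_m = mrbpome - proteome
    if stray_p:
        logger.warning("%d proteome genes outside transcriptome; dropped", len(stray_p))
        proteome &= transcriptome
    if stray_m:
        logger.warning("%d mRBPome genes outside proteome; dropped", len(stray_m))
        mrbpome &= proteome

    clusters = sorted(assignment.unique())
    assigned = assignment[assignment.index.isin(transcriptome)]
    rows = []
    for k in clusters:
        members = set(assigned.index[assigned == k])
        if not members:
            rows.append((k, 0, 0, 0, 0, 1.0, math.nan, 0, 0, 0, 0, 1.0, math.nan))
            continue
        s1 = _step_fisher(transcriptome, members, proteome)
        s2 = _step_fisher(proteome, members & proteome, mrbpome)
        rows.append((k, *s1, *s2))
    df = pd.DataFrame(
        rows,
        columns=[
            "cluster",
            "a1", "b1", "c1", "d1", "p1", "odds_ratio1",
            "a2", "b2", "c2", "d2", "p2", "odds_ratio2",
        ],
    )
    for step in ("1", "2"):
        df[f"p{step}_adj"] = multipletests(df[f"p{step}"].to_numpy(), method="fdr_bh")[1]
    return df
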