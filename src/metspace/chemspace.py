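"""Descriptive chemical-space analysis.

Unit-variance PCA, Ward hierarchical clustering with an inertia-based
dendrogram cut, cluster-purity bookkeeping, and conditional inference
trees on binary fingerprint features.  These tools characterize how
metabolites and background compounds occupy descriptor space before any
supervised modelling: which physicochemical axes separate the classes,
whether natural sub-groupings exist, and which substructural features
carry the strongest class association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom


@dataclass
class PCAResult:
    scores: np.ndarray       # samples x components
    loadings: np.ndarray     # variables x components
    explained: np.ndarray    # variance fraction per component (sums to 1)
    columns: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)

    def n_components_for(self, variance: float) -> int:
        """Smallest number of leading components explaining >= ``variance``."""
        cum = np.cumsum(self.explained)
        return int(np.searchsorted(cum, variance - 1e-12) + 1)


def pca(X, standardize: bool = True, columns: list[str] | None = None) -> PCAResult:
    """PCA via SVD of the centered (and optionally unit-variance) matrix.

    Standardizing makes this the eigendecomposition of the correlation
    matrix.  Constant columns cannot be standardized and are dropped with
    a warning.  Sign convention: the largest-magnitude loading of each
    component is positive.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    cols = list(columns) if columns is not None else [f"x{i}" for i in range(X.shape[1])]
    dropped: list[str] = []
    if standardize:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            dropped = [c for c, k in zip(cols, keep) if not k]
            warnings.warn(f"dropping constant columns: {dropped}")
            X, cols = X[:, keep], [c for c, k in zip(cols, keep) if k]
            sd = sd[keep]
        Z = (X - X.mean(axis=0)) / sd
    else:
        Z = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(Vt.shape[0]):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * S
    var = S**2
    explained = var / var.sum() if var.sum() > 0 else var
    return PCAResult(scores=scores, loadings=Vt.T, explained=explained, columns=cols, dropped=dropped)


@dataclass
class Dendrogram:
    """Ward merge sequence in scipy linkage form (n-1 rows: pair, height, size)."""

    merges: np.ndarray
    n_leaves: int

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def ward_cluster(scores) -> Dendrogram:
    """Ward minimum-variance agglomeration over Euclidean distances."""
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    Z = linkage(X, method="ward")
    return Dendrogram(merges=Z, n_leaves=X.shape[0])


def cut_by_inertia(d: Dendrogram, kmin: int = 2, kmax: int = 10) -> np.ndarray:
    """Cut the dendrogram at the point of maximal loss of intra-cluster inertia.

    With Ward linkage the within-cluster inertia gained by the merge that
    takes k clusters to k-1 equals height^2 / 2, so the chosen k maximizes
    the ratio dW(k) / dW(k+1) over k in [kmin, kmax].  Returns 1-based
    cluster labels for the k-cluster partition.
    """
    n = d.n_leaves
    kmax = min(kmax, n - 1) if n > 2 else min(kmax, n)
    kmin = max(2, kmin)
    if kmax < kmin:
        kmax = kmin
    h = d.heights

    def delta_w(k: int) -> float:
        # merge index taking k clusters to k-1 is n-k (0-based)
        return float(h[n - k] ** 2) / 2.0

    best_k, best_ratio = kmin, -np.inf
    for k in range(kmin, kmax + 1):
        num, den = delta_w(k), delta_w(k + 1)
        if den > 0:
            ratio = num / den
        else:
            ratio = np.inf if num > 0 else 0.0
        if ratio > best_ratio:
            best_k, best_ratio = k, ratio
    return fcluster(d.merges, t=best_k, criterion="maxclust")


@dataclass
class ClusterContingency:
    """cluster x class count table with per-cluster purity."""

    counts: pd.DataFrame  # rows: cluster label, columns: class name

    @staticmethod
    def from_labels(cluster_labels, class_labels) -> "ClusterContingency":
        return ClusterContingency(pd.crosstab(pd.Series(cluster_labels, name="cluster"),
                                              pd.Series(class_labels, name="class")))


def cluster_purity(counts) -> np.ndarray:
    """Percent of each cluster occupied by its dominant class."""
    table = counts.counts.to_numpy() if isinstance(counts, ClusterContingency) else np.asarray(counts)
    if table.ndim == 1:
        table = table[None, :]
    totals = table.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("empty cluster")
    return 100.0 * table.max(axis=1) / totals


# --- conditional inference tree -------------------------------------------

def exact_association_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p-value for 2x2 association of binary x and y.

    The permutation distribution of the count n(x=1, y=1) under label
    shuffling is hypergeometric; the p-value sums the probability mass of
    all outcomes no more likely than the observed one.
    """
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    n = len(y)
    K = int(y.sum())
    n1 = int(x.sum())
    a = int(((x == 1) & (y == 1)).sum())
    rv = hypergeom(n, K, n1)
    lo = max(0, n1 + K - n)
    hi = min(n1, K)
    support = np.arange(lo, hi + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())


@dataclass
class CITNode:
    n0: int
    n1: int
    feature: int | None = None
    p_adjusted: float | None = None
    left: "CITNode | None" = None   # feature present
    right: "CITNode | None" = None  # feature absent

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def size(self) -> int:
        return self.n0 + self.n1


@dataclass
class CITree:
    root: CITNode
    alpha: float
    min_node: int
    feature_names: list[str] = field(default_factory=list)

    def render(self) -> str:
        lines: list[str] = []

        def rec(node: CITNode, indent: int, tag: str) -> None:
            pad = "  " * indent
            if node.is_leaf:
                lines.append(f"{pad}{tag}leaf [class0={node.n0}, class1={node.n1}]")
            else:
                name = (
                    self.feature_names[node.feature]
                    if node.feature < len(self.feature_names)
                    else f"f{node.feature}"
                )
                lines.append(
                    f"{pad}{tag}split on {name} (p_adj={node.p_adjusted:.4g}) "
                    f"[class0={node.n0}, class1={node.n1}]"
                )
                rec(node.left, indent + 1, "present: ")
                rec(node.right, indent + 1, "absent:  ")

        rec(self.root, 0, "")
        return "\n".join(lines)

    def to_dot(self) -> str:
        lines = ["digraph cit {", "  node [shape=box];"]
        counter = [0]

        def rec(node: CITNode) -> int:
            idx = counter[0]
            counter[0] += 1
            if node.is_leaf:
                lines.append(f'  n{idx} [label="0:{node.n0} / 1:{node.n1}"];')
            else:
                name = (
                    self.feature_names[node.feature]
                    if node.feature < len(self.feature_names)
                    else f"f{node.feature}"
                )
                lines.append(f'  n{idx} [label="{name}\\np={node.p_adjusted:.3g}"];')
                li = rec(node.left)
                ri = rec(node.right)
                lines.append(f'  n{idx} -> n{li} [label="present"];')
                lines.append(f'  n{idx} -> n{ri} [label="absent"];')
            return idx

        rec(self.root)
        lines.append("}")
        return "\n".join(lines)


def conditional_inference_tree(
    X,
    y,
    alpha: float = 0.05,
    min_node: int = 20,
    feature_names: list[str] | None = None,
) -> CITree:
    """Recursive partitioning with permutation-test covariate selection.

    At each node the exact (hypergeometric) two-sided association p-value
    is computed for every candidate binary feature, Bonferroni-adjusted
    over the features tested; the node splits on the minimum adjusted
    p-value when it is <= ``alpha`` and the node holds >= ``min_node``
    samples, sending feature-present samples left.
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=int)
    if not np.isin(X, (0, 1)).all() or not np.isin(y, (0, 1)).all():
        raise ValueError("X and y must be binary")
    X = X.astype(int)

    def build(idx: np.ndarray) -> CITNode:
        yi = y[idx]
        node = CITNode(n0=int((yi == 0).sum()), n1=int((yi == 1).sum()))
        if node.size < min_node or node.n0 == 0 or node.n1 == 0:
            return node
        Xi = X[idx]
        cols = np.flatnonzero((Xi.sum(axis=0) > 0) & (Xi.sum(axis=0) < len(idx)))
        if cols.size == 0:
            return node
        pvals = np.array([exact_association_pvalue(Xi[:, j], yi) for j in cols])
        p_adj = np.minimum(1.0, pvals * cols.size)
        best = int(np.argmin(p_adj))  # ties -> lowest feature index
        if p_adj[best] > alpha:
            return node
        j = int(cols[best])
        node.feature = j
        node.p_adjusted = float(p_adj[best])
        present = Xi[:, j] == 1
        node.left = build(idx[present])
        node.right = build(idx[~present])
        return node

    root = build(np.arange(len(y)))
    return CITree(root=root, alpha=alpha, min_node=min_node,
                  feature_names=list(feature_names) if feature_names else [])
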