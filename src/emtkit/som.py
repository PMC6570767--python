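"""Semi-supervised E/M gene classification with a self-organizing map.

Genes are mapped onto a 10 × 10 hexagonal grid by an online SOM trained on
row-scaled logFC profiles (the full data set presented 1000 times, learning
rate declining linearly from 0.05 to 0.01).  Grid nodes are then labeled E or
M wherever one curated annotation outnumbers the other at least 2:1, labels
are propagated to unannotated genes in labeled nodes, and the codebook
vectors of M-dominant nodes are hierarchically clustered to reveal M-gene
sub-classes (cluster count chosen by the within-cluster-sum-of-squares elbow).

A plain two-cluster hierarchical baseline on the same row-scaled profiles is
provided for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted


def row_scale(matrix) -> np.ndarray:
    """Center each row to mean 0 and scale to unit (sample) standard deviation.

    Constant rows cannot be scaled; they are returned as all-zero rows with a
    warning, so they land together on the map rather than crashing training.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("row_scale expects a 2-D matrix with >= 2 columns")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    const = (sd == 0.0).ravel()
    if const.any():
        warnings.warn(
            f"{const.sum()} constant row(s) scaled to zero", RuntimeWarning,
            stacklevel=2,
        )
    sd[sd == 0.0] = 1.0
    out = (x - mean) / sd
    out[const] = 0.0
    return out


def hex_positions(n_rows: int, n_cols: int) -> np.ndarray:
    """Planar coordinates of a hexagonal grid (odd rows offset by half a cell)."""
    pos = np.empty((n_rows * n_cols, 2))
    for r in range(n_rows):
        for c in range(n_cols):
            pos[r * n_cols + c] = (c + 0.5 * (r % 2), r * np.sqrt(3) / 2.0)
    return pos


@dataclass
class NodeLabeling:
    """Node → {E, M, mixed, empty} with per-node annotation counts.

    ``at_ratio_boundary`` flags nodes sitting exactly at the 2:1 dominance
    cutoff, where the labeling is sensitive to the >= vs > reading of the rule.
    """

    labels: np.ndarray  # (n_nodes,) of str
    e_counts: np.ndarray
    m_counts: np.ndarray
    n_genes: np.ndarray
    at_ratio_boundary: np.ndarray


def label_nodes(
    assignment: np.ndarray,
    annotations: np.ndarray,
    n_nodes: int,
    ratio: float = 2.0,
) -> NodeLabeling:
    """Label each node by annotation dominance (E:M or M:E at least ``ratio``).

    Unannotated genes are ignored for labeling; nodes without any assigned
    gene are 'empty'; nodes whose annotated genes do not reach the dominance
    ratio (including nodes with only unannotated genes) are 'mixed'.
    """
    annotations = np.asarray(annotations, dtype=object)
    if not np.isin(annotations, ("E", "M")).any():
        raise ValueError("at least one annotated gene is required")
    e_counts = np.zeros(n_nodes, dtype=int)
    m_counts = np.zeros(n_nodes, dtype=int)
    n_genes = np.zeros(n_nodes, dtype=int)
    for node, ann in zip(assignment, annotations):
        n_genes[node] += 1
        if ann == "E":
            e_counts[node] += 1
        elif ann == "M":
            m_counts[node] += 1
    labels = np.full(n_nodes, "mixed", dtype=object)
    boundary = np.zeros(n_nodes, dtype=bool)
    for i in range(n_nodes):
        if n_genes[i] == 0:
            labels[i] = "empty"
            continue
        e, m = e_counts[i], m_counts[i]
        if e == 0 and m == 0:
            continue  # only unannotated genes: stays 'mixed' (unlabeled)
        if m >= ratio * e and m > 0:
            labels[i] = "M"
            boundary[i] = e > 0 and m == ratio * e
        elif e >= ratio * m and e > 0:
            labels[i] = "E"
            boundary[i] = m > 0 and e == ratio * m
    return NodeLabeling(labels, e_counts, m_counts, n_genes, boundary)


class SOMClassifier(ClassifierMixin, BaseEstimator):
    """Semi-supervised E/M classifier built on an online hexagonal SOM.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions (10 × 10 by default).
    n_epochs : int
        Number of times the full data set is presented to the network.
    lr_start, lr_end : float
        Learning rate, declining linearly across training.
    dominance_ratio : float
        E:M (or M:E) count ratio above which a node is labeled.
    scale_rows : bool
        Row-scale the input logFC matrix before training.
    radius_start_frac : float
        Initial bubble-neighborhood radius as a fraction of the grid diameter
        (decays linearly to one inter-node spacing).
    random_state : int
        Seed for codebook initialisation and per-epoch sample shuffling.

    Attributes
    ----------
    codebook_ : ndarray of shape (n_rows * n_cols, n_features)
    assignment_ : ndarray of shape (n_samples,)
        Best-matching node per training gene.
    node_labeling_ : NodeLabeling
    labels_ : ndarray of shape (n_samples,)
        Propagated per-gene call in {'E', 'M', 'none'}.
    quantization_error_ : float
        Mean distance of each training sample to its BMU after training.
    propagation_report_ : dict
        correct / incorrect / unclassified fractions among annotated genes.
    """

    def __init__(
        self,
        n_rows: int = 10,
        n_cols: int = 10,
        n_epochs: int = 1000,
        lr_start: float = 0.05,
        lr_end: float = 0.01,
        dominance_ratio: float = 2.0,
        scale_rows: bool = True,
        radius_start_frac: float = 2.0 / 3.0,
        random_state: int = 0,
    ):
        self.n_rows = n_rows
        self.n_cols = n_cols
        self.n_epochs = n_epochs
        self.lr_start = lr_start
        self.lr_end = lr_end
        self.dominance_ratio = dominance_ratio
        self.scale_rows = scale_rows
        self.radius_start_frac = radius_start_frac
        self.random_state = random_state

    # -- training ---------------------------------------------------------

    def _prepare(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a nonempty 2-D matrix")
        if not np.isfinite(X).all():
            raise ValueError("X contains NaN or infinite values")
        return row_scale(X) if self.scale_rows else X

    def fit(self, X, y):
        """Train the map on all genes; label nodes from the annotated subset.

        ``y`` holds the curated annotation per gene: 'E', 'M', or 'none' for
        genes without one (these take part in training and receive propagated
        labels, but do not vote in node labeling).
        """
        Xs = self._prepare(X)
        y = np.asarray(y, dtype=object)
        if y.shape[0] != Xs.shape[0]:
            raise ValueError("X and y length mismatch")
        n_nodes = self.n_rows * self.n_cols
        rng = np.random.default_rng(self.random_state)

        pos = hex_positions(self.n_rows, self.n_cols)
        grid_dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
        diameter = float(grid_dist.max())

        # init codebooks from random training samples (with replacement)
        codebook = Xs[rng.integers(0, Xs.shape[0], n_nodes)].copy()

        self.initial_quantization_error_ = self._qe(Xs, codebook)

        n = Xs.shape[0]
        total = self.n_epochs * n
        step = 0
        for _ in range(self.n_epochs):
            order = rng.permutation(n)
            for i in order:
                frac = step / max(total - 1, 1)
                lr = self.lr_start + (self.lr_end - self.lr_start) * frac
                # bubble neighborhood shrinking linearly from a fraction of
                # the grid diameter to below one inter-node spacing, so late
                # training fine-tunes only the BMU
                radius = self.radius_start_frac * diameter * (1.0 - frac)
                x = Xs[i]
                d2 = ((codebook - x) ** 2).sum(axis=1)
                bmu = int(np.argmin(d2))
                mask = grid_dist[bmu] <= radius
                codebook[mask] += lr * (x - codebook[mask])
                step += 1

        self.codebook_ = codebook
        self.grid_positions_ = pos
        self.assignment_ = self._bmu(Xs, codebook)
        self.quantization_error_ = self._qe(Xs, codebook)
        self.node_labeling_ = label_nodes(
            self.assignment_, y, n_nodes, self.dominance_ratio
        )
        self.labels_, self.propagation_report_ = propagate_annotations(
            self.assignment_, self.node_labeling_, y
        )
        self.classes_ = np.array(["E", "M", "none"], dtype=object)
        self.n_features_in_ = Xs.shape[1]
        return self

    @staticmethod
    def _bmu(X: np.ndarray, codebook: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)

    @staticmethod
    def _qe(X: np.ndarray, codebook: np.ndarray) -> float:
        d2 = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
        return float(np.sqrt(d2.min(axis=1)).mean())

    def predict(self, X):
        """E/M call for new profiles via their best-matching node's label."""
        check_is_fitted(self, "codebook_")
        Xs = self._prepare(X)
        nodes = self._bmu(Xs, self.codebook_)
        labels = self.node_labeling_.labels[nodes]
        return np.where(np.isin(labels, ("E", "M")), labels, "none")


def propagate_annotations(
    assignment: np.ndarray, labeling: NodeLabeling, annotations: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Give every gene in an E- or M-labeled node that node's label.

    Genes in mixed/empty nodes stay 'none'.  The report holds the fractions of
    annotated genes that were correctly / incorrectly classified or left
    unclassified, measured against the curated annotations.
    """
    node_label = labeling.labels[assignment]
    calls = np.where(np.isin(node_label, ("E", "M")), node_label, "none")
    annotations = np.asarray(annotations, dtype=object)
    annotated = np.isin(annotations, ("E", "M"))
    n_ann = int(annotated.sum())
    correct = int(np.sum(annotated & (calls == annotations)))
    unclassified = int(np.sum(annotated & (calls == "none")))
    incorrect = n_ann - correct - unclassified
    report = {
        "n_annotated": n_ann,
        "correct_frac": correct / n_ann if n_ann else float("nan"),
        "incorrect_frac": incorrect / n_ann if n_ann else float("nan"),
        "unclassified_frac": unclassified / n_ann if n_ann else float("nan"),
    }
    return calls, report


def elbow_k(wss_curve) -> int:
    """Cluster count at the elbow of a WSS-vs-k curve (k = 1, 2, ... order).

    The elbow is the k with the largest second difference of the curve; ties
    break toward the smallest k.  Needs at least 3 points.
    """
    w = np.asarray(wss_curve, dtype=float)
    if w.size < 3:
        raise ValueError("elbow_k needs a WSS curve with >= 3 points")
    second = w[:-2] - 2.0 * w[1:-1] + w[2:]  # curvature at k = 2 .. len-1
    return int(np.argmax(second)) + 2


@dataclass
class MClusterResult:
    """Hierarchical clustering of M-dominant node codebooks, cut at k.

    ``gene_clusters`` maps every gene to M1/M2/.../other ('other' also holds
    genes outside M-labeled nodes); cluster names are ordered by descending
    gene count (M1 largest).
    """

    node_ids: np.ndarray  # the M-labeled node indices that were clustered
    node_clusters: dict  # node id -> cluster name
    gene_clusters: np.ndarray = field(repr=False)  # (n_genes,) of str
    linkage: np.ndarray = field(repr=False)
    wss_curve: np.ndarray = None
    k: int = 0


def _wss(points: np.ndarray, assignments: np.ndarray) -> float:
    total = 0.0
    for cl in np.unique(assignments):
        sub = points[assignments == cl]
        total += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return total


def cluster_m_nodes(
    som: SOMClassifier,
    k: int | None = None,
    k_max: int = 8,
    linkage_method: str = "complete",
    min_node_variance: float | None = None,
    n_named: int = 3,
) -> MClusterResult:
    """Cluster the codebooks of M-dominant nodes and derive gene-level clusters.

    Euclidean complete-linkage agglomeration on the selected codebook
    vectors; the cut level defaults to the WSS elbow over k = 1..k_max but can
    be fixed (e.g. k=4).  The ``n_named`` largest clusters by gene count are
    named M1, M2, ... and all remaining clusters collapse to 'other'.
    ``min_node_variance`` optionally drops M nodes whose codebook variance is
    below the threshold (never-expressed gene nodes); off by default.
    """
    check_is_fitted(som, "codebook_")
    m_nodes = np.flatnonzero(som.node_labeling_.labels == "M")
    if min_node_variance is not None:
        keep = som.codebook_[m_nodes].var(axis=1) >= min_node_variance
        m_nodes = m_nodes[keep]
    if m_nodes.size < 2:
        raise ValueError("need at least 2 M-labeled nodes to cluster")
    points = som.codebook_[m_nodes]
    Z = linkage(pdist(points, metric="euclidean"), method=linkage_method)

    k_hi = min(k_max, m_nodes.size)
    wss = np.array(
        [_wss(points, fcluster(Z, kk, criterion="maxclust")) for kk in range(1, k_hi + 1)]
    )
    if k is None:
        k = elbow_k(wss) if wss.size >= 3 else min(2, k_hi)
    k = min(k, k_hi)
    node_assign = fcluster(Z, k, criterion="maxclust")

    # gene counts per node cluster -> name by descending size
    gene_node = som.assignment_
    counts = {
        cl: int(np.isin(gene_node, m_nodes[node_assign == cl]).sum())
        for cl in np.unique(node_assign)
    }
    # deterministic order: by count desc, then cluster id asc
    ordered = sorted(counts, key=lambda cl: (-counts[cl], cl))
    names = {}
    for rank, cl in enumerate(ordered):
        names[cl] = f"M{rank + 1}" if rank < n_named else "other"

    node_clusters = {int(nid): names[cl] for nid, cl in zip(m_nodes, node_assign)}
    gene_clusters = np.full(gene_node.shape[0], "other", dtype=object)
    for nid, name in node_clusters.items():
        gene_clusters[gene_node == nid] = name
    return MClusterResult(
        node_ids=m_nodes,
        node_clusters=node_clusters,
        gene_clusters=gene_clusters,
        linkage=Z,
        wss_curve=wss,
        k=int(k),
    )


class HierarchicalBaseline(ClassifierMixin, BaseEstimator):
    """Two-cluster agglomerative baseline on row-scaled logFC profiles.

    The plain alternative to the SOM pipeline: Euclidean complete-linkage
    clustering of annotated genes cut into two clusters, each labeled by its
    majority annotation.  ``misclassification_rate_`` is the fraction of
    annotated genes whose cluster majority disagrees with their annotation.
    """

    def __init__(self, linkage_method: str = "complete", scale_rows: bool = True):
        self.linkage_method = linkage_method
        self.scale_rows = scale_rows

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        annotated = np.isin(y, ("E", "M"))
        if annotated.sum() < 2:
            raise ValueError("need >= 2 annotated genes")
        Xa = X[annotated]
        if self.scale_rows:
            Xa = row_scale(Xa)
        ya = y[annotated]
        Z = linkage(pdist(Xa, metric="euclidean"), method=self.linkage_method)
        part = fcluster(Z, 2, criterion="maxclust")
        cluster_label = {}
        for cl in (1, 2):
            members = ya[part == cl]
            n_e, n_m = int((members == "E").sum()), int((members == "M").sum())
            cluster_label[cl] = "E" if n_e >= n_m else "M"
        calls = np.array([cluster_label[c] for c in part], dtype=object)
        self.linkage_ = Z
        self.partition_ = part
        self.cluster_labels_ = cluster_label
        self.labels_ = calls
        self.annotated_mask_ = annotated
        self.misclassification_rate_ = float(np.mean(calls != ya))
        return self


def hclust_baseline(X, annotations) -> tuple[np.ndarray, float]:
    """Functional wrapper: two-cluster cut and misclassification rate."""
    est = HierarchicalBaseline().fit(X, annotations)
    return est.labels_, est.misclassification_rate_
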