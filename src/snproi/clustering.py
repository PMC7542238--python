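"""Stage 1 — LD-aware SNP distance, hierarchical clustering and redundancy filtering.

SNPs in strong linkage disequilibrium (LD) carry near-duplicate information; this
module measures pairwise dissimilarity between SNP columns, builds an agglomerative
dendrogram under one of five linkage rules, scores each (distance, linkage)
combination by its cophenetic correlation, and prunes each flat cluster down to
its medoid SNP. It also builds the SNP partition used by the stage-2 group-sparse
penalty, either from connected components of the r^2 >= threshold LD graph or from
gene membership.

Distances act on the additive genotype codes {0,1,2} across samples:

* ``euclidean``           (sum_i (u_i - v_i)^2)^(1/2)
* ``absolute``            sum_i |u_i - v_i|  (city-block)
* ``minkowski``           (sum_i |u_i - v_i|^r)^(1/r), any r > 0; r < 1 is a
                          power dissimilarity, not a metric (triangle inequality
                          fails) — accepted with a warning since clustering only
                          needs dissimilarities
* ``variance_weighted``   (sum_i (u_i - v_i)^2 / s_i^2)^(1/2), where s_i^2 is the
                          variance of sample i's genotypes across SNPs
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import GenotypeMatrix

logger = logging.getLogger("snproi")

DISTANCE_KINDS = ("euclidean", "absolute", "minkowski", "variance_weighted")
LINKAGES = ("single", "complete", "centroid", "average", "ward")


@dataclass
class DistanceMatrix:
    """Symmetric p x p SNP dissimilarity matrix with zero diagonal."""

    values: np.ndarray
    kind: str
    snp_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (self.values < 0).any():
            raise ValueError("distances must be non-negative")

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class LDMatrix:
    """Pairwise squared-correlation (r^2) LD matrix of genotype codes."""

    values: np.ndarray
    constant_snps: np.ndarray | None = None  # bool mask of zero-variance SNPs


@dataclass
class Dendrogram:
    """Agglomerative merge tree in scipy linkage-matrix encoding.

    ``merges`` has p-1 rows (left id, right id, height, size); leaf ids are
    0..p-1, internal node i created by merge row i-p.
    """

    merges: np.ndarray
    linkage: str
    p: int

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster labels (1..K) from cutting into ``n_clusters`` clusters."""
        return hierarchy.fcluster(self.merges, t=n_clusters, criterion="maxclust")

    def to_newick(self, leaf_names: list[str] | None = None) -> str:
        """Newick string; branch length = parent merge height - child height."""
        names = leaf_names or [str(i) for i in range(self.p)]
        tree = hierarchy.to_tree(self.merges)

        def rec(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{names[node.id]}:{length:.10g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        left = rec(tree.left, tree.dist)
        right = rec(tree.right, tree.dist)
        return f"({left},{right});"


@dataclass
class SNPGroups:
    """Partition of SNP indices into K non-empty groups (labels 0..K-1)."""

    assignment: np.ndarray

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        labels = np.unique(self.assignment)
        if not np.array_equal(labels, np.arange(labels.size)):
            # relabel to a dense 0..K-1 range
            remap = {lab: i for i, lab in enumerate(labels)}
            self.assignment = np.array([remap[a] for a in self.assignment])

    @property
    def n_groups(self) -> int:
        return int(self.assignment.max()) + 1 if self.assignment.size else 0

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignment)

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == k)

    @classmethod
    def singletons(cls, p: int) -> "SNPGroups":
        return cls(np.arange(p))


def _genotype_array(g) -> np.ndarray:
    if isinstance(g, GenotypeMatrix):
        return np.asarray(g.values, dtype=float)
    return check_array(np.asarray(g, dtype=float))


def snp_distance(g, kind: str = "euclidean", r: float = 2.0) -> DistanceMatrix:
    """Pairwise dissimilarity between SNP columns over samples."""
    X = _genotype_array(g)  # n x p
    if kind not in DISTANCE_KINDS:
        raise ValueError(f"unknown distance kind {kind!r}; choose from {DISTANCE_KINDS}")
    cols = X.T  # p x n, observations = SNPs
    if kind == "euclidean":
        d = squareform(pdist(cols, metric="euclidean"))
    elif kind == "absolute":
        d = squareform(pdist(cols, metric="cityblock"))
    elif kind == "minkowski":
        if r is None or r <= 0:
            raise ValueError("minkowski exponent r must be > 0")
        if r < 1:
            warnings.warn(
                f"minkowski r={r} < 1 is a power dissimilarity, not a metric",
                UserWarning, stacklevel=2,
            )
            d = _power_dissimilarity(cols, r)
        else:
            d = squareform(pdist(cols, metric="minkowski", p=r))
    else:  # variance_weighted
        s2 = X.var(axis=1, ddof=0)  # per-sample variance across SNPs
        zero = np.flatnonzero(s2 <= 0)
        if zero.size:
            raise ValueError(
                f"variance_weighted distance undefined: sample index {zero[0]} has "
                "zero genotype variance across SNPs"
            )
        d = squareform(pdist(cols / np.sqrt(s2), metric="euclidean"))
    ids = list(g.snp_ids) if isinstance(g, GenotypeMatrix) else None
    return DistanceMatrix(d, kind, ids)


def _power_dissimilarity(cols: np.ndarray, r: float) -> np.ndarray:
    """(sum |u-v|^r)^(1/r) for r in (0,1), computed row-block-wise."""
    p = cols.shape[0]
    out = np.zeros((p, p))
    for j in range(p):
        diff = np.abs(cols[j + 1:] - cols[j])
        out[j, j + 1:] = np.power(diff, r).sum(axis=1)
    out = out + out.T
    return np.power(out, 1.0 / r)


def ld_r2(g) -> LDMatrix:
    """Squared Pearson correlation of additive genotype codes between SNP pairs.

    Zero-variance (constant) SNPs get r^2 = 0 everywhere, including the
    diagonal, and are flagged in ``constant_snps``.
    """
    X = _genotype_array(g)
    p = X.shape[1]
    sd = X.std(axis=0, ddof=0)
    constant = sd <= 0
    if constant.any():
        logger.warning("ld_r2: %d constant SNP columns set to r^2=0", int(constant.sum()))
    Xc = X - X.mean(axis=0)
    safe_sd = np.where(constant, 1.0, sd)
    Z = Xc / safe_sd
    corr = (Z.T @ Z) / X.shape[0]
    r2 = np.clip(corr**2, 0.0, 1.0)
    r2[constant, :] = 0.0
    r2[:, constant] = 0.0
    np.fill_diagonal(r2, np.where(constant, 0.0, 1.0))
    return LDMatrix(r2, constant_snps=constant)


def hierarchical_cluster(d: DistanceMatrix, linkage: str = "single") -> Dendrogram:
    """Bottom-up agglomerative clustering: repeatedly merge the closest pair."""
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    if d.p < 2:
        raise ValueError("need at least 2 SNPs to cluster")
    Z = hierarchy.linkage(d.condensed(), method=linkage)
    if linkage == "centroid" and np.any(np.diff(Z[:, 2]) < -1e-12):
        logger.info("centroid linkage produced inversions (expected; heights non-monotone)")
    return Dendrogram(Z, linkage, d.p)


def cophenetic_correlation(t: Dendrogram, d: DistanceMatrix) -> float:
    """Pearson correlation between original and cophenetic pairwise distances.

    The cophenetic distance of a pair is the merge height at which the two
    leaves first join; correlation near 1 means the tree faithfully encodes
    the distance structure.
    """
    if t.p != d.p:
        raise ValueError("dendrogram and distance matrix disagree on p")
    if d.p < 3:
        raise ValueError("cophenetic correlation undefined for p < 3")
    c, _ = hierarchy.cophenet(t.merges, d.condensed())
    return float(c)


def cluster_medoids(labels: np.ndarray, d: DistanceMatrix) -> np.ndarray:
    """Index of the medoid of each flat cluster, sorted ascending.

    The medoid minimizes the summed distance to all other cluster members;
    ties break toward the smaller SNP index.
    """
    keep = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        sub = d.values[np.ix_(members, members)]
        keep.append(int(members[int(np.argmin(sub.sum(axis=1)))]))
    return np.sort(np.asarray(keep))


def filter_redundant(g: GenotypeMatrix, t: Dendrogram, d: DistanceMatrix,
                     n_clusters: int) -> GenotypeMatrix:
    """Cut the dendrogram into flat clusters and keep one medoid SNP per cluster."""
    if not 1 <= n_clusters <= g.p_snps:
        raise ValueError(f"n_clusters={n_clusters} out of range [1, {g.p_snps}]")
    labels = t.cut(n_clusters)
    keep = cluster_medoids(labels, d)
    logger.info("filter_redundant: %d -> %d SNPs (%d clusters requested)",
                g.p_snps, keep.size, n_clusters)
    return g.subset_snps(keep)


def build_groups(g, mode: str = "ld", ld: LDMatrix | None = None,
                 threshold: float = 0.2,
                 gene_of: dict[str, str] | None = None) -> SNPGroups:
    """Partition SNPs for the group-sparse penalty.

    mode='ld'   — connected components of the graph with an edge wherever
                  r^2 >= threshold (single-linkage closure of the pairwise rule,
                  which is not transitive on its own).
    mode='gene' — one group per gene symbol; unannotated SNPs become singletons.
    """
    if mode == "ld":
        if ld is None:
            ld = ld_r2(g)
        A = ld.values >= threshold
        np.fill_diagonal(A, False)
        n_comp, labels = connected_components(csr_matrix(A), directed=False)
        return SNPGroups(labels)
    if mode == "gene":
        gene_of = gene_of if gene_of is not None else (
            g.gene_of if isinstance(g, GenotypeMatrix) else None)
        if gene_of is None:
            raise ValueError("mode='gene' requires a snp_id -> gene map")
        snp_ids = g.snp_ids if isinstance(g, GenotypeMatrix) else [
            str(i) for i in range(np.asarray(g).shape[1])]
        labels = np.empty(len(snp_ids), dtype=int)
        gene_label: dict[str, int] = {}
        next_label = 0
        for j, sid in enumerate(snp_ids):
            gene = gene_of.get(sid)
            if gene is None:
                labels[j] = next_label  # unannotated -> singleton
                next_label += 1
            else:
                if gene not in gene_label:
                    gene_label[gene] = next_label
                    next_label += 1
                labels[j] = gene_label[gene]
        return SNPGroups(labels)
    raise ValueError(f"unknown grouping mode {mode!r}; choose 'ld' or 'gene'")


def linkage_distance_screen(g, minkowski_r: float = 0.23) -> pd.DataFrame:
    """Cophenetic-correlation grid over 4 distance kinds x 5 linkage rules.

    Returns a DataFrame (rows = distance kinds, columns = linkages) whose
    ``attrs['best']`` records the argmax (distance, linkage) pair — the
    combination whose dendrogram most faithfully preserves the distances.
    """
    grid = pd.DataFrame(index=list(DISTANCE_KINDS), columns=list(LINKAGES), dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for kind in DISTANCE_KINDS:
            d = snp_distance(g, kind=kind, r=minkowski_r if kind == "minkowski" else 2.0)
            for link in LINKAGES:
                t = hierarchical_cluster(d, linkage=link)
                grid.loc[kind, link] = cophenetic_correlation(t, d)
    flat = grid.stack()
    best = flat.idxmax()
    grid.attrs["best"] = (best[0], best[1], float(flat.max()))
    return grid


class LDHierarchicalFilter(BaseEstimator, TransformerMixin):
    """Redundancy-pruning transformer: cluster SNPs, keep one medoid per cluster.

    Parameters
    ----------
    distance : {'euclidean', 'absolute', 'minkowski', 'variance_weighted'}
        Pairwise dissimilarity between SNP columns.
    minkowski_r : float
        Exponent for the minkowski distance (only used for that kind);
        values below 1 give a power dissimilarity and emit a warning.
    linkage : {'single', 'complete', 'centroid', 'average', 'ward'}
        Agglomeration rule.
    n_clusters : int or None
        Number of flat clusters to cut the dendrogram into; ``None`` means
        p // 2 (halve the panel).

    Attributes
    ----------
    support_ : ndarray of int
        Indices (ascending) of the retained medoid SNPs.
    linkage_matrix_ : ndarray
        scipy-format merge table.
    cophenetic_correlation_ : float
        Agreement between tree and distances on the training panel.
    """

    def __init__(self, distance: str = "euclidean", minkowski_r: float = 0.23,
                 linkage: str = "average", n_clusters: int | None = None):
        self.distance = distance
        self.minkowski_r = minkowski_r
        self.linkage = linkage
        self.n_clusters = n_clusters

    def fit(self, X, y=None):
        X = check_array(X)
        p = X.shape[1]
        n_clusters = self.n_clusters if self.n_clusters is not None else max(1, p // 2)
        d = snp_distance(X, kind=self.distance, r=self.minkowski_r)
        t = hierarchical_cluster(d, linkage=self.linkage)
        labels = t.cut(n_clusters)
        self.support_ = cluster_medoids(labels, d)
        self.labels_ = labels
        self.linkage_matrix_ = t.merges
        self.dendrogram_ = t
        self.cophenetic_correlation_ = (
            cophenetic_correlation(t, d) if p >= 3 else float("nan"))
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}")
        return X[:, self.support_]
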