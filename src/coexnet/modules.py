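"""Module detection, eigengenes, membership, and intramodular connectivity.

A module is a branch of the average-linkage dendrogram of ``1 - TOM`` accepted
by the dynamic cut in :mod:`coexnet._treecut`. Label 0 is the unassigned
("grey") pool. Each module is summarized by its eigengene -- the first
principal component of the standardized member expression, sign-oriented to
correlate non-negatively with the module's mean expression profile and scaled
to unit variance. Module membership kME is the Pearson correlation of a gene
with an eigengene; intramodular connectivity kIM is the adjacency a gene sends
into its own module, and scaled kIM divides by the maximum observed kIM in
that module so hubs score 1 regardless of module size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from ._treecut import absorb_unassigned, cut_dendrogram
from .errors import DegenerateInputError
from .network import Network, build_network

__all__ = [
    "ModuleSet",
    "detect_modules",
    "compute_eigengenes",
    "compute_membership_and_connectivity",
    "merge_similar_modules",
    "module_sizes",
    "ModuleDetector",
]


@dataclass
class ModuleSet:
    """Gene-to-module assignment with the per-module summaries."""

    assignment: pd.Series  # gene -> int label, 0 = unassigned
    eigengenes: pd.DataFrame | None = None  # modules x samples
    kme: pd.DataFrame | None = None  # genes x modules
    kim: pd.Series | None = None
    kim_scaled: pd.Series | None = None

    @property
    def labels(self) -> list[int]:
        return sorted(l for l in self.assignment.unique() if l != 0)


def module_sizes(assignment: pd.Series) -> pd.Series:
    counts = assignment[assignment != 0].value_counts().sort_index()
    counts.name = "size"
    return counts


def detect_modules(
    net: Network,
    min_module_size: int = 30,
    deep_split: int = 3,
    assign_outliers: bool = True,
) -> ModuleSet:
    """Cut the TOM dendrogram of a network into modules.

    ``deep_split`` in 0..3 monotonically increases splitting sensitivity.
    Branches smaller than ``min_module_size`` stay unassigned. When
    ``assign_outliers`` is on, leftover genes whose mean TOM to some module
    matches that module's weakest member are attached to it.
    """
    n = net.n_genes
    if n < min_module_size:
        warnings.warn(
            f"universe of {n} genes is smaller than min_module_size="
            f"{min_module_size}; all genes left unassigned",
            stacklevel=2,
        )
        labels = np.zeros(n, dtype=int)
    else:
        labels = cut_dendrogram(
            1.0 - net.tom, min_cluster_size=min_module_size, deep_split=deep_split
        )
        if assign_outliers and labels.max() > 0:
            labels = absorb_unassigned(labels, net.tom)
    assignment = pd.Series(labels, index=net.gene_ids, name="module")
    return ModuleSet(assignment=assignment)


def compute_eigengenes(expr: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    """First principal component summary profile of each module.

    Member genes are z-scored across samples; the first right singular vector
    of the module submatrix is oriented to correlate non-negatively with the
    module mean profile and returned with unit variance. Rows are module
    labels, columns sample ids.
    """
    if expr.shape[1] < 3:
        raise DegenerateInputError("need at least 3 samples to compute eigengenes")
    labels = sorted(l for l in pd.unique(assignment) if l != 0)
    rows = {}
    for label in labels:
        genes = assignment.index[assignment == label]
        sub = expr.loc[genes].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=1)
        if np.any(sd == 0):
            bad = genes[int(np.flatnonzero(sd == 0)[0])]
            raise DegenerateInputError(
                f"gene {bad!r} in module {label} has zero variance"
            )
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        mean_profile = z.mean(axis=0)
        if np.corrcoef(me, mean_profile)[0, 1] < 0:
            me = -me
        me = me / me.std(ddof=1)
        rows[label] = me
    return pd.DataFrame(rows, index=expr.columns).T


def _row_correlations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlations of each row of x with each row of y."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = xc @ yc.T
    den = np.outer(
        np.sqrt((xc ** 2).sum(axis=1)), np.sqrt((yc ** 2).sum(axis=1))
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def compute_membership_and_connectivity(
    expr: pd.DataFrame,
    net: Network,
    assignment: pd.Series,
    eigengenes: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """kME (gene x module correlation), kIM, and scaled kIM.

    kIM sums a gene's adjacency to the other genes of its own module; scaled
    kIM divides by the maximum kIM observed in that module (0 when the module
    maximum is 0). Unassigned genes get kIM = scaled kIM = 0.
    """
    if eigengenes is None:
        eigengenes = compute_eigengenes(expr, assignment)
    kme_values = _row_correlations(
        expr.to_numpy(dtype=float), eigengenes.to_numpy(dtype=float)
    )
    kme = pd.DataFrame(kme_values, index=expr.index, columns=eigengenes.index)

    labels = assignment.to_numpy()
    adj = net.adjacency
    kim = np.zeros(len(labels))
    kim_scaled = np.zeros(len(labels))
    for label in np.unique(labels):
        if label == 0:
            continue
        members = np.flatnonzero(labels == label)
        sub = adj[np.ix_(members, members)].copy()
        np.fill_diagonal(sub, 0.0)
        k = sub.sum(axis=1)
        kim[members] = k
        kmax = k.max() if len(k) else 0.0
        if kmax > 0:
            kim_scaled[members] = k / kmax
    return (
        kme,
        pd.Series(kim, index=assignment.index, name="kim"),
        pd.Series(kim_scaled, index=assignment.index, name="kim_scaled"),
    )


def merge_similar_modules(
    expr: pd.DataFrame | list[pd.DataFrame],
    assignment: pd.Series,
    cut_height: float = 0.2,
    max_iter: int = 20,
) -> pd.Series:
    """Merge modules whose eigengenes are highly correlated.

    Modules are clustered by average linkage on eigengene dissimilarity
    ``1 - cor(ME_i, ME_j)``; branches below ``cut_height`` collapse into one
    module (keeping the smallest participating label), eigengenes are
    recomputed, and the procedure iterates until stable.

    ``expr`` may be a list of expression matrices over the same genes (the
    consensus pathway): dissimilarity is then ``1 - min_s cor_s``, the most
    conservative cross-set similarity.
    """
    exprs = expr if isinstance(expr, list) else [expr]
    assignment = assignment.copy()
    for _ in range(max_iter):
        labels = sorted(l for l in pd.unique(assignment) if l != 0)
        if len(labels) < 2:
            break
        sims = []
        for mat in exprs:
            me = compute_eigengenes(mat, assignment)
            sims.append(np.corrcoef(me.to_numpy()))
        similarity = np.minimum.reduce(sims)
        diss = 1.0 - similarity
        np.fill_diagonal(diss, 0.0)
        diss = np.maximum(diss, 0.0)
        z = hierarchy.linkage(squareform(diss, checks=False), method="average")
        groups = hierarchy.fcluster(z, t=cut_height, criterion="distance")
        if len(np.unique(groups)) == len(labels):
            break
        remap = {}
        for group in np.unique(groups):
            members = [labels[i] for i in np.flatnonzero(groups == group)]
            target = min(members)
            for m in members:
                remap[m] = target
        assignment = assignment.map(lambda l: remap.get(l, l))
    # compact labels to 1..K by decreasing size, deterministically
    sizes = module_sizes(assignment)
    order = sizes.sort_values(ascending=False, kind="stable").index
    final = {old: new for new, old in enumerate(order, start=1)}
    final[0] = 0
    return assignment.map(final).rename("module")


class ModuleDetector(ClusterMixin, BaseEstimator):
    """Coexpression module detection as a scikit-learn style feature clusterer.

    Follows the sklearn sample-axis convention: ``fit`` takes ``X`` of shape
    (n_samples, n_genes) and clusters the *columns* (genes), exposing
    ``labels_`` over genes (0 = unassigned) along with the fitted network and
    module summaries.

    Parameters
    ----------
    power : soft-threshold exponent of the unsigned adjacency.
    min_module_size : smallest accepted module.
    deep_split : splitting sensitivity, 0..3.
    merge_cut_height : when set, eigengene-similar modules are merged at this
        dissimilarity (the consensus pathway's 0.2 by convention; off by
        default for single-species runs).

    Attributes
    ----------
    labels_ : ndarray of shape (n_genes,)
    network_ : fitted :class:`~coexnet.network.Network`
    eigengenes_ : DataFrame (modules x samples)
    kme_ : DataFrame (genes x modules)
    kim_, kim_scaled_ : ndarray of shape (n_genes,)
    n_modules_ : int
    """

    def __init__(
        self,
        power: float = 6.0,
        min_module_size: int = 30,
        deep_split: int = 3,
        merge_cut_height: float | None = None,
        assign_outliers: bool = True,
    ):
        self.power = power
        self.min_module_size = min_module_size
        self.deep_split = deep_split
        self.merge_cut_height = merge_cut_height
        self.assign_outliers = assign_outliers

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2d (n_samples, n_genes)")
        if isinstance(X, np.ndarray):
            gene_ids = [f"g{i}" for i in range(X.shape[1])]
        expr = pd.DataFrame(
            X.T, index=gene_ids, columns=[f"s{i}" for i in range(X.shape[0])]
        )
        self.network_ = build_network(expr, self.power)
        mods = detect_modules(
            self.network_,
            min_module_size=self.min_module_size,
            deep_split=self.deep_split,
            assign_outliers=self.assign_outliers,
        )
        assignment = mods.assignment
        if self.merge_cut_height is not None and assignment.max() > 1:
            assignment = merge_similar_modules(
                expr, assignment, cut_height=self.merge_cut_height
            )
        self.assignment_ = assignment
        self.labels_ = assignment.to_numpy()
        self.n_modules_ = int(len([l for l in np.unique(self.labels_) if l != 0]))
        if self.n_modules_:
            self.eigengenes_ = compute_eigengenes(expr, assignment)
            self.kme_, kim, kim_scaled = compute_membership_and_connectivity(
                expr, self.network_, assignment, self.eigengenes_
            )
            self.kim_ = kim.to_numpy()
            self.kim_scaled_ = kim_scaled.to_numpy()
        else:
            self.eigengenes_ = None
            self.kme_ = None
            self.kim_ = np.zeros(X.shape[1])
            self.kim_scaled_ = np.zeros(X.shape[1])
        return self
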