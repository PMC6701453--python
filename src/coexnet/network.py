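"""Weighted coexpression network construction.

The network over a gene universe is the unsigned soft-thresholded adjacency
``a_ij = |cor(x_i, x_j)|^beta`` together with its topological overlap matrix

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),

where ``l_ij = sum_{u != i,j} a_iu * a_uj`` counts shared neighborhood and
``k_i = sum_{u != i} a_iu`` is connectivity. ``1 - TOM`` is the clustering
dissimilarity used downstream. Pearson correlation is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateInputError

__all__ = [
    "Network",
    "adjacency_from_expression",
    "topological_overlap",
    "build_network",
    "scale_free_fit",
    "pick_soft_threshold",
]


@dataclass
class Network:
    """Soft-thresholded adjacency and topological overlap for a gene universe."""

    gene_ids: list[str]
    power: float
    adjacency: np.ndarray
    tom: np.ndarray
    adjacency_type: str = "unsigned"

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.adjacency.shape != (n, n) or self.tom.shape != (n, n):
            raise ConfigurationError("adjacency/TOM shape does not match gene_ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def connectivity(self) -> np.ndarray:
        """Whole-network connectivity k_i (adjacency row sums, diagonal excluded)."""
        return self.adjacency.sum(axis=0) - np.diag(self.adjacency)


def _check_variance(values: np.ndarray, gene_ids) -> None:
    sd = values.std(axis=1)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        raise DegenerateInputError(
            f"gene {gene_ids[degenerate[0]]!r} has zero variance across samples"
        )


def adjacency_from_expression(expr: pd.DataFrame, power: float) -> np.ndarray:
    """Unsigned adjacency |Pearson r|^power with unit diagonal."""
    if power <= 0:
        raise ConfigurationError("power must be positive")
    if expr.shape[1] < 3:
        raise DegenerateInputError("need at least 3 samples to build a network")
    values = expr.to_numpy(dtype=float)
    _check_variance(values, list(expr.index))
    corr = np.corrcoef(values)
    np.clip(np.abs(corr, out=corr), 0.0, 1.0, out=corr)
    adj = corr ** power
    np.fill_diagonal(adj, 1.0)
    return adj


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an unsigned adjacency (unit diagonal)."""
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    shared = a @ a  # l_ij; diagonal terms vanish because diag(a) = 0
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def build_network(expr: pd.DataFrame, power: float) -> Network:
    """Build the unsigned coexpression network for a genes x samples matrix."""
    adj = adjacency_from_expression(expr, power)
    tom = topological_overlap(adj)
    return Network(gene_ids=list(expr.index), power=float(power),
                   adjacency=adj, tom=tom)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of a connectivity distribution.

    Bins k into ``n_bins`` equal-width bins, regresses log10 p(k) on
    log10(mean k per bin), and returns ``(signed_r2, mean_k)`` where the R^2 is
    signed negatively when the slope is positive (a rising degree distribution
    is the opposite of scale-free).
    """
    k = np.asarray(connectivity, dtype=float)
    mean_k = float(k.mean())
    if k.max() == k.min():
        return 0.0, mean_k
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=k, minlength=n_bins)
    nonempty = counts > 0
    freq = counts[nonempty] / k.size
    centers = sums[nonempty] / counts[nonempty]
    usable = centers > 0
    if usable.sum() < 3:
        return 0.0, mean_k
    fit = stats.linregress(np.log10(centers[usable]), np.log10(freq[usable]))
    signed_r2 = float(-np.sign(fit.slope) * fit.rvalue ** 2)
    return signed_r2, mean_k


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_powers=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> tuple[float, pd.DataFrame]:
    """Choose a soft-threshold power by the scale-free topology criterion.

    Returns the smallest candidate whose signed fit R^2 reaches ``r2_target``;
    when no candidate reaches it, falls back to the candidate of maximal R^2
    and flags the non-attainment in the fit table's ``target_met`` column.
    """
    candidates = sorted(float(p) for p in candidate_powers)
    if len(candidates) < 2:
        raise ConfigurationError("need at least 2 candidate powers")
    if expr.shape[1] < 4:
        raise DegenerateInputError("need at least 4 samples to pick a power")
    values = expr.to_numpy(dtype=float)
    _check_variance(values, list(expr.index))
    corr = np.abs(np.corrcoef(values))
    np.clip(corr, 0.0, 1.0, out=corr)
    np.fill_diagonal(corr, 0.0)

    rows = []
    for p in candidates:
        k = (corr ** p).sum(axis=0)
        signed_r2, mean_k = scale_free_fit(k, n_bins=n_bins)
        rows.append({"power": p, "signed_r2": signed_r2, "mean_k": mean_k})
    table = pd.DataFrame(rows)
    passing = table[table["signed_r2"] >= r2_target]
    if len(passing):
        chosen = float(passing["power"].iloc[0])
        table["target_met"] = True
    else:
        chosen = float(table.loc[table["signed_r2"].idxmax(), "power"])
        table["target_met"] = False
    table["chosen"] = table["power"] == chosen
    return chosen, table
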