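"""Cross-species consensus module analysis over a homolog universe.

Per-species topological overlap matrices are computed over the 1:1 homolog
pairs, the second species' TOM is scaled onto the first by quantile-matching
(a power transform equating the chosen off-diagonal quantile, species A --
the primate analogue -- serving as the reference), and the consensus TOM is
the parallel elementwise minimum. Modules cut from ``1 - consensus`` are
"meta-modules": gene sets coexpressed in *both* species; a module private to
one species leaves no signal in the minimum and dissolves. Eigengene merging
in the consensus pathway uses the minimum of the two species' eigengene
correlations as similarity, the conservative choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyResultError
from .modules import (
    compute_eigengenes,
    compute_membership_and_connectivity,
    detect_modules,
    merge_similar_modules,
)
from .network import Network, build_network
from .stats import OverlapResult, correlate_with_trait, hypergeometric_overlap

__all__ = [
    "collapse_to_genes",
    "scale_tom",
    "consensus_tom",
    "ConsensusResult",
    "detect_meta_modules",
    "ConsensusModuleDetector",
    "cross_tabulate",
]


def collapse_to_genes(expr: pd.DataFrame, annot: pd.DataFrame) -> pd.DataFrame:
    """Collapse probesets to one row per gene symbol.

    Keeps the probeset with the highest mean expression for each symbol,
    breaking ties by probeset id; probesets without a symbol are dropped.
    Returns a matrix indexed by symbol.
    """
    ann = annot.reindex(expr.index)
    symbol = ann["symbol"].astype("string")
    keep = symbol.notna() & (symbol.str.strip() != "")
    sub = expr.loc[keep.to_numpy()]
    syms = symbol[keep.to_numpy()]
    means = sub.mean(axis=1)
    choice = (
        pd.DataFrame({"symbol": syms.to_numpy(), "mean": means.to_numpy(),
                      "probeset": sub.index})
        .sort_values(["symbol", "mean", "probeset"],
                     ascending=[True, False, True], kind="stable")
        .drop_duplicates("symbol", keep="first")
    )
    out = sub.loc[choice["probeset"]]
    out.index = pd.Index(choice["symbol"], name="symbol")
    return out


def _offdiag(matrix: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(matrix, k=1)
    return matrix[iu]


def scale_tom(
    tom_target: np.ndarray, tom_reference: np.ndarray, quantile: float = 0.95
) -> np.ndarray:
    """Scale one TOM onto another by quantile-matching power transform.

    Raises the target elementwise to ``log(q_ref) / log(q_target)`` so its
    chosen off-diagonal quantile equals the reference's. Both quantiles must
    lie strictly inside (0, 1); identical quantiles give the identity.
    """
    if tom_target.shape != tom_reference.shape:
        raise ConfigurationError("TOM matrices must have identical shapes")
    if not 0 < quantile < 1:
        raise ConfigurationError("quantile must lie strictly in (0, 1)")
    # order-statistic quantiles: a power transform maps them exactly, so the
    # scaled matrix's quantile matches the reference's to machine precision
    q_t = float(np.quantile(_offdiag(tom_target), quantile, method="lower"))
    q_r = float(np.quantile(_offdiag(tom_reference), quantile, method="lower"))
    for name, q in (("target", q_t), ("reference", q_r)):
        if not 0 < q < 1:
            raise ConfigurationError(
                f"degenerate {name} quantile {q!r}; cannot scale"
            )
    if q_t == q_r:
        return tom_target.copy()
    exponent = np.log(q_r) / np.log(q_t)
    scaled = tom_target ** exponent
    np.fill_diagonal(scaled, 1.0)
    return scaled


def consensus_tom(tom_a: np.ndarray, tom_b: np.ndarray) -> np.ndarray:
    """Parallel minimum of two aligned TOM matrices."""
    if tom_a.shape != tom_b.shape:
        raise ConfigurationError("TOM matrices are not aligned")
    return np.minimum(tom_a, tom_b)


@dataclass
class ConsensusResult:
    """Meta-module assignment with per-species summaries and inputs."""

    pairs: pd.DataFrame  # aligned homolog pairs actually analyzed
    assignment: pd.Series  # indexed by species A gene id; 0 = unassigned
    network_a: Network
    network_b: Network
    tom_b_scaled: np.ndarray
    consensus: np.ndarray
    eigengenes: dict[str, pd.DataFrame] = field(default_factory=dict)
    kme: dict[str, pd.DataFrame] = field(default_factory=dict)
    trait_correlations: dict[str, pd.DataFrame] = field(default_factory=dict)

    def assignment_for_species(self, species: str) -> pd.Series:
        """The meta assignment re-indexed by that species' gene ids."""
        col = "species_a" if species == "a" else "species_b"
        return pd.Series(
            self.assignment.to_numpy(), index=self.pairs[col].to_numpy(),
            name="meta_module",
        )


def detect_meta_modules(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    homolog_map: pd.DataFrame,
    info_a: pd.DataFrame | None = None,
    info_b: pd.DataFrame | None = None,
    power: float = 8.0,
    deep_split: int = 3,
    min_module_size: int = 30,
    merge_cut: float = 0.2,
    scale_quantile: float = 0.95,
    phenotype: str = "ethanol_intake",
) -> ConsensusResult:
    """Run the two-species consensus module analysis.

    ``homolog_map`` must have columns ``species_a``/``species_b``; only pairs
    present in both matrices are analyzed. When sample tables are given,
    per-species eigengene-trait correlations are computed for ``phenotype``.
    """
    pairs = homolog_map[
        homolog_map["species_a"].isin(expr_a.index)
        & homolog_map["species_b"].isin(expr_b.index)
    ].reset_index(drop=True)
    if pairs.empty:
        raise EmptyResultError("no homolog pairs present in both matrices")
    for col in ("species_a", "species_b"):
        if pairs[col].duplicated().any():
            raise ConfigurationError("homolog map is not 1:1 after alignment")

    sub_a = expr_a.loc[pairs["species_a"]]
    sub_b = expr_b.loc[pairs["species_b"]]

    net_a = build_network(sub_a, power)
    net_b = build_network(sub_b, power)
    tom_b_scaled = scale_tom(net_b.tom, net_a.tom, quantile=scale_quantile)
    cons = consensus_tom(net_a.tom, tom_b_scaled)

    cons_net = Network(
        gene_ids=list(pairs["species_a"]), power=power,
        adjacency=np.minimum(net_a.adjacency, net_b.adjacency), tom=cons,
    )
    mods = detect_modules(
        cons_net, min_module_size=min_module_size, deep_split=deep_split
    )
    assignment = mods.assignment
    if assignment.max() > 1:
        # merge on the conservative cross-species eigengene similarity
        sub_b_aligned = sub_b.copy()
        sub_b_aligned.index = sub_a.index
        assignment = merge_similar_modules(
            [sub_a, sub_b_aligned], assignment, cut_height=merge_cut
        )

    result = ConsensusResult(
        pairs=pairs,
        assignment=assignment.rename("meta_module"),
        network_a=net_a,
        network_b=net_b,
        tom_b_scaled=tom_b_scaled,
        consensus=cons,
    )
    if assignment.max() > 0:
        assign_b = pd.Series(
            assignment.to_numpy(), index=sub_b.index, name="meta_module"
        )
        for species, sub, assign, info in (
            ("a", sub_a, assignment, info_a),
            ("b", sub_b, assign_b, info_b),
        ):
            me = compute_eigengenes(sub, assign)
            result.eigengenes[species] = me
            net = net_a if species == "a" else net_b
            kme, _, _ = compute_membership_and_connectivity(sub, net, assign, me)
            result.kme[species] = kme
            if info is not None and phenotype in info.columns:
                result.trait_correlations[species] = correlate_with_trait(
                    me, info, phenotype
                )
    return result


class ConsensusModuleDetector:
    """Estimator-style wrapper around :func:`detect_meta_modules`.

    Parameters are set at construction; ``fit(expr_a, expr_b, homolog_map)``
    stores the fitted :class:`ConsensusResult` attributes with trailing
    underscores. Takes two expression matrices, so it is deliberately not a
    sklearn ``BaseEstimator`` (the one-X contract cannot express it).
    """

    def __init__(
        self,
        power: float = 8.0,
        deep_split: int = 3,
        min_module_size: int = 30,
        merge_cut: float = 0.2,
        scale_quantile: float = 0.95,
    ):
        self.power = power
        self.deep_split = deep_split
        self.min_module_size = min_module_size
        self.merge_cut = merge_cut
        self.scale_quantile = scale_quantile

    def fit(self, expr_a, expr_b, homolog_map, info_a=None, info_b=None):
        result = detect_meta_modules(
            expr_a, expr_b, homolog_map, info_a=info_a, info_b=info_b,
            power=self.power, deep_split=self.deep_split,
            min_module_size=self.min_module_size, merge_cut=self.merge_cut,
            scale_quantile=self.scale_quantile,
        )
        self.result_ = result
        self.assignment_ = result.assignment
        self.labels_ = result.assignment.to_numpy()
        self.n_modules_ = int(len([l for l in np.unique(self.labels_) if l != 0]))
        return self


def cross_tabulate(
    meta_assignment: pd.Series,
    species_assignment: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Overlap grid between meta-modules and single-species modules.

    Both assignments must be indexed by the same gene universe (the homolog
    universe). Each (meta, species) module pair gets its overlap count and
    hypergeometric upper-tail p, plus a significance flag at ``alpha``.
    """
    universe = meta_assignment.index.intersection(species_assignment.index)
    if len(universe) == 0:
        raise ConfigurationError("assignments share no genes")
    meta = meta_assignment.loc[universe]
    spec = species_assignment.loc[universe]
    rows = []
    for m in sorted(l for l in meta.unique() if l != 0):
        set_m = set(universe[meta == m])
        for s in sorted(l for l in spec.unique() if l != 0):
            set_s = set(universe[spec == s])
            ov: OverlapResult = hypergeometric_overlap(set_m, set_s, set(universe))
            rows.append(
                {
                    "meta_module": m,
                    "species_module": s,
                    "n_meta": ov.n_a,
                    "n_species": ov.n_b,
                    "n_overlap": ov.n_overlap,
                    "p": ov.p,
                    "significant": ov.p <= alpha,
                }
            )
    return pd.DataFrame(rows)
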