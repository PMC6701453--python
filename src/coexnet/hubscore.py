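"""Ethanol-related hub score (ERHS).

ERHS ranks candidate genes by combining network centrality with two kinds of
ethanol relevance:

    ERHS = scaled kIM + (1 - intake p-value) + (1 - DE p-value)

Each term lies in [0, 1] with 1 the most relevant, so the score lies in
[0, 3]; scaling kIM by the module maximum makes the centrality term
comparable across large and small modules. The intake p is the two-sided p of
the gene's Pearson correlation with the intake phenotype over treated samples
only; the DE p is the raw (unadjusted) moderated-t p. Genes outside any
module keep scaled kIM = 0 but are still scored and ranked.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["compute_erhs", "erhs_table", "rank_candidates"]


def _check_unit_interval(values: np.ndarray, name: str) -> None:
    if np.any(np.isnan(values)) or np.any(values < 0) or np.any(values > 1):
        raise ConfigurationError(f"{name} must lie in [0, 1] with no missing values")


def compute_erhs(kim_scaled, intake_p, de_p):
    """Three-term hub score; vectorized, scalar in -> scalar out."""
    ks = np.asarray(kim_scaled, dtype=float)
    ip = np.asarray(intake_p, dtype=float)
    dp = np.asarray(de_p, dtype=float)
    for arr, name in ((ks, "kim_scaled"), (ip, "intake_p"), (dp, "de_p")):
        _check_unit_interval(arr, name)
    score = ks + (1.0 - ip) + (1.0 - dp)
    if score.ndim == 0:
        return float(score)
    return score


def erhs_table(
    assignment: pd.Series,
    kim_scaled: pd.Series,
    intake_p: pd.Series,
    de_p: pd.Series,
) -> pd.DataFrame:
    """Assemble the per-gene ERHS table from aligned gene-indexed series."""
    genes = assignment.index
    for series, name in (
        (kim_scaled, "kim_scaled"),
        (intake_p, "intake_p"),
        (de_p, "de_p"),
    ):
        if not genes.isin(series.index).all():
            raise ConfigurationError(f"{name} does not cover all genes")
    table = pd.DataFrame(
        {
            "module": assignment,
            "kim_scaled": kim_scaled.loc[genes].astype(float),
            "intake_p": intake_p.loc[genes].astype(float),
            "de_p": de_p.loc[genes].astype(float),
        },
        index=genes,
    )
    table["erhs"] = compute_erhs(
        table["kim_scaled"].to_numpy(),
        table["intake_p"].to_numpy(),
        table["de_p"].to_numpy(),
    )
    table.index.name = "gene_id"
    return table


def rank_candidates(
    table: pd.DataFrame, per_module_n: int = 25, global_n: int = 250
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-N candidates per module and study-wide.

    Sorted by ERHS descending; ties broken by gene id ascending, so repeated
    runs order tied genes identically. Returns ``(per_module, global)``
    frames, the first restricted to assigned modules.
    """
    if table.empty:
        raise ConfigurationError("ERHS table is empty")
    flat = table.reset_index() if "gene_id" not in table.columns else table.copy()
    ordered = flat.sort_values(
        ["erhs", "gene_id"], ascending=[False, True], kind="stable"
    )
    top_global = ordered.head(global_n).copy()
    top_global["rank"] = np.arange(1, len(top_global) + 1)
    per_module = (
        ordered[ordered["module"] != 0]
        .groupby("module", group_keys=False)
        .head(per_module_n)
        .copy()
    )
    per_module["rank_in_module"] = per_module.groupby("module").cumcount() + 1
    return per_module, top_global
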