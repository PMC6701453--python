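"""Probeset filtering for normalized (log2 / RMA-style) expression matrices.

Four per-gene filters are applied in a fixed reporting order: control probes,
unannotated probes, low expression (value below ``low_expr_threshold`` in at
least ``low_expr_fraction`` of samples), and low variability (unscaled median
absolute deviation below ``mad_min``). Each filter is a predicate on a gene's
full sample vector, so the surviving set does not depend on the order; only
the per-step removal counts in the report do.

The MAD here is the raw median of absolute deviations from the median, with no
1.4826 consistency factor: the variability cutoff is calibrated against that
raw definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyResultError

__all__ = ["FilterReport", "filter_probesets", "unscaled_mad"]


def unscaled_mad(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Median of absolute deviations from the median, unscaled."""
    med = np.median(values, axis=axis, keepdims=True)
    return np.median(np.abs(values - med), axis=axis)


@dataclass
class FilterReport:
    """Accounting of genes removed at each filtering step."""

    n_input: int = 0
    n_control_removed: int = 0
    n_unannotated_removed: int = 0
    n_low_expression_removed: int = 0
    n_low_mad_removed: int = 0
    n_kept: int = 0
    params: dict = field(default_factory=dict)

    def lines(self) -> list[str]:
        return [
            f"input probesets: {self.n_input}",
            f"removed as control probes: {self.n_control_removed}",
            f"removed as unannotated: {self.n_unannotated_removed}",
            f"removed by low-expression filter: {self.n_low_expression_removed}",
            f"removed by MAD filter: {self.n_low_mad_removed}",
            f"passed all filters: {self.n_kept}",
        ]


def filter_probesets(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    low_expr_threshold: float = 3.5,
    low_expr_fraction: float = 0.80,
    mad_min: float = 0.065,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the standard probeset filters to a genes x samples matrix.

    Parameters
    ----------
    expr
        Normalized log-scale expression, genes in rows.
    annot
        Annotation frame indexed by gene id with ``symbol`` (NaN/empty when
        unannotated) and boolean ``is_control_probe``; must cover every gene.
    low_expr_threshold, low_expr_fraction
        A gene is removed when its value is strictly below the threshold in at
        least ``ceil(low_expr_fraction * n_samples)`` samples.
    mad_min
        Genes with unscaled MAD strictly below this are removed.

    Returns
    -------
    (filtered matrix, FilterReport)
    """
    missing = expr.index.difference(annot.index)
    if len(missing) > 0:
        raise ConfigurationError(
            f"annotation does not cover {len(missing)} gene(s), e.g. {missing[0]!r}"
        )
    if not 0 < low_expr_fraction <= 1:
        raise ConfigurationError("low_expr_fraction must be in (0, 1]")

    n_samples = expr.shape[1]
    ann = annot.loc[expr.index]
    is_control = ann["is_control_probe"].to_numpy(dtype=bool)
    symbol = ann["symbol"]
    unannotated = symbol.isna().to_numpy() | (symbol.astype(str).str.strip() == "").to_numpy()

    values = expr.to_numpy(dtype=float)
    n_low = (values < low_expr_threshold).sum(axis=1)
    low_expressed = n_low >= math.ceil(low_expr_fraction * n_samples)
    low_mad = unscaled_mad(values, axis=1) < mad_min

    report = FilterReport(
        n_input=expr.shape[0],
        params={
            "low_expr_threshold": low_expr_threshold,
            "low_expr_fraction": low_expr_fraction,
            "mad_min": mad_min,
        },
    )
    keep = np.ones(expr.shape[0], dtype=bool)

    for mask, attr in (
        (is_control, "n_control_removed"),
        (unannotated, "n_unannotated_removed"),
        (low_expressed, "n_low_expression_removed"),
        (low_mad, "n_low_mad_removed"),
    ):
        removed_now = keep & mask
        setattr(report, attr, int(removed_now.sum()))
        keep &= ~mask

    report.n_kept = int(keep.sum())
    if report.n_kept == 0:
        raise EmptyResultError("no probesets passed the filters")
    return expr.loc[keep], report
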