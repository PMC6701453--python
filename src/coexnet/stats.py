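"""Module- and gene-level statistics.

Covers the four statistical work-horses of the pipeline: Pearson trait
correlation under the drinker-only convention (samples with a missing
phenotype are dropped, never zero-filled, so treated-only phenotypes use
treated samples alone), empirical-Bayes moderated two-group t-tests,
hypergeometric gene-set overlap, and permutation validation of module
topological overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DegenerateInputError, UndefinedCorrelationError
from .network import Network

__all__ = [
    "correlate_with_trait",
    "pearson_with_p",
    "moderated_t_test",
    "bh_fdr",
    "OverlapResult",
    "hypergeometric_overlap",
    "permutation_module_validation",
    "membership_significance_validation",
]


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pearson r of two vectors with the exact two-sided t-based p-value.

    Pairs with a missing value in either vector are dropped. Returns
    ``(r, p, n_used)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        raise UndefinedCorrelationError(
            f"only {n} usable sample(s); need at least 3"
        )
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("zero variance in one of the vectors")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p), n


def correlate_with_trait(
    profiles: pd.DataFrame,
    info: pd.DataFrame,
    phenotype: str,
    drop_missing: bool = True,
) -> pd.DataFrame:
    """Correlate each row profile (gene or module eigengene) with a phenotype.

    Samples with a missing phenotype are excluded from the correlation --
    controls of a treated-only phenotype therefore never enter as zeros, and
    ``n_used`` reports the count actually correlated.
    """
    if phenotype not in info.columns:
        raise ConfigurationError(f"phenotype {phenotype!r} not in sample table")
    if not drop_missing and info[phenotype].isna().any():
        raise UndefinedCorrelationError(
            f"phenotype {phenotype!r} has missing values and drop_missing is off"
        )
    common = [s for s in profiles.columns if s in info.index]
    if len(common) < 3:
        raise ConfigurationError("profiles and sample table share fewer than 3 samples")
    trait = info.loc[common, phenotype].to_numpy(dtype=float)
    rows = []
    for entity, profile in profiles[common].iterrows():
        r, p, n = pearson_with_p(profile.to_numpy(dtype=float), trait)
        rows.append(
            {"entity_id": entity, "phenotype": phenotype, "r": r, "p": p, "n_used": n}
        )
    return pd.DataFrame(rows)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match the scaled inverse-chi-square prior on gene variances.

    Works on log variances: with z = log(s^2), E z = log(s0^2) + psi(d0/2) -
    log(d0/2) + ... and Var z = psi'(df/2) + psi'(d0/2). Returns
    ``(prior_df d0, prior variance s0^2)``; d0 = inf when the observed spread
    of log-variances is no larger than expected from chi-square noise alone.
    """
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    n = e.size
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1)) - special.polygamma(1, df / 2.0)
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    half_d0 = _trigamma_inverse(e_var)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0_sq


def moderated_t_test(
    expr: pd.DataFrame,
    info: pd.DataFrame,
    alpha: float = 0.01,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Two-group (treated vs control) moderated t-test per gene.

    Gene-wise residual variances are shrunk toward a common prior variance
    estimated by moment matching under a scaled inverse-chi-square model, and
    the moderated t is referenced to a t distribution with ``d0 + d`` degrees
    of freedom. ``prior_df`` overrides the estimated d0 (0 recovers the
    ordinary equal-variance t; ``inf`` pins every variance at the prior).

    Returns a frame with log_ratio (treated - control mean), t, p, q
    (Benjamini-Hochberg) and a ``significant`` flag at ``q <= alpha``.
    """
    common = [s for s in expr.columns if s in info.index]
    groups = info.loc[common, "group"]
    treated = [s for s in common if groups[s] == "treated"]
    control = [s for s in common if groups[s] == "control"]
    n1, n2 = len(treated), len(control)
    if n1 < 2 or n2 < 2:
        raise DegenerateInputError(
            f"need >= 2 samples per group, got treated={n1}, control={n2}"
        )
    df_resid = n1 + n2 - 2
    xt = expr[treated].to_numpy(dtype=float)
    xc = expr[control].to_numpy(dtype=float)
    diff = xt.mean(axis=1) - xc.mean(axis=1)
    ss = ((xt - xt.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (xc - xc.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid
    if np.all(s2 == 0):
        raise DegenerateInputError("all genes have zero residual variance")

    if prior_df is None:
        d0, s0_sq = _fit_variance_prior(s2[s2 > 0], df_resid)
    else:
        d0 = float(prior_df)
        _, s0_sq = _fit_variance_prior(s2[s2 > 0], df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = df_resid
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    q = bh_fdr(p)
    return pd.DataFrame(
        {
            "gene_id": expr.index,
            "log_ratio": diff,
            "t": t,
            "p": p,
            "q": q,
            "significant": q <= alpha,
        }
    ).set_index("gene_id")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ConfigurationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric upper-tail overlap between two gene sets."""

    n_a: int
    n_b: int
    n_universe: int
    n_overlap: int
    p: float


def hypergeometric_overlap(set_a, set_b, universe) -> OverlapResult:
    """Upper-tail P(X >= overlap) of drawing |B| genes from the universe."""
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ConfigurationError("both sets must be contained in the universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, len(u), len(a), len(b)))
    return OverlapResult(
        n_a=len(a), n_b=len(b), n_universe=len(u), n_overlap=k, p=min(p, 1.0)
    )


def permutation_module_validation(
    net: Network,
    assignment: pd.Series,
    n_perm: int = 100,
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Compare each module's mean TOM against random gene sets of equal size.

    The statistic is the mean off-diagonal TOM within the module; the null
    draws ``n_perm`` uniform random same-size gene sets without replacement
    from the analyzed universe. The empirical p uses the add-one convention
    ``(1 + #{null >= observed}) / (n_perm + 1)`` and is therefore never 0.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = assignment.to_numpy()
    order = {g: i for i, g in enumerate(net.gene_ids)}
    idx_of = np.array([order[g] for g in assignment.index])
    tom = net.tom
    n = net.n_genes

    def mean_tom(members: np.ndarray) -> float:
        sub = tom[np.ix_(members, members)]
        m = len(members)
        return float((sub.sum() - np.trace(sub)) / (m * (m - 1)))

    rows = []
    for label in sorted(l for l in np.unique(labels) if l != 0):
        members = idx_of[labels == label]
        if len(members) < 2:
            raise DegenerateInputError(f"module {label} has fewer than 2 genes")
        observed = mean_tom(members)
        # sorted draws make a draw equal to the module (or the whole
        # universe) reproduce the observed statistic bit-for-bit
        null = np.array(
            [
                mean_tom(np.sort(rng.choice(n, size=len(members), replace=False)))
                for _ in range(n_perm)
            ]
        )
        p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
        rows.append(
            {
                "module": label,
                "size": len(members),
                "observed_mean_tom": observed,
                "null_mean_tom": float(null.mean()),
                "empirical_p": p,
            }
        )
    return pd.DataFrame(rows)


def membership_significance_validation(
    membership: pd.Series, gene_significance: pd.Series
) -> tuple[float, float]:
    """Correlate membership strength with gene significance across a module.

    Both series must be indexed by the module's genes; the caller picks the
    figure variant (kME vs trait correlation, or -log10 membership p vs
    -log10 DE p). Returns ``(r, p)``.
    """
    common = membership.index.intersection(gene_significance.index)
    if len(common) < 3:
        raise DegenerateInputError(
            f"module has {len(common)} gene(s); need at least 3"
        )
    r, p, _ = pearson_with_p(
        membership.loc[common].to_numpy(dtype=float),
        gene_significance.loc[common].to_numpy(dtype=float),
    )
    return r, p
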