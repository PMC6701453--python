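"""Two-species synthetic expression studies with planted ground truth.

The generator emulates the structure of a paired chronic-ethanol microarray
study -- a primate-analogue species A (default 32 treated drinkers, 11
controls) and a rodent-analogue species B (default 23 treated, 24 controls)
-- through a per-module factor model. For each planted module ``m`` and
sample ``j``, a latent factor ``f_mj ~ N(0, 1)`` drives member genes:

    x_gj = base_g + lambda_g * f_mj + de-shift + eps,  eps ~ N(0, noise_sd^2)

with loadings ``lambda_g`` drawn uniformly from ``within_module_loading_range``
(planted hubs get the range maximum, making the scaled-connectivity ground
truth unambiguous). Background genes are baseline plus noise. A continuous
intake trait is defined for treated samples only -- controls carry missing
values, never zeros -- as ``sum_m trait_loading_m * f_m + N(0, 1)``. Modules
with nonzero ``de_effect`` shift their member genes by ``de_effect *
noise_sd`` in treated samples. Modules flagged shared are planted in both
species with the same loading template over homologous partner genes; the
1:1 homolog map covers ``homolog_fraction`` of each species' genes and always
contains the shared-module genes.

Everything is drawn from one seeded `numpy` Generator per call, so a config
plus seed pins the outputs byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["SimConfig", "SimTruth", "generate_study", "annotation_for"]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic two-species experiment.

    Defaults mirror the chronic-ethanol study design this generator emulates:
    sample sizes of 32/11 (species A treated/control) and 23/24 (species B),
    six planted modules spanning a desk-scale version of the observed module
    size range, roughly half of them shared across species, trait-coupled
    modules disjoint from differential-expression modules, and a homolog map
    covering ~70% of genes.
    """

    seed: int = 0
    n_genes_per_species: int = 2000
    module_sizes: tuple[int, ...] = (30, 50, 80, 120, 250, 400)
    shared_module_flags: tuple[bool, ...] = (True, False, True, False, True, False)
    n_treated_a: int = 32
    n_control_a: int = 11
    n_treated_b: int = 23
    n_control_b: int = 24
    trait_loading: tuple[float, ...] = (0.8, 0.4, 0.0, 0.0, 0.0, 0.0)
    de_effect: tuple[float, ...] = (0.0, 0.0, 2.5, 0.0, 1.2, 0.0)
    emergent_hub_flags: tuple[bool, ...] | None = None
    hub_fraction: float = 0.1
    within_module_loading_range: tuple[float, float] = (0.7, 1.0)
    noise_sd: float = 0.6
    homolog_fraction: float = 0.7
    baseline_range: tuple[float, float] = (4.0, 12.0)
    baseline_species_jitter_sd: float = 0.3

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def validate(self) -> None:
        k = self.n_modules
        if sum(self.module_sizes) > self.n_genes_per_species:
            raise ConfigurationError("sum of module sizes exceeds n_genes_per_species")
        if any(s < 1 for s in self.module_sizes):
            raise ConfigurationError("module sizes must be >= 1")
        for name in ("shared_module_flags", "trait_loading", "de_effect"):
            if len(getattr(self, name)) != k:
                raise ConfigurationError(f"{name} must have one entry per module")
        if self.emergent_hub_flags is not None and len(self.emergent_hub_flags) != k:
            raise ConfigurationError("emergent_hub_flags must have one entry per module")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if not 0 <= self.hub_fraction <= 1:
            raise ConfigurationError("hub_fraction must be in [0, 1]")
        if not 0 < self.homolog_fraction <= 1:
            raise ConfigurationError("homolog_fraction must be in (0, 1]")
        lo, hi = self.within_module_loading_range
        if lo > hi:
            raise ConfigurationError("within_module_loading_range must be (lo, hi)")
        for n in (self.n_treated_a, self.n_control_a, self.n_treated_b, self.n_control_b):
            if n < 0:
                raise ConfigurationError("sample counts must be non-negative")
        n_mapped = int(np.floor(self.homolog_fraction * self.n_genes_per_species))
        shared_genes = sum(
            s for s, f in zip(self.module_sizes, self.shared_module_flags) if f
        )
        if shared_genes > n_mapped:
            raise ConfigurationError(
                "homolog_fraction too small to map all shared-module genes"
            )


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside the generated matrices."""

    module_of_gene: pd.Series  # gene -> planted label, 0 = background
    hub_flags: pd.Series
    de_flags: pd.Series
    emergent_hub_flags: pd.Series
    trait_values: pd.Series  # sample -> intake; NaN for controls
    homolog_pairs: pd.DataFrame  # columns species_a, species_b
    config: dict = field(default_factory=dict)


def _gene_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(n)]


def _sample_table(prefix: str, species: str, n_treated: int, n_control: int,
                  trait: np.ndarray) -> pd.DataFrame:
    ids = [f"{prefix}_t{i:03d}" for i in range(n_treated)] + [
        f"{prefix}_c{i:03d}" for i in range(n_control)
    ]
    group = ["treated"] * n_treated + ["control"] * n_control
    intake = np.concatenate([trait, np.full(n_control, np.nan)])
    return pd.DataFrame(
        {"species": species, "group": group, "ethanol_intake": intake}, index=ids
    )


def _simulate_species(
    rng: np.random.Generator,
    cfg: SimConfig,
    gene_ids: list[str],
    module_present: list[bool],
    loading_templates: list[np.ndarray | None],
    n_treated: int,
    n_control: int,
    baseline_common: np.ndarray,
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """One species' matrix; returns (expr, trait, per-gene truth arrays)."""
    n_genes = cfg.n_genes_per_species
    n_samples = n_treated + n_control
    lo, hi = cfg.within_module_loading_range

    module_of = np.zeros(n_genes, dtype=int)
    hub = np.zeros(n_genes, dtype=bool)
    de = np.zeros(n_genes, dtype=bool)
    emergent = np.zeros(n_genes, dtype=bool)

    # baselines are conserved across species up to a jitter, so homologous
    # genes keep correlated expression ranks (orthologs tend to preserve
    # absolute expression level)
    baseline = baseline_common + rng.normal(
        0.0, cfg.baseline_species_jitter_sd, size=n_genes
    )
    x = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(n_genes, n_samples))
    treated_cols = np.arange(n_treated)
    control_cols = np.arange(n_treated, n_samples)
    trait = rng.normal(0.0, 1.0, size=n_treated)
    emergent_flags = cfg.emergent_hub_flags or (False,) * cfg.n_modules

    start = 0
    for m, size in enumerate(cfg.module_sizes):
        members = np.arange(start, start + size)
        start += size
        # factors are drawn even for absent modules to keep the random
        # stream layout identical across shared/private configurations
        factor = rng.normal(0.0, 1.0, size=n_samples)
        template = loading_templates[m]
        if template is None:
            template = rng.uniform(lo, hi, size=size)
            n_hubs = int(np.ceil(cfg.hub_fraction * size)) if cfg.hub_fraction > 0 else 0
            template[:n_hubs] = hi
            loading_templates[m] = template
        if not module_present[m]:
            continue
        module_of[members] = m + 1
        n_hubs = int(np.ceil(cfg.hub_fraction * size)) if cfg.hub_fraction > 0 else 0
        hub[members[:n_hubs]] = True
        x[members] += np.outer(template, factor)
        if emergent_flags[m]:
            g = members[-1]  # last member: loading 0 in controls, max in treated
            x[g] -= template[-1] * factor  # undo the uniform loading
            x[g, treated_cols] += hi * factor[treated_cols]
            emergent[g] = True
            hub[g] = False
        if cfg.de_effect[m] != 0.0:
            x[np.ix_(members, treated_cols)] += cfg.de_effect[m] * cfg.noise_sd
            de[members] = True
        trait += cfg.trait_loading[m] * factor[treated_cols]

    expr = pd.DataFrame(x, index=gene_ids)
    truth = {"module_of": module_of, "hub": hub, "de": de, "emergent": emergent}
    return expr, trait, truth


def generate_study(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate the two-species study.

    Returns ``(expr_a, expr_b, info_a, info_b, truth)``: genes x samples
    expression matrices, sample tables with the treated-only intake
    phenotype, and the planted truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes_per_species
    genes_a = _gene_ids("gA", n)
    genes_b = _gene_ids("gB", n)

    present_a = [True] * config.n_modules
    present_b = list(config.shared_module_flags)
    templates: list[np.ndarray | None] = [None] * config.n_modules
    baseline_common = rng.uniform(*config.baseline_range, size=n)

    expr_a, trait_a, truth_a = _simulate_species(
        rng, config, genes_a, present_a, templates,
        config.n_treated_a, config.n_control_a, baseline_common,
    )
    # shared modules reuse species A's loading template; private slots are
    # reset so species B would draw fresh ones (it skips absent modules)
    templates_b = [
        t if flag else None for t, flag in zip(templates, config.shared_module_flags)
    ]
    expr_b, trait_b, truth_b = _simulate_species(
        rng, config, genes_b, present_b, templates_b,
        config.n_treated_b, config.n_control_b, baseline_common,
    )

    info_a = _sample_table("A", "species_a", config.n_treated_a,
                           config.n_control_a, trait_a)
    info_b = _sample_table("B", "species_b", config.n_treated_b,
                           config.n_control_b, trait_b)
    expr_a.columns = info_a.index
    expr_b.columns = info_b.index

    # homolog map: gene i of A pairs with gene i of B; shared-module genes
    # are always mapped, the remainder filled by a random draw
    n_mapped = int(np.floor(config.homolog_fraction * n))
    must_map = np.flatnonzero(
        np.isin(
            truth_a["module_of"],
            [m + 1 for m, f in enumerate(config.shared_module_flags) if f],
        )
    )
    rest = np.setdiff1d(np.arange(n), must_map)
    extra = rng.choice(rest, size=n_mapped - len(must_map), replace=False)
    mapped = np.sort(np.concatenate([must_map, extra]))
    homolog_pairs = pd.DataFrame(
        {
            "species_a": [genes_a[i] for i in mapped],
            "species_b": [genes_b[i] for i in mapped],
        }
    )

    index = pd.Index(genes_a + genes_b, name="gene_id")
    truth = SimTruth(
        module_of_gene=pd.Series(
            np.concatenate([truth_a["module_of"], truth_b["module_of"]]),
            index=index, name="planted_module",
        ),
        hub_flags=pd.Series(
            np.concatenate([truth_a["hub"], truth_b["hub"]]), index=index,
            name="is_hub",
        ),
        de_flags=pd.Series(
            np.concatenate([truth_a["de"], truth_b["de"]]), index=index,
            name="is_de",
        ),
        emergent_hub_flags=pd.Series(
            np.concatenate([truth_a["emergent"], truth_b["emergent"]]),
            index=index, name="is_emergent_hub",
        ),
        trait_values=pd.concat(
            [info_a["ethanol_intake"], info_b["ethanol_intake"]]
        ).rename("ethanol_intake"),
        homolog_pairs=homolog_pairs,
        config=asdict(config),
    )
    return expr_a, expr_b, info_a, info_b, truth


def annotation_for(expr: pd.DataFrame) -> pd.DataFrame:
    """Trivial annotation for generated matrices (symbol = gene id)."""
    return pd.DataFrame(
        {"symbol": expr.index, "is_control_probe": False}, index=expr.index
    )
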