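"""Run configuration: every tunable of the pipeline with its default.

Defaults are the standard parameterization of the analysis: probeset filters
at 3.5 / 80% / 0.065, soft-threshold power 6 for single-species networks and
8 for the consensus run, deep split 3, minimum module size 30, eigengene
merge cut 0.2 (consensus pathway), 100 permutations, DE alpha 0.01. A config
file (YAML) can override any field and command-line flags win over the file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from .errors import ConfigurationError


@dataclass
class RunConfig:
    seed: int = 0
    low_expr_threshold: float = 3.5
    low_expr_fraction: float = 0.8
    mad_min: float = 0.065
    power_single: float = 6.0
    power_consensus: float = 8.0
    deep_split: int = 3
    min_module_size: int = 30
    merge_cut: float = 0.2
    n_perm: int = 100
    de_alpha: float = 0.01
    scale_quantile: float = 0.95
    phenotype: str = "ethanol_intake"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def load(cls, path: str | None = None, **overrides) -> "RunConfig":
        """Build a config from an optional YAML file plus keyword overrides.

        Overrides with value ``None`` are ignored (unset flags).
        """
        values: dict = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
            if not isinstance(data, dict):
                raise ConfigurationError(f"{path}: config must be a mapping")
            known = {f.name for f in fields(cls)}
            unknown = set(data) - known
            if unknown:
                raise ConfigurationError(
                    f"{path}: unknown config key(s): {sorted(unknown)}"
                )
            values.update(data)
        values.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**values)
        if cfg.deep_split not in (0, 1, 2, 3):
            raise ConfigurationError("deep_split must be in {0,1,2,3}")
        if cfg.n_perm < 1:
            raise ConfigurationError("n_perm must be >= 1")
        return cfg
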