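"""Declarative run configuration for the pipeline.

A single YAML file drives every stage; the three study scenarios differ
only in set membership, so a scenario is a config value, not a code
path.  Defaults give a desk-scale population that runs end to end in
minutes.
"""

from __future__ import annotations

import copy
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from heatgp.errors import ConfigError
from heatgp.predict import McmcConfig, MixtureSpec
from heatgp.prioritize import SelectionConfig

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "scenario": 1,
    "simulate": {
        "n_discovery_cows": 2000,
        "n_reference_bulls": 400,
        "daughters_per_bull": 50,
        "n_validation_cows": 400,
        "map_config": {
            "n_chrom": 5,
            "chrom_length_bp": 10_000_000,
            "n_array_snps": 3000,
            "n_sequence_snps": 30_000,
        },
        "fst": 0.1,
        "mixture_proportions": [0.99, 0.006, 0.003, 0.001],
        "h2_slope": 0.25,
        "h2_intercept": 0.35,
        "genetic_variance_slope": 0.25,
        "genetic_variance_intercept": 1.0,
        "traits": ["milk", "fat", "protein"],
        "validation_breeds": {},
    },
    "climate": {"thi_min": 40.0, "thi_max": 85.0, "threshold": 60.0},
    "phenotypes": {"min_records": 4},
    "thresholds": {"maf": 0.005},
    "selection": {
        "window_bp": 100_000,
        "step_bp": 50_000,
        "neg_log10_thresholds": [2.0, 3.0],
        "ld_r2_max": 0.95,
        "ld_window_snps": 50,
        "ld_step_snps": 5,
    },
    # desk-scale MCMC; the model's reference configuration is 5 chains of
    # 40,000 iterations with 20,000 burn-in (see docs/methods.md)
    "mcmc": {"n_chains": 2, "n_iter": 3000, "burn_in": 1500, "thin": 10},
    "prediction": {
        "c": 0.2,
        "weight_records": True,
        "topsnp_threshold": 3.0,
        "topsnp_source": "single_trait",
        "gblup": True,
    },
    "validation": {"lr_partial_fraction": 0.5},
}


def _deep_update(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    raw: dict

    @classmethod
    def default(cls, **overrides) -> "RunConfig":
        return cls(_deep_update(DEFAULT_CONFIG, overrides))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        cfg = cls(_deep_update(DEFAULT_CONFIG, user))
        cfg.validate()
        return cfg

    def __getitem__(self, key):
        return self.raw[key]

    def validate(self) -> None:
        """Fail fast on invalid settings, before any compute."""
        self.mcmc()          # raises on burn_in >= n_iter etc.
        self.selection()
        if self.raw["scenario"] not in (1, 2, 3):
            raise ConfigError(f"scenario must be 1, 2 or 3, got {self.raw['scenario']}")
        maf = self.raw["thresholds"]["maf"]
        if not 0 <= maf < 0.5:
            raise ConfigError(f"MAF threshold must be in [0, 0.5), got {maf}")

    def mcmc(self, seed: int | None = None) -> McmcConfig:
        m = self.raw["mcmc"]
        return McmcConfig(n_chains=m["n_chains"], n_iter=m["n_iter"],
                          burn_in=m["burn_in"], thin=m.get("thin", 10),
                          seed=self.raw["seed"] if seed is None else seed)

    def selection(self, threshold: float | None = None) -> SelectionConfig:
        s = self.raw["selection"]
        return SelectionConfig(
            window_bp=s["window_bp"], step_bp=s["step_bp"],
            neg_log10_threshold=threshold if threshold is not None
            else s["neg_log10_thresholds"][-1],
            ld_r2_max=s["ld_r2_max"], ld_window_snps=s["ld_window_snps"],
            ld_step_snps=s["ld_step_snps"], maf_min=self.raw["thresholds"]["maf"])

    def mixture(self) -> MixtureSpec:
        return MixtureSpec()

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.raw, fh, sort_keys=True)
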