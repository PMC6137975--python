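"""Run and simulation configuration objects.

All configs are frozen dataclasses validated on construction; ``from_yaml``
/ ``to_yaml`` round-trip them for provenance copies written next to run
outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

PROBE_CATEGORIES = ("BODY", "PROMOTER", "TE", "BODY+TE", "PROM+TE", "INTERGENIC")


class ConfigError(ValueError):
    """Raised when a configuration fails validation."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic MeDIP-chip experiment.

    Signal values are dimensionless normalized log-type intensities drawn
    from a two-component Gaussian mixture; ``p_high`` is the per-probe
    probability of the high (methylated) component, so the low-component
    weight is ``1 - p_high``.
    """

    n_chromosomes: int = 3
    chromosome_length: int = 2_000_000
    window_size: int = 50_000
    n_genes: int = 300
    te_fraction: float = 0.1
    mu_low: float = -1.0
    sigma_low: float = 0.4
    mu_high: float = 1.0
    sigma_high: float = 0.4
    p_high: float = 0.65
    dmr_fraction: float = 0.1
    p_hyper: float = 0.7
    delta: float = 4.0
    n_replicates: int = 5
    sigma_rep: float = 0.3
    gene_body_length: int = 2_000
    flank_length: int = 500
    background_probes_per_window: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_chromosomes > 0, "n_chromosomes must be > 0")
        _require(self.chromosome_length > 0, "chromosome_length must be > 0")
        _require(self.window_size > 0, "window_size must be > 0")
        _require(self.n_genes >= 0, "n_genes must be >= 0")
        for name in ("te_fraction", "p_high", "dmr_fraction", "p_hyper"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, f"{name} must be in [0, 1], got {v}")
        _require(self.sigma_low > 0 and self.sigma_high > 0, "mixture sigmas must be > 0")
        _require(self.mu_low < self.mu_high, "mu_low must be < mu_high")
        _require(self.n_replicates >= 1, "n_replicates must be >= 1")
        _require(self.sigma_rep > 0, "sigma_rep must be > 0")
        _require(self.gene_body_length > 0 and self.flank_length > 0, "gene geometry must be > 0")
        _require(self.background_probes_per_window >= 0, "background_probes_per_window must be >= 0")

    @property
    def lambda_low(self) -> float:
        return 1.0 - self.p_high

    @property
    def mixture(self) -> tuple[float, float, float, float, float]:
        """(lambda_low, mu_low, sigma_low, mu_high, sigma_high)."""
        return (self.lambda_low, self.mu_low, self.sigma_low, self.mu_high, self.sigma_high)

    @property
    def n_windows(self) -> int:
        per_chrom = -(-self.chromosome_length // self.window_size)  # ceil div
        return self.n_chromosomes * per_chrom


@dataclass(frozen=True)
class HplcSimConfig:
    """Parameters of the synthetic nucleoside-quantification experiment."""

    n_genotypes: int = 8
    conditions: tuple[str, ...] = ("favorable", "unfavorable")
    base_mC: float = 30.0
    genotype_sd: float = 2.0
    env_effect: float = 1.5
    gxe_sd: float = 1.0
    noise_sd: float = 0.5
    technical_sd: float = 0.2
    biomass_r_favorable: float = 0.8
    biomass_r_unfavorable: float = -0.8
    n_individuals: int = 4
    n_hydrolysis: int = 2
    n_runs: int = 2
    total_nucleoside: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_genotypes >= 1, "n_genotypes must be >= 1")
        _require(len(self.conditions) >= 1, "at least one condition label required")
        _require(len(set(self.conditions)) == len(self.conditions), "condition labels must be unique")
        _require(0.0 <= self.base_mC <= 100.0, "base_mC must be a percentage in [0, 100]")
        for name in ("genotype_sd", "gxe_sd", "noise_sd", "technical_sd"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(0.0 < self.biomass_r_favorable <= 1.0,
                 "biomass_r_favorable must be in (0, 1]")
        _require(-1.0 <= self.biomass_r_unfavorable < 0.0,
                 "biomass_r_unfavorable must be in [-1, 0)")
        for name in ("n_individuals", "n_hydrolysis", "n_runs"):
            _require(getattr(self, name) >= 1, f"{name} must be >= 1")
        _require(self.total_nucleoside > 0, "total_nucleoside must be > 0")


@dataclass(frozen=True)
class RunConfig:
    """Analysis-stage parameters shared by the CLI subcommands."""

    window_size: int = 50_000
    ref_fraction: float = 0.2
    alpha: float = 0.05
    fdr_method: str = "bh"
    min_probes_per_window: int = 3
    seed: int = 0
    condition_favorable: str = "favorable"
    condition_unfavorable: str = "unfavorable"
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require(0.0 < self.ref_fraction < 1.0, "ref_fraction must be in (0, 1)")
        _require(0.0 < self.alpha < 1.0, "alpha must be in (0, 1)")
        _require(self.window_size >= 1000, "window_size must be >= 1000 bp")
        _require(self.fdr_method in ("bh", "local"), "fdr_method must be 'bh' or 'local'")
        _require(self.min_probes_per_window >= 1, "min_probes_per_window must be >= 1")


_CONFIG_TYPES = {"run": RunConfig, "sim": SimConfig, "hplc_sim": HplcSimConfig}


def load_config(path: str | Path, kind: str = "run"):
    """Load a config of the given kind ('run', 'sim', 'hplc_sim') from YAML."""
    cls = _CONFIG_TYPES[kind]
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a YAML mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown {kind} config keys {sorted(unknown)}")
    if "conditions" in raw and isinstance(raw["conditions"], list):
        raw["conditions"] = tuple(raw["conditions"])
    return cls(**raw)


def dump_config(config, path: str | Path) -> None:
    """Write a resolved copy of ``config`` as YAML (provenance record)."""
    data = dataclasses.asdict(config)
    for key, value in data.items():
        if isinstance(value, tuple):
            data[key] = list(value)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
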