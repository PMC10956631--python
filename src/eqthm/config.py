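"""Configuration objects for the synthetic generator and the pipeline.

Defaults encode the study conditions the analysis emulates: a right-skewed
5hmC landscape with a low grand mean and a small "systematic" subset with
clearly elevated hydroxymethylation, assayed in a couple of hundred placental
samples, with cis effects of 5hmC (on the M-value scale) on gene expression.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml


class ConfigError(ValueError):
    """Raised when a configuration is internally inconsistent or infeasible."""


@dataclass
class SynthConfig:
    """Parameters of the synthetic EPIC-like BS/oxBS + expression dataset.

    Proportions are on the beta-value scale in [0, 1]; positions are 1-based
    base pairs on a single synthetic autosome.
    """

    n_samples: int = 200
    n_genes: int = 100
    n_cpgs: int = 2000
    chrom_length: int = 20_000_000
    seed: int = 0

    # 5hmC landscape
    frac_systematic: float = 0.068
    base_hmc_mean: float = 0.03
    systematic_hmc_mean: float = 0.15
    hmc_mean_concentration: float = 6.0
    hmc_sample_concentration: float = 30.0
    noise_sd: float = 0.02

    # planted cis effects
    n_true_eqthm: int = 15
    effect_beta1: float = 0.8
    n_true_dhmr: int = 2
    dhmr_span_cpgs: int = 5
    dhmr_factor_effect: float = 0.9
    dhmr_cpg_spacing: int = 150

    # expression + confounding
    expr_noise_sd: float = 1.0
    cov_h_strength: float = 0.10
    cov_expr_strength: float = 0.35

    chrom: str = "chr1S"

    def validate(self) -> None:
        for name in ("n_samples", "n_genes", "n_cpgs", "chrom_length",
                     "dhmr_span_cpgs", "dhmr_cpg_spacing"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("n_true_eqthm", "n_true_dhmr"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("frac_systematic", "base_hmc_mean", "systematic_hmc_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a proportion in [0,1], got {v}")
        if self.noise_sd < 0 or self.expr_noise_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        n_planted_cpgs = self.n_true_dhmr * self.dhmr_span_cpgs
        if n_planted_cpgs > self.n_cpgs:
            raise ConfigError(
                f"infeasible density: {self.n_true_dhmr} DHMRs x "
                f"{self.dhmr_span_cpgs} CpGs exceed n_cpgs={self.n_cpgs}")
        if self.n_true_eqthm + self.n_true_dhmr > self.n_genes:
            raise ConfigError(
                "infeasible density: more planted eQTHM/DHMR genes than genes")
        if self.n_cpgs < self.n_genes:
            raise ConfigError("need at least one CpG per gene (n_cpgs >= n_genes)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SynthConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters.

    Stage-parameter defaults are the values the analysis is defined by:
    systematic rule 5hmC >= 0.10 in at least 50% of samples, a 1 Mb cis
    window, 1,000 permutations, a 1e-4 corrected-p region seed threshold,
    regional alpha 0.05 and a >=3 CpG region rule.
    """

    synth: SynthConfig = field(default_factory=SynthConfig)
    out_dir: str = "results/pipeline"

    # preprocess
    tau: float = 0.10
    min_frac: float = 0.5
    m_value_eps: float = 1e-6

    # annotate / scan
    window: int = 1_000_000
    n_perm: int = 1000
    fdr_level: float = 0.05
    n_pcs: int = 5
    screen_alpha: float = 0.05

    # dhmr
    seed_thresh: float = 1e-4
    max_gap: int = 1000
    max_lag: int = 1000
    acf_bin_width: int = 250
    alpha: float = 0.05
    min_cpgs: int = 3

    # stage toggles
    run_simulate: bool = True
    run_preprocess: bool = True
    run_annotate: bool = True
    run_scan: bool = True
    run_dhmr: bool = True
    run_enrich: bool = True

    def validate(self) -> None:
        self.synth.validate()
        if not 0 < self.tau < 1:
            raise ConfigError("tau must be in (0,1)")
        if not 0 < self.min_frac <= 1:
            raise ConfigError("min_frac must be in (0,1]")
        if self.window <= 0 or self.n_perm < 2:
            raise ConfigError("window must be positive and n_perm >= 2")
        for name in ("fdr_level", "alpha", "seed_thresh", "screen_alpha"):
            if not 0 < getattr(self, name) < 1:
                raise ConfigError(f"{name} must be in (0,1)")
        if self.min_cpgs < 1 or self.max_gap <= 0 or self.max_lag <= 0:
            raise ConfigError("min_cpgs, max_gap, max_lag must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        synth = d.pop("synth", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        return cls(synth=SynthConfig.from_dict(synth), **d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
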