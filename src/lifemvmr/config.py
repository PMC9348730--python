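"""Scenario configuration for the lifecourse liability simulations.

A :class:`ScenarioConfig` is a complete parameterisation of one structural
scenario: the data-generating constants (SNP counts, liability effect
variances and correlations, structural path coefficients, confounding,
residual noise, cohort sizes) together with the estimation settings
(instrument-selection p-value threshold, number of repetitions, master seed,
whether Steiger filtering is applied).

Five named presets are bundled as YAML files and cover the structural
scenarios of the simulation study:

``two_liabilities``
    Two measured exposures driven by two distinct (correlated) liabilities.
``one_liability``
    Both measured exposures driven by the same single liability, so the
    genetic associations of the two exposures differ only by estimation
    noise (the conditionally-weak-instrument case).
``collider``
    Two liabilities plus a block of outcome-associated SNPs and a causal
    effect of the outcome on the later exposure, making the later exposure
    a collider.
``three_liabilities_correlated`` / ``three_liabilities_independent``
    Three liabilities of which only the first two exposure measurements are
    included in the estimation; the third-period genetic effects are either
    correlated with, or independent of, the included periods.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

from .errors import ConfigError

TWO_LIABILITIES = "two_liabilities"
ONE_LIABILITY = "one_liability"
COLLIDER = "collider"
THREE_CORRELATED = "three_liabilities_correlated"
THREE_INDEPENDENT = "three_liabilities_independent"

SCENARIOS = (
    TWO_LIABILITIES,
    ONE_LIABILITY,
    COLLIDER,
    THREE_CORRELATED,
    THREE_INDEPENDENT,
)

#: number of liabilities implied by each scenario
_N_LIABILITIES = {
    TWO_LIABILITIES: 2,
    ONE_LIABILITY: 1,
    COLLIDER: 2,
    THREE_CORRELATED: 3,
    THREE_INDEPENDENT: 3,
}

#: number of measured exposure time points per scenario
_N_EXPOSURES = {
    TWO_LIABILITIES: 2,
    ONE_LIABILITY: 2,
    COLLIDER: 2,
    THREE_CORRELATED: 3,
    THREE_INDEPENDENT: 3,
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete parameterisation of one structural scenario.

    Effect sizes are on the per-allele scale for SNP effects and unitless
    (standardised-ish trait scale) for structural path coefficients.
    """

    scenario_id: str
    # --- genetic architecture -------------------------------------------
    n_snps: int = 150
    n_outcome_snps: int = 0
    effect_variance_total: float = 0.1
    #: correlation matrix (rows = liabilities) of the per-SNP liability effects
    effect_corr: tuple = ((1.0, 0.25), (0.25, 1.0))
    maf_range: tuple = (0.05, 0.5)
    # --- structural path coefficients -----------------------------------
    beta1: float = 0.2
    beta2: float = 0.3
    beta3: float = 0.0
    gamma12: float = 0.1
    gamma23: float = 0.0
    delta_y2: float = 0.0
    # --- confounding and residual noise ---------------------------------
    confounder_corr: float = 0.8
    confounder_effect_x: float = 0.3
    confounder_effect_y: float = 0.3
    noise_sd_x: tuple = (0.935, 0.912)
    noise_sd_y: float = 0.7
    # --- cohorts and estimation settings --------------------------------
    n_exposure_sample: int = 150_000
    n_outcome_sample: int = 150_000
    n_reps: int = 2000
    seed: int = 2022
    p_threshold: float = 5e-8
    apply_steiger: bool = False

    # ------------------------------------------------------------------
    def __post_init__(self):
        object.__setattr__(self, "effect_corr",
                           tuple(tuple(float(v) for v in row) for row in self.effect_corr))
        object.__setattr__(self, "noise_sd_x", tuple(float(v) for v in self.noise_sd_x))
        object.__setattr__(self, "maf_range", tuple(float(v) for v in self.maf_range))
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_liabilities(self) -> int:
        return _N_LIABILITIES[self.scenario_id]

    @property
    def n_exposures(self) -> int:
        """Number of measured exposure time points (simulated)."""
        return _N_EXPOSURES[self.scenario_id]

    @property
    def exposure_names(self) -> tuple:
        return tuple(f"X{k + 1}" for k in range(self.n_exposures))

    @property
    def estimated_exposures(self) -> tuple:
        """Exposures included in the MR/MVMR estimation (always X1, X2)."""
        return ("X1", "X2")

    @property
    def betas(self) -> tuple:
        return (self.beta1, self.beta2, self.beta3)[: self.n_exposures]

    @property
    def total_snps(self) -> int:
        return self.n_snps + self.n_outcome_snps

    @property
    def effect_corr_matrix(self) -> np.ndarray:
        return np.asarray(self.effect_corr, dtype=float)

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.scenario_id not in SCENARIOS:
            raise ConfigError(f"unknown scenario_id {self.scenario_id!r}; "
                              f"expected one of {SCENARIOS}")
        if self.n_snps <= 0 or self.n_outcome_snps < 0:
            raise ConfigError("SNP counts must be positive (n_outcome_snps >= 0)")
        if min(self.n_exposure_sample, self.n_outcome_sample, self.n_reps) <= 0:
            raise ConfigError("sample sizes and n_reps must be strictly positive")
        if not (0.0 < self.p_threshold < 1.0) and self.p_threshold != 1.0:
            # p_threshold == 1.0 is allowed as the degenerate select-everything case
            raise ConfigError("p_threshold must lie in (0, 1]")
        R = self.effect_corr_matrix
        if R.shape != (self.n_liabilities, self.n_liabilities):
            raise ConfigError(
                f"effect_corr must be {self.n_liabilities}x{self.n_liabilities} "
                f"for scenario {self.scenario_id!r}, got {R.shape}")
        if not np.allclose(R, R.T):
            raise ConfigError("effect_corr must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise ConfigError("effect_corr must have unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ConfigError("effect_corr must be positive semi-definite")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < lo < hi <= 0.5")
        if len(self.noise_sd_x) != self.n_exposures:
            raise ConfigError(
                f"noise_sd_x must have one entry per exposure "
                f"({self.n_exposures}), got {len(self.noise_sd_x)}")
        if any(sd < 0 for sd in self.noise_sd_x) or self.noise_sd_y < 0:
            raise ConfigError("residual standard deviations must be non-negative")
        if not -1.0 <= self.confounder_corr <= 1.0:
            raise ConfigError("confounder_corr must lie in [-1, 1]")
        if self.scenario_id == COLLIDER:
            if self.n_outcome_snps <= 0:
                raise ConfigError("collider scenario requires n_outcome_snps > 0")
            if self.delta_y2 == 0:
                raise ConfigError("collider scenario requires delta_y2 != 0")
        else:
            if self.n_outcome_snps != 0:
                raise ConfigError("outcome-associated SNPs only exist in the "
                                  "collider scenario")
            if self.delta_y2 != 0:
                raise ConfigError("delta_y2 (Y -> X2) only applies to the "
                                  "collider scenario")

    # ------------------------------------------------------------------
    def scaled(self, n_reps: int | None = None, n_sample: int | None = None,
               **overrides) -> "ScenarioConfig":
        """Return a copy with rescaled repetitions / cohort sizes."""
        kw = dict(overrides)
        if n_reps is not None:
            kw["n_reps"] = int(n_reps)
        if n_sample is not None:
            kw["n_exposure_sample"] = int(n_sample)
            kw["n_outcome_sample"] = int(n_sample)
        return replace(self, **kw)

    # --- (de)serialisation ---------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["effect_corr"] = [list(row) for row in self.effect_corr]
        d["noise_sd_x"] = list(self.noise_sd_x)
        d["maf_range"] = list(self.maf_range)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError(f"configuration file {path} did not parse to a mapping")
        return cls.from_dict(d)


def preset(name: str, **overrides) -> ScenarioConfig:
    """Load one of the bundled scenario presets (optionally overriding fields)."""
    if name not in SCENARIOS:
        raise ConfigError(f"unknown preset {name!r}; expected one of {SCENARIOS}")
    ref = resources.files("lifemvmr").joinpath(f"presets/{name}.yaml")
    with resources.as_file(ref) as path:
        cfg = ScenarioConfig.from_yaml(path)
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg
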