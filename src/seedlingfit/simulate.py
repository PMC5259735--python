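"""Synthetic longitudinal and destructive-harvest data generators.

The generators emulate the study design the analysis assumes: four lines
(two parents, two reciprocal F1s), repeated non-destructive measurements
every other day up to day 12 on the same plants with AR1-correlated,
heteroskedastic Gaussian errors, and destructive harvests in which every
plant contributes a single observation.  Generating truth defaults to the
published best-model estimates (:mod:`seedlingfit.params`).

Noise defaults: the marginal error standard deviation on the final
measurement day equals 10% of the trait's final-day mean (averaged across
levels) and decreases toward earlier days through the exponential variance
function (delta = 0.2 per day); decay-trait harvests instead anchor the
scale at 10% of the mean initial plateau with per-harvest sd ratios.
Negative draws can optionally be truncated at zero (off by default: the
generator's purpose is data that exactly follow the fitted error model;
truncation is a realism option whose use is reported in the dataset).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import params as libparams
from .curves import family_info
from .data import Dataset
from .fitting import CovarianceSpec, build_plant_covariance
from .grouping import GroupingScheme, default_lines, make_scheme

__all__ = [
    "SimulationConfig",
    "default_config",
    "simulate_trajectories",
    "simulate_destructive",
    "simulate_seed_traits",
]

DEFAULT_STRATUM_RATIOS = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5)


@dataclass
class SimulationConfig:
    """Truth, design and noise for one simulated trait."""

    trait: str
    scheme: GroupingScheme
    truth: Mapping[str, object]          # level -> curve parameter dataclass
    family: str
    plants_per_line: int = 14
    days: Sequence[float] = libparams.MEASUREMENT_DAYS
    destructive: bool = False
    sigma: float | None = None           # None -> 10% anchor rule
    rho: float = 0.5
    variance: str = "exponential"        # constant | exponential | per_stratum
    delta: float = 0.2
    stratum_ratios: Mapping[float, float] | None = None
    truncate_at_zero: bool = False
    seed: int | None = None

    def __post_init__(self):
        days = tuple(float(d) for d in self.days)
        if len(days) < 1 or any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("days must be strictly increasing")
        self.days = days
        if self.plants_per_line < 1:
            raise ValueError("plants_per_line must be >= 1")
        if not -1 < self.rho < 1:
            raise ValueError("|rho| must be < 1")
        family_info(self.family)
        missing = [lv for lv in self.scheme.levels if lv not in self.truth]
        if missing:
            raise ValueError(f"truth missing levels {missing}")
        if self.variance == "per_stratum" and self.stratum_ratios is None:
            self.stratum_ratios = {
                d: DEFAULT_STRATUM_RATIOS[i % len(DEFAULT_STRATUM_RATIOS)]
                for i, d in enumerate(self.days)}

    @property
    def covariance(self) -> CovarianceSpec:
        corr = "independent" if self.destructive else "ar1"
        return CovarianceSpec(correlation=corr, variance=self.variance)

    def resolved_sigma(self) -> float:
        """The residual scale, applying the 10% anchor when unset."""
        if self.sigma is not None:
            return float(self.sigma)
        fam = family_info(self.family)
        last = self.days[-1]
        if self.family == "decay":
            # anchor on the initial plateau, where the signal is largest
            anchor = float(np.mean([self.truth[lv].maximum
                                    for lv in self.scheme.levels]))
            return 0.1 * anchor
        mean_last = float(np.mean(
            [fam.value(np.array([last]), *self.truth[lv].to_array())[0]
             for lv in self.scheme.levels]))
        target_sd = 0.1 * mean_last
        if self.variance == "exponential":
            return target_sd * math.exp(-self.delta * last)
        if self.variance == "per_stratum":
            return target_sd / float(self.stratum_ratios[last])
        return target_sd


def default_config(trait: str, *, plants_per_line: int = 14,
                   seed: int | None = None, **overrides) -> SimulationConfig:
    """Study-design configuration for a named trait with published truth
    under the maternal seed-size grouping."""
    if trait not in libparams.TRAIT_FAMILY:
        raise ValueError(f"unknown trait {trait!r}; expected one of "
                         f"{sorted(libparams.TRAIT_FAMILY)}")
    scheme = make_scheme("MAPHE", default_lines())
    family = libparams.TRAIT_FAMILY[trait]
    destructive = trait in libparams.DESTRUCTIVE_TRAITS
    variance = "per_stratum" if family == "decay" else "exponential"
    cfg = SimulationConfig(
        trait=trait, scheme=scheme, truth=dict(libparams.GROWTH_TRUTH[trait]),
        family=family, plants_per_line=plants_per_line,
        destructive=destructive, variance=variance, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


def _line_level(config: SimulationConfig, line_id: str) -> str:
    try:
        return config.scheme.level_of[line_id]
    except KeyError:
        raise ValueError(f"line {line_id!r} not mapped by scheme "
                         f"{config.scheme.name}") from None


def _mean_vector(config: SimulationConfig, level: str,
                 days: np.ndarray) -> np.ndarray:
    fam = family_info(config.family)
    return fam.value(days, *config.truth[level].to_array())


def _finalize(records: list, config: SimulationConfig,
              n_truncated: int) -> Dataset:
    df = pd.DataFrame(records,
                      columns=["plant_id", "line_id", "day", "trait",
                               "value"])
    ds = Dataset(df)
    ds.n_truncated = n_truncated
    return ds


def simulate_trajectories(config: SimulationConfig) -> Dataset:
    """Repeated measurements on the same plants with AR1 x variance-function
    Gaussian errors; reproducible from ``config.seed``."""
    if config.destructive:
        raise ValueError("config is destructive; use simulate_destructive")
    rng = np.random.default_rng(config.seed)
    days = np.asarray(config.days)
    sigma = config.resolved_sigma()
    cov_spec = config.covariance
    records = []
    n_trunc = 0
    chol_cache = {}
    for line in sorted(config.scheme.level_of):
        level = _line_level(config, line)
        mu = _mean_vector(config, level, days)
        if level not in chol_cache:
            V = build_plant_covariance(
                cov_spec, days, sigma=sigma, rho=config.rho,
                delta=config.delta, ratios=config.stratum_ratios)
            chol_cache[level] = np.linalg.cholesky(V)
        L = chol_cache[level]
        z = rng.standard_normal((config.plants_per_line, days.size))
        values = mu + z @ L.T
        if config.truncate_at_zero:
            neg = values < 0
            n_trunc += int(neg.sum())
            values = np.where(neg, 0.0, values)
        for i in range(config.plants_per_line):
            pid = f"{line}_p{i + 1}"
            for d, v in zip(days, values[i]):
                records.append((pid, line, float(d), config.trait, float(v)))
    return _finalize(records, config, n_trunc)


def simulate_destructive(config: SimulationConfig) -> Dataset:
    """Independent plants per harvest day (one observation per plant);
    ``plants_per_line`` is the number harvested per line per day."""
    if not config.destructive:
        raise ValueError("config is not destructive; "
                         "use simulate_trajectories")
    rng = np.random.default_rng(config.seed)
    days = np.asarray(config.days)
    sigma = config.resolved_sigma()
    if config.variance == "exponential":
        sds = sigma * np.exp(np.clip(config.delta * days, -350, 350))
    elif config.variance == "per_stratum":
        sds = sigma * np.array([config.stratum_ratios[d] for d in days])
    else:
        sds = np.full(days.size, sigma)
    records = []
    n_trunc = 0
    for line in sorted(config.scheme.level_of):
        level = _line_level(config, line)
        mu = _mean_vector(config, level, days)
        draws = mu + sds * rng.standard_normal(
            (config.plants_per_line, days.size))
        if config.truncate_at_zero:
            neg = draws < 0
            n_trunc += int(neg.sum())
            draws = np.where(neg, 0.0, draws)
        for j, d in enumerate(days):
            for i in range(config.plants_per_line):
                pid = f"{line}_d{int(d)}_p{i + 1}"
                records.append((pid, line, float(d), config.trait,
                                float(draws[i, j])))
    return _finalize(records, config, n_trunc)


def simulate_seed_traits(line: str, n: int, trait: str = "weight",
                         seed: int | None = None) -> pd.DataFrame:
    """Independent normal draws of a seed descriptor for one line.

    Means and pooled standard errors come from the published seed table
    (30-seed samples); the per-seed sd is SE * sqrt(30).
    """
    if n < 2:
        raise ValueError("need n >= 2 seeds")
    try:
        mean, se = libparams.SEED_TRAIT_TABLE[line][trait]
    except KeyError:
        raise ValueError(f"unknown line {line!r} or trait {trait!r}") \
            from None
    rng = np.random.default_rng(seed)
    sd = se * math.sqrt(libparams.SEED_TRAIT_N)
    values = rng.normal(mean, sd, size=n)
    return pd.DataFrame({"line": line, "trait": trait, "value": values})
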