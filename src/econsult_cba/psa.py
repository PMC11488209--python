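"""Probabilistic and one-way sensitivity analysis over the CBA model.

Input uncertainty is propagated by Monte Carlo: each named model input gets a
distribution (gamma for costs and counts, beta for proportions, point for
fixed values) calibrated by method of moments from a mean and SD. SD sources,
in order of precedence: an SD stated alongside the mean, an SD recovered from
a printed 95% CI as (hi - lo)/3.92, and otherwise the conventional 10%-of-
mean rule. Per-metric results are summarized by the mean over draws and
percentile 95% intervals.

Ratio metrics are reported as means of per-draw ratios. By Jensen's
inequality this exceeds the ratio of means whenever the cost varies, and it
is the estimator under which headline ROI/BCR figures in probabilistic
evaluations are usually quoted.

Each named quantity draws from its own seed-derived substream, so adding a
quantity to a spec never perturbs the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import DomainError

METRICS = ("total_cost", "total_benefit", "net_benefit", "bcr", "roi")

#: model: mapping of sampled input arrays -> (total_benefit, total_cost) arrays,
#: in dollars.
Model = Callable[[Mapping[str, np.ndarray]], tuple[np.ndarray, np.ndarray]]


@dataclass(frozen=True)
class DistributionSpec:
    """Distributional assumption for one model input."""

    family: str  # gamma | beta | point
    mean: float
    sd: float = 0.0
    source: str = "stated_sd"  # stated_sd | ci_derived | ten_percent_rule

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise DomainError("sd must be >= 0")
        if self.family == "gamma":
            if self.mean <= 0:
                raise DomainError("gamma requires mean > 0")
        elif self.family == "beta":
            if not 0 < self.mean < 1:
                raise DomainError("beta requires mean in (0, 1)")
            if self.sd**2 >= self.mean * (1 - self.mean):
                raise DomainError("beta requires sd^2 < mean(1-mean)")
        elif self.family == "point":
            if self.sd != 0:
                raise DomainError("point requires sd = 0")
        else:
            raise DomainError(f"unknown family {self.family!r}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "point" or self.sd == 0:
            return np.full(n, self.mean)
        if self.family == "gamma":
            shape, scale = gamma_from_moments(self.mean, self.sd)
            return rng.gamma(shape, scale, n)
        a, b = beta_from_moments(self.mean, self.sd)
        return rng.beta(a, b, n)


@dataclass(frozen=True)
class PsaSpec:
    quantity_specs: dict[str, DistributionSpec]
    n_draws: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise DomainError("n_draws must be >= 1")


@dataclass(frozen=True)
class PsaSummary:
    """Per-metric mean and percentile 95% CI, plus the raw draw table."""

    means: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    n_draws: int
    seed: int
    draws: pd.DataFrame = field(repr=False, compare=False, default=None)


def gamma_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Shape and scale matching the requested mean and SD exactly."""
    if mean <= 0 or sd <= 0:
        raise DomainError("gamma_from_moments requires positive mean and sd")
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return shape, scale


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Alpha and beta matching the requested mean and SD exactly."""
    if not 0 < mean < 1 or sd <= 0:
        raise DomainError("beta_from_moments requires mean in (0,1) and sd > 0")
    if sd**2 >= mean * (1 - mean):
        raise DomainError("sd too large for a beta distribution with this mean")
    nu = mean * (1 - mean) / sd**2 - 1
    return mean * nu, (1 - mean) * nu


def sd_from_ci95(lo: float, hi: float) -> float:
    """SD implied by a printed 95% CI under a normal approximation: (hi-lo)/3.92."""
    if hi < lo:
        raise DomainError("CI upper bound below lower bound")
    return (hi - lo) / 3.92


def percentile_ci(draws: np.ndarray, level: float = 95.0) -> tuple[float, float]:
    """Empirical percentile interval with linear interpolation."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise DomainError("percentile_ci requires at least one draw")
    tail = (100.0 - level) / 2.0
    lo, hi = np.percentile(draws, [tail, 100.0 - tail], method="linear")
    return float(lo), float(hi)


def _substream(seed: int, name: str) -> np.random.Generator:
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def sample_inputs(spec: PsaSpec) -> dict[str, np.ndarray]:
    """One array of draws per named quantity, each from its own substream."""
    return {
        name: dspec.sample(_substream(spec.seed, name), spec.n_draws)
        for name, dspec in spec.quantity_specs.items()
    }


def run_psa(model: Model, spec: PsaSpec, cost_multiplier: float = 1.0) -> PsaSummary:
    """Seeded Monte Carlo over the model; identical seed, identical draws.

    ``cost_multiplier`` scales every sampled cost before metric evaluation
    (the one-way scenario hook); draws themselves are unchanged, so the
    multiplier-1 run and a scenario run share input samples.
    """
    if cost_multiplier <= 0:
        raise DomainError("cost_multiplier must be positive")
    inputs = sample_inputs(spec)
    benefit, cost = model(inputs)
    cost = np.asarray(cost, dtype=float) * cost_multiplier
    benefit = np.asarray(benefit, dtype=float)
    draws = pd.DataFrame(
        {
            "total_cost": cost,
            "total_benefit": benefit,
            "net_benefit": benefit - cost,
            "bcr": benefit / cost,
            "roi": (benefit - cost) / cost,
        }
    )
    means = {m: float(draws[m].mean()) for m in METRICS}
    ci = {m: percentile_ci(draws[m].to_numpy()) for m in METRICS}
    return PsaSummary(
        means=means,
        ci_low={m: ci[m][0] for m in METRICS},
        ci_high={m: ci[m][1] for m in METRICS},
        n_draws=spec.n_draws,
        seed=spec.seed,
        draws=draws,
    )


def one_way_scenario(model: Model, spec: PsaSpec, cost_multiplier: float) -> PsaSummary:
    """Cost-multiplier scenario: same input draws, every sampled cost scaled."""
    return run_psa(model, spec, cost_multiplier=cost_multiplier)


def aggregate_model(inputs: Mapping[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Model whose inputs ARE the totals: quantities 'total_benefit', 'total_cost'."""
    return np.asarray(inputs["total_benefit"]), np.asarray(inputs["total_cost"])


def component_model(
    consults_by_specialty: Mapping[str, int],
    net_avoided_dollars: Mapping[str, float],
) -> Model:
    """Benefit built from sampled avoidance proportion; cost sampled directly.

    Expects quantities 'avoidance_proportion' and 'total_cost' in the spec.
    """

    def model(inputs: Mapping[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        p = np.asarray(inputs["avoidance_proportion"], dtype=float)
        benefit = sum(
            n * p * net_avoided_dollars[s] for s, n in consults_by_specialty.items()
        )
        return np.asarray(benefit, dtype=float), np.asarray(inputs["total_cost"])

    return model


def with_seed(spec: PsaSpec, seed: int) -> PsaSpec:
    return replace(spec, seed=seed)
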