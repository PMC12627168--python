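"""Population model: normal parents, metaregression, and priors.

Individual diffusion parameters are modelled as draws from normal parent
distributions.  Exactly one parameter -- the *criterion* -- has its mean
shifted by ``beta * x`` for an external covariate x (per participant in
between-subjects designs, per condition in within-subject designs)::

    crit_pc   ~ Normal(mu_crit + beta * x_pc, sigma_crit^2)
    other_p   ~ Normal(mu_other, sigma_other^2)

The parents are deliberately untruncated (individual draws that violate the
diffusion support are vetoed by the likelihood's -inf sentinel during
sampling, and by rejection resampling in the simulator).

Default priors are weakly informative over the empirically plausible ranges
for two-choice RT tasks; the beta prior is an analytic normal so that the
Savage-Dickey density ratio at beta = 0 is well defined.  All priors are
configurable through :class:`PriorSpec`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .likelihood import LikelihoodConfig, NEG_INF, loglik_dataset

__all__ = [
    "PopulationParams", "PriorSpec",
    "NormalPrior", "TruncNormalPrior", "UniformPrior",
    "log_prior", "log_group", "log_posterior",
    "POP_PARAM_NAMES",
]

_HALF_LOG_2PI = 0.5 * math.log(2.0 * math.pi)

POP_PARAM_NAMES = ("mu_drift", "sigma_drift", "mu_boundary", "sigma_boundary",
                   "mu_ndt", "sigma_ndt", "beta")


@dataclass(frozen=True)
class PopulationParams:
    """Group-level means/SDs, regression weight and its criterion."""

    mu_drift: float = 1.0
    sigma_drift: float = 0.4
    mu_boundary: float = 1.5
    sigma_boundary: float = 0.2
    mu_ndt: float = 0.4
    sigma_ndt: float = 0.05
    beta: float = 0.0
    criterion: Literal["drift", "boundary", "ndt"] = "drift"

    def validate(self) -> None:
        for name in ("sigma_drift", "sigma_boundary", "sigma_ndt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.mu_boundary <= 0:
            raise ValueError("mu_boundary must be > 0")
        if self.mu_ndt < 0:
            raise ValueError("mu_ndt must be >= 0")
        if self.criterion not in ("drift", "boundary", "ndt"):
            raise ValueError(f"unknown criterion {self.criterion!r}")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in POP_PARAM_NAMES + ("criterion",)}

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in POP_PARAM_NAMES])

    @classmethod
    def from_vector(cls, vec, criterion="drift") -> "PopulationParams":
        kw = dict(zip(POP_PARAM_NAMES, map(float, vec)))
        return cls(criterion=criterion, **kw)


class NormalPrior:
    """Normal(loc, scale^2) prior."""

    def __init__(self, loc: float, scale: float):
        if scale <= 0:
            raise ValueError("scale must be > 0")
        self.loc, self.scale = float(loc), float(scale)
        self._const = -_HALF_LOG_2PI - math.log(self.scale)

    def logpdf(self, x: float) -> float:
        z = (x - self.loc) / self.scale
        return self._const - 0.5 * z * z

    def median(self) -> float:
        return self.loc

    def sample(self, rng) -> float:
        return float(rng.normal(self.loc, self.scale))

    def to_dict(self) -> dict:
        return {"family": "normal", "loc": self.loc, "scale": self.scale}


class TruncNormalPrior:
    """Normal(loc, scale^2) truncated to (low, high)."""

    def __init__(self, loc: float, scale: float, low: float, high: float):
        if scale <= 0 or not low < high:
            raise ValueError("need scale > 0 and low < high")
        from scipy.stats import norm
        self.loc, self.scale = float(loc), float(scale)
        self.low, self.high = float(low), float(high)
        a, b = (self.low - loc) / scale, (self.high - loc) / scale
        self._log_z = math.log(norm.cdf(b) - norm.cdf(a))
        self._const = -_HALF_LOG_2PI - math.log(self.scale) - self._log_z
        self._median = float(norm.ppf(
            norm.cdf(a) + 0.5 * (norm.cdf(b) - norm.cdf(a))) * scale + loc)

    def logpdf(self, x: float) -> float:
        if not self.low < x < self.high:
            return NEG_INF
        z = (x - self.loc) / self.scale
        return self._const - 0.5 * z * z

    def median(self) -> float:
        return self._median

    def sample(self, rng) -> float:
        while True:
            x = float(rng.normal(self.loc, self.scale))
            if self.low < x < self.high:
                return x

    def to_dict(self) -> dict:
        return {"family": "truncated_normal", "loc": self.loc,
                "scale": self.scale, "low": self.low, "high": self.high}


class UniformPrior:
    """Uniform(low, high) prior."""

    def __init__(self, low: float, high: float):
        if not low < high:
            raise ValueError("need low < high")
        self.low, self.high = float(low), float(high)
        self._logd = -math.log(self.high - self.low)

    def logpdf(self, x: float) -> float:
        return self._logd if self.low <= x <= self.high else NEG_INF

    def median(self) -> float:
        return 0.5 * (self.low + self.high)

    def sample(self, rng) -> float:
        return float(rng.uniform(self.low, self.high))

    def to_dict(self) -> dict:
        return {"family": "uniform", "low": self.low, "high": self.high}


_FAMILIES = {"normal": NormalPrior, "truncated_normal": TruncNormalPrior,
             "uniform": UniformPrior}


def prior_from_dict(d: dict):
    d = dict(d)
    family = d.pop("family")
    try:
        cls = _FAMILIES[family]
    except KeyError:
        raise ValueError(f"unknown prior family {family!r}") from None
    return cls(**d)


@dataclass(frozen=True)
class PriorSpec:
    """One proper, evaluable prior per population parameter.

    Defaults (weakly informative over plausible two-choice RT ranges):
    mu_drift ~ Normal(0, 2^2); mu_boundary ~ Normal(1.5, 1) on (0.1, 5);
    mu_ndt ~ Normal(0.3, 0.25^2) on (0, 1); all sigmas ~ Uniform(0.01, 3);
    beta ~ Normal(0, 1).
    """

    mu_drift: NormalPrior = field(default_factory=lambda: NormalPrior(0.0, 2.0))
    sigma_drift: UniformPrior = field(
        default_factory=lambda: UniformPrior(0.01, 3.0))
    mu_boundary: TruncNormalPrior = field(
        default_factory=lambda: TruncNormalPrior(1.5, 1.0, 0.1, 5.0))
    sigma_boundary: UniformPrior = field(
        default_factory=lambda: UniformPrior(0.01, 3.0))
    mu_ndt: TruncNormalPrior = field(
        default_factory=lambda: TruncNormalPrior(0.3, 0.25, 0.0, 1.0))
    sigma_ndt: UniformPrior = field(
        default_factory=lambda: UniformPrior(0.01, 3.0))
    beta: NormalPrior = field(default_factory=lambda: NormalPrior(0.0, 1.0))

    def to_dict(self) -> dict:
        return {k: getattr(self, k).to_dict() for k in POP_PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(**{k: prior_from_dict(v) for k, v in d.items()})


def log_prior(pop: PopulationParams, priors: PriorSpec) -> float:
    """Sum of log prior densities; -inf outside any prior's support."""
    total = 0.0
    for name in POP_PARAM_NAMES:
        lp = getattr(priors, name).logpdf(getattr(pop, name))
        if lp == NEG_INF:
            return NEG_INF
        total += lp
    return total


def _normal_logpdf_sum(x, mean, sd) -> float:
    x = np.asarray(x, float)
    z = (x - mean) / sd
    return float(-x.size * (_HALF_LOG_2PI + math.log(sd)) - 0.5 * np.sum(z * z))


def log_group(params_table, pop: PopulationParams, x=None) -> float:
    """Log density of individual parameters under the normal parents.

    ``params_table`` is a DataFrame with columns ``participant, condition,
    drift, boundary, ndt``; the covariate ``x`` (per row, defaulting to the
    table's own ``x`` column) shifts the criterion parameter's mean by
    ``beta * x``.  Non-criterion parameters are shared across a participant's
    conditions and contribute one term per participant.
    """
    pop.validate()
    if x is None:
        x = params_table["x"].values
    x = np.asarray(x, float)
    if x.shape[0] != len(params_table):
        raise ValueError("covariate length does not match table")
    means = {"drift": pop.mu_drift, "boundary": pop.mu_boundary,
             "ndt": pop.mu_ndt}
    sds = {"drift": pop.sigma_drift, "boundary": pop.sigma_boundary,
           "ndt": pop.sigma_ndt}
    total = 0.0
    crit = pop.criterion
    total += _normal_logpdf_sum(params_table[crit].values,
                                means[crit] + pop.beta * x, sds[crit])
    dedup = params_table.drop_duplicates("participant")
    for name in ("drift", "boundary", "ndt"):
        if name == crit:
            continue
        total += _normal_logpdf_sum(dedup[name].values, means[name], sds[name])
    return total if np.isfinite(total) else NEG_INF


def log_posterior(pop: PopulationParams, params_table, stats_table, priors:
                  PriorSpec, cfg: LikelihoodConfig = LikelihoodConfig(),
                  x=None) -> float:
    """Unnormalised log posterior: prior + group density + proxy likelihood."""
    lp = log_prior(pop, priors)
    if lp == NEG_INF:
        return NEG_INF
    lg = log_group(params_table, pop, x=x)
    if lg == NEG_INF:
        return NEG_INF
    ll = loglik_dataset(params_table, stats_table, cfg)
    total = lp + lg + ll
    return total if np.isfinite(total) else NEG_INF
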