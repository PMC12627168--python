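"""Closed-form EZ-diffusion system.

The EZ-diffusion method maps the three parameters of a simple (unbiased,
three-parameter) drift diffusion model -- drift rate ``nu``, boundary
separation ``alpha`` and nondecision time ``tau`` -- onto three summary
statistics of two-choice response-time data: the accuracy rate, and the mean
and variance of the correct response times.  The *forward* system predicts
the statistics from the parameters; the *inverse* system recovers the
parameters from observed statistics in closed form.

All functions are vectorised over numpy arrays; the diffusion coefficient is
fixed at 1 and the starting point at ``alpha / 2`` (unbiased start), which is
the scaling under which these closed forms hold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "DDMParams",
    "SummaryStats",
    "PredictedStats",
    "summarize",
    "forward",
    "inverse",
    "edge_correct",
]

# Below this |alpha*nu| the forward moment formulas are evaluated by their
# series expansion around nu = 0 (removable singularity).
_SMALL_Z = 1e-3


@dataclass(frozen=True)
class DDMParams:
    """Diffusion parameters of one empirical unit.

    drift : evidence accumulated per second (any sign)
    boundary : separation between the response boundaries (> 0)
    ndt : nondecision time in seconds (>= 0)
    """

    drift: float
    boundary: float
    ndt: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.drift, self.boundary, self.ndt])):
            raise ValueError("DDM parameters must be finite")
        if self.boundary <= 0:
            raise ValueError(f"boundary must be > 0, got {self.boundary}")
        if self.ndt < 0:
            raise ValueError(f"ndt must be >= 0, got {self.ndt}")


@dataclass(frozen=True)
class SummaryStats:
    """Observed per-cell summary statistics scored by the proxy likelihood.

    n_trials : total number of trials N in the cell
    n_correct : number of correct (upper-boundary) responses
    mean_rt : mean of the correct response times, seconds
    var_rt : unbiased sample variance of the correct response times, s^2
    """

    n_trials: int
    n_correct: int
    mean_rt: float
    var_rt: float

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError("a summary cell needs at least 2 trials")
        if not 0 <= self.n_correct <= self.n_trials:
            raise ValueError("n_correct must lie in [0, n_trials]")
        if self.var_rt < 0:
            raise ValueError("var_rt must be >= 0")

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_trials


@dataclass(frozen=True)
class PredictedStats:
    """Model-implied accuracy rate and correct-RT mean / variance."""

    pred_accuracy: float
    pred_mean: float
    pred_var: float


def summarize(trials: Iterable[tuple[int, float]] | np.ndarray,
              correct_only: bool = True) -> SummaryStats:
    """Reduce trial-level data to the per-cell summary statistics.

    Parameters
    ----------
    trials
        Sequence of ``(accuracy, rt)`` pairs or an ``(n, 2)`` array.
    correct_only
        If True (default), the RT mean and variance are computed over correct
        trials only.  In the unbiased three-parameter diffusion model correct
        and error RT distributions coincide, so an all-trials variant is
        offered for robustness checks.

    Raises
    ------
    ValueError
        If fewer than 2 trials enter the RT moments (variance undefined) --
        the cell is too small to summarise.
    """
    arr = np.asarray(list(trials) if not isinstance(trials, np.ndarray) else trials,
                     dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("trials must be (accuracy, rt) pairs")
    acc = arr[:, 0]
    rt = arr[:, 1]
    if not np.isin(acc, (0.0, 1.0)).all():
        raise ValueError("accuracy values must be 0 or 1")
    n = arr.shape[0]
    n_correct = int(acc.sum())
    sel = rt[acc == 1.0] if correct_only else rt
    if sel.size < 2:
        raise ValueError(
            f"need at least 2 {'correct ' if correct_only else ''}trials to "
            f"compute an RT variance, got {sel.size}")
    return SummaryStats(n_trials=n, n_correct=n_correct,
                        mean_rt=float(sel.mean()),
                        var_rt=float(sel.var(ddof=1)))


def forward_arrays(drift, boundary, ndt):
    """Vectorised forward system; returns ``(acc, mean, var)`` arrays.

    Let ``q = exp(-alpha*nu)`` and ``z = alpha*nu``.  Then::

        R = 1 / (q + 1)                       = expit(z)
        M = tau + (alpha / 2 nu) tanh(z / 2)
        V = (alpha / 2 nu^3) (tanh(z/2) - z / (2 cosh^2(z/2)))

    The tanh/sech forms are algebraically identical to the textbook
    expressions but stable for large |z|.  Near z = 0 the removable
    singularity is handled by the series
    ``M -> tau + alpha^2/4 - alpha^4 nu^2/48`` and
    ``V -> alpha^4/24 - alpha^6 nu^2/120``.
    """
    nu = np.asarray(drift, dtype=float)
    a = np.asarray(boundary, dtype=float)
    t = np.asarray(ndt, dtype=float)
    if np.any(a <= 0):
        raise ValueError("boundary must be > 0")
    z = a * nu
    from scipy.special import expit

    acc = expit(z)
    small = np.abs(z) < _SMALL_Z
    # avoid 0/0 warnings in the masked-out branch
    nu_safe = np.where(small, 1.0, nu)
    z_safe = np.where(small, 1.0, z)
    th = np.tanh(z_safe / 2.0)
    sech2 = 1.0 / np.cosh(z_safe / 2.0) ** 2
    mean_big = t + (a / (2.0 * nu_safe)) * th
    var_big = (a / (2.0 * nu_safe ** 3)) * (th - (z_safe / 2.0) * sech2)
    mean_small = t + a ** 2 / 4.0 - a ** 4 * nu ** 2 / 48.0
    var_small = a ** 4 / 24.0 - a ** 6 * nu ** 2 / 120.0
    mean = np.where(small, mean_small, mean_big)
    var = np.where(small, var_small, var_big)
    return acc, mean, var


def forward(params: DDMParams) -> PredictedStats:
    """Predicted accuracy rate and correct-RT mean/variance for one unit."""
    acc, mean, var = forward_arrays(params.drift, params.boundary, params.ndt)
    return PredictedStats(float(acc), float(mean), float(var))


def inverse_arrays(acc_rate, mean_rt, var_rt):
    """Vectorised inverse system; returns ``(drift, boundary, ndt)`` arrays.

    ``acc_rate`` must be strictly inside (0, 1) and different from 1/2
    (apply :func:`edge_correct` first); ``var_rt`` must be positive.
    """
    r = np.asarray(acc_rate, dtype=float)
    m = np.asarray(mean_rt, dtype=float)
    v = np.asarray(var_rt, dtype=float)
    if np.any((r <= 0) | (r >= 1)):
        raise ValueError("accuracy rate must lie strictly in (0, 1); "
                         "apply edge correction first")
    if np.any(r == 0.5):
        raise ValueError("accuracy rate exactly 1/2: drift estimate is 0 and "
                         "the boundary estimate is undefined (chance-level cell)")
    if np.any(v <= 0):
        raise ValueError("var_rt must be > 0 to invert")
    L = np.log(r / (1.0 - r))
    # the radicand L(R^2 L - R L + R - 1/2)/V equals nu^4 under the forward
    # system, hence the fourth root (it is non-negative on both sides of 1/2)
    inner = L * (r ** 2 * L - r * L + r - 0.5) / v
    nu = np.sign(r - 0.5) * inner ** 0.25
    alpha = L / nu
    q = np.exp(-nu * alpha)
    ndt = m - (alpha / (2.0 * nu)) * ((1.0 - q) / (1.0 + q))
    return nu, alpha, ndt


def inverse(stats: SummaryStats, edge_rule: str = "half_count") -> DDMParams:
    """Closed-form EZ parameter estimates from one cell's summaries.

    ``edge_rule`` controls how accuracy rates of exactly 0 or 1 are pulled
    into the open interval before the logit (see :func:`edge_correct`);
    ``"none"`` disables the correction and lets extreme cells raise.
    """
    r = edge_correct(stats.n_correct, stats.n_trials, rule=edge_rule)
    nu, alpha, ndt = inverse_arrays(r, stats.mean_rt, stats.var_rt)
    return DDMParams(float(nu), float(alpha), float(ndt))


def edge_correct(n_correct: int, n_trials: int, rule: str = "half_count") -> float:
    """Accuracy rate with extreme proportions pulled off the {0, 1} edges.

    The logit in the inverse system diverges at accuracy 0 or 1; the standard
    remedy replaces those with ``1/(2N)`` and ``1 - 1/(2N)`` respectively
    (``rule="half_count"``).  Interior proportions are returned unchanged.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if not 0 <= n_correct <= n_trials:
        raise ValueError("n_correct must lie in [0, n_trials]")
    r = n_correct / n_trials
    if rule == "none":
        return r
    if rule != "half_count":
        raise ValueError(f"unknown edge rule {rule!r}")
    if n_correct == 0:
        return 1.0 / (2.0 * n_trials)
    if n_correct == n_trials:
        return 1.0 - 1.0 / (2.0 * n_trials)
    return r
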