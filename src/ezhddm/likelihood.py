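"""Proxy likelihood over per-cell summary statistics.

Instead of the (expensive) Wiener first-passage density, each design cell's
data enter through three summary statistics whose sampling distributions are
tractable given the diffusion parameters:

* number of correct trials  ``T_ob ~ Binomial(R_pr, N)``
* mean correct RT           ``M_ob ~ Normal(M_pr, V_pr / N)``
* correct-RT variance       ``V_ob ~ Gamma((N-1)/2, 2 V_pr / (N-1))``,
  approximated for large N by ``Normal(V_pr, 2 V_pr^2 / (N-1))``

where (R_pr, M_pr, V_pr) are the forward EZ predictions.  The product of the
three terms is a likelihood for (nu, alpha, tau) whose maximiser coincides
(asymptotically in N; see :func:`mle_cell`) with the closed-form inverse-EZ
estimators.

Everything here is a pure function of in-memory arrays; invalid parameter
proposals yield ``-inf`` so that an MCMC sampler rejects them cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import gammaln, log_expit

from .ez import DDMParams, SummaryStats, forward_arrays, inverse

__all__ = ["LikelihoodConfig", "loglik_cell", "loglik_cells_arrays",
           "loglik_dataset", "mle_cell", "NEG_INF"]

NEG_INF = -np.inf

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class LikelihoodConfig:
    """Choice of sampling law for the RT variance and a minimum cell size.

    variance_law : 'normal_approx' (large-N normal form, the default) or
        'gamma_exact' (the exact scaled chi-squared / gamma law)
    min_n : smallest admissible N per cell
    """

    variance_law: Literal["normal_approx", "gamma_exact"] = "normal_approx"
    min_n: int = 2

    def __post_init__(self) -> None:
        if self.variance_law not in ("normal_approx", "gamma_exact"):
            raise ValueError(f"unknown variance law {self.variance_law!r}")
        if self.min_n < 2:
            raise ValueError("min_n must be >= 2")


def loglik_cells_arrays(drift, boundary, ndt, n, n_correct, mean_rt, var_rt,
                        cfg: LikelihoodConfig = LikelihoodConfig(),
                        log_binom_coef=None) -> np.ndarray:
    """Vectorised per-cell log likelihood; ``-inf`` where parameters invalid.

    ``log_binom_coef`` may carry precomputed ``log C(N, T_ob)`` terms (they
    do not depend on the parameters, so samplers cache them).
    """
    nu = np.asarray(drift, float)
    a = np.asarray(boundary, float)
    tau = np.asarray(ndt, float)
    n = np.asarray(n, float)
    t_ob = np.asarray(n_correct, float)
    m_ob = np.asarray(mean_rt, float)
    v_ob = np.asarray(var_rt, float)
    if np.any(n < cfg.min_n):
        raise ValueError(f"cells with N < {cfg.min_n} are not admissible")

    # support: boundary strictly positive, nondecision time non-negative
    # (a negative tau would let the unbounded low-drift ridge of the EZ
    # system absorb arbitrarily long decision times)
    valid = np.isfinite(nu) & np.isfinite(a) & np.isfinite(tau) & \
        (a > 0) & (tau >= 0)
    a_safe = np.where(valid, a, 1.0)
    z = a_safe * nu
    _, m_pr, v_pr = forward_arrays(nu, a_safe, tau)

    if log_binom_coef is None:
        log_binom_coef = (gammaln(n + 1) - gammaln(t_ob + 1)
                          - gammaln(n - t_ob + 1))
    # Binomial(T_ob | expit(z), N) in a form stable for any z
    ll = log_binom_coef + t_ob * log_expit(z) + (n - t_ob) * log_expit(-z)
    # Normal(M_ob | M_pr, V_pr / N)
    s2_m = v_pr / n
    ll = ll - _HALF_LOG_2PI - 0.5 * np.log(s2_m) - (m_ob - m_pr) ** 2 / (2.0 * s2_m)
    if cfg.variance_law == "normal_approx":
        s2_v = 2.0 * v_pr ** 2 / (n - 1.0)
        ll = ll - _HALF_LOG_2PI - 0.5 * np.log(s2_v) \
            - (v_ob - v_pr) ** 2 / (2.0 * s2_v)
    else:  # gamma_exact
        k = (n - 1.0) / 2.0
        theta = 2.0 * v_pr / (n - 1.0)
        ll = ll + (k - 1.0) * np.log(v_ob) - v_ob / theta \
            - k * np.log(theta) - gammaln(k)
    return np.where(valid & np.isfinite(ll), ll, NEG_INF)


def loglik_cell(params: DDMParams, stats: SummaryStats,
                cfg: LikelihoodConfig = LikelihoodConfig()) -> float:
    """Proxy log likelihood of one cell's summaries given one unit's params."""
    return float(loglik_cells_arrays(
        params.drift, params.boundary, params.ndt,
        stats.n_trials, stats.n_correct, stats.mean_rt, stats.var_rt, cfg))


def loglik_dataset(params_table, stats_table,
                   cfg: LikelihoodConfig = LikelihoodConfig()) -> float:
    """Sum of per-cell log likelihoods over aligned tables.

    Both tables must be DataFrames indexed identically on
    ``(participant, condition)``; ``params_table`` carries columns
    ``drift, boundary, ndt`` and ``stats_table`` carries
    ``n_trials, n_correct, mean_rt, var_rt``.
    """
    keys = ["participant", "condition"]
    p = params_table.sort_values(keys).reset_index(drop=True)
    s = stats_table.sort_values(keys).reset_index(drop=True)
    if len(p) != len(s) or not (p[keys].values == s[keys].values).all():
        raise ValueError("parameter and summary tables are not aligned on "
                         "(participant, condition)")
    ll = loglik_cells_arrays(
        p["drift"].values, p["boundary"].values, p["ndt"].values,
        s["n_trials"].values, s["n_correct"].values,
        s["mean_rt"].values, s["var_rt"].values, cfg)
    total = ll.sum()
    return float(total) if np.isfinite(total) else NEG_INF


def mle_cell(stats: SummaryStats, edge_rule: str = "half_count") -> DDMParams:
    """Maximum-likelihood parameters of the proxy model for one cell.

    The closed-form inverse-EZ estimators maximise the proxy likelihood: the
    binomial term is maximised when the predicted accuracy equals the
    observed rate, and the nondecision time frees the mean term to sit at its
    peak.  The variance term introduces an O(1/N) offset (the exact joint
    maximiser has predicted variance ``V_ob (N-1)/N`` under the gamma law
    because the mean term's variance also depends on V_pr), which vanishes
    with the cell size; the estimators are exact as N grows.
    """
    return inverse(stats, edge_rule=edge_rule)
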