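"""Adaptive Metropolis-within-Gibbs sampling and convergence diagnostics.

Two samplers share the same Metropolis machinery:

* :func:`run_mcmc` -- a generic scalar-blocked random-walk sampler for an
  arbitrary log-density closure (used for toy targets and validation).
* :func:`fit_hierarchical` -- a structured sampler for the hierarchical
  proxy model that exploits its conditional independence: all individual
  parameters of one kind are proposed and accepted elementwise in a single
  vectorised sweep (valid because, given the population parameters, the
  units are conditionally independent), while the seven population-level
  scalars get classic random-walk updates.

Proposal standard deviations adapt toward a 0.44 acceptance rate by
stochastic approximation during warmup only, so detailed balance holds for
the retained draws.  Scale parameters are updated on the log scale with the
Jacobian correction.  Chains are run sequentially from independent
sub-streams of the configured seed, so runs are reproducible bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .ez import edge_correct, inverse_arrays
from .likelihood import LikelihoodConfig, NEG_INF, loglik_cells_arrays
from .model import POP_PARAM_NAMES, PopulationParams, PriorSpec

__all__ = ["SamplerConfig", "PosteriorSamples", "run_mcmc",
           "fit_hierarchical", "init_from_ez", "diagnostics",
           "split_rhat", "effective_sample_size"]

_TARGET_ACCEPT = 0.44


@dataclass(frozen=True)
class SamplerConfig:
    """Run-length and adaptation settings for the samplers."""

    n_chains: int = 4
    n_warmup: int = 2000
    n_draws: int = 5000
    seed: int | None = None
    init_proposal_sd: float = 0.1
    target_accept: float = _TARGET_ACCEPT

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.n_warmup < 0:
            raise ValueError("n_warmup must be >= 0")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must be in (0, 1)")


@dataclass
class PosteriorSamples:
    """Post-warmup draws with per-block acceptance rates and provenance.

    draws : array of shape (n_chains, n_draws, n_params); finite everywhere
    names : parameter names matching the last axis
    accept_rates : post-warmup acceptance rate per proposal block
    config : the resolved SamplerConfig
    """

    draws: np.ndarray
    names: list[str]
    accept_rates: dict[str, float]
    config: SamplerConfig
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("parameter names must be unique")
        if self.draws.shape[2] != len(self.names):
            raise ValueError("draws / names mismatch")
        if not np.isfinite(self.draws).all():
            raise ValueError("posterior draws must be finite")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (n_chains, n_draws)."""
        return self.draws[:, :, self.names.index(name)]

    def pooled(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (chain, iter, parameter, value) table."""
        C, D, K = self.draws.shape
        return pd.DataFrame({
            "chain": np.repeat(np.arange(C), D * K),
            "iter": np.tile(np.repeat(np.arange(D), K), C),
            "parameter": np.tile(self.names, C * D),
            "value": self.draws.reshape(-1),
        })


# ---------------------------------------------------------------------------
# diagnostics

def split_rhat(x: np.ndarray) -> float:
    """Split-R-hat of one parameter's draws, shape (n_chains, n_draws).

    Each chain is split in half; the statistic compares between- and
    within-half variances.  Identical constant chains give exactly 1.
    """
    x = np.asarray(x, float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("expected (n_chains, n_draws) draws")
    n = x.shape[1] // 2
    if n < 2:
        return np.nan
    halves = np.concatenate([x[:, :n], x[:, x.shape[1] - n:]], axis=0)
    W = halves.var(axis=1, ddof=1).mean()
    if W == 0.0:
        return 1.0
    B_over_n = halves.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * W + B_over_n
    return float(math.sqrt(var_plus / W))


def _autocov(y: np.ndarray) -> np.ndarray:
    """Biased autocovariance of one sequence via FFT."""
    n = y.size
    yc = y - y.mean()
    m = int(2 ** math.ceil(math.log2(2 * n)))
    f = np.fft.rfft(yc, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    return acov


def effective_sample_size(x: np.ndarray) -> float:
    """Autocorrelation-based ESS over chains (Geyer initial monotone rule)."""
    x = np.asarray(x, float)
    if x.ndim != 2:
        raise ValueError("expected (n_chains, n_draws) draws")
    m, n = x.shape
    if n < 4:
        return np.nan
    acov = np.mean([_autocov(x[c]) for c in range(m)], axis=0)
    chain_var = x.var(axis=1, ddof=1).mean()
    if chain_var == 0.0:
        return float(m * n)
    mean_var = acov[0] * n / (n - 1)
    var_plus = mean_var * (n - 1) / n
    if m > 1:
        var_plus += x.mean(axis=1).var(ddof=1)
    rho = 1.0 - (mean_var - acov) / var_plus
    # Geyer: sum pair autocorrelations while positive and non-increasing
    npair = (n - n % 2) // 2
    pairs = rho[0:2 * npair:2] + rho[1:2 * npair:2]
    s = 0.0
    prev = np.inf
    for p in pairs:
        if p < 0:
            break
        p = min(p, prev)
        prev = p
        s += p
    tau = max(-1.0 + 2.0 * s, 1.0 / math.log10(n + 10))
    return float(min(m * n / tau, m * n))


def diagnostics(samples: PosteriorSamples,
                rhat_threshold: float = 1.05) -> pd.DataFrame:
    """Per-parameter split-R-hat and ESS, with a convergence flag."""
    if samples.n_chains < 2:
        raise ValueError("diagnostics require at least 2 chains")
    rows = []
    for i, name in enumerate(samples.names):
        x = samples.draws[:, :, i]
        r = split_rhat(x)
        e = effective_sample_size(x)
        rows.append((name, r, e, bool(r > rhat_threshold)))
    return pd.DataFrame(rows, columns=["parameter", "rhat", "ess", "flagged"])


# ---------------------------------------------------------------------------
# generic scalar Metropolis-within-Gibbs

def _adapt(log_sd: float, acc_prob: float, t: int, target: float) -> float:
    return log_sd + (acc_prob - target) / math.sqrt(t)


def run_mcmc(log_target: Callable[[np.ndarray], float],
             x0: Sequence[float],
             cfg: SamplerConfig,
             names: Sequence[str] | None = None,
             max_init_attempts: int = 100) -> PosteriorSamples:
    """Sample an arbitrary target density with scalar random-walk blocks.

    ``log_target`` maps a parameter vector to an unnormalised log density
    (``-inf`` outside the support).  If the density is not finite at ``x0``,
    jittered restarts are attempted a bounded number of times.
    """
    x0 = np.asarray(x0, float)
    k = x0.size
    names = list(names) if names is not None else [f"x{i}" for i in range(k)]
    ss = np.random.SeedSequence(cfg.seed)
    chain_seeds = ss.spawn(cfg.n_chains)
    draws = np.empty((cfg.n_chains, cfg.n_draws, k))
    acc_counts = np.zeros(k)
    for c, cs in enumerate(chain_seeds):
        rng = np.random.default_rng(cs)
        x = x0.copy()
        lp = log_target(x)
        attempts = 0
        while not np.isfinite(lp):
            attempts += 1
            if attempts > max_init_attempts:
                raise RuntimeError("no finite initialization found")
            x = x0 + rng.normal(0.0, cfg.init_proposal_sd, size=k)
            lp = log_target(x)
        log_sd = np.full(k, math.log(cfg.init_proposal_sd))
        for it in range(cfg.n_warmup + cfg.n_draws):
            warm = it < cfg.n_warmup
            for j in range(k):
                prop = x.copy()
                prop[j] += math.exp(log_sd[j]) * rng.standard_normal()
                lp_prop = log_target(prop)
                delta = lp_prop - lp
                acc_prob = 1.0 if delta >= 0 else (
                    math.exp(delta) if np.isfinite(delta) else 0.0)
                if rng.random() < acc_prob:
                    x, lp = prop, lp_prop
                if warm:
                    log_sd[j] = _adapt(log_sd[j], acc_prob, it + 1,
                                       cfg.target_accept)
                else:
                    acc_counts[j] += acc_prob
            if not warm:
                draws[c, it - cfg.n_warmup] = x
    rates = {n: float(acc_counts[j] / (cfg.n_chains * cfg.n_draws))
             for j, n in enumerate(names)}
    return PosteriorSamples(draws=draws, names=names, accept_rates=rates,
                            config=cfg)


# ---------------------------------------------------------------------------
# structured hierarchical sampler

_PARAM_ORDER = ("drift", "boundary", "ndt")


class _HierData:
    """Precomputed per-cell data and index structure for one dataset."""

    def __init__(self, stats: pd.DataFrame, criterion: str):
        stats = stats.sort_values(["participant", "condition"]).reset_index(
            drop=True)
        req = {"participant", "condition", "x", "n_trials", "n_correct",
               "mean_rt", "var_rt"}
        missing = req - set(stats.columns)
        if missing:
            raise ValueError(f"summary table lacks columns {sorted(missing)}")
        self.criterion = criterion
        self.stats = stats
        self.n = stats["n_trials"].to_numpy(float)
        self.t_ob = stats["n_correct"].to_numpy(float)
        self.m_ob = stats["mean_rt"].to_numpy(float)
        self.v_ob = stats["var_rt"].to_numpy(float)
        self.x = stats["x"].to_numpy(float)
        participants = stats["participant"].to_numpy()
        uniq, self.part_idx = np.unique(participants, return_inverse=True)
        self.participants = uniq
        self.P = uniq.size
        self.R = len(stats)
        self.log_binom_coef = (gammaln(self.n + 1) - gammaln(self.t_ob + 1)
                               - gammaln(self.n - self.t_ob + 1))

    def cell_loglik(self, crit_cells, others, cfg):
        """Per-cell proxy log likelihood for the current state."""
        vals = {self.criterion: crit_cells}
        for name, v in others.items():
            vals[name] = v[self.part_idx]
        return loglik_cells_arrays(
            vals["drift"], vals["boundary"], vals["ndt"],
            self.n, self.t_ob, self.m_ob, self.v_ob, cfg,
            log_binom_coef=self.log_binom_coef)


def init_from_ez(stats: pd.DataFrame, criterion: str = "drift",
                 priors: PriorSpec | None = None):
    """Initial values from per-cell inverse-EZ estimates.

    Cells where the inversion is undefined (chance-level accuracy after edge
    correction, or non-positive RT variance) fall back to the prior medians
    of the corresponding population means.  The population-level initials
    are the mean/SD of the per-cell estimates (SDs clipped into the prior
    support); ``beta`` always starts at 0.
    """
    priors = priors or PriorSpec()
    data = _HierData(stats, criterion)
    fallback = {"drift": priors.mu_drift.median(),
                "boundary": priors.mu_boundary.median(),
                "ndt": priors.mu_ndt.median()}
    est = {k: np.empty(data.R) for k in _PARAM_ORDER}
    for i in range(data.R):
        try:
            if not (np.isfinite(data.v_ob[i]) and data.v_ob[i] > 0
                    and np.isfinite(data.m_ob[i])):
                raise ValueError("degenerate cell")
            r = edge_correct(data.t_ob[i], int(data.n[i]))
            nu, a, tau = inverse_arrays(r, data.m_ob[i], data.v_ob[i])
            est["drift"][i], est["boundary"][i], est["ndt"][i] = nu, a, tau
        except (ValueError, FloatingPointError):
            for k in _PARAM_ORDER:
                est[k][i] = fallback[k]
    # keep initial values inside the likelihood support (noisy small-T cells
    # can yield negative tau or extreme boundary estimates)
    est["ndt"] = np.maximum(est["ndt"], 0.0)
    est["boundary"] = np.clip(est["boundary"], 0.02, 10.0)
    crit_cells = est[criterion]
    others = {}
    for k in _PARAM_ORDER:
        if k == criterion:
            continue
        # participant-level: average the cell estimates
        sums = np.bincount(data.part_idx, weights=est[k], minlength=data.P)
        counts = np.bincount(data.part_idx, minlength=data.P)
        others[k] = sums / counts
    mu = {k: float(np.mean(est[k])) for k in _PARAM_ORDER}
    sd = {k: float(np.std(est[k], ddof=1)) if data.R > 1 else 0.1
          for k in _PARAM_ORDER}
    for k in sd:
        sd[k] = max(sd[k], 0.02)
    vals = {"mu_drift": mu["drift"], "sigma_drift": sd["drift"],
            "mu_boundary": mu["boundary"], "sigma_boundary": sd["boundary"],
            "mu_ndt": mu["ndt"], "sigma_ndt": sd["ndt"], "beta": 0.0}
    # project the moment-based values into each prior's support
    for name, v in vals.items():
        prior = getattr(priors, name)
        lo = getattr(prior, "low", -np.inf)
        hi = getattr(prior, "high", np.inf)
        span = hi - lo
        margin = 0.01 * span if np.isfinite(span) else 0.0
        vals[name] = float(np.clip(v, lo + margin, hi - margin))
    pop = PopulationParams(criterion=criterion, **vals)
    return crit_cells, others, pop


def _norm_ll(x, mean, sd):
    z = (x - mean) / sd
    return -np.log(sd) - 0.5 * z * z  # 2pi constant cancels in MH ratios


def fit_hierarchical(stats: pd.DataFrame, criterion: str = "drift",
                     priors: PriorSpec | None = None,
                     cfg: SamplerConfig | None = None,
                     lik_cfg: LikelihoodConfig | None = None,
                     ) -> PosteriorSamples:
    """Posterior sampling for the hierarchical proxy model.

    ``stats`` is the per-cell summary table (participant, condition, x,
    n_trials, n_correct, mean_rt, var_rt).  Returns post-warmup draws for
    the seven population parameters and every individual parameter.
    """
    priors = priors or PriorSpec()
    cfg = cfg or SamplerConfig()
    lik_cfg = lik_cfg or LikelihoodConfig()
    data = _HierData(stats, criterion)
    crit = criterion
    other_names = [k for k in _PARAM_ORDER if k != crit]
    mu_of = {"drift": "mu_drift", "boundary": "mu_boundary", "ndt": "mu_ndt"}
    sd_of = {"drift": "sigma_drift", "boundary": "sigma_boundary",
             "ndt": "sigma_ndt"}

    crit0, others0, pop0 = init_from_ez(stats, criterion, priors)
    ll0 = data.cell_loglik(crit0, others0, lik_cfg)
    if not np.isfinite(ll0).all():
        raise RuntimeError("proxy likelihood not finite at the EZ "
                           "initialisation; check the summary table")

    names = list(POP_PARAM_NAMES)
    cell_names = [f"{crit}[{int(p)},{int(c)}]" for p, c in
                  zip(data.stats["participant"], data.stats["condition"])]
    other_param_names = [f"{k}[{int(p)}]" for k in other_names
                         for p in data.participants]
    names = names + cell_names + other_param_names
    K = len(names)
    draws = np.empty((cfg.n_chains, cfg.n_draws, K))
    acc_acc: dict[str, float] = {f"indiv_{crit}": 0.0,
                                 **{f"indiv_{k}": 0.0 for k in other_names},
                                 **{k: 0.0 for k in POP_PARAM_NAMES},
                                 **{f"joint_{k}": 0.0
                                    for k in POP_PARAM_NAMES}}

    ss = np.random.SeedSequence(cfg.seed)
    for c_idx, cs in enumerate(ss.spawn(cfg.n_chains)):
        rng = np.random.default_rng(cs)
        crit_cells = crit0.copy()
        others = {k: v.copy() for k, v in others0.items()}
        pop = {k: getattr(pop0, k) for k in POP_PARAM_NAMES}
        cur_ll = data.cell_loglik(crit_cells, others, lik_cfg)

        ls_crit = np.full(data.R, math.log(cfg.init_proposal_sd))
        ls_other = {k: np.full(data.P, math.log(cfg.init_proposal_sd))
                    for k in other_names}
        # population blocks start near their conditional scales (the
        # conditional SD of a mean given P individuals is sigma/sqrt(P),
        # of log sigma is 1/sqrt(2P), of beta is sigma/sqrt(Sxx)); the 2.4
        # factor is the standard optimal scalar random-walk scaling.
        sxx = float(np.sum((data.x - data.x.mean()) ** 2)) or 1.0
        pop_scale = {}
        for nm in _PARAM_ORDER:
            s = max(getattr(pop0, sd_of[nm]), 1e-3)
            n_units = data.R if nm == crit else data.P
            pop_scale[mu_of[nm]] = 2.4 * s / math.sqrt(n_units)
            pop_scale[sd_of[nm]] = 2.4 / math.sqrt(2.0 * n_units)
        pop_scale["beta"] = 2.4 * max(getattr(pop0, sd_of[crit]), 1e-3) \
            / math.sqrt(sxx)
        ls_pop = {k: math.log(pop_scale[k]) for k in POP_PARAM_NAMES}
        # joint-move step sizes (translation of a mean with its individuals,
        # rescaling of an SD with its residuals, beta with the criterion
        # cells); these moves walk the data-limited directions that scalar
        # conditional updates cannot traverse in a centred hierarchy
        ls_joint = {k: math.log(pop_scale[k]) for k in POP_PARAM_NAMES}

        def group_crit(vals, pop_):
            return _norm_ll(vals, pop_[mu_of[crit]] + pop_["beta"] * data.x,
                            pop_[sd_of[crit]])

        def group_other(k, vals, pop_):
            return _norm_ll(vals, pop_[mu_of[k]], pop_[sd_of[k]])

        def pop_logp(pop_):
            lp = 0.0
            for k in POP_PARAM_NAMES:
                v = getattr(priors, k).logpdf(pop_[k])
                if v == NEG_INF:
                    return NEG_INF
                lp += v
            return lp

        if pop_logp(pop) == NEG_INF:
            raise RuntimeError("initial population values outside the prior "
                               "support")
        cur_gc = group_crit(crit_cells, pop)
        cur_go = {k: group_other(k, others[k], pop) for k in other_names}

        for it in range(cfg.n_warmup + cfg.n_draws):
            warm = it < cfg.n_warmup
            t = it + 1

            # --- criterion parameter, one scalar MH step per cell ---------
            prop = crit_cells + np.exp(ls_crit) * rng.standard_normal(data.R)
            ll_prop = data.cell_loglik(prop, others, lik_cfg)
            gc_prop = group_crit(prop, pop)
            delta = (ll_prop - cur_ll) + (gc_prop - cur_gc)
            acc_p = np.exp(np.minimum(delta, 0.0))
            acc_p = np.where(np.isnan(acc_p), 0.0, acc_p)
            take = rng.random(data.R) < acc_p
            crit_cells = np.where(take, prop, crit_cells)
            cur_ll = np.where(take, ll_prop, cur_ll)
            cur_gc = np.where(take, gc_prop, cur_gc)
            if warm:
                ls_crit += (acc_p - cfg.target_accept) / math.sqrt(t)
            else:
                acc_acc[f"indiv_{crit}"] += float(acc_p.mean())

            # --- other individual parameters, per participant -------------
            for k in other_names:
                prop_p = others[k] + np.exp(ls_other[k]) * \
                    rng.standard_normal(data.P)
                others_prop = dict(others)
                others_prop[k] = prop_p
                ll_prop = data.cell_loglik(crit_cells, others_prop, lik_cfg)
                dll = np.bincount(data.part_idx, weights=ll_prop - cur_ll,
                                  minlength=data.P)
                go_prop = group_other(k, prop_p, pop)
                delta = dll + (go_prop - cur_go[k])
                acc_p = np.exp(np.minimum(delta, 0.0))
                acc_p = np.where(np.isnan(acc_p), 0.0, acc_p)
                take = rng.random(data.P) < acc_p
                others[k] = np.where(take, prop_p, others[k])
                take_cells = take[data.part_idx]
                cur_ll = np.where(take_cells, ll_prop, cur_ll)
                cur_go[k] = np.where(take, go_prop, cur_go[k])
                if warm:
                    ls_other[k] += (acc_p - cfg.target_accept) / math.sqrt(t)
                else:
                    acc_acc[f"indiv_{k}"] += float(acc_p.mean())

            # --- population scalars ---------------------------------------
            for k in POP_PARAM_NAMES:
                on_log = k.startswith("sigma")
                old = pop[k]
                step = math.exp(ls_pop[k]) * rng.standard_normal()
                new = math.exp(math.log(old) + step) if on_log else old + step
                pop_prop = dict(pop)
                pop_prop[k] = new
                pr = getattr(priors, k).logpdf(new)
                if pr == NEG_INF:
                    delta = NEG_INF
                else:
                    delta = pr - getattr(priors, k).logpdf(old)
                    if k in (mu_of[crit], sd_of[crit], "beta"):
                        gc_prop = group_crit(crit_cells, pop_prop)
                        delta += float(np.sum(gc_prop - cur_gc))
                    else:
                        kk = next(o for o in other_names
                                  if k in (mu_of[o], sd_of[o]))
                        go_prop = group_other(kk, others[kk], pop_prop)
                        delta += float(np.sum(go_prop - cur_go[kk]))
                    if on_log:
                        delta += math.log(new) - math.log(old)  # Jacobian
                acc_p = 1.0 if delta >= 0 else (
                    math.exp(delta) if np.isfinite(delta) else 0.0)
                if rng.random() < acc_p:
                    pop[k] = new
                    if k in (mu_of[crit], sd_of[crit], "beta"):
                        cur_gc = gc_prop
                    else:
                        cur_go[kk] = go_prop
                if warm:
                    ls_pop[k] += (acc_p - cfg.target_accept) / math.sqrt(t)
                else:
                    acc_acc[k] += acc_p

            # --- joint moves along the slow hierarchical directions -------
            def _joint(key, make_state, extra_delta=0.0):
                """One Metropolis step on a deterministic joint proposal."""
                nonlocal cur_ll
                step = math.exp(ls_joint[key]) * rng.standard_normal()
                new_pop_val, new_crit, new_oth = make_state(step)
                pr_new = getattr(priors, key).logpdf(new_pop_val)
                if pr_new == NEG_INF:
                    delta = NEG_INF
                    ll_new = None
                else:
                    ll_new = data.cell_loglik(
                        new_crit if new_crit is not None else crit_cells,
                        new_oth if new_oth is not None else others, lik_cfg)
                    delta = (pr_new - getattr(priors, key).logpdf(pop[key])
                             + float(np.sum(ll_new - cur_ll))
                             + extra_delta * step)
                acc_p = 1.0 if delta >= 0 else (
                    math.exp(delta) if np.isfinite(delta) else 0.0)
                accepted = rng.random() < acc_p
                if accepted:
                    pop[key] = new_pop_val
                    cur_ll = ll_new
                if warm:
                    ls_joint[key] += (acc_p - cfg.target_accept) / math.sqrt(t)
                else:
                    acc_acc[f"joint_{key}"] += acc_p
                return accepted, step, new_crit, new_oth

            # mean of the criterion: shift mu and every cell together
            def mk_mu_crit(d):
                return pop[mu_of[crit]] + d, crit_cells + d, None
            ok, _, new_crit, _ = _joint(mu_of[crit], mk_mu_crit)
            if ok:
                crit_cells = new_crit

            # SD of the criterion: rescale residuals around the cell means
            # (log-scale proposal; the e^{dR} map Jacobian cancels the
            # group-density change, leaving the +d log-sigma Jacobian)
            def mk_sd_crit(d):
                c = math.exp(d)
                mean_vec = pop[mu_of[crit]] + pop["beta"] * data.x
                return (c * pop[sd_of[crit]],
                        mean_vec + c * (crit_cells - mean_vec), None)
            ok, step, new_crit, _ = _joint(sd_of[crit], mk_sd_crit,
                                           extra_delta=1.0)
            if ok:
                crit_cells = new_crit
                cur_gc = cur_gc - step  # -log c per cell

            # beta: tilt the criterion cells along the covariate
            def mk_beta(d):
                return pop["beta"] + d, crit_cells + d * data.x, None
            ok, _, new_crit, _ = _joint("beta", mk_beta)
            if ok:
                crit_cells = new_crit

            for k in other_names:
                def mk_mu_oth(d, k=k):
                    oth = dict(others)
                    oth[k] = others[k] + d
                    return pop[mu_of[k]] + d, None, oth
                ok, _, _, new_oth = _joint(mu_of[k], mk_mu_oth)
                if ok:
                    others = new_oth

                def mk_sd_oth(d, k=k):
                    c = math.exp(d)
                    oth = dict(others)
                    oth[k] = pop[mu_of[k]] + c * (others[k] - pop[mu_of[k]])
                    return c * pop[sd_of[k]], None, oth
                ok, step, _, new_oth = _joint(sd_of[k], mk_sd_oth,
                                              extra_delta=1.0)
                if ok:
                    others = new_oth
                    cur_go[k] = cur_go[k] - step

            if not warm:
                j = it - cfg.n_warmup
                row = draws[c_idx, j]
                row[:7] = [pop[k] for k in POP_PARAM_NAMES]
                row[7:7 + data.R] = crit_cells
                off = 7 + data.R
                for k in other_names:
                    row[off:off + data.P] = others[k]
                    off += data.P

    denom = cfg.n_chains * cfg.n_draws
    rates = {k: v / denom for k, v in acc_acc.items()}
    return PosteriorSamples(
        draws=draws, names=names, accept_rates=rates, config=cfg,
        meta={"criterion": criterion, "priors": priors.to_dict(),
              "likelihood": {"variance_law": lik_cfg.variance_law,
                             "min_n": lik_cfg.min_n},
              "n_participants": int(data.P), "n_cells": int(data.R)})
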