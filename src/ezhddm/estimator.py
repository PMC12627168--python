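"""Scikit-learn-style front end for the hierarchical proxy model."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .likelihood import LikelihoodConfig
from .model import POP_PARAM_NAMES, PriorSpec
from .sampler import PosteriorSamples, SamplerConfig, diagnostics, \
    fit_hierarchical

__all__ = ["EZHierarchicalDDM"]


class EZHierarchicalDDM(BaseEstimator):
    """Hierarchical Bayesian drift diffusion model with a proxy likelihood.

    Each design cell's choice/RT data enter through three summary statistics
    (number correct, mean and variance of correct RTs) whose sampling
    distributions form a tractable likelihood for the cell's diffusion
    parameters.  Individual parameters are pooled through normal parent
    distributions, and the mean of one *criterion* parameter is regressed on
    an external covariate with weight ``beta``.

    Parameters
    ----------
    criterion : {'drift', 'boundary', 'ndt'}
        Which diffusion parameter carries the covariate effect.
    priors : PriorSpec or None
        Priors on the population parameters; None uses the weakly
        informative defaults.
    variance_law : {'normal_approx', 'gamma_exact'}
        Sampling law used for the RT variance term.
    n_chains, n_warmup, n_draws, seed, proposal_sd
        Sampler settings (see :class:`~ezhddm.sampler.SamplerConfig`).
    min_correct : int
        Cells with fewer correct trials than this (or with missing RT
        moments) are dropped with a record in ``dropped_cells_``.

    Attributes
    ----------
    posterior_ : PosteriorSamples
    diagnostics_ : DataFrame with split-R-hat and ESS per parameter
    summary_ : DataFrame of posterior mean / sd / central 95% interval for
        the population parameters
    dropped_cells_ : DataFrame of summary rows excluded before fitting

    Examples
    --------
    >>> model = EZHierarchicalDDM(criterion='drift', seed=1)
    >>> model.fit(summaries)            # doctest: +SKIP
    >>> model.summary_.loc['beta']      # doctest: +SKIP
    """

    def __init__(self, criterion: str = "drift", priors: PriorSpec | None = None,
                 variance_law: str = "normal_approx", n_chains: int = 4,
                 n_warmup: int = 2000, n_draws: int = 5000,
                 seed: int | None = None, proposal_sd: float = 0.1,
                 min_correct: int = 2):
        self.criterion = criterion
        self.priors = priors
        self.variance_law = variance_law
        self.n_chains = n_chains
        self.n_warmup = n_warmup
        self.n_draws = n_draws
        self.seed = seed
        self.proposal_sd = proposal_sd
        self.min_correct = min_correct

    # ------------------------------------------------------------------
    def fit(self, summaries: pd.DataFrame, x=None) -> "EZHierarchicalDDM":
        """Sample the posterior given a per-cell summary table.

        ``summaries`` needs columns participant, condition, n_trials,
        n_correct, mean_rt, var_rt and (unless ``x`` is given) a covariate
        column ``x``.  ``x`` may override the covariate as an array aligned
        with the rows.
        """
        df = summaries.copy()
        if x is not None:
            df["x"] = np.asarray(x, float)
        if "x" not in df.columns:
            raise ValueError("no covariate: provide an 'x' column or the x= "
                             "argument")
        if "condition" not in df.columns:
            df["condition"] = 0
        ok = (df["n_correct"] >= self.min_correct) & \
            np.isfinite(df["mean_rt"]) & np.isfinite(df["var_rt"]) & \
            (df["var_rt"] > 0)
        self.dropped_cells_ = df.loc[~ok].copy()
        df = df.loc[ok]
        if not len(df):
            raise ValueError("no usable summary cells")
        cfg = SamplerConfig(n_chains=self.n_chains, n_warmup=self.n_warmup,
                            n_draws=self.n_draws, seed=self.seed,
                            init_proposal_sd=self.proposal_sd)
        lik = LikelihoodConfig(variance_law=self.variance_law)
        self.posterior_ = fit_hierarchical(
            df, criterion=self.criterion, priors=self.priors or PriorSpec(),
            cfg=cfg, lik_cfg=lik)
        self.diagnostics_ = diagnostics(self.posterior_) \
            if self.n_chains >= 2 else None
        self.summary_ = self._summarise(self.posterior_)
        return self

    @staticmethod
    def _summarise(post: PosteriorSamples) -> pd.DataFrame:
        rows = {}
        for name in POP_PARAM_NAMES:
            d = post.pooled(name)
            lo, hi = np.quantile(d, [0.025, 0.975])
            rows[name] = {"mean": d.mean(), "sd": d.std(ddof=1),
                          "q2.5": lo, "q97.5": hi}
        return pd.DataFrame(rows).T

    # ------------------------------------------------------------------
    def beta_draws(self) -> np.ndarray:
        """Pooled post-warmup draws of the regression weight."""
        self._check_fitted()
        return self.posterior_.pooled("beta")

    def credible_interval(self, name: str, level: float = 0.95):
        """Central credible interval for any sampled parameter."""
        self._check_fitted()
        a = (1.0 - level) / 2.0
        d = self.posterior_.pooled(name)
        return tuple(np.quantile(d, [a, 1.0 - a]))

    def _check_fitted(self) -> None:
        if not hasattr(self, "posterior_"):
            raise RuntimeError("this model is not fitted yet; call fit first")
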