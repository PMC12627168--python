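"""Wiener diffusion simulator and hierarchical dataset generator.

Trials are drawn from an unbiased Wiener diffusion: evidence starts at
``alpha/2``, accumulates with drift ``nu`` and unit diffusion coefficient,
and is absorbed at 0 (error) or ``alpha`` (correct); the response time is the
nondecision time ``tau`` plus the first-passage time.  The walk is integrated
by Euler-Maruyama with a configurable step ``dt`` (default 1e-4 s), so the
first-passage quantities carry an O(sqrt(dt)) discretisation bias that the
test suite bounds by a step-halving check.

The hierarchical generator draws individual (nu, alpha, tau) from normal
parent distributions whose criterion-parameter mean is shifted by
``beta * x`` (metaregression), simulates trials per design cell, and returns
the per-cell summary statistics together with the true parameters for
recovery scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .ez import DDMParams

__all__ = [
    "DEFAULT_DT",
    "DesignSpec",
    "simulate_trial",
    "simulate_dataset",
    "simulate_trials_arrays",
    "simulate_hierarchical",
    "write_trials",
]

DEFAULT_DT = 1e-4

Criterion = Literal["drift", "boundary", "ndt"]
DesignKind = Literal["ttest_between", "ttest_within", "regression"]

# rejection-resampling floors for hierarchical individual draws
ALPHA_FLOOR = 0.01
TAU_FLOOR = 0.0


@dataclass(frozen=True)
class DesignSpec:
    """Design of a simulated hierarchical experiment.

    n_participants : P, number of participants
    n_trials : T, trials per design cell
    design_kind : 'ttest_between' (binary x per participant),
        'ttest_within' (one cell per condition per participant, x per
        condition) or 'regression' (x in [0, 1] per participant)
    criterion : which diffusion parameter carries the regression weight
    covariate : optional explicit covariate values; if omitted, a balanced
        0/1 split (t-test designs) or evenly spaced values in [0, 1]
        (regression) are used
    """

    n_participants: int
    n_trials: int
    design_kind: DesignKind = "ttest_between"
    criterion: Criterion = "drift"
    covariate: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        if self.n_trials < 2:
            raise ValueError("need at least 2 trials per cell (RT variance)")
        if self.design_kind not in ("ttest_between", "ttest_within", "regression"):
            raise ValueError(f"unknown design kind {self.design_kind!r}")
        if self.criterion not in ("drift", "boundary", "ndt"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.covariate is not None:
            n = len(self.covariate)
            expect = 2 if self.design_kind == "ttest_within" else self.n_participants
            if n != expect:
                raise ValueError(
                    f"covariate length {n} does not match design (expected {expect})")

    @property
    def n_conditions(self) -> int:
        return 2 if self.design_kind == "ttest_within" else 1

    def covariate_values(self) -> np.ndarray:
        """Covariate as a (P, C) array (C = 1 for between designs)."""
        P = self.n_participants
        if self.design_kind == "ttest_within":
            x = np.array([0.0, 1.0]) if self.covariate is None \
                else np.asarray(self.covariate, dtype=float)
            return np.tile(x, (P, 1))
        if self.covariate is not None:
            x = np.asarray(self.covariate, dtype=float)
        elif self.design_kind == "ttest_between":
            x = (np.arange(P) >= P // 2).astype(float)
        else:  # regression: evenly spaced on [0, 1]
            x = np.linspace(0.0, 1.0, P) if P > 1 else np.array([0.5])
        return x.reshape(P, 1)


def discretization_tolerance(params: DDMParams, dt: float,
                             safety: float = 2.5):
    """Documented Euler-Maruyama bias bound for the three summary statistics.

    A discrete-time walk can only be absorbed on a grid point, which is
    equivalent (to leading order) to widening each boundary by
    ``0.5826 * sqrt(dt)`` (the Brownian continuity-correction constant).
    The returned tolerances are ``safety`` times the effect of that widening
    on the closed-form accuracy, mean and variance; the safety factor covers
    the neglected higher-order terms.  Returns (tol_accuracy, tol_mean,
    tol_var).
    """
    from .ez import forward_arrays

    shift = 2.0 * 0.5826 * np.sqrt(dt)
    base = forward_arrays(params.drift, params.boundary, params.ndt)
    wide = forward_arrays(params.drift, params.boundary + shift, params.ndt)
    return tuple(float(safety * abs(w - b)) for b, w in zip(base, wide))


def _check_sim_args(dt: float) -> None:
    if not (np.isfinite(dt) and dt > 0):
        raise ValueError(f"dt must be a positive finite number, got {dt}")


def simulate_trials_arrays(drift, boundary, ndt, dt: float,
                           rng: np.random.Generator,
                           max_steps: int | None = None):
    """Simulate one trial per element of the (broadcast) parameter arrays.

    Returns ``(accuracy, rt)`` float arrays.  All walkers advance in
    lock-step; absorbed walkers drop out of the active set, so the cost is
    proportional to the summed decision times divided by ``dt``.
    """
    _check_sim_args(dt)
    nu, a, tau = np.broadcast_arrays(np.asarray(drift, float),
                                     np.asarray(boundary, float),
                                     np.asarray(ndt, float))
    if not (np.isfinite(nu).all() and np.isfinite(a).all() and np.isfinite(tau).all()):
        raise ValueError("diffusion parameters must be finite")
    if np.any(a <= 0):
        raise ValueError("boundary must be > 0")
    if np.any(tau < 0):
        raise ValueError("ndt must be >= 0")
    shape = nu.shape
    n = nu.size
    nu = nu.ravel()
    a = a.ravel()
    tau = tau.ravel()
    if max_steps is None:
        # generous cap: ~200x the zero-drift expected decision time
        max_steps = int(np.ceil(200.0 * np.max(a) ** 2 / 4.0 / dt)) + 10_000

    x = a / 2.0
    acc = np.zeros(n)
    steps = np.zeros(n, dtype=np.int64)
    active = np.arange(n)
    sqdt = np.sqrt(dt)
    k = 0
    while active.size and k < max_steps:
        k += 1
        x[active] += nu[active] * dt + sqdt * rng.standard_normal(active.size)
        xa = x[active]
        hit_up = xa >= a[active]
        hit_lo = xa <= 0.0
        done = hit_up | hit_lo
        if done.any():
            idx = active[done]
            acc[idx] = hit_up[done].astype(float)
            steps[idx] = k
            active = active[~done]
    if active.size:
        raise RuntimeError(
            f"{active.size} walkers not absorbed after {max_steps} steps")
    rt = tau + steps * dt
    return acc.reshape(shape), rt.reshape(shape)


def simulate_trial(params: DDMParams, dt: float = DEFAULT_DT,
                   rng: np.random.Generator | None = None) -> tuple[int, float]:
    """One (accuracy, rt) trial from the diffusion process."""
    rng = np.random.default_rng() if rng is None else rng
    acc, rt = simulate_trials_arrays(params.drift, params.boundary, params.ndt,
                                     dt, rng)
    return int(acc), float(rt)


def simulate_dataset(params: DDMParams, n_trials: int, dt: float = DEFAULT_DT,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """``(n_trials, 2)`` array of i.i.d. (accuracy, rt) trials."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    acc, rt = simulate_trials_arrays(np.full(n_trials, params.drift),
                                     np.full(n_trials, params.boundary),
                                     np.full(n_trials, params.ndt), dt, rng)
    return np.column_stack([acc, rt])


def draw_individuals(design: DesignSpec, pop, rng: np.random.Generator):
    """Draw true individual parameters under the hierarchical model.

    Returns ``(crit, other, rejections)`` where ``crit`` is the criterion
    parameter with shape (P, C), ``other`` maps the two remaining parameter
    names to (P,) arrays, and ``rejections`` counts positivity-floor redraws.
    Boundary draws below 0.01 and nondecision-time draws below 0 are
    rejection-resampled, since the untruncated parents can produce invalid
    diffusion parameters.
    """
    x = design.covariate_values()  # (P, C)
    P, C = x.shape
    means = {"drift": pop.mu_drift, "boundary": pop.mu_boundary, "ndt": pop.mu_ndt}
    sds = {"drift": pop.sigma_drift, "boundary": pop.sigma_boundary,
           "ndt": pop.sigma_ndt}
    floors = {"drift": -np.inf, "boundary": ALPHA_FLOOR, "ndt": TAU_FLOOR}
    rejections = 0

    def _draw(mean, sd, floor):
        nonlocal rejections
        out = rng.normal(mean, sd)
        bad = out < floor
        while np.any(bad):
            rejections += int(bad.sum())
            out = np.where(bad, rng.normal(mean, sd), out)
            bad = out < floor
        return out

    crit_mean = means[design.criterion] + pop.beta * x
    crit = _draw(crit_mean, np.full_like(x, sds[design.criterion]),
                 floors[design.criterion])
    other = {}
    for name in ("drift", "boundary", "ndt"):
        if name == design.criterion:
            continue
        other[name] = _draw(np.full(P, means[name]), np.full(P, sds[name]),
                            floors[name])
    return crit, other, rejections


def simulate_hierarchical(design: DesignSpec, pop,
                          rng: np.random.Generator | None = None,
                          dt: float = DEFAULT_DT,
                          return_trials: bool = False):
    """Simulate a full hierarchical dataset and summarise it per cell.

    Parameters
    ----------
    design : DesignSpec
    pop : PopulationParams
        Group-level means/SDs and the regression weight ``beta`` (the
        criterion named in ``design`` carries the weight).
    rng, dt
        Random stream and integrator step.
    return_trials
        Also return the trial-level long-format DataFrame.

    Returns
    -------
    summaries : DataFrame with columns participant, condition, x, n_trials,
        n_correct, mean_rt, var_rt (one row per design cell)
    truth : DataFrame with the true individual parameters per cell
    (+ trials : DataFrame, if requested)
    """
    pop.validate()
    rng = np.random.default_rng() if rng is None else rng
    _check_sim_args(dt)
    x = design.covariate_values()
    P, C = x.shape
    T = design.n_trials
    crit, other, rejections = draw_individuals(design, pop, rng)

    # full (P, C) parameter grids; non-criterion parameters shared over cells
    grids = {design.criterion: crit}
    for name, vals in other.items():
        grids[name] = np.tile(vals.reshape(P, 1), (1, C))
    nu_g, a_g, tau_g = grids["drift"], grids["boundary"], grids["ndt"]

    # one big vectorised batch: (P, C, T) walkers
    acc, rt = simulate_trials_arrays(
        np.repeat(nu_g[..., None], T, axis=2),
        np.repeat(a_g[..., None], T, axis=2),
        np.repeat(tau_g[..., None], T, axis=2), dt, rng)

    rows, truth_rows, trial_rows = [], [], []
    for p in range(P):
        for c in range(C):
            cell_acc, cell_rt = acc[p, c], rt[p, c]
            corr = cell_rt[cell_acc == 1.0]
            if corr.size >= 2:
                mean_rt, var_rt = float(corr.mean()), float(corr.var(ddof=1))
            else:  # cell too small to summarise; flagged with NaN moments
                mean_rt, var_rt = np.nan, np.nan
            rows.append((p, c, x[p, c], T, int(cell_acc.sum()), mean_rt, var_rt))
            truth_rows.append((p, c, x[p, c], nu_g[p, c], a_g[p, c], tau_g[p, c]))
            if return_trials:
                trial_rows.append(pd.DataFrame({
                    "participant": p, "condition": c,
                    "accuracy": cell_acc.astype(int), "rt": cell_rt}))
    summaries = pd.DataFrame(rows, columns=[
        "participant", "condition", "x", "n_trials", "n_correct",
        "mean_rt", "var_rt"])
    truth = pd.DataFrame(truth_rows, columns=[
        "participant", "condition", "x", "drift", "boundary", "ndt"])
    truth.attrs["rejections"] = rejections
    if return_trials:
        return summaries, truth, pd.concat(trial_rows, ignore_index=True)
    return summaries, truth


def write_trials(trials: pd.DataFrame, truth: pd.DataFrame, out_dir,
                 *, seed, dt: float, design: DesignSpec, pop) -> None:
    """Write trial-level and true-parameter CSVs plus a provenance sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials.to_csv(out / "trials.csv", index=False)
    truth.to_csv(out / "true_parameters.csv", index=False)
    meta = {
        "seed": seed, "dt": dt,
        "design": {
            "n_participants": design.n_participants,
            "n_trials": design.n_trials,
            "design_kind": design.design_kind,
            "criterion": design.criterion,
        },
        "population": pop.to_dict(),
        "parent_rejections": int(truth.attrs.get("rejections", 0)),
    }
    (out / "simulation.json").write_text(json.dumps(meta, indent=2))
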