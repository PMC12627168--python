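"""Proxy likelihood: sampling-law terms, additivity, MLE identity."""

import math

import numpy as np
import pandas as pd
import pytest

from ezhddm.ez import (DDMParams, SummaryStats, edge_correct, forward,
                       forward_arrays, inverse_arrays)
from ezhddm.likelihood import (LikelihoodConfig, NEG_INF, loglik_cell,
                               loglik_cells_arrays, loglik_dataset, mle_cell)


def _stats_from(params, n, rng):
    """Draw one summary-statistics triple from the proxy's own laws."""
    r, m, v = forward_arrays(params.drift, params.boundary, params.ndt)
    t_ob = int(rng.binomial(n, r))
    m_ob = float(rng.normal(m, np.sqrt(v / n)))
    v_ob = float(rng.gamma((n - 1) / 2, 2 * v / (n - 1)))
    return SummaryStats(n, t_ob, m_ob, v_ob)


class TestCellLikelihood:
    def test_binomial_term_value(self):
        # isolate Eq.-11-style term: params whose predicted accuracy is 0.7,
        # compared against the directly evaluated pmf C(10,7) 0.7^7 0.3^3
        from scipy.stats import binom

        alpha_nu = math.log(0.7 / 0.3)
        p = DDMParams(alpha_nu, 1.0, 0.1)  # boundary 1 => z = drift
        _, m_pr, v_pr = forward_arrays(p.drift, p.boundary, p.ndt)
        stats = SummaryStats(10, 7, float(m_pr), float(v_pr))
        total = loglik_cell(p, stats)
        # subtract the analytically known mean/variance terms at their peaks
        mean_term = -0.5 * math.log(2 * math.pi * v_pr / 10)
        var_term = -0.5 * math.log(2 * math.pi * 2 * v_pr ** 2 / 9)
        binom_term = total - mean_term - var_term
        assert binom_term == pytest.approx(math.log(0.266828), abs=1e-5)
        assert binom_term == pytest.approx(binom.logpmf(7, 10, 0.7), abs=1e-9)

    def test_mean_term_peaks_at_predicted_mean(self):
        p = DDMParams(1.2, 1.1, 0.25)
        pred = forward(p)
        s0 = SummaryStats(200, 150, pred.pred_mean, pred.pred_var)
        shifted = SummaryStats(200, 150, pred.pred_mean + 0.01, pred.pred_var)
        assert loglik_cell(p, s0) > loglik_cell(p, shifted)

    def test_gamma_and_normal_laws_agree_for_large_cells(self):
        # observed variances within two sampling SDs of the prediction: the
        # central-limit regime where the normal form stands in for the gamma
        p = DDMParams(1.0, 1.4, 0.3)
        pred = forward(p)
        n = 10_000
        sd_v = pred.pred_var * np.sqrt(2.0 / (n - 1))
        t = int(round(pred.pred_accuracy * n))
        for z in np.linspace(-2, 2, 17):
            s = SummaryStats(n, t, pred.pred_mean, pred.pred_var + z * sd_v)
            a = loglik_cell(p, s, LikelihoodConfig("normal_approx"))
            b = loglik_cell(p, s, LikelihoodConfig("gamma_exact"))
            assert abs(a - b) < 1e-2

    def test_invalid_parameters_yield_sentinel(self):
        s = SummaryStats(50, 30, 0.5, 0.03)
        assert loglik_cells_arrays(1.0, -1.0, 0.3, 50, 30, 0.5, 0.03) == NEG_INF
        assert loglik_cells_arrays(1.0, 1.0, -0.1, 50, 30, 0.5, 0.03) == NEG_INF
        assert np.isfinite(loglik_cell(DDMParams(1, 1, 0.3), s))

    def test_unknown_variance_law_rejected(self):
        with pytest.raises(ValueError):
            LikelihoodConfig(variance_law="lognormal")


class TestDatasetLikelihood:
    @pytest.fixture
    def tables(self, rng):
        rows_p, rows_s = [], []
        for i in range(5):
            p = DDMParams(float(rng.uniform(0.5, 2)),
                          float(rng.uniform(0.8, 2)),
                          float(rng.uniform(0.2, 0.4)))
            s = _stats_from(p, 80, rng)
            rows_p.append((i, 0, p.drift, p.boundary, p.ndt))
            rows_s.append((i, 0, s.n_trials, s.n_correct, s.mean_rt, s.var_rt))
        pt = pd.DataFrame(rows_p, columns=["participant", "condition",
                                           "drift", "boundary", "ndt"])
        st = pd.DataFrame(rows_s, columns=["participant", "condition",
                                           "n_trials", "n_correct",
                                           "mean_rt", "var_rt"])
        return pt, st

    def test_single_cell_matches_cell_function(self, tables):
        pt, st = tables
        one = loglik_dataset(pt.iloc[:1], st.iloc[:1])
        p = DDMParams(pt.drift[0], pt.boundary[0], pt.ndt[0])
        s = SummaryStats(int(st.n_trials[0]), int(st.n_correct[0]),
                         st.mean_rt[0], st.var_rt[0])
        assert one == pytest.approx(loglik_cell(p, s))

    def test_permutation_invariance(self, tables):
        pt, st = tables
        shuffled = st.sample(frac=1.0, random_state=1)
        assert loglik_dataset(pt, shuffled) == pytest.approx(
            loglik_dataset(pt, st))

    def test_duplicating_a_cell_doubles_its_contribution(self, tables):
        pt, st = tables
        base = loglik_dataset(pt, st)
        first = loglik_dataset(pt.iloc[:1], st.iloc[:1])
        pt2 = pd.concat([pt, pt.iloc[:1].assign(participant=99)])
        st2 = pd.concat([st, st.iloc[:1].assign(participant=99)])
        assert loglik_dataset(pt2, st2) == pytest.approx(base + first)

    def test_misaligned_tables_raise(self, tables):
        pt, st = tables
        with pytest.raises(ValueError):
            loglik_dataset(pt, st.assign(participant=st.participant + 1))


class TestMLEIdentity:
    def test_noise_free_roundtrip(self):
        pred = forward(DDMParams(1.0, 1.0, 0.3))
        # a cell whose observed rate is exactly the prediction
        n = 10_000
        t = int(round(pred.pred_accuracy * n))
        s = SummaryStats(n, t, pred.pred_mean, pred.pred_var)
        est = mle_cell(s)
        r = edge_correct(t, n)
        exact = inverse_arrays(r, pred.pred_mean, pred.pred_var)
        assert est.drift == pytest.approx(float(exact[0]))

    def test_hillclimb_converges_to_inverse(self, rng):
        from scipy.optimize import minimize

        for _ in range(5):
            p = DDMParams(float(rng.uniform(0.5, 2.0)),
                          float(rng.uniform(0.8, 2.0)),
                          float(rng.uniform(0.2, 0.4)))
            n = 100_000
            s = _stats_from(p, n, rng)
            est = np.array(inverse_arrays(edge_correct(s.n_correct, n),
                                          s.mean_rt, s.var_rt))

            def nll(x):
                v = float(loglik_cells_arrays(x[0], x[1], x[2], n,
                                              s.n_correct, s.mean_rt,
                                              s.var_rt))
                return -v if np.isfinite(v) else 1e12

            res = minimize(nll, est * 1.001, method="Nelder-Mead",
                           options=dict(xatol=1e-9, fatol=1e-12,
                                        maxfev=20000))
            assert np.max(np.abs(res.x - est)) < 1e-4

    def test_gradient_vanishes_at_inverse_estimates(self, rng):
        p = DDMParams(1.2, 1.1, 0.3)
        n = 100_000
        s = _stats_from(p, n, rng)
        est = np.array(inverse_arrays(edge_correct(s.n_correct, n),
                                      s.mean_rt, s.var_rt))

        def ll(x):
            return float(loglik_cells_arrays(x[0], x[1], x[2], n,
                                             s.n_correct, s.mean_rt,
                                             s.var_rt))

        h = 1e-5
        for j in range(3):
            e = np.zeros(3)
            e[j] = h
            g = (ll(est + e) - ll(est - e)) / (2 * h)
            # scaled by the local curvature-implied natural step
            assert abs(g) * h < 1e-4

    def test_finite_cell_gap_is_order_one_over_n(self, rng):
        # at realistic cell sizes the exact maximiser sits O(1/N) away from
        # the closed-form estimates (the variance term's normalisation);
        # document that the gap is small but need not vanish
        from scipy.optimize import minimize

        p = DDMParams(1.0, 1.2, 0.3)
        n = 200
        s = _stats_from(p, n, rng)
        est = np.array(inverse_arrays(edge_correct(s.n_correct, n),
                                      s.mean_rt, s.var_rt))

        def nll(x):
            v = float(loglik_cells_arrays(x[0], x[1], x[2], n, s.n_correct,
                                          s.mean_rt, s.var_rt))
            return -v if np.isfinite(v) else 1e12

        res = minimize(nll, est * 1.001, method="Nelder-Mead",
                       options=dict(xatol=1e-10, fatol=1e-13, maxfev=20000))
        gap = np.max(np.abs(res.x - est))
        assert gap < 0.05


def test_variance_sampling_law_matches_sample_variances(rng):
    """Sample variances of normal RT batches follow the stated gamma law."""
    from scipy.stats import gamma, kstest

    n, v_pr = 50, 0.03
    draws = rng.normal(0.5, np.sqrt(v_pr), size=(10_000, n))
    sample_vars = draws.var(axis=1, ddof=1)
    res = kstest(sample_vars, gamma(a=(n - 1) / 2,
                                    scale=2 * v_pr / (n - 1)).cdf)
    assert res.pvalue > 0.01
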