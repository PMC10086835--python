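"""Likelihood, fitting, shrinkage limits, EDF, and information criteria."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import ostreg
from conftest import build_panel, small_sim_config
from helpers import loglik_bruteforce
from ostreg.model import (
    DEFAULT_LAMBDA_GRID,
    ModelSpec,
    _design,
    _gh_eval,
    _hermgauss,
    category_logprob,
    fit,
    marginal_loglik,
    select_lambda,
)
from ostreg.panel import key_set, person_medians
from ostreg.penalty import PenaltySpec, build_penalty_spec, coef_layout


THETA6 = np.array([-1.0, 1.0, 3.0, 5.0, 7.0, 9.0])


class TestCategoryLogprob:
    def test_bottom_category_closed_form(self):
        assert category_logprob(0.0, THETA6, 1) == pytest.approx(np.log(expit(-1.0)))

    def test_probabilities_sum_to_one(self):
        for eta in (-3.0, 0.0, 2.5, 11.0):
            total = sum(np.exp(category_logprob(eta, THETA6, m)) for m in range(1, 8))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_median_category_at_cutpoint(self):
        # eta = theta_m makes P(Y <= m) = 1/2
        for m in range(1, 7):
            cum = sum(
                np.exp(category_logprob(THETA6[m - 1], THETA6, k))
                for k in range(1, m + 1)
            )
            assert cum == pytest.approx(0.5, abs=1e-12)

    def test_rejects_nonmonotone_cutpoints(self):
        with pytest.raises(ValueError, match="increasing"):
            category_logprob(0.0, [1.0, 0.5], 1)


def _five_subject_panel():
    records = [
        (1, 2, 1), (1, 3, 2), (1, 2, 3),
        (2, 1, 2), (2, 2, 1), (2, 1, 1),
        (3, 3, 3), (3, 3, 2),
        (4, 2, 2), (4, 2, 3), (4, 1, 1),
        (5, 1, 3), (5, 2, 2),
    ]
    return build_panel(records, m_x=3, m_y=3)


class TestMarginalLoglik:
    def test_sigma_zero_equals_independent_likelihood(self):
        panel = _five_subject_panel()
        traits = person_medians(panel)
        spec = ModelSpec(m_y=3, mode="linear")
        zeta = np.array([0.3, -0.2, 0.5])
        theta = np.array([-1.0, 0.8])
        ll = marginal_loglik(spec, panel, traits, zeta, theta, 0.0)
        md = _design(spec, panel, traits, None)
        direct = 0.0
        for i in range(md.n_obs):
            eta = md.X[i] @ zeta
            direct += float(category_logprob(eta, theta, int(md.y[i])))
        assert ll == pytest.approx(direct, abs=1e-10)

    def test_matches_dense_integration_oracle(self):
        # 1 subject with 2 observations, then the full 5-subject fixture
        panel = _five_subject_panel()
        traits = person_medians(panel)
        spec = ModelSpec(m_y=3, mode="linear")
        zeta = np.array([0.1, -0.4, 0.6])
        theta = np.array([-1.0, 1.2])
        ll = marginal_loglik(spec, panel, traits, zeta, theta, 1.0)
        brute = loglik_bruteforce(panel, traits, "linear", zeta, theta, 1.0)
        assert ll == pytest.approx(brute, abs=1e-8)

    def test_stable_under_node_doubling(self):
        panel = _five_subject_panel()
        traits = person_medians(panel)
        zeta = np.array([0.2, 0.3, -0.5])
        theta = np.array([-1.0, 0.5])
        lls = []
        for nodes in (15, 31):
            spec = ModelSpec(m_y=3, mode="linear", quadrature_nodes=nodes)
            lls.append(marginal_loglik(spec, panel, traits, zeta, theta, 0.8))
        assert abs(lls[0] - lls[1]) < 1e-6

    def test_nonmonotone_theta_rejected(self):
        panel = _five_subject_panel()
        traits = person_medians(panel)
        spec = ModelSpec(m_y=3, mode="linear")
        with pytest.raises(ValueError, match="increasing"):
            marginal_loglik(spec, panel, traits, np.zeros(3), [1.0, -1.0], 1.0)


class TestFit:
    def test_gradient_small_at_reported_optimum(self, grid_model):
        panel, traits, keys, layout, pen = grid_model
        spec = ModelSpec(m_y=panel.m_y, mode="penalized", layout=layout, penalty=pen)
        res = fit(spec, panel, traits, keys, lam=1.0, gtol=1e-7, ftol=1e-14,
                  maxiter=2000)
        assert res.converged
        assert res.grad_norm <= 1e-5

    def test_empty_category_errors(self):
        records = [(1, 1, 1), (1, 2, 3), (2, 1, 3), (2, 2, 1)]
        panel = build_panel(records, m_x=2, m_y=3)
        traits = person_medians(panel)
        with pytest.raises(ValueError, match=r"empty response categories: \[2\]"):
            fit(ModelSpec(m_y=3, mode="linear"), panel, traits)

    def test_theta_constraint_and_monotonicity(self, grid_model):
        panel, traits, keys, layout, pen = grid_model
        res = fit(ModelSpec(m_y=panel.m_y, mode="linear"), panel, traits)
        assert res.theta_hat[0] == -1.0
        assert np.all(np.diff(res.theta_hat) > 0)
        assert res.sigma_u_hat >= 0

    def test_penalized_at_zero_equals_unpenalized(self, grid_model):
        panel, traits, keys, layout, pen = grid_model
        pen_spec = ModelSpec(m_y=panel.m_y, mode="penalized", layout=layout, penalty=pen)
        unp_spec = ModelSpec(m_y=panel.m_y, mode="unpenalized", layout=layout)
        a = fit(pen_spec, panel, traits, keys, 0.0)
        b = fit(unp_spec, panel, traits, keys, 0.0)
        np.testing.assert_allclose(a.zeta_hat, b.zeta_hat, atol=1e-12)
        assert a.aic == pytest.approx(b.aic, abs=1e-9)
        assert a.edf_fixed == layout.n_params == b.edf_fixed

    def test_huge_lambda_recovers_linear_fit(self, grid_model):
        panel, traits, keys, layout, pen = grid_model
        pen_spec = ModelSpec(m_y=panel.m_y, mode="penalized", layout=layout, penalty=pen)
        big = fit(pen_spec, panel, traits, keys, 1e8, ftol=1e-12)
        lin = fit(ModelSpec(m_y=panel.m_y, mode="linear"), panel, traits, ftol=1e-12)
        f_big = big.f_hat
        f_lin = lin.implied_f(layout.cells)
        diff = max(abs(f_big[c] - f_lin[c]) for c in layout.cells)
        assert diff <= 1e-3
        assert big.edf_fixed == pytest.approx(3.0, abs=0.01)

    def test_edf_monotone_in_lambda(self, grid_model):
        panel, traits, keys, layout, pen = grid_model
        spec = ModelSpec(m_y=panel.m_y, mode="penalized", layout=layout, penalty=pen)
        edfs = [
            fit(spec, panel, traits, keys, lam).edf_fixed for lam in (0.1, 1.0, 10.0)
        ]
        assert edfs[0] > edfs[1] > edfs[2]
        assert all(3.0 <= e <= layout.n_params for e in edfs)

    def test_edf_partition_sums_to_total(self, grid_model):
        panel, traits, keys, layout, pen = grid_model
        spec = ModelSpec(m_y=panel.m_y, mode="penalized", layout=layout, penalty=pen)
        res = fit(spec, panel, traits, keys, 5.0)
        assert sum(res.edf_parts.values()) == pytest.approx(res.edf_fixed, abs=1e-8)

    def test_aic_complexity_difference(self, grid_model):
        # equal log-likelihoods: AIC difference is exactly twice the EDF gap
        panel, traits, keys, layout, pen = grid_model
        unp = fit(ModelSpec(m_y=panel.m_y, mode="unpenalized", layout=layout),
                  panel, traits, keys)
        lin = fit(ModelSpec(m_y=panel.m_y, mode="linear"), panel, traits)
        gap_unp = unp.aic + 2 * unp.loglik
        gap_lin = lin.aic + 2 * lin.loglik
        assert gap_unp - gap_lin == pytest.approx(2 * (layout.n_params - 3), abs=1e-9)


class TestAgainstStatsmodels:
    def test_cumulative_logit_matches_ordered_model(self):
        """With no subject effect, our fit reduces to plain cumulative
        logistic regression; statsmodels' OrderedModel is the oracle.

        Parametrizations differ (we anchor theta_1 = -1 and keep a free
        intercept), so location-invariant contrasts are compared: cutpoint
        gaps and f-value differences between cells.
        """
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        rng = np.random.default_rng(42)
        # no true subject effect: responses depend on the current state only
        records = []
        for i in range(150):
            for _ in range(4):
                s = int(rng.integers(1, 4))
                lat = 0.5 * s + rng.logistic()
                y = 1 + int(np.searchsorted([0.3, 1.7], lat))
                records.append((i, s, y))
        panel = build_panel(records, m_x=3, m_y=3)
        traits = person_medians(panel)
        keys = key_set(panel, traits)
        layout = coef_layout(keys, traits.global_median)
        spec = ModelSpec(m_y=3, mode="unpenalized", layout=layout)
        res = fit(spec, panel, traits, keys, ftol=1e-12)
        assert res.sigma_u_hat < 0.2  # no true subject effect

        md = _design(spec, panel, traits, keys)
        X = pd.DataFrame(md.X[:, 1:], columns=res.coef_names[1:])
        om = OrderedModel(pd.Series(md.y), X, distr="logit")
        om_res = om.fit(method="bfgs", disp=False)
        # OrderedModel: P(Y<=m) = F(c_m - x'b); our eta enters with the same
        # sign, so slopes are directly comparable
        for j, name in enumerate(res.coef_names[1:]):
            assert om_res.params[name] == pytest.approx(
                res.zeta_hat[1 + j], abs=0.02
            ), name
        # cutpoint gap (location-free)
        sm_cuts = om.transform_threshold_params(om_res.params)[1:-1]
        assert sm_cuts[1] - sm_cuts[0] == pytest.approx(
            res.theta_hat[1] - res.theta_hat[0], abs=0.02
        )


class TestSelectLambda:
    def test_rejects_empty_grid(self, grid_model):
        panel, traits, keys, layout, pen = grid_model
        spec = ModelSpec(m_y=panel.m_y, mode="penalized", layout=layout, penalty=pen)
        with pytest.raises(ValueError):
            select_lambda(spec, panel, traits, keys, np.array([]))

    def test_linear_truth_selects_heavy_shrinkage(self):
        cfg = small_sim_config(p=1.0, seed=4)
        rng = np.random.default_rng(cfg.seed)
        panel = ostreg.trim_response_levels(ostreg.simulate_panel(cfg, rng))
        traits = person_medians(panel)
        keys = key_set(panel, traits)
        layout = coef_layout(keys, traits.global_median)
        pen = build_penalty_spec(keys, layout)
        spec = ModelSpec(m_y=panel.m_y, mode="penalized", layout=layout, penalty=pen)
        lam, res = select_lambda(spec, panel, traits, keys)
        assert res.edf_fixed < 8.0  # close to the 3 fixed effects of the truth

    def test_nonlinear_truth_keeps_higher_edf(self):
        # full-size replicate: the scaled-down panels carry too little
        # curvature information to resist full shrinkage
        cfg = ostreg.SimConfig(p=1 / 3, seed=4)
        rng = np.random.default_rng(cfg.seed)
        panel = ostreg.trim_response_levels(ostreg.simulate_panel(cfg, rng))
        traits = person_medians(panel)
        keys = key_set(panel, traits)
        layout = coef_layout(keys, traits.global_median)
        pen = build_penalty_spec(keys, layout)
        spec = ModelSpec(m_y=panel.m_y, mode="penalized", layout=layout, penalty=pen)
        lam, res = select_lambda(spec, panel, traits, keys)
        assert res.edf_fixed > 8.0

    def test_criterion_matches_bruteforce_hierarchical_marginal(self):
        """On a 2-parameter model, the Laplace criterion should track the
        exact hierarchical marginal: the penalized coefficient integrated
        against its N(0, 1/lambda) implied prior, flat prior on the rest.
        Differences across lambda values must agree."""
        rng = np.random.default_rng(7)
        records = []
        for i in range(60):
            u = rng.normal(0.0, 0.5)
            states = [2, 2, 2, int(rng.integers(2, 4))]  # lower median always 2
            for s in states:
                lat = 0.3 - 0.5 * (s - 2) + u + rng.logistic()
                y = 1 + int(np.searchsorted([-0.5, 0.9], lat))
                records.append((i, s, y))
        panel = build_panel(records, m_x=3, m_y=3)
        traits = person_medians(panel)
        keys = key_set(panel, traits)
        layout = coef_layout(keys, traits.global_median)
        assert layout.n_params == 2  # alpha and gamma[2,3]
        d = np.array([[0.0, 1.0]])
        pen = PenaltySpec(
            d_rows=d, a_matrix=layout.a_matrix(), p_matrix=d.T @ d, layout=layout
        )
        spec = ModelSpec(m_y=3, mode="penalized", layout=layout, penalty=pen)
        lams = np.array([0.5, 5.0, 50.0])
        _, _, path = select_lambda(
            spec, panel, traits, keys, lams, return_path=True, ftol=1e-12
        )
        crit = {lam: c for lam, c, _ in path}
        fits = {lam: r for lam, _, r in path}

        # brute force: nested numerical integration.  Inner: random intercept
        # u by dense trapezoid per subject.  Outer: 2-d trapezoid over
        # (alpha, gamma) with the N(0, 1/lambda) prior the penalty implies on
        # gamma and a flat prior on alpha, all at the (theta, sigma) the
        # package profiled for that lambda.
        df = panel.data
        is3 = (df["x"].to_numpy() == 3).astype(float)
        yv = df["y"].to_numpy()
        subj = df["subject"].to_numpy()
        starts = np.flatnonzero(np.r_[True, subj[1:] != subj[:-1]])

        def marg_ll(a, g_grid, theta, sigma):
            pad = np.concatenate([[-np.inf], theta, [np.inf]])
            ug = np.linspace(-6 * sigma, 6 * sigma, 241)
            phi = np.exp(-0.5 * (ug / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
            eta = a + np.outer(is3, np.asarray(g_grid))  # (n, G)
            up = pad[yv][:, None, None] - eta[:, :, None] - ug[None, None, :]
            lo = pad[yv - 1][:, None, None] - eta[:, :, None] - ug[None, None, :]
            logp = np.log(expit(up) - expit(lo))
            per_subj = np.add.reduceat(logp, starts, axis=0)  # (I, G, U)
            m = per_subj.max(axis=2, keepdims=True)
            lik = np.trapezoid(np.exp(per_subj - m) * phi[None, None, :], ug, axis=2)
            return (np.log(lik) + m[:, :, 0]).sum(axis=0)  # (G,)

        def brute(lam, res):
            a_grid = np.linspace(res.zeta_hat[0] - 1.2, res.zeta_hat[0] + 1.2, 41)
            g_grid = np.linspace(-1.8, 1.8, 81)
            vals = np.stack(
                [marg_ll(a, g_grid, res.theta_hat, res.sigma_u_hat) for a in a_grid]
            )
            prior = 0.5 * np.log(lam / (2 * np.pi)) - 0.5 * lam * g_grid**2
            m = vals.max()
            inner = np.trapezoid(np.exp(vals + prior[None, :] - m), g_grid, axis=1)
            return m + np.log(np.trapezoid(inner, a_grid))

        bf = {lam: brute(lam, fits[lam]) for lam in lams}
        # the criterion omits the flat-prior constant (p - rank)/2 log(2pi);
        # compare lambda-to-lambda differences
        for l1, l2 in [(0.5, 5.0), (5.0, 50.0)]:
            assert crit[l1] - crit[l2] == pytest.approx(bf[l1] - bf[l2], abs=0.05)
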