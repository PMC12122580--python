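import numpy as np
import pytest
from scipy.optimize import root
from scipy.special import expit

from ltrcmiss import (CovariateModel, PiModel, StepFunction, aipw_fit,
                      bootstrap_se, fit_cox, fit_pi, posterior_x, solve_eta)
from ltrcmiss.simulate import ScenarioConfig, simulate_scenario

from conftest import make_sample


# ------------------------------------------------------------ posterior

class TestPosterior:
    def _unit_sample(self, T, delta):
        return make_sample(entry=[0, 0], time=[T, T + 1],
                           status=[delta, 1], x=[np.nan, 1],
                           w=np.zeros((2, 0), int))

    def test_hand_computed_closed_form(self):
        # prior 0.5, delta=1, beta1=log 2, H0(T)=1:
        # q1 = 0.5 * 2 * e^-2, q0 = 0.5 * 1 * e^-1 -> posterior 2/(2+e)
        s = self._unit_sample(T=1.0, delta=1)
        H0 = StepFunction(times=np.array([0.5]), increments=np.array([1.0]))
        model = CovariateModel(eta=np.array([0.0]))
        post = posterior_x(model, np.array([np.log(2)]), H0, s)
        assert post[0] == pytest.approx(2.0 / (2.0 + np.e), abs=1e-12)

    def test_brute_force_enumeration_agrees(self):
        rng = np.random.default_rng(0)
        n = 12
        s = make_sample(entry=np.zeros(n), time=rng.uniform(1, 8, n),
                        status=rng.integers(0, 2, n) | np.eye(1, n, 0, int)[0],
                        x=rng.integers(0, 2, n).astype(float),
                        w=rng.integers(0, 2, (n, 2)))
        H0 = StepFunction(times=np.sort(rng.uniform(1, 8, 4)),
                          increments=rng.uniform(0, 0.4, 4))
        eta = np.array([0.3, 0.6, -0.4])
        beta = np.array([0.8, 0.5, -0.2])
        model = CovariateModel(eta=eta)
        post = posterior_x(model, beta, H0, s)
        for i in range(n):
            w = s.w[i].astype(float)
            prior = expit(eta[0] + eta[1:] @ w)
            q = []
            for x in (0.0, 1.0):
                lp = beta[0] * x + beta[1:] @ w
                q.append(prior ** x * (1 - prior) ** (1 - x)
                         * np.exp(lp) ** s.status[i]
                         * np.exp(-float(H0(s.time[i])) * np.exp(lp)))
            assert post[i] == pytest.approx(q[1] / (q[0] + q[1]), abs=1e-10)

    def test_zero_beta1_returns_prior(self):
        s = self._unit_sample(T=2.0, delta=1)
        H0 = StepFunction(times=np.array([1.0]), increments=np.array([0.7]))
        model = CovariateModel(eta=np.array([0.4]))
        post = posterior_x(model, np.array([0.0]), H0, s)
        np.testing.assert_allclose(post, expit(0.4), atol=1e-12)

    def test_censored_before_first_jump_returns_prior(self):
        s = self._unit_sample(T=0.5, delta=0)
        H0 = StepFunction(times=np.array([1.0]), increments=np.array([0.7]))
        model = CovariateModel(eta=np.array([-0.3]))
        post = posterior_x(model, np.array([1.2]), H0, s)
        assert post[0] == pytest.approx(expit(-0.3), abs=1e-12)


# ------------------------------------------------------------ solve_eta

def _simple_missing_sample(n, rng, theta=0.3):
    w = rng.integers(0, 2, (n, 1))
    x = (rng.random(n) < expit(0.5 + 0.7 * w[:, 0])).astype(float)
    lp = 0.8 * x + 0.5 * w[:, 0]
    time = (-np.log(rng.random(n)) * np.exp(-lp)) ** 2 / 0.1
    cens = rng.uniform(0, np.quantile(time, 0.9), n)
    status = (time <= cens).astype(int)
    tt = np.minimum(time, cens)
    x_obs = x.copy()
    x_obs[rng.random(n) < theta] = np.nan
    if not status.any():
        status[0] = 1
    return make_sample(entry=np.zeros(n), time=tt, status=status, x=x_obs, w=w)


class TestSolveEta:
    def test_no_missing_equals_plain_logistic_ml(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(1)
        s = _simple_missing_sample(400, rng, theta=0.0)
        pi = PiModel(terms=["1"], coefficients=np.array([30.0]),
                     fitted_pi=np.ones(s.n))
        H0 = StepFunction(times=np.array([1.0]), increments=np.array([0.1]))
        model = solve_eta(s, pi, beta=np.array([0.8, 0.5]), H0=H0)
        design = np.column_stack([np.ones(s.n), s.w[:, 0]])
        ml = sm.Logit(s.x, design).fit(disp=0)
        np.testing.assert_allclose(model.eta, ml.params, atol=1e-5)

    def test_recovers_population_eta_at_large_n(self):
        cfg = ScenarioConfig(n=20000, q=0.0)
        s, _ = simulate_scenario(cfg, 3)
        pi = fit_pi(s, ["1", "w1"])
        cc = fit_cox(__import__("ltrcmiss").complete_cases(s))
        from ltrcmiss import breslow_h0, complete_cases
        H0 = breslow_h0(complete_cases(s), cc)
        model = solve_eta(s, pi, beta=cc.beta, H0=H0)
        np.testing.assert_allclose(
            model.eta, [0.5, np.log(2), -np.log(2), np.log(1.5)], atol=0.1)


# ------------------------------------------------------------- aipw_fit

class TestAIPWFit:
    def test_reduces_to_cox_fit_without_missingness(self):
        rng = np.random.default_rng(2)
        s = _simple_missing_sample(150, rng, theta=0.0)
        pi = PiModel(terms=["1"], coefficients=np.array([30.0]),
                     fitted_pi=np.ones(s.n))
        fit = aipw_fit(s, pi)
        plain = fit_cox(s)
        np.testing.assert_allclose(fit.beta, plain.beta, atol=1e-4)

    def test_residual_trace_reaches_tolerance(self):
        rng = np.random.default_rng(3)
        s = _simple_missing_sample(200, rng)
        fit = aipw_fit(s, fit_pi(s, ["1", "delta"]))
        assert fit.converged
        assert fit.residual_trace[-1] < 1e-6 or fit.iterations > 1

    def test_h0_monotone(self):
        rng = np.random.default_rng(4)
        s = _simple_missing_sample(200, rng)
        fit = aipw_fit(s, fit_pi(s, ["1", "delta"]))
        assert np.all(fit.H0.increments >= 0)

    def test_matches_brute_force_root_finder(self):
        """Joint root of the AIPW score, eta score and Breslow
        self-consistency equations, found by an independent solver with
        loop-based two-point enumeration, matches the alternating
        algorithm to 1e-4."""
        rng = np.random.default_rng(30)
        s = _simple_missing_sample(30, rng, theta=0.35)
        pi = fit_pi(s, ["1", "delta"])
        fit = aipw_fit(s, pi)

        n = s.n
        piv = pi.fitted_pi
        ev_times = np.unique(s.time[s.status == 1])
        d = len(ev_times)
        p = 2  # (x, w1)

        def unpack(v):
            return v[:p], v[p:2 * p], v[2 * p:]

        def H_of(t, inc):
            return float(np.sum(inc[ev_times <= t]))

        def posterior(i, beta, eta, inc):
            w = float(s.w[i, 0])
            prior = expit(eta[0] + eta[1] * w)
            q = []
            for x in (0.0, 1.0):
                lp = beta[0] * x + beta[1] * w
                q.append((prior if x == 1 else 1 - prior)
                         * np.exp(lp) ** s.status[i]
                         * np.exp(-H_of(s.time[i], inc) * np.exp(lp)))
            return q[1] / (q[0] + q[1])

        def residuals(v):
            beta, eta, inc = unpack(v)
            post = [posterior(i, beta, eta, inc) for i in range(n)]

            def S(m, t):
                tot = np.zeros(p) if m == 1 else 0.0
                for j in range(n):
                    if not (s.entry[j] < t <= s.time[j]):
                        continue
                    w = float(s.w[j, 0])
                    aj = s.r[j] / piv[j]
                    # observed part
                    if s.r[j] == 1:
                        lp = beta[0] * s.x[j] + beta[1] * w
                        r0 = np.exp(lp)
                        r1 = np.array([s.x[j], w]) * r0
                    else:
                        r0, r1 = 0.0, np.zeros(p)
                    # expectation part, two-point enumeration
                    e0, e1 = 0.0, np.zeros(p)
                    for x in (0.0, 1.0):
                        wt = post[j] if x == 1 else 1 - post[j]
                        lp = beta[0] * x + beta[1] * w
                        e0 += wt * np.exp(lp)
                        e1 += wt * np.array([x, w]) * np.exp(lp)
                    if m == 0:
                        tot += aj * r0 + (1 - aj) * e0
                    else:
                        tot += aj * r1 + (1 - aj) * e1
                return tot / n

            # Eq. 3 score
            u = np.zeros(p)
            for i in range(n):
                if s.status[i] != 1:
                    continue
                ai = s.r[i] / piv[i]
                zbar = S(1, s.time[i]) / S(0, s.time[i])
                w = float(s.w[i, 0])
                if s.r[i] == 1:
                    u += ai * (np.array([s.x[i], w]) - zbar)
                u += (1 - ai) * (np.array([post[i], w]) - zbar)
            u /= n

            # eta score
            g = np.zeros(p)
            for i in range(n):
                w = float(s.w[i, 0])
                mu = expit(eta[0] + eta[1] * w)
                ai = s.r[i] / piv[i]
                xi = s.x[i] if s.r[i] == 1 else 0.0
                g += (ai * xi + (1 - ai) * post[i] - mu) * np.array([1.0, w])
            g /= n

            # Breslow self-consistency
            h = np.zeros(d)
            for e, t in enumerate(ev_times):
                num = np.sum((s.time == t) & (s.status == 1))
                h[e] = inc[e] - num / (n * S(0, t))
            return np.concatenate([u, g, h])

        x0 = np.concatenate([np.zeros(p), np.zeros(p), np.full(d, 0.05)])
        sol = root(residuals, x0, method="hybr", tol=1e-12)
        assert sol.success
        beta_oracle = sol.x[:p]
        np.testing.assert_allclose(fit.beta, beta_oracle, atol=1e-4)

    def test_double_robustness_scaled(self):
        # gamma = 0, delta-MAR: either a wrong pi model (W-only) with a
        # correct covariate model, or a correct pi with a covariate model
        # missing W2/W3, must still give small bias
        import warnings
        warnings.filterwarnings("ignore")
        cfg = ScenarioConfig(q=0.0, mechanism="MAR-delta")
        rng = np.random.default_rng(21)
        est_a, est_b = [], []
        for _ in range(80):
            s, _ = simulate_scenario(cfg, rng)
            est_a.append(aipw_fit(s, fit_pi(s, ["1", "delta"]),
                                  eta_w_cols=[0]).beta[0])
            est_b.append(aipw_fit(s, fit_pi(s, ["1", "w1", "w2", "w3"]))
                         .beta[0])
        assert abs(np.mean(est_a) - cfg.beta1) < 0.08
        assert abs(np.mean(est_b) - cfg.beta1) < 0.08


# ------------------------------------------------------------ bootstrap

class TestBootstrap:
    def test_seed_determinism(self):
        rng = np.random.default_rng(6)
        s = _simple_missing_sample(120, rng)
        se1, est1 = bootstrap_se(s, ["1", "delta"], n_boot=8, rng=11)
        se2, est2 = bootstrap_se(s, ["1", "delta"], n_boot=8, rng=11)
        np.testing.assert_array_equal(est1, est2)
        np.testing.assert_array_equal(se1, se2)

    def test_bootstrap_se_tracks_monte_carlo_sd(self):
        import warnings
        warnings.filterwarnings("ignore")
        cfg = ScenarioConfig(q=0.0)
        rng = np.random.default_rng(17)
        mc = []
        for _ in range(60):
            s, _ = simulate_scenario(cfg, rng)
            mc.append(aipw_fit(s, fit_pi(s, ["1", "w1"])).beta[0])
        mc_sd = np.std(mc, ddof=1)
        s, _ = simulate_scenario(cfg, 170)
        se, _ = bootstrap_se(s, ["1", "w1"], n_boot=120, rng=1)
        assert abs(se[0] / mc_sd - 1.0) < 0.30
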