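"""Augmented inverse-probability-weighted (AIPW) estimation of the
truncated Cox model with a missing binary covariate.

The estimating equation weights each complete case by ``R_i / pi_i`` and
augments it with a term built from the conditional law of the missing
covariate given the observed data, ``P(X = 1 | T, delta, W)``.  That
posterior combines a user-specified logistic covariate model
``logit P(X=1|W) = eta0 + eta1'W`` with the Cox-model likelihood of the
observed outcome,

    P(X = x | T, delta, W)  proportional to
        P(X = x | W) * exp(lp_x)^delta * exp(-H0(T) * exp(lp_x)),

where ``lp_x = beta1 * x + beta2'W``; the baseline-hazard factor common to
both x values cancels.  The estimator is doubly robust: it is consistent if
either the missingness model pi or the covariate model is correctly
specified (and estimable — under heavy left truncation the covariate model
is estimated from a selection-biased sample, which erodes the second
route).

All at-risk sums use the truncation-adjusted indicator
``Y*_i(t) = I(L_i < t <= T_i)``.  Standard errors come from bootstrap
resampling of subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .cox import (ConvergenceError, StepFunction, breslow_h0, fit_cox,
                  _risk_mask)
from .data import LTRCSample, expand_w
from .missingness import (PI_FLOOR, DegenerateSampleError, PiModel, _logit_ml,
                          complete_cases, fit_pi)

__all__ = [
    "CovariateModel",
    "AIPWFit",
    "posterior_x",
    "solve_eta",
    "aipw_fit",
    "bootstrap_se",
]


@dataclass
class CovariateModel:
    """Logistic model for the population law of X given W.

    ``eta`` holds the intercept followed by coefficients of the expanded W
    indicators (or the subset in ``w_cols`` when the covariate model is
    deliberately restricted, e.g. to study misspecification).  The score
    function is the usual logistic one,
    ``psi_eta(x, w) = (x - expit(eta' (1, w))) * (1, w)``.
    """

    eta: np.ndarray
    w_cols: list | None = None

    def design(self, w_expanded: np.ndarray) -> np.ndarray:
        cols = (w_expanded if self.w_cols is None
                else w_expanded[:, self.w_cols])
        return np.column_stack([np.ones(len(w_expanded)), cols])

    def prior(self, w_expanded: np.ndarray) -> np.ndarray:
        """P(X = 1 | W) for rows of an expanded-indicator W matrix."""
        return expit(self.design(w_expanded) @ self.eta)


@dataclass
class AIPWFit:
    """Converged AIPW solution (standard errors filled in by bootstrap)."""

    beta: np.ndarray
    eta: np.ndarray
    H0: StepFunction
    posterior: np.ndarray        # P(X=1 | T, delta, W) for every subject
    iterations: int
    converged: bool
    residual_trace: list = field(default_factory=list)
    se: np.ndarray | None = None
    n_boot: int = 0
    names: list = field(default_factory=list)


def posterior_x(model: CovariateModel, beta: np.ndarray, H0: StepFunction,
                sample: LTRCSample) -> np.ndarray:
    """Posterior P(X = 1 | T, delta, W) for every subject in the sample.

    Uses only (T, delta, W), never the observed X, so it is defined for
    complete and incomplete subjects alike.  Degenerate priors (0 or 1) are
    returned unchanged.
    """
    Wx = expand_w(sample.w)
    prior = model.prior(Wx)
    beta = np.asarray(beta, dtype=float)
    lp_w = Wx @ beta[1:]
    h = H0(sample.time)
    d = sample.status.astype(float)
    # log q_x = log p(x|W) + delta * lp_x - H0(T) e^{lp_x}; baseline cancels
    with np.errstate(divide="ignore"):
        lq1 = np.log(prior) + d * (beta[0] + lp_w) - h * np.exp(beta[0] + lp_w)
        lq0 = np.log1p(-prior) + d * lp_w - h * np.exp(lp_w)
    post = expit(lq1 - lq0)
    deg = (prior == 0.0) | (prior == 1.0)
    if deg.any():
        post[deg] = prior[deg]
    return post


def solve_eta(sample: LTRCSample, pi: PiModel, beta: np.ndarray,
              H0: StepFunction, init_eta: np.ndarray | None = None,
              tol: float = 1e-6, max_iter: int = 200,
              w_cols: list | None = None) -> CovariateModel:
    """Solve the augmented score equation for the covariate-model eta.

    The equation replaces the unavailable logistic score of incomplete
    subjects with its conditional expectation under the posterior, weighting
    complete subjects by ``R/pi`` and everyone by ``1 - R/pi``:

        sum_i (R_i/pi_i) psi_eta(X_i, W_i)
            + (1 - R_i/pi_i) E[psi_eta(X, W_i) | T_i, delta_i, W_i]  =  0.

    Because the posterior itself depends on eta, the fixed point is found
    by alternating a posterior refresh with one Newton step on the logistic
    score with the pseudo-response held fixed.
    """
    if not (sample.r == 1).any():
        raise DegenerateSampleError("no complete cases: eta is not estimable")
    Wx = expand_w(sample.w)
    design = CovariateModel(eta=np.empty(0), w_cols=w_cols).design(Wx)
    a = sample.r / pi.fitted_pi
    b = 1.0 - a
    x_obs = np.where(sample.r == 1, sample.x, 0.0)
    if init_eta is None:
        mask = sample.r == 1
        init_eta, _ = _logit_ml(sample.x[mask], design[mask],
                                "covariate model")
    eta = np.asarray(init_eta, dtype=float).copy()
    for it in range(1, max_iter + 1):
        post = posterior_x(CovariateModel(eta=eta, w_cols=w_cols), beta, H0,
                           sample)
        pseudo = a * x_obs + b * post
        mu = expit(design @ eta)
        score = design.T @ (pseudo - mu)
        J = (design * (mu * (1 - mu))[:, None]).T @ design
        try:
            step = np.linalg.solve(J, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular eta Jacobian: {exc}") from exc
        eta = eta + step
        if np.max(np.abs(step)) < tol:
            return CovariateModel(eta=eta, w_cols=w_cols)
    raise ConvergenceError(
        f"eta score iteration did not converge in {max_iter} steps; "
        f"last eta = {eta}")


def _aipw_sums(beta, a, b, post, Wx, x_obs, mask, n):
    """Posterior-mixed at-risk sums S^(0), S^(1), S^(2) on the event grid."""
    p = 1 + Wx.shape[1]
    lp_w = Wx @ beta[1:]
    e0 = np.exp(lp_w)                       # risk score with X = 0
    e1 = np.exp(beta[0] + lp_w)             # risk score with X = 1
    r0_obs = np.where(x_obs == 1, e1, e0)
    Er0 = (1 - post) * e0 + post * e1
    c0 = a * r0_obs + b * Er0               # mixed r^(0) contribution

    Z0 = np.column_stack([np.zeros(n), Wx])
    Z1 = np.column_stack([np.ones(n), Wx])
    Zobs = np.column_stack([x_obs, Wx])
    r1_obs = Zobs * r0_obs[:, None]
    Er1 = Z0 * ((1 - post) * e0)[:, None] + Z1 * (post * e1)[:, None]
    c1 = a[:, None] * r1_obs + b[:, None] * Er1

    def sq(Z, w):
        return (Z[:, :, None] * Z[:, None, :]) * w[:, None, None]

    c2 = (a[:, None, None] * sq(Zobs, r0_obs)
          + b[:, None, None] * (sq(Z0, (1 - post) * e0) + sq(Z1, post * e1)))

    S0 = (mask @ c0) / n
    S1 = (mask @ c1) / n
    S2 = (mask @ c2.reshape(n, p * p)).reshape(-1, p, p) / n
    return S0, S1, S2


def aipw_fit(sample: LTRCSample, pi: PiModel, tol: float = 1e-6,
             max_iter: int = 300, eta_w_cols: list | None = None) -> AIPWFit:
    """Solve the AIPW estimating equation by an alternating algorithm.

    Starting from the complete-case truncated Cox fit (beta, Breslow H0)
    and the complete-case logistic ML for eta, each outer iteration
    refreshes the covariate posteriors, re-solves the eta score equation,
    rebuilds the posterior-mixed at-risk sums and the Breslow-type baseline
    hazard, and takes one Newton step on beta.  Convergence is declared
    when the joint (beta, eta) change falls below ``tol``.
    """
    if pi.fitted_pi.shape[0] != sample.n:
        raise ValueError("pi model was fitted on a different sample")
    if np.any(pi.fitted_pi < PI_FLOOR):
        raise ValueError(f"fitted pi below {PI_FLOOR}: weights would explode")

    cc = complete_cases(sample)
    cc_fit = fit_cox(cc)
    beta = cc_fit.beta.copy()
    H0 = breslow_h0(cc, cc_fit)
    Wx = expand_w(sample.w)
    design_eta = CovariateModel(eta=np.empty(0), w_cols=eta_w_cols).design(Wx)
    mask_cc = sample.r == 1
    eta, _ = _logit_ml(sample.x[mask_cc], design_eta[mask_cc],
                       "covariate model")

    n = sample.n
    a = sample.r / pi.fitted_pi
    b = 1.0 - a
    x_obs = np.where(sample.r == 1, sample.x, 0.0)
    ev = sample.status == 1
    tgrid, d_e = np.unique(sample.time[ev], return_counts=True)
    d_e = d_e.astype(float)
    mask = _risk_mask(sample.entry, sample.time, tgrid)
    # index of each subject's own event time on the grid (events only)
    ev_idx = np.searchsorted(tgrid, sample.time[ev])
    Zobs = np.column_stack([x_obs, Wx])

    converged = False
    trace = []
    post = None
    damping = 1.0
    for it in range(1, max_iter + 1):
        model = solve_eta(sample, pi, beta, H0, init_eta=eta, tol=tol,
                          w_cols=eta_w_cols)
        eta_new = model.eta
        post = posterior_x(model, beta, H0, sample)

        S0, S1, S2 = _aipw_sums(beta, a, b, post, Wx, x_obs, mask, n)
        if np.any(S0[d_e > 0] <= 0):
            raise ConvergenceError("nonpositive at-risk sum at an event time")
        H0 = StepFunction(times=tgrid, increments=d_e / (n * S0))

        # score of Eq. (3): events only; the augmentation replaces X by its
        # posterior mean for the (1 - R/pi)-weighted share
        zmix = (a[:, None] * Zobs
                + b[:, None] * np.column_stack([post, Wx]))[ev]
        zbar = (S1 / S0[:, None])[ev_idx]
        U = (zmix - zbar).sum(axis=0) / n
        V = (S2 / S0[:, None, None])[ev_idx] \
            - zbar[:, :, None] * zbar[:, None, :]
        J = V.sum(axis=0) / n
        try:
            step = np.linalg.solve(J, U)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular AIPW Jacobian: {exc}") from exc
        resid = float(np.linalg.norm(U))
        # a non-decreasing residual signals an alternation limit cycle
        # (possible under model misspecification); damp the beta update
        if trace and resid >= trace[-1]:
            damping = max(damping * 0.5, 1.0 / 64.0)
        else:
            damping = min(damping * 1.3, 1.0)
        beta_new = beta + damping * step
        trace.append(resid)

        delta = max(np.max(np.abs(beta_new - beta)),
                    np.max(np.abs(eta_new - eta)))
        beta, eta = beta_new, eta_new
        if np.max(np.abs(beta)) > 20.0:
            raise ConvergenceError("AIPW beta diverged beyond |beta| = 20")
        # primary criterion: the estimating-equation residual is solved
        # (the eta score is solved exactly inside solve_eta); the joint
        # parameter change covers the exactly-stationary case
        if resid < tol or delta < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"AIPW alternation did not converge in {max_iter} iterations; "
            f"residual trace tail = {trace[-5:]}")
    names = ["x"] + [f"w{k+1}" for k in range(Wx.shape[1])]
    return AIPWFit(beta=beta, eta=eta, H0=H0, posterior=post,
                   iterations=it, converged=True, residual_trace=trace,
                   names=names)


def bootstrap_se(sample: LTRCSample, pi_spec: list[str], n_boot: int = 500,
                 rng: np.random.Generator | int | None = None,
                 max_failure_fraction: float = 0.2,
                 **aipw_kwargs) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap standard errors for the AIPW coefficients.

    Resamples subjects with replacement, refits the pi model and the full
    AIPW procedure on each replicate, and returns the standard deviation of
    the converged replicate estimates together with the estimates
    themselves.  Replicates on which any stage fails are dropped; more than
    ``max_failure_fraction`` failures aborts.
    """
    rng = np.random.default_rng(rng)
    estimates, failures = [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, sample.n, sample.n)
        try:
            boot = sample.subset(idx)
            fit = aipw_fit(boot, fit_pi(boot, pi_spec), **aipw_kwargs)
            estimates.append(fit.beta)
        except Exception:
            failures += 1
    if failures > max_failure_fraction * n_boot:
        raise ConvergenceError(
            f"{failures}/{n_boot} bootstrap replicates failed; sample too "
            "fragile for bootstrap inference")
    est = np.array(estimates)
    se = est.std(axis=0, ddof=1) if len(est) > 1 else np.zeros(est.shape[1])
    return se, est
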