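"""Weighted Cox partial likelihood with the left-truncation risk-set
adjustment, plus Breslow and Nelson-Aalen cumulative-hazard estimators.

Delayed entry is handled by replacing the usual at-risk indicator
``Y_i(t) = I(t <= T_i)`` with ``Y*_i(t) = I(L_i < t <= T_i)``: a subject
contributes to a risk set only after entering the study.  Ties are handled
with the Breslow approximation throughout (simulated event times are
continuous, so ties are a measure-zero corner).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import LTRCSample

__all__ = [
    "CoxFit",
    "StepFunction",
    "at_risk",
    "fit_cox",
    "nelson_aalen",
    "breslow_h0",
    "ConvergenceError",
    "EstimationError",
]

#: coefficient magnitude beyond which the likelihood is declared monotone
DIVERGENCE_BOUND = 20.0
#: maximum number of step halvings per Newton iteration
MAX_HALVINGS = 10


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed (rank deficiency, monotone likelihood, ...)."""


class EstimationError(RuntimeError):
    """A nonparametric estimate is undefined on the given sample."""


@dataclass
class StepFunction:
    """Right-continuous nondecreasing step function, 0 before the first jump."""

    times: np.ndarray
    increments: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.increments = np.asarray(self.increments, dtype=float)
        if self.times.ndim != 1 or self.increments.shape != self.times.shape:
            raise ValueError("times and increments must be 1-d and congruent")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("jump times must be strictly increasing")
        if np.any(self.times <= 0):
            raise ValueError("jump times must be positive")
        if np.any(self.increments < 0):
            raise ValueError("increments must be nonnegative")
        self._cum = np.concatenate([[0.0], np.cumsum(self.increments)])

    def __call__(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        return self._cum[idx]


@dataclass
class CoxFit:
    """Result of a (weighted) truncated Cox partial-likelihood fit."""

    beta: np.ndarray
    covariance: np.ndarray
    se: np.ndarray
    iterations: int
    converged: bool
    loglik: float
    names: list = field(default_factory=list)

    def confint(self, level: float = 0.95) -> np.ndarray:
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2.0)
        return np.column_stack([self.beta - z * self.se, self.beta + z * self.se])


def at_risk(sample: LTRCSample, t: float) -> np.ndarray:
    """At-risk indicators ``Y*_i(t) = I(L_i < t <= T_i)``."""
    if t <= 0:
        raise ValueError("risk sets are defined for t > 0")
    return ((sample.entry < t) & (t <= sample.time)).astype(int)


def _risk_mask(entry: np.ndarray, time: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Boolean (len(grid), n) matrix with Y*_i(t) for each grid time t."""
    g = grid[:, None]
    return (entry[None, :] < g) & (g <= time[None, :])


def _event_structure(sample: LTRCSample):
    """Distinct event times, per-time weighted event counts, risk mask."""
    ev = sample.status == 1
    tgrid, inverse = np.unique(sample.time[ev], return_inverse=True)
    dw = np.bincount(inverse, weights=sample.weight[ev],
                     minlength=len(tgrid))
    mask = _risk_mask(sample.entry, sample.time, tgrid)
    return tgrid, dw, mask


def _loglik_score_info(beta, Z, weight, status, dw, mask, ZZ=None):
    """Weighted Breslow partial log-likelihood, score, and information."""
    eta = Z @ beta
    we = weight * np.exp(eta)
    s0 = mask @ we                               # (d,)
    s1 = mask @ (we[:, None] * Z)                # (d, p)
    ev = status == 1
    loglik = float(np.sum(weight[ev] * eta[ev]) - np.sum(dw * np.log(s0)))
    zbar = s1 / s0[:, None]
    score = (weight[ev, None] * Z[ev]).sum(axis=0) - (dw[:, None] * zbar).sum(axis=0)
    p = Z.shape[1]
    if ZZ is None:
        # per-risk-set second moment: S2_e = sum_j we_j Z_j Z_j'
        ZZ = (Z[:, :, None] * Z[:, None, :]).reshape(len(we), p * p)
    s2 = (mask @ (we[:, None] * ZZ)).reshape(-1, p, p)
    info = np.einsum("d,dij->ij", dw, s2 / s0[:, None, None]) \
        - np.einsum("d,di,dj->ij", dw, zbar, zbar)
    return loglik, score, info


def fit_cox(sample: LTRCSample, use_weights: bool = True,
            init: np.ndarray | None = None, tol: float = 1e-8,
            max_iter: int = 50, robust: bool = False) -> CoxFit:
    """Newton-Raphson maximisation of the weighted truncated partial likelihood.

    The design is ``(x, expanded W)``; ``x`` must be complete (filter or
    impute first).  Risk sets use ``Y*_i(t)``, so delayed-entry subjects are
    excluded from risk sets before their entry time.  The covariance is the
    inverse of the weighted observed information at the optimum; with
    ``robust=True`` it is the sandwich built from per-subject score
    residuals, appropriate when the weights are estimated inverse
    probabilities rather than sampling constants.

    Raises
    ------
    ValueError
        If ``x`` has missing entries.
    ConvergenceError
        On rank deficiency or a diverging (monotone-likelihood) path.
    """
    if np.isnan(sample.x).any():
        raise ValueError("fit_cox requires complete x; filter or impute first")
    Z = sample.design_matrix()
    names = ["x"] + [f"w{k+1}" for k in range(Z.shape[1] - 1)]
    weight = sample.weight if use_weights else np.ones(sample.n)
    tgrid, dw, mask = _event_structure(sample)
    return _newton_cox(Z, weight, sample.status, sample.time, tgrid, dw,
                       mask, names=names, init=init, tol=tol,
                       max_iter=max_iter, robust=robust)


def _newton_cox(Z, weight, status, time, tgrid, dw, mask, names=None,
                init=None, tol=1e-8, max_iter=50, robust=False) -> CoxFit:
    """Newton-Raphson core on a precomputed risk-set structure."""
    # identifiability: the design must vary within the union of risk sets
    in_risk = mask.any(axis=0)
    Zr = Z[in_risk]
    centered = Zr - Zr.mean(axis=0)
    if np.linalg.matrix_rank(centered) < Z.shape[1]:
        raise ConvergenceError(
            "design matrix is rank deficient on the at-risk set "
            "(a covariate is constant or collinear)")

    n, p = Z.shape
    ZZ = (Z[:, :, None] * Z[:, None, :]).reshape(n, p * p)
    beta = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()
    loglik, score, info = _loglik_score_info(beta, Z, weight, status,
                                             dw, mask, ZZ)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(score)) <= tol:
            converged = True
            it -= 1
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        new_beta = beta + step
        new_ll, new_score, new_info = _loglik_score_info(
            new_beta, Z, weight, status, dw, mask, ZZ)
        halvings = 0
        while new_ll < loglik and halvings < MAX_HALVINGS:
            step /= 2.0
            halvings += 1
            new_beta = beta + step
            new_ll, new_score, new_info = _loglik_score_info(
                new_beta, Z, weight, status, dw, mask, ZZ)
        beta, loglik, score, info = new_beta, new_ll, new_score, new_info
        if np.max(np.abs(beta)) > DIVERGENCE_BOUND:
            raise ConvergenceError(
                f"|beta| exceeded {DIVERGENCE_BOUND}: monotone likelihood or "
                "separation in the risk sets")
    else:
        it = max_iter
    if np.max(np.abs(score)) <= tol:
        converged = True
    inv_info = np.linalg.inv(info)
    if robust:
        resid = _score_residuals(beta, Z, weight, status, time,
                                 tgrid, dw, mask)
        covariance = inv_info @ (resid.T @ resid) @ inv_info
    else:
        covariance = inv_info
    return CoxFit(beta=beta, covariance=covariance,
                  se=np.sqrt(np.diag(covariance)), iterations=it,
                  converged=converged, loglik=loglik,
                  names=names or [f"z{k}" for k in range(p)])


def _score_residuals(beta, Z, weight, status, time, tgrid, dw, mask):
    """Per-subject weighted score residuals U_i; they sum to the score.

    U_i = w_i delta_i (Z_i - Zbar(T_i))
          - sum_e Y*_i(t_e) (dw_e / S0_e) w_i e^{beta'Z_i} (Z_i - Zbar(t_e)).
    """
    we = weight * np.exp(Z @ beta)
    s0 = mask @ we
    zbar = (mask @ (we[:, None] * Z)) / s0[:, None]
    ev = status == 1
    n, p = Z.shape
    U = np.zeros((n, p))
    own_row = np.searchsorted(tgrid, time[ev])
    U[ev] = weight[ev, None] * (Z[ev] - zbar[own_row])
    A = dw / s0
    U -= we[:, None] * (Z * (mask.T @ A)[:, None]
                        - mask.T @ (A[:, None] * zbar))
    return U


def nelson_aalen(sample: LTRCSample) -> StepFunction:
    """Nelson-Aalen cumulative-hazard estimate with truncated risk sets.

    The increment at each distinct event time is (events at t) / (number at
    risk under ``Y*``); tied events share a single jump.
    """
    if not (sample.status == 1).any():
        return StepFunction(times=np.empty(0), increments=np.empty(0))
    ev = sample.status == 1
    tgrid, d = np.unique(sample.time[ev], return_counts=True)
    # Y*(t) = #{L < t} - #{T < t}; O(n log n) via sorted-array counts
    entry_sorted = np.sort(sample.entry)
    time_sorted = np.sort(sample.time)
    y = (np.searchsorted(entry_sorted, tgrid, side="left")
         - np.searchsorted(time_sorted, tgrid, side="left")).astype(float)
    if np.any(y == 0):
        t_bad = tgrid[np.argmax(y == 0)]
        raise EstimationError(f"no subjects at risk at event time {t_bad}")
    return StepFunction(times=tgrid, increments=d.astype(float) / y)


def breslow_h0(sample: LTRCSample, fit: CoxFit) -> StepFunction:
    """Breslow cumulative baseline hazard given fitted coefficients.

    Increment at event time t:  (sum of weights of events at t) /
    (sum_j w_j Y*_j(t) exp(beta' Z_j)).  Reduces to ``nelson_aalen`` at
    ``beta = 0`` with unit weights.
    """
    if np.isnan(sample.x).any():
        raise ValueError("breslow_h0 requires complete x")
    tgrid, dw, mask = _event_structure(sample)
    if tgrid.size == 0:
        return StepFunction(times=np.empty(0), increments=np.empty(0))
    we = sample.weight * np.exp(sample.design_matrix() @ fit.beta)
    s0 = mask @ we
    if np.any(s0 == 0):
        t_bad = tgrid[np.argmax(s0 == 0)]
        raise EstimationError(f"no subjects at risk at event time {t_bad}")
    return StepFunction(times=tgrid, increments=dw / s0)
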