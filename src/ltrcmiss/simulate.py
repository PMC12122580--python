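"""Synthetic left-truncated right-censored samples with covariate missingness.

The generative design mirrors a prospective cohort with delayed entry:

* three binary covariates ``W ~ iid Bernoulli(0.5)``;
* the covariate of interest ``X | W`` logistic with intercept ``eta0 = 0.5``
  and slopes ``eta1 = (log 2, -log 2, log 1.5)``;
* failure times from a Cox model with Weibull baseline hazard
  ``h0(t) = rho * kappa * (rho t)^(kappa - 1)``, ``rho = 0.1``,
  ``kappa = 0.5``, W-coefficients ``beta2 = (log 2, -log 2, log 1.5)`` and an
  X coefficient of ``log 2`` or ``log 4``;
* entry times ``L ~ c1 * Beta(6, 1.5)``; subjects whose event precedes
  entry (``L >= T``) are discarded, which is the left-truncation selection;
* censoring ``C = c1 + C'`` with ``C' ~ Weibull(shape 4, scale c2)``, so
  ``P(C > L) = 1`` holds by construction;
* missingness in X that is MCAR (constant pi), related to the event
  indicator (``logit pi = a + log(4) * delta``), or related to the observed
  time (``logit pi = alpha0 - alpha1 * sqrt(T)``).

The free constants ``c1`` (entry scale), ``c2`` (censoring scale) and the
missingness intercept are calibrated by Monte Carlo bisection to hit the
requested truncation, censoring and missingness rates, in that dependency
order.  Calibrations use a fixed internal seed, distinct from simulation
seeds, and are cached per scenario.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .data import LTRCSample, expand_w
from .missingness import DegenerateSampleError

__all__ = [
    "ScenarioConfig",
    "Calibration",
    "gen_failure_time",
    "gen_sample",
    "calibrate",
    "get_calibration",
    "inject_missingness",
    "simulate_scenario",
    "CalibrationError",
]

#: internal seed for calibration draws — never used for simulation samples
CALIBRATION_SEED = 20240702
#: absolute tolerance on calibrated Monte Carlo rates
CALIBRATION_TOL = 0.005

MECHANISMS = ("MCAR", "MAR-delta", "MAR-T")


class CalibrationError(RuntimeError):
    """Bisection could not bracket or reach the target rate."""


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario (defaults: the reference study conditions)."""

    n: int = 300
    q: float = 0.0                      # target truncation rate P(L > T)
    lam: float = 0.1                    # target censoring rate, post-selection
    theta: float = 0.5                  # target missingness rate, post-selection
    beta1: float = math.log(4)
    beta2: tuple = (math.log(2), -math.log(2), math.log(1.5))
    eta0: float = 0.5
    eta1: tuple = (math.log(2), -math.log(2), math.log(1.5))
    rho: float = 0.1
    kappa: float = 0.5
    entry_shape: tuple = (6.0, 1.5)
    censor_shape: float = 4.0
    mechanism: str = "MCAR"
    mar_delta_slope: float = math.log(4)
    mar_t_slope: float | None = None    # defaults from the censoring rate

    def __post_init__(self):
        if not 0 <= self.q < 1:
            raise ValueError("q must be in [0, 1)")
        if not (0 < self.lam < 1 and 0 < self.theta < 1):
            raise ValueError("lam and theta must be in (0, 1)")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        if min(self.rho, self.kappa, self.censor_shape,
               *self.entry_shape) <= 0:
            raise ValueError("scale/shape parameters must be positive")

    @property
    def t_slope(self) -> float:
        """alpha1 of the T-dependent mechanism; steeper under heavy censoring
        because censoring compresses the observed-time distribution."""
        if self.mar_t_slope is not None:
            return self.mar_t_slope
        return math.log(1.25) if self.lam <= 0.3 else math.log(3)

    def _rate_key(self) -> tuple:
        """Cache key for calibration: everything except n."""
        return (self.q, self.lam, self.theta, self.beta1, self.beta2,
                self.eta0, self.eta1, self.rho, self.kappa, self.entry_shape,
                self.censor_shape, self.mechanism, self.mar_delta_slope,
                self.t_slope)


@dataclass
class Calibration:
    c1: float
    c2: float
    intercept: float


def gen_failure_time(config: ScenarioConfig, linear_predictor: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Failure times by inverse-transform from the Weibull-baseline Cox model.

    With ``H0(t) = (rho t)^kappa`` and hazard multiplier ``exp(lp)``,
    ``U = (1/rho) * (-log u * exp(-lp))^(1/kappa)`` for ``u ~ Uniform(0,1)``.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    u = rng.random(lp.shape)
    return (1.0 / config.rho) * (-np.log(u) * np.exp(-lp)) ** (1.0 / config.kappa)


def _draw_population(config: ScenarioConfig, size: int,
                     rng: np.random.Generator):
    """(W, X, U) for `size` subjects from the untruncated population."""
    W = (rng.random((size, 3)) < 0.5).astype(int)
    px = expit(config.eta0 + W @ np.asarray(config.eta1))
    X = (rng.random(size) < px).astype(float)
    lp = config.beta1 * X + W @ np.asarray(config.beta2)
    U = gen_failure_time(config, lp, rng)
    return W, X, U


def _bisect(g, lo: float, hi: float, increasing: bool, what: str,
            max_iter: int = 200) -> float:
    """Bisection on a monotone Monte Carlo rate function g (target 0)."""
    glo, ghi = g(lo), g(hi)
    expansions = 0
    while glo * ghi > 0:
        expansions += 1
        if expansions > 60:
            raise CalibrationError(
                f"could not bracket {what}: g({lo})={glo:.4f}, "
                f"g({hi})={ghi:.4f}")
        if (ghi < 0) == increasing:
            lo, hi = hi, hi * 2 if hi > 0 else 1.0
            glo, ghi = ghi, g(hi)
        else:
            hi, lo = lo, lo / 2 if lo > 0 else -1.0
            ghi, glo = glo, g(lo)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        gm = g(mid)
        if abs(gm) <= CALIBRATION_TOL / 4 or (hi - lo) < 1e-12 * max(1.0, abs(mid)):
            return mid
        if (gm > 0) == increasing:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


_CAL_CACHE: dict = {}


def calibrate(config: ScenarioConfig, target: str | None = None,
              mc_size: int = 200_000,
              rng_seed: int = CALIBRATION_SEED) -> float | Calibration:
    """Monte Carlo calibration of c1, c2 and the missingness intercept.

    Uses common random numbers across bisection steps, so each rate is a
    monotone deterministic function of the constant being solved for.
    Returns one constant when ``target`` in {"c1", "c2", "miss-intercept"}
    is given, otherwise the full :class:`Calibration`.
    """
    rng = np.random.default_rng(rng_seed)
    _, _, U = _draw_population(config, mc_size, rng)
    B = rng.beta(*config.entry_shape, mc_size)
    Wb = rng.weibull(config.censor_shape, mc_size)

    if config.q == 0:
        c1 = 0.0
    else:
        # L > T  <=>  L > U  (L < C always), so truncation depends on c1 only
        c1 = _bisect(lambda c: np.mean(c * B >= U) - config.q,
                     0.0, 1.0, increasing=True, what="c1")
    L = c1 * B
    retained = L < U
    Ur, Wbr = U[retained], Wb[retained]

    def cens_rate(c2):
        return np.mean(Ur > c1 + c2 * Wbr) - config.lam

    c2 = _bisect(cens_rate, 1e-6, 1.0, increasing=False, what="c2")
    T = np.minimum(Ur, c1 + c2 * Wbr)
    delta = (Ur <= c1 + c2 * Wbr).astype(float)

    if config.mechanism == "MCAR":
        intercept = float(logit(1.0 - config.theta))
    elif config.mechanism == "MAR-delta":
        intercept = _bisect(
            lambda a: np.mean(1.0 - expit(a + config.mar_delta_slope * delta))
            - config.theta,
            -5.0, 5.0, increasing=False, what="delta-MAR intercept")
    else:
        st = np.sqrt(T)
        intercept = _bisect(
            lambda a0: np.mean(1.0 - expit(a0 - config.t_slope * st))
            - config.theta,
            -5.0, 5.0, increasing=False, what="T-MAR intercept")

    cal = Calibration(c1=float(c1), c2=float(c2), intercept=float(intercept))
    if target is None:
        return cal
    try:
        return {"c1": cal.c1, "c2": cal.c2, "miss-intercept": cal.intercept}[target]
    except KeyError:
        raise ValueError(f"unknown calibration target {target!r}") from None


def get_calibration(config: ScenarioConfig) -> Calibration:
    """Cached calibration for the scenario's rate parameters."""
    key = config._rate_key()
    if key not in _CAL_CACHE:
        _CAL_CACHE[key] = calibrate(config)
    return _CAL_CACHE[key]


def gen_sample(config: ScenarioConfig,
               rng: np.random.Generator | int | None = None,
               calibration: Calibration | None = None):
    """One pre-missingness sample plus the latent record.

    Draws ``ceil(n / (1 - q))`` subjects and discards those with
    ``L >= T``; the retained count is random around ``n`` (trimming to
    exactly n would distort the entry distribution).  Returns
    ``(LTRCSample, latent)`` where ``latent`` holds the uncensored failure
    and censoring times of the retained subjects and the removal count.
    """
    rng = np.random.default_rng(rng)
    cal = calibration or get_calibration(config)
    m = math.ceil(config.n / (1.0 - config.q))
    W, X, U = _draw_population(config, m, rng)
    L = cal.c1 * rng.beta(*config.entry_shape, m) if config.q > 0 else np.zeros(m)
    C = cal.c1 + cal.c2 * rng.weibull(config.censor_shape, m)
    T = np.minimum(U, C)
    delta = (U <= C).astype(int)
    keep = L < T
    n_kept = int(keep.sum())
    if abs(n_kept - config.n) > 0.25 * config.n:
        warnings.warn(
            f"retained {n_kept} subjects vs target {config.n}: "
            "calibration drift", stacklevel=2)
    Tk = T[keep]
    if np.unique(Tk).size < Tk.size:
        warnings.warn("duplicate observed times in generated sample",
                      stacklevel=2)
    sample = LTRCSample(entry=L[keep], time=Tk, status=delta[keep],
                        x=X[keep], w=W[keep])
    latent = {"U": U[keep], "C": C[keep], "n_removed": m - n_kept,
              "calibration": cal}
    return sample, latent


def inject_missingness(sample: LTRCSample, config: ScenarioConfig,
                       intercept: float,
                       rng: np.random.Generator | int | None = None) -> LTRCSample:
    """Blank X at random according to the scenario's missingness mechanism."""
    rng = np.random.default_rng(rng)
    if config.mechanism == "MCAR":
        lp = np.full(sample.n, intercept)
    elif config.mechanism == "MAR-delta":
        lp = intercept + config.mar_delta_slope * sample.status
    else:
        lp = intercept - config.t_slope * np.sqrt(sample.time)
    R = (rng.random(sample.n) < expit(lp)).astype(int)
    n_params = 1 + expand_w(sample.w).shape[1]
    if R.sum() < n_params + 2:
        raise DegenerateSampleError(
            f"only {int(R.sum())} complete cases for {n_params} Cox parameters")
    x = np.where(R == 1, sample.x, np.nan)
    return sample.with_x(x)


def simulate_scenario(config: ScenarioConfig,
                      rng: np.random.Generator | int | None = None):
    """Generate one sample and apply missingness; returns (sample, latent)."""
    rng = np.random.default_rng(rng)
    cal = get_calibration(config)
    full, latent = gen_sample(config, rng, calibration=cal)
    miss = inject_missingness(full, config, cal.intercept, rng)
    latent["complete_sample"] = full
    return miss, latent
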