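"""Multiple imputation of a missing binary covariate under left truncation.

When X is binary, W categorical, and ``logit P(X=1|W) = eta0 + eta1'W``
in the population, the conditional law of X given the observed survival
data is again logistic, with predictors W, the event indicator, the
cumulative hazard at the observed time, and its interaction with W.  The
cumulative hazard is not known; it is replaced by the Nelson-Aalen estimate
of the marginal H(T), computed once on the full sample with
truncation-adjusted risk sets.  Each imputed dataset is analysed with the
truncated Cox model and the results are pooled with Rubin's rules.

Left truncation enters twice: through the risk-set adjustment in both the
hazard estimate and the analysis model, and — less benignly — through the
fact that the imputation model is estimated from a selection-biased sample,
which is exactly the failure mode this package's simulations quantify.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import t as t_dist

from .cox import ConvergenceError, StepFunction, fit_cox, nelson_aalen
from .data import LTRCSample, expand_w
from .missingness import DegenerateSampleError

__all__ = [
    "ImputationFit",
    "PooledEstimate",
    "build_imputation_design",
    "fit_imputation_model",
    "impute_once",
    "mi_estimate",
]


@dataclass
class ImputationFit:
    """Fit of the logistic imputation model on the complete cases."""

    coefficients: np.ndarray
    coefficient_covariance: np.ndarray
    n_complete: int


def _augmented_logit(y: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Augmented weighted logistic fit (White, Daniel & Royston stabiliser).

    The imputation design packs an intercept, W indicators, the event
    indicator, H(T) and H(T) x W interactions into a modest complete-case
    subsample, so quasi-separation is routine; unstabilised ML then yields
    near-infinite coefficients and a covariance that makes proper-MI
    coefficient redraws meaningless.  The standard remedy in the MI
    literature augments the data with lightly weighted pseudo-observations:
    for every predictor, rows at the predictor's mean +/- 0.5 SD (clamped to
    its observed range, other predictors at their means) paired with both
    outcome values, the pseudo-rows sharing total weight p + 1.  Returns
    (coefficients, inverse weighted information).
    """
    import statsmodels.api as sm

    X = design[:, 1:]                       # predictors without the intercept
    ncol = X.shape[1]
    mean, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    lo, hi = X.min(axis=0), X.max(axis=0)
    rows, ys = [], []
    for j in range(ncol):
        for yc in (0.0, 1.0):
            for sgn in (0.5, -0.5):
                r = mean.copy()
                r[j] = np.clip(mean[j] + sgn * sd[j], lo[j], hi[j])
                rows.append(r)
                ys.append(yc)
    Xa = np.vstack([X, np.array(rows)])
    Da = np.column_stack([np.ones(len(Xa)), Xa])
    ya = np.concatenate([y, np.array(ys)])
    w = np.concatenate([np.ones(len(y)),
                        np.full(len(rows), (ncol + 1) / len(rows))])
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        try:
            res = sm.GLM(ya, Da, family=sm.families.Binomial(),
                         var_weights=w).fit(maxiter=100)
        except np.linalg.LinAlgError as exc:
            raise DegenerateSampleError(
                f"singular imputation-model information: {exc}") from exc
    coef = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    if not (np.all(np.isfinite(coef)) and np.all(np.isfinite(cov))):
        raise DegenerateSampleError(
            "imputation model produced non-finite estimates")
    return coef, cov


def build_imputation_design(sample: LTRCSample, H: StepFunction) -> np.ndarray:
    """Per-subject imputation-model row ``(1, W, delta, H(T), H(T)*W)``.

    ``H`` is evaluated right-continuously at the observed time, so a subject
    whose T precedes the first jump contributes H = 0.
    """
    Wx = expand_w(sample.w)
    h = H(sample.time)
    return np.column_stack([
        np.ones(sample.n), Wx, sample.status.astype(float), h,
        h[:, None] * Wx,
    ])


def fit_imputation_model(sample: LTRCSample, H: StepFunction) -> ImputationFit:
    """Stabilised logistic fit of X on the imputation design, complete
    cases only (see :func:`_augmented_logit` for why stabilised)."""
    mask = sample.r == 1
    design = build_imputation_design(sample, H)[mask]
    x = sample.x[mask]
    if design.shape[0] < design.shape[1]:
        raise DegenerateSampleError(
            f"{design.shape[0]} complete cases cannot identify "
            f"{design.shape[1]} imputation-model terms")
    if x.min() == x.max():
        raise DegenerateSampleError("x is constant among complete cases")
    coef, cov = _augmented_logit(x, design)
    return ImputationFit(coefficients=coef, coefficient_covariance=cov,
                         n_complete=int(mask.sum()))


def impute_once(sample: LTRCSample, fit: ImputationFit, H: StepFunction,
                rng: np.random.Generator, proper: bool = True) -> LTRCSample:
    """One proper imputation of the missing X values.

    The imputation-model coefficients are redrawn from their asymptotic
    normal approximation (proper MI, required for Rubin's-rules variance
    validity; the augmented fit keeps the approximation well behaved), then
    missing X are drawn Bernoulli from the implied probabilities.  Observed
    X are untouched.  ``proper=False`` imputes at the fitted coefficients,
    which understates the between-imputation variance.
    """
    miss = sample.r == 0
    if not miss.any():
        return sample
    coef = fit.coefficients
    if proper:
        coef = rng.multivariate_normal(fit.coefficients,
                                       fit.coefficient_covariance,
                                       method="eigh")
    p = expit(build_imputation_design(sample, H)[miss] @ coef)
    x = sample.x.copy()
    x[miss] = (rng.random(miss.sum()) < p).astype(float)
    return sample.with_x(x)


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of per-imputation Cox fits."""

    m: int
    point: np.ndarray
    within: np.ndarray           # mean of per-imputation covariances
    between: np.ndarray          # empirical covariance of the estimates
    total: np.ndarray            # within + (1 + 1/m) * between
    se: np.ndarray
    df: np.ndarray               # Rubin (1987) per-coefficient df
    ci: np.ndarray               # (p, 2) t-based 95% interval
    names: list


def pool_rubin(betas: np.ndarray, covariances: np.ndarray,
               names: list | None = None, level: float = 0.95) -> PooledEstimate:
    """Rubin's rules for m point estimates and their covariances."""
    m = betas.shape[0]
    point = betas.mean(axis=0)
    within = covariances.mean(axis=0)
    dev = betas - point
    between = (dev.T @ dev) / (m - 1) if m > 1 else np.zeros_like(within)
    total = within + (1.0 + 1.0 / m) * between
    se = np.sqrt(np.diag(total))
    w_d, b_d = np.diag(within), np.diag(between)
    df = np.full_like(w_d, np.inf)
    pos = b_d > 0
    df[pos] = (m - 1) * (1.0 + w_d[pos] / ((1.0 + 1.0 / m) * b_d[pos])) ** 2
    tq = np.where(np.isfinite(df), t_dist.ppf(0.5 + level / 2.0,
                                              np.where(np.isfinite(df), df, 1.0)),
                  t_dist.ppf(0.5 + level / 2.0, 1e9))
    ci = np.column_stack([point - tq * se, point + tq * se])
    return PooledEstimate(m=m, point=point, within=within, between=between,
                          total=total, se=se, df=df, ci=ci,
                          names=names or [])


def mi_estimate(sample: LTRCSample, m: int = 100,
                rng: np.random.Generator | int | None = None,
                proper: bool = True, **cox_kwargs) -> PooledEstimate:
    """Full MI pipeline: Nelson-Aalen H, imputation fits, Rubin pooling.

    ``H(T)`` is estimated once on the full sample (complete and incomplete
    subjects) with truncation-adjusted risk sets.  Imputations whose Cox fit
    fails to converge are rejected and redrawn, up to ``3 m`` attempts.
    """
    if m < 2:
        raise ValueError("m must be at least 2 for Rubin's rules")
    if not (sample.r == 0).any():
        raise ValueError("sample has no missing x; MI is not applicable")
    rng = np.random.default_rng(rng)
    H = nelson_aalen(sample)
    imp_fit = fit_imputation_model(sample, H)

    # the risk-set structure is shared by every completed dataset: only x
    # changes between imputations, so precompute it once
    from .cox import _event_structure, _newton_cox
    from .data import expand_w
    tgrid, dw, mask = _event_structure(sample)
    Wx = expand_w(sample.w)
    design_miss = build_imputation_design(sample, H)[sample.r == 0]
    miss = sample.r == 0
    names = ["x"] + [f"w{k+1}" for k in range(Wx.shape[1])]
    weight = sample.weight

    betas, covs = [], []
    attempts = 0
    while len(betas) < m:
        attempts += 1
        if attempts > 3 * m:
            raise ConvergenceError(
                f"only {len(betas)}/{m} imputations produced a converged "
                f"Cox fit after {attempts} attempts")
        coef = imp_fit.coefficients
        if proper:
            coef = rng.multivariate_normal(imp_fit.coefficients,
                                           imp_fit.coefficient_covariance,
                                           method="eigh")
        p_miss = expit(design_miss @ coef)
        x = sample.x.copy()
        x[miss] = (rng.random(miss.sum()) < p_miss).astype(float)
        try:
            fit = _newton_cox(np.column_stack([x, Wx]), weight,
                              sample.status, sample.time, tgrid, dw, mask,
                              names=names, **cox_kwargs)
        except ConvergenceError:
            continue
        betas.append(fit.beta)
        covs.append(fit.covariance)
    return pool_rubin(np.array(betas), np.array(covs), names=names)
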