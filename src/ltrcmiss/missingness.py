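"""Missingness-probability modelling, complete-case and IPW estimators.

``pi_i = P(R_i = 1 | data)`` is the probability that the covariate of
interest is observed for subject i.  Under a missing-at-random mechanism
that depends on the observed outcome, the complete-case subsample is not
representative; weighting complete cases by ``1 / pi_i`` restores
representativeness provided the pi model is correctly specified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .cox import CoxFit, fit_cox
from .data import LTRCSample, expand_w

__all__ = [
    "PiModel",
    "fit_pi",
    "ipw_fit",
    "complete_cases",
    "build_terms",
    "PI_FLOOR",
    "DegenerateSampleError",
    "SeparationError",
]

#: fitted probabilities below this raise rather than silently exploding weights
PI_FLOOR = 1e-6

#: recognised term names for pi-model (and general logistic) designs
TERM_NAMES = ("1", "delta", "sqrtT", "lateT", "lateL")


class DegenerateSampleError(ValueError):
    """The requested analysis is undefined on this sample (e.g. no complete
    cases, or R constant)."""


class SeparationError(RuntimeError):
    """Logistic ML estimate does not exist (complete separation)."""


def build_terms(sample: LTRCSample, spec: list[str]) -> np.ndarray:
    """Design matrix for the term mini-language.

    Recognised terms: ``1`` (intercept), ``delta``, ``sqrtT``, ``w<k>``
    (indicator expansion of the k-th W column), ``lateT`` / ``lateL``
    (median splits of T and L).
    """
    cols, idx = [], []
    for term in spec:
        if term == "1":
            cols.append(np.ones(sample.n))
        elif term == "delta":
            cols.append(sample.status.astype(float))
        elif term == "sqrtT":
            cols.append(np.sqrt(sample.time))
        elif term == "lateT":
            cols.append((sample.time > np.median(sample.time)).astype(float))
        elif term == "lateL":
            cols.append((sample.entry > np.median(sample.entry)).astype(float))
        elif term.startswith("w") and term[1:].isdigit():
            k = int(term[1:]) - 1
            if not 0 <= k < sample.n_w:
                raise ValueError(f"term {term!r}: sample has {sample.n_w} W columns")
            block = expand_w(sample.w[:, [k]])
            cols.extend(block.T)
        else:
            raise ValueError(f"unknown pi-model term {term!r}")
    return np.column_stack(cols)


@dataclass
class PiModel:
    """Fitted logistic model for P(R = 1 | terms)."""

    terms: list
    coefficients: np.ndarray
    fitted_pi: np.ndarray


def _logit_ml(y: np.ndarray, design: np.ndarray, context: str) -> tuple[np.ndarray, np.ndarray]:
    """Logistic ML fit returning (coefficients, covariance).

    Uses IRLS (as R's ``glm`` does); quasi-separated fits with large but
    finite coefficients are accepted — only a genuinely nonexistent MLE
    (perfect separation, non-finite estimates) raises SeparationError.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(
                maxiter=100)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                np.linalg.LinAlgError) as exc:
            raise SeparationError(
                f"{context}: complete separation; consider a smaller model "
                "(e.g. intercept only)") from exc
    coef = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    if not (np.all(np.isfinite(coef)) and np.all(np.isfinite(cov))):
        raise SeparationError(
            f"{context}: logistic ML produced non-finite estimates "
            "(separation); consider a smaller model (e.g. intercept only)")
    return coef, cov


def fit_pi(sample: LTRCSample, predictor_spec: list[str]) -> PiModel:
    """Maximum-likelihood logistic regression of R on the specified terms."""
    r = sample.r.astype(float)
    if r.min() == r.max():
        raise DegenerateSampleError("R is constant; pi model is undefined")
    design = build_terms(sample, predictor_spec)
    if sample.n < design.shape[1]:
        raise DegenerateSampleError(
            f"n={sample.n} smaller than the {design.shape[1]}-term pi design")
    coef, _ = _logit_ml(r, design, "pi model")
    from scipy.special import expit
    fitted = expit(design @ coef)
    return PiModel(terms=list(predictor_spec), coefficients=coef, fitted_pi=fitted)


def complete_cases(sample: LTRCSample) -> LTRCSample:
    """Subsample with X observed; weights reset to 1."""
    mask = sample.r == 1
    if not mask.any():
        raise DegenerateSampleError("no complete cases")
    sub = sample.subset(mask)
    return sub.with_weight(np.ones(sub.n))


def ipw_fit(sample: LTRCSample, pi: PiModel, **cox_kwargs) -> CoxFit:
    """Inverse-probability-weighted truncated Cox fit.

    Complete cases receive weight ``1 / pi_hat_i``; the weighted partial
    likelihood is then maximised as usual.  The covariance is a robust
    sandwich built from per-subject score residuals (the inverse weighted
    information alone is badly anti-conservative when weights are inverse
    probabilities of order 1/pi); it still ignores the estimation of
    ``pi_hat`` itself and is mildly approximate.
    """
    if pi.fitted_pi.shape[0] != sample.n:
        raise ValueError("pi model was fitted on a different sample")
    if np.any(pi.fitted_pi < PI_FLOOR):
        raise ValueError(
            f"fitted pi below {PI_FLOOR}: weights would explode")
    mask = sample.r == 1
    if not mask.any():
        raise DegenerateSampleError("no complete cases")
    sub = sample.subset(mask).with_weight(1.0 / pi.fitted_pi[mask])
    cox_kwargs.setdefault("robust", True)
    return fit_cox(sub, use_weights=True, **cox_kwargs)
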