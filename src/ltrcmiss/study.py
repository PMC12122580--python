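"""Monte Carlo scenario runner: bias / SD / mean(SE) / coverage per method.

One scenario fixes a data-generating configuration (truncation, censoring,
missingness rates, hazard ratios, mechanism) and runs each requested
estimator on ``reps`` independent samples.  Reported per method:

* ``bias``      mean(beta1_hat) - beta1 and ``pct_bias`` = 100 * bias / beta1;
* ``sd``        empirical standard deviation of beta1_hat;
* ``mean_se``   mean of the per-replicate standard-error estimates;
* ``coverage``  fraction of nominal-95% intervals containing beta1;
* ``failures``  non-converged replicates (excluded from the summaries).

Method labels:  ``CD`` (complete data, the no-missingness benchmark),
``CC`` (complete case), ``IPW``, ``AIPW``, ``MI``; IPW/AIPW labels may carry
a suffix (e.g. ``IPW_piI``) to run the same estimator under a different
missingness-model specification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .aipw import aipw_fit, bootstrap_se

from .cox import fit_cox
from .mi import mi_estimate
from .missingness import complete_cases, fit_pi, ipw_fit
from .simulate import ScenarioConfig, gen_sample, get_calibration, \
    inject_missingness

__all__ = ["run_scenario", "compare_tables", "default_pi_spec"]

Z95 = 1.959963984540054


def default_pi_spec(config: ScenarioConfig) -> list[str]:
    """The correctly specified missingness model for each mechanism."""
    return {"MCAR": ["1", "w1"],
            "MAR-delta": ["1", "delta"],
            "MAR-T": ["1", "sqrtT"]}[config.mechanism]


def _base_method(label: str) -> str:
    return label.split("_")[0].upper()


def run_scenario(config: ScenarioConfig, methods: list[str],
                 pi_specs: dict[str, list[str]] | None = None,
                 reps: int = 500, master_seed: int = 0,
                 m_mi: int = 100, aipw_boot: int = 0,
                 mi_seed_offset: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run one scenario; returns (metrics table, replicate-level results).

    ``pi_specs`` maps a method label to its missingness-model terms; labels
    without an entry use the mechanism's correct specification.  AIPW
    confidence intervals require a bootstrap (``aipw_boot`` replicates per
    simulation replicate); with ``aipw_boot = 0`` AIPW reports point
    estimates only and its SE/coverage are NaN.
    """
    pi_specs = pi_specs or {}
    cal = get_calibration(config)
    seeds = np.random.SeedSequence(master_seed).spawn(reps)
    rows = []
    for rep, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        full, _ = gen_sample(config, rng, calibration=cal)
        miss = inject_missingness(full, config, cal.intercept, rng)
        for label in methods:
            kind = _base_method(label)
            est = se = lo = hi = np.nan
            ok = True
            try:
                if kind == "CD":
                    fit = fit_cox(full)
                    est, se = fit.beta[0], fit.se[0]
                    lo, hi = est - Z95 * se, est + Z95 * se
                elif kind == "CC":
                    fit = fit_cox(complete_cases(miss))
                    est, se = fit.beta[0], fit.se[0]
                    lo, hi = est - Z95 * se, est + Z95 * se
                elif kind == "IPW":
                    spec = pi_specs.get(label, default_pi_spec(config))
                    fit = ipw_fit(miss, fit_pi(miss, spec))
                    est, se = fit.beta[0], fit.se[0]
                    lo, hi = est - Z95 * se, est + Z95 * se
                elif kind == "AIPW":
                    spec = pi_specs.get(label, default_pi_spec(config))
                    fit = aipw_fit(miss, fit_pi(miss, spec))
                    est = fit.beta[0]
                    if aipw_boot > 0:
                        boot_se, _ = bootstrap_se(miss, spec, n_boot=aipw_boot,
                                                  rng=rng)
                        se = boot_se[0]
                        lo, hi = est - Z95 * se, est + Z95 * se
                elif kind == "MI":
                    pooled = mi_estimate(miss, m=m_mi, rng=rng)
                    est, se = pooled.point[0], pooled.se[0]
                    lo, hi = pooled.ci[0]
                else:
                    raise ValueError(f"unknown method label {label!r}")
            except Exception:
                ok = False
            rows.append({"rep": rep, "method": label, "converged": ok,
                         "estimate": est, "se": se, "ci_lo": lo, "ci_hi": hi})
    replicates = pd.DataFrame(rows)

    out = []
    for label in methods:
        sub = replicates[replicates.method == label]
        good = sub[sub.converged]
        est = good.estimate.to_numpy()
        cov_mask = good.ci_lo.notna() & good.ci_hi.notna()
        cov = ((good.ci_lo[cov_mask] <= config.beta1)
               & (config.beta1 <= good.ci_hi[cov_mask]))
        bias = est.mean() - config.beta1 if len(est) else np.nan
        out.append({
            "mechanism": config.mechanism, "q": config.q, "lam": config.lam,
            "theta": config.theta, "beta1": config.beta1, "n": config.n,
            "method": label, "reps": len(sub),
            "bias": bias, "pct_bias": 100.0 * bias / config.beta1,
            "sd": est.std(ddof=1) if len(est) > 1 else np.nan,
            "mean_se": good.se.mean() if good.se.notna().any() else np.nan,
            "coverage": cov.mean() if cov_mask.any() else np.nan,
            "failures": int((~sub.converged).sum()),
        })
        if (~sub.converged).sum() > 0.1 * len(sub):
            import warnings
            warnings.warn(f"method {label}: >10% replicate failures",
                          stacklevel=2)
    return pd.DataFrame(out), replicates


def compare_tables(metrics: pd.DataFrame, reference: pd.DataFrame,
                   mc_tolerance_multiplier: float = 2.0) -> pd.DataFrame:
    """Cell-by-cell comparison of computed metrics against printed values.

    ``reference`` rows carry ``method``, ``metric`` (one of bias / sd /
    mean_se / coverage), the printed ``value``, the scenario keys present in
    ``metrics`` (e.g. ``q``), and for bias cells the printed Monte Carlo
    ``sd`` used to scale the sampling band.  Pass bands:

    * bias:      |computed - printed| <= multiplier * printed_sd / sqrt(reps)
    * sd, mean_se: 15% relative
    * coverage:  2 * sqrt(0.05 * 0.95 / reps) + 0.02
    """
    keys = [k for k in ("mechanism", "q", "lam", "theta", "beta1", "n")
            if k in reference.columns]
    merged = reference.merge(metrics, on=keys + ["method"], how="inner",
                             suffixes=("_ref", ""))
    if merged.empty:
        raise ValueError("no scenario/method overlap between computed "
                         "metrics and the reference table")
    rows = []
    for _, row in merged.iterrows():
        metric = row["metric"]
        computed = row[metric]
        printed = row["value"]
        reps = row["reps"]
        if metric == "bias":
            tol = mc_tolerance_multiplier * row["sd_ref"] / np.sqrt(reps)
        elif metric in ("sd", "mean_se"):
            tol = 0.15 * abs(printed)
        elif metric == "coverage":
            tol = 2.0 * np.sqrt(0.05 * 0.95 / reps) + 0.02
        else:
            raise ValueError(f"unknown metric {metric!r}")
        rows.append({**{k: row[k] for k in keys}, "method": row["method"],
                     "metric": metric, "printed": printed,
                     "computed": computed, "tolerance": tol,
                     "pass": bool(abs(computed - printed) <= tol)})
    return pd.DataFrame(rows)
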