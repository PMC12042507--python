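"""Inverse-variance meta-analysis of per-cohort association results.

Continuous outcomes are pooled with a fixed-effects model; binary outcomes
with a DerSimonian-Laird random-effects model on the log-odds-ratio scale,
matching the convention of pooling regression coefficients and log ORs with
normal 95% intervals (multiplier 1.96).  Heterogeneity is summarized by
Cochran's Q and the DL between-cohort variance tau^2 (truncated at zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import InputError

Z_95 = 1.959963984540054


@dataclass(frozen=True)
class MetaResult:
    model: str  # "fixed" | "random"
    k: int
    pooled: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    q_stat: float
    tau2: float
    weights: tuple[float, ...]  # normalized, sum to 1
    labels: tuple[str, ...]
    note: str = ""


def _validate(estimates, ses, labels):
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.shape != se.shape or est.ndim != 1 or len(est) == 0:
        raise InputError("estimates and standard errors must be equal-length 1-d arrays")
    if np.any(~np.isfinite(est)) or np.any(~np.isfinite(se)):
        raise InputError("estimates and standard errors must be finite")
    if np.any(se <= 0):
        raise InputError("standard errors must be positive")
    if labels is None:
        labels = tuple(f"study_{i + 1}" for i in range(len(est)))
    else:
        labels = tuple(str(x) for x in labels)
        if len(labels) != len(est):
            raise InputError("labels length mismatch")
    return est, se, labels


def _finish(model, est, se_i, labels, weights_raw, tau2, q_stat, note=""):
    w = weights_raw / weights_raw.sum()
    pooled = float(np.sum(w * est))
    pooled_se = float(1.0 / np.sqrt(weights_raw.sum()))
    z = pooled / pooled_se
    return MetaResult(
        model=model,
        k=len(est),
        pooled=pooled,
        se=pooled_se,
        ci_low=pooled - Z_95 * pooled_se,
        ci_high=pooled + Z_95 * pooled_se,
        z=float(z),
        p=float(2 * norm.sf(abs(z))),
        q_stat=float(q_stat),
        tau2=float(tau2),
        weights=tuple(float(x) for x in w),
        labels=labels,
        note=note,
    )


def _q_statistic(est: np.ndarray, w: np.ndarray) -> float:
    pooled = np.sum(w * est) / np.sum(w)
    return float(np.sum(w * (est - pooled) ** 2))


def fixed_effects(estimates, ses, labels=None) -> MetaResult:
    """Inverse-variance fixed-effects pooling (weights 1/se^2)."""
    est, se, labels = _validate(estimates, ses, labels)
    w = 1.0 / se**2
    q = _q_statistic(est, w)
    note = "single study: pass-through" if len(est) == 1 else ""
    return _finish("fixed", est, se, labels, w, tau2=0.0, q_stat=q, note=note)


def random_effects(estimates, ses, labels=None, method: str = "dl") -> MetaResult:
    """Random-effects pooling with a DerSimonian-Laird (default) or REML
    between-study variance estimate.

    DL: tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) with
    fixed-effects weights w = 1/se^2.  REML: tau^2 maximizes the restricted
    log-likelihood (bounded scalar search).  Either way the pooled estimate
    uses weights 1/(se^2 + tau^2).  A single study passes through
    (tau^2 = 0).
    """
    est, se, labels = _validate(estimates, ses, labels)
    if method not in ("dl", "reml"):
        raise InputError(f"unknown tau^2 estimator {method!r}")
    w_fixed = 1.0 / se**2
    q = _q_statistic(est, w_fixed)
    k = len(est)
    if k == 1:
        return _finish("random", est, se, labels, w_fixed, 0.0, q, "single study: pass-through")
    if method == "dl":
        denom = w_fixed.sum() - (w_fixed**2).sum() / w_fixed.sum()
        tau2 = max(0.0, (q - (k - 1)) / denom)
    else:
        tau2 = _reml_tau2(est, se)
    w = 1.0 / (se**2 + tau2)
    return _finish("random", est, se, labels, w, tau2, q)


def _restricted_loglik(tau2: float, est: np.ndarray, se: np.ndarray) -> float:
    v = se**2 + tau2
    w = 1.0 / v
    mu = np.sum(w * est) / np.sum(w)
    return float(
        -0.5 * np.sum(np.log(v))
        - 0.5 * np.log(np.sum(w))
        - 0.5 * np.sum(w * (est - mu) ** 2)
    )


def _reml_tau2(est: np.ndarray, se: np.ndarray) -> float:
    from scipy.optimize import minimize_scalar

    # generous bracket: between-study variance cannot usefully exceed the
    # total spread of the estimates plus the largest within-study variance
    upper = max(float(np.var(est)) * 10 + float(np.max(se)) ** 2 * 10, 1e-3)
    result = minimize_scalar(
        lambda t: -_restricted_loglik(t, est, se),
        bounds=(0.0, upper),
        method="bounded",
        options={"xatol": 1e-12},
    )
    tau2 = float(result.x)
    # the bounded search can stall a hair inside the boundary
    if _restricted_loglik(0.0, est, se) >= _restricted_loglik(tau2, est, se):
        return 0.0
    return tau2


def pool_all(
    cohort_results: pd.DataFrame,
    model: str = "auto",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool per-cohort association results over every outcome-by-stratum cell.

    ``cohort_results`` is the concatenated association sheet with a
    ``cohort`` column plus ``outcome``, ``stratum``, ``model`` ("linear" /
    "logistic"), ``estimate`` (coefficient or log OR) and ``se``.  With
    ``model="auto"`` continuous (linear) outcomes are pooled fixed-effects
    and binary (logistic) outcomes random-effects.

    Returns the pooled table and a forest-plot table with one row per cohort
    per cell plus a pooled row (kind = "study" / "pooled").
    """
    required = {"cohort", "outcome", "stratum", "model", "estimate", "se"}
    missing = required - set(cohort_results.columns)
    if missing:
        raise InputError(f"cohort results missing columns: {sorted(missing)}")
    if model not in ("auto", "fixed", "random"):
        raise InputError(f"unknown pooling model {model!r}")

    pooled_rows = []
    forest_rows = []
    for (outcome, stratum, model_type), cell in cohort_results.groupby(
        ["outcome", "stratum", "model"], sort=True
    ):
        cell = cell.sort_values("cohort")
        use = (
            {"linear": "fixed", "logistic": "random"}[model_type]
            if model == "auto"
            else model
        )
        pool_fn = fixed_effects if use == "fixed" else random_effects
        res = pool_fn(cell["estimate"], cell["se"], cell["cohort"])
        is_binary = model_type == "logistic"
        pooled_rows.append(
            {
                "outcome": outcome,
                "stratum": stratum,
                "model_type": model_type,
                "pool_model": res.model,
                "k": res.k,
                "estimate": res.pooled,
                "se": res.se,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "z": res.z,
                "p": res.p,
                "q_stat": res.q_stat,
                "tau2": res.tau2,
                "or": np.exp(res.pooled) if is_binary else np.nan,
                "or_ci_low": np.exp(res.ci_low) if is_binary else np.nan,
                "or_ci_high": np.exp(res.ci_high) if is_binary else np.nan,
                "note": res.note,
            }
        )
        for (_, row), weight in zip(cell.iterrows(), res.weights):
            forest_rows.append(
                {
                    "outcome": outcome,
                    "stratum": stratum,
                    "kind": "study",
                    "label": row["cohort"],
                    "estimate": row["estimate"],
                    "ci_low": row["estimate"] - Z_95 * row["se"],
                    "ci_high": row["estimate"] + Z_95 * row["se"],
                    "weight": weight,
                }
            )
        forest_rows.append(
            {
                "outcome": outcome,
                "stratum": stratum,
                "kind": "pooled",
                "label": f"pooled ({res.model})",
                "estimate": res.pooled,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "weight": 1.0,
            }
        )
    return pd.DataFrame(pooled_rows), pd.DataFrame(forest_rows)
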