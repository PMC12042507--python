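"""Per-cohort association of the proxy usage label with phenotypes.

Continuous outcomes are rank-based inverse-normal transformed (Blom offset
c = 3/8, average ranks for ties) and fitted by ordinary least squares with
age, sex and fasting status as covariates.  Binary outcomes are fitted by
maximum-likelihood logistic regression adjusted for age and sex, and are
only analysed when the cohort has more than ``min_cases`` cases.  P-values
within one cohort, stratum and model type form a Benjamini-Hochberg FDR
family.

The exposure throughout is the elevated-vs-control contrast of the proxy
usage label; excluded samples never enter a model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .errors import CollinearityError, ConvergenceError, InputError, InsufficientDataError
from .proxy import CONTROL, ELEVATED

Z_95 = 1.959963984540054  # standard normal 97.5% quantile

DEFAULT_CONTINUOUS_OUTCOMES: tuple[str, ...] = (
    "systolic_bp",
    "diastolic_bp",
    "total_cholesterol",
    "hdl_cholesterol",
    "non_hdl_cholesterol",
    "ldl_cholesterol",
    "glucose",
    "insulin",
)
DEFAULT_BINARY_OUTCOMES: tuple[str, ...] = (
    "hypertension",
    "type2_diabetes",
    "stroke",
    "death",
)

STRATA: tuple[str, ...] = ("all", "women", "men")


@dataclass
class AssocResult:
    outcome: str
    stratum: str
    model: str  # "linear" | "logistic"
    estimate: float
    se: float
    p: float
    n: int
    n_cases: int | None = None
    odds_ratio: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    q: float | None = None
    note: str = ""
    dropped_rows: int = 0


@dataclass
class SkippedOutcome:
    outcome: str
    stratum: str
    reason: str


def inverse_normal_transform(values, c: float = 3.0 / 8.0) -> pd.Series | np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    Non-missing values map to Phi^-1((r - c) / (m - 2c + 1)) with average
    ranks for ties; missing values stay missing.  At least two non-missing
    values are required.
    """
    is_series = isinstance(values, pd.Series)
    x = values.to_numpy(dtype=float) if is_series else np.asarray(values, dtype=float)
    mask = ~np.isnan(x)
    m = int(mask.sum())
    if m < 2:
        raise InputError(f"inverse-normal transform needs >= 2 non-missing values, got {m}")
    out = np.full_like(x, np.nan, dtype=float)
    ranks = rankdata(x[mask], method="average")
    out[mask] = ndtri((ranks - c) / (m - 2 * c + 1))
    if is_series:
        return pd.Series(out, index=values.index, name=values.name)
    return out


def _design(
    data: pd.DataFrame, covariates: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    cols = ["const", "elevated", *covariates]
    X = np.column_stack(
        [np.ones(len(data)), data["elevated"].to_numpy(dtype=float)]
        + [data[c].to_numpy(dtype=float) for c in covariates]
    )
    return X, cols


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns whose removal restores full rank
        suspects = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise CollinearityError(suspects or names)


def fit_linear(
    data: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] = ("age", "sex", "fasting"),
) -> AssocResult:
    """OLS of a (transformed) continuous outcome on the elevated indicator.

    ``data`` must contain the outcome, an ``elevated`` 0/1 column and the
    covariates; rows with any missing value are dropped (complete case).
    """
    needed = [outcome, "elevated", *covariates]
    sub = data[needed].dropna()
    dropped = len(data) - len(sub)
    X, names = _design(sub, covariates)
    if len(sub) <= X.shape[1]:
        raise InsufficientDataError(
            f"{len(sub)} usable rows for {X.shape[1]} parameters ({outcome})"
        )
    _check_rank(X, names)
    fit = sm.OLS(sub[outcome].to_numpy(dtype=float), X).fit()
    note = ""
    if fit.ssr <= 1e-12:
        note = "zero residual variance (perfect fit)"
    return AssocResult(
        outcome=outcome,
        stratum="all",
        model="linear",
        estimate=float(fit.params[1]),
        se=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
        n=len(sub),
        note=note,
        dropped_rows=dropped,
    )


def fit_logistic(
    data: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] = ("age", "sex"),
    min_cases: int = 10,
    tol: float = 1e-10,
    maxiter: int = 100,
) -> AssocResult:
    """Maximum-likelihood logistic fit of a binary outcome on the elevated
    indicator, with Wald standard errors and a 95% CI on the odds ratio.

    Cohorts with ``min_cases`` or fewer cases are not analysed: the caller
    receives :class:`InsufficientDataError` and records the skip.
    Separation or non-convergence raises :class:`ConvergenceError`.
    """
    needed = [outcome, "elevated", *covariates]
    sub = data[needed].dropna()
    dropped = len(data) - len(sub)
    y = sub[outcome].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise InputError(f"binary outcome {outcome} must be coded 0/1")
    n_cases = int(y.sum())
    if n_cases == 0 or n_cases == len(y):
        raise InsufficientDataError(f"{outcome}: only one outcome class present")
    if n_cases <= min_cases:
        raise InsufficientDataError(
            f"{outcome}: {n_cases} cases (more than {min_cases} required)"
        )
    X, names = _design(sub, covariates)
    if len(sub) <= X.shape[1]:
        raise InsufficientDataError(
            f"{len(sub)} usable rows for {X.shape[1]} parameters ({outcome})"
        )
    _check_rank(X, names)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0, method="newton", tol=tol, maxiter=maxiter)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise ConvergenceError(f"{outcome}: separation in logistic fit") from exc
    if not fit.mle_retvals.get("converged", False):
        raise ConvergenceError(f"{outcome}: logistic fit did not converge")
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not (np.isfinite(beta) and np.isfinite(se)):
        raise ConvergenceError(f"{outcome}: non-finite logistic estimates")
    return AssocResult(
        outcome=outcome,
        stratum="all",
        model="logistic",
        estimate=beta,
        se=se,
        p=float(fit.pvalues[1]),
        n=len(sub),
        n_cases=n_cases,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z_95 * se)),
        ci_high=float(np.exp(beta + Z_95 * se)),
        dropped_rows=dropped,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        return p
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_cohort_associations(
    assignments: pd.DataFrame,
    phenotypes: pd.DataFrame,
    continuous_outcomes=DEFAULT_CONTINUOUS_OUTCOMES,
    binary_outcomes=DEFAULT_BINARY_OUTCOMES,
    strata: tuple[str, ...] = STRATA,
    min_cases: int = 10,
    female_code: int = 1,
) -> tuple[list[AssocResult], list[SkippedOutcome]]:
    """All outcome-by-stratum association models for one cohort.

    ``assignments`` is the proxy table (columns ``sample_id``, ``usage``);
    ``phenotypes`` carries ``sample_id``, ``age``, ``sex``, ``fasting`` and
    the outcome columns.  Only control and elevated samples enter any model.
    Continuous outcomes are inverse-normal transformed within the analysed
    stratum; sex-stratified models drop the sex covariate.  FDR adjustment
    is applied within each (stratum, model-type) family.  Per-outcome
    failures are recorded and the run continues.
    """
    usage = assignments[["sample_id", "usage"]]
    merged = usage.merge(phenotypes, on="sample_id", how="inner", validate="one_to_one")
    analysis = merged[merged["usage"].isin([CONTROL, ELEVATED])].copy()
    analysis["elevated"] = (analysis["usage"] == ELEVATED).astype(float)

    results: list[AssocResult] = []
    skipped: list[SkippedOutcome] = []
    for stratum in strata:
        if stratum == "all":
            frame = analysis
            lin_covs: tuple[str, ...] = ("age", "sex", "fasting")
            log_covs: tuple[str, ...] = ("age", "sex")
        elif stratum in ("women", "men"):
            want = female_code if stratum == "women" else 1 - female_code
            frame = analysis[analysis["sex"] == want]
            lin_covs = ("age", "fasting")
            log_covs = ("age",)
        else:
            raise InputError(f"unknown stratum {stratum!r}")

        stratum_results: dict[str, list[AssocResult]] = {"linear": [], "logistic": []}
        for outcome in continuous_outcomes:
            if outcome not in frame.columns:
                skipped.append(SkippedOutcome(outcome, stratum, "column absent"))
                continue
            try:
                transformed = frame.copy()
                transformed[outcome] = inverse_normal_transform(frame[outcome])
                res = fit_linear(transformed, outcome, lin_covs)
            except (InputError, InsufficientDataError, CollinearityError) as exc:
                skipped.append(SkippedOutcome(outcome, stratum, str(exc)))
                continue
            res.stratum = stratum
            stratum_results["linear"].append(res)
        for outcome in binary_outcomes:
            if outcome not in frame.columns:
                skipped.append(SkippedOutcome(outcome, stratum, "column absent"))
                continue
            try:
                res = fit_logistic(frame, outcome, log_covs, min_cases=min_cases)
            except (InputError, InsufficientDataError, ConvergenceError, CollinearityError) as exc:
                skipped.append(SkippedOutcome(outcome, stratum, str(exc)))
                continue
            res.stratum = stratum
            stratum_results["logistic"].append(res)

        for family in stratum_results.values():
            if family:
                adjusted = bh_fdr([r.p for r in family])
                for r, q in zip(family, adjusted):
                    r.q = float(q)
                results.extend(family)
    return results, skipped


def results_to_frame(results: list[AssocResult]) -> pd.DataFrame:
    """Flatten association results into the canonical results sheet."""
    return pd.DataFrame(
        [
            {
                "outcome": r.outcome,
                "stratum": r.stratum,
                "model": r.model,
                "estimate": r.estimate,
                "se": r.se,
                "p": r.p,
                "q": r.q,
                "n": r.n,
                "n_cases": r.n_cases,
                "or": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "note": r.note,
            }
            for r in results
        ]
    )
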