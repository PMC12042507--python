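"""Relative nc886 expression, group fold changes and bimodality screening.

Expression of the two nc886 fragments (nc886-3p, nc886-5p) is quantified by
qPCR and expressed relative to the median of imprinted individuals via the
delta-delta-Cq convention: relative expression = 2^-(Cq - median reference
Cq), so the reference group has median relative expression 1 by
construction.

Fold changes between groups default to ratios of medians, consistent with
the median-based reference; a means-based variant is available.  The
two-group p-value for a contrast is Welch's t on log2 expression by default,
with a Mann-Whitney option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import genetics
from .errors import InputError
from .methylation import IMPRINTED

SPECIES: tuple[str, ...] = ("nc886_3p", "nc886_5p")


@dataclass(frozen=True)
class FoldChangeResult:
    fc: float
    log2_fc: float
    n_a: int
    n_b: int
    p_value: float
    test: str
    summary: str  # "median" or "mean"


@dataclass(frozen=True)
class BimodalityReport:
    bimodal: bool
    n: int
    means_log2: tuple[float, float]  # sorted two-component means (log2 scale)
    weight: float  # mixing weight of the upper component
    delta_bic: float  # BIC(1 component) - BIC(2 components); >0 favours two
    min_separation: float


def relative_expression(
    cq: pd.Series,
    reference_samples,
) -> pd.Series:
    """Delta-delta-Cq relative expression against a reference group.

    ``cq`` is a Series of raw quantification cycles indexed by sample id;
    ``reference_samples`` the ids whose median Cq anchors the scale.
    """
    reference_samples = [s for s in reference_samples if s in cq.index]
    if not reference_samples:
        raise InputError("reference sample set is empty or disjoint from the Cq data")
    ref_median = float(cq.loc[reference_samples].median())
    return (2.0 ** (-(cq - ref_median))).rename(cq.name)


def group_fold_change(
    values_a: pd.Series | np.ndarray,
    values_b: pd.Series | np.ndarray,
    summary: str = "median",
    test: str = "welch",
) -> FoldChangeResult:
    """Fold change of group A over group B (B is the reference/denominator).

    Both groups must contain strictly positive relative-expression values.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise InputError("both groups must be non-empty")
    if np.any(a <= 0) or np.any(b <= 0):
        raise InputError("relative expression values must be positive")
    if summary == "median":
        fc = float(np.median(a) / np.median(b))
    elif summary == "mean":
        fc = float(np.mean(a) / np.mean(b))
    else:
        raise InputError(f"unknown summary {summary!r}")
    log_a, log_b = np.log2(a), np.log2(b)
    if test == "welch":
        if len(a) < 2 or len(b) < 2 or (np.ptp(log_a) == 0 and np.ptp(log_b) == 0):
            p = float("nan")
        else:
            p = float(stats.ttest_ind(log_a, log_b, equal_var=False).pvalue)
    elif test == "mannwhitney":
        p = float(stats.mannwhitneyu(log_a, log_b, alternative="two-sided").pvalue)
    else:
        raise InputError(f"unknown test {test!r}")
    return FoldChangeResult(
        fc=fc,
        log2_fc=float(np.log2(fc)),
        n_a=len(a),
        n_b=len(b),
        p_value=p,
        test=test,
        summary=summary,
    )


def pofo_expression_contrast(
    expression: pd.DataFrame,
    pofo: pd.DataFrame,
    epistatus: pd.DataFrame,
    species: str = "nc886_3p",
    summary: str = "median",
    test: str = "welch",
) -> FoldChangeResult:
    """Paternal- vs maternal-origin expression contrast in imprinted
    heterozygotes.

    The analysis population is samples that are (a) imprinted, (b) have a
    resolved parent-of-origin call (``maternal`` or ``paternal`` — which also
    implies a heterozygous genotype), and (c) have expression data for the
    requested species.  Returns the fold change with the paternal-origin
    group in the numerator.
    """
    if species not in expression.columns:
        raise InputError(f"expression sheet has no column {species!r}")
    expr = expression.set_index("sample_id")[species]
    origin = pofo.set_index("sample_id")["origin"]
    status = epistatus["status"] if "status" in epistatus.columns else epistatus.iloc[:, 0]

    imprinted_ids = set(status.index[status == IMPRINTED])
    groups: dict[str, list[float]] = {genetics.PATERNAL: [], genetics.MATERNAL: []}
    for sample_id, o in origin.items():
        if o in groups and sample_id in imprinted_ids and sample_id in expr.index:
            value = expr.loc[sample_id]
            if not pd.isna(value):
                groups[o].append(float(value))
    for name, values in groups.items():
        if not values:
            raise InputError(f"no usable samples in the {name}-origin group")
    return group_fold_change(
        groups[genetics.PATERNAL], groups[genetics.MATERNAL], summary=summary, test=test
    )


def bimodality_report(
    values,
    min_separation: float = 0.5,
    random_state: int = 0,
) -> BimodalityReport:
    """One- vs two-component Gaussian mixture comparison on log2 expression.

    Fits equal-variance mixtures with one and two components and flags the
    distribution as bimodal when the two-component fit has the lower BIC and
    the component means are at least ``min_separation`` apart on the log2
    scale.  The equal-variance constraint keeps the two-component model from
    spending its extra parameters on a heavy tail rather than a second mode.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 10:
        raise InputError(f"need at least 10 values for a bimodality report, got {len(x)}")
    if np.any(x <= 0):
        raise InputError("expression values must be positive")
    log_x = np.log2(x).reshape(-1, 1)

    if np.ptp(log_x) == 0:
        return BimodalityReport(
            bimodal=False,
            n=len(x),
            means_log2=(float(log_x[0, 0]), float(log_x[0, 0])),
            weight=0.0,
            delta_bic=-np.inf,
            min_separation=min_separation,
        )

    fits = {}
    for k in (1, 2):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="tied",
            n_init=5,
            random_state=random_state,
            reg_covar=1e-6,
        ).fit(log_x)
        fits[k] = gm
    delta_bic = float(fits[1].bic(log_x) - fits[2].bic(log_x))
    means = np.sort(fits[2].means_.ravel())
    upper_idx = int(np.argmax(fits[2].means_.ravel()))
    weight = float(fits[2].weights_[upper_idx])
    separation = float(means[1] - means[0])
    return BimodalityReport(
        bimodal=bool(delta_bic > 0 and separation >= min_separation),
        n=len(x),
        means_log2=(float(means[0]), float(means[1])),
        weight=weight,
        delta_bic=delta_bic,
        min_separation=min_separation,
    )
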