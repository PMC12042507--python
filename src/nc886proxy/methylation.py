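"""Epigenotype classification of the nc886 differentially methylated region.

The nc886/vtRNA2-1 locus is polymorphically imprinted: roughly three quarters
of individuals of European ancestry carry one methylated (silenced, maternal)
and one unmethylated allele, while most of the rest carry two unmethylated
alleles.  The per-individual median beta value over 11 CpG probes in the DMR
separates these states cleanly into three groups:

* ``imprinted``       — median beta >= 0.4 (monoallelic methylation)
* ``intermediate``    — 0.2 <= median beta < 0.4
* ``non_methylated``  — median beta < 0.2 (both alleles unmethylated)

The published thresholds are strict inequalities that leave the boundary
points 0.2 and 0.4 unassigned; this module resolves them with half-open
intervals [0.4, 1], [0.2, 0.4), [0, 0.2), which is configurable via the
``low``/``high`` arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

#: The 11 classification CpG probes of the nc886 DMR (450K/EPIC shared ids).
DMR_PROBES: tuple[str, ...] = (
    "cg07158503",
    "cg11608150",
    "cg06478886",
    "cg04481923",
    "cg18678645",
    "cg06536614",
    "cg25340688",
    "cg26896946",
    "cg00124993",
    "cg08745965",
    "cg18797653",
)

#: Bimodal probes in the region that are rejected by default because of their
#: tendency towards hypomethylation bias.
HYPOMETHYLATION_BIASED_PROBES: frozenset[str] = frozenset(
    {"cg04515200", "cg13581155", "cg11978884"}
)

IMPRINTED = "imprinted"
INTERMEDIATE = "intermediate"
NON_METHYLATED = "non_methylated"
UNKNOWN = "unknown"

EPISTATUS_LEVELS: tuple[str, ...] = (IMPRINTED, INTERMEDIATE, NON_METHYLATED)

DEFAULT_MIN_PROBES = 6


@dataclass(frozen=True)
class EpiStatusCall:
    """Per-sample DMR summary and epigenotype label."""

    sample_id: str
    median_beta: float  # NaN when no probe was usable
    n_probes_used: int
    status: str


def _check_matrix(matrix: pd.DataFrame) -> None:
    if matrix.index.has_duplicates:
        raise InputError("duplicate sample ids in methylation matrix")
    if matrix.columns.has_duplicates:
        raise InputError("duplicate probe ids in methylation matrix")
    values = matrix.to_numpy(dtype=float)
    bad = (values < 0) | (values > 1)
    if np.any(bad & ~np.isnan(values)):
        raise InputError("methylation beta values must lie in [0, 1]")


def summarize_dmr(
    matrix: pd.DataFrame,
    probes: tuple[str, ...] | list[str] = DMR_PROBES,
    allow_biased: bool = False,
) -> pd.DataFrame:
    """Median beta over the listed probes, per sample.

    Parameters
    ----------
    matrix
        Samples in rows (index = sample id), probes in columns, beta values
        in [0, 1]; NaN marks a missing measurement.
    probes
        Probe ids to summarize.  Probes absent from the matrix are ignored,
        but at least one must be present.
    allow_biased
        Accept probes from :data:`HYPOMETHYLATION_BIASED_PROBES`; off by
        default because those probes distort the three-group separation.

    Returns
    -------
    DataFrame indexed by sample id with columns ``median_beta`` (NaN when a
    sample has no usable probe) and ``n_probes_used``.
    """
    if len(probes) == 0:
        raise InputError("probe list is empty")
    if not allow_biased:
        rejected = sorted(set(probes) & HYPOMETHYLATION_BIASED_PROBES)
        if rejected:
            raise InputError(
                f"hypomethylation-biased probes not allowed in probe list: {rejected}"
            )
    _check_matrix(matrix)
    present = [p for p in probes if p in matrix.columns]
    if not present:
        raise InputError("none of the listed probes is present in the matrix")
    sub = matrix[present].astype(float)
    return pd.DataFrame(
        {
            "median_beta": sub.median(axis=1, skipna=True),
            "n_probes_used": sub.notna().sum(axis=1).astype(int),
        },
        index=matrix.index,
    )


def classify_epistatus(median_beta: float, low: float = 0.2, high: float = 0.4) -> str:
    """Three-group epigenotype from a median beta value.

    Boundary rule: values >= ``high`` are imprinted, values in
    [``low``, ``high``) intermediate, values < ``low`` non-methylated.
    """
    if not 0 <= low < high <= 1:
        raise InputError(f"thresholds must satisfy 0 <= low < high <= 1, got {low}, {high}")
    if np.isnan(median_beta) or not 0 <= median_beta <= 1:
        raise InputError(f"median beta must lie in [0, 1], got {median_beta}")
    if median_beta >= high:
        return IMPRINTED
    if median_beta < low:
        return NON_METHYLATED
    return INTERMEDIATE


def classify_cohort(
    matrix: pd.DataFrame,
    probes: tuple[str, ...] | list[str] = DMR_PROBES,
    min_probes: int = DEFAULT_MIN_PROBES,
    low: float = 0.2,
    high: float = 0.4,
    allow_biased: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify every sample and tabulate group proportions.

    Samples with fewer than ``min_probes`` usable probes are labelled
    ``unknown`` and excluded from the proportion summary (which is taken over
    classified samples only and sums to 1).

    Returns
    -------
    calls : DataFrame indexed by sample id with ``median_beta``,
        ``n_probes_used`` and ``status``.
    proportions : Series over the three epigenotype levels.
    """
    summary = summarize_dmr(matrix, probes, allow_biased=allow_biased)
    status = [
        classify_epistatus(row.median_beta, low, high)
        if row.n_probes_used >= min_probes
        else UNKNOWN
        for row in summary.itertuples()
    ]
    calls = summary.assign(status=status)
    known = calls.loc[calls["status"] != UNKNOWN, "status"]
    if len(known):
        proportions = known.value_counts(normalize=True).reindex(
            EPISTATUS_LEVELS, fill_value=0.0
        )
    else:
        proportions = pd.Series(np.nan, index=list(EPISTATUS_LEVELS))
    proportions.name = "proportion"
    return calls, proportions
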