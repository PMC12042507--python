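"""The genotype-by-epigenotype proxy for lifelong nc886 RNA levels.

Combining the three epigenotypes (imprinted / intermediate / non-methylated)
with the three rs1799962 genotypes (T/T, T/C, C/C) gives nine groups.  Each
group receives a usage label for the downstream phenotype associations:

* ``control``  — imprinted T/T: silenced maternal allele, no minor allele;
  the baseline nc886 expression state.
* ``elevated`` — any non-methylated group, plus imprinted C/C: genetics
  and/or epigenetics guarantee upregulated nc886 RNA.
* ``excluded`` — every intermediate group (heterogeneous, hard to classify
  across datasets) and imprinted T/C (the minor allele may sit on either the
  silenced maternal or the active paternal copy, so its effect is mixed and
  parental origin is unknown for most samples).

With ``pofo_rescue`` enabled, imprinted heterozygotes whose minor-allele
origin was resolved from trio data are reassigned — paternal origin to
``elevated``, maternal origin to ``control`` — a sensitivity analysis that is
off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import genetics
from .errors import InputError
from .methylation import EPISTATUS_LEVELS, IMPRINTED, INTERMEDIATE, NON_METHYLATED, UNKNOWN

CONTROL = "control"
ELEVATED = "elevated"
EXCLUDED = "excluded"

USAGE_LEVELS: tuple[str, ...] = (CONTROL, ELEVATED, EXCLUDED)

#: Canonical ordering of the nine proxy groups, genotype within epigenotype
#: ordered as the published frequency tables list them.
GROUP_ORDER: tuple[tuple[str, str], ...] = (
    (IMPRINTED, "TT"),
    (INTERMEDIATE, "TT"),
    (NON_METHYLATED, "TT"),
    (IMPRINTED, "TC"),
    (INTERMEDIATE, "TC"),
    (NON_METHYLATED, "TC"),
    (IMPRINTED, "CC"),
    (INTERMEDIATE, "CC"),
    (NON_METHYLATED, "CC"),
)


@dataclass(frozen=True)
class ProxyAssignment:
    sample_id: str
    epistatus: str
    genotype: str | None
    usage: str
    reason: str = ""


def usage_label(
    epistatus: str,
    genotype: str | None,
    pofo: str | None = None,
    pofo_rescue: bool = False,
) -> tuple[str, str]:
    """Usage label plus a human-readable reason for exclusions.

    ``epistatus`` may be ``unknown`` and ``genotype`` may be None; both lead
    to exclusion with a recorded reason rather than an error.
    """
    if epistatus == UNKNOWN:
        return EXCLUDED, "unknown epigenotype"
    if epistatus not in EPISTATUS_LEVELS:
        raise InputError(f"unrecognized epigenotype {epistatus!r}")
    if genotype is None:
        return EXCLUDED, "missing genotype"
    if genotype not in genetics.GENOTYPES:
        raise InputError(f"unrecognized genotype {genotype!r}")
    if epistatus == INTERMEDIATE:
        return EXCLUDED, "intermediate epigenotype"
    if epistatus == IMPRINTED and genotype == "TC":
        if pofo_rescue and pofo == genetics.PATERNAL:
            return ELEVATED, "pofo rescue: paternal minor allele"
        if pofo_rescue and pofo == genetics.MATERNAL:
            return CONTROL, "pofo rescue: maternal minor allele"
        return EXCLUDED, "imprinted heterozygote, parental origin unresolved"
    if epistatus == IMPRINTED and genotype == "TT":
        return CONTROL, ""
    return ELEVATED, ""


def build_proxy(
    sample_id: str,
    epistatus: str,
    genotype: str | None,
    pofo: str | None = None,
    pofo_rescue: bool = False,
) -> ProxyAssignment:
    usage, reason = usage_label(epistatus, genotype, pofo, pofo_rescue)
    return ProxyAssignment(sample_id, epistatus, genotype, usage, reason)


def assign_cohort(
    epistatus: pd.DataFrame,
    genotypes: pd.DataFrame,
    pofo: pd.DataFrame | None = None,
    pofo_rescue: bool = False,
) -> pd.DataFrame:
    """Join epigenotype calls with genotypes and assign usage labels.

    ``epistatus`` is the call table from :func:`~nc886proxy.methylation.classify_cohort`
    (indexed by sample id, column ``status``); ``genotypes`` has columns
    ``sample_id`` and ``genotype``.  Samples missing from either sheet are
    excluded with a recorded reason, never dropped silently.
    """
    geno = genotypes.set_index("sample_id")["genotype"]
    origin = (
        pofo.set_index("sample_id")["origin"] if pofo is not None else pd.Series(dtype=object)
    )
    rows = []
    for sample_id, row in epistatus.iterrows():
        raw = geno.get(sample_id)
        g = genetics.parse_genotype(raw) if raw is not None else None
        assignment = build_proxy(
            str(sample_id), row["status"], g, origin.get(sample_id), pofo_rescue
        )
        rows.append(assignment)
    out = pd.DataFrame([vars(a) for a in rows])
    return out


def frequency_table(assignments: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group and per-usage counts with display percentages.

    Percentages are 100*count/n; a ``percent_display`` column carries the
    half-up two-decimal rounding used in published tables.  Groups with
    unknown epigenotype or missing genotype are tallied under usage only.
    """
    if assignments.empty:
        raise InputError("no assignments to tabulate")
    n = len(assignments)

    group_rows = []
    for status, genotype in GROUP_ORDER:
        count = int(
            (
                (assignments["epistatus"] == status)
                & (assignments["genotype"] == genotype)
            ).sum()
        )
        pct = 100.0 * count / n
        group_rows.append((status, genotype, count, pct, _round_half_up(pct)))
    groups = pd.DataFrame(
        group_rows, columns=["epistatus", "genotype", "count", "percent", "percent_display"]
    )

    usage_rows = []
    for usage in USAGE_LEVELS:
        count = int((assignments["usage"] == usage).sum())
        pct = 100.0 * count / n
        usage_rows.append((usage, count, pct, _round_half_up(pct)))
    usage = pd.DataFrame(
        usage_rows, columns=["usage", "count", "percent", "percent_display"]
    )
    return groups, usage


def usage_from_group_percentages(groups) -> dict[str, float]:
    """Usage-level percentages implied by nine group percentages.

    ``groups`` is either a mapping keyed by (epistatus, genotype) pairs or a
    sequence of nine values in :data:`GROUP_ORDER`.  Pure arithmetic over the
    assignment rules: control = imprinted T/T; elevated = the three
    non-methylated groups plus imprinted C/C; excluded = the rest.
    """
    if not isinstance(groups, dict):
        values = list(groups)
        if len(values) != 9:
            raise InputError(f"expected 9 group percentages, got {len(values)}")
        groups = dict(zip(GROUP_ORDER, values))
    missing = set(GROUP_ORDER) - set(groups)
    if missing:
        raise InputError(f"missing group percentages for {sorted(missing)}")
    if any(v < 0 for v in groups.values()):
        raise InputError("group percentages must be non-negative")
    totals = {CONTROL: 0.0, ELEVATED: 0.0, EXCLUDED: 0.0}
    for (status, genotype), value in groups.items():
        label, _ = usage_label(status, genotype)
        totals[label] += float(value)
    return totals


def _round_half_up(value: float, decimals: int = 2) -> float:
    factor = 10**decimals
    return float(np.floor(value * factor + 0.5) / factor)
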