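"""TSV plumbing and input validation for the four cohort sheets.

The canonical interchange format is UTF-8 TSV with a header row and "NA" for
missing values.  The four sheets are:

* methylation: ``sample_id`` + one column per CpG probe id;
* genotypes: ``sample_id``, ``genotype`` and optionally ``maternal_allele``,
  ``paternal_allele``, ``mother_genotype``, ``father_genotype``;
* expression: ``sample_id``, ``nc886_3p``, ``nc886_5p``;
* phenotypes: ``sample_id``, ``age``, ``sex``, ``fasting`` + outcome columns.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genetics
from .errors import InputError

NA = "NA"


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", na_rep=NA, index=index)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    if not os.path.exists(path):
        raise InputError(f"input file not found: {path}")
    return pd.read_csv(
        path, sep="\t", na_values=[NA], keep_default_na=False, index_col=index_col
    )


def write_cohort(cohort, outdir) -> dict[str, str]:
    """Write a simulated cohort's four sheets (plus the latent truth) as TSV."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    meth = cohort.methylation.reset_index()
    for name, df in (
        ("methylation", meth),
        ("genotypes", cohort.genotypes),
        ("expression", cohort.expression),
        ("phenotypes", cohort.phenotypes),
        ("truth", cohort.truth),
    ):
        path = os.path.join(outdir, f"{name}.tsv")
        write_tsv(df, path)
        paths[name] = path
    return paths


@dataclass(frozen=True)
class Finding:
    level: str  # "fatal" | "warning"
    sheet: str
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def fatal(self) -> bool:
        return any(f.level == "fatal" for f in self.findings)

    def add(self, level: str, sheet: str, message: str) -> None:
        self.findings.append(Finding(level, sheet, message))

    def raise_if_fatal(self) -> None:
        if self.fatal:
            problems = "; ".join(
                f"[{f.sheet}] {f.message}" for f in self.findings if f.level == "fatal"
            )
            raise InputError(f"fatal validation findings: {problems}")


def _check_sample_ids(df: pd.DataFrame, sheet: str, report: ValidationReport) -> None:
    if "sample_id" not in df.columns:
        report.add("fatal", sheet, "missing sample_id column")
        return
    dup = df["sample_id"].duplicated()
    if dup.any():
        report.add("fatal", sheet, f"{int(dup.sum())} duplicated sample ids")


def validate_inputs(
    methylation: pd.DataFrame | None = None,
    genotypes: pd.DataFrame | None = None,
    expression: pd.DataFrame | None = None,
    phenotypes: pd.DataFrame | None = None,
) -> ValidationReport:
    """Cross-sheet validation: id uniqueness, value ranges, coding, joins.

    Non-fatal findings (e.g. incomplete join coverage) are warnings; data
    that would corrupt downstream stages (out-of-range betas, unparseable
    genotypes, non-binary sex/fasting coding) is fatal.
    """
    report = ValidationReport()
    sheets: dict[str, pd.DataFrame] = {}

    if methylation is not None:
        sheets["methylation"] = methylation
        _check_sample_ids(methylation, "methylation", report)
        probe_cols = [c for c in methylation.columns if c != "sample_id"]
        if not probe_cols:
            report.add("fatal", "methylation", "no probe columns")
        else:
            values = methylation[probe_cols].to_numpy(dtype=float)
            bad = ((values < 0) | (values > 1)) & ~np.isnan(values)
            if bad.any():
                report.add(
                    "fatal", "methylation", f"{int(bad.sum())} beta values outside [0, 1]"
                )

    if genotypes is not None:
        sheets["genotypes"] = genotypes
        _check_sample_ids(genotypes, "genotypes", report)
        if "genotype" not in genotypes.columns:
            report.add("fatal", "genotypes", "missing genotype column")
        else:
            for value in genotypes["genotype"].dropna().unique():
                try:
                    genetics.parse_genotype(value)
                except InputError:
                    report.add("fatal", "genotypes", f"unknown genotype string {value!r}")

    if expression is not None:
        sheets["expression"] = expression
        _check_sample_ids(expression, "expression", report)
        for col in ("nc886_3p", "nc886_5p"):
            if col in expression.columns:
                vals = expression[col].dropna()
                if (vals <= 0).any():
                    report.add("fatal", "expression", f"non-positive values in {col}")
            else:
                report.add("warning", "expression", f"missing species column {col}")

    if phenotypes is not None:
        sheets["phenotypes"] = phenotypes
        _check_sample_ids(phenotypes, "phenotypes", report)
        for col in ("sex", "fasting"):
            if col in phenotypes.columns:
                values = set(phenotypes[col].dropna().unique())
                if not values <= {0, 1}:
                    report.add(
                        "fatal", "phenotypes", f"{col} must be coded 0/1, saw {sorted(values)}"
                    )
            else:
                report.add("warning", "phenotypes", f"missing covariate column {col}")
        if "age" in phenotypes.columns and (phenotypes["age"].dropna() < 0).any():
            report.add("fatal", "phenotypes", "negative ages")

    # join coverage across sheets
    id_sets = {
        name: set(df["sample_id"]) for name, df in sheets.items() if "sample_id" in df.columns
    }
    if len(id_sets) > 1:
        union = set.union(*id_sets.values())
        for name, ids in id_sets.items():
            missing = len(union) - len(ids)
            if missing:
                report.add(
                    "warning",
                    name,
                    f"{missing}/{len(union)} samples from other sheets absent here",
                )
    return report
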