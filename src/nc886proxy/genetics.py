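"""rs1799962 genotypes and trio-based parent-of-origin inference.

rs1799962 is the lead SNP representing cis-acting genetic regulation of nc886
RNA levels (major allele T, minor allele C).  Because the maternal nc886
allele is silenced in imprinted individuals, the phenotypic effect of the
minor allele depends on which parent transmitted it; family trios allow the
parental origin to be resolved whenever Mendelian logic forces it.

Parent-of-origin categories for a child's minor allele:

* ``paternal`` / ``maternal`` — origin forced by the known parent genotypes
  (a single known parent suffices when it cannot have transmitted, or must
  have transmitted, the minor allele);
* ``ambiguous``       — both parents heterozygous, either transmission fits;
* ``unknown``         — a parent genotype needed to decide is missing;
* ``not_applicable``  — homozygous child, no single minor-allele origin;
* ``mendelian_error`` — no transmission pattern is consistent with the trio.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import pandas as pd

from .errors import InputError

MAJOR_ALLELE = "T"
MINOR_ALLELE = "C"

GENOTYPES: tuple[str, ...] = ("TT", "TC", "CC")

PATERNAL = "paternal"
MATERNAL = "maternal"
AMBIGUOUS = "ambiguous"
UNKNOWN = "unknown"
MENDELIAN_ERROR = "mendelian_error"
NOT_APPLICABLE = "not_applicable"

POFO_CATEGORIES: tuple[str, ...] = (
    PATERNAL,
    MATERNAL,
    AMBIGUOUS,
    UNKNOWN,
    MENDELIAN_ERROR,
    NOT_APPLICABLE,
)


def parse_genotype(
    value,
    major: str = MAJOR_ALLELE,
    minor: str = MINOR_ALLELE,
) -> str | None:
    """Normalize a genotype string to major-first two-letter form.

    Accepts "T/C", "CT", "tc" etc.; returns None for missing markers
    ("", "NA", None, NaN).  Unknown alleles raise :class:`InputError`.
    """
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip().upper().replace("/", "").replace("|", "")
    if text in ("", "NA", "NAN", "."):
        return None
    if len(text) != 2 or any(a not in (major, minor) for a in text):
        raise InputError(f"unrecognized genotype {value!r} for alleles {major}/{minor}")
    # canonical order: major allele first
    n_minor = text.count(minor)
    return minor * n_minor + major * (2 - n_minor) if n_minor == 2 else (
        major * (2 - n_minor) + minor * n_minor
    )


def minor_allele_count(genotype: str, minor: str = MINOR_ALLELE) -> int:
    return genotype.count(minor)


def genotype_frequencies(
    genotypes: Iterable[str],
) -> tuple[pd.Series, float]:
    """Genotype frequency triple (TT, TC, CC) and the minor allele frequency."""
    genos = [parse_genotype(g) for g in genotypes]
    genos = [g for g in genos if g is not None]
    if not genos:
        raise InputError("no non-missing genotypes supplied")
    counts = Counter(genos)
    n = len(genos)
    freqs = pd.Series(
        {g: counts.get(g, 0) / n for g in GENOTYPES}, name="frequency"
    )
    maf = (counts.get("TC", 0) + 2 * counts.get("CC", 0)) / (2 * n)
    return freqs, maf


def _transmissible(parent: str | None) -> set[str]:
    """Alleles a parent can transmit; missing parent is unconstrained."""
    if parent is None:
        return {MAJOR_ALLELE, MINOR_ALLELE}
    return set(parent)


def assign_parent_of_origin(
    child: str,
    mother: str | None = None,
    father: str | None = None,
) -> str:
    """Parent-of-origin call for the child's minor allele.

    All three genotypes must already be normalized ("TT"/"TC"/"CC" or None
    for a missing parent); :func:`parse_genotype` does that.  Mendelian
    consistency is checked first (against however many parents are known),
    so an impossible trio is reported as ``mendelian_error`` even when the
    child is homozygous.
    """
    if child not in GENOTYPES:
        raise InputError(f"child genotype must be one of {GENOTYPES}, got {child!r}")
    for parent in (mother, father):
        if parent is not None and parent not in GENOTYPES:
            raise InputError(f"parent genotype must be one of {GENOTYPES} or None")

    child_pair = (child[0], child[1])
    feasible: set[tuple[str, str]] = set()  # (maternal allele, paternal allele)
    for m in _transmissible(mother):
        for f in _transmissible(father):
            if (m, f) == child_pair or (f, m) == child_pair:
                feasible.add((m, f))
    if not feasible:
        return MENDELIAN_ERROR
    if child[0] == child[1]:
        return NOT_APPLICABLE
    origins = {MATERNAL if m == MINOR_ALLELE else PATERNAL for m, _ in feasible}
    if origins == {MATERNAL}:
        return MATERNAL
    if origins == {PATERNAL}:
        return PATERNAL
    # both transmissions feasible: ambiguous when fully observed, otherwise
    # the missing parent is what keeps the origin undecided
    return AMBIGUOUS if (mother is not None and father is not None) else UNKNOWN


def call_pofo_cohort(
    trios: pd.DataFrame | Sequence[tuple],
) -> tuple[pd.DataFrame, Counter]:
    """Vectorized parent-of-origin calling over a cohort of trios.

    ``trios`` is a DataFrame with columns ``sample_id``, ``genotype``,
    ``mother_genotype``, ``father_genotype`` (missing parents as NA), or a
    sequence of (sample_id, child, mother, father) tuples.

    Returns the per-sample call table and a tally over categories.
    """
    if not isinstance(trios, pd.DataFrame):
        trios = pd.DataFrame(
            trios, columns=["sample_id", "genotype", "mother_genotype", "father_genotype"]
        )
    if trios.empty:
        raise InputError("no trios supplied")
    calls = []
    for row in trios.itertuples():
        child = parse_genotype(row.genotype)
        if child is None:
            raise InputError(f"missing child genotype for sample {row.sample_id}")
        origin = assign_parent_of_origin(
            child,
            parse_genotype(row.mother_genotype),
            parse_genotype(row.father_genotype),
        )
        calls.append((row.sample_id, origin))
    result = pd.DataFrame(calls, columns=["sample_id", "origin"])
    tally = Counter(result["origin"])
    return result, tally


def genotypes_from_vcf(
    vcf_path: str,
    variant_id: str,
    samples: Sequence[str] | None = None,
    major: str = MAJOR_ALLELE,
    minor: str = MINOR_ALLELE,
) -> pd.DataFrame:
    """Extract one biallelic variant's genotypes from a VCF into the
    standard genotype sheet (columns ``sample_id``, ``genotype``).

    Requires cyvcf2 (optional dependency).  The variant is located by its ID
    column; REF/ALT are mapped onto the configured major/minor symbols by
    allele letter.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise InputError("cyvcf2 is required for VCF extraction") from exc

    vcf = VCF(vcf_path)
    if samples is not None:
        vcf.set_samples(list(samples))
    for variant in vcf:
        if variant.ID != variant_id:
            continue
        alleles = [variant.REF] + list(variant.ALT)
        if not set(alleles) <= {major, minor}:
            raise InputError(
                f"variant {variant_id} alleles {alleles} do not match {major}/{minor}"
            )
        rows = []
        for sample, gt in zip(vcf.samples, variant.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                rows.append((sample, None))
            else:
                rows.append((sample, parse_genotype(alleles[a] + alleles[b])))
        return pd.DataFrame(rows, columns=["sample_id", "genotype"])
    raise InputError(f"variant {variant_id} not found in {vcf_path}")
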