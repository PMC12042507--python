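"""End-to-end orchestration: classify -> parent-of-origin -> proxy ->
per-cohort associations -> meta-analysis.

A pipeline run consumes one or more cohorts' sheets, writes every stage's
output TSV under a run directory, and records a manifest (input checksums,
configuration, seed, package version) so reruns on identical inputs are
byte-identical apart from the manifest timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time

import pandas as pd
import yaml

from . import __version__, association, genetics, io, meta, methylation, proxy
from .errors import ConfigError, InputError

log = logging.getLogger("nc886proxy")


@dataclasses.dataclass
class CohortInputs:
    name: str
    methylation: str
    genotypes: str
    phenotypes: str
    expression: str | None = None


@dataclasses.dataclass
class PipelineConfig:
    cohorts: list[CohortInputs]
    probes: tuple[str, ...] = methylation.DMR_PROBES
    min_probes: int = methylation.DEFAULT_MIN_PROBES
    low_threshold: float = 0.2
    high_threshold: float = 0.4
    continuous_outcomes: tuple[str, ...] = association.DEFAULT_CONTINUOUS_OUTCOMES
    binary_outcomes: tuple[str, ...] = association.DEFAULT_BINARY_OUTCOMES
    strata: tuple[str, ...] = association.STRATA
    min_cases: int = 10
    pofo_rescue: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not self.cohorts:
            raise ConfigError("pipeline config lists no cohorts")
        if not 0 < self.low_threshold < self.high_threshold < 1:
            raise ConfigError("thresholds must satisfy 0 < low < high < 1")
        for cohort in self.cohorts:
            for attr in ("methylation", "genotypes", "phenotypes"):
                path = getattr(cohort, attr)
                if not os.path.exists(path):
                    raise InputError(f"cohort {cohort.name}: missing input file {path}")
            if cohort.expression and not os.path.exists(cohort.expression):
                raise InputError(
                    f"cohort {cohort.name}: missing input file {cohort.expression}"
                )


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cohorts = [CohortInputs(**c) for c in raw.pop("cohorts")]
    known = {f.name for f in dataclasses.fields(PipelineConfig)} - {"cohorts"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
    for key in ("probes", "continuous_outcomes", "binary_outcomes", "strata"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(cohorts=cohorts, **raw)


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage for every cohort, then pool across cohorts.

    Returns the manifest dict (also written to ``<outdir>/manifest.json``).
    Any stage failure raises with the stage and cohort named, after writing
    a partial manifest.
    """
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {
        "package": "nc886proxy",
        "version": __version__,
        "seed": config.seed,
        "config": {
            **{
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k != "cohorts"
            },
            "cohorts": [dataclasses.asdict(c) for c in config.cohorts],
        },
        "inputs": {},
        "outputs": {},
        "stages": [],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def fail(stage: str, cohort: str, exc: Exception):
        manifest["stages"].append({"stage": stage, "cohort": cohort, "status": "failed"})
        _write_manifest(manifest, outdir)
        raise type(exc)(f"stage {stage!r} failed for cohort {cohort!r}: {exc}") from exc

    all_results = []
    for cohort in config.cohorts:
        cohort_dir = os.path.join(outdir, cohort.name)
        os.makedirs(cohort_dir, exist_ok=True)
        for attr in ("methylation", "genotypes", "phenotypes", "expression"):
            path = getattr(cohort, attr)
            if path:
                manifest["inputs"][f"{cohort.name}/{attr}"] = _sha256(path)

        try:
            meth = io.read_tsv(cohort.methylation, index_col="sample_id")
            genos = io.read_tsv(cohort.genotypes)
            phenos = io.read_tsv(cohort.phenotypes)
            report = io.validate_inputs(
                methylation=meth.reset_index(), genotypes=genos, phenotypes=phenos
            )
            for finding in report.findings:
                log.log(
                    logging.ERROR if finding.level == "fatal" else logging.WARNING,
                    "%s: [%s] %s", cohort.name, finding.sheet, finding.message,
                )
            report.raise_if_fatal()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            fail("validate", cohort.name, exc)

        try:
            calls, proportions = methylation.classify_cohort(
                meth,
                probes=config.probes,
                min_probes=config.min_probes,
                low=config.low_threshold,
                high=config.high_threshold,
            )
            io.write_tsv(calls.reset_index(), os.path.join(cohort_dir, "epistatus.tsv"))
            log.info("%s: epigenotype proportions %s", cohort.name, proportions.to_dict())
        except Exception as exc:  # noqa: BLE001
            fail("classify", cohort.name, exc)
        manifest["stages"].append(
            {"stage": "classify", "cohort": cohort.name, "status": "ok", "n": len(calls)}
        )

        pofo_calls = None
        if {"mother_genotype", "father_genotype"} <= set(genos.columns):
            try:
                pofo_calls, tally = genetics.call_pofo_cohort(
                    genos[["sample_id", "genotype", "mother_genotype", "father_genotype"]]
                )
                io.write_tsv(pofo_calls, os.path.join(cohort_dir, "pofo.tsv"))
                log.info("%s: parent-of-origin tally %s", cohort.name, dict(tally))
            except Exception as exc:  # noqa: BLE001
                fail("pofo", cohort.name, exc)
            manifest["stages"].append(
                {"stage": "pofo", "cohort": cohort.name, "status": "ok", "tally": dict(tally)}
            )

        try:
            assignments = proxy.assign_cohort(
                calls, genos, pofo=pofo_calls, pofo_rescue=config.pofo_rescue
            )
            groups, usage = proxy.frequency_table(assignments)
            io.write_tsv(assignments, os.path.join(cohort_dir, "proxy.tsv"))
            io.write_tsv(groups, os.path.join(cohort_dir, "proxy_groups.tsv"))
            io.write_tsv(usage, os.path.join(cohort_dir, "proxy_usage.tsv"))
            log.info(
                "%s: usage counts %s", cohort.name,
                dict(zip(usage["usage"], usage["count"])),
            )
        except Exception as exc:  # noqa: BLE001
            fail("proxy", cohort.name, exc)
        manifest["stages"].append(
            {"stage": "proxy", "cohort": cohort.name, "status": "ok"}
        )

        try:
            results, skipped = association.run_cohort_associations(
                assignments,
                phenos,
                continuous_outcomes=config.continuous_outcomes,
                binary_outcomes=config.binary_outcomes,
                strata=config.strata,
                min_cases=config.min_cases,
            )
            frame = association.results_to_frame(results)
            frame.insert(0, "cohort", cohort.name)
            io.write_tsv(frame, os.path.join(cohort_dir, "associations.tsv"))
            for skip in skipped:
                log.info(
                    "%s: skipped %s [%s]: %s",
                    cohort.name, skip.outcome, skip.stratum, skip.reason,
                )
            all_results.append(frame)
        except Exception as exc:  # noqa: BLE001
            fail("assoc", cohort.name, exc)
        manifest["stages"].append(
            {
                "stage": "assoc",
                "cohort": cohort.name,
                "status": "ok",
                "n_results": len(results),
                "n_skipped": len(skipped),
            }
        )

    try:
        combined = pd.concat(all_results, ignore_index=True)
        io.write_tsv(combined, os.path.join(outdir, "associations_all.tsv"))
        pooled, forest = meta.pool_all(combined)
        io.write_tsv(pooled, os.path.join(outdir, "meta.tsv"))
        io.write_tsv(forest, os.path.join(outdir, "forest.tsv"))
    except Exception as exc:  # noqa: BLE001
        fail("meta", "-", exc)
    manifest["stages"].append({"stage": "meta", "cohort": "-", "status": "ok"})

    for root, _, files in os.walk(outdir):
        for name in sorted(files):
            if name.endswith(".tsv"):
                path = os.path.join(root, name)
                manifest["outputs"][os.path.relpath(path, outdir)] = _sha256(path)
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir) -> None:
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
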