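"""End-to-end orchestration: DE -> correlation -> overlay -> concordance -> cohort.

A run is driven by a :class:`PipelineConfig` (loadable from YAML); stages
whose inputs are absent are skipped and logged, never silently.  Outputs are
the candidate table, the concordance report, the cohort report and a run
manifest (package version, seed, config hash) — byte-identical across runs
with the same seed and config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, correlation, crossspecies, de, io, prioritize
from .cohort import run_cohort_analysis
from .errors import ConfigurationError

log = logging.getLogger("panelmark")


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run; unset paths skip their stage."""

    expr_path: str | None = None
    meta_path: str | None = None
    annot_path: str | None = None
    trait_path: str | None = None
    human_de_path: str | None = None
    cohort_path: str | None = None
    ortholog_path: str | None = None
    out_dir: str = "results/run"

    de_min_abs_logfc: float = 1.0
    de_max_p_adj: float = 0.05
    corr_max_p: float = 1e-3
    concordance_alpha: float = 0.05
    known_markers: list[str] = field(
        default_factory=lambda: sorted(io.DEFAULT_KNOWN_MARKERS)
    )
    cohort_covariates: list[str] = field(
        default_factory=lambda: ["age_yr", "bmi_kg_m2", "htn", "dm", "egfr", "ldl_mg_dl"]
    )
    biomarker_scale: str = "raw"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def validate(self) -> None:
        for name in ("de_max_p_adj", "corr_max_p", "concordance_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigurationError(f"{name} must be in (0, 1], got {v}")
        if self.de_min_abs_logfc < 0:
            raise ConfigurationError("de_min_abs_logfc must be >= 0")
        for name in (
            "expr_path", "meta_path", "annot_path", "trait_path",
            "human_de_path", "cohort_path", "ortholog_path",
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{name}: file not found: {p}")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage whose inputs are present, in pipeline order.

    Returns a dict with the in-memory stage outputs and the list of skipped
    stages; writes TSV reports plus ``manifest.json`` under
    ``config.out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"skipped": [], "outputs": {}}
    t0 = time.perf_counter()

    annotation = io.read_annotation(config.annot_path) if config.annot_path else None

    de_table = corr_table = None
    if config.expr_path and config.meta_path:
        panel = io.read_expression(config.expr_path, config.meta_path)
        de_table = de.run_de(panel, annotation)
        de.write_de_table(de_table, out / "de.tsv")
        results["outputs"]["de"] = out / "de.tsv"
        log.info("de: %d probes (%.2fs)", len(de_table), time.perf_counter() - t0)
        if config.trait_path:
            trait = io.read_trait(config.trait_path)
            strain_means = correlation.strain_summarize(panel, arm="treated")
            corr_table = correlation.correlate_trait(
                strain_means, trait, annotation=annotation
            )
            correlation.write_corr_table(corr_table, out / "corr.tsv")
            results["outputs"]["corr"] = out / "corr.tsv"
        else:
            results["skipped"].append("trait_correlation: no trait_path")
            log.info("skipping trait correlation: no trait_path")
    else:
        results["skipped"].append("diffexpr: no expr_path/meta_path")
        log.info("skipping DE: no expression input")

    candidates = None
    if de_table is not None and corr_table is not None:
        top_de_list = prioritize.top_de(
            de_table, min_abs_logfc=config.de_min_abs_logfc,
            max_p=config.de_max_p_adj, p_col="p_adj",
        )
        top_corr_list = prioritize.top_corr(corr_table, max_p=config.corr_max_p)
        candidates = prioritize.overlay(
            top_de_list, top_corr_list, known_markers=set(config.known_markers)
        )
        if config.human_de_path:
            human = io.read_human_de(config.human_de_path)
            ortho = (
                pd.read_csv(config.ortholog_path, sep="\t")
                if config.ortholog_path
                else None
            )
            report = crossspecies.concordance(
                candidates, human, alpha=config.concordance_alpha,
                ortholog_table=ortho,
            )
            candidates = crossspecies.annotate_candidates(candidates, report)
            report.to_csv(out / "concordance.tsv", sep="\t", index=False,
                          lineterminator="\n")
            results["outputs"]["concordance"] = out / "concordance.tsv"
            results["concordance"] = report
        else:
            results["skipped"].append("cross_species: no human_de_path")
            log.info("skipping concordance: no human DE table")
        candidates.to_csv(out / "candidates.tsv", sep="\t", index=False,
                          lineterminator="\n")
        results["outputs"]["candidates"] = out / "candidates.tsv"
        results["candidates"] = candidates
    elif de_table is not None:
        results["skipped"].append("prioritization: no correlation table")

    if config.cohort_path:
        cohort = io.read_cohort(config.cohort_path)
        report = run_cohort_analysis(
            cohort, covariates=tuple(config.cohort_covariates),
            biomarker_scale=config.biomarker_scale,
        )
        report.table.to_csv(out / "cohort_logistic.tsv", sep="\t", index=False,
                            lineterminator="\n")
        report.baseline.to_csv(out / "cohort_baseline.tsv", sep="\t", index=False,
                               lineterminator="\n")
        results["outputs"]["cohort"] = out / "cohort_logistic.tsv"
        results["cohort_report"] = report
    else:
        results["skipped"].append("cohort_stats: no cohort_path")
        log.info("skipping cohort stage: no cohort_path")

    manifest = {
        "panelmark_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages_skipped": results["skipped"],
        "outputs": sorted(str(p.name) for p in results["outputs"].values()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("run complete in %.2fs", time.perf_counter() - t0)
    results["manifest"] = manifest
    return results


def demo(out_dir: str | Path | None = None) -> dict:
    """Reproduce the published overlay from the packaged printed tables.

    Runs the overlay on the packaged top-DE and top-correlation fixtures and
    the concordance check against the quoted human DE values; returns (and
    optionally writes) the candidate table and concordance report.
    """
    t1 = io.load_table1_fixture()
    t2 = io.load_table2_fixture()
    human = io.load_human_de_fixture()
    top_de_list = prioritize.top_de(t1, min_abs_logfc=1.0)
    top_corr_list = prioritize.top_corr(t2, max_p=1e-3)
    candidates = prioritize.overlay(top_de_list, top_corr_list)
    # known markers are also checked against the human table, alongside the
    # novel candidates
    known_in_t1 = top_de_list[top_de_list["symbol"].isin(io.DEFAULT_KNOWN_MARKERS)]
    nppb = pd.DataFrame(
        [{"symbol": "Nppb", "best_logfc": 0.0}]  # trait-correlated, not DE
    )
    check = pd.concat(
        [
            candidates[["symbol", "best_logfc"]],
            known_in_t1[["symbol", "logFC"]].rename(columns={"logFC": "best_logfc"}),
            nppb,
        ],
        ignore_index=True,
    ).drop_duplicates("symbol")
    report = crossspecies.concordance(check, human, alpha=0.05)
    candidates = crossspecies.annotate_candidates(candidates, report)
    out = {
        "candidates": candidates,
        "novel": sorted(prioritize.novel_candidates(candidates)),
        "concordance": report,
    }
    if out_dir is not None:
        p = Path(out_dir)
        p.mkdir(parents=True, exist_ok=True)
        candidates.to_csv(p / "demo_candidates.tsv", sep="\t", index=False,
                          lineterminator="\n")
        report.to_csv(p / "demo_concordance.tsv", sep="\t", index=False,
                      lineterminator="\n")
    return out
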