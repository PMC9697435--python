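"""End-to-end orchestration: simulate/load -> preprocess -> models -> tables.

A :class:`RunConfig` (usually loaded from YAML) names the inputs, output
directory, thresholds and seed.  :func:`run_pipeline` executes the toggled
stages in order, writes every result table under the output directory and
finishes with a ``manifest.json`` mapping each artifact to its SHA-256
content hash; reruns with the same seed reproduce identical hashes, and a
stage whose outputs already match the manifest can be skipped.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .anova import interaction_anova_table, paired_anova_table
from .clinical import clinical_association_table, stratified_tests
from .dml import bh_fdr, call_dml, class_iv_export, summarize_partition
from .genesets import enrichment_score, gene_set_table
from .preprocess import quantile_normalize
from .simulate import SimulationConfig, simulate_clinical, simulate_expression, \
    simulate_methylation

__all__ = ["RunConfig", "load_run_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline run configuration.

    When ``simulate`` is true the input matrices, sheet, manifest and gene
    sets are generated synthetically (``sim_overrides`` tweaks the
    generator); otherwise the ``*_path`` entries must point at existing
    files.  Thresholds are the FDR level for DML calling, the alpha of the
    tissue x onset interaction test, and the significance level feeding the
    enrichment gene list.
    """

    outdir: str = "results"
    seed: int = 0
    simulate: bool = True
    sim_overrides: dict = field(default_factory=dict)
    expression_path: str | None = None
    methylation_path: str | None = None
    sheet_path: str | None = None
    annotation_path: str | None = None
    gmt_path: str | None = None
    fdr_alpha: float = 0.05
    interaction_alpha: float = 0.05
    go_alpha: float = 0.05
    stages: dict = field(
        default_factory=lambda: {
            "preprocess": True,
            "anova": True,
            "geneset": True,
            "enrich": True,
            "dml": True,
            "clinical": True,
        }
    )

    def validate(self) -> None:
        for name in ("fdr_alpha", "interaction_alpha", "go_alpha"):
            value = getattr(self, name)
            if not (0.0 < value < 1.0):
                raise io.ValidationError(f"{name} must lie in (0, 1)")
        if not self.simulate:
            for name in ("expression_path", "sheet_path", "annotation_path"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise io.ValidationError(
                        f"{name} must point at an existing file when simulate=false"
                    )
        unknown = set(self.stages) - {
            "preprocess", "anova", "geneset", "enrich", "dml", "clinical"
        }
        if unknown:
            raise io.ValidationError(f"unknown stage toggle(s): {sorted(unknown)}")


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are errors."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise io.ValidationError(f"unknown config key(s): {sorted(unknown)}")
    config = RunConfig(**raw)
    config.validate()
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, resume: bool = False) -> dict:
    """Execute the configured stages; returns the artifact manifest.

    With ``resume=True`` a stage is skipped when all of its outputs exist
    and hash-match an existing manifest.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger = io.get_logger(outdir / "pipeline.log")
    manifest_path = outdir / "manifest.json"
    previous = {}
    if resume and manifest_path.exists():
        previous = json.loads(manifest_path.read_text())

    def done(*names: str) -> bool:
        return all(
            (outdir / n).exists() and previous.get(n) == _sha256(outdir / n)
            for n in names
        )

    artifacts: list[str] = []

    # --- inputs ---
    if config.simulate:
        sim = replace(SimulationConfig(seed=config.seed), **config.sim_overrides)
        with io.log_stage("simulate", logger=logger):
            expr, sheet, truth = simulate_expression(sim)
            beta, meth_sheet, meth_truth = simulate_methylation(sim)
            clin_sheet = simulate_clinical(sim)
            # carry clinical covariates onto the expression sheet
            merged = sheet.data.merge(
                clin_sheet.persons().drop(columns=["onset_group"]),
                on="person_id", how="left",
            )
            sheet = io.SampleSheet(merged)
        io.write_matrix(expr, outdir / "expression.tsv")
        io.write_matrix(beta, outdir / "methylation_beta.tsv")
        io.write_sample_sheet(sheet, outdir / "sample_sheet.tsv")
        io.write_annotation(truth.annotation(), outdir / "annotation.tsv")
        io.write_annotation(meth_truth.annotation(), outdir / "cpg_manifest.tsv")
        io.write_gene_sets(truth.gene_set_collection(), outdir / "gene_sets.gmt")
        truth.features.to_csv(outdir / "truth_expression.tsv", sep="\t", index=False)
        meth_truth.features.to_csv(outdir / "truth_methylation.tsv", sep="\t",
                                   index=False)
        annotation = truth.annotation()
        gene_sets = truth.gene_set_collection()
        manifest_ann = meth_truth.annotation()
        artifacts += [
            "expression.tsv", "methylation_beta.tsv", "sample_sheet.tsv",
            "annotation.tsv", "cpg_manifest.tsv", "gene_sets.gmt",
            "truth_expression.tsv", "truth_methylation.tsv",
        ]
    else:
        expr = io.read_matrix(config.expression_path, "expression_log2")
        sheet = io.read_sample_sheet(config.sheet_path)
        annotation = io.read_annotation(config.annotation_path)
        beta = (io.read_matrix(config.methylation_path, "methylation_beta")
                if config.methylation_path else None)
        gene_sets = (io.read_gene_sets(config.gmt_path)
                     if config.gmt_path else None)
        manifest_ann = annotation

    # --- preprocess ---
    if config.stages.get("preprocess", True):
        if not (resume and done("expression_norm.tsv")):
            with io.log_stage("preprocess", shape=expr.shape, logger=logger):
                expr = quantile_normalize(expr)
            io.write_matrix(expr, outdir / "expression_norm.tsv")
        else:
            expr = io.read_matrix(outdir / "expression_norm.tsv",
                                  "expression_log2")
        artifacts.append("expression_norm.tsv")

    # --- per-feature ANOVA ---
    fits = None
    if config.stages.get("anova", True):
        with io.log_stage("anova", shape=expr.shape, logger=logger):
            fits = interaction_anova_table(expr, sheet)
            paired = paired_anova_table(expr, sheet)
            fits = fits.merge(
                paired[["feature_id", "effect", "se", "F", "p",
                        "fold_change", "ci_low", "ci_high"]],
                on="feature_id",
            )
        io.write_results_table(fits, outdir / "anova_fits.tsv")
        artifacts.append("anova_fits.tsv")

    # --- gene sets ---
    if config.stages.get("geneset", True) and gene_sets is not None:
        with io.log_stage("geneset", shape=(len(gene_sets),), logger=logger):
            sets_tab = gene_set_table(expr, sheet, gene_sets, annotation,
                                      with_interaction=True)
        io.write_results_table(sets_tab, outdir / "gene_sets.tsv")
        artifacts.append("gene_sets.tsv")

    # --- enrichment ---
    if config.stages.get("enrich", True) and gene_sets is not None and fits is not None:
        with io.log_stage("enrich", logger=logger):
            gene_of = annotation.gene_of()
            fits_g = fits.assign(
                gene=lambda t: t["feature_id"].map(gene_of)
            ).dropna(subset=["gene", "p"])
            gene_p = fits_g.groupby("gene")["p"].min()
            q = bh_fdr(gene_p.to_numpy())
            sig = list(gene_p.index[q <= config.go_alpha])
            chip = list(gene_p.index)
            rows = []
            for name, members in gene_sets:
                present = [g for g in members if g in set(chip)]
                if not present:
                    continue
                res = enrichment_score(sig, present, chip, category=name)
                rows.append(res.__dict__)
        io.write_results_table(pd.DataFrame(rows), outdir / "enrichment.tsv")
        artifacts.append("enrichment.tsv")

    # --- methylation DML ---
    if config.stages.get("dml", True) and beta is not None:
        meth_design = meth_sheet if config.simulate else sheet
        with io.log_stage("dml", shape=beta.shape, logger=logger):
            records = call_dml(beta, meth_design, manifest_ann,
                               fdr_alpha=config.fdr_alpha,
                               interaction_alpha=config.interaction_alpha)
            summary = summarize_partition(records)
            class_iv = class_iv_export(records)
        io.write_results_table(records, outdir / "dml.tsv")
        io.write_results_table(summary, outdir / "dml_summary.tsv")
        io.write_results_table(class_iv, outdir / "dml_class_iv.tsv")
        artifacts += ["dml.tsv", "dml_summary.tsv", "dml_class_iv.tsv"]

    # --- clinical ---
    if config.stages.get("clinical", True):
        clin_source = clin_sheet if config.simulate else sheet
        covs = clin_source.clinical_covariates
        if covs:
            with io.log_stage("clinical", logger=logger):
                assoc = clinical_association_table(clin_source)
                strat_rows = []
                if "stage" in covs:
                    for cov in ("lvi", "pni"):
                        if cov not in covs:
                            continue
                        per_stratum = stratified_tests(
                            clin_source, cov, "onset_group", "stage"
                        )
                        for level, res in per_stratum.items():
                            strat_rows.append(
                                {
                                    "stratum": level,
                                    "covariate": cov,
                                    "chi2": res.chi2 if res else np.nan,
                                    "p": res.p if res else np.nan,
                                    "note": "" if res else "untestable",
                                }
                            )
            io.write_results_table(assoc, outdir / "clinical.tsv")
            artifacts.append("clinical.tsv")
            if strat_rows:
                io.write_results_table(pd.DataFrame(strat_rows),
                                       outdir / "clinical_stratified.tsv")
                artifacts.append("clinical_stratified.tsv")

    manifest = {name: _sha256(outdir / name) for name in artifacts}
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
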