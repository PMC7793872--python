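"""End-to-end orchestration: filters -> normalization -> PCA feature
extraction -> enrichment -> interaction networks, with a machine-readable
run report.

:func:`run_stages` executes the whole chain on in-memory objects (what the
tests and analysis scripts call); :func:`run_pipeline` wraps it with file
IO, stage-tagged error propagation and artifact writing.  Reruns on
identical inputs and configuration are bit-identical: no stage uses
randomness.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .enrichment import GeneSetCollection, fisher_enrichment, load_gmt
from .errors import ConfigurationError, CosigError, PipelineError
from .io import (
    CountMatrix,
    attach_lengths,
    filter_samples,
    load_annotation,
    load_counts,
    load_sample_table,
    merge_cohorts,
    sample_accounting,
)
from .networks import (
    InteractionGraph,
    build_networks,
    load_interactions,
    networks_to_frame,
)
from .pca_fe import SignatureSet, correlate_genes, extract_signatures, run_pca, select_components
from .preprocess import (
    compute_logfc,
    filter_by_annotation,
    filter_by_cpm,
    filter_by_logfc,
    normalize_uqua,
)

logger = logging.getLogger("cosig")

__all__ = ["PipelineParams", "RunConfig", "RunReport", "StageResults", "run_stages", "run_pipeline"]


@dataclass(frozen=True)
class PipelineParams:
    """All stage thresholds; defaults are the reference parameterization."""

    cpm_threshold: float = 0.5
    cpm_min_fraction: float = 0.9
    logfc_threshold: float = 1.0
    variance_target: float = 0.6
    percentile: float = 95.0
    alpha: float = 0.001
    min_score: float = 1.3
    max_network_size: int = 35

    def validate(self) -> None:
        if self.cpm_threshold < 0:
            raise ConfigurationError("cpm_threshold must be non-negative")
        if not 0 < self.cpm_min_fraction <= 1:
            raise ConfigurationError("cpm_min_fraction must be in (0, 1]")
        if self.logfc_threshold < 0:
            raise ConfigurationError("logfc_threshold must be non-negative")
        if not 0 < self.variance_target <= 1:
            raise ConfigurationError("variance_target must be in (0, 1]")
        if not 0 <= self.percentile <= 100:
            raise ConfigurationError("percentile must be in [0, 100]")
        if not 0 < self.alpha <= 1:
            raise ConfigurationError("alpha must be in (0, 1]")
        if self.min_score < 0:
            raise ConfigurationError("min_score must be non-negative")
        if self.max_network_size < 2:
            raise ConfigurationError("max_network_size must be at least 2")


@dataclass
class RunReport:
    """Per-stage accounting mirroring the pipeline narrative."""

    n_samples: int
    n_tumor: int
    n_normal: int
    genes_total: int
    genes_after_cpm: int
    genes_after_annotation: int
    genes_after_logfc: int
    n_components_retained: int
    n_signatures: int
    n_up: int
    n_down: int
    n_sets_tested: int | None = None
    n_sets_significant: int | None = None
    n_networks: int | None = None
    version: str = __version__
    config: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_up + self.n_down != self.n_signatures:
            raise PipelineError("report", "up + down must equal the signature count")
        chain = [
            self.genes_total,
            self.genes_after_cpm,
            self.genes_after_annotation,
            self.genes_after_logfc,
            self.n_signatures,
        ]
        if any(a < b for a, b in zip(chain, chain[1:])):
            raise PipelineError("report", "gene counts must be non-increasing through filters")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclass
class StageResults:
    """Everything the chain produced, stage by stage."""

    counts: CountMatrix
    meta: pd.DataFrame
    after_cpm: CountMatrix
    after_annotation: CountMatrix
    expr: pd.DataFrame
    fc: pd.DataFrame
    candidates: set[str]
    m: int
    signatures: SignatureSet
    enrichment: pd.DataFrame | None
    networks: list
    report: RunReport


def run_stages(
    cm: CountMatrix,
    meta: pd.DataFrame,
    annotated_ids: set[str] | None = None,
    gene_sets: GeneSetCollection | None = None,
    interactions: InteractionGraph | None = None,
    params: PipelineParams = PipelineParams(),
    keep_sex: Sequence[str] = ("female",),
    keep_types: Sequence[str] = ("tumor", "normal"),
    scale: bool = False,
    direct_only: bool = False,
) -> StageResults:
    """Run every stage on in-memory inputs and return all intermediates."""
    params.validate()

    def stage(name):
        logger.info("stage %s", name)
        return name

    name = stage("filter_samples")
    try:
        cm, meta = filter_samples(cm, meta, keep_sex=keep_sex, keep_types=keep_types)
        accounting = sample_accounting(meta)
        logger.info(
            "samples retained: %d tumor + %d normal = %d",
            accounting["tumor"], accounting["normal"], accounting["total"],
        )
        genes_total = cm.n_genes

        name = stage("filter_by_cpm")
        after_cpm = filter_by_cpm(cm, params.cpm_threshold, params.cpm_min_fraction)
        logger.info("genes after CPM filter: %d / %d", after_cpm.n_genes, genes_total)

        name = stage("filter_by_annotation")
        if annotated_ids is not None:
            after_annotation = filter_by_annotation(after_cpm, annotated_ids)
        else:
            after_annotation = after_cpm
        logger.info("genes after annotation filter: %d", after_annotation.n_genes)

        name = stage("normalize_uqua")
        expr = normalize_uqua(after_annotation)

        name = stage("compute_logfc")
        fc = compute_logfc(expr, meta)
        candidates = filter_by_logfc(fc, params.logfc_threshold)
        logger.info("genes after |logFC| > %g filter: %d", params.logfc_threshold, len(candidates))

        name = stage("pca_feature_extraction")
        if len(candidates) >= 2 and expr.shape[1] >= 3:
            if scale:
                sub = expr.loc[sorted(candidates)]
                centered = sub.sub(sub.mean(axis=1), axis=0)
                sd = sub.std(axis=1, ddof=1).replace(0.0, 1.0)
                expr_for_pca = expr.copy()
                expr_for_pca.loc[sub.index] = centered.div(sd, axis=0)
            else:
                expr_for_pca = expr
            pca = run_pca(expr_for_pca, gene_subset=candidates)
            m = select_components(pca, params.variance_target)
            corr = correlate_genes(expr_for_pca.loc[[g for g in expr.index if g in candidates]], pca, m)
            signatures = extract_signatures(corr, fc, params.percentile, params.alpha)
        else:
            logger.info("too few candidate genes for PCA; empty signature set")
            m = 0
            signatures = SignatureSet(
                table=pd.DataFrame(
                    columns=["components", "max_abs_r", "p_value", "direction"],
                    index=pd.Index([], name="gene_id"),
                )
            )
        logger.info(
            "signatures: %d (%d up, %d down) from %d components",
            len(signatures), signatures.n_up, signatures.n_down, m,
        )

        name = stage("enrichment")
        enrichment = None
        n_sets_tested = n_sets_significant = None
        if gene_sets is not None and len(signatures):
            universe = set(after_annotation.gene_ids)
            enrichment = fisher_enrichment(
                signatures.genes, gene_sets, universe, min_score=params.min_score
            )
            n_sets_tested = int(enrichment["tested"].sum())
            n_sets_significant = int(enrichment["significant"].sum())
            logger.info("enriched sets: %d of %d tested", n_sets_significant, n_sets_tested)

        name = stage("networks")
        networks = []
        n_networks = None
        if interactions is not None and len(signatures):
            ig = interactions.restrict_direct() if direct_only else interactions
            networks = build_networks(ig, signatures.genes, params.max_network_size)
            n_networks = len(networks)
            logger.info("networks built: %d", n_networks)
    except CosigError as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(name, str(exc)) from exc

    report = RunReport(
        n_samples=accounting["total"],
        n_tumor=accounting["tumor"],
        n_normal=accounting["normal"],
        genes_total=genes_total,
        genes_after_cpm=after_cpm.n_genes,
        genes_after_annotation=after_annotation.n_genes,
        genes_after_logfc=len(candidates),
        n_components_retained=m,
        n_signatures=len(signatures),
        n_up=signatures.n_up,
        n_down=signatures.n_down,
        n_sets_tested=n_sets_tested,
        n_sets_significant=n_sets_significant,
        n_networks=n_networks,
        config=dataclasses.asdict(params),
    )
    report.validate()
    return StageResults(
        counts=cm,
        meta=meta,
        after_cpm=after_cpm,
        after_annotation=after_annotation,
        expr=expr,
        fc=fc,
        candidates=candidates,
        m=m,
        signatures=signatures,
        enrichment=enrichment,
        networks=networks,
        report=report,
    )


@dataclass
class RunConfig:
    """File-level configuration for a full pipeline run."""

    counts: list[str]
    metadata: str
    outdir: str
    annotation: str | None = None
    gmt: str | None = None
    interactions: str | None = None
    counts_format: str = "tsv"
    params: PipelineParams = field(default_factory=PipelineParams)
    keep_sex: tuple[str, ...] = ("female",)
    keep_types: tuple[str, ...] = ("tumor", "normal")
    keep_unknown_sex: bool = False
    strip_gene_versions: bool = False
    scale: bool = False
    direct_only: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        params_raw = raw.pop("params", {})
        known = {f.name for f in dataclasses.fields(PipelineParams)}
        bad = set(params_raw) - known
        if bad:
            raise ConfigurationError(f"unknown pipeline parameter(s) {sorted(bad)}")
        counts = raw.pop("counts", None)
        if counts is None:
            raise ConfigurationError("config must name at least one counts file")
        if isinstance(counts, str):
            counts = [counts]
        field_names = {f.name for f in dataclasses.fields(cls)} - {"counts", "params"}
        bad = set(raw) - field_names
        if bad:
            raise ConfigurationError(f"unknown config key(s) {sorted(bad)}")
        for key in ("keep_sex", "keep_types"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(counts=counts, params=PipelineParams(**params_raw), **raw)


def run_pipeline(config: RunConfig) -> RunReport:
    """Load inputs per ``config``, run every stage and write all artifacts."""
    params = config.params
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def load_stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (CosigError, OSError) as exc:
            raise PipelineError(name, str(exc)) from exc

    matrices = [
        load_stage("load_counts", load_counts, p, config.counts_format) for p in config.counts
    ]
    cm = matrices[0] if len(matrices) == 1 else load_stage("merge_cohorts", merge_cohorts, matrices)
    if config.strip_gene_versions:
        cm = cm.strip_gene_versions()
    meta = load_stage("load_metadata", load_sample_table, config.metadata)
    annotated_ids = None
    if config.annotation:
        annot = load_stage("load_annotation", load_annotation, config.annotation)
        cm = attach_lengths(cm, annot)
        annotated_ids = set(annot["gene_id"])
    gene_sets = load_stage("load_gmt", load_gmt, config.gmt) if config.gmt else None
    interactions = (
        load_stage("load_interactions", load_interactions, config.interactions)
        if config.interactions
        else None
    )

    keep_sex = set(config.keep_sex) | ({"unknown"} if config.keep_unknown_sex else set())
    results = run_stages(
        cm,
        meta,
        annotated_ids=annotated_ids,
        gene_sets=gene_sets,
        interactions=interactions,
        params=params,
        keep_sex=keep_sex,
        keep_types=config.keep_types,
        scale=config.scale,
        direct_only=config.direct_only,
    )

    # artifacts are written only after every stage succeeded, so a failed
    # run leaves no partial outputs behind
    expr_out = results.expr.copy()
    expr_out.index.name = "gene_id"
    expr_out.to_csv(outdir / "normalized.tsv", sep="\t", float_format="%.10g")
    fc_out = results.fc.copy()
    fc_out.index.name = "gene_id"
    fc_out.to_csv(outdir / "fold_change.tsv", sep="\t", float_format="%.10g")
    sig = results.signatures.table.copy()
    sig["components"] = ["|".join(f"PC{c}" for c in comps) for comps in sig["components"]]
    sig.to_csv(outdir / "signatures.tsv", sep="\t", float_format="%.10g")
    if results.enrichment is not None:
        results.enrichment.to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.10g"
        )
    if results.networks:
        networks_to_frame(results.networks).to_csv(
            outdir / "networks.tsv", sep="\t", index=False, float_format="%.10g"
        )
    results.report.to_json(outdir / "report.json")
    return results.report
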