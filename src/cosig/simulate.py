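"""Synthetic multi-cohort RNA-seq counts with planted tumor-dysregulated genes.

The generator emulates the statistical structure that the downstream
signature-extraction pipeline assumes: several cohorts that share one gene
universe but differ in tissue baseline, variable library sizes, and a common
set of genes shifted up or down in tumors of *every* cohort.  One cohort may
lack normal samples, as happens for ovarian solid-tissue normals in public
repositories.

Counts follow a negative-binomial model with mean/dispersion
parameterization (variance = mu + dispersion * mu^2).  For gene ``g`` in
sample ``s`` of cohort ``c``::

    mu[g, s] = exp(baseline[g] + ln2 * (tissue[c, g] + delta[g] * is_tumor[s]))
               * libsize[s] / exp(libsize_log_mean)

with ``delta[g] = +effect_log2fc`` for planted up genes, ``-effect_log2fc``
for planted down genes and 0 otherwise, and ``tissue[c, g] ~
Normal(0, tissue_effect_sd)`` drawn once per cohort/gene pair (log2 scale).
A single :class:`numpy.random.Generator` seeded from ``config.seed`` drives
every draw, so identical configurations reproduce bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import (
    CountMatrix,
    write_annotation,
    write_counts,
    write_sample_table,
)

__all__ = [
    "CohortSpec",
    "SynthConfig",
    "TruthLabels",
    "generate_cohorts",
    "null_config",
    "write_dataset",
    "synthetic_gene_sets",
    "synthetic_interaction_table",
]


@dataclass(frozen=True)
class CohortSpec:
    """One cohort: a name and its tumor / normal sample counts."""

    name: str
    n_tumor: int
    n_normal: int


def _default_cohorts() -> tuple[CohortSpec, ...]:
    # three cohorts with distinct tissue baselines; the middle one has no
    # normal samples (the ovarian-like case)
    return (
        CohortSpec("cohortA", 150, 30),
        CohortSpec("cohortB", 100, 0),
        CohortSpec("cohortC", 120, 20),
    )


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; defaults are the package's reference study
    conditions (three cohorts, 3,000 genes, 200 planted genes at |log2FC| = 2).

    Parameters
    ----------
    baseline_log_mean, baseline_log_sd:
        Natural-log mean and sd of per-gene baseline abundance; exp(baseline)
        is the expected count at the nominal library size.
    tissue_effect_sd:
        SD (log2 units) of the per-(cohort, gene) baseline shift.
    dispersion:
        Negative-binomial dispersion alpha, variance = mu + alpha * mu^2.
    libsize_log_mean, libsize_log_sd:
        Natural-log parameters of the log-normal library-size distribution.
    """

    n_genes: int = 3000
    cohorts: tuple[CohortSpec, ...] = field(default_factory=_default_cohorts)
    n_planted_up: int = 100
    n_planted_down: int = 100
    effect_log2fc: float = 2.0
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.5
    tissue_effect_sd: float = 0.5
    dispersion: float = 0.2
    libsize_log_mean: float = math.log(3.0e6)
    libsize_log_sd: float = 0.35
    gene_length_range: tuple[int, int] = (300, 10000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if not self.cohorts:
            raise ConfigurationError("cohorts must be non-empty")
        names = [c.name for c in self.cohorts]
        if len(set(names)) != len(names):
            raise ConfigurationError("cohorts must have unique names")
        for c in self.cohorts:
            if c.n_tumor < 0 or c.n_normal < 0:
                raise ConfigurationError(
                    f"cohorts[{c.name!r}].n_tumor/n_normal must be non-negative"
                )
        if sum(c.n_tumor + c.n_normal for c in self.cohorts) == 0:
            raise ConfigurationError("cohorts must contain at least one sample")
        if not any(c.n_normal > 0 for c in self.cohorts):
            raise ConfigurationError(
                "cohorts: at least one cohort needs n_normal > 0 "
                "(a pooled normal reference must exist)"
            )
        if self.n_planted_up < 0:
            raise ConfigurationError("n_planted_up must be non-negative")
        if self.n_planted_down < 0:
            raise ConfigurationError("n_planted_down must be non-negative")
        if self.n_planted_up + self.n_planted_down > self.n_genes:
            raise ConfigurationError(
                "n_planted_up + n_planted_down must not exceed n_genes"
            )
        if self.effect_log2fc <= 0:
            raise ConfigurationError("effect_log2fc must be positive")
        if self.tissue_effect_sd < 0:
            raise ConfigurationError("tissue_effect_sd must be non-negative")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        if self.baseline_log_sd < 0:
            raise ConfigurationError("baseline_log_sd must be non-negative")
        if self.libsize_log_sd < 0:
            raise ConfigurationError("libsize_log_sd must be non-negative")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError(
                "gene_length_range must be a pair of positive integers lo <= hi"
            )


def null_config(config: SynthConfig) -> SynthConfig:
    """The pure-noise control: no planted genes, no tissue baselines."""
    return replace(config, n_planted_up=0, n_planted_down=0, tissue_effect_sd=0.0)


@dataclass(frozen=True)
class TruthLabels:
    """Ground truth for a generated dataset."""

    planted_up: frozenset[str]
    planted_down: frozenset[str]
    effects: Mapping[str, float]  # gene id -> true log2 effect (0 if unplanted)

    @property
    def planted(self) -> frozenset[str]:
        return self.planted_up | self.planted_down


def generate_cohorts(config: SynthConfig) -> tuple[CountMatrix, pd.DataFrame, TruthLabels]:
    """Draw a multi-cohort count matrix, its metadata table and truth labels."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(g)]

    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=g)
    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=g)

    # planted effects split exactly between up and down, leading gene ids
    delta = np.zeros(g)
    up_ids = gene_ids[: config.n_planted_up]
    down_ids = gene_ids[config.n_planted_up : config.n_planted_up + config.n_planted_down]
    delta[: config.n_planted_up] = config.effect_log2fc
    delta[config.n_planted_up : config.n_planted_up + config.n_planted_down] = (
        -config.effect_log2fc
    )

    sample_ids: list[str] = []
    patient_ids: list[str] = []
    cohort_col: list[str] = []
    type_col: list[str] = []
    mu_cols: list[np.ndarray] = []
    ln2 = math.log(2.0)
    ref_libsize = math.exp(config.libsize_log_mean)

    for cohort in config.cohorts:
        tissue = rng.normal(0.0, config.tissue_effect_sd, size=g)
        n_c = cohort.n_tumor + cohort.n_normal
        libsizes = np.exp(
            rng.normal(config.libsize_log_mean, config.libsize_log_sd, size=n_c)
        )
        for j in range(n_c):
            is_tumor = j < cohort.n_tumor
            label = "T" if is_tumor else "N"
            k = j if is_tumor else j - cohort.n_tumor
            sample_ids.append(f"{cohort.name}-{label}{k:04d}")
            patient_ids.append(f"{cohort.name}-P{j:04d}")
            cohort_col.append(cohort.name)
            type_col.append("tumor" if is_tumor else "normal")
            log_mu = baseline + ln2 * (tissue + delta * is_tumor)
            mu_cols.append(np.exp(log_mu) * (libsizes[j] / ref_libsize))

    mu = np.column_stack(mu_cols)
    size = 1.0 / config.dispersion  # NB "number of successes" parameter
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p).astype(np.int64)

    cm = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        pd.Series(lengths.astype(float), index=gene_ids),
    )
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "patient_id": patient_ids,
            "cohort": cohort_col,
            "sample_type": type_col,
            "sex": "female",
        }
    )
    truth = TruthLabels(
        planted_up=frozenset(up_ids),
        planted_down=frozenset(down_ids),
        effects=dict(zip(gene_ids, delta)),
    )
    return cm, meta, truth


def write_dataset(
    cm: CountMatrix,
    meta: pd.DataFrame,
    truth: TruthLabels,
    outdir: str | Path,
    counts_format: str = "tsv",
) -> dict[str, Path]:
    """Write counts, metadata, annotation and truth tables under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / ("counts.tsv" if counts_format == "tsv" else "counts_mtx"),
        "metadata": outdir / "metadata.tsv",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_counts(cm, paths["counts"], format=counts_format)
    write_sample_table(meta, paths["metadata"])
    annot = pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "length_bp": cm.gene_lengths.astype(int).to_numpy(),
            "biotype": "protein_coding",
        }
    )
    write_annotation(annot, paths["annotation"])
    effects = pd.Series(truth.effects, name="true_log2fc")
    effects.rename_axis("gene_id").to_csv(paths["truth"], sep="\t")
    return paths


# ---------------------------------------------------------------------------
# companion resources with known ground truth, for the enrichment and
# network stages (the public GMT / interaction inputs are user-supplied in
# real analyses; these emulate them around the planted genes)
# ---------------------------------------------------------------------------


def synthetic_gene_sets(
    gene_ids: list[str],
    truth: TruthLabels,
    seed: int,
    n_signal_sets: int = 4,
    n_null_sets: int = 20,
    set_size: int = 40,
    signal_fraction: float = 0.6,
):
    """A gene-set collection in which a few sets are enriched in planted genes.

    Signal sets draw ``signal_fraction`` of their members from the planted
    genes and the rest at random; null sets are uniform draws.  Returns a
    :class:`~cosig.enrichment.GeneSetCollection`.
    """
    from .enrichment import GeneSetCollection

    rng = np.random.default_rng(seed)
    planted = sorted(truth.planted)
    universe = list(gene_ids)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for i in range(n_signal_sets):
        n_sig = min(int(round(signal_fraction * set_size)), len(planted))
        members = set(rng.choice(planted, size=n_sig, replace=False)) if n_sig else set()
        pool = [x for x in universe if x not in members]
        members |= set(rng.choice(pool, size=set_size - len(members), replace=False))
        name = f"SIGNAL_SET_{i + 1}"
        sets[name] = frozenset(members)
        descriptions[name] = "planted-gene enriched set"
    for i in range(n_null_sets):
        members = set(rng.choice(universe, size=set_size, replace=False))
        name = f"NULL_SET_{i + 1}"
        sets[name] = frozenset(members)
        descriptions[name] = "uniform background set"
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def synthetic_interaction_table(
    gene_ids: list[str],
    truth: TruthLabels,
    seed: int,
    n_hubs: int = 5,
    targets_per_hub: int = 25,
    n_background_edges: int = 400,
) -> pd.DataFrame:
    """An interaction edge list wiring planted genes to hub regulators.

    Each hub connects to planted targets with signed edges concordant with
    the planted direction (activating edges to up genes, inhibiting to down
    genes), so a sign-consistency regulator call should flag hubs as
    activated.  Background edges are unsigned uniform pairs.  Columns:
    source, target, directness, relation, sign.
    """
    rng = np.random.default_rng(seed)
    planted = sorted(truth.planted)
    relations = np.array(["E", "T", "P", "PP"])
    rows: list[tuple[str, str, str, str, str]] = []
    hubs = [f"HUB{i + 1:02d}" for i in range(n_hubs)]
    for hub in hubs:
        n_t = min(targets_per_hub, len(planted))
        targets = rng.choice(planted, size=n_t, replace=False) if n_t else []
        for t in targets:
            sign = "activating" if t in truth.planted_up else "inhibiting"
            rows.append(
                (
                    hub,
                    t,
                    rng.choice(["direct", "indirect"]),
                    rng.choice(relations),
                    sign,
                )
            )
    seen = {(min(a, b), max(a, b), r) for a, b, _, r, _ in rows}
    while len(rows) < len(hubs) * min(targets_per_hub, len(planted)) + n_background_edges:
        a, b = rng.choice(gene_ids, size=2, replace=False)
        rel = str(rng.choice(relations))
        key = (min(a, b), max(a, b), rel)
        if key in seen:
            continue
        seen.add(key)
        rows.append((a, b, str(rng.choice(["direct", "indirect"])), rel, "unknown"))
    return pd.DataFrame(
        rows, columns=["source", "target", "directness", "relation", "sign"]
    )
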