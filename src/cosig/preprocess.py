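"""Filtering and normalization front end.

Order of operations mirrors the pipeline: CPM expression filter, annotation
filter, upper-quartile normalization with gene-length correction, log2
transform, then the pooled tumor-vs-normal log fold-change pre-filter.

Conventions fixed here (they make every rule well defined for any input):

* "CPM above t" is a strict inequality; "in at least a fraction f of
  samples" means at least ``ceil(f * n_samples)`` samples.
* The per-sample upper quartile is the linearly interpolated 75th
  percentile of the *nonzero* length-corrected values; samples are rescaled
  to the geometric mean of those quartiles (a symmetric, order-independent
  reference).
* logFC is the difference of mean log2-normalized expression, tumor minus
  normal, pooled across all cohorts that contribute samples of each type;
  the |logFC| > t filter uses a strict inequality.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConsistencyError, DegenerateSampleError
from .io import CountMatrix, validate_sample_table

__all__ = [
    "cpm",
    "filter_by_cpm",
    "filter_by_annotation",
    "uq_scale",
    "normalize_uqua",
    "compute_logfc",
    "filter_by_logfc",
]


def cpm(cm: CountMatrix) -> pd.DataFrame:
    """Counts per million: counts / library size * 1e6, per sample."""
    libsize = cm.counts.sum(axis=0)
    zero = libsize.index[libsize == 0]
    if len(zero):
        raise DegenerateSampleError(f"zero library size for sample {zero[0]!r}")
    return cm.counts / libsize * 1.0e6


def filter_by_cpm(
    cm: CountMatrix, threshold: float = 0.5, min_fraction: float = 0.9
) -> CountMatrix:
    """Keep genes with CPM > ``threshold`` in >= ceil(min_fraction * n) samples."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    need = math.ceil(min_fraction * cm.n_samples)
    passing = (cpm(cm) > threshold).sum(axis=1) >= need
    return cm.subset_genes(list(cm.counts.index[passing]))


def filter_by_annotation(cm: CountMatrix, annotated_ids: Iterable[str]) -> CountMatrix:
    """Keep exactly the genes present in ``annotated_ids``, preserving order."""
    annotated = set(annotated_ids)
    kept = [g for g in cm.gene_ids if g in annotated]
    if not kept:
        warnings.warn("annotation filter removed every gene", stacklevel=2)
    return cm.subset_genes(kept)


def _upper_quartiles(v: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-sample 75th percentile (linear interpolation) of masked values."""
    n_samples = v.shape[1]
    uq = np.empty(n_samples)
    for j in range(n_samples):
        vals = v[mask[:, j], j]
        if vals.size == 0:
            raise DegenerateSampleError(
                f"sample at column {j} has no nonzero counts to normalize"
            )
        uq[j] = np.percentile(vals, 75)
    if (uq == 0).any():
        j = int(np.argwhere(uq == 0)[0][0])
        raise DegenerateSampleError(f"zero upper quartile for sample at column {j}")
    return uq


def uq_scale(
    v: pd.DataFrame, nonzero_mask: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Equalize per-sample upper quartiles of nonzero values.

    Each sample is multiplied by (geometric mean of all upper quartiles) /
    (its own upper quartile); returns the rescaled matrix and the factors.
    Applying the scaling twice changes nothing (the quartiles are already
    equal after one pass).
    """
    mask = (v > 0) if nonzero_mask is None else nonzero_mask.astype(bool)
    uq = _upper_quartiles(v.to_numpy(float), mask.to_numpy())
    reference = math.exp(float(np.mean(np.log(uq))))
    factors = reference / uq
    return v * factors, factors


def normalize_uqua(cm: CountMatrix) -> pd.DataFrame:
    """Length-corrected upper-quartile normalization, log2(x + 1) scale.

    Steps: (1) divide each gene by its length in kb; (2) rescale each sample
    so the 75th percentiles of nonzero length-corrected values are equal
    across samples; (3) log2(x + 1).
    """
    missing = cm.missing_length_genes
    if missing:
        raise ConsistencyError(
            f"{len(missing)} gene(s) lack a length annotation "
            f"(first: {missing[0]!r}); attach lengths before normalizing"
        )
    v = cm.counts.div(cm.gene_lengths / 1000.0, axis=0)
    w, _ = uq_scale(v, nonzero_mask=cm.counts > 0)
    return np.log2(w + 1.0)


def compute_logfc(expr: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Pooled tumor-minus-normal mean log2 expression difference per gene.

    Normals from every cohort that has them form one pooled reference (a
    cohort without normal samples contributes tumors only).  Returns a
    DataFrame indexed by gene id with columns ``logfc`` and ``direction``
    (up / down / none).
    """
    meta = validate_sample_table(meta)
    types = meta.set_index("sample_id")["sample_type"]
    missing = [s for s in expr.columns if s not in types.index]
    if missing:
        raise ConsistencyError(f"expression column(s) missing from metadata: {missing[:5]}")
    tumor_cols = [s for s in expr.columns if types[s] == "tumor"]
    normal_cols = [s for s in expr.columns if types[s] == "normal"]
    if not tumor_cols or not normal_cols:
        raise ConsistencyError(
            "logFC needs at least one tumor and one normal sample "
            "(a cohort set without normals cannot be contrasted)"
        )
    logfc = expr[tumor_cols].mean(axis=1) - expr[normal_cols].mean(axis=1)
    direction = np.where(logfc > 0, "up", np.where(logfc < 0, "down", "none"))
    return pd.DataFrame({"logfc": logfc, "direction": direction}, index=expr.index)


def filter_by_logfc(fc: pd.DataFrame, threshold: float = 1.0) -> set[str]:
    """Gene ids with |logFC| strictly greater than ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return set(fc.index[fc["logfc"].abs() > threshold])
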