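"""PCA-based unsupervised feature extraction.

Samples are the observations and genes the variables: the expression matrix
is transposed to samples x genes, each gene is mean-centered (not scaled —
values already share the log2 normalized scale) and decomposed by PCA.
Components are retained up to a cumulative explained-variance target.  A
gene joins the signature set if, for at least one retained component, the
absolute Pearson correlation between its expression and the component's
score vector (i) exceeds the per-component 95th percentile of absolute
correlations over all genes and (ii) has a two-sided p-value below alpha.
Direction labels (up/down vs the normal reference) are carried over from
the fold-change table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .errors import ConsistencyError, DegenerateInputError

__all__ = [
    "PCAResult",
    "CorrelationResult",
    "SignatureSet",
    "run_pca",
    "select_components",
    "correlate_genes",
    "extract_signatures",
]

_EPS = 1e-12


@dataclass
class PCAResult:
    """Scores (samples x components) and explained-variance fractions."""

    scores: pd.DataFrame
    variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class CorrelationResult:
    """Per-(gene, component) Pearson r and two-sided p over samples."""

    r: pd.DataFrame  # genes x components
    p: pd.DataFrame
    n_samples: int
    degenerate_genes: frozenset[str]  # zero-variance genes (r undefined)


@dataclass
class SignatureSet:
    """Selected genes with their selecting components, max |r|, p, direction.

    ``table`` is indexed by gene id with columns ``components`` (tuple of
    1-based component indices), ``max_abs_r``, ``p_value``, ``direction``.
    """

    table: pd.DataFrame

    @property
    def genes(self) -> set[str]:
        return set(self.table.index)

    @property
    def n_up(self) -> int:
        return int((self.table["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["direction"] == "down").sum())

    def __len__(self) -> int:
        return len(self.table)


def run_pca(expr: pd.DataFrame, gene_subset: set[str] | None = None) -> PCAResult:
    """Full PCA of ``expr`` (genes x samples), optionally on a gene subset.

    Returns all ``min(n_samples, n_genes)`` components; variance fractions
    sum to 1.
    """
    genes = (
        [g for g in expr.index if g in gene_subset] if gene_subset is not None else list(expr.index)
    )
    if len(genes) < 2:
        raise DegenerateInputError("PCA needs at least 2 genes")
    X = expr.loc[genes].T.to_numpy(dtype=float)  # samples x genes
    if X.shape[0] < 3:
        raise DegenerateInputError("PCA needs at least 3 samples")
    if np.allclose(X.var(axis=0).sum(), 0.0):
        raise DegenerateInputError("zero total variance: constant expression matrix")
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=expr.columns, columns=cols),
        variance_fraction=pca.explained_variance_ratio_.copy(),
    )


def select_components(pca: PCAResult, target: float = 0.6) -> int:
    """Smallest m whose cumulative explained-variance fraction reaches ``target``."""
    if not 0 < target <= 1:
        raise ValueError("target must be in (0, 1]")
    cumulative = np.cumsum(pca.variance_fraction)
    reached = np.nonzero(cumulative >= target - _EPS)[0]
    if len(reached) == 0:  # numerically short of 1.0; all components needed
        return pca.n_components
    return int(reached[0]) + 1


def correlate_genes(expr: pd.DataFrame, pca: PCAResult, m: int) -> CorrelationResult:
    """Pearson r and two-sided p between every gene and the first m components.

    p comes from ``t = r * sqrt((n - 2) / (1 - r^2))`` on ``n - 2`` degrees
    of freedom.  Genes with zero variance get NaN r/p and are flagged rather
    than failing the run.
    """
    if m > pca.n_components:
        raise ValueError(f"m = {m} exceeds available components ({pca.n_components})")
    n = expr.shape[1]
    if n < 3:
        raise DegenerateInputError("correlation needs at least 3 samples")
    X = expr.to_numpy(dtype=float)  # genes x samples
    S = pca.scores.iloc[:, :m].to_numpy(dtype=float)  # samples x m
    Xc = X - X.mean(axis=1, keepdims=True)
    Sc = S - S.mean(axis=0, keepdims=True)
    x_norm = np.sqrt((Xc**2).sum(axis=1))
    s_norm = np.sqrt((Sc**2).sum(axis=0))
    degenerate = x_norm == 0
    x_norm_safe = np.where(degenerate, 1.0, x_norm)
    r = (Xc @ Sc) / x_norm_safe[:, None] / s_norm[None, :]
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 0.0))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(t), 0.0, p)  # |r| = 1 -> t = inf -> p = 0
    r[degenerate, :] = np.nan
    p[degenerate, :] = np.nan
    cols = list(pca.scores.columns[:m])
    return CorrelationResult(
        r=pd.DataFrame(r, index=expr.index, columns=cols),
        p=pd.DataFrame(p, index=expr.index, columns=cols),
        n_samples=n,
        degenerate_genes=frozenset(expr.index[degenerate]),
    )


def extract_signatures(
    corr: CorrelationResult,
    fc: pd.DataFrame,
    percentile: float = 95.0,
    alpha: float = 0.001,
    adjust: bool = False,
) -> SignatureSet:
    """Dual-threshold selection over all retained components.

    For component j, the cutoff ``q_j`` is the ``percentile``-th percentile
    (linear interpolation) of |r(., j)| over all genes; gene g is selected
    by j iff ``|r(g, j)| > q_j`` (strict, so boundary ties drop out) and
    ``p(g, j) < alpha``.  The signature set is the union over components.
    With ``adjust=True`` the p threshold applies to Benjamini-Hochberg
    adjusted p-values per component instead of raw ones (off by default).
    """
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must be in [0, 100]")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    abs_r = corr.r.abs()
    p = corr.p.copy()
    if adjust:
        for col in p.columns:
            finite = p[col].notna()
            p.loc[finite, col] = multipletests(p.loc[finite, col], method="fdr_bh")[1]
    selected: dict[str, list[int]] = {}
    for j, col in enumerate(abs_r.columns, start=1):
        col_abs = abs_r[col].dropna()
        if col_abs.empty:
            continue
        q_j = float(np.percentile(col_abs.to_numpy(), percentile))
        hits = abs_r.index[(abs_r[col] > q_j) & (p[col] < alpha)]
        for g in hits:
            selected.setdefault(g, []).append(j)
    rows = []
    for g in corr.r.index:  # preserve matrix gene order
        if g not in selected:
            continue
        comps = selected[g]
        sub = abs_r.loc[g].iloc[[c - 1 for c in comps]]
        best = int(np.argmax(sub.to_numpy()))
        best_comp = comps[best]
        if g in fc.index:
            direction = fc.at[g, "direction"]
        else:
            raise ConsistencyError(f"selected gene {g!r} missing from fold-change table")
        rows.append(
            {
                "gene_id": g,
                "components": tuple(comps),
                "max_abs_r": float(sub.iloc[best]),
                "p_value": float(corr.p.at[g, f"PC{best_comp}"]),
                "direction": direction,
            }
        )
    table = pd.DataFrame(
        rows, columns=["gene_id", "components", "max_abs_r", "p_value", "direction"]
    ).set_index("gene_id")
    return SignatureSet(table=table)
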