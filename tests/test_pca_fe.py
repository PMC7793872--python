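"""PCA feature extraction: decomposition oracle, dual-threshold selector."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from cosig.errors import DegenerateInputError
from cosig.pca_fe import (
    PCAResult,
    correlate_genes,
    extract_signatures,
    run_pca,
    select_components,
)


def _expr_from(matrix, genes=None, samples=None):
    genes = genes or [f"g{i}" for i in range(matrix.shape[0])]
    samples = samples or [f"s{j}" for j in range(matrix.shape[1])]
    return pd.DataFrame(matrix, index=genes, columns=samples)


def _fc_for(expr):
    return pd.DataFrame(
        {"logfc": 2.0, "direction": "up"}, index=expr.index
    )


# -- run_pca ---------------------------------------------------------------


def test_rank_one_matrix_explains_everything(rng):
    base = rng.normal(size=6)
    matrix = np.vstack([base * 3, np.full(6, 2.0), np.full(6, -1.0)])
    pca = run_pca(_expr_from(matrix))
    assert pca.variance_fraction[0] == pytest.approx(1.0)


def test_variance_fractions_match_eigendecomposition(rng):
    """Fractions equal the sorted eigenvalues of the sample covariance of
    the centered samples-x-genes matrix (independent eigh oracle)."""
    for _ in range(20):
        X = rng.normal(size=(8, 10))  # samples x genes
        pca = run_pca(_expr_from(X.T))
        eigvals = np.linalg.eigvalsh(np.cov(X, rowvar=False))[::-1]
        eigvals = np.clip(eigvals, 0, None)
        expected = eigvals / eigvals.sum()
        assert np.allclose(pca.variance_fraction, expected[: len(pca.variance_fraction)], atol=1e-8)
        assert pca.variance_fraction.sum() == pytest.approx(1.0, abs=1e-8)


def test_duplicating_samples_preserves_fractions(rng):
    X = rng.normal(size=(10, 6))
    expr = _expr_from(X)
    doubled = pd.concat([expr, expr.add_suffix("_dup", axis=1)], axis=1)
    a = run_pca(expr).variance_fraction
    b = run_pca(doubled).variance_fraction
    assert np.allclose(a, b[: len(a)], atol=1e-8)


def test_scores_are_orthogonal(rng):
    pca = run_pca(_expr_from(rng.normal(size=(12, 9))))
    S = pca.scores.to_numpy()
    gram = S.T @ S
    norms = np.sqrt(np.diag(gram))
    keep = norms > 1e-8
    normalized = gram[np.ix_(keep, keep)] / np.outer(norms[keep], norms[keep])
    assert np.allclose(normalized, np.eye(keep.sum()), atol=1e-8)


def test_constant_matrix_is_degenerate():
    with pytest.raises(DegenerateInputError):
        run_pca(_expr_from(np.full((4, 5), 3.0)))


# -- select_components -----------------------------------------------------


def test_component_count_forced_by_cumulative_sums():
    pca = PCAResult(
        scores=pd.DataFrame(np.zeros((3, 3))), variance_fraction=np.array([0.5, 0.3, 0.2])
    )
    assert select_components(pca, target=0.6) == 2
    assert select_components(pca, target=0.5) == 1
    assert select_components(pca, target=1.0) == 3


def test_full_variance_target_keeps_all_nonzero_components(rng):
    pca = run_pca(_expr_from(rng.normal(size=(5, 8))))
    m = select_components(pca, target=1.0)
    assert np.cumsum(pca.variance_fraction)[m - 1] == pytest.approx(1.0, abs=1e-9)


# -- correlate_genes -------------------------------------------------------


def test_gene_equal_to_scores_has_unit_correlation(rng):
    X = rng.normal(size=(5, 10))
    expr = _expr_from(X)
    pca = run_pca(expr)
    expr2 = expr.copy()
    expr2.loc["g0"] = pca.scores["PC1"].to_numpy()
    corr = correlate_genes(expr2, pca, m=1)
    assert abs(corr.r.at["g0", "PC1"]) == pytest.approx(1.0)
    assert corr.p.at["g0", "PC1"] < 1e-12


def test_orthogonal_gene_has_zero_correlation():
    scores = np.array([1.0, -1.0, 1.0, -1.0])
    expr = _expr_from(np.vstack([scores * 2, [1.0, 1.0, -1.0, -1.0]]))
    pca = run_pca(expr)
    corr = correlate_genes(expr, pca, m=2)
    # g1 has zero covariance with PC1 (which is driven by g0)
    assert corr.r.at["g1", "PC1"] == pytest.approx(0.0, abs=1e-12)
    assert corr.p.at["g1", "PC1"] == pytest.approx(1.0)


def test_correlations_match_textbook_formula(rng):
    """r and p per (gene, component) agree with scipy.stats.pearsonr on a
    30-sample fixture to 1e-10."""
    X = rng.normal(size=(15, 30))
    expr = _expr_from(X)
    pca = run_pca(expr)
    m = 4
    corr = correlate_genes(expr, pca, m)
    for g in expr.index:
        for j in range(m):
            r_ref, p_ref = scipy.stats.pearsonr(
                expr.loc[g].to_numpy(), pca.scores.iloc[:, j].to_numpy()
            )
            assert corr.r.iloc[expr.index.get_loc(g), j] == pytest.approx(r_ref, abs=1e-10)
            assert corr.p.iloc[expr.index.get_loc(g), j] == pytest.approx(p_ref, abs=1e-10)


def test_zero_variance_gene_is_flagged_not_fatal(rng):
    X = rng.normal(size=(6, 12))
    X[3] = 5.0
    expr = _expr_from(X)
    pca = run_pca(expr)
    corr = correlate_genes(expr, pca, m=2)
    assert "g3" in corr.degenerate_genes
    assert np.isnan(corr.r.at["g3", "PC1"])


# -- extract_signatures ----------------------------------------------------


def test_identical_correlations_select_nothing(rng):
    """If every gene has the same |r| with a component, none exceeds the
    95th percentile of that constant distribution."""
    scores = rng.normal(size=8)
    X = np.vstack([scores + rng.normal(scale=1e-9, size=8) for _ in range(10)])
    expr = _expr_from(X)
    pca = run_pca(expr)
    corr = correlate_genes(expr, pca, m=1)
    corr.r.iloc[:, 0] = 0.9  # force exact ties
    corr.p.iloc[:, 0] = 1e-9
    sigs = extract_signatures(corr, _fc_for(expr))
    assert len(sigs) == 0


def test_top_five_percent_selected(rng):
    """Of 100 genes, exactly the 5 with the largest |r| pass the percentile
    rule when their p-values also pass."""
    n = 20
    scores = rng.normal(size=n)
    strengths = np.linspace(0.05, 1.0, 100)
    X = np.array([s * scores + rng.normal(scale=0.05, size=n) for s in strengths])
    expr = _expr_from(X)
    pca = run_pca(expr)
    corr = correlate_genes(expr, pca, m=1)
    sigs = extract_signatures(corr, _fc_for(expr))
    abs_r = corr.r["PC1"].abs().sort_values(ascending=False)
    assert sigs.genes == set(abs_r.index[:5])


def test_selection_invariant_to_score_sign_flip(rng):
    X = rng.normal(size=(40, 15))
    expr = _expr_from(X)
    pca = run_pca(expr)
    m = select_components(pca, 0.6)
    corr = correlate_genes(expr, pca, m)
    flipped = PCAResult(scores=-pca.scores, variance_fraction=pca.variance_fraction)
    corr_flipped = correlate_genes(expr, flipped, m)
    a = extract_signatures(corr, _fc_for(expr))
    b = extract_signatures(corr_flipped, _fc_for(expr))
    assert a.genes == b.genes


def test_at_most_five_percent_per_component(rng):
    """On tie-free data no component can select more than floor(5% genes)."""
    X = rng.normal(size=(200, 30))
    expr = _expr_from(X)
    pca = run_pca(expr)
    m = 5
    corr = correlate_genes(expr, pca, m)
    for col in corr.r.columns:
        q = np.percentile(corr.r[col].abs(), 95)
        assert (corr.r[col].abs() > q).sum() <= int(0.05 * 200)


def test_direction_carried_from_fold_change(rng):
    n = 12
    scores = rng.normal(size=n)
    X = np.array([s * scores + rng.normal(scale=0.05, size=n) for s in np.linspace(0.1, 1, 40)])
    expr = _expr_from(X)
    fc = pd.DataFrame(
        {
            "logfc": np.where(np.arange(40) % 2 == 0, 2.0, -2.0),
            "direction": np.where(np.arange(40) % 2 == 0, "up", "down"),
        },
        index=expr.index,
    )
    pca = run_pca(expr)
    corr = correlate_genes(expr, pca, m=1)
    sigs = extract_signatures(corr, fc)
    assert len(sigs) > 0
    assert sigs.n_up + sigs.n_down == len(sigs)
    for g in sigs.genes:
        assert sigs.table.at[g, "direction"] == fc.at[g, "direction"]


# -- brute-force equivalence ----------------------------------------------


def _brute_force_selector(expr, fc, target=0.6, percentile=95.0, alpha=0.001):
    """Straight-line reimplementation of the whole selector with numpy SVD,
    per-pair scipy correlations and a hand-rolled percentile."""
    X = expr.to_numpy(float).T  # samples x genes
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    frac = var / var.sum()
    cum = 0.0
    m = 0
    for f in frac:
        cum += f
        m += 1
        if cum >= target - 1e-12:
            break
    scores = U * s  # samples x components
    selected = {}
    n_genes = X.shape[1]
    for j in range(m):
        rs, ps = [], []
        for i in range(n_genes):
            r, p = scipy.stats.pearsonr(X[:, i], scores[:, j])
            rs.append(abs(r))
            ps.append(p)
        ordered = sorted(rs)
        h = (n_genes - 1) * percentile / 100.0
        lo, hi = int(np.floor(h)), int(np.ceil(h))
        q = ordered[lo] + (h - lo) * (ordered[hi] - ordered[lo])
        for i in range(n_genes):
            if rs[i] > q and ps[i] < alpha:
                selected.setdefault(expr.index[i], set()).add(j + 1)
    return selected


def test_selector_matches_brute_force(rng):
    """The full selector equals an independent straight-line implementation
    on 30 random matrices of up to 50 genes x 20 samples."""
    for _ in range(30):
        n_genes = int(rng.integers(5, 51))
        n_samples = int(rng.integers(4, 21))
        X = rng.normal(size=(n_genes, n_samples))
        # plant a correlated block so some selections actually pass alpha
        factor = rng.normal(size=n_samples)
        k = max(2, n_genes // 4)
        X[:k] += 2.0 * factor
        expr = _expr_from(X)
        fc = _fc_for(expr)
        pca = run_pca(expr)
        m = select_components(pca, 0.6)
        corr = correlate_genes(expr, pca, m)
        sigs = extract_signatures(corr, fc)
        expected = _brute_force_selector(expr, fc)
        assert sigs.genes == set(expected)
        for g in sigs.genes:
            assert set(sigs.table.at[g, "components"]) == expected[g]
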