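"""Normalization front end: CPM, filters, UQ scaling, logFC."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from cosig.errors import ConsistencyError, DegenerateSampleError
from cosig.io import CountMatrix
from cosig.preprocess import (
    compute_logfc,
    cpm,
    filter_by_annotation,
    filter_by_cpm,
    filter_by_logfc,
    normalize_uqua,
    uq_scale,
)
from cosig.simulate import CohortSpec, SynthConfig, generate_cohorts


def _cm(values, genes=None, samples=None, lengths=None):
    genes = genes or [f"g{i}" for i in range(len(values))]
    samples = samples or [f"s{j}" for j in range(len(values[0]))]
    return CountMatrix(pd.DataFrame(values, index=genes, columns=samples), lengths)


# -- cpm -------------------------------------------------------------------


def test_cpm_uniform_sample():
    out = cpm(_cm([[1], [1]]))
    assert list(out.iloc[:, 0]) == [500000.0, 500000.0]


def test_cpm_zero_and_full():
    out = cpm(_cm([[0], [10]]))
    assert list(out.iloc[:, 0]) == [0.0, 1.0e6]


def test_cpm_matches_per_entry_formula(rng):
    values = rng.integers(0, 50, size=(5, 4))
    values[0, :] += 1  # avoid an all-zero column
    out = cpm(_cm(values.tolist()))
    libsize = values.sum(axis=0)
    for i in range(5):
        for j in range(4):
            assert out.iloc[i, j] == pytest.approx(values[i, j] / libsize[j] * 1e6)


def test_cpm_columns_sum_to_million(small_dataset):
    cm_, _, _ = small_dataset
    sums = cpm(cm_).sum(axis=0)
    assert np.allclose(sums, 1e6, rtol=1e-6)


def test_cpm_zero_library_size_names_sample():
    with pytest.raises(DegenerateSampleError, match="s1"):
        cpm(_cm([[1, 0], [2, 0]]))


# -- filter_by_cpm ---------------------------------------------------------


def test_all_zero_gene_is_removed():
    out = filter_by_cpm(_cm([[0, 0, 0], [5, 5, 5]]), threshold=0.1)
    assert out.gene_ids == ["g1"]


def test_ceiling_rule_with_four_samples():
    """min_fraction 0.9 of 4 samples requires ceil(3.6) = 4 passing samples:
    enumerated over genes passing in 4, 3 and 2 samples."""
    # a filler gene keeps every library size near 1e6 so CPM ~ count
    cm_ = _cm(
        [[1, 1, 1, 1], [1, 1, 1, 0], [1, 0, 1, 0], [10**6] * 4],
        genes=["all4", "only3", "only2", "filler"],
    )
    out = filter_by_cpm(cm_, threshold=0.5, min_fraction=0.9)
    kept = set(out.gene_ids)
    assert "all4" in kept and "only3" not in kept and "only2" not in kept


def test_filter_monotone_in_threshold(small_dataset):
    cm_, _, _ = small_dataset
    genes_low = set(filter_by_cpm(cm_, threshold=0.5).gene_ids)
    genes_high = set(filter_by_cpm(cm_, threshold=5.0).gene_ids)
    assert genes_high <= genes_low


# -- filter_by_annotation --------------------------------------------------


def test_annotation_identity_and_disjoint(tiny_counts):
    cm_, _ = tiny_counts
    assert filter_by_annotation(cm_, set(cm_.gene_ids)).counts.equals(cm_.counts)
    with pytest.warns(UserWarning, match="every gene"):
        empty = filter_by_annotation(cm_, {"nothing"})
    assert empty.n_genes == 0
    assert empty.sample_ids == cm_.sample_ids


# -- normalize_uqua --------------------------------------------------------


def test_identical_samples_give_unit_factors(tiny_counts):
    cm_, _ = tiny_counts
    same = CountMatrix(
        pd.concat([cm_.counts[["s1"]]] * 3, axis=1).set_axis(["a", "b", "c"], axis=1),
        cm_.gene_lengths,
    )
    expr = normalize_uqua(same)
    v = same.counts["a"] / (same.gene_lengths / 1000.0)
    expected = np.log2(v + 1)
    for col in expr.columns:
        assert np.allclose(expr[col], expected)


def test_doubling_a_sample_is_normalized_away(tiny_counts):
    cm_, _ = tiny_counts
    doubled = CountMatrix(
        pd.DataFrame(
            {"A": cm_.counts["s1"], "B": 2 * cm_.counts["s1"], "C": cm_.counts["s2"]}
        ),
        cm_.gene_lengths,
    )
    expr = normalize_uqua(doubled)
    assert np.allclose(expr["A"], expr["B"])


def _manual_percentile_75(values):
    """Independent linear-interpolation 75th percentile."""
    v = sorted(values)
    h = (len(v) - 1) * 0.75
    lo = math.floor(h)
    hi = math.ceil(h)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def test_upper_quartiles_equal_after_scaling():
    """On negative-binomial fixtures the per-sample 75th percentiles of
    nonzero scaled values agree to 1e-9 relative, per an independent
    percentile computation."""
    config = SynthConfig(
        n_genes=50,
        cohorts=(CohortSpec("one", 3, 3),),
        n_planted_up=5,
        n_planted_down=5,
        baseline_log_mean=2.0,  # low counts -> plenty of zeros
        seed=21,
    )
    cm_, _, _ = generate_cohorts(config)
    v = cm_.counts.div(cm_.gene_lengths / 1000.0, axis=0)
    w, _ = uq_scale(v, nonzero_mask=cm_.counts > 0)
    quartiles = [
        _manual_percentile_75(w.loc[cm_.counts[c] > 0, c].to_numpy())
        for c in w.columns
    ]
    assert np.allclose(quartiles, quartiles[0], rtol=1e-9)


def test_uq_scaling_is_idempotent(small_dataset):
    cm_, _, _ = small_dataset
    v = cm_.counts.div(cm_.gene_lengths / 1000.0, axis=0)
    once, _ = uq_scale(v, nonzero_mask=cm_.counts > 0)
    twice, factors = uq_scale(once, nonzero_mask=cm_.counts > 0)
    assert np.allclose(factors, 1.0, rtol=1e-9)
    assert np.allclose(once.to_numpy(), twice.to_numpy(), rtol=1e-9)


def test_sample_with_no_nonzero_counts_is_degenerate():
    cm_ = _cm([[1, 0], [2, 0]], lengths=pd.Series({"g0": 1000.0, "g1": 1000.0}))
    with pytest.raises(DegenerateSampleError):
        normalize_uqua(cm_)


def test_missing_lengths_block_normalization():
    cm_ = _cm([[1, 2], [3, 4]], lengths=pd.Series({"g0": 1000.0}))
    with pytest.raises(ConsistencyError, match="g1"):
        normalize_uqua(cm_)


# -- logFC -----------------------------------------------------------------


def _expr(values, genes, samples):
    return pd.DataFrame(values, index=genes, columns=samples)


def _meta(samples, types):
    return pd.DataFrame(
        {
            "sample_id": samples,
            "patient_id": samples,
            "cohort": "c",
            "sample_type": types,
            "sex": "female",
        }
    )


def test_logfc_zero_when_means_match():
    expr = _expr([[1.0, 3.0, 2.0, 2.0]], ["g"], ["t1", "t2", "n1", "n2"])
    fc = compute_logfc(expr, _meta(["t1", "t2", "n1", "n2"], ["tumor"] * 2 + ["normal"] * 2))
    assert fc.at["g", "logfc"] == 0.0
    assert fc.at["g", "direction"] == "none"


def test_logfc_constant_groups():
    expr = _expr([[3.0, 3.0, 1.0, 1.0]], ["g"], ["t1", "t2", "n1", "n2"])
    fc = compute_logfc(expr, _meta(["t1", "t2", "n1", "n2"], ["tumor"] * 2 + ["normal"] * 2))
    assert fc.at["g", "logfc"] == pytest.approx(2.0)
    assert fc.at["g", "direction"] == "up"


def test_logfc_requires_normals():
    expr = _expr([[1.0, 2.0, 3.0]], ["g"], ["t1", "t2", "t3"])
    with pytest.raises(ConsistencyError, match="normal"):
        compute_logfc(expr, _meta(["t1", "t2", "t3"], ["tumor"] * 3))


def test_planted_effect_recovered_after_normalization(small_dataset):
    """Mean post-normalization logFC of planted up genes lands within 0.3
    of the planted +2 (attenuation from the log2(x + 1) floor allowed)."""
    cm_, meta, truth = small_dataset
    expr = normalize_uqua(cm_)
    fc = compute_logfc(expr, meta)
    up_mean = fc.loc[sorted(truth.planted_up), "logfc"].mean()
    down_mean = fc.loc[sorted(truth.planted_down), "logfc"].mean()
    assert up_mean == pytest.approx(2.0, abs=0.3)
    assert down_mean == pytest.approx(-2.0, abs=0.3)


def test_logfc_filter_boundary_is_strict():
    fc = pd.DataFrame(
        {"logfc": [1.0, -1.5, 0.5, -1.0], "direction": ["up", "down", "up", "down"]},
        index=["exact", "in", "out", "exact_neg"],
    )
    assert filter_by_logfc(fc, threshold=1.0) == {"in"}


def test_front_end_passes_planted_genes(small_config):
    """>= 95% of planted |log2FC| = 2 genes survive CPM + annotation +
    normalization + |logFC| > 1, averaged over three seeds."""
    rates = []
    for seed in (1, 2, 3):
        cm_, meta, truth = generate_cohorts(dataclasses.replace(small_config, seed=seed))
        filtered = filter_by_cpm(cm_)
        filtered = filter_by_annotation(filtered, set(cm_.gene_ids))
        expr = normalize_uqua(filtered)
        kept = filter_by_logfc(compute_logfc(expr, meta))
        rates.append(len(kept & truth.planted) / len(truth.planted))
    assert np.mean(rates) >= 0.95
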