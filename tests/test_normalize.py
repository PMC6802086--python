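"""Quantile, log2, fold and batch normalization against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ctcpanel as cp
from ctcpanel.matrix import ExpressionMatrix, MatrixError
from ctcpanel.normalize import batch_scale_correct, quantile_normalize


def _matrix(values, scale="linear"):
    arr = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                     columns=[f"s{j}" for j in range(arr.shape[1])]),
        scale=scale,
    )


# -- quantile normalization -------------------------------------------------


def test_quantile_hand_computed_example():
    m = _matrix(np.array([[1, 4], [2, 5], [3, 6]]))
    out = quantile_normalize(m)
    expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
    np.testing.assert_allclose(out.values.to_numpy(), expected)


def test_quantile_rank_order_preserved():
    m = _matrix(np.array([[3, 40], [1, 60], [2, 50]]))
    out = quantile_normalize(m).values.to_numpy()
    for j in range(2):
        assert (np.argsort(out[:, j]) == np.argsort(m.values.to_numpy()[:, j])).all()


def test_quantile_identical_columns_fixed_point(random_matrix):
    col = np.random.default_rng(3).uniform(1, 100, size=20)
    m = _matrix(np.column_stack([col, col, col]))
    out = quantile_normalize(m)
    np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy(), rtol=1e-12)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(0, 10_000), st.integers(3, 40), st.integers(2, 8))
def test_quantile_sorted_columns_equal_and_idempotent(seed, n_genes, n_samples):
    rng = np.random.default_rng(seed)
    m = _matrix(rng.uniform(0, 500, size=(n_genes, n_samples)))
    out = quantile_normalize(m)
    arr = out.values.to_numpy()
    target = np.sort(m.values.to_numpy(), axis=0).mean(axis=1)
    for j in range(n_samples):
        np.testing.assert_allclose(np.sort(arr[:, j]), target, rtol=1e-12)
    twice = quantile_normalize(out)
    np.testing.assert_allclose(twice.values.to_numpy(), arr, rtol=0, atol=1e-12)


def test_quantile_single_sample_warns_unchanged():
    m = _matrix([[1.0], [2.0]])
    with pytest.warns(UserWarning):
        out = quantile_normalize(m)
    np.testing.assert_array_equal(out.values.to_numpy(), m.values.to_numpy())


def test_quantile_ties_get_mean_of_tied_quantiles():
    # column with a tie: averaged ranks -> mean of the tied targets
    m = _matrix(np.array([[1, 10], [1, 20], [5, 30]]))
    out = quantile_normalize(m).values.to_numpy()
    target = np.sort(m.values.to_numpy(), axis=0).mean(axis=1)  # [5.5, 10.5, 17.5]
    assert out[0, 0] == out[1, 0] == pytest.approx((target[0] + target[1]) / 2)


# -- log2 -------------------------------------------------------------------


def test_log2_closed_forms_and_guard():
    m = _matrix([[15.0, 0.0]])
    out = cp.log2_transform(m, pseudocount=1)
    np.testing.assert_allclose(out.values.to_numpy(), [[4.0, 0.0]])
    assert out.scale == "log2"
    with pytest.raises(MatrixError, match="already log2"):
        cp.log2_transform(out)


def test_log2_preserves_order(random_matrix):
    m = random_matrix(n_genes=40, n_samples=1, seed=5)
    out = cp.log2_transform(m, pseudocount=1)
    x = m.values.to_numpy().ravel()
    y = out.values.to_numpy().ravel()
    assert (np.argsort(x) == np.argsort(y)).all()


# -- median-to-control folds ------------------------------------------------


def test_median_fold_closed_form():
    sample = _matrix([[100.0]])
    controls = _matrix([[4.0, 5.0, 6.0]])
    out = cp.median_normalize_to_controls(sample, controls)
    assert out.values.iloc[0, 0] == pytest.approx(20.0)


def test_median_fold_identity_at_control_median():
    controls = _matrix(np.array([[4, 5, 6], [1, 2, 3]], dtype=float))
    sample = _matrix(np.array([[5.0], [2.0]]))
    out = cp.median_normalize_to_controls(sample, controls)
    np.testing.assert_allclose(out.values.to_numpy(), 1.0)


def test_median_fold_matches_per_gene_loop_oracle(random_matrix):
    m = random_matrix(n_genes=50, n_samples=20, seed=11)
    controls = random_matrix(n_genes=50, n_samples=9, seed=12)
    out = cp.median_normalize_to_controls(m, controls, pseudocount=0.5)
    for g in m.gene_ids:
        med = float(np.median(controls.values.loc[g].to_numpy()))
        for s in m.sample_ids:
            expected = (m.values.loc[g, s] + 0.5) / (med + 0.5)
            assert out.values.loc[g, s] == pytest.approx(expected, abs=1e-12)


def test_median_fold_empty_controls_error(random_matrix):
    m = random_matrix(n_genes=5, n_samples=2)
    empty = ExpressionMatrix(pd.DataFrame(index=m.values.index, columns=[], dtype=float))
    with pytest.raises(MatrixError, match="empty control"):
        cp.median_normalize_to_controls(m, empty)


# -- batch correction -------------------------------------------------------


def test_batch_two_dataset_closed_form():
    a = _matrix(np.full((2, 2), 4.0), scale="log2")
    b = _matrix(np.full((2, 2), 8.0), scale="log2")
    corrected, reports = batch_scale_correct({"A": a, "B": b})
    by_id = {r.dataset_id: r for r in reports}
    assert by_id["A"].scale_factor == pytest.approx(1.5)
    assert by_id["B"].scale_factor == pytest.approx(0.75)
    assert by_id["A"].post_mean == pytest.approx(6.0)
    assert by_id["B"].post_mean == pytest.approx(6.0)


def test_batch_single_dataset_identity():
    a = _matrix(np.array([[4.0, 5.0]]), scale="log2")
    corrected, reports = batch_scale_correct({"A": a})
    assert reports[0].scale_factor == pytest.approx(1.0)
    np.testing.assert_allclose(corrected["A"].values.to_numpy(), a.values.to_numpy())


def test_batch_seventeen_synthetic_groups_equalized(small_config):
    cfg = cp.GeneratorConfig(**{**vars(small_config), "n_datasets": 17})
    matrices, truth = cp.generate_batched_datasets(cfg)
    corrected, reports = batch_scale_correct(matrices)
    assert len(reports) == 17
    post = np.array([r.post_mean for r in reports])
    np.testing.assert_allclose(post, post[0], rtol=1e-9)
    # recovered factors proportional to inverse planted factors
    prod = np.array([r.scale_factor * truth.batch_factors[r.dataset_id] for r in reports])
    np.testing.assert_allclose(prod, prod[0], rtol=1e-9)


def test_batch_preserves_within_dataset_ratios(random_matrix):
    a = random_matrix(n_genes=10, n_samples=4, seed=2, scale="log2")
    a.values.iloc[:] = np.abs(a.values.to_numpy()) + 1.0
    b = random_matrix(n_genes=10, n_samples=4, seed=3, scale="log2")
    b.values.iloc[:] = np.abs(b.values.to_numpy()) + 5.0
    corrected, _ = batch_scale_correct({"A": a, "B": b})
    orig = a.values.to_numpy()
    new = corrected["A"].values.to_numpy()
    np.testing.assert_allclose(new / new[0, 0], orig / orig[0, 0], rtol=1e-12)


def test_batch_nonpositive_mean_errors():
    a = _matrix(np.zeros((2, 2)), scale="log2")
    b = _matrix(np.full((2, 2), 8.0), scale="log2")
    with pytest.raises(MatrixError, match="grand mean"):
        batch_scale_correct({"A": a, "B": b})


def test_batch_additive_mode_equalizes_by_shift():
    a = _matrix(np.full((2, 2), 4.0), scale="log2")
    b = _matrix(np.full((2, 2), 8.0), scale="log2")
    corrected, reports = batch_scale_correct({"A": a, "B": b}, mode="additive")
    assert all(r.post_mean == pytest.approx(6.0) for r in reports)
    np.testing.assert_allclose(corrected["A"].values.to_numpy(), 6.0)
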