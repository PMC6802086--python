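"""Background estimation, fold filtering and probeset collapse."""

import numpy as np
import pandas as pd
import pytest

import ctcpanel as cp
from ctcpanel.matrix import ExpressionMatrix, MatrixError


def _matrix(values):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    return ExpressionMatrix(
        pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                     columns=[f"s{j}" for j in range(arr.shape[1])])
    )


# -- background -------------------------------------------------------------


def test_background_constant_matrix():
    m = _matrix(np.full((5, 4), 3.0))
    for q in (0.1, 0.5, 0.99, 1.0):
        cfg = cp.SelectionConfig(background_quantile=q)
        assert cp.estimate_background(m, cfg) == pytest.approx(3.0)


def test_background_quantile_against_independent_interpolation():
    # values 1..100; type-7 quantile at 0.99: position 1 + 0.99*99 = 99.01
    m = _matrix(np.arange(1, 101, dtype=float).reshape(10, 10))
    cfg = cp.SelectionConfig(background_quantile=0.99)
    vals = np.sort(m.values.to_numpy().ravel())
    pos = 0.99 * (vals.size - 1)
    lo, hi = int(np.floor(pos)), int(np.ceil(pos))
    expected = vals[lo] + (pos - lo) * (vals[hi] - vals[lo])
    assert expected == pytest.approx(99.01)
    assert cp.estimate_background(m, cfg) == pytest.approx(expected)


def test_background_override_is_linear_of_log2():
    m = _matrix(np.full((2, 2), 3.0))
    cfg = cp.SelectionConfig(background_level_override=4.0)
    assert cp.estimate_background(m, cfg) == pytest.approx(16.0)


def test_background_empty_blood_errors():
    empty = ExpressionMatrix(pd.DataFrame(dtype=float))
    with pytest.raises(MatrixError, match="empty"):
        cp.estimate_background(empty, cp.SelectionConfig())


# -- fold changes -----------------------------------------------------------


def test_fold_closed_form_and_identity():
    tumor = _matrix([[200.0, 200.0]])
    blood = _matrix([[10.0, 10.0]])
    table = cp.compute_fold_changes(tumor, blood)
    assert table["fold_change"].iloc[0] == pytest.approx(20.0)
    same = cp.compute_fold_changes(blood, blood)
    np.testing.assert_allclose(same["fold_change"], 1.0)


def test_fold_matches_per_gene_loop_oracle(random_matrix):
    tumor = random_matrix(n_genes=40, n_samples=15, seed=21)
    blood = random_matrix(n_genes=40, n_samples=25, seed=22)
    table = cp.compute_fold_changes(tumor, blood).set_index("probeset_id")
    for g in tumor.gene_ids:
        t_mean = sum(tumor.values.loc[g]) / 15
        b_mean = sum(blood.values.loc[g]) / 25
        assert table.loc[g, "fold_change"] == pytest.approx(t_mean / b_mean, abs=1e-12)


def test_fold_gene_mismatch_errors(random_matrix):
    tumor = random_matrix(n_genes=5, n_samples=2, seed=1)
    blood = random_matrix(n_genes=6, n_samples=2, seed=1)
    with pytest.raises(MatrixError, match="gene lists"):
        cp.compute_fold_changes(tumor, blood)


# -- selection --------------------------------------------------------------


def _fold_table():
    return pd.DataFrame(
        {
            "probeset_id": ["a", "b", "c", "d"],
            "blood_mean": [5.0, 5.0, 50.0, 5.0],
            "tumor_mean": [60.0, 45.0, 2500.0, 40.0],
            "fold_change": [12.0, 9.0, 50.0, 8.0],
        }
    )


def test_select_threshold_semantics():
    panel = cp.select_markers(_fold_table(), background=10.0)
    # fold 12 at background -> in; fold 9 -> out; blood above background -> out
    assert panel.probeset_ids == ["a"]
    assert panel.entries["at_background_in_blood"].all()


def test_select_orders_by_descending_fold_then_id():
    table = pd.DataFrame(
        {
            "probeset_id": ["z", "a", "m"],
            "blood_mean": [1.0, 1.0, 1.0],
            "tumor_mean": [20.0, 20.0, 30.0],
            "fold_change": [20.0, 20.0, 30.0],
        }
    )
    panel = cp.select_markers(table, background=10.0)
    assert panel.probeset_ids == ["m", "a", "z"]


def test_select_equals_brute_force_filter(random_matrix):
    rng = np.random.default_rng(31)
    n = 200
    table = pd.DataFrame(
        {
            "probeset_id": [f"PS{i:04d}" for i in range(n)],
            "blood_mean": rng.uniform(0.5, 30, n),
            "tumor_mean": rng.uniform(1, 4000, n),
        }
    )
    table["fold_change"] = table["tumor_mean"] / table["blood_mean"]
    cfg = cp.SelectionConfig(min_fold=10)
    background = 15.0
    panel = cp.select_markers(table, background, cfg)
    brute = {
        row.probeset_id
        for row in table.itertuples()
        if row.blood_mean <= background and row.fold_change >= 10
    }
    assert set(panel.probeset_ids) == brute


def test_select_panels_nest_as_min_fold_rises():
    rng = np.random.default_rng(5)
    n = 300
    table = pd.DataFrame(
        {
            "probeset_id": [f"PS{i}" for i in range(n)],
            "blood_mean": rng.uniform(0.5, 20, n),
            "tumor_mean": rng.uniform(1, 5000, n),
        }
    )
    table["fold_change"] = table["tumor_mean"] / table["blood_mean"]
    previous = None
    for min_fold in (2, 5, 10, 50, 200):
        ids = set(cp.select_markers(table, 10.0, cp.SelectionConfig(min_fold=min_fold)).probeset_ids)
        if previous is not None:
            assert ids <= previous
        previous = ids


def test_select_recovers_planted_markers(small_config):
    data = cp.generate_discovery_dataset(small_config)
    cfg = cp.SelectionConfig()
    background = cp.estimate_background(data.blood, cfg)
    table = cp.compute_fold_changes(data.tumor, data.blood, cfg)
    panel = cp.select_markers(table, background, cfg)
    assert set(panel.probeset_ids) == set(data.truth.marker_probesets)


def test_empty_panel_is_valid():
    panel = cp.select_markers(_fold_table(), background=0.1)
    assert len(panel) == 0


# -- collapse ---------------------------------------------------------------


def test_collapse_keeps_max_fold_probeset():
    panel = cp.select_markers(
        pd.DataFrame(
            {
                "probeset_id": ["p1", "p2"],
                "blood_mean": [1.0, 1.0],
                "tumor_mean": [15.0, 40.0],
                "fold_change": [15.0, 40.0],
            }
        ),
        background=5.0,
    )
    annotation = pd.DataFrame({"probeset_id": ["p1", "p2"], "gene_symbol": ["KRT19", "KRT19"]})
    gene_panel = cp.collapse_probesets(panel, annotation)
    assert len(gene_panel) == 1
    assert gene_panel.entries["probeset_id"].iloc[0] == "p2"
    assert gene_panel.entries["fold_change"].iloc[0] == pytest.approx(40.0)


def test_collapse_85_probesets_to_80_genes(small_config):
    data = cp.generate_discovery_dataset(small_config)
    cfg = cp.SelectionConfig()
    panel = cp.select_markers(
        cp.compute_fold_changes(data.tumor, data.blood, cfg),
        cp.estimate_background(data.blood, cfg),
        cfg,
    )
    assert len(panel) == 85
    gene_panel = cp.collapse_probesets(panel, data.annotation)
    assert len(gene_panel) == 80


def test_collapse_distinct_genes_unchanged():
    panel = cp.select_markers(_fold_table(), background=10.0)
    annotation = pd.DataFrame({"probeset_id": ["a"], "gene_symbol": ["EPCAM"]})
    assert len(cp.collapse_probesets(panel, annotation)) == len(panel)


def test_collapse_unannotated_probeset_errors():
    panel = cp.select_markers(_fold_table(), background=10.0)
    annotation = pd.DataFrame({"probeset_id": ["other"], "gene_symbol": ["X"]})
    with pytest.raises(MatrixError, match="a"):
        cp.collapse_probesets(panel, annotation)


def test_selection_config_invariants():
    with pytest.raises(ValueError):
        cp.SelectionConfig(min_fold=1.0)
    with pytest.raises(ValueError):
        cp.SelectionConfig(background_quantile=0.0)
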