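"""Functional and effective connectivity estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oscportraits.ec import ECMatrix, compute_fc, cross_train, ec_similarity, fit_ec
from oscportraits.elements import CATEGORIES, element_columns
from oscportraits.io import META_COLUMNS
from oscportraits.synth import SynthConfig, generate_portraits, ground_truth_ec


def _iid_table(n=2000, seed=0, n_subjects=2):
    """Trial table whose 48 elements are independent white noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 48))
    df = pd.DataFrame(X, columns=element_columns())
    df.insert(0, "duration", 1.0)
    df.insert(0, "error", rng.normal(size=n))
    df.insert(0, "category", "NR-Hit")
    df.insert(0, "subject", np.repeat([f"S{i}" for i in range(n_subjects)], n // n_subjects))
    return df


def test_fc_independent_elements_near_zero():
    fc = compute_fc(_iid_table(10_000), n_boot=10, seed=1)
    off = fc.weights[~np.eye(48, dtype=bool)]
    assert np.abs(off).max() < 0.05
    np.testing.assert_allclose(np.diag(fc.weights), 1.0)
    np.testing.assert_allclose(fc.weights, fc.weights.T, atol=1e-12)


def test_fc_duplicated_column_is_unit_correlation():
    tab = _iid_table(500, seed=2)
    tab["IC1_Pre_alpha"] = tab["IC1_Pre_theta"]
    fc = compute_fc(tab, n_boot=5, seed=0)
    assert fc.weights[0, 1] == pytest.approx(1.0)


def test_fc_constant_column_rejected_by_name():
    tab = _iid_table(200, seed=3)
    tab["IC3_Post_gamma"] = 2.5
    with pytest.raises(ValueError, match="IC3_Post_gamma"):
        compute_fc(tab, n_boot=2, seed=0)


def test_fc_full_sample_invariant_to_trial_order():
    tab = _iid_table(400, seed=4)
    fc1 = compute_fc(tab, n_boot=1, frac=1.0, seed=0)
    perm = tab.sample(frac=1.0, random_state=9).reset_index(drop=True)
    fc2 = compute_fc(perm, n_boot=1, frac=1.0, seed=0)
    np.testing.assert_allclose(fc1.weights, fc2.weights, atol=1e-12)


@pytest.fixture(scope="module")
def recovery_setup():
    cfg = SynthConfig(n_subjects=4, trials_per_category={"NR-Hit": 500}, seed=21)
    table, _ = generate_portraits(cfg)
    truth = ground_truth_ec(cfg, "NR-Hit", standardized=True)
    return cfg, table, truth


def test_ec_recovers_ground_truth(recovery_setup):
    cfg, table, truth = recovery_setup
    ec = fit_ec(table, n_boot=10, seed=0)
    mask = ~np.eye(48, dtype=bool)
    r = stats.pearsonr(truth.weights[mask], ec.weights[mask])[0]
    assert r > 0.75
    assert np.nanmean(ec.performance) > 0.3


def test_ec_recovery_improves_with_trial_count():
    rs = []
    for n_per in (125, 500, 1250):
        cfg = SynthConfig(
            n_subjects=4, trials_per_category={"NR-Hit": n_per}, seed=21
        )
        table, _ = generate_portraits(cfg)
        truth = ground_truth_ec(cfg, "NR-Hit", standardized=True)
        ec = fit_ec(table, n_boot=5, seed=0)
        mask = ~np.eye(48, dtype=bool)
        rs.append(stats.pearsonr(truth.weights[mask], ec.weights[mask])[0])
    assert rs[0] < rs[1] < rs[2]


def test_ec_reproducible_and_scale_invariant(recovery_setup):
    _, table, _ = recovery_setup
    ec1 = fit_ec(table, n_boot=3, seed=7)
    ec2 = fit_ec(table, n_boot=3, seed=7)
    np.testing.assert_array_equal(ec1.weights, ec2.weights)
    scaled = table.copy()
    cols = element_columns()
    scaled[cols] = scaled[cols] * 37.5
    ec3 = fit_ec(scaled, n_boot=3, seed=7)
    np.testing.assert_allclose(ec1.weights, ec3.weights, atol=1e-6)


def test_ec_independent_elements_centered_on_zero_performance():
    ec = fit_ec(_iid_table(3000, seed=5), n_boot=5, seed=1)
    assert abs(np.nanmean(ec.performance)) < 0.05


def test_ec_behavior_nodes_require_columns(recovery_setup):
    _, table, _ = recovery_setup
    bad = table.drop(columns=["error"])
    with pytest.raises(ValueError, match="error"):
        fit_ec(bad, include_behavior=True, n_boot=2, seed=0)
    ec = fit_ec(table, include_behavior=True, n_boot=2, seed=0)
    assert ec.nodes[-2:] == ["error", "duration"]
    assert ec.weights.shape == (50, 50)
    sub = ec.element_submatrix()
    assert len(sub.nodes) == 48


def test_ec_similarity_contracts():
    rng = np.random.default_rng(0)
    w = rng.normal(size=(48, 48))
    np.fill_diagonal(w, 0.0)
    ecA = ECMatrix(nodes=element_columns(), weights=w)
    ecB = ECMatrix(nodes=element_columns(), weights=-w)
    assert ec_similarity(ecA, ecA) == pytest.approx(1.0)
    assert ec_similarity(ecA, ecB) == pytest.approx(-1.0)
    w2 = rng.normal(size=(48, 48))
    np.fill_diagonal(w2, 0.0)
    ecC = ECMatrix(nodes=element_columns(), weights=w2)
    assert abs(ec_similarity(ecA, ecC)) < 0.06
    ecD = ECMatrix(nodes=list(reversed(element_columns())), weights=w)
    with pytest.raises(ValueError, match="node"):
        ec_similarity(ecA, ecD)


def test_ec_matrix_exports(tmp_path):
    rng = np.random.default_rng(1)
    w = rng.normal(size=(48, 48))
    np.fill_diagonal(w, 0.0)
    ec = ECMatrix(nodes=element_columns(), weights=w, provenance="pooled")
    ec.to_csv(tmp_path / "ec.csv")
    back = pd.read_csv(tmp_path / "ec.csv", index_col=0)
    np.testing.assert_allclose(back.to_numpy(float), w)
    edges = ec.to_edge_list(tmp_path / "edges.tsv")
    assert len(edges) == 48 * 47
    g = ec.to_networkx()
    assert g.number_of_nodes() == 48


def test_cross_train_diagonal_equals_own_cv_meaning():
    """Two identically generated categories: the matrix is flat."""
    cfg = SynthConfig(
        n_subjects=3,
        trials_per_category={"NR-Hit": 80, "RS-Hit": 80},
        category_perturbation=0.0,
        couple_labels=False,
        seed=13,
    )
    table, _ = generate_portraits(cfg)
    ct = cross_train(table, n_boot=4, seed=2)
    M = ct.to_numpy()
    assert M.shape == (2, 2)
    assert abs(M[0, 0] - M[0, 1]) < 0.04
    assert abs(M[1, 1] - M[1, 0]) < 0.04
    with pytest.raises(ValueError, match="Ct-Miss"):
        cross_train(table, categories=["NR-Hit", "Ct-Miss"], n_boot=2)
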