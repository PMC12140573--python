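"""Homophily, permutation nulls, strong links and node strengths."""

import numpy as np
import pytest

from oscportraits.ec import ECMatrix
from oscportraits.elements import ElementIndex, element_columns, element_labels
from oscportraits.netstats import (
    HomophilyTriplet,
    delta_homophily,
    homophily,
    homophily_null,
    node_strengths,
    strong_links,
)


def _ec(weights, nodes=None):
    w = np.asarray(weights, dtype=float)
    np.fill_diagonal(w, 0.0)
    return ECMatrix(nodes=nodes or element_columns(), weights=w)


def _uniform_complete():
    return _ec(np.ones((48, 48)))


def test_uniform_graph_matches_pair_counting_closed_forms():
    """On the uniform complete directed graph the homophily ratios equal
    (#levels * group * (group-1)) / (48 * 47) per axis."""
    h = homophily(_uniform_complete())
    assert h.spatial == pytest.approx(4 * 12 * 11 / (48 * 47), abs=1e-12)
    assert h.spectral == pytest.approx(4 * 12 * 11 / (48 * 47), abs=1e-12)
    assert h.temporal == pytest.approx(3 * 16 * 15 / (48 * 47), abs=1e-12)


def test_within_region_only_weights_give_spatial_homophily_one():
    regions = np.array(element_labels("spatial"))
    w = (regions[:, None] == regions[None, :]).astype(float)
    h = homophily(_ec(w))
    assert h.spatial == pytest.approx(1.0)
    assert h.spectral < 1.0 and h.temporal < 1.0


def test_homophily_invariant_to_weight_rescaling():
    rng = np.random.default_rng(0)
    w = rng.normal(size=(48, 48))
    h1 = homophily(_ec(w.copy()))
    h2 = homophily(_ec(4.2 * w))
    for axis in ("spatial", "spectral", "temporal"):
        assert getattr(h1, axis) == pytest.approx(getattr(h2, axis), abs=1e-12)


def test_zero_weight_graph_rejected():
    with pytest.raises(ValueError, match="zero total weight"):
        homophily(_ec(np.zeros((48, 48))))


def test_strong_links_mark_top_three_percent_by_sort_and_count():
    """Distinct weights: the 97th-percentile rule marks the top ~3%,
    verified against an explicit sort-and-count oracle."""
    rng = np.random.default_rng(7)
    for n_nodes, seed in ((11, 0), (25, 1), (48, 2)):
        w = rng.permutation(np.arange(1.0, n_nodes * (n_nodes - 1) + 1.0))
        W = np.zeros((n_nodes, n_nodes))
        W[~np.eye(n_nodes, dtype=bool)] = w
        ec = ECMatrix(nodes=[f"n{i}" for i in range(n_nodes)], weights=W)
        mask = strong_links(ec, percentile=97.0)
        vals = np.sort(w)
        threshold = np.percentile(vals, 97.0)
        expected = int((vals > threshold).sum())  # sort-and-count oracle
        assert mask.sum() == expected
        # roughly the top 3% of m = n*(n-1) distinct weights
        assert expected == pytest.approx(0.03 * w.size, abs=1.5)
        # the marked entries are exactly the largest ones
        assert set(W[mask]) == set(vals[-expected:])


def test_strong_links_tie_and_sign_conventions():
    ec = _ec(np.full((48, 48), 2.5))
    assert strong_links(ec).sum() == 0  # nothing strictly above the tie
    rng = np.random.default_rng(1)
    w = rng.normal(size=(48, 48))
    m1 = strong_links(_ec(w.copy()))
    m2 = strong_links(_ec(-w.copy()))
    np.testing.assert_array_equal(m1, m2)
    with pytest.raises(ValueError, match="percentile"):
        strong_links(ec, percentile=0.0)


def test_homophily_null_block_diagonal_is_extreme():
    regions = np.array(element_labels("spatial"))
    w = (regions[:, None] == regions[None, :]).astype(float)
    null = homophily_null(_ec(w), "spatial", n_shuffles=200, seed=0)
    assert null.observed == pytest.approx(1.0)
    assert null.p_value == pytest.approx(1.0 / 201.0)
    again = homophily_null(_ec(w), "spatial", n_shuffles=200, seed=0)
    np.testing.assert_array_equal(null.values, again.values)
    with pytest.raises(ValueError, match="axis"):
        homophily_null(_ec(w), "chromatic")


def test_null_mean_matches_label_frequency_expectation():
    """Permutation-null mean approaches the pair-counting expectation."""
    rng = np.random.default_rng(2)
    w = np.abs(rng.normal(size=(48, 48)))
    null = homophily_null(_ec(w), "temporal", n_shuffles=800, seed=3)
    assert null.values.mean() == pytest.approx(3 * 16 * 15 / (48 * 47), abs=0.01)


def test_delta_homophily():
    h1 = HomophilyTriplet(0.4, 0.3, 0.2)
    assert delta_homophily(h1, h1) == pytest.approx((0.0, 0.0, 0.0))
    h2 = HomophilyTriplet(0.44, 0.3, 0.2)
    d = delta_homophily(h2, h1)
    assert d[0] == pytest.approx(10.0)
    assert d[1] == d[2] == pytest.approx(0.0)
    with pytest.raises(ValueError, match="zero"):
        delta_homophily(h1, HomophilyTriplet(0.0, 0.3, 0.2))


def test_node_strengths_star_and_isolated():
    w = np.zeros((48, 48))
    hub = ElementIndex("IC2", "During", "beta").name
    hub_i = element_columns().index(hub)
    targets = [1, 2, 3, 4, 5]
    for t in targets:
        w[t, hub_i] = 2.0  # hub is the source of 5 links of weight 2
    ec = _ec(w)
    s = node_strengths(ec, hub)
    assert s.out_strength == pytest.approx(10.0)
    assert s.in_strength == pytest.approx(0.0)
    assert s.out_count == 5 and s.in_count == 0
    iso = node_strengths(ec, "IC4_Post_gamma")
    assert (iso.in_strength, iso.out_strength, iso.in_count, iso.out_count) == (
        0.0,
        0.0,
        0,
        0,
    )
    with pytest.raises(ValueError, match="unknown node"):
        node_strengths(ec, "IC9_Pre_theta")


def test_homophily_increases_with_block_loading():
    """Pooled EC homophily rises as the generator's structured loading
    fraction grows."""
    from oscportraits.ec import fit_ec
    from oscportraits.synth import SynthConfig, generate_portraits

    means = []
    for bl in (0.0, 0.5, 0.9):
        cfg = SynthConfig(
            n_subjects=3,
            trials_per_category={"NR-Hit": 250},
            block_loading=bl,
            n_latent=4,  # all-random factors so block_loading acts alone
            seed=31,
        )
        table, _ = generate_portraits(cfg)
        ec = fit_ec(table, n_boot=4, seed=1)
        h = homophily(ec)
        means.append(np.mean([h.spatial, h.spectral, h.temporal]))
    assert means[0] < means[1] < means[2]
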