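from collections import Counter

import networkx as nx
import numpy as np
import pytest

from m6adriver import (
    NullOccurrenceTable,
    RandomizationConfig,
    RWRConfig,
    build_null_model,
    build_null_occurrence_table,
    empirical_pvalue,
    fit_pvalue_model,
    load_model,
    save_model,
    switch_randomize,
)
from m6adriver.errors import RandomizationError


def _edge_set(graph):
    return set(map(frozenset, graph.edges()))


class TestSwitchRandomize:
    def test_exact_degree_sequence_preserved(self, toy_ppi):
        cfg = RandomizationConfig(n_networks=1, rng_seed=1)
        randomized = switch_randomize(toy_ppi, cfg, 0)
        assert dict(randomized.degree()) == dict(toy_ppi.degree())

    def test_simplicity_preserved(self, toy_ppi):
        cfg = RandomizationConfig(n_networks=1, rng_seed=2)
        randomized = switch_randomize(toy_ppi, cfg, 0)
        assert nx.number_of_selfloops(randomized) == 0
        # nx.Graph cannot hold multi-edges; verify edge count instead
        assert randomized.number_of_edges() == toy_ppi.number_of_edges()

    def test_actually_rewires(self, toy_ppi):
        cfg = RandomizationConfig(n_networks=1, rng_seed=3)
        randomized = switch_randomize(toy_ppi, cfg, 0)
        assert _edge_set(randomized) != _edge_set(toy_ppi)

    def test_deterministic_per_seed_and_index(self, toy_ppi):
        cfg = RandomizationConfig(n_networks=1, rng_seed=4)
        a = switch_randomize(toy_ppi, cfg, 5)
        b = switch_randomize(toy_ppi, cfg, 5)
        c = switch_randomize(toy_ppi, cfg, 6)
        assert _edge_set(a) == _edge_set(b)
        assert _edge_set(a) != _edge_set(c)

    def test_four_cycle_switch_keeps_degrees(self):
        cycle = nx.cycle_graph(4)
        cfg = RandomizationConfig(n_networks=1, rng_seed=0)
        randomized = switch_randomize(cycle, cfg, 0)
        assert dict(randomized.degree()) == dict(cycle.degree())
        assert nx.number_of_selfloops(randomized) == 0

    def test_too_few_edges(self):
        with pytest.raises(RandomizationError):
            switch_randomize(nx.Graph([("A", "B")]), RandomizationConfig(), 0)


def hand_table():
    """Worked occurrence table: 500 hits of degree-5 genes over 100 networks,
    100 degree-5 genes in the network -> freq 5.0, p 0.05."""
    return NullOccurrenceTable(
        seed_degrees=[3],
        counts={3: Counter({5: 500, 8: 0})},
        ppi_degree_counts={5: 100, 8: 40},
        n_networks=100,
        k=10,
    )


def test_occurrence_formulas_on_hand_built_table():
    table = hand_table()
    assert table.freq(3, 5) == 5.0
    assert table.p(3, 5) == 0.05
    assert table.freq(3, 8) == 0.0
    assert table.p(3, 8) == 0.0


def test_occurrence_frame_columns():
    frame = hand_table().to_frame()
    assert list(frame.columns) == [
        "seed_degree",
        "candidate_degree",
        "occurrences",
        "freq",
        "p_raw",
    ]
    assert frame.loc[
        (frame.seed_degree == 3) & (frame.candidate_degree == 5), "p_raw"
    ].item() == 0.05


def test_build_table_deterministic_and_bounded(path_graph):
    cfg = RandomizationConfig(n_networks=1, rng_seed=0, switches_per_edge=1, k=10)
    rwr_cfg = RWRConfig()
    a = build_null_occurrence_table(path_graph, cfg, rwr_cfg)
    b = build_null_occurrence_table(path_graph, cfg, rwr_cfg)
    assert a.counts == b.counts
    # one network, one seed per class: each S_j holds at most K entries
    for d_j in a.seed_degrees:
        assert sum(a.counts[d_j].values()) <= cfg.k


def test_build_table_pools_over_networks(toy_ppi):
    cfg = RandomizationConfig(n_networks=3, rng_seed=9, k=10)
    table = build_null_occurrence_table(toy_ppi, cfg)
    assert table.seed_degrees == sorted({d for _, d in toy_ppi.degree()})
    for d_j in table.seed_degrees:
        total = sum(table.counts[d_j].values())
        assert 0 < total <= cfg.n_networks * cfg.k


def test_constant_table_fits_constant():
    table = NullOccurrenceTable(
        seed_degrees=[2],
        counts={2: Counter({1: 20, 4: 8, 9: 4, 16: 2})},
        ppi_degree_counts={1: 10, 4: 4, 9: 2, 16: 1},
        n_networks=100,
        k=10,
    )
    # every raw p is 0.02
    model = fit_pvalue_model(table)
    for degree in [1, 2, 4, 9, 16, 100]:
        assert empirical_pvalue(model, 2, degree) == pytest.approx(0.02, abs=1e-9)


def test_fit_is_monotone_and_bounded():
    table = NullOccurrenceTable(
        seed_degrees=[4],
        counts={4: Counter({1: 100, 10: 400, 100: 90})},
        ppi_degree_counts={1: 100, 10: 20, 100: 1},
        n_networks=100,
        k=10,
    )
    model = fit_pvalue_model(table)
    grid = np.arange(1, 101)
    values = [empirical_pvalue(model, 4, int(d)) for d in grid]
    assert all(0.0 <= v <= 1.0 for v in values)
    assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))
    assert values[0] <= empirical_pvalue(model, 4, 10) <= values[-1]


def test_query_beyond_grid_clamps_to_boundary(toy_null_model):
    model = toy_null_model
    d_j = model.seed_classes()[0]
    lo = empirical_pvalue(model, d_j, 0)
    hi = empirical_pvalue(model, d_j, 10_000)
    assert lo == pytest.approx(model.fitted[d_j][0])
    assert hi == pytest.approx(model.fitted[d_j][-1])


def test_sparse_class_falls_back_to_step_function():
    table = NullOccurrenceTable(
        seed_degrees=[7],
        counts={7: Counter({2: 30, 5: 10})},  # only 2 distinct observed degrees
        ppi_degree_counts={2: 50, 5: 20, 9: 5},
        n_networks=100,
        k=10,
    )
    model = fit_pvalue_model(table)
    assert 7 in model.step_classes
    assert empirical_pvalue(model, 7, 2) == pytest.approx(table.p(7, 2))
    assert empirical_pvalue(model, 7, 5) == pytest.approx(table.p(7, 5))
    # step: queries between grid points take the previous grid value
    assert empirical_pvalue(model, 7, 4) == pytest.approx(table.p(7, 2))


def test_unknown_seed_degree_uses_nearest_class(toy_null_model):
    classes = toy_null_model.seed_classes()
    missing = max(classes) + 1
    assert missing not in toy_null_model.fitted
    expected = empirical_pvalue(toy_null_model, max(classes), 3)
    assert empirical_pvalue(toy_null_model, missing, 3) == expected


def test_model_serialization_round_trip(tmp_path, toy_null_model):
    path = tmp_path / "model.tsv"
    save_model(toy_null_model, path)
    back = load_model(path)
    assert back.seed_classes() == toy_null_model.seed_classes()
    assert np.array_equal(back.grid, toy_null_model.grid)
    for d_j in toy_null_model.seed_classes():
        assert np.array_equal(back.fitted[d_j], toy_null_model.fitted[d_j])
    assert back.step_classes == toy_null_model.step_classes
    assert back.provenance["network_hash"] == toy_null_model.provenance["network_hash"]


def test_full_model_reproducible(toy_ppi):
    cfg = RandomizationConfig(n_networks=5, rng_seed=21)
    a = build_null_model(toy_ppi, cfg)
    b = build_null_model(toy_ppi, cfg)
    for d_j in a.seed_classes():
        assert np.array_equal(a.fitted[d_j], b.fitted[d_j])
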