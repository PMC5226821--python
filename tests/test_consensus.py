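import networkx as nx
import pytest

from m6adriver import (
    UNREACHABLE,
    CandidateAssessment,
    DmMSite,
    build_consensus,
    edge_weight,
    pool_edges,
    sites_to_genes,
    weighted_consensus_score,
    write_network,
)
from m6adriver.consensus import read_network_tsv


def _assessment(rs, seed, cand, kept=True, p=0.01, L=1, rank=1):
    return CandidateAssessment(
        rs_id=rs, seed=seed, candidate=cand, rank=rank,
        probability=0.1, p=p, L=L, kept=kept,
    )


def _geneset(rs_id, gene_fdrs, log2fc=2.0):
    sites = [
        DmMSite(g, "chr1", 100, 200, "+", log2fc, fdr) for g, fdr in gene_fdrs.items()
    ]
    return sites_to_genes(sites, rs_id)


def test_pool_requires_both_endpoints_dmmg_somewhere():
    assessments = {
        "RS1": [_assessment("RS1", "g1", "g2"), _assessment("RS1", "g1", "g9")],
    }
    pool = pool_edges(assessments, dmmg_union={"g1", "g2"})
    assert ("g1", "g2") in pool.rs_ids
    assert ("g1", "g9") not in pool.rs_ids  # g9 never a DmMG


def test_cross_rs_endpoint_rule():
    # g2 is a DmMG only in RS2, but the kept interaction arose in RS1
    assessments = {"RS1": [_assessment("RS1", "g1", "g2")]}
    pool = pool_edges(assessments, dmmg_union={"g1", "g2"})
    assert pool.rs_ids[("g1", "g2")] == {"RS1"}


def test_reciprocal_pair_counts_rs_once():
    assessments = {
        "RS1": [_assessment("RS1", "g1", "g2"), _assessment("RS1", "g2", "g1")]
    }
    pool = pool_edges(assessments, dmmg_union={"g1", "g2"})
    assert pool.rs_ids[("g1", "g2")] == {"RS1"}


def test_pool_ignores_dropped_assessments():
    assessments = {"RS1": [_assessment("RS1", "g1", "g2", kept=False)]}
    assert len(pool_edges(assessments, {"g1", "g2"})) == 0


def test_pool_records_best_evidence():
    assessments = {
        "RS1": [_assessment("RS1", "g1", "g2", p=0.04, L=2)],
        "RS2": [_assessment("RS2", "g1", "g2", p=0.01, L=1)],
    }
    pool = pool_edges(assessments, {"g1", "g2"})
    assert pool.min_p[("g1", "g2")] == 0.01
    assert pool.min_L[("g1", "g2")] == 1


def _two_rs_fixture():
    assessments = {
        "RS1": [_assessment("RS1", "g1", "g2"), _assessment("RS1", "g1", "g3")],
        "RS2": [_assessment("RS2", "g1", "g2")],
    }
    genesets = [
        _geneset("RS1", {"g1": 1e-6, "g2": 1e-4, "g3": 1e-3}),
        _geneset("RS2", {"g1": 1e-5, "g2": 1e-2}),
    ]
    pool = pool_edges(assessments, {"g1", "g2", "g3"})
    return pool, genesets


def test_strict_recurrence_keeps_only_edges_in_every_rs():
    pool, genesets = _two_rs_fixture()
    cn = build_consensus(pool, genesets)
    assert set(cn.edges) == {("g1", "g2")}
    assert cn.edges[("g1", "g2")]["recurrence"] == 2
    assert cn.mdr_genes == {"g1", "g2"}  # g3 incident to no retained edge


def test_min_recurrence_one_equals_pool():
    pool, genesets = _two_rs_fixture()
    cn = build_consensus(pool, genesets, min_recurrence=1)
    assert set(cn.edges) == set(pool.rs_ids)


def test_lowering_threshold_never_removes_edges():
    pool, genesets = _two_rs_fixture()
    strict = set(build_consensus(pool, genesets).edges)
    permissive = set(build_consensus(pool, genesets, min_recurrence=1).edges)
    assert strict <= permissive


def test_node_annotations():
    pool, genesets = _two_rs_fixture()
    cn = build_consensus(pool, genesets)
    assert cn.nodes["g1"]["dmmg_occurrence"] == 2
    assert cn.nodes["g2"]["label"] == "hyper"


def test_consensus_label_majority_and_tie():
    genesets = [
        _geneset("RS1", {"g1": 1e-3}, log2fc=2.0),
        _geneset("RS2", {"g1": 1e-6}, log2fc=-1.0),
    ]
    assessments = {
        rs: [_assessment(rs, "g1", "g1x")] for rs in ("RS1", "RS2")
    }
    for gs in genesets:  # make the partner a DmMG too
        gs.genes["g1x"] = gs.genes["g1"]
    pool = pool_edges(assessments, {"g1", "g1x"})
    cn = build_consensus(pool, genesets)
    # tie (1 hyper vs 1 hypo) -> label of globally best-FDR site (RS2, hypo)
    assert cn.nodes["g1"]["label"] == "hypo"


def test_edge_weight_arithmetic():
    assert edge_weight(0.01, 0.0001) == pytest.approx(3.0)
    assert edge_weight(1.0, 1.0) == 0.0


def test_edge_weight_floors_zero_fdr():
    assert edge_weight(0.0, 1.0, fdr_floor=1e-10) == pytest.approx(5.0)


def test_weighted_score_sums_over_rs():
    genesets = [
        _geneset("RS1", {"g1": 0.01, "g2": 0.0001}),
        _geneset("RS2", {"g1": 0.1, "g2": 0.1}),  # fdr 0.1 > cutoff: not DmMGs in RS2
    ]
    genesets[1] = _geneset("RS2", {"g1": 0.01, "g2": 0.01})
    assessments = {
        "RS1": [_assessment("RS1", "g1", "g2")],
        "RS2": [_assessment("RS2", "g1", "g2")],
    }
    pool = pool_edges(assessments, {"g1", "g2"})
    scores = weighted_consensus_score(pool, genesets)
    # RS1: (2 + 4)/2 = 3; RS2: (2 + 2)/2 = 2
    assert scores[("g1", "g2")] == pytest.approx(5.0)


def test_weighted_score_gap_fills_missing_endpoint():
    # g2 is a DmMG only in RS1; edge occurs in RS2 -> g2 FDR taken from RS1
    genesets = [
        _geneset("RS1", {"g1": 0.01, "g2": 0.0001}),
        _geneset("RS2", {"g1": 0.01}),
    ]
    assessments = {"RS2": [_assessment("RS2", "g1", "g2")]}
    pool = pool_edges(assessments, {"g1", "g2"})
    scores = weighted_consensus_score(pool, genesets)
    assert scores[("g1", "g2")] == pytest.approx((2 + 4) / 2)


def test_write_tsv_round_trip(tmp_path):
    pool, genesets = _two_rs_fixture()
    cn = build_consensus(pool, genesets, min_recurrence=1)
    path = tmp_path / "consensus.tsv"
    write_network(cn, path, fmt="tsv")
    back = read_network_tsv(path)
    assert set(back.edges) == set(cn.edges)
    assert set(back.nodes) == set(cn.nodes)
    for pair in cn.edges:
        assert back.edges[pair]["recurrence"] == cn.edges[pair]["recurrence"]
        assert back.edges[pair]["min_L"] == cn.edges[pair]["min_L"]


def test_write_graphml_preserves_counts(tmp_path):
    pool, genesets = _two_rs_fixture()
    cn = build_consensus(pool, genesets, min_recurrence=1)
    path = tmp_path / "consensus.graphml"
    write_network(cn, path, fmt="graphml")
    back = nx.read_graphml(path)
    assert back.number_of_nodes() == len(cn.nodes)
    assert back.number_of_edges() == len(cn.edges)


def test_write_sif(tmp_path):
    pool, genesets = _two_rs_fixture()
    cn = build_consensus(pool, genesets)
    path = tmp_path / "consensus.sif"
    write_network(cn, path, fmt="sif")
    assert path.read_text() == "g1\tpp\tg2\n"


def test_empty_consensus_writes_header_only(tmp_path):
    pool, genesets = _two_rs_fixture()
    cn = build_consensus(pool, genesets, min_recurrence=3)  # nothing recurs 3x
    assert len(cn.edges) == 0
    path = tmp_path / "empty.tsv"
    write_network(cn, path, fmt="tsv")
    assert path.read_text().strip() == "gene_a\tgene_b\trecurrence\tmin_L\tmin_p"
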