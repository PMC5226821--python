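"""Cross-replicate consensus: pooled edges, recurrence, driver genes.

Kept seed-candidate interactions from all replicate sets are pooled into a
universal edge pool, restricted to pairs whose BOTH endpoints are DmMGs in at
least one RS (the same RS or different ones).  Edges recurring in every RS
(default; a lower ``min_recurrence`` is configurable) form the consensus
driver network, and the genes incident to a retained edge are the predicted
m6A-driven genes.  An optional weighted score per edge,

    w = (-log10 x - log10 y) / 2,   s = sum of w over the RSs with the edge,

with x, y the endpoints' gene-level peak FDRs in that RS, supports
threshold-based consensus construction as an alternative to strict recurrence.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .dmm import DmMGeneSet
from .network import UNREACHABLE
from .significance import CandidateAssessment

logger = logging.getLogger(__name__)


def _pair(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass
class EdgePool:
    """Per unordered gene pair: the RSs where it was kept, plus evidence."""

    rs_ids: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    min_L: dict[tuple[str, str], object] = field(default_factory=dict)
    min_p: dict[tuple[str, str], float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rs_ids)


@dataclass
class ConsensusNetwork:
    """Retained edges with recurrence counts; nodes are the driver genes."""

    edges: dict[tuple[str, str], dict] = field(default_factory=dict)
    nodes: dict[str, dict] = field(default_factory=dict)
    n_rs: int = 0

    @property
    def mdr_genes(self) -> set[str]:
        return set(self.nodes)


def pool_edges(
    assessments_by_rs: dict[str, list[CandidateAssessment]],
    dmmg_union: set[str],
) -> EdgePool:
    """Pool kept assessments across RSs under the DmMG-endpoint constraint.

    Only pairs with both endpoints in ``dmmg_union`` (DmMG in >= 1 RS, not
    necessarily the same one) enter the pool.  A pair arising as u->v and
    v->u within one RS counts that RS once.
    """
    pool = EdgePool()
    excluded = 0
    for rs_id, assessments in assessments_by_rs.items():
        for a in assessments:
            if not a.kept:
                continue
            if a.seed not in dmmg_union or a.candidate not in dmmg_union:
                excluded += 1
                continue
            pair = _pair(a.seed, a.candidate)
            pool.rs_ids.setdefault(pair, set()).add(rs_id)
            old_L = pool.min_L.get(pair, UNREACHABLE)
            if old_L == UNREACHABLE or (a.L != UNREACHABLE and a.L < old_L):
                pool.min_L[pair] = a.L
            pool.min_p[pair] = min(pool.min_p.get(pair, 1.0), a.p)
    if excluded:
        logger.info("edge pool: %d kept pair(s) excluded (endpoint not a DmMG)", excluded)
    return pool


def _consensus_label(gene: str, genesets: list[DmMGeneSet]) -> str:
    """Majority hyper/hypo vote over RSs; tie -> sign of globally best-FDR site."""
    votes = Counter()
    best = None  # (fdr, -|log2fc|) of the best site across RSs
    best_label = "hyper"
    for gs in genesets:
        call = gs.genes.get(gene)
        if call is None:
            continue
        votes[call.label] += 1
        key = (call.best_fdr, -abs(call.best_log2fc))
        if best is None or key < best:
            best = key
            best_label = call.label
    if votes["hyper"] > votes["hypo"]:
        return "hyper"
    if votes["hypo"] > votes["hyper"]:
        return "hypo"
    return best_label


def build_consensus(
    pool: EdgePool,
    genesets: list[DmMGeneSet],
    min_recurrence: int | None = None,
) -> ConsensusNetwork:
    """Extract edges meeting the recurrence rule and derive driver genes.

    ``min_recurrence=None`` means the strict rule: the edge must occur in
    every RS.  Each driver gene carries its hyper/hypo label and the number
    of RSs in which it is itself a DmMG.
    """
    n_rs = len(genesets)
    threshold = n_rs if min_recurrence is None else min_recurrence
    cn = ConsensusNetwork(n_rs=n_rs)
    for pair, rs_ids in pool.rs_ids.items():
        if len(rs_ids) >= threshold:
            cn.edges[pair] = {
                "recurrence": len(rs_ids),
                "rs_ids": sorted(rs_ids),
                "min_L": pool.min_L[pair],
                "min_p": pool.min_p[pair],
            }
    if not cn.edges:
        logger.warning("consensus network is empty at recurrence >= %d", threshold)
    for u, v in cn.edges:
        for gene in (u, v):
            if gene not in cn.nodes:
                cn.nodes[gene] = {
                    "label": _consensus_label(gene, genesets),
                    "dmmg_occurrence": sum(gene in gs for gs in genesets),
                }
    return cn


def edge_weight(x: float, y: float, fdr_floor: float = 1e-300) -> float:
    """Per-RS edge weight w = (-log10 x - log10 y) / 2 from endpoint FDRs."""
    if x <= 0 or y <= 0:
        logger.warning("FDR of 0 floored at %g for weighting", fdr_floor)
    x = max(x, fdr_floor)
    y = max(y, fdr_floor)
    w = (-math.log10(x) - math.log10(y)) / 2.0
    return 0.0 if w == 0 else w


def weighted_consensus_score(
    pool: EdgePool,
    genesets: list[DmMGeneSet],
    fdr_floor: float = 1e-300,
) -> dict[tuple[str, str], float]:
    """Consensus score s per pooled edge: the sum of w over its RSs.

    If an endpoint is not a DmMG in a given RS (a cross-RS endpoint), its
    FDR for that RS is gap-filled with its best FDR across all RSs.
    """
    by_rs = {gs.rs_id: gs for gs in genesets}
    best_overall: dict[str, float] = {}
    for gs in genesets:
        for gene, call in gs.genes.items():
            best_overall[gene] = min(best_overall.get(gene, 1.0), call.best_fdr)

    def fdr_in_rs(gene: str, rs_id: str) -> float:
        call = by_rs[rs_id].genes.get(gene)
        if call is not None:
            return call.best_fdr
        logger.debug("gene %s not a DmMG in %s; using best FDR across RSs", gene, rs_id)
        return best_overall[gene]

    scores = {}
    for pair, rs_ids in pool.rs_ids.items():
        u, v = pair
        scores[pair] = sum(
            edge_weight(fdr_in_rs(u, rs), fdr_in_rs(v, rs), fdr_floor)
            for rs in sorted(rs_ids)
        )
    return scores


def _edge_frame(
    cn: ConsensusNetwork, scores: dict[tuple[str, str], float] | None
) -> pd.DataFrame:
    rows = []
    for (u, v), info in sorted(cn.edges.items()):
        row = {
            "gene_a": u,
            "gene_b": v,
            "recurrence": info["recurrence"],
            "min_L": "UNREACHABLE" if info["min_L"] == UNREACHABLE else info["min_L"],
            "min_p": info["min_p"],
        }
        if scores is not None:
            row["score"] = scores.get((u, v))
        rows.append(row)
    cols = ["gene_a", "gene_b", "recurrence", "min_L", "min_p"]
    if scores is not None:
        cols.append("score")
    return pd.DataFrame(rows, columns=cols)


def _node_frame(cn: ConsensusNetwork) -> pd.DataFrame:
    rows = [
        {"gene": g, "label": info["label"], "dmmg_occurrence": info["dmmg_occurrence"]}
        for g, info in sorted(cn.nodes.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "label", "dmmg_occurrence"])


def write_network(
    cn: ConsensusNetwork,
    path: str | Path,
    fmt: str = "tsv",
    scores: dict[tuple[str, str], float] | None = None,
) -> None:
    """Write the consensus network as TSV (edge + node tables), GraphML or SIF.

    The TSV dialect writes ``<path>`` as the edge table and ``<path>`` with a
    ``.nodes.tsv`` suffix as the node table; it round-trips all annotations.
    """
    path = Path(path)
    if fmt == "tsv":
        _edge_frame(cn, scores).to_csv(path, sep="\t", index=False)
        node_path = path.with_suffix(".nodes.tsv")
        _node_frame(cn).to_csv(node_path, sep="\t", index=False)
    elif fmt == "graphml":
        graph = nx.Graph()
        for gene, info in cn.nodes.items():
            graph.add_node(gene, **info)
        for (u, v), info in cn.edges.items():
            attrs = {
                "recurrence": info["recurrence"],
                "min_L": -1 if info["min_L"] == UNREACHABLE else int(info["min_L"]),
                "min_p": float(info["min_p"]),
            }
            if scores is not None and (u, v) in scores:
                attrs["score"] = scores[(u, v)]
            graph.add_edge(u, v, **attrs)
        for _, data in graph.nodes(data=True):
            data.pop("rs_ids", None)
        nx.write_graphml(graph, str(path))
    elif fmt == "sif":
        with open(path, "w") as handle:
            for u, v in sorted(cn.edges):
                handle.write(f"{u}\tpp\t{v}\n")
    else:
        raise ValueError(f"unknown output format {fmt!r}")


def read_network_tsv(path: str | Path) -> ConsensusNetwork:
    """Re-read a TSV pair written by :func:`write_network` (lossless)."""
    path = Path(path)
    edges = pd.read_csv(path, sep="\t")
    nodes = pd.read_csv(path.with_suffix(".nodes.tsv"), sep="\t")
    cn = ConsensusNetwork()
    for row in edges.itertuples(index=False):
        L = UNREACHABLE if row.min_L == "UNREACHABLE" else int(row.min_L)
        cn.edges[(row.gene_a, row.gene_b)] = {
            "recurrence": int(row.recurrence),
            "rs_ids": [],
            "min_L": L,
            "min_p": float(row.min_p),
        }
    for row in nodes.itertuples(index=False):
        cn.nodes[row.gene] = {
            "label": row.label,
            "dmmg_occurrence": int(row.dmmg_occurrence),
        }
    return cn
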