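"""End-to-end orchestration: genes in -> consensus driver network out.

The per-RS stages (walk from each DmMG, significance filter) and the
cross-RS consensus are pure functions of the network, the gene sets, and a
prebuilt null model, so a model built once per reference network can be
reused across studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .consensus import (
    ConsensusNetwork,
    EdgePool,
    build_consensus,
    pool_edges,
    weighted_consensus_score,
)
from .dmm import DmMGeneSet, summarize_study
from .errors import M6ADriverError, ProvenanceError
from .network import network_hash
from .null_model import NullPValueModel
from .rwr import RWRConfig, build_transition_matrix, run_rwr, top_candidates
from .significance import CandidateAssessment, assess_candidates

logger = logging.getLogger(__name__)


@dataclass
class StudyResult:
    """Everything the pipeline produced for one study."""

    assessments_by_rs: dict[str, list[CandidateAssessment]]
    pool: EdgePool
    consensus: ConsensusNetwork
    scores: dict[tuple[str, str], float] | None
    summary: pd.DataFrame
    mdr_summary: pd.DataFrame

    @property
    def mdr_genes(self) -> set[str]:
        return self.consensus.mdr_genes


def check_provenance(graph: nx.Graph, model: NullPValueModel) -> None:
    """Refuse to apply a null model built on a different network."""
    stored = model.provenance.get("network_hash")
    if stored is not None and stored != network_hash(graph):
        raise ProvenanceError(
            "null model was built on a different network "
            f"(model hash {stored}, network hash {network_hash(graph)})"
        )


def run_study(
    graph: nx.Graph,
    genesets: list[DmMGeneSet],
    model: NullPValueModel,
    rwr_cfg: RWRConfig | None = None,
    k: int = 10,
    alpha: float = 0.05,
    min_recurrence: int | None = None,
    weighted_score: bool = False,
) -> StudyResult:
    """Run the propagation, filtering and consensus stages for one study.

    Per RS, every DmMG present in the network seeds one walk; its top-K
    candidates are assessed (empirical p from the null model, shortest path
    to the seed) and kept per "p < alpha or L = 1".  Kept interactions are
    pooled across RSs with the DmMG-endpoint constraint, and edges meeting
    the recurrence rule (default: present in every RS) form the consensus
    network whose nodes are the predicted driver genes.
    """
    check_provenance(graph, model)
    rwr_cfg = rwr_cfg or RWRConfig()
    tm = build_transition_matrix(graph)

    any_in_network = False
    assessments_by_rs: dict[str, list[CandidateAssessment]] = {}
    for gs in genesets:
        seeds_in_network = sorted(g for g in gs.genes if g in graph)
        skipped = len(gs.genes) - len(seeds_in_network)
        if skipped:
            logger.info(
                "RS %s: %d DmMG(s) absent from the network, skipped by propagation",
                gs.rs_id,
                skipped,
            )
        if seeds_in_network:
            any_in_network = True
        rs_assessments: list[CandidateAssessment] = []
        for seed in seeds_in_network:
            pv = run_rwr(tm, {seed}, rwr_cfg)
            candidates = top_candidates(pv, k)
            rs_assessments.extend(
                assess_candidates(
                    graph, seed, candidates, model, alpha=alpha, rs_id=gs.rs_id
                )
            )
        assessments_by_rs[gs.rs_id] = rs_assessments
    if not any_in_network:
        raise M6ADriverError("no replicate set has any DmMG present in the network")

    dmmg_union = {g for gs in genesets for g in gs.genes}
    pool = pool_edges(assessments_by_rs, dmmg_union)
    cn = build_consensus(pool, genesets, min_recurrence=min_recurrence)
    scores = weighted_consensus_score(pool, genesets) if weighted_score else None

    return StudyResult(
        assessments_by_rs=assessments_by_rs,
        pool=pool,
        consensus=cn,
        scores=scores,
        summary=summarize_study(genesets),
        mdr_summary=summarize_study(genesets, gene_subset=cn.mdr_genes),
    )
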