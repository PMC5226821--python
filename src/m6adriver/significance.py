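"""Topological/biological significance filter for walk candidates.

A candidate is kept iff its degree-conditioned empirical p-value is below
``alpha`` (strict inequality, default 0.05) OR it directly interacts with its
seed (shortest path L = 1).  The L = 1 branch protects direct interactors
from removal by the purely degree-based null, which would otherwise discard
functionally linked hubs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .network import UNREACHABLE, shortest_path_length
from .null_model import NullPValueModel, empirical_pvalue

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateAssessment:
    """One (seed, candidate) pair with its evidence and verdict."""

    rs_id: str
    seed: str
    candidate: str
    rank: int
    probability: float
    p: float
    L: object  # positive int, or the UNREACHABLE sentinel
    kept: bool


def keep_rule(p: float, L, alpha: float = 0.05) -> bool:
    """The retention rule: p < alpha OR L = 1."""
    return p < alpha or L == 1


def assess_candidates(
    graph: nx.Graph,
    seed: str,
    candidates: list[tuple[str, float]],
    model: NullPValueModel,
    alpha: float = 0.05,
    rs_id: str = "",
) -> list[CandidateAssessment]:
    """Assess a seed's ranked candidates; input order is preserved.

    p comes from the fitted null surface at (degree(seed), degree(candidate));
    L is the unweighted shortest-path distance in the reference network.
    """
    seed_degree = graph.degree(seed)
    assessments = []
    for rank, (candidate, probability) in enumerate(candidates, start=1):
        if candidate not in graph:
            logger.warning("candidate %s not in network; skipped", candidate)
            continue
        p = empirical_pvalue(model, seed_degree, graph.degree(candidate))
        L = shortest_path_length(graph, seed, candidate)
        assessments.append(
            CandidateAssessment(
                rs_id=rs_id,
                seed=seed,
                candidate=candidate,
                rank=rank,
                probability=probability,
                p=p,
                L=L,
                kept=keep_rule(p, L, alpha),
            )
        )
    return assessments


def assessments_to_frame(assessments: list[CandidateAssessment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rs_id": a.rs_id,
                "seed": a.seed,
                "candidate": a.candidate,
                "rank": a.rank,
                "probability": a.probability,
                "p": a.p,
                "L": "UNREACHABLE" if a.L == UNREACHABLE else a.L,
                "kept": a.kept,
            }
            for a in assessments
        ],
        columns=["rs_id", "seed", "candidate", "rank", "probability", "p", "L", "kept"],
    )


def write_assessments_tsv(
    assessments: list[CandidateAssessment], path: str | Path
) -> None:
    assessments_to_frame(assessments).to_csv(path, sep="\t", index=False)
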