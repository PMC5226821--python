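"""Degree-conditioned empirical null for network propagation.

A candidate gene prioritized by a random walk can rank highly simply because
it is a hub.  To calibrate this, the reference network is rewired into
``n_networks`` degree-preserving random copies (double-edge switching).  In
each copy, one uniformly drawn node per seed-degree class d_j starts a walk,
and the degrees of its top-K candidates are pooled into an occurrence
multiset S_j.  For a candidate degree d_i,

    freq_ij = (# occurrences of degree-d_i genes in S_j)
              / (# degree-d_i genes in the reference network)
    p_ij    = freq_ij / n_networks

is the empirical probability that a degree-d_i gene is prioritized by chance
from a degree-d_j seed.  A locally smoothed regression of p_ij on d_i per
seed class, projected to be non-decreasing (the chance of random selection
grows with candidate degree) and clipped to [0, 1], gives the query surface
p = f_j(d).  Once fitted, assessing a candidate takes two degree lookups and
one function evaluation — no further walks on random networks.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import FormatError, RandomizationError
from .network import network_hash
from .rwr import RWRConfig, build_transition_matrix, run_rwr, top_candidates

logger = logging.getLogger(__name__)

MODEL_FILE_VERSION = "1"


@dataclass(frozen=True)
class RandomizationConfig:
    """How many random networks, switching effort, top-K, and the RNG seed.

    ``switches_per_edge`` (Q) sets the total attempted double-edge switches
    to Q x |E|; attempts that would create a self-loop or duplicate edge are
    rejected, which is what preserves simplicity.
    """

    n_networks: int = 100
    switches_per_edge: int = 10
    rng_seed: int = 0
    k: int = 10

    def __post_init__(self) -> None:
        if self.n_networks < 1:
            raise ValueError("n_networks must be >= 1")
        if self.switches_per_edge < 1:
            raise ValueError("switches_per_edge must be >= 1")


def switch_randomize(
    graph: nx.Graph, cfg: RandomizationConfig, network_index: int
) -> nx.Graph:
    """One degree-preserving random copy of ``graph``.

    Performs Q x |E| attempted double-edge switches: two distinct edges
    (a, b), (c, d) are replaced by (a, c), (b, d) (endpoint pairing chosen at
    random) unless that would introduce a self-loop or a duplicate edge, in
    which case the attempt is rejected and the network left unchanged.  The
    per-node degree map of the result equals the input's exactly.
    Deterministic given (cfg.rng_seed, network_index).
    """
    m = graph.number_of_edges()
    if m < 2:
        raise RandomizationError("need >= 2 edges to switch-randomize")
    rng = np.random.default_rng([cfg.rng_seed, network_index])

    edges = [tuple(e) for e in graph.edges()]
    edge_set = {frozenset(e) for e in edges}
    n_attempts = cfg.switches_per_edge * m
    pairs = rng.integers(0, m, size=(n_attempts, 2))
    flips = rng.random(n_attempts) < 0.5
    rejected = 0
    for (i, j), flip in zip(pairs, flips):
        if i == j:
            rejected += 1
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flip:
            c, d = d, c
        # propose (a, c), (b, d)
        if a == c or b == d:
            rejected += 1
            continue
        new1, new2 = frozenset((a, c)), frozenset((b, d))
        if new1 in edge_set or new2 in edge_set:
            rejected += 1
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i] = (a, c)
        edges[j] = (b, d)
    logger.debug(
        "randomize[%d]: %d/%d attempts rejected", network_index, rejected, n_attempts
    )

    randomized = nx.Graph()
    randomized.add_nodes_from(graph.nodes())
    randomized.add_edges_from(edges)
    return randomized


@dataclass
class NullOccurrenceTable:
    """Pooled top-K degree occurrences per seed-degree class.

    ``counts[d_j]`` maps candidate degree -> number of occurrences in S_j;
    ``ppi_degree_counts`` maps degree -> number of reference-network genes of
    that degree.  ``freq`` and ``p`` apply the normalization described in the
    module docstring; raw values are kept unclipped (clipping to [0, 1]
    happens at fit time).
    """

    seed_degrees: list[int]
    counts: dict[int, Counter]
    ppi_degree_counts: dict[int, int]
    n_networks: int
    k: int

    def freq(self, seed_degree: int, candidate_degree: int) -> float:
        occ = self.counts[seed_degree].get(candidate_degree, 0)
        return occ / self.ppi_degree_counts[candidate_degree]

    def p(self, seed_degree: int, candidate_degree: int) -> float:
        return self.freq(seed_degree, candidate_degree) / self.n_networks

    def to_frame(self) -> pd.DataFrame:
        grid = sorted(self.ppi_degree_counts)
        rows = [
            {
                "seed_degree": dj,
                "candidate_degree": di,
                "occurrences": self.counts[dj].get(di, 0),
                "freq": self.freq(dj, di),
                "p_raw": self.p(dj, di),
            }
            for dj in self.seed_degrees
            for di in grid
        ]
        return pd.DataFrame(rows)


def build_null_occurrence_table(
    graph: nx.Graph,
    cfg: RandomizationConfig,
    rwr_cfg: RWRConfig | None = None,
) -> NullOccurrenceTable:
    """Run the randomization protocol and pool top-K candidate degrees.

    For every random network and every seed-degree class, one node of that
    degree is drawn uniformly (a fresh draw per network, so the null averages
    over topological position) and seeds a walk; the degrees of its top-K
    non-seed candidates are added to that class's multiset.  RNG streams are
    split per (network index, class index) so results are reproducible
    regardless of execution order.
    """
    rwr_cfg = rwr_cfg or RWRConfig()
    degrees = dict(graph.degree())
    seed_degrees = sorted(set(degrees.values()))
    nodes_by_degree = {
        d: sorted(n for n, dn in degrees.items() if dn == d) for d in seed_degrees
    }
    ppi_degree_counts = dict(Counter(degrees.values()))
    counts: dict[int, Counter] = {d: Counter() for d in seed_degrees}

    for net_idx in range(cfg.n_networks):
        random_net = switch_randomize(graph, cfg, net_idx)
        tm = build_transition_matrix(random_net)
        rand_degrees = dict(random_net.degree())
        for cls_idx, d_j in enumerate(seed_degrees):
            rng = np.random.default_rng([cfg.rng_seed, net_idx, cls_idx])
            pool = nodes_by_degree[d_j]
            seed = pool[int(rng.integers(len(pool)))]
            pv = run_rwr(tm, {seed}, rwr_cfg)
            for cand, _prob in top_candidates(pv, cfg.k):
                counts[d_j][rand_degrees[cand]] += 1

    return NullOccurrenceTable(
        seed_degrees=seed_degrees,
        counts=counts,
        ppi_degree_counts=ppi_degree_counts,
        n_networks=cfg.n_networks,
        k=cfg.k,
    )


@dataclass
class NullPValueModel:
    """Fitted, monotone p-value surface f_j(d) per seed-degree class.

    ``grid`` is the sorted vector of the reference network's degree classes;
    ``fitted[d_j]`` the fitted p at each grid degree, non-decreasing and in
    [0, 1].  ``step_classes`` marks classes where too few distinct candidate
    degrees were observed for a regression and a step function of the raw
    p values is used instead.  Queries off the grid interpolate linearly
    (step classes: previous-value); queries outside the grid clamp to the
    boundary value.
    """

    grid: np.ndarray
    fitted: dict[int, np.ndarray]
    step_classes: frozenset[int] = frozenset()
    provenance: dict = field(default_factory=dict)

    def seed_classes(self) -> list[int]:
        return sorted(self.fitted)

    def __call__(self, seed_degree: int, candidate_degree: int) -> float:
        return empirical_pvalue(self, seed_degree, candidate_degree)


def fit_pvalue_model(
    table: NullOccurrenceTable,
    nn_frac: float = 0.7,
    graph_hash: str | None = None,
) -> NullPValueModel:
    """Fit the per-class monotone p-value surface from an occurrence table.

    Per class: locally weighted regression (lowess) of raw p on log10 degree
    with nearest-neighbor fraction ``nn_frac``, then isotonic projection to
    enforce the observed monotone increase of chance selection with degree,
    then clipping to [0, 1].  Degrees never observed in S_j enter as p = 0
    points so the surface is defined over the whole degree range.  A class
    with fewer than 3 distinct observed candidate degrees falls back to a
    step function of the raw p values.
    """
    grid = np.asarray(sorted(table.ppi_degree_counts), dtype=float)
    log_grid = np.log10(grid)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")

    fitted: dict[int, np.ndarray] = {}
    step_classes = set()
    for d_j in table.seed_degrees:
        raw = np.array([table.p(d_j, int(d)) for d in grid])
        n_observed = sum(1 for c in table.counts[d_j].values() if c > 0)
        if n_observed < 3 or len(grid) < 3:
            logger.info(
                "class %d: only %d distinct candidate degrees observed; "
                "using step-function fit",
                d_j,
                n_observed,
            )
            fitted[d_j] = np.clip(raw, 0.0, 1.0)
            step_classes.add(d_j)
            continue
        smooth = lowess(raw, log_grid, frac=nn_frac, return_sorted=False)
        monotone = iso.fit_transform(log_grid, smooth)
        fitted[d_j] = np.clip(monotone, 0.0, 1.0)

    provenance = {
        "version": MODEL_FILE_VERSION,
        "rng_seed": None,
        "n_networks": table.n_networks,
        "k": table.k,
        "nn_frac": nn_frac,
    }
    if graph_hash is not None:
        provenance["network_hash"] = graph_hash
    return NullPValueModel(
        grid=grid,
        fitted=fitted,
        step_classes=frozenset(step_classes),
        provenance=provenance,
    )


def build_null_model(
    graph: nx.Graph,
    cfg: RandomizationConfig,
    rwr_cfg: RWRConfig | None = None,
    nn_frac: float = 0.7,
) -> NullPValueModel:
    """Occurrence table + fit in one call, stamped with full provenance."""
    table = build_null_occurrence_table(graph, cfg, rwr_cfg)
    model = fit_pvalue_model(table, nn_frac=nn_frac, graph_hash=network_hash(graph))
    model.provenance.update(
        rng_seed=cfg.rng_seed, switches_per_edge=cfg.switches_per_edge
    )
    return model


def empirical_pvalue(
    model: NullPValueModel, seed_degree: int, candidate_degree: int
) -> float:
    """Evaluate f_j(candidate_degree) for the class with d_j = seed_degree.

    An unknown seed degree falls back to the nearest fitted class (with a
    warning); candidate degrees off the grid interpolate, and degrees outside
    the observed range return the boundary fitted value.
    """
    if seed_degree not in model.fitted:
        classes = np.array(model.seed_classes())
        nearest = int(classes[np.argmin(np.abs(classes - seed_degree))])
        logger.warning(
            "seed degree %d is not a fitted class; using nearest class %d",
            seed_degree,
            nearest,
        )
        seed_degree = nearest
    values = model.fitted[seed_degree]
    if seed_degree in model.step_classes:
        idx = int(np.searchsorted(model.grid, candidate_degree, side="right")) - 1
        idx = min(max(idx, 0), len(values) - 1)
        return float(values[idx])
    return float(np.interp(candidate_degree, model.grid, values))


def save_model(model: NullPValueModel, path: str | Path) -> None:
    """Serialize the fitted surface to a versioned flat TSV.

    Provenance (RNG seed, network counts, network hash) is written as '#'
    header lines so a model built once on a reference network can be reused
    across studies, with reuse on the wrong network detectable.
    """
    with open(path, "w") as handle:
        handle.write(f"#model_version\t{MODEL_FILE_VERSION}\n")
        for key in sorted(model.provenance):
            if key != "version":
                handle.write(f"#{key}\t{model.provenance[key]}\n")
        handle.write("seed_degree\tcandidate_degree\tp_fitted\tfit_kind\n")
        for d_j in model.seed_classes():
            kind = "step" if d_j in model.step_classes else "regression"
            for d, p in zip(model.grid, model.fitted[d_j]):
                handle.write(f"{d_j}\t{int(d)}\t{float(p)!r}\t{kind}\n")


def load_model(path: str | Path) -> NullPValueModel:
    provenance: dict = {}
    with open(path) as handle:
        pos = handle.tell()
        line = handle.readline()
        while line.startswith("#"):
            key, _, value = line[1:].rstrip("\n").partition("\t")
            provenance[key] = value
            pos = handle.tell()
            line = handle.readline()
        handle.seek(pos)
        table = pd.read_csv(handle, sep="\t", float_precision="round_trip")
    if provenance.get("model_version") != MODEL_FILE_VERSION:
        raise FormatError(f"{path}: unsupported or missing model version")

    grid = np.asarray(sorted(table["candidate_degree"].unique()), dtype=float)
    fitted: dict[int, np.ndarray] = {}
    step_classes = set()
    for d_j, sub in table.groupby("seed_degree"):
        sub = sub.sort_values("candidate_degree")
        fitted[int(d_j)] = sub["p_fitted"].to_numpy()
        if (sub["fit_kind"] == "step").any():
            step_classes.add(int(d_j))
    return NullPValueModel(
        grid=grid,
        fitted=fitted,
        step_classes=frozenset(step_classes),
        provenance=provenance,
    )
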