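"""Synthetic networks and replicate-set studies with planted ground truth.

Real differential-methylation studies suffer replicate variance: a gene
significant in one replicate set may be missed in another.  The planted-study
generator emulates exactly that — a densely interacting module of "driver"
genes observed per RS with dropout noise, against sporadic background calls —
so every pipeline stage can be exercised with a known answer and no external
downloads.

Planted sites draw FDRs log-uniformly from [1e-10, 1e-3] and background
sites from [1e-3, 0.049]: both pass the default 0.05 call cutoff, but the
separation lets weighted-score behaviour be tested as well.  Planting is
hyper-only by default (positive log2 fold changes, the direction expected
when a demethylase is active or a methylase intact); a mixed-sign mode is
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .dmm import DmMSite
from .errors import M6ADriverError
from .network import preprocess_network, write_edge_list

PLANTED_FDR_RANGE = (1e-10, 1e-3)
BACKGROUND_FDR_RANGE = (1e-3, 0.049)


@dataclass
class PlantedStudy:
    """A toy network plus per-RS site tables with a known driver module."""

    network: nx.Graph
    module_genes: set[str]
    n_rs: int
    site_tables: dict[str, list[DmMSite]] = field(default_factory=dict)
    dropout: float = 0.0
    background_rate: float = 0.0
    rng_seed: int = 0

    @property
    def rs_ids(self) -> list[str]:
        return sorted(self.site_tables)


def generate_toy_ppi(
    n_nodes: int,
    model: str = "barabasi_albert",
    rng_seed: int = 0,
    **params,
) -> nx.Graph:
    """A small preprocessed interaction network, deterministic per seed.

    ``barabasi_albert`` (param ``attachment``, default 2) gives the degree
    heterogeneity of real interactomes; ``erdos_renyi`` (param ``p``) and
    ``configuration`` (param ``degree_sequence``) are provided for contrast.
    Node names are ``G0001``-style gene ids.
    """
    if n_nodes < 10:
        raise ValueError("n_nodes must be >= 10")
    if model == "barabasi_albert":
        graph = nx.barabasi_albert_graph(
            n_nodes, params.get("attachment", 2), seed=rng_seed
        )
    elif model == "erdos_renyi":
        graph = nx.erdos_renyi_graph(n_nodes, params.get("p", 0.05), seed=rng_seed)
    elif model == "configuration":
        seq = params["degree_sequence"]
        graph = nx.Graph(nx.configuration_model(seq, seed=rng_seed))
        graph.remove_edges_from(nx.selfloop_edges(graph))
    else:
        raise ValueError(f"unknown network model {model!r}")

    graph.remove_nodes_from([n for n, d in graph.degree() if d == 0])
    if graph.number_of_edges() == 0:
        raise M6ADriverError(f"{model} parameters produced an empty network")
    width = len(str(n_nodes))
    mapping = {n: f"G{n + 1:0{width}d}" for n in graph.nodes()}
    return preprocess_network(nx.relabel_nodes(graph, mapping))


def _pick_module(graph: nx.Graph, module_size: int, rng: np.random.Generator) -> set[str]:
    """Seed the module at the highest-degree node and grow through neighbors.

    Greedy growth by connectivity to the current module keeps the planted
    genes densely interacting, mirroring the premise that functionally
    related driver genes cluster in the interactome.
    """
    degrees = dict(graph.degree())
    hub = max(sorted(degrees), key=lambda n: degrees[n])
    module = {hub}
    while len(module) < module_size:
        frontier = sorted(
            {nbr for m in module for nbr in graph.neighbors(m)} - module
        )
        if not frontier:
            raise M6ADriverError(
                f"cannot embed a module of size {module_size}: neighborhood exhausted"
            )
        # prefer neighbors most connected to the module, then by degree
        frontier.sort(
            key=lambda n: (
                -sum(graph.has_edge(n, m) for m in module),
                -degrees[n],
                n,
            )
        )
        module.add(frontier[0])
    return module


def _draw_sites(
    gene: str,
    rng: np.random.Generator,
    fdr_range: tuple[float, float],
    hyper_only: bool,
) -> list[DmMSite]:
    n_sites = int(rng.integers(1, 4))
    sites = []
    for i in range(n_sites):
        log_fdr = rng.uniform(np.log10(fdr_range[0]), np.log10(fdr_range[1]))
        magnitude = rng.uniform(0.5, 4.0)
        sign = 1.0 if hyper_only or rng.random() < 0.5 else -1.0
        start = int(rng.integers(1_000, 1_000_000))
        sites.append(
            DmMSite(
                gene=gene,
                chrom=f"chr{int(rng.integers(1, 23))}",
                start=start,
                end=start + int(rng.integers(50, 300)),
                strand="+" if rng.random() < 0.5 else "-",
                log2fc=float(sign * magnitude),
                fdr=float(10.0**log_fdr),
            )
        )
    return sites


def generate_planted_study(
    network: nx.Graph,
    module_size: int = 12,
    n_rs: int = 4,
    dropout: float = 0.3,
    background_rate: float = 0.02,
    rng_seed: int = 0,
    hyper_only: bool = True,
) -> PlantedStudy:
    """Plant a driver module and emit per-RS site tables around it.

    Per RS, each module gene is observed (1-3 sites) with probability
    1 - ``dropout``; each non-module gene is spuriously called with
    probability ``background_rate``.  Deterministic per ``rng_seed``.
    """
    if module_size > network.number_of_nodes():
        raise ValueError("module_size exceeds network size")
    if not (0.0 <= dropout <= 1.0 and 0.0 <= background_rate <= 1.0):
        raise ValueError("dropout and background_rate must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    module = _pick_module(network, module_size, rng)
    background = sorted(set(network.nodes()) - module)

    site_tables: dict[str, list[DmMSite]] = {}
    for rs_idx in range(n_rs):
        rs_rng = np.random.default_rng([rng_seed, rs_idx])
        sites: list[DmMSite] = []
        for gene in sorted(module):
            if rs_rng.random() >= dropout:
                sites.extend(_draw_sites(gene, rs_rng, PLANTED_FDR_RANGE, hyper_only))
        for gene in background:
            if rs_rng.random() < background_rate:
                sites.extend(
                    _draw_sites(gene, rs_rng, BACKGROUND_FDR_RANGE, hyper_only)
                )
        site_tables[f"RS{rs_idx + 1}"] = sites

    return PlantedStudy(
        network=network,
        module_genes=module,
        n_rs=n_rs,
        site_tables=site_tables,
        dropout=dropout,
        background_rate=background_rate,
        rng_seed=rng_seed,
    )


def write_study(study: PlantedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write the network and per-RS site tables in the dialects the readers
    expect; returns the paths keyed by 'network' and each rs_id."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    network_path = outdir / "network.tsv"
    write_edge_list(study.network, network_path)
    paths["network"] = network_path
    header = "gene\tchrom\tstart\tend\tstrand\tlog2fc\tfdr\n"
    for rs_id, sites in study.site_tables.items():
        path = outdir / f"sites_{rs_id}.tsv"
        with open(path, "w") as handle:
            handle.write(header)
            for s in sites:
                handle.write(
                    f"{s.gene}\t{s.chrom}\t{s.start}\t{s.end}\t{s.strand}\t"
                    f"{s.log2fc!r}\t{s.fdr!r}\n"
                )
        paths[rs_id] = path
    return paths
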