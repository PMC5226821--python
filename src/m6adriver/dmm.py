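"""Differential m6A methylation input: site tables and gene-level calls.

Each replicate set (RS) — one treated IP/input pair plus one untreated pair —
yields an independent table of differential methylation (DmM) sites, typically
the tabular output of a peak caller run in differential mode.  A gene is a
DmM gene (DmMG) in an RS if its mRNA harbors at least one site passing the
FDR cutoff; its hyper/hypo label is the sign of its most differential site's
methylation log2 fold change.

"Most differential" is resolved as: smallest FDR, ties broken by larger
|log2fc|, then by genomic order.  Coordinates follow the BED convention
(0-based half-open); strand is carried through but never used downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Default column names of a site table (override via ``columns=``).
DEFAULT_SITE_COLUMNS = {
    "gene": "gene",
    "chrom": "chrom",
    "start": "start",
    "end": "end",
    "strand": "strand",
    "log2fc": "log2fc",
    "fdr": "fdr",
}


@dataclass(frozen=True)
class DmMSite:
    """One differential methylation site call."""

    gene: str
    chrom: str
    start: int
    end: int
    strand: str
    log2fc: float
    fdr: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"site {self.gene} {self.chrom}:{self.start}-{self.end}: "
                "start must be < end"
            )
        if not 0.0 <= self.fdr <= 1.0:
            raise ValidationError(
                f"site {self.gene} {self.chrom}:{self.start}-{self.end}: "
                f"fdr {self.fdr} outside [0, 1]"
            )


@dataclass(frozen=True)
class GeneCall:
    """Gene-level aggregation of the sites attributed to one gene."""

    n_sites: int
    best_fdr: float
    best_log2fc: float

    @property
    def label(self) -> str:
        return "hyper" if self.best_log2fc > 0 else "hypo"


@dataclass
class DmMGeneSet:
    """The DmMGs of one replicate set."""

    rs_id: str
    genes: dict[str, GeneCall] = field(default_factory=dict)
    n_sites_total: int = 0

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)


def read_dmm_sites(
    path: str | Path, columns: dict[str, str] | None = None
) -> list[DmMSite]:
    """Read a tab-delimited site table into a list of :class:`DmMSite`.

    Raises :class:`FormatError` naming any missing column, and
    :class:`ValidationError` citing the (1-based data) row number for
    unparseable numerics or out-of-range FDR values.
    """
    cols = dict(DEFAULT_SITE_COLUMNS)
    if columns:
        cols.update(columns)
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in cols.values() if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    sites: list[DmMSite] = []
    for row_no, row in enumerate(table.itertuples(index=False), start=1):
        rec = dict(zip(table.columns, row))
        try:
            site = DmMSite(
                gene=rec[cols["gene"]],
                chrom=rec[cols["chrom"]],
                start=int(rec[cols["start"]]),
                end=int(rec[cols["end"]]),
                strand=rec[cols["strand"]],
                log2fc=float(rec[cols["log2fc"]]),
                fdr=float(rec[cols["fdr"]]),
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: row {row_no}: {exc}") from exc
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {row_no}: {exc}") from exc
        sites.append(site)
    return sites


def _site_sort_key(site: DmMSite) -> tuple:
    # smallest FDR first; tie -> larger |log2fc|; tie -> genomic order
    return (site.fdr, -abs(site.log2fc), site.chrom, site.start, site.end)


def sites_to_genes(
    sites: list[DmMSite], rs_id: str, fdr_cutoff: float = 0.05
) -> DmMGeneSet:
    """Aggregate site calls to the replicate set's DmMG set.

    Only sites with ``fdr <= fdr_cutoff`` contribute.  Per gene the best site
    (smallest FDR, ties by larger |log2fc| then coordinate) determines the
    reported FDR, fold change, and hyper/hypo label.
    """
    surviving = [s for s in sites if s.fdr <= fdr_cutoff]
    if sites and not surviving:
        logger.warning("RS %s: no sites pass fdr <= %g", rs_id, fdr_cutoff)
    by_gene: dict[str, list[DmMSite]] = {}
    for site in surviving:
        by_gene.setdefault(site.gene, []).append(site)

    genes = {}
    for gene, gene_sites in by_gene.items():
        best = min(gene_sites, key=_site_sort_key)
        genes[gene] = GeneCall(
            n_sites=len(gene_sites),
            best_fdr=best.fdr,
            best_log2fc=best.log2fc,
        )
    return DmMGeneSet(rs_id=rs_id, genes=genes, n_sites_total=len(surviving))


def summarize_study(
    genesets: list[DmMGeneSet], gene_subset: set[str] | None = None
) -> pd.DataFrame:
    """Per-RS summary: site/gene totals, sites per gene, hyper/hypo counts.

    ``gene_subset`` restricts the summary to a designated set of genes
    (e.g. the final predicted driver genes).
    """
    rows = []
    for gs in genesets:
        genes = gs.genes
        if gene_subset is not None:
            genes = {g: c for g, c in genes.items() if g in gene_subset}
        n_sites = sum(c.n_sites for c in genes.values())
        n_genes = len(genes)
        rows.append(
            {
                "rs_id": gs.rs_id,
                "n_sites": n_sites,
                "n_genes": n_genes,
                "sites_per_gene": round(n_sites / n_genes, 2) if n_genes else 0.0,
                "n_hyper": sum(c.label == "hyper" for c in genes.values()),
                "n_hypo": sum(c.label == "hypo" for c in genes.values()),
            }
        )
    return pd.DataFrame(rows)


def write_geneset_tsv(geneset: DmMGeneSet, path: str | Path) -> None:
    rows = [
        {
            "gene": gene,
            "n_sites": call.n_sites,
            "best_fdr": call.best_fdr,
            "best_log2fc": call.best_log2fc,
            "label": call.label,
        }
        for gene, call in sorted(geneset.genes.items())
    ]
    pd.DataFrame(
        rows, columns=["gene", "n_sites", "best_fdr", "best_log2fc", "label"]
    ).to_csv(path, sep="\t", index=False)
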