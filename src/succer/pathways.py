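"""Hypergeometric over-representation of gene sets in a DEG query.

The universe defaults to the genes present in both the expression table and
the gene-set collection; the query is filtered to |log2FC| > fc_filter before
testing, mirroring the fold-change gate applied upstream of the pathway
stage. Raw P < alpha is the significance gate; BH q-values are reported
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import ExpressionRecord, GeneSetCollection
from .stats import bh_qvalues, hypergeom_upper_tail


@dataclass
class EnrichmentRecord:
    set_name: str
    k: int  # query genes in set
    K: int  # universe genes in set
    n: int  # query size
    N: int  # universe size
    p: float
    q: float | None = None
    members: list[tuple[str, float]] = field(default_factory=list)
    significant: bool = False


def enrich(
    query_genes: list[str] | set[str],
    sets: GeneSetCollection,
    expression: list[ExpressionRecord],
    universe: set[str] | None = None,
    alpha: float = 0.05,
    fc_filter: float = 1.0,
) -> tuple[list[EnrichmentRecord], int]:
    """Test every gene set for over-representation in the query.

    Returns records sorted by p ascending (ties by name) and the number of
    query genes dropped for falling outside the universe.
    """
    fc = {r.gene_id: r.log2fc for r in expression}
    if universe is None:
        universe = sets.all_genes() & set(fc)
    if not universe:
        raise ValueError("empty enrichment universe")
    query = {
        g for g in query_genes
        if g in fc and abs(fc[g]) > fc_filter
    }
    n_dropped = len(query - universe)
    query &= universe
    n, N = len(query), len(universe)
    records: list[EnrichmentRecord] = []
    for name, genes in sets:
        set_universe = set(genes) & universe
        members = sorted(query & set_universe)
        k, K = len(members), len(set_universe)
        if k == 0:
            continue
        p = hypergeom_upper_tail(k, K, n, N)
        records.append(
            EnrichmentRecord(
                name, k, K, n, N, p,
                members=[(g, fc[g]) for g in members],
            )
        )
    records.sort(key=lambda r: (r.p, r.set_name))
    qs = bh_qvalues([r.p for r in records])
    for rec, q in zip(records, qs):
        rec.q = float(q)
        rec.significant = rec.p < alpha
    return records, n_dropped


def top_pathway_genes(
    records: list[EnrichmentRecord], top_n: int = 10
) -> list[tuple[str, float]]:
    """Unique member genes of the top-N enriched sets with their log2FC,
    sorted by |log2FC| descending (the pathway–DEG panel)."""
    seen: dict[str, float] = {}
    for rec in records[:top_n]:
        for gene, fc in rec.members:
            seen.setdefault(gene, fc)
    return sorted(seen.items(), key=lambda t: (-abs(t[1]), t[0]))
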