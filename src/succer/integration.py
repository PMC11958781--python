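"""Linking differential regions to genes and to differential expression.

Each region is assigned to the single gene whose TSS is closest to the region
midpoint, kept only when that unsigned distance is within 100 kb (the
distance gate is strand-agnostic). For per-gene scatter statistics, the
representative region of a gene carrying several assignments is the one with
the largest |log2fc|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ExpressionRecord, GeneModel
from .ders import DER, GAIN, LOSS
from .stats import (
    CorrelationResult,
    PairedTestResult,
    pearson_fc_correlation,
    wilcoxon_signed_rank,
)


@dataclass
class DERGeneAssignment:
    der_id: str
    der_class: str
    gene_id: str
    distance: float  # |DER midpoint - TSS|, bp
    der_log2fc: float
    gene_log2fc: float | None = None
    gene_significant: bool | None = None


def assign_nearest_gene(
    ders: list[DER],
    genes: list[GeneModel],
    max_dist: int = 100_000,
) -> tuple[list[DERGeneAssignment], int]:
    """Nearest-TSS gene per DER within ``max_dist``; returns (assignments,
    number of DERs dropped for lying beyond the gate). Ties break on the
    lexicographically smallest gene_id."""
    by_chrom: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
    for chrom in {g.chrom for g in genes}:
        chrom_genes = sorted(
            (g for g in genes if g.chrom == chrom), key=lambda g: (g.tss, g.gene_id)
        )
        by_chrom[chrom] = (np.array([g.tss for g in chrom_genes]), chrom_genes)

    assignments: list[DERGeneAssignment] = []
    n_dropped = 0
    for der in ders:
        entry = by_chrom.get(der.region.chrom)
        if entry is None:
            n_dropped += 1
            continue
        tss_arr, chrom_genes = entry
        mid = der.region.midpoint
        idx = int(np.searchsorted(tss_arr, mid))
        best = None
        best_d = None
        for j in range(max(0, idx - 2), min(len(chrom_genes), idx + 2)):
            g = chrom_genes[j]
            d = abs(mid - g.tss)
            if (
                best_d is None
                or d < best_d
                or (d == best_d and g.gene_id < best.gene_id)
            ):
                best, best_d = g, d
        if best is None or best_d > max_dist:
            n_dropped += 1
            continue
        der.gene_id = best.gene_id
        assignments.append(
            DERGeneAssignment(der.der_id, der.der_class, best.gene_id,
                              float(best_d), der.log2fc)
        )
    return assignments, n_dropped


def attach_expression(
    assignments: list[DERGeneAssignment],
    expression: list[ExpressionRecord],
) -> tuple[list[DERGeneAssignment], int]:
    """Fill gene log2FC / DEG flags; assignments whose gene is absent from the
    expression table are excluded (never imputed) and counted."""
    table = {r.gene_id: r for r in expression}
    kept: list[DERGeneAssignment] = []
    n_missing = 0
    for a in assignments:
        rec = table.get(a.gene_id)
        if rec is None:
            n_missing += 1
            continue
        a.gene_log2fc = rec.log2fc
        a.gene_significant = rec.significant
        kept.append(a)
    return kept, n_missing


def intersect_with_degs(
    assignments: list[DERGeneAssignment],
    expression: list[ExpressionRecord],
) -> dict[str, set[str]]:
    """Unique genes per class that are linked to >= 1 DER of that class and
    carry the DEG flag (the Venn intersection of nearest genes with DEGs)."""
    kept, _ = attach_expression(list(assignments), expression)
    out: dict[str, set[str]] = {GAIN: set(), LOSS: set()}
    for a in kept:
        if a.gene_significant:
            out[a.der_class].add(a.gene_id)
    return out


def representative_pairs(
    assignments: list[DERGeneAssignment],
    deg_only: bool = False,
    all_pairs: bool = False,
) -> list[DERGeneAssignment]:
    """One assignment per gene (the DER with max |log2fc|), unless
    ``all_pairs``; optionally restricted to DEG-flagged genes."""
    pool = [
        a for a in assignments
        if a.gene_log2fc is not None and (not deg_only or a.gene_significant)
    ]
    if all_pairs:
        return pool
    best: dict[str, DERGeneAssignment] = {}
    for a in pool:
        cur = best.get(a.gene_id)
        if cur is None or abs(a.der_log2fc) > abs(cur.der_log2fc):
            best[a.gene_id] = a
    return [best[g] for g in sorted(best)]


def der_deg_correlation(
    assignments: list[DERGeneAssignment],
    deg_only: bool = False,
    all_pairs: bool = False,
) -> CorrelationResult:
    """Pearson correlation between region and gene fold changes."""
    pairs = representative_pairs(assignments, deg_only=deg_only, all_pairs=all_pairs)
    x = [a.der_log2fc for a in pairs]
    y = [a.gene_log2fc for a in pairs]
    return pearson_fc_correlation(x, y)


def class_expression_shift(
    assignments: list[DERGeneAssignment],
    expression: list[ExpressionRecord],
    der_class: str,
) -> PairedTestResult:
    """Paired signed-rank test of case vs ctrl expression (log2(x+1)) over the
    unique genes linked to a DER class — the box-plot comparison."""
    table = {r.gene_id: r for r in expression}
    genes = sorted({a.gene_id for a in assignments if a.der_class == der_class})
    case = [np.log2(table[g].mean_case + 1) for g in genes if g in table]
    ctrl = [np.log2(table[g].mean_ctrl + 1) for g in genes if g in table]
    return wilcoxon_signed_rank(np.array(case), np.array(ctrl))


def cross_mark_concordance(
    assignments_mark1: list[DERGeneAssignment],
    assignments_mark2: list[DERGeneAssignment],
) -> dict:
    """Concordance of two marks on shared nearest genes: sign agreement of
    region fold changes and their Pearson r (omitted below 3 shared genes)."""
    rep1 = {a.gene_id: a for a in representative_pairs(assignments_mark1)}
    rep2 = {a.gene_id: a for a in representative_pairs(assignments_mark2)}
    shared = sorted(set(rep1) & set(rep2))
    result: dict = {"n_shared_genes": len(shared)}
    if not shared:
        result["sign_agreement"] = float("nan")
        return result
    fc1 = np.array([rep1[g].der_log2fc for g in shared])
    fc2 = np.array([rep2[g].der_log2fc for g in shared])
    result["sign_agreement"] = float(np.mean(np.sign(fc1) == np.sign(fc2)))
    if len(shared) >= 3 and np.ptp(fc1) > 0 and np.ptp(fc2) > 0:
        corr = pearson_fc_correlation(fc1, fc2)
        result["r"] = corr.r
        result["p"] = corr.p
    return result
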