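"""Core genomic domain types and interval algebra.

All coordinates are 0-based, half-open (BED-native) throughout the package;
1-based inputs (GTF) are converted on read. The transcription start site of a
minus-strand gene is ``tx_end - 1`` — the last covered base — so that the TSS
is always a valid coordinate on the chromosome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Region:
    """A genomic interval, optionally carrying a name, score, strand and summit.

    ``summit`` is an offset from ``start`` (narrowPeak convention), pointing at
    the base of maximal enrichment within the region.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."
    summit: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.summit is not None and not (0 <= self.summit < self.end - self.start):
            raise ValueError(
                f"summit offset {self.summit} outside region of length {len(self)}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def summit_pos(self) -> int:
        """Absolute summit coordinate; falls back to the region midpoint."""
        if self.summit is not None:
            return self.start + self.summit
        return self.midpoint

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A transcript-level gene model with exon structure.

    TSS/TES are strand-oriented: on ``+`` the TSS is ``tx_start`` and the TES
    is ``tx_end - 1``; on ``-`` they swap.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"gene {self.gene_id}: invalid transcript bounds")
        self.exons = sorted(self.exons)
        prev_end = None
        for (s, e) in self.exons:
            if s < self.tx_start or e > self.tx_end or s >= e:
                raise ValueError(
                    f"gene {self.gene_id}: exon [{s},{e}) outside transcript "
                    f"[{self.tx_start},{self.tx_end})"
                )
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e
        if not self.exons:
            self.exons = [(self.tx_start, self.tx_end)]

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tes(self) -> int:
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    def contains(self, pos: int) -> bool:
        return self.tx_start <= pos < self.tx_end

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)


@dataclass
class ExpressionRecord:
    """Per-gene expression summary: group means (FPKM-like), log2FC, DEG flag."""

    gene_id: str
    mean_ctrl: float
    mean_case: float
    log2fc: float
    significant: bool

    def __post_init__(self) -> None:
        if self.mean_ctrl < 0 or self.mean_case < 0:
            raise ValueError(f"gene {self.gene_id}: negative expression mean")


class GeneSetCollection:
    """Named gene sets (GMT semantics): set name -> member gene ids."""

    def __init__(
        self,
        sets: dict[str, list[str]],
        descriptions: dict[str, str] | None = None,
    ) -> None:
        for name, genes in sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")
        self.sets = dict(sets)
        self.descriptions = dict(descriptions or {})

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out.update(genes)
        return out


class GenomeAssets:
    """Chromosome sizes plus (optionally) per-chromosome nucleotide strings."""

    def __init__(
        self,
        chrom_sizes: dict[str, int],
        sequences: dict[str, str] | None = None,
    ) -> None:
        self.chrom_sizes = dict(chrom_sizes)
        self.sequences = dict(sequences) if sequences is not None else None
        if self.sequences is not None:
            for chrom, seq in self.sequences.items():
                if chrom not in self.chrom_sizes:
                    self.chrom_sizes[chrom] = len(seq)
                elif len(seq) != self.chrom_sizes[chrom]:
                    raise ValueError(
                        f"sequence length {len(seq)} != chrom_sizes entry "
                        f"{self.chrom_sizes[chrom]} for {chrom}"
                    )

    def check_region(self, region: Region) -> None:
        if region.chrom not in self.chrom_sizes:
            raise ValueError(f"unknown chromosome {region.chrom!r}")
        if region.end > self.chrom_sizes[region.chrom]:
            raise ValueError(
                f"region {region.chrom}:{region.start}-{region.end} exceeds "
                f"chromosome length {self.chrom_sizes[region.chrom]}"
            )

    def fetch(self, region: Region, strand: str = "+") -> str:
        """Return the nucleotide sequence of ``region``; '-' gives the
        reverse complement."""
        if self.sequences is None:
            raise ValueError("no sequence loaded for this genome")
        self.check_region(region)
        seq = self.sequences[region.chrom][region.start : region.end]
        return reverse_complement(seq) if strand == "-" else seq


def fetch_sequence(assets: GenomeAssets, region: Region, strand: str = "+") -> str:
    return assets.fetch(region, strand)


def merge_intervals(intervals: list[Region], gap: int = 0) -> list[Region]:
    """Merge intervals closer than or equal to ``gap`` bp apart.

    Book-ended intervals ([0,10) and [10,20)) merge at gap=0, matching the
    dominant merge semantics of genomic toolkits. Output is sorted by
    (chrom, start) and non-overlapping.
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    merged: list[Region] = []
    for iv in sorted(intervals, key=lambda r: (r.chrom, r.start, r.end)):
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start <= merged[-1].end + gap
        ):
            if iv.end > merged[-1].end:
                merged[-1] = Region(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(Region(iv.chrom, iv.start, iv.end))
    return merged


class FragmentIndex:
    """Sorted per-chromosome arrays supporting O(log n) overlap counting.

    A fragment [s, e) overlaps a query [qs, qe) iff s < qe and e > qs; the
    complement events (s >= qe, e <= qs) are disjoint, so the count is
    n - #(starts >= qe) - #(ends <= qs).
    """

    def __init__(self, fragments: list[Region]) -> None:
        self.n_total = len(fragments)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[Region]] = {}
        for f in fragments:
            by_chrom.setdefault(f.chrom, []).append(f)
        for chrom, frs in by_chrom.items():
            self._starts[chrom] = np.sort(np.array([f.start for f in frs]))
            self._ends[chrom] = np.sort(np.array([f.end for f in frs]))

    @classmethod
    def from_arrays(cls, chroms, starts, ends) -> "FragmentIndex":
        """Build directly from parallel chrom/start/end arrays (fast path)."""
        self = cls.__new__(cls)
        chroms = np.asarray(chroms)
        starts = np.asarray(starts)
        ends = np.asarray(ends)
        self.n_total = len(starts)
        self._starts = {}
        self._ends = {}
        for chrom in np.unique(chroms):
            mask = chroms == chrom
            self._starts[str(chrom)] = np.sort(starts[mask])
            self._ends[str(chrom)] = np.sort(ends[mask])
        return self

    def count(self, region: Region) -> int:
        starts = self._starts.get(region.chrom)
        if starts is None:
            return 0
        ends = self._ends[region.chrom]
        n = len(starts)
        n_right = n - np.searchsorted(starts, region.end, side="left")
        n_left = np.searchsorted(ends, region.start, side="right")
        return int(n - n_right - n_left)


def count_overlapping_fragments(
    region: Region, fragments: "list[Region] | FragmentIndex"
) -> int:
    """Number of fragments sharing >= 1 bp with ``region`` (half-open)."""
    if isinstance(fragments, FragmentIndex):
        return fragments.count(region)
    return FragmentIndex(fragments).count(region)


class SignalTrack:
    """Piecewise-constant coverage (bedGraph semantics); missing bases read 0."""

    def __init__(self, intervals: list[tuple[Region, float]]) -> None:
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[tuple[Region, float]]] = {}
        for reg, val in intervals:
            by_chrom.setdefault(reg.chrom, []).append((reg, val))
        for chrom, items in by_chrom.items():
            items.sort(key=lambda rv: rv[0].start)
            prev_end = -1
            for reg, _ in items:
                if reg.start < prev_end:
                    raise ValueError(
                        f"overlapping bedGraph intervals on {chrom} at {reg.start}"
                    )
                prev_end = reg.end
            self._starts[chrom] = np.array([r.start for r, _ in items])
            self._ends[chrom] = np.array([r.end for r, _ in items])
            self._values[chrom] = np.array([v for _, v in items], dtype=float)

    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Materialize per-base values over [start, end); out-of-track = 0.

        ``start`` may be negative and ``end`` may exceed the chromosome —
        those positions read 0, which is what flank queries at contig edges
        need.
        """
        if end <= start:
            raise ValueError("end must exceed start")
        out = np.zeros(end - start, dtype=float)
        starts = self._starts.get(chrom)
        if starts is None:
            return out
        ends = self._ends[chrom]
        values = self._values[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        for i in range(lo, hi):
            s = max(int(starts[i]), start)
            e = min(int(ends[i]), end)
            if s < e:
                out[s - start : e - start] = values[i]
        return out

    def mean(self, chrom: str, start: int, end: int) -> float:
        return float(self.per_base(chrom, start, end).mean())


def nearest_tss(
    pos: int, chrom: str, genes: list[GeneModel]
) -> tuple[GeneModel | None, float]:
    """Gene with the TSS closest to ``pos`` on ``chrom`` (unsigned distance).

    Ties break on lexicographically smallest gene_id. Returns (None, inf)
    when no gene lies on the chromosome.
    """
    best: GeneModel | None = None
    best_d = math.inf
    for g in genes:
        if g.chrom != chrom:
            continue
        d = abs(pos - g.tss)
        if d < best_d or (d == best_d and best is not None and g.gene_id < best.gene_id):
            best, best_d = g, d
    return best, best_d
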