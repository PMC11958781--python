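"""Differential enrichment: consensus regions, RPKM quantification, the
fold-change GAIN/LOSS rule, feature annotation and meta-profiles.

A region is GAIN when its case-group mean RPKM exceeds the control-group mean
by more than the fold threshold (after adding a small pseudocount to both
means), and LOSS in the mirror case. The pseudocount stabilizes ratios at
regions with near-zero signal, where a raw ratio would be undefined or
explode; it defaults to 0.5 RPKM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    FragmentIndex,
    GeneModel,
    Region,
    SignalTrack,
    merge_intervals,
    nearest_tss,
)

GAIN = "GAIN"
LOSS = "LOSS"

FEATURES = ("promoter-TSS", "TES", "exon", "intron", "intergenic")


@dataclass
class DERConfig:
    fold_threshold: float = 2.0
    pseudocount: float = 0.5
    mode: str = "fragments"

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if self.mode not in ("fragments", "track"):
            raise ValueError("mode must be 'fragments' or 'track'")


@dataclass
class RPKMMatrix:
    """Regions x samples RPKM values with library sizes and a group design.

    RPKM = count * 1e9 / (region_length_bp * library_size) in fragment mode.
    """

    regions: list[Region]
    samples: list[str]
    values: np.ndarray  # shape (n_regions, n_samples)
    groups: dict[str, str]  # sample -> "ctrl" | "case"
    library_sizes: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.regions), len(self.samples)):
            raise ValueError("RPKM matrix shape does not match regions x samples")
        if (self.values < 0).any():
            raise ValueError("RPKM values must be non-negative")
        for s in self.samples:
            if self.groups.get(s) not in ("ctrl", "case"):
                raise ValueError(f"sample {s!r} missing a ctrl/case group label")

    def group_means(self) -> tuple[np.ndarray, np.ndarray]:
        ctrl = [i for i, s in enumerate(self.samples) if self.groups[s] == "ctrl"]
        case = [i for i, s in enumerate(self.samples) if self.groups[s] == "case"]
        if not ctrl or not case:
            raise ValueError("need at least one sample in each group")
        return self.values[:, ctrl].mean(axis=1), self.values[:, case].mean(axis=1)


@dataclass
class DER:
    region: Region
    mean_ctrl: float
    mean_case: float
    log2fc: float
    der_class: str
    feature: str | None = None
    distance_to_tss: float | None = None
    gene_id: str | None = None

    @property
    def der_id(self) -> str:
        if self.region.name:
            return self.region.name
        return f"{self.region.chrom}:{self.region.start}-{self.region.end}"


@dataclass
class MetaProfile:
    positions: np.ndarray  # bin label coordinates (bp or scaled units)
    values: np.ndarray
    bin_width: int
    n_used: int
    n_skipped: int = 0


def build_consensus(
    per_sample_peaks: dict[str, list[Region]],
) -> tuple[list[Region], dict[str, list[str]]]:
    """Union-merge all samples' peaks into a consensus set.

    Returns the merged regions (named cr000000, ...) and, per consensus id,
    the list of samples contributing at least one overlapping peak.
    """
    if not per_sample_peaks:
        raise ValueError("no peak files supplied")
    all_peaks = [p for peaks in per_sample_peaks.values() for p in peaks]
    if not all_peaks:
        raise ValueError("no peaks: union of per-sample peak sets is empty")
    merged = merge_intervals(all_peaks, gap=0)
    consensus: list[Region] = []
    provenance: dict[str, list[str]] = {}
    for i, reg in enumerate(merged):
        named = Region(reg.chrom, reg.start, reg.end, name=f"cr{i:06d}")
        consensus.append(named)
        provenance[named.name] = sorted(
            s
            for s, peaks in per_sample_peaks.items()
            if any(named.overlaps(p) for p in peaks)
        )
    return consensus, provenance


def quantify_regions(
    consensus: list[Region],
    samples: dict[str, "FragmentIndex | list[Region] | SignalTrack"],
    groups: dict[str, str],
    mode: str = "fragments",
) -> RPKMMatrix:
    """Quantify every consensus region in every sample.

    ``fragments`` mode computes RPKM from overlap counts and per-sample
    library sizes (= total fragments); ``track`` mode averages an already
    RPKM-normalized coverage track over the region.
    """
    names = sorted(samples)
    values = np.zeros((len(consensus), len(names)))
    library_sizes: dict[str, int] = {}
    for j, sample in enumerate(names):
        source = samples[sample]
        if mode == "fragments":
            index = (
                source if isinstance(source, FragmentIndex) else FragmentIndex(source)
            )
            if index.n_total == 0:
                raise ValueError(f"sample {sample!r} has library size 0")
            library_sizes[sample] = index.n_total
            for i, reg in enumerate(consensus):
                count = index.count(reg)
                values[i, j] = count * 1e9 / (len(reg) * index.n_total)
        elif mode == "track":
            if not isinstance(source, SignalTrack):
                raise ValueError("track mode requires SignalTrack inputs")
            for i, reg in enumerate(consensus):
                values[i, j] = source.mean(reg.chrom, reg.start, reg.end)
        else:
            raise ValueError(f"unknown quantification mode {mode!r}")
    return RPKMMatrix(
        consensus, names, values, groups,
        library_sizes if mode == "fragments" else None,
    )


def call_ders(matrix: RPKMMatrix, config: DERConfig | None = None) -> list[DER]:
    """Apply the fold-change rule to group-mean RPKMs.

    GAIN iff (mean_case + eps) / (mean_ctrl + eps) > tau; LOSS in the mirror
    direction. Output is sorted GAIN before LOSS, by |log2fc| descending
    within class.
    """
    config = config or DERConfig()
    eps, tau = config.pseudocount, config.fold_threshold
    mean_ctrl, mean_case = matrix.group_means()
    ders: list[DER] = []
    for i, reg in enumerate(matrix.regions):
        mc, mf = float(mean_ctrl[i]), float(mean_case[i])
        ratio = (mf + eps) / (mc + eps)
        if ratio > tau:
            cls = GAIN
        elif 1.0 / ratio > tau:
            cls = LOSS
        else:
            continue
        ders.append(DER(reg, mc, mf, math.log2(ratio), cls))
    ders.sort(key=lambda d: (d.der_class != GAIN, -abs(d.log2fc)))
    return ders


def annotate_feature(
    region: Region,
    genes: list[GeneModel],
    promoter_window: tuple[int, int] = (-1000, 100),
    tes_margin: int = 100,
) -> tuple[str, float]:
    """Feature label and signed strand-oriented TSS distance for a region.

    The region midpoint drives annotation with precedence
    promoter-TSS > TES > exon > intron > intergenic. The promoter window is
    strand-oriented around the TSS; negative distances are upstream. The
    returned distance refers to the nearest TSS overall (inf when no gene
    shares the chromosome).
    """
    mid = region.midpoint
    gene, _ = nearest_tss(mid, region.chrom, genes)
    if gene is None:
        return "intergenic", math.inf
    signed = float(mid - gene.tss if gene.strand == "+" else gene.tss - mid)

    is_promoter = is_tes = in_exon = in_intron = False
    lo, hi = promoter_window
    for g in genes:
        if g.chrom != region.chrom:
            continue
        d = mid - g.tss if g.strand == "+" else g.tss - mid
        if lo <= d < hi:
            is_promoter = True
        if abs(mid - g.tes) <= tes_margin:
            is_tes = True
        if g.contains(mid):
            if g.in_exon(mid):
                in_exon = True
            else:
                in_intron = True
    if is_promoter:
        label = "promoter-TSS"
    elif is_tes:
        label = "TES"
    elif in_exon:
        label = "exon"
    elif in_intron:
        label = "intron"
    else:
        label = "intergenic"
    return label, signed


def annotate_ders(
    ders: list[DER],
    genes: list[GeneModel],
    promoter_window: tuple[int, int] = (-1000, 100),
    tes_margin: int = 100,
) -> list[DER]:
    for der in ders:
        der.feature, der.distance_to_tss = annotate_feature(
            der.region, genes, promoter_window, tes_margin
        )
    return ders


DISTANCE_BINS = ((0, 1_000), (1_000, 10_000), (10_000, 100_000), (100_000, math.inf))
DISTANCE_LABELS = ("0-1kb", "1-10kb", "10-100kb", ">100kb")


def distance_summary(ders: list[DER]):
    """Per-class TSS-distance bin fractions and per-chromosome counts."""
    import pandas as pd

    if not ders:
        return pd.DataFrame(), pd.DataFrame()
    rows = []
    for cls in (GAIN, LOSS):
        dists = [abs(d.distance_to_tss) for d in ders if d.der_class == cls
                 and d.distance_to_tss is not None]
        if not dists:
            continue
        n = len(dists)
        fracs = {
            label: sum(1 for x in dists if lo <= x < hi) / n
            for label, (lo, hi) in zip(DISTANCE_LABELS, DISTANCE_BINS)
        }
        rows.append({"class": cls, "n": n, **fracs})
    dist_df = pd.DataFrame(rows)
    chrom_rows = []
    for cls in (GAIN, LOSS):
        counts: dict[str, int] = {}
        for d in ders:
            if d.der_class == cls:
                counts[d.region.chrom] = counts.get(d.region.chrom, 0) + 1
        for chrom in sorted(counts):
            chrom_rows.append({"class": cls, "chrom": chrom, "count": counts[chrom]})
    return dist_df, pd.DataFrame(chrom_rows)


def meta_profile(
    track: SignalTrack,
    genes: list[GeneModel],
    upstream: int = 2000,
    downstream: int = 2000,
    body_bins: int = 100,
    bin_width: int = 20,
) -> MetaProfile:
    """Scaled meta-gene profile: fixed-width flanks, body rescaled to
    ``body_bins`` bins, strand-oriented (upstream of the TSS comes first)."""
    n_up = upstream // bin_width
    n_down = downstream // bin_width
    profiles = []
    n_skipped = 0
    for g in genes:
        length = g.tx_end - g.tx_start
        if length < body_bins:
            n_skipped += 1
            continue
        up = track.per_base(g.chrom, g.tx_start - upstream, g.tx_start)
        body = track.per_base(g.chrom, g.tx_start, g.tx_end)
        down = track.per_base(g.chrom, g.tx_end, g.tx_end + downstream)
        if g.strand == "-":
            up, body, down = down[::-1], body[::-1], up[::-1]
        up_bins = up.reshape(n_up, bin_width).mean(axis=1)
        down_bins = down.reshape(n_down, bin_width).mean(axis=1)
        edges = np.linspace(0, length, body_bins + 1)
        csum = np.concatenate([[0.0], np.cumsum(body)])
        cum_at = np.interp(edges, np.arange(length + 1), csum)
        body_binned = np.diff(cum_at) / np.diff(edges)
        profiles.append(np.concatenate([up_bins, body_binned, down_bins]))
    if not profiles:
        raise ValueError("no gene long enough for the requested body bins")
    mean_profile = np.mean(profiles, axis=0)
    positions = np.arange(len(mean_profile), dtype=float)
    return MetaProfile(positions, mean_profile, bin_width, len(profiles), n_skipped)


def der_center_profile(
    track: SignalTrack,
    ders: list[DER],
    flank: int = 2000,
    bin_width: int = 20,
) -> MetaProfile:
    """Mean signal in fixed-width bins across +-flank around DER centers."""
    n_bins = 2 * flank // bin_width
    acc = np.zeros(n_bins)
    for der in ders:
        center = der.region.summit_pos
        vals = track.per_base(der.region.chrom, center - flank, center + flank)
        acc += vals.reshape(n_bins, bin_width).mean(axis=1)
    if not ders:
        raise ValueError("no regions to profile")
    positions = np.arange(-flank, flank, bin_width) + bin_width / 2.0
    return MetaProfile(positions, acc / len(ders), bin_width, len(ders))
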