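"""PWM scanning, motif enrichment at summit windows, DETF calling,
occurrence profiles and promoter-proximal target assignment.

Scoring is summed log2-odds of the position probability matrix against a
background base distribution; a hit requires a score of at least
``threshold_frac`` (default 0.8) of the motif's maximum attainable score.
Both strands are scanned; N bases contribute 0 to the score (they are read as
background).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ExpressionRecord, GeneModel, GenomeAssets, Region
from .ders import DER, GAIN, LOSS
from .stats import bh_qvalues, binom_upper_tail, hypergeom_upper_tail

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}


def encode(seq: str) -> np.ndarray:
    """A=0 C=1 G=2 T=3, anything else (N) = 4."""
    out = np.full(len(seq), 4, dtype=np.int8)
    for base, code in _CODE.items():
        mask = np.frombuffer(seq.upper().encode(), dtype=np.uint8) == ord(base)
        out[mask] = code
    return out


@dataclass
class PWM:
    name: str
    tf_name: str
    counts: np.ndarray  # 4 x L raw counts (A, C, G, T rows)
    probs: np.ndarray  # 4 x L probabilities after pseudocounting
    background: np.ndarray
    alpha: float

    @classmethod
    def from_counts(
        cls,
        name: str,
        tf_name: str,
        counts: np.ndarray,
        alpha: float = 0.01,
        background: np.ndarray | None = None,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if counts.shape[0] != 4:
            raise ValueError("PFM must have 4 rows (A, C, G, T)")
        if (counts < 0).any():
            raise ValueError("PFM counts must be non-negative")
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        if abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")
        probs = (counts + alpha) / (counts + alpha).sum(axis=0, keepdims=True)
        return cls(name, tf_name, counts, probs, bg, alpha)

    @classmethod
    def from_consensus(
        cls, name: str, tf_name: str, consensus: str, weight: float = 100.0
    ) -> "PWM":
        counts = np.zeros((4, len(consensus)))
        for i, base in enumerate(consensus.upper()):
            counts[_CODE[base], i] = weight
        return cls.from_counts(name, tf_name, counts)

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """5 x L: rows A,C,G,T plus an all-zero row for N."""
        lo = np.log2(self.probs / self.background[:, None])
        return np.vstack([lo, np.zeros((1, self.length))])

    @property
    def max_score(self) -> float:
        return float(self.log_odds[:4].max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        rc_counts = self.counts[::-1, ::-1]
        return PWM.from_counts(
            self.name, self.tf_name, rc_counts, self.alpha, self.background[::-1]
        )


@dataclass
class MotifHit:
    window_id: str
    offset: int  # hit start relative to window start
    strand: str
    score: float
    midpoint_offset: float | None = None  # hit midpoint relative to summit


@dataclass
class MotifEnrichmentResult:
    motif: str
    tf_name: str
    k: int
    n: int
    k_bg: int
    n_bg: int
    p: float
    q: float | None = None

    @property
    def fraction_target(self) -> float:
        return self.k / self.n


@dataclass
class OccurrenceProfile:
    edges: np.ndarray  # bin edges, bp relative to summit
    density: np.ndarray  # hits / (bp * window)
    n_windows: int
    total_hits: int


@dataclass
class DETF:
    tf_name: str
    gene_id: str
    direction: str  # "up" | "down"
    enrichment_p: float
    expression_log2fc: float
    expression_level: float  # log2(FPKM + 1), case group


@dataclass
class SummitWindow:
    window_id: str
    chrom: str
    start: int
    end: int
    summit: int  # absolute coordinate
    sequence: str


def _score_positions(codes: np.ndarray, pwm: PWM) -> np.ndarray:
    """Score every start position on the given (already encoded) strand."""
    L = pwm.length
    n_pos = len(codes) - L + 1
    if n_pos <= 0:
        return np.zeros(0)
    lo = pwm.log_odds
    scores = np.zeros(n_pos)
    for j in range(L):
        scores += lo[codes[j : j + n_pos], j]
    return scores


def scan_pwm(
    sequence: str,
    pwm: PWM,
    threshold_frac: float = 0.8,
    window_id: str = "",
) -> list[MotifHit]:
    """All above-threshold hits on both strands, with overlapping hits on the
    same strand collapsed to the best-scoring one.

    A minus-strand hit at offset i means the reverse complement of
    sequence[i:i+L] matches the motif; its coordinates stay on the forward
    strand.
    """
    if pwm.length > len(sequence):
        return []
    threshold = threshold_frac * pwm.max_score
    codes = encode(sequence)
    hits: list[MotifHit] = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        scores = _score_positions(codes, mat)
        for i in np.nonzero(scores >= threshold)[0]:
            hits.append(MotifHit(window_id, int(i), strand, float(scores[i])))
    return _collapse_overlaps(hits, pwm.length)


def _collapse_overlaps(hits: list[MotifHit], length: int) -> list[MotifHit]:
    kept: list[MotifHit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.offset, h.strand)):
        clash = any(
            k.strand == h.strand and abs(k.offset - h.offset) < length for k in kept
        )
        if not clash:
            kept.append(h)
    kept.sort(key=lambda h: (h.offset, h.strand))
    return kept


def summit_windows(
    ders: list[DER],
    assets: GenomeAssets,
    halfwidth: int = 200,
) -> tuple[list[SummitWindow], int]:
    """Sequence windows of +-halfwidth around each region summit (falling back
    to the midpoint), clipped to chromosome bounds. Returns (windows, number
    skipped for lying entirely off-chromosome)."""
    windows: list[SummitWindow] = []
    n_skipped = 0
    for der in ders:
        chrom = der.region.chrom
        size = assets.chrom_sizes.get(chrom)
        if size is None:
            raise ValueError(f"unknown chromosome {chrom!r}")
        summit = der.region.summit_pos
        start = max(0, summit - halfwidth)
        end = min(size, summit + halfwidth)
        if start >= end:
            n_skipped += 1
            continue
        seq = assets.fetch(Region(chrom, start, end))
        windows.append(SummitWindow(der.der_id, chrom, start, end, summit, seq))
    return windows, n_skipped


def windows_with_hits(
    windows: list[SummitWindow], pwm: PWM, threshold_frac: float = 0.8
) -> int:
    return sum(
        1 for w in windows if scan_pwm(w.sequence, pwm, threshold_frac, w.window_id)
    )


def motif_enrichment(
    target_windows: list[SummitWindow],
    background_windows: list[SummitWindow],
    pwm_library: list[PWM],
    threshold_frac: float = 0.8,
    statistic: str = "binomial",
) -> list[MotifEnrichmentResult]:
    """Per-motif window-level enrichment of targets over background.

    One-sided binomial tail against p0 = background hit fraction (floored at
    1/(2 n_bg)); a hypergeometric variant on the pooled windows is available
    for small fixed backgrounds. Sorted by p ascending; BH q-values attached.
    """
    if not pwm_library:
        raise ValueError("empty PWM library")
    if not target_windows or not background_windows:
        raise ValueError("need at least one target and one background window")
    results = []
    n, n_bg = len(target_windows), len(background_windows)
    for pwm in pwm_library:
        k = windows_with_hits(target_windows, pwm, threshold_frac)
        k_bg = windows_with_hits(background_windows, pwm, threshold_frac)
        if statistic == "binomial":
            p0 = max(k_bg / n_bg, 1.0 / (2 * n_bg))
            p = binom_upper_tail(k, n, min(p0, 1.0))
        elif statistic == "hypergeometric":
            p = hypergeom_upper_tail(k, k + k_bg, n, n + n_bg)
        else:
            raise ValueError(f"unknown enrichment statistic {statistic!r}")
        results.append(
            MotifEnrichmentResult(pwm.name, pwm.tf_name, k, n, k_bg, n_bg, p)
        )
    results.sort(key=lambda r: (r.p, r.motif))
    qs = bh_qvalues([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def identify_detfs(
    enrichment_gain: list[MotifEnrichmentResult],
    enrichment_loss: list[MotifEnrichmentResult],
    expression: list[ExpressionRecord],
    tf_gene_map: dict[str, str],
    p_threshold: float = 0.01,
) -> tuple[list[DETF], int]:
    """Intersect motif enrichment with TF expression.

    up-DETF: motif enriched in GAIN windows (p < threshold) and the TF's own
    gene significantly upregulated; down-DETF mirrors with LOSS and
    downregulation. TF names unmappable to a gene id are skipped and counted.
    """
    table = {r.gene_id: r for r in expression}
    detfs: list[DETF] = []
    n_unmapped = 0
    for enr, direction in ((enrichment_gain, "up"), (enrichment_loss, "down")):
        for res in enr:
            if res.p >= p_threshold:
                continue
            gene_id = tf_gene_map.get(res.tf_name)
            if gene_id is None or gene_id not in table:
                n_unmapped += 1
                continue
            rec = table[gene_id]
            if not rec.significant:
                continue
            if direction == "up" and rec.log2fc <= 0:
                continue
            if direction == "down" and rec.log2fc >= 0:
                continue
            detfs.append(
                DETF(
                    res.tf_name,
                    gene_id,
                    direction,
                    res.p,
                    rec.log2fc,
                    float(np.log2(rec.mean_case + 1)),
                )
            )
    return detfs, n_unmapped


def occurrence_profile(
    pwm: PWM,
    ders: list[DER],
    assets: GenomeAssets,
    halfwidth: int = 500,
    bin_width: int = 10,
    threshold_frac: float = 0.8,
) -> OccurrenceProfile:
    """Binned density of motif-hit midpoints over [-halfwidth, +halfwidth)
    around summits, in hits per bp per window. The conservation identity
    sum(density) * bin_width * n_windows == total hits holds exactly."""
    windows, _ = summit_windows(ders, assets, halfwidth)
    edges = np.arange(-halfwidth, halfwidth + bin_width, bin_width, dtype=float)
    counts = np.zeros(len(edges) - 1)
    total = 0
    for w in windows:
        for hit in scan_pwm(w.sequence, pwm, threshold_frac, w.window_id):
            midpoint = w.start + hit.offset + (pwm.length - 1) / 2.0
            rel = midpoint - w.summit
            idx = int(np.floor((rel + halfwidth) / bin_width))
            if 0 <= idx < len(counts):
                counts[idx] += 1
                total += 1
    n_windows = max(len(windows), 1)
    density = counts / (bin_width * n_windows)
    return OccurrenceProfile(edges, density, len(windows), total)


def tf_targets(
    pwm: PWM,
    genes: list[GeneModel],
    assets: GenomeAssets,
    expression: list[ExpressionRecord],
    promoter_halfwidth: int = 2000,
    threshold_frac: float = 0.8,
    deg_only: bool = True,
) -> list[tuple[str, float]]:
    """DEGs with a motif hit whose midpoint lies within +-promoter_halfwidth
    of the TSS (strand-agnostic gate), sorted by |log2FC| descending.

    The scanned window is padded by one motif length on each side so that a
    hit straddling the gate boundary is still scored; the midpoint gate is
    half-open: [TSS - halfwidth, TSS + halfwidth).
    """
    table = {r.gene_id: r for r in expression}
    targets: list[tuple[str, float]] = []
    for g in genes:
        rec = table.get(g.gene_id)
        if rec is None or (deg_only and not rec.significant):
            continue
        size = assets.chrom_sizes[g.chrom]
        start = max(0, g.tss - promoter_halfwidth - pwm.length)
        end = min(size, g.tss + promoter_halfwidth + pwm.length)
        if start >= end:
            continue
        seq = assets.fetch(Region(g.chrom, start, end))
        for hit in scan_pwm(seq, pwm, threshold_frac, g.gene_id):
            midpoint = start + hit.offset + (pwm.length - 1) / 2.0
            if g.tss - promoter_halfwidth <= midpoint < g.tss + promoter_halfwidth:
                targets.append((g.gene_id, rec.log2fc))
                break
    targets.sort(key=lambda t: (-abs(t[1]), t[0]))
    return targets
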