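"""Synthetic study generator with known ground truth.

Emulates the statistical structure of a two-condition, two-replicate
CUT&Tag + RNA-seq study: a random genome, non-overlapping gene models,
consensus enrichment regions with negative-binomially distributed fragment
counts and planted fold-change effects, an expression table whose gene
fold changes correlate with the planted region effects at a configurable
Pearson rho, motif instances written preferentially into GAIN summit
windows, and one gene set enriched in GAIN-linked upregulated genes.

Counts follow a Gamma–Poisson (negative binomial) model with a shared
dispersion phi: mean mu = depth * u_r * 2^(beta_r * [case]) with region
baseline u_r log-normal, variance mu + mu^2/phi. phi = inf recovers Poisson.

Determinism: one master seed; each stage draws from its own child stream
(numpy SeedSequence spawn keys), so stages are re-runnable in isolation and
identical configs yield byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import GeneModel, GenomeAssets, Region
from .motifs import PWM
from . import io as sio

_BASES = np.array(list("ACGT"))

# child-stream spawn keys, one per stage
_STAGE_GENOME, _STAGE_GENES, _STAGE_SIGNAL = 0, 1, 2
_STAGE_EXPRESSION, _STAGE_MOTIFS, _STAGE_SETS = 3, 4, 5


def stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 500_000
    gc: float = 0.45
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (1_000, 3_000)
    n_regions: int = 1_000
    region_width: int = 400
    frac_gain: float = 0.10
    frac_loss: float = 0.10
    effect_log2: tuple[float, float] = (math.log2(3.0), 3.0)
    depth: float = 200.0
    dispersion: float = 10.0
    baseline_sigma: float = 0.5
    fragment_length: int = 100
    background_frags_per_region: float = 500.0
    n_reps: int = 2
    rho_target: float = 0.7
    expr_noise_sd: float = 1.5
    deg_log2fc: float = 1.0
    motif_consensus: str = "TGACTCA"
    motif_tf_name: str = "AP1"
    n_decoy_motifs: int = 5
    decoy_motif_length: int = 8
    p_fg: float = 0.6
    p_bg: float = 0.05
    motif_offset_sd: float = 50.0
    motif_halfwidth: int = 200
    n_gene_sets: int = 20
    gene_set_size: int = 30
    planted_set_enrichment: float = 0.6

    def __post_init__(self) -> None:
        if not (0 <= self.frac_gain and 0 <= self.frac_loss
                and self.frac_gain + self.frac_loss <= 1):
            raise ValueError("frac_gain + frac_loss must lie in [0, 1]")
        if not (0 <= self.p_bg <= self.p_fg <= 1):
            raise ValueError("need 0 <= p_bg <= p_fg <= 1")
        if not (-1 <= self.rho_target <= 1):
            raise ValueError("rho_target must lie in [-1, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion phi must be positive (inf = Poisson)")
        if not (0 < self.gc < 1):
            raise ValueError("gc must lie in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("need at least one replicate per condition")
        if self.expr_noise_sd < 0:
            raise ValueError("expr_noise_sd must be non-negative")

    @property
    def n_gain(self) -> int:
        return int(round(self.frac_gain * self.n_regions))

    @property
    def n_loss(self) -> int:
        return int(round(self.frac_loss * self.n_regions))

    @property
    def sample_names(self) -> list[str]:
        return [f"ctrl_rep{i+1}" for i in range(self.n_reps)] + [
            f"case_rep{i+1}" for i in range(self.n_reps)
        ]

    @property
    def groups(self) -> dict[str, str]:
        return {s: ("ctrl" if s.startswith("ctrl") else "case")
                for s in self.sample_names}


@dataclass
class SimulationResult:
    config: SimulationConfig
    assets: GenomeAssets
    genes: list[GeneModel]
    regions: list[Region]
    fragments: dict[str, pd.DataFrame]  # chrom/start/end per sample
    expression: list
    gene_sets: "object"
    pwms: list[PWM]
    tf_gene_map: dict[str, str]
    truth: dict[str, pd.DataFrame]


def simulate_genome_and_genes(
    config: SimulationConfig,
) -> tuple[GenomeAssets, list[GeneModel]]:
    """I.i.d. genome at the configured base composition plus non-overlapping
    genes on alternating strands, each with 2–5 exons."""
    rng = stage_rng(config.seed, _STAGE_GENOME)
    p = np.array([
        (1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2,
    ])
    sequences = {}
    for c in range(config.n_chroms):
        bases = rng.choice(_BASES, size=config.chrom_length, p=p)
        sequences[f"chr{c+1}"] = "".join(bases)
    assets = GenomeAssets({c: len(s) for c, s in sequences.items()}, sequences)

    genes: list[GeneModel] = []
    if config.n_genes == 0:
        return assets, genes
    rng_genes = stage_rng(config.seed, _STAGE_GENES)
    per_chrom = _split_across(config.n_genes, config.n_chroms)
    lo, hi = config.gene_length_range
    gi = 0
    for c, n_here in enumerate(per_chrom):
        chrom = f"chr{c+1}"
        if n_here == 0:
            continue
        block = config.chrom_length // n_here
        if block < hi + 200:
            raise ValueError(
                f"genome too small for {config.n_genes} genes: need at least "
                f"{(hi + 200) * n_here} bp per chromosome"
            )
        for b in range(n_here):
            length = int(rng_genes.integers(lo, hi + 1))
            margin = block - length
            start = b * block + int(rng_genes.integers(100, max(101, margin - 100)))
            strand = "+" if gi % 2 == 0 else "-"
            n_exons = int(rng_genes.integers(2, 6))
            cuts = np.sort(
                rng_genes.choice(np.arange(1, length), 2 * n_exons - 2, replace=False)
            )
            bounds = np.concatenate([[0], cuts, [length]])
            exons = [
                (start + int(bounds[2 * k]), start + int(bounds[2 * k + 1]))
                for k in range(n_exons)
            ]
            genes.append(
                GeneModel(f"g{gi:05d}", chrom, strand, start, start + length, exons)
            )
            gi += 1
    return assets, genes


def _split_across(total: int, parts: int) -> list[int]:
    base = total // parts
    out = [base] * parts
    for i in range(total - base * parts):
        out[i] += 1
    return out


def simulate_signal(
    config: SimulationConfig,
    genes: list[GeneModel],
) -> tuple[list[Region], dict[str, pd.DataFrame], pd.DataFrame]:
    """Consensus regions, per-sample fragment tables, and the region truth.

    Regions tile the genome in non-overlapping slots (with a 1 bp guard so
    adjacent regions never book-end); each planted (GAIN or LOSS) region is
    moved inside its slot to sit next to a distinct gene's TSS, which
    guarantees the nearest-gene step downstream has recoverable signal.
    Summits are recorded at region midpoints.

    Besides region-derived fragments, each sample receives a genome-wide
    uniform background (``background_frags_per_region`` expected fragments
    per region equivalent) placed in the gaps between regions. This emulates
    the unenriched majority of a CUT&Tag library and keeps per-sample library
    sizes comparable between conditions, as they are in real data, so that
    RPKM ratios are not distorted by the planted effect mass.

    Fragment tables are DataFrames with columns chrom/start/end, sorted by
    position within chromosome.
    """
    rng = stage_rng(config.seed, _STAGE_SIGNAL)
    n_planted = config.n_gain + config.n_loss
    if n_planted > len(genes):
        raise ValueError(
            f"{n_planted} planted regions need at least as many genes "
            f"({len(genes)} available)"
        )
    per_chrom = _split_across(config.n_regions, config.n_chroms)
    slots: list[tuple[str, int, int]] = []  # (chrom, slot_start, slot_end)
    for c, n_here in enumerate(per_chrom):
        chrom = f"chr{c+1}"
        if n_here == 0:
            continue
        width = config.chrom_length // n_here
        if width < config.region_width + 2:
            raise ValueError(
                "genome too small for the requested regions: need at least "
                f"{(config.region_width + 2) * n_here} bp per chromosome"
            )
        for b in range(n_here):
            slots.append((chrom, b * width, (b + 1) * width))

    # default placement: jittered within the slot, 1 bp short of the slot end
    starts = []
    for chrom, s0, s1 in slots:
        jitter_max = (s1 - s0) - config.region_width - 1
        starts.append(s0 + int(rng.integers(0, jitter_max + 1)))

    # choose planted genes and pull the nearest free slot next to each TSS
    planted_gene_idx = rng.choice(len(genes), size=n_planted, replace=False)
    slot_centers = np.array([(s0 + s1) // 2 for _, s0, s1 in slots])
    slot_chroms = np.array([c for c, _, _ in slots])
    used: set[int] = set()
    planted_slot: dict[int, tuple[int, str]] = {}  # slot -> (gene_idx, class)
    classes = ["GAIN"] * config.n_gain + ["LOSS"] * config.n_loss
    for gidx, cls in zip(planted_gene_idx, classes):
        gene = genes[int(gidx)]
        cand = np.nonzero(slot_chroms == gene.chrom)[0]
        order = cand[np.argsort(np.abs(slot_centers[cand] - gene.tss), kind="stable")]
        slot_i = next(int(i) for i in order if int(i) not in used)
        used.add(slot_i)
        planted_slot[slot_i] = (int(gidx), cls)
        chrom, s0, s1 = slots[slot_i]
        starts[slot_i] = int(
            np.clip(gene.tss - config.region_width // 2,
                    s0, s1 - config.region_width - 1)
        )

    regions: list[Region] = []
    rows = []
    lo_b, hi_b = config.effect_log2
    for i, (chrom, s0, s1) in enumerate(slots):
        start = starts[i]
        reg = Region(
            chrom, start, start + config.region_width,
            name=f"r{i:05d}", summit=config.region_width // 2,
        )
        regions.append(reg)
        if i in planted_slot:
            gidx, cls = planted_slot[i]
            beta = float(rng.uniform(lo_b, hi_b))
            if cls == "LOSS":
                beta = -beta
            gene = genes[gidx]
            rows.append(
                dict(region_id=reg.name, chrom=chrom, start=reg.start, end=reg.end,
                     cls=cls, beta=beta, linked_gene=gene.gene_id,
                     tss_distance=abs(reg.midpoint - gene.tss))
            )
        else:
            rows.append(
                dict(region_id=reg.name, chrom=chrom, start=reg.start, end=reg.end,
                     cls="null", beta=0.0, linked_gene="", tss_distance=np.nan)
            )
    truth = pd.DataFrame(rows)

    baseline = rng.lognormal(mean=0.0, sigma=config.baseline_sigma,
                             size=len(regions))
    gap_chroms, gap_starts, gap_counts = _background_gaps(
        config, regions, config.fragment_length
    )
    gap_cum = np.cumsum(gap_counts)
    n_bg_expected = config.background_frags_per_region * config.n_regions

    fragments: dict[str, pd.DataFrame] = {}
    beta = truth["beta"].to_numpy()
    flen = config.fragment_length
    for sample in config.sample_names:
        is_case = config.groups[sample] == "case"
        mu = config.depth * baseline * np.power(2.0, beta * is_case)
        counts = _nb_counts(rng, mu, config.dispersion)
        chrom_parts: list[np.ndarray] = []
        start_parts: list[np.ndarray] = []
        for reg, c in zip(regions, counts):
            if c == 0:
                continue
            hi = reg.end - flen
            fs = rng.integers(reg.start, max(reg.start + 1, hi + 1), size=int(c))
            start_parts.append(fs)
            chrom_parts.append(np.full(int(c), reg.chrom))
        if gap_cum[-1] > 0 and n_bg_expected > 0:
            n_bg = int(rng.poisson(n_bg_expected))
            u = rng.integers(0, gap_cum[-1], size=n_bg)
            gi = np.searchsorted(gap_cum, u, side="right")
            cum0 = np.concatenate([[0], gap_cum])
            offset = u - cum0[gi]
            start_parts.append(gap_starts[gi] + offset)
            chrom_parts.append(gap_chroms[gi])
        df = pd.DataFrame({
            "chrom": np.concatenate(chrom_parts),
            "start": np.concatenate(start_parts).astype(np.int64),
        })
        df["end"] = df["start"] + flen
        df = df.sort_values(["chrom", "start"], kind="mergesort",
                            ignore_index=True)
        fragments[sample] = df
    return regions, fragments, truth


def _background_gaps(
    config: SimulationConfig, regions: list[Region], flen: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Allowed background start positions: the inter-region gaps, shrunk so a
    fragment never overlaps a region. Returns per-gap chrom, first allowed
    start, and number of allowed starts."""
    chroms, starts, counts = [], [], []
    by_chrom: dict[str, list[Region]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, length in ((f"chr{c+1}", config.chrom_length)
                          for c in range(config.n_chroms)):
        regs = sorted(by_chrom.get(chrom, []), key=lambda r: r.start)
        prev = 0
        bounds = [(r.start, r.end) for r in regs] + [(length, length)]
        for s, e in bounds:
            lo, hi = prev, s - flen  # last allowed start
            if hi >= lo:
                chroms.append(chrom)
                starts.append(lo)
                counts.append(hi - lo + 1)
            prev = e
    return (np.array(chroms), np.array(starts, dtype=np.int64),
            np.array(counts, dtype=np.int64))


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, phi: float
) -> np.ndarray:
    """Gamma–Poisson draw with mean mu, variance mu + mu^2/phi."""
    if math.isinf(phi):
        return rng.poisson(mu)
    lam = rng.gamma(shape=phi, scale=mu / phi)
    return rng.poisson(lam)


def simulate_expression(
    config: SimulationConfig,
    truth_regions: pd.DataFrame,
    genes: list[GeneModel],
) -> tuple[list, pd.DataFrame]:
    """Expression table whose linked-gene log2FCs track the planted region
    effects at the configured population Pearson correlation.

    For linked genes, log2FC = a * beta + e with e ~ N(0, expr_noise_sd) and
    a = rho * sd(e) / (sd(beta) * sqrt(1 - rho^2)); unlinked genes draw pure
    noise. The DEG flag is |log2FC| > deg_log2fc (default 1), the fold filter
    the pathway stage applies downstream.
    """
    from .core import ExpressionRecord

    rng = stage_rng(config.seed, _STAGE_EXPRESSION)
    planted = truth_regions[truth_regions["cls"] != "null"]
    linked = dict(zip(planted["linked_gene"], planted["beta"]))
    rho, sd_e = config.rho_target, config.expr_noise_sd
    betas = np.array(list(linked.values()))
    if abs(rho) == 1.0:
        if sd_e != 0:
            a = 1.0  # exact correlation requires zero noise; scale is free
            sd_e = 0.0
        else:
            a = 1.0
        a = math.copysign(a, rho)
    elif rho == 0.0:
        a = 0.0
    else:
        if sd_e == 0:
            raise ValueError(
                "rho_target strictly between 0 and 1 needs expr_noise_sd > 0"
            )
        sd_b = float(betas.std()) if len(betas) else 1.0
        if sd_b == 0:
            raise ValueError("planted effects have zero spread; cannot hit rho")
        a = rho * sd_e / (sd_b * math.sqrt(1 - rho**2))

    records = []
    gene_rows = []
    region_of_gene = dict(zip(planted["linked_gene"], planted["region_id"]))
    for g in genes:
        if g.gene_id in linked:
            log2fc = a * linked[g.gene_id] + (
                rng.normal(0.0, sd_e) if sd_e > 0 else 0.0
            )
            linked_region = region_of_gene[g.gene_id]
        else:
            log2fc = rng.normal(0.0, sd_e) if sd_e > 0 else 0.0
            linked_region = ""
        mean_ctrl = float(rng.lognormal(mean=2.0, sigma=1.0))
        mean_case = mean_ctrl * 2.0**log2fc
        deg = abs(log2fc) > config.deg_log2fc
        records.append(
            ExpressionRecord(g.gene_id, mean_ctrl, mean_case, float(log2fc), deg)
        )
        gene_rows.append(
            dict(gene_id=g.gene_id, log2fc=float(log2fc), deg=deg,
                 linked_region=linked_region)
        )
    return records, pd.DataFrame(gene_rows)


def plant_motifs(
    config: SimulationConfig,
    fg_windows: list[Region],
    bg_windows: list[Region],
    assets: GenomeAssets,
    pwm: PWM | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Write motif instances into the genome sequence.

    With probability p_fg (foreground windows) or p_bg (background), one
    instance sampled from the PWM is written at an offset ~ N(0,
    motif_offset_sd) from the window summit, clipped so the motif stays
    inside the window. Mutates ``assets.sequences`` in place and returns the
    per-window truth (planted flag and motif-midpoint offset from summit).
    """
    if rng is None:
        rng = stage_rng(config.seed, _STAGE_MOTIFS)
    if pwm is None:
        pwm = PWM.from_consensus("planted", config.motif_tf_name,
                                 config.motif_consensus)
    L = pwm.length
    buffers = {c: bytearray(s, "ascii") for c, s in assets.sequences.items()}
    rows = []
    for windows, p_plant, kind in ((fg_windows, config.p_fg, "fg"),
                                   (bg_windows, config.p_bg, "bg")):
        for w in windows:
            if L > len(w):
                raise ValueError(
                    f"motif length {L} exceeds window length {len(w)}"
                )
            planted = bool(rng.random() < p_plant)
            offset = np.nan
            if planted:
                summit = w.summit_pos
                shift = rng.normal(0.0, config.motif_offset_sd)
                mid = summit + shift
                half = (L - 1) / 2.0
                mid = float(np.clip(mid, w.start + half, w.end - 1 - half))
                start = int(round(mid - half))
                start = max(w.start, min(start, w.end - L))
                instance = _sample_instance(rng, pwm)
                buffers[w.chrom][start : start + L] = instance.encode()
                offset = start + half - summit
            rows.append(
                dict(window_id=w.name or f"{w.chrom}:{w.start}-{w.end}",
                     kind=kind, planted=planted, center_offset=offset)
            )
    for c in buffers:
        assets.sequences[c] = buffers[c].decode("ascii")
    return pd.DataFrame(rows)


def _sample_instance(rng: np.random.Generator, pwm: PWM) -> str:
    idx = [int(rng.choice(4, p=pwm.probs[:, j])) for j in range(pwm.length)]
    return "".join("ACGT"[i] for i in idx)


def make_decoy_pwms(config: SimulationConfig) -> list[PWM]:
    """Random sharp consensus motifs never planted anywhere."""
    rng = stage_rng(config.seed, _STAGE_MOTIFS + 100)
    decoys = []
    for d in range(config.n_decoy_motifs):
        consensus = "".join(rng.choice(_BASES, size=config.decoy_motif_length))
        decoys.append(PWM.from_consensus(f"decoy{d:02d}", f"DECOY{d:02d}", consensus))
    return decoys


def simulate_gene_sets(
    config: SimulationConfig,
    truth_genes: pd.DataFrame,
):
    """Gene-set collection with one set enriched in GAIN-linked up-DEGs.

    The planted set draws ``planted_set_enrichment`` of its members from the
    realized GAIN-linked upregulated DEGs; decoy sets are uniform draws.
    """
    from .core import GeneSetCollection

    rng = stage_rng(config.seed, _STAGE_SETS)
    all_genes = truth_genes["gene_id"].tolist()
    up_linked = truth_genes[
        (truth_genes["linked_region"] != "")
        & truth_genes["deg"]
        & (truth_genes["log2fc"] > 0)
    ]["gene_id"].tolist()
    size = min(config.gene_set_size, len(all_genes))
    n_fg = min(int(round(size * config.planted_set_enrichment)), len(up_linked))
    fg = list(rng.choice(up_linked, size=n_fg, replace=False)) if n_fg else []
    rest_pool = sorted(set(all_genes) - set(fg))
    rest = list(rng.choice(rest_pool, size=size - n_fg, replace=False))
    sets = {"planted_set": sorted(fg + rest)}
    descriptions = {"planted_set": "planted GAIN-linked up-DEG set"}
    for s in range(config.n_gene_sets - 1):
        members = sorted(rng.choice(all_genes, size=size, replace=False))
        sets[f"decoy_set{s:02d}"] = members
        descriptions[f"decoy_set{s:02d}"] = "random decoy set"
    return GeneSetCollection(sets, descriptions), "planted_set"


def simulate_study(config: SimulationConfig) -> SimulationResult:
    """Run every stage and assemble an internally consistent toy study."""
    assets, genes = simulate_genome_and_genes(config)
    regions, fragments, truth_regions = simulate_signal(config, genes)
    expression, truth_genes = simulate_expression(config, truth_regions, genes)

    planted_pwm = PWM.from_consensus("planted", config.motif_tf_name,
                                     config.motif_consensus)
    fg = [r for r, cls in zip(regions, truth_regions["cls"]) if cls == "GAIN"]
    bg = [r for r, cls in zip(regions, truth_regions["cls"]) if cls == "null"]
    fgw = [_window_around(r, config.motif_halfwidth, assets) for r in fg]
    bgw = [_window_around(r, config.motif_halfwidth, assets) for r in bg]
    truth_motifs = plant_motifs(config, fgw, bgw, assets, planted_pwm)
    pwms = [planted_pwm] + make_decoy_pwms(config)

    # TF identity: the planted motif's TF is the strongest realized
    # GAIN-linked upregulated DEG; decoys map to arbitrary unlinked genes.
    up = truth_genes[
        (truth_genes["linked_region"] != "")
        & truth_genes["deg"]
        & (truth_genes["log2fc"] > 0)
    ].sort_values("log2fc", ascending=False)
    if up.empty:
        raise ValueError("no GAIN-linked upregulated DEG to serve as the TF gene")
    tf_gene_map = {config.motif_tf_name: str(up.iloc[0]["gene_id"])}
    unlinked = truth_genes[truth_genes["linked_region"] == ""]["gene_id"].tolist()
    rng_map = stage_rng(config.seed, _STAGE_SETS + 100)
    for pwm in pwms[1:]:
        tf_gene_map[pwm.tf_name] = str(rng_map.choice(unlinked))

    gene_sets, planted_set = simulate_gene_sets(config, truth_genes)
    truth = {
        "regions": truth_regions,
        "genes": truth_genes,
        "motifs": truth_motifs,
        "meta": pd.DataFrame(
            [dict(planted_set=planted_set,
                  tf_gene=tf_gene_map[config.motif_tf_name])]
        ),
    }
    return SimulationResult(
        config, assets, genes, regions, fragments, expression,
        gene_sets, pwms, tf_gene_map, truth,
    )


def _window_around(region: Region, halfwidth: int, assets: GenomeAssets) -> Region:
    summit = region.summit_pos
    size = assets.chrom_sizes[region.chrom]
    start = max(0, summit - halfwidth)
    end = min(size, summit + halfwidth)
    w = Region(region.chrom, start, end, name=region.name)
    w.summit = summit - start
    return w


def write_study(result: SimulationResult, outdir) -> dict[str, str]:
    """Write every artifact of the study as plain text; returns name -> path."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    def path(name: str) -> str:
        p = os.path.join(str(outdir), name)
        paths[name] = p
        return p

    sio.write_fasta(result.assets, path("genome.fa"))
    sio.write_gene_models(result.genes, path("genes.bed"))
    sio.write_intervals(result.regions, path("consensus.bed"), "narrowpeak")
    for sample in result.config.sample_names:
        sio.write_intervals(result.regions, path(f"peaks_{sample}.bed"),
                            "narrowpeak")
        result.fragments[sample].to_csv(
            path(f"fragments_{sample}.bed"), sep="\t",
            header=False, index=False,
        )
    sio.write_expression_table(result.expression, path("expression.tsv"))
    sio.write_gene_sets(result.gene_sets, path("sets.gmt"))
    sio.write_pwms(result.pwms, path("motifs.pfm"))
    with open(path("tf_map.tsv"), "w") as fh:
        for tf, gene in sorted(result.tf_gene_map.items()):
            fh.write(f"{tf}\t{gene}\n")
    for name, df in result.truth.items():
        df.to_csv(path(f"truth_{name}.tsv"), sep="\t", index=False)
    with open(path("config.txt"), "w") as fh:
        for key, value in asdict(result.config).items():
            fh.write(f"{key}\t{value}\n")
    return paths
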