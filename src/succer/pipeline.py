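"""End-to-end orchestration: stage functions over declared files, a manifest
with content checksums, and a one-command synthetic demonstration run.

Every stage reads only declared input files and writes declared outputs, so
each is runnable standalone; the manifest echoes all parameters and checksums
so a manifest alone re-specifies the run.
"""

from __future__ import annotations

import glob as globlib
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import pandas as pd

from . import io as sio
from .core import FragmentIndex, Region
from .ders import (
    DER,
    DERConfig,
    GAIN,
    LOSS,
    annotate_ders,
    build_consensus,
    call_ders,
    distance_summary,
    quantify_regions,
)
from .integration import (
    assign_nearest_gene,
    attach_expression,
    class_expression_shift,
    cross_mark_concordance,
    der_deg_correlation,
    intersect_with_degs,
)
from .motifs import identify_detfs, motif_enrichment, occurrence_profile, \
    summit_windows, tf_targets
from .pathways import enrich
from .simulate import SimulationConfig, simulate_study, write_study

log = logging.getLogger("succer")

DER_COLUMNS = [
    "chrom", "start", "end", "name", "summit", "class", "mean_ctrl",
    "mean_case", "log2fc", "feature", "dist_tss", "gene_id",
]


def write_der_table(ders: list[DER], path: str) -> None:
    rows = []
    for d in ders:
        rows.append({
            "chrom": d.region.chrom, "start": d.region.start,
            "end": d.region.end, "name": d.der_id,
            "summit": d.region.summit if d.region.summit is not None else -1,
            "class": d.der_class,
            "mean_ctrl": round(d.mean_ctrl, 6), "mean_case": round(d.mean_case, 6),
            "log2fc": round(d.log2fc, 6),
            "feature": d.feature or "", "dist_tss": d.distance_to_tss,
            "gene_id": d.gene_id or "",
        })
    pd.DataFrame(rows, columns=DER_COLUMNS).to_csv(path, sep="\t", index=False)


def read_der_table(path: str) -> list[DER]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    ders = []
    for row in df.to_dict("records"):
        summit = None if int(row["summit"]) < 0 else int(row["summit"])
        reg = Region(row["chrom"], int(row["start"]), int(row["end"]),
                     name=str(row["name"]), summit=summit)
        der = DER(reg, float(row["mean_ctrl"]), float(row["mean_case"]),
                  float(row["log2fc"]), str(row["class"]))
        der.feature = str(row["feature"]) or None
        der.distance_to_tss = (
            float(row["dist_tss"]) if row["dist_tss"] != "" else None
        )
        der.gene_id = str(row["gene_id"]) or None
        ders.append(der)
    return ders


@dataclass
class RunConfig:
    """Paths and parameters for a full pipeline run."""

    outdir: str
    seed: int = 0
    simulate: bool = True
    sim: SimulationConfig | None = None
    # external inputs (used when simulate=False)
    genome: str | None = None
    genes: str | None = None
    peaks: dict[str, str] = field(default_factory=dict)  # sample -> path
    fragments: dict[str, str] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)
    expression: str | None = None
    gene_sets: str | None = None
    pwms: str | None = None
    tf_map: str | None = None
    # stage parameters
    fold_threshold: float = 2.0
    pseudocount: float = 0.5
    max_dist: int = 100_000
    motif_halfwidth: int = 200
    occurrence_halfwidth: int = 500
    promoter_halfwidth: int = 2000
    motif_p_threshold: float = 0.01
    pathway_alpha: float = 0.05
    fc_filter: float = 1.0
    threshold_frac: float = 0.8

    def validate(self) -> None:
        if self.simulate:
            return
        required = {
            "genome": self.genome, "genes": self.genes,
            "expression": self.expression, "gene_sets": self.gene_sets,
            "pwms": self.pwms,
        }
        for name, p in required.items():
            if p is None or not os.path.exists(p):
                raise FileNotFoundError(f"input {name!r} missing: {p}")
        for sample, p in {**self.peaks, **self.fragments}.items():
            if not os.path.exists(p):
                raise FileNotFoundError(f"input for sample {sample!r} missing: {p}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in order and return the run manifest."""
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "parameters": {
            k: v for k, v in vars(cfg).items()
            if isinstance(v, (int, float, str, bool))
        },
        "stages": [],
        "checksums": {},
        "summary": {},
    }
    outputs: list[str] = []

    def out(name: str) -> str:
        p = os.path.join(cfg.outdir, name)
        outputs.append(p)
        return p

    def stage(name):
        manifest["stages"].append({"name": name, "t0": time.time()})
        log.info("stage %s", name)

    def stage_done():
        entry = manifest["stages"][-1]
        entry["seconds"] = round(time.time() - entry.pop("t0"), 3)

    # ------------------------------------------------------------- simulate
    stage("simulate")
    if cfg.simulate:
        sim_cfg = cfg.sim or SimulationConfig(seed=cfg.seed)
        sim_dir = os.path.join(cfg.outdir, "sim")
        result = simulate_study(sim_cfg)
        sim_paths = write_study(result, sim_dir)
        outputs.extend(sim_paths.values())
        cfg.genome = sim_paths["genome.fa"]
        cfg.genes = sim_paths["genes.bed"]
        cfg.peaks = {s: sim_paths[f"peaks_{s}.bed"]
                     for s in sim_cfg.sample_names}
        cfg.fragments = {s: sim_paths[f"fragments_{s}.bed"]
                         for s in sim_cfg.sample_names}
        cfg.groups = sim_cfg.groups
        cfg.expression = sim_paths["expression.tsv"]
        cfg.gene_sets = sim_paths["sets.gmt"]
        cfg.pwms = sim_paths["motifs.pfm"]
        cfg.tf_map = sim_paths["tf_map.tsv"]
    stage_done()

    assets = sio.read_fasta(cfg.genome)
    genes = sio.read_gene_models(cfg.genes)
    expression = sio.read_expression_table(cfg.expression)

    # ------------------------------------------------------------ consensus
    stage("consensus")
    per_sample = {
        s: sio.read_intervals(p, "narrowpeak", assets)
        for s, p in cfg.peaks.items()
    }
    consensus, provenance = build_consensus(per_sample)
    sio.write_intervals(consensus, out("consensus.bed"), "bed6")
    with open(out("consensus_provenance.tsv"), "w") as fh:
        fh.write("region\tsamples\n")
        for name in sorted(provenance):
            fh.write(f"{name}\t{','.join(provenance[name])}\n")
    stage_done()

    # ------------------------------------------------------------- quantify
    stage("quantify")
    samples = {s: sio.read_fragments(p) for s, p in cfg.fragments.items()}
    matrix = quantify_regions(consensus, samples, cfg.groups, mode="fragments")
    rpkm_df = pd.DataFrame(
        matrix.values.round(6), columns=matrix.samples,
        index=[r.name for r in matrix.regions],
    )
    rpkm_df.index.name = "region"
    rpkm_df.to_csv(out("rpkm.tsv"), sep="\t")
    stage_done()

    # ---------------------------------------------------- call-ders/annotate
    stage("call-ders")
    der_cfg = DERConfig(cfg.fold_threshold, cfg.pseudocount)
    ders = call_ders(matrix, der_cfg)
    stage_done()

    stage("annotate")
    annotate_ders(ders, genes)
    assignments, n_far = assign_nearest_gene(ders, genes, cfg.max_dist)
    log.info("%d DERs beyond %d bp of any TSS dropped", n_far, cfg.max_dist)
    write_der_table(ders, out("ders.tsv"))
    for cls, fname in ((GAIN, "gain.bed"), (LOSS, "loss.bed")):
        sio.write_intervals(
            [d.region for d in ders if d.der_class == cls], out(fname), "bed6"
        )
    dist_df, chrom_df = distance_summary(ders)
    dist_df.to_csv(out("distance_bins.tsv"), sep="\t", index=False)
    chrom_df.to_csv(out("chromosome_counts.tsv"), sep="\t", index=False)
    stage_done()

    # ------------------------------------------------------------ integrate
    stage("integrate")
    assignments, n_missing = attach_expression(assignments, expression)
    log.info("%d assigned genes absent from the expression table", n_missing)
    pd.DataFrame([vars(a) for a in assignments]).to_csv(
        out("assignments.tsv"), sep="\t", index=False
    )
    deg_sets = intersect_with_degs(assignments, expression)
    integration_summary: dict = {
        "n_assignments": len(assignments),
        "n_dropped_beyond_max_dist": n_far,
        "n_missing_expression": n_missing,
        "n_gain_deg_genes": len(deg_sets[GAIN]),
        "n_loss_deg_genes": len(deg_sets[LOSS]),
    }
    try:
        corr = der_deg_correlation(assignments)
        integration_summary.update(
            pearson_r=round(corr.r, 6), pearson_p=corr.p, n_pairs=corr.n
        )
    except ValueError as exc:
        integration_summary["pearson_error"] = str(exc)
    for cls in (GAIN, LOSS):
        try:
            res = class_expression_shift(assignments, expression, cls)
            integration_summary[f"wilcoxon_{cls.lower()}_p"] = res.p
            integration_summary[f"wilcoxon_{cls.lower()}_W"] = res.W
        except ValueError as exc:
            integration_summary[f"wilcoxon_{cls.lower()}_error"] = str(exc)
    with open(out("integration_summary.json"), "w") as fh:
        json.dump(integration_summary, fh, indent=2, sort_keys=True)
    for cls in (GAIN, LOSS):
        with open(out(f"{cls.lower()}_deg_genes.txt"), "w") as fh:
            fh.write("\n".join(sorted(deg_sets[cls])) + "\n")
    stage_done()

    # --------------------------------------------------------------- motifs
    stage("motifs")
    pwms = sio.read_pwms(cfg.pwms)
    tf_map: dict[str, str] = {}
    if cfg.tf_map and os.path.exists(cfg.tf_map):
        with open(cfg.tf_map) as fh:
            for line in fh:
                if line.strip():
                    tf, gene = line.rstrip("\n").split("\t")
                    tf_map[tf] = gene
    called = {d.der_id for d in ders}
    background_regions = [
        DER(r, 0.0, 0.0, 0.0, "null") for r in consensus if r.name not in called
    ]
    bg_windows, _ = summit_windows(background_regions, assets, cfg.motif_halfwidth)
    enrichments = {}
    for cls in (GAIN, LOSS):
        cls_ders = [d for d in ders if d.der_class == cls]
        if not cls_ders or not bg_windows:
            enrichments[cls] = []
            continue
        tw, n_clip = summit_windows(cls_ders, assets, cfg.motif_halfwidth)
        results = motif_enrichment(tw, bg_windows, pwms, cfg.threshold_frac)
        enrichments[cls] = results
        pd.DataFrame([
            dict(motif=r.motif, tf=r.tf_name, k=r.k, n=r.n, k_bg=r.k_bg,
                 n_bg=r.n_bg, fraction_target=round(r.fraction_target, 6),
                 p=r.p, q=r.q)
            for r in results
        ]).to_csv(out(f"motif_enrichment_{cls.lower()}.tsv"), sep="\t",
                  index=False)
    detfs, n_unmapped = identify_detfs(
        enrichments[GAIN], enrichments[LOSS], expression, tf_map,
        cfg.motif_p_threshold,
    )
    pd.DataFrame([vars(d) for d in detfs]).to_csv(
        out("detfs.tsv"), sep="\t", index=False
    )
    gain_ders = [d for d in ders if d.der_class == GAIN]
    motif_summary: dict = {"n_detfs": len(detfs), "n_unmapped_tfs": n_unmapped}
    if pwms and gain_ders:
        prof = occurrence_profile(pwms[0], gain_ders, assets,
                                  cfg.occurrence_halfwidth)
        pd.DataFrame({
            "bin_start": prof.edges[:-1].astype(int),
            "density": prof.density.round(8),
        }).to_csv(out("occurrence_profile.tsv"), sep="\t", index=False)
        targets = tf_targets(pwms[0], genes, assets, expression,
                             cfg.promoter_halfwidth, cfg.threshold_frac)
        pd.DataFrame(targets, columns=["gene_id", "log2fc"]).to_csv(
            out("tf_targets.tsv"), sep="\t", index=False
        )
        motif_summary["n_targets"] = len(targets)
    with open(out("motif_summary.json"), "w") as fh:
        json.dump(motif_summary, fh, indent=2, sort_keys=True)
    stage_done()

    # --------------------------------------------------------------- enrich
    stage("enrich")
    sets = sio.read_gene_sets(cfg.gene_sets)
    pathway_records = {}
    for cls in (GAIN, LOSS):
        records, n_dropped = enrich(
            deg_sets[cls], sets, expression,
            alpha=cfg.pathway_alpha, fc_filter=cfg.fc_filter,
        )
        pathway_records[cls] = records
        pd.DataFrame([
            dict(set=r.set_name, k=r.k, K=r.K, n=r.n, N=r.N, p=r.p, q=r.q,
                 significant=r.significant,
                 members=",".join(g for g, _ in r.members))
            for r in records
        ]).to_csv(out(f"pathways_{cls.lower()}.tsv"), sep="\t", index=False)
    stage_done()

    # --------------------------------------------------------------- report
    stage("report")
    _write_report(out("report.txt"), ders, dist_df, integration_summary,
                  enrichments, detfs, pathway_records)
    stage_done()

    manifest["summary"] = {
        "n_consensus": len(consensus),
        "n_gain": sum(1 for d in ders if d.der_class == GAIN),
        "n_loss": sum(1 for d in ders if d.der_class == LOSS),
        **integration_summary,
        **motif_summary,
    }
    for p in outputs:
        manifest["checksums"][os.path.relpath(p, cfg.outdir)] = _sha256(p)
    for entry in manifest["stages"]:
        entry.pop("t0", None)
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write_report(path, ders, dist_df, integration_summary, enrichments,
                  detfs, pathway_records) -> None:
    lines = ["# succer run report", ""]
    n_gain = sum(1 for d in ders if d.der_class == GAIN)
    n_loss = sum(1 for d in ders if d.der_class == LOSS)
    lines += [f"DERs: {n_gain} GAIN, {n_loss} LOSS", ""]
    lines.append("## Feature annotation (counts)")
    feat_counts: dict[tuple[str, str], int] = {}
    for d in ders:
        feat_counts[(d.der_class, d.feature or "?")] = (
            feat_counts.get((d.der_class, d.feature or "?"), 0) + 1
        )
    for (cls, feat), count in sorted(feat_counts.items()):
        lines.append(f"  {cls:<5} {feat:<14} {count}")
    lines.append("")
    if len(dist_df):
        lines.append("## TSS-distance bins (fractions)")
        lines.append(dist_df.to_string(index=False))
        lines.append("")
    lines.append("## Integration")
    for key in sorted(integration_summary):
        lines.append(f"  {key}: {integration_summary[key]}")
    lines.append("")
    for cls, results in enrichments.items():
        lines.append(f"## Top motifs ({cls})")
        for r in results[:5]:
            lines.append(
                f"  {r.motif:<10} k/n={r.k}/{r.n} bg={r.k_bg}/{r.n_bg} "
                f"p={r.p:.3g}"
            )
        lines.append("")
    lines.append("## DETFs")
    for d in detfs:
        lines.append(
            f"  {d.tf_name:<10} {d.direction:<5} p={d.enrichment_p:.3g} "
            f"log2FC={d.expression_log2fc:.2f}"
        )
    lines.append("")
    for cls, records in pathway_records.items():
        lines.append(f"## Top pathways ({cls})")
        for r in records[:5]:
            lines.append(f"  {r.set_name:<14} k/K={r.k}/{r.K} p={r.p:.3g}")
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def run_demo(outdir: str, seed: int = 1,
             sim: SimulationConfig | None = None) -> dict:
    """One-command synthetic demonstration run."""
    cfg = RunConfig(outdir=outdir, seed=seed, simulate=True,
                    sim=sim or SimulationConfig(seed=seed))
    return run_pipeline(cfg)


def expand_sample_glob(pattern: str, prefix: str) -> dict[str, str]:
    """Map sample names out of files matching ``pattern`` by stripping
    ``prefix`` and the extension from the basename."""
    out = {}
    for p in sorted(globlib.glob(pattern)):
        base = os.path.basename(p)
        name = base[len(prefix):] if base.startswith(prefix) else base
        out[os.path.splitext(name)[0]] = p
    return out
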