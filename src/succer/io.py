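"""Readers and writers for the plain-text formats the pipeline exchanges.

BED-family coordinates are kept exactly as read (0-based half-open). GTF input
is converted to the internal 0-based convention on read.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    ExpressionRecord,
    GeneModel,
    GeneSetCollection,
    GenomeAssets,
    Region,
    SignalTrack,
)

INTERVAL_FORMATS = ("bed3", "bed6", "narrowpeak", "fragments-bed", "bedgraph")


def _parse_int(token: str, path: str, lineno: int, what: str) -> int:
    try:
        value = int(token)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: malformed {what} {token!r}") from exc
    if value < 0:
        raise ValueError(f"{path}:{lineno}: negative {what} {token!r}")
    return value


def _iter_data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_intervals(
    path: str,
    format: str = "bed6",
    assets: GenomeAssets | None = None,
):
    """Read an interval file; for ``bedgraph`` returns a SignalTrack.

    Malformed lines raise with the offending line number; regions on
    chromosomes absent from ``assets`` (when provided) are an error.
    """
    if format not in INTERVAL_FORMATS:
        raise ValueError(f"unknown interval format {format!r}")
    regions: list[Region] = []
    track_items: list[tuple[Region, float]] = []
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: fewer than 3 tab-separated fields")
        chrom = fields[0]
        start = _parse_int(fields[1], path, lineno, "start")
        end = _parse_int(fields[2], path, lineno, "end")
        if start >= end:
            raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
        if assets is not None and chrom not in assets.chrom_sizes:
            raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if format == "bedgraph":
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: bedGraph needs a value column")
            track_items.append((Region(chrom, start, end), float(fields[3])))
            continue
        name = score = strand = summit = None
        if format in ("bed6", "narrowpeak") and len(fields) >= 6:
            name = fields[3] if fields[3] != "." else None
            score = float(fields[4]) if fields[4] != "." else None
            strand = fields[5]
        elif len(fields) >= 4 and format in ("bed6", "narrowpeak"):
            name = fields[3]
        if format == "narrowpeak" and len(fields) >= 10 and fields[9] != "-1":
            summit = _parse_int(fields[9], path, lineno, "summit offset")
        regions.append(
            Region(chrom, start, end, name=name, score=score,
                   strand=strand or ".", summit=summit)
        )
    if format == "bedgraph":
        return SignalTrack(track_items)
    return regions


def write_intervals(regions: list[Region], path: str, format: str = "bed6") -> None:
    with open(path, "w") as fh:
        for r in regions:
            if format == "bed3" or format == "fragments-bed":
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
            elif format == "bed6":
                score = "." if r.score is None else _fmt_score(r.score)
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.name or '.'}\t"
                    f"{score}\t{r.strand}\n"
                )
            elif format == "narrowpeak":
                score = "0" if r.score is None else _fmt_score(r.score)
                summit = -1 if r.summit is None else r.summit
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.name or '.'}\t{score}\t"
                    f"{r.strand}\t0\t-1\t-1\t{summit}\n"
                )
            else:
                raise ValueError(f"cannot write format {format!r}")


def _fmt_score(score: float) -> str:
    return str(int(score)) if float(score).is_integer() else repr(float(score))


def read_gene_models(path: str) -> list[GeneModel]:
    """Read gene models from BED6/BED12 (or minimal GTF by .gtf suffix)."""
    if str(path).endswith((".gtf", ".gff")):
        return _read_gtf(path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 6:
            raise ValueError(f"{path}:{lineno}: gene BED needs >= 6 columns")
        chrom = fields[0]
        start = _parse_int(fields[1], path, lineno, "start")
        end = _parse_int(fields[2], path, lineno, "end")
        gene_id, strand = fields[3], fields[5]
        if gene_id in seen:
            raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        exons: list[tuple[int, int]] = []
        if len(fields) >= 12:
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != len(offsets):
                raise ValueError(f"{path}:{lineno}: blockSizes/blockStarts mismatch")
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
        genes.append(GeneModel(gene_id, chrom, strand, start, end, exons))
    return genes


def _read_gtf(path: str) -> list[GeneModel]:
    tx: dict[str, dict] = {}
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 9:
            raise ValueError(f"{path}:{lineno}: GTF needs 9 columns")
        chrom, _, feature, start1, end1, _, strand, _, attrs = fields[:9]
        if feature not in ("transcript", "exon", "gene"):
            continue
        gene_id = None
        for part in attrs.split(";"):
            part = part.strip()
            if part.startswith("gene_id"):
                gene_id = part.split(None, 1)[1].strip().strip('"')
        if gene_id is None:
            raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
        start = _parse_int(start1, path, lineno, "start") - 1  # 1-based -> 0-based
        end = _parse_int(end1, path, lineno, "end")
        rec = tx.setdefault(
            gene_id, {"chrom": chrom, "strand": strand, "start": start,
                      "end": end, "exons": []}
        )
        rec["start"] = min(rec["start"], start)
        rec["end"] = max(rec["end"], end)
        if feature == "exon":
            rec["exons"].append((start, end))
    return [
        GeneModel(gid, r["chrom"], r["strand"], r["start"], r["end"], r["exons"])
        for gid, r in tx.items()
    ]


def write_gene_models(genes: list[GeneModel], path: str) -> None:
    """Write gene models as BED12."""
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.tx_start) for s, e in g.exons)
            fh.write(
                f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.tx_start}\t{g.tx_end}\t0\t{len(g.exons)}\t{sizes}\t{offsets}\n"
            )


def read_fasta(path: str) -> GenomeAssets:
    sequences = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    if not sequences:
        raise ValueError(f"{path}: no FASTA records")
    return GenomeAssets({c: len(s) for c, s in sequences.items()}, sequences)


def write_fasta(assets: GenomeAssets, path: str) -> None:
    if assets.sequences is None:
        raise ValueError("genome has no sequence to write")
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in sorted(assets.sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_gene_sets(path: str) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT needs name, description, genes")
        name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = genes
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + list(genes)) + "\n")


def read_fragments(path: str):
    """Fast fragment-BED reader returning a FragmentIndex (pandas C parser)."""
    from .core import FragmentIndex

    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    if (df["start"] >= df["end"]).any():
        bad = int((df["start"] >= df["end"]).idxmax()) + 1
        raise ValueError(f"{path}:{bad}: start >= end")
    return FragmentIndex.from_arrays(
        df["chrom"].to_numpy(), df["start"].to_numpy(), df["end"].to_numpy()
    )


EXPRESSION_COLUMNS = ["gene_id", "mean_ctrl", "mean_case", "log2fc", "significant"]


def read_expression_table(path: str) -> list[ExpressionRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing expression columns {missing}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    records = []
    for row in df.itertuples(index=False):
        sig = row.significant
        if isinstance(sig, str):
            sig = sig.strip().lower() in ("true", "1", "yes")
        records.append(
            ExpressionRecord(
                str(row.gene_id),
                float(row.mean_ctrl),
                float(row.mean_case),
                float(row.log2fc),
                bool(sig),
            )
        )
    return records


def write_expression_table(records: list[ExpressionRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(EXPRESSION_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.mean_ctrl:.6g}\t{r.mean_case:.6g}\t"
                f"{r.log2fc:.6g}\t{r.significant}\n"
            )


def read_pwms(path: str):
    """Read JASPAR-style PFMs: ``>name tf`` then four A/C/G/T count rows.

    Rows may be bare numbers or JASPAR bracketed (``A [ 1 2 3 ]``).
    """
    from .motifs import PWM

    pwms = []
    name = tf_name = None
    rows: list[list[float]] = []

    def flush():
        if name is None:
            return
        if len(rows) != 4:
            raise ValueError(f"{path}: motif {name!r} needs 4 count rows")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"{path}: motif {name!r} has ragged rows")
        pwms.append(PWM.from_counts(name, tf_name or name, np.array(rows)))

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split()
                name = parts[0]
                tf_name = parts[1] if len(parts) > 1 else None
                rows = []
            else:
                tokens = line.replace("[", " ").replace("]", " ").split()
                if tokens and tokens[0].upper() in "ACGT" and len(tokens[0]) == 1:
                    tokens = tokens[1:]
                rows.append([float(t) for t in tokens])
    flush()
    return pwms


def write_pwms(pwms, path: str) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name} {pwm.tf_name}\n")
            for row in pwm.counts:
                fh.write(" ".join(f"{v:g}" for v in row) + "\n")
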