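"""Readers and writers for the plain-text formats the pipeline consumes.

BED3/BED6 (peaks, regions), tab-separated BEDPE-like loop tables
(``chromA startA endA chromB startB endB score``), GFF3 gene subsets,
bedGraph signal and FASTA genomes. All coordinates are converted to the
package-internal 0-based half-open convention on read (GFF3 start − 1);
BED and bedGraph are native. Every emitted file carries a header comment
line with the tool version; readers tolerate ``#``/``track``/``browser``
lines and report malformed lines with their line number. Round-trips are
lossless for coordinates, names, scores and strands.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .intervals import GeneModel, GenomicInterval
from .signal import SignalTrack

HEADER = f"#pcgloop v{__version__}"

LOOP_COLUMNS = ["chromA", "startA", "endA", "chromB", "startB", "endB", "score"]


@dataclass(frozen=True)
class BedRecord:
    """One BED3/BED6 line; ``name``/``score`` are None for pure BED3."""

    interval: GenomicInterval
    name: str | None = None
    score: float | None = None


def _is_skippable(line: str) -> bool:
    s = line.strip()
    return not s or s.startswith("#") or s.startswith("track") or s.startswith("browser")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[BedRecord]:
    records: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED fields")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 and fields[3] != "." else None
                score = (
                    float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
                )
                strand = fields[5] if len(fields) > 5 else "."
                iv = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            records.append(BedRecord(iv, name, score))
    return records


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    return [r.interval for r in read_bed(path)]


def write_bed(records: Iterable[BedRecord | GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(HEADER + "\n")
        for rec in records:
            if isinstance(rec, GenomicInterval):
                rec = BedRecord(rec)
            iv = rec.interval
            if rec.name is None and rec.score is None and iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = rec.name if rec.name is not None else "."
                score = f"{rec.score:g}" if rec.score is not None else "."
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )


# ---------------------------------------------------------------------------
# BEDPE-like loop tables


def read_loop_table(path: str | Path) -> pd.DataFrame:
    """Read a BEDPE-like anchor-pair table with a score column."""
    df = pd.read_csv(path, sep="\t", comment="#", header=0)
    missing = [c for c in LOOP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing loop-table columns {missing}")
    for side in "AB":
        bad = df[f"start{side}"] >= df[f"end{side}"]
        if bad.any():
            raise ValueError(
                f"{path}: line {int(df.index[bad][0]) + 2}: start >= end on anchor {side}"
            )
    return df


def write_loop_table(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(HEADER + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Generic versioned TSV reader (classified loops, truth tables...)."""
    return pd.read_csv(path, sep="\t", comment="#", header=0)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(HEADER + "\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3


def read_gff3_genes(path: str | Path, promoter_window: int = 1000) -> list[GeneModel]:
    """Load gene models (gene + exon features) from a GFF3 subset.

    GFF3 is 1-based inclusive; starts are decremented on read. Exons are
    attached to their parent gene via the ``Parent``/``ID`` attributes
    (direct parent or via an mRNA level).
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        gene_id = gene.id
        strand = gene.strand if gene.strand in ("+", "-") else "."
        interval = GenomicInterval(gene.seqid, gene.start - 1, gene.end, strand)
        exons = tuple(
            GenomicInterval(ex.seqid, ex.start - 1, ex.end, strand)
            for ex in db.children(gene, featuretype="exon", order_by="start")
        )
        genes.append(GeneModel(gene_id, interval, exons, promoter_window))
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(HEADER + "\n")
        for gene in genes:
            iv = gene.interval
            strand = iv.strand if iv.strand in ("+", "-") else "."
            fh.write(
                f"{iv.chrom}\tpcgloop\tgene\t{iv.start + 1}\t{iv.end}\t.\t{strand}\t.\t"
                f"ID={gene.gene_id}\n"
            )
            for i, exon in enumerate(gene.exons, start=1):
                fh.write(
                    f"{exon.chrom}\tpcgloop\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{strand}\t.\tID={gene.gene_id}.exon{i};Parent={gene.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a bedGraph into a :class:`SignalTrack`.

    Unsorted input is accepted (sorted on load); overlapping intervals
    raise an error, since a coverage density is single-valued per base.
    """
    records: list[tuple[GenomicInterval, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: fewer than 4 bedGraph fields")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                value = float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            records.append((iv, value))
    return SignalTrack(records)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(HEADER + "\n")
        for iv, value in track:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")
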