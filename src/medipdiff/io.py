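"""Readers and writers for the standard formats.

Coordinate conventions at the boundary: BED is native 0-based half-open and
passes through unchanged; GTF/GFF is 1-based closed and is converted on
read (start - 1). All tables are TSV with headers.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import Gene
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Genome FASTA -> {chrom: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(assembly: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in assembly.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3/BED6 -> DataFrame with 0-based half-open coordinates (native)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: malformed BED line (fewer than 3 fields)")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            if end <= start or start < 0:
                raise ValueError(f"{path}:{ln}: invalid interval [{start}, {end})")
            row = {"chrom": parts[0], "start": start, "end": end}
            for i, col in enumerate(("name", "score", "strand"), start=3):
                if len(parts) > i:
                    row[col] = parts[i]
            rows.append(row)
    return pd.DataFrame(rows)


def write_bed(
    intervals: Iterable[GenomicInterval] | pd.DataFrame,
    path: str | Path,
    *,
    names: Sequence[str] | None = None,
    header_comment: str | None = None,
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        if isinstance(intervals, pd.DataFrame):
            intervals.to_csv(fh, sep="\t", header=False, index=False)
            return
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"region_{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_gtf(path: str | Path) -> list[Gene]:
    """GTF/GFF gene models -> list of Gene (converted to 0-based half-open).

    Tolerant of gene_id/transcript_id dialects via gffutils; genes are
    inferred from transcripts/exons when no explicit gene features exist.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=False,
        disable_infer_transcripts=False,
    )
    genes: list[Gene] = []
    for g in db.features_of_type("gene"):
        gene_id = g.attributes.get("gene_id", [g.id])[0]
        exons = sorted(
            (e.start - 1, e.end)
            for e in db.children(g, featuretype="exon")
        )
        genes.append(
            Gene(
                gene_id=gene_id,
                chrom=g.seqid,
                start=g.start - 1,
                end=g.end,
                strand=g.strand if g.strand in ("+", "-") else ".",
                exons=exons,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gtf(genes: Iterable[Gene], path: str | Path, *, source: str = "medipdiff") -> None:
    """Write gene models as GTF (1-based closed on output)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\t{source}\ttranscript\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def read_counts(path: str | Path) -> pd.DataFrame:
    """Window count TSV (chrom, start, end, then one column per sample)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


def write_counts(df: pd.DataFrame, path: str | Path, *, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene expression TSV indexed by gene_id, with optional de_flag/silent columns."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'gene_id'")
    df = df.set_index("gene_id")
    if "silent" in df.columns:
        df["silent"] = df["silent"].astype(bool)
    return df


def write_expression(df: pd.DataFrame, path: str | Path, *, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=True)


def read_placements(path: str | Path) -> pd.DataFrame:
    """BED-like placements with a sample_id column (4th or named).

    Accepts either a 4+-column BED whose name field is the sample id, or a
    TSV with an explicit header containing chrom/start/end/sample_id.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("chrom"):
        df = pd.read_csv(path, sep="\t")
    else:
        df = read_bed(path)
        if "name" not in df.columns:
            raise ValueError(f"{path}: placements need a 4th column with the sample id")
        df = df.rename(columns={"name": "sample_id"})
    missing = {"chrom", "start", "end", "sample_id"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df[["chrom", "start", "end", "sample_id"]]


def write_placements(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "sample_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )
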