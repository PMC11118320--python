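"""Readers and writers for the plain-text genomic formats the pipeline touches.

Supported inputs: BED3/BED6 and ENCODE narrowPeak peak files, a two-column
genome layout TSV (chrom, length), a gene annotation TSV (gene_id, chrom,
strand, tss, biotype) and a minimal GFF3 converter for deriving that table.
All coordinates are emitted and stored 0-based half-open; 1-based dialects
are converted at the reader boundary.
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .intervals import GeneModel, GenomeLayout, IntervalSet


class ParseError(ValueError):
    """Malformed record in a genomic text file (message names the line)."""


_SKIP_PREFIXES = ("track", "browser", "#")

_NARROWPEAK_COLS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signalValue", "pValue", "qValue", "peak",
]


def read_peak_records(path, fmt: str = "bed") -> pd.DataFrame:
    """Read BED or narrowPeak records, preserving extra columns.

    Header, track and comment lines are skipped.  Coordinates are validated
    per record; malformed lines raise :class:`ParseError` naming the line
    number.  The returned frame keeps records in file order without merging.
    """
    if fmt not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown format {fmt!r}; expected 'bed' or 'narrowPeak'")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if fmt == "narrowPeak" and len(fields) != 10:
                raise ParseError(
                    f"{path}: line {lineno}: narrowPeak requires 10 columns, "
                    f"got {len(fields)}"
                )
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: need >= 3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from None
            if start < 0 or start >= end:
                raise ParseError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            rows.append([fields[0], start, end, *fields[3:]])
    ncol = max((len(r) for r in rows), default=3)
    if fmt == "narrowPeak":
        columns = _NARROWPEAK_COLS
    else:
        columns = ["chrom", "start", "end", "name", "score", "strand"][:ncol]
        columns += [f"col{i}" for i in range(len(columns), ncol)]
    rows = [r + [None] * (len(columns) - len(r)) for r in rows]
    return pd.DataFrame(rows, columns=columns)


def read_intervals(path, fmt: str = "bed") -> IntervalSet:
    """Read a peak file as a normalized (merged) :class:`IntervalSet`."""
    df = read_peak_records(path, fmt=fmt)
    return IntervalSet(zip(df["chrom"], df["start"], df["end"]))


def write_intervals(iset: IntervalSet, path) -> None:
    """Write an IntervalSet as BED3 in canonical order."""
    with open(path, "w") as fh:
        for iv in iset.intervals():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_genome_layout(path) -> GenomeLayout:
    """Two-column TSV (chrom, length), no header."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: need 2 columns")
            try:
                lengths[fields[0]] = int(fields[1])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer length"
                ) from None
    return GenomeLayout(lengths)


def write_genome_layout(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in layout.items():
            fh.write(f"{chrom}\t{length}\n")


GENE_TABLE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "biotype"]


def read_gene_table(path) -> list[GeneModel]:
    """Gene annotation TSV with header gene_id, chrom, strand, tss, biotype."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return [
        GeneModel(
            gene_id=row.gene_id,
            chrom=row.chrom,
            strand=row.strand,
            tss=int(row.tss),
            biotype=row.biotype,
        )
        for row in df.itertuples()
    ]


def write_gene_table(genes: Sequence[GeneModel], path) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand, g.tss, g.biotype) for g in genes],
        columns=GENE_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def genes_from_gff3(path, feature: str = "gene") -> list[GeneModel]:
    """Minimal GFF3 converter: extracts gene_id, strand, biotype and TSS.

    Only the fields needed for promoter analytics are parsed.  GFF3 is
    1-based inclusive; the TSS is converted to a 0-based position (start-1
    for + strand, end-1 for - strand).
    """
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: line {lineno}: need 9 columns")
            if fields[2] != feature:
                continue
            chrom, start, end, strand = (
                fields[0], int(fields[3]), int(fields[4]), fields[6],
            )
            attrs = {}
            for item in fields[8].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k.strip()] = v.strip()
            gene_id = attrs.get("gene_id") or attrs.get("ID")
            if gene_id is None:
                raise ParseError(f"{path}: line {lineno}: no gene_id/ID attribute")
            tss = start - 1 if strand == "+" else end - 1
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    tss=tss,
                    biotype=attrs.get("gene_biotype", attrs.get("biotype", "")),
                )
            )
    return genes


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
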