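"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython; the remaining formats (BED3, minimal VCF,
marker TSV, BEDPE-like pair TSV) are simple tab-separated tables handled
with pandas. Coordinates on disk follow each format's convention (BED and
pair tables 0-based half-open; VCF 1-based) and are converted here, once.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import ContigRecord, ContigSet, GenomicInterval

PAIR_COLUMNS = [
    "pair_id",
    "contig1", "start1", "end1", "strand1",
    "contig2", "start2", "end2", "strand2",
]

MARKER_COLUMNS = [
    "marker", "map", "linkage_group", "map_position",
    "contig", "contig_pos", "strand",
]


def read_fasta(path: str | Path) -> ContigSet:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        records.append(ContigRecord(rec.id, len(seq), seq))
    return ContigSet(records)


def write_fasta(contigs: ContigSet, path: str | Path, width: int = 80) -> None:
    recs = [
        SeqRecord(Seq(contigs.sequence_of(cid)), id=cid, description="")
        for cid in contigs.ids
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(recs)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            contig, start, end = line.split("\t")[:3]
            out.append(GenomicInterval(contig, int(start), int(end)))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Minimal VCF reader: CHROM/POS/ID/REF/ALT/QUAL columns, POS converted
    to 0-based ``pos``."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            rows.append((f[0], int(f[1]) - 1, f[3], f[4], float(f[5])))
    return pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "qual"])


def write_vcf(variants: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in variants.itertuples(index=False):
            fh.write(
                f"{row.contig}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t"
                f"{row.qual:.2f}\t.\t.\n"
            )


def read_pairs(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"contig1": str, "contig2": str})


def write_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_markers(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "linkage_group": str})
    missing = set(MARKER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"marker table missing columns: {sorted(missing)}")
    return df


def write_markers(markers: pd.DataFrame, path: str | Path) -> None:
    markers.to_csv(path, sep="\t", index=False)
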