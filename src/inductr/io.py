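"""Readers and writers for the pipeline's on-disk formats.

All tables are plain TSV. Depth tables use the samtools-depth dialect
(contig, 1-based position, depth); regions travel as BED (0-based,
half-open) with optional completeness in column 5; alignment blocks use the
BLAST tabular dialect (qid, sid, pident, qstart, qend, sstart, send —
1-based inclusive). FASTA goes through Biopython.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from inductr.regions import ProphageRegion


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_depth_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["contig", "pos", "depth"]
    )


def write_depth_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df[["contig", "pos", "depth"]].to_csv(path, sep="\t", header=False, index=False)


def read_regions_bed(path: str | Path) -> list[ProphageRegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            completeness = None
            if len(fields) >= 5 and fields[4] not in (".", ""):
                completeness = float(fields[4])
            regions.append(
                ProphageRegion(
                    contig_id=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    region_id=fields[3] if len(fields) >= 4 else "",
                    completeness=completeness,
                )
            )
    return regions


def write_regions_bed(regions: list[ProphageRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            score = "." if r.completeness is None else f"{r.completeness:g}"
            fh.write(f"{r.contig_id}\t{r.start}\t{r.end}\t{r.region_id}\t{score}\n")


BLAST_COLUMNS = ["qid", "sid", "pident", "qstart", "qend", "sstart", "send"]


def read_blast_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df = df.iloc[:, : len(BLAST_COLUMNS)]
    df.columns = BLAST_COLUMNS
    return df


def write_blast_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df[BLAST_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
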