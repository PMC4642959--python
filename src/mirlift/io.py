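"""FASTA/FASTQ/GFF3/BED input-output helpers.

Sequence sets move through the pipeline as ordered ``dict[str, str]``
(name -> sequence); Biopython handles the on-disk formats.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> uppercase-sequence dict."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: dict[str, str], path: str | os.PathLike) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def iter_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str, str]]:
    """Yield (read id, sequence, Phred+33 quality string) from a FASTQ file."""
    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield title.split()[0], seq.upper(), qual


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for name, seq, qual in reads:
            handle.write(f"@{name}\n{seq}\n+\n{qual}\n")


def mean_quality(qual: str) -> float:
    """Mean Phred score of a +33-encoded quality string."""
    if not qual:
        return 0.0
    return (sum(qual.encode("ascii")) - 33 * len(qual)) / len(qual)


def write_gff3(rows: Iterable[dict], path: str | os.PathLike) -> None:
    """Write annotation rows as GFF3 (1-based inclusive coordinates).

    Each row needs: chrom, start, end (0-based half-open), strand, name and
    optional extra attribute keys under ``attributes``.
    """
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for row in rows:
            attrs = {"ID": row["name"], "Name": row["name"], **row.get("attributes", {})}
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
            handle.write(
                "\t".join(
                    [
                        row["chrom"],
                        "mirlift",
                        row.get("feature", "miRNA_primary_transcript"),
                        str(row["start"] + 1),
                        str(row["end"]),
                        ".",
                        row["strand"],
                        ".",
                        attr_str,
                    ]
                )
                + "\n"
            )


def write_bed(rows: Iterable[dict], path: str | os.PathLike) -> None:
    """Write annotation rows as 6-column BED (0-based half-open)."""
    with open(path, "w") as handle:
        for row in rows:
            handle.write(
                "\t".join(
                    [
                        row["chrom"],
                        str(row["start"]),
                        str(row["end"]),
                        row["name"],
                        str(row.get("score", 0)),
                        row["strand"],
                    ]
                )
                + "\n"
            )
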