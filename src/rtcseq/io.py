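"""Readers and writers for the plain-text formats the pipeline speaks.

FASTA/FASTQ go through Biopython; BED, bedGraph and the TSV tables are
simple enough to stream directly.  BED and bedGraph are 0-based
half-open on disk and converted to 1-based inclusive coordinates in
memory (see :mod:`rtcseq.types`).
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import CoverageProfile, DomainAnnotation, KineticsSeries, TranscriptRecord


# ---------------------------------------------------------------------------
# FASTA / class table

def write_fasta(transcripts: Sequence[TranscriptRecord], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.id, description=f"class={t.rna_class}")
        for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike, classes: Mapping[str, str] | None = None) -> list[TranscriptRecord]:
    """Read transcripts; class labels come from ``classes`` or from a
    ``class=...`` token in the FASTA description (default ``CDS``)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rna_class = None
        if classes is not None:
            rna_class = classes.get(rec.id)
        if rna_class is None:
            for token in rec.description.split():
                if token.startswith("class="):
                    rna_class = token.split("=", 1)[1]
        out.append(TranscriptRecord(rec.id, str(rec.seq), rna_class or "CDS"))
    return out


def write_class_tsv(transcripts: Sequence[TranscriptRecord], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"transcript_id": [t.id for t in transcripts],
         "rna_class": [t.rna_class for t in transcripts],
         "length": [t.length for t in transcripts]}
    ).to_csv(path, sep="\t", index=False)


def read_class_tsv(path: str | os.PathLike) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["transcript_id"], df["rna_class"]))


# ---------------------------------------------------------------------------
# BED (6-column) for domain annotations

def write_bed(domains: Sequence[DomainAnnotation], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for d in domains:
            # 1-based inclusive -> 0-based half-open
            fh.write(f"{d.transcript_id}\t{d.start - 1}\t{d.end}\t{d.name}\t0\t+\n")


def read_bed(path: str | os.PathLike) -> list[DomainAnnotation]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            out.append(DomainAnnotation(chrom, name, start + 1, end))
    return out


# ---------------------------------------------------------------------------
# bedGraph coverage

def write_bedgraph(profiles: Iterable[CoverageProfile], path: str | os.PathLike) -> None:
    """Write per-position counts, run-length-collapsed; zero runs are
    omitted (absent positions read back as 0)."""
    with open(path, "w") as fh:
        for p in profiles:
            counts = np.asarray(p.counts)
            if counts.size == 0:
                continue
            changes = np.flatnonzero(np.diff(counts)) + 1
            starts = np.concatenate([[0], changes])
            ends = np.concatenate([changes, [counts.size]])
            for s, e in zip(starts, ends):
                v = counts[s]
                if v != 0:
                    fh.write(f"{p.transcript_id}\t{s}\t{e}\t{v}\n")


def read_bedgraph(path: str | os.PathLike) -> list[tuple[str, int, int, float]]:
    """Raw bedGraph records (chrom, 0-based start, end, value)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            out.append((chrom, int(start), int(end), float(value)))
    return out


# ---------------------------------------------------------------------------
# FASTQ

def write_fastq(reads: Sequence[tuple[str, str]], path: str | os.PathLike, quality_char: str = "I") -> None:
    """Write (read_id, sequence) pairs with constant Phred+33 quality."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# kinetics / Miller tables

def write_kinetics_tsv(series: KineticsSeries, path: str | os.PathLike) -> None:
    pd.DataFrame({"time_s": series.time, "signal": series.signal}).to_csv(
        path, sep="\t", index=False
    )


def read_kinetics_tsv(path: str | os.PathLike, background: float = 0.0) -> KineticsSeries:
    df = pd.read_csv(path, sep="\t")
    return KineticsSeries(df["time_s"].to_numpy(), df["signal"].to_numpy(), background)
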