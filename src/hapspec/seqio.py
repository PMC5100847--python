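"""Reading and writing the file formats the pipeline touches.

All parsing is centralised here: FASTA and FASTQ (via Biopython, with
validation layered on top), the two-column k-mer ``histo`` dialect written
by the common k-mer counters, BED3 interval tables, and TSV tables.

Conventions
-----------
* Sequences are uppercased on read; characters outside {A,C,G,T,N} (IUPAC
  ambiguity codes and stray symbols) are mapped to N and the number of such
  replacements is logged as a warning.
* Gzip compression is detected from the two magic bytes, never the file
  extension.
* Intervals are 0-based half-open internally (BED convention).
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import IO, Iterable

import pandas as pd
from Bio import SeqIO

from .records import KmerHistogram, ReadRecord, SequenceRecord

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
_TO_N = str.maketrans(
    {c: "N" for c in map(chr, range(65, 91)) if c not in _VALID}
)


class ParseError(ValueError):
    """A malformed input file."""


def _open_text(path: str | Path) -> IO[str]:
    """Open possibly-gzipped text, sniffing the gzip magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sanitize(seq: str, rec_id: str, counter: list[int]) -> str:
    seq = seq.upper()
    n_bad = sum(1 for c in seq if c not in _VALID)
    if n_bad:
        counter[0] += n_bad
        seq = seq.translate(_TO_N)
        if any(c not in _VALID for c in seq):
            bad = sorted({c for c in seq if c not in _VALID})
            raise ParseError(f"record {rec_id!r}: unexpected characters {bad}")
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file.

    Raises
    ------
    ParseError
        On an empty sequence or a duplicate record id.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    replaced = [0]
    with _open_text(path) as fh:
        for i, rec in enumerate(SeqIO.parse(fh, "fasta"), start=1):
            if not rec.id:
                raise ParseError(f"{path}: record {i} has an empty id")
            if rec.id in seen:
                raise ParseError(f"{path}: duplicate sequence id {rec.id!r} (record {i})")
            seq = _sanitize(str(rec.seq), rec.id, replaced)
            if not seq:
                raise ParseError(f"{path}: record {rec.id!r} (record {i}) has an empty sequence")
            seen.add(rec.id)
            records.append(SequenceRecord(rec.id, seq, rec.description[len(rec.id):].strip()))
    if replaced[0]:
        logger.warning("%s: replaced %d non-ACGTN characters with N", path, replaced[0])
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, line_width: int = 60
) -> None:
    """Write records as FASTA with fixed line width (round-trips with read_fasta)."""
    if line_width < 1:
        raise ValueError("line_width must be positive")
    with open(path, "wt") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), line_width):
                fh.write(rec.sequence[i : i + line_width] + "\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Read a (possibly gzipped) 4-line FASTQ file with Sanger qualities."""
    reads: list[ReadRecord] = []
    replaced = [0]
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
                seq = _sanitize(str(rec.seq), rec.id, replaced)
                reads.append(ReadRecord(rec.id, seq, qual))
        except ValueError as exc:  # Biopython flags seq/quality length mismatch
            raise ParseError(f"{path}: {exc}") from exc
    if replaced[0]:
        logger.warning("%s: replaced %d non-ACGTN characters with N", path, replaced[0])
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def read_kmer_histogram(path: str | Path) -> KmerHistogram:
    """Read the two-column whitespace ``multiplicity  n_kmers`` histogram dialect.

    Multiplicities must be strictly increasing positive integers.
    """
    counts: dict[int, int] = {}
    last = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
            try:
                m, n = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field") from exc
            if m <= last:
                raise ParseError(
                    f"{path}:{lineno}: multiplicity {m} not strictly increasing"
                )
            if n < 0:
                raise ParseError(f"{path}:{lineno}: negative k-mer count")
            counts[m] = n
            last = m
    return KmerHistogram(counts)


def write_kmer_histogram(hist: KmerHistogram, path: str | Path) -> None:
    with open(path, "wt") as fh:
        for m in sorted(hist.counts):
            fh.write(f"{m} {hist.counts[m]}\n")


def read_bed3(path: str | Path) -> pd.DataFrame:
    """Read BED3(+1) intervals: chrom, start, end[, name]; 0-based half-open."""
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or end < start:
                raise ParseError(f"{path}:{lineno}: bad interval [{start}, {end})")
            name = parts[3] if len(parts) > 3 else ""
            rows.append((parts[0], start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV table with a header row."""
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
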