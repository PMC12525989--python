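"""Sequence I/O and coordinate utilities shared by the whole pipeline.

All internal coordinates are 0-based half-open. Every text output (BED
start excepted, which is 0-based by convention; VCF and TSV position
columns) is 1-based inclusive. Sequences are stored as uppercase strings
over the alphabet {A, C, G, T, N}.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MIN_READ_LEN = 30


class SeqIOError(ValueError):
    """Malformed sequence input (bad FASTA/FASTQ, duplicate ids, ...)."""


@dataclass
class Genome:
    """An ordered collection of chromosome sequences.

    The coordinate frame for everything downstream: oligos, windows,
    variants and markers all refer to (chrom_id, 0-based offset) in this
    object.
    """

    records: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c for c, _ in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            for c in ids:
                if c in seen:
                    raise SeqIOError(f"duplicate id {c}")
                seen.add(c)
        for c, s in self.records:
            if not s:
                raise SeqIOError(f"empty sequence for record {c}")

    @property
    def chrom_ids(self) -> list[str]:
        return [c for c, _ in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records)

    def seq(self, chrom: str) -> str:
        for c, s in self.records:
            if c == chrom:
                return s
        raise KeyError(chrom)

    def total_length(self) -> int:
        return sum(len(s) for _, s in self.records)

    def group_of(self, chrom: str) -> int:
        """1-based index of a chromosome; stands in for the homoeologous
        group number (group g = g-th chromosome of the reference)."""
        for i, (c, _) in enumerate(self.records):
            if c == chrom:
                return i + 1
        raise KeyError(chrom)


@dataclass
class Read:
    """A single short read. Mates of a pair are carried independently."""

    id: str
    sequence: str
    mate: int | None = None  # 1 or 2 for paired data

    def __len__(self) -> int:
        return len(self.sequence)


def _open_maybe_gzip(path: str | Path) -> io.TextIOBase:
    """Open text, sniffing gzip by magic bytes rather than extension."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def sanitize_sequence(seq: str) -> tuple[str, int]:
    """Uppercase and map any character outside {A,C,G,T,N} to N.

    Returns the cleaned sequence and the number of substituted characters.
    """
    seq = seq.upper()
    if set(seq) <= DNA_ALPHABET:
        return seq, 0
    cleaned = "".join(c if c in DNA_ALPHABET else "N" for c in seq)
    n_sub = sum(1 for a, b in zip(seq, cleaned) if a != b)
    return cleaned, n_sub


def read_fasta(path: str | Path) -> Genome:
    """Read a (possibly gzipped) FASTA file into a Genome.

    Sequences are uppercased; non-ACGTN characters become N (count is
    logged). Duplicate record ids and empty files are hard errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    name: str | None = None
    chunks: list[str] = []
    n_sub_total = 0

    def _flush() -> None:
        nonlocal n_sub_total
        if name is None:
            return
        seq, n_sub = sanitize_sequence("".join(chunks))
        n_sub_total += n_sub
        if not seq:
            raise SeqIOError(f"empty sequence for record {name}")
        records.append((name, seq))

    with _open_maybe_gzip(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise SeqIOError("FASTA record with empty id")
                if name in seen:
                    raise SeqIOError(f"duplicate id {name}")
                seen.add(name)
                chunks = []
            else:
                if name is None:
                    raise SeqIOError(f"sequence data before first header in {path}")
                chunks.append(line)
        _flush()
    if not records:
        raise SeqIOError(f"no FASTA records in {path}")
    if n_sub_total:
        logger.info("read_fasta(%s): %d non-ACGTN characters mapped to N", path, n_sub_total)
    return Genome(records)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "wt") as fh:
        for chrom, seq in genome:
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path, min_len: int = MIN_READ_LEN) -> Iterator[Read]:
    """Stream reads from a (possibly gzipped) FASTQ file.

    Reads shorter than ``min_len`` are skipped (count logged). Truncated
    records or length-mismatched quality strings are hard errors with the
    offending line number. Mate flags are taken from trailing /1, /2 id
    suffixes when present.
    """
    n_short = 0
    n_total = 0
    with _open_maybe_gzip(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                break
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise SeqIOError(f"{path}: expected '@' header at line {lineno}")
            seq_line = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise SeqIOError(f"{path}: truncated FASTQ record at line {lineno}")
            lineno += 3
            if not plus.startswith("+"):
                raise SeqIOError(f"{path}: expected '+' separator at line {lineno - 1}")
            if len(seq_line) != len(qual):
                raise SeqIOError(
                    f"{path}: sequence/quality length mismatch at line {lineno}"
                )
            n_total += 1
            rid = header[1:].split()[0] if len(header) > 1 else f"read{n_total}"
            mate: int | None = None
            if rid.endswith("/1"):
                mate, rid = 1, rid[:-2]
            elif rid.endswith("/2"):
                mate, rid = 2, rid[:-2]
            seq, _ = sanitize_sequence(seq_line)
            if len(seq) < min_len:
                n_short += 1
                continue
            yield Read(rid, seq, mate)
    if n_total == 0:
        logger.warning("read_fastq(%s): empty file", path)
    if n_short:
        logger.info("read_fastq(%s): skipped %d reads shorter than %d nt", path, n_short, min_len)


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution."""
    if not set(seq) <= DNA_ALPHABET:
        bad = sorted(set(seq) - DNA_ALPHABET)
        raise SeqIOError(f"non-DNA characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Tabular / interval output helpers (BED, TSV, minimal VCF)
# ---------------------------------------------------------------------------

def write_bed(intervals: Sequence[tuple], path: str | Path) -> None:
    """Write 6-column BED: (chrom, start0, end, name, score, strand)."""
    with open(path, "wt") as fh:
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def write_tsv(rows: Sequence[Sequence], header: Sequence[str], path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth at site">\n'
    '##INFO=<ID=AF,Number=1,Type=Float,Description="Supporting allele fraction">\n'
    '##INFO=<ID=TYPE,Number=1,Type=String,Description="SNP, INS or DEL">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def write_vcf(variants: Sequence, path: str | Path) -> None:
    """Write a minimal 8-column VCF. ``variants`` are noref.Variant objects
    (duck-typed: chrom, pos [1-based], ref_allele, alt_allele, vclass,
    depth, allele_fraction)."""
    with open(path, "wt") as fh:
        fh.write(VCF_HEADER)
        for i, v in enumerate(variants):
            info = f"DP={v.depth};AF={v.allele_fraction:.3f};TYPE={v.vclass}"
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.chrom}_{v.pos}_{i}\t{v.ref_allele}\t"
                f"{v.alt_allele}\t.\tPASS\t{info}\n"
            )


def read_vcf(path: str | Path) -> list[tuple[str, int, str, str]]:
    """Read the minimal VCF back as (chrom, pos1, ref, alt) tuples."""
    out = []
    with _open_maybe_gzip(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), f[3], f[4]))
    return out
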