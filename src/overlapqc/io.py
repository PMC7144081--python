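"""Reading and writing of sequence formats.

Everything the pipeline touches is normalized to :class:`SequenceRecord`:
uppercase bases over ``{A, C, G, T, N}``, optional Phred qualities as a
``uint8`` array. FASTA, FASTQ (Phred+33, optionally gzip-compressed) and
unaligned BAM/SAM are supported; alignment information in BAM input is
ignored, only sequence and qualities are read.

All coordinates in this package are 0-based, half-open.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
MAX_PHRED = 93

# uppercase + U->T; anything else (incl. IUPAC ambiguity codes) becomes N
_NORMALIZE = bytes.maketrans(
    bytes(range(256)),
    bytes(
        ord(chr(c).upper()) if chr(c).upper() in "ACGTN" else (ord("T") if chr(c).upper() == "U" else ord("N"))
        for c in range(256)
    ),
)


@dataclass
class SequenceRecord:
    """One long read.

    Parameters
    ----------
    read_id
        Unique identifier within one dataset pass.
    seq
        Uppercase sequence over ``{A,C,G,T,N}``.
    quals
        Optional Phred values (one per base, each in ``[0, 93]``);
        ``None`` for FASTA input.
    """

    read_id: str
    seq: str
    quals: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be non-empty")
        if self.quals is not None:
            self.quals = np.asarray(self.quals, dtype=np.uint8)
            if len(self.quals) != len(self.seq):
                raise ValueError(
                    f"record {self.read_id!r}: {len(self.quals)} quality values "
                    f"for {len(self.seq)} bases"
                )
            if self.quals.size and self.quals.max() > MAX_PHRED:
                raise ValueError(f"record {self.read_id!r}: Phred value above {MAX_PHRED}")

    @property
    def length(self) -> int:
        return len(self.seq)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequenceRecord):
            return NotImplemented
        if self.read_id != other.read_id or self.seq != other.seq:
            return False
        if (self.quals is None) != (other.quals is None):
            return False
        return self.quals is None or bool(np.array_equal(self.quals, other.quals))


def normalize_seq(raw: str) -> str:
    """Uppercase, map U->T, and replace non-ACGTN characters with N."""
    return raw.encode("ascii", errors="replace").translate(_NORMALIZE).decode("ascii")


class FormatError(ValueError):
    """Unreadable or malformed sequence file."""


def sniff_format(path: str | Path) -> str:
    """Guess the file format from extension and magic bytes.

    Returns one of ``fasta``, ``fastq``, ``bam``, ``sam``.
    """
    path = Path(path)
    name = path.name.lower()
    for suffix, fmt in ((".bam", "bam"), (".sam", "sam")):
        if name.endswith(suffix):
            return fmt
    stripped = name[:-3] if name.endswith(".gz") else name
    if stripped.endswith((".fq", ".fastq")):
        return "fastq"
    if stripped.endswith((".fa", ".fasta", ".fna")):
        return "fasta"
    # fall back on content
    opener = gzip.open if _is_gzip(path) else open
    try:
        with opener(path, "rt") as fh:
            first = fh.read(1)
    except (OSError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise FormatError(f"cannot determine sequence format of {path}")


def _is_gzip(path: Path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def read_sequences(
    path: str | Path,
    format_hint: Optional[str] = None,
) -> Iterator[SequenceRecord]:
    """Stream records from a FASTA/FASTQ(.gz) or unaligned BAM/SAM file.

    Bases are uppercased, U mapped to T and other non-ACGTN characters
    replaced by N (counted and logged). FASTQ/BAM qualities are decoded
    to Phred integers; FASTA records carry no qualities.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint or sniff_format(path)
    if fmt in ("bam", "sam"):
        yield from _read_bam(path)
    elif fmt == "fastq":
        yield from _read_fastq(path)
    elif fmt == "fasta":
        yield from _read_fasta(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _open_text(path: Path):
    return gzip.open(path, "rt") if _is_gzip(path) else open(path, "rt")


def _count_replacements(raw: str, clean: str) -> int:
    return sum(1 for a, b in zip(raw.upper().replace("U", "T"), clean) if a != b)


def _read_fasta(path: Path) -> Iterator[SequenceRecord]:
    from Bio import SeqIO

    n_replaced = 0
    with _open_text(path) as fh:
        for i, rec in enumerate(SeqIO.parse(fh, "fasta")):
            if not rec.id:
                raise FormatError(f"{path}: record {i + 1} has an empty id")
            raw = str(rec.seq)
            seq = normalize_seq(raw)
            n_replaced += _count_replacements(raw, seq)
            yield SequenceRecord(rec.id, seq)
    if n_replaced:
        logger.info("%s: replaced %d non-ACGTN characters with N", path, n_replaced)


def _read_fastq(path: Path) -> Iterator[SequenceRecord]:
    n_replaced = 0
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                break
            lineno += 1
            if not header.startswith("@"):
                raise FormatError(f"{path}:{lineno}: expected '@' header, got {header[:20]!r}")
            seq_line = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual_line = fh.readline().rstrip("\n")
            if not qual_line and not plus:
                raise FormatError(f"{path}:{lineno}: truncated FASTQ record")
            lineno += 3
            if len(seq_line) != len(qual_line):
                raise FormatError(
                    f"{path}:{lineno}: sequence length {len(seq_line)} != "
                    f"quality length {len(qual_line)}"
                )
            read_id = header[1:].split()[0] if len(header) > 1 else ""
            if not read_id:
                raise FormatError(f"{path}:{lineno - 3}: record has an empty id")
            seq = normalize_seq(seq_line)
            n_replaced += _count_replacements(seq_line, seq)
            quals = np.frombuffer(qual_line.encode("ascii"), dtype=np.uint8) - 33
            yield SequenceRecord(read_id, seq, quals)
    if n_replaced:
        logger.info("%s: replaced %d non-ACGTN characters with N", path, n_replaced)


def _read_bam(path: Path) -> Iterator[SequenceRecord]:
    import pysam

    save = pysam.set_verbosity(0)  # silence missing-index warning
    try:
        with pysam.AlignmentFile(str(path), check_sq=False) as bam:
            for i, rec in enumerate(bam):
                if rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.query_sequence is None:
                    raise FormatError(
                        f"{path}: record {rec.query_name or i + 1} has no sequence ('*')"
                    )
                seq = normalize_seq(rec.query_sequence)
                quals = None
                if rec.query_qualities is not None:
                    quals = np.asarray(rec.query_qualities, dtype=np.uint8)
                yield SequenceRecord(rec.query_name, seq, quals)
    finally:
        pysam.set_verbosity(save)


def write_fastx(
    records: Iterable[SequenceRecord],
    path: str | Path,
    format: str = "fastq",
    fill_q: Optional[int] = None,
) -> int:
    """Write records as FASTA or FASTQ (gzip if the path ends in .gz).

    Writing FASTQ from records without qualities is an error unless
    ``fill_q`` provides an explicit constant Phred fill — confidence is
    never fabricated silently.

    Returns the number of records written.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"format must be 'fasta' or 'fastq', got {format!r}")
    path = Path(path)
    opener = gzip.open if path.name.endswith(".gz") else open
    n = 0
    with opener(path, "wt") as fh:
        for rec in records:
            if format == "fasta":
                fh.write(f">{rec.read_id}\n{rec.seq}\n")
            else:
                quals = rec.quals
                if quals is None:
                    if fill_q is None:
                        raise ValueError(
                            f"record {rec.read_id!r} has no qualities; pass fill_q "
                            "to write FASTQ from quality-less records"
                        )
                    quals = np.full(rec.length, fill_q, dtype=np.uint8)
                qual_str = (quals + 33).astype(np.uint8).tobytes().decode("ascii")
                fh.write(f"@{rec.read_id}\n{rec.seq}\n+\n{qual_str}\n")
            n += 1
    return n


def write_tsv(frame, path: str | Path) -> None:
    """Write a per-read table as TSV with '.' for missing values."""
    frame.to_csv(path, sep="\t", index=False, na_rep=".")
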