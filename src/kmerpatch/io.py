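"""Shared I/O: FASTA/FASTQ (plain or gzip), k-mer table TSV, run manifests.

All coordinates in written artifacts are 0-based, half-open (BED
convention). Gzip is detected from magic bytes, not extensions, on input;
on output a ``.gz`` suffix selects compression.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, IO, Iterable, List, Optional, Tuple, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .kmer_core import KmerCountTable, canonical

__all__ = [
    "FormatError",
    "RunManifest",
    "open_text",
    "read_fasta",
    "read_fastq",
    "read_kmer_table",
    "read_sequences",
    "write_fasta",
    "write_fastq",
    "write_kmer_table",
]

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Malformed input file content."""


def open_text(path: PathLike, mode: str = "rt") -> IO[str]:
    """Open plain or gzipped text; gzip is sniffed from magic bytes.

    Gzip output omits the timestamp and filename header fields so reruns
    with identical content produce bit-identical files.
    """
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode)
        return open(path, mode)
    if path.suffix == ".gz":
        raw = gzip.GzipFile(fileobj=open(path, "wb"), mode="wb", mtime=0)
        import io as _io

        return _io.TextIOWrapper(raw)
    return open(path, mode)


def read_fasta(path: PathLike) -> List[SeqRecord]:
    """Read FASTA records (IDs, descriptions and sequences preserved)."""
    with open_text(path) as fh:
        try:
            return list(SeqIO.parse(fh, "fasta"))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc


def write_fasta(records: Iterable, path: PathLike, wrap: int = 80) -> None:
    """Write FASTA with configurable line wrap (default 80 columns).

    ``records`` may be Biopython ``SeqRecord`` objects or ``(id, seq)``
    pairs.
    """
    with open_text(path, "wt") as fh:
        for rec in records:
            if isinstance(rec, tuple):
                header, seq = rec
            else:
                header = rec.description if rec.description else rec.id
                seq = str(rec.seq)
            fh.write(f">{header}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def read_fastq(path: PathLike) -> List[SeqRecord]:
    """Read FASTQ records; malformed records raise with the record named."""
    with open_text(path) as fh:
        try:
            return list(SeqIO.parse(fh, "fastq"))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc


def write_fastq(reads: Iterable[Tuple[str, str]], path: PathLike) -> None:
    """Write ``(id, sequence)`` pairs as FASTQ with uniform quality."""
    with open_text(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_sequences(path: PathLike) -> List[SeqRecord]:
    """Read FASTA or FASTQ (sniffed from the first record character)."""
    with open_text(path) as fh:
        first = fh.read(1)
    if first == "@":
        return read_fastq(path)
    if first == ">":
        return read_fasta(path)
    if first == "":
        return []
    raise FormatError(f"{path}: not FASTA or FASTQ (starts with {first!r})")


def write_kmer_table(table: KmerCountTable, path: PathLike) -> None:
    """Write a k-mer table TSV: ``#k=<k>`` header, then sorted kmer/count."""
    with open_text(path, "wt") as fh:
        fh.write(f"#k={table.k}\n")
        for kmer in sorted(table.counts):
            fh.write(f"{kmer}\t{table.counts[kmer]}\n")


def read_kmer_table(path: PathLike) -> KmerCountTable:
    """Read a k-mer table TSV written by :func:`write_kmer_table`.

    Raises
    ------
    FormatError
        On a missing/invalid ``#k=`` header, keys whose length mismatches
        the header k, non-canonical keys, or unparsable counts — each named
        with its line number.
    """
    path = Path(path)
    with open_text(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#k="):
            raise FormatError(f"{path}:1: expected '#k=<k>' header, got {header!r}")
        try:
            k = int(header[3:])
        except ValueError as exc:
            raise FormatError(f"{path}:1: unparsable k in header {header!r}") from exc
        counts: Dict[str, int] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'kmer<TAB>count'")
            kmer, count_s = parts
            if len(kmer) != k:
                raise FormatError(
                    f"{path}:{lineno}: key {kmer!r} has length {len(kmer)}, "
                    f"header says k={k}"
                )
            if kmer != canonical(kmer):
                raise FormatError(f"{path}:{lineno}: key {kmer!r} is not canonical")
            try:
                counts[kmer] = int(count_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: unparsable count {count_s!r}"
                ) from exc
    try:
        return KmerCountTable(k, counts)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def sha256_file(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written next to every file-producing command.

    Timings are opt-in (``record_timings``) because wall-clock durations
    would break bit-identical reruns; everything else in the manifest is a
    pure function of the inputs and parameters.
    """

    tool: str = "kmerpatch"
    version: str = "0.1.0"
    command: str = ""
    parameters: Dict[str, object] = field(default_factory=dict)
    inputs: Dict[str, str] = field(default_factory=dict)  # path -> sha256
    seeds: Dict[str, int] = field(default_factory=dict)
    timings: Dict[str, float] = field(default_factory=dict)

    def add_input(self, path: PathLike) -> None:
        self.inputs[str(path)] = sha256_file(path)

    def to_json(self) -> str:
        payload = {
            "tool": self.tool,
            "version": self.version,
            "command": self.command,
            "parameters": self.parameters,
            "inputs": self.inputs,
            "seeds": self.seeds,
            "timings": self.timings,
        }
        return json.dumps(payload, sort_keys=True, indent=2) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        data = json.loads(text)
        return cls(**data)

    def write(self, path: PathLike) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def read(cls, path: PathLike) -> "RunManifest":
        return cls.from_json(Path(path).read_text())
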