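"""Reading and writing the package's on-disk formats.

Reads are represented in memory as ``(read_id, sequence)`` string pairs
throughout the package; FASTQ/FASTA parsing goes through Biopython and is
transparent to gzip compression.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

Read = tuple[str, str]

#: constant PHRED quality written for simulated/filtered FASTQ (Q30)
FASTQ_QUAL_CHAR = "?"


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def sniff_format(path: str | Path) -> str:
    """Guess 'fastq' or 'fasta' from the file name."""
    name = Path(path).name.lower()
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    if name.endswith((".fa", ".fasta", ".fna", ".ffn", ".faa")):
        return "fasta"
    raise ValueError(f"cannot infer sequence format from file name: {path}")


def read_sequences(path: str | Path, fmt: str | None = None) -> Iterator[Read]:
    """Yield ``(id, sequence)`` pairs from a FASTQ/FASTA file (gzip ok)."""
    fmt = fmt or sniff_format(path)
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, str(rec.seq).upper()


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    """Write reads as 4-line FASTQ with a constant quality string."""
    n = 0
    with _open_text(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{FASTQ_QUAL_CHAR * len(seq)}\n")
            n += 1
    return n


def write_fasta(records: Iterable[Read], path: str | Path) -> int:
    """Write ``(id, sequence)`` pairs as wrapped FASTA."""
    n = 0
    with _open_text(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> list[Read]:
    return list(read_sequences(path, "fasta"))


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample_id<TAB>group`` table (no header)."""
    labels: dict[str, str] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"labels file must have 2 tab-separated columns: {line!r}")
            sid, grp = fields
            if sid in labels:
                raise ValueError(f"duplicate sample id in labels file: {sid}")
            labels[sid] = grp
    return labels


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for sid, grp in labels.items():
            fh.write(f"{sid}\t{grp}\n")


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON dump (sorted keys, fixed separators)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
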