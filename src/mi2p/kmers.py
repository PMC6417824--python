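"""Canonical k-mer counting and the k-mer × sample count matrix.

Canonical means the lexicographically smaller of a k-mer and its reverse
complement, which makes counting independent of sequencing strand.  Counting
is done fully in memory with 2-bit encoded k-mer codes; this targets
cohort sizes of tens of samples at a few million reads each, not the
disk-based scale of dedicated counters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from . import io as _io
from ._encoding import (
    codes_to_kmers,
    concat_encode,
    kmer_to_code,
    window_codes,
)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonicalize(kmer: str) -> str:
    """Return the lexicographically smaller of ``kmer`` and its reverse complement.

    The k-mer must be over {A,C,G,T}; ambiguous bases must be filtered by the
    caller beforehand.
    """
    kmer = kmer.upper()
    if any(b not in "ACGT" for b in kmer):
        raise ValueError(f"cannot canonicalize k-mer with ambiguous bases: {kmer!r}")
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class SampleKmerCounts:
    """Canonical k-mer counts of one sample, kept as sorted code arrays."""

    k: int
    codes: np.ndarray  # int64, sorted unique canonical codes
    counts: np.ndarray  # int64, parallel to codes
    n_windows: int  # total valid windows counted
    n_reads: int  # reads seen (including ones shorter than k)

    def as_dict(self) -> dict[str, int]:
        return dict(zip(codes_to_kmers(self.codes, self.k), self.counts.tolist()))


def count_sample_codes(
    reads: Iterable[str | tuple[str, str]], k: int, chunk_bases: int = 4_000_000
) -> SampleKmerCounts:
    """Count canonical k-mers of one sample on the int64 code level.

    ``reads`` may be plain sequences or ``(read_id, sequence)`` pairs.
    Every length-k window over {A,C,G,T} contributes one count to its
    canonical k-mer; windows touching any other symbol are skipped.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    uniq_parts: list[np.ndarray] = []
    cnt_parts: list[np.ndarray] = []
    n_windows = 0
    n_reads = 0

    def flush(seqs: list[str]) -> None:
        nonlocal n_windows
        codes, _ = concat_encode(seqs)
        canon, valid = window_codes(codes, k)
        canon = canon[valid]
        n_windows += canon.size
        if canon.size:
            u, c = np.unique(canon, return_counts=True)
            uniq_parts.append(u)
            cnt_parts.append(c)

    buf: list[str] = []
    buf_bases = 0
    for r in reads:
        seq = r[1] if isinstance(r, tuple) else r
        n_reads += 1
        buf.append(seq)
        buf_bases += len(seq)
        if buf_bases >= chunk_bases:
            flush(buf)
            buf, buf_bases = [], 0
    if buf:
        flush(buf)

    if not uniq_parts:
        return SampleKmerCounts(k, np.empty(0, np.int64), np.empty(0, np.int64), 0, n_reads)
    allu = np.concatenate(uniq_parts)
    allc = np.concatenate(cnt_parts)
    u, inv = np.unique(allu, return_inverse=True)
    c = np.zeros(u.size, dtype=np.int64)
    np.add.at(c, inv, allc)
    return SampleKmerCounts(k, u, c, n_windows, n_reads)


def count_sample(reads: Iterable[str | tuple[str, str]], k: int) -> dict[str, int]:
    """Canonical k-mer → count map for one sample (string interface)."""
    return count_sample_codes(reads, k).as_dict()


@dataclass
class KmerCountMatrix:
    """Canonical k-mer × sample count matrix with per-sample read totals.

    ``codes`` holds the canonical k-mers as sorted base-4 integer codes;
    numeric order equals lexicographic order of the decoded strings.
    ``sample_read_totals`` carries the per-sample sequencing depth used for
    counts-per-million normalization; ``sample_window_totals`` records how
    many valid k-mer windows each sample contributed in total (before any
    prevalence filtering).
    """

    k: int
    codes: np.ndarray  # (n_kmers,) int64 sorted
    samples: list[str]
    counts: np.ndarray  # (n_kmers, n_samples) int64
    sample_read_totals: dict[str, int]
    sample_window_totals: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.codes.size, len(self.samples)):
            raise ValueError("counts shape does not match kmers × samples")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def kmers(self) -> list[str]:
        return codes_to_kmers(self.codes, self.k)

    @property
    def n_kmers(self) -> int:
        return int(self.codes.size)

    def to_tsv(self, path: str | Path) -> None:
        """Serialize as TSV (kmer + one column per sample) with a JSON sidecar."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("kmer\t" + "\t".join(self.samples) + "\n")
            kmers = self.kmers
            for i, km in enumerate(kmers):
                fh.write(km + "\t" + "\t".join(map(str, self.counts[i])) + "\n")
        _io.write_json(
            {
                "k": self.k,
                "sample_read_totals": self.sample_read_totals,
                "sample_window_totals": self.sample_window_totals,
            },
            path.with_suffix(path.suffix + ".json"),
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KmerCountMatrix":
        path = Path(path)
        side = _io.read_json(path.with_suffix(path.suffix + ".json"))
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            samples = header[1:]
            kmers: list[int] = []
            rows: list[list[int]] = []
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                kmers.append(kmer_to_code(fields[0]))
                rows.append([int(x) for x in fields[1:]])
        counts = (
            np.asarray(rows, dtype=np.int64)
            if rows
            else np.empty((0, len(samples)), dtype=np.int64)
        )
        return cls(
            k=int(side["k"]),
            codes=np.asarray(kmers, dtype=np.int64),
            samples=samples,
            counts=counts,
            sample_read_totals={s: int(v) for s, v in side["sample_read_totals"].items()},
            sample_window_totals={
                s: int(v) for s, v in side.get("sample_window_totals", {}).items()
            },
        )


def build_matrix(
    per_sample_counts: Mapping[str, SampleKmerCounts | Mapping[str, int]],
    min_prevalence: int = 2,
    k: int | None = None,
    sample_read_totals: Mapping[str, int] | None = None,
) -> KmerCountMatrix:
    """Assemble per-sample counts into a k-mer × sample matrix.

    Keeps the union of k-mers observed in at least ``min_prevalence``
    samples, in lexicographic order.  ``sample_read_totals`` defaults to each
    sample's total valid window count when read totals are not supplied
    (string-dict input carries no read information).
    """
    if not per_sample_counts:
        raise ValueError("no samples")
    samples = list(per_sample_counts)

    norm: dict[str, SampleKmerCounts] = {}
    for sid, sc in per_sample_counts.items():
        if isinstance(sc, SampleKmerCounts):
            norm[sid] = sc
        else:  # plain {kmer: count} dict
            if not sc:
                kk = k
                if kk is None:
                    raise ValueError("k must be given when a sample has no k-mers")
                norm[sid] = SampleKmerCounts(kk, np.empty(0, np.int64), np.empty(0, np.int64), 0, 0)
                continue
            lens = {len(x) for x in sc}
            if len(lens) != 1:
                raise ValueError(f"inconsistent k-mer lengths in sample {sid}: {sorted(lens)}")
            kk = lens.pop()
            codes = np.asarray([kmer_to_code(x) for x in sc], dtype=np.int64)
            cnts = np.asarray(list(sc.values()), dtype=np.int64)
            order = np.argsort(codes)
            norm[sid] = SampleKmerCounts(kk, codes[order], cnts[order], int(cnts.sum()), 0)

    ks = {sc.k for sc in norm.values()}
    if len(ks) != 1:
        raise ValueError(f"inconsistent k across samples: {sorted(ks)}")
    k_final = ks.pop()
    if k is not None and k != k_final:
        raise ValueError(f"stated k={k} does not match counted k={k_final}")

    nonempty = [norm[s].codes for s in samples if norm[s].codes.size]
    if nonempty:
        allcodes = np.concatenate(nonempty)
        union, prevalence = np.unique(allcodes, return_counts=True)
        union = union[prevalence >= min_prevalence]
    else:
        union = np.empty(0, dtype=np.int64)

    counts = np.zeros((union.size, len(samples)), dtype=np.int64)
    for j, sid in enumerate(samples):
        sc = norm[sid]
        if sc.codes.size == 0 or union.size == 0:
            continue
        pos = np.searchsorted(union, sc.codes)
        pos_ok = pos < union.size
        hit = np.zeros(sc.codes.size, dtype=bool)
        hit[pos_ok] = union[pos[pos_ok]] == sc.codes[pos_ok]
        counts[pos[hit], j] = sc.counts[hit]

    window_totals = {s: int(norm[s].n_windows) for s in samples}
    if sample_read_totals is not None:
        read_totals = {s: int(sample_read_totals[s]) for s in samples}
    else:
        read_totals = {
            s: (int(norm[s].n_reads) if norm[s].n_reads else window_totals[s]) for s in samples
        }
    return KmerCountMatrix(
        k=k_final,
        codes=union,
        samples=samples,
        counts=counts,
        sample_read_totals=read_totals,
        sample_window_totals=window_totals,
    )


def normalize_depth(m: KmerCountMatrix) -> np.ndarray:
    """Counts-per-million by sample sequencing depth.

    entry(i, j) = counts(i, j) * 1e6 / sample_read_totals[j].
    """
    totals = np.asarray([m.sample_read_totals[s] for s in m.samples], dtype=np.float64)
    if (totals <= 0).any():
        bad = [s for s in m.samples if m.sample_read_totals[s] <= 0]
        raise ValueError(f"non-positive read totals for samples: {bad}")
    return m.counts.astype(np.float64) * 1e6 / totals[np.newaxis, :]


def count_samples(
    reads_by_sample: Mapping[str, Iterable[str | tuple[str, str]]],
    k: int,
) -> dict[str, SampleKmerCounts]:
    """Count canonical k-mers for every sample of a cohort."""
    return {sid: count_sample_codes(reads, k) for sid, reads in reads_by_sample.items()}
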