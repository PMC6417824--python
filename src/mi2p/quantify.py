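"""Marker-gene quantification from read-to-gene assignments.

A read is *unique* when it is assigned to exactly one gene and
*multi-mapped* otherwise.  Unique reads are counted directly; each
multi-mapped read distributes one unit of mass across its genes in
proportion to the genes' unique counts (the convention used for gene
profiling of gut metagenome catalogs), falling back to an equal split when
none of its genes has unique support.  Raw per-gene counts are then
normalized per kilobase of gene per million sample reads (RPKM-style).

Assignments can come either from the deterministic built-in k-mer matcher
or from a SAM file produced by an external aligner.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from ._encoding import concat_encode, window_codes
from .io import Read


@dataclass(frozen=True)
class ReadAssignment:
    """One read and the distinct genes it aligns to."""

    read_id: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("gene_ids must be non-empty")

    @property
    def is_unique(self) -> bool:
        return len(self.gene_ids) == 1


@dataclass(frozen=True)
class GeneAbundance:
    gene_id: str
    unique_count: int
    apportioned_count: float
    normalized_abundance: float


def _gene_items(genes: Iterable) -> list[tuple[str, str]]:
    """Normalize gene inputs ((id, seq) pairs or objects) to (id, seq)."""
    out = []
    for g in genes:
        if isinstance(g, tuple):
            out.append((g[0], g[1]))
        else:
            seq = getattr(g, "nucleotide_sequence", None) or getattr(g, "sequence")
            out.append((g.gene_id, seq))
    return out


class GeneKmerIndex:
    """Canonical k-mer → gene lookup for the built-in matcher.

    Each (k-mer, gene) pair appears once, so a window of a read contributes
    at most one shared-window count per gene regardless of how often the
    k-mer occurs within the gene.
    """

    def __init__(self, genes: Iterable, k_seed: int = 21):
        items = _gene_items(genes)
        if not items:
            raise ValueError("gene set must be non-empty")
        self.k = k_seed
        self.gene_ids = [gid for gid, _ in items]
        pair_codes = []
        pair_genes = []
        for gi, (_, seq) in enumerate(items):
            codes, _ = concat_encode([seq])
            canon, valid = window_codes(codes, k_seed)
            u = np.unique(canon[valid])
            pair_codes.append(u)
            pair_genes.append(np.full(u.size, gi, dtype=np.int64))
        codes = np.concatenate(pair_codes)
        gidx = np.concatenate(pair_genes)
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.gidx = gidx[order]


def map_reads_builtin(
    reads: Iterable[Read],
    genes: Iterable,
    min_matching_windows: int = 5,
    k_seed: int = 21,
) -> list[ReadAssignment]:
    """Assign reads to genes by shared canonical k-mer windows.

    A read is assigned to every gene with which it shares at least
    ``min_matching_windows`` k-mer windows (canonical, so both strands
    match); reads matching no gene are omitted.  The matcher is
    deterministic and alignment-free, suited to exact or near-exact
    matches; diverged reads should be aligned externally and supplied as
    SAM (:func:`ingest_sam`).
    """
    if min_matching_windows < 1:
        raise ValueError("min_matching_windows must be >= 1")
    index = genes if isinstance(genes, GeneKmerIndex) else GeneKmerIndex(genes, k_seed)
    reads = list(reads)
    if not reads:
        return []

    codes, starts = concat_encode(seq for _, seq in reads)
    canon, valid = window_codes(codes, index.k)
    win_pos = np.arange(canon.size)
    read_idx = np.searchsorted(starts, win_pos, side="right") - 1
    read_idx = read_idx[valid]
    canon = canon[valid]

    lo = np.searchsorted(index.codes, canon, side="left")
    hi = np.searchsorted(index.codes, canon, side="right")
    span = hi - lo
    matched = span > 0
    if not matched.any():
        return []
    lo, span, read_m = lo[matched], span[matched], read_idx[matched]
    # expand ranges: each matched window contributes one row per index entry
    reps = np.repeat(np.arange(lo.size), span)
    offsets = np.arange(span.sum()) - np.repeat(np.cumsum(span) - span, span)
    entry = lo[reps] + offsets
    gene_of_hit = index.gidx[entry]
    read_of_hit = read_m[reps]

    n_genes = len(index.gene_ids)
    keys = read_of_hit.astype(np.int64) * n_genes + gene_of_hit
    uk, counts = np.unique(keys, return_counts=True)
    good = counts >= min_matching_windows
    uk = uk[good]
    assignments: dict[int, list[str]] = {}
    for key in uk:
        r, g = divmod(int(key), n_genes)
        assignments.setdefault(r, []).append(index.gene_ids[g])
    return [
        ReadAssignment(reads[r][0], frozenset(gs))
        for r, gs in sorted(assignments.items())
    ]


def ingest_sam(path: str | Path, valid_gene_ids: Iterable[str]) -> list[ReadAssignment]:
    """Read-to-gene assignments from a SAM file against the repository genes.

    Unmapped records are skipped; primary and secondary alignments of the
    same read are pooled into one gene-id set.  Alignments to references
    outside ``valid_gene_ids`` raise.
    """
    valid = set(valid_gene_ids)
    pooled: dict[str, set[str]] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            ref = rec.reference_name
            if ref not in valid:
                raise ValueError(f"alignment to unknown reference {ref!r}")
            if rec.query_name not in pooled:
                pooled[rec.query_name] = set()
                order.append(rec.query_name)
            pooled[rec.query_name].add(ref)
    return [ReadAssignment(rid, frozenset(pooled[rid])) for rid in order]


def apportion_counts(
    assignments: Sequence[ReadAssignment],
) -> dict[str, tuple[int, float]]:
    """Unique counts plus proportional apportionment of multi-mapped reads.

    Returns gene_id → (U_g, raw_g) with
    raw_g = U_g + Σ_{multi reads r with g ∈ G_r} U_g / Σ_{g' ∈ G_r} U_{g'},
    splitting equally when every gene of a read has zero unique count.
    Total mass is conserved: Σ raw_g equals the number of assigned reads.
    """
    unique: dict[str, int] = {}
    seen: set[str] = set()
    for a in assignments:
        if a.read_id in seen:
            raise ValueError(f"read {a.read_id!r} appears more than once")
        seen.add(a.read_id)
        for g in a.gene_ids:
            unique.setdefault(g, 0)
        if a.is_unique:
            (g,) = a.gene_ids
            unique[g] += 1

    raw = {g: float(u) for g, u in unique.items()}
    for a in assignments:
        if a.is_unique:
            continue
        denom = sum(unique[g] for g in a.gene_ids)
        if denom > 0:
            for g in a.gene_ids:
                raw[g] += unique[g] / denom
        else:
            share = 1.0 / len(a.gene_ids)
            for g in a.gene_ids:
                raw[g] += share
    return {g: (unique[g], raw[g]) for g in unique}


def normalize_rpkm(
    raw: Mapping[str, float],
    gene_lengths_bp: Mapping[str, int],
    total_sample_reads: int,
) -> dict[str, float]:
    """Per-kilobase-per-million normalization of raw gene counts.

    abundance_g = raw_g / (L_g / 1000) / (total_sample_reads / 1e6).
    ``total_sample_reads`` is the sample's total read count (not the mapped
    count) unless the caller chooses otherwise.
    """
    if total_sample_reads <= 0:
        raise ValueError("total_sample_reads must be positive")
    out = {}
    for g, r in raw.items():
        L = gene_lengths_bp[g]
        if L <= 0:
            raise ValueError(f"gene {g!r} has non-positive length")
        out[g] = r / (L / 1000.0) / (total_sample_reads / 1e6)
    return out


def quantify_sample(
    assignments: Sequence[ReadAssignment],
    gene_lengths_bp: Mapping[str, int],
    total_sample_reads: int,
) -> dict[str, GeneAbundance]:
    """Apportion and normalize; genes with no assigned read get zeros."""
    ur = apportion_counts(assignments)
    raw = {g: r for g, (_, r) in ur.items()}
    for g in gene_lengths_bp:
        raw.setdefault(g, 0.0)
    rpkm = normalize_rpkm(raw, gene_lengths_bp, total_sample_reads)
    return {
        g: GeneAbundance(
            gene_id=g,
            unique_count=ur.get(g, (0, 0.0))[0],
            apportioned_count=raw[g],
            normalized_abundance=rpkm[g],
        )
        for g in gene_lengths_bp
    }


def abundance_table(
    per_sample: Mapping[str, Mapping[str, GeneAbundance]],
    gene_ids: Sequence[str],
):
    """Gene × sample RPKM table (pandas DataFrame) from per-sample results."""
    import pandas as pd

    data = {
        sid: [abund[g].normalized_abundance for g in gene_ids]
        for sid, abund in per_sample.items()
    }
    return pd.DataFrame(data, index=list(gene_ids))
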