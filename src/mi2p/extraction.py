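"""Subtractive read extraction by differential k-mer voting.

A read is extracted when at least ``min_votes`` of its k-mer windows are
differential between the two groups; among extracted reads, those whose
windows are dominated by cohort-wide abundant k-mers (typically from
abundant common species) are dropped as redundant.  Both rules operate on
canonical k-mers and are therefore strand-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._encoding import concat_encode, window_codes
from .differential import DifferentialKmerSet, KmerSet
from .io import Read


@dataclass
class ExtractionParams:
    """Voting / redundancy thresholds.

    min_votes: differential windows required to extract a read (absolute
        count; >= 2 by default so one sequencing error cannot produce a
        false vote on its own).
    max_abundant_fraction: a read is redundant when the fraction of its
        valid windows hitting the abundant set strictly exceeds this.
    """

    k: int
    min_votes: int = 2
    max_abundant_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.min_votes < 1:
            raise ValueError("min_votes must be >= 1")
        if not (0.0 <= self.max_abundant_fraction <= 1.0):
            raise ValueError("max_abundant_fraction must lie in [0, 1]")


def _window_hits(seq: str, kset: DifferentialKmerSet | KmerSet, k: int) -> tuple[int, int]:
    """(hits, valid_windows) of one read against a canonical k-mer set."""
    codes, _ = concat_encode([seq])
    canon, valid = window_codes(codes, k)
    canon = canon[valid]
    if canon.size == 0:
        return 0, 0
    return int(kset.contains_codes(canon).sum()), int(canon.size)


def vote_read(
    read: str, diff: DifferentialKmerSet, params: ExtractionParams
) -> tuple[int, bool]:
    """Count differential windows of a read and apply the vote threshold."""
    votes, _ = _window_hits(read, diff, params.k)
    return votes, votes >= params.min_votes


def is_redundant(
    read: str, abundant: KmerSet | DifferentialKmerSet, params: ExtractionParams
) -> bool:
    """True iff abundant windows / valid windows strictly exceed the cap.

    Reads with zero valid windows are never redundant.
    """
    hits, total = _window_hits(read, abundant, params.k)
    if total == 0:
        return False
    return hits / total > params.max_abundant_fraction


def extract_sample(
    reads: Iterable[Read],
    diff: DifferentialKmerSet,
    abundant: KmerSet | None,
    params: ExtractionParams,
) -> tuple[list[Read], dict[str, int]]:
    """Extract the differential sub-metagenome of one sample.

    Applies the vote rule to every read and the redundancy rule only to
    reads that pass voting, preserving input order.  Returns the kept reads
    and counters {n_input, n_voted, n_redundant, n_kept}.
    """
    reads = list(reads)
    n_input = len(reads)
    if n_input == 0 or len(diff) == 0:
        return [], {"n_input": n_input, "n_voted": 0, "n_redundant": 0, "n_kept": 0}

    k = params.k
    if k != diff.k:
        raise ValueError(f"params.k={k} does not match differential set k={diff.k}")
    codes, starts = concat_encode(seq for _, seq in reads)
    canon, valid = window_codes(codes, k)
    # read index of each window start position
    win_pos = np.arange(canon.size)
    read_idx = np.searchsorted(starts, win_pos, side="right") - 1
    read_idx = read_idx[valid]
    canon = canon[valid]

    votes = np.zeros(n_input, dtype=np.int64)
    np.add.at(votes, read_idx[diff.contains_codes(canon)], 1)
    voted = votes >= params.min_votes

    redundant = np.zeros(n_input, dtype=bool)
    if abundant is not None and len(abundant) > 0:
        total_windows = np.bincount(read_idx, minlength=n_input)
        abundant_windows = np.zeros(n_input, dtype=np.int64)
        np.add.at(abundant_windows, read_idx[abundant.contains_codes(canon)], 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(total_windows > 0, abundant_windows / np.maximum(total_windows, 1), 0.0)
        redundant = frac > params.max_abundant_fraction

    keep = voted & ~redundant
    kept = [reads[i] for i in np.flatnonzero(keep)]
    stats = {
        "n_input": n_input,
        "n_voted": int(voted.sum()),
        "n_redundant": int((voted & redundant).sum()),
        "n_kept": len(kept),
    }
    return kept, stats
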