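"""Two-group differential abundance testing with the Wilcoxon rank-sum test.

The same machinery serves two stages of the pipeline: screening canonical
k-mers on the depth-normalized k-mer count matrix, and pre-filtering
candidate genes on the abundance table.  P-values are two-sided; small,
tie-free problems use the exact Mann–Whitney U null distribution, larger or
tied problems a tie-corrected normal approximation with continuity
correction.  Multiple testing is controlled with Benjamini–Hochberg
step-up adjusted values ("q-values").
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _stats

from ._encoding import codes_to_kmers, kmer_to_code
from .kmers import KmerCountMatrix, canonicalize, normalize_depth

UP_IN_GROUP1 = "up_in_group1"
UP_IN_GROUP2 = "up_in_group2"
TIED = "tied"

#: largest per-group size for which the exact U distribution is used
EXACT_MAX_N = 8


@dataclass(frozen=True)
class WrsResult:
    """Mann–Whitney U of group 1 over group 2 with a two-sided p-value."""

    u_statistic: float
    p_value: float
    direction: str  # UP_IN_GROUP1 | UP_IN_GROUP2 | TIED


@lru_cache(maxsize=None)
def _u_count(n1: int, n2: int, u: int) -> int:
    """Number of rank assignments of n1 group-1 ranks with U statistic == u."""
    if u < 0 or u > n1 * n2:
        return 0
    if n1 == 0 or n2 == 0:
        return 1 if u == 0 else 0
    # classic recurrence: largest rank belongs to group 1 (contributes n2)
    # or to group 2 (contributes nothing)
    return _u_count(n1 - 1, n2, u - n2) + _u_count(n1, n2 - 1, u)


def _exact_two_sided_p(u: float, n1: int, n2: int) -> float:
    """Two-sided exact p: 2 * min tail of the tie-free U null, capped at 1."""
    from math import comb

    total = comb(n1 + n2, n1)
    lo = sum(_u_count(n1, n2, v) for v in range(0, int(u) + 1))
    # distribution is symmetric around n1*n2/2 in the tie-free case
    hi = sum(_u_count(n1, n2, v) for v in range(int(np.ceil(u)), n1 * n2 + 1))
    return min(1.0, 2.0 * min(lo, hi) / total)


def wrs_test(x: Sequence[float], y: Sequence[float]) -> WrsResult:
    """Wilcoxon rank-sum (Mann–Whitney) test of group ``x`` against ``y``.

    U is the Mann–Whitney statistic of group 1 computed from midranks.  For
    group sizes up to 8 with no ties the exact two-sided p is computed from
    the U null distribution; otherwise a normal approximation with tie and
    continuity correction is used.  Direction compares rank sums.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _stats.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mean = n1 * n2 / 2.0
    if u1 > mean:
        direction = UP_IN_GROUP1
    elif u1 < mean:
        direction = UP_IN_GROUP2
    else:
        direction = TIED

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    n = n1 + n2
    if not has_ties and n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        p = _exact_two_sided_p(u1, n1, n2)
        return WrsResult(u1, p, direction)

    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return WrsResult(u1, 1.0, TIED)
    diff = u1 - mean
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / np.sqrt(var)
    p = min(1.0, 2.0 * float(_stats.norm.sf(abs(z))))
    return WrsResult(u1, p, direction)


def _wrs_matrix(X: np.ndarray, n1: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise tie-corrected normal-approximation WRS test.

    ``X`` is (n_rows, n1+n2) with group-1 samples in the first ``n1``
    columns.  Returns (u, p, direction_sign) where direction_sign is +1 for
    up-in-group-1, −1 for up-in-group-2 and 0 for tied.
    """
    n_rows, m = X.shape
    n2 = m - n1
    ranks = _stats.rankdata(X, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mean = n1 * n2 / 2.0

    # per-row tie term sum(t^3 - t) over runs of equal values
    S = np.sort(X, axis=1)
    boundary = np.ones((n_rows, m), dtype=bool)
    boundary[:, 1:] = S[:, 1:] != S[:, :-1]
    gid = np.cumsum(boundary, axis=1)  # 1..#runs within each row
    gid_global = gid + (np.arange(n_rows)[:, None] * (m + 1))
    run_len = np.bincount(gid_global.ravel(), minlength=n_rows * (m + 1) + 1)
    run_len = run_len[: n_rows * (m + 1) + 1]
    contrib = run_len.astype(np.float64) ** 3 - run_len
    row_of_group = np.arange(contrib.size) // (m + 1)
    tie_term = np.bincount(row_of_group, weights=contrib, minlength=n_rows + 1)[:n_rows]

    n = m
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    diff = u1 - mean
    sign = np.sign(diff)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (diff - 0.5 * sign) / np.sqrt(var)
    p = np.where(var > 0, 2.0 * _stats.norm.sf(np.abs(z)), 1.0)
    p = np.minimum(p, 1.0)
    return u1, p, sign.astype(np.int8)


def wrs_test_rows(
    X: np.ndarray, n1: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise WRS tests matching :func:`wrs_test`'s branch selection.

    Uses the vectorized normal approximation when both groups exceed the
    exact-test size threshold, otherwise falls back to the scalar test per
    row so small-sample p-values stay exact.
    """
    X = np.asarray(X, dtype=np.float64)
    n2 = X.shape[1] - n1
    u, p, sign = _wrs_matrix(X, n1)
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        # replace the approximation with the exact p on tie-free rows
        S = np.sort(X, axis=1)
        tie_free = ~(S[:, 1:] == S[:, :-1]).any(axis=1)
        for i in np.flatnonzero(tie_free):
            p[i] = _exact_two_sided_p(u[i], n1, n2)
    return u, p, sign


def bh_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values in the original order.

    q_(i) = min_{j >= i}( p_(j) * m / j ), clipped to 1.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=np.float64)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _split_groups(
    samples: Sequence[str], labels: Mapping[str, str]
) -> tuple[str, str, np.ndarray, np.ndarray]:
    """Resolve the two groups; 'case' (if present) is group 1."""
    groups = sorted({labels[s] for s in samples})
    if len(groups) != 2:
        raise ValueError(f"labels must define exactly two groups, got {groups}")
    if "case" in groups:
        g1 = "case"
        g2 = groups[0] if groups[1] == "case" else groups[1]
    else:
        g1, g2 = groups
    idx1 = np.asarray([i for i, s in enumerate(samples) if labels[s] == g1])
    idx2 = np.asarray([i for i, s in enumerate(samples) if labels[s] == g2])
    if idx1.size < 2 or idx2.size < 2:
        raise ValueError("need at least 2 samples per group")
    return g1, g2, idx1, idx2


@dataclass
class DifferentialKmerSet:
    """Canonical k-mers passing the WRS / q-value screen.

    Arrays are parallel and ordered by k-mer code; ``direction`` is +1 for
    up in group 1 (``group1``), −1 for up in group 2, 0 for tied.
    """

    k: int
    codes: np.ndarray  # sorted int64
    u: np.ndarray
    p: np.ndarray
    q: np.ndarray
    direction: np.ndarray  # int8
    q_cutoff: float
    group1: str = "case"
    group2: str = "control"

    def __len__(self) -> int:
        return int(self.codes.size)

    def __contains__(self, kmer: str) -> bool:
        code = kmer_to_code(canonicalize(kmer))
        i = int(np.searchsorted(self.codes, code))
        return i < self.codes.size and self.codes[i] == code

    def contains_codes(self, codes: np.ndarray) -> np.ndarray:
        """Boolean membership mask for an array of canonical codes."""
        pos = np.searchsorted(self.codes, codes)
        ok = pos < self.codes.size
        out = np.zeros(codes.shape, dtype=bool)
        out[ok] = self.codes[pos[ok]] == codes[ok]
        return out

    @property
    def kmers(self) -> list[str]:
        return codes_to_kmers(self.codes, self.k)

    @property
    def entries(self) -> dict[str, tuple[WrsResult, float]]:
        dirs = {1: UP_IN_GROUP1, -1: UP_IN_GROUP2, 0: TIED}
        return {
            km: (WrsResult(float(u), float(p), dirs[int(d)]), float(q))
            for km, u, p, q, d in zip(self.kmers, self.u, self.p, self.q, self.direction)
        }

    def to_tsv(self, path: str | Path) -> None:
        dirs = {1: UP_IN_GROUP1, -1: UP_IN_GROUP2, 0: TIED}
        with open(path, "w") as fh:
            fh.write(f"# k={self.k}\tq_cutoff={self.q_cutoff}\tgroup1={self.group1}\tgroup2={self.group2}\n")
            fh.write("kmer\tU\tp\tq\tdirection\n")
            for km, u, p, q, d in zip(self.kmers, self.u, self.p, self.q, self.direction):
                fh.write(f"{km}\t{u:.6g}\t{p:.6g}\t{q:.6g}\t{dirs[int(d)]}\n")


def select_differential_kmers(
    matrix: KmerCountMatrix,
    labels: Mapping[str, str],
    q_cutoff: float = 0.05,
    normalize: bool = True,
) -> DifferentialKmerSet:
    """Screen every k-mer row with the WRS test and keep rows with q <= cutoff.

    By default rows are depth-normalized to counts-per-million before
    testing so group comparisons are not confounded with sequencing depth;
    set ``normalize=False`` to test raw counts.
    """
    g1, g2, idx1, idx2 = _split_groups(matrix.samples, labels)
    X = normalize_depth(matrix) if normalize else matrix.counts.astype(np.float64)
    Xo = np.concatenate([X[:, idx1], X[:, idx2]], axis=1)
    u, p, sign = wrs_test_rows(Xo, idx1.size)
    q = bh_qvalues(p)
    keep = q <= q_cutoff
    return DifferentialKmerSet(
        k=matrix.k,
        codes=matrix.codes[keep],
        u=u[keep],
        p=p[keep],
        q=q[keep],
        direction=sign[keep],
        q_cutoff=q_cutoff,
        group1=g1,
        group2=g2,
    )


@dataclass
class KmerSet:
    """A plain set of canonical k-mers backed by sorted codes."""

    k: int
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.sort(np.asarray(self.codes, dtype=np.int64))

    def __len__(self) -> int:
        return int(self.codes.size)

    def __contains__(self, kmer: str) -> bool:
        code = kmer_to_code(canonicalize(kmer))
        i = int(np.searchsorted(self.codes, code))
        return i < self.codes.size and self.codes[i] == code

    def contains_codes(self, codes: np.ndarray) -> np.ndarray:
        pos = np.searchsorted(self.codes, codes)
        ok = pos < self.codes.size
        out = np.zeros(codes.shape, dtype=bool)
        out[ok] = self.codes[pos[ok]] == codes[ok]
        return out

    @property
    def kmers(self) -> list[str]:
        return codes_to_kmers(self.codes, self.k)

    def to_text(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for km in self.kmers:
                fh.write(km + "\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "KmerSet":
        with open(path) as fh:
            kmers = [line.strip() for line in fh if line.strip()]
        if not kmers:
            return cls(k=0, codes=np.empty(0, np.int64))
        k = len(kmers[0])
        return cls(k=k, codes=np.asarray([kmer_to_code(x) for x in kmers], dtype=np.int64))


def identify_abundant_kmers(
    matrix: KmerCountMatrix,
    top_quantile: float = 0.01,
    normalize: bool = True,
) -> KmerSet:
    """Cohort-wide abundant k-mers: the top fraction by mean normalized count.

    Returns the ``ceil(top_quantile * n_kmers)`` k-mers with the highest mean
    depth-normalized count across all samples; ties are broken toward the
    lexicographically smaller k-mer.  These typically stem from abundant
    common species and are used to drop redundant reads.
    """
    if not (0 < top_quantile < 1):
        raise ValueError("top_quantile must lie in (0, 1)")
    n = matrix.n_kmers
    if n == 0:
        return KmerSet(k=matrix.k, codes=np.empty(0, np.int64))
    X = normalize_depth(matrix) if normalize else matrix.counts.astype(np.float64)
    means = X.mean(axis=1)
    n_sel = int(np.ceil(top_quantile * n))
    # sort by (-mean, code): codes are already sorted ascending, and a stable
    # sort on -mean therefore breaks ties lexicographically
    order = np.argsort(-means, kind="stable")[:n_sel]
    return KmerSet(k=matrix.k, codes=matrix.codes[order])
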