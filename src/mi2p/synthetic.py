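"""Two-group synthetic metagenome cohorts with planted differential genes.

The generator emulates the structure of a case/control shotgun cohort at
desk scale: a catalog of random genes, a subset of which are planted
markers whose group-mean abundance differs by a stated fold-change; per
sample, gene abundances are drawn log-normally around the group mean,
reads are drawn multinomially across genes and sampled as uniform-random
substrings from either strand with i.i.d. substitution errors.  A truth
ledger records the planted markers and the realized per-gene read counts
so every downstream stage can be scored against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as _io
from ._encoding import _LETTER, encode

ENRICHED_IN_CASE = "enriched_in_case"
DEPLETED_IN_CASE = "depleted_in_case"
BACKGROUND = "background"

#: spread (sd, natural-log scale) of per-gene baseline abundance across the
#: catalog, giving the uneven gene abundance profile real metagenomes show
BASELINE_LOG_SD = 1.0


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    sequence: str
    length_bp: int
    is_marker: bool
    direction: str  # ENRICHED_IN_CASE | DEPLETED_IN_CASE | BACKGROUND

    def __post_init__(self) -> None:
        if self.length_bp != len(self.sequence):
            raise ValueError("length_bp must equal len(sequence)")
        if self.is_marker == (self.direction == BACKGROUND):
            raise ValueError("marker flag and direction disagree")


@dataclass
class CohortDesign:
    """Sizes, effect sizes and noise levels of one synthetic cohort."""

    n_case: int = 30
    n_control: int = 30
    n_genes: int = 200
    n_markers: int = 20
    fold_change: float = 4.0
    read_length_bp: int = 100
    reads_per_sample: int = 20_000
    substitution_error_rate: float = 0.005
    abundance_dispersion: float = 0.5  # sd of log-normal per-sample abundance
    seed: int = 0

    def validate(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("need at least one sample per group")
        if not 0 <= self.n_markers <= self.n_genes:
            raise ValueError("n_markers must lie in [0, n_genes]")
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")
        if not 0 <= self.substitution_error_rate < 1:
            raise ValueError("substitution_error_rate must lie in [0, 1)")
        if self.abundance_dispersion < 0:
            raise ValueError("abundance_dispersion must be >= 0")
        if self.read_length_bp < 1 or self.reads_per_sample < 0:
            raise ValueError("invalid read length or count")


@dataclass
class CohortTruth:
    """Ground-truth ledger of one simulated cohort."""

    design: CohortDesign
    marker_ids: list[str]
    directions: dict[str, str]  # gene_id -> direction (markers only)
    per_sample_gene_reads: pd.DataFrame  # genes × samples, ints
    labels: dict[str, str]  # sample -> case|control

    def to_json(self, path: str | Path) -> None:
        _io.write_json(
            {
                "design": asdict(self.design),
                "marker_ids": self.marker_ids,
                "directions": self.directions,
                "labels": self.labels,
                "gene_ids": list(self.per_sample_gene_reads.index),
                "samples": list(self.per_sample_gene_reads.columns),
                "per_sample_gene_reads": self.per_sample_gene_reads.values.tolist(),
            },
            path,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortTruth":
        d = _io.read_json(path)
        return cls(
            design=CohortDesign(**d["design"]),
            marker_ids=d["marker_ids"],
            directions=d["directions"],
            per_sample_gene_reads=pd.DataFrame(
                np.asarray(d["per_sample_gene_reads"], dtype=np.int64),
                index=d["gene_ids"],
                columns=d["samples"],
            ),
            labels=d["labels"],
        )


def generate_catalog(
    n_genes: int,
    n_markers: int,
    length_range: tuple[int, int] = (300, 1500),
    seed: int = 0,
) -> list[GeneModel]:
    """Random gene catalog with ``n_markers`` planted marker genes.

    Sequences are i.i.d. uniform over {A,C,G,T}; markers are split as
    evenly as possible between case-enriched and case-depleted, with the
    extra one (odd counts) going to the enriched side.  Deterministic for a
    fixed seed.
    """
    if n_genes < 0 or not 0 <= n_markers <= n_genes:
        raise ValueError("need 0 <= n_markers <= n_genes")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length_range {length_range}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCA7A]))
    width = len(str(max(n_genes - 1, 0)))
    genes = []
    n_enriched = (n_markers + 1) // 2
    for i in range(n_genes):
        L = int(rng.integers(lo, hi + 1))
        seq = _LETTER[rng.integers(0, 4, L)].tobytes().decode("ascii")
        if i < n_enriched:
            direction, marker = ENRICHED_IN_CASE, True
        elif i < n_markers:
            direction, marker = DEPLETED_IN_CASE, True
        else:
            direction, marker = BACKGROUND, False
        genes.append(
            GeneModel(
                gene_id=f"gene{i:0{width}d}",
                sequence=seq,
                length_bp=L,
                is_marker=marker,
                direction=direction,
            )
        )
    return genes


def _group_log_means(
    catalog: list[GeneModel], design: CohortDesign, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene log-mean abundance for (case, control).

    Marker genes sit log(fold_change)/2 above the baseline in their
    enriched group and the same amount below it in the other, so the
    case/control group-mean ratio is exactly the fold change.
    """
    base = rng.normal(0.0, BASELINE_LOG_SD, len(catalog))
    half = np.log(design.fold_change) / 2.0
    shift = np.array(
        [
            half if g.direction == ENRICHED_IN_CASE else (-half if g.direction == DEPLETED_IN_CASE else 0.0)
            for g in catalog
        ]
    )
    return base + shift, base - shift


def _sample_ids(design: CohortDesign) -> tuple[list[str], dict[str, str]]:
    cases = [f"case{i:02d}" for i in range(design.n_case)]
    controls = [f"ctrl{i:02d}" for i in range(design.n_control)]
    labels = {s: "case" for s in cases} | {s: "control" for s in controls}
    return cases + controls, labels


def simulate_abundance_matrix(
    catalog_or_design: list[GeneModel] | CohortDesign,
    design: CohortDesign | None = None,
) -> tuple[pd.DataFrame, dict[str, str], CohortTruth]:
    """Gene × sample log-normal abundance matrix with planted fold-changes.

    Shortcut for classifier tests that skips read simulation.  May be
    called with just a :class:`CohortDesign` (a catalog is generated from
    the design's seed) or with an explicit catalog plus design.  Returns
    (table, labels, truth); the truth ledger's read-count matrix is empty.
    """
    if isinstance(catalog_or_design, CohortDesign):
        design = catalog_or_design
        design.validate()
        catalog = generate_catalog(design.n_genes, design.n_markers, seed=design.seed)
    else:
        catalog = catalog_or_design
        assert design is not None
        design.validate()
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0xAB0D]))
    mu_case, mu_ctrl = _group_log_means(catalog, design, rng)
    samples, labels = _sample_ids(design)
    cols = {}
    for sid in samples:
        mu = mu_case if labels[sid] == "case" else mu_ctrl
        cols[sid] = np.exp(rng.normal(mu, design.abundance_dispersion))
    table = pd.DataFrame(cols, index=[g.gene_id for g in catalog])
    truth = CohortTruth(
        design=design,
        marker_ids=[g.gene_id for g in catalog if g.is_marker],
        directions={g.gene_id: g.direction for g in catalog if g.is_marker},
        per_sample_gene_reads=pd.DataFrame(
            np.zeros((len(catalog), 0), dtype=np.int64), index=table.index
        ),
        labels=labels,
    )
    return table, labels, truth


def _reads_for_gene(
    gene_codes: np.ndarray,
    n_reads: int,
    read_len: int,
    error_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_reads, read_len) base-code matrix of substrings with errors."""
    L = gene_codes.size
    starts = rng.integers(0, L - read_len + 1, n_reads)
    sub = gene_codes[starts[:, None] + np.arange(read_len)]
    flip = rng.random(n_reads) < 0.5
    sub[flip] = 3 - sub[flip, ::-1]  # reverse complement
    if error_rate > 0:
        err = rng.random((n_reads, read_len)) < error_rate
        shift = rng.integers(1, 4, (n_reads, read_len))
        sub = np.where(err, (sub + shift) % 4, sub)
    return sub


def simulate_cohort(
    catalog: list[GeneModel], design: CohortDesign
) -> tuple[dict[str, list[tuple[str, str]]], CohortTruth]:
    """Simulate per-sample read sets and the matching truth ledger.

    Reads per sample are multinomial across genes with probabilities
    proportional to (abundance × number of read start positions); each read
    is a uniform-random substring of its gene, reverse-complemented with
    probability 0.5, with i.i.d. substitution errors.  Read ids encode the
    sample and origin gene as ``sample:gene_id:serial``.
    """
    if not catalog:
        raise ValueError("catalog must be non-empty")
    design.validate()
    min_len = min(g.length_bp for g in catalog)
    if design.read_length_bp > min_len:
        raise ValueError(
            f"read_length_bp={design.read_length_bp} exceeds shortest gene ({min_len} bp)"
        )
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0x5EAD]))
    mu_case, mu_ctrl = _group_log_means(catalog, design, rng)
    samples, labels = _sample_ids(design)
    gene_codes = [encode(g.sequence) for g in catalog]
    n_starts = np.array([g.length_bp - design.read_length_bp + 1 for g in catalog], dtype=np.float64)

    counts_matrix = np.zeros((len(catalog), len(samples)), dtype=np.int64)
    reads_by_sample: dict[str, list[tuple[str, str]]] = {}
    rl = design.read_length_bp
    for j, sid in enumerate(samples):
        mu = mu_case if labels[sid] == "case" else mu_ctrl
        abund = np.exp(rng.normal(mu, design.abundance_dispersion))
        p = abund * n_starts
        p /= p.sum()
        counts = rng.multinomial(design.reads_per_sample, p)
        counts_matrix[:, j] = counts
        reads: list[tuple[str, str]] = []
        for gi, c in enumerate(counts):
            if c == 0:
                continue
            mat = _reads_for_gene(gene_codes[gi], int(c), rl, design.substitution_error_rate, rng)
            letters = _LETTER[mat]
            seqs = letters.reshape(-1).view(f"S{rl}")
            gid = catalog[gi].gene_id
            reads.extend(
                (f"{sid}:{gid}:{i}", s.decode("ascii")) for i, s in enumerate(seqs)
            )
        reads_by_sample[sid] = reads

    truth = CohortTruth(
        design=design,
        marker_ids=[g.gene_id for g in catalog if g.is_marker],
        directions={g.gene_id: g.direction for g in catalog if g.is_marker},
        per_sample_gene_reads=pd.DataFrame(
            counts_matrix, index=[g.gene_id for g in catalog], columns=samples
        ),
        labels=labels,
    )
    return reads_by_sample, truth


def read_origin(read_id: str) -> str:
    """Origin gene_id encoded in a simulated read id (``sample:gene:serial``)."""
    return read_id.split(":")[1]


def write_cohort(
    reads_by_sample: Mapping[str, list[tuple[str, str]]],
    truth: CohortTruth,
    out_dir: str | Path,
    gzip_reads: bool = False,
) -> None:
    """Write FASTQ per sample plus labels.tsv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if gzip_reads else ".fastq"
    for sid, reads in reads_by_sample.items():
        _io.write_fastq(reads, out / f"{sid}{suffix}")
    _io.write_labels(truth.labels, out / "labels.tsv")
    truth.to_json(out / "truth.json")


def write_catalog_fasta(catalog: list[GeneModel], path: str | Path) -> None:
    _io.write_fasta([(g.gene_id, g.sequence) for g in catalog], path)
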