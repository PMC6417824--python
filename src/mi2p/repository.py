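"""The distributable marker-gene repository.

A repository bundles, for one host phenotype, the marker gene sequences
(nucleotide, optionally protein), per-gene metadata (length, enrichment
direction, free-text annotation), a trained phenotype predictor, the
feature order the predictor expects, and a provenance record of how it was
built.  Annotations are opaque strings stored as-is; the repository never
computes them.

Directory layout (format version 1):

    genes.fna        nucleotide FASTA, one record per marker gene
    genes.faa        protein FASTA (optional)
    metadata.tsv     gene_id, length_bp, direction, annotation, annotation_source
    model.joblib     the trained predictor
    repository.json  name, format_version, feature_order, model spec, provenance
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import joblib

from . import io as _io

FORMAT_VERSION = "1"

ENRICHED = "enriched"
DEPLETED = "depleted"

_METADATA_COLUMNS = ["gene_id", "length_bp", "direction", "annotation", "annotation_source"]


class RepositoryError(ValueError):
    """Raised when a repository fails structural validation on load/save."""


@dataclass
class MarkerGene:
    gene_id: str
    nucleotide_sequence: str
    direction: str  # ENRICHED | DEPLETED (in the case group)
    protein_sequence: Optional[str] = None
    annotation: str = ""
    annotation_source: str = ""

    @property
    def length_bp(self) -> int:
        return len(self.nucleotide_sequence)


@dataclass
class MarkerRepository:
    name: str
    genes: list[MarkerGene]
    trained_predictor: object
    feature_order: list[str]
    model_spec: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def gene_lengths(self) -> dict[str, int]:
        return {g.gene_id: g.length_bp for g in self.genes}


def validate_repository(repo: MarkerRepository) -> list[str]:
    """Collect every invariant violation (never stops at the first).

    Checks gene-id uniqueness, sequence alphabet and length, agreement of
    feature_order with the gene set, and the predictor's expected feature
    count.  Returns an empty list for a clean repository.
    """
    violations: list[str] = []
    if not repo.genes:
        violations.append("repository contains no genes")
    ids = [g.gene_id for g in repo.genes]
    seen = set()
    for gid in ids:
        if gid in seen:
            violations.append(f"duplicate gene_id {gid!r}")
        seen.add(gid)
    for g in repo.genes:
        if not g.nucleotide_sequence:
            violations.append(f"gene {g.gene_id!r} has empty sequence")
        elif any(b not in "ACGT" for b in g.nucleotide_sequence):
            violations.append(f"gene {g.gene_id!r} sequence contains non-ACGT symbols")
        if g.direction not in (ENRICHED, DEPLETED):
            violations.append(f"gene {g.gene_id!r} has invalid direction {g.direction!r}")
    if sorted(repo.feature_order) != sorted(ids):
        violations.append("feature_order is not a permutation of the gene ids")
    n_expected = getattr(repo.trained_predictor, "n_features_in_", None)
    if n_expected is not None and n_expected != len(repo.feature_order):
        violations.append(
            f"predictor expects {n_expected} features but feature_order has {len(repo.feature_order)}"
        )
    trained_names = getattr(repo.trained_predictor, "feature_names_in_", None)
    if trained_names is not None and list(trained_names) != list(repo.feature_order):
        violations.append("feature_order does not match the order the predictor was trained with")
    return violations


def save_repository(repo: MarkerRepository, path: str | Path) -> None:
    """Write the repository directory; round-trips through load_repository."""
    violations = validate_repository(repo)
    if violations:
        raise RepositoryError("; ".join(violations))
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_fasta([(g.gene_id, g.nucleotide_sequence) for g in repo.genes], out / "genes.fna")
    proteins = [(g.gene_id, g.protein_sequence) for g in repo.genes if g.protein_sequence]
    if proteins:
        _io.write_fasta(proteins, out / "genes.faa")
    with open(out / "metadata.tsv", "w") as fh:
        fh.write("\t".join(_METADATA_COLUMNS) + "\n")
        for g in repo.genes:
            fh.write(
                f"{g.gene_id}\t{g.length_bp}\t{g.direction}\t{g.annotation}\t{g.annotation_source}\n"
            )
    joblib.dump(repo.trained_predictor, out / "model.joblib")
    _io.write_json(
        {
            "format_version": FORMAT_VERSION,
            "name": repo.name,
            "feature_order": repo.feature_order,
            "model_spec": repo.model_spec,
            "provenance": repo.provenance,
        },
        out / "repository.json",
    )


def load_repository(path: str | Path) -> MarkerRepository:
    """Load and validate a repository directory."""
    root = Path(path)
    for required in ("genes.fna", "metadata.tsv", "model.joblib", "repository.json"):
        if not (root / required).exists():
            raise RepositoryError(f"missing repository file: {required}")
    manifest = _io.read_json(root / "repository.json")
    if manifest.get("format_version") != FORMAT_VERSION:
        raise RepositoryError(
            f"unsupported repository format version {manifest.get('format_version')!r}"
        )

    nt = {}
    for gid, seq in _io.read_fasta(root / "genes.fna"):
        if gid in nt:
            raise RepositoryError(f"duplicate gene_id {gid!r} in genes.fna")
        nt[gid] = seq
    prot = {}
    if (root / "genes.faa").exists():
        prot = dict(_io.read_fasta(root / "genes.faa"))

    genes: list[MarkerGene] = []
    with open(root / "metadata.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _METADATA_COLUMNS:
            raise RepositoryError(f"unexpected metadata columns {header}")
        for line in fh:
            gid, length_bp, direction, annotation, source = line.rstrip("\n").split("\t")
            if gid not in nt:
                raise RepositoryError(f"metadata row for {gid!r} has no FASTA record")
            if int(length_bp) != len(nt[gid]):
                raise RepositoryError(f"length mismatch for gene {gid!r}")
            genes.append(
                MarkerGene(
                    gene_id=gid,
                    nucleotide_sequence=nt[gid],
                    direction=direction,
                    protein_sequence=prot.get(gid),
                    annotation=annotation,
                    annotation_source=source,
                )
            )
    meta_ids = {g.gene_id for g in genes}
    extra = set(nt) - meta_ids
    if extra:
        raise RepositoryError(f"FASTA records without metadata rows: {sorted(extra)}")

    repo = MarkerRepository(
        name=manifest["name"],
        genes=genes,
        trained_predictor=joblib.load(root / "model.joblib"),
        feature_order=list(manifest["feature_order"]),
        model_spec=manifest.get("model_spec", {}),
        provenance=manifest.get("provenance", {}),
    )
    violations = validate_repository(repo)
    if violations:
        raise RepositoryError("; ".join(violations))
    return repo
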