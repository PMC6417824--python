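"""End-to-end orchestration: marker discovery (build) and prediction.

``build_repository`` runs the discovery chain on a labeled two-group cohort
of read sets — canonical k-mer counting, Wilcoxon screening of k-mers,
voting-based read extraction, candidate-gene quantification, gene-level
q-value pre-filtering, feature selection, classifier training — and
packages the result as a distributable marker repository.

``predict_sample`` runs the three prediction steps on a query metagenome:
map reads onto the repository's marker genes (built-in matcher or an
externally produced SAM), quantify them with multi-mapping apportionment
and RPKM normalization, and score the phenotype with the stored predictor.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from . import io as _io
from .differential import identify_abundant_kmers, select_differential_kmers
from .extraction import ExtractionParams, extract_sample
from .kmers import build_matrix, count_samples
from .models import ModelSpec, l1_select, qvalue_prefilter, train_predictor, tree_select
from .quantify import abundance_table, map_reads_builtin, GeneKmerIndex, ingest_sam, quantify_sample
from .repository import DEPLETED, ENRICHED, MarkerGene, MarkerRepository, load_repository, save_repository

logger = logging.getLogger("mi2p")


class PipelineError(RuntimeError):
    """A pipeline stage could not proceed (e.g. no genes survive selection)."""


@dataclass
class BuildParams:
    """Every tunable of the discovery pipeline, recorded in provenance."""

    k: int = 21
    min_prevalence: int = 2
    q_cutoff_kmer: float = 0.05
    q_cutoff_gene: float = 0.05
    top_quantile: float = 0.01
    min_votes: int = 2
    max_abundant_fraction: float = 0.5
    k_seed: int = 21
    min_matching_windows: int = 5
    selection: str = "tree"  # "tree" | "l1" | "none"
    model: ModelSpec = field(default_factory=ModelSpec)
    seed: int = 0


def build_repository(
    reads_by_sample: Mapping[str, Sequence[tuple[str, str]]],
    labels: Mapping[str, str],
    candidate_genes: Sequence[tuple[str, str]],
    params: BuildParams | None = None,
    name: str = "phenotype",
) -> tuple[MarkerRepository, dict]:
    """Discover marker genes and train the default predictor.

    ``candidate_genes`` are (gene_id, sequence) pairs, e.g. genes predicted
    from an external assembly of the extracted reads (assembly itself is
    not part of this package) or the synthetic truth catalog.  Returns the
    repository plus a report dict with per-stage statistics.  Raises
    :class:`PipelineError` when no gene survives selection.
    """
    params = params or BuildParams()
    samples = list(reads_by_sample)
    groups = {labels[s] for s in samples}
    if len(groups) != 2:
        raise PipelineError(f"labels must define exactly two groups, got {sorted(groups)}")
    for g in sorted(groups):
        if sum(labels[s] == g for s in samples) < 2:
            raise PipelineError(f"group {g!r} has fewer than 2 samples")
    if not candidate_genes:
        raise PipelineError("candidate gene set is empty")

    logger.info("stage 1/6: counting canonical %d-mers in %d samples", params.k, len(samples))
    counts = count_samples(reads_by_sample, params.k)
    matrix = build_matrix(counts, min_prevalence=params.min_prevalence)

    logger.info("stage 2/6: differential k-mer screen (%d k-mers)", matrix.n_kmers)
    diff = select_differential_kmers(matrix, labels, q_cutoff=params.q_cutoff_kmer)
    abundant = identify_abundant_kmers(matrix, top_quantile=params.top_quantile)
    logger.info("  %d differential k-mers, %d abundant k-mers", len(diff), len(abundant))
    if len(diff) == 0:
        raise PipelineError(
            "no differential k-mers at q <= "
            f"{params.q_cutoff_kmer}; the groups may not differ"
        )

    logger.info("stage 3/6: voting-based read extraction")
    xparams = ExtractionParams(
        k=params.k,
        min_votes=params.min_votes,
        max_abundant_fraction=params.max_abundant_fraction,
    )
    extraction_stats = {}
    for sid in samples:
        _, stats = extract_sample(reads_by_sample[sid], diff, abundant, xparams)
        extraction_stats[sid] = stats

    logger.info("stage 4/6: quantifying %d candidate genes", len(candidate_genes))
    index = GeneKmerIndex(candidate_genes, k_seed=params.k_seed)
    lengths = {gid: len(seq) for gid, seq in candidate_genes}
    per_sample = {}
    for sid in samples:
        reads = reads_by_sample[sid]
        assignments = map_reads_builtin(
            reads, index, min_matching_windows=params.min_matching_windows
        )
        per_sample[sid] = quantify_sample(assignments, lengths, max(len(reads), 1))
    table = abundance_table(per_sample, [gid for gid, _ in candidate_genes])

    logger.info("stage 5/6: gene-level q-value pre-filter and feature selection")
    kept = qvalue_prefilter(table, labels, q_cutoff=params.q_cutoff_gene)
    if kept.shape[0] == 0:
        raise PipelineError(f"no genes surviving the q <= {params.q_cutoff_gene} pre-filter")
    if params.selection == "tree" and kept.shape[0] >= 2:
        selected = tree_select(kept, labels, seed=params.seed)
    elif params.selection == "l1" and kept.shape[0] >= 2:
        selected = l1_select(kept, labels)
    else:
        selected = list(kept.index)
    if not selected:
        raise PipelineError("no genes surviving feature selection")
    logger.info("  %d candidate genes -> %d markers", table.shape[0], len(selected))

    # enrichment direction of each selected gene from the gene-stage WRS screen
    from .models import WilcoxonSelector

    wsel = WilcoxonSelector(q_cutoff=1.0).fit(table.T.to_numpy(dtype=np.float64),
                                              np.asarray([labels[s] for s in table.columns]))
    direction_of = {
        gid: (ENRICHED if d >= 0 else DEPLETED)
        for gid, d in zip(table.index, wsel.directions_)
    }

    logger.info("stage 6/6: training %s predictor", params.model.family)
    model_spec = ModelSpec(**{**params.model.to_dict(), "seed": params.seed})
    predictor = train_predictor(table.loc[selected], labels, model_spec)

    seqs = dict(candidate_genes)
    genes = [
        MarkerGene(
            gene_id=gid,
            nucleotide_sequence=seqs[gid],
            direction=direction_of[gid],
        )
        for gid in selected
    ]
    provenance = {
        "mi2p_version": __version__,
        "params": {
            **{k: v for k, v in asdict(params).items() if k != "model"},
            "model": model_spec.to_dict(),
        },
        "n_samples": {g: int(sum(labels[s] == g for s in samples)) for g in sorted(groups)},
        "n_candidate_genes": len(candidate_genes),
        "n_differential_kmers": len(diff),
        "n_genes_after_prefilter": int(kept.shape[0]),
        "extraction": extraction_stats,
    }
    repo = MarkerRepository(
        name=name,
        genes=genes,
        trained_predictor=predictor,
        feature_order=list(selected),
        model_spec=model_spec.to_dict(),
        provenance=provenance,
    )
    report = {
        "abundance_table": table,
        "differential_kmers": diff,
        "abundant_kmers": abundant,
        "extraction_stats": extraction_stats,
        "selected_genes": list(selected),
    }
    return repo, report


@dataclass
class PredictionReport:
    """Outcome of predicting one query metagenome against a repository."""

    sample_id: str
    repository_name: str
    predicted_label: str  # "case" | "control"
    case_probability: float
    gene_abundances: dict[str, float]  # gene_id -> RPKM, repository feature order
    n_reads_total: int
    n_reads_assigned: int
    provenance: dict

    def to_json(self, path: str | Path) -> None:
        _io.write_json(asdict(self), path)


def predict_sample(
    reads: Sequence[tuple[str, str]],
    repo: MarkerRepository,
    sample_id: str = "query",
    sam_path: str | Path | None = None,
    min_matching_windows: int = 5,
    k_seed: int = 21,
) -> PredictionReport:
    """Map → quantify → predict for one query read set.

    With ``sam_path`` the read-to-gene assignments come from an external
    aligner's SAM against the repository FASTA; otherwise the built-in
    k-mer matcher is used.  Features are ordered exactly as the
    repository's ``feature_order`` before scoring.
    """
    reads = list(reads)
    if not reads and sam_path is None:
        raise PipelineError("query read set is empty")
    if sam_path is not None:
        assignments = ingest_sam(sam_path, [g.gene_id for g in repo.genes])
    else:
        assignments = map_reads_builtin(
            reads, repo.genes, min_matching_windows=min_matching_windows, k_seed=k_seed
        )
    lengths = repo.gene_lengths()
    n_total = len(reads) if reads else len(assignments)
    abund = quantify_sample(assignments, lengths, max(n_total, 1))
    features = np.asarray(
        [[abund[g].normalized_abundance for g in repo.feature_order]]
    )
    predictor = repo.trained_predictor
    p_case = float(predictor.case_probability(features)[0])
    label = "case" if p_case >= 0.5 else "control"
    return PredictionReport(
        sample_id=sample_id,
        repository_name=repo.name,
        predicted_label=label,
        case_probability=p_case,
        gene_abundances={g: float(abund[g].normalized_abundance) for g in repo.feature_order},
        n_reads_total=n_total,
        n_reads_assigned=len(assignments),
        provenance={
            "mi2p_version": __version__,
            "mapper": "sam" if sam_path is not None else "builtin",
            "min_matching_windows": min_matching_windows,
            "k_seed": k_seed,
            "model_spec": repo.model_spec,
        },
    )


def run_build(
    reads_dir: str | Path,
    labels_tsv: str | Path,
    genes_fasta: str | Path,
    out_dir: str | Path,
    params: BuildParams | None = None,
    name: str = "phenotype",
) -> MarkerRepository:
    """File-level build: read cohort FASTQ + labels + candidate genes, save repo."""
    labels = _io.read_labels(labels_tsv)
    reads_dir = Path(reads_dir)
    reads_by_sample = {}
    for sid in labels:
        matches = sorted(
            p
            for p in reads_dir.iterdir()
            if p.name.startswith(sid + ".")
        )
        if not matches:
            raise PipelineError(f"no reads file for sample {sid!r} in {reads_dir}")
        reads_by_sample[sid] = list(_io.read_sequences(matches[0]))
    candidate_genes = _io.read_fasta(genes_fasta)
    repo, _ = build_repository(reads_by_sample, labels, candidate_genes, params, name=name)
    save_repository(repo, out_dir)
    return repo


def run_predict(
    reads_path: str | Path,
    repo_dir: str | Path,
    out_json: str | Path,
    sam_path: str | Path | None = None,
    abundance_tsv: str | Path | None = None,
) -> PredictionReport:
    """File-level predict: reads + repository directory → JSON report."""
    repo = load_repository(repo_dir)
    reads = list(_io.read_sequences(reads_path)) if reads_path else []
    report = predict_sample(
        reads,
        repo,
        sample_id=Path(reads_path).name.split(".")[0] if reads_path else "query",
        sam_path=sam_path,
    )
    report.to_json(out_json)
    if abundance_tsv is not None:
        with open(abundance_tsv, "w") as fh:
            fh.write("gene_id\trpkm\n")
            for gid in repo.feature_order:
                fh.write(f"{gid}\t{report.gene_abundances[gid]:.6g}\n")
    return report
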