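"""End-to-end orchestration of the deconvolution workflow.

Stage order: coverage -> 16S identification -> homology taxonomy ->
graph taxonomy extension -> composition -> per-rank ensemble
classification with graph-based prediction correction -> (flow A)
UMAP+DBSCAN target-cluster selection with graph extension to short
contigs, or (flow B) direct extraction of the voted target contigs.
Both algorithms (SVM and RF) produce parallel, independently complete
output trees; a single master seed governs all randomness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import clustering as clu
from .classifier import infer_rank_targets, infer_target_lineage, nested_classify
from .composition import build_kmer_matrix, kmer_feature_columns
from .coverage import compute_coverage
from .evaluation import PerformanceReport, score
from .io import (
    ContigSet,
    RunConfig,
    SixteenSRecord,
    build_16s_records,
    ensure_output_layout,
    filter_hits,
    read_16s_gff,
    read_contigs,
    read_hits,
    read_lineage,
    read_mate_links,
    read_table,
    write_table,
)
from .pair_graph import build_graph, transfer_labels, write_edge_list
from .taxonomy import TaxonomyLabels, assign_taxonomy, identify_16s_target

logger = logging.getLogger("endobin")

_ALGO_FOLDER = {"svm": "SVMoutput", "rf": "RFoutput"}
_CLUSTER_FOLDER = {"svm": "ClusteringOutputSVM", "rf": "ClusteringOutputRF"}


@dataclass
class PipelineInputs:
    """Parsed inputs of one run."""

    contigs: ContigSet
    links: pd.DataFrame
    hits: pd.DataFrame                       # filtered, nt+protein merged
    lineage: pd.DataFrame
    gff_16s: pd.DataFrame | None = None      # contig_id,start,end,strand
    hits_16s: pd.DataFrame | None = None
    sixteen_s: list[SixteenSRecord] | None = None
    truth: dict[str, str] | None = None      # contig -> target/other

    @classmethod
    def from_paths(
        cls,
        cfg: RunConfig,
        contigs_path,
        links_path,
        nt_hits_path=None,
        prot_hits_path=None,
        lineage_path=None,
        gff_16s_path=None,
        hits_16s_path=None,
        truth_path=None,
    ) -> "PipelineInputs":
        contigs = read_contigs(contigs_path)
        links = read_mate_links(links_path, min_mapq=cfg.min_mapq)
        tables = []
        if nt_hits_path:
            tables.append(read_hits(nt_hits_path, "nucleotide", cfg, contigs=contigs))
        if prot_hits_path:
            tables.append(read_hits(prot_hits_path, "protein", cfg, contigs=contigs))
        if not tables:
            raise ValueError("at least one homology hit table is required")
        hits = pd.concat(tables, ignore_index=True)
        lineage = read_lineage(lineage_path)
        gff = read_16s_gff(gff_16s_path) if gff_16s_path else None
        hits16 = (
            read_hits(hits_16s_path, "nucleotide", cfg, contigs=contigs)
            if hits_16s_path else None
        )
        truth = None
        if truth_path:
            tab = read_table(truth_path)
            truth = dict(zip(tab["contig_id"], tab["truth"]))
        return cls(contigs=contigs, links=links, hits=hits, lineage=lineage,
                   gff_16s=gff, hits_16s=hits16, truth=truth)

    @classmethod
    def from_mixture(cls, mixture, cfg: RunConfig, rank: str | None = None) -> "PipelineInputs":
        """Wire a :class:`~endobin.synthetic.SyntheticMixture` directly."""
        truth = None
        if cfg.target_rank_label is not None:
            if rank is None:
                # truth rank = the rank at which the target label lives
                from .io import CANONICAL_RANKS

                rank = next(
                    (r for r in CANONICAL_RANKS
                     if r in mixture.truth.columns
                     and (mixture.truth[r] == cfg.target_rank_label).any()),
                    cfg.rank_sequence[-1],
                )
            truth = mixture.truth_map(rank, cfg.target_rank_label)
        return cls(
            contigs=mixture.contigs,
            links=mixture.links,
            hits=filter_hits(mixture.hits, cfg),
            lineage=mixture.lineage,
            sixteen_s=[SixteenSRecord(r.contig_id, r.start, r.end, r.strand,
                                      dict(r.assigned_taxon), r.contig_coverage)
                       for r in mixture.sixteen_s],
            truth=truth,
        )


@dataclass
class PipelineState:
    """Stage checkpoints and per-algorithm results of one run."""

    cfg: RunConfig
    stages: dict[str, bool] = field(default_factory=dict)
    artifacts: dict[str, Path] = field(default_factory=dict)
    coverage: pd.DataFrame | None = None
    labels: TaxonomyLabels | None = None
    target_16s_contig: str | None = None
    target_sets: dict[str, set[str]] = field(default_factory=dict)
    cluster_extension_added: dict[str, set[str]] = field(default_factory=dict)
    reports: dict[str, PerformanceReport] = field(default_factory=dict)
    heldout_accuracy: dict[str, float] = field(default_factory=dict)


def run_pipeline(
    cfg: RunConfig,
    inputs: PipelineInputs,
    outdir: str | Path | None = None,
    algos: tuple[str, ...] = ("svm", "rf"),
) -> PipelineState:
    """Run the full workflow and (optionally) write the standard output tree."""
    if cfg.target_rank_label is None:
        raise ValueError("run_pipeline requires cfg.target_rank_label")
    state = PipelineState(cfg=cfg)
    folders = ensure_output_layout(outdir) if outdir is not None else None
    final_rank = cfg.rank_sequence[-1]
    # the target label may sit at a finer rank than the last classification
    # rank (e.g. a class-level target with superkingdom-only classification):
    # classification extracts the target's ancestor at final_rank, while the
    # 16S anchor is matched at the target label's own rank
    target_rank, _ = infer_target_lineage(inputs.lineage, cfg.target_rank_label)
    restrict_label = infer_rank_targets(
        inputs.lineage, cfg.rank_sequence, cfg.target_rank_label
    )[final_rank]

    def _stage(name):
        def wrap(fn):
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            state.stages[name] = True
            return result
        return wrap

    # -- coverage -----------------------------------------------------------
    coverage = _stage("coverage")(lambda: compute_coverage(inputs.links, inputs.contigs))
    state.coverage = coverage

    # -- 16S identification -------------------------------------------------
    def _records():
        if inputs.sixteen_s is not None:
            cov = dict(zip(coverage["contig_id"], coverage["coverage"]))
            for rec in inputs.sixteen_s:
                rec.contig_coverage = float(cov.get(rec.contig_id, rec.contig_coverage))
            return inputs.sixteen_s
        if inputs.gff_16s is None or inputs.hits_16s is None:
            return []
        return build_16s_records(inputs.gff_16s, inputs.hits_16s, inputs.lineage,
                                 coverage=coverage, contigs=inputs.contigs)

    records = _stage("sixteen_s")(_records)
    if cfg.clustering_enabled:
        state.target_16s_contig = identify_16s_target(
            records, cfg.target_rank_label, target_rank
        )

    # -- homology taxonomy + graph extension --------------------------------
    def _taxonomy():
        labels = TaxonomyLabels()
        for rank in cfg.rank_sequence:
            labels.merge(assign_taxonomy(inputs.hits, inputs.lineage, rank, cfg))
        return labels

    labels = _stage("taxonomy")(_taxonomy)
    graph = _stage("graph")(lambda: build_graph(inputs.links, cfg))
    for rank in cfg.rank_sequence:
        labels, ext_report = transfer_labels(graph, labels, rank, cfg,
                                             mode="extend_taxonomy")
        if folders:
            write_table(ext_report,
                        folders["Taxonomy"] / f"graph_extension_{rank}.tsv")
    state.labels = labels
    state.stages["taxonomy_extension"] = True

    # -- composition --------------------------------------------------------
    kmat = _stage("composition")(lambda: build_kmer_matrix(inputs.contigs, cfg))

    if folders:
        write_table(coverage, folders["Coverage"] / "coverage.tsv")
        comp = kmat.reset_index()
        cov_map = dict(zip(coverage["contig_id"], coverage["coverage"]))
        comp.insert(2, "coverage", comp["contig_id"].map(cov_map))
        cols = ["contig_id", "gc", "coverage"] + kmer_feature_columns(kmat)
        write_table(comp[cols], folders["Coverage"] / "composition.tsv")
        write_table(labels.to_frame(), folders["Taxonomy"] / "labels.tsv")
        write_table(inputs.hits, folders["Taxonomy"] / "filtered_hits.tsv")
        write_edge_list(graph, folders["Taxonomy"] / "pair_graph_edges.tsv")

    # -- classification + target extraction, per algorithm ------------------
    for algo in algos:
        labels_a, vms = nested_classify(
            kmat, labels, algo, cfg, graph=graph, lineage=inputs.lineage,
            coverage=coverage,
        )
        state.heldout_accuracy[algo] = float(
            pd.concat([vm.replicate_scores["accuracy"] for vm in vms]).mean()
        )
        if folders:
            folder = folders[_ALGO_FOLDER[algo]]
            for vm in vms:
                write_table(vm.votes.rename_axis("contig_id").reset_index(),
                            folder / f"votes_{vm.rank}.tsv")
                write_table(vm.replicate_scores, folder / f"heldout_{vm.rank}.tsv")
            write_table(labels_a.to_frame(), folder / "labels.tsv")

        predicted_target = sorted(
            c for c in kmat.index
            if labels_a.label_of(c, final_rank) == restrict_label
        )

        if cfg.clustering_enabled:
            assign = clu.embed_and_cluster(kmat.loc[predicted_target], coverage, cfg)
            target_set = clu.select_target_cluster(assign, state.target_16s_contig)
            extended, cluster_report = clu.extend_target_set(target_set, assign, graph, cfg)
            state.cluster_extension_added[algo] = extended - target_set
            final_set = extended
            if folders:
                folder = folders[_CLUSTER_FOLDER[algo]]
                write_table(assign.frame.rename_axis("contig_id").reset_index(),
                            folder / "clusters.tsv")
                write_table(cluster_report, folder / "cluster_extension.tsv")
        else:
            final_set = set(predicted_target)
            folder = folders[_ALGO_FOLDER[algo]] if folders else None

        state.target_sets[algo] = final_set
        state.stages[f"classification_{algo}"] = True

        if folders:
            folder = folders[_CLUSTER_FOLDER[algo] if cfg.clustering_enabled
                             else _ALGO_FOLDER[algo]]
            (folder / "target_contigs.txt").write_text(
                "\n".join(sorted(final_set)) + "\n"
            )
            inputs.contigs.subset(sorted(final_set)).write_fasta(
                folder / "target_contigs.fasta"
            )
            state.artifacts[f"target_fasta_{algo}"] = folder / "target_contigs.fasta"

        if inputs.truth is not None:
            report = score(final_set, inputs.truth, inputs.contigs.lengths)
            state.reports[algo] = report
            if folders:
                write_table(report.to_frame(), folder / "performance.tsv")
            logger.info("performance (%s):\n%s", algo, report.summary())

    state.stages["clustering"] = cfg.clustering_enabled
    return state
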