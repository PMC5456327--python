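"""End-to-end orchestration: harmonization -> consensus merging ->
functionality tags -> enrichment -> fold-change clustering -> disease
and regulatory overlays, driven by one run configuration.

Every stage writes its table to the output directory and contributes
counts to a funnel report, so a run is auditable and byte-reproducible:
identical configuration and inputs give identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

import fabrymeta.cluster as fc
import fabrymeta.disease as fdis
import fabrymeta.enrich as fen
import fabrymeta.io_formats as fio
import fabrymeta.merge as fm
import fabrymeta.simulate as fsim
import fabrymeta.tags as ft
from fabrymeta.errors import ConfigError
from fabrymeta.harmonize import (ThresholdConfig, apply_thresholds,
                                 collapse_within_study, map_identifiers)

logger = logging.getLogger(__name__)

GROUP_ORDER = ("naive", "ERT")


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run.

    Optional inputs (gene sets, disease tables, regulatory edges) switch
    their stages on; the core funnel always runs.
    """

    measurements: str
    studies: str
    alias_map: str
    outdir: str
    gene_sets: str | None = None
    disease_tables: dict = field(default_factory=dict)  # group -> path
    edge_files: tuple = ()
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    enrichment: fen.EnrichmentConfig = field(
        default_factory=fen.EnrichmentConfig)
    min_sources: int = 2
    overlap_granularity: str = "fluid"
    cluster_metric: str = "euclidean"
    cluster_linkage: str = "average"
    min_networks: int = 2
    seed: int = 0
    make_figures: bool = False

    def validate(self) -> None:
        for label, p in [("measurements", self.measurements),
                         ("studies", self.studies),
                         ("alias_map", self.alias_map),
                         ("gene_sets", self.gene_sets),
                         *[(f"disease_tables[{g}]", p)
                           for g, p in self.disease_tables.items()],
                         *[("edge_file", p) for p in self.edge_files]]:
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{label} path does not exist: {p}")
        if int(self.seed) != self.seed:
            raise ConfigError("seed must be an integer")


def _write(df: pd.DataFrame, outdir: Path, name: str, outputs: list) -> None:
    df.to_csv(outdir / name, sep="\t", index=False)
    outputs.append(name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and return the run report.

    The report holds the filtering funnel (input, mapped, collapsed,
    thresholded, consensus, removed contradictions, overlapping), the
    per-group up/down totals, every parameter used, and the list of
    written artifacts. It is also written to ``report.json``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    measurements, studies = fio.read_measurements(
        config.measurements, config.studies)
    alias_map = fio.read_alias_map(config.alias_map)

    mapped, unmapped = map_identifiers(measurements, alias_map)
    _write(unmapped, outdir, "unmapped.tsv", outputs)

    features, dropped_groups = collapse_within_study(
        mapped, return_dropped=True)
    _write(features, outdir, "harmonized.tsv", outputs)
    _write(dropped_groups, outdir, "within_study_conflicts.tsv", outputs)

    thresholded = apply_thresholds(features, studies, config.thresholds)
    _write(thresholded, outdir, "thresholded.tsv", outputs)

    gene_sets = fio.read_gmt(config.gene_sets) if config.gene_sets else None

    funnel = {
        "n_measurements": len(measurements),
        "n_mapped": len(mapped),
        "n_unmapped": len(unmapped),
        "n_collapse_groups_total": len(features) + len(dropped_groups),
        "n_features_after_collapse": len(features),
        "n_within_study_conflicts_dropped": len(dropped_groups),
        "n_features_after_threshold": len(thresholded),
        "n_features_rejected_by_threshold":
            len(features) - len(thresholded),
    }
    groups_report = {}
    consensus_frames = []
    for group in GROUP_ORDER:
        consensus, removed = fm.consistency_merge(thresholded, group, studies)
        consensus_frames.append(consensus)
        _write(consensus, outdir, f"consensus_{group}.tsv", outputs)
        _write(removed, outdir, f"removed_contradictions_{group}.tsv", outputs)
        grp_rep = {
            "n_consensus": len(consensus),
            "n_removed_contradictions": len(removed),
            "n_distinct_clusters": len(consensus) + len(removed),
            "n_up": int((consensus["direction"] == "up").sum()),
            "n_down": int((consensus["direction"] == "down").sum()),
        }
        if len(consensus):
            tag_summary = ft.summarize_tags(consensus, group)
            _write(tag_summary, outdir, f"tags_{group}.tsv", outputs)
        if gene_sets and len(consensus):
            directions = dict(zip(consensus["cluster_id"],
                                  consensus["direction"]))
            results = fen.enrich(consensus["cluster_id"], gene_sets,
                                 directions=directions,
                                 config=config.enrichment)
            _write(results, outdir, f"enrichment_{group}.tsv", outputs)
            term_groups = fen.group_terms(results, gene_sets,
                                          config.enrichment)
            tg = pd.DataFrame(
                [(g.representative, ",".join(g.members),
                  round(g.mean_kappa, 6)) for g in term_groups],
                columns=["representative", "members", "mean_kappa"])
            _write(tg, outdir, f"term_groups_{group}.tsv", outputs)
            zs = fen.pathway_zscores(consensus["cluster_id"], gene_sets,
                                     config.enrichment)
            zs["z"] = zs["z"].round(6)
            _write(zs, outdir, f"zscores_{group}.tsv", outputs)
            grp_rep["n_significant_terms"] = int(
                (results["p_adjusted"] < config.enrichment.alpha).sum())
            grp_rep["n_term_groups"] = len(term_groups)
            grp_rep["n_significant_zscores"] = int(zs["significant"].sum())
        disease_path = config.disease_tables.get(group)
        if disease_path and len(consensus):
            table = fdis.read_disease_table(disease_path)
            ranking = fdis.rank_shared_genes(consensus["cluster_id"], table)
            _write(ranking, outdir, f"disease_ranking_{group}.tsv", outputs)
            grp_rep["n_diseases_with_shared_genes"] = len(ranking)
        groups_report[group] = grp_rep

    overlaps = fm.find_overlaps(thresholded, studies,
                                min_sources=config.min_sources,
                                granularity=config.overlap_granularity)
    _write(overlaps, outdir, "overlaps.tsv", outputs)
    funnel["n_overlapping"] = len(overlaps)

    clustering_report = {}
    if len(overlaps):
        matrix, annotations = fc.build_matrix(
            thresholded, overlaps["cluster_id"], studies)
        matrix, dropped_rows = fc.filter_pairwise_complete(matrix)
        clustering_report["n_rows_dropped_for_sparsity"] = len(dropped_rows)
        mat_out = matrix.round(6).reset_index()
        _write(mat_out, outdir, "matrix.tsv", outputs)
        clustering_report["n_matrix_rows"] = int(matrix.shape[0])
        clustering_report["n_matrix_columns"] = int(matrix.shape[1])
        if matrix.shape[0] >= 2:
            tree = fc.hcluster(matrix, metric=config.cluster_metric,
                               method=config.cluster_linkage)
            table = fc.linkage_table(tree)
            table["height"] = table["height"].round(6)
            _write(table, outdir, "linkage.tsv", outputs)
            clustering_report["leaf_order"] = [
                tree.labels[i] for i in tree.leaf_order]
            if config.make_figures:
                fc.plot_heatmap(matrix, annotations, outdir / "heatmap.png",
                                row_tree=tree)
                outputs.append("heatmap.png")

    overlay_report = {}
    if config.edge_files:
        edges = [e for p in config.edge_files for e in fio.read_edges(p)]
        query = set()
        for consensus in consensus_frames:
            query |= set(consensus["cluster_id"])
        directions = {}
        for consensus in consensus_frames:
            directions.update(zip(consensus["cluster_id"],
                                  consensus["direction"]))
        overlay = fdis.regulatory_overlay(query, edges,
                                          min_networks=config.min_networks,
                                          directions=directions)
        fdis.write_overlay_sif(overlay, outdir / "overlay.sif")
        outputs.append("overlay.sif")
        overlay_report = {
            "status": overlay.status,
            "n_networks": overlay.n_networks,
            "n_edges": overlay.graph.number_of_edges(),
        }

    parameters = {
        "thresholds": asdict(config.thresholds),
        "enrichment": asdict(config.enrichment),
        "min_sources": config.min_sources,
        "overlap_granularity": config.overlap_granularity,
        "cluster_metric": config.cluster_metric,
        "cluster_linkage": config.cluster_linkage,
        "min_networks": config.min_networks,
        "seed": config.seed,
    }
    report = {
        "parameters": parameters,
        "funnel": funnel,
        "groups": groups_report,
        "clustering": clustering_report,
        "overlay": overlay_report,
        "outputs": sorted(outputs),
    }
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def simulate_inputs(outdir: str | Path, seed: int = 0,
                    config: fsim.GeneratorConfig | None = None) -> RunConfig:
    """Write synthetic inputs to a directory and return a ready RunConfig.

    Also writes ``truth.tsv`` recording the planted structure.
    """
    cfg = config or fsim.GeneratorConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    measurements, studies, alias_map, truth = fsim.generate_studies(cfg, seed)
    gene_sets = fsim.generate_gene_sets(truth, cfg, seed)
    fio.write_measurements(measurements, outdir / "measurements.tsv")
    fio.write_studies(studies, outdir / "studies.tsv")
    fio.write_alias_map(alias_map, outdir / "aliases.tsv")
    fio.write_gmt(gene_sets, outdir / "gene_sets.gmt")
    fsim.write_truth(truth, outdir / "truth.tsv")
    return RunConfig(
        measurements=str(outdir / "measurements.tsv"),
        studies=str(outdir / "studies.tsv"),
        alias_map=str(outdir / "aliases.tsv"),
        gene_sets=str(outdir / "gene_sets.gmt"),
        outdir=str(outdir / "results"),
        seed=seed,
    )
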