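"""End-to-end orchestration: preprocessing through panel analytics.

Each test condition gets its own subdirectory of artifacts; a single master
seed is expanded into fixed per-stage seeds so a rerun with the same config
reproduces every deterministic artifact bit for bit. The run manifest
records seeds, thresholds, stage counts and checksums of the text artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analytics, annotations as annot_io, core_data, graph_builder, panels
from .dgi import EmbeddingMatrix, GCNConfig, train_and_embed
from .errors import CoexpanelError, ConfigurationError
from .fixtures import PHOTO_PATHWAY

logger = logging.getLogger(__name__)

# per-stage offsets applied to the master seed
SEED_LAYOUT, SEED_TRAIN, SEED_CLUSTER, SEED_MODULARITY = 0, 1, 2, 3


@dataclass
class PipelineConfig:
    """Everything a full run needs; mirrors the documented defaults."""

    expression_path: str = ""
    design_path: str = ""
    annotation_path: str = ""
    deg_table_paths: dict = field(default_factory=dict)  # condition -> path
    test_conditions: list = field(default_factory=lambda: ["blue", "yellow"])
    control_condition: str = "dark"
    min_mean_expression: float = 1.0
    target_mean_degree: float = 5.0
    degree_tolerance: float = 0.25
    perplexity: float = 20.0
    tsne_max_iter: int = 1000
    tsne_theta: float = 0.4
    use_subcellular: bool = True
    gcn: dict = field(default_factory=dict)
    cluster_candidates: list = field(default_factory=lambda: [24, 10, 7])
    default_n_clusters: int = 7
    pca_dims: int = 16
    reference_pathway: str = PHOTO_PATHWAY
    fas_k: int = 2
    pd_keywords: list = field(default_factory=lambda: list(analytics.PD_KEYWORDS))
    enrichment_p_max: float = 0.01
    enrichment_fc_low: float = 0.5
    enrichment_fc_high: float = 2.0
    enrichment_min_fpkm: float = 10.0
    network_r_min: float = 0.9
    network_p_max: float = 0.05
    seed: int = 0
    output_dir: str = "coexpanel_run"

    def __post_init__(self) -> None:
        for name in (
            "min_mean_expression",
            "target_mean_degree",
            "perplexity",
            "enrichment_p_max",
            "network_r_min",
            "network_p_max",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls(**raw)

    def gcn_config(self, seed: int) -> GCNConfig:
        return GCNConfig(**{"seed": seed, **self.gcn})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class Pipeline:
    """Stage-by-stage runner over a run directory."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.output_dir)
        self.manifest: dict = {
            "config": asdict(config),
            "seed": config.seed,
            "stages": {},
            "conditions": {},
        }

    # -- inputs ---------------------------------------------------------

    def load_inputs(self) -> None:
        cfg = self.config
        for label, path in (
            ("expression", cfg.expression_path),
            ("design", cfg.design_path),
            ("annotations", cfg.annotation_path),
        ):
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"{label} file not found: {path!r}")
        design = core_data.read_design_table(cfg.design_path)
        self.expr = core_data.read_expression_table(cfg.expression_path, design)
        self.annot = annot_io.read_annotation_table(cfg.annotation_path)
        for cond in cfg.test_conditions + [cfg.control_condition]:
            if cond not in self.expr.conditions:
                raise ConfigurationError(f"condition {cond!r} missing from design")
        self.manifest["stages"]["inputs"] = {
            "n_genes": len(self.expr.gene_ids),
            "n_samples": len(self.expr.sample_ids),
            "conditions": self.expr.conditions,
        }

    # -- stages ---------------------------------------------------------

    def stage_preprocess(self) -> None:
        cfg = self.config
        valid: dict[str, pd.DataFrame] = {}
        counts = {}
        for cond in cfg.test_conditions:
            if cond in cfg.deg_table_paths:
                degs = core_data.read_deg_table(cfg.deg_table_paths[cond])
            else:
                degs = core_data.differential_expression(
                    self.expr, cond, cfg.control_condition
                )
            vdeg = core_data.filter_valid_degs(degs, cfg.min_mean_expression)
            valid[cond] = vdeg
            counts[cond] = {"degs": int(degs["is_deg"].sum()), "valid_degs": len(vdeg)}
            cdir = self.outdir / cond
            cdir.mkdir(parents=True, exist_ok=True)
            core_data.write_deg_table(degs, cdir / "degs.tsv")
            core_data.write_deg_table(vdeg, cdir / "valid_degs.tsv")
        self.datasets = core_data.split_condition_datasets(
            self.expr, valid, cfg.control_condition
        )
        self.manifest["stages"]["preprocess"] = counts

    def stage_graph(self, cond: str) -> None:
        cfg = self.config
        ds = self.datasets[cond]
        norm = core_data.log_normalize(ds.expression.data)
        aligned = annot_io.align_annotations(self.annot, norm.index)
        graph = graph_builder.graph_from_dataset(
            norm,
            aligned,
            use_subcellular=cfg.use_subcellular,
            perplexity=cfg.perplexity,
            max_iter=cfg.tsne_max_iter,
            theta=cfg.tsne_theta,
            target_mean_degree=cfg.target_mean_degree,
            degree_tolerance=cfg.degree_tolerance,
            seed=cfg.seed + SEED_LAYOUT,
        )
        cdir = self.outdir / cond
        graph_builder.write_layout(graph, cdir / "layout.tsv")
        graph_builder.write_edge_list(graph, cdir / "edges.tsv")
        pd.DataFrame(
            graph.X,
            index=graph.node_ids,
            columns=[*norm.columns, "signal_peptide", "transmembrane"],
        ).rename_axis("gene_id").to_csv(cdir / "features.tsv", sep="\t")
        self.graphs = getattr(self, "graphs", {})
        self.graphs[cond] = graph
        self.manifest["conditions"].setdefault(cond, {})["graph"] = {
            "n_nodes": graph.n_nodes,
            "n_edges": int(len(graph.edges)),
            "mean_degree": graph.mean_degree,
            "threshold": graph.threshold,
            **{k: v for k, v in graph.metadata.items()},
        }

    def stage_train(self, cond: str) -> None:
        cfg = self.config
        graph = self.graphs[cond]
        emb, state = train_and_embed(graph, cfg.gcn_config(cfg.seed + SEED_TRAIN))
        cdir = self.outdir / cond
        emb.to_frame().to_csv(cdir / "embeddings.tsv", sep="\t")
        state.training_log.to_csv(cdir / "training_log.csv", index=False)
        self.embeddings = getattr(self, "embeddings", {})
        self.embeddings[cond] = emb
        self.manifest["conditions"][cond]["train"] = {
            "epochs_run": len(state.training_log),
            "best_objective": float(state.training_log["objective"].max()),
        }

    def stage_cluster(self, cond: str) -> None:
        cfg = self.config
        emb = self.embeddings[cond]
        cdir = self.outdir / cond
        assigns: dict[int, panels.PanelAssignment] = {}
        for n in cfg.cluster_candidates:
            assign = panels.cluster_panels(
                emb, n, cfg.pca_dims, seed=cfg.seed + SEED_CLUSTER
            )
            assigns[n] = assign
            assign.to_frame().to_csv(cdir / f"assignments_n{n}.tsv", sep="\t", index=False)
        self.assignments = getattr(self, "assignments", {})
        self.assignments[cond] = assigns
        self.manifest["conditions"][cond]["cluster"] = {
            "candidates": list(cfg.cluster_candidates)
        }

    def stage_evaluate(self, cond: str) -> None:
        cfg = self.config
        ds = self.datasets[cond]
        assigns = self.assignments[cond]
        aligned = annot_io.align_annotations(self.annot, ds.gene_ids)
        ref_genes = annot_io.pathway_members(aligned, cfg.reference_pathway)
        cdir = self.outdir / cond
        if ref_genes:
            chosen, report = panels.select_cluster_number(
                assigns, ref_genes, k=cfg.fas_k
            )
            report.to_csv(cdir / "cluster_number_report.csv", index=False)
        else:
            logger.warning(
                "reference pathway %r absent from %s; defaulting to n=%d",
                cfg.reference_pathway,
                cond,
                cfg.default_n_clusters,
            )
            chosen = cfg.default_n_clusters
        expr_matrix = ds.expression.data.to_numpy(float)
        evalrep = panels.evaluation_report(
            expr_matrix,
            assigns.values(),
            {cfg.reference_pathway: ref_genes} if ref_genes else {},
            k=cfg.fas_k,
        )
        evalrep.to_csv(cdir / "evaluation.csv", index=False)
        self.chosen_n = getattr(self, "chosen_n", {})
        self.chosen_n[cond] = chosen
        self.manifest["conditions"][cond]["evaluate"] = {"chosen_n": chosen}

    def stage_analyze(self, cond: str) -> None:
        cfg = self.config
        ds = self.datasets[cond]
        assign = self.assignments[cond][self.chosen_n[cond]]
        aligned = annot_io.align_annotations(self.annot, ds.gene_ids)
        cdir = self.outdir / cond

        pd_genes = analytics.extract_function_genes(
            aligned, cfg.pd_keywords, ds.expression.data, cfg.min_mean_expression
        )
        photo_genes = annot_io.pathway_members(aligned, cfg.reference_pathway)
        designation = analytics.designate_panels(
            assign, pd_genes, photo_genes, ds.expression.data, ds.degs
        )
        designation.stats.to_csv(cdir / "designations.csv", index=False)

        light_samples = ds.expression.samples_of(cond)
        dark_samples = ds.expression.samples_of(cfg.control_condition)
        series = assign.as_series()
        analyzed: dict[str, list[str]] = {}
        for role, cluster in (("hgp", designation.hgp), ("sgp", designation.sgp)):
            if cluster is None:
                continue
            analyzed[role] = list(series.index[series == cluster])
        if designation.hgp is not None and designation.sgp is not None:
            analyzed["merged"] = sorted(set(analyzed["hgp"]) | set(analyzed["sgp"]))

        net_info = {}
        for role, members in analyzed.items():
            try:
                enr = analytics.enrich_pathways(
                    members,
                    aligned,
                    ds.expression.data,
                    light_samples,
                    dark_samples,
                    p_max=cfg.enrichment_p_max,
                    fc_low=cfg.enrichment_fc_low,
                    fc_high=cfg.enrichment_fc_high,
                    min_fpkm=cfg.enrichment_min_fpkm,
                )
                enr.to_csv(cdir / f"enrichment_{role}.csv", index=False)
            except CoexpanelError as exc:
                logger.warning("enrichment skipped for %s/%s: %s", cond, role, exc)
            if role == "merged" or len(members) < 2:
                continue
            net = analytics.build_topology_network(
                ds.expression.data.loc[members],
                r_min=cfg.network_r_min,
                p_max=cfg.network_p_max,
            )
            if net.number_of_edges() == 0:
                logger.warning("network for %s/%s has no edges", cond, role)
                continue
            metrics = analytics.compute_topology_metrics(
                net, seed=cfg.seed + SEED_MODULARITY
            )
            metrics.to_csv(cdir / f"network_{role}_metrics.tsv", sep="\t")
            analytics.export_network(net, metrics, cdir / f"network_{role}.gexf")
            landmarks = analytics.landmark_genes(
                metrics, ds.expression.data, light_samples
            )
            pd.DataFrame(
                [
                    {"modularity_class": cid, "rank": i + 1, "gene_id": g}
                    for cid, glist in sorted(landmarks.items())
                    for i, g in enumerate(glist)
                ]
            ).to_csv(cdir / f"landmarks_{role}.tsv", sep="\t", index=False)
            net_info[role] = {
                "n_nodes": net.number_of_nodes(),
                "n_edges": net.number_of_edges(),
                "n_classes": int(metrics["modularity_class"].nunique()),
            }
        self.manifest["conditions"][cond]["analyze"] = {
            "n_pd_genes": len(pd_genes),
            "n_reference_pathway_genes": len(photo_genes),
            "hgp": designation.hgp,
            "sgp": designation.sgp,
            "conflict": designation.conflict,
            "networks": net_info,
        }

    # -- orchestration --------------------------------------------------

    def run(self) -> Path:
        self.outdir.mkdir(parents=True, exist_ok=True)
        stage = "load_inputs"
        try:
            self.load_inputs()
            stage = "preprocess"
            self.stage_preprocess()
            for cond in self.config.test_conditions:
                for stage_name, fn in (
                    ("graph", self.stage_graph),
                    ("train", self.stage_train),
                    ("cluster", self.stage_cluster),
                    ("evaluate", self.stage_evaluate),
                    ("analyze", self.stage_analyze),
                ):
                    stage = f"{stage_name}[{cond}]"
                    fn(cond)
        except Exception as exc:
            (self.outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
            raise CoexpanelError(f"pipeline failed at stage {stage}: {exc}") from exc
        self._write_manifest()
        return self.outdir

    def _write_manifest(self) -> None:
        checksums = {}
        for path in sorted(self.outdir.rglob("*")):
            if path.is_file() and path.suffix in {".tsv", ".csv", ".json"}:
                checksums[str(path.relative_to(self.outdir))] = _sha256(path)
        self.manifest["checksums"] = checksums
        (self.outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True, default=_jsonify)
        )


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    return Pipeline(config).run()
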