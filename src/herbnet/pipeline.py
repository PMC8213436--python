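"""End-to-end pipeline: annotate -> DEG -> counter-regulation -> network ->
hub extraction -> key-constituent selection -> enrichment.

A :class:`PipelineConfig` carries every threshold with the study defaults
(5 mDa / 10 ppm mass tolerance, fold change 2 and p < 0.05, similarity 0.80,
QED 0.49, hub-rule multipliers 2/1/1, top-30 enrichment) so a bare run on
synthetic inputs reproduces the study parameterization.  Each applied
threshold is logged, making a run auditable against its configuration.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from . import annotate as ann
from . import diffexpr as de
from . import enrichment as enr
from . import io as hio
from . import network as net
from . import selection as sel
from .synthetic import GeneratorConfig, generate_all

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths (or a generator config) plus every stage threshold."""

    # input paths; all must be set unless a generator config is given
    features_csv: Optional[str] = None
    library_csv: Optional[str] = None
    counts_prefix: Optional[str] = None
    predictions_csv: Optional[str] = None
    constituent_library_csv: Optional[str] = None
    disease_genes_txt: Optional[str] = None
    ppi_tsv: Optional[str] = None
    genesets_gmt: Optional[str] = None
    generator: Optional[GeneratorConfig] = None

    # thresholds, study defaults
    tolerance_mda: float = 5.0
    tolerance_ppm: float = 10.0
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    similarity_threshold: float = 0.80
    qed_threshold: float = 0.49
    degree_mult: float = 2.0
    betweenness_mult: float = 1.0
    closeness_mult: float = 1.0
    enrichment_top: int = 30

    group_control: str = "Con"
    group_disease: str = "TNF"
    group_treated: str = "TNF+WBT"

    out_dir: Optional[str] = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("tolerance_mda", "tolerance_ppm", "fc_threshold", "p_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("similarity_threshold", "qed_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.generator is None:
            required = [
                "features_csv", "library_csv", "counts_prefix", "predictions_csv",
                "constituent_library_csv", "disease_genes_txt", "ppi_tsv",
                "genesets_gmt",
            ]
            missing = [n for n in required if getattr(self, n) is None]
            if missing:
                raise ValueError(
                    f"no generator configured and missing input path(s): {missing}"
                )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if gen is not None:
            if gen is True or gen == {}:
                cfg.generator = GeneratorConfig(seed=cfg.seed)
            else:
                cfg.generator = GeneratorConfig(**{**gen, "seed": gen.get("seed", cfg.seed)})
        cfg.validate()
        return cfg


@dataclass
class RunReport:
    """Per-stage counts, the configuration echo and wall time."""

    n_features: int = 0
    n_annotated_features: int = 0
    n_matches: int = 0
    deg1_up: int = 0
    deg1_down: int = 0
    deg1_total: int = 0
    deg2_up: int = 0
    deg2_down: int = 0
    deg2_total: int = 0
    n_counter_regulated: int = 0
    n_anti_genes: int = 0
    stage1_nodes: int = 0
    stage1_edges: int = 0
    stage1_density: Optional[float] = None
    n_core: int = 0
    stage2_nodes: int = 0
    stage2_edges: int = 0
    stage2_density: Optional[float] = None
    n_hubs: int = 0
    n_filtered_predictions: int = 0
    n_key_constituents: int = 0
    n_herbs: int = 0
    n_enriched_sets: int = 0
    top_enriched: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    config: dict = field(default_factory=dict)
    version: str = ""
    wall_time_s: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_text(self) -> str:
        lines = ["pipeline run report", "-" * 40]
        for k, v in self.to_dict().items():
            if k in ("config", "top_enriched", "warnings"):
                continue
            lines.append(f"{k:28s} {v}")
        if self.top_enriched:
            lines.append("top enriched sets: " + ", ".join(self.top_enriched[:5]))
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


def _load_inputs(cfg: PipelineConfig) -> dict:
    if cfg.generator is not None:
        logger.info("generating synthetic inputs (seed=%d)", cfg.generator.seed)
        return generate_all(cfg.generator)
    sets, desc = hio.read_gmt(cfg.genesets_gmt)
    disease = set(Path(cfg.disease_genes_txt).read_text().split())
    import pandas as pd

    return {
        "library": hio.read_library_csv(cfg.library_csv),
        "features": hio.read_feature_csv(cfg.features_csv),
        "counts": hio.read_counts(cfg.counts_prefix),
        "ppi": hio.read_edge_tsv(cfg.ppi_tsv),
        "predictions": pd.read_csv(cfg.predictions_csv),
        "constituent_library": pd.read_csv(cfg.constituent_library_csv),
        "disease_genes": disease,
        "gene_sets": sets,
        "universe": frozenset(),
        "ground_truth": None,
        "config": None,
    }


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute every stage in order; write tables/report when out_dir is set."""
    from . import __version__

    cfg.validate()
    t0 = time.time()
    report = RunReport(version=__version__)
    data = _load_inputs(cfg)
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # 1. MS annotation ------------------------------------------------------
    tol = ann.Tolerance(cfg.tolerance_mda, cfg.tolerance_ppm)
    logger.info("mass tolerance: %.1f mDa / %.1f ppm (inclusive OR)", tol.mda, tol.ppm)
    matches = ann.match_features(data["features"], data["library"], tolerance=tol)
    report.n_features = len(data["features"])
    report.n_matches = len(matches)
    report.n_annotated_features = len({m.feature for m in matches})
    if out:
        import pandas as pd

        pd.DataFrame(
            [
                (m.feature.rt, m.feature.mz, m.feature.polarity, m.compound,
                 m.adduct, m.theoretical_mz, m.error_mda, m.error_ppm)
                for m in matches
            ],
            columns=["rt", "mz", "polarity", "compound", "adduct",
                     "theoretical_mz", "error_mda", "error_ppm"],
        ).to_csv(out / "annotations.csv", index=False)

    # 2. differential expression + counter-regulation -----------------------
    logger.info("DEG thresholds: fold change >= %.1f, p < %.3f",
                cfg.fc_threshold, cfg.p_threshold)
    counts = data["counts"]
    deg1 = de.call_degs(counts, cfg.group_control, cfg.group_disease,
                        cfg.fc_threshold, cfg.p_threshold)
    deg2 = de.call_degs(counts, cfg.group_disease, cfg.group_treated,
                        cfg.fc_threshold, cfg.p_threshold)
    counter = de.counter_regulated(deg1, deg2)
    report.deg1_up, report.deg1_down, report.deg1_total = deg1.n_up, deg1.n_down, deg1.n_total
    report.deg2_up, report.deg2_down, report.deg2_total = deg2.n_up, deg2.n_down, deg2.n_total
    report.n_counter_regulated = len(counter)
    if out:
        deg1.table.to_csv(out / "deg_disease_vs_control.csv")
        deg2.table.to_csv(out / "deg_treated_vs_disease.csv")
        (out / "counter_regulated.txt").write_text("\n".join(sorted(counter)) + "\n")

    # 3. anti-inflammatory gene set -----------------------------------------
    # the counter-regulated genes are the anti-inflammatory seed of the
    # tripartite network; with too few of them the union of both DEG lists
    # is used instead
    anti = counter if len(counter) >= 2 else set(deg1.flagged) | set(deg2.flagged)
    report.n_anti_genes = len(anti)

    # 4. tripartite network + two-stage hub extraction ----------------------
    preds = sel.filter_predictions(
        data["predictions"], cfg.similarity_threshold, cfg.qed_threshold
    )
    report.n_filtered_predictions = len(preds)
    logger.info("prediction filters: similarity >= %.2f, QED >= %.2f",
                cfg.similarity_threshold, cfg.qed_threshold)
    graph = net.build_network(anti, preds, data["disease_genes"], data["ppi"])
    hubres = net.extract_hubs(
        graph, data["ppi"],
        degree_mult=cfg.degree_mult,
        betweenness_mult=cfg.betweenness_mult,
        closeness_mult=cfg.closeness_mult,
    )
    report.stage1_nodes = hubres.stage1.n_nodes
    report.stage1_edges = hubres.stage1.n_edges
    report.stage1_density = hubres.stage1.density
    report.n_core = len(hubres.core)
    if hubres.stage2 is not None:
        report.stage2_nodes = hubres.stage2.n_nodes
        report.stage2_edges = hubres.stage2.n_edges
        report.stage2_density = hubres.stage2.density
    report.n_hubs = len(hubres.hubs)
    report.warnings.extend(hubres.warnings)
    if out:
        hio.write_json(hubres.to_dict(), out / "hub_result.json")
        hio.write_graphml(graph, out / "network.graphml")

    # 5. key-constituent selection ------------------------------------------
    scores = sel.hub_target_frequency(preds, hubres.hubs or hubres.core or anti,
                                      library=data["constituent_library"])
    selection = sel.select_key_constituents(scores)
    report.n_key_constituents = len(selection.selected)
    report.n_herbs = selection.n_herbs
    if out:
        scores.to_csv(out / "constituent_scores.csv", index=False)
        hio.write_json(
            {
                "selected": sorted(selection.selected),
                "median_frequency": selection.median_frequency,
                "median_content": selection.median_content,
                "herbs": selection.herbs,
            },
            out / "key_constituents.json",
        )

    # 6. enrichment ----------------------------------------------------------
    collection = enr.GeneSetCollection(dict(data["gene_sets"]),
                                       universe=data.get("universe") or frozenset())
    query = hubres.hubs or hubres.core
    result = enr.enrich(query, collection, top=cfg.enrichment_top) if query else None
    if result is not None:
        report.n_enriched_sets = int((result["qvalue"] < 0.05).sum())
        report.top_enriched = list(result["set"].head(10))
        if out:
            result.to_csv(out / "enrichment.csv", index=False)
    else:
        report.warnings.append("enrichment skipped: empty hub set")

    report.config = {k: v for k, v in asdict(cfg).items() if k != "generator"}
    if cfg.generator is not None:
        report.config["generator"] = asdict(cfg.generator)
    report.wall_time_s = round(time.time() - t0, 3)
    if out:
        hio.write_json(report.to_dict(), out / "report.json")
        (out / "report.txt").write_text(report.to_text() + "\n")
        if data.get("ground_truth") is not None:
            data["ground_truth"].to_json(out / "ground_truth.json")
    return report
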