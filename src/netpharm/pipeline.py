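"""End-to-end orchestration of the screening stages.

Compound ADMET screen → disease-target union → drug/disease Venn
intersection → compound-target bipartite network → PPI core extraction
→ over-representation analysis (optionally plus a dose-response fit),
all from one configuration, writing every intermediate artifact and a
JSON run report of stage-by-stage counts.  Reruns on identical inputs
produce identical reports.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

from . import bioassay_stats, compound_screen, enrichment, ppi_core, target_sets

__all__ = ["PipelineConfig", "PipelineError", "run", "REPORT_SCHEMA"]

logger = logging.getLogger("netpharm")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths and thresholds for one full run.

    Thresholds default to the conventional screen settings: peak area
    > 0.12 %, target-prediction score >= 0.8, PPI confidence >= 0.9,
    two conjunctive median-filter rounds on all four centralities, raw
    p <= 0.05 with top-10 GO / top-30 pathway reporting.
    """

    compound_table: str
    disease_lists: Sequence[str]
    drug_target_map: str
    ppi_edges: str
    gmt_files: dict  # category -> path
    out_dir: str
    plate: Optional[str] = None
    min_peak_area_pct: float = 0.12
    target_score_floor: float = 0.8
    ppi_min_score: float = 0.9
    core_metrics: Sequence[str] = ppi_core.ALL_METRICS
    core_rounds: int = 2
    enrich_alpha: float = 0.05
    top_go: int = 10
    top_pathway: int = 30
    enrich_on: str = "common"  # "common" | "core"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.min_peak_area_pct):
            raise ValueError("min_peak_area_pct must be >= 0")
        for name, v in (("target_score_floor", self.target_score_floor), ("ppi_min_score", self.ppi_min_score)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.enrich_on not in ("common", "core"):
            raise ValueError("enrich_on must be 'common' or 'core'")


#: Minimal JSON schema the run report validates against.
REPORT_SCHEMA = {
    "type": "object",
    "required": ["stages", "flags", "core_genes", "significant_terms"],
    "properties": {
        "stages": {"type": "object"},
        "flags": {"type": "array"},
        "core_genes": {"type": "array"},
        "significant_terms": {"type": "integer"},
    },
}


def validate_report(report: dict) -> None:
    """Check the report against :data:`REPORT_SCHEMA` (structure + types)."""
    for key in REPORT_SCHEMA["required"]:
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
    if not isinstance(report["stages"], dict) or not isinstance(report["flags"], list):
        raise ValueError("report stage/flag containers have wrong types")
    if not isinstance(report["core_genes"], list) or not isinstance(report["significant_terms"], int):
        raise ValueError("report core/term fields have wrong types")


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
                raise PipelineError(name, exc) from exc
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run(cfg: PipelineConfig) -> dict:
    """Execute the full screen; returns (and writes) the run report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {"stages": {}, "flags": [], "core_genes": [], "significant_terms": 0}
    try:
        _run_stages(cfg, out, report)
    except PipelineError:
        (out / "FAILED").write_text("pipeline aborted; partial outputs retained\n")
        raise
    validate_report(report)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "report.md").write_text(_render_markdown(report))
    return report


def _run_stages(cfg: PipelineConfig, out: Path, report: dict) -> None:
    # -- compound screen
    @_stage("compound_screen")
    def stage_compounds():
        pairs = compound_screen.parse_compound_table(cfg.compound_table)
        rules = compound_screen.ScreenRules(min_peak_area_pct=cfg.min_peak_area_pct)
        have_areas = all(rec.peak_area_pct is not None for rec, _ in pairs)
        if have_areas:
            kept_recs = set(id(r) for r in compound_screen.filter_peaks([r for r, _ in pairs], rules))
            pairs_peak = [(r, p) for r, p in pairs if id(r) in kept_recs]
        else:
            pairs_peak = pairs
            report["flags"].append("no_peak_areas")
        log: list = []
        passed = compound_screen.admet_filter(pairs_peak, rules, rejection_log=log)
        compound_screen.write_compound_table(passed, out / "compounds_passed.tsv")
        with open(out / "compounds_rejected.tsv", "w") as fh:
            fh.write("name\tfailed_rule\n")
            for name, rule in log:
                fh.write(f"{name}\t{rule}\n")
        report["stages"]["compounds"] = {
            "parsed": len(pairs), "after_peak_filter": len(pairs_peak), "passed_admet": len(passed),
        }
        return passed

    passed = stage_compounds()

    # -- targets
    @_stage("target_sets")
    def stage_targets():
        disease_sets = []
        for p in cfg.disease_lists:
            ts, stats = target_sets.load_gene_list(p, name=Path(p).stem, kind="disease")
            disease_sets.append(ts)
        disease_union, per_source = target_sets.union_disease_targets(disease_sets)
        cmap = target_sets.load_target_map(cfg.drug_target_map, score_floor=cfg.target_score_floor)
        drug = target_sets.TargetSet(name="drug", genes=cmap.all_targets(), kind="drug")
        common = target_sets.intersect_drug_disease(drug, disease_union)
        target_sets.write_gene_list(common, out / "common_targets.txt")
        with open(out / "venn_counts.tsv", "w") as fh:
            fh.write("set_a\tset_b\tcount\n")
            for row in target_sets.venn_counts(disease_sets + [drug]):
                fh.write(f"{row['set_a']}\t{row['set_b']}\t{row['count']}\n")
        net = target_sets.build_bipartite(cmap, common)
        target_sets.write_sif(net, out / "drug_target_network.sif")
        report["stages"]["targets"] = {
            "per_source": per_source,
            "disease_union": len(disease_union.genes),
            "drug_targets": len(drug.genes),
            "common_targets": len(common.genes),
            "bipartite_edges": len(net.edges),
        }
        if len(common.genes) == 0:
            report["flags"].append("no_common_targets")
        return common

    common = stage_targets()

    # -- PPI core
    @_stage("ppi_core")
    def stage_ppi():
        g_full = ppi_core.load_edge_list(cfg.ppi_edges, min_score=cfg.ppi_min_score)
        g = g_full.subgraph([v for v in g_full if v in common.genes]).copy()
        if g.number_of_nodes():
            result = ppi_core.extract_core(g, metrics=cfg.core_metrics, rounds=cfg.core_rounds)
            ppi_core.write_centrality_table(g, out / "centrality.tsv")
        else:
            result = ppi_core.CoreExtractionResult(rounds=[], core_nodes=[], exhausted=True)
        (out / "core_targets.txt").write_text("".join(f"{v}\n" for v in result.core_nodes))
        report["stages"]["ppi"] = {
            "graph_nodes": g.number_of_nodes(),
            "graph_edges": g.number_of_edges(),
            "rounds": result.rounds,
            "core_size": len(result.core_nodes),
            "exhausted": result.exhausted,
        }
        report["core_genes"] = list(result.core_nodes)
        return result

    core = stage_ppi()

    # -- enrichment
    @_stage("enrichment")
    def stage_enrich():
        query_genes = common.genes if cfg.enrich_on == "common" else frozenset(core.core_nodes)
        query = target_sets.TargetSet(name="query", genes=query_genes, kind="drug") if query_genes \
            else target_sets.TargetSet(name="query", genes=frozenset(), kind="drug")
        records: list = []
        if query_genes:
            collection = []
            for cat, path in cfg.gmt_files.items():
                collection.extend(enrichment.read_gmt(path, category=cat))
            records = enrichment.run_ora(query, collection)
        top = enrichment.select_top(
            records,
            per_category={"BP": cfg.top_go, "CC": cfg.top_go, "MF": cfg.top_go, "pathway": cfg.top_pathway},
            alpha=cfg.enrich_alpha,
        )
        enrichment.write_enrichment_table(records, out / "enrichment.tsv")
        enrichment.write_enrichment_table(top, out / "enrichment_top.tsv")
        sig = [r for r in records if r.p_value <= cfg.enrich_alpha]
        report["stages"]["enrichment"] = {
            "tested_terms": len(records),
            "significant": len(sig),
            "reported_top": len(top),
        }
        report["significant_terms"] = len(sig)

    stage_enrich()

    # -- optional dose-response
    if cfg.plate:
        @_stage("bioassay")
        def stage_assay():
            doses, ods, blank, control = bioassay_stats.read_plate(cfg.plate)
            viab = bioassay_stats.plate_viability(doses, ods, blank, control)
            fit = bioassay_stats.fit_ic50(doses, viab, seed=cfg.seed)
            report["stages"]["bioassay"] = {
                "ic50": fit.ic50, "hill": fit.hill, "lower": fit.lower, "upper": fit.upper,
                "residual_se": fit.residual_se, "in_range": fit.in_range,
            }

        stage_assay()


def _render_markdown(report: dict) -> str:
    lines = ["# Screening run report", ""]
    for stage, payload in report["stages"].items():
        lines.append(f"## {stage}")
        for k, v in payload.items():
            lines.append(f"- {k}: {v}")
        lines.append("")
    if report["core_genes"]:
        lines.append("## Core targets (degree-ranked)")
        lines.append(", ".join(report["core_genes"]))
        lines.append("")
    if report["flags"]:
        lines.append("## Flags")
        lines.extend(f"- {f}" for f in report["flags"])
        lines.append("")
    return "\n".join(lines)
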