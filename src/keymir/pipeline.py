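"""End-to-end orchestration: expression → static → dynamic → modules → rank.

The stages mirror the study's narrative: classify drug-reversed
dysregulated miRNAs from the four-group expression table, score their
regulatory capacity (static score, on one or two PPI networks), score their
regulatory efficiency (dynamic perturbation score), locate their regulatory
emphasis (largest cohesive module of the target-induced subnetwork, scored
against disease gene sets), and finally rank the candidates.

The ranking rule codifies the narrative filter as an explicit lexicographic
sort, so it is testable: keep reversed miRNAs with enhanced static
regulation (on both networks when two are given), order by the disease-set
enrichment p-value of the largest module (ascending), then dynamic score
(descending), then identifier.  This is this package's interpretation; the
original analysis combined the same evidence narratively.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import expression as expr
from . import modules as mod
from . import network as netmod
from . import perturbation as pert
from .errors import InputError, NotFoundError, UndefinedResultError

logger = logging.getLogger("keymir")


@dataclass
class PipelineConfig:
    """Every tunable constant of the analysis, with the study's defaults."""

    # expression stage
    group_map: dict[str, str] = field(default_factory=dict)
    dysregulation_threshold: float = 0.5   # log2 units
    reversal_fold_threshold: float = 1.5   # linear fold, strict
    # network stage
    confidence_threshold: float = 0.7
    static_offset: float = 3.3
    static_cutoff: float = 0.6
    target_p_cutoff: float = 0.01
    # perturbation stage
    association_constant: float = 1.0
    fold_over: float = 0.5
    fold_under: float = 2.0
    subgroup_thresholds: tuple[float, float] = (1.2, 2.0)
    solver_tol: float = 1e-10
    solver_max_iter: int = 10000
    # module stage
    clusterone_penalty: float = 2.0
    clusterone_min_size: int = 3
    clusterone_min_density: float = 0.5
    clusterone_overlap_merge: float = 0.8
    enrichment_p_cutoff: float = 0.05
    disease_set_id: str | None = None      # None -> best adjusted p over sets
    # bookkeeping
    rng_seed: int = 0
    # inputs (file mode; in-memory mode passes objects to run_pipeline)
    expression_path: str | None = None
    edges_path: str | None = None
    edges2_path: str | None = None         # optional second network
    targets_path: str | None = None
    abundance_path: str | None = None
    gene_sets_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if "subgroup_thresholds" in payload:
            payload["subgroup_thresholds"] = tuple(
                payload["subgroup_thresholds"])
        return cls(**payload)

    def to_dict(self) -> dict:
        payload = dataclasses.asdict(self)
        payload["subgroup_thresholds"] = list(self.subgroup_thresholds)
        return payload


@dataclass
class MiRNAScoreRecord:
    """All per-miRNA evidence combined across stages."""

    mirna_id: str
    call: expr.DysregulationCall
    static_net1: netmod.StaticScoreRecord | None = None
    static_net2: netmod.StaticScoreRecord | None = None
    enhanced_net1: bool | None = None
    enhanced_net2: bool | None = None
    enhanced_both: bool | None = None
    dynamic: pert.MiRNAPerturbationRecord | None = None
    target_confidence: float | None = None
    largest_module: mod.FunctionalModule | None = None
    disease_enrichment_p: float | None = None


@dataclass
class PipelineResult:
    config: PipelineConfig
    records: dict[str, MiRNAScoreRecord]
    ranking: list[str]
    similarity: pd.DataFrame | None
    correlation: dict | None
    manifest: dict


def _sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    digest.update(Path(path).read_bytes())
    return digest.hexdigest()


def _disease_p(module: mod.FunctionalModule | None,
               disease_set_id: str | None) -> float | None:
    """Adjusted enrichment p of the configured disease set (or the best set)."""
    if module is None or not module.enrichment:
        return None
    if disease_set_id is None:
        return min(r.adjusted_p for r in module.enrichment)
    for r in module.enrichment:
        if r.gene_set_id == disease_set_id:
            return r.adjusted_p
    return None


def rank_key_mirnas(records: Mapping[str, MiRNAScoreRecord]) -> list[str]:
    """Filter to reversed miRNAs with enhanced static regulation and sort.

    Sort key: disease-set enrichment p of the largest module ascending
    (missing module/enrichment sorts last), then dynamic score descending
    (missing last), then miRNA identifier.  Returns an ordered identifier
    list; empty (with a warning) when no candidate passes the filter.
    """
    candidates = [r for r in records.values()
                  if r.call.is_prmir and r.enhanced_both]

    def sort_key(r: MiRNAScoreRecord):
        p = r.disease_enrichment_p
        d = r.dynamic.dynamic_score if (r.dynamic is not None and
                                        r.dynamic.dynamic_score is not None) \
            else None
        return (p is None, p if p is not None else 0.0,
                d is None, -(d if d is not None else 0.0),
                r.mirna_id)

    if not candidates:
        logger.warning("no reversed miRNA passed the enhanced-static filter; "
                       "ranking is empty")
        return []
    return [r.mirna_id for r in sorted(candidates, key=sort_key)]


def run_pipeline(config: PipelineConfig,
                 table: expr.ExpressionTable | None = None,
                 net1: netmod.PPINetwork | None = None,
                 net2: netmod.PPINetwork | None = None,
                 target_map: netmod.TargetMap | None = None,
                 abundance: Mapping[str, float] | None = None,
                 gene_sets: mod.GeneSetCollection | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full analysis; inputs come from files named in the config
    unless passed in memory.  Writes the report bundle when ``out_dir`` is
    given."""
    manifest: dict = {"config": config.to_dict(), "inputs": {}}

    # ---- load inputs -----------------------------------------------------
    if table is None:
        if config.expression_path is None:
            raise InputError("no expression table provided")
        table = expr.ExpressionTable.read_tsv(config.expression_path,
                                              group_map=config.group_map)
        manifest["inputs"]["expression"] = _sha256(config.expression_path)
    if net1 is None:
        if config.edges_path is None:
            raise InputError("no PPI edge list provided")
        net1 = netmod.build_network(config.edges_path,
                                    config.confidence_threshold)
        manifest["inputs"]["edges"] = _sha256(config.edges_path)
    if net2 is None and config.edges2_path is not None:
        net2 = netmod.build_network(config.edges2_path,
                                    config.confidence_threshold)
        manifest["inputs"]["edges2"] = _sha256(config.edges2_path)
    if target_map is None:
        if config.targets_path is None:
            raise InputError("no target map provided")
        target_map = netmod.TargetMap.read_tsv(config.targets_path)
        manifest["inputs"]["targets"] = _sha256(config.targets_path)
    if abundance is None and config.abundance_path is not None:
        abundance = netmod.read_abundance_tsv(config.abundance_path)
        manifest["inputs"]["abundance"] = _sha256(config.abundance_path)
    if gene_sets is None and config.gene_sets_path is not None:
        gene_sets = mod.GeneSetCollection.read_gmt(config.gene_sets_path)
        manifest["inputs"]["gene_sets"] = _sha256(config.gene_sets_path)

    if not target_map.entries:
        raise InputError("static stage: empty target map")
    target_genes = target_map.all_genes()
    if not target_genes & set(net1.nodes):
        examples = sorted(target_genes)[:5]
        raise InputError(f"identifier-space mismatch: no target gene appears "
                         f"in the PPI network (examples: {examples})")

    # ---- expression stage ------------------------------------------------
    logger.info("expression stage: %d miRNAs", len(table.mirnas))
    calls = expr.detect_dysregulated(table, config.dysregulation_threshold)
    calls = expr.identify_prmirs(calls, table,
                                 config.reversal_fold_threshold)
    records = {c.mirna_id: MiRNAScoreRecord(c.mirna_id, c) for c in calls}
    dmirs = [c.mirna_id for c in calls if c.is_dysregulated]
    similarity = None
    if len(dmirs) >= 3:
        try:
            similarity = expr.similarity_matrix(table, dmirs)
        except UndefinedResultError as err:
            logger.warning("similarity matrix undefined: %s", err)

    # ---- static stage ----------------------------------------------------
    logger.info("static stage: %d dysregulated miRNAs on %d-node network",
                len(dmirs), net1.number_of_nodes())
    static1, static2 = [], []
    for mirna in dmirs:
        entry = target_map.entries.get(mirna, [])
        if entry:
            records[mirna].target_confidence = \
                netmod.target_confidence_summary(entry, config.target_p_cutoff)
        rec1 = netmod.static_score(net1, target_map.genes(mirna),
                                   config.static_offset, config.static_cutoff,
                                   mirna_id=mirna, network_id="net1")
        records[mirna].static_net1 = rec1
        static1.append(rec1)
        if net2 is not None:
            rec2 = netmod.static_score(net2, target_map.genes(mirna),
                                       config.static_offset,
                                       config.static_cutoff,
                                       mirna_id=mirna, network_id="net2")
            records[mirna].static_net2 = rec2
            static2.append(rec2)
    if net2 is None:
        logger.info("single-network mode: enhanced_both degrades to the "
                    "first network's flag")
    flags = netmod.classify_enhanced(static1,
                                     static2 if net2 is not None else None,
                                     config.static_cutoff)
    for mirna, f in flags.items():
        records[mirna].enhanced_net1 = f["enhanced_net1"]
        records[mirna].enhanced_net2 = f["enhanced_net2"]
        records[mirna].enhanced_both = f["enhanced_both"]

    # ---- dynamic stage ---------------------------------------------------
    if abundance is not None:
        matched = netmod.attach_abundance(net1, abundance)
        logger.info("dynamic stage: %d/%d nodes with measured abundance",
                    matched, net1.number_of_nodes())
    if all("abundance" in net1.nodes[v] for v in net1.nodes):
        directions = {c.mirna_id: c.direction for c in calls}
        dyn_records = pert.score_all_mirnas(
            net1, target_map, directions=directions,
            K=config.association_constant, fold_over=config.fold_over,
            fold_under=config.fold_under,
            thresholds=config.subgroup_thresholds,
            tol=config.solver_tol, max_iter=config.solver_max_iter,
            mirnas=dmirs)
        for rec in dyn_records:
            records[rec.mirna_id].dynamic = rec
        correlation = None
        try:
            scores = {r.mirna_id: r.dynamic_score for r in dyn_records}
            covariate = {r.mirna_id: r.mean_log2_target_abundance
                         for r in dyn_records}
            r, p, n = pert.correlate(scores, covariate)
            correlation = {"pearson_r": r, "p_value": p, "n": n}
        except UndefinedResultError as err:
            logger.warning("dynamic-score correlation undefined: %s", err)
    else:
        logger.warning("no abundances available; dynamic stage skipped")
        correlation = None

    # ---- module stage ----------------------------------------------------
    universe = set(net1.nodes)
    for mirna in dmirs:
        if not (records[mirna].call.is_prmir and records[mirna].enhanced_both):
            continue
        sub = mod.target_subnetwork(net1, target_map.genes(mirna))
        if sub.number_of_nodes() == 0:
            continue
        found = mod.cluster_one(sub, config.clusterone_penalty,
                                config.clusterone_min_size,
                                config.clusterone_min_density,
                                config.clusterone_overlap_merge)
        try:
            top = mod.largest_module(found)
        except NotFoundError:
            continue
        if gene_sets is not None and len(gene_sets):
            top = mod.enrich_module(top, gene_sets, universe)
        records[mirna].largest_module = top
        records[mirna].disease_enrichment_p = _disease_p(
            top, config.disease_set_id)

    # ---- ranking + report ------------------------------------------------
    ranking = rank_key_mirnas(records)
    result = PipelineResult(config, records, ranking, similarity,
                            correlation, manifest)
    if out_dir is not None:
        write_report(result, out_dir)
    return result


def scores_to_frame(records: Mapping[str, MiRNAScoreRecord]) -> pd.DataFrame:
    rows = []
    for mirna in sorted(records):
        r = records[mirna]
        dyn = r.dynamic

        def opt(value):
            return np.nan if value is None else value

        rows.append({
            "mirna_id": mirna,
            "delta_disease": r.call.delta_disease,
            "direction": r.call.direction,
            "is_dysregulated": r.call.is_dysregulated,
            "is_prmir": r.call.is_prmir,
            "reversal_fold": r.call.reversal_fold,
            "static_score_net1": opt(r.static_net1.static_score
                                     if r.static_net1 else None),
            "static_score_net2": opt(r.static_net2.static_score
                                     if r.static_net2 else None),
            "enhanced_net1": r.enhanced_net1,
            "enhanced_net2": r.enhanced_net2,
            "enhanced_both": r.enhanced_both,
            "dynamic_score": opt(dyn.dynamic_score if dyn else None),
            "mean_log2_target_abundance":
                opt(dyn.mean_log2_target_abundance if dyn else None),
            "target_confidence": opt(r.target_confidence),
            "largest_module_size": opt(r.largest_module.size
                                       if r.largest_module else None),
            "disease_enrichment_p": opt(r.disease_enrichment_p),
        })
    return pd.DataFrame(rows).set_index("mirna_id")


def write_report(result: PipelineResult, out_dir: str | Path) -> None:
    """Write the report bundle: score table, similarity matrix, module
    memberships, correlation summary, ranking and run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scores_to_frame(result.records).to_csv(out / "mirna_scores.tsv",
                                           sep="\t", float_format="%.6g")
    if result.similarity is not None:
        result.similarity.to_csv(out / "similarity.tsv", sep="\t",
                                 float_format="%.6g")
    with open(out / "modules.tsv", "w") as handle:
        handle.write("mirna_id\tsize\tcohesiveness\tdensity\tmembers\n")
        for mirna in sorted(result.records):
            m = result.records[mirna].largest_module
            if m is None:
                continue
            handle.write(f"{mirna}\t{m.size}\t{m.cohesiveness:.6g}\t"
                         f"{m.density:.6g}\t{','.join(sorted(m.members))}\n")
    with open(out / "enrichment.tsv", "w") as handle:
        handle.write("mirna_id\tgene_set_id\toverlap\tp_value\tadjusted_p\n")
        for mirna in sorted(result.records):
            m = result.records[mirna].largest_module
            if m is None:
                continue
            for e in m.enrichment:
                handle.write(f"{mirna}\t{e.gene_set_id}\t{e.overlap}\t"
                             f"{e.p_value:.6g}\t{e.adjusted_p:.6g}\n")
    (out / "ranking.txt").write_text(
        "".join(f"{m}\n" for m in result.ranking))
    if result.correlation is not None:
        (out / "correlation.json").write_text(
            json.dumps(result.correlation, indent=2, sort_keys=True))
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True))
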