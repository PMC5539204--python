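"""End-to-end pipeline driver.

Stage order mirrors the analysis design: gene differential expression
(quantile normalization + moderated t), miRNA quantification on the Ct scale
(geNorm reference selection + efficiency-corrected ratios with the
randomization test), consensus-target anti-correlation network construction
with Jaccard overlaps and topology statistics, and over-representation
analysis with kappa clustering.  Every stage writes its outputs under the
configured output directory and contributes counts to a machine-readable
run report; rerunning with the same config and inputs reproduces identical
outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import PipelineConfig
from .de import DifferentialExpression, filter_de, quantile_normalize
from .enrich import EnrichmentAnalysis, GeneSetCollection
from .errors import InputError
from .network import (
    AlgorithmRegistry,
    augment_with_ppi,
    build_network,
    consensus_targets,
    jaccard_overlap,
    topology_stats,
)
from .qpcr import RelativeExpression, genorm_stability

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _select_references(ct: pd.DataFrame, candidates: list[str], n_references: int):
    """geNorm-rank candidate normalizers and keep the most stable ones."""
    if len(candidates) < 3:
        return list(candidates), None
    stability = genorm_stability(ct[ct["target"].isin(candidates)])
    return stability.ranking[: min(n_references, len(candidates))], stability


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the run report (also written as JSON)."""
    missing = [str(p) for p in config.required_inputs().values() if not p.exists()]
    if missing:
        raise InputError(f"missing input file(s): {missing}")

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": {}, "warnings": []}

    # ---------------------------------------------------------- gene DE
    genes = io.read_expression(config.gene_expression)
    groups = io.read_sample_map(config.sample_map)
    if config.quantile_normalization:
        genes = quantile_normalize(genes)
    model = DifferentialExpression(genes, groups, reference=config.control_group)
    de = model.fit()
    genes_up, genes_down = de.filter(fc_cut=config.fc_cut, p_cut=config.p_cut, use_adjusted=config.use_adjusted)
    de.to_tsv(out / "de_genes.tsv")
    io.write_id_list(genes_up, out / "de_genes_up.txt")
    io.write_id_list(genes_down, out / "de_genes_down.txt")
    report["stages"]["gene_de"] = {
        "n_features": int(len(de.table)),
        "n_up": len(genes_up),
        "n_down": len(genes_down),
        "d0": float(de.d0) if np.isfinite(de.d0) else "inf",
        "s0sq": float(de.s0sq),
        "quantile_normalized": bool(config.quantile_normalization),
    }

    # --------------------------------------------------------- miRNA DE
    ct = io.read_ct(config.mirna_ct)
    all_targets = sorted(set(ct["target"]))
    candidates = list(config.reference_mirnas) or [t for t in all_targets if t.startswith("ref_")]
    if not candidates:
        raise InputError("no candidate reference targets: set reference_mirnas or prefix ids with 'ref_'")
    references, stability = _select_references(ct, candidates, config.n_references)
    if stability is not None:
        io.write_json(
            {
                "m_values": {k: float(v) for k, v in stability.m_values.items()},
                "ranking": stability.ranking,
                "exclusion_order": stability.exclusion_order,
                "pairwise_variation": {str(k): float(v) for k, v in stability.pairwise_variation.items()},
                "selected": references,
            },
            out / "genorm.json",
        )
    targets = [t for t in all_targets if t not in set(candidates)]
    rel = RelativeExpression(
        ct,
        groups,
        references=references,
        targets=targets,
        control=config.control_group,
        treated=config.case_group,
    ).fit(n_permutations=config.n_permutations, seed=config.seed % 2**31)
    mtab = rel.table.set_index("target")
    mirna_de_frame = pd.DataFrame({"log2fc": mtab["log2_ratio"], "p": mtab["p_value"], "p_adj": mtab["p_value"]})
    mirnas_up, mirnas_down = filter_de(
        mirna_de_frame, fc_cut=config.fc_cut, p_cut=config.p_cut, use_adjusted=config.use_adjusted
    )
    rel.to_tsv(out / "mirna_relative_expression.tsv")
    io.write_id_list(mirnas_up, out / "de_mirnas_up.txt")
    io.write_id_list(mirnas_down, out / "de_mirnas_down.txt")
    report["stages"]["mirna_de"] = {
        "n_targets": len(targets),
        "references_used": list(references),
        "n_up": len(mirnas_up),
        "n_down": len(mirnas_down),
    }

    # ------------------------------------------------------- integration
    predictions = io.read_predictions(config.predictions)
    registry = AlgorithmRegistry.from_table(predictions)
    candidates_df = consensus_targets(
        predictions, registry, min_algorithms=config.min_algorithms, accept_validated=config.accept_validated
    )
    gene_lfc = de.table["log2fc"].to_dict()
    mirna_lfc = mtab["log2_ratio"].to_dict()
    net = build_network(
        candidates_df,
        mirnas_up,
        mirnas_down,
        genes_up,
        genes_down,
        mirna_log2fc=mirna_lfc,
        gene_log2fc=gene_lfc,
    )
    if config.ppi:
        ppi = pd.read_csv(config.ppi, sep="\t", dtype=str)
        if not {"gene_1", "gene_2"} <= set(ppi.columns):
            raise InputError(f"PPI table {config.ppi} needs columns (gene_1, gene_2)")
        augment_with_ppi(net, ppi)
    jc = jaccard_overlap(net)
    stats = topology_stats(net)
    net.to_sif(out / "network.sif")
    net.to_graphml(out / "network.graphml")
    jc.to_csv(out / "jaccard_overlap.tsv", sep="\t", index=False, float_format="%.6g")
    io.write_json(stats.to_dict(), out / "topology.json")
    if net.n_skipped_unknown:
        report["warnings"].append(f"integration: skipped {net.n_skipped_unknown} candidate(s) referencing non-DE features")
    if net.n_skipped_ppi:
        report["warnings"].append(f"integration: skipped {net.n_skipped_ppi} PPI edge(s) with unmatched gene ids")
    report["stages"]["integration"] = {
        "n_candidate_pairs": int(len(candidates_df)),
        "n_edges": stats.n_interactions,
        "n_mirnas": stats.n_mirnas,
        "n_genes": stats.n_genes,
        "n_jaccard_edges": int(len(jc)),
        "n_dropped_same_direction": net.n_dropped_same_direction,
        "n_skipped_unknown": net.n_skipped_unknown,
    }

    # -------------------------------------------------------- enrichment
    collection = GeneSetCollection.from_gmt(config.gene_sets)
    universe = list(genes.index)
    enrich_report = {}
    for label, query in (
        ("de_genes", genes_up + genes_down),
        ("network_genes", net.genes),
    ):
        if not query:
            enrich_report[label] = {"n_query": 0, "n_tested": 0, "n_enriched": 0, "n_clusters": 0}
            continue
        res = EnrichmentAnalysis(query, collection, universe, min_overlap=config.min_overlap).fit()
        clustered, representatives = res.cluster(
            threshold=config.kappa_threshold, alpha=config.enrichment_p_cutoff
        )
        clustered.to_csv(out / f"enrichment_{label}.tsv", sep="\t", index=False, float_format="%.6g")
        enrich_report[label] = {
            "n_query": len(res.query),
            "n_tested": int(len(res.table)),
            "n_enriched": int(len(res.significant(config.enrichment_p_cutoff))),
            "n_clusters": len(representatives),
            "representatives": representatives,
        }
    report["stages"]["enrichment"] = enrich_report

    io.write_json(report, out / "report.json")
    return report
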