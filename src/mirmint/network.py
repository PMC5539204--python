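"""Consensus miRNA-target integration and anti-correlation network construction.

Candidate miRNA-gene interactions are pooled across several prediction
algorithms and curated validated-target databases.  A pair is retained when
at least ``min_algorithms`` distinct prediction algorithms report it, or
(optionally) when any curated database lists it as experimentally validated.
Retained candidates are then paired against differential-expression calls:
an edge miRNA -> gene enters the regulatory network only when both features
are differentially expressed in opposite directions (a repressor and its
target should be anti-correlated).  miRNA-miRNA overlap edges are weighted
by the Jaccard coefficient of the two target sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "AlgorithmRegistry",
    "consensus_targets",
    "build_network",
    "RegulatoryNetwork",
    "jaccard_overlap",
    "TopologyStats",
    "topology_stats",
    "augment_with_ppi",
]


@dataclass(frozen=True)
class AlgorithmRegistry:
    """Declares which evidence sources are prediction algorithms and which
    are curated validated-target databases."""

    prediction: frozenset[str]
    validated: frozenset[str]

    def __post_init__(self):
        overlap = self.prediction & self.validated
        if overlap:
            raise InputError(f"source(s) {sorted(overlap)} registered as both prediction and validated")

    @property
    def all_names(self) -> frozenset[str]:
        return self.prediction | self.validated

    @classmethod
    def from_table(cls, predictions: pd.DataFrame) -> "AlgorithmRegistry":
        """Infer the registry from a prediction table: any source that ever
        emits a validated row is treated as a curated database."""
        validated = frozenset(predictions.loc[predictions["validated"], "algorithm"])
        prediction = frozenset(predictions["algorithm"]) - validated
        return cls(prediction=prediction, validated=validated)


def consensus_targets(
    predictions: pd.DataFrame,
    registry: AlgorithmRegistry,
    min_algorithms: int = 4,
    accept_validated: bool = True,
) -> pd.DataFrame:
    """Filter pooled prediction evidence down to consensus candidate pairs.

    Returns a DataFrame with one row per retained (mirna, gene) pair and
    columns ``support`` (count of distinct prediction algorithms) and
    ``validated`` (any curated-database row; sticky over duplicates).
    """
    unknown = set(predictions["algorithm"]) - set(registry.all_names)
    if unknown:
        raise InputError(
            f"unknown algorithm name(s) {sorted(unknown)}; registry: "
            f"prediction={sorted(registry.prediction)}, validated={sorted(registry.validated)}"
        )
    df = predictions.copy()
    df["is_prediction"] = df["algorithm"].isin(registry.prediction)
    df["is_validated_row"] = df["algorithm"].isin(registry.validated) & df["validated"].astype(bool)

    grouped = df.groupby(["mirna", "gene"], sort=True).agg(
        support=("algorithm", lambda s: s[df.loc[s.index, "is_prediction"]].nunique()),
        validated=("is_validated_row", "any"),
    )
    keep = grouped["support"] >= min_algorithms
    if accept_validated:
        keep |= grouped["validated"]
    out = grouped[keep].reset_index()
    return out


@dataclass
class RegulatoryNetwork:
    """Bipartite miRNA -> gene regulatory network with overlap edges.

    ``graph`` is a networkx DiGraph; nodes carry attributes ``kind``
    ("mirna"/"gene"), ``direction`` ("up"/"down") and ``log2fc``; regulatory
    edges carry ``support`` and ``validated``.  miRNA-miRNA Jaccard-overlap
    edges and optional gene-gene protein-interaction annotation edges are
    stored with ``interaction`` attributes "mirna_overlap" and "ppi".
    """

    graph: nx.DiGraph
    n_skipped_unknown: int = 0
    n_dropped_same_direction: int = 0
    n_skipped_ppi: int = 0
    _jc: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def mirnas(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "mirna")

    @property
    def genes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "gene")

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {
            (u, v)
            for u, v, d in self.graph.edges(data=True)
            if d.get("interaction", "regulates") == "regulates"
        }

    def targets_of(self, mirna: str) -> set[str]:
        return {v for _, v, d in self.graph.out_edges(mirna, data=True) if d.get("interaction", "regulates") == "regulates"}

    # ------------------------------------------------------------- export
    def to_sif(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for u, v, d in sorted(self.graph.edges(data=True)):
                fh.write(f"{u}\t{d.get('interaction', 'regulates')}\t{v}\n")

    def to_graphml(self, path) -> None:
        g = self.graph.copy()
        for _, _, d in g.edges(data=True):
            d.setdefault("interaction", "regulates")
            if "validated" in d:
                d["validated"] = int(d["validated"])
        nx.write_graphml(g, path)


def _direction_map(up: list[str], down: list[str], log2fc: dict[str, float] | None, what: str):
    both = set(up) & set(down)
    if both:
        raise InputError(f"{what} feature(s) {sorted(both)} appear in both up and down lists")
    out = {}
    for f in up:
        out[f] = ("up", (log2fc or {}).get(f, float("nan")))
    for f in down:
        out[f] = ("down", (log2fc or {}).get(f, float("nan")))
    return out


def build_network(
    candidates: pd.DataFrame,
    de_mirnas_up: list[str],
    de_mirnas_down: list[str],
    de_genes_up: list[str],
    de_genes_down: list[str],
    mirna_log2fc: dict[str, float] | None = None,
    gene_log2fc: dict[str, float] | None = None,
) -> RegulatoryNetwork:
    """Build the anti-correlation regulatory network from consensus candidates.

    An edge is kept only when the miRNA and the gene are both differentially
    expressed and their directions are opposite.  Candidates whose miRNA or
    gene is not differentially expressed at all are skipped (counted);
    same-direction pairs are dropped (counted separately).  Nodes exist only
    for features with at least one retained edge.
    """
    mirna_dir = _direction_map(de_mirnas_up, de_mirnas_down, mirna_log2fc, "miRNA")
    gene_dir = _direction_map(de_genes_up, de_genes_down, gene_log2fc, "gene")

    g = nx.DiGraph()
    skipped = dropped = 0
    for row in candidates.itertuples(index=False):
        m, gene = row.mirna, row.gene
        if m not in mirna_dir or gene not in gene_dir:
            skipped += 1
            continue
        if mirna_dir[m][0] == gene_dir[gene][0]:
            dropped += 1
            continue
        g.add_node(m, kind="mirna", direction=mirna_dir[m][0], log2fc=mirna_dir[m][1])
        g.add_node(gene, kind="gene", direction=gene_dir[gene][0], log2fc=gene_dir[gene][1])
        g.add_edge(m, gene, interaction="regulates", support=int(row.support), validated=bool(row.validated))
    if skipped:
        logger.warning("build_network: skipped %d candidate(s) referencing non-DE features", skipped)
    return RegulatoryNetwork(graph=g, n_skipped_unknown=skipped, n_dropped_same_direction=dropped)


def jaccard_overlap(net: RegulatoryNetwork) -> pd.DataFrame:
    """miRNA-miRNA overlap edges weighted by the Jaccard coefficient.

    JC(m1, m2) = |T1 & T2| / |T1 | T2| over the two target sets; pairs with
    JC = 0 are omitted.  The edges are also written into the network graph
    with ``interaction="mirna_overlap"``.
    """
    mirnas = net.mirnas
    rows = []
    for i, m1 in enumerate(mirnas):
        t1 = net.targets_of(m1)
        for m2 in mirnas[i + 1 :]:
            t2 = net.targets_of(m2)
            if not t1 or not t2:
                continue
            inter = len(t1 & t2)
            if inter == 0:
                continue
            jc = inter / len(t1 | t2)
            rows.append((m1, m2, jc))
            net.graph.add_edge(m1, m2, interaction="mirna_overlap", jc=jc)
    jc_df = pd.DataFrame(rows, columns=["mirna_1", "mirna_2", "jc"])
    net._jc = jc_df
    return jc_df


@dataclass(frozen=True)
class TopologyStats:
    """Degree bookkeeping of a regulatory network."""

    n_interactions: int
    n_mirnas: int
    n_genes: int
    targets_per_mirna: dict[str, int]
    regulators_per_gene: dict[str, int]
    min_targets_k: int
    frac_mirnas_with_min_targets: float
    coregulation_m: int
    coregulated_genes: list[str]

    def to_dict(self) -> dict:
        return {
            "n_interactions": self.n_interactions,
            "n_mirnas": self.n_mirnas,
            "n_genes": self.n_genes,
            "targets_per_mirna": self.targets_per_mirna,
            "regulators_per_gene": self.regulators_per_gene,
            "min_targets_k": self.min_targets_k,
            "frac_mirnas_with_min_targets": self.frac_mirnas_with_min_targets,
            "coregulation_m": self.coregulation_m,
            "coregulated_genes": self.coregulated_genes,
        }


def topology_stats(net: RegulatoryNetwork, min_targets: int = 2, coregulation: int = 3) -> TopologyStats:
    """Summarize network topology: interaction counts, per-node degrees,
    the fraction of miRNAs with at least ``min_targets`` targets, and genes
    co-regulated by at least ``coregulation`` miRNAs."""
    edges = net.edges
    targets = {m: len(net.targets_of(m)) for m in net.mirnas}
    regulators: dict[str, int] = {g: 0 for g in net.genes}
    for _, g in edges:
        regulators[g] += 1
    n_mirnas = len(targets)
    frac = (sum(1 for c in targets.values() if c >= min_targets) / n_mirnas) if n_mirnas else 0.0
    coreg = sorted(g for g, c in regulators.items() if c >= coregulation)
    return TopologyStats(
        n_interactions=len(edges),
        n_mirnas=n_mirnas,
        n_genes=len(regulators),
        targets_per_mirna=targets,
        regulators_per_gene=regulators,
        min_targets_k=min_targets,
        frac_mirnas_with_min_targets=frac,
        coregulation_m=coregulation,
        coregulated_genes=coreg,
    )


def augment_with_ppi(net: RegulatoryNetwork, ppi_edges: pd.DataFrame) -> RegulatoryNetwork:
    """Annotate the network with gene-gene protein-interaction edges.

    ``ppi_edges`` needs columns (gene_1, gene_2) in the same gene-id
    namespace as the network.  Edges touching genes absent from the network
    are skipped and counted; regulatory edges are untouched.
    """
    genes = set(net.genes)
    skipped = 0
    for row in ppi_edges.itertuples(index=False):
        a, b = row.gene_1, row.gene_2
        if a in genes and b in genes:
            net.graph.add_edge(a, b, interaction="ppi")
        else:
            skipped += 1
    if skipped:
        logger.warning("augment_with_ppi: skipped %d edge(s) with unmatched gene ids", skipped)
    net.n_skipped_ppi = skipped
    return net
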