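"""Over-representation analysis and kappa-score clustering of enriched terms.

Enrichment of a query gene list against a gene-set collection uses the
upper-tail hypergeometric test: with a universe of N genes, a term of K
members and a query of n genes overlapping the term in k genes,

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

with Benjamini-Hochberg adjustment across tested terms.  Relationships
between enriched terms are quantified by Cohen's kappa on their gene
membership indicator vectors over the universe, and terms are grouped into
functional clusters as connected components of the graph whose edges join
term pairs with kappa at or above a threshold (0.3 by default); each
cluster is represented by its lowest-p term.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

__all__ = [
    "GeneSetCollection",
    "hypergeom_pvalue",
    "EnrichmentAnalysis",
    "EnrichmentResults",
    "kappa_matrix",
    "cluster_terms",
]


class GeneSetCollection:
    """A GMT-style collection: term id -> (description, member gene set)."""

    def __init__(self, sets: dict[str, tuple[str, list[str]]]):
        self._sets: dict[str, tuple[str, frozenset[str]]] = {}
        for term, (desc, members) in sets.items():
            ms = frozenset(members)
            if not ms:
                raise InputError(f"gene set {term!r} is empty")
            self._sets[term] = (desc, ms)

    def __len__(self):
        return len(self._sets)

    def __contains__(self, term):
        return term in self._sets

    def __iter__(self):
        return iter(self._sets)

    def members(self, term: str) -> frozenset[str]:
        return self._sets[term][1]

    def description(self, term: str) -> str:
        return self._sets[term][0]

    def items(self):
        return self._sets.items()

    def restricted_to(self, universe: set[str]) -> "GeneSetCollection":
        """Drop members outside the universe; terms left empty are removed."""
        out = {}
        for term, (desc, ms) in self._sets.items():
            kept = ms & universe
            if kept:
                out[term] = (desc, sorted(kept))
        return GeneSetCollection(out)

    def to_gmt(self, path) -> None:
        from . import io

        io.write_gmt({t: (d, sorted(m)) for t, (d, m) in self._sets.items()}, path)

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        from . import io

        return cls(io.read_gmt(path))


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k); k = 0 gives 1."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise InputError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class EnrichmentResults:
    """Per-term enrichment table plus clustering state.

    ``table`` columns: term, description, k, K, n, N, p, p_adj, genes
    (comma-joined overlap) — and, after :meth:`cluster`, a ``cluster``
    column with the representative term per cluster in ``representatives``.
    """

    table: pd.DataFrame
    universe: tuple[str, ...]
    query: tuple[str, ...]
    n_dropped_query: int
    collection: GeneSetCollection

    def significant(self, alpha: float = 0.001, use_adjusted: bool = False) -> pd.DataFrame:
        col = "p_adj" if use_adjusted else "p"
        return self.table[self.table[col] <= alpha]

    def kappa_matrix(self, alpha: float = 0.001, use_adjusted: bool = False) -> pd.DataFrame:
        terms = list(self.significant(alpha, use_adjusted)["term"])
        memberships = {t: self.collection.members(t) & set(self.universe) for t in terms}
        return kappa_matrix(memberships, universe=list(self.universe))

    def cluster(self, threshold: float = 0.3, alpha: float = 0.001, use_adjusted: bool = False):
        """Kappa-cluster the enriched terms; returns (table with cluster
        column, representative term per cluster)."""
        sig = self.significant(alpha, use_adjusted)
        if len(sig) == 0:
            out = self.table.copy()
            out["cluster"] = pd.NA
            return out, {}
        if len(sig) == 1:
            term = sig["term"].iloc[0]
            out = self.table.copy()
            out["cluster"] = out["term"].map({term: 1})
            return out, {1: term}
        kap = self.kappa_matrix(alpha, use_adjusted)
        pvals = pd.Series(sig["p"].to_numpy(), index=sig["term"].to_numpy())
        assignment, representatives = cluster_terms(kap, threshold=threshold, pvalues=pvals)
        out = self.table.copy()
        out["cluster"] = out["term"].map(assignment)
        return out, representatives

    def summary(self, alpha: float = 0.001) -> str:
        sig = self.significant(alpha)
        lines = [
            "Over-representation analysis (upper-tail hypergeometric)",
            f"  query: {len(self.query)} genes (dropped {self.n_dropped_query} outside universe); "
            f"universe: {len(self.universe)} genes; terms tested: {len(self.table)}",
            f"  enriched at p <= {alpha}: {len(sig)}",
            "",
            sig.head(10).to_string(index=False, float_format=lambda v: f"{v:.3g}"),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


class EnrichmentAnalysis:
    """Hypergeometric over-representation model for one query gene list.

    Parameters
    ----------
    query : gene ids of interest (e.g. a DE list or network targets);
        entries outside the universe are dropped with a count kept.
    collection : the gene-set collection to test.
    universe : background gene ids (typically all measured features).
    min_overlap : smallest query/term overlap for a term to be tested.
    """

    def __init__(self, query, collection: GeneSetCollection, universe, min_overlap: int = 1):
        universe = list(dict.fromkeys(universe))
        if not universe:
            raise InputError("empty universe")
        uni_set = set(universe)
        query = list(dict.fromkeys(query))
        if not query:
            raise InputError("empty query")
        kept = [g for g in query if g in uni_set]
        self.n_dropped_query = len(query) - len(kept)
        if not kept:
            raise InputError("no query gene is in the universe")
        self.query = kept
        self.universe = universe
        self.collection = collection.restricted_to(uni_set)
        self.min_overlap = min_overlap

    def fit(self) -> EnrichmentResults:
        n = len(self.query)
        N = len(self.universe)
        qset = set(self.query)
        rows = []
        for term, (desc, members) in sorted(self.collection.items()):
            K = len(members)
            overlap = sorted(members & qset)
            k = len(overlap)
            if k < self.min_overlap:
                continue
            rows.append((term, desc, k, K, n, N, hypergeom_pvalue(k, K, n, N), ",".join(overlap)))
        table = pd.DataFrame(rows, columns=["term", "description", "k", "K", "n", "N", "p", "genes"])
        if len(table):
            table["p_adj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
        else:
            table["p_adj"] = pd.Series(dtype=float)
        table = table[["term", "description", "k", "K", "n", "N", "p", "p_adj", "genes"]]
        table = table.sort_values(["p", "term"]).reset_index(drop=True)
        return EnrichmentResults(
            table=table,
            universe=tuple(self.universe),
            query=tuple(self.query),
            n_dropped_query=self.n_dropped_query,
            collection=self.collection,
        )


def kappa_matrix(memberships: dict[str, frozenset[str] | set[str]], universe: list[str]) -> pd.DataFrame:
    """Pairwise Cohen's kappa between term membership vectors.

    For terms A and B as 0/1 indicators over the universe of size N with
    joint counts n11, n10, n01, n00: observed agreement po = (n11 + n00)/N,
    chance agreement pe = ((n11+n10)(n11+n01) + (n01+n00)(n10+n00))/N^2 and
    kappa = (po - pe)/(1 - pe).  kappa(A, A) = 1 by convention; pairs with
    pe = 1 (both terms empty or both full) are reported as 0.
    """
    if len(memberships) < 2:
        raise InputError("kappa matrix needs >= 2 terms")
    terms = list(memberships)
    N = len(universe)
    m = np.zeros((len(terms), N), dtype=float)
    index = {g: i for i, g in enumerate(universe)}
    for i, t in enumerate(terms):
        for g in memberships[t]:
            if g in index:
                m[i, index[g]] = 1.0
    n11 = m @ m.T
    row = m.sum(axis=1)
    n10 = row[:, None] - n11
    n01 = row[None, :] - n11
    n00 = N - n11 - n10 - n01
    po = (n11 + n00) / N
    pe = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / N**2
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (po - pe) / (1.0 - pe)
    kappa = np.where(np.isclose(pe, 1.0), 0.0, kappa)
    np.fill_diagonal(kappa, 1.0)
    return pd.DataFrame(kappa, index=terms, columns=terms)


def cluster_terms(
    kappa: pd.DataFrame, threshold: float = 0.3, pvalues: pd.Series | None = None
) -> tuple[dict[str, int], dict[int, str]]:
    """Group terms into connected components of the kappa >= threshold graph.

    Returns ``(assignment, representatives)``: term -> cluster id (1-based,
    ordered by the representative's p-value when given, else by term id) and
    cluster id -> representative (lowest-p member).
    """
    if not (-1.0 <= threshold <= 1.0):
        raise InputError(f"kappa threshold must be in [-1, 1], got {threshold}")
    if kappa.shape[0] != kappa.shape[1] or list(kappa.index) != list(kappa.columns):
        raise InputError("kappa matrix must be square with matching labels")
    terms = list(kappa.index)
    g = nx.Graph()
    g.add_nodes_from(terms)
    vals = kappa.to_numpy()
    for i, t1 in enumerate(terms):
        for j in range(i + 1, len(terms)):
            if vals[i, j] >= threshold:
                g.add_edge(t1, terms[j])

    def rep_key(term):
        return (float(pvalues[term]), term) if pvalues is not None else (0.0, term)

    components = [sorted(c) for c in nx.connected_components(g)]
    reps = {min(c, key=rep_key): c for c in components}
    ordered = sorted(reps, key=rep_key)
    assignment: dict[str, int] = {}
    representatives: dict[int, str] = {}
    for cid, rep in enumerate(ordered, start=1):
        representatives[cid] = rep
        for t in reps[rep]:
            assignment[t] = cid
    return assignment, representatives
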