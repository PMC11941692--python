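"""Protein–protein interaction network statistics for a protein set.

Given a scored interaction database and a query protein set, this module
builds the induced subgraph above a score threshold (0.4 by default, the
conventional medium-confidence cutoff) and computes the classic
connectivity readout: observed edges, expected edges under a stated null,
their ratio (edge enrichment), average node degree, average clustering
coefficient, and an empirical network-enrichment p-value.

Two nulls are offered. The analytic *density* null takes the background
edge density of the whole database, so the expected induced edge count is
C(n,2) · 2E/(N(N−1)). The *sampling* null (default) draws random node sets
of equal size from the database universe and counts their induced edges;
its p-value is the fraction of draws with at least the observed edge count,
with a +1/(draws+1) correction so p is never exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "InteractionDatabase",
    "NetworkStats",
    "read_interaction_db",
    "induced_graph",
    "network_parameters",
]

DEFAULT_MIN_SCORE = 0.4


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Lexicographically ordered undirected pair; self-loops rejected."""
    if a == b:
        raise ValueError(f"self-loop {a!r}–{b!r} not allowed")
    return (a, b) if a < b else (b, a)


@dataclass
class InteractionDatabase:
    """One evidence source: scored undirected edges over a node universe."""

    name: str
    edges: dict[tuple[str, str], float]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        fixed: dict[tuple[str, str], float] = {}
        for (a, b), score in self.edges.items():
            fixed[canonical_pair(a, b)] = float(score)
        self.edges = fixed
        if not self.universe:
            self.universe = {node for pair in self.edges for node in pair}
        else:
            self.universe |= {node for pair in self.edges for node in pair}

    def neighbors(self, node: str, min_score: float = 0.0) -> set[str]:
        """Adjacent symbols with edge score ≥ min_score."""
        out = set()
        for (a, b), score in self.edges.items():
            if score < min_score:
                continue
            if a == node:
                out.add(b)
            elif b == node:
                out.add(a)
        return out

    @classmethod
    def from_star(cls, name: str, center: str, partners: set[str]) -> "InteractionDatabase":
        """Association-list source as a star graph around a query protein.

        List-based resources record partners of a query without pairwise
        scores; they are ingested as score-1.0 edges from the query to each
        partner so they can participate in consensus filters.
        """
        edges = {canonical_pair(center, p): 1.0 for p in partners if p != center}
        return cls(name=name, edges=edges)


@dataclass
class NetworkStats:
    """Connectivity summary of an induced protein network."""

    n_nodes: int
    observed_edges: int
    expected_edges: float
    edge_enrichment: float
    avg_degree: float
    avg_clustering: float
    ppi_pvalue: float
    null_spec: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def read_interaction_db(path: str | Path, name: str | None = None) -> InteractionDatabase:
    """Read a three-column TSV (proteinA, proteinB, score) database."""
    path = Path(path)
    edges: dict[tuple[str, str], float] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            edges[canonical_pair(fields[0].strip().upper(), fields[1].strip().upper())] = float(
                fields[2]
            )
    return InteractionDatabase(name=name or path.stem, edges=edges)


def induced_graph(
    proteins: set[str], db: InteractionDatabase, min_score: float = DEFAULT_MIN_SCORE
) -> nx.Graph:
    """Subgraph induced by ``proteins ∩ db.universe`` above the score cutoff."""
    nodes = set(proteins) & db.universe
    if not nodes:
        raise ValueError("no query protein occurs in the database universe")
    graph = nx.Graph()
    graph.add_nodes_from(sorted(nodes))
    for (a, b), score in db.edges.items():
        if score >= min_score and a in nodes and b in nodes:
            graph.add_edge(a, b, score=score)
    return graph


def _induced_edge_count(
    nodes: np.ndarray, edge_index: dict[str, set[str]]
) -> int:
    node_set = set(nodes)
    count = 0
    for a in node_set:
        for b in edge_index.get(a, ()):
            if b in node_set:
                count += 1
    return count


def network_parameters(
    graph: nx.Graph,
    db: InteractionDatabase,
    null: str = "sampling",
    n_draws: int = 1000,
    seed: int = 0,
    min_score: float = DEFAULT_MIN_SCORE,
) -> NetworkStats:
    """Edge enrichment, degrees, clustering and an enrichment p-value.

    ``graph`` must come from :func:`induced_graph` on the same ``db`` and
    ``min_score``. Average clustering counts degree-<2 nodes as 0 and
    includes them in the mean. Under the density null the p-value is not
    defined and is reported as NaN; under the sampling null it carries the
    +1/(n_draws+1) correction.
    """
    import warnings

    n = graph.number_of_nodes()
    observed = graph.number_of_edges()
    avg_degree = 2.0 * observed / n if n else 0.0
    avg_clustering = nx.average_clustering(graph) if n else 0.0

    bg_edges = [pair for pair, score in db.edges.items() if score >= min_score]
    n_bg = len(db.universe)
    density = 2.0 * len(bg_edges) / (n_bg * (n_bg - 1)) if n_bg > 1 else 0.0

    if null == "density":
        expected = math.comb(n, 2) * density
        pvalue = float("nan")
        null_spec = f"analytic density over {db.name} universe (N={n_bg})"
    elif null == "sampling":
        if n_draws < 100:
            warnings.warn("sampling null with <100 draws is unreliable", stacklevel=2)
        rng = np.random.Generator(np.random.MT19937(seed))
        edge_index: dict[str, set[str]] = {}
        for a, b in bg_edges:
            edge_index.setdefault(a, set()).add(b)
        universe_arr = np.array(sorted(db.universe), dtype=object)
        draws = np.empty(n_draws, dtype=np.int64)
        for i in range(n_draws):
            sample = rng.choice(universe_arr, size=n, replace=False)
            draws[i] = _induced_edge_count(sample, edge_index)
        expected = float(draws.mean())
        pvalue = (int((draws >= observed).sum()) + 1) / (n_draws + 1)
        null_spec = (
            f"empirical same-size node resampling from {db.name} universe "
            f"(N={n_bg}, draws={n_draws}, seed={seed})"
        )
    else:
        raise ValueError("null must be 'density' or 'sampling'")

    enrichment = observed / expected if expected > 0 else float("inf") if observed else 0.0
    return NetworkStats(
        n_nodes=n,
        observed_edges=observed,
        expected_edges=expected,
        edge_enrichment=enrichment,
        avg_degree=avg_degree,
        avg_clustering=avg_clustering,
        ppi_pvalue=pvalue,
        null_spec=null_spec,
    )
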