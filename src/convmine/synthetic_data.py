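"""Synthetic inputs with planted, recoverable structure.

Every downstream stage of the pipeline (commonality levels, consensus
interactome expansion, drug-signature frequency ranking, null testing) is
exercised against data generated here, where the ground truth is known by
construction:

- signature collections with a planted shared core and tunable re-use of
  previously drawn symbols across categories;
- several interaction databases over a common universe, sharing a planted
  consensus edge set (each consensus edge present in at least two databases)
  plus database-private noise edges;
- GMT libraries with terms planted to overlap a chosen query by an exact
  count, and drug-atlas libraries with one protein planted at a chosen
  inclusion frequency across terms.

All generators are pure functions of their configuration and seed, built on
a Mersenne-Twister generator, so identical seeds give identical outputs.
Symbols are synthetic (``G``-prefixed) to avoid implying real-gene claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network_stats import InteractionDatabase
from .signature_io import GeneSetLibrary, SignatureSet

__all__ = [
    "SynthesisConfig",
    "gen_universe",
    "gen_signature_collection",
    "gen_ppi_databases",
    "gen_library_with_planted_enrichment",
    "gen_drug_atlas",
]


def _rng(seed: int) -> np.random.Generator:
    # MT19937 contract: the random lists this emulates were Mersenne-Twister draws
    return np.random.Generator(np.random.MT19937(seed))


@dataclass
class SynthesisConfig:
    """Knobs for all generators; unused fields are ignored by each one.

    Defaults mirror the study conditions the generators emulate: 10
    categories of 100 proteins over a genome-scale universe, 7 interaction
    databases with a ≥2-database consensus, and a 35-term drug atlas with
    one protein planted in 27 terms.
    """

    universe_size: int = 20_000
    n_categories: int = 10
    category_size: int = 100
    core_size: int = 0
    pairwise_share: float = 0.0
    n_databases: int = 7
    consensus_edge_count: int = 200
    db_noise_edge_count: int = 50
    n_terms: int = 35
    term_size: int = 50
    planted_terms: list[tuple[str, int]] = field(default_factory=list)
    planted_frequency_protein: str = "G_PLANTED"
    planted_frequency_count: int = 27
    core_symbols: list[str] | None = None  # fixed core instead of a random draw
    planted_edges: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_symbols is not None:
            self.core_size = len(self.core_symbols)
        if self.core_size > self.category_size:
            raise ValueError("core_size must not exceed category_size")
        if not 0.0 <= self.pairwise_share <= 1.0:
            raise ValueError("pairwise_share must be in [0, 1]")


def gen_universe(n: int, seed: int = 0) -> list[str]:
    """``n`` distinct symbols G000001..G<n>, in fixed order.

    The seed is accepted for interface symmetry; enumeration is inherently
    deterministic.
    """
    if n <= 0:
        raise ValueError("universe size must be positive")
    return [f"G{i:06d}" for i in range(1, n + 1)]


def gen_signature_collection(cfg: SynthesisConfig, name: str = "synthetic") -> SignatureSet:
    """Signature collection with a planted fully-shared core.

    Each of the ``n_categories`` categories holds ``category_size`` symbols:
    the ``core_size`` planted core symbols (present in every category, hence
    commonality exactly ``n_categories``) plus fill symbols. With
    probability ``pairwise_share`` a fill symbol is re-drawn from symbols
    already used by earlier categories, which tunes pairwise overlap; at
    ``pairwise_share=0`` fills are fresh uniform draws from the universe.
    """
    if cfg.category_size > cfg.universe_size:
        raise ValueError("category_size must not exceed universe_size")
    rng = _rng(cfg.seed)
    universe = np.array(gen_universe(cfg.universe_size), dtype=object)
    if cfg.core_symbols is not None:
        core = list(cfg.core_symbols)
    else:
        core = list(rng.choice(universe, size=cfg.core_size, replace=False))
    used: dict[str, None] = dict.fromkeys(core)
    categories: dict[str, list[str]] = {}
    for i in range(cfg.n_categories):
        members = dict.fromkeys(core)
        while len(members) < cfg.category_size:
            pool_prev = [s for s in used if s not in members]
            if pool_prev and rng.random() < cfg.pairwise_share:
                sym = pool_prev[rng.integers(len(pool_prev))]
            else:
                sym = universe[rng.integers(cfg.universe_size)]
            members.setdefault(sym, None)
        categories[f"CAT{i + 1:02d}"] = list(members)
        used.update(members)
    return SignatureSet(
        name=name, categories=categories, provenance=f"synthetic seed={cfg.seed}"
    )


def gen_ppi_databases(cfg: SynthesisConfig) -> list[InteractionDatabase]:
    """Interaction databases sharing a planted consensus edge set.

    Every consensus edge is assigned to at least two (uniformly 2..N)
    named databases; each database additionally receives
    ``db_noise_edge_count`` private noise edges that appear nowhere else.
    Scores are uniform(0.15, 1.0). Consensus edges therefore survive a
    ≥2-database filter and noise edges never do.

    ``cfg.planted_edges`` lets callers pin specific pairs into the
    consensus set (deduplicated, self-loops rejected) on top of
    ``consensus_edge_count`` random ones.
    """
    n_pairs = cfg.universe_size * (cfg.universe_size - 1) // 2
    need = cfg.consensus_edge_count + cfg.n_databases * cfg.db_noise_edge_count
    if need > n_pairs:
        raise ValueError("requested edge counts exceed the number of possible pairs")
    if cfg.n_databases < 2:
        raise ValueError("need at least two databases for a consensus")
    rng = _rng(cfg.seed)
    universe = gen_universe(cfg.universe_size)

    def draw_edge(taken: set[tuple[str, str]]) -> tuple[str, str]:
        while True:
            i, j = rng.choice(cfg.universe_size, size=2, replace=False)
            pair = tuple(sorted((universe[i], universe[j])))
            if pair not in taken:
                return pair  # type: ignore[return-value]

    taken: set[tuple[str, str]] = set()
    consensus: list[tuple[str, str]] = []
    for a, b in cfg.planted_edges:
        if a == b:
            raise ValueError(f"planted self-loop {a!r}")
        pair = (a, b) if a < b else (b, a)
        if pair not in taken:
            taken.add(pair)
            consensus.append(pair)
    for _ in range(cfg.consensus_edge_count):
        pair = draw_edge(taken)
        taken.add(pair)
        consensus.append(pair)

    per_db_edges: list[dict[tuple[str, str], float]] = [{} for _ in range(cfg.n_databases)]
    for pair in consensus:
        k = int(rng.integers(2, cfg.n_databases + 1))
        for db_i in rng.choice(cfg.n_databases, size=k, replace=False):
            per_db_edges[db_i][pair] = float(rng.uniform(0.15, 1.0))
    for db_i in range(cfg.n_databases):
        for _ in range(cfg.db_noise_edge_count):
            pair = draw_edge(taken)
            taken.add(pair)
            per_db_edges[db_i][pair] = float(rng.uniform(0.15, 1.0))

    return [
        InteractionDatabase(name=f"DB{i + 1}", edges=edges, universe=set(universe))
        for i, edges in enumerate(per_db_edges)
    ]


def _fresh_symbols(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def gen_library_with_planted_enrichment(
    query: set[str], cfg: SynthesisConfig
) -> GeneSetLibrary:
    """GMT library whose planted terms overlap ``query`` by an exact count.

    Each ``(label, k)`` in ``cfg.planted_terms`` yields a term of
    ``term_size`` members containing exactly ``k`` query symbols, the rest
    drawn from outside the query. Remaining terms (up to ``n_terms``) are
    uniform fillers over the whole universe. The library universe is the
    generator universe plus the query.
    """
    rng = _rng(cfg.seed)
    universe = set(gen_universe(cfg.universe_size)) | set(query)
    non_query = np.array(sorted(universe - set(query)), dtype=object)
    query_arr = np.array(sorted(query), dtype=object)
    universe_arr = np.array(sorted(universe), dtype=object)

    terms: dict[str, set[str]] = {}
    for label, k in cfg.planted_terms:
        if k > len(query_arr):
            raise ValueError(f"planted overlap {k} exceeds query size {len(query_arr)}")
        if k > cfg.term_size:
            raise ValueError(f"planted overlap {k} exceeds term size {cfg.term_size}")
        hits = list(rng.choice(query_arr, size=k, replace=False))
        fill = list(rng.choice(non_query, size=cfg.term_size - k, replace=False))
        terms[label] = set(hits) | set(fill)
    for i in range(cfg.n_terms - len(cfg.planted_terms)):
        members = rng.choice(universe_arr, size=cfg.term_size, replace=False)
        terms[f"FILLER{i + 1:03d}"] = set(members)
    return GeneSetLibrary(terms=terms, universe=universe)


def gen_drug_atlas(cfg: SynthesisConfig) -> GeneSetLibrary:
    """Drug-response-style library with one protein at a planted frequency.

    ``planted_frequency_protein`` is inserted into exactly
    ``planted_frequency_count`` of the ``n_terms`` terms; all other members
    are uniform draws from the universe. Emulates a therapeutic-signature
    atlas where one protein recurs across many drug responses.
    """
    if cfg.planted_frequency_count > cfg.n_terms:
        raise ValueError("planted frequency count exceeds the number of terms")
    rng = _rng(cfg.seed)
    universe_list = gen_universe(cfg.universe_size)
    universe = set(universe_list) | {cfg.planted_frequency_protein}
    universe_arr = np.array(universe_list, dtype=object)

    hosts = set(rng.choice(cfg.n_terms, size=cfg.planted_frequency_count, replace=False))
    terms: dict[str, set[str]] = {}
    for i in range(cfg.n_terms):
        members = set(rng.choice(universe_arr, size=cfg.term_size, replace=False))
        if i in hosts:
            members.add(cfg.planted_frequency_protein)
        terms[f"DRUG{i + 1:03d}"] = members
    return GeneSetLibrary(terms=terms, universe=universe)
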