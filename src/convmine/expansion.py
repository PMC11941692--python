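"""Multi-database consensus interactome expansion.

A protein is a *consensus interactor* of a seed when it is adjacent to the
seed (at or above a score threshold) in at least ``min_db`` of the supplied
interaction databases — requiring independent evidence sources to agree
before an edge is trusted. Expanding a seed cohort aggregates the per-seed
consensus sets and counts, for every interactor, how many seeds' consensus
sets contain it (its *seed commonality*). Slicing the aggregate at
increasing seed-commonality thresholds yields nested protein sets of
increasing convergence.

Score thresholds apply only to databases that carry scores; association-
list sources ingested as score-1.0 star graphs always pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .network_stats import InteractionDatabase

logger = logging.getLogger(__name__)

__all__ = ["ExpansionResult", "consensus_interactors", "expand_seeds", "slice_expansion"]


@dataclass
class ExpansionResult:
    """Aggregate of per-seed consensus interactor sets."""

    seeds: list[str]
    per_seed: dict[str, set[str]]
    aggregate: dict[str, int]  # interactor → number of seeds whose consensus set holds it
    min_db: int
    min_score: float
    databases: list[str]

    @property
    def proteins(self) -> set[str]:
        return set(self.aggregate)

    def seed_commonality_histogram(self) -> dict[int, int]:
        """Distribution of how many seeds each interactor is consensus for."""
        hist: dict[int, int] = {}
        for count in self.aggregate.values():
            hist[count] = hist.get(count, 0) + 1
        return dict(sorted(hist.items()))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("symbol\tseed_commonality\n")
            for sym, count in sorted(self.aggregate.items(), key=lambda kv: (-kv[1], kv[0])):
                handle.write(f"{sym}\t{count}\n")


def consensus_interactors(
    seed: str,
    dbs: list[InteractionDatabase],
    min_db: int = 2,
    min_score: float = 0.4,
) -> set[str]:
    """Symbols adjacent to ``seed`` in at least ``min_db`` databases.

    The seed itself is never returned. A seed absent from every database
    yields an empty set with a warning.
    """
    if min_db < 1:
        raise ValueError("min_db must be ≥ 1")
    if not dbs:
        raise ValueError("no interaction databases supplied")
    support: dict[str, int] = {}
    found = False
    for db in dbs:
        if seed not in db.universe:
            continue
        found = True
        for partner in db.neighbors(seed, min_score=min_score):
            support[partner] = support.get(partner, 0) + 1
    if not found:
        logger.warning("seed %r absent from every database", seed)
    return {sym for sym, n in support.items() if n >= min_db and sym != seed}


def expand_seeds(
    seeds: list[str],
    dbs: list[InteractionDatabase],
    min_db: int = 2,
    min_score: float = 0.4,
) -> ExpansionResult:
    """Aggregate consensus interactors over a seed cohort.

    Seed proteins that turn up as interactors of other seeds are retained
    in the aggregate.
    """
    if not seeds:
        raise ValueError("seed list is empty")
    per_seed = {
        seed: consensus_interactors(seed, dbs, min_db=min_db, min_score=min_score)
        for seed in seeds
    }
    aggregate: dict[str, int] = {}
    for interactors in per_seed.values():
        for sym in interactors:
            aggregate[sym] = aggregate.get(sym, 0) + 1
    return ExpansionResult(
        seeds=list(seeds),
        per_seed=per_seed,
        aggregate=aggregate,
        min_db=min_db,
        min_score=min_score,
        databases=[db.name for db in dbs],
    )


def slice_expansion(exp: ExpansionResult, min_seed_count: int) -> set[str]:
    """Interactors whose seed commonality is at least ``min_seed_count``.

    Slices are nested: raising the threshold never adds proteins.
    """
    if min_seed_count < 1:
        raise ValueError("min_seed_count must be ≥ 1")
    return {sym for sym, count in exp.aggregate.items() if count >= min_seed_count}
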