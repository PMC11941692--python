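"""Over-representation analysis (ORA) on GMT gene-set libraries.

For a query set of n symbols within a universe of N, and a term of K
members, the overlap k is tested with the hypergeometric upper tail
P(X ≥ k). A term is reported when at least ``min_overlap`` query proteins
enrich it (default 2) at raw p ≤ ``alpha`` (default 0.05). Benjamini–
Hochberg adjustment is available behind a flag but does not drive the
inclusion filter.

The universe is always an explicit parameter of the analysis: by default
the library's own declared universe. Query symbols outside the universe are
counted and logged but excluded from n.

Each record also carries the reporting metrics used downstream:
``input_fraction`` (percent of the effective query inside the term) and a
``combined_metric`` := (−log10 p) · k, a simple significance-times-support
score for top-k ranking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .signature_io import GeneSetLibrary

logger = logging.getLogger(__name__)

__all__ = [
    "ORAConfig",
    "EnrichmentRecord",
    "hypergeom_tail",
    "run_ora",
    "bh_adjust",
    "top_k_report",
    "records_to_frame",
]


@dataclass
class ORAConfig:
    """Inclusion rules for ORA: ≥ min_overlap enriching proteins at p ≤ alpha."""

    min_overlap: int = 2
    alpha: float = 0.05
    universe: set[str] | None = None  # None → library universe
    adjust: str = "none"  # {"none", "BH"}

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be ≥ 1")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.adjust not in ("none", "BH"):
            raise ValueError("adjust must be 'none' or 'BH'")


@dataclass
class EnrichmentRecord:
    term: str
    k: int  # overlap count
    K: int  # term size in universe
    n: int  # effective query size
    N: int  # universe size
    p: float
    q: float | None
    overlap: set[str] = field(repr=False)
    neglog10p: float = 0.0
    input_fraction: float = 0.0
    combined_metric: float = 0.0


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X ≥ k) for X ~ Hypergeometric(N, K, n).

    Evaluated through the log survival function for stability at extreme
    parameters.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"infeasible overlap k={k} for K={K}, n={n}")
    if K > N or n > N:
        raise ValueError(f"K={K} and n={n} must not exceed N={N}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); exponentiate the log-sf for numerical stability
    return float(math.exp(stats.hypergeom.logsf(k - 1, N, K, n)))


def run_ora(
    query: set[str], lib: GeneSetLibrary, cfg: ORAConfig | None = None
) -> list[EnrichmentRecord]:
    """Test every library term against the query; keep significant records.

    Records satisfy k ≥ min_overlap and raw p ≤ alpha, sorted by p
    ascending with ties broken by larger k then term label. Output is
    invariant to query and library ordering.
    """
    cfg = cfg or ORAConfig()
    universe = cfg.universe if cfg.universe is not None else lib.universe
    effective = set(query) & universe
    dropped = len(set(query)) - len(effective)
    if dropped:
        logger.warning("%d query symbol(s) outside the universe were excluded", dropped)
    if not effective:
        raise ValueError("no query symbol lies in the analysis universe")
    n, N = len(effective), len(universe)

    records = []
    for term, members in lib.terms.items():
        members_in = members & universe
        overlap = members_in & effective
        k, K = len(overlap), len(members_in)
        if k < cfg.min_overlap or K == 0:
            continue
        p = hypergeom_tail(k, K, n, N)
        if p > cfg.alpha:
            continue
        neglog = -math.log10(p) if p > 0 else float("inf")
        records.append(
            EnrichmentRecord(
                term=term,
                k=k,
                K=K,
                n=n,
                N=N,
                p=p,
                q=None,
                overlap=overlap,
                neglog10p=neglog,
                input_fraction=100.0 * k / n,
                combined_metric=neglog * k,
            )
        )
    records.sort(key=lambda r: (r.p, -r.k, r.term))
    if cfg.adjust == "BH" and records:
        for rec, q in zip(records, bh_adjust([r.p for r in records])):
            rec.q = q
    return records


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, ≤ 1)."""
    if not pvalues:
        return []
    adjusted = stats.false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")
    return [float(q) for q in adjusted]


def top_k_report(
    records: list[EnrichmentRecord], k: int, metric: str = "p"
) -> list[EnrichmentRecord]:
    """First k records under a metric: ``p`` ascending or ``combined_metric``
    descending; ties resolved by p, then larger overlap, then term label."""
    if metric == "p":
        ordered = sorted(records, key=lambda r: (r.p, -r.k, r.term))
    elif metric == "combined_metric":
        ordered = sorted(records, key=lambda r: (-r.combined_metric, r.p, -r.k, r.term))
    else:
        raise ValueError("metric must be 'p' or 'combined_metric'")
    return ordered[:k]


def records_to_frame(records: list[EnrichmentRecord]):
    """EnrichmentRecord list as a DataFrame ready for TSV export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "term": r.term,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p": r.p,
                "q": r.q,
                "neglog10p": r.neglog10p,
                "input_fraction": r.input_fraction,
                "combined_metric": r.combined_metric,
                "overlap": ";".join(sorted(r.overlap)),
            }
            for r in records
        ]
    )
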