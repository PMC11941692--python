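"""Drug-response-signature enrichment across expansion slices.

The workflow: ORA-enrich every seed-commonality slice of an interactome
expansion against a drug-response signature library, intersect the
significant term sets across slices to find the drug responses common to
every analysis stream, and then rank proteins by how many of those common
terms' ORA overlap sets contain them. The top of that frequency ranking is
the protein most consistently tied to the shared drug responses.

Counting uses the ORA *overlap* (enriching) proteins by default; counting
full term membership is available behind a flag. Slices with zero
significant terms are excluded from the intersection by default (an
all-stream intersection over the informative slices); a strict mode treats
them as absorbing empties.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

from .enrichment import EnrichmentRecord, ORAConfig, run_ora
from .signature_io import GeneSetLibrary

logger = logging.getLogger(__name__)

__all__ = [
    "FrequencyRanking",
    "enrich_slices",
    "common_terms",
    "frequency_ranking",
    "word_frequency_table",
]


@dataclass
class FrequencyRanking:
    """Protein inclusion frequencies across a common term set."""

    common_terms: set[str]
    per_term_symbols: dict[str, set[str]]
    frequency: dict[str, int]
    ranking: list[str]  # frequency desc, ties lexicographic

    @property
    def top(self) -> str:
        return self.ranking[0]


def enrich_slices(
    slices: dict[int, set[str]],
    atlas: GeneSetLibrary,
    cfg: ORAConfig | None = None,
) -> dict[int, list[EnrichmentRecord]]:
    """Run ORA for each slice; empty result sets are allowed and logged."""
    if not slices or all(not s for s in slices.values()):
        raise ValueError("all slices are empty")
    results: dict[int, list[EnrichmentRecord]] = {}
    for threshold, members in sorted(slices.items()):
        if not members:
            results[threshold] = []
            logger.info("slice ≥%d is empty; no enrichment run", threshold)
            continue
        try:
            records = run_ora(members, atlas, cfg)
        except ValueError:
            records = []
        if not records:
            logger.info("slice ≥%d: no significant terms", threshold)
        results[threshold] = records
    return results


def common_terms(
    per_slice: dict[int, list[EnrichmentRecord]], strict: bool = False
) -> set[str]:
    """Terms significant in every slice.

    Slices with zero significant terms are dropped from the intersection
    unless ``strict`` is set, in which case they make it empty.
    """
    term_sets = [{r.term for r in records} for records in per_slice.values()]
    if not strict:
        term_sets = [s for s in term_sets if s]
    if not term_sets:
        return set()
    common = term_sets[0]
    for s in term_sets[1:]:
        common &= s
    return common


def frequency_ranking(
    common: set[str],
    per_slice: dict[int, list[EnrichmentRecord]],
    atlas: GeneSetLibrary | None = None,
    count_full_membership: bool = False,
) -> FrequencyRanking:
    """Rank proteins by the number of common terms that include them.

    By default a protein counts toward a term when it appears in any ORA
    overlap set for that term (union over slices). With
    ``count_full_membership`` the term's full atlas membership is counted
    instead (requires ``atlas``).
    """
    if not common:
        raise ValueError("common term set is empty")
    per_term: dict[str, set[str]] = {}
    if count_full_membership:
        if atlas is None:
            raise ValueError("atlas is required to count full term membership")
        for term in common:
            per_term[term] = set(atlas.terms[term])
    else:
        for records in per_slice.values():
            for rec in records:
                if rec.term in common:
                    per_term.setdefault(rec.term, set()).update(rec.overlap)
    freq = Counter()
    for symbols in per_term.values():
        freq.update(symbols)
    ranking = sorted(freq, key=lambda s: (-freq[s], s))
    return FrequencyRanking(
        common_terms=set(common),
        per_term_symbols=per_term,
        frequency=dict(freq),
        ranking=ranking,
    )


def word_frequency_table(tokens: list[str]) -> list[tuple[str, int]]:
    """Descending-count frequency table of a token multiset."""
    counts = Counter(tokens)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
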