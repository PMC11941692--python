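import numpy as np
import pytest

from convmine.commonality import build_incidence
from convmine.enrichment import hypergeom_tail
from convmine.synthetic_data import (
    SynthesisConfig,
    gen_drug_atlas,
    gen_library_with_planted_enrichment,
    gen_ppi_databases,
    gen_signature_collection,
    gen_universe,
)


def test_universe_enumeration_and_determinism():
    assert gen_universe(3) == ["G000001", "G000002", "G000003"]
    assert gen_universe(50, seed=1) == gen_universe(50, seed=2)
    with pytest.raises(ValueError):
        gen_universe(0)


def test_planted_core_has_full_commonality():
    cfg = SynthesisConfig(
        universe_size=500, n_categories=10, category_size=30, core_size=5, seed=3
    )
    sigs = gen_signature_collection(cfg)
    inc = build_incidence(sigs)
    full = inc.commonality[inc.commonality == 10]
    assert len(full) >= 5  # the 5 core proteins, plus rare incidental ones
    assert all(len(v) == 30 for v in sigs.categories.values())


def test_signature_generator_is_deterministic():
    cfg = SynthesisConfig(universe_size=300, n_categories=4, category_size=20, seed=9)
    assert gen_signature_collection(cfg).categories == gen_signature_collection(cfg).categories


def test_distinct_count_matches_uniform_subset_expectation():
    """With no core and no sharing, each category is a uniform random
    subset, so E[distinct] = U·(1 − (1 − c/U)^k); check the Monte-Carlo
    mean over 100 seeds against this closed form."""
    U, c, k = 500, 20, 5
    expected = U * (1 - (1 - c / U) ** k)
    counts = []
    for seed in range(100):
        cfg = SynthesisConfig(
            universe_size=U, n_categories=k, category_size=c, core_size=0,
            pairwise_share=0.0, seed=seed,
        )
        counts.append(len(gen_signature_collection(cfg).all_symbols()))
    mean = np.mean(counts)
    sem = np.std(counts, ddof=1) / 10
    assert abs(mean - expected) < 4 * sem + 1e-9


def test_infeasible_sizes_rejected():
    with pytest.raises(ValueError):
        SynthesisConfig(category_size=10, core_size=11)
    with pytest.raises(ValueError):
        gen_signature_collection(SynthesisConfig(universe_size=5, category_size=10))


def _db_count(dbs, pair):
    pair = tuple(sorted(pair))
    return sum(pair in db.edges for db in dbs)


def test_consensus_edges_in_at_least_two_databases_and_noise_private():
    cfg = SynthesisConfig(
        universe_size=200, n_databases=3, consensus_edge_count=10,
        db_noise_edge_count=5, seed=4,
    )
    dbs = gen_ppi_databases(cfg)
    counts = {}
    for db in dbs:
        for pair in db.edges:
            counts[pair] = counts.get(pair, 0) + 1
    consensus = {p for p, n in counts.items() if n >= 2}
    private = {p for p, n in counts.items() if n == 1}
    assert len(consensus) == 10
    assert len(private) == 3 * 5
    assert all(0.15 <= s <= 1.0 for db in dbs for s in db.edges.values())


def test_noiseless_consensus_filter_recovers_exact_edge_set():
    cfg = SynthesisConfig(
        universe_size=100, n_databases=4, consensus_edge_count=15,
        db_noise_edge_count=0, seed=5,
    )
    dbs = gen_ppi_databases(cfg)
    counts = {}
    for db in dbs:
        for pair in db.edges:
            counts[pair] = counts.get(pair, 0) + 1
    assert all(n >= 2 for n in counts.values())
    assert len(counts) == 15


def test_planted_edges_are_pinned_into_consensus():
    planted = [("G000001", "G000002"), ("G000003", "G000001")]
    cfg = SynthesisConfig(
        universe_size=50, n_databases=3, consensus_edge_count=0,
        db_noise_edge_count=2, planted_edges=planted, seed=6,
    )
    dbs = gen_ppi_databases(cfg)
    for pair in planted:
        assert _db_count(dbs, pair) >= 2


def test_ppi_generator_determinism_and_edge_budget_check():
    cfg = SynthesisConfig(universe_size=60, n_databases=3, consensus_edge_count=8,
                          db_noise_edge_count=3, seed=7)
    a, b = gen_ppi_databases(cfg), gen_ppi_databases(cfg)
    assert [db.edges for db in a] == [db.edges for db in b]
    with pytest.raises(ValueError, match="possible pairs"):
        gen_ppi_databases(SynthesisConfig(universe_size=4, consensus_edge_count=100))


def test_planted_term_overlap_is_exact_and_detectable():
    query = set(gen_universe(1000)[:20])
    cfg = SynthesisConfig(
        universe_size=1000, n_terms=5, term_size=20,
        planted_terms=[("HIT", 8), ("MISS", 0)], seed=8,
    )
    lib = gen_library_with_planted_enrichment(query, cfg)
    assert len(lib.terms["HIT"] & query) == 8
    assert len(lib.terms["MISS"] & query) == 0
    # closed-form tail: 8 of 20 in a 20-member term over 1000 symbols
    assert hypergeom_tail(8, 20, 20, len(lib.universe)) < 1e-8


def test_planted_enrichment_determinism_and_bounds():
    query = set(gen_universe(100)[:10])
    cfg = SynthesisConfig(universe_size=100, n_terms=3, term_size=10,
                          planted_terms=[("T", 4)], seed=11)
    assert (
        gen_library_with_planted_enrichment(query, cfg).terms
        == gen_library_with_planted_enrichment(query, cfg).terms
    )
    bad = SynthesisConfig(universe_size=100, n_terms=3, term_size=10,
                          planted_terms=[("T", 11)], seed=11)
    with pytest.raises(ValueError):
        gen_library_with_planted_enrichment(query, bad)


@pytest.mark.parametrize("count", [0, 27, 35])
def test_drug_atlas_planted_inclusion_frequency(count):
    cfg = SynthesisConfig(
        universe_size=500, n_terms=35, term_size=20,
        planted_frequency_protein="G_SPECIAL", planted_frequency_count=count, seed=12,
    )
    atlas = gen_drug_atlas(cfg)
    present = sum("G_SPECIAL" in members for members in atlas.terms.values())
    assert present == count


def test_drug_atlas_rejects_overfull_planting():
    with pytest.raises(ValueError):
        gen_drug_atlas(SynthesisConfig(n_terms=10, planted_frequency_count=11))
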