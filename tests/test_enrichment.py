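import itertools
import math
from fractions import Fraction

import pytest

from convmine.enrichment import (
    ORAConfig,
    bh_adjust,
    hypergeom_tail,
    run_ora,
    top_k_report,
)
from convmine.signature_io import GeneSetLibrary
from convmine.synthetic_data import SynthesisConfig, gen_library_with_planted_enrichment, gen_universe


def enumerate_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """Exact tail by enumerating all C(N, n) draws of n items from N with
    the first K marked."""
    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return Fraction(hits, total)


def test_tail_trivial_boundaries():
    assert hypergeom_tail(0, 4, 5, 10) == 1.0
    assert hypergeom_tail(3, 3, 3, 3) == 1.0


def test_tail_frozen_enumeration_example():
    # 66 of the C(10,5)=252 subsets contain ≥3 of 4 marked items
    assert hypergeom_tail(3, 4, 5, 10) == pytest.approx(66 / 252, rel=1e-12)


def test_tail_matches_enumeration_small_grid():
    for N in (5, 7, 9):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(K, n) + 1):
                    exact = float(enumerate_tail(k, K, n, N))
                    assert hypergeom_tail(k, K, n, N) == pytest.approx(exact, abs=1e-12)


def test_tail_monotone_nonincreasing_in_k():
    values = [hypergeom_tail(k, 10, 15, 60) for k in range(11)]
    assert all(a >= b - 1e-15 for a, b in zip(values, values[1:]))


def test_tail_rejects_infeasible_parameters():
    with pytest.raises(ValueError):
        hypergeom_tail(5, 4, 10, 20)
    with pytest.raises(ValueError):
        hypergeom_tail(1, 25, 10, 20)


def test_ora_recovers_planted_terms_only():
    query = set(gen_universe(1000)[:20])
    cfg = SynthesisConfig(
        universe_size=1000, n_terms=12, term_size=20,
        planted_terms=[("HIT_A", 8), ("HIT_B", 6), ("NONE", 0)], seed=2,
    )
    lib = gen_library_with_planted_enrichment(query, cfg)
    records = run_ora(query, lib, ORAConfig())
    terms = [r.term for r in records]
    assert "HIT_A" in terms and "HIT_B" in terms
    assert "NONE" not in terms
    for r in records:
        assert r.k >= 2 and r.p <= 0.05
        assert r.p == pytest.approx(hypergeom_tail(r.k, r.K, r.n, r.N), rel=1e-12)
        assert r.neglog10p == pytest.approx(-math.log10(r.p))
        assert r.combined_metric == pytest.approx(r.neglog10p * r.k)


def test_ora_min_overlap_rule_excludes_single_protein_terms():
    lib = GeneSetLibrary(
        terms={"single": {"P1"}, "pair": {"P1", "P2"}},
        universe={f"P{i}" for i in range(1, 200)},
    )
    records = run_ora({"P1", "P2"}, lib, ORAConfig(min_overlap=2))
    assert [r.term for r in records] == ["pair"]


def test_ora_input_fraction_for_core_query():
    # 14 of a 21-protein query inside one term → input fraction 66.7%
    universe = set(gen_universe(2000))
    query = set(sorted(universe)[:21])
    term = set(sorted(query)[:14]) | set(sorted(universe)[1000:1006])
    lib = GeneSetLibrary(terms={"pathway": term}, universe=universe)
    (record,) = run_ora(query, lib, ORAConfig())
    assert record.input_fraction == pytest.approx(100 * 14 / 21, rel=1e-9)


def test_ora_invariant_to_orderings():
    universe = set(gen_universe(300))
    lib_terms = {
        "t1": set(gen_universe(300)[:30]),
        "t2": set(gen_universe(300)[20:55]),
    }
    query = set(gen_universe(300)[10:40])
    lib_fwd = GeneSetLibrary(terms=dict(lib_terms), universe=universe)
    lib_rev = GeneSetLibrary(terms=dict(reversed(lib_terms.items())), universe=universe)
    fwd = run_ora(query, lib_fwd, ORAConfig())
    rev = run_ora(set(sorted(query, reverse=True)), lib_rev, ORAConfig())
    assert [(r.term, r.k, r.p) for r in fwd] == [(r.term, r.k, r.p) for r in rev]


def test_ora_empty_effective_query_errors():
    lib = GeneSetLibrary(terms={"t": {"A", "B"}}, universe={"A", "B", "C"})
    with pytest.raises(ValueError, match="universe"):
        run_ora({"Z1", "Z2"}, lib, ORAConfig())


@pytest.mark.parametrize(
    "pvalues,expected",
    [
        ([0.05], [0.05]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.03, 0.03, 0.03], [0.03, 0.03, 0.03]),
    ],
)
def test_bh_step_up_hand_examples(pvalues, expected):
    assert bh_adjust(pvalues) == pytest.approx(expected)


def test_bh_monotone_and_capped():
    adjusted = bh_adjust([0.9, 0.001, 0.5, 0.04, 1.0])
    ranked = sorted(zip([0.9, 0.001, 0.5, 0.04, 1.0], adjusted))
    assert all(q <= 1.0 for q in adjusted)
    assert all(a[1] <= b[1] + 1e-12 for a, b in zip(ranked, ranked[1:]))


def test_top_k_report_orderings():
    universe = set(gen_universe(500))
    lib = GeneSetLibrary(
        terms={
            "big_k": set(gen_universe(500)[:40]),
            "small_k": set(gen_universe(500)[:2]) | set(gen_universe(500)[400:410]),
        },
        universe=universe,
    )
    query = set(gen_universe(500)[:40])
    records = run_ora(query, lib, ORAConfig())
    assert top_k_report(records, 5, "p") == sorted(records, key=lambda r: (r.p, -r.k, r.term))[:5]
    by_metric = top_k_report(records, 5, "combined_metric")
    assert [r.combined_metric for r in by_metric] == sorted(
        [r.combined_metric for r in by_metric], reverse=True
    )
    assert len(top_k_report(records[:1], 5, "p")) == 1
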