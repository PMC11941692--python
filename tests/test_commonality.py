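import itertools
import string

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from convmine.commonality import (
    build_incidence,
    build_levels,
    commonality_stats,
    overlap_percent,
    threshold_by_commonality,
    unique_fraction,
    venn4,
)
from convmine.signature_io import SignatureSet

symbols = st.text(alphabet=string.ascii_uppercase, min_size=1, max_size=3)
symbol_sets = st.sets(symbols, max_size=15)
collections = st.dictionaries(
    st.sampled_from(["C1", "C2", "C3", "C4"]),
    st.lists(symbols, min_size=1, max_size=12, unique=True),
    min_size=1,
    max_size=4,
)


def _sigs(cats):
    return SignatureSet(name="t", categories=cats, provenance="")


def test_incidence_two_set_example(tiny_sigs):
    inc = build_incidence(tiny_sigs)
    assert inc.proteins == ["P", "Q"]
    assert inc.commonality["P"] == 1 and inc.commonality["Q"] == 2


def test_incidence_column_sums_equal_category_sizes():
    sigs = _sigs({"A": ["P", "Q", "R"], "B": ["Q"], "C": ["R", "S"]})
    inc = build_incidence(sigs)
    for label, members in sigs.categories.items():
        assert inc.membership[label].sum() == len(members)


def test_empty_signature_set_rejected():
    with pytest.raises((ValueError, TypeError)):
        build_incidence(_sigs({}))


def test_commonality_stats_hand_example(tiny_sigs):
    stats = commonality_stats(build_incidence(tiny_sigs))
    assert stats.histogram == {1: 1, 2: 1}
    assert stats.mean == 1.5


def test_identical_categories_give_zero_sd():
    inc = build_incidence(_sigs({"A": ["P", "Q"], "B": ["P", "Q"], "C": ["P", "Q"]}))
    stats = commonality_stats(inc)
    assert stats.histogram == {3: 2}
    assert stats.sd == 0.0 and stats.two_sd == 0.0


@given(collections)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_histogram_conservation(cats):
    """Σ level·count over the histogram equals Σ post-dedup category sizes."""
    inc = build_incidence(_sigs(cats))
    stats = commonality_stats(inc)
    assert sum(stats.histogram.values()) == len(inc.proteins)
    assert sum(level * n for level, n in stats.histogram.items()) == sum(
        len(v) for v in cats.values()
    )


def test_unique_fraction_hand_example():
    per_cat, mean, _sem = unique_fraction(build_incidence(_sigs({"A": ["P", "Q"], "B": ["Q", "R"]})))
    assert per_cat == {"A": 50.0, "B": 50.0}
    assert mean == 50.0


@pytest.mark.parametrize(
    "a,b,denom,expected",
    [
        (set("ABCDE"), set("ABCDE"), 5, 100.0),
        (set("AB"), set("CD"), "min-size", 0.0),
        (set("ABC"), set("BCD"), "union", 50.0),
    ],
)
def test_overlap_percent_examples(a, b, denom, expected):
    assert overlap_percent(a, b, denom) == expected


def test_overlap_percent_auto_uses_fixed_100_for_matched_lists():
    a = {f"P{i}" for i in range(100)}
    b = set(list(a)[:20]) | {f"Q{i}" for i in range(80)}
    assert overlap_percent(a, b) == 20.0


def test_overlap_percent_zero_denominator_errors():
    with pytest.raises(ValueError):
        overlap_percent(set(), set(), "union")


@given(symbol_sets, symbol_sets)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_overlap_percent_symmetric_and_bounded(a, b):
    if not (a | b):
        return
    for denom in ("min-size", "union"):
        if denom == "min-size" and (not a or not b):
            continue
        value = overlap_percent(a, b, denom)
        assert value == overlap_percent(b, a, denom)
        assert 0.0 <= value <= 100.0


def test_venn4_disjoint_totals_have_no_multi_regions():
    result = venn4({"A", "B"}, set(), {"C"}, set())
    assert result.all_four == set()
    assert result.exactly_three == set()
    assert result.counts["1000"] == 2 and result.counts["0010"] == 1


def test_venn4_subset_precondition_enforced():
    with pytest.raises(ValueError, match="subset"):
        venn4({"A"}, {"B"}, {"C"}, set())


@given(symbol_sets, symbol_sets, symbol_sets, symbol_sets)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_venn4_matches_brute_force_enumeration(d_all, d_sh, m_all, m_sh):
    d_shared, m_shared = d_sh & d_all, m_sh & m_all
    result = venn4(d_all, d_shared, m_all, m_shared)
    sets = (d_all, d_shared, m_all, m_shared)
    brute: dict[str, set[str]] = {}
    for p in d_all | m_all:
        key = "".join("1" if p in s else "0" for s in sets)
        brute.setdefault(key, set()).add(p)
    for key, members in result.regions.items():
        assert members == brute.get(key, set())
    assert sum(result.counts.values()) == len(d_all | m_all)


def test_threshold_fixed_k_and_diagnostics():
    inc = build_incidence(_sigs({"A": ["P", "Q"], "B": ["P"], "C": ["P", "R"]}))
    result = threshold_by_commonality(inc, 3)
    assert result.proteins == {"P"}
    assert result.effective_threshold == 3
    assert result.mean == pytest.approx((3 + 1 + 1) / 3)


def test_threshold_no_protein_qualifies():
    inc = build_incidence(_sigs({"A": ["P"], "B": ["Q"]}))
    assert threshold_by_commonality(inc, 2).proteins == set()


def test_threshold_mean_plus_2sd_rounds_up():
    inc = build_incidence(_sigs({"A": ["P", "Q"], "B": ["P"], "C": ["P", "R"]}))
    result = threshold_by_commonality(inc, "mean_plus_2sd")
    import math

    assert result.effective_threshold == max(1, math.ceil(result.mean_plus_two_sd))


def test_levels_hand_constructed_example():
    """Brute-force check of each level definition on a small instance."""
    disease = _sigs({"D1": ["A", "B", "C", "E"], "D2": ["A", "B", "F"], "D3": ["A", "G"]})
    mechanism = _sigs({"M1": ["A", "C", "H"], "M2": ["A", "D", "H"], "M3": ["D", "I"]})
    d_inc, m_inc = build_incidence(disease), build_incidence(mechanism)
    levels = build_levels(d_inc, m_inc, 3)
    # commonalities: disease A=3,B=2,C=1,E=1,F=1,G=1; mechanism A=2,C=1,H=2,D=2,I=1
    assert levels.level5 == {"A"}  # ≥2 diseases and ≥2 mechanisms
    # three-of-four: B (2 diseases, 0 mech) is not in m_all → only in d_all+d_shared (2 sets)
    # C: d_all, m_all, not shared in either → totals-only; H: mech-only
    assert levels.level4 == {"A"}
    assert levels.level3 == {"A", "C"}
    assert levels.level2 == {"A", "C"}  # threshold 3: only A (disease commonality 3)
    assert levels.level1 == {"A", "B", "C", "D", "E", "F", "G", "H", "I"}


@given(collections, collections)
@settings(max_examples=40, deadline=None, derandomize=True)
def test_level_nesting_invariant(d_cats, m_cats):
    levels = build_levels(
        build_incidence(_sigs(d_cats)), build_incidence(_sigs(m_cats)), 2
    )
    assert levels.level5 <= levels.level4 <= levels.level3 <= levels.level2 <= levels.level1
    assert set(levels.audit) == levels.level1


def test_level_audit_reason_codes_match_membership():
    disease = _sigs({"D1": ["A", "B"], "D2": ["A", "B"]})
    mechanism = _sigs({"M1": ["A", "C"], "M2": ["A", "C"]})
    levels = build_levels(build_incidence(disease), build_incidence(mechanism), 3)
    assert levels.audit["A"] == "L5:all-four"
    assert all(code.startswith(("L5", "L4", "L3", "L2", "L1")) for code in levels.audit.values())
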