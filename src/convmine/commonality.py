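"""Protein × category incidence analysis.

The central object is the incidence matrix: a binary protein × category
membership table. A protein's *commonality* is its row sum — the number of
signatures (diseases, aging mechanisms, ...) that contain it. From the
incidence matrix this module derives:

- commonality histograms with mean/SD summaries and mean+2SD thresholds;
- per-category unique-protein fractions (commonality exactly 1);
- pairwise overlap percentages between signatures;
- a four-way Venn partition of (all diseases, multi-disease proteins,
  all mechanisms, multi-mechanism proteins) into its 15 regions;
- the nested convergence levels L5 ⊆ L4 ⊆ L3 ⊆ L2 ⊆ L1, from the
  strictest cohort (proteins shared by ≥2 diseases AND ≥2 mechanisms)
  out to the union of everything observed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .signature_io import SignatureSet

__all__ = [
    "IncidenceMatrix",
    "CommonalityStats",
    "ThresholdResult",
    "LevelSet",
    "build_incidence",
    "commonality_stats",
    "unique_fraction",
    "overlap_percent",
    "venn4",
    "threshold_by_commonality",
    "build_levels",
]


@dataclass
class IncidenceMatrix:
    """Binary protein × category membership with per-protein row sums."""

    membership: pd.DataFrame  # index: proteins (lexicographic), columns: categories

    def __post_init__(self) -> None:
        if self.membership.empty:
            raise ValueError("incidence matrix is empty")

    @property
    def proteins(self) -> list[str]:
        return list(self.membership.index)

    @property
    def categories(self) -> list[str]:
        return list(self.membership.columns)

    @property
    def commonality(self) -> pd.Series:
        """Row sums: number of categories containing each protein."""
        return self.membership.sum(axis=1)

    def proteins_with_commonality(self, min_count: int) -> set[str]:
        counts = self.commonality
        return set(counts.index[counts >= min_count])

    def to_tsv(self, path: str | Path) -> None:
        out = self.membership.copy()
        out["commonality"] = self.commonality
        out.to_csv(path, sep="\t", index_label="protein")


def build_incidence(sigs: SignatureSet) -> IncidenceMatrix:
    """Incidence matrix of a signature collection.

    Every distinct symbol appears exactly once as a row (lexicographic
    order); column sums equal the de-duplicated category sizes.
    """
    if not sigs.categories:
        raise ValueError("signature set has no categories")
    proteins = sorted(sigs.all_symbols())
    data = {
        label: [1 if p in member_set else 0 for p in proteins]
        for label, member_set in ((lb, set(ss)) for lb, ss in sigs.categories.items())
    }
    membership = pd.DataFrame(data, index=proteins, dtype=np.int8)
    return IncidenceMatrix(membership=membership)


@dataclass
class CommonalityStats:
    """Histogram and moments of the commonality distribution.

    ``sd`` follows the sample convention (n−1 denominator); the population
    value is carried alongside so printed mean+2SD thresholds can be
    checked under either convention.
    """

    histogram: dict[int, int]
    mean: float
    sd: float
    sd_population: float
    two_sd: float
    mean_plus_two_sd: float
    unique_fraction_per_category: dict[str, float]
    unique_fraction_mean: float
    unique_fraction_sem: float


def commonality_stats(inc: IncidenceMatrix) -> CommonalityStats:
    counts = inc.commonality.to_numpy()
    values, freq = np.unique(counts, return_counts=True)
    histogram = {int(v): int(f) for v, f in zip(values, freq)}
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if len(counts) > 1 else 0.0
    sd_pop = float(counts.std(ddof=0))
    per_cat, uf_mean, uf_sem = unique_fraction(inc)
    return CommonalityStats(
        histogram=histogram,
        mean=mean,
        sd=sd,
        sd_population=sd_pop,
        two_sd=2.0 * sd,
        mean_plus_two_sd=mean + 2.0 * sd,
        unique_fraction_per_category=per_cat,
        unique_fraction_mean=uf_mean,
        unique_fraction_sem=uf_sem,
    )


def unique_fraction(inc: IncidenceMatrix) -> tuple[dict[str, float], float, float]:
    """Percent of each category's proteins with commonality exactly 1.

    Returns (per-category percents, mean, SEM).
    """
    counts = inc.commonality
    unique_proteins = set(counts.index[counts == 1])
    per_cat: dict[str, float] = {}
    for label in inc.categories:
        col = inc.membership[label]
        members = set(col.index[col == 1])
        per_cat[label] = 100.0 * len(members & unique_proteins) / len(members)
    values = np.array(list(per_cat.values()))
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / math.sqrt(len(values))) if len(values) > 1 else 0.0
    return per_cat, mean, sem


def overlap_percent(
    a: set[str], b: set[str], denominator: str | int = "auto"
) -> float:
    """Percent overlap ``100·|a∩b| / denominator``.

    ``denominator`` may be an explicit integer (fixed size), ``"min-size"``,
    ``"union"``, or ``"auto"``: fixed 100 when both sets have exactly 100
    members (the design of equal-length 100-protein signatures), else the
    smaller set size.
    """
    inter = len(set(a) & set(b))
    if denominator == "auto":
        denom = 100 if len(a) == len(b) == 100 else min(len(a), len(b))
    elif denominator == "min-size":
        denom = min(len(a), len(b))
    elif denominator == "union":
        denom = len(set(a) | set(b))
    elif isinstance(denominator, int):
        denom = denominator
    else:
        raise ValueError(f"unknown denominator rule {denominator!r}")
    if denom == 0:
        raise ValueError("overlap denominator is zero")
    return 100.0 * inter / denom


@dataclass
class Venn4:
    """Partition of four sets into the 15 non-empty membership regions.

    Region keys are 4-character strings of '1'/'0' flags in input order
    (d_all, d_shared, m_all, m_shared); e.g. '1111' is the all-four region.
    """

    regions: dict[str, set[str]]

    @property
    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.regions.items()}

    @property
    def all_four(self) -> set[str]:
        return self.regions["1111"]

    @property
    def exactly_three(self) -> set[str]:
        out: set[str] = set()
        for key, members in self.regions.items():
            if key.count("1") == 3:
                out |= members
        return out

    @property
    def totals_only(self) -> set[str]:
        """Proteins in both totals but neither multi-membership set."""
        return self.regions["1010"]


def venn4(
    d_all: set[str], d_shared: set[str], m_all: set[str], m_shared: set[str]
) -> Venn4:
    """Four-way Venn partition with subset preconditions validated.

    Requires ``d_shared ⊆ d_all`` and ``m_shared ⊆ m_all``; region counts
    sum to ``|d_all ∪ m_all|``.
    """
    if not d_shared <= d_all:
        raise ValueError("d_shared is not a subset of d_all")
    if not m_shared <= m_all:
        raise ValueError("m_shared is not a subset of m_all")
    sets = (d_all, d_shared, m_all, m_shared)
    regions: dict[str, set[str]] = {
        "".join(flags): set()
        for flags in map("".join, itertools.product("01", repeat=4))
        if "1" in flags
    }
    for protein in d_all | m_all:
        key = "".join("1" if protein in s else "0" for s in sets)
        regions[key].add(protein)
    return Venn4(regions=regions)


@dataclass
class ThresholdResult:
    proteins: set[str]
    effective_threshold: int
    mean: float
    sd: float
    two_sd: float
    mean_plus_two_sd: float
    rule: str


def threshold_by_commonality(
    inc: IncidenceMatrix, rule: str | int = 3
) -> ThresholdResult:
    """Proteins whose commonality reaches a threshold.

    ``rule`` is either a fixed integer k (the operational default, k=3:
    present in at least three categories) or ``"mean_plus_2sd"``, which
    rounds mean+2·SD up to the next integer. Diagnostics always carry the
    mean, SD and mean+2SD so either convention can be inspected.
    """
    stats = commonality_stats(inc)
    if rule == "mean_plus_2sd":
        effective = max(1, math.ceil(stats.mean_plus_two_sd))
        rule_name = "mean_plus_2sd"
    elif isinstance(rule, int):
        if rule < 1:
            raise ValueError("fixed threshold must be ≥ 1")
        effective = rule
        rule_name = f"fixed k={rule}"
    else:
        raise ValueError(f"unknown threshold rule {rule!r}")
    return ThresholdResult(
        proteins=inc.proteins_with_commonality(effective),
        effective_threshold=effective,
        mean=stats.mean,
        sd=stats.sd,
        two_sd=stats.two_sd,
        mean_plus_two_sd=stats.mean_plus_two_sd,
        rule=rule_name,
    )


@dataclass
class LevelSet:
    """Nested convergence cohorts L5 ⊆ L4 ⊆ L3 ⊆ L2 ⊆ L1.

    L5: proteins in ≥2 diseases and ≥2 mechanisms (the all-four Venn
    region). L4: plus proteins in exactly three of the four Venn sets.
    L3: plus proteins in exactly one disease and exactly one mechanism.
    L2: plus proteins reaching the commonality threshold in either arm.
    L1: the union of every observed protein. ``audit`` maps each protein
    to the reason code of the innermost level that admitted it.
    """

    level5: set[str]
    level4: set[str]
    level3: set[str]
    level2: set[str]
    level1: set[str]
    audit: dict[str, str]

    def as_dict(self) -> dict[str, set[str]]:
        return {
            "level5": self.level5,
            "level4": self.level4,
            "level3": self.level3,
            "level2": self.level2,
            "level1": self.level1,
        }

    def sizes(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.as_dict().items()}

    def write(self, directory: str | Path) -> None:
        """One symbol-list file per level plus a JSON audit."""
        import json

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, members in self.as_dict().items():
            (directory / f"{name}.txt").write_text(
                "\n".join(sorted(members)) + "\n", encoding="utf-8"
            )
        (directory / "audit.json").write_text(
            json.dumps(dict(sorted(self.audit.items())), indent=1), encoding="utf-8"
        )


def build_levels(
    disease_inc: IncidenceMatrix,
    mechanism_inc: IncidenceMatrix,
    threshold_rule: str | int = 3,
) -> LevelSet:
    """Construct the five nested convergence levels from the two incidences."""
    d_all = set(disease_inc.proteins)
    m_all = set(mechanism_inc.proteins)
    d_shared = disease_inc.proteins_with_commonality(2)
    m_shared = mechanism_inc.proteins_with_commonality(2)
    venn = venn4(d_all, d_shared, m_all, m_shared)

    level5 = set(venn.all_four)
    level4 = level5 | venn.exactly_three
    level3 = level4 | venn.totals_only
    thresh_d = threshold_by_commonality(disease_inc, threshold_rule)
    thresh_m = threshold_by_commonality(mechanism_inc, threshold_rule)
    level2 = level3 | thresh_d.proteins | thresh_m.proteins
    level1 = d_all | m_all

    audit: dict[str, str] = {}
    for protein in level1:
        if protein in level5:
            audit[protein] = "L5:all-four"
        elif protein in level4:
            audit[protein] = "L4:three-of-four"
        elif protein in level3:
            audit[protein] = "L3:totals-only-shared"
        elif protein in level2:
            audit[protein] = "L2:commonality-threshold"
        else:
            audit[protein] = "L1:union"
    return LevelSet(
        level5=level5,
        level4=level4,
        level3=level3,
        level2=level2,
        level1=level1,
        audit=audit,
    )
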