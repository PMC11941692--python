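"""One-command synthetic demo of the full pipeline.

Builds, from a single seed, a complete set of pipeline inputs with known
planted structure at the study's native scale — 10 disease and 10
mechanism signatures of 100 proteins sharing a 21-protein core, seven
interaction databases with a ≥2-database consensus, a 35-term drug-response
atlas with one protein planted in 27 terms, a pathway library with a term
planted to overlap the core, and a partner-protein interactor list — then
writes them in the package's TSV/GMT dialects next to a ready-to-run YAML
config. The planted ground truth is recorded in ``ledger.json`` so tests
and the acceptance script can check recovery.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .expansion import consensus_interactors, expand_seeds
from .pipeline import stage_seed
from .signature_io import GeneSetLibrary, SignatureSet, write_library, write_signatures
from .synthetic_data import (
    SynthesisConfig,
    gen_ppi_databases,
    gen_signature_collection,
    gen_universe,
)

__all__ = ["write_demo_inputs"]

UNIVERSE_SIZE = 3000
N_CATEGORIES = 10
CATEGORY_SIZE = 100
CORE_SIZE = 21
N_DATABASES = 7
PARTNERS_PER_SEED = 25
N_ANCHORS = 6  # planted at seed-commonality 19, like the most conserved interactors
N_ATLAS_TERMS = 35
N_FILLER_TERMS = 5
PLANTED_FREQUENCY = 27  # atlas terms holding the planted frequency protein
PARTNER_SIGNATURE_SIZE = 40
MIN_SCORE = 0.15  # generator scores are uniform(0.15, 1); keep every consensus edge


def _db_tsv(db, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for (a, b), score in sorted(db.edges.items()):
            handle.write(f"{a}\t{b}\t{score:.4f}\n")


def write_demo_inputs(directory: str | Path, seed: int = 0) -> Path:
    """Generate all demo inputs under ``directory``; return the config path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.Generator(np.random.MT19937(stage_seed(seed, "demo-layout")))
    universe = gen_universe(UNIVERSE_SIZE)
    universe_arr = np.array(universe, dtype=object)

    # Planted identities: shared core, anchors (incl. the frequency protein),
    # and the partner protein, all drawn disjointly from the universe.
    picks = list(rng.choice(universe_arr, size=CORE_SIZE + N_ANCHORS + 1, replace=False))
    core = sorted(picks[:CORE_SIZE])
    anchors = sorted(picks[CORE_SIZE : CORE_SIZE + N_ANCHORS])
    freq_protein = anchors[0]
    partner_protein = picks[-1]

    # Signature collections share the planted core; fills are independent.
    disease = gen_signature_collection(
        SynthesisConfig(
            universe_size=UNIVERSE_SIZE,
            n_categories=N_CATEGORIES,
            category_size=CATEGORY_SIZE,
            core_symbols=core,
            seed=stage_seed(seed, "demo-disease"),
        ),
        name="demo-disease",
    )
    mechanism = gen_signature_collection(
        SynthesisConfig(
            universe_size=UNIVERSE_SIZE,
            n_categories=N_CATEGORIES,
            category_size=CATEGORY_SIZE,
            core_symbols=core,
            seed=stage_seed(seed, "demo-mechanism"),
        ),
        name="demo-mechanism",
    )

    # Bibliometric-style comparison lists: ~20 symbols recalled per disease
    # category plus random fill, giving a planted ≈20% overlap.
    comparison: dict[str, list[str]] = {}
    for label, members in disease.categories.items():
        recalled = list(rng.choice(np.array(members, dtype=object), size=20, replace=False))
        pool = [s for s in universe if s not in set(recalled)]
        fill = list(rng.choice(np.array(pool, dtype=object), size=80, replace=False))
        comparison[label] = recalled + fill
    comparison_set = SignatureSet(
        name="demo-comparison", categories=comparison, provenance="synthetic"
    )

    # Consensus edges: per-seed partner stars, anchor edges to 19 of the 21
    # seeds, and the partner protein's own star (30 expansion members + 10
    # fresh symbols, wired after expansion below).
    planted: list[tuple[str, str]] = []
    for s in core:
        partners = rng.choice(universe_arr, size=PARTNERS_PER_SEED, replace=False)
        planted.extend((s, p) for p in partners if p != s)
    for anchor in anchors:
        hosts = rng.choice(np.array(core, dtype=object), size=19, replace=False)
        planted.extend((s, anchor) for s in hosts if s != anchor)

    dbs = gen_ppi_databases(
        SynthesisConfig(
            universe_size=UNIVERSE_SIZE,
            n_databases=N_DATABASES,
            consensus_edge_count=0,
            db_noise_edge_count=40,
            planted_edges=planted,
            seed=stage_seed(seed, "demo-ppi"),
        )
    )
    exp = expand_seeds(core, dbs, min_db=2, min_score=MIN_SCORE)
    non_seed_members = sorted(exp.aggregate.keys() - set(core))

    # Extended stars for the frequency protein (its own interactome beyond
    # the 19 seeds: 40 expansion members + 60 fresh) and for the partner
    # protein (15 of the frequency protein's expansion partners + 15 other
    # expansion members + 10 fresh), planted as consensus edges in a second
    # generator pass with the same seed so determinism and the ≥2-database
    # property are preserved.
    freq_inside = list(
        rng.choice(np.array(non_seed_members, dtype=object), size=40, replace=False)
    )
    fresh_pool = np.array(
        [s for s in universe if s not in exp.aggregate and s not in picks], dtype=object
    )
    freq_outside = list(rng.choice(fresh_pool, size=60, replace=False))
    partner_inside = freq_inside[:15] + [
        s for s in non_seed_members if s not in set(freq_inside)
    ][:15]
    partner_outside = [s for s in fresh_pool if s not in set(freq_outside)][
        : PARTNER_SIGNATURE_SIZE - 30
    ]
    extra = [(freq_protein, p) for p in freq_inside + freq_outside if p != freq_protein]
    extra += [
        (partner_protein, p)
        for p in partner_inside + partner_outside
        if p != partner_protein
    ]
    dbs = gen_ppi_databases(
        SynthesisConfig(
            universe_size=UNIVERSE_SIZE,
            n_databases=N_DATABASES,
            consensus_edge_count=0,
            db_noise_edge_count=40,
            planted_edges=planted + extra,
            seed=stage_seed(seed, "demo-ppi"),
        )
    )
    exp = expand_seeds(core, dbs, min_db=2, min_score=MIN_SCORE)

    # Drug atlas: each of the 35 planted terms carries two rotating anchors
    # (commonality-19 proteins, keeping the term significant in every
    # slice), the frequency protein in exactly 27 terms, plus mid-expansion
    # and random padding. Anchors rotate so none can out-rank the planted
    # frequency protein.
    high = np.array(sorted(exp.aggregate, key=lambda s: (-exp.aggregate[s], s))[:60], dtype=object)
    hosts = set(rng.choice(N_ATLAS_TERMS, size=PLANTED_FREQUENCY, replace=False))
    rotating = [a for a in anchors if a != freq_protein]
    atlas_terms: dict[str, set[str]] = {}
    for i in range(N_ATLAS_TERMS):
        members = {rotating[i % len(rotating)], rotating[(i + 1) % len(rotating)]}
        members |= set(rng.choice(high, size=9, replace=False))
        members |= set(rng.choice(universe_arr, size=3, replace=False))
        members.discard(freq_protein)
        if i in hosts:
            members.add(freq_protein)
        atlas_terms[f"DRUG{i + 1:03d}"] = members
    for i in range(N_FILLER_TERMS):
        atlas_terms[f"FILLER{i + 1:02d}"] = set(rng.choice(universe_arr, size=15, replace=False))
    atlas = GeneSetLibrary(terms=atlas_terms, universe=set(universe))

    # Pathway library: one term planted to overlap the 21-protein core by 14.
    path_terms: dict[str, set[str]] = {}
    core_hits = set(rng.choice(np.array(core, dtype=object), size=14, replace=False))
    path_fill = set(rng.choice(universe_arr, size=6, replace=False)) - core_hits
    path_terms["LONGEVITY_CORE"] = core_hits | path_fill
    for i in range(19):
        path_terms[f"PATHWAY{i + 1:02d}"] = set(rng.choice(universe_arr, size=20, replace=False))
    pathways = GeneSetLibrary(terms=path_terms, universe=set(universe))

    partner_signature = sorted(
        consensus_interactors(partner_protein, dbs, min_db=2, min_score=MIN_SCORE)
    )

    # ---- write everything ------------------------------------------------
    write_signatures(disease, directory / "disease.tsv", format="tsv")
    write_signatures(mechanism, directory / "mechanism.tsv", format="tsv")
    write_signatures(comparison_set, directory / "comparison.tsv", format="tsv")
    for db in dbs:
        _db_tsv(db, directory / f"{db.name.lower()}.tsv")
    write_library(atlas, directory / "atlas.gmt")
    write_library(pathways, directory / "pathways.gmt")
    (directory / "universe.txt").write_text("\n".join(universe) + "\n", encoding="utf-8")
    (directory / "partner.txt").write_text(
        "\n".join(partner_signature) + "\n", encoding="utf-8"
    )

    config = {
        "disease_signatures": "disease.tsv",
        "mechanism_signatures": "mechanism.tsv",
        "comparison_signatures": "comparison.tsv",
        "signature_format": "tsv",
        "databases": [f"db{i + 1}.tsv" for i in range(N_DATABASES)],
        "drug_atlas": "atlas.gmt",
        "enrichment_libraries": ["pathways.gmt"],
        "universe_file": "universe.txt",
        "partner_signature": "partner.txt",
        "out_dir": "out",
        "min_db": 2,
        "min_score": MIN_SCORE,
        "min_overlap": 2,
        "alpha": 0.05,
        "threshold_rule": 3,
        "n_draws": 300,
        "seed": seed,
    }
    config_path = directory / "demo.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False), encoding="utf-8")

    ledger = {
        "seed": seed,
        "core": core,
        "anchors": anchors,
        "frequency_protein": freq_protein,
        "planted_frequency": PLANTED_FREQUENCY,
        "partner_protein": partner_protein,
        "partner_signature_size": len(partner_signature),
        "partner_inside_expansion": sorted(set(partner_inside)),
        "frequency_protein_star_size": 19 + len(freq_inside) + len(freq_outside),
        "planted_pair_overlap": sorted(set(partner_inside) & set(freq_inside)),
        "planted_pathway_term": "LONGEVITY_CORE",
        "planted_pathway_overlap": 14,
        "n_atlas_terms_planted": N_ATLAS_TERMS,
        "expansion_size": len(exp.aggregate),
    }
    (directory / "ledger.json").write_text(json.dumps(ledger, indent=1), encoding="utf-8")
    return config_path
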