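"""End-to-end convergence-mining pipeline.

Orchestrates the full workflow from a YAML config: incidence and
commonality statistics for the disease and mechanism signature collections,
the four-way Venn partition and nested convergence levels, per-level ORA
against annotation libraries (tracking the input-fraction trend), consensus
interactome expansion of the innermost level, slice-wise enrichment against
a drug-signature atlas, intersection of the significant terms, protein
frequency ranking, construction of a consensus interactome signature for
the top-ranked protein, and intersection-null testing of that signature
against the expansion (and optionally against a second protein's
signature).

Every stage writes TSV/JSON outputs plus a run manifest recording inputs,
content hashes, seeds and package version. All randomness derives from the
single config seed through a per-stage rule: SHA-256 of ``"<seed>:<stage>"``
reduced mod 2^31, so stages are independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .commonality import build_incidence, build_levels, commonality_stats, overlap_percent
from .drug_frequency import common_terms, enrich_slices, frequency_ranking
from .enrichment import ORAConfig, records_to_frame, run_ora
from .expansion import consensus_interactors, expand_seeds, slice_expansion
from .network_stats import read_interaction_db
from .null_models import DEFAULT_N_DRAWS, default_universe, intersection_null
from .signature_io import read_library, read_signatures, read_symbol_list

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SHA-256 of "<seed>:<stage>" mod 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Validated file paths and parameters for a full run."""

    disease_signatures: Path
    mechanism_signatures: Path
    databases: list[Path]
    drug_atlas: Path
    out_dir: Path
    signature_format: str = "tsv"
    comparison_signatures: Path | None = None  # bibliometric-style comparison lists
    enrichment_libraries: list[Path] = field(default_factory=list)
    universe_file: Path | None = None
    partner_signature: Path | None = None  # second protein's interactor list
    min_db: int = 2
    min_score: float = 0.4
    min_overlap: int = 2
    alpha: float = 0.05
    threshold_rule: int | str = 3
    n_draws: int = DEFAULT_N_DRAWS
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
        base = path.parent

        def resolve(p):
            return (base / p).resolve() if p else None

        cfg = cls(
            disease_signatures=resolve(raw["disease_signatures"]),
            mechanism_signatures=resolve(raw["mechanism_signatures"]),
            databases=[resolve(p) for p in raw["databases"]],
            drug_atlas=resolve(raw["drug_atlas"]),
            out_dir=(base / raw.get("out_dir", "out")).resolve(),
            signature_format=raw.get("signature_format", "tsv"),
            comparison_signatures=resolve(raw.get("comparison_signatures")),
            enrichment_libraries=[resolve(p) for p in raw.get("enrichment_libraries", [])],
            universe_file=resolve(raw.get("universe_file")),
            partner_signature=resolve(raw.get("partner_signature")),
            min_db=int(raw.get("min_db", 2)),
            min_score=float(raw.get("min_score", 0.4)),
            min_overlap=int(raw.get("min_overlap", 2)),
            alpha=float(raw.get("alpha", 0.05)),
            threshold_rule=raw.get("threshold_rule", 3),
            n_draws=int(raw.get("n_draws", DEFAULT_N_DRAWS)),
            seed=int(raw.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        required = {
            "disease_signatures": self.disease_signatures,
            "mechanism_signatures": self.mechanism_signatures,
            "drug_atlas": self.drug_atlas,
            **{f"database[{i}]": p for i, p in enumerate(self.databases)},
        }
        for label, p in required.items():
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"pipeline input {label} missing: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonable), encoding="utf-8")


def _jsonable(obj):
    if isinstance(obj, set):
        return sorted(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in order; return the manifest dictionary.

    Stage failures abort the run; the manifest (written even on failure)
    records which stages completed.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "min_db": cfg.min_db,
            "min_score": cfg.min_score,
            "min_overlap": cfg.min_overlap,
            "alpha": cfg.alpha,
            "threshold_rule": cfg.threshold_rule,
            "n_draws": cfg.n_draws,
        },
        "inputs": {},
        "stages_completed": [],
        "results": {},
    }
    for p in [cfg.disease_signatures, cfg.mechanism_signatures, cfg.drug_atlas, *cfg.databases]:
        manifest["inputs"][str(p)] = _sha256(Path(p))

    try:
        _run_stages(cfg, out, manifest)
    finally:
        _dump_json(manifest, out / "manifest.json")
    return manifest


def _run_stages(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    ora_cfg = ORAConfig(min_overlap=cfg.min_overlap, alpha=cfg.alpha)
    results = manifest["results"]

    # The analysis universe is explicit: the supplied universe file, or the
    # default 20k-symbol proteome-scale background. All GMT libraries and
    # null draws share it.
    universe = (
        read_symbol_list(cfg.universe_file) if cfg.universe_file else default_universe()
    )
    universe_set = set(universe)
    manifest["parameters"]["universe_size"] = len(universe_set)

    # --- commonality -----------------------------------------------------
    disease = read_signatures(cfg.disease_signatures, format=cfg.signature_format)
    mechanism = read_signatures(cfg.mechanism_signatures, format=cfg.signature_format)
    d_inc, m_inc = build_incidence(disease), build_incidence(mechanism)
    d_stats, m_stats = commonality_stats(d_inc), commonality_stats(m_inc)
    d_inc.to_tsv(out / "disease_incidence.tsv")
    m_inc.to_tsv(out / "mechanism_incidence.tsv")
    results["commonality"] = {
        "disease_distinct_proteins": len(d_inc.proteins),
        "mechanism_distinct_proteins": len(m_inc.proteins),
        "disease_mean_commonality": d_stats.mean,
        "disease_two_sd": d_stats.two_sd,
        "mechanism_mean_commonality": m_stats.mean,
        "mechanism_two_sd": m_stats.two_sd,
        "disease_unique_fraction_mean": d_stats.unique_fraction_mean,
        "disease_unique_fraction_sem": d_stats.unique_fraction_sem,
        "mechanism_unique_fraction_mean": m_stats.unique_fraction_mean,
        "mechanism_unique_fraction_sem": m_stats.unique_fraction_sem,
    }
    manifest["stages_completed"].append("commonality")

    # --- optional comparison overlap (bibliometric-style lists) ----------
    if cfg.comparison_signatures:
        comparison = read_signatures(cfg.comparison_signatures, format=cfg.signature_format)
        overlaps = [
            overlap_percent(set(disease.categories[label]), set(members))
            for label, members in comparison.categories.items()
            if label in disease.categories
        ]
        if overlaps:
            results["comparison_overlap"] = {
                "per_category_percent": overlaps,
                "mean_percent": sum(overlaps) / len(overlaps),
            }
        manifest["stages_completed"].append("comparison_overlap")

    # --- levels ----------------------------------------------------------
    levels = build_levels(d_inc, m_inc, cfg.threshold_rule)
    levels.write(out / "levels")
    results["levels"] = levels.sizes()
    manifest["stages_completed"].append("levels")

    # --- per-level ORA (input-fraction trend) ----------------------------
    if cfg.enrichment_libraries:
        trend: dict[str, dict] = {}
        for lib_path in cfg.enrichment_libraries:
            lib = read_library(lib_path, universe=universe_set)
            per_level = {}
            for name, members in levels.as_dict().items():
                try:
                    records = run_ora(members, lib, ora_cfg)
                except ValueError:
                    records = []
                if records:
                    records_to_frame(records).to_csv(
                        out / f"ora_{Path(lib_path).stem}_{name}.tsv", sep="\t", index=False
                    )
                per_level[name] = {
                    "n_significant": len(records),
                    "top_input_fraction": records[0].input_fraction if records else None,
                }
            trend[Path(lib_path).stem] = per_level
        results["level_enrichment"] = trend
        manifest["stages_completed"].append("level_enrichment")

    # --- expansion of the innermost level --------------------------------
    dbs = [read_interaction_db(p) for p in cfg.databases]
    seeds = sorted(levels.level5)
    if not seeds:
        raise RuntimeError("innermost level is empty; nothing to expand")
    exp = expand_seeds(seeds, dbs, min_db=cfg.min_db, min_score=cfg.min_score)
    exp.write_tsv(out / "expansion.tsv")
    results["expansion"] = {
        "n_seeds": len(seeds),
        "aggregate_size": len(exp.aggregate),
        "seed_commonality_histogram": exp.seed_commonality_histogram(),
        "per_seed_mean": (
            sum(len(s) for s in exp.per_seed.values()) / len(exp.per_seed)
        ),
    }
    manifest["stages_completed"].append("expansion")

    # --- drug-atlas slice enrichment + frequency ranking -----------------
    atlas = read_library(cfg.drug_atlas, universe=universe_set)
    max_count = max(exp.aggregate.values(), default=1)
    slices = {
        k: slice_expansion(exp, k)
        for k in range(1, max_count + 1)
        if slice_expansion(exp, k)
    }
    per_slice = enrich_slices(slices, atlas, ora_cfg)
    common = common_terms(per_slice)
    (out / "common_terms.txt").write_text("\n".join(sorted(common)) + "\n", encoding="utf-8")
    results["drug_enrichment"] = {
        "n_slices": len(slices),
        "per_slice_significant": {k: len(v) for k, v in per_slice.items()},
        "n_common_terms": len(common),
    }
    manifest["stages_completed"].append("drug_enrichment")

    if common:
        ranking = frequency_ranking(common, per_slice)
        with open(out / "frequency_ranking.tsv", "w", encoding="utf-8") as handle:
            handle.write("symbol\tfrequency\n")
            for sym in ranking.ranking:
                handle.write(f"{sym}\t{ranking.frequency[sym]}\n")
        top = ranking.top
        results["frequency_ranking"] = {
            "top_protein": top,
            "top_frequency": ranking.frequency[top],
            "n_ranked": len(ranking.ranking),
        }
        manifest["stages_completed"].append("frequency_ranking")

        # --- consensus signature of the top-ranked protein ---------------
        signature = consensus_interactors(top, dbs, min_db=cfg.min_db, min_score=cfg.min_score)
        (out / "top_protein_signature.txt").write_text(
            "\n".join(sorted(signature)) + "\n", encoding="utf-8"
        )
        observed = len(signature & exp.proteins)
        null = intersection_null(
            query_size=max(len(signature), 1),
            target=exp.proteins,
            universe=universe,
            n_draws=cfg.n_draws,
            seed=stage_seed(cfg.seed, "top-protein-null"),
            observed=observed,
        )
        results["top_protein_vs_expansion"] = {
            "top_protein": top,
            "signature_size": len(signature),
            "observed_intersection": observed,
            "null_mean": null.null_mean,
            "null_sem": null.null_sem,
            "analytic_expectation": null.analytic_expectation,
            "z": null.z,
        }
        _dump_json(null.to_dict(), out / "top_protein_null.json")
        manifest["stages_completed"].append("top_protein_null")

        # --- optional partner-protein intersection ------------------------
        if cfg.partner_signature:
            partner = set(read_symbol_list(cfg.partner_signature))
            observed_pair = len(signature & partner)
            pair_null = intersection_null(
                query_size=max(len(signature), 1),
                target=partner,
                universe=universe,
                n_draws=cfg.n_draws,
                seed=stage_seed(cfg.seed, "partner-null"),
                observed=observed_pair,
            )
            results["top_protein_vs_partner"] = {
                "partner_size": len(partner),
                "observed_intersection": observed_pair,
                "null_mean": pair_null.null_mean,
                "null_sem": pair_null.null_sem,
                "z": pair_null.z,
            }
            manifest["stages_completed"].append("partner_null")
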