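"""Pipeline orchestration: configuration, stage execution and reporting.

Stages run in dependency order -- library construction, docking-record
post-processing, chemotype enrichment, interaction profiling -- with
conservation profiling independent of the rest.  Stages exchange data
through files in the output directory; the summary report is JSON.  With a
fixed configuration and seed, every TSV output is byte-identical across
runs (timestamps appear only in log messages).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import (
    conservation_profiler as conservation,
    enrichment_analysis as enrichment,
    interaction_profiler as interactions,
    library_builder as library,
    screening_postprocess as postprocess,
    synthetic_data as synth,
)
from .chem_core import write_smiles_file

logger = logging.getLogger("oxascreen")


class ConfigError(ValueError):
    """Invalid configuration value or unknown key."""


class MissingInputError(FileNotFoundError):
    """A stage's upstream output or input file is absent."""


@dataclass
class PipelineConfig:
    # library construction
    min_heavy: int = 6
    max_heavy: int = 12
    budget: int = 18
    dedupe_threshold: float = 0.95
    # post-processing
    anchor_cutoff: float = 2.0
    # enrichment
    cluster_threshold: float = 0.7
    alpha: float = 20.0
    # synthetic study conditions
    seed: int = 0
    n_compounds: int = 2000
    n_families: int = 8
    members_per_family: int = 3
    anchor_pass_prob: float = 0.755
    group_correlation: float = 0.8
    score_noise_sd: float = 0.25
    planted_effect: float = 1.0
    # stage toggles
    stages: tuple[str, ...] = (
        "library", "postprocess", "enrichment", "interactions", "conservation",
    )

    def validate(self) -> "PipelineConfig":
        checks = [
            ("min_heavy", 1 <= self.min_heavy <= self.max_heavy),
            ("max_heavy", self.max_heavy >= self.min_heavy),
            ("budget", self.budget >= 2),
            ("dedupe_threshold", 0.0 < self.dedupe_threshold <= 1.0),
            ("anchor_cutoff", self.anchor_cutoff > 0.0),
            ("cluster_threshold", 0.0 < self.cluster_threshold <= 1.0),
            ("alpha", self.alpha > 0.0),
            ("n_compounds", self.n_compounds >= 1),
            ("anchor_pass_prob", 0.0 < self.anchor_pass_prob <= 1.0),
            ("group_correlation", -1.0 <= self.group_correlation <= 1.0),
            ("score_noise_sd", self.score_noise_sd >= 0.0),
        ]
        for key, ok in checks:
            if not ok:
                raise ConfigError(
                    f"config key {key!r} = {getattr(self, key)!r} violates its constraint"
                )
        known = {"library", "postprocess", "enrichment", "interactions", "conservation"}
        unknown = set(self.stages) - known
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        return self


def load_config(path: str | Path) -> PipelineConfig:
    """Load a ``key: value`` configuration file; defaults fill the gaps and
    unknown keys are rejected."""
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping of key: value pairs")
    names = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "stages" in data:
        data["stages"] = tuple(data["stages"])
    return PipelineConfig(**data).validate()


def write_config(path: str | Path, config: PipelineConfig) -> None:
    data = dataclasses.asdict(config)
    data["stages"] = list(data["stages"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _planted_cluster(blocks, config) -> synth.PlantedCluster:
    # the first chemotype family in the block list is the planted "good"
    # R1 chemotype for Gram-negative species
    family = [b.id for b in blocks[: config.members_per_family]]
    return synth.PlantedCluster(
        block_ids=frozenset(family),
        position="R1",
        group="gram_negative",
        effect=config.planted_effect,
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the enabled stages on a synthetic study and write per-stage
    outputs plus a JSON summary report into ``out_dir``."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "stages": {}}
    report["config"]["stages"] = list(config.stages)
    timings: dict[str, float] = {}

    blocks = None
    records = None
    consensus = {}

    # --- library -----------------------------------------------------------
    if "library" in config.stages:
        t0 = time.perf_counter()
        family_blocks = synth.generate_block_families(
            config.n_families, config.members_per_family, seed=config.seed,
            level="chemotype",
        )
        extra = synth.generate_building_blocks(
            40, seed=config.seed + 1, heavy_range=(config.min_heavy, config.max_heavy)
        )
        seen: set[str] = set()
        blocks = []
        for b in family_blocks + extra:
            if b.id not in seen:
                seen.add(b.id)
                blocks.append(b)
        blocks = library.filter_blocks(blocks, config.min_heavy, config.max_heavy)
        blocks = library.dedupe_by_similarity(blocks, 1.0)  # drop exact duplicates
        write_smiles_file(out / "blocks.smi", [b.mol for b in blocks])
        compounds = synth.generate_compound_specs(
            blocks, config.n_compounds, seed=config.seed + 2
        )
        with open(out / "compounds.tsv", "w") as fh:
            fh.write("identifier\tr1_id\tr2_id\n")
            for c in compounds:
                fh.write(f"{c.identifier}\t{c.r1_block}\t{c.r2_block}\n")
        timings["library"] = time.perf_counter() - t0
        report["stages"]["library"] = {
            "n_blocks": len(blocks),
            "n_compounds": len(compounds),
        }
    else:
        report["stages"]["library"] = {"skipped": True}

    # --- postprocess -------------------------------------------------------
    if "postprocess" in config.stages:
        if blocks is None:
            raise MissingInputError("postprocess requires the library stage")
        t0 = time.perf_counter()
        params = synth.SimulationParams(
            seed=config.seed + 3,
            n_compounds=config.n_compounds,
            anchor_pass_prob=config.anchor_pass_prob,
            group_correlation=config.group_correlation,
            score_noise_sd=config.score_noise_sd,
            planted_clusters=(_planted_cluster(blocks, config),),
        )
        records = synth.generate_docking_records(compounds, params)
        postprocess.write_docking_records(out / "docking_records.tsv", records)
        passing = postprocess.anchor_consistency_filter(
            records, cutoff=config.anchor_cutoff
        )
        pass_fraction = len(passing) / len(compounds)
        accuracy = (
            postprocess.docking_accuracy(pass_fraction, len(params.isoforms))
            if pass_fraction > 0 else float("nan")
        )
        kept = [r for r in records if r.compound_id in passing]
        by_isoform = {}
        for iso in params.isoforms:
            iso_records = [r for r in kept if r.isoform == iso.code]
            by_isoform[iso.code] = postprocess.fuse_isoform(iso_records)
        for group in ("gram_negative", "gram_positive", "all"):
            consensus[group] = postprocess.group_consensus(by_isoform, group)
            postprocess.write_ranked_list(
                out / f"consensus_{group}.tsv", consensus[group]
            )
        correlation = postprocess.rank_correlation(
            consensus["gram_negative"], consensus["gram_positive"]
        )
        timings["postprocess"] = time.perf_counter() - t0
        report["stages"]["postprocess"] = {
            "n_screened": len(compounds),
            "n_passing": len(passing),
            "pass_fraction": pass_fraction,
            "estimated_accuracy": accuracy,
            "group_rank_correlation": correlation,
        }
        top = consensus["all"].ids[:5]
        report["stages"]["postprocess"]["top_compounds"] = [
            {
                "compound_id": cid,
                "rank": i + 1,
                "fused_sum": consensus["all"].sums[cid],
            }
            for i, cid in enumerate(top)
        ]
    else:
        report["stages"]["postprocess"] = {"skipped": True}

    # --- enrichment --------------------------------------------------------
    if "enrichment" in config.stages:
        if not consensus:
            raise MissingInputError("enrichment requires the postprocess stage")
        t0 = time.perf_counter()
        clusters = enrichment.cluster_blocks(blocks, config.cluster_threshold)
        enrichment.write_cluster_members(out / "block_clusters.tsv", clusters)
        cells = []
        deltas = []
        for position in ("R1", "R2"):
            neg = enrichment.enrichment_cells(
                consensus["gram_negative"], clusters, position, "gram_negative",
                alpha=config.alpha,
            )
            pos = enrichment.enrichment_cells(
                consensus["gram_positive"], clusters, position, "gram_positive",
                alpha=config.alpha,
            )
            cells.extend(neg + pos)
            neg_by = {c.cluster_id: c for c in neg}
            pos_by = {c.cluster_id: c for c in pos}
            for cid in sorted(set(neg_by) & set(pos_by)):
                deltas.append(
                    (cid, position, enrichment.delta_bedroc(neg_by[cid], pos_by[cid]))
                )
        enrichment.write_enrichment_table(out / "enrichment.tsv", cells)
        enrichment.write_delta_table(out / "delta_bedroc.tsv", deltas)
        timings["enrichment"] = time.perf_counter() - t0
        report["stages"]["enrichment"] = {
            "n_clusters": len(clusters),
            "n_cells": len(cells),
            "n_flagged": sum(1 for _, _, d in deltas if enrichment.is_flagged(d)),
        }
    else:
        report["stages"]["enrichment"] = {"skipped": True}

    # --- interactions ------------------------------------------------------
    if "interactions" in config.stages:
        if not consensus:
            raise MissingInputError("interactions requires the postprocess stage")
        t0 = time.perf_counter()
        table = conservation.load_binding_site_table()
        residues = [p.residue_number for p in table]
        import numpy as np

        rng = np.random.default_rng(config.seed + 4)
        classes = list(interactions.CONTACT_CLASSES)
        contacts_per_compound = []
        top = consensus["all"].ids[:10]
        for k, cid in enumerate(top):
            n_contacts = int(rng.integers(2, 5))
            prescription = [
                (int(rng.choice(residues)), classes[int(rng.integers(0, len(classes)))])
                for _ in range(n_contacts)
            ]
            protein, ligand = synth.generate_complex(prescription, seed=config.seed + k)
            interactions.write_complex(out / f"complex_{k:02d}.pdb", protein, ligand)
            contacts_per_compound.append(
                interactions.detect_contacts(protein, ligand)
            )
        profiles = interactions.residue_profiles(contacts_per_compound, residues)
        interactions.write_profiles_tsv(out / "residue_profiles.tsv", profiles)
        shares = interactions.halogen_contributions(contacts_per_compound)
        interactions.write_halogen_shares_tsv(out / "halogen_shares.tsv", shares)
        timings["interactions"] = time.perf_counter() - t0
        report["stages"]["interactions"] = {
            "n_complexes": len(contacts_per_compound),
            "n_contacts": sum(len(c) for c in contacts_per_compound),
            "n_halogen_residues": len(shares),
        }
    else:
        report["stages"]["interactions"] = {"skipped": True}

    # --- conservation ------------------------------------------------------
    if "conservation" in config.stages:
        t0 = time.perf_counter()
        table = conservation.load_binding_site_table()
        mean, sd = conservation.entropy_summary([p.entropy_bits for p in table])
        background = conservation.load_background_composition()
        counts = {"conserved_all": 0, "gram_specific": 0, "variable": 0}
        for p in table:
            counts[conservation.classify_position_conservation(p)] += 1
        timings["conservation"] = time.perf_counter() - t0
        report["stages"]["conservation"] = {
            "n_positions": len(table),
            "mean_entropy_bits": mean,
            "sd_entropy_bits": sd,
            "background_max_entropy_bits": conservation.background_max_entropy(background),
            "classification_counts": counts,
        }
    else:
        report["stages"]["conservation"] = {"skipped": True}

    for stage, seconds in timings.items():
        logger.info("stage %s finished in %.2f s", stage, seconds)
    report["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
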