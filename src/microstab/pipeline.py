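"""Config-driven orchestration of the full analysis.

Stages run in a fixed order mirroring the analysis narrative: obtain a
feature table (from files or the synthetic generator), validate the inputs
against each other, filter low-abundance ASVs and organelles, rarefy,
compute alpha diversity with group tests, beta diversity with ordination
and permutation tests, the CV stability curves, and the indicator-family
analysis.  Every stochastic stage gets its own seed derived from the master
seed by stable hashing of the stage name, and the run manifest records all
of them together with the effective parameters and input digests, so a run
can be reproduced exactly from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alphadiv, betadiv, indicators, simulate, stability, tabletools
from .tabletools import (
    FeatureTable,
    PhyloTree,
    SampleMetadata,
    TaxonomyMap,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "rarefy", "beta", "stability", "indicators")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed: master combined with a hash of the name."""
    return (int(master) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    # either all four input paths ...
    table_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    # ... or a simulation request
    simulate: bool = False
    species_per_group: int = 3
    samples_per_species: int = 12
    # analysis parameters
    depth: int = 2300
    min_total: int = 10
    permutations: int = 999
    subset_sizes: tuple[int, ...] = stability.DEFAULT_SIZES
    replicates: int = 3
    abundance_threshold: float = stability.DEFAULT_ABUNDANCE_THRESHOLD
    max_order: int | None = None
    metrics: tuple[str, ...] = ("bray", "uu", "wu")
    seed: int = 0
    outdir: str = "microstab_out"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.subset_sizes, list):
            cfg.subset_sizes = tuple(cfg.subset_sizes)
        if isinstance(cfg.metrics, list):
            cfg.metrics = tuple(cfg.metrics)
        return cfg

    def validate(self) -> None:
        if not self.simulate:
            missing = [
                name
                for name, p in (
                    ("table", self.table_path),
                    ("taxonomy", self.taxonomy_path),
                    ("metadata", self.metadata_path),
                )
                if p is None
            ]
            if missing:
                raise ValueError(f"missing input paths: {missing}")
            if ("uu" in self.metrics or "wu" in self.metrics) and self.tree_path is None:
                raise ValueError("UniFrac requested but no tree provided")


def validate_inputs(
    table: FeatureTable,
    tax: TaxonomyMap,
    meta: SampleMetadata,
    tree: PhyloTree | None = None,
) -> list[str]:
    """Cross-check the four inputs; returns a list of human-readable issues."""
    issues = []
    meta_samples = set(meta.sample_ids)
    for s in table.sample_ids:
        if s not in meta_samples:
            issues.append(f"sample {s!r} missing from metadata")
    for t in table.taxon_ids:
        if t not in tax:
            issues.append(f"taxon {t!r} missing from taxonomy")
    if tree is not None:
        leaves = {leaf.name for leaf in tree.tips()}
        for t in table.taxon_ids:
            if t not in leaves:
                issues.append(f"taxon {t!r} missing from tree")
    return issues


def _digest(path: str) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _perm_row(result: betadiv.PermTestResult) -> dict:
    return {
        "method": result.method,
        "statistic": result.statistic,
        "effect": result.effect,
        "p": result.p,
        "permutations": result.permutations,
        "seed": result.seed,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write stage outputs plus a manifest.

    Returns the report dictionary that is also written to ``report.json``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {stage: stage_seed(config.seed, stage) for stage in STAGES}
    manifest: dict = {
        "seeds": seeds,
        "parameters": {
            "depth": config.depth,
            "min_total": config.min_total,
            "permutations": config.permutations,
            "subset_sizes": list(config.subset_sizes),
            "replicates": config.replicates,
            "abundance_threshold": config.abundance_threshold,
            "max_order": config.max_order,
            "metrics": list(config.metrics),
            "seed": config.seed,
        },
        "inputs": {},
    }

    # --- stage: inputs -----------------------------------------------------
    if config.simulate:
        spec = simulate.SimulationSpec(
            profiles=simulate.default_profiles(),
            species_per_group=config.species_per_group,
            samples_per_species=config.samples_per_species,
            seed=seeds["simulate"],
        )
        table, tax, meta, tree = simulate.simulate_dataset(spec)
        manifest["inputs"]["mode"] = "simulated"
        manifest["inputs"]["species_per_group"] = config.species_per_group
        manifest["inputs"]["samples_per_species"] = config.samples_per_species
    else:
        table = tabletools.read_feature_table(config.table_path)
        tax = tabletools.read_taxonomy(config.taxonomy_path)
        meta = tabletools.read_metadata(config.metadata_path)
        tree = tabletools.read_tree(config.tree_path) if config.tree_path else None
        manifest["inputs"]["mode"] = "files"
        for name, p in (
            ("table", config.table_path),
            ("taxonomy", config.taxonomy_path),
            ("metadata", config.metadata_path),
            ("tree", config.tree_path),
        ):
            if p:
                manifest["inputs"][name] = {"path": str(p), "sha256": _digest(p)}

    issues = validate_inputs(table, tax, meta, tree)
    if issues:
        raise ValueError("input validation failed: " + "; ".join(issues[:10]))

    # --- stage: filtering and rarefaction ----------------------------------
    filtered = tabletools.filter_low_abundance(table, config.min_total)
    filtered = tabletools.filter_organelles(filtered, tax)
    rarefied = tabletools.rarefy(filtered, config.depth, seeds["rarefy"])
    tabletools.write_feature_table(rarefied, outdir / "rarefied.tsv")
    meta_r = SampleMetadata(meta.records.loc[rarefied.sample_ids])
    groups = meta_r.column("group")

    report: dict = {"n_samples": len(rarefied.sample_ids),
                    "n_taxa": len(rarefied.taxon_ids)}

    # --- stage: alpha diversity --------------------------------------------
    alpha = alphadiv.alpha_diversity(rarefied)
    alpha.per_sample.to_csv(outdir / "alpha.tsv", sep="\t", index_label="sample_id")
    alpha_tests = {}
    for index_name in ("richness", "shannon", "ens"):
        test = alphadiv.kruskal_dunn(alpha.per_sample[index_name], groups)
        alpha_tests[index_name] = {
            "kw_statistic": test.kw_statistic,
            "kw_p": test.kw_p,
            "df": test.df,
        }
        test.pairwise.to_csv(
            outdir / f"alpha_dunn_{index_name}.tsv", sep="\t", index=False
        )
    report["alpha"] = {
        "group_medians": alpha.group_summary(groups).to_dict(),
        "tests": alpha_tests,
    }

    # --- stage: beta diversity ---------------------------------------------
    beta_report = {}
    metric_fns = {
        "bray": lambda: betadiv.bray_curtis(rarefied),
        "uu": lambda: betadiv.unweighted_unifrac(rarefied, tree),
        "wu": lambda: betadiv.weighted_unifrac(rarefied, tree),
    }
    for metric in config.metrics:
        dm = metric_fns[metric]()
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            outdir / f"distance_{metric}.tsv", sep="\t"
        )
        ordination = betadiv.pcoa(dm)
        ordination.coordinates.iloc[:, :3].to_csv(
            outdir / f"pcoa_{metric}.tsv", sep="\t", index_label="sample_id"
        )
        entry = {
            "proportion_explained_first3": [
                float(x) for x in ordination.proportion_explained[:3]
            ],
            "tests": [],
        }
        for test_fn in (betadiv.anosim, betadiv.permanova, betadiv.permdisp):
            result = test_fn(dm, groups, config.permutations, seeds["beta"])
            entry["tests"].append(_perm_row(result))
        beta_report[metric] = entry
    report["beta"] = beta_report

    # --- stage: stability ---------------------------------------------------
    family_table = tabletools.aggregate_to_family(filtered, tax)
    family_rel = tabletools.to_relative(family_table)
    stats_records = stability.family_stats(family_rel, meta)
    curves_frames = []
    stab_rows = []
    regressions = []
    for diet in sorted(pd.unique(meta.column("diet"))):
        families = stability.abundance_filter(
            family_rel, meta, diet, config.abundance_threshold
        )
        diet_species = sorted(
            pd.unique(meta.column("species")[meta.column("diet") == diet])
        )
        for species in diet_species:
            n_sp = len(meta.samples_of_species(species))
            if n_sp < min(config.subset_sizes):
                logger.info("stability: %s has %d samples; skipped", species, n_sp)
                continue
            curves = stability.subsample_stability(
                family_rel, meta, species, families,
                config.subset_sizes, config.replicates,
                stage_seed(seeds["stability"], species),
            )
            curves_frames.append(stability.stability_table(curves))
            for fam, curve in curves.items():
                size = (
                    stability.stabilization_size(curve)
                    if curve.full_cv is not None else None
                )
                stab_rows.append(
                    {"species": species, "family": fam, "diet": diet,
                     "full_cv": curve.full_cv, "stabilization_n": size}
                )
        # regressions across species of this diet: CV vs sample count and
        # CV vs mean abundance, one per family
        for fam in families:
            pts_n = [
                (r.n_samples, r.cv)
                for r in stats_records
                if r.family == fam and r.species in diet_species
            ]
            pts_a = [
                (r.mean_rel_abundance * 100, r.cv)
                for r in stats_records
                if r.family == fam and r.species in diet_species
            ]
            for pts, kind in ((pts_n, "sample-count"), (pts_a, "mean-abundance")):
                try:
                    reg = stability.cv_regression(pts, kind)
                except ValueError:
                    continue
                regressions.append(
                    {"diet": diet, "family": fam, "x_kind": kind,
                     "slope": reg.slope, "intercept": reg.intercept,
                     "p_slope": reg.p_slope, "n_points": reg.n_points}
                )
    if curves_frames:
        pd.concat(curves_frames, ignore_index=True).to_csv(
            outdir / "stability_curves.tsv", sep="\t", index=False
        )
    pd.DataFrame(stab_rows).to_csv(
        outdir / "stabilization.tsv", sep="\t", index=False
    )
    pd.DataFrame(regressions).to_csv(
        outdir / "cv_regressions.tsv", sep="\t", index=False
    )
    report["stability"] = {
        "n_curves": sum(len(f) for f in curves_frames),
        "n_regressions": len(regressions),
    }

    # --- stage: indicators ---------------------------------------------------
    results = indicators.best_indicator(
        family_rel, meta, config.max_order,
        config.permutations, seed=seeds["indicators"],
    )
    table_ind = indicators.indicator_table(results)
    table_ind.to_csv(outdir / "indicators.tsv", sep="\t", index=False)
    significant = table_ind[table_ind["p"] <= 0.05]
    report["indicators"] = {
        "n_families_tested": len(table_ind),
        "n_significant": int(len(significant)),
        "per_combination": significant.groupby("combination").size().to_dict(),
    }

    manifest["report"] = "report.json"
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
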