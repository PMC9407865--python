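"""End-to-end orchestration: simulate → discover → annotate → popgen →
assoc → expr/luc as one reproducible run.

A run is driven by a JSON config (versioned schema) that surfaces every
module threshold in one place; it writes all stage outputs into one
directory plus a manifest with the config hash, the seed, and a SHA-256
checksum of every stage input/output. Re-running with an unchanged
config skips stages whose inputs and outputs are unchanged, and the
deterministic stages reproduce identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from pathlib import Path
from typing import Any, Callable

import pandas as pd

from . import __version__
from . import annotate as annotate_mod
from . import assoc as assoc_mod
from . import discover as discover_mod
from . import expr as expr_mod
from . import io as rio
from . import popgen as popgen_mod
from . import simulate as sim

__all__ = ["ConfigError", "StageError", "default_config", "validate_config", "run_all"]

log = logging.getLogger("ripkit")

SCHEMA_VERSION = 1
ALL_STAGES = ["simulate", "discover", "annotate", "popgen", "assoc", "expr", "luc"]


class ConfigError(ValueError):
    """Config fails schema validation (reported before any stage runs)."""


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()


def default_config(seed: int = 42) -> dict:
    """The packaged fixture configuration, JSON-serializable."""
    loci = []
    for cfg in sim.default_locus_configs(seed):
        d = dataclasses.asdict(cfg)
        d.pop("seed")
        loci.append(d)
    return {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "stages": list(ALL_STAGES),
        "simulate": {
            "loci": loci,
            "populations": [dataclasses.asdict(p) for p in sim.default_population_specs()],
            "phenotype_counts": dataclasses.asdict(sim.default_phenotype_counts()),
            "traits": [dataclasses.asdict(t) for t in sim.default_trait_specs()],
            "expression": dataclasses.asdict(sim.default_expression_spec()),
            "luciferase": dataclasses.asdict(sim.default_luciferase_spec()),
        },
        "discover": {"params": {}},
        "annotate": {"params": {}},
        "assoc": {"trait": "age_100kg", "dispersion": "sem"},
        "expr": {"calibrator": "+/+"},
        "luc": {"control": "pGL3-basic"},
    }


def _locus_config(d: dict, seed: int) -> sim.SimConfig:
    d = dict(d)
    d["library"] = tuple(sim.ConsensusSpec(**c) for c in d.get("library", []))
    d["insertions"] = tuple(sim.InsertionSpec(**i) for i in d.get("insertions", []))
    d["breeds"] = tuple(
        sim.BreedSpec(
            name=b["name"],
            carries=tuple(b.get("carries", ())),
            snp_rate=b.get("snp_rate", 0.01),
            indel_rate=b.get("indel_rate", 0.0),
        )
        for b in d.get("breeds", [])
    )
    return sim.SimConfig(seed=seed, **d)


def validate_config(config: dict) -> None:
    """Pre-flight schema check; raises :class:`ConfigError` before any stage runs."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a JSON object")
    if config.get("schema_version") != SCHEMA_VERSION:
        raise ConfigError(f"schema_version must be {SCHEMA_VERSION}")
    if not isinstance(config.get("seed"), int):
        raise ConfigError("integer 'seed' is required")
    stages = config.get("stages", ALL_STAGES)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
    simsec = config.get("simulate")
    downstream = set(stages) - {"simulate"}
    if downstream and (not isinstance(simsec, dict) or not simsec.get("loci")):
        raise ConfigError("pipeline stages require simulate.loci")
    if "simulate" in stages:
        for locus in simsec["loci"]:
            if "gene_name" not in locus:
                raise ConfigError("every simulate.loci entry needs gene_name")
    for section, key in (("assoc", "trait"), ("expr", "calibrator"), ("luc", "control")):
        if section in stages and not isinstance(config.get(section, {}), dict):
            raise ConfigError(f"section {section!r} must be an object")


def run_all(config: dict | str | os.PathLike, outdir: str | os.PathLike) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config["seed"]
    stages = config.get("stages", ALL_STAGES)
    gene_names = [d["gene_name"] for d in config.get("simulate", {}).get("loci", [])]

    manifest_path = outdir / "manifest.json"
    previous: dict = {}
    if manifest_path.exists():
        try:
            previous = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            previous = {}

    manifest: dict[str, Any] = {
        "tool_version": __version__,
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "config_hash": _config_hash(config),
        "stages": [],
    }
    same_config = previous.get("config_hash") == manifest["config_hash"]

    def prior(name: str) -> dict:
        for st in previous.get("stages", []):
            if st["name"] == name:
                return st
        return {}

    def run_stage(name: str, inputs: list[Path], outputs: list[Path], fn: Callable[[], None]) -> None:
        if name not in stages:
            return
        t0 = time.time()
        st = prior(name)
        unchanged = (
            same_config
            and st
            and all(p.exists() for p in inputs + outputs)
            and {p.name: _sha256(p) for p in inputs} == st.get("inputs")
            and {p.name: _sha256(p) for p in outputs} == st.get("outputs")
        )
        if unchanged:
            log.info("stage %s unchanged, skipped", name)
        else:
            try:
                fn()
            except (ConfigError, StageError):
                raise
            except Exception as exc:  # stage boundary: name the failing stage
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.time() - t0)
        manifest["stages"].append(
            {
                "name": name,
                "skipped": bool(unchanged),
                "seconds": round(time.time() - t0, 3),
                "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
                "outputs": {p.name: _sha256(p) for p in outputs if p.exists()},
            }
        )

    dparams = discover_mod.DiscoveryParams(**config.get("discover", {}).get("params", {}))
    aparams = annotate_mod.AnnotationParams(**config.get("annotate", {}).get("params", {}))

    # ---- simulate ---------------------------------------------------------
    sim_outputs = [outdir / "gene_model.tsv", outdir / "truth.tsv"]
    for g in gene_names:
        sim_outputs += [outdir / f"{g}.bait.fa", outdir / f"{g}.assemblies.fa", outdir / f"{g}.library.fa"]
    simsec = config.get("simulate", {})
    for key, fname in (
        ("populations", "genotypes.tsv"),
        ("traits", "phenotypes.tsv"),
        ("expression", "ct.tsv"),
        ("luciferase", "luciferase.tsv"),
    ):
        if simsec.get(key):
            sim_outputs.append(outdir / fname)

    def do_simulate() -> None:
        truth_frames, models = [], []
        for locus_dict in simsec["loci"]:
            cfg = _locus_config(locus_dict, seed)
            bait, model, library = sim.make_locus(cfg)
            assemblies, truth = sim.make_assemblies(bait, model, library, cfg)
            g = cfg.gene_name
            rio.write_fasta([bait], outdir / f"{g}.bait.fa")
            rio.write_fasta(assemblies, outdir / f"{g}.assemblies.fa")
            rio.write_repeat_library(library, outdir / f"{g}.library.fa")
            truth.insert(0, "gene", g)
            truth_frames.append(truth)
            models.append(model)
        rio.write_gene_models(models, outdir / "gene_model.tsv")
        pd.concat(truth_frames).to_csv(outdir / "truth.tsv", sep="\t", index=False)
        if simsec.get("populations"):
            rows = [
                (gene_names[0], sim.make_population(sim.PopulationSpec(**p), seed))
                for p in simsec["populations"]
            ]
            rio.write_genotype_table(rows, outdir / "genotypes.tsv")
        if simsec.get("traits"):
            counts = sim.GenotypeCounts(**simsec["phenotype_counts"])
            traits = [
                sim.TraitSpec(t["name"], tuple(t["means"]), tuple(t["sds"]))
                for t in simsec["traits"]
            ]
            sim.make_phenotypes(counts, traits, seed).to_csv(
                outdir / "phenotypes.tsv", sep="\t", index=False
            )
        if simsec.get("expression"):
            e = simsec["expression"]
            spec = sim.ExpressionSpec(
                groups=tuple(tuple(g) for g in e["groups"]),
                calibrator=e.get("calibrator", "+/+"),
                noise_sd=e.get("noise_sd", 0.2),
                base_ct_reference=e.get("base_ct_reference", 17.0),
                base_dct=e.get("base_dct", 5.0),
                reference_sd=e.get("reference_sd", 0.3),
            )
            sim.make_ct_table(spec, seed).to_csv(outdir / "ct.tsv", sep="\t", index=False)
        if simsec.get("luciferase"):
            ls = simsec["luciferase"]
            spec = sim.LuciferaseSpec(
                constructs=tuple(tuple(c) for c in ls["constructs"]),
                control=ls.get("control", "pGL3-basic"),
            )
            sim.make_luciferase(spec, seed).to_csv(
                outdir / "luciferase.tsv", sep="\t", index=False
            )

    run_stage("simulate", [], sim_outputs, do_simulate)

    # ---- discover ---------------------------------------------------------
    disc_inputs = [p for g in gene_names for p in (outdir / f"{g}.bait.fa", outdir / f"{g}.assemblies.fa")]
    disc_outputs = [outdir / f"{g}.candidates.tsv" for g in gene_names]

    def do_discover() -> None:
        for g in gene_names:
            bait = rio.read_fasta(outdir / f"{g}.bait.fa")[0]
            assemblies = rio.read_fasta(outdir / f"{g}.assemblies.fa")
            clustered = discover_mod.discover_svs(bait, assemblies, dparams)
            rio.write_candidates(clustered, outdir / f"{g}.candidates.tsv")

    run_stage("discover", disc_inputs, disc_outputs, do_discover)

    # ---- annotate ---------------------------------------------------------
    ann_inputs = disc_inputs + [outdir / f"{g}.library.fa" for g in gene_names] + [outdir / "gene_model.tsv"]

    def do_annotate() -> None:
        models = rio.read_gene_models(outdir / "gene_model.tsv")
        all_records = []
        for g in gene_names:
            bait = rio.read_fasta(outdir / f"{g}.bait.fa")[0]
            assemblies = rio.read_fasta(outdir / f"{g}.assemblies.fa")
            library = rio.read_repeat_library(outdir / f"{g}.library.fa")
            # clustering is redone here so cluster members stay available
            # for TSD corroboration (the candidates TSV drops that detail)
            clustered = discover_mod.discover_svs(bait, assemblies, dparams)
            all_records.extend(
                annotate_mod.annotate_insertions(clustered, library, models[g], bait, aparams)
            )
        rio.write_rip_table(all_records, outdir / "rips.tsv")
        rio.write_rip_bed(all_records, outdir / "rips.bed")

    run_stage("annotate", ann_inputs, [outdir / "rips.tsv", outdir / "rips.bed"], do_annotate)

    # ---- popgen -----------------------------------------------------------
    def do_popgen() -> None:
        rows = rio.read_genotype_table(outdir / "genotypes.tsv")
        popgen_mod.popgen_table(rows).to_csv(outdir / "popgen.tsv", sep="\t", index=False)

    run_stage("popgen", [outdir / "genotypes.tsv"], [outdir / "popgen.tsv"], do_popgen)

    # ---- assoc ------------------------------------------------------------
    def do_assoc() -> None:
        asec = config.get("assoc", {})
        table = rio.read_phenotype_table(outdir / "phenotypes.tsv")
        result = assoc_mod.anova_tukey(table, asec.get("trait", "age_100kg"))
        out = assoc_mod.summary_table(result, asec.get("dispersion", "sem"))
        out["anova_p"] = f"{result.anova_p:.4g}"
        out.to_csv(outdir / "assoc.tsv", sep="\t", index=False)

    run_stage("assoc", [outdir / "phenotypes.tsv"], [outdir / "assoc.tsv"], do_assoc)

    # ---- expr / luc -------------------------------------------------------
    def do_expr() -> None:
        table = rio.read_ct_table(outdir / "ct.tsv")
        res = expr_mod.ddct(table, config.get("expr", {}).get("calibrator", "+/+"))
        res.group_stats.to_csv(outdir / "expr.tsv", sep="\t", index=False)

    run_stage("expr", [outdir / "ct.tsv"], [outdir / "expr.tsv"], do_expr)

    def do_luc() -> None:
        table = rio.read_luciferase_table(outdir / "luciferase.tsv")
        res = expr_mod.luciferase_relative(table, config.get("luc", {}).get("control", "pGL3-basic"))
        res.group_stats.to_csv(outdir / "luc.tsv", sep="\t", index=False)

    run_stage("luc", [outdir / "luciferase.tsv"], [outdir / "luc.tsv"], do_luc)

    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
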