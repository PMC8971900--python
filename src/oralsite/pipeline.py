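"""End-to-end orchestration: simulate/load -> prepare -> analyses -> manifest.

Stages run in a fixed order (singleton removal, rarefaction at 95% of the
minimum sample total, diversity, assembly, classification, discrimination).
Every stage writes plain TSV/JSON files into its own subdirectory and the
run ends with a manifest recording the config snapshot, the master seed,
the derived per-stage seeds, SHA-256 digests of every output file and
per-stage wall-clock.  Stage outputs are byte-reproducible for a fixed
config + seed; the manifest itself additionally contains timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time

import pandas as pd
import yaml

from . import __version__
from ._util import ConfigurationError, stream_seed
from . import assembly as assembly_mod
from . import classify as classify_mod
from . import discriminate as discriminate_mod
from . import diversity as diversity_mod
from .feature_table import (
    HABITATS,
    collapse,
    rarefaction_depth,
    rarefy,
    read_feature_table,
    read_metadata,
    read_taxonomy,
    remove_singletons,
    to_relative,
)
from .synthetic_data import (
    SimulationConfig,
    default_profiles,
    generate_paired_study,
    inject_unique_species,
    write_study,
)

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "prepare", "diversity", "assembly", "classify", "discriminate")
_TOP_KEYS = {"seed", "inputs", *_STAGES}
_FLOAT_FMT = "%.10g"


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def load_config(config) -> dict:
    if isinstance(config, (str, os.PathLike)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigurationError("config must be a mapping")
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    if "inputs" in config and "simulate" in config:
        raise ConfigurationError(
            "config has both 'inputs' and 'simulate'; the data source is ambiguous")
    if "inputs" not in config and "simulate" not in config:
        raise ConfigurationError("config needs either 'inputs' or 'simulate'")
    return config


def run_all(config, out_dir: str, seed: int | None = None) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    config = load_config(config)
    master_seed = int(seed if seed is not None else config.get("seed", 0))
    os.makedirs(out_dir, exist_ok=True)
    stage_seeds = {s: stream_seed(master_seed, f"stage/{s}") for s in _STAGES}
    manifest: dict = {
        "package": "oralsite",
        "version": __version__,
        "seed": master_seed,
        "stage_seeds": stage_seeds,
        "config": config,
        "stages": {},
        "outputs": {},
        "status": "running",
    }
    manifest_path = os.path.join(out_dir, "manifest.json")

    def _finish_stage(name: str, stage_dir: str, t0: float) -> None:
        files = sorted(
            os.path.join(stage_dir, f) for f in os.listdir(stage_dir)
            if os.path.isfile(os.path.join(stage_dir, f)))
        for f in files:
            manifest["outputs"][os.path.relpath(f, out_dir)] = _digest(f)
        manifest["stages"][name] = {"seconds": round(time.monotonic() - t0, 3),
                                    "status": "ok"}
        logger.info("stage %s finished in %.1fs", name,
                    manifest["stages"][name]["seconds"])

    current = None
    try:
        for name in _STAGES:
            current = name
            stage_dir = os.path.join(out_dir, name)
            os.makedirs(stage_dir, exist_ok=True)
            t0 = time.monotonic()
            runner = globals()[f"_stage_{name}"]
            runner(config, stage_dir, stage_seeds[name], _ctx)
            _finish_stage(name, stage_dir, t0)
        manifest["status"] = "ok"
    except Exception:
        manifest["stages"][current] = {"status": "failed"}
        manifest["status"] = f"failed at stage {current!r}"
        _write_json(manifest, manifest_path)
        raise
    finally:
        _ctx.clear()
    _write_json(manifest, manifest_path)
    return manifest


#: scratch space carrying in-memory objects between stages of one run
_ctx: dict = {}


def _stage_simulate(config, stage_dir, seed, ctx) -> None:
    if "inputs" in config:
        paths = config["inputs"]
        table = read_feature_table(paths["feature_table"])
        taxonomy = read_taxonomy(paths["taxonomy"])
        metadata = read_metadata(paths["metadata"])
        ctx.update(table=table, taxonomy=taxonomy, metadata=metadata)
        return
    opts = dict(config.get("simulate") or {})
    unique_individuals = opts.pop("unique_individuals", None)
    if "reads" in opts and isinstance(opts["reads"], list):
        opts["reads"] = tuple(opts["reads"])
    sim = SimulationConfig(seed=seed, **opts)
    saliva, mucosa = default_profiles()
    table, taxonomy, metadata = generate_paired_study(sim, saliva, mucosa)
    truth = None
    if sim.unique_per_individual:
        table, taxonomy, truth = inject_unique_species(
            table, metadata, sim.unique_per_individual,
            rel_abundance=sim.unique_rel_abundance, seed=seed,
            individuals=unique_individuals, taxonomy=taxonomy)
    write_study(table, taxonomy, metadata, stage_dir)
    _write_json(
        {"per_individual": truth.per_individual if truth else {},
         "planted_fraction": truth.planted_fraction if truth else 0.0,
         "warnings": truth.warnings if truth else []},
        os.path.join(stage_dir, "planted_truth.json"))
    ctx.update(table=table, taxonomy=taxonomy, metadata=metadata)


def _stage_prepare(config, stage_dir, seed, ctx) -> None:
    opts = config.get("prepare") or {}
    table = remove_singletons(ctx["table"])
    depth = rarefaction_depth(table, fraction=opts.get("min_fraction", 0.95))
    prepared = rarefy(table, depth, seed=seed)
    metadata = ctx["metadata"].subset(prepared.sample_ids)
    from .feature_table import write_feature_table

    write_feature_table(prepared, os.path.join(stage_dir, "prepared_table.tsv"))
    _write_json({"rarefaction_depth": depth,
                 "n_samples": prepared.shape[0],
                 "n_features": prepared.shape[1]},
                os.path.join(stage_dir, "prepare_summary.json"))
    ctx.update(prepared=prepared, metadata=metadata)


def _stage_diversity(config, stage_dir, seed, ctx) -> None:
    prepared, metadata, taxonomy = ctx["prepared"], ctx["metadata"], ctx["taxonomy"]
    alpha = diversity_mod.alpha_diversity_frame(prepared)
    _write_tsv(alpha, os.path.join(stage_dir, "alpha_diversity.tsv"))

    tests = {m: diversity_mod.compare_groups(alpha[m], metadata).as_dict()
             for m in alpha.columns}
    if "age" in metadata.data.columns:
        tests["spearman_age_shannon"] = {
            h: vars(r) for h, r in
            diversity_mod.spearman_age(alpha["shannon"], metadata).items()}
    _write_json(tests, os.path.join(stage_dir, "group_tests.json"))

    rel = to_relative(prepared)
    dm = diversity_mod.bray_curtis(rel)
    _write_tsv(pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids),
               os.path.join(stage_dir, "bray_curtis.tsv"))
    emb = diversity_mod.nmds(dm, seed=seed)
    _write_tsv(emb.coordinates, os.path.join(stage_dir, "nmds.tsv"))
    _write_json({"stress": emb.stress, "converged": emb.converged},
                os.path.join(stage_dir, "nmds_stats.json"))

    genus = collapse(prepared, taxonomy, "genus")
    da = diversity_mod.differential_abundance(to_relative(genus), metadata)
    _write_tsv(da, os.path.join(stage_dir, "differential_abundance_genus.tsv"))
    ctx["genus_table"] = genus


def _stage_assembly(config, stage_dir, seed, ctx) -> None:
    opts = config.get("assembly") or {}
    n_null = int(opts.get("n_null", 999))
    prepared, metadata = ctx["prepared"], ctx["metadata"]
    rows = []
    for habitat in HABITATS:
        sub = prepared.filter_samples(metadata.samples_for(habitat))
        fit = assembly_mod.fit_ncm(sub)
        _write_tsv(fit.taxa, os.path.join(stage_dir, f"ncm_{habitat}.tsv"))
        _write_json({"nm": fit.nm, "nm_ci": list(fit.nm_ci),
                     "r_squared": fit.r_squared,
                     "detection_limit": fit.detection_limit,
                     "partition_counts": fit.partition_counts()},
                    os.path.join(stage_dir, f"ncm_{habitat}.json"))
        res = assembly_mod.null_model(prepared, metadata, habitat,
                                      n_null=n_null, seed=seed)
        rows.append(res.as_row())
    table2 = pd.DataFrame(rows).set_index("group")
    _write_tsv(table2, os.path.join(stage_dir, "null_model.tsv"))
    _write_json({r["group"]: r for r in rows},
                os.path.join(stage_dir, "null_model.json"))


def _stage_classify(config, stage_dir, seed, ctx) -> None:
    opts = config.get("classify") or {}
    report = classify_mod.classify_habitat(
        ctx["prepared"], ctx["metadata"],
        top_k=int(opts.get("top_k", 30)), seed=seed,
        n_estimators=int(opts.get("n_estimators", classify_mod.DEFAULT_N_ESTIMATORS)),
        individual_aware=bool(opts.get("individual_aware", False)))
    _write_json(report.as_dict(), os.path.join(stage_dir, "classifier.json"))
    _write_tsv(report.importances.to_frame("importance"),
               os.path.join(stage_dir, "importances.tsv"))


def _stage_discriminate(config, stage_dir, seed, ctx) -> None:
    opts = config.get("discriminate") or {}
    threshold = int(opts.get("rank_threshold", 100))
    prepared, metadata, taxonomy = ctx["prepared"], ctx["metadata"], ctx["taxonomy"]
    species = collapse(prepared, taxonomy, "species")
    genus = ctx.get("genus_table")
    if genus is None:
        genus = collapse(prepared, taxonomy, "genus")
    for habitat in HABITATS:
        if not metadata.samples_for(habitat):
            continue
        report = discriminate_mod.discrimination_report(
            species, genus, metadata, rank_threshold=threshold, habitat=habitat)
        _write_json(report.as_dict(),
                    os.path.join(stage_dir, f"discrimination_{habitat}.json"))
        _write_tsv(report.code, os.path.join(stage_dir, f"microbial_code_{habitat}.tsv"))
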