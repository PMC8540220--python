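"""End-to-end orchestration: screen -> map -> RP2 -> RP1 -> SPNs -> evaluation.

Every stage writes its output to disk so each step is independently
re-runnable and inspectable; a ``manifest.json`` records the configuration
snapshot, input digests, per-stage counts and timestamps.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from pathlib import Path

import yaml

from gi_refine.exceptions import ConfigurationError
from gi_refine import evaluation, io, mutation, network as net, screen as scr

logger = logging.getLogger(__name__)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_pipeline(config, outdir=None) -> dict:
    """Run the full pipeline from a YAML config path (or dict).

    Config layout::

        inputs:
          depletion: path            # required
          depletion_orientation: auto
          expression: path           # optional (exclusion disabled without it)
          expression_orientation: auto
          mutations: path            # required (variant table)
          network: path              # required when refinement requested
          network_directed: false
          reference: path            # optional (enables evaluation)
        mutation: {recurrence_threshold: 0.03, strict: true}
        screen:   {fdr_threshold: 0.2, min_group_size: 3, t_variant: welch,
                   exclusion: true, expression_zero_epsilon: 0.0}
        refine:   {distances: [2, 1], direction_mode: either,
                   fixed_point: false, exclude_self: false}
        output:   {dir: path}

    Returns the manifest dict (also written to ``manifest.json``).
    """
    cfg = _load_config(config)
    inputs = cfg.get("inputs", {})
    out = Path(outdir or cfg.get("output", {}).get("dir", "gi_refine_out"))

    # fail fast on configuration before any compute
    for key in ("depletion", "mutations"):
        if not inputs.get(key):
            raise ConfigurationError(f"inputs.{key} is required")
    refine_cfg = cfg.get("refine", {})
    distances = list(refine_cfg.get("distances", [2, 1]))
    if distances and not inputs.get("network"):
        raise ConfigurationError("inputs.network is required when refinement is requested")
    for p in ("depletion", "mutations", "expression", "network", "reference"):
        if inputs.get(p) and not Path(inputs[p]).exists():
            raise ConfigurationError(f"inputs.{p}: file not found: {inputs[p]}")

    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg, "inputs": {}, "stages": {}, "started": _now()}
    for key in ("depletion", "mutations", "expression", "network", "reference"):
        if inputs.get(key):
            manifest["inputs"][key] = {"path": str(inputs[key]), "sha256": _digest(inputs[key])}

    # --- load ---------------------------------------------------------------
    depletion = io.read_score_matrix(
        inputs["depletion"], role="depletion",
        orientation=inputs.get("depletion_orientation", "auto"),
    )
    variants = io.read_variant_table(inputs["mutations"])
    expression = None
    if inputs.get("expression"):
        expression = io.read_score_matrix(
            inputs["expression"], role="expression",
            orientation=inputs.get("expression_orientation", "auto"),
        )

    # --- mutation calling ----------------------------------------------------
    mut_cfg = cfg.get("mutation", {})
    mm = mutation.call_functional_mutations(variants, vocabulary=mut_cfg.get("vocabulary"))
    recurrent = mutation.select_recurrent_genes(
        mm,
        threshold=mut_cfg.get("recurrence_threshold", 0.03),
        strict=mut_cfg.get("strict", True),
    )
    manifest["stages"]["mutation_calling"] = {
        "n_genes": len(mm.genes),
        "n_cells": len(mm.cells),
        "n_recurrent": len(recurrent),
        "time": _now(),
    }

    # --- screen --------------------------------------------------------------
    s = cfg.get("screen", {})
    test_config = scr.TestConfig(
        fdr_threshold=s.get("fdr_threshold", 0.2),
        min_group_size=s.get("min_group_size", 3),
        t_variant=s.get("t_variant", "welch"),
        exclusion_enabled=s.get("exclusion", True),
        expression_zero_epsilon=s.get("expression_zero_epsilon", 0.0),
    )
    gi = scr.characterize_gis(depletion, expression, mm, recurrent, test_config, label="screen")
    io.write_gi_table(gi, out / "gi_screen.tsv")
    manifest["stages"]["screen"] = {
        "m_tests": gi.m_tests,
        "n_skipped": gi.n_skipped,
        "n_gis": len(gi),
        "n_masked_entries": gi.config.get("n_masked_entries", 0),
        "time": _now(),
    }

    # --- refinement ------------------------------------------------------------
    stage_tables = {}
    if distances:
        gn = net.load_network(inputs["network"], directed=bool(inputs.get("network_directed", False)))
        mode = refine_cfg.get("direction_mode", "either")
        mapped = net.map_sps(gi, gn, exclude_self=refine_cfg.get("exclude_self", False))
        init_results = {
            q: net.RefinementResult(q, 0, frozenset(m["initial"]), frozenset(m["initial"]),
                                    frozenset(), skipped=m["skipped"], direction_mode=mode)
            for q, m in mapped.items()
        }
        init_table = net.filter_gi_table(gi, init_results, label="INIT")
        io.write_gi_table(init_table, out / "gi_init.tsv")
        stage_tables["INIT"] = init_table
        manifest["stages"]["map"] = {
            "n_mutated_genes": len(mapped),
            "n_skipped": sum(m["skipped"] for m in mapped.values()),
            "n_unmapped_sps": sum(m["n_unmapped"] for m in mapped.values()),
            "n_initial_gis": len(init_table),
            "time": _now(),
        }
        spn_dir = out / "spn"
        spn_dir.mkdir(exist_ok=True)
        for k in distances:
            results = {
                q: net.refine(m["initial"], gn, k, direction_mode=mode, mutated_gene=q,
                              fixed_point=refine_cfg.get("fixed_point", False))
                for q, m in mapped.items()
            }
            stage = f"RP{k}"
            table = net.filter_gi_table(gi, results, label=stage)
            io.write_gi_table(table, out / f"gi_rp{k}.tsv")
            stage_tables[stage] = table
            n_spn = 0
            for q, res in sorted(results.items()):
                if res.skipped:
                    continue
                spn = net.build_spn(res, gn, gi_table=gi)
                net.export_spn(spn, spn_dir / f"{q}_spn{k}.tsv", format="tsv")
                n_spn += 1
            manifest["stages"][stage] = {
                "n_gis": len(table),
                "n_spns": n_spn,
                "time": _now(),
            }

    # --- evaluation -------------------------------------------------------------
    if inputs.get("reference") and stage_tables:
        reference = evaluation.load_reference_pairs(inputs["reference"])
        metrics = evaluation.stage_comparison(stage_tables, reference)
        metrics.to_csv(out / "evaluation.tsv", sep="\t", index=False)
        manifest["stages"]["evaluation"] = {
            "n_reference": len(reference),
            "metrics": metrics.to_dict(orient="records"),
            "time": _now(),
        }

    manifest["finished"] = _now()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
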