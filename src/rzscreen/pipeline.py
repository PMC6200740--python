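"""End-to-end pipeline runner: simulate -> signatures -> de -> enrich ->
connectivity -> chemgen -> motifs, driven by one YAML config.

Every randomized stage draws from the single config seed; a run writes
its outputs under ``outdir`` plus a ``manifest.json`` recording the config
hash, seed, per-stage outputs with row counts, and the package version.
Rerunning an identical config reproduces identical outputs and manifests
for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chemgen import chemogenomic_screen, group_set_drugs
from .connectivity import (DiseaseSignature, build_connectivity_matrix,
                           mds_embed, reversal_screen)
from .differential import (AnalysisConfig, call_de, categorize_table,
                           differential_de, gene_drug_counts,
                           mantel_haenszel_responsiveness)
from .enrichment import set_enrichment
from .io import (GeneSetCollection, write_fasta, write_gct, write_gmt,
                 write_table)
from .motifs import MotifPattern, cohort_enrichment, motif_density_test
from .signatures import build_signature_tensor, tensor_to_gct
from .simulate import (ScreenConfig, simulate_drug_annotations,
                       simulate_gene_sets, simulate_screen,
                       simulate_sequences_and_variants)

logger = logging.getLogger("rzscreen")

STAGES = ("simulate", "signatures", "de", "enrich", "connectivity",
          "chemgen", "motifs")
# each stage requires all stages before it in this chain
_CHAIN = {
    "signatures": "simulate",
    "de": "signatures",
    "enrich": "signatures",
    "connectivity": "signatures",
    "chemgen": "enrich",
    "motifs": "simulate",
}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list = field(default_factory=list)

    def record(self, stage: str, outputs: dict, elapsed: float) -> None:
        self.stages.append({"stage": stage, "outputs": outputs,
                            "seconds": round(elapsed, 3)})

    def to_json(self) -> str:
        return json.dumps({
            "config_hash": self.config_hash, "seed": self.seed,
            "version": self.version, "stages": self.stages}, indent=2)


def load_config(path) -> dict:
    try:
        with open(path) as fh:
            config = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ValueError(f"unparseable config {path}: {exc}") from exc
    if not isinstance(config, dict):
        raise ValueError(f"config {path} is not a mapping")
    return config


def validate_config(config: dict) -> list[str]:
    """Check every threshold, stage and group definition; list ALL
    violations, not just the first."""
    problems = []
    if "seed" not in config:
        problems.append("missing required key 'seed' (randomized stages "
                        "refuse to default silently)")
    stages = config.get("stages", list(STAGES))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        problems.append(f"unknown stages {unknown}")
    for s in stages:
        dep = _CHAIN.get(s)
        if dep and dep not in stages:
            problems.append(f"stage '{s}' requires stage '{dep}'")
    analysis = config.get("analysis", {})
    for key in ("de_threshold", "diff_threshold", "negligible_threshold"):
        if key in analysis and analysis[key] <= 0:
            problems.append(f"analysis.{key} must be > 0, "
                            f"got {analysis[key]}")
    screen = dict(config.get("screen", {}))
    screen.pop("preset", None)
    try:
        cfg = ScreenConfig(**screen, seed=config.get("seed", 0))
    except (TypeError, ValueError) as exc:
        problems.append(f"screen config invalid: {exc}")
        cfg = None
    for comparison in config.get("comparisons", []):
        for g in (comparison.get("group_a"), comparison.get("group_b")):
            if cfg and g not in cfg.n_cell_lines:
                problems.append(f"comparison references unknown group {g!r}")
    conn = config.get("connectivity", {})
    if conn.get("n_permutations", 1000) < 100:
        problems.append("connectivity.n_permutations must be >= 100")
    motifs = config.get("motifs", {})
    if "motif" in motifs:
        try:
            MotifPattern(motifs["motif"])
        except ValueError as exc:
            problems.append(f"motifs.motif invalid: {exc}")
    return problems


def _write(df: pd.DataFrame, path: Path) -> dict:
    write_table(df, path)
    return {"path": str(path), "rows": int(len(df))}


def run_pipeline(config: dict | str | Path, outdir=None) -> RunManifest:
    """Execute the configured stages in dependency order.

    ``config`` is a YAML path or an already-parsed mapping.  Raises on the
    first failing stage; validation problems abort before any stage runs.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(outdir or config.get("outdir", "rzscreen_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    stages = [s for s in STAGES if s in config.get("stages", list(STAGES))]
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = RunManifest(hashlib.sha256(blob).hexdigest()[:16], seed,
                           __version__)

    analysis = AnalysisConfig(**config.get("analysis", {}))
    state: dict = {}
    for stage in stages:
        t0 = time.monotonic()
        logger.info("stage %s ...", stage)
        outputs = _run_stage(stage, config, state, seed, outdir, analysis)
        manifest.record(stage, outputs, time.monotonic() - t0)
        logger.info("stage %s done (%.2fs)", stage,
                    time.monotonic() - t0)
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


def _run_stage(stage, config, state, seed, outdir, analysis):
    if stage == "simulate":
        return _stage_simulate(config, state, seed, outdir)
    if stage == "signatures":
        gct = tensor_to_gct(
            state.setdefault("tensor",
                             build_signature_tensor(state["screen"])))
        path = outdir / "signatures.gct"
        write_gct(gct, path)
        return {"signatures": {"path": str(path), "rows": gct.shape[0]}}
    if stage == "de":
        return _stage_de(config, state, outdir, analysis)
    if stage == "enrich":
        return _stage_enrich(config, state, outdir)
    if stage == "connectivity":
        return _stage_connectivity(config, state, seed, outdir)
    if stage == "chemgen":
        return _stage_chemgen(config, state, seed, outdir)
    if stage == "motifs":
        return _stage_motifs(config, state, seed, outdir)
    raise ValueError(f"unknown stage {stage!r}")


def _stage_simulate(config, state, seed, outdir):
    screen_cfg = dict(config.get("screen", {}))
    preset = screen_cfg.pop("preset", "scaled_down")
    factory = {"scaled_down": ScreenConfig.scaled_down,
               "full_size": ScreenConfig.full_size}[preset]
    sets_cfg = config.get("gene_sets", {})
    planted = {name: tuple(v) for name, v in
               sets_cfg.get("planted", {}).items()}
    n_genes = screen_cfg.get("n_genes", 500)
    universe = [f"G{i:05d}" for i in range(n_genes)]
    collection, update = simulate_gene_sets(
        universe, sets_cfg.get("n_sets", 20),
        sets_cfg.get("set_size", 25), planted=planted, seed=seed + 1)
    cfg = factory(**screen_cfg, seed=seed,
                  planted_set_shifts=update["set_shifts"])
    screen, truth = simulate_screen(cfg)
    truth.enriched_sets = update["enriched_sets"]
    state.update(screen=screen, truth=truth, sets=collection,
                 screen_config=cfg)
    gct_path = outdir / "expression.gct"
    ann_path = outdir / "annotation.tsv"
    gmt_path = outdir / "gene_sets.gmt"
    truth_path = outdir / "truth.json"
    write_gct(screen.matrix, gct_path)
    write_table(screen.annotation, ann_path)
    write_gmt(collection, gmt_path)
    truth_path.write_text(json.dumps({
        "reverser_drugs": truth.reverser_drugs,
        "disease_up": truth.disease_up,
        "disease_down": truth.disease_down,
        "enriched_sets": truth.enriched_sets,
        "n_planted_base_effects": int((truth.base_effect != 0).sum()),
    }, indent=2))
    return {"expression": {"path": str(gct_path),
                           "rows": screen.matrix.shape[0]},
            "annotation": {"path": str(ann_path),
                           "rows": len(screen.annotation)},
            "gene_sets": {"path": str(gmt_path), "rows": len(collection)},
            "truth": {"path": str(truth_path), "rows": 1}}


def _stage_de(config, state, outdir, analysis):
    tensor = state["tensor"]
    groups = sorted(set(tensor.group_labels.values()))
    outputs = {}
    de_tables = {}
    for g in groups:
        de_tables[g] = call_de(tensor, g, analysis)
        outputs[f"de_{g}"] = _write(de_tables[g],
                                    outdir / f"de_{g}.tsv")
    state["de_tables"] = de_tables
    comparisons = config.get("comparisons") or _default_comparisons(groups)
    rows = []
    for comp in comparisons:
        a, b = comp["group_a"], comp["group_b"]
        diff = differential_de(tensor, a, b, analysis)
        outputs[f"diff_{a}_vs_{b}"] = _write(
            diff, outdir / f"diff_{a}_vs_{b}.tsv")
        cats = categorize_table(tensor, a, b, analysis)
        outputs[f"categories_{a}_vs_{b}"] = _write(
            cats, outdir / f"categories_{a}_vs_{b}.tsv")
        mh = mantel_haenszel_responsiveness(
            tensor, a, b, analysis, n_comparisons=len(comparisons))
        rows.append((a, b, mh.common_odds_ratio, mh.chi_square,
                     mh.p_value, mh.bonferroni_p, mh.n_strata))
    mh_table = pd.DataFrame(rows, columns=[
        "group_a", "group_b", "common_odds_ratio", "chi_square",
        "p_value", "bonferroni_p", "n_strata"])
    outputs["mantel_haenszel"] = _write(mh_table, outdir / "mh.tsv")
    counts, summary = gene_drug_counts(
        pd.concat(de_tables.values(), ignore_index=True))
    outputs["gene_drug_counts"] = _write(
        counts.reset_index(name="n_drugs"), outdir / "gene_drug_counts.tsv")
    state["mh"] = mh_table
    state["gene_summary"] = summary
    return outputs


def _default_comparisons(groups):
    comps = []
    if {"NPC_control", "NPC_SZ"} <= set(groups):
        comps.append({"group_a": "NPC_SZ", "group_b": "NPC_control"})
    return comps


def _stage_enrich(config, state, outdir):
    tensor, sets = state["tensor"], state["sets"]
    cfg = config.get("enrichment", {})
    result = set_enrichment(
        tensor, cfg.get("group_a", "NPC_SZ"),
        cfg.get("group_b", "NPC_control"), sets,
        variant=cfg.get("variant", "v1"))
    state["enrichments"] = result
    return {"enrichment": _write(result, outdir / "enrichment.tsv")}


def _stage_connectivity(config, state, seed, outdir):
    tensor, truth = state["tensor"], state["truth"]
    cfg = config.get("connectivity", {})
    disease = DiseaseSignature(frozenset(truth.disease_up),
                               frozenset(truth.disease_down),
                               label="planted_disease_signature")
    matrix = build_connectivity_matrix(tensor, disease,
                                       aggregate=cfg.get("aggregate",
                                                         "by_group"))
    screen_table = reversal_screen(
        matrix, disease, n_genes=len(tensor.genes),
        n_permutations=cfg.get("n_permutations", 1000),
        seed=seed + 2, fdr=cfg.get("fdr", 0.1))
    percell = build_connectivity_matrix(tensor, disease, aggregate="none")
    embedding = mds_embed(percell, n_dims=cfg.get("n_dims", 2))
    state["reversal"] = screen_table
    out = {
        "connectivity_matrix": _write(
            matrix.rename_axis("drug").reset_index(),
            outdir / "connectivity.tsv"),
        "reversal": _write(screen_table, outdir / "reversal.tsv"),
        "mds": _write(embedding.rename_axis("cell_line").reset_index(),
                      outdir / "mds.tsv"),
    }
    return out


def _stage_chemgen(config, state, seed, outdir):
    cfg = config.get("chemgen", {})
    tensor = state["tensor"]
    groups = group_set_drugs(state["enrichments"],
                             fdr=cfg.get("fdr", 0.1),
                             min_drugs=cfg.get("min_drugs", 3))
    classes = cfg.get("classes", ["target", "side_effect"])
    planted = cfg.get("planted", [])
    annotations, _ = simulate_drug_annotations(
        tensor.drugs, classes,
        n_features=cfg.get("n_features", 10),
        planted=[(tuple(p[0]), p[1], p[2]) for p in planted],
        seed=seed + 3)
    ann_path = outdir / "drug_annotations.tsv"
    write_table(annotations, ann_path)
    result = chemogenomic_screen(groups, annotations, tensor.drugs,
                                 classes=classes)
    state["chemgen"] = result
    return {"drug_annotations": {"path": str(ann_path),
                                 "rows": len(annotations)},
            "chemgen": _write(result, outdir / "chemgen.tsv")}


def _stage_motifs(config, state, seed, outdir):
    cfg = config.get("motifs", {})
    motif = MotifPattern(cfg.get("motif", "ACUK"))
    seqs, variants, truth = simulate_sequences_and_variants(
        n_seqs=cfg.get("n_seqs", 30), length=cfg.get("length", 1000),
        motif=motif,
        density_high=cfg.get("density_high", 4.0),
        density_low=cfg.get("density_low", 1.0),
        n_variants=cfg.get("n_variants",
                           {"SZ": 200, "control": 200}),
        in_motif_fraction=cfg.get("in_motif_fraction",
                                  {"SZ": 0.3, "control": 0.1}),
        seed=seed + 4)
    fasta_path = outdir / "sequences.fasta"
    var_path = outdir / "variants.tsv"
    write_fasta(seqs, fasta_path)
    write_table(variants, var_path)
    high = [s for n, s in seqs.items() if n.startswith("high")]
    low = [s for n, s in seqs.items() if n.startswith("low")]
    density = motif_density_test(high, low, motif)
    cohorts = [c for c in variants["cohort"].unique() if c != "control"]
    enr = cohort_enrichment(variants, motif, sorted(cohorts), "control")
    state["motif_density"] = density
    state["motif_enrichment"] = enr
    density_path = outdir / "motif_density.json"
    density_path.write_text(json.dumps(density, indent=2))
    return {"sequences": {"path": str(fasta_path), "rows": len(seqs)},
            "variants": {"path": str(var_path), "rows": len(variants)},
            "motif_density": {"path": str(density_path), "rows": 1},
            "motif_enrichment": _write(enr, outdir / "motif_enrichment.tsv")}
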