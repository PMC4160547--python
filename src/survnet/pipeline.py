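"""End-to-end workflow: score -> module -> robustness -> randomise ->
landscape -> gsea -> enrich -> ages, driven by a YAML config, with a JSON
run manifest (config snapshot, input digests, seeds, stage timings, output
paths) for auditability."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from importlib.metadata import version as _pkg_version
from pathlib import Path

from . import enrichment as _enr
from .datatypes import load_age_table, load_gmt
from .model import SurvivalNetworkModel
from .module_search import write_module_graphml

logger = logging.getLogger(__name__)

STAGES = ("score", "module", "robustness", "randomise", "landscape",
          "gsea", "enrich", "ages")


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the enabled stages in order and write a run manifest.

    ``config`` keys: inputs {mutations, clinical, network, gmt?, ages?,
    repertoires?}, seed, pcut/size, stages {name: bool}, and per-stage
    parameter blocks (robustness, randomise, landscape, gsea).
    Stage failure raises with the stage named; prior outputs are kept.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = config["inputs"]
    seed = int(config.get("seed", 0))
    enabled = {s: bool(config.get("stages", {}).get(s, True)) for s in STAGES}
    if enabled["enrich"] and "gmt" not in inputs:
        enabled["enrich"] = False
    if enabled["ages"] and ("ages" not in inputs or "repertoires" not in inputs):
        enabled["ages"] = False

    manifest = {
        "tool": "survnet",
        "version": _pkg_version("survnet"),
        "config": config,
        "seed": seed,
        "inputs": {k: {"path": str(v), "sha256": _digest(v)}
                   for k, v in inputs.items()},
        "stages": {},
        "outputs": {},
    }

    model = SurvivalNetworkModel.from_files(inputs["mutations"],
                                            inputs["clinical"],
                                            inputs["network"])
    results = None

    def stage(name, fn):
        if not enabled[name]:
            logger.info("stage %s disabled", name)
            return
        t0 = time.perf_counter()
        try:
            outputs = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "seconds": round(time.perf_counter() - t0, 3),
        }
        for label, path in outputs.items():
            manifest["outputs"][f"{name}.{label}"] = {
                "path": str(path), "sha256": _digest(path)}

    def do_score_module():
        nonlocal results
        fit_kw = {"min_mutated": int(config.get("min_mutated", 2))}
        if "size" in config:
            fit_kw["size"] = int(config["size"])
            fit_kw["tol"] = int(config.get("tol", 2))
        else:
            fit_kw["pcut"] = float(config.get("pcut", 0.05))
        results = model.fit(**fit_kw)

    def score_stage():
        do_score_module()
        p = outdir / "scores.tsv"
        results.gene_scores.to_csv(p, sep="\t", index=False)
        return {"scores": p}

    def module_stage():
        p = outdir / "module.graphml"
        write_module_graphml(results.module, p)
        t = outdir / "module.tsv"
        results.module.to_frame().to_csv(t, sep="\t", index=False)
        return {"graphml": p, "table": t}

    def robustness_stage():
        conf = results.edge_confidence(
            tol=int(config.get("robustness", {}).get("tol", 2)))
        p = outdir / "edge_confidence.tsv"
        conf.to_csv(p, sep="\t", index=False)
        return {"edge_confidence": p}

    def randomise_stage():
        blk = config.get("randomise", {})
        sig = results.edge_significance(R=int(blk.get("reps", 100)),
                                        n_bins=int(blk.get("n_bins", 10)),
                                        seed=seed)
        p = outdir / "edge_significance.tsv"
        sig.table.to_csv(p, sep="\t", index=False)
        q = outdir / "edge_significance_aggregate.json"
        with open(q, "w") as fh:
            json.dump({"aggregated_p": sig.aggregated_p,
                       "n_randomisations": sig.n_randomisations}, fh)
        return {"edges": p, "aggregate": q}

    def landscape_stage():
        blk = config.get("landscape", {})
        ls = results.landscape(rows=int(blk.get("rows", 6)),
                               cols=int(blk.get("cols", 6)), seed=seed)
        p = outdir / "landscape.tsv"
        ls.to_frame().to_csv(p, sep="\t", index=False)
        tree = results.nj_tree(boot_reps=int(blk.get("boot", 100)), seed=seed)
        q = outdir / "tree.nwk"
        q.write_text(tree.newick + "\n")
        return {"assignments": p, "tree": q}

    def gsea_stage():
        blk = config.get("gsea", {})
        res = results.gsea_hr(weight=float(blk.get("weight", 1.0)),
                              R=int(blk.get("reps", 1000)), seed=seed)
        p = outdir / "gsea.json"
        with open(p, "w") as fh:
            json.dump({"es": res.es, "nes": res.nes, "pval": res.pval,
                       "peak_rank": res.peak_rank, "n_hits": res.n_hits}, fh)
        return {"gsea": p}

    def enrich_stage():
        collection = load_gmt(inputs["gmt"])
        if collection.relations:
            collection = _enr.propagate_ontology(collection)
        df = results.enrich(collection)
        p = outdir / "enrichment.tsv"
        df.to_csv(p, sep="\t", index=False)
        return {"enrichment": p}

    def ages_stage():
        ages = load_age_table(inputs["ages"], inputs["repertoires"])
        df = results.phylostratum(ages)
        p = outdir / "ages.tsv"
        df.to_csv(p, sep="\t", index=False)
        return {"ages": p}

    stage("score", score_stage)
    if results is None:      # score disabled but later stages need the fit
        do_score_module()
    stage("module", module_stage)
    stage("robustness", robustness_stage)
    stage("randomise", randomise_stage)
    stage("landscape", landscape_stage)
    stage("gsea", gsea_stage)
    stage("enrich", enrich_stage)
    stage("ages", ages_stage)

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    manifest["manifest_path"] = str(manifest_path)
    return manifest
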