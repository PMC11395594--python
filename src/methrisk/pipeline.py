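"""End-to-end orchestration: clock training -> Shapley screening -> network
panel selection -> stage classification, with a deterministic provenance
manifest.

A single global seed derives per-stage seeds (seed + stage index), so each
stage is independently reproducible.  Every intermediate artifact is always
written — auditability of the screening funnel (all sites -> top-k sites ->
genes -> module -> marker panel) is the point of the method.  The manifest
records, per stage, a key hashing the stage's config and input files and a
checksum per output file; reruns with ``resume=True`` skip stages whose keys
and outputs are unchanged.  Wall-clock timings go to a separate file so the
manifest itself is byte-stable under a fixed seed.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attribution, clock, ddr, netselect
from .data_io import (MetricsReport, config_hash, impute_mean, read_annotation,
                      read_beta_matrix, read_cohort, read_edges, read_gmt,
                      write_report)

log = logging.getLogger("methrisk")

DEFAULTS: dict = {
    "inputs": {
        "beta": None, "cohort": None, "annotation": None,
        "edges": None, "gmt": None,
    },
    "clock": {
        "fc1_width": 64, "kernel_sizes": [1, 8, 16, 32],
        "channels_per_scale": 4, "fc2_width": 16,
        "learning_rate": 1e-3, "epochs": 100, "batch_size": 32,
        "loss_name": "mae",
    },
    "attribution": {
        "k": 150, "n_permutations": 32, "n_reference": 16,
        "n_eval": 12, "block_size": 1,
    },
    "netselect": {
        "min_confidence": 0.0, "degree_cutoff": 2, "node_score_cutoff": 0.2,
        "haircut": True, "top_m": 4, "alpha": 0.05,
    },
    "ddr": {
        "grid": "small", "k_outer": 5, "k_inner": 3,
        "epochs": 200, "batch_size": 128,
    },
    "seed": 0,
    "outdir": "methrisk_out",
}


class ConfigError(ValueError):
    """Aggregated configuration problems."""


def validate_config(source: str | Path | dict | None) -> dict:
    """Merge a YAML/JSON/dict config over the defaults.

    Unknown keys warn; invalid values are aggregated into one ConfigError.
    Returns the normalized config dict.
    """
    if source is None:
        user: dict = {}
    elif isinstance(source, dict):
        user = source
    else:
        user = yaml.safe_load(Path(source).read_text()) or {}
    cfg = copy.deepcopy(DEFAULTS)
    warnings: list[str] = []
    _merge(cfg, user, warnings, path="")
    for w in warnings:
        log.warning(w)

    errors: list[str] = []
    c = cfg["clock"]
    if not c["kernel_sizes"] or any(k < 1 for k in c["kernel_sizes"]):
        errors.append("clock.kernel_sizes must be non-empty positive integers")
    elif max(c["kernel_sizes"]) > c["fc1_width"]:
        errors.append("clock kernel size exceeds fc1_width")
    for key in ("fc1_width", "channels_per_scale", "fc2_width", "epochs", "batch_size"):
        if c[key] < 1:
            errors.append(f"clock.{key} must be positive")
    a = cfg["attribution"]
    for key in ("k", "n_permutations", "n_reference", "n_eval", "block_size"):
        if a[key] < 1:
            errors.append(f"attribution.{key} must be positive")
    ns = cfg["netselect"]
    if not 0.0 <= ns["node_score_cutoff"] <= 1.0:
        errors.append("netselect.node_score_cutoff must be in [0, 1]")
    if cfg["ddr"]["grid"] not in ("small", "full"):
        errors.append("ddr.grid must be 'small' or 'full'")
    if errors:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return cfg


def _merge(base: dict, user: dict, warnings: list[str], path: str) -> None:
    for key, value in user.items():
        here = f"{path}{key}"
        if key not in base:
            warnings.append(f"unknown config key {here!r} ignored")
            continue
        if isinstance(base[key], dict) and isinstance(value, dict):
            _merge(base[key], value, warnings, here + ".")
        else:
            base[key] = value


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_key(section_cfg: dict, input_paths: list[Path], seed: int) -> str:
    # keyed by file basename + content hash, not absolute path, so the key
    # is stable across relocated working directories
    payload = {"config": section_cfg, "seed": seed,
               "inputs": {p.name: _sha256(p) for p in input_paths}}
    return config_hash(payload)


class _Manifest:
    """Stage provenance.  Output paths are stored relative to the output
    directory so the manifest bytes depend only on seed, config and data."""

    def __init__(self, outdir: Path, resume: bool) -> None:
        self.outdir = outdir
        self.path = outdir / "manifest.json"
        self.timings_path = outdir / "timings.json"
        self.previous = (json.loads(self.path.read_text())
                         if resume and self.path.exists() else {"stages": []})
        self.stages: list[dict] = []
        self.timings: dict[str, float] = {}

    def can_skip(self, name: str, key: str) -> bool:
        for st in self.previous.get("stages", []):
            if st["name"] == name and st["key"] == key:
                ok = all((self.outdir / p).exists()
                         and _sha256(self.outdir / p) == h
                         for p, h in st["outputs"].items())
                if ok:
                    self.stages.append(st)
                    return True
        return False

    def record(self, name: str, key: str, outputs: list[Path], elapsed: float) -> None:
        rel = {str(Path(p).resolve().relative_to(self.outdir.resolve())): _sha256(Path(p))
               for p in outputs}
        self.stages.append({"name": name, "key": key, "outputs": rel})
        self.timings[name] = round(elapsed, 3)

    def write(self, seed: int, cfg: dict) -> None:
        # outdir and input locations are excluded: stage keys already pin
        # the input *contents*, and the manifest must not depend on where
        # the run happens to live
        hashable = {k: v for k, v in cfg.items() if k not in ("outdir", "inputs")}
        body = {"seed": seed, "config_hash": config_hash(hashable),
                "stages": self.stages}
        self.path.write_text(json.dumps(body, indent=1, sort_keys=True) + "\n")
        self.timings_path.write_text(json.dumps(self.timings, indent=1,
                                                sort_keys=True) + "\n")


def run_pipeline(config: dict, resume: bool = False) -> dict:
    """Execute the four stages in order; returns a summary dict with the
    manifest path, the marker panel and the metrics report."""
    cfg = validate_config(config)
    seed = int(cfg["seed"])
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: seed=%d outdir=%s config=%s",
             seed, outdir, config_hash(cfg))

    paths = {k: Path(v) for k, v in cfg["inputs"].items() if v}
    missing = [str(p) for p in paths.values() if not p.exists()]
    if missing:
        raise ConfigError(f"missing input file(s): {missing}")
    required = {"beta", "cohort", "annotation", "edges", "gmt"}
    absent = required - set(paths)
    if absent:
        raise ConfigError(f"config lacks input path(s): {sorted(absent)}")

    manifest = _Manifest(outdir, resume)
    summary: dict = {"manifest": manifest.path}

    beta = impute_mean(read_beta_matrix(paths["beta"]))
    cohort = read_cohort(paths["cohort"])

    # --- stage 0: clock ---------------------------------------------------
    clock_dir = outdir / "clock"
    key = _stage_key(cfg["clock"], [paths["beta"], paths["cohort"]], seed + 0)
    outputs = [clock_dir / "clock.json", clock_dir / "clock_params.npy",
               outdir / "predicted_ages.tsv"]
    if not (resume and manifest.can_skip("clock", key)):
        t0 = time.perf_counter()
        ccfg = clock.ClockConfig(n_input_sites=beta.n_cpgs, seed=seed + 0,
                                 kernel_sizes=tuple(cfg["clock"]["kernel_sizes"]),
                                 **{k_: cfg["clock"][k_] for k_ in
                                    ("fc1_width", "channels_per_scale", "fc2_width",
                                     "learning_rate", "epochs", "batch_size",
                                     "loss_name")})
        model = clock.build_clock(ccfg)
        clock.train_clock(model, beta, cohort.ages(beta.sample_ids), ccfg)
        clock.save_clock(model, clock_dir)
        pred = clock.predict_age(model, beta)
        pd.DataFrame({"sample_id": beta.sample_ids,
                      "predicted_age": np.round(pred, 4)}).to_csv(
            outdir / "predicted_ages.tsv", sep="\t", index=False)
        manifest.record("clock", key, outputs, time.perf_counter() - t0)
        log.info("clock trained: final loss %.4f", model.history[-1])
    trained = clock.load_clock(clock_dir)

    # --- stage 1: attribution --------------------------------------------
    acfg = cfg["attribution"]
    shap_path = outdir / "shap.tsv"
    key = _stage_key(acfg, [paths["beta"], paths["annotation"],
                            clock_dir / "clock_params.npy"], seed + 1)
    if not (resume and manifest.can_skip("attribution", key)):
        t0 = time.perf_counter()
        rng = np.random.default_rng(seed + 1)
        n = beta.n_samples
        ref_idx = rng.choice(n, size=min(acfg["n_reference"], n), replace=False)
        rest = np.setdiff1d(np.arange(n), ref_idx)
        eval_idx = rng.choice(rest, size=min(acfg["n_eval"], rest.size),
                              replace=False)
        ids = beta.sample_ids
        result = attribution.attribute_clock(
            trained,
            beta.subset_samples([ids[i] for i in eval_idx]),
            beta.subset_samples([ids[i] for i in ref_idx]),
            n_permutations=acfg["n_permutations"], seed=seed + 1,
            block_size=acfg["block_size"])
        ann = read_annotation(paths["annotation"]).table.set_index("cpg_id")
        rows = pd.DataFrame({"cpg_id": result.cpg_ids,
                             "score": np.round(result.site_score, 8)})
        rows = rows.join(ann[["gene", "chromosome", "position"]], on="cpg_id")
        rows.sort_values(["score", "cpg_id"], ascending=[False, True],
                         inplace=True)
        rows.to_csv(shap_path, sep="\t", index=False)
        manifest.record("attribution", key, [shap_path], time.perf_counter() - t0)
        log.info("attribution done over %d sites", len(result.cpg_ids))

    # --- stage 2: panel selection ----------------------------------------
    ncfg = cfg["netselect"]
    panel_paths = [outdir / "complexes.tsv", outdir / "enrichment.tsv",
                   outdir / "panel.tsv", outdir / "panel_provenance.json"]
    key = _stage_key({**ncfg, "k": acfg["k"]},
                     [shap_path, paths["annotation"], paths["edges"],
                      paths["gmt"]], seed + 2)
    if not (resume and manifest.can_skip("netselect", key)):
        t0 = time.perf_counter()
        shap = pd.read_csv(shap_path, sep="\t", dtype={"cpg_id": str})
        selected = shap.sort_values(["score", "cpg_id"],
                                    ascending=[False, True])["cpg_id"]
        selected = selected.head(acfg["k"]).tolist()
        annotation = read_annotation(paths["annotation"])
        gmap = netselect.map_cpgs_to_genes(selected, annotation)
        network = read_edges(paths["edges"], ncfg["min_confidence"])
        induced = netselect.induce_network(gmap.genes, network,
                                           ncfg["min_confidence"])
        complexes = netselect.mcode_cluster(
            induced, degree_cutoff=ncfg["degree_cutoff"],
            node_score_cutoff=ncfg["node_score_cutoff"],
            haircut=ncfg["haircut"])
        collection = read_gmt(paths["gmt"])
        universe = collection.universe or {
            g for gg in annotation.table["gene"] for g in str(gg).split(";")}
        choice = netselect.choose_key_complex(
            complexes, collection, universe,
            top_m=ncfg["top_m"], alpha=ncfg["alpha"])
        panel = netselect.genes_to_marker_cpgs(choice["chosen"], gmap.table)

        pd.DataFrame([{"rank": i, "score": round(c.score, 6),
                       "density": round(c.density, 6), "size": len(c.genes),
                       "seed_vertex": c.seed_vertex, "genes": ";".join(c.genes)}
                      for i, c in enumerate(complexes)]).to_csv(
            panel_paths[0], sep="\t", index=False)
        ev = choice["candidates"][choice["chosen_rank"]]["enrichment"]
        ev.table.to_csv(panel_paths[1], sep="\t", index=False,
                        float_format="%.6g")
        write_report(panel, panel_paths[2], seed=seed + 2, config=ncfg)
        provenance = {
            "chosen_rank": choice["chosen_rank"],
            "min_adjusted_p": choice["min_adjusted_p"],
            "below_threshold": bool(choice["below_threshold"]),
            "n_selected_sites": len(selected),
            "n_mapped_genes": len(gmap.genes),
            "n_unmapped_sites": len(gmap.unmapped),
            "panel_genes": panel.genes,
            "panel_size": len(panel.cpg_ids),
        }
        panel_paths[3].write_text(json.dumps(provenance, indent=1,
                                             sort_keys=True) + "\n")
        manifest.record("netselect", key,
                        panel_paths + [panel_paths[2].with_suffix(
                            panel_paths[2].suffix + ".meta.json")],
                        time.perf_counter() - t0)
        log.info("panel selected: %d CpGs on %d genes",
                 len(panel.cpg_ids), len(panel.genes))
    panel_df = pd.read_csv(outdir / "panel.tsv", sep="\t", dtype=str)
    summary["panel_cpgs"] = panel_df["cpg_id"].tolist()
    summary["panel_genes"] = sorted(set(panel_df["gene"]))

    # --- stage 3: stage classifier ----------------------------------------
    dcfg = cfg["ddr"]
    metrics_path = outdir / "stage_metrics.tsv"
    key = _stage_key(dcfg, [outdir / "panel.tsv", paths["beta"],
                            paths["cohort"]], seed + 3)
    ddr_outputs = [metrics_path, outdir / "stage_cv_details.json"]
    if not (resume and manifest.can_skip("ddr", key)):
        t0 = time.perf_counter()
        grid = ddr.DdrGrid() if dcfg["grid"] == "full" else ddr.DdrGrid.small()
        fixed = ddr.DdrTrainFixed(epochs=dcfg["epochs"],
                                  batch_size=dcfg["batch_size"], seed=seed + 3)
        plan = ddr.make_cv_plan(cohort, dcfg["k_outer"], dcfg["k_inner"],
                                seed=seed + 3)
        beta_panel = beta.subset_cpgs(summary["panel_cpgs"])
        report, details = ddr.run_cv(beta_panel, cohort, grid, fixed, plan)
        report.table.to_csv(metrics_path, sep="\t", index=False,
                            float_format="%.6f")
        (outdir / "stage_cv_details.json").write_text(
            json.dumps(details, indent=1, sort_keys=True, default=str) + "\n")
        manifest.record("ddr", key, ddr_outputs, time.perf_counter() - t0)
        log.info("stage classifier CV complete")
    summary["metrics"] = MetricsReport(pd.read_csv(metrics_path, sep="\t"))

    manifest.write(seed, cfg)
    summary["stages"] = [s["name"] for s in manifest.stages]
    return summary
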