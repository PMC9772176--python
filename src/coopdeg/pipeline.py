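"""End-to-end orchestration: simulate (or load) → DE → clustering →
concordance → proximity → enrichment → motif → qPCR, with a manifest of
output checksums so a rerun under the same config is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from coopdeg import clusters as _clusters
from coopdeg import concordance as _concord
from coopdeg import de as _de
from coopdeg import enrichment as _enrich
from coopdeg import io as _io
from coopdeg import proximity as _prox
from coopdeg import simulate as _sim

log = logging.getLogger("coopdeg.pipeline")

DEFAULT_THRESHOLDS = {"fc_min": 2.0, "q_max": 0.05, "rpkm_min": 1.0,
                      "dev_fc_min": 2.0}


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict[str, Any], outdir: str | Path) -> dict[str, Any]:
    """Run the full analysis from a config mapping; returns the manifest.

    Config keys: ``simulation`` (SimulationConfig fields; presence switches
    on simulation mode), ``thresholds`` (fc_min, q_max, rpkm_min,
    dev_fc_min), ``proximity`` (n_permutations, statistic), ``enrichment``
    (min_term_size), ``seed``. File-input mode instead takes ``expression``,
    ``design``, ``loci`` ... paths; any enabled stage whose input is missing
    halts with the stage and input named.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    prox_cfg = {"n_permutations": 1000, "statistic": "median_nn_distance",
                **config.get("proximity", {})}
    enr_cfg = {"min_term_size": 3, **config.get("enrichment", {})}
    manifest: dict[str, Any] = {"seed": seed, "thresholds": thresholds,
                                "outputs": {}, "summary": {}}

    def emit(name: str, df: pd.DataFrame, params: dict | None = None,
             index: bool = False) -> None:
        path = outdir / name
        _io.write_table(df, path, params=params, index=index)
        manifest["outputs"][name] = _checksum(path)

    # ---- stage: inputs -------------------------------------------------
    dataset: _sim.SyntheticDataset | None = None
    if "simulation" in config:
        log.info("stage simulate: %s", config["simulation"])
        sim_fields = dict(config["simulation"])
        sim_fields.setdefault("seed", seed)
        if "log2fc_distribution" in sim_fields:
            sim_fields["log2fc_distribution"] = _sim.Log2FCDistribution(
                **sim_fields["log2fc_distribution"])
        sim_cfg = _sim.SimulationConfig(**sim_fields)
        dataset = _sim.simulate_dataset(sim_cfg)
        matrix = dataset.matrix
        loci = dataset.loci
        lengths = pd.Series({g.gene_id: g.length_bp for g in loci})
        emit("truth.tsv", dataset.truth, index=True)
        _io.write_expression(matrix, outdir / "expression.tsv",
                             outdir / "design.tsv")
        manifest["outputs"]["expression.tsv"] = _checksum(outdir / "expression.tsv")
        manifest["outputs"]["design.tsv"] = _checksum(outdir / "design.tsv")
        _io.write_gff3(loci, outdir / "genes.gff3")
        manifest["outputs"]["genes.gff3"] = _checksum(outdir / "genes.gff3")
        cond_a, cond_b = "control", "mutant"
    else:
        for key in ("expression", "design"):
            if key not in config:
                raise ValueError(f"stage de: missing required input {key!r}")
        matrix = _io.read_expression(config["expression"], config["design"],
                                     unit=config.get("unit", "counts"))
        cond_a = config.get("condition_a", "control")
        cond_b = config.get("condition_b", "mutant")
        loci = (_io.read_gene_loci(config["loci"], config.get("loci_format", "gff3"))
                if "loci" in config else None)
        lengths = (pd.Series({g.gene_id: g.length_bp for g in loci})
                   if loci is not None else None)

    # ---- stage: differential expression --------------------------------
    log.info("stage de: %s vs %s, thresholds %s", cond_b, cond_a, thresholds)
    result = _de.call_degs(
        matrix, cond_a, cond_b, fc_min=thresholds["fc_min"],
        q_max=thresholds["q_max"], rpkm_min=thresholds["rpkm_min"],
        gene_lengths=lengths)
    emit("de_results.tsv", result.table, params=thresholds, index=True)
    manifest["summary"]["de_counts"] = result.counts()

    # ---- stage: cluster classification ----------------------------------
    assignments = _clusters.classify_contrast(result)
    emit("clusters.tsv", assignments, index=True)
    counts = _clusters.cluster_counts(assignments)
    emit("cluster_counts.tsv", counts.rename_axis("cluster").reset_index())
    manifest["summary"]["cluster_counts"] = {k: int(v) for k, v in counts.items()}

    # ---- stage: concordance (simulation mode only has a companion) ------
    if dataset is not None:
        comp_result = _de.call_degs(
            dataset.companion_matrix, "control2", "mutant2",
            fc_min=thresholds["fc_min"], q_max=thresholds["q_max"],
            rpkm_min=thresholds["rpkm_min"],
            gene_lengths=pd.Series({g.gene_id: g.length_bp for g in loci}))
        emit("companion_de_results.tsv", comp_result.table, index=True)
        summaries = []
        for selection in ("all", "degs_x", "degs_y", "common_degs"):
            try:
                s = _concord.subset_compare(result, comp_result,
                                            selection=selection)
            except ValueError as err:
                log.warning("concordance %s skipped: %s", selection, err)
                continue
            summaries.append(s.to_series())
        emit("concordance.tsv", pd.DataFrame(summaries))
        manifest["summary"]["concordance"] = {
            s["selection"]: float(s["pearson_r"]) for s in summaries}

        # developmental contrast: FC-only labels + anti-correlation summary
        dev_fc = dataset.truth["dev_signed_fc"]
        dev_labels = _de.call_developmental_degs(dev_fc,
                                                 fc_min=thresholds["dev_fc_min"])
        dev_table = pd.DataFrame({"dev_signed_fc": dev_fc,
                                  "dev_status": dev_labels})
        emit("developmental.tsv", dev_table, index=True)
        deg_idx = result.degs()
        if len(deg_idx) >= 3:
            dev_sum = _concord.quadrant_summary(
                result.table.loc[deg_idx, "log2_fc"].to_numpy(),
                dataset.truth.loc[deg_idx, "dev_log2fc"].to_numpy(),
                selection="degs_vs_development")
            emit("dev_concordance.tsv", pd.DataFrame([dev_sum.to_series()]))
            manifest["summary"]["dev_r"] = dev_sum.pearson_r

    # ---- stage: genomic proximity ---------------------------------------
    if loci is not None:
        members = set(result.degs())
        if len(members) >= 2:
            prox = _prox.permutation_test(
                loci, members, n_permutations=int(prox_cfg["n_permutations"]),
                statistic=prox_cfg["statistic"], seed=seed + 101)
            emit("proximity.tsv", pd.DataFrame([prox.to_series()]))
            emit("proximity_null.tsv",
                 pd.DataFrame({"null_statistic": prox.null_distribution}))
            manifest["summary"]["proximity_p"] = prox.empirical_p
    elif config.get("require_proximity"):
        raise ValueError("stage proximity: missing required input 'loci'")

    # ---- stage: enrichment ----------------------------------------------
    term_map = None
    if dataset is not None:
        term_map = dataset.term_map
    elif "terms" in config:
        term_map = _enrich.read_term_map(config["terms"])
    if term_map:
        background = set(result.table.index[result.table["status"] != "filtered"])
        query = set(result.degs("up")) & background
        if query:
            enr = _enrich.hypergeometric_enrichment(
                query, background, term_map,
                min_term_size=int(enr_cfg["min_term_size"]))
            emit("enrichment.tsv", enr)
            manifest["summary"]["n_enriched_terms"] = int(
                (enr["q_value"] < 0.05).sum()) if len(enr) else 0

    # ---- stage: promoter motif ------------------------------------------
    if dataset is not None:
        up = list(result.degs("up"))
        profiles = [_enrich.count_motif(dataset.promoters[g],
                                        dataset.config.motif) for g in up]
        if profiles:
            dist = _enrich.copy_number_distribution(profiles)
            emit("motif_distribution.tsv",
                 dist.rename_axis("copies").reset_index())
            manifest["summary"]["motif_copy_pct"] = {
                k: float(v) for k, v in dist.items()}

    # ---- stage: qPCR validation -----------------------------------------
    if dataset is not None:
        qpcr_fcs = {
            g: _concord.qpcr_fold_change(dataset.qpcr, g, "mutant", "control")
            for g in dataset.qpcr_panel
        }
        r, p = _concord.validate_qpcr(qpcr_fcs, result.table["log2_fc"])
        qpcr_table = pd.DataFrame(
            [{"target_gene": g, "delta_delta_ct": fc.delta_delta_ct,
              "qpcr_fold_change": fc.fold_change,
              "qpcr_log2_fc": fc.log2_fc,
              "rnaseq_log2_fc": float(result.table.loc[g, "log2_fc"])}
             for g, fc in qpcr_fcs.items()])
        emit("qpcr_validation.tsv", qpcr_table,
             params={"pearson_r": r, "p_value": p})
        manifest["summary"]["qpcr_r"] = r

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %d outputs", len(manifest["outputs"]))
    return manifest
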