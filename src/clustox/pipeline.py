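"""End-to-end orchestration: simulate -> filter -> SOM -> merge -> map ->
enrich -> pathways -> validate, with one global seed and a JSON run report.

The run report collects counts at every attrition step, cluster counts
before/after merging, the BUM fit and its FDR cutoff, per-cluster
enriched-gene counts, the pathway-null contrast, and the Tanimoto
summary.  When ground truth is available (simulated runs) it also scores
recovery: adjusted Rand index of clusters vs planted groups and the
fraction of planted (cluster, gene) pairs flagged enriched.

Configs are flat YAML with per-stage sections; every stage writes its
tabular outputs as TSV into the run directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chem, merging, pathways as pw, synthetic, validation
from .enrichment import enrich_clusters
from .som import (ActivityMatrix, ClusterAssignment, SomConfig, assign_bmu,
                  filter_complete, quantization_error, train_som)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},            # SimulationConfig overrides; omit -> use "inputs"
    "som": {"grid_rows": 4, "grid_cols": 3, "n_epochs": 15},
    "merge": {"min_size": 15},
    "enrich": {"fdr": 0.01},
    "pathways": {"alpha": 0.05, "n_null_reps": 0, "gene_source": "enriched"},
    "validate": {"max_pairs": 2_000_000},
}


def _stage_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage seed derived from the single global seed."""
    return (seed * 1_000_003 + 7919 * stage + 1) % (2 ** 31)


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    config = {k: (dict(v) if isinstance(v, dict) else v)
              for k, v in DEFAULT_CONFIG.items()}
    for key, value in (user or {}).items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


def _simulate_stage(config: dict, seed: int, outdir: Path):
    sim_kwargs = dict(config.get("simulate") or {})
    sim_kwargs["seed"] = seed
    sim_config = synthetic.SimulationConfig(**sim_kwargs)
    matrix, truth = synthetic.simulate_activity_matrix(sim_config)
    annotations = synthetic.simulate_annotations(truth, sim_config)
    collection = synthetic.simulate_pathways(truth, sim_config)
    fingerprints = synthetic.simulate_fingerprints(truth, sim_config)

    matrix.write_tsv(outdir / "activity.tsv")
    synthetic.write_annotations_tsv(annotations, outdir / "annotations.tsv")
    collection.write_gmt(outdir / "pathways.gmt")
    fingerprints.write_tsv(outdir / "fingerprints.tsv")
    synthetic.write_ground_truth_json(truth, outdir / "ground_truth.json")
    return sim_config, matrix, truth, annotations, collection, fingerprints


def _load_inputs(config: dict):
    inputs = config.get("inputs") or {}
    required = ("activity", "annotations", "pathways", "fingerprints")
    missing = [k for k in required if k not in inputs]
    if missing:
        raise ValueError(f"config lacks a 'simulate' block and inputs for {missing}")
    matrix = ActivityMatrix.read_tsv(inputs["activity"])
    paths = inputs["annotations"]
    frames = [pd.read_csv(p, sep="\t", dtype=str) for p in
              (paths if isinstance(paths, list) else [paths])]
    annotations = pd.concat(frames, ignore_index=True)
    collection = pw.PathwayCollection.read_gmt(inputs["pathways"])
    fingerprints = validation.FingerprintSet.read_tsv(inputs["fingerprints"])
    return matrix, annotations, collection, fingerprints


def _map_stage(compound_ids: list[str], annotations: pd.DataFrame, outdir: Path):
    """Join source annotation tables to the library via connectivity keys.

    Simulated annotation tables carry compound IDs; both sides are keyed
    with the deterministic pseudo connectivity key so the join mirrors
    the real InChIKey-block workflow.
    """
    records = [chem.CompoundRecord(cid, connectivity_key=synthetic.synthetic_key(cid))
               for cid in compound_ids]
    keyed = annotations.assign(
        connectivity_key=annotations["compound_id"].map(synthetic.synthetic_key))
    sources = {name: sub[["source", "connectivity_key", "gene"]]
               for name, sub in keyed.groupby("source")}
    result = chem.map_compounds(records, sources)
    result.write_tsv(outdir / "annotations_mapped.tsv")
    with open(outdir / "mapping_stats.json", "w") as fh:
        json.dump(result.stats, fh, indent=1, sort_keys=True)
    return result


def _majority_cluster_of_groups(truth_labels: np.ndarray,
                                cluster_labels: np.ndarray) -> dict[int, int]:
    mapping: dict[int, int] = {}
    for group in np.unique(truth_labels):
        if group == synthetic.INACTIVE:
            continue
        members = cluster_labels[truth_labels == group]
        values, counts = np.unique(members, return_counts=True)
        mapping[int(group)] = int(values[np.argmax(counts)])
    return mapping


def planted_recovery(truth: synthetic.GroundTruth, assignment: ClusterAssignment,
                     results: pd.DataFrame) -> float:
    """Fraction of planted (group-cluster, group-gene) pairs flagged enriched.

    Each planted group is matched to the cluster holding the majority of
    its members; recovery asks whether that cluster's planted genes are
    flagged in the enrichment results.
    """
    truth_labels = truth.group_labels(assignment.compound_ids)
    mapping = _majority_cluster_of_groups(truth_labels, assignment.labels)
    flagged = {(int(r.cluster), r.gene) for r in
               results[results["enriched"]].itertuples(index=False)}
    total = hits = 0
    for group, cluster in mapping.items():
        for gene in truth.planted_gene_sets[group]:
            total += 1
            hits += (cluster, gene) in flagged
    return hits / total if total else float("nan")


def run_pipeline(config: dict | str | Path, outdir, seed: int | None = None) -> dict:
    """Execute every stage and return (and write) the JSON run report."""
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = merge_config(config)
    if seed is not None:
        config["seed"] = int(seed)
    base_seed = int(config["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {"seed": base_seed, "stages": {}}

    simulated = "simulate" in config and config["simulate"] is not None \
        and "inputs" not in config
    truth = None
    if simulated:
        sim_config, raw_matrix, truth, annotations, collection, fingerprints = \
            _simulate_stage(config, _stage_seed(base_seed, 0), outdir)
        report["stages"]["simulate"] = {
            "config": dataclasses.asdict(sim_config),
            "n_compounds": raw_matrix.n_compounds,
            "n_assays": raw_matrix.n_assays,
            "n_inactive": int(sum(1 for g in truth.group_of_compound.values()
                                  if g == synthetic.INACTIVE)),
        }
    else:
        raw_matrix, annotations, collection, fingerprints = _load_inputs(config)

    matrix, n_removed = filter_complete(raw_matrix)
    report["stages"]["filter"] = {"n_compounds": matrix.n_compounds,
                                  "n_removed": n_removed}

    som_kwargs = dict(config.get("som") or {})
    som_kwargs["seed"] = _stage_seed(base_seed, 1)
    som_config = SomConfig(**som_kwargs)
    codebook = train_som(matrix, som_config)
    codebook.write_tsv(outdir / "codebook.tsv")
    assignment = assign_bmu(codebook, matrix)
    assignment.write_tsv(outdir / "assignment_pre_merge.tsv")
    qe = quantization_error(codebook, matrix, assignment)
    report["stages"]["som"] = {
        "grid": [som_config.grid_rows, som_config.grid_cols],
        "n_epochs": som_config.n_epochs,
        "n_occupied_units": len(assignment.sizes()),
        "quantization_error": qe,
    }

    merge_kwargs = dict(config.get("merge") or {})
    merge_result = merging.merge_small_clusters(assignment, codebook, **merge_kwargs)
    merged = merge_result.assignment
    merged.write_tsv(outdir / "assignment.tsv")
    merge_result.log.to_csv(outdir / "merge_log.tsv", sep="\t", index=False)
    report["stages"]["merge"] = {
        "min_size": merge_kwargs.get("min_size", 15),
        "n_clusters_before": len(assignment.sizes()),
        "n_clusters_after": len(merged.sizes()),
        "n_merges": merge_result.n_merges,
    }

    mapping = _map_stage(matrix.compound_ids, annotations, outdir)
    report["stages"]["map"] = mapping.stats
    compound_annotations = mapping.compound_annotations

    enrich_kwargs = dict(config.get("enrich") or {})
    outcome = enrich_clusters(merged, compound_annotations, **enrich_kwargs)
    outcome.write_tsv(outdir / "enrichment.tsv")
    counts = outcome.enriched_counts()
    report["stages"]["enrich"] = {
        "fdr": outcome.fdr,
        "bum": {"lambda": outcome.bum.lambda_, "a_shape": outcome.bum.a_shape,
                "pi_ub": outcome.bum.pi_ub, "n_pvalues": outcome.bum.n_pvalues},
        "tau": outcome.tau,
        "n_tested_pairs": len(outcome.results),
        "n_enriched_pairs": int(outcome.results["enriched"].sum()),
        "n_clusters_with_enriched_genes": len(counts),
        "enriched_genes_per_cluster": {str(k): v for k, v in sorted(counts.items())},
    }
    with open(outdir / "bum_fit.json", "w") as fh:
        json.dump(report["stages"]["enrich"] | {"stage": "enrich"}, fh,
                  indent=1, sort_keys=True)

    pw_kwargs = dict(config.get("pathways") or {})
    n_null_reps = int(pw_kwargs.pop("n_null_reps", 0))
    alpha = float(pw_kwargs.pop("alpha", 0.05))
    gene_source = pw_kwargs.pop("gene_source", "enriched")
    fdr = enrich_kwargs.get("fdr", 0.01)
    actual = pw.count_significant_pathways(merged, compound_annotations, collection,
                                           alpha, gene_source, fdr)
    pw_report = {"alpha": alpha, "n_pathways": len(collection),
                 "actual_significant_pathways": actual}
    if n_null_reps > 0:
        null = pw.randomized_pathway_null(merged, compound_annotations, collection,
                                          n_reps=n_null_reps, alpha=alpha,
                                          seed=_stage_seed(base_seed, 2),
                                          gene_source=gene_source, fdr=fdr)
        pd.DataFrame({"replicate": np.arange(n_null_reps),
                      "n_significant": null.null_counts}).to_csv(
            outdir / "pathway_null.tsv", sep="\t", index=False)
        pw_report["null"] = null.summary()
    report["stages"]["pathways"] = pw_report

    val_kwargs = dict(config.get("validate") or {})
    summary = validation.intra_inter_summary(fingerprints, merged,
                                             seed=_stage_seed(base_seed, 3),
                                             **val_kwargs)
    report["stages"]["validate"] = summary.to_dict()
    with open(outdir / "tanimoto_summary.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=1, sort_keys=True)

    if truth is not None:
        truth_labels = truth.group_labels(merged.compound_ids)
        report["recovery"] = {
            "adjusted_rand_index": validation.adjusted_rand_index(
                truth_labels, merged.labels),
            "planted_gene_recovery": planted_recovery(truth, merged, outcome.results),
        }

    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    logger.info("pipeline finished; report at %s", report_path)
    return report
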