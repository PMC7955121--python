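"""End-to-end orchestration of the synthetic walkthrough.

Stages (any of which can be fed from files instead of the simulators):

1. simulate single-cell counts with planted drug-tolerant markers;
2. filter cells on detected genes and log-normalize;
3. detect per-cluster markers and write them as a GMT collection;
4. simulate the perturbation database and build one PRL per drug;
5. rank drugs by NES of the query cluster's up-markers in each PRL;
6. simulate the patient cohort, compute SLEA z-scores, build survival
   groups, and run log-rank / Cox / Kaplan–Meier;
7. overlap enrichment of the marker modules against an annotation
   collection.

Every artifact is a plain TSV/RNK/GMT/JSON file, every stage derives its
seed from the single run seed, and a manifest captures inputs, parameters,
seeds, outputs and row counts. Re-running the same configuration reproduces
byte-identical result tables.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import gsea, markers, overlap, signatures, simulate, slea_survival
from .io import (
    ConfigError,
    ExpressionMatrix,
    GeneSetCollection,
    load_config,
    log_stage,
    read_mtx_triplet,
    read_table,
    write_gmt,
    write_mtx_triplet,
    write_rnk,
    write_table,
)

__all__ = ["run_pipeline", "default_demo_config"]


def default_demo_config(seed: int = 7) -> dict:
    """The all-simulated demo: study-scale inputs, moderate permutation depth."""
    return {
        "seed": seed,
        "filter": {"min_genes": 1, "max_genes": 10**9},
        "markers": {"min_pct": 0.01, "min_log2fc": 0.1, "alpha": 0.05},
        "query": {"cluster": "2", "n_perm": 500},
        "slea": {"n_rand": 2000},
        "enrich": {"n_random_sets": 20, "set_size": 50},
    }


def _subseed(base: int, offset: int) -> int:
    return int(np.random.SeedSequence([base, offset]).generate_state(1)[0] % 2**31)


class _Manifest:
    def __init__(self):
        self.stages = []

    def add(self, name, params, seed, outputs, row_counts, t0):
        self.stages.append(
            {
                "name": name,
                "parameters": params,
                "seed": seed,
                "outputs": [str(p) for p in outputs],
                "row_counts": row_counts,
                "wall_time_s": round(time.perf_counter() - t0, 3),
            }
        )


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run the full analysis; returns the manifest (also written to disk)."""
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest = _Manifest()

    inputs = cfg.get("inputs", {}) or {}

    # -- stage 1: single-cell counts ---------------------------------------
    t0 = time.perf_counter()
    sc_seed = _subseed(seed, 1)
    sc_cfg = simulate.default_scrna_config(seed=sc_seed)
    if "mtx_dir" in inputs:
        mtx_dir = Path(inputs["mtx_dir"])
        counts = read_mtx_triplet(
            mtx_dir / "matrix.mtx", mtx_dir / "features.tsv", mtx_dir / "barcodes.tsv"
        )
        ann = read_table(inputs["annotation"], required=["obs_id", "cluster"])
        sc_truth = pd.DataFrame(columns=["cluster", "gene", "effect"])
        paths = []
    else:
        counts, ann, sc_truth = simulate.simulate_scrna(sc_cfg)
        paths = list(write_mtx_triplet(counts, outdir / "scrna"))
        paths.append(write_table(ann, outdir / "annotation.tsv"))
        paths.append(write_table(sc_truth, outdir / "scrna_truth.tsv"))
    log_stage("simulate_scrna", genes=counts.n_genes, cells=counts.n_obs, seed=sc_seed)
    manifest.add(
        "simulate_scrna", {"n_genes": counts.n_genes, "cells": counts.n_obs},
        sc_seed, paths, {"cells": counts.n_obs}, t0,
    )

    # -- stage 2: QC + normalization ---------------------------------------
    t0 = time.perf_counter()
    fcfg = cfg.get("filter", {})
    filtered = markers.filter_cells(
        counts, int(fcfg.get("min_genes", 1)), int(fcfg.get("max_genes", 10**9))
    )
    lognorm = markers.lognormalize(filtered)
    log_stage("preprocess", kept=filtered.n_obs, of=counts.n_obs)
    manifest.add("preprocess", dict(fcfg), None, [], {"cells_kept": filtered.n_obs}, t0)

    # -- stage 3: marker detection -----------------------------------------
    t0 = time.perf_counter()
    mcfg = cfg.get("markers", {})
    marker_df = markers.find_markers(
        lognorm,
        ann,
        min_pct=float(mcfg.get("min_pct", 0.01)),
        min_log2fc=float(mcfg.get("min_log2fc", 0.1)),
        alpha=float(mcfg.get("alpha", 0.05)),
    )
    marker_path = write_table(marker_df, outdir / "markers.tsv")
    up = marker_df[marker_df["direction"] == "up"]
    sets = {
        f"cluster_{c}_up": ("up-markers", sub["gene"].tolist())
        for c, sub in up.groupby("cluster")
        if len(sub)
    }
    if not sets:
        raise ConfigError("no up-markers detected; cannot build marker gene sets")
    gmt_path = write_gmt(GeneSetCollection(sets=sets), outdir / "markers.gmt")
    log_stage("find_markers", records=len(marker_df), sets=len(sets))
    manifest.add(
        "find_markers", dict(mcfg), None, [marker_path, gmt_path],
        {"marker_records": len(marker_df)}, t0,
    )

    # -- stage 4: perturbation DB + PRLs -----------------------------------
    t0 = time.perf_counter()
    db_seed = _subseed(seed, 2)
    if "perturb_db" in inputs:
        db = signatures.PerturbationDB.from_long(read_table(inputs["perturb_db"]))
        db_truth = pd.DataFrame(columns=["drug", "gene", "shift"])
    else:
        db_cfg = simulate.default_perturb_config(seed=db_seed)
        db, db_truth = simulate.simulate_perturbation_db(db_cfg)
    prls = signatures.build_prls(db)
    prl_dir = outdir / "prls"
    prl_dir.mkdir(exist_ok=True)
    prl_paths = [write_rnk(rl, prl_dir / f"{drug}.rnk") for drug, rl in sorted(prls.items())]
    index_path = write_table(
        pd.DataFrame({"drug": sorted(prls), "rnk": [p.name for p in prl_paths]}),
        outdir / "prl_index.tsv",
    )
    truth_path = write_table(db_truth, outdir / "db_truth.tsv")
    log_stage("build_prls", drugs=len(prls), seed=db_seed)
    manifest.add(
        "build_prls", {"n_drugs": len(prls)}, db_seed,
        [index_path, truth_path, *prl_paths], {"drugs": len(prls)}, t0,
    )

    # -- stage 5: drug ranking ---------------------------------------------
    t0 = time.perf_counter()
    qcfg = cfg.get("query", {})
    query_cluster = str(qcfg.get("cluster", "2"))
    set_name = f"cluster_{query_cluster}_up"
    if set_name not in sets:
        raise ConfigError(f"no up-marker set for query cluster {query_cluster!r}")
    marker_set = sets[set_name][1]
    q_seed = _subseed(seed, 3)
    ranking = gsea.rank_drugs(
        prls, marker_set, n_perm=int(qcfg.get("n_perm", 500)), seed=q_seed
    )
    ranking_path = write_table(ranking, outdir / "ranking.tsv")
    log_stage("rank_drugs", drugs=len(ranking), top=ranking["drug"].iloc[0], seed=q_seed)
    manifest.add(
        "rank_drugs", {"cluster": query_cluster, "n_perm": int(qcfg.get("n_perm", 500))},
        q_seed, [ranking_path], {"drugs": len(ranking)}, t0,
    )

    # -- stage 5b: per-cell responsiveness score to the top drug -----------
    t0 = time.perf_counter()
    top_drug = ranking["drug"].iloc[0]
    responsive = sorted(set(ranking["leading_edge"].iloc[0].split(",")) & set(marker_set))
    score_seed = _subseed(seed, 4)
    score = markers.module_score(lognorm, responsive or marker_set, seed=score_seed)
    score_path = write_table(
        pd.DataFrame({"obs_id": score.index, "score": score.to_numpy()}),
        outdir / "module_scores.tsv",
    )
    manifest.add(
        "module_score", {"drug": top_drug, "n_set": len(responsive or marker_set)},
        score_seed, [score_path], {"cells": len(score)}, t0,
    )

    # -- stage 6: cohort SLEA + survival -----------------------------------
    t0 = time.perf_counter()
    cohort_seed = _subseed(seed, 5)
    co_cfg = simulate.default_cohort_config(seed=cohort_seed)
    surv = None
    if "cohort_expr" in inputs:
        frame = read_table(inputs["cohort_expr"]).set_index("gene")
        expr = ExpressionMatrix(
            list(frame.index), list(frame.columns), frame.to_numpy(float), layer="signature"
        )
        co_truth = pd.DataFrame(columns=["sample", "enriched"])
        if "survival" in inputs:
            surv = read_table(inputs["survival"], required=["sample", "time", "event"])
        cohort_marker_set = cfg.get("slea", {}).get("marker_set", co_cfg.marker_set)
    else:
        expr, surv, co_truth = simulate.simulate_cohort(co_cfg)
        cohort_marker_set = co_cfg.marker_set
    slea_seed = _subseed(seed, 6)
    slea_df = slea_survival.slea(
        expr, cohort_marker_set, n_rand=int(cfg.get("slea", {}).get("n_rand", 2000)),
        seed=slea_seed,
    )
    slea_path = write_table(slea_df, outdir / "slea.tsv")
    stage_paths = [slea_path]
    if surv is None:
        log_stage("survival", skipped="no survival table supplied")
    else:
        groups = slea_survival.make_groups(slea_df)
        st = surv.merge(groups, on="sample")
        stage_paths.append(write_table(st, outdir / "groups.tsv"))
        chi2_stat, lr_p = slea_survival.logrank(st)
        hr, ci, cox_p = slea_survival.cox_hr(st)
        km = slea_survival.km_curve(st)
        stage_paths.append(write_table(km, outdir / "km.tsv"))
        stats = {
            "logrank_chi2": chi2_stat,
            "logrank_p": lr_p,
            "cox_hr": hr,
            "cox_ci95": list(ci),
            "cox_p": cox_p,
            "n_high": int((st["group"] == "high").sum()),
            "n_rest": int((st["group"] == "rest").sum()),
        }
        stats_path = outdir / "stats.json"
        stats_path.write_text(json.dumps(stats, indent=2, sort_keys=True) + "\n")
        stage_paths.append(stats_path)
        log_stage("slea_survival", hr=round(hr, 3), logrank_p=lr_p, seed=slea_seed)
    stage_paths.append(write_table(co_truth, outdir / "cohort_truth.tsv"))
    manifest.add(
        "slea_survival", {"n_rand": int(cfg.get("slea", {}).get("n_rand", 2000))},
        slea_seed, stage_paths, {"samples": len(slea_df)}, t0,
    )

    # -- stage 7: overlap enrichment of marker modules ---------------------
    t0 = time.perf_counter()
    ecfg = cfg.get("enrich", {})
    e_seed = _subseed(seed, 7)
    rng = np.random.default_rng(e_seed)
    background = list(lognorm.gene_ids)
    coll_sets = {}
    planted = [g for g, _ in sc_cfg.marker_plan.get(query_cluster, [])]
    if planted:
        coll_sets["PLANTED_MARKERS"] = ("planted drug-tolerant markers", planted)
    n_random = int(ecfg.get("n_random_sets", 20))
    set_size = int(ecfg.get("set_size", 50))
    for i in range(n_random):
        members = sorted(rng.choice(background, size=set_size, replace=False))
        coll_sets[f"RANDOM_{i:02d}"] = ("random annotation set", members)
    coll = GeneSetCollection(sets=coll_sets)
    modules = {name: members for name, (_, members) in sets.items()}
    enr = overlap.enrich_collection(modules, coll, background)
    enr_path = write_table(enr, outdir / "enrich.tsv")
    log_stage("overlap_enrichment", pairs=len(enr), seed=e_seed)
    manifest.add(
        "overlap_enrichment", {"n_random_sets": n_random, "set_size": set_size},
        e_seed, [enr_path], {"pairs": len(enr)}, t0,
    )

    out = {"seed": seed, "stages": manifest.stages}
    (outdir / "manifest.json").write_text(json.dumps(out, indent=2) + "\n")
    return out
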