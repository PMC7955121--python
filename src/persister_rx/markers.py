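"""Cell QC, normalization, cluster-marker detection and per-cell set scores.

The marker detector follows the standard single-cell recipe: cells are
filtered on the number of detected genes (nFeature), counts are
log-normalized to transcripts-per-``scale_factor``
(``ln(1 + count / cell_total * scale_factor)``), and each cluster is tested
one-vs-rest per gene with a Wilcoxon rank-sum test. A gene is reported as a
marker of a cluster when

* Bonferroni-adjusted p < ``alpha`` (family = genes × clusters tested),
* |log2 fold change| ≥ ``min_log2fc``, where the fold change compares
  de-logged cluster means with a +1 pseudocount, and
* the gene is detected in at least ``min_pct`` of cells on the higher of
  the two sides (so down-markers remain detectable).

Also here: Seurat-style per-cell module scores (set mean minus
expression-bin-matched control genes), dot-plot summary statistics
(avg.exp / pct.exp / avg.exp.scaled) and silhouette-width cluster QC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import squareform, pdist
from scipy.stats import mannwhitneyu

from .io import ConfigError, ExpressionMatrix, log

__all__ = [
    "filter_cells",
    "lognormalize",
    "find_markers",
    "module_score",
    "dotplot_stats",
    "silhouette",
]


def filter_cells(m: ExpressionMatrix, min_genes: int, max_genes: int) -> ExpressionMatrix:
    """Keep cells whose detected-gene count lies in [min_genes, max_genes]."""
    if m.layer != "counts":
        raise ConfigError("filter_cells expects a counts layer")
    if min_genes > max_genes:
        raise ConfigError(f"min_genes ({min_genes}) > max_genes ({max_genes})")
    nfeat = m.genes_per_obs()
    keep = (nfeat >= min_genes) & (nfeat <= max_genes)
    if not keep.any():
        raise ConfigError(
            f"no cells with detected-gene count in [{min_genes}, {max_genes}]"
        )
    return m.subset_obs(keep)


def lognormalize(m: ExpressionMatrix, scale_factor: float = 1e4) -> ExpressionMatrix:
    """LogNormalize: value = ln(1 + count / cell_total * scale_factor)."""
    if m.layer != "counts":
        raise ConfigError("lognormalize expects a counts layer")
    if sp.issparse(m.values):
        totals = np.asarray(m.values.sum(axis=0)).ravel().astype(float)
    else:
        totals = m.values.sum(axis=0).astype(float)
    if (totals == 0).any():
        raise ConfigError(
            "cells with zero total counts present; run filter_cells first"
        )
    if sp.issparse(m.values):
        vals = m.values.tocsc().astype(float)
        # scale each column in place on the sparse data vector
        for j in range(vals.shape[1]):
            sl = slice(vals.indptr[j], vals.indptr[j + 1])
            vals.data[sl] = np.log1p(vals.data[sl] / totals[j] * scale_factor)
    else:
        vals = np.log1p(m.values / totals[None, :] * scale_factor)
    return ExpressionMatrix(list(m.gene_ids), list(m.obs_ids), vals, layer="lognorm")


def _align_annotation(m: ExpressionMatrix, ann: pd.DataFrame) -> pd.DataFrame:
    ann = ann.set_index("obs_id") if "obs_id" in ann.columns else ann
    missing = [o for o in m.obs_ids if o not in ann.index]
    if missing:
        raise ConfigError(f"annotation missing observations {missing[:5]}")
    return ann.loc[m.obs_ids]


def find_markers(
    m: ExpressionMatrix,
    ann: pd.DataFrame,
    min_pct: float = 0.01,
    min_log2fc: float = 0.1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker detection per cluster.

    Returns a DataFrame with columns gene, cluster, log2fc, pct_in, pct_out,
    p, p_adj, direction, sorted by p_adj then |log2fc| descending. p_adj is
    Bonferroni over genes × clusters tested. Clusters with fewer than 3
    cells are skipped with a warning.
    """
    if m.layer != "lognorm":
        raise ConfigError("find_markers expects a lognorm layer")
    ann = _align_annotation(m, ann)
    labels = ann["cluster"].astype(str).to_numpy()
    clusters = sorted(set(labels))
    if len(clusters) < 2:
        raise ConfigError("need at least 2 clusters")

    x = m.dense()
    expm1 = np.expm1(x)
    detected = x > 0
    tested = [c for c in clusters if (labels == c).sum() >= 3]
    for c in clusters:
        if c not in tested:
            log.warning("cluster %s has <3 cells; skipped", c)
    n_tests = m.n_genes * len(tested)

    records = []
    for c in tested:
        inm = labels == c
        n_in, n_out = int(inm.sum()), int((~inm).sum())
        if n_out < 3:
            log.warning("rest group for cluster %s has <3 cells; skipped", c)
            continue
        xi, xo = x[:, inm], x[:, ~inm]
        pct_in = detected[:, inm].mean(axis=1)
        pct_out = detected[:, ~inm].mean(axis=1)
        log2fc = np.log2(
            (expm1[:, inm].mean(axis=1) + 1) / (expm1[:, ~inm].mean(axis=1) + 1)
        )
        if min(n_in, n_out) <= 8:
            # exact null distribution is feasible and tie-free data match
            # full enumeration; fall back per gene
            p = np.array(
                [
                    mannwhitneyu(xi[g], xo[g], alternative="two-sided", method="auto").pvalue
                    for g in range(m.n_genes)
                ]
            )
        else:
            res = mannwhitneyu(xi, xo, alternative="two-sided", method="asymptotic", axis=1)
            p = np.asarray(res.pvalue)
        p = np.nan_to_num(p, nan=1.0)  # zero-variance genes carry no evidence
        p_adj = np.minimum(p * n_tests, 1.0)
        keep = (
            (np.abs(log2fc) >= min_log2fc)
            & (np.maximum(pct_in, pct_out) >= min_pct)
            & (p_adj < alpha)
        )
        for g in np.flatnonzero(keep):
            records.append(
                {
                    "gene": m.gene_ids[g],
                    "cluster": c,
                    "log2fc": log2fc[g],
                    "pct_in": pct_in[g],
                    "pct_out": pct_out[g],
                    "p": p[g],
                    "p_adj": p_adj[g],
                    "direction": "up" if log2fc[g] > 0 else "down",
                }
            )
    out = pd.DataFrame(
        records,
        columns=["gene", "cluster", "log2fc", "pct_in", "pct_out", "p", "p_adj", "direction"],
    )
    if len(out):
        out = out.sort_values(
            ["p_adj", "log2fc"],
            key=lambda s: s.abs() if s.name == "log2fc" else s,
            ascending=[True, False],
        ).reset_index(drop=True)
    return out


def module_score(
    m: ExpressionMatrix,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell gene-set score: set mean minus bin-matched control mean.

    Genes are binned into ``n_bins`` by average expression across cells; for
    every set gene, ``n_ctrl`` control genes are sampled (without
    replacement, capped at the bin size) from its bin. The score of a cell
    is the mean of the set genes minus the mean of the pooled control draw.
    Deterministic given the seed.
    """
    if m.n_genes < n_bins:
        raise ConfigError(f"need at least n_bins={n_bins} genes in the universe")
    gene_pos = {g: i for i, g in enumerate(m.gene_ids)}
    eff = [g for g in gene_set if g in gene_pos]
    dropped = len(gene_set) - len(eff)
    if dropped:
        log.warning("module_score: %d set genes outside universe dropped", dropped)
    if not eff:
        raise ConfigError("gene set has no genes in the matrix universe")

    x = m.dense()
    avg = x.mean(axis=1)
    # equal-occupancy bins on the average-expression ranking
    order_rank = pd.Series(avg, index=m.gene_ids).rank(method="first")
    bins = pd.qcut(order_rank, n_bins, labels=False)

    rng = np.random.default_rng(seed)
    ctrl_idx: list[int] = []
    for g in eff:
        pool = np.flatnonzero(bins.to_numpy() == bins[g])
        take = min(n_ctrl, pool.size)
        ctrl_idx.extend(rng.choice(pool, size=take, replace=False))
    set_idx = [gene_pos[g] for g in eff]
    score = x[set_idx].mean(axis=0) - x[ctrl_idx].mean(axis=0)
    return pd.Series(score, index=m.obs_ids, name="module_score")


def dotplot_stats(
    m: ExpressionMatrix,
    ann: pd.DataFrame,
    genes: list[str],
    groups: list[str],
    group_by: str = "cluster",
) -> pd.DataFrame:
    """Dot-plot statistics per (gene, group).

    avg_exp = sum of expression / number of cells; pct_exp = fraction of
    cells with expression > 0; avg_exp_scaled = avg_exp divided by the sum
    of avg_exp over the compared groups (0 when all compared groups are 0).
    """
    ann = _align_annotation(m, ann)
    labels = ann[group_by].astype(str).to_numpy()
    known = set(labels)
    unknown = [g for g in groups if g not in known]
    if unknown:
        raise ConfigError(f"unknown group label(s) {unknown}")
    gene_pos = {g: i for i, g in enumerate(m.gene_ids)}
    missing = [g for g in genes if g not in gene_pos]
    if missing:
        raise ConfigError(f"genes not in matrix: {missing[:5]}")
    x = m.dense()

    rows = []
    for gene in genes:
        gi = gene_pos[gene]
        avgs = {}
        for grp in groups:
            cols = labels == grp
            v = x[gi, cols]
            avgs[grp] = (float(v.mean()), float((v > 0).mean()))
        total = sum(a for a, _ in avgs.values())
        for grp in groups:
            a, pct = avgs[grp]
            rows.append(
                {
                    "gene": gene,
                    "group": grp,
                    "avg_exp": a,
                    "pct_exp": pct,
                    "avg_exp_scaled": a / total if total > 0 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def silhouette(embedding: np.ndarray, ann: pd.DataFrame) -> dict:
    """Silhouette widths s(i) = (b - a)/max(a, b) on Euclidean distances.

    ``embedding`` is observations × dimensions, rows aligned with the
    annotation order. Returns {"per_cell_width", "mean_width",
    "by_cluster_mean"}. Cells in singleton clusters get width 0.
    """
    labels = ann["cluster"].astype(str).to_numpy()
    emb = np.asarray(embedding, dtype=float)
    if emb.shape[0] != len(labels):
        raise ConfigError("embedding rows must match annotation rows")
    clusters = sorted(set(labels))
    if len(clusters) < 2:
        raise ConfigError("need at least 2 clusters")

    d = squareform(pdist(emb))
    n = len(labels)
    widths = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            log.warning("singleton cluster %s: silhouette width set to 0", labels[i])
            continue
        a = d[i, own].sum() / (own.sum() - 1)  # exclude self
        b = min(d[i, labels == c].mean() for c in clusters if c != labels[i])
        widths[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)

    per_cluster = {
        c: float(widths[labels == c].mean()) for c in clusters
    }
    return {
        "per_cell_width": widths,
        "mean_width": float(widths.mean()),
        "by_cluster_mean": per_cluster,
    }
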