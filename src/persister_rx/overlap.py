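"""Overlap enrichment of marker lists against annotation collections.

For a marker list (module) of n background genes and an annotation set
covering a fraction p0 = K/|background| of the background, the overlap k is
scored with the right tail of a Binomial(n, p0): P(X >= k). P-values are
Benjamini–Hochberg corrected across the full module × set family of one
invocation. A hypergeometric (sampling-without-replacement) alternative is
available behind a flag for comparison.

``filter_heatmap`` reproduces the heatmap filtering used for reporting:
keep annotation sets above a minimum size that reach a minimum overlap and
significance in at least one module of interest, and that stay
non-significant in every designated contrast module (e.g. the untreated
condition).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import binom, hypergeom
from statsmodels.stats.multitest import multipletests

from .io import ConfigError, GeneSetCollection, log

__all__ = ["binom_right_tail", "enrich_collection", "filter_heatmap"]


def binom_right_tail(k: int, n: int, p0: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p0), via the survival function."""
    if not 0 <= k <= n:
        raise ConfigError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p0 <= 1.0:
        raise ConfigError(f"need 0 <= p0 <= 1, got {p0}")
    if k == 0:
        return 1.0
    return float(binom.sf(k - 1, n, p0))


def enrich_collection(
    markers: dict[str, list[str]],
    coll: GeneSetCollection,
    background: list[str],
    model: str = "binomial",
) -> pd.DataFrame:
    """Overlap enrichment of each marker module against each annotation set.

    Returns one row per (module, set): n_markers, overlap_k, bg_set_size,
    bg_size, p_right, q. Marker genes outside the background are dropped
    with a warning; q is BH over all module × set pairs.
    """
    if model not in ("binomial", "hypergeometric"):
        raise ConfigError(f"unknown model {model!r}")
    bg = sorted(set(g.strip() for g in background))
    if not bg:
        raise ConfigError("empty background")
    bg_set = set(bg)

    rows = []
    for module_id in sorted(markers):
        mod = set(markers[module_id]) & bg_set
        dropped = len(set(markers[module_id])) - len(mod)
        if dropped:
            log.warning("module %s: %d marker genes outside background dropped", module_id, dropped)
        n = len(mod)
        for set_id in coll.names():
            members = set(coll.members(set_id)) & bg_set
            big_k = len(members)
            k = len(mod & members)
            p0 = big_k / len(bg)
            if model == "binomial":
                p_right = binom_right_tail(k, n, p0)
            else:
                p_right = float(hypergeom.sf(k - 1, len(bg), big_k, n)) if k > 0 else 1.0
            rows.append(
                {
                    "module_id": module_id,
                    "set_id": set_id,
                    "n_markers": n,
                    "overlap_k": k,
                    "bg_set_size": big_k,
                    "bg_size": len(bg),
                    "p_right": p_right,
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p_right"], method="fdr_bh")[1]
    else:
        df["q"] = []
    return df


def filter_heatmap(
    results: pd.DataFrame,
    min_set_size: int = 20,
    min_overlap: int = 10,
    p_max: float = 1e-5,
    contrast_p_min: float = 1e-3,
    contrast_modules: list[str] | None = None,
) -> pd.DataFrame:
    """Module × set matrix of q-values after report-style filtering.

    A set is kept iff its background size exceeds ``min_set_size``, some
    non-contrast module reaches ``overlap_k >= min_overlap`` and
    ``p_right < p_max``, and every contrast module has
    ``p_right > contrast_p_min``. Cells with p_right >= p_max are set to
    NaN (the non-significant sentinel).
    """
    contrast = set(contrast_modules or [])
    keep_sets = []
    for set_id, sub in results.groupby("set_id"):
        if not (sub["bg_set_size"] > min_set_size).all():
            continue
        focal = sub[~sub["module_id"].isin(contrast)]
        if not ((focal["overlap_k"] >= min_overlap) & (focal["p_right"] < p_max)).any():
            continue
        ctr = sub[sub["module_id"].isin(contrast)]
        if len(ctr) and not (ctr["p_right"] > contrast_p_min).all():
            continue
        keep_sets.append(set_id)
    if not keep_sets:
        log.warning("all annotation sets removed by the heatmap filter")
        return pd.DataFrame()
    sub = results[results["set_id"].isin(keep_sets)].copy()
    sub.loc[sub["p_right"] >= p_max, "q"] = np.nan
    return sub.pivot(index="module_id", columns="set_id", values="q")
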