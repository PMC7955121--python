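"""Preranked gene-set enrichment with the weighted Kolmogorov–Smirnov-like
running-sum statistic, permutation NES/p, and drug ranking.

Walking a ranked list from top to bottom, the running sum increases at every
gene-set hit by ``|score|**weight_exp`` (normalized over the hits) and
decreases at every miss by ``1/(N - n_hits)``. The enrichment score ES is
the running-sum value of maximal absolute deviation; at ``weight_exp = 0``
(or when the list carries no scores) this reduces to the classical
Kolmogorov–Smirnov-style statistic. ES > 0 means the set concentrates at
the top of the list (up-regulated), ES < 0 at the bottom.

The null is built by gene-set permutation — random same-size sets drawn
from the list's universe — because a preranked consensus list carries no
sample-level replicates to permute. NES divides ES by the mean |ES| of
same-sign null values; p-values carry the +1 permutation correction and are
never 0. The drug-ranking FDR follows the classic tail-ratio estimator:
the fraction of pooled same-sign null NES at least as extreme, divided by
the corresponding fraction of observed NES, clipped to [0, 1] and
monotonized from the most extreme NES inward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ConfigError, RankedList, log

__all__ = [
    "EnrichmentResult",
    "enrichment_score",
    "nes_and_p",
    "rank_drugs",
    "mean_set_score",
]


@dataclass
class EnrichmentResult:
    list_id: str
    set_id: str
    es: float
    nes: float
    p: float
    fdr_q: float = float("nan")
    leading_edge: list[str] = field(default_factory=list)


def _hit_weights(rl: RankedList, weight_exp: float) -> np.ndarray:
    """Per-position weights |score|^weight_exp (all ones when unweighted)."""
    if rl.scores is None or weight_exp == 0:
        return np.ones(len(rl))
    return np.abs(np.asarray(rl.scores, dtype=float)) ** weight_exp


def _es_from_hits(hit_mask: np.ndarray, w: np.ndarray) -> tuple[float, int, np.ndarray]:
    """ES, extremum position and running sum for one hit indicator vector."""
    n = hit_mask.size
    n_hits = int(hit_mask.sum())
    steps = np.full(n, -1.0 / (n - n_hits))
    hw = w * hit_mask
    denom = hw.sum()
    if denom == 0:  # all hit scores exactly 0: fall back to uniform increments
        hw = hit_mask.astype(float)
        denom = hw.sum()
    steps[hit_mask] = hw[hit_mask] / denom
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak, running


def enrichment_score(
    rl: RankedList, gene_set: list[str], weight_exp: float = 1.0
) -> tuple[float, list[str], np.ndarray]:
    """ES of ``gene_set`` in ``rl``; returns (es, leading_edge, running_sum).

    The leading edge contains the hit genes at or before the running-sum
    extremum for positive ES, and at or after it for negative ES.
    """
    positions = {g: i for i, g in enumerate(rl.genes)}
    hits = sorted({positions[g] for g in gene_set if g in positions})
    if not hits:
        raise ConfigError("gene set has no genes in the ranked list")
    if len(hits) == len(rl):
        raise ConfigError("gene set equals the whole universe; ES undefined")
    hit_mask = np.zeros(len(rl), dtype=bool)
    hit_mask[hits] = True
    es, peak, running = _es_from_hits(hit_mask, _hit_weights(rl, weight_exp))
    if es >= 0:
        edge = [rl.genes[i] for i in hits if i <= peak]
    else:
        edge = [rl.genes[i] for i in hits if i >= peak]
    return es, edge, running


def _null_es(
    rl: RankedList, set_size: int, n_perm: int, seed: int, weight_exp: float
) -> np.ndarray:
    """ES of ``n_perm`` random same-size gene sets (gene-set permutation)."""
    n = len(rl)
    w = _hit_weights(rl, weight_exp)
    rng = np.random.default_rng(seed)
    out = np.empty(n_perm)
    chunk = max(1, int(2e6 // n))
    miss_step = -1.0 / (n - set_size)
    for start in range(0, n_perm, chunk):
        k = min(chunk, n_perm - start)
        # random S-subsets via partial argsort of uniform keys
        keys = rng.random((k, n))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        steps = np.full((k, n), miss_step)
        rows = np.repeat(np.arange(k), set_size)
        hw = w[idx.ravel()]
        denom = hw.reshape(k, set_size).sum(axis=1)
        steps[rows, idx.ravel()] = hw / np.repeat(denom, set_size)
        running = np.cumsum(steps, axis=1)
        peaks = np.argmax(np.abs(running), axis=1)
        out[start : start + k] = running[np.arange(k), peaks]
    return out


def _nes_p_from_null(es: float, null: np.ndarray) -> tuple[float, float]:
    if es == 0:
        return 0.0, 1.0
    same = null[null > 0] if es > 0 else null[null < 0]
    if same.size == 0:
        # sign preserved by normalizing against the whole null instead
        log.warning("no null ES shares the observed sign; p guarded to 1")
        scale = np.abs(null).mean() if null.size else 1.0
        return float(es / scale), 1.0
    nes = es / np.abs(same).mean()
    p = (1 + int((np.abs(same) >= abs(es)).sum())) / (1 + same.size)
    return float(nes), float(p)


def nes_and_p(
    rl: RankedList,
    gene_set: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight_exp: float = 1.0,
) -> EnrichmentResult:
    """Normalized enrichment score and permutation p for one (list, set)."""
    if n_perm < 100:
        raise ConfigError("n_perm must be >= 100")
    es, edge, _ = enrichment_score(rl, gene_set, weight_exp)
    in_list = sum(1 for g in set(gene_set) if g in set(rl.genes))
    null = _null_es(rl, in_list, n_perm, seed, weight_exp)
    nes, p = _nes_p_from_null(es, null)
    return EnrichmentResult(
        list_id=rl.list_id, set_id="query", es=es, nes=nes, p=p, leading_edge=edge
    )


def _tail_fdr(obs_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """Classic tail-ratio FDR over a family of observed NES with pooled null.

    q(i) = [frac of same-sign null at least as extreme as nes_i] /
           [frac of same-sign observed at least as extreme], clipped to
    [0, 1] and monotonized by a running minimum from the least extreme |NES|
    outward within each sign class (so q is non-increasing in |NES|).
    """
    q = np.ones_like(obs_nes, dtype=float)
    for sign in (1, -1):
        omask = obs_nes * sign > 0
        if not omask.any():
            continue
        nvals = null_nes[null_nes * sign > 0]
        ovals = obs_nes[omask]
        raw = np.empty(ovals.size)
        for i, v in enumerate(np.abs(ovals)):
            num = (np.abs(nvals) >= v).mean() if nvals.size else 1.0
            den = (np.abs(ovals) >= v).mean()
            raw[i] = min(1.0, num / den) if den > 0 else 1.0
        # monotonize: more extreme |NES| can never have larger q
        order = np.argsort(-np.abs(ovals))
        running = np.minimum.accumulate(raw[order][::-1])[::-1]
        mono = np.empty_like(raw)
        mono[order] = running
        q[omask] = mono
    return q


def rank_drugs(
    prls: dict[str, RankedList],
    marker_set: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight_exp: float = 1.0,
) -> pd.DataFrame:
    """Rank drugs by NES of ``marker_set`` in each drug's PRL, ascending.

    The most negative NES leads — those drugs down-regulate the marker set
    most strongly. Columns: drug, es, nes, p, fdr_q, neglog10_q,
    leading_edge. FDR pools the permutation null across the drug family.
    """
    if len(prls) < 2:
        raise ConfigError("need at least 2 drugs to rank")
    drugs = sorted(prls)
    rows, null_pool = [], []
    seeds = np.random.SeedSequence(seed).spawn(len(drugs))
    for drug, ss in zip(drugs, seeds):
        rl = prls[drug]
        es, edge, _ = enrichment_score(rl, marker_set, weight_exp)
        in_list = sum(1 for g in set(marker_set) if g in set(rl.genes))
        null = _null_es(rl, in_list, n_perm, int(ss.generate_state(1)[0] % 2**31), weight_exp)
        nes, p = _nes_p_from_null(es, null)
        # normalize null ES the same way to make the pooled null comparable
        pos, neg = null[null > 0], null[null < 0]
        null_nes = np.concatenate(
            [
                pos / pos.mean() if pos.size else pos,
                neg / np.abs(neg).mean() if neg.size else neg,
            ]
        )
        null_pool.append(null_nes)
        rows.append(
            {"drug": drug, "es": es, "nes": nes, "p": p, "leading_edge": ",".join(edge)}
        )
    df = pd.DataFrame(rows)
    q = _tail_fdr(df["nes"].to_numpy(), np.concatenate(null_pool))
    floor = 1.0 / (n_perm * len(drugs))
    df["fdr_q"] = q
    df["neglog10_q"] = -np.log10(np.maximum(q, floor))
    df = df.sort_values("nes", ascending=True, kind="mergesort").reset_index(drop=True)
    return df[["drug", "es", "nes", "p", "fdr_q", "neglog10_q", "leading_edge"]]


def mean_set_score(score_vector: dict[str, float], gene_set: list[str]) -> tuple[float, int]:
    """Mean of per-gene scores over set members present; (mean, n_missing)."""
    present = [g for g in gene_set if g in score_vector]
    missing = len(gene_set) - len(present)
    if not present:
        raise ConfigError("gene set has no genes in the score vector")
    return float(np.mean([score_vector[g] for g in present])), missing
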