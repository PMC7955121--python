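"""Consensus drug signatures: one Prototype Ranked List (PRL) per drug.

A perturbation-response database stores, for every (drug, cell line,
condition) experiment, a per-gene fold change between treated and untreated
states. For each drug the pipeline

1. averages fold changes over the conditions of each cell line
   (weighted mean; weights default to 1) and ranks the genes — the
   cell-line signature;
2. merges the per-cell-line rankings with a hierarchical majority-voting
   scheme: repeatedly merge the two closest lists (Spearman footrule
   distance on rank vectors) by Borda mean rank until one consensus
   ranking — the PRL — remains.

Genes consistently up-regulated across cell lines rise to the top of the
PRL; consistently down-regulated genes sink to the bottom. The merge gives
every cell line equal weight regardless of its number of conditions.

PRLs carry centered rank scores (N - 2 rank + 1)/N in (-1, 1) so that the
weighted enrichment statistic downstream is defined even for pure rankings
and stays two-sided (see :func:`rank_scores`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ConfigError, FormatError, RankedList, log

__all__ = [
    "PerturbationDB",
    "cellline_signature",
    "merge_prl",
    "build_prls",
    "rank_scores",
]


@dataclass
class PerturbationDB:
    """Gene × experiment fold-change matrix with a (drug, cell_line, condition) index.

    ``index`` is a DataFrame with columns drug, cell_line, condition and an
    optional positive ``weight`` (default 1); ``values[i, j]`` is the fold
    change of gene i in experiment j.
    """

    genes: list[str]
    index: pd.DataFrame
    values: np.ndarray

    def __post_init__(self):
        if "weight" not in self.index.columns:
            self.index = self.index.assign(weight=1.0)
        if (self.index["weight"] <= 0).any():
            raise ConfigError("experiment weights must be positive")
        key = self.index[["drug", "cell_line", "condition"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise FormatError(f"duplicate experiment triple {tuple(dup)}")
        if self.values.shape != (len(self.genes), len(self.index)):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.index)} experiments"
            )

    def drugs(self) -> list[str]:
        return list(pd.unique(self.index["drug"]))

    def cell_lines(self, drug: str) -> list[str]:
        return list(pd.unique(self.index.loc[self.index["drug"] == drug, "cell_line"]))

    # -- long TSV round trip ------------------------------------------------

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "PerturbationDB":
        """Build from a long table with columns drug, cell_line, condition,
        gene, fold_change and optional weight.

        Genes missing from some experiments are imputed as fold change 0
        (neutral) with a logged warning.
        """
        required = {"drug", "cell_line", "condition", "gene", "fold_change"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"perturbation table missing columns {sorted(missing)}")
        genes = sorted(pd.unique(df["gene"]))
        wide = df.pivot_table(
            index="gene",
            columns=["drug", "cell_line", "condition"],
            values="fold_change",
            aggfunc="first",
        ).reindex(genes)
        if wide.isna().any().any():
            n_missing = int(wide.isna().sum().sum())
            log.warning("perturbation db: %d missing gene entries imputed as 0", n_missing)
            wide = wide.fillna(0.0)
        index = pd.DataFrame(wide.columns.tolist(), columns=["drug", "cell_line", "condition"])
        if "weight" in df.columns:
            w = df.groupby(["drug", "cell_line", "condition"])["weight"].first()
            index["weight"] = [
                float(w.loc[tuple(r)]) for r in index.itertuples(index=False, name=None)
            ]
        return cls(genes=genes, index=index, values=wide.to_numpy())

    def to_long(self) -> pd.DataFrame:
        rows = []
        for j, (drug, cl, cond, w) in enumerate(
            self.index[["drug", "cell_line", "condition", "weight"]].itertuples(
                index=False, name=None
            )
        ):
            rows.append(
                pd.DataFrame(
                    {
                        "drug": drug,
                        "cell_line": cl,
                        "condition": cond,
                        "gene": self.genes,
                        "fold_change": self.values[:, j],
                        "weight": w,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def rank_scores(n: int) -> list[float]:
    """Centered rank scores (N - 2 rank + 1)/N in (-1, 1), non-increasing.

    Symmetric about zero, like the fold-change scores they stand in for:
    top-ranked genes score near +1, bottom-ranked near -1. This keeps the
    weighted enrichment statistic two-sided — hits at either extreme carry
    large weight — so the permutation null produces both signs and NES is
    defined for down-regulated sets as well as up-regulated ones.
    """
    return [(n - 2 * r - 1) / n for r in range(n)]


def _ranked_from_scores(list_id: str, genes: list[str], scores: np.ndarray) -> RankedList:
    order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
    return RankedList(
        list_id=list_id,
        genes=[genes[i] for i in order],
        scores=[float(scores[i]) for i in order],
    )


def cellline_signature(db: PerturbationDB, drug: str, cell_line: str) -> RankedList:
    """Weighted-average fold change over a (drug, cell line)'s conditions,
    genes ranked by that score descending (lexicographic tie-break)."""
    mask = (db.index["drug"] == drug) & (db.index["cell_line"] == cell_line)
    cols = np.flatnonzero(mask.to_numpy())
    if cols.size == 0:
        raise ConfigError(f"no experiments for drug {drug!r} in cell line {cell_line!r}")
    w = db.index["weight"].to_numpy()[cols]
    score = db.values[:, cols] @ w / w.sum()
    return _ranked_from_scores(f"{drug}|{cell_line}", db.genes, score)


def _footrule(ra: np.ndarray, rb: np.ndarray) -> int:
    """Spearman footrule distance between two rank vectors."""
    return int(np.abs(ra - rb).sum())


def _borda(lists: list[RankedList], list_id: str) -> RankedList:
    """Merge by mean rank, re-sorted ascending, lexicographic tie-break."""
    genes = sorted(lists[0].genes)
    rank_mat = np.empty((len(lists), len(genes)))
    for i, rl in enumerate(lists):
        ranks = rl.ranks()
        rank_mat[i] = [ranks[g] for g in genes]
    mean_rank = rank_mat.mean(axis=0)
    order = sorted(range(len(genes)), key=lambda i: (mean_rank[i], genes[i]))
    merged = [genes[i] for i in order]
    return RankedList(list_id=list_id, genes=merged, scores=rank_scores(len(merged)))


def merge_prl(lists: list[RankedList]) -> RankedList:
    """Hierarchical majority-vote merge of rankings over one gene universe.

    Repeatedly merges the two closest lists (Spearman footrule on rank
    vectors; ties broken by input position) via Borda mean rank until one
    remains. A single input is returned unchanged. Deterministic, and
    invariant to the order in which the lists are supplied.
    """
    if not lists:
        raise ConfigError("merge_prl needs at least one list")
    universe = set(lists[0].genes)
    for rl in lists[1:]:
        if set(rl.genes) != universe:
            diff = sorted(set(rl.genes) ^ universe)
            raise FormatError(f"gene universes differ; symmetric difference {diff[:5]}")
    if len(lists) == 1:
        return lists[0]

    # order-invariance: process lists in a canonical order (by list id)
    pool = sorted(lists, key=lambda rl: rl.list_id)
    genes = sorted(universe)
    while len(pool) > 1:
        rank_vecs = []
        for rl in pool:
            ranks = rl.ranks()
            rank_vecs.append(np.array([ranks[g] for g in genes]))
        best = None
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                d = _footrule(rank_vecs[i], rank_vecs[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        _, i, j = best
        merged = _borda([pool[i], pool[j]], f"({pool[i].list_id}+{pool[j].list_id})")
        pool = [rl for k, rl in enumerate(pool) if k not in (i, j)] + [merged]
    out = pool[0]
    return RankedList(list_id=out.list_id, genes=out.genes, scores=rank_scores(len(out)))


def build_prls(db: PerturbationDB) -> dict[str, RankedList]:
    """One PRL per drug: average within cell line, merge across cell lines."""
    if len(db.index) == 0:
        raise ConfigError("empty perturbation database")
    prls: dict[str, RankedList] = {}
    for drug in db.drugs():
        per_cl = [cellline_signature(db, drug, cl) for cl in db.cell_lines(drug)]
        merged = merge_prl(per_cl)
        prls[drug] = RankedList(
            list_id=drug, genes=merged.genes, scores=rank_scores(len(merged))
        )
    return prls
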