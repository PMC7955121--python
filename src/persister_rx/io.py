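"""Readers/writers for every external format the pipeline touches.

Formats: MatrixMarket coordinate triplets (matrix.mtx + features.tsv +
barcodes.tsv), GMT gene-set collections, RNK two-column ranked lists, and
header-carrying TSV tables for annotations, fold changes, survival data and
results.

Conventions fixed here and relied on everywhere downstream:

* gene/observation identifiers are matched by exact string equality after
  stripping surrounding whitespace — no case folding;
* MTX files are 1-based (the standard); all in-memory indices are 0-based;
* whenever a ranking must break ties, ties are broken lexicographically on
  the gene id, so every downstream ranking is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

log = logging.getLogger("persister_rx")

__all__ = [
    "FormatError",
    "ConfigError",
    "ExpressionMatrix",
    "GeneSetCollection",
    "RankedList",
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_gmt",
    "write_gmt",
    "read_rnk",
    "write_rnk",
    "read_table",
    "write_table",
    "load_config",
    "log_stage",
]


class FormatError(ValueError):
    """An input file violates its stated grammar."""


class ConfigError(ValueError):
    """A configuration value violates its contract."""


def log_stage(stage: str, **fields) -> None:
    """Emit one structured log line for a pipeline stage."""
    payload = " ".join(f"{k}={v}" for k, v in fields.items())
    log.info("stage=%s %s", stage, payload)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise FormatError(f"duplicate {what}: {sorted(set(dups))[:5]}")


@dataclass
class ExpressionMatrix:
    """A genes × observations expression matrix.

    ``layer`` tags the scale of ``values``: raw ``counts`` (finite,
    non-negative), ``lognorm`` (log1p-normalized) or ``signature``
    (fold changes / arbitrary real scores).
    """

    gene_ids: list[str]
    obs_ids: list[str]
    values: np.ndarray | sp.spmatrix
    layer: str = "counts"

    def __post_init__(self):
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.obs_ids = [str(o).strip() for o in self.obs_ids]
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.obs_ids, "observation ids")
        if self.layer not in ("counts", "lognorm", "signature"):
            raise ConfigError(f"unknown layer tag {self.layer!r}")
        if self.values.shape != (len(self.gene_ids), len(self.obs_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.obs_ids)} observations"
            )
        if self.layer == "counts":
            data = self.values.data if sp.issparse(self.values) else self.values
            if data.size and (not np.all(np.isfinite(data)) or data.min() < 0):
                raise FormatError("counts layer must contain finite values >= 0")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_obs(self) -> int:
        return len(self.obs_ids)

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def genes_per_obs(self) -> np.ndarray:
        """Number of genes detected (value > 0) in each observation (nFeature)."""
        if sp.issparse(self.values):
            return np.asarray((self.values > 0).sum(axis=0)).ravel()
        return (self.values > 0).sum(axis=0)

    def subset_obs(self, keep: np.ndarray) -> "ExpressionMatrix":
        """Column subset by boolean mask or index array; gene universe unchanged."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        vals = self.values.tocsc()[:, keep] if sp.issparse(self.values) else self.values[:, keep]
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            obs_ids=[self.obs_ids[i] for i in keep],
            values=vals,
            layer=self.layer,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.gene_ids, columns=self.obs_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions, as read from a GMT file."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self):
        for name, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            _check_unique(members, f"members of set {name!r}")

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class RankedList:
    """An ordered gene list, rank 1 = top (most up-regulated).

    Scores, when present, are parallel to ``genes`` and non-increasing.
    """

    list_id: str
    genes: list[str]
    scores: list[float] | None = None

    def __post_init__(self):
        self.genes = [str(g).strip() for g in self.genes]
        _check_unique(self.genes, f"genes in ranked list {self.list_id!r}")
        if self.scores is not None:
            if len(self.scores) != len(self.genes):
                raise FormatError("scores and genes differ in length")
            s = np.asarray(self.scores, dtype=float)
            if s.size > 1 and np.any(np.diff(s) > 1e-12):
                raise FormatError("scores must be non-increasing down the ranking")

    def __len__(self) -> int:
        return len(self.genes)

    def ranks(self) -> dict[str, int]:
        """gene -> 1-based rank."""
        return {g: i + 1 for i, g in enumerate(self.genes)}


# ---------------------------------------------------------------------------
# MatrixMarket triplet
# ---------------------------------------------------------------------------

def _read_id_column(path: Path, what: str) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[0].strip())
    _check_unique(ids, what)
    return ids


def read_mtx_triplet(matrix_path, features_path, barcodes_path) -> ExpressionMatrix:
    """Read a 10x/Drop-seq style DGE triplet into a counts matrix.

    Genes keep the order of the features file; integer entries are preserved
    exactly.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    genes = _read_id_column(Path(features_path), "gene ids")
    barcodes = _read_id_column(Path(barcodes_path), "barcodes")
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"MTX header declares shape {mat.shape} but features/barcodes files "
            f"provide {len(genes)} x {len(barcodes)}"
        )
    mat = sp.csc_matrix(mat)
    if mat.nnz and np.allclose(mat.data, np.round(mat.data)):
        mat = mat.astype(np.int64)
    return ExpressionMatrix(gene_ids=genes, obs_ids=barcodes, values=mat, layer="counts")


def write_mtx_triplet(m: ExpressionMatrix, outdir) -> tuple[Path, Path, Path]:
    """Write matrix.mtx + features.tsv + barcodes.tsv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mtx, feat, bc = outdir / "matrix.mtx", outdir / "features.tsv", outdir / "barcodes.tsv"
    scipy.io.mmwrite(str(mtx), sp.coo_matrix(m.values))
    feat.write_text("".join(f"{g}\n" for g in m.gene_ids))
    bc.write_text("".join(f"{b}\n" for b in m.obs_ids))
    return mtx, feat, bc


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>member...`` per line.

    Duplicate members within a line are dropped (first occurrence kept) with
    a logged warning; duplicate set names are a format error.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            name, desc = fields[0].strip(), fields[1]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members, seen = [], set()
            for g in fields[2:]:
                g = g.strip()
                if not g:
                    continue
                if g in seen:
                    log.warning("GMT set %s: duplicate member %s dropped", name, g)
                    continue
                seen.add(g)
                members.append(g)
            sets[name] = (desc, members)
    return GeneSetCollection(sets=sets)


def write_gmt(coll: GeneSetCollection, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, (desc, members) in coll.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")
    return path


# ---------------------------------------------------------------------------
# RNK
# ---------------------------------------------------------------------------

def read_rnk(path, list_id: str | None = None) -> RankedList:
    """Read a two-column gene<TAB>score file into a RankedList.

    Genes are ordered by score descending; ties broken by gene id ascending.
    """
    genes, scores, seen = [], [], set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: RNK line needs exactly 2 fields")
            g = fields[0].strip()
            if g in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene {g!r}")
            seen.add(g)
            try:
                s = float(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric score {fields[1]!r}") from exc
            genes.append(g)
            scores.append(s)
    order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
    return RankedList(
        list_id=list_id or Path(path).stem,
        genes=[genes[i] for i in order],
        scores=[scores[i] for i in order],
    )


def write_rnk(rl: RankedList, path) -> Path:
    if rl.scores is None:
        raise ConfigError("RankedList has no scores; RNK requires gene\\tscore")
    path = Path(path)
    with open(path, "w") as fh:
        for g, s in zip(rl.genes, rl.scores):
            fh.write(f"{g}\t{s:.10g}\n")
    return path


# ---------------------------------------------------------------------------
# Generic TSV tables, config
# ---------------------------------------------------------------------------

def read_table(path, required: Sequence[str] = ()) -> pd.DataFrame:
    """Read a header-carrying TSV; check required columns exist."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    for c in df.columns:
        if df[c].dtype == object:
            df[c] = df[c].astype(str).str.strip()
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def load_config(path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ConfigError(f"{path}: config must be a mapping at top level")
    return dict(cfg)
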