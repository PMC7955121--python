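"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Three generators, each a pure function of its config (seed included):

* :func:`simulate_scrna` — clustered negative-binomial single-cell counts
  with planted per-cluster marker genes (a drug-tolerant state whose markers
  the downstream marker detector must recover);
* :func:`simulate_perturbation_db` — a drug × cell-line × condition
  fold-change database in which designated "effective" drugs shift a target
  gene set down (or up), emulating a perturbation-response catalog;
* :func:`simulate_cohort` — a bulk cohort whose survival hazard depends on
  whether a sample carries an up-shifted marker-set signature.

Default configurations are the desk-scale study conditions: 2,000 genes,
5 clusters × 300 cells with fifty 4-fold markers planted in one cluster;
50 drugs × 3 cell lines × 3 conditions with one planted down-regulator
(shift 2, noise SD 1); and a 126-sample cohort split ~51/75 into
marker-enriched and background samples with a true hazard ratio of 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import ConfigError, ExpressionMatrix
from .signatures import PerturbationDB

__all__ = [
    "ScrnaSimConfig",
    "PerturbSimConfig",
    "CohortSimConfig",
    "default_scrna_config",
    "default_perturb_config",
    "default_cohort_config",
    "simulate_scrna",
    "simulate_perturbation_db",
    "simulate_cohort",
    "gene_universe",
]


def gene_universe(n_genes: int) -> list[str]:
    """Deterministic synthetic gene ids G0000, G0001, ..."""
    width = max(4, len(str(n_genes - 1)))
    return [f"G{i:0{width}d}" for i in range(n_genes)]


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

@dataclass
class ScrnaSimConfig:
    """Negative-binomial single-cell counts with planted cluster markers.

    ``marker_plan`` maps cluster label -> list of (gene id, log2 effect ≥ 0);
    inside that cluster the gene's NB mean is multiplied by ``2**effect``.
    ``dispersion`` is the NB size parameter theta (var = mu + mu^2/theta),
    shared across genes. Per-cell library-size factors are log-normal with
    coefficient of variation ``library_size_cv`` and mean 1.
    """

    n_genes: int = 2000
    cluster_sizes: list[int] = field(default_factory=lambda: [300] * 5)
    marker_plan: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    baseline_mean: float = 0.5
    dispersion: float = 2.0
    library_size_cv: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if len(self.cluster_sizes) < 2:
            raise ConfigError("need at least 2 clusters")
        if any(s <= 0 for s in self.cluster_sizes):
            raise ConfigError("cluster sizes must be positive")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ConfigError("baseline_mean and dispersion must be positive")
        if self.library_size_cv < 0:
            raise ConfigError("library_size_cv must be >= 0")
        universe = set(gene_universe(self.n_genes))
        for cluster, plan in self.marker_plan.items():
            for gene, effect in plan:
                if gene not in universe:
                    raise ConfigError(f"planted marker {gene!r} outside gene universe")
                if not math.isfinite(effect) or effect < 0:
                    raise ConfigError(f"effect size for {gene!r} must be finite and >= 0")


@dataclass
class PerturbSimConfig:
    """Drug × cell-line × condition fold-change vectors, Gaussian noise.

    ``effective_drugs`` maps drug id -> (target gene list, shift > 0, sign),
    sign in {"down", "up"}: targets are shifted by -shift (down) or +shift
    (up) in every condition of that drug.
    """

    n_genes: int = 2000
    n_drugs: int = 50
    n_cell_lines: int = 3
    conditions_per_pair: int = 3
    effective_drugs: dict[str, tuple[list[str], float, str]] = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_drugs, self.n_cell_lines, self.conditions_per_pair) < 1:
            raise ConfigError("db dimensions must be >= 1")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        drugs = set(self.drug_ids())
        universe = set(gene_universe(self.n_genes))
        for drug, (targets, shift, sign) in self.effective_drugs.items():
            if drug not in drugs:
                raise ConfigError(f"effective drug {drug!r} outside drug universe")
            if sign not in ("down", "up"):
                raise ConfigError(f"sign must be 'down' or 'up', got {sign!r}")
            if not set(targets) <= universe:
                raise ConfigError(f"target set of {drug!r} outside gene universe")

    def drug_ids(self) -> list[str]:
        return [f"D{i:03d}" for i in range(self.n_drugs)]

    def cell_line_ids(self) -> list[str]:
        return [f"CL{i}" for i in range(self.n_cell_lines)]

    def condition_ids(self) -> list[str]:
        return [f"C{i}" for i in range(self.conditions_per_pair)]


@dataclass
class CohortSimConfig:
    """Bulk cohort with a marker-enriched subgroup carrying excess hazard.

    Expression is N(0, 1) per gene per sample; in enriched samples every
    ``marker_set`` gene is shifted by ``enrichment_shift``. Survival times
    are exponential with hazard ``baseline_hazard * exp(log_hazard_ratio *
    enriched)``; a ``censor_rate`` fraction of samples is censored at a
    uniform time before their event.
    """

    n_genes: int = 2000
    n_samples: int = 126
    marker_set: list[str] = field(default_factory=lambda: gene_universe(2000)[:30])
    enriched_fraction: float = 51 / 126
    enrichment_shift: float = 1.0
    baseline_hazard: float = 0.1
    log_hazard_ratio: float = math.log(2.0)
    censor_rate: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.enriched_fraction < 1:
            raise ConfigError("enriched_fraction must be in (0, 1)")
        if not 0 <= self.censor_rate < 1:
            raise ConfigError("censor_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be positive")
        if not set(self.marker_set) <= set(gene_universe(self.n_genes)):
            raise ConfigError("marker_set outside gene universe")


def default_scrna_config(seed: int = 0) -> ScrnaSimConfig:
    """5 × 300 cells, 2,000 genes, fifty 4-fold markers planted in cluster 2."""
    genes = gene_universe(2000)
    plan = {"2": [(g, 2.0) for g in genes[:50]]}
    return ScrnaSimConfig(marker_plan=plan, seed=seed)


def default_perturb_config(seed: int = 0) -> PerturbSimConfig:
    """50 drugs × 3 cell lines × 3 conditions; D000 down-shifts 50 targets by 2."""
    genes = gene_universe(2000)
    return PerturbSimConfig(
        effective_drugs={"D000": (genes[:50], 2.0, "down")}, seed=seed
    )


def default_cohort_config(seed: int = 0) -> CohortSimConfig:
    """126 samples, ~51 enriched (shift 1.0 on 30 markers), true HR = 2."""
    return CohortSimConfig(seed=seed)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def simulate_scrna(cfg: ScrnaSimConfig) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Draw clustered NB counts; returns (counts, annotation, truth).

    Annotation columns: obs_id, cluster, condition, sample. Clusters that
    carry planted markers are labeled condition "treated" (the drug-tolerant
    side of the design), the rest "untreated". Truth columns: cluster, gene,
    effect (log2).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = gene_universe(cfg.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    n_cells = sum(cfg.cluster_sizes)
    clusters = [str(c) for c in range(len(cfg.cluster_sizes))]

    # per-cell log-normal library factors, mean 1, CV = library_size_cv
    if cfg.library_size_cv > 0:
        sigma2 = math.log1p(cfg.library_size_cv**2)
        lib = rng.lognormal(mean=-sigma2 / 2, sigma=math.sqrt(sigma2), size=n_cells)
    else:
        lib = np.ones(n_cells)

    cell_cluster = np.repeat(np.arange(len(cfg.cluster_sizes)), cfg.cluster_sizes)
    mean = np.full((cfg.n_genes, n_cells), cfg.baseline_mean)
    truth_rows = []
    for cluster, plan in cfg.marker_plan.items():
        cols = np.flatnonzero(cell_cluster == clusters.index(cluster))
        for gene, effect in plan:
            mean[gene_index[gene], cols] *= 2.0**effect
            truth_rows.append({"cluster": cluster, "gene": gene, "effect": effect})
    mean *= lib[None, :]

    # NB via gamma-Poisson mixture: lam ~ Gamma(theta, mu/theta), x ~ Poisson(lam)
    lam = rng.gamma(shape=cfg.dispersion, scale=mean / cfg.dispersion)
    counts = rng.poisson(lam).astype(np.int64)

    obs_ids = [f"cell{i:05d}" for i in range(n_cells)]
    marker_clusters = set(cfg.marker_plan)
    ann = pd.DataFrame(
        {
            "obs_id": obs_ids,
            "cluster": [clusters[c] for c in cell_cluster],
            "condition": [
                "treated" if clusters[c] in marker_clusters else "untreated"
                for c in cell_cluster
            ],
            "sample": "sim",
        }
    )
    truth = pd.DataFrame(truth_rows, columns=["cluster", "gene", "effect"])
    m = ExpressionMatrix(genes, obs_ids, sp.csc_matrix(counts), layer="counts")
    return m, ann, truth


def simulate_perturbation_db(cfg: PerturbSimConfig) -> tuple[PerturbationDB, pd.DataFrame]:
    """Draw fold-change vectors per (drug, cell line, condition); returns (db, truth)."""
    rng = np.random.default_rng(cfg.seed)
    genes = gene_universe(cfg.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    index_rows = []
    for drug in cfg.drug_ids():
        for cl in cfg.cell_line_ids():
            for cond in cfg.condition_ids():
                index_rows.append((drug, cl, cond))
    n_exp = len(index_rows)
    values = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_exp))

    truth_rows = []
    for drug, (targets, shift, sign) in cfg.effective_drugs.items():
        delta = -shift if sign == "down" else shift
        tgt_idx = [gene_index[g] for g in targets]
        exp_cols = [j for j, (d, _, _) in enumerate(index_rows) if d == drug]
        values[np.ix_(tgt_idx, exp_cols)] += delta
        for g in targets:
            truth_rows.append({"drug": drug, "gene": g, "shift": delta})

    index = pd.DataFrame(index_rows, columns=["drug", "cell_line", "condition"])
    index["weight"] = 1.0
    db = PerturbationDB(genes=genes, index=index, values=values)
    truth = pd.DataFrame(truth_rows, columns=["drug", "gene", "shift"])
    return db, truth


def simulate_cohort(
    cfg: CohortSimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Draw cohort expression + survival; returns (expr, survival, truth).

    Survival columns: sample, time, event. Truth columns: sample, enriched.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = gene_universe(cfg.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    samples = [f"S{i:03d}" for i in range(cfg.n_samples)]

    n_enriched = int(round(cfg.enriched_fraction * cfg.n_samples))
    enriched = np.zeros(cfg.n_samples, dtype=bool)
    enriched[rng.choice(cfg.n_samples, size=n_enriched, replace=False)] = True

    expr = rng.normal(0.0, 1.0, size=(cfg.n_genes, cfg.n_samples))
    marker_idx = [gene_index[g] for g in cfg.marker_set]
    expr[np.ix_(marker_idx, np.flatnonzero(enriched))] += cfg.enrichment_shift

    hazard = cfg.baseline_hazard * np.exp(cfg.log_hazard_ratio * enriched.astype(float))
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(cfg.n_samples) < cfg.censor_rate
    t_obs = np.where(censored, rng.uniform(0, t_event), t_event)
    t_obs = np.maximum(t_obs, 1e-9)  # times must be strictly positive
    event = (~censored).astype(int)

    surv = pd.DataFrame({"sample": samples, "time": t_obs, "event": event})
    truth = pd.DataFrame({"sample": samples, "enriched": enriched.astype(int)})
    m = ExpressionMatrix(genes, samples, expr, layer="signature")
    return m, surv, truth
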