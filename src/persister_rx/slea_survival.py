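"""Sample-level enrichment analysis (SLEA) and survival stratification.

For each sample, SLEA compares the mean expression of a marker gene set to
the distribution of means of random gene sets of the same size drawn from
the expression universe. The z-score

    z = (observed mean - mean of null means) / sd of null means

gets a two-sided normal p-value, Benjamini–Hochberg correction across the
cohort, and a three-way class: "up" if z > 1.96 and q < 0.05, "down" if
z < -1.96 and q < 0.05, otherwise "ns". One shared draw of random sets is
reused across all samples (a paired null), which removes between-sample
Monte-Carlo noise from the cohort-level comparison.

Survival groups put the "up" samples ("high") against everyone else
("rest"); the two-group log-rank statistic is computed directly from the
pooled event-time table, while the univariate Cox hazard ratio delegates to
lifelines. Kaplan–Meier curves are product-limit estimates per group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy.stats import chi2, norm
from statsmodels.stats.multitest import multipletests

from .io import ConfigError, ExpressionMatrix, log

__all__ = ["slea", "make_groups", "logrank", "cox_hr", "km_curve"]

Z_THRESHOLD = 1.96
Q_THRESHOLD = 0.05


def slea(
    m: ExpressionMatrix,
    marker_set: list[str],
    n_rand: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample marker-set enrichment z-scores against random-set nulls.

    Returns a DataFrame with columns sample, observed_mean, null_mean,
    null_sd, z, p, q, klass.
    """
    if n_rand < 1000:
        raise ConfigError("n_rand must be >= 1000")
    gene_pos = {g: i for i, g in enumerate(m.gene_ids)}
    idx = [gene_pos[g] for g in marker_set if g in gene_pos]
    if len(idx) < 2:
        raise ConfigError("need at least 2 marker genes present in the matrix")
    s = len(idx)
    x = m.dense()
    observed = x[idx].mean(axis=0)

    rng = np.random.default_rng(seed)
    # draw set positions in lexicographically sorted gene-id space so z is
    # invariant to the storage order of the matrix rows
    sorted_rows = np.array(sorted(range(m.n_genes), key=lambda i: m.gene_ids[i]))
    null_means = np.empty((n_rand, m.n_obs))
    chunk = max(1, int(5e6 // (s * m.n_obs)))
    for start in range(0, n_rand, chunk):
        k = min(chunk, n_rand - start)
        draw = np.argpartition(rng.random((k, m.n_genes)), s - 1, axis=1)[:, :s]
        null_means[start : start + k] = x[sorted_rows[draw]].mean(axis=1)

    null_mean = null_means.mean(axis=0)
    null_sd = null_means.std(axis=0, ddof=1)
    z = np.zeros(m.n_obs)
    # a constant sample leaves only summation-order ulp noise in the null;
    # treat SD below machine-precision scale as degenerate
    degenerate = null_sd <= 1e-10 * np.maximum(np.abs(null_mean), 1.0)
    if degenerate.any():
        log.warning("%d samples with zero null SD; z set to 0", int(degenerate.sum()))
    ok = ~degenerate
    z[ok] = (observed[ok] - null_mean[ok]) / null_sd[ok]
    p = 2 * norm.sf(np.abs(z))
    q = multipletests(p, method="fdr_bh")[1]
    klass = np.where(
        (z > Z_THRESHOLD) & (q < Q_THRESHOLD),
        "up",
        np.where((z < -Z_THRESHOLD) & (q < Q_THRESHOLD), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "sample": m.obs_ids,
            "observed_mean": observed,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "z": z,
            "p": p,
            "q": q,
            "klass": klass,
        }
    )


def make_groups(results: pd.DataFrame) -> pd.DataFrame:
    """Survival groups: "high" = SLEA class up; "rest" = everyone else.

    Refuses to produce a degenerate (single-group) comparison.
    """
    if results.empty:
        raise ConfigError("no SLEA results to group")
    group = np.where(results["klass"] == "up", "high", "rest")
    counts = pd.Series(group).value_counts()
    if counts.get("high", 0) == 0 or counts.get("rest", 0) == 0:
        raise ConfigError(
            "group comparison refused: one of the groups (high/rest) is empty; "
            f"class counts: {results['klass'].value_counts().to_dict()}"
        )
    return pd.DataFrame({"sample": results["sample"], "group": group})


def _check_survival(st: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    for col in ("time", "event", "group"):
        if col not in st.columns:
            raise ConfigError(f"survival table missing column {col!r}")
    t = st["time"].to_numpy(dtype=float)
    e = st["event"].to_numpy(dtype=int)
    g = st["group"].astype(str).to_numpy()
    if not np.all(np.isfinite(t)) or (t <= 0).any():
        raise ConfigError("survival times must be finite and > 0")
    if len(set(g)) != 2:
        raise ConfigError(f"need exactly 2 groups, found {sorted(set(g))}")
    if e.sum() == 0:
        raise ConfigError("no events in the survival table")
    return t, e, g


def logrank(st: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2 statistic, p).

    At every distinct event time t_j with d_j pooled events and n_j at
    risk (n_1j in group 1), the group-1 expectation is d_j n_1j / n_j and
    the hypergeometric variance d_j (n_1j/n_j)(1 - n_1j/n_j)(n_j - d_j)/(n_j - 1);
    chi2 = (O - E)^2 / V on 1 df.
    """
    t, e, g = _check_survival(st)
    groups = sorted(set(g))
    g1 = g == groups[0]
    o_minus_e, var = 0.0, 0.0
    for tj in np.unique(t[e == 1]):
        at_risk = t >= tj
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((t == tj) & (e == 1)).sum()
        d1 = ((t == tj) & (e == 1) & g1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    return float(stat), float(chi2.sf(stat, df=1))


def cox_hr(st: pd.DataFrame) -> tuple[float, tuple[float, float], float]:
    """Univariate Cox PH on the binary group indicator ("high" vs "rest").

    Returns (hazard ratio, (ci_low, ci_high), Wald p). The indicator is 1
    for the lexicographically larger group label unless the labels are
    high/rest, in which case "high" is the exposed group.
    """
    t, e, g = _check_survival(st)
    groups = sorted(set(g))
    exposed = "high" if "high" in groups else groups[1]
    ind = (g == exposed).astype(float)
    if e[ind == 1].sum() == 0 or e[ind == 0].sum() == 0:
        raise ConfigError("a group has no events; Cox hazard ratio is not estimable")
    df = pd.DataFrame({"time": t, "event": e, "exposed": ind})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:
        raise ConfigError(f"Cox fit failed (separation or degenerate data): {exc}") from exc
    beta = float(cph.params_["exposed"])
    se = float(cph.standard_errors_["exposed"])
    hr = float(np.exp(beta))
    ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
    p = float(cph.summary.loc["exposed", "p"])
    return hr, ci, p


def km_curve(st: pd.DataFrame) -> pd.DataFrame:
    """Kaplan–Meier product-limit estimate per group.

    Returns long-format rows (group, time, survival, at_risk) including the
    origin point (time 0, survival 1).
    """
    t, e, g = _check_survival(st)
    rows = []
    for grp in sorted(set(g)):
        tg, eg = t[g == grp], e[g == grp]
        surv = 1.0
        rows.append({"group": grp, "time": 0.0, "survival": 1.0, "at_risk": int(len(tg))})
        for tj in np.unique(tg):
            at_risk = int((tg >= tj).sum())
            d = int(((tg == tj) & (eg == 1)).sum())
            if d > 0:
                surv *= 1 - d / at_risk
            rows.append({"group": grp, "time": float(tj), "survival": surv, "at_risk": at_risk})
    return pd.DataFrame(rows)
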