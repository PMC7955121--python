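import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from persister_rx import simulate, slea_survival
from persister_rx.io import ConfigError, ExpressionMatrix


def _expr(vals, gene_prefix="g", sample_prefix="s"):
    n_genes, n_samples = vals.shape
    return ExpressionMatrix(
        [f"{gene_prefix}{i:03d}" for i in range(n_genes)],
        [f"{sample_prefix}{j:03d}" for j in range(n_samples)],
        np.asarray(vals, dtype=float),
        layer="signature",
    )


class TestSlea:
    def test_constant_sample_z_zero(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(100, 5))
        vals[:, 0] = 3.14  # every gene identical in sample 0
        m = _expr(vals)
        res = slea_survival.slea(m, m.gene_ids[:10], n_rand=1000, seed=1)
        row = res.iloc[0]
        assert row.z == pytest.approx(0.0, abs=1e-9)
        assert row.klass == "ns"

    def test_classification_rule(self):
        """Samples shifted strongly up/down on the marker set get classed
        up/down (z beyond ±1.96, q < 0.05); unshifted samples are ns."""
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(200, 30))
        vals[:20, 0] += 3.0
        vals[:20, 1] -= 3.0
        m = _expr(vals)
        res = slea_survival.slea(m, m.gene_ids[:20], n_rand=2000, seed=2)
        assert res.iloc[0].klass == "up" and res.iloc[0].z > 1.96 and res.iloc[0].q < 0.05
        assert res.iloc[1].klass == "down" and res.iloc[1].z < -1.96 and res.iloc[1].q < 0.05
        assert (res.iloc[2:].klass == "ns").mean() > 0.9

    def test_invariant_to_gene_row_permutation(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(80, 10))
        m = _expr(vals)
        perm = rng.permutation(80)
        m_perm = ExpressionMatrix(
            [m.gene_ids[i] for i in perm], m.obs_ids, vals[perm], layer="signature"
        )
        r1 = slea_survival.slea(m, m.gene_ids[:8], n_rand=1000, seed=4)
        r2 = slea_survival.slea(m_perm, m.gene_ids[:8], n_rand=1000, seed=4)
        assert np.allclose(r1.z, r2.z)

    def test_equivariant_under_per_sample_affine(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(80, 10))
        scaled = vals * 3.7 + 11.0
        r1 = slea_survival.slea(_expr(vals), [f"g{i:03d}" for i in range(8)],
                                n_rand=1000, seed=6)
        r2 = slea_survival.slea(_expr(scaled), [f"g{i:03d}" for i in range(8)],
                                n_rand=1000, seed=6)
        assert np.allclose(r1.z, r2.z)

    def test_bh_q_matches_direct_formula(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(120, 25))
        res = slea_survival.slea(_expr(vals), [f"g{i:03d}" for i in range(10)],
                                 n_rand=1000, seed=8)
        p = res.p.to_numpy()
        n = len(p)
        order = np.argsort(p)
        q_direct = np.empty(n)
        running = 1.0
        for rank_idx in range(n - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, p[i] * n / (rank_idx + 1))
            q_direct[i] = running
        assert np.allclose(res.q, q_direct)

    def test_small_set_rejected(self):
        m = _expr(np.ones((10, 3)))
        with pytest.raises(ConfigError):
            slea_survival.slea(m, ["g000"], n_rand=1000, seed=0)


class TestMakeGroups:
    def test_partition(self):
        res = pd.DataFrame({"sample": ["a", "b", "c"], "klass": ["up", "ns", "down"]})
        out = slea_survival.make_groups(res)
        assert out.group.tolist() == ["high", "rest", "rest"]

    def test_all_ns_refused(self):
        res = pd.DataFrame({"sample": ["a", "b"], "klass": ["ns", "ns"]})
        with pytest.raises(ConfigError, match="refused"):
            slea_survival.make_groups(res)


class TestLogrank:
    def test_identical_groups_null(self):
        base = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 0]})
        st = pd.concat(
            [base.assign(group="high", sample=["a1", "a2", "a3"]),
             base.assign(group="rest", sample=["b1", "b2", "b3"])]
        )
        chi2, p = slea_survival.logrank(st)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_tabulated_toy(self, toy_survival):
        """Events at t=1,2 in 'high' and t=4,5,6 in 'rest'; O-E and the
        hypergeometric variance are summed by hand over the 5 event times."""
        # t=1: n=6, n_high=3, d=1, d_high=1 -> O-E += 1 - 1/2,  V += (1/2)(1/2)
        # t=2: n=5, n_high=2, d=1, d_high=1 -> O-E += 1 - 2/5,  V += (2/5)(3/5)
        # t=4: n=3, n_high=0, d=1 -> O-E += 0,                  V += 0
        # t=5: n=2, d=1 -> 0; t=6: n=1, d=1 -> 0
        o_minus_e = (1 - 0.5) + (1 - 0.4)
        var = 0.25 + 0.24
        expected = o_minus_e**2 / var
        chi2, p = slea_survival.logrank(toy_survival)
        assert chi2 == pytest.approx(expected, abs=1e-12)

    def test_matches_lifelines_on_random_data(self):
        rng = np.random.default_rng(9)
        n = 60
        st = pd.DataFrame(
            {
                "sample": [f"s{i}" for i in range(n)],
                "time": rng.exponential(5, size=n),
                "event": rng.integers(0, 2, size=n),
                "group": rng.choice(["high", "rest"], size=n),
            }
        )
        st.loc[0, "event"] = 1  # guarantee an event
        chi2, p = slea_survival.logrank(st)
        hi = st.group == "high"
        ref = logrank_test(
            st.time[hi], st.time[~hi], st.event[hi], st.event[~hi]
        )
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_no_events_rejected(self):
        st = pd.DataFrame(
            {"sample": ["a", "b"], "time": [1.0, 2.0], "event": [0, 0],
             "group": ["high", "rest"]}
        )
        with pytest.raises(ConfigError, match="no events"):
            slea_survival.logrank(st)


class TestCox:
    def _sim_table(self, seed, lhr):
        cfg = simulate.CohortSimConfig(
            n_genes=60, n_samples=120, marker_set=simulate.gene_universe(60)[:10],
            log_hazard_ratio=lhr, seed=seed,
        )
        _, surv, truth = simulate.simulate_cohort(cfg)
        surv = surv.merge(truth, on="sample")
        surv["group"] = np.where(surv.enriched == 1, "high", "rest")
        return surv

    def test_null_hr_near_one(self):
        st = self._sim_table(seed=10, lhr=0.0)
        hr, ci, p = slea_survival.cox_hr(st)
        assert ci[0] < 1.0 < ci[1]

    def test_relabel_inverts_hr(self):
        st = self._sim_table(seed=11, lhr=np.log(2))
        hr, _, _ = slea_survival.cox_hr(st)
        flipped = st.assign(group=st.group.map({"high": "rest", "rest": "high"}))
        hr_flip, _, _ = slea_survival.cox_hr(flipped)
        assert hr_flip == pytest.approx(1 / hr, rel=1e-6)

    def test_recovers_planted_hazard_ratio(self):
        st = self._sim_table(seed=12, lhr=np.log(2))
        hr, ci, p = slea_survival.cox_hr(st)
        assert 1.2 < hr < 3.5


class TestKm:
    def test_flat_at_one_without_events(self):
        st = pd.DataFrame(
            {"sample": ["a", "b", "c", "d"], "time": [1.0, 2.0, 3.0, 4.0],
             "event": [0, 0, 0, 1], "group": ["high", "high", "rest", "rest"]}
        )
        km = slea_survival.km_curve(st)
        assert (km[km.group == "high"].survival == 1.0).all()

    def test_single_event_product_limit(self):
        st = pd.DataFrame(
            {"sample": list("abcd"), "time": [2.0, 3.0, 4.0, 5.0],
             "event": [1, 0, 0, 0], "group": ["high"] * 4}
        )
        st = pd.concat([st, pd.DataFrame({"sample": ["e"], "time": [1.0],
                                          "event": [1], "group": ["rest"]})])
        km = slea_survival.km_curve(st)
        hi = km[km.group == "high"]
        assert hi[hi.time == 2.0].survival.iloc[0] == pytest.approx(3 / 4)

    def test_matches_lifelines_product(self, toy_survival):
        km = slea_survival.km_curve(toy_survival)
        for grp in ("high", "rest"):
            sub = toy_survival[toy_survival.group == grp]
            kmf = KaplanMeierFitter().fit(sub.time, sub.event)
            ours = km[km.group == grp].set_index("time").survival
            for t in sub.time:
                assert ours.loc[float(t)] == pytest.approx(
                    float(kmf.survival_function_at_times(t).iloc[0])
                )
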