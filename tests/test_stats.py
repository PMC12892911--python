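"""Statistical layer against brute-force enumeration and closed-form oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import brute_percentile
from zebraphen import simulate as sim
from zebraphen.errors import InsufficientDataError
from zebraphen.stats import (
    anova_tukey,
    bonferroni,
    boxplot_stats,
    fisher_exact_2x2,
    km_logrank,
    kruskal_dunn,
    mann_whitney_u,
)

# ---------------------------------------------------------------------------
# independent oracles


def mwu_exact_enumeration(x, y):
    """Exact two-sided MWU p by enumerating all rank assignments."""
    m, n = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    u_obs = ranks[:m].sum() - m * (m + 1) / 2
    us = []
    for comb in itertools.combinations(range(m + n), m):
        r = np.arange(1, m + n + 1)[list(comb)]
        us.append(r.sum() - m * (m + 1) / 2)
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return u_obs, min(p, 1.0)


def fisher_enumeration(table):
    """Two-sided Fisher p by summing hypergeometric probs <= observed."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    def prob(k):
        return (math.comb(r1, k) * math.comb(n - r1, c1 - k)
                / math.comb(n, c1))
    p_obs = prob(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return sum(prob(k) for k in range(lo, hi + 1)
               if prob(k) <= p_obs * (1 + 1e-9))


def km_by_hand(times, events):
    """Product-limit estimate at each distinct event time."""
    order = np.argsort(times)
    times, events = np.asarray(times)[order], np.asarray(events)[order]
    s = 1.0
    curve = {0.0: 1.0}
    for t in sorted(set(times[events == 1])):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= (at_risk - d) / at_risk
        curve[t] = s
    return curve


# ---------------------------------------------------------------------------


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        x = [1.0, 2.0, 3.0]
        _, p = mann_whitney_u(x, x)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_branch_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, size=7)
        y = rng.normal(0.8, 1, size=6)
        u, p = mann_whitney_u(x, y)
        u_oracle, p_oracle = mwu_exact_enumeration(x, y)
        assert u == pytest.approx(u_oracle)
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=8), rng.normal(size=5)
        ux, px = mann_whitney_u(x, y)
        uy, py = mann_whitney_u(y, x)
        assert px == pytest.approx(py)
        assert uy == pytest.approx(len(x) * len(y) - ux)

    def test_large_or_tied_samples_use_corrected_normal(self):
        rng = np.random.default_rng(2)
        x = np.round(rng.normal(0, 1, size=30), 1)  # ties
        y = np.round(rng.normal(0.5, 1, size=25), 1)
        _, p = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic").pvalue
        assert p == pytest.approx(float(ref))

    def test_empty_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            mann_whitney_u([], [1.0])


class TestFisher:
    def test_balanced_table_p_one(self):
        _, p = fisher_exact_2x2([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table",
        [[[10, 0], [0, 10]], [[8, 2], [3, 7]], [[12, 5], [7, 9]],
         [[1, 9], [6, 4]]],
    )
    def test_matches_hypergeometric_enumeration(self, table):
        _, p = fisher_exact_2x2(table)
        assert p == pytest.approx(fisher_enumeration(table), abs=1e-9)

    def test_transpose_invariance(self):
        t = [[8, 2], [3, 7]]
        _, p1 = fisher_exact_2x2(t)
        _, p2 = fisher_exact_2x2(np.array(t).T)
        assert p1 == pytest.approx(p2)

    def test_zero_margin_degenerate(self):
        _, p = fisher_exact_2x2([[0, 0], [3, 7]])
        assert p == 1.0


class TestKruskalDunn:
    def test_two_group_case_equals_mwu_normal_approx(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 12), rng.normal(0.7, 1, 15)
        res = kruskal_dunn({"a": x, "b": y})
        # KW with 2 groups is algebraically the two-sided MWU normal
        # approximation without continuity correction
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic",
                               use_continuity=False).pvalue
        assert res.pvalue == pytest.approx(float(ref), abs=1e-6)

    def test_identical_groups_all_adjusted_p_one(self):
        res = kruskal_dunn({"a": [2.0, 2.0], "b": [2.0, 2.0],
                            "c": [2.0, 2.0]})
        assert res.statistic == 0.0
        assert res.pvalue == 1.0
        assert (res.pairwise["p_adjusted"] == 1.0).all()

    def test_adjusted_p_bonferroni_of_raw(self):
        rng = np.random.default_rng(3)
        groups = {k: rng.normal(mu, 1, 9)
                  for k, mu in (("a", 0), ("b", 0.5), ("c", 1.5))}
        res = kruskal_dunn(groups)
        m = len(res.pairwise)
        assert m == 3
        for _, row in res.pairwise.iterrows():
            assert row["p_adjusted"] == pytest.approx(
                bonferroni(row["p_raw"], m)
            )
            assert row["p_adjusted"] >= row["p_raw"]

    def test_order_invariance(self):
        g = {"a": [3.0, 1.0, 5.0], "b": [2.0, 6.0, 4.0]}
        g_perm = {"a": [5.0, 3.0, 1.0], "b": [4.0, 2.0, 6.0]}
        assert kruskal_dunn(g).pvalue == pytest.approx(
            kruskal_dunn(g_perm).pvalue
        )


class TestAnovaTukey:
    def test_two_equal_groups_f_is_t_squared(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        res = anova_tukey({"a": x, "b": y})
        tstat = sps.ttest_ind(x, y).statistic
        assert res.statistic == pytest.approx(tstat**2)

    def test_zero_variance_identical_groups(self):
        res = anova_tukey({"a": [4.0, 4.0], "b": [4.0, 4.0]})
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_label_permutation_of_identical_data(self):
        data = [1.0, 2.5, 3.5, 2.0]
        r1 = anova_tukey({"a": data, "b": data})
        r2 = anova_tukey({"b": data, "a": data})
        assert r1.statistic == pytest.approx(r2.statistic)
        pd.testing.assert_frame_equal(r1.pairwise, r2.pairwise)

    def test_power_for_two_sigma_shift(self):
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            g = {"a": rng.normal(0, 1, 10), "b": rng.normal(2, 1, 10)}
            res = anova_tukey(g)
            if (res.pairwise["p_adjusted"] < 0.05).all():
                hits += 1
        assert hits / n_rep >= 0.95


class TestKmLogrank:
    def test_small_instance_matches_hand_computed_product_limit(self):
        # group A: deaths at 1 and 2, censor at 2, death at 5
        times_a = [1.0, 2.0, 2.0, 5.0]
        events_a = [1, 1, 0, 1]
        rec = pd.DataFrame(
            {
                "subject": [f"s{i}" for i in range(6)],
                "group": ["A"] * 4 + ["B"] * 2,
                "time": times_a + [3.0, 4.0],
                "event": events_a + [1, 0],
            }
        )
        res = km_logrank(rec)
        hand = km_by_hand(times_a, events_a)  # {1: .75, 2: .5, 5: 0}
        curve = res["curves"]["A"].set_index("time")["survival"]
        for t, s in hand.items():
            assert curve.loc[t] == pytest.approx(s)

    def test_no_events_curves_one_and_p_undefined(self):
        rec = pd.DataFrame(
            {
                "subject": list("abcd"),
                "group": ["A", "A", "B", "B"],
                "time": [9.0] * 4,
                "event": [0] * 4,
            }
        )
        res = km_logrank(rec)
        assert not res["any_event"]
        for g in ("A", "B"):
            assert (res["curves"][g]["survival"] == 1.0).all()
        assert res["pairwise"]["p_raw"].iloc[0] is None

    def test_pairwise_bonferroni_over_three_groups(self):
        rec = sim.simulate_survival({"a": 0.05, "b": 0.2, "c": 0.6},
                                    n_per_group=30, seed=1)
        res = km_logrank(rec)
        assert len(res["pairwise"]) == 3
        for _, row in res["pairwise"].iterrows():
            assert row["p_adjusted"] == pytest.approx(
                bonferroni(row["p_raw"], 3)
            )

    def test_alive_at_horizon_matches_curve(self):
        rec = sim.simulate_survival({"a": 0.3, "b": 0.05}, n_per_group=40,
                                    seed=2)
        res = km_logrank(rec, horizon=9.0)
        for g in ("a", "b"):
            end = res["curves"][g]["survival"].iloc[-1]
            assert res["alive_at_horizon"][g] == pytest.approx(end)


class TestBoxplot:
    def test_elements_match_brute_force_quantiles(self):
        rng = np.random.default_rng(0)
        v = rng.normal(10, 3, size=200)
        v[:3] = [40.0, -30.0, 45.0]  # clear outliers
        out = boxplot_stats(v)
        assert out["median"] == pytest.approx(brute_percentile(v, 50))
        assert out["q1"] == pytest.approx(brute_percentile(v, 25))
        assert out["q3"] == pytest.approx(brute_percentile(v, 75))
        iqr = out["q3"] - out["q1"]
        inside = v[(v >= out["q1"] - 1.5 * iqr) & (v <= out["q3"] + 1.5 * iqr)]
        assert out["whisker_lo"] == inside.min()
        assert out["whisker_hi"] == inside.max()
        assert set(out["outliers"]) == {40.0, -30.0, 45.0}
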