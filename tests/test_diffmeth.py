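import numpy as np
import pytest
from scipy import stats

import methpanel as mp
from tests.conftest import make_groups_bm


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def anova_oracle(groups):
    """Textbook sums-of-squares one-way ANOVA, computed with plain loops."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ssb = 0.0
    ssw = 0.0
    for g in groups:
        m = sum(g) / len(g)
        ssb += len(g) * (m - grand) ** 2
        for v in g:
            ssw += (v - m) ** 2
    k, n = len(groups), len(all_vals)
    f = (ssb / (k - 1)) / (ssw / (n - k))
    return f, stats.f.sf(f, k - 1, n - k)


def studentized_range_sf_oracle(q, k, df, n_nodes=240):
    """Survival function of the studentized range, by direct quadrature of
    its defining double integral (independent of scipy's implementation).

    P(Q <= q) = \\int_0^inf g_df(s) * k * \\int phi(z)
                [Phi(z) - Phi(z - q s)]^(k-1) dz ds
    where g_df is the density of chi_df / sqrt(df).
    """
    # outer nodes over s in (0, 4): chi_df/sqrt(df) concentrates near 1
    xs, ws = np.polynomial.legendre.leggauss(n_nodes)
    s = 2.0 + 2.0 * xs          # map [-1,1] -> (0, 4)
    w_s = 2.0 * ws
    # inner nodes over z in (-9, 9)
    xz, wz = np.polynomial.legendre.leggauss(n_nodes)
    z = 9.0 * xz
    w_z = 9.0 * wz

    # chi_df/sqrt(df) density, written out explicitly
    from math import lgamma
    log_gs = ((df / 2.0) * np.log(df / 2.0) + (df - 1) * np.log(s)
              - df * s ** 2 / 2.0 - lgamma(df / 2.0)
              + np.log(2.0))
    g = np.exp(log_gs)

    phi_z = stats.norm.pdf(z)
    cdf_z = stats.norm.cdf(z)
    # inner integral for each outer node: u = q * s
    u = q * s
    inner = np.empty_like(s)
    for i, ui in enumerate(u):
        inner[i] = np.sum(
            w_z * phi_z * (cdf_z - stats.norm.cdf(z - ui)) ** (k - 1))
    cdf = float(np.sum(w_s * g * k * inner))
    return 1.0 - min(max(cdf, 0.0), 1.0)


def test_studentized_range_oracle_is_sound():
    """The quadrature oracle reproduces scipy's distribution itself."""
    for q, k, df in [(3.5, 3, 12), (2.0, 4, 20), (5.0, 8, 40)]:
        assert studentized_range_sf_oracle(q, k, df) == pytest.approx(
            stats.studentized_range.sf(q, k, df), abs=1e-7)


# ---------------------------------------------------------------------------
# one_way_anova
# ---------------------------------------------------------------------------

class TestOneWayAnova:
    def test_degenerate_constant_groups(self):
        bm, labels = make_groups_bm({"A": [0.3, 0.3], "B": [0.3, 0.3]})
        f, p = mp.one_way_anova(bm.values_for("p1"), labels)
        assert np.isnan(f) and np.isnan(p)

    def test_perfect_separation(self):
        bm, labels = make_groups_bm({"A": [0.1, 0.1], "B": [0.9, 0.9]})
        f, p = mp.one_way_anova(bm.values_for("p1"), labels)
        assert np.isinf(f) and p == 0.0

    def test_three_group_textbook_value(self):
        groups = {"A": [0.1, 0.2, 0.15], "B": [0.3, 0.35, 0.4],
                  "C": [0.7, 0.8, 0.75]}
        bm, labels = make_groups_bm(groups)
        f, p = mp.one_way_anova(bm.values_for("p1"), labels)
        f_exp, p_exp = anova_oracle(list(groups.values()))
        assert f == pytest.approx(f_exp, abs=1e-8)
        assert p == pytest.approx(p_exp, abs=1e-8)

    def test_matches_scipy_and_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = rng.integers(2, 6)
            groups = {f"g{c}": rng.random(rng.integers(3, 9)).tolist()
                      for c in range(k)}
            bm, labels = make_groups_bm(groups)
            f, p = mp.one_way_anova(bm.values_for("p1"), labels)
            f_sp, p_sp = stats.f_oneway(*groups.values())
            f_or, p_or = anova_oracle(list(groups.values()))
            assert f == pytest.approx(f_sp, abs=1e-6)
            assert f == pytest.approx(f_or, abs=1e-6)
            assert p == pytest.approx(p_or, abs=1e-8)

    def test_small_class_flagged_unevaluable(self):
        bm, labels = make_groups_bm({"A": [0.1], "B": [0.5, 0.6]})
        f, p = mp.one_way_anova(bm.values_for("p1"), labels)
        assert np.isnan(f)

    def test_shift_invariance(self):
        """F is unchanged when a constant is added to every value."""
        rng = np.random.default_rng(1)
        groups = {c: (0.2 * rng.random(6)).tolist() for c in "ABC"}
        shifted = {c: [v + 0.3 for v in vals] for c, vals in groups.items()}
        f1, _ = mp.one_way_anova(make_groups_bm(groups)[0].values_for("p1"),
                                 make_groups_bm(groups)[1])
        f2, _ = mp.one_way_anova(
            make_groups_bm(shifted)[0].values_for("p1"),
            make_groups_bm(shifted)[1])
        assert f1 == pytest.approx(f2, rel=1e-9)


# ---------------------------------------------------------------------------
# tukey_hsd
# ---------------------------------------------------------------------------

class TestTukeyHSD:
    def test_two_groups_equals_pooled_t_test(self):
        a = [0.12, 0.18, 0.22, 0.16]
        b = [0.35, 0.31, 0.42, 0.38, 0.36]
        bm, labels = make_groups_bm({"A": a, "B": b})
        res = mp.tukey_hsd(bm.values_for("p1"), labels)
        t, p_t = stats.ttest_ind(a, b, equal_var=True)
        assert res["p_adj"].iloc[0] == pytest.approx(p_t, abs=1e-9)
        assert res["delta_beta"].iloc[0] == pytest.approx(
            np.mean(a) - np.mean(b))

    def test_equal_means_gives_p_near_one(self):
        bm, labels = make_groups_bm(
            {"A": [0.4, 0.5, 0.6], "B": [0.45, 0.5, 0.55],
             "C": [0.5, 0.4, 0.6]})
        res = mp.tukey_hsd(bm.values_for("p1"), labels)
        assert (res["p_adj"] > 0.9).all()

    def test_three_group_matches_independent_oracle(self):
        groups = {"A": [0.10, 0.15, 0.12, 0.18],
                  "B": [0.30, 0.28, 0.35],
                  "C": [0.55, 0.60, 0.52, 0.58, 0.61]}
        bm, labels = make_groups_bm(groups)
        res = mp.tukey_hsd(bm.values_for("p1"), labels)
        ns = [len(g) for g in groups.values()]
        means = [np.mean(g) for g in groups.values()]
        ssw = sum(((np.array(g) - m) ** 2).sum()
                  for g, m in zip(groups.values(), means))
        df = sum(ns) - 3
        msw = ssw / df
        pairs = [(0, 1), (0, 2), (1, 2)]
        for row, (i, j) in zip(res.itertuples(), pairs):
            q = abs(means[i] - means[j]) / np.sqrt(
                msw / 2 * (1 / ns[i] + 1 / ns[j]))
            assert row.p_adj == pytest.approx(
                studentized_range_sf_oracle(q, 3, df), abs=1e-6)

    def test_matches_scipy_tukey_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            k = rng.integers(3, 6)
            groups = [rng.random(rng.integers(4, 9)) for _ in range(k)]
            bm, labels = make_groups_bm(
                {f"g{c}": g.tolist() for c, g in enumerate(groups)})
            mine = mp.tukey_hsd(bm.values_for("p1"), labels)
            ref = stats.tukey_hsd(*groups)
            for row_i, row in enumerate(mine.itertuples()):
                a = int(row.class_a[1:])
                b = int(row.class_b[1:])
                assert row.p_adj == pytest.approx(
                    ref.pvalue[a, b], abs=1e-6)


# ---------------------------------------------------------------------------
# select_candidate_cpgs
# ---------------------------------------------------------------------------

class TestCandidateFilter:
    def test_planted_probes_pass_one_vs_all(self, small_cohort):
        res = mp.select_candidate_cpgs(small_cohort["bm"],
                                       small_cohort["labels"])
        planted = set(small_cohort["truth"].all_planted)
        assert planted <= set(res.candidates)
        # qualifying class is the planted class
        for cls, probes in small_cohort["truth"].planted.items():
            for p in probes:
                assert res.table.loc[p, "qualifying_class"] == cls

    def test_small_shift_fails_delta_threshold(self):
        cfg = mp.SimConfig(n_classes=4, samples_per_class=20,
                           n_probes=200, informative_per_class=5,
                           effect_delta=0.1, precision=30.0, seed=21)
        bm, labels, truth, _ = mp.generate_beta_dataset(cfg)
        res = mp.select_candidate_cpgs(bm, labels,
                                       mp.FilterConfig(delta=0.2))
        assert not set(truth.all_planted) & set(res.candidates)

    def test_constant_probe_fails(self):
        bm, labels = make_groups_bm({"A": [0.5] * 4, "B": [0.5] * 4,
                                     "C": [0.5] * 4})
        res = mp.select_candidate_cpgs(bm, labels)
        assert res.candidates == []
        assert not res.table["pass"].iloc[0]

    def test_one_vs_all_subset_of_any_pair(self, small_cohort):
        bm, labels = small_cohort["bm"], small_cohort["labels"]
        ova = mp.select_candidate_cpgs(
            bm, labels, mp.FilterConfig(criterion="one_vs_all"))
        ap = mp.select_candidate_cpgs(
            bm, labels, mp.FilterConfig(criterion="any_pair"))
        assert set(ova.candidates) <= set(ap.candidates)

    def test_single_probe_agrees_with_vectorized_path(self, small_cohort):
        """Matrix-level ANOVA equals the single-probe computation."""
        bm, labels = small_cohort["bm"], small_cohort["labels"]
        res = mp.select_candidate_cpgs(bm, labels)
        rng = np.random.default_rng(5)
        for p in rng.choice(bm.probe_ids, 10, replace=False):
            f, pv = mp.one_way_anova(bm.values_for(p), labels)
            assert res.table.loc[p, "F"] == pytest.approx(f, rel=1e-9)
            assert res.table.loc[p, "p_anova"] == pytest.approx(
                pv, abs=1e-12)

    def test_pass_implies_significant_anova(self, small_cohort):
        res = mp.select_candidate_cpgs(small_cohort["bm"],
                                       small_cohort["labels"])
        passed = res.table[res.table["pass"]]
        assert (passed["p_anova"] < res.config.alpha).all()

    def test_missing_values_complete_case(self):
        bm, labels = make_groups_bm(
            {"A": [0.1, 0.12, np.nan, 0.11], "B": [0.8, 0.82, 0.81, 0.79],
             "C": [0.4, 0.42, 0.41, 0.43]})
        res = mp.select_candidate_cpgs(bm, labels,
                                       mp.FilterConfig(alpha=0.05))
        f_drop, _ = mp.one_way_anova(bm.values_for("p1"), labels)
        assert res.table["F"].iloc[0] == pytest.approx(f_drop, rel=1e-9)

    def test_empty_result_warns(self):
        bm, labels = make_groups_bm(
            {"A": [0.50, 0.51, 0.49], "B": [0.50, 0.49, 0.51]})
        with pytest.warns(UserWarning, match="no probe passed"):
            res = mp.select_candidate_cpgs(bm, labels)
        assert res.candidates == []
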