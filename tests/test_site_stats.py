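"""Proportion/count tests, PAC summaries and ratio comparisons, PCA and
ward.D clustering."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pacmeth import simulate, site_stats
from .conftest import simulate_comparison


def fisher_oracle(table):
    """Independent enumeration oracle: exact rational two-sided Fisher p
    via factorials and Fraction arithmetic."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0
    f = math.factorial

    def prob(x):
        y = c1 - x
        return Fraction(f(r1) * f(r2) * f(c1) * f(n - c1), f(n) * f(x) * f(r1 - x) * f(y) * f(r2 - y))

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs:
            total += px
    return float(total)


class TestTwoPropChisq:
    @pytest.mark.parametrize(
        "x1,x2,expected",
        [(770, 435, 93.14), (759, 435, 87.90)],
    )
    def test_printed_dmr_count_values(self, x1, x2, expected):
        for m in (3.0e6, 3.25e6):
            chi2, p = site_stats.two_prop_chisq(x1, x2, m)
            assert chi2 == pytest.approx(expected, abs=0.25)
            assert p < 1e-4

    def test_large_n_limit(self):
        for x1, x2 in [(770, 435), (759, 435)]:
            limit = (x1 - x2) ** 2 / (x1 + x2)
            chi2, _ = site_stats.two_prop_chisq(x1, x2, 1e8)
            assert abs(chi2 - limit) < 0.01

    def test_equal_counts_zero(self):
        assert site_stats.two_prop_chisq(5, 5, 100) == (0.0, 1.0)

    def test_yates_correction_lowers_statistic(self):
        plain, _ = site_stats.two_prop_chisq(770, 435, 3.25e6)
        yates, _ = site_stats.two_prop_chisq(770, 435, 3.25e6, correction=True)
        assert yates < plain


class TestFisherExact2x2:
    def test_hand_enumerated_example(self):
        assert site_stats.fisher_exact_2x2([[1, 9], [11, 3]]) == pytest.approx(0.00276, abs=5e-6)

    def test_identical_rows_p_one(self):
        assert site_stats.fisher_exact_2x2([[4, 6], [4, 6]]) == 1.0

    def test_empty_margin_p_one(self):
        assert site_stats.fisher_exact_2x2([[0, 0], [3, 5]]) == 1.0

    def test_direction_table_from_printed_totals(self):
        # 770 x 5.19% vs 759 x 57.44% hypermethylated
        assert site_stats.fisher_exact_2x2([[40, 730], [436, 323]]) <= 1e-4

    def test_matches_independent_oracle_on_random_tables(self, rng):
        for _ in range(300):
            t = rng.integers(0, 16, size=(2, 2))
            assert site_stats.fisher_exact_2x2(t) == fisher_oracle(t.tolist())

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(200):
            t = rng.integers(0, 12, size=(2, 2))
            ours = site_stats.fisher_exact_2x2(t)
            ref = stats.fisher_exact(t)[1]
            assert ours == pytest.approx(ref, rel=1e-6, abs=1e-12)


class TestFisherExactRxc:
    def test_proportional_columns_near_one(self):
        p = site_stats.fisher_exact_rxc([[10, 20, 30], [20, 40, 60]], rounds=4000, seed=1)
        assert p > 0.5

    def test_agrees_with_2x2_within_mc_error(self, rng):
        for _ in range(10):
            t = rng.integers(0, 12, size=(2, 2))
            exact = site_stats.fisher_exact_2x2(t)
            rounds = 4000
            mc = site_stats.fisher_exact_rxc(t, rounds=rounds, seed=5)
            se = np.sqrt(max(exact * (1 - exact), 1e-6) / rounds)
            assert abs(mc - exact) <= 3 * se + 2.0 / rounds

    def test_three_site_direction_table_significant(self):
        p = site_stats.fisher_exact_rxc(
            [[40, 43, 436], [730, 392, 323]], rounds=10_000, seed=2
        )
        assert p <= 1e-4

    def test_wide_table_rejected(self):
        with pytest.raises(ValueError):
            site_stats.fisher_exact_rxc(np.ones((2, 6), dtype=int))


class TestPacSummaries:
    def test_single_bird_degenerate_stats(self):
        table = simulate.generate_pac_table([simulate.SiteProfile("X", 2.0, 1)], seed=3)
        s = site_stats.summarize_pac(table, "X")
        assert (s["mean"] == s["median"]).all()
        assert (s["mean"] == s["min"]).all() and (s["mean"] == s["max"]).all()
        assert (s["sd"] == 0).all()

    def test_total_dominates_usepa_subset(self):
        table = simulate.generate_pac_table(simulate.default_site_profiles(), seed=4)
        for site in table["site"].unique():
            s = site_stats.summarize_pac(table, site)
            assert s.loc["ΣPAC", "mean"] >= s.loc["ΣUSEPA16", "mean"]

    def test_reference_usepa_round_trip(self):
        """The REFERENCE profile (mean USEPA16 1.89 ng/g) is recovered
        within 15% at n=50."""
        prof = simulate.SiteProfile("REFERENCE", 3.66, 50, mean_usepa=1.89)
        table = simulate.generate_pac_table([prof], seed=6)
        s = site_stats.summarize_pac(table, "REFERENCE")
        assert s.loc["ΣUSEPA16", "mean"] == pytest.approx(1.89, rel=0.15)


class TestRatioTests:
    def test_identical_groups_not_significant(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        h, p = site_stats.kruskal_wallis([g, g.copy(), g.copy()])
        assert h == pytest.approx(0.0, abs=1e-9)
        assert p > 0.9

    def test_hand_ranked_kruskal(self):
        h, _ = site_stats.kruskal_wallis(
            [np.array([1, 2, 3]), np.array([4, 5, 6]), np.array([7, 8, 9])]
        )
        assert h == pytest.approx(7.2)

    def test_site_pattern_matches_study(self):
        """Calibrated site profiles (4.99 / 1.81 / 0.63, n=20): SEEP differs
        from both anthropogenic sites (BH p < 0.001) while SPILL vs SHIP is
        not significant, in >= 90% of replicates."""
        profiles = [
            simulate.SiteProfile("SPILL", 4.99, 20, tail_fraction=0.3),
            simulate.SiteProfile("SHIP", 1.81, 20),
            simulate.SiteProfile("SEEP", 0.63, 20),
        ]
        seep_hits = spillship_ns = reps = 50
        seep_ok = ns_ok = 0
        for rep in range(reps):
            table = simulate.generate_pac_table(profiles, seed=1000 + rep)
            groups = {
                s: site_stats.lmw_hmw_ratio(table, s)[1].to_numpy()
                for s in ("SPILL", "SHIP", "SEEP")
            }
            mat = site_stats.pairwise_wilcoxon_bh(groups)
            if mat.loc["SEEP", "SPILL"] < 1e-3 and mat.loc["SEEP", "SHIP"] < 1e-3:
                seep_ok += 1
            if mat.loc["SPILL", "SHIP"] > 0.05:
                ns_ok += 1
        assert seep_ok >= 0.9 * reps
        assert ns_ok >= 0.9 * reps


class TestPca:
    def test_distinct_sample_separates_on_pc1(self):
        _, _, m = simulate_comparison(seed=61, n_cpg=300, n_per_group=(1, 2))
        # make the two EXPOSED samples identical and REFERENCE distinct
        idx = m.group_index("EXPOSED")
        m.n_meth[:, idx[1]] = m.n_meth[:, idx[0]]
        m.n_total[:, idx[1]] = m.n_total[:, idx[0]]
        scores, _ = site_stats.pca_percent_meth(m)
        ref = m.group_index("REFERENCE")[0]
        others = [i for i in range(3) if i != ref]
        gap = abs(scores.iloc[ref, 0] - scores.iloc[others, 0].mean())
        within = abs(scores.iloc[others[0], 0] - scores.iloc[others[1], 0])
        assert gap > within

    def test_percent_variance_sums_to_100(self):
        _, _, m = simulate_comparison(seed=62, n_cpg=400)
        _, pct = site_stats.pca_percent_meth(m)
        assert pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_group_shift_separates_groups(self):
        """A global exposed-group shift shows up as PC1 separation
        (positive silhouette) in >= 90% of replicates."""
        from sklearn.metrics import silhouette_score

        hits = 0
        reps = 20
        for rep in range(reps):
            maps = simulate.generate_genome_layout(1, 120_000, 400, 50, seed=700 + rep)
            dmrs = simulate.plant_dmrs(maps, 25, delta=0.3, hyper_fraction=0.5, seed=800 + rep)
            tables, sheet = simulate.generate_methylomes(maps, dmrs, (6, 6), seed=900 + rep)
            from pacmeth import meth_io

            m = meth_io.unite(tables, sheet)
            scores, _ = site_stats.pca_percent_meth(m)
            labels = (m.samples["group"] == "EXPOSED").astype(int)
            if silhouette_score(scores.iloc[:, :1], labels) > 0:
                hits += 1
        assert hits >= 0.9 * reps


class TestHclustWard:
    def test_correlated_pair_merges_first(self):
        _, _, m = simulate_comparison(seed=63, n_cpg=300, n_per_group=(2, 2))
        idx = m.group_index("EXPOSED")
        m.n_meth[:, idx[1]] = m.n_meth[:, idx[0]]
        m.n_total[:, idx[1]] = m.n_total[:, idx[0]]
        Z, labels = site_stats.hclust_ward(m)
        first = {labels[int(Z[0, 0])], labels[int(Z[0, 1])]}
        assert first == {"EXPOSED_01", "EXPOSED_02"}
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-9)

    def test_heights_nondecreasing(self):
        _, _, m = simulate_comparison(seed=64, n_cpg=400)
        Z, _ = site_stats.hclust_ward(m)
        assert (np.diff(Z[:, 2]) >= -1e-9).all()

    def test_two_planted_clusters_recovered(self):
        """Cutting at k=2 recovers the exposure groups in >= 90% of
        replicates with a strong planted shift."""
        from pacmeth import meth_io

        hits = 0
        reps = 20
        for rep in range(reps):
            maps = simulate.generate_genome_layout(1, 120_000, 400, 50, seed=300 + rep)
            dmrs = simulate.plant_dmrs(maps, 25, delta=0.3, hyper_fraction=0.5, seed=400 + rep)
            tables, sheet = simulate.generate_methylomes(maps, dmrs, (4, 4), seed=500 + rep)
            m = meth_io.unite(tables, sheet)
            Z, labels = site_stats.hclust_ward(m)
            cut = site_stats.cut_tree(Z, 2)
            truth = (m.samples["group"] == "EXPOSED").astype(int).to_numpy()
            if (cut == truth).all() or (cut == 1 - truth).all():
                hits += 1
        assert hits >= 0.9 * reps
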