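"""Count-file parsing, destranding, filtering, normalization, uniting and
the lane overdispersion diagnostic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pacmeth import meth_io, simulate
from .conftest import make_table, simulate_comparison


class TestReadWrite:
    def test_coverage_line_arithmetic(self, tmp_path):
        p = tmp_path / "s.cov"
        p.write_text("chr1\t100\t100\t50.0\t5\t5\n")
        t = meth_io.read_bismark_coverage(p)
        rec = t.data.iloc[0]
        assert (rec["chrom"], rec["pos"], rec["strand"]) == ("chr1", 100, "+")
        assert (rec["n_meth"], rec["n_total"]) == (5, 10)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.cov"
        p.write_text("")
        assert len(meth_io.read_bismark_coverage(p)) == 0

    def test_inconsistent_percent_warns_counts_win(self, tmp_path):
        p = tmp_path / "s.cov"
        p.write_text("chr1\t100\t100\t60.0\t5\t5\n")
        with pytest.warns(UserWarning, match="counts"):
            t = meth_io.read_bismark_coverage(p)
        assert t.data.iloc[0]["n_meth"] == 5 and t.data.iloc[0]["n_total"] == 10

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "s.cov"
        p.write_text("chr1\t100\t100\t50.0\t5\t5\nchr1\tXX\t200\t50.0\t5\t5\n")
        with pytest.raises(ValueError, match="line 2"):
            meth_io.read_bismark_coverage(p)

    def test_cytosine_report_dialect_keeps_strand(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("chr1\t100\t+\t5\t5\tCpG\tCGA\nchr1\t101\t-\t3\t3\tCpG\tCGT\n")
        t = meth_io.read_bismark_coverage(p)
        assert list(t.data["strand"]) == ["+", "-"]
        assert list(t.data["n_total"]) == [10, 6]

    def test_round_trip_identity(self, tmp_path):
        maps = simulate.generate_genome_layout(1, 50_000, 300, 50, seed=6)
        tables, _ = simulate.generate_methylomes(maps, [], (1, 1), seed=7)
        p = tmp_path / "rt.cov"
        meth_io.write_bismark_coverage(tables[0], p)
        back = meth_io.read_bismark_coverage(p, sample_id=tables[0].sample_id)
        pd.testing.assert_frame_equal(back.data, tables[0].data, check_dtype=False)


class TestDestrand:
    def test_merge_and_orphan(self):
        t = make_table(
            [("chr1", 100, "+", 5, 10), ("chr1", 101, "-", 3, 6), ("chr1", 201, "-", 3, 6)]
        )
        d = meth_io.destrand(t).data
        assert len(d) == 2
        assert tuple(d.iloc[0][["pos", "n_meth", "n_total"]]) == (100, 8, 16)
        assert tuple(d.iloc[1][["pos", "n_meth", "n_total"]]) == (200, 3, 6)
        assert (d["strand"] == "+").all()

    def test_halves_records_when_both_strands(self):
        recs = [("chr1", p, "+", 2, 5) for p in range(100, 200, 10)]
        recs += [("chr1", p + 1, "-", 1, 4) for p in range(100, 200, 10)]
        d = meth_io.destrand(make_table(recs))
        assert len(d) == len(recs) // 2

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.tuples(
                st.integers(1, 50),
                st.sampled_from("+-"),
                st.integers(0, 5),
                st.integers(0, 10),
            ),
            min_size=0,
            max_size=30,
            unique_by=lambda r: (r[0], r[1]),
        )
    )
    def test_conservation_property(self, recs):
        rows = [("chr1", pos * 3, s, min(m, n), n) for pos, s, m, n in recs]
        t = make_table(rows)
        d = meth_io.destrand(t)
        assert d.data["n_meth"].sum() == t.data["n_meth"].sum()
        assert d.data["n_total"].sum() == t.data["n_total"].sum()


class TestFilterByCoverage:
    def test_paper_thresholds(self):
        t = make_table([("chr1", p, "+", 0, n) for p, n in zip((10, 20, 30, 40), (4, 5, 100, 101))])
        kept = meth_io.filter_by_coverage(t, lo=5, hi=100, high_percentile=99.9)
        assert list(kept.data["n_total"]) == [5, 100]

    def test_all_below_lo_empty(self):
        t = make_table([("chr1", 10, "+", 0, 2), ("chr1", 20, "+", 1, 3)])
        assert len(meth_io.filter_by_coverage(t)) == 0

    def test_percentile_removes_extreme(self):
        rows = [("chr1", 2 * i + 2, "+", 5, 20) for i in range(999)]
        rows.append(("chr1", 4000, "+", 5, 10_000))
        t = make_table(rows)
        kept = meth_io.filter_by_coverage(t, lo=5, hi=100_000, high_percentile=99.9)
        assert 10_000 not in set(kept.data["n_total"])
        assert len(kept) == 999

    def test_idempotent(self):
        rows = [("chr1", 2 * i + 2, "+", i % 4, 4 + i % 30) for i in range(200)]
        once = meth_io.filter_by_coverage(make_table(rows))
        twice = meth_io.filter_by_coverage(once)
        pd.testing.assert_frame_equal(once.data, twice.data)


class TestNormalizeCoverage:
    def test_identical_samples_identity(self):
        rows = [("chr1", 2 * i + 2, "+", 1, 10) for i in range(20)]
        a, b = make_table(rows, "a"), make_table(rows, "b")
        out, rep = meth_io.normalize_coverage([a, b])
        assert all(f == 1.0 for f in rep.scaling_factors.values())
        pd.testing.assert_frame_equal(out[0].data, a.data)

    def test_median_of_medians_factors(self):
        a = make_table([("chr1", 2 * i + 2, "+", 2, 10) for i in range(9)], "a")
        b = make_table([("chr1", 2 * i + 2, "+", 2, 20) for i in range(9)], "b")
        _, rep = meth_io.normalize_coverage([a, b])
        assert rep.scaling_factors == {"a": 1.5, "b": 0.75}

    def test_proportion_preserved_within_one_read(self, rng):
        rows = [
            ("chr1", 2 * i + 2, "+", int(m), int(n))
            for i, (n, m) in enumerate(
                zip(rng.integers(5, 80, 300), rng.integers(0, 5, 300))
            )
        ]
        a = make_table(rows, "a")
        b = make_table([(c, p, s, m, n * 3) for c, p, s, m, n in rows], "b")
        out, _ = meth_io.normalize_coverage([a, b])
        for before, after in zip([a, b], out):
            p0 = before.data["n_meth"] / before.data["n_total"]
            p1 = after.data["n_meth"] / after.data["n_total"]
            assert (np.abs(p0 - p1) <= 1.0 / after.data["n_total"] + 1e-12).all()

    def test_zero_median_raises(self):
        a = make_table([("chr1", 2, "+", 0, 0)], "a")
        b = make_table([("chr1", 2, "+", 0, 5)], "b")
        with pytest.raises(ValueError, match="median"):
            meth_io.normalize_coverage([a, b])


class TestUnite:
    def _sheet(self, ids, group="G", lane=0):
        return pd.DataFrame({"sample_id": ids, "group": group, "lane": lane})

    def test_threshold_ceiling_rule(self):
        # 5 samples, locus A covered by all, locus B by 3 (dropped at 0.8),
        # locus C by 4 (kept: ceiling(0.8*5)=4)
        tables = []
        for i in range(5):
            rows = [("chr1", 10, "+", 1, 5)]
            if i < 3:
                rows.append(("chr1", 20, "+", 1, 5))
            if i < 4:
                rows.append(("chr1", 30, "+", 1, 5))
            tables.append(make_table(rows, f"s{i}"))
        m = meth_io.unite(tables, self._sheet([f"s{i}" for i in range(5)]))
        assert list(m.loci["pos"]) == [10, 30]

    def test_unknown_sample_raises(self):
        tables = [make_table([("chr1", 10, "+", 1, 5)], "sX")]
        with pytest.raises(ValueError, match="sX"):
            meth_io.unite(tables, self._sheet(["s0"]))

    def test_sample_order_permutation_invariant(self):
        tables, sheet = simulate.generate_methylomes(
            simulate.generate_genome_layout(1, 300_000, 300, 50, seed=3), [], (3, 3), seed=5
        )
        m_fwd = meth_io.unite(tables, sheet)
        m_rev = meth_io.unite(tables[::-1], sheet)
        pd.testing.assert_frame_equal(m_fwd.loci, m_rev.loci)
        np.testing.assert_array_equal(m_fwd.n_total, m_rev.n_total)

    def test_matrix_tsv_round_trip(self, tmp_path):
        _, _, m = simulate_comparison(seed=5, n_cpg=200)
        p = tmp_path / "u.tsv"
        m.to_tsv(p)
        back = meth_io.UnitedMatrix.from_tsv(p)
        pd.testing.assert_frame_equal(back.loci, m.loci, check_dtype=False)
        np.testing.assert_allclose(back.n_meth, m.n_meth)
        assert list(back.samples["group"]) == list(m.samples["group"])


class TestLaneOverdispersion:
    def test_null_lambda_near_one(self):
        # identical lane behaviour, pure binomial sampling
        _, _, m = simulate_comparison(
            seed=17, n_cpg=3000, dispersion=0.0, preprocess=False
        )
        lam = meth_io.lane_overdispersion(m)
        assert 0.8 < lam < 1.2

    def test_lane_offset_inflates_lambda(self):
        _, _, m0 = simulate_comparison(seed=19, n_cpg=1500, dispersion=0.0, preprocess=False)
        _, _, m1 = simulate_comparison(
            seed=19, n_cpg=1500, dispersion=0.0, lane_offset=0.2, preprocess=False
        )
        assert meth_io.lane_overdispersion(m1) > max(1.5, meth_io.lane_overdispersion(m0))

    def test_single_lane_raises(self):
        _, _, m = simulate_comparison(seed=4, n_cpg=200, n_lanes=1, preprocess=False)
        with pytest.raises(ValueError, match="lane"):
            meth_io.lane_overdispersion(m)
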