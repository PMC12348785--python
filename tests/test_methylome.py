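"""Methylation levels, the DMR filter cascade, and distribution summaries."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_sample
from oracles import bh_stepup, fisher_two_sided
from rddmscan import methylome as me
from rddmscan import refmodel as rm
from statsmodels.stats.multitest import multipletests


class TestSiteLevel:
    @pytest.mark.parametrize("meth,total,expected", [(30, 60, 0.5), (0, 10, 0.0), (7, 7, 1.0)])
    def test_ratio(self, meth, total, expected):
        assert me.site_level(meth, total) == expected

    def test_uncovered_is_nan(self):
        assert np.isnan(me.site_level(0, 0))

    def test_meth_exceeding_total_errors(self):
        with pytest.raises(ValueError):
            me.site_level(5, 4)


class TestGlobalLevel:
    def test_pooled_ratio_not_mean_of_fractions(self):
        s = make_sample([("c", 1, "+", "CG", 9, 10), ("c", 2, "+", "CG", 1, 10)])
        assert me.global_level(s, "CG") == 50.0
        # the unweighted mean of site fractions is the same here; make them differ
        s2 = make_sample([("c", 1, "+", "CG", 9, 10), ("c", 2, "+", "CG", 10, 100)])
        assert me.global_level(s2, "CG") == pytest.approx(100 * 19 / 110)
        assert me.global_level(s2, "CG", pooled=False) == pytest.approx(100 * (0.9 + 0.1) / 2)

    def test_all_unmethylated(self):
        s = make_sample([("c", i, "+", "CHH", 0, 10) for i in range(1, 6)])
        assert me.global_level(s, "CHH") == 0.0

    def test_no_covered_sites_nan(self):
        s = make_sample([("c", 1, "+", "CG", 0, 0)])
        assert np.isnan(me.global_level(s, "CG"))
        assert np.isnan(me.global_level(s, "CHH"))


class TestRegionProfile:
    def test_uniform_methylome_is_flat(self, toy_genes):
        rows = [("c", p, "+", "CG", 3, 10) for p in range(1, 30_001, 37)]
        s = make_sample(rows)
        prof = me.region_profile(s, toy_genes, rm.RegionSpec(), "CG", {"c": 30_000})
        for label, value in prof["regions"].items():
            assert value == pytest.approx(30.0), label

    def test_hand_computed_two_gene_toy(self, toy_genes):
        rows = [
            ("c", 10_300, "+", "CG", 8, 10),   # exon of gP
            ("c", 10_350, "+", "CG", 2, 10),   # exon of gP
            ("c", 10_800, "+", "CG", 5, 5),    # intron of gP
            ("c", 9_950, "+", "CG", 0, 10),    # upstream2k of gP
        ]
        prof = me.region_profile(make_sample(rows), toy_genes, rm.RegionSpec(), "CG", {"c": 30_000})
        assert prof["regions"]["exon"] == pytest.approx(100 * 10 / 20)
        assert prof["regions"]["intron"] == pytest.approx(100.0)
        assert prof["regions"]["upstream2k"] == pytest.approx(0.0)

    def test_empty_region_is_nan(self, toy_genes):
        rows = [("c", 10_300, "+", "CG", 8, 10)]
        prof = me.region_profile(make_sample(rows), toy_genes, rm.RegionSpec(), "CG", {"c": 30_000})
        assert np.isnan(prof["regions"]["3UTR"])


def window_samples(meth_t, tot_t, meth_c, tot_c, context="CG"):
    """One 1-kb window with the given pooled counts split over two sites."""
    def split(m, t):
        return [("c", 101, "+", context, m // 2, t // 2), ("c", 201, "+", context, m - m // 2, t - t // 2)]

    treat = make_sample(split(meth_t, tot_t), "t", 10)
    ctrl = make_sample(split(meth_c, tot_c), "ctl", 0)
    return [treat], [ctrl]


class TestDmrFilterCascade:
    def test_clear_hyper_window_called(self):
        treat, ctrl = window_samples(48, 60, 12, 60)
        out = me.call_dmrs(treat, ctrl, "CG", me.DmrParams())
        assert len(out) == 1
        row = out.iloc[0]
        assert row["polarity"] == "hyper"
        assert row["diff"] == pytest.approx(60.0)
        assert row["fold_change"] == pytest.approx(4.0)
        assert row["p"] == pytest.approx(fisher_two_sided(48, 12, 12, 48), abs=1e-12)
        assert (row["start"], row["end"]) == (1, 1000)

    def test_low_coverage_window_excluded_before_testing(self):
        treat, ctrl = window_samples(25, 29, 1, 60)  # treat pooled total 29 < 30
        out = me.call_dmrs(treat, ctrl, "CG", me.DmrParams())
        assert len(out) == 0

    def test_fold_change_filter_rejects_small_ratio(self):
        # 40% vs 24% at high depth: diff 16 > 15 but FC 1.67 < 2
        treat, ctrl = window_samples(400, 1000, 240, 1000)
        out = me.call_dmrs(treat, ctrl, "CG", me.DmrParams())
        assert len(out) == 0

    def test_diff_filter_rejects_small_difference(self):
        # 50% vs 42% at high depth: diff 8 <= 15, regardless of p
        treat, ctrl = window_samples(2500, 5000, 2100, 5000)
        out = me.call_dmrs(treat, ctrl, "CG", me.DmrParams())
        assert len(out) == 0

    def test_zero_control_level_gives_infinite_fc(self):
        treat, ctrl = window_samples(40, 60, 0, 60, context="CHH")
        out = me.call_dmrs(treat, ctrl, "CHH", me.DmrParams())
        assert len(out) == 1
        assert np.isinf(out.iloc[0]["fold_change"])

    def test_empty_group_errors(self):
        treat, _ = window_samples(10, 30, 10, 30)
        with pytest.raises(ValueError):
            me.call_dmrs(treat, [], "CG", me.DmrParams())

    def test_swapping_groups_flips_polarity_keeps_p_q(self, small_sim, small_truth):
        cx = small_sim["cx"]
        t = [me.read_cx_report(cx["meth_10dpt_r1"], "a", 10, 1),
             me.read_cx_report(cx["meth_10dpt_r2"], "b", 10, 2)]
        c = [me.read_cx_report(cx["meth_0dpt_r1"], "x", 0, 1),
             me.read_cx_report(cx["meth_0dpt_r2"], "y", 0, 2)]
        fwd = me.call_dmrs(t, c, "CHH", me.DmrParams())
        rev = me.call_dmrs(c, t, "CHH", me.DmrParams())
        assert len(fwd) > 0
        key = ["chrom", "start"]
        merged = fwd.merge(rev, on=key, suffixes=("_f", "_r"))
        assert len(merged) == len(fwd) == len(rev)
        assert (merged["polarity_f"] != merged["polarity_r"]).all()
        assert merged["diff_f"].to_numpy() == pytest.approx(-merged["diff_r"].to_numpy())
        assert merged["p_f"].to_numpy() == pytest.approx(merged["p_r"].to_numpy(), abs=1e-12)
        assert merged["q_f"].to_numpy() == pytest.approx(merged["q_r"].to_numpy(), abs=1e-12)


class TestStatOracles:
    def test_fisher_p_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, 4))
            got = me.test_window_table(a, b, c, d)
            assert got == pytest.approx(fisher_two_sided(a, b, c, d), abs=1e-9)

    def test_bh_matches_stepup_definition(self):
        # agreement at float precision: the step-up formula p*m/k vs the
        # equivalent p/(k/m) differ by at most a couple of ulp
        rng = np.random.default_rng(6)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            got = multipletests(p, method="fdr_bh")[1]
            ref = np.array(bh_stepup(list(p)))
            np.testing.assert_allclose(got, ref, rtol=1e-12, atol=0)


class TestDmrDistribution:
    def test_gene_intergenic_split_and_te_single_base(self, toy_genes):
        dmrs = pd.DataFrame(
            {
                "chrom": ["c", "c"],
                "start": [10_001, 27_001],
                "end": [11_000, 28_000],
                "context": "CHH",
                "polarity": ["hyper", "hyper"],
                "comparison": "x",
            }
        )
        te = rm.TeAnnotation([("c", 28_000, 28_500)])  # shares exactly 1 bp with DMR 2
        out = me.dmr_distribution(dmrs, toy_genes, te, rm.RegionSpec(), {"c": 30_000})
        genic = out[(out["partition"] == "genic")].set_index("value")["fraction"]
        assert genic["gene"] == pytest.approx(0.5)
        assert genic["intergenic"] == pytest.approx(0.5)
        te_part = out[(out["partition"] == "te")].set_index("value")
        assert te_part.loc["TE", "count"] == 1

    def test_fractions_sum_to_one_within_partition(self, toy_genes):
        rng = np.random.default_rng(3)
        starts = rng.integers(0, 29, 12) * 1000 + 1
        dmrs = pd.DataFrame(
            {
                "chrom": "c",
                "start": starts,
                "end": starts + 999,
                "context": "CG",
                "polarity": rng.choice(["hyper", "hypo"], 12),
                "comparison": "x",
            }
        )
        te = rm.TeAnnotation([("c", 5_000, 6_000)])
        out = me.dmr_distribution(dmrs, toy_genes, te, rm.RegionSpec(), {"c": 30_000})
        for (part, pol), grp in out[out["partition"] != "tss_region"].groupby(["partition", "polarity"]):
            assert grp["fraction"].sum() == pytest.approx(1.0), (part, pol)


class TestCxIO:
    def test_roundtrip(self, tmp_path):
        s = make_sample(
            [("c", 1, "+", "CG", 3, 10), ("c", 5, "-", "CHH", 0, 4)], "s1", 5, 2
        )
        p = tmp_path / "s1.cx.tsv"
        me.write_cx_report(s, p)
        back = me.read_cx_report(p, "s1", 5, 2)
        pd.testing.assert_frame_equal(
            back.sites[["chrom", "pos", "strand", "context", "meth", "total"]],
            s.sites,
        )

    def test_negative_count_names_line(self, tmp_path):
        p = tmp_path / "bad.cx.tsv"
        p.write_text("c\t1\t+\t3\t7\tCG\tCGA\nc\t2\t+\t-1\t7\tCG\tCGA\n")
        with pytest.raises(ValueError, match="line 2"):
            me.read_cx_report(p, "bad", 0)
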