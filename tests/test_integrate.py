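"""DMR-DSR association, target genes, the RdDM screen, and term enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import fisher_two_sided, hypergeom_upper_tail
from rddmscan import integrate as ig
from rddmscan import refmodel as rm


class TestOddsRatio:
    def test_plain_cross_product(self):
        assert ig.odds_ratio_2x2([[10, 5], [2, 20]]) == pytest.approx(20.0)

    def test_symmetric_table(self):
        assert ig.odds_ratio_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)
        assert stats.fisher_exact([[5, 5], [5, 5]])[1] == pytest.approx(1.0)

    def test_haldane_correction_on_zero_cell(self):
        expected = (0.5 * 5.5) / (10.5 * 5.5)
        assert ig.odds_ratio_2x2([[0, 10], [5, 5]]) == pytest.approx(expected)

    def test_row_scaling_invariance(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 30, 4))
            k = int(rng.integers(2, 6))
            base = ig.odds_ratio_2x2([[a, b], [c, d]])
            assert ig.odds_ratio_2x2([[a * k, b * k], [c, d]]) == pytest.approx(base)  # row 1
            assert ig.odds_ratio_2x2([[a, b], [c * k, d * k]]) == pytest.approx(base)  # row 2
            assert ig.odds_ratio_2x2([[a * k, b], [c * k, d]]) == pytest.approx(base)  # col 1
            assert ig.odds_ratio_2x2([[a, b * k], [c, d * k]]) == pytest.approx(base)  # col 2

    def test_transpose_inverts_or_preserves_p(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(1, 25, 4))
            orr = ig.odds_ratio_2x2([[a, b], [c, d]])
            swapped = ig.odds_ratio_2x2([[b, a], [d, c]])
            assert swapped == pytest.approx(1.0 / orr)
            p1 = stats.fisher_exact([[a, b], [c, d]])[1]
            p2 = stats.fisher_exact([[b, a], [d, c]])[1]
            assert p1 == pytest.approx(p2, abs=1e-12)


def _assoc_inputs():
    """Five clusters: two down-DSRs overlap hypo DMRs, arranged for a known table."""
    info = pd.DataFrame(
        {
            "chrom": ["c"] * 5,
            "start": [1, 1001, 2001, 3001, 4001],
            "end": [1000, 2000, 3000, 4000, 5000],
        },
        index=pd.Index([f"c;{s};{s + 999}" for s in (1, 1001, 2001, 3001, 4001)], name="cluster_id"),
    )
    dsr = pd.DataFrame(
        {
            "feature_id": info.index,
            "log2fc": [-2, -2, 0, 0, 2],
            "p": 0.01,
            "q": 0.01,
            "direction": ["down", "down", "ns", "ns", "up"],
            "size_class": "24nt",
        }
    )
    dmrs = pd.DataFrame(
        {
            "chrom": ["c", "c"],
            "start": [1, 2001],
            "end": [1000, 3000],
            "context": "CHH",
            "polarity": ["hypo", "hypo"],
        }
    )
    return dmrs, info, dsr


class TestAssociation:
    def test_contingency_construction_and_fisher(self):
        dmrs, info, dsr = _assoc_inputs()
        res = ig.associate_dmr_dsr(dmrs, info, dsr, "hypo", "down", size_class="24nt")
        # down-DSRs: clusters 1,2; DMR overlap: clusters 1,3
        assert res.table == ((1, 1), (1, 2))
        assert res.p == pytest.approx(fisher_two_sided(1, 1, 1, 2), abs=1e-12)
        assert res.neg_log10_p == pytest.approx(-math.log10(res.p))

    def test_empty_background_errors(self):
        dmrs, info, dsr = _assoc_inputs()
        with pytest.raises(ValueError, match="background"):
            ig.associate_dmr_dsr(dmrs, info, dsr[dsr["size_class"] == "none"], "hypo", "down")

    def test_association_table_covers_all_strata(self):
        dmrs, info, dsr = _assoc_inputs()
        out = ig.association_table(dmrs, info, dsr, size_classes=("24nt",))
        assert len(out) == 4
        assert set(zip(out["dmr_polarity"], out["dsr_direction"])) == {
            ("hyper", "up"), ("hyper", "down"), ("hypo", "up"), ("hypo", "down"),
        }
        # cells always partition the background
        assert ((out["a"] + out["b"] + out["c"] + out["d"]) == len(info)).all()


class TestDmrTargetGenes:
    def make_dmrs(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "context", "polarity"])

    def test_single_base_overlap_is_target(self, toy_genes):
        # gP promoter: [8001, 10501]
        dmrs = self.make_dmrs([("c", 7_500, 8_001, "CHH", "hypo")])
        out = ig.dmr_target_genes(dmrs, toy_genes, rm.RegionSpec(), {"c": 30_000})
        assert list(out["gene_id"]) == ["gP"]
        assert out.iloc[0]["overlap_bp"] == 1

    def test_gene_body_past_promoter_not_target(self, toy_genes):
        dmrs = self.make_dmrs([("c", 11_000, 11_800, "CHH", "hypo")])  # inside gP, past tss+500
        out = ig.dmr_target_genes(dmrs, toy_genes, rm.RegionSpec(), {"c": 30_000})
        assert len(out) == 0

    def test_minus_strand_window_is_strand_aware(self, toy_genes):
        # gM tss=22000; promoter [21500, 24000]; 1 kb left of tss is gene body, not promoter
        inside = self.make_dmrs([("c", 23_001, 23_500, "CHH", "hypo")])
        outside = self.make_dmrs([("c", 20_500, 21_000, "CHH", "hypo")])
        assert list(ig.dmr_target_genes(inside, toy_genes, rm.RegionSpec(), {"c": 30_000})["gene_id"]) == ["gM"]
        assert len(ig.dmr_target_genes(outside, toy_genes, rm.RegionSpec(), {"c": 30_000})) == 0

    def test_order_invariance(self, toy_genes):
        dmrs = self.make_dmrs(
            [("c", 8_001, 9_000, "CHH", "hypo"), ("c", 21_600, 22_400, "CG", "hyper")]
        )
        a = ig.dmr_target_genes(dmrs, toy_genes, rm.RegionSpec(), {"c": 30_000})
        b = ig.dmr_target_genes(
            dmrs.iloc[::-1].reset_index(drop=True), list(reversed(toy_genes)), rm.RegionSpec(), {"c": 30_000}
        )
        pd.testing.assert_frame_equal(
            a.sort_values(["gene_id", "dmr_start"]).reset_index(drop=True),
            b.sort_values(["gene_id", "dmr_start"]).reset_index(drop=True),
        )


class TestVennCounts:
    def test_intersections(self):
        out = ig.venn_counts({"a", "b", "c"}, {"b", "c", "d"}, {"e"})
        assert out["targets_and_up"] == 2
        assert out["targets_and_down"] == 0
        assert out["targets_only"] == 1
        assert out["up_only"] == 1
        assert out["down_only"] == 1

    def test_disjoint_and_containment(self):
        assert ig.venn_counts({"a"}, {"b"}, {"c"})["targets_and_up"] == 0
        assert ig.venn_counts({"a", "b"}, {"a", "b", "c"}, set())["targets_and_up"] == 2

    def test_gene_in_both_directions_errors(self):
        with pytest.raises(ValueError, match="both"):
            ig.venn_counts(set(), {"g"}, {"g"})


def _screen_inputs(dsr_direction="down", deg_direction="up"):
    """One + strand gene whose promoter tile carries a CHH hypo DMR, a 24-nt cluster, and a TE."""
    gene = rm.GeneModel("gX", "c", "+", tss=5_001, tes=6_000)
    dmrs = pd.DataFrame(
        {"chrom": ["c"], "start": [4_001], "end": [5_000], "context": "CHH",
         "polarity": ["hypo"], "diff": [-40.0], "comparison": "10dpt_vs_0dpt"}
    )
    info = pd.DataFrame(
        {"chrom": ["c"], "start": [4_001], "end": [5_000]},
        index=pd.Index(["c;4001;5000"], name="cluster_id"),
    )
    dsr = pd.DataFrame(
        {"feature_id": ["c;4001;5000"], "log2fc": [-2.0 if dsr_direction == "down" else 2.0],
         "p": 0.001, "q": 0.01, "direction": [dsr_direction], "size_class": "24nt",
         "comparison": "10dpt_vs_0dpt"}
    )
    degs = pd.DataFrame(
        {"feature_id": ["gX"], "log2fc": [2.0 if deg_direction == "up" else -2.0],
         "p": 0.001, "q": 0.01, "direction": [deg_direction], "comparison": "10dpt_vs_0dpt"}
    )
    te = rm.TeAnnotation([("c", 4_200, 4_500)])
    return dmrs, info, dsr, degs, [gene], te


class TestRddmScreen:
    def test_full_pattern_recovered_with_te_flag(self):
        dmrs, info, dsr, degs, genes, te = _screen_inputs()
        out = ig.screen_rddm(dmrs, info, dsr, degs, genes, te, rm.RegionSpec(), {"c": 30_000})
        assert list(out["gene_id"]) == ["gX"]
        assert bool(out.iloc[0]["te_in_promoter"]) is True
        assert out.iloc[0]["cluster_id"] == "c;4001;5000"

    def test_ns_cluster_breaks_conjunction(self):
        dmrs, info, dsr, degs, genes, te = _screen_inputs()
        dsr["direction"] = "ns"
        out = ig.screen_rddm(dmrs, info, dsr, degs, genes, te, rm.RegionSpec(), {"c": 30_000})
        assert len(out) == 0

    def test_canonical_and_mirror_disjoint(self):
        dmrs, info, dsr, degs, genes, te = _screen_inputs()
        canonical = ig.screen_rddm(dmrs, info, dsr, degs, genes, te, rm.RegionSpec(), {"c": 30_000}, "canonical")
        mirror = ig.screen_rddm(dmrs, info, dsr, degs, genes, te, rm.RegionSpec(), {"c": 30_000}, "mirror")
        assert set(canonical["gene_id"]).isdisjoint(set(mirror["gene_id"]))

    def test_oshox28_like_fixture_passes(self):
        """Synthetic stand-in for the reported candidate: upstream TE, promoter CHH
        hypomethylation, decreased 24-nt cluster (Chr6;2121001;2122000), increased mRNA."""
        gene = rm.GeneModel("LOC_Os06g04850", "Chr6", "+", tss=2_122_500, tes=2_124_000)
        dmrs = pd.DataFrame(
            {"chrom": ["Chr6"], "start": [2_121_001], "end": [2_122_000], "context": "CHH",
             "polarity": ["hypo"], "diff": [-25.0], "comparison": "10dpt_vs_0dpt"}
        )
        info = pd.DataFrame(
            {"chrom": ["Chr6"], "start": [2_121_001], "end": [2_122_000]},
            index=pd.Index(["Chr6;2121001;2122000"], name="cluster_id"),
        )
        dsr = pd.DataFrame(
            {"feature_id": ["Chr6;2121001;2122000"], "log2fc": [-1.8], "p": 0.001, "q": 0.02,
             "direction": ["down"], "size_class": "24nt", "comparison": "10dpt_vs_0dpt"}
        )
        degs = pd.DataFrame(
            {"feature_id": ["LOC_Os06g04850"], "log2fc": [1.6], "p": 0.001, "q": 0.02,
             "direction": ["up"], "comparison": "10dpt_vs_0dpt"}
        )
        te = rm.TeAnnotation([("Chr6", 2_121_200, 2_121_700)])
        out = ig.screen_rddm(dmrs, info, dsr, degs, [gene], te, rm.RegionSpec(), {"Chr6": 3_000_000})
        assert list(out["gene_id"]) == ["LOC_Os06g04850"]
        assert bool(out.iloc[0]["te_in_promoter"]) is True

    def test_mismatched_comparisons_error(self):
        dmrs, info, dsr, degs, genes, te = _screen_inputs()
        degs["comparison"] = "5dpt_vs_0dpt"
        with pytest.raises(ValueError, match="comparison"):
            ig.screen_rddm(dmrs, info, dsr, degs, genes, te, rm.RegionSpec(), {"c": 30_000})


class TestTermEnrichment:
    def test_universal_term_has_p_one(self):
        bg = {f"g{i}" for i in range(20)}
        tm = {g: ["T"] for g in bg}
        out = ig.term_enrichment({"g1", "g2"}, bg, tm)
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_exact_closed_form_for_perfect_selection(self):
        bg = {f"g{i}" for i in range(100)}
        carriers = {f"g{i}" for i in range(5)}
        tm = {g: ["T"] for g in carriers}
        out = ig.term_enrichment(set(carriers), bg, tm)
        assert out.iloc[0]["p"] == pytest.approx(1.0 / math.comb(100, 5), rel=1e-9)
        assert out.iloc[0]["p"] == pytest.approx(hypergeom_upper_tail(5, 100, 5, 5), rel=1e-9)

    def test_term_absent_from_selection_not_reported(self):
        bg = {"a", "b", "c", "d"}
        tm = {"a": ["T1"], "b": ["T2"]}
        out = ig.term_enrichment({"b"}, bg, tm)
        assert list(out["term_id"]) == ["T2"]

    def test_empty_selection_errors(self):
        with pytest.raises(ValueError, match="empty"):
            ig.term_enrichment(set(), {"a"}, {})

    def test_dataframe_term_map_and_names(self):
        tm = pd.DataFrame(
            {"gene_id": ["a", "b"], "term_id": ["T1", "T1"], "term_name": ["stress response"] * 2}
        )
        out = ig.term_enrichment({"a"}, {"a", "b", "c"}, tm)
        assert out.iloc[0]["term_name"] == "stress response"
        assert out.iloc[0]["k"] == 1 and out.iloc[0]["K"] == 2
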