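import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from srnaherit import annotation, clustering
from srnaherit.types import Feature, GenomeAnnotation

from conftest import make_reads


def simple_annotation(features, length=100_000, chroms=("chr1",)):
    return GenomeAnnotation(chromosomes={c: length for c in chroms}, features=list(features))


class TestAssignCategory:
    def run_one(self, reads, features):
        ann = simple_annotation(features)
        clusters = clustering.build_clusters(reads)
        assert len(clusters) == 1
        return annotation.annotate_clusters(clusters, reads, ann).iloc[0]

    def test_te_majority(self):
        reads = make_reads(
            [("a", "chr1", 1000, 24, "+", 80, 1), ("b", "chr1", 1300, 24, "+", 20, 1)]
        )
        call = self.run_one(reads, [Feature("te1", "transposable_element", "chr1", 990, 1100, "+")])
        assert call["category"] == "TE"
        assert call["majority_fraction"] == pytest.approx(0.8)

    def test_near_gene_when_no_te_within_window(self):
        reads = make_reads([("a", "chr1", 1000, 24, "+", 10, 1)])
        call = self.run_one(reads, [Feature("g1", "gene", "chr1", 1324, 1500, "+")])
        # gene 300 bp downstream of the cluster boundary, no TE anywhere
        assert call["category"] == "near_gene_500"
        assert call["nearest_feature_id"] == "g1"
        assert call["nearest_distance"] == 300

    def test_intergenic_when_nothing_within_window(self):
        reads = make_reads([("a", "chr1", 1000, 24, "+", 10, 1)])
        call = self.run_one(reads, [Feature("g1", "gene", "chr1", 2000, 2500, "+")])
        assert call["category"] == "intergenic"

    def test_te_precedence_on_shared_overlap(self):
        reads = make_reads([("a", "chr1", 1000, 24, "+", 10, 1)])
        call = self.run_one(
            reads,
            [
                Feature("g1", "gene", "chr1", 900, 1100, "+"),
                Feature("te1", "transposable_element", "chr1", 990, 1030, "+"),
            ],
        )
        assert call["category"] == "TE"

    def test_worked_example_categories(self, worked_pipeline):
        calls = annotation.annotate_clusters(
            worked_pipeline["clusters"], worked_pipeline["reads"], worked_pipeline["exp"].annotation
        )
        truth = worked_pipeline["exp"].truth
        from srnaherit.simulate import match_truth_to_clusters

        matched = match_truth_to_clusters(truth, worked_pipeline["clusters"])
        for pid, row in truth.iterrows():
            assert calls.loc[matched[pid], "category"] == row["category"]


class TestTeWithin1kb:
    def gene(self, start=5000, end=6000):
        return Feature("g", "gene", "chr1", start, end, "+")

    def make(self, te_intervals):
        feats = [self.gene()] + [
            Feature(f"te{i}", "transposable_element", "chr1", s, e, "+")
            for i, (s, e) in enumerate(te_intervals)
        ]
        return simple_annotation(feats)

    @pytest.mark.parametrize(
        "interval,expected",
        [((6999, 7100), True), ((7001, 7100), False), ((5500, 5600), True), ((6500, 6600), True)],
    )
    def test_boundary_and_overlap(self, interval, expected):
        # gene ends at 6000; a TE starting at 6999 sits 999 bp away, at 7001 -> 1001 bp
        ann = self.make([interval])
        assert annotation.te_within_1kb(self.gene(), ann) is expected

    def test_no_te_on_chromosome(self):
        ann = self.make([])
        assert annotation.te_within_1kb(self.gene(), ann) is False

    def test_worked_example_flags(self, worked_pipeline):
        calls = annotation.annotate_clusters(
            worked_pipeline["clusters"], worked_pipeline["reads"], worked_pipeline["exp"].annotation
        )
        assert calls.loc["cl_chr1_7000", "te_within_1kb"] == True  # noqa: E712
        assert calls.loc["cl_chr1_5000", "te_within_1kb"] == False  # noqa: E712


class TestSizeClassProfile:
    @pytest.mark.parametrize(
        "rows,expected",
        [
            ([("a", "chr1", 0, 24, "+", 90, 1), ("b", "chr1", 30, 21, "+", 10, 1)], "large"),
            ([("a", "chr1", 0, 21, "+", 60, 1), ("b", "chr1", 30, 24, "+", 40, 1)], "small"),
            ([("a", "chr1", 0, 22, "+", 50, 1), ("b", "chr1", 30, 23, "+", 50, 1)], "other"),
        ],
    )
    def test_dominance_and_ties(self, rows, expected):
        reads = make_reads([(s, c, st + 100, ln, d, ab, nl) for s, c, st, ln, d, ab, nl in rows])
        dominant, hist = annotation.size_class_profile(reads)
        assert dominant == expected
        assert hist.sum() == pytest.approx(reads["abundance"].sum())


class TestFeatureRpkm:
    def design(self):
        return pd.DataFrame(
            [{"library_id": "lib1", "genotype": "CC", "bio_rep": 1, "tech_rep": 1,
              "total_mapped_reads": 1_000_000}]
        )

    def test_unit_identity_on_1kb_te(self):
        # 17 reads-per-million worth of abundance on a 1 kb TE -> 17 RPKM
        ann = simple_annotation([Feature("te1", "transposable_element", "chr1", 1000, 2000, "+")])
        reads = make_reads([("a", "chr1", 1500, 24, "+", 17, 1)])
        rpkm = annotation.feature_rpkm(reads, ann, self.design())
        te = rpkm[rpkm["feature_kind"] == "transposable_element"].iloc[0]
        assert te["rpkm"] == pytest.approx(17.0)

    def test_zero_reads_on_kind_gives_zero(self):
        ann = simple_annotation(
            [
                Feature("te1", "transposable_element", "chr1", 1000, 2000, "+"),
                Feature("g1", "gene", "chr1", 5000, 6000, "+"),
                Feature("c1", "CDS", "chr1", 5000, 6000, "+", parent_id="g1"),
            ]
        )
        reads = make_reads([("a", "chr1", 1500, 24, "+", 5, 1)])
        rpkm = annotation.feature_rpkm(reads, ann, self.design()).set_index("feature_kind")
        assert rpkm.loc["CDS", "rpkm"] == 0.0

    def test_invariant_to_splitting_a_feature(self):
        whole = simple_annotation([Feature("te1", "transposable_element", "chr1", 1000, 3000, "+")])
        split = simple_annotation(
            [
                Feature("te1a", "transposable_element", "chr1", 1000, 2000, "+"),
                Feature("te1b", "transposable_element", "chr1", 2000, 3000, "+"),
            ]
        )
        reads = make_reads([("a", "chr1", 1500, 24, "+", 9, 1), ("b", "chr1", 2500, 24, "+", 3, 1)])
        r1 = annotation.feature_rpkm(reads, whole, self.design()).set_index("feature_kind")
        r2 = annotation.feature_rpkm(reads, split, self.design()).set_index("feature_kind")
        assert r1.loc["transposable_element", "rpkm"] == pytest.approx(
            r2.loc["transposable_element", "rpkm"]
        )

    def test_precedence_te_over_cds(self):
        ann = simple_annotation(
            [
                Feature("g1", "gene", "chr1", 1000, 2000, "+"),
                Feature("c1", "CDS", "chr1", 1000, 2000, "+", parent_id="g1"),
                Feature("te1", "transposable_element", "chr1", 1400, 1600, "+"),
            ]
        )
        reads = make_reads([("a", "chr1", 1450, 24, "+", 10, 1)])
        rpkm = annotation.feature_rpkm(reads, ann, self.design()).set_index("feature_kind")
        assert rpkm.loc["transposable_element", "rpkm"] > 0
        assert rpkm.loc["CDS", "rpkm"] == 0.0


class TestPatternAssociation:
    def make_tables(self, assignments):
        calls = pd.DataFrame(
            [
                {"cluster_id": f"c{i}", "is_de": True, "pattern": pat}
                for i, (pat, _cat) in enumerate(assignments)
            ]
        ).set_index("cluster_id")
        anns = pd.DataFrame(
            [
                {"cluster_id": f"c{i}", "category": cat}
                for i, (_pat, cat) in enumerate(assignments)
            ]
        ).set_index("cluster_id")
        return calls, anns

    def test_expected_overlap_has_large_tail(self):
        # half TE / half gene, patterns independent of category
        assignments = (
            [("additive", "TE")] * 10 + [("LP", "TE")] * 10
            + [("additive", "gene")] * 10 + [("LP", "gene")] * 10
        )
        calls, anns = self.make_tables(assignments)
        p_hyper, _ = annotation.pattern_association(calls, anns, "TE", "additive")
        assert p_hyper >= 0.5

    def test_perfect_association_is_significant(self):
        assignments = [("additive", "TE")] * 20 + [("LP", "gene")] * 20
        calls, anns = self.make_tables(assignments)
        p_hyper, p_chi2 = annotation.pattern_association(calls, anns, "TE", "additive")
        assert p_hyper < 0.001
        assert p_chi2 < 0.001

    def test_hypergeometric_tail_matches_enumeration(self):
        # 2x2 with N=40, K=18 additive, n=16 TE clusters, observed overlap 12
        assignments = (
            [("additive", "TE")] * 12 + [("LP", "TE")] * 4
            + [("additive", "gene")] * 6 + [("LP", "gene")] * 18
        )
        calls, anns = self.make_tables(assignments)
        p_hyper, _ = annotation.pattern_association(calls, anns, "TE", "additive")
        N, K, n = 40, 18, 16
        expected = sum(
            math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
            for i in range(12, min(K, n) + 1)
        )
        assert p_hyper == pytest.approx(expected, rel=1e-12)

    def test_observed_study_scale_association(self):
        # 102 of 160 TE clusters additive among 368 DE clusters with 152 additive
        assignments = (
            [("additive", "TE")] * 102 + [("LP", "TE")] * 58
            + [("additive", "gene")] * 50 + [("LP", "gene")] * 158
        )
        calls, anns = self.make_tables(assignments)
        p_hyper, p_chi2 = annotation.pattern_association(calls, anns, "TE", "additive")
        assert p_hyper < 0.001
        assert p_chi2 < 0.001

    def test_empty_margin_warns_and_returns_one(self):
        calls, anns = self.make_tables([("LP", "gene")] * 5)
        with pytest.warns(UserWarning, match="empty margin"):
            p_hyper, p_chi2 = annotation.pattern_association(calls, anns, "TE", "additive")
        assert p_hyper == 1.0 and p_chi2 == 1.0
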