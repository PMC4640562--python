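"""Counterfactual pairing and background-rate calibration."""

import pytest

from clstest.cohort import (
    TumorMutationList,
    counterfactual_pairs,
    load_cohort,
    pair_cls,
    summarize_cohort,
)
from clstest.exceptions import InputError, ValidationError
from clstest.variant_io import LocusKey


def key(i: int) -> LocusKey:
    return LocusKey("chr1", i, "A", "T")


def tumor(tid, pid, loci, group=None, genes=None):
    return TumorMutationList(
        tumor_id=tid, patient_id=pid, mutations=frozenset(loci),
        group_label=group, genes=genes,
    )


class TestCounterfactualPairs:
    def test_cross_group_yields_product_count(self):
        cohort = (
            [tumor(f"er{i}", f"p{i}", [], group="ER+") for i in range(357)]
            + [tumor(f"tn{i}", f"q{i}", [], group="TN") for i in range(46)]
        )
        pairs = counterfactual_pairs(cohort, "cross_group", group_a="ER+", group_b="TN")
        assert sum(1 for _ in pairs) == 357 * 46

    def test_same_patient_never_paired(self):
        cohort = [tumor("t1", "p1", []), tumor("t2", "p1", [])]
        assert list(counterfactual_pairs(cohort, "all_cross_patient")) == []

    def test_all_cross_patient_is_choose_two(self):
        cohort = [tumor(f"t{i}", f"p{i}", []) for i in range(5)]
        assert sum(1 for _ in counterfactual_pairs(cohort, "all_cross_patient")) == 10

    def test_random_subsample_deterministic_and_cross_patient(self):
        cohort = [tumor(f"t{i}", f"p{i % 4}", []) for i in range(8)]
        a = list(counterfactual_pairs(cohort, "random_cross_patient", k=5, seed=3))
        b = list(counterfactual_pairs(cohort, "random_cross_patient", k=5, seed=3))
        assert a == b and len(a) == 5
        by_id = {t.tumor_id: t.patient_id for t in cohort}
        assert all(by_id[x] != by_id[y] for x, y in a)

    def test_missing_group_label_is_error(self):
        cohort = [tumor("t1", "p1", [], group="ER+"), tumor("t2", "p2", [], group="TN")]
        with pytest.raises(ValidationError, match="HER2"):
            list(counterfactual_pairs(cohort, "cross_group", group_a="ER+", group_b="HER2"))


class TestPairCls:
    def test_disjoint_lists(self):
        a = tumor("a", "p1", [key(i) for i in range(1, 11)])
        b = tumor("b", "p2", [key(i) for i in range(100, 115)])
        assert pair_cls(a, b)[:2] == (0, 25)

    def test_identical_lists(self):
        loci = [key(i) for i in range(1, 8)]
        X, n, shared = pair_cls(tumor("a", "p1", loci), tumor("b", "p2", loci))
        assert (X, n) == (7, 7) and shared == frozenset(loci)

    def test_partial_overlap_and_symmetry(self):
        a = tumor("a", "p1", [key(1), key(2), key(3)])
        b = tumor("b", "p2", [key(2), key(3), key(4), key(5)])
        assert pair_cls(a, b)[:2] == (2, 5)
        assert pair_cls(a, b) == pair_cls(b, a)


class TestSummarizeCohort:
    def test_all_disjoint_cohort_floors_p0(self):
        cohort = [
            tumor(f"t{i}", f"p{i}", [key(100 * i + j) for j in range(1, 21)]) for i in range(4)
        ]
        s = summarize_cohort(cohort)
        assert s.frac_zero_cls == 1.0
        assert s.max_cls == 0.0
        assert s.suggested_p0 == 0.03

    def test_hand_enumerated_histogram(self):
        # 3 tumors / 3 patients; intersections 1,0,0; unions 50 each
        common = key(1)
        t1 = tumor("t1", "p1", [common] + [key(i) for i in range(10, 59)])
        t2 = tumor("t2", "p2", [common] + [key(i) for i in range(100, 149)])
        t3 = tumor("t3", "p3", [key(i) for i in range(200, 250)])
        s = summarize_cohort([t1, t2, t3])
        assert s.num_pairs == 3
        assert s.cls_histogram == {0: 2, 1: 1}
        assert s.frac_zero_cls == pytest.approx(2 / 3)
        assert s.max_cls == pytest.approx(100 * 1 / 99)

    def test_histogram_counts_sum_to_num_pairs(self):
        cohort = [
            tumor(f"t{i}", f"p{i}", [key(j) for j in range(i + 1, i + 31)]) for i in range(6)
        ]
        s = summarize_cohort(cohort)
        assert sum(s.cls_histogram.values()) == s.num_pairs == 15

    def test_planted_recurrent_gene_ranks_first(self):
        # the same driver locus, mapped to GENE_R, is planted in every tumor
        driver = key(9999)
        cohort = []
        for i in range(5):
            loci = [driver] + [key(1000 * i + j) for j in range(1, 31)]
            genes = {driver: "GENE_R"}
            cohort.append(tumor(f"t{i}", f"p{i}", loci, genes=genes))
        s = summarize_cohort(cohort)
        top = max(s.shared_locus_tally, key=s.shared_locus_tally.get)
        assert top == "GENE_R"
        assert s.shared_locus_tally["GENE_R"] == 10  # every C(5,2) pair shares it

    def test_max_cls_matches_independent_recompute(self, rng):
        cohort = []
        for i in range(6):
            loci = rng.choice(500, size=40, replace=False)
            cohort.append(tumor(f"t{i}", f"p{i}", [key(int(x) + 1) for x in loci]))
        s = summarize_cohort(cohort)
        brute = max(
            100 * pair_cls(a, b)[0] / pair_cls(a, b)[1]
            for i, a in enumerate(cohort)
            for b in cohort[i + 1:]
        )
        assert s.max_cls == pytest.approx(brute)

    def test_suggested_p0_rises_above_heavy_sharing(self):
        # two tumors sharing 10% of a 100-locus union push the percentile past 4%
        shared = [key(i) for i in range(1, 11)]
        t1 = tumor("t1", "p1", shared + [key(i) for i in range(100, 145)])
        t2 = tumor("t2", "p2", shared + [key(i) for i in range(200, 245)])
        s = summarize_cohort([t1, t2])
        assert s.suggested_p0 > 0.04

    def test_degenerate_cohort_rejected(self):
        with pytest.raises(ValidationError):
            summarize_cohort([tumor("t1", "p1", []), tumor("t2", "p1", [])])


class TestLoadCohort:
    def test_directory_and_manifest(self, tmp_path):
        (tmp_path / "m.tsv").write_text(
            "tumor_id\tpatient_id\tgroup_label\nT1\tP1\tER+\nT2\tP2\tTN\n"
        )
        (tmp_path / "T1.tsv").write_text("chrom\tpos\tref\talt\tgene\nchr1\t5\tA\tT\tTP53\n")
        (tmp_path / "T2.tsv").write_text("chrom\tpos\tref\talt\nchr1\t5\tA\tT\nchr2\t9\tC\tG\n")
        cohort = load_cohort(tmp_path, tmp_path / "m.tsv")
        assert [t.tumor_id for t in cohort] == ["T1", "T2"]
        assert cohort[0].genes[key(5)] == "TP53"
        X, n, _ = pair_cls(cohort[0], cohort[1])
        assert (X, n) == (1, 2)

    def test_missing_list_file(self, tmp_path):
        (tmp_path / "m.tsv").write_text("tumor_id\tpatient_id\nT1\tP1\n")
        with pytest.raises(InputError, match="T1"):
            load_cohort(tmp_path, tmp_path / "m.tsv")
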