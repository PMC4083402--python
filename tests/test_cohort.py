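"""Annotation, pathogenicity aggregation, cohort matrices and statistics."""

import io

import numpy as np
import pandas as pd
import pytest

from mitohet import LocusAnnotation, find_homopolymers, reference_from_string
from mitohet.cohort import (
    aggregate_pathogenicity,
    annotate_calls,
    build_hf_matrix,
    classify_source,
    group_compare,
    hier_cluster,
    load_repeat_intervals,
    load_variability,
    normalize_by_locus,
    sharedness,
)


def calls_frame(rows):
    return pd.DataFrame(
        rows, columns=["sample", "pos", "ref", "alt", "vtype", "hf", "zygosity"]
    )


class TestAnnotateCalls:
    @pytest.fixture
    def setup(self):
        ref = reference_from_string("x", "ACGTCCCCGTACGTACGTAC")  # C run at 5..8
        runs = find_homopolymers(ref)
        loci = [LocusAnnotation("GENE", 2, 10)]
        return ref, runs, loci

    def test_insertion_anchor_adjacent_to_run(self, setup):
        ref, runs, loci = setup
        calls = calls_frame(
            [
                ("s", 6, "C", "CC", "insertion", 0.2, "heteroplasmic"),
                ("s", 4, "T", "TC", "insertion", 0.2, "heteroplasmic"),  # anchor+1 in run
                ("s", 12, "G", "GA", "insertion", 0.2, "heteroplasmic"),
            ]
        )
        out = annotate_calls(calls, loci, runs, ref.length)
        assert list(out["in_homopolymer"]) == [True, True, False]

    def test_variability_strict_cutoff(self, setup):
        ref, runs, loci = setup
        calls = calls_frame(
            [
                ("s", 3, "G", "A", "mismatch", 0.5, "heteroplasmic"),
                ("s", 5, "C", "T", "mismatch", 0.5, "heteroplasmic"),
                ("s", 7, "C", "T", "mismatch", 0.5, "heteroplasmic"),
            ]
        )
        out = annotate_calls(
            calls, loci, runs, ref.length, variability={3: 0.19, 5: 0.20}
        )
        assert out["low_variability"].tolist() == [True, False, pd.NA][0:2] + [pd.NA]
        assert np.isnan(out["variability"].iloc[2])

    def test_locus_and_repeat_flags(self, setup):
        ref, runs, loci = setup
        calls = calls_frame(
            [
                ("s", 3, "G", "A", "mismatch", 1.0, "homoplasmic"),
                ("s", 15, "A", "G", "mismatch", 1.0, "homoplasmic"),
            ]
        )
        out = annotate_calls(calls, loci, runs, ref.length, repeat_intervals=[(14, 16)])
        assert out["locus"].tolist() == ["GENE", "intergenic"]
        assert out["in_repeat"].tolist() == [False, True]

    def test_loaders(self):
        assert load_variability(io.StringIO("pos\tvariability\n5\t0.1\n")) == {5: 0.1}
        assert load_repeat_intervals(io.StringIO("chrM\t10\t20\n")) == [(11, 20)]
        with pytest.raises(ValueError):
            load_variability(io.StringIO("5\t1.5\n"))


class TestPathogenicity:
    def frame(self, **kw):
        base = {
            "pos": [10],
            "ref": ["A"],
            "alt": ["G"],
            "mutpred_score": [None],
            "polyphen_class": [None],
            "snpsgo_class": [None],
        }
        base.update({k: [v] for k, v in kw.items()})
        return pd.DataFrame(base)

    def test_mutpred_threshold_inclusive(self):
        out = aggregate_pathogenicity(
            self.frame(mutpred_score=0.70, polyphen_class="neutral", snpsgo_class="neutral")
        )
        assert out["damaging_any"].iloc[0] and not out["damaging_all"].iloc[0]

    def test_any_vs_all(self):
        out = aggregate_pathogenicity(
            self.frame(mutpred_score=0.69, polyphen_class="Disease", snpsgo_class="disease")
        )
        assert out["damaging_any"].iloc[0] and not out["damaging_all"].iloc[0]

    def test_all_three_damaging(self):
        out = aggregate_pathogenicity(
            self.frame(mutpred_score=0.9, polyphen_class="disease", snpsgo_class="disease")
        )
        assert out["damaging_all"].iloc[0]

    def test_out_of_range_score_rejected(self):
        df = pd.concat(
            [
                self.frame(mutpred_score=1.2),
                self.frame(mutpred_score=0.8),
            ]
        )
        out = aggregate_pathogenicity(df)
        assert len(out) == 1

    def test_row_without_any_tool_raises(self):
        with pytest.raises(ValueError):
            aggregate_pathogenicity(self.frame())


class TestSharedness:
    def test_private_and_shared(self):
        calls = calls_frame(
            [
                ("s1", 10, "A", "G", "mismatch", 1.0, "homoplasmic"),
                ("s2", 10, "A", "G", "mismatch", 0.5, "heteroplasmic"),
                ("s3", 10, "A", "G", "mismatch", 0.5, "heteroplasmic"),
                ("s1", 20, "C", "T", "mismatch", 0.5, "heteroplasmic"),
            ]
        )
        pops = pd.DataFrame(
            {"sample": ["s1", "s2", "s3"], "population": ["P1", "P1", "P2"]}
        )
        out = sharedness(calls, pops).set_index("pos")
        assert out.loc[10, "n_samples"] == 3 and out.loc[10, "n_populations"] == 2
        assert bool(out.loc[10, "shared"]) and not bool(out.loc[20, "shared"])

    def test_empty_cohort(self):
        assert sharedness(calls_frame([])).empty


class TestNormalizeByLocus:
    def test_rate_per_bp(self):
        loci = [LocusAnnotation("G1", 1, 1000)]
        rows = [("s", p, "A", "G", "mismatch", 1.0, "homoplasmic") for p in range(1, 11)]
        out = normalize_by_locus(calls_frame(rows), loci, L=2000)
        row = out[(out.locus == "G1") & (out.zygosity == "homoplasmic") & (out.vtype == "mismatch")]
        assert row["count"].iloc[0] == 10 and row["rate"].iloc[0] == pytest.approx(0.01)

    def test_wrapped_locus_length(self):
        loci = [LocusAnnotation("D", 1990, 10)]
        out = normalize_by_locus(calls_frame([]), loci, L=2000)
        assert out[out.locus == "D"]["length"].iloc[0] == 21

    def test_intergenic_bucket(self):
        loci = [LocusAnnotation("G1", 1, 100)]
        rows = [("s", 150, "A", "G", "mismatch", 0.5, "heteroplasmic")]
        out = normalize_by_locus(calls_frame(rows), loci, L=200)
        row = out[(out.locus == "intergenic") & (out.zygosity == "heteroplasmic") & (out.vtype == "mismatch")]
        assert row["count"].iloc[0] == 1


class TestClassifySource:
    def test_thresholds(self):
        df = pd.DataFrame(
            {"sample": list("abcd"), "ebv_coverage": [0, 401, 400, 100]}
        )
        out = classify_source(df)
        assert out["label"].tolist() == ["blood", "LCL", "unknown", "unknown"]

    def test_partition(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"sample": range(50), "ebv_coverage": rng.uniform(0, 1000, 50)}
        )
        out = classify_source(df)
        assert out["label"].isin(["blood", "LCL", "unknown"]).all()

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_source(pd.DataFrame({"sample": ["a"], "ebv_coverage": [-1]}))


class TestHFMatrix:
    def test_row_sums_conserved(self):
        calls = calls_frame(
            [
                ("s1", 1, "A", "G", "mismatch", 1.0, "homoplasmic"),
                ("s1", 2, "A", "G", "mismatch", 1.0, "homoplasmic"),
                ("s1", 3, "A", "G", "mismatch", 0.05, "heteroplasmic"),
                ("s2", 4, "A", "G", "mismatch", 0.5, "heteroplasmic"),
            ]
        )
        mat = build_hf_matrix(calls)
        assert mat.loc["s1", "1.00"] == 2 and mat.loc["s1", "≤0.10"] == 1
        assert mat.sum(axis=1).tolist() == [3, 1]

    def test_sample_without_calls_possible(self):
        calls = calls_frame([("s1", 1, "A", "G", "mismatch", 1.0, "homoplasmic")])
        mat = build_hf_matrix(calls)
        assert mat.shape == (1, 11)


class TestHierCluster:
    def test_identical_rows_merge_at_zero(self):
        mat = pd.DataFrame([[1, 2], [1, 2], [9, 9]], index=["a", "b", "c"])
        res = hier_cluster(mat)
        assert res.row_linkage[0, 2] == 0.0  # first merge height
        # the identical pair stays adjacent in the leaf ordering
        ia, ib = res.row_order.index("a"), res.row_order.index("b")
        assert abs(ia - ib) == 1

    def test_first_merge_joins_closest_pair(self):
        mat = pd.DataFrame([[0, 0], [3, 4], [100, 100]], index=list("abc"))
        res = hier_cluster(mat)
        # hand-computed Euclidean distances: d(a,b)=5, others >> 5
        assert res.row_linkage[0, 2] == pytest.approx(5.0)
        assert set(res.row_linkage[0, :2].astype(int)) == {0, 1}

    def test_permutation_invariant_topology(self):
        mat = pd.DataFrame(
            [[0, 0], [3, 4], [100, 100], [50, 50]], index=list("abcd")
        )
        res1 = hier_cluster(mat)
        res2 = hier_cluster(mat.iloc[[2, 0, 3, 1]])
        assert np.allclose(sorted(res1.row_linkage[:, 2]), sorted(res2.row_linkage[:, 2]))

    def test_single_row_identity_with_warning(self):
        mat = pd.DataFrame([[1, 2]], index=["only"])
        res = hier_cluster(mat)
        assert res.row_order == ["only"] and res.row_linkage is None

    def test_newick_contains_all_leaves(self):
        mat = pd.DataFrame([[0, 0], [3, 4], [100, 100]], index=list("abc"))
        res = hier_cluster(mat)
        for leaf in "abc":
            assert leaf in res.row_newick
        assert res.row_newick.endswith(";")


class TestGroupCompare:
    def test_identical_groups(self):
        res = group_compare([1, 2, 3, 4], [1, 2, 3, 4], mode="t_two_tailed")
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_one_tailed_is_half_two_tailed_in_direction(self):
        a, b = [5, 6, 7, 8], [1, 2, 3, 4]
        two = group_compare(a, b, mode="t_two_tailed")
        one = group_compare(a, b, mode="t_one_tailed")
        assert one.pvalue == pytest.approx(two.pvalue / 2)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1], [1, 2], mode="t_two_tailed")

    def test_fisher_2x2_derived_value(self):
        res = group_compare([[1, 9], [11, 3]], mode="fisher_2x2")
        # enumeration oracle value (~0.0028)
        from mitohet.validation import fisher_2x2_exact

        assert res.pvalue == pytest.approx(fisher_2x2_exact(1, 9, 11, 3), abs=1e-12)

    def test_fisher_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            group_compare([[1, -1], [2, 3]], mode="fisher_2x2")

    def test_montecarlo_fisher_deterministic_and_close_to_exact(self):
        table = [[1, 9], [11, 3]]
        r1 = group_compare(table, mode="fisher_rxc_montecarlo", seed=11, n_replicates=40000)
        r2 = group_compare(table, mode="fisher_rxc_montecarlo", seed=11, n_replicates=40000)
        assert r1.pvalue == r2.pvalue and r1.n_replicates == 40000
        from mitohet.validation import fisher_2x2_exact

        assert r1.pvalue == pytest.approx(fisher_2x2_exact(1, 9, 11, 3), abs=0.003)

    def test_montecarlo_rxc_shape(self):
        table = [[5, 1, 0], [2, 4, 6]]
        res = group_compare(table, mode="fisher_rxc_montecarlo", seed=3, n_replicates=5000)
        assert 0 < res.pvalue <= 1
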