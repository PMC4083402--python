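"""Variant calling filters, HF computation, classification and writers."""

import io

import numpy as np
import pytest

from mitohet import (
    FilterThresholds,
    call_deletions,
    call_insertions,
    call_mismatches,
    classify_hf,
    simulate_reference,
    write_bed,
    write_vcf,
)
from mitohet.calling import HF_CLASS_LABELS, VariantCall
from mitohet.pileup import BASE_INDEX, InsertionPileup, PileupTable
from mitohet.validation import _synthetic_pileup


@pytest.fixture(scope="module")
def ref200():
    return simulate_reference(200, seed=7)


def alt_base(refbase):
    return "ACGT"[("ACGT".index(refbase) + 1) % 4]


class TestCallMismatches:
    def test_hf_formula(self, ref200):
        pos = 100
        alt = alt_base(ref200.base(pos))
        table = _synthetic_pileup(ref200, pos, 15, 5, alt, alt_qs=30)
        calls = [c for c in call_mismatches(table, ref200) if c.pos == pos]
        assert len(calls) == 1
        c = calls[0]
        assert (c.alt_depth, c.total_depth, c.hf) == (5, 20, 0.25)
        assert c.zygosity == "heteroplasmic" and c.is_pass

    def test_rd_boundary(self, ref200):
        pos = 100
        alt = alt_base(ref200.base(pos))
        table = _synthetic_pileup(ref200, pos, 2, 2, alt, alt_qs=30)  # rd=4
        calls = [c for c in call_mismatches(table, ref200, verbose=True) if c.pos == pos]
        assert calls[0].filter_status == "fail_rd"

    def test_qs_boundary(self, ref200):
        pos = 100
        alt = alt_base(ref200.base(pos))
        table = _synthetic_pileup(ref200, pos, 40, 10, alt, alt_qs=24)
        calls = [c for c in call_mismatches(table, ref200, verbose=True) if c.pos == pos]
        assert calls[0].filter_status == "fail_qs"

    def test_threshold_monotonicity(self, ref200):
        rng = np.random.default_rng(3)
        table = PileupTable(ref200)
        for p in range(1, 201):
            b = ref200.sequence[p - 1]
            table.counts[p - 1, BASE_INDEX[b]] = rng.integers(0, 30)
            table.qhist[p - 1, BASE_INDEX[b], 30] = table.counts[p - 1, BASE_INDEX[b]]
            a = alt_base(b)
            n_alt = int(rng.integers(0, 6))
            table.counts[p - 1, BASE_INDEX[a]] = n_alt
            table.qhist[p - 1, BASE_INDEX[a], int(rng.integers(20, 40))] = n_alt

        def pass_set(th):
            return {
                (c.pos, c.alt_allele) for c in call_mismatches(table, ref200, th)
            }

        base = pass_set(FilterThresholds())
        assert pass_set(FilterThresholds(min_qs=30)) <= base
        assert pass_set(FilterThresholds(min_rd=10)) <= base
        assert pass_set(FilterThresholds(min_qs=30, min_rd=10)) <= base


class TestCallInsertions:
    def make(self, support, anchor_rd, qs):
        return InsertionPileup(
            anchor_pos=100,
            inserted_seq="T",
            support=support,
            ins_quals=[qs] * support,
            anchor_rd=anchor_rd,
        )

    def test_anchor_denominator(self, ref200):
        table = _synthetic_pileup(ref200, 100, 60, 0, "A", 30)
        calls = call_insertions([self.make(6, 60, 32)], table, ref=ref200)
        c = calls[0]
        assert c.hf == pytest.approx(0.10)
        anchor = ref200.base(100)
        assert c.ref_allele == anchor and c.alt_allele == anchor + "T"

    def test_rd_boundary(self, ref200):
        table = _synthetic_pileup(ref200, 100, 4, 0, "A", 30)
        calls = call_insertions([self.make(6, 4, 32)], table, ref=ref200, verbose=True)
        assert calls[0].filter_status == "fail_rd"

    def test_qs_exactly_25_passes(self, ref200):
        table = _synthetic_pileup(ref200, 100, 60, 0, "A", 30)
        calls = call_insertions([self.make(6, 60, 25)], table, ref=ref200)
        assert calls[0].is_pass

    def test_zero_anchor_depth_fails(self, ref200):
        table = PileupTable(ref200)
        calls = call_insertions([self.make(3, 0, 30)], table, ref=ref200, verbose=True)
        assert calls[0].filter_status == "fail_rd"


class TestCallDeletions:
    def deletion_table(self, ref, pos, dlen, del_count, match_count, flank_qs=33, flank_rd=50):
        table = _synthetic_pileup(
            ref, pos, match_count, 0, "A", 30, background_depth=flank_rd, background_qs=flank_qs
        )
        i = pos - 1
        refbase = ref.sequence[i]
        table.counts[i] = 0
        table.qhist[i] = 0
        table.counts[i, BASE_INDEX[refbase]] = match_count
        table.qhist[i, BASE_INDEX[refbase], 30] = match_count
        for k in range(dlen):
            table.del_count[(pos - 1 + k) % ref.length] = del_count
        table.deletions[(pos, dlen)] = del_count
        return table

    def test_homoplasmic_boundary(self, ref200):
        table = self.deletion_table(ref200, 100, 2, del_count=50, match_count=0)
        c = call_deletions(table, ref=ref200)[0]
        assert c.hf == 1.0 and c.zygosity == "homoplasmic"
        assert c.alt_depth == 50 and c.total_depth == 50

    def test_upstream_flank_qs_fails(self, ref200):
        table = self.deletion_table(ref200, 100, 2, 50, 0, flank_qs=24)
        c = call_deletions(table, ref=ref200, verbose=True)[0]
        assert c.filter_status == "fail_flank"

    def test_flank_wraps_near_origin(self, ref200):
        # deletion at position 2: upstream flank wraps to L-3..L, 1
        table = self.deletion_table(ref200, 2, 1, del_count=20, match_count=0)
        c = call_deletions(table, ref=ref200)[0]
        assert c.is_pass and c.pos == 2

    def test_deletion_longer_than_genome_rejected(self, ref200):
        table = PileupTable(ref200)
        table.deletions[(5, 200)] = 3
        assert call_deletions(table, ref=ref200, verbose=True) == []


class TestClassifyHF:
    @pytest.mark.parametrize(
        "hf,label",
        [
            (0.95, "0.91-0.99"),
            (0.05, "≤0.10"),
            (1.0, "1.00"),
            (0.10, "≤0.10"),
            (0.11, "0.11-0.20"),
            (0.90, "0.81-0.90"),
            (0.91, "0.91-0.99"),
            (0.996, "1.00"),
            (0.994, "0.91-0.99"),
        ],
    )
    def test_examples(self, hf, label):
        assert classify_hf(hf) == label

    def test_exhaustive_and_exclusive(self):
        # every representable 2-decimal HF lands in exactly one class
        for cents in range(1, 101):
            label = classify_hf(cents / 100)
            assert label in HF_CLASS_LABELS

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify_hf(0.0)


def example_calls():
    return [
        VariantCall(263, "A", "G", "mismatch", 50, 50, 1.0, 35, "PASS"),
        VariantCall(301, "CGG", "", "deletion", 10, 40, 0.25, 33, "PASS"),
        VariantCall(310, "T", "TC", "insertion", 5, 50, 0.1, 30, "PASS"),
    ]


class TestWriters:
    def test_bed_convention(self):
        buf = io.StringIO()
        write_bed(example_calls(), buf)
        rows = [ln.split("\t") for ln in buf.getvalue().strip().split("\n")]
        assert [(r[1], r[2]) for r in rows] == [("262", "263"), ("300", "303"), ("309", "310")]

    def test_vcf_left_anchoring(self, ref200):
        calls = [
            VariantCall(263 % 200, "A", "G", "mismatch", 50, 50, 1.0, 35, "PASS"),
            VariantCall(100, ref200.slice(100, 1), "", "deletion", 10, 40, 0.25, 33, "PASS"),
            VariantCall(110, ref200.base(110), ref200.base(110) + "C", "insertion", 5, 50, 0.1, 30, "PASS"),
        ]
        buf = io.StringIO()
        write_vcf(calls, "s1", ref200, buf)
        records = [ln.split("\t") for ln in buf.getvalue().split("\n") if ln and not ln.startswith("#")]
        by_pos = {int(r[1]): r for r in records}
        # deletion: POS is the base before, REF = that base + deleted, ALT = that base
        anchor = ref200.base(99)
        assert by_pos[99][3] == anchor + ref200.slice(100, 1)
        assert by_pos[99][4] == anchor
        # insertion: REF anchor base, ALT anchor+insert
        assert by_pos[110][3] == ref200.base(110)
        assert by_pos[110][4] == ref200.base(110) + "C"

    def test_vcf_sample_fields(self, ref200):
        buf = io.StringIO()
        write_vcf(
            [VariantCall(50, ref200.base(50), alt_base(ref200.base(50)), "mismatch", 5, 20, 0.25, 30, "PASS")],
            "s1",
            ref200,
            buf,
        )
        data_line = [ln for ln in buf.getvalue().split("\n") if ln and not ln.startswith("#")][0]
        fmt, sample = data_line.split("\t")[8:10]
        assert fmt == "GT:DP:VD:HF"
        assert sample.split(":")[1:] == ["20", "5", "0.2500"]
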