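"""Read simulator: determinism, truth-table exactness, end-to-end recovery."""

import numpy as np
import pytest

from mitohet import (
    FilterThresholds,
    PlantedVariant,
    SimulationConfig,
    build_pileup,
    call_variants,
    make_fixture_cohort,
    mark_duplicates,
    read_sam,
    simulate_alignments,
    simulate_reads,
    simulate_reference,
)


class TestSimulateReference:
    def test_deterministic(self):
        assert simulate_reference(500, seed=3).sequence == simulate_reference(500, seed=3).sequence

    def test_gc_extremes(self):
        assert set(simulate_reference(200, seed=1, gc_fraction=1.0).sequence) <= {"G", "C"}
        assert set(simulate_reference(200, seed=1, gc_fraction=0.0).sequence) <= {"A", "T"}

    def test_rcrs_scale_length(self):
        assert simulate_reference(16569, seed=1).length == 16569

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            simulate_reference(50, seed=1)


def mismatch_at(ref, pos, hf):
    refbase = ref.base(pos)
    alt = "ACGT"[("ACGT".index(refbase) + 1) % 4]
    return PlantedVariant(pos, "mismatch", refbase, alt, hf)


class TestSimulateReads:
    def test_same_seed_byte_identical_sam(self):
        ref = simulate_reference(400, seed=2)
        cfg = SimulationConfig(
            planted=(mismatch_at(ref, 200, 0.5),),
            read_length=50,
            fragment_mean=120,
            fragment_sd=10,
            target_depth=30,
            seed=9,
        )
        assert simulate_reads(ref, cfg)[0] == simulate_reads(ref, cfg)[0]

    def test_homoplasmic_error_free_realized_hf_is_one(self):
        ref = simulate_reference(400, seed=2)
        cfg = SimulationConfig(
            planted=(mismatch_at(ref, 200, 1.0),),
            read_length=50,
            fragment_mean=120,
            fragment_sd=10,
            target_depth=100,
            error_rate=0.0,
            seed=5,
        )
        _, truth = simulate_alignments(ref, cfg)
        assert truth["realized_hf"].iloc[0] == 1.0 and truth["cover"].iloc[0] > 0

    def test_truth_matches_pipeline_counts_when_error_free(self):
        ref = simulate_reference(400, seed=2)
        cfg = SimulationConfig(
            planted=(mismatch_at(ref, 150, 0.4), mismatch_at(ref, 250, 0.9)),
            read_length=50,
            fragment_mean=120,
            fragment_sd=10,
            target_depth=60,
            duplicate_rate=0.0,
            error_rate=0.0,
            seed=7,
        )
        reads, truth = simulate_alignments(ref, cfg)
        pileup = build_pileup(reads, ref)
        from mitohet.pileup import BASE_INDEX

        for _, row in truth.iterrows():
            i = int(row["pos"]) - 1
            assert int(pileup.counts[i, BASE_INDEX[row["alt_allele"]]]) == row["support"]
            assert int(pileup.rd[i]) == row["cover"]

    def test_realized_binomial_sampling(self):
        # alt counts at planted HF 0.5 stay within 3 sigma in almost all seeds
        ref = simulate_reference(300, seed=2)
        hits = 0
        n = 60
        for s in range(n):
            cfg = SimulationConfig(
                planted=(mismatch_at(ref, 150, 0.5),),
                read_length=50,
                fragment_mean=120,
                fragment_sd=5,
                target_depth=200,
                duplicate_rate=0.0,
                error_rate=0.0,
                seed=s,
            )
            _, truth = simulate_alignments(ref, cfg)
            cover = int(truth["cover"].iloc[0])
            hf = float(truth["realized_hf"].iloc[0])
            if abs(hf - 0.5) <= 3 * np.sqrt(0.25 / cover):
                hits += 1
        assert hits >= n - 2

    def test_sam_round_trip_lossless(self):
        ref = simulate_reference(300, seed=4)
        cfg = SimulationConfig(
            planted=(
                mismatch_at(ref, 100, 0.5),
                PlantedVariant(150, "insertion", "", "TTA", 0.5),
                PlantedVariant(200, "deletion", ref.slice(200, 2), "", 0.5),
            ),
            read_length=50,
            fragment_mean=120,
            fragment_sd=10,
            target_depth=40,
            duplicate_rate=0.2,
            error_rate=0.005,
            seed=8,
        )
        sam_text, _ = simulate_reads(ref, cfg)
        body = [ln for ln in sam_text.splitlines() if not ln.startswith("@")]
        reads = read_sam(sam_text, reference=ref)
        assert [r.to_sam() for r in reads] == body

    def test_indel_truth_support(self):
        ref = simulate_reference(400, seed=6)
        cfg = SimulationConfig(
            planted=(
                PlantedVariant(150, "insertion", "", "TT", 1.0),
                PlantedVariant(250, "deletion", ref.slice(250, 3), "", 1.0),
            ),
            read_length=50,
            fragment_mean=120,
            fragment_sd=10,
            target_depth=60,
            duplicate_rate=0.0,
            error_rate=0.0,
            seed=3,
        )
        reads, truth = simulate_alignments(ref, cfg)
        pileup = build_pileup(reads, ref)
        ins = {(p.anchor_pos, p.inserted_seq): p.support for p in pileup.insertion_pileups()}
        assert ins[(150, "TT")] == truth.set_index("pos").loc[150, "support"]
        assert pileup.deletions[(250, 3)] == truth.set_index("pos").loc[250, "support"]

    def test_origin_spanning_gives_full_breadth(self):
        ref = simulate_reference(400, seed=6)
        cfg = SimulationConfig(
            read_length=50,
            fragment_mean=120,
            fragment_sd=10,
            target_depth=50,
            allow_origin_spanning=True,
            error_rate=0.0,
            seed=3,
        )
        sam_text, _ = simulate_reads(ref, cfg)
        reads = read_sam(sam_text, reference=ref)
        pileup = build_pileup(reads, ref)
        assert int(pileup.rd.min()) > 0

    def test_overlapping_indels_rejected(self):
        ref = simulate_reference(400, seed=6)
        cfg = SimulationConfig(
            planted=(
                PlantedVariant(150, "deletion", ref.slice(150, 3), "", 0.5),
                PlantedVariant(151, "insertion", "", "A", 0.5),
            ),
            read_length=50,
            fragment_mean=120,
            target_depth=10,
            seed=1,
        )
        with pytest.raises(ValueError, match="overlap"):
            simulate_alignments(ref, cfg)

    def test_end_to_end_recovery(self):
        # >= 95% of planted variants with HF >= 0.1 recovered at depth >= 100
        rng = np.random.default_rng(12)
        found = total = 0
        for trial in range(8):
            ref = simulate_reference(400, seed=int(rng.integers(2**31 - 1)))
            planted = []
            for pos in (120, 180, 240, 300):
                hf = float(rng.choice([0.1, 0.3, 0.6, 1.0]))
                planted.append(mismatch_at(ref, pos, hf))
            cfg = SimulationConfig(
                planted=tuple(planted),
                read_length=50,
                fragment_mean=120,
                fragment_sd=10,
                target_depth=120,
                error_rate=0.002,
                seed=int(rng.integers(2**31 - 1)),
            )
            reads, _ = simulate_alignments(ref, cfg)
            mark_duplicates(reads)
            pileup = build_pileup(reads, ref)
            pass_keys = {
                (c.pos, c.alt_allele)
                for c in call_variants(pileup, ref, FilterThresholds())
            }
            for v in planted:
                total += 1
                if (v.pos, v.alt_allele) in pass_keys:
                    found += 1
        assert found / total >= 0.95


@pytest.fixture(scope="module")
def fixture():
    return make_fixture_cohort(n_samples=6, seed=4, target_depth=40)


class TestFixtureCohort:
    def test_deterministic(self, fixture):
        again = make_fixture_cohort(n_samples=6, seed=4, target_depth=40)
        assert fixture.sam_texts == again.sam_texts

    def test_metadata_covers_samples(self, fixture):
        assert set(fixture.metadata["sample"]) == set(fixture.sam_texts)
        assert fixture.metadata["ebv_coverage"].min() >= 0

    def test_private_variants_are_private(self, fixture):
        # the 3 non-defining planted variants of each sample appear in no other
        defined = {p for d in fixture.definitions for p, _ in d.defining_sites}
        private = {
            s: {v.pos for v in planted if v.pos not in defined}
            for s, planted in fixture.planted.items()
        }
        samples = list(private)
        for i, s in enumerate(samples):
            for t in samples[i + 1 :]:
                assert not (private[s] & private[t])

    def test_writes_text_fixture_tree(self, fixture, tmp_path):
        make_fixture_cohort(n_samples=2, seed=4, target_depth=20, outdir=str(tmp_path))
        assert (tmp_path / "reference.fasta").exists()
        assert (tmp_path / "haplogroups.tsv").exists()
        assert (tmp_path / "S001.sam").exists()
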