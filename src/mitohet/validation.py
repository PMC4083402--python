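"""Independent oracles and seeded validation experiments.

This module deliberately re-implements the calling rules in the most literal,
slowest possible way (dict-based per-read scans, ``statistics.median``,
exact rational hypergeometric enumeration) so that the optimized pipeline in
:mod:`mitohet.pileup` / :mod:`mitohet.calling` can be checked against an
independent code path on simulated data.  The experiment functions are the
basis of the package's property-based self-checks: heteroplasmic-fraction
recovery, filter boundary behaviour, consensus round-trips, haplogroup
recovery, duplicate handling and the statistics cross-checks.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import replace
from fractions import Fraction

import numpy as np

from .alignment import AlignedRead, mark_duplicates
from .calling import (
    FilterThresholds,
    call_mismatches,
    call_variants,
)
from .consensus import assign_haplogroup, build_consensus
from .pileup import PileupTable, build_pileup
from .reference import CircularReference
from .simulate import (
    PlantedVariant,
    SimulationConfig,
    make_fixture_cohort,
    simulate_alignments,
    simulate_reference,
)

# ----------------------------------------------------------------------
# literal brute-force pileup and caller (the oracle)


def oracle_pileup(reads: list[AlignedRead], ref: CircularReference) -> dict:
    """Per-read scan into plain dicts; duplicates/secondary/unmapped excluded."""
    L = ref.length
    counts = {p: {b: 0 for b in "ACGT"} for p in range(1, L + 1)}
    quals = {p: {b: [] for b in "ACGT"} for p in range(1, L + 1)}
    delc = {p: 0 for p in range(1, L + 1)}
    ins: dict[tuple[int, str], list[list[int]]] = {}
    dels: dict[tuple[int, int], int] = {}
    for r in reads:
        if r.is_unmapped or r.is_secondary or r.is_duplicate:
            continue
        rpos, q = r.pos, 0
        for op, n in r.cigar:
            if op in "M=X":
                for i in range(n):
                    p = (rpos - 1 + i) % L + 1
                    b = r.seq[q + i]
                    if b in "ACGT":
                        counts[p][b] += 1
                        quals[p][b].append(r.qual[q + i])
                rpos += n
                q += n
            elif op == "I":
                a = (rpos - 2) % L + 1
                ins.setdefault((a, r.seq[q : q + n]), []).append(list(r.qual[q : q + n]))
                q += n
            elif op == "D":
                s = (rpos - 1) % L + 1
                for i in range(n):
                    delc[(rpos - 1 + i) % L + 1] += 1
                dels[(s, n)] = dels.get((s, n), 0) + 1
                rpos += n
            elif op == "S":
                q += n
            elif op == "N":
                rpos += n
    return {"counts": counts, "quals": quals, "delc": delc, "ins": ins, "dels": dels}


def _orc_rd(orc: dict, p: int) -> int:
    return sum(orc["counts"][p].values()) + orc["delc"][p]


def oracle_pass_calls(
    orc: dict, ref: CircularReference, th: FilterThresholds = FilterThresholds()
) -> set[tuple]:
    """Literal application of the filters; returns the PASS call set.

    Elements: (vtype, pos, ref_allele, alt_allele, alt_depth, total_depth).
    """
    L = ref.length
    out: set[tuple] = set()
    for p in range(1, L + 1):
        refbase = ref.sequence[p - 1]
        if refbase == "N":
            continue
        rd = _orc_rd(orc, p)
        for alt in "ACGT":
            if alt == refbase:
                continue
            n = orc["counts"][p][alt]
            if n >= max(th.min_alt_reads, 1) and rd >= th.min_rd:
                if statistics.median(orc["quals"][p][alt]) >= th.min_qs:
                    out.add(("mismatch", p, refbase, alt, n, rd))
    for (a, seq), qlists in orc["ins"].items():
        support = len(qlists)
        anchor_rd = _orc_rd(orc, a)
        flat = [q for ql in qlists for q in ql]
        if (
            support >= max(th.min_alt_reads, 1)
            and anchor_rd >= th.min_rd
            and statistics.median(flat) >= th.min_qs
        ):
            base = ref.sequence[a - 1]
            out.add(("insertion", a, base, base + seq, support, anchor_rd))
    for (s, k), n in orc["dels"].items():
        if k >= L or n < max(th.min_alt_reads, 1):
            continue
        sides_ok = True
        for side in ("up", "down"):
            if side == "up":
                positions = [(s - j - 1) % L + 1 for j in range(1, th.flank_len + 1)]
            else:
                positions = [(s + k - 1 + j - 1) % L + 1 for j in range(1, th.flank_len + 1)]
            rds = [_orc_rd(orc, p) for p in positions]
            pooled = [q for p in positions for b in "ACGT" for q in orc["quals"][p][b]]
            med_qs = statistics.median(pooled) if pooled else 0
            if statistics.median(rds) < th.min_rd or med_qs < th.min_qs:
                sides_ok = False
        if sides_ok:
            deleted = "".join(ref.sequence[(s - 1 + j) % L] for j in range(k))
            out.add(("deletion", s, deleted, "", n, _orc_rd(orc, s)))
    return out


def implementation_pass_calls(
    pileup: PileupTable, ref: CircularReference, th: FilterThresholds = FilterThresholds()
) -> set[tuple]:
    return {
        (c.vtype, c.pos, c.ref_allele, c.alt_allele, c.alt_depth, c.total_depth)
        for c in call_variants(pileup, ref, th)
        if c.is_pass
    }


def pileups_agree(pileup: PileupTable, orc: dict) -> bool:
    """Counts, deletion depths, qual multisets and indel records must match."""
    from .pileup import BASE_INDEX

    for p in range(1, pileup.L + 1):
        i = p - 1
        for b in "ACGT":
            if int(pileup.counts[i, BASE_INDEX[b]]) != orc["counts"][p][b]:
                return False
            hist = pileup.qhist[i, BASE_INDEX[b]]
            impl = sorted(
                int(v) for v in np.repeat(np.arange(hist.shape[0]), hist)
            )
            if impl != sorted(orc["quals"][p][b]):
                return False
        if int(pileup.del_count[i]) != orc["delc"][p]:
            return False
    impl_ins = {
        key: sorted(vals) for key, vals in pileup.insertions.items()
    }
    orc_ins = {
        key: sorted(q for ql in qlists for q in ql)
        for key, qlists in orc["ins"].items()
    }
    if impl_ins != orc_ins:
        return False
    return dict(pileup.deletions) == orc["dels"]


# ----------------------------------------------------------------------
# experiment: HF estimator recovery

HF_GRID = (0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 1.00)


def hf_recovery_experiment(
    n_seeds: int = 500,
    base_seed: int = 1,
    target_depth: float = 200.0,
) -> dict:
    """Recovery of planted heteroplasmic fractions through the full pipeline.

    Each replicate simulates error-free depth-200 paired reads (with 15% PCR
    duplicates that the pipeline must remove) carrying one mismatch at every
    HF on the grid, then measures the called HF against the planted value
    with the binomial 3-sigma band 3*sqrt(h*(1-h)/cover).  Also counts
    spurious homoplasmies (rounded HF 1.00 from planted h <= 0.9) and PASS
    calls at planted-free positions, which must be absent without sequencing
    errors.
    """
    L = 460
    ref = simulate_reference(L, seed=base_seed)
    positions = [155 + 25 * k for k in range(len(HF_GRID))]
    planted = tuple(
        PlantedVariant(
            pos=p,
            vtype="mismatch",
            ref_allele=ref.base(p),
            alt_allele="ACGT"[("ACGT".index(ref.base(p)) + 1) % 4],
            target_hf=h,
        )
        for p, h in zip(positions, HF_GRID)
    )
    rng = np.random.default_rng(base_seed)
    seeds = rng.integers(0, 2**31 - 1, n_seeds)
    th = FilterThresholds()
    within = {h: 0 for h in HF_GRID}
    totals = {h: 0 for h in HF_GRID}
    spurious_homoplasmy = 0
    false_positives = 0
    for s in seeds:
        config = SimulationConfig(
            planted=planted,
            read_length=60,
            fragment_mean=150.0,
            fragment_sd=10.0,
            target_depth=target_depth,
            duplicate_rate=0.15,
            error_rate=0.0,
            seed=int(s),
        )
        reads, truth = simulate_alignments(ref, config)
        mark_duplicates(reads)
        pileup = build_pileup(reads, ref)
        calls = call_mismatches(pileup, ref, th)
        by_pos = {(c.pos, c.alt_allele): c for c in calls if c.is_pass}
        planted_keys = set()
        for v, cover in zip(planted, truth["cover"]):
            planted_keys.add((v.pos, v.alt_allele))
            call = by_pos.get((v.pos, v.alt_allele))
            est = call.hf if call is not None else 0.0
            bound = 3 * math.sqrt(v.target_hf * (1 - v.target_hf) / max(int(cover), 1))
            totals[v.target_hf] += 1
            if abs(est - v.target_hf) <= bound:
                within[v.target_hf] += 1
            if v.target_hf <= 0.9 and round(est, 2) == 1.0:
                spurious_homoplasmy += 1
        false_positives += sum(1 for key in by_pos if key not in planted_keys)
    return {
        "within": within,
        "totals": totals,
        "spurious_homoplasmy": spurious_homoplasmy,
        "false_positives": false_positives,
        "n_seeds": n_seeds,
    }


# ----------------------------------------------------------------------
# experiment: caller vs literal oracle on random simulations


def oracle_equivalence_experiment(n_sims: int = 100, base_seed: int = 1) -> dict:
    """PASS sets and pileups of the pipeline vs the literal oracle.

    Random small simulations (<= 200 reads) with mixed mismatches, indels,
    sequencing errors and duplicates, run through SAM text and back.
    """
    from .alignment import read_sam
    from .simulate import simulate_reads

    rng = np.random.default_rng(base_seed)
    calls_agree = 0
    pileups_ok = 0
    for _ in range(n_sims):
        L = 200
        ref = simulate_reference(L, seed=int(rng.integers(2**31 - 1)))
        planted = []
        used: set[int] = set()
        for _v in range(int(rng.integers(2, 5))):
            while True:
                p = int(rng.integers(20, L - 20))
                if all(abs(p - u) > 6 for u in used):
                    used.add(p)
                    break
            vtype = str(rng.choice(["mismatch", "mismatch", "insertion", "deletion"]))
            hf = float(rng.choice([0.1, 0.3, 0.5, 0.8, 1.0]))
            refbase = ref.base(p)
            if vtype == "mismatch":
                alt = str(rng.choice([b for b in "ACGT" if b != refbase]))
                planted.append(PlantedVariant(p, "mismatch", refbase, alt, hf))
            elif vtype == "insertion":
                ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
                planted.append(PlantedVariant(p, "insertion", "", ins, hf))
            else:
                k = int(rng.integers(1, 4))
                planted.append(PlantedVariant(p, "deletion", ref.slice(p, k), "", hf))
        config = SimulationConfig(
            planted=tuple(planted),
            read_length=50,
            fragment_mean=110.0,
            fragment_sd=15.0,
            target_depth=45.0,
            duplicate_rate=float(rng.choice([0.0, 0.1])),
            error_rate=float(rng.choice([0.0, 0.005])),
            seed=int(rng.integers(2**31 - 1)),
        )
        sam_text, _truth = simulate_reads(ref, config)
        reads = read_sam(sam_text, reference=ref)
        mark_duplicates(reads)
        pileup = build_pileup(reads, ref)
        orc = oracle_pileup(reads, ref)
        if pileups_agree(pileup, orc):
            pileups_ok += 1
        if implementation_pass_calls(pileup, ref) == oracle_pass_calls(orc, ref):
            calls_agree += 1
    return {"calls_agree": calls_agree, "pileups_agree": pileups_ok, "n_sims": n_sims}


# ----------------------------------------------------------------------
# experiment: filter boundaries


def _synthetic_pileup(
    ref: CircularReference,
    pos: int,
    ref_count: int,
    alt_count: int,
    alt_base: str,
    alt_qs: int,
    background_depth: int = 50,
    background_qs: int = 35,
) -> PileupTable:
    """Hand-constructed pileup: uniform background plus one candidate site."""
    from .pileup import BASE_INDEX

    table = PileupTable(ref)
    for p in range(1, ref.length + 1):
        b = ref.sequence[p - 1]
        if b not in "ACGT":
            continue
        table.counts[p - 1, BASE_INDEX[b]] = background_depth
        table.qhist[p - 1, BASE_INDEX[b], background_qs] = background_depth
    i = pos - 1
    refbase = ref.sequence[i]
    table.counts[i] = 0
    table.qhist[i] = 0
    table.counts[i, BASE_INDEX[refbase]] = ref_count
    table.qhist[i, BASE_INDEX[refbase], background_qs] = ref_count
    table.counts[i, BASE_INDEX[alt_base]] = alt_count
    table.qhist[i, BASE_INDEX[alt_base], alt_qs] = alt_count
    return table


def filter_boundary_suite() -> dict:
    """PASS/fail flips at the inclusive thresholds QS>=25 and rd>=5.

    Constructed pileups probe each boundary independently for mismatches,
    insertions and deletion flanks; returns per-check booleans.
    """
    from .pileup import BASE_INDEX

    ref = simulate_reference(200, seed=7)
    th = FilterThresholds()
    pos = 100
    refbase = ref.base(pos)
    alt = "ACGT"[("ACGT".index(refbase) + 1) % 4]
    checks: dict[str, bool] = {}

    def mismatch_status(rd_total: int, alt_qs: int) -> str:
        table = _synthetic_pileup(ref, pos, rd_total - 2, 2, alt, alt_qs)
        calls = call_mismatches(table, ref, th, verbose=True)
        match = [c for c in calls if c.pos == pos and c.alt_allele == alt]
        return match[0].filter_status if match else "absent"

    checks["mismatch_qs_25_passes"] = mismatch_status(50, 25) == "PASS"
    checks["mismatch_qs_24_fails"] = mismatch_status(50, 24) == "fail_qs"
    checks["mismatch_rd_5_passes"] = mismatch_status(5, 30) == "PASS"
    checks["mismatch_rd_4_fails"] = mismatch_status(4, 30) == "fail_rd"

    from .calling import call_insertions
    from .pileup import InsertionPileup

    def insertion_status(anchor_rd: int, qs: int) -> str:
        table = _synthetic_pileup(ref, pos, anchor_rd, 0, alt, 30)
        ip = InsertionPileup(
            anchor_pos=pos, inserted_seq="A", support=2, ins_quals=[qs, qs], anchor_rd=anchor_rd
        )
        calls = call_insertions([ip], table, th, ref=ref, verbose=True)
        return calls[0].filter_status

    checks["insertion_qs_25_passes"] = insertion_status(50, 25) == "PASS"
    checks["insertion_qs_24_fails"] = insertion_status(50, 24) == "fail_qs"
    checks["insertion_rd_5_passes"] = insertion_status(5, 30) == "PASS"
    checks["insertion_rd_4_fails"] = insertion_status(4, 30) == "fail_rd"

    from .calling import call_deletions

    def deletion_status(flank_qs: int, flank_rd: int) -> str:
        table = _synthetic_pileup(
            ref, pos, 50, 0, alt, 30, background_depth=flank_rd, background_qs=flank_qs
        )
        i = pos - 1
        table.counts[i] = 0
        table.qhist[i] = 0
        table.del_count[i] = 10
        table.deletions[(pos, 1)] = 10
        calls = call_deletions(table, th, ref=ref, verbose=True)
        return calls[0].filter_status

    checks["deletion_flank_qs_25_passes"] = deletion_status(25, 50) == "PASS"
    checks["deletion_flank_qs_24_fails"] = deletion_status(24, 50) == "fail_flank"
    checks["deletion_flank_rd_5_passes"] = deletion_status(30, 5) == "PASS"
    checks["deletion_flank_rd_4_fails"] = deletion_status(30, 4) == "fail_flank"
    return checks


# ----------------------------------------------------------------------
# experiment: consensus round-trip


def consensus_roundtrip_experiment(seed: int = 1, n_variants: int = 12) -> dict:
    """Mutate a reference everywhere at HF 1.0, resequence, rebuild, compare.

    Origin-spanning fragments are enabled so every position reaches calling
    depth; the rebuilt consensus must equal the mutated genome exactly with
    zero gaps.
    """
    rng = np.random.default_rng(seed)
    L = 800
    ref = simulate_reference(L, seed=int(rng.integers(2**31 - 1)))
    positions = sorted(
        int(p) for p in rng.choice(np.arange(1, L + 1), size=n_variants, replace=False)
    )
    planted = []
    mutated = list(ref.sequence)
    for p in positions:
        refbase = ref.base(p)
        alt = str(rng.choice([b for b in "ACGT" if b != refbase]))
        mutated[p - 1] = alt
        planted.append(PlantedVariant(p, "mismatch", refbase, alt, 1.0))
    config = SimulationConfig(
        planted=tuple(planted),
        read_length=60,
        fragment_mean=150.0,
        fragment_sd=15.0,
        target_depth=60.0,
        duplicate_rate=0.1,
        error_rate=0.0,
        allow_origin_spanning=True,
        seed=int(rng.integers(2**31 - 1)),
    )
    reads, _ = simulate_alignments(ref, config)
    mark_duplicates(reads)
    pileup = build_pileup(reads, ref)
    th = FilterThresholds()
    calls = call_variants(pileup, ref, th)
    cons = build_consensus(calls, pileup, ref, th)
    expected = "".join(mutated)
    mismatching = sum(1 for a, b in zip(cons.sequence, expected) if a != b)
    return {
        "identical": cons.sequence == expected,
        "mismatching_positions": mismatching,
        "gap_count": cons.gap_count,
        "n_variants": n_variants,
    }


# ----------------------------------------------------------------------
# experiment: haplogroup recovery


def haplogroup_recovery_experiment(seed: int = 1, n_samples: int = 20) -> dict:
    """Cohort round-trip: simulate from haplogroups, call, rebuild, assign.

    Full coverage of the defining sites must give 100% correct assignment at
    P_Hg = 1.0; masking one of ten defining sites must give P_Hg = 0.9 and an
    unreliable flag (strict > 0.90 rule).
    """
    fixture = make_fixture_cohort(n_samples=n_samples, seed=seed)
    ref = fixture.reference
    th = FilterThresholds()
    from .alignment import read_sam
    from .consensus import ConsensusSequence

    correct = 0
    p_hgs = []
    masked_p_hg = None
    masked_reliable = None
    for i, (sample, sam_text) in enumerate(sorted(fixture.sam_texts.items())):
        reads = read_sam(sam_text, reference=ref)
        mark_duplicates(reads)
        pileup = build_pileup(reads, ref)
        calls = call_variants(pileup, ref, th)
        cons = build_consensus(calls, pileup, ref, th, name=sample)
        best, _ranked = assign_haplogroup(cons, fixture.definitions)
        true_hg = fixture.metadata.set_index("sample").loc[sample, "haplogroup"]
        if best.name == true_hg:
            correct += 1
        p_hgs.append(best.p_hg)
        if i == 0:
            # mask one defining site of the true haplogroup with a gap
            hg = next(d for d in fixture.definitions if d.name == true_hg)
            mask_pos = hg.defining_sites[0][0]
            seq = list(cons.sequence)
            seq[mask_pos - 1] = "N"
            masked = ConsensusSequence(name=cons.name, sequence="".join(seq))
            mb, _ = assign_haplogroup(masked, fixture.definitions)
            masked_p_hg = mb.p_hg
            masked_reliable = mb.reliable
    return {
        "n_samples": n_samples,
        "correct": correct,
        "min_p_hg": min(p_hgs),
        "masked_p_hg": masked_p_hg,
        "masked_reliable": masked_reliable,
    }


# ----------------------------------------------------------------------
# experiment: duplicate handling


def duplicate_experiment(seed: int = 1) -> dict:
    """Idempotence of marking and survivor count == distinct fragment groups."""
    ref = simulate_reference(500, seed=seed)
    config = SimulationConfig(
        read_length=60,
        fragment_mean=150.0,
        fragment_sd=15.0,
        target_depth=60.0,
        duplicate_rate=0.5,
        error_rate=0.0,
        seed=seed + 1,
    )
    reads, _ = simulate_alignments(ref, config)
    mark_duplicates(reads)
    flags1 = [r.is_duplicate for r in reads]
    mark_duplicates(reads)
    flags2 = [r.is_duplicate for r in reads]
    # distinct groups computed independently from coordinates
    pairs: dict[str, list[AlignedRead]] = {}
    for r in reads:
        pairs.setdefault(r.qname, []).append(r)
    group_keys = set()
    for members in pairs.values():
        key = tuple(sorted((m.five_prime_coordinate(), m.is_reverse) for m in members))
        group_keys.add(key)
    survivor_pairs = {
        qname for qname, members in pairs.items() if not any(m.is_duplicate for m in members)
    }
    return {
        "idempotent": flags1 == flags2,
        "n_groups": len(group_keys),
        "n_survivors": len(survivor_pairs),
        "n_fragments": len(pairs),
    }


# ----------------------------------------------------------------------
# statistics oracle: exact rational two-sided Fisher


def fisher_2x2_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration (exact rationals).

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed that of the observed table (ties included
    exactly).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    pmf = {
        k: Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
        for k in range(lo, hi + 1)
    }
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs))


def fisher_agreement_experiment(max_n: int = 40) -> dict:
    """Compare the implementation against the enumeration oracle.

    Exhaustive over all 2x2 tables with total N <= max_n, enumerated by
    margins so the hypergeometric distribution is built once per margin set
    (degenerate tables with an empty row or column included; both routes
    give p = 1 there).
    """
    from .cohort import group_compare

    max_err = 0.0
    n_tables = 0
    for n in range(0, max_n + 1):
        for r1 in range(n + 1):
            r2 = n - r1
            for c1 in range(n + 1):
                denom = math.comb(n, c1)
                lo, hi = max(0, c1 - r2), min(c1, r1)
                pmf = {
                    k: Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
                    for k in range(lo, hi + 1)
                }
                # two-sided p for every observed a, via sorted prefix sums
                ordered = sorted(pmf.items(), key=lambda kv: kv[1])
                prefix: list[Fraction] = []
                acc = Fraction(0)
                for _k, p in ordered:
                    acc += p
                    prefix.append(acc)
                exact_p: dict[int, float] = {}
                for idx in range(len(ordered)):
                    # include all ties with the observed probability
                    j = idx
                    while j + 1 < len(ordered) and ordered[j + 1][1] == ordered[idx][1]:
                        j += 1
                    exact_p[ordered[idx][0]] = float(prefix[j])
                for a in range(lo, hi + 1):
                    b, c = r1 - a, c1 - a
                    d = r2 - c
                    res = group_compare([[a, b], [c, d]], mode="fisher_2x2")
                    max_err = max(max_err, abs(res.pvalue - exact_p[a]))
                    n_tables += 1
    return {"max_abs_error": max_err, "n_tables": n_tables}
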