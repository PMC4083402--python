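"""Heteroplasmy-aware paired-end read simulator with truth tables.

Heteroplasmy is modeled at the fragment level: each sequenced fragment is
drawn from the variant haplotype independently with probability equal to the
planted heteroplasmic fraction, so both mates of a pair share the haplotype
(as in real mtDNA libraries, where a fragment comes from one molecule).
Fragments are sampled uniformly on the circle.  By default fragments that
would span the coordinate origin are rejected and resampled, keeping every
alignment a standard linear SAM record; with
``allow_origin_spanning=True`` such fragments are kept and any read crossing
the origin is emitted as two unpaired SAM records, one per side.

PCR duplicates are extra copies of existing fragments with fresh base
qualities.  The truth table records, per planted variant, the realized
covering and supporting read counts over the unique (pre-duplication)
fragments, so realized HF = support / cover exactly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .alignment import AlignedRead, write_sam
from .reference import CircularReference

BASES = "ACGT"


@dataclass(frozen=True)
class PlantedVariant:
    """One variant to plant at a known heteroplasmic fraction.

    ``pos``: 1-based; for insertions the 5' anchor base, for deletions the
    first deleted base.  ``ref_allele``/``alt_allele``: mismatch = one base
    each; insertion = "" -> inserted sequence; deletion = deleted sequence ->
    "".
    """

    pos: int
    vtype: str  # mismatch | insertion | deletion
    ref_allele: str
    alt_allele: str
    target_hf: float

    def __post_init__(self):
        if not 0 < self.target_hf <= 1:
            raise ValueError("target_hf must lie in (0, 1]")
        if self.vtype not in ("mismatch", "insertion", "deletion"):
            raise ValueError(f"unknown vtype {self.vtype!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated sample.

    Defaults emulate Illumina paired-end off-target mtDNA capture: 100-bp
    mates, ~300-bp fragments, deep (200x) coverage, Phred means near 33 with
    a floor of 2, a 0.1% per-base error rate and 15% PCR duplication.
    """

    planted: tuple[PlantedVariant, ...] = ()
    read_length: int = 100
    fragment_mean: float = 300.0
    fragment_sd: float = 60.0
    target_depth: float = 200.0
    qs_mean: float = 33.0
    qs_sd: float = 4.0
    qs_floor: int = 2
    duplicate_rate: float = 0.15
    error_rate: float = 0.001
    allow_origin_spanning: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.read_length > self.fragment_mean:
            raise ValueError("read_length must not exceed fragment_mean")
        for rate in (self.duplicate_rate, self.error_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0,1]")
        if self.target_depth <= 0:
            raise ValueError("target_depth must be positive")


def simulate_reference(length: int, seed: int, gc_fraction: float = 0.44) -> CircularReference:
    """Seeded random circular reference with the requested GC content.

    The 0.44 default mirrors the GC content of the human mitochondrial
    genome.
    """
    if length < 100:
        raise ValueError("reference length must be >= 100")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    seq = "".join(rng.choice(list(BASES), size=length, p=p))
    return CircularReference(name=f"sim_ref_{seed}", sequence=seq)


def _validate_planted(ref: CircularReference, planted: tuple[PlantedVariant, ...]) -> None:
    L = ref.length
    spans: list[tuple[int, int]] = []
    for v in planted:
        if not 1 <= v.pos <= L:
            raise ValueError(f"planted variant position {v.pos} outside reference")
        if v.vtype == "mismatch":
            if ref.base(v.pos) != v.ref_allele:
                raise ValueError(
                    f"mismatch at {v.pos}: reference is {ref.base(v.pos)}, "
                    f"not {v.ref_allele}"
                )
            if v.alt_allele == v.ref_allele or len(v.alt_allele) != 1:
                raise ValueError(f"bad mismatch alt at {v.pos}")
        elif v.vtype == "deletion":
            k = len(v.ref_allele)
            if v.pos + k - 1 > L:
                raise ValueError("planted deletions must not cross the origin")
            if ref.slice(v.pos, k) != v.ref_allele:
                raise ValueError(f"deletion at {v.pos}: reference disagrees")
            spans.append((v.pos, v.pos + k - 1))
        elif v.vtype == "insertion":
            spans.append((v.pos, v.pos))
    spans.sort()
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError("planted indels must not overlap")


# ----------------------------------------------------------------------
# fragment construction (coordinates are "unrolled": a fragment spanning the
# origin uses positions beyond L; normalization happens at emission)


def _fragment_ops(
    ref: CircularReference,
    fstart: int,
    fend: int,
    carried: list[PlantedVariant],
) -> tuple[list, dict[int, str]]:
    """Alignment ops of one fragment: [('M', ref_start, len) | ('I', anchor, seq)
    | ('D', ref_start, len)], plus the substitution map for carried mismatches."""
    ops: list = []
    subs: dict[int, str] = {}
    cur = fstart
    for v in sorted(carried, key=lambda v: v.pos):
        if v.vtype == "mismatch":
            if fstart <= v.pos <= fend:
                subs[v.pos] = v.alt_allele
        elif v.vtype == "insertion":
            a = v.pos
            if fstart <= a < fend and a >= cur:
                ops.append(("M", cur, a - cur + 1))
                ops.append(("I", a, v.alt_allele))
                cur = a + 1
        else:  # deletion
            s, k = v.pos, len(v.ref_allele)
            if s > fstart and s + k - 1 < fend and s >= cur:
                if s > cur:
                    ops.append(("M", cur, s - cur))
                ops.append(("D", s, k))
                cur = s + k
    if cur <= fend:
        ops.append(("M", cur, fend - cur + 1))
    return ops, subs


def _fragment_query(ref: CircularReference, ops: list, subs: dict[int, str]) -> str:
    parts = []
    for op in ops:
        if op[0] == "M":
            _, rs, ln = op
            seg = list(ref.slice(rs, ln))
            for p, alt in subs.items():
                if rs <= p < rs + ln:
                    seg[p - rs] = alt
            parts.append("".join(seg))
        elif op[0] == "I":
            parts.append(op[2])
    return "".join(parts)


def _slice_alignment(ops: list, q0: int, q1: int) -> tuple[int, list[tuple[str, int]]]:
    """CIGAR and (unrolled) 1-based start of the query window [q0, q1)."""
    cigar: list[tuple[str, int]] = []
    start_ref: int | None = None

    def push(op: str, n: int):
        if n <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + n)
        else:
            cigar.append((op, n))

    q = 0
    for op in ops:
        if op[0] == "M":
            _, rs, ln = op
            lo, hi = max(q, q0), min(q + ln, q1)
            if lo < hi:
                if start_ref is None:
                    start_ref = rs + (lo - q)
                push("M", hi - lo)
            q += ln
        elif op[0] == "I":
            _, a, seq = op
            ln = len(seq)
            lo, hi = max(q, q0), min(q + ln, q1)
            if lo < hi:
                if start_ref is None:
                    start_ref = a + 1  # leading insertion: pos is next M base
                push("I", hi - lo)
            q += ln
        else:  # D sits between query positions q-1 and q
            _, rs, k = op
            if q0 < q < q1:
                push("D", k)
        if q >= q1:
            break
    # drop a trailing D left by an exactly-flush window
    while cigar and cigar[-1][0] == "D":
        cigar.pop()
    assert start_ref is not None
    return start_ref, cigar


def _split_at_origin(
    start: int, cigar: list[tuple[str, int]], seq: str, quals: list[int], L: int
) -> list[tuple[int, list[tuple[str, int]], str, list[int]]]:
    """Cut an unrolled alignment at the reference origin into linear pieces.

    Planted deletions never cross the origin, so a D op lies fully on one
    side; a D left dangling at a piece boundary is dropped (that read simply
    stops observing the event at the origin).
    """
    pieces: list[tuple[int, list, str, list[int]]] = []
    cur_start = (start - 1) % L + 1
    cur_cigar: list[tuple[str, int]] = []
    cur_q0 = 0
    rpos = cur_start
    q = 0

    def flush(q_end: int):
        nonlocal cur_cigar, cur_q0, cur_start
        cig = list(cur_cigar)
        while cig and cig[-1][0] == "D":
            cig.pop()
        while cig and cig[0][0] == "D":
            cig.pop(0)
        if any(op == "M" for op, _ in cig):
            pieces.append((cur_start, cig, seq[cur_q0:q_end], quals[cur_q0:q_end]))
        cur_cigar = []
        cur_q0 = q_end

    def push(op: str, n: int):
        if n <= 0:
            return
        if cur_cigar and cur_cigar[-1][0] == op:
            cur_cigar[-1] = (op, cur_cigar[-1][1] + n)
        else:
            cur_cigar.append((op, n))

    for op, n in cigar:
        if op in "MD":
            while n > 0:
                room = L - rpos + 1
                take = min(n, room)
                push(op, take)
                if op == "M":
                    q += take
                rpos += take
                n -= take
                if rpos == L + 1:
                    flush(q)
                    rpos = 1
                    cur_start = 1
        elif op == "I":
            push("I", n)
            q += n
    flush(q)
    return pieces


def _emitted_base(read_start: int, cigar: list[tuple[str, int]], seq: str, p: int):
    """Base this read emits at reference position p, or None (deleted/uncovered)."""
    rpos, q = read_start, 0
    for op, n in cigar:
        if op == "M":
            if rpos <= p < rpos + n:
                return seq[q + (p - rpos)]
            rpos += n
            q += n
        elif op == "I":
            q += n
        elif op == "D":
            if rpos <= p < rpos + n:
                return None
            rpos += n
        elif op == "S":
            q += n
    return None


def _has_insertion(read_start, cigar, seq, anchor: int, ins: str) -> bool:
    rpos, q = read_start, 0
    for op, n in cigar:
        if op == "M":
            rpos += n
            q += n
        elif op == "I":
            if rpos - 1 == anchor and n == len(ins) and seq[q : q + n] == ins:
                return True
            q += n
        elif op == "D":
            rpos += n
    return False


def _has_deletion(read_start, cigar, start: int, k: int) -> bool:
    rpos = read_start
    for op, n in cigar:
        if op == "M":
            rpos += n
        elif op == "D":
            if rpos == start and n == k:
                return True
            rpos += n
    return False


# ----------------------------------------------------------------------


def simulate_alignments(
    ref: CircularReference, config: SimulationConfig
) -> tuple[list[AlignedRead], pd.DataFrame]:
    """Generate paired reads and the per-variant truth table.

    Returns ``(reads, truth)`` where ``truth`` has one row per planted
    variant with columns pos, vtype, ref_allele, alt_allele, planted_hf,
    cover, support, realized_hf.
    """
    _validate_planted(ref, tuple(config.planted))
    rng = np.random.default_rng(config.seed)
    L = ref.length
    rl = config.read_length
    n_frag = max(1, int(round(config.target_depth * L / (2 * rl))))

    flens = np.clip(
        np.round(rng.normal(config.fragment_mean, config.fragment_sd, n_frag)),
        rl,
        L,
    ).astype(int)
    if config.allow_origin_spanning:
        fstarts = rng.integers(1, L + 1, n_frag)
    else:
        fstarts = np.array([rng.integers(1, L - fl + 2) for fl in flens], dtype=int)

    planted = list(config.planted)
    if planted:
        carry = rng.random((n_frag, len(planted))) < np.array(
            [v.target_hf for v in planted]
        )
    else:
        carry = np.zeros((n_frag, 0), dtype=bool)

    cover = np.zeros(len(planted), dtype=int)
    support = np.zeros(len(planted), dtype=int)

    base_arr = np.frombuffer(("".join(BASES)).encode(), dtype=np.uint8)

    def make_quals(n: int) -> np.ndarray:
        q = np.round(rng.normal(config.qs_mean, config.qs_sd, n)).astype(int)
        return np.clip(q, config.qs_floor, 60)

    def inject_errors(seq: str, quals: np.ndarray) -> tuple[str, np.ndarray]:
        if config.error_rate == 0:
            return seq, quals
        mask = rng.random(len(seq)) < config.error_rate
        if not mask.any():
            return seq, quals
        chars = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        for i in np.nonzero(mask)[0]:
            choices = base_arr[base_arr != chars[i]]
            chars[i] = rng.choice(choices)
        quals = quals.copy()
        quals[mask] = np.maximum(config.qs_floor, quals[mask] - 15)
        return chars.tobytes().decode(), quals

    reads: list[AlignedRead] = []
    # per-fragment geometry cache for duplicate re-emission
    frag_cache: list[tuple[list, str]] = []

    def build_fragment(fi: int) -> tuple[list, str, dict[int, int]]:
        """ops, query and the unrolled position of each carried variant."""
        fstart, flen = int(fstarts[fi]), int(flens[fi])
        fend = fstart + flen - 1
        carried: list[PlantedVariant] = []
        p_eff: dict[int, int] = {}
        for j in np.nonzero(carry[fi])[0]:
            v = planted[j]
            pos = None
            if fstart <= v.pos <= fend:
                pos = v.pos
            elif fstart <= v.pos + L <= fend:
                pos = v.pos + L
            if pos is not None:
                carried.append(replace(v, pos=pos))
                p_eff[int(j)] = pos
        if carried:
            ops, subs = _fragment_ops(ref, fstart, fend, carried)
            query = _fragment_query(ref, ops, subs)
        else:
            ops = [("M", fstart, flen)]
            query = ref.slice(fstart, flen)
        return ops, query, p_eff

    def mate_windows(qlen: int) -> tuple[tuple[int, int], tuple[int, int]]:
        return (0, min(rl, qlen)), (max(0, qlen - rl), qlen)

    def emit_fragment(fi: int, ops, query, qname: str, p_eff: dict[int, int] | None):
        qlen = len(query)
        mates = []
        for q0, q1 in mate_windows(qlen):
            start_ref, cigar = _slice_alignment(ops, q0, q1)
            seq = query[q0:q1]
            quals = make_quals(len(seq))
            seq, quals = inject_errors(seq, quals)
            mates.append((start_ref, cigar, seq, [int(x) for x in quals]))

        if p_eff is not None:  # truth accounting on unrolled coordinates
            for widx, (start_ref, cigar, seq, quals) in enumerate(mates):
                read_end = start_ref + sum(n for op, n in cigar if op in "MDN") - 1
                for j, pos in p_eff.items():
                    v = planted[j]
                    if not start_ref <= pos <= read_end:
                        continue
                    cover[j] += 1
                    if v.vtype == "mismatch":
                        if _emitted_base(start_ref, cigar, seq, pos) == v.alt_allele:
                            support[j] += 1
                    elif v.vtype == "insertion":
                        if _has_insertion(start_ref, cigar, seq, pos, v.alt_allele):
                            support[j] += 1
                    else:
                        if _has_deletion(start_ref, cigar, pos, len(v.ref_allele)):
                            support[j] += 1
                # a non-carrying read still covers the variant position
                for j, v in enumerate(planted):
                    if j in p_eff:
                        continue
                    for pos in (v.pos, v.pos + L):
                        if start_ref <= pos <= read_end:
                            cover[j] += 1
                            break

        wraps = any(s + sum(n for op, n in cig if op in "MD") - 1 > L for s, cig, _, _ in mates)
        if not wraps and all(s <= L for s, *_ in mates):
            span2 = sum(n for op, n in mates[1][1] if op in "MD")
            tlen = mates[1][0] + span2 - mates[0][0]
            for widx, (start_ref, cigar, seq, quals) in enumerate(mates):
                reads.append(
                    AlignedRead(
                        qname=qname,
                        flag=(99, 147)[widx],
                        rname=ref.name,
                        pos=start_ref,
                        mapq=60,
                        cigar=cigar,
                        seq=seq,
                        qual=quals,
                        rnext="=",
                        pnext=mates[1 - widx][0],
                        tlen=tlen if widx == 0 else -tlen,
                    )
                )
        else:
            # origin-spanning fragment: emit each piece as an unpaired record
            for widx, (start_ref, cigar, seq, quals) in enumerate(mates):
                pieces = _split_at_origin(start_ref, cigar, seq, quals, L)
                for k, (ps, pcig, pseq, pqual) in enumerate(pieces):
                    reads.append(
                        AlignedRead(
                            qname=f"{qname}/{widx + 1}{chr(97 + k)}",
                            flag=16 if widx == 1 else 0,
                            rname=ref.name,
                            pos=ps,
                            mapq=60,
                            cigar=pcig,
                            seq=pseq,
                            qual=pqual,
                            rnext="*",
                            pnext=0,
                            tlen=0,
                        )
                    )

    for fi in range(n_frag):
        ops, query, p_eff = build_fragment(fi)
        emit_fragment(fi, ops, query, f"frag{fi:06d}", p_eff)
        frag_cache.append((ops, query))

    # PCR duplicates: re-emit a fraction of fragments with fresh qualities
    n_dup = int(round(config.duplicate_rate * n_frag))
    if n_dup:
        dup_idx = sorted(int(i) for i in rng.choice(n_frag, size=n_dup, replace=False))
        for k, fi in enumerate(dup_idx):
            ops, query = frag_cache[fi]
            emit_fragment(fi, ops, query, f"frag{fi:06d}.dup{k}", None)

    truth = pd.DataFrame(
        {
            "pos": [v.pos for v in planted],
            "vtype": [v.vtype for v in planted],
            "ref_allele": [v.ref_allele for v in planted],
            "alt_allele": [v.alt_allele for v in planted],
            "planted_hf": [v.target_hf for v in planted],
            "cover": cover,
            "support": support,
        }
    )
    truth["realized_hf"] = np.where(
        truth["cover"] > 0, truth["support"] / truth["cover"].clip(lower=1), np.nan
    )
    return reads, truth


def simulate_reads(
    ref: CircularReference, config: SimulationConfig
) -> tuple[str, pd.DataFrame]:
    """Like :func:`simulate_alignments`, but returns SAM text."""
    reads, truth = simulate_alignments(ref, config)
    buf = io.StringIO()
    write_sam(reads, ref, buf)
    return buf.getvalue(), truth


# ----------------------------------------------------------------------
# cohort fixtures


@dataclass
class CohortFixture:
    """A synthetic cohort: reference, haplogroup table, per-sample reads."""

    reference: CircularReference
    definitions: list  # HaplogroupDefinition
    sam_texts: dict[str, str]
    truths: dict[str, pd.DataFrame]
    planted: dict[str, list[PlantedVariant]]
    metadata: pd.DataFrame


def make_haplogroup_definitions(
    ref: CircularReference,
    n_haplogroups: int = 5,
    sites_per_hg: int = 10,
    seed: int = 0,
    margin: int = 60,
):
    """Synthetic Phylotree-style definitions: disjoint defining sites per clade."""
    from .consensus import HaplogroupDefinition

    rng = np.random.default_rng(seed)
    usable = np.arange(margin + 1, ref.length - margin)
    picks = rng.choice(usable, size=n_haplogroups * sites_per_hg, replace=False)
    defs = []
    for h in range(n_haplogroups):
        sites = []
        for pos in sorted(int(p) for p in picks[h * sites_per_hg : (h + 1) * sites_per_hg]):
            refbase = ref.base(pos)
            alt = rng.choice([b for b in BASES if b != refbase])
            sites.append((pos, str(alt)))
        defs.append(HaplogroupDefinition(name=f"HG{h + 1}", defining_sites=tuple(sites)))
    return defs


def make_fixture_cohort(
    n_samples: int = 20,
    seed: int = 0,
    ref: CircularReference | None = None,
    definitions=None,
    ref_length: int = 2000,
    n_haplogroups: int = 5,
    sites_per_hg: int = 10,
    n_private: int = 3,
    target_depth: float = 80.0,
    read_length: int = 80,
    fragment_mean: float = 200.0,
    fragment_sd: float = 25.0,
    error_rate: float = 0.0,
    duplicate_rate: float = 0.1,
    outdir: str | None = None,
) -> CohortFixture:
    """Simulate a cohort of samples drawn from synthetic haplogroups.

    Each sample carries all defining mismatches of its haplogroup at HF 1.0
    plus ``n_private`` private heteroplasmic mismatches; population labels
    follow the haplogroup, and EBV coverage cycles through blood (0), LCL
    (>400) and intermediate values for source-classification tests.
    Defining sites are kept one fragment length away from the origin so that
    they sit at full depth even without origin-spanning fragments.
    """
    rng = np.random.default_rng(seed)
    if ref is None:
        ref = simulate_reference(ref_length, seed=int(rng.integers(2**31 - 1)))
    if definitions is None:
        definitions = make_haplogroup_definitions(
            ref,
            n_haplogroups,
            sites_per_hg,
            seed=int(rng.integers(2**31 - 1)),
            margin=int(fragment_mean) + 60,
        )
    defined_positions = {p for d in definitions for p, _ in d.defining_sites}

    sam_texts: dict[str, str] = {}
    truths: dict[str, pd.DataFrame] = {}
    planted_map: dict[str, list[PlantedVariant]] = {}
    meta_rows = []
    for i in range(n_samples):
        sample = f"S{i + 1:03d}"
        hg = definitions[i % len(definitions)]
        planted = [
            PlantedVariant(
                pos=p, vtype="mismatch", ref_allele=ref.base(p), alt_allele=a, target_hf=1.0
            )
            for p, a in hg.defining_sites
        ]
        taken = set(defined_positions)
        for _ in range(n_private):
            while True:
                p = int(rng.integers(40, ref.length - 40))
                if p not in taken:
                    taken.add(p)
                    break
            refbase = ref.base(p)
            alt = str(rng.choice([b for b in BASES if b != refbase]))
            hf = float(rng.choice([0.05, 0.2, 0.4, 0.6, 0.8, 0.95]))
            planted.append(
                PlantedVariant(
                    pos=p, vtype="mismatch", ref_allele=refbase, alt_allele=alt, target_hf=hf
                )
            )
        config = SimulationConfig(
            planted=tuple(planted),
            read_length=read_length,
            fragment_mean=fragment_mean,
            fragment_sd=fragment_sd,
            target_depth=target_depth,
            duplicate_rate=duplicate_rate,
            error_rate=error_rate,
            seed=int(rng.integers(2**31 - 1)),
        )
        sam_text, truth = simulate_reads(ref, config)
        sam_texts[sample] = sam_text
        truths[sample] = truth
        planted_map[sample] = planted
        mod = i % 3
        ebv = 0.0 if mod == 0 else (float(rng.uniform(401, 1200)) if mod == 1 else float(rng.uniform(10, 400)))
        meta_rows.append(
            {
                "sample": sample,
                "population": f"POP_{hg.name}",
                "gender": "F" if i % 2 == 0 else "M",
                "ebv_coverage": round(ebv, 1),
                "haplogroup": hg.name,
            }
        )
    metadata = pd.DataFrame(meta_rows)

    fixture = CohortFixture(
        reference=ref,
        definitions=definitions,
        sam_texts=sam_texts,
        truths=truths,
        planted=planted_map,
        metadata=metadata,
    )
    if outdir is not None:
        import os

        from .consensus import write_haplogroup_definitions

        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "reference.fasta"), "w") as fh:
            fh.write(f">{ref.name}\n{ref.sequence}\n")
        with open(os.path.join(outdir, "haplogroups.tsv"), "w") as fh:
            write_haplogroup_definitions(definitions, fh)
        metadata.to_csv(os.path.join(outdir, "metadata.tsv"), sep="\t", index=False)
        for sample, text in sam_texts.items():
            with open(os.path.join(outdir, f"{sample}.sam"), "w") as fh:
                fh.write(text)
            truths[sample].to_csv(
                os.path.join(outdir, f"{sample}.truth.tsv"), sep="\t", index=False
            )
    return fixture
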