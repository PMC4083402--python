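"""Per-position allele/quality pileup tables and coverage summaries.

The pileup is the substrate of all calling: per 1-based position it holds
base counts, the number of deletion-spanning reads, and Phred histograms per
base (so exact medians are available without storing every value).  Total
depth ``rd`` at a position counts matched bases plus deletion-spanning reads
— deletions are evidence about the position and must sit in the HF
denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignedRead, walk_cigar
from .reference import CircularReference, LocusAnnotation

log = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
QMAX = 93  # highest representable Phred in SAM text

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def median_from_hist(hist: np.ndarray) -> float:
    """Exact median of the multiset encoded by a count histogram (empty -> 0)."""
    n = int(hist.sum())
    if n == 0:
        return 0.0
    cum = np.cumsum(hist)
    lo = int(np.searchsorted(cum, (n + 1) // 2))
    if n % 2 == 1:
        return float(lo)
    hi = int(np.searchsorted(cum, n // 2 + 1))
    return (lo + hi) / 2.0


def median(values) -> float:
    vals = sorted(values)
    if not vals:
        return 0.0
    n = len(vals)
    mid = n // 2
    if n % 2 == 1:
        return float(vals[mid])
    return (vals[mid - 1] + vals[mid]) / 2.0


@dataclass
class SitePileup:
    """Read-level evidence at one reference position."""

    pos: int
    counts: dict[str, int]
    del_count: int
    quals: dict[str, list[int]]
    median_qs: float

    @property
    def rd(self) -> int:
        return sum(self.counts.values()) + self.del_count


@dataclass
class InsertionPileup:
    """Merged support for one inserted sequence at one 5' anchor position."""

    anchor_pos: int
    inserted_seq: str
    support: int
    ins_quals: list[int]
    anchor_rd: int


@dataclass
class CoverageSummary:
    breadth: float
    mean_depth: float
    per_locus: dict[str, tuple[float, float]]
    gap_count: int


class PileupTable:
    """Array-backed pileup over all positions 1..L of a circular reference.

    ``counts``:   (L, 4) int — A/C/G/T match counts per position.
    ``del_count``:(L,) int   — reads whose deletion spans the position.
    ``qhist``:    (L, 4, QMAX+1) int — Phred histogram per position and base.
    ``insertions``: (anchor_pos, inserted_seq) -> list of per-read median Phreds.
    ``deletions``:  (start_pos, del_len) -> supporting read count.
    """

    def __init__(self, ref: CircularReference):
        self.ref = ref
        L = ref.length
        self.counts = np.zeros((L, 4), dtype=np.int32)
        self.del_count = np.zeros(L, dtype=np.int32)
        self.qhist = np.zeros((L, 4, QMAX + 1), dtype=np.int32)
        self.insertions: dict[tuple[int, str], list[int]] = {}
        self.deletions: dict[tuple[int, int], int] = {}

    # ------------------------------------------------------------------
    @property
    def L(self) -> int:
        return self.ref.length

    @property
    def rd(self) -> np.ndarray:
        return self.counts.sum(axis=1) + self.del_count

    def rd_at(self, pos: int) -> int:
        i = self.ref.normalize(pos) - 1
        return int(self.counts[i].sum() + self.del_count[i])

    def add_read(self, read: AlignedRead) -> None:
        """Accumulate one mapped read (vectorized over M segments)."""
        L = self.L
        rpos = read.pos
        q = 0
        seq_codes = _BASE_CODE[np.frombuffer(read.seq.encode(), dtype=np.uint8)]
        quals = np.asarray(read.qual, dtype=np.int64)
        for op, n in read.cigar:
            if op in "M=X":
                idx = (rpos - 1 + np.arange(n)) % L
                codes = seq_codes[q : q + n]
                ok = codes >= 0  # non-ACGT read bases carry no evidence
                if ok.all():
                    np.add.at(self.counts, (idx, codes), 1)
                    np.add.at(
                        self.qhist, (idx, codes, np.minimum(quals[q : q + n], QMAX)), 1
                    )
                else:
                    np.add.at(self.counts, (idx[ok], codes[ok]), 1)
                    np.add.at(
                        self.qhist,
                        (idx[ok], codes[ok], np.minimum(quals[q : q + n][ok], QMAX)),
                        1,
                    )
                rpos += n
                q += n
            elif op == "I":
                anchor = (rpos - 2) % L + 1
                key = (anchor, read.seq[q : q + n])
                self.insertions.setdefault(key, []).extend(read.qual[q : q + n])
                q += n
            elif op == "D":
                start = (rpos - 1) % L + 1
                idx = (rpos - 1 + np.arange(n)) % L
                self.del_count[idx] += 1
                key = (start, n)
                self.deletions[key] = self.deletions.get(key, 0) + 1
                rpos += n
            elif op == "S":
                q += n
            elif op == "N":
                rpos += n
        # insertion support counting: reads contribute one unit per event; the
        # qual list length is support * len(seq), see insertion_pileups()

    def site(self, pos: int) -> SitePileup:
        i = self.ref.normalize(pos) - 1
        counts = {b: int(self.counts[i, BASE_INDEX[b]]) for b in BASES}
        quals = {
            b: [
                int(qv)
                for qv in np.repeat(
                    np.arange(QMAX + 1), self.qhist[i, BASE_INDEX[b]]
                )
            ]
            for b in BASES
        }
        pooled = self.qhist[i].sum(axis=0)
        return SitePileup(
            pos=self.ref.normalize(pos),
            counts=counts,
            del_count=int(self.del_count[i]),
            quals=quals,
            median_qs=median_from_hist(pooled),
        )

    def base_median_qs(self, pos: int, base: str) -> float:
        i = self.ref.normalize(pos) - 1
        return median_from_hist(self.qhist[i, BASE_INDEX[base]])

    def site_median_qs(self, pos: int) -> float:
        i = self.ref.normalize(pos) - 1
        return median_from_hist(self.qhist[i].sum(axis=0))

    def insertion_pileups(self) -> list[InsertionPileup]:
        """Merged insertion records with anchor depth snapshotted now."""
        out = []
        for (anchor, seq), quals in sorted(self.insertions.items()):
            support = len(quals) // len(seq)
            out.append(
                InsertionPileup(
                    anchor_pos=anchor,
                    inserted_seq=seq,
                    support=support,
                    ins_quals=list(quals),
                    anchor_rd=self.rd_at(anchor),
                )
            )
        return out

    def to_tsv(self, handle) -> None:
        """Per-position table: pos, A, C, G, T, del, rd, median_qs."""
        handle.write("pos\tA\tC\tG\tT\tdel\trd\tmedian_qs\n")
        rd = self.rd
        for i in range(self.L):
            handle.write(
                f"{i + 1}\t"
                + "\t".join(str(int(self.counts[i, j])) for j in range(4))
                + f"\t{int(self.del_count[i])}\t{int(rd[i])}\t"
                + f"{median_from_hist(self.qhist[i].sum(axis=0)):g}\n"
            )


def build_pileup(
    reads: list[AlignedRead],
    ref: CircularReference,
    use_duplicates: bool = False,
) -> PileupTable:
    """Aggregate mapped primary reads into a :class:`PileupTable`.

    Duplicate-flagged reads are excluded unless ``use_duplicates`` is set.
    Every position 1..L is present (zero-filled).
    """
    table = PileupTable(ref)
    for r in reads:
        if r.is_unmapped or r.is_secondary:
            continue
        if r.is_duplicate and not use_duplicates:
            continue
        table.add_read(r)
    return table


def summarize_coverage(
    pileup: PileupTable,
    loci: list[LocusAnnotation] | None = None,
    min_rd: int = 5,
) -> CoverageSummary:
    """Breadth, mean depth, per-locus medians and gap count (rd < min_rd)."""
    rd = pileup.rd
    breadth = float((rd >= 1).mean())
    mean_depth = float(rd.mean())
    per_locus: dict[str, tuple[float, float]] = {}
    if loci:
        for lc in loci:
            if lc.start <= lc.end:
                positions = list(range(lc.start, lc.end + 1))
            else:
                positions = list(range(lc.start, pileup.L + 1)) + list(
                    range(1, lc.end + 1)
                )
            depths = [int(rd[p - 1]) for p in positions]
            qs = [pileup.site_median_qs(p) for p in positions]
            per_locus[lc.locus] = (median(depths), median(qs))
    gap_count = int((rd < min_rd).sum())
    return CoverageSummary(
        breadth=breadth, mean_depth=mean_depth, per_locus=per_locus, gap_count=gap_count
    )
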