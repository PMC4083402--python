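"""Circular mitochondrial reference handling, locus annotation and homopolymer track.

The human mtDNA reference (rCRS-style) is a circular molecule; positions are
1-based inclusive throughout the toolkit, matching the ``m.3946G>A`` convention
of the mitochondrial literature.  Conversion to 0-based half-open coordinates
happens only at BED boundaries.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

from Bio import SeqIO

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

LOCUS_CLASSES = ("protein_coding", "tRNA", "rRNA", "control", "intergenic", "other")


class ReferenceFormatError(ValueError):
    """Raised for malformed reference FASTA or locus tables."""


@dataclass(frozen=True)
class CircularReference:
    """A circular nucleotide sequence with 1-based modular coordinates."""

    name: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def normalize(self, p: int) -> int:
        """Map any integer position onto 1..L (circular wrap)."""
        return (p - 1) % self.length + 1

    def base(self, p: int) -> str:
        return self.sequence[self.normalize(p) - 1]

    def slice(self, start: int, length: int) -> str:
        """Circular substring of ``length`` bases beginning at 1-based ``start``."""
        out = []
        for i in range(length):
            out.append(self.base(start + i))
        return "".join(out)


@dataclass(frozen=True)
class LocusAnnotation:
    """A named mtDNA locus; ``start > end`` denotes a wrap-around interval."""

    locus: str
    start: int
    end: int
    klass: str = "other"

    def length(self, L: int) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return L - self.start + 1 + self.end

    def contains(self, p: int) -> bool:
        if self.start <= self.end:
            return self.start <= p <= self.end
        return p >= self.start or p <= self.end


@dataclass(frozen=True)
class HomopolymerRun:
    """Maximal run of >=2 identical bases; may wrap across the origin."""

    start: int
    base: str
    run_length: int

    def positions(self, L: int) -> list[int]:
        return [(self.start - 1 + i) % L + 1 for i in range(self.run_length)]


def load_reference(source) -> CircularReference:
    """Read exactly one FASTA record into a :class:`CircularReference`.

    ``source`` may be a path or an open text handle.  Sequence is uppercased;
    characters outside A/C/G/T/N and multi-record input are rejected.
    """
    if isinstance(source, str):
        handle = open(source)
        close = True
    else:
        handle = source
        close = False
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if close:
            handle.close()
    if not records:
        raise ReferenceFormatError("empty FASTA stream: no records found")
    if len(records) > 1:
        raise ReferenceFormatError(
            f"multiple records in reference FASTA ({len(records)}); exactly one expected"
        )
    rec = records[0]
    seq = str(rec.seq).upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ReferenceFormatError(
            f"illegal characters in reference sequence: {sorted(bad)}"
        )
    if not seq:
        raise ReferenceFormatError("reference record has empty sequence")
    return CircularReference(name=rec.id, sequence=seq)


def reference_from_string(name: str, sequence: str) -> CircularReference:
    return load_reference(io.StringIO(f">{name}\n{sequence}\n"))


def normalize_position(ref: CircularReference, p: int) -> int:
    """((p-1) mod L) + 1 — circular coordinate normalization."""
    return ref.normalize(p)


def find_homopolymers(ref: CircularReference, circular: bool = True) -> list[HomopolymerRun]:
    """Maximal homopolymer runs (length >= 2), sorted by start position.

    A run crossing the origin is reported once, with ``start`` near the end of
    the sequence and wrap semantics.  'N' bases never join a run.
    """
    s = ref.sequence
    L = len(s)
    if L == 0:
        return []
    # linear maximal runs
    runs: list[tuple[int, str, int]] = []  # (start0, base, length)
    i = 0
    while i < L:
        j = i
        while j + 1 < L and s[j + 1] == s[i]:
            j += 1
        runs.append((i, s[i], j - i + 1))
        i = j + 1
    if circular and len(runs) > 1 and runs[0][1] == runs[-1][1]:
        # first and last linear runs share a base across the origin: merge
        first = runs.pop(0)
        last = runs.pop()
        runs.append((last[0], last[1], last[2] + first[2]))
    elif circular and len(runs) == 1:
        pass  # whole sequence is one run; already maximal
    out = [
        HomopolymerRun(start=start0 + 1, base=base, run_length=n)
        for start0, base, n in runs
        if n >= 2 and base != "N"
    ]
    out.sort(key=lambda r: r.start)
    return out


def in_homopolymer(runs: list[HomopolymerRun], p: int, L: int) -> bool:
    """True when 1-based position ``p`` lies inside any run (wrap-aware)."""
    for r in runs:
        end = r.start + r.run_length - 1
        if end <= L:
            if r.start <= p <= end:
                return True
        else:  # wraps
            if p >= r.start or p <= end - L:
                return True
    return False


def locus_of(loci: list[LocusAnnotation], p: int) -> list[str]:
    """All locus labels containing position ``p``; empty list means intergenic."""
    return [lc.locus for lc in loci if lc.contains(p)]


def load_loci(source, L: int | None = None) -> list[LocusAnnotation]:
    """Read a locus table: BED (0-based half-open) or headered 1-based TSV.

    The TSV dialect has columns ``locus  start  end  class`` with a header
    line; anything else is treated as BED (chrom start end name [class]).
    """
    if isinstance(source, str):
        handle = open(source)
        close = True
    else:
        handle = source
        close = False
    loci: list[LocusAnnotation] = []
    try:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    finally:
        if close:
            handle.close()
    if not lines:
        return loci
    header_is_tsv = lines[0].lower().split("\t")[0] == "locus"
    if header_is_tsv:
        cols = lines[0].lower().split("\t")
        for ln in lines[1:]:
            parts = ln.split("\t")
            row = dict(zip(cols, parts))
            loci.append(
                LocusAnnotation(
                    locus=row["locus"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    klass=row.get("class", "other") or "other",
                )
            )
    else:
        for ln in lines:
            if ln.startswith(("#", "track", "browser")):
                continue
            parts = ln.split("\t")
            start0, end1 = int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{parts[0]}:{start0}-{end1}"
            klass = parts[4] if len(parts) > 4 and parts[4] in LOCUS_CLASSES else "other"
            loci.append(LocusAnnotation(locus=name, start=start0 + 1, end=end1, klass=klass))
    for lc in loci:
        if lc.start < 1 or lc.end < 1:
            raise ReferenceFormatError(f"locus {lc.locus}: positions must be >= 1")
        if L is not None and (lc.start > L or lc.end > L):
            raise ReferenceFormatError(f"locus {lc.locus}: coordinates exceed reference length {L}")
    return loci


def intergenic_length(loci: list[LocusAnnotation], L: int) -> int:
    """Number of positions covered by no locus."""
    covered = [False] * (L + 1)
    for lc in loci:
        start, end = lc.start, lc.end
        if start <= end:
            rng = range(start, end + 1)
        else:
            rng = list(range(start, L + 1)) + list(range(1, end + 1))
        for p in rng:
            covered[p] = True
    return L - sum(covered[1:])
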