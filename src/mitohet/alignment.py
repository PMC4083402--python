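"""SAM parsing, CIGAR walking into per-position events, and PCR-duplicate marking.

Field-level SAM record parsing is delegated to pysam; this module wraps it to
give per-line error reporting, validates the CIGAR/sequence length contract,
and implements the event model (match/insertion/deletion) on which variant
calling operates.  All reference positions are 1-based and normalized onto the
circular reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pysam

from .reference import CircularReference

log = logging.getLogger(__name__)

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800

QUERY_CONSUMING = set("MIS=X")
REF_CONSUMING = set("MD=XN")
CIGAR_OPS = "MIDNSHP=X"


class SamFormatError(ValueError):
    """Raised for unrecoverable SAM format problems."""


@dataclass
class AlignedRead:
    """One SAM alignment record (mutable duplicate flag)."""

    qname: str
    flag: int
    rname: str
    pos: int  # 1-based leftmost mapped position
    mapq: int
    cigar: list[tuple[str, int]]
    seq: str
    qual: list[int]  # per-base Phred integers
    rnext: str = "*"
    pnext: int = 0  # 1-based or 0 when absent
    tlen: int = 0

    # -- flag accessors -------------------------------------------------
    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY))

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & FLAG_DUPLICATE)

    def set_duplicate(self, value: bool) -> None:
        if value:
            self.flag |= FLAG_DUPLICATE
        else:
            self.flag &= ~FLAG_DUPLICATE

    # -- derived geometry ----------------------------------------------
    def reference_span(self) -> int:
        """Number of reference positions consumed by the alignment."""
        return sum(n for op, n in self.cigar if op in REF_CONSUMING)

    def reference_end(self) -> int:
        """1-based last consumed reference position (not normalized)."""
        return self.pos + self.reference_span() - 1

    def unclipped_start(self) -> int:
        lead = 0
        for op, n in self.cigar:
            if op in "SH":
                lead += n
            else:
                break
        return self.pos - lead

    def unclipped_end(self) -> int:
        trail = 0
        for op, n in reversed(self.cigar):
            if op in "SH":
                trail += n
            else:
                break
        return self.reference_end() + trail

    def five_prime_coordinate(self) -> int:
        """Unclipped 5' coordinate (fragment-orientation aware)."""
        return self.unclipped_end() if self.is_reverse else self.unclipped_start()

    def query_length_from_cigar(self) -> int:
        return sum(n for op, n in self.cigar if op in QUERY_CONSUMING)

    def to_sam(self) -> str:
        cig = "".join(f"{n}{op}" for op, n in self.cigar) if self.cigar else "*"
        qual = "".join(chr(q + 33) for q in self.qual) if self.qual else "*"
        return "\t".join(
            [
                self.qname,
                str(self.flag),
                self.rname,
                str(self.pos),
                str(self.mapq),
                cig,
                self.rnext,
                str(self.pnext),
                str(self.tlen),
                self.seq if self.seq else "*",
                qual,
            ]
        )


@dataclass(frozen=True)
class AlignmentEvent:
    """One reference-anchored observation produced by walking a CIGAR.

    ``match_base``: one covered position and its base/Phred.
    ``insertion``: inserted sequence anchored at the reference base 5' of it.
    ``deletion``: first deleted position with ``del_len`` deleted bases.
    """

    kind: str  # match_base | insertion | deletion
    ref_pos: int
    bases: str
    quals: tuple[int, ...] = ()
    del_len: int = 0


def _cigar_from_pysam(seg: pysam.AlignedSegment) -> list[tuple[str, int]]:
    return [(CIGAR_OPS[op], n) for op, n in (seg.cigartuples or [])]


def _header_for(reference: CircularReference | None, sq: list[tuple[str, int]]):
    if sq:
        return pysam.AlignmentHeader.from_references(
            [name for name, _ in sq], [ln for _, ln in sq]
        )
    if reference is not None:
        return pysam.AlignmentHeader.from_references([reference.name], [reference.length])
    # headerless input with no reference supplied: permissive catch-all
    return None


def read_sam(
    source,
    reference: CircularReference | None = None,
    include_unmapped: bool = False,
    include_secondary: bool = False,
    strict: bool = False,
) -> list[AlignedRead]:
    """Parse SAM text into :class:`AlignedRead` records.

    By default yields mapped primary reads only.  Records whose CIGAR does not
    account for the sequence length are rejected individually (counted and
    logged with their line number); unknown CIGAR operations raise.  When a
    header with @SQ is present and a reference is supplied, the reference name
    must match.
    """
    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            lines = fh.read().splitlines()
    elif isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in source]

    sq: list[tuple[str, int]] = []
    body: list[tuple[int, str]] = []
    for lineno, ln in enumerate(lines, start=1):
        if not ln.strip():
            continue
        if ln.startswith("@"):
            if ln.startswith("@SQ"):
                fields = dict(
                    f.split(":", 1) for f in ln.split("\t")[1:] if ":" in f
                )
                sq.append((fields.get("SN", "*"), int(fields.get("LN", 0))))
            continue
        body.append((lineno, ln))

    if sq and reference is not None:
        names = {name for name, _ in sq}
        if reference.name not in names:
            raise SamFormatError(
                f"SAM header references {sorted(names)} but loaded reference is "
                f"{reference.name!r}"
            )

    header = _header_for(reference, sq)
    if header is None:
        # build a permissive header from the reference names seen in the body
        names = sorted({ln.split("\t")[2] for _, ln in body if len(ln.split("\t")) > 2})
        names = [n for n in names if n != "*"] or ["*"]
        header = pysam.AlignmentHeader.from_references(names, [2**29 - 1] * len(names))

    reads: list[AlignedRead] = []
    n_rejected = 0
    for lineno, ln in body:
        try:
            seg = pysam.AlignedSegment.fromstring(ln, header)
        except Exception as exc:  # malformed line
            if strict:
                raise SamFormatError(f"line {lineno}: {exc}") from exc
            log.warning("rejecting malformed SAM line %d: %s", lineno, exc)
            n_rejected += 1
            continue
        cigar = _cigar_from_pysam(seg)
        unknown = [op for op, _ in cigar if op not in CIGAR_OPS]
        if unknown:
            raise SamFormatError(f"line {lineno}: unknown CIGAR op {unknown}")
        seq = seg.query_sequence or ""
        qual = list(seg.query_qualities) if seg.query_qualities is not None else [0] * len(seq)
        read = AlignedRead(
            qname=seg.query_name or "*",
            flag=seg.flag,
            rname=seg.reference_name or "*",
            pos=(seg.reference_start + 1) if seg.reference_start is not None else 0,
            mapq=seg.mapping_quality,
            cigar=cigar,
            seq=seq,
            qual=qual,
            rnext="="
            if seg.next_reference_name == seg.reference_name and seg.next_reference_id >= 0
            else (seg.next_reference_name or "*"),
            pnext=(seg.next_reference_start + 1) if seg.next_reference_start >= 0 else 0,
            tlen=seg.template_length,
        )
        if not read.is_unmapped and cigar and read.query_length_from_cigar() != len(seq):
            log.warning(
                "rejecting SAM line %d (%s): CIGAR accounts for %d query bases, "
                "sequence has %d",
                lineno,
                read.qname,
                read.query_length_from_cigar(),
                len(seq),
            )
            n_rejected += 1
            continue
        if read.is_unmapped and not include_unmapped:
            continue
        if read.is_secondary and not include_secondary:
            continue
        reads.append(read)
    if n_rejected:
        log.info("read_sam rejected %d malformed record(s)", n_rejected)
    return reads


def walk_cigar(read: AlignedRead, ref: CircularReference) -> list[AlignmentEvent]:
    """Expand a mapped read into reference-anchored alignment events.

    M/=/X emit one ``match_base`` per covered position; I emits one
    ``insertion`` anchored at the previous reference position (position L for
    a leading insertion, by circularity); D emits one ``deletion``; S/H
    consume query/nothing.  N skips reference like a deletion but emits no
    event (spliced alignment, unexpected on mtDNA — logged).
    """
    events: list[AlignmentEvent] = []
    rpos = read.pos
    q = 0
    for op, n in read.cigar:
        if op in "M=X":
            for i in range(n):
                events.append(
                    AlignmentEvent(
                        kind="match_base",
                        ref_pos=ref.normalize(rpos + i),
                        bases=read.seq[q + i],
                        quals=(read.qual[q + i],),
                    )
                )
            rpos += n
            q += n
        elif op == "I":
            anchor = ref.normalize(rpos - 1)
            if rpos == read.pos:
                log.debug(
                    "leading insertion in %s anchored at position %d (circular)",
                    read.qname,
                    anchor,
                )
            events.append(
                AlignmentEvent(
                    kind="insertion",
                    ref_pos=anchor,
                    bases=read.seq[q : q + n],
                    quals=tuple(read.qual[q : q + n]),
                )
            )
            q += n
        elif op == "D":
            events.append(
                AlignmentEvent(
                    kind="deletion",
                    ref_pos=ref.normalize(rpos),
                    bases="",
                    del_len=n,
                )
            )
            rpos += n
        elif op == "S":
            q += n
        elif op == "H" or op == "P":
            pass
        elif op == "N":
            log.warning("N CIGAR op in %s treated as reference skip", read.qname)
            rpos += n
        else:  # pragma: no cover - guarded in read_sam
            raise SamFormatError(f"unknown CIGAR op {op!r}")
    return events


def mark_duplicates(
    reads: list[AlignedRead], pair_quality: str = "sum"
) -> list[AlignedRead]:
    """Flag PCR duplicates in place; returns the same list.

    Fragments are grouped by (unclipped 5' start, orientation) of both mates
    — the standard coordinate criterion.  Within a group the record (or pair)
    with the highest summed base quality keeps a clear flag; ties break on
    lexicographically smallest qname.  Idempotent: flags are recomputed from
    scratch on every call.
    """
    for r in reads:
        r.set_duplicate(False)

    mapped = [r for r in reads if not r.is_unmapped and not r.is_secondary]
    # pair up primary mates by qname
    by_name: dict[str, list[AlignedRead]] = {}
    for r in mapped:
        by_name.setdefault(r.qname, []).append(r)

    groups: dict[tuple, list[tuple[str, int, list[AlignedRead]]]] = {}
    for qname, members in by_name.items():
        pair = [r for r in members if r.is_paired]
        if len(pair) == 2:
            key_parts = sorted(
                (r.five_prime_coordinate(), r.is_reverse) for r in pair
            )
            key = ("pair", tuple(key_parts))
            score = sum(sum(r.qual) for r in pair) if pair_quality == "sum" else max(
                sum(r.qual) for r in pair
            )
            groups.setdefault(key, []).append((qname, score, pair))
        else:
            for r in members:
                key = ("single", r.five_prime_coordinate(), r.is_reverse)
                groups.setdefault(key, []).append((qname, sum(r.qual), [r]))

    for key, entries in groups.items():
        entries.sort(key=lambda e: (-e[1], e[0]))
        for qname, _score, recs in entries[1:]:
            for r in recs:
                r.set_duplicate(True)
    return reads


def write_sam(
    reads: list[AlignedRead], reference: CircularReference, handle
) -> None:
    """Emit reads as SAM text with a minimal header."""
    handle.write("@HD\tVN:1.6\tSO:unsorted\n")
    handle.write(f"@SQ\tSN:{reference.name}\tLN:{reference.length}\n")
    for r in reads:
        handle.write(r.to_sam() + "\n")
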