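"""Mismatch/insertion/deletion calling with quality, depth and flank filters.

Heteroplasmic fraction (HF) is the variant read depth over the total read
depth at the same position — at the 5' anchor position for insertions, at the
first deleted position for deletions.  Filters are inclusive: a candidate
passes at median Phred >= 25 and depth >= 5 exactly.  Deletions are judged on
their 5-bp upstream and downstream flanking regions instead (median QS >= 25
and median rd >= 5 on each side, circular near the origin).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pileup import BASES, BASE_INDEX, InsertionPileup, PileupTable, median, median_from_hist
from .reference import CircularReference

log = logging.getLogger(__name__)

HF_CLASS_LABELS = (
    "≤0.10",
    "0.11-0.20",
    "0.21-0.30",
    "0.31-0.40",
    "0.41-0.50",
    "0.51-0.60",
    "0.61-0.70",
    "0.71-0.80",
    "0.81-0.90",
    "0.91-0.99",
    "1.00",
)


@dataclass(frozen=True)
class FilterThresholds:
    """Calling cut-offs; defaults are the pipeline's published values."""

    min_qs: int = 25  # median Phred per variant (or per flank, deletions)
    min_rd: int = 5  # read depth per position (or per flank, deletions)
    flank_len: int = 5  # bp on each side of a deletion
    consensus_hf: float = 0.75  # fixation threshold for the consensus base
    min_alt_reads: int = 1

    def __post_init__(self):
        if not 0 < self.consensus_hf <= 1:
            raise ValueError("consensus_hf must lie in (0, 1]")
        if min(self.min_qs, self.min_rd, self.flank_len, self.min_alt_reads) < 0:
            raise ValueError("thresholds must be nonnegative")


@dataclass(frozen=True)
class VariantCall:
    """One called mismatch, insertion or deletion with its HF."""

    pos: int
    ref_allele: str
    alt_allele: str
    vtype: str  # mismatch | insertion | deletion
    alt_depth: int
    total_depth: int
    hf: float
    median_qs: float
    filter_status: str  # PASS | fail_qs | fail_rd | fail_flank

    @property
    def zygosity(self) -> str:
        return "homoplasmic" if round(self.hf, 2) == 1.0 else "heteroplasmic"

    @property
    def is_pass(self) -> bool:
        return self.filter_status == "PASS"


def classify_hf(hf: float) -> str:
    """Bin an HF into the eleven heteroplasmy classes (2-decimal rounding)."""
    if hf <= 0:
        raise ValueError(f"HF must be positive, got {hf}")
    cents = int(round(round(hf, 2) * 100))
    if cents <= 10:
        return HF_CLASS_LABELS[0]
    if cents >= 100:
        return HF_CLASS_LABELS[10]
    if cents >= 91:
        return HF_CLASS_LABELS[9]
    return HF_CLASS_LABELS[(cents - 1) // 10]


def call_mismatches(
    pileup: PileupTable,
    ref: CircularReference,
    th: FilterThresholds = FilterThresholds(),
    verbose: bool = False,
) -> list[VariantCall]:
    """Call single-base substitutions from the per-position pileup.

    A candidate alt base passes when the position depth is >= min_rd and the
    median Phred of its supporting bases is >= min_qs.  With ``verbose``,
    failing candidates are emitted with their failure status.
    """
    calls: list[VariantCall] = []
    rd = pileup.rd
    counts = pileup.counts
    # candidate positions: any non-reference base observed
    ref_codes = np.array(
        [BASE_INDEX.get(b, -1) for b in ref.sequence], dtype=np.int64
    )
    nonref = counts.copy()
    valid = ref_codes >= 0
    rows = np.arange(len(ref_codes))[valid]
    nonref[rows, ref_codes[valid]] = 0
    cand_pos = np.nonzero(nonref.sum(axis=1) > 0)[0]
    for i in cand_pos:
        refbase = ref.sequence[i]
        if refbase == "N":
            log.debug("skipping position %d: reference base is N", i + 1)
            continue
        for b in BASES:
            if b == refbase:
                continue
            n_alt = int(counts[i, BASE_INDEX[b]])
            if n_alt < max(th.min_alt_reads, 1):
                continue
            total = int(rd[i])
            mq = median_from_hist(pileup.qhist[i, BASE_INDEX[b]])
            if total < th.min_rd:
                status = "fail_rd"
            elif mq < th.min_qs:
                status = "fail_qs"
            else:
                status = "PASS"
            if status != "PASS" and not verbose:
                continue
            calls.append(
                VariantCall(
                    pos=int(i) + 1,
                    ref_allele=refbase,
                    alt_allele=b,
                    vtype="mismatch",
                    alt_depth=n_alt,
                    total_depth=total,
                    hf=n_alt / total,
                    median_qs=mq,
                    filter_status=status,
                )
            )
    return calls


def call_insertions(
    ins_pileups: list[InsertionPileup],
    pileup: PileupTable,
    th: FilterThresholds = FilterThresholds(),
    ref: CircularReference | None = None,
    verbose: bool = False,
) -> list[VariantCall]:
    """Call insertions; HF uses the depth of the 5' anchor position."""
    ref = ref if ref is not None else pileup.ref
    calls: list[VariantCall] = []
    for ip in ins_pileups:
        if ip.support < max(th.min_alt_reads, 1):
            continue
        mq = median(ip.ins_quals)
        if ip.anchor_rd == 0 or ip.anchor_rd < th.min_rd:
            status = "fail_rd"
        elif mq < th.min_qs:
            status = "fail_qs"
        else:
            status = "PASS"
        if status != "PASS" and not verbose:
            continue
        anchor_base = ref.base(ip.anchor_pos)
        hf = ip.support / ip.anchor_rd if ip.anchor_rd else 0.0
        calls.append(
            VariantCall(
                pos=ip.anchor_pos,
                ref_allele=anchor_base,
                alt_allele=anchor_base + ip.inserted_seq,
                vtype="insertion",
                alt_depth=ip.support,
                total_depth=ip.anchor_rd,
                hf=hf,
                median_qs=mq,
                filter_status=status,
            )
        )
    return calls


def _flank_medians(
    pileup: PileupTable, positions: list[int]
) -> tuple[float, float]:
    """(median rd, median QS) over a set of flank positions.

    rd median is over the per-position depths (zero-depth positions count as
    zeros); QS median pools the match-base Phreds of all flank positions.
    """
    rd = pileup.rd
    depths = [int(rd[pileup.ref.normalize(p) - 1]) for p in positions]
    hist = np.zeros(pileup.qhist.shape[2], dtype=np.int64)
    for p in positions:
        hist += pileup.qhist[pileup.ref.normalize(p) - 1].sum(axis=0)
    return median(depths), median_from_hist(hist)


def call_deletions(
    pileup: PileupTable,
    th: FilterThresholds = FilterThresholds(),
    ref: CircularReference | None = None,
    verbose: bool = False,
) -> list[VariantCall]:
    """Call deletions; goodness is judged on the two 5-bp flanking regions.

    Each side must independently reach median QS >= min_qs and median rd >=
    min_rd.  HF is the supporting-read count over the total depth at the
    first deleted position (deletion-spanning reads included in the
    denominator).
    """
    ref = ref if ref is not None else pileup.ref
    L = ref.length
    calls: list[VariantCall] = []
    for (start, dlen), n_del in sorted(pileup.deletions.items()):
        if dlen >= L:
            log.warning("rejecting malformed deletion at %d: length %d >= L", start, dlen)
            continue
        if n_del < max(th.min_alt_reads, 1):
            continue
        up = [start - k for k in range(th.flank_len, 0, -1)]
        down = [start + dlen + k for k in range(th.flank_len)]
        up_rd, up_qs = _flank_medians(pileup, up)
        down_rd, down_qs = _flank_medians(pileup, down)
        ok = (
            up_rd >= th.min_rd
            and down_rd >= th.min_rd
            and up_qs >= th.min_qs
            and down_qs >= th.min_qs
        )
        status = "PASS" if ok else "fail_flank"
        if status != "PASS" and not verbose:
            continue
        total = pileup.rd_at(start)
        deleted_seq = ref.slice(start, dlen)
        calls.append(
            VariantCall(
                pos=start,
                ref_allele=deleted_seq,
                alt_allele="",
                vtype="deletion",
                alt_depth=n_del,
                total_depth=total,
                hf=n_del / total if total else 0.0,
                median_qs=min(up_qs, down_qs),
                filter_status=status,
            )
        )
    return calls


def call_variants(
    pileup: PileupTable,
    ref: CircularReference,
    th: FilterThresholds = FilterThresholds(),
    verbose: bool = False,
) -> list[VariantCall]:
    """All PASS calls (mismatches, insertions, deletions), sorted by position."""
    calls = (
        call_mismatches(pileup, ref, th, verbose=verbose)
        + call_insertions(pileup.insertion_pileups(), pileup, th, ref=ref, verbose=verbose)
        + call_deletions(pileup, th, ref=ref, verbose=verbose)
    )
    calls.sort(key=lambda c: (c.pos, c.vtype, c.alt_allele))
    return calls


# ----------------------------------------------------------------------
# serialization


def write_vcf(
    calls: list[VariantCall],
    sample_id: str,
    ref: CircularReference,
    handle,
) -> None:
    """VCF 4.2 with left-anchored indels and HF/depths in the sample column."""
    handle.write("##fileformat=VCFv4.2\n")
    handle.write(f"##contig=<ID={ref.name},length={ref.length}>\n")
    handle.write(
        '##FILTER=<ID=PASS,Description="Median QS>=25, rd>=5 '
        '(deletion flanks: median QS>=25 and rd>=5 per side)">\n'
    )
    handle.write('##INFO=<ID=VT,Number=1,Type=String,Description="Variant type">\n')
    handle.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    handle.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
    handle.write(
        '##FORMAT=<ID=VD,Number=1,Type=Integer,Description="Variant-supporting depth">\n'
    )
    handle.write(
        '##FORMAT=<ID=HF,Number=1,Type=Float,Description="Heteroplasmic fraction">\n'
    )
    handle.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id + "\n"
    )
    records = []
    for c in calls:
        if not c.is_pass:
            continue
        if c.vtype == "mismatch":
            pos, vref, valt = c.pos, c.ref_allele, c.alt_allele
        elif c.vtype == "insertion":
            pos, vref, valt = c.pos, c.ref_allele, c.alt_allele
        else:  # deletion: REF includes the preceding base, ALT is that base
            anchor = ref.normalize(c.pos - 1)
            base = ref.base(anchor)
            pos, vref, valt = anchor, base + c.ref_allele, base
        gt = "1" if c.zygosity == "homoplasmic" else "0/1"
        records.append(
            (
                pos,
                f"{ref.name}\t{pos}\t.\t{vref}\t{valt}\t.\tPASS\tVT={c.vtype}\t"
                f"GT:DP:VD:HF\t{gt}:{c.total_depth}:{c.alt_depth}:{c.hf:.4f}",
            )
        )
    for _pos, line in sorted(records, key=lambda r: r[0]):
        handle.write(line + "\n")


def write_bed(calls: list[VariantCall], handle, chrom: str = "chrM") -> None:
    """BED with 0-based start and 1-based end coordinates.

    Mismatch at p -> (p-1, p); deletion of k bases starting at s ->
    (s-1, s+k-1); insertion anchored at a -> (a-1, a).
    """
    for c in calls:
        if not c.is_pass:
            continue
        if c.vtype == "mismatch":
            start, end = c.pos - 1, c.pos
            name = f"mismatch|{c.ref_allele}>{c.alt_allele}|HF={c.hf:.4f}"
        elif c.vtype == "deletion":
            k = len(c.ref_allele)
            start, end = c.pos - 1, c.pos + k - 1
            name = f"deletion|{c.ref_allele}>-|HF={c.hf:.4f}"
        else:
            start, end = c.pos - 1, c.pos
            name = f"insertion|{c.ref_allele}>{c.alt_allele}|HF={c.hf:.4f}"
        handle.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def calls_to_dataframe(
    calls: list[VariantCall], sample_id: str | None = None
) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {
            "pos": c.pos,
            "ref": c.ref_allele,
            "alt": c.alt_allele,
            "vtype": c.vtype,
            "alt_depth": c.alt_depth,
            "total_depth": c.total_depth,
            "hf": c.hf,
            "median_qs": c.median_qs,
            "zygosity": c.zygosity,
            "filter_status": c.filter_status,
            "hf_class": classify_hf(c.hf) if c.hf > 0 else "",
        }
        if sample_id is not None:
            row["sample"] = sample_id
        rows.append(row)
    cols = [
        "pos", "ref", "alt", "vtype", "alt_depth", "total_depth", "hf",
        "median_qs", "zygosity", "filter_status", "hf_class",
    ]
    if sample_id is not None:
        cols = ["sample"] + cols
    return pd.DataFrame(rows, columns=cols)
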