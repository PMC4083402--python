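"""Per-sample consensus genome with IUPAC ambiguity coding and haplogroup scoring.

The consensus is length-preserving: only single-base substitutions are
applied.  A mismatch with HF >= 0.75 fixes the alt base; below that the IUPAC
code covering {reference base} + {called alt bases} is written, so
heteroplasmic information survives into downstream matching.  Positions with
depth below the calling minimum become 'N' (gaps).

Haplogroup assignment scores each user-supplied definition (Phylotree-style
"haplogroup -> defining position/allele" table) by
``P_Hg = Nph / N_ph_exp``: the fraction of expected defining sites whose
consensus character matches the derived allele, IUPAC sets included.  The
assignment is reliable when P_Hg exceeds 0.90 (strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Data.IUPACData import ambiguous_dna_values

from .calling import FilterThresholds, VariantCall
from .pileup import PileupTable
from .reference import CircularReference

log = logging.getLogger(__name__)

# base-set -> IUPAC code (single bases map to themselves; 'X' alias dropped)
IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(bases)
    for code, bases in ambiguous_dna_values.items()
    if code != "X"
}
SET_TO_IUPAC: dict[frozenset[str], str] = {s: c for c, s in IUPAC_SETS.items()}


@dataclass(frozen=True)
class ConsensusSequence:
    """Length-L genome string over ACGTN + IUPAC ambiguity codes."""

    name: str
    sequence: str

    @property
    def gap_count(self) -> int:
        return self.sequence.count("N")

    def to_fasta(self, handle) -> None:
        handle.write(f">{self.name}\n")
        seq = self.sequence
        for i in range(0, len(seq), 70):
            handle.write(seq[i : i + 70] + "\n")


def load_consensus_fasta(source) -> ConsensusSequence:
    """Read one FASTA record that may contain IUPAC ambiguity codes and N."""
    from Bio import SeqIO

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
    if len(records) != 1:
        raise ValueError(f"expected exactly one consensus record, found {len(records)}")
    seq = str(records[0].seq).upper()
    allowed = set("ACGTN") | set(IUPAC_SETS)
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"illegal characters in consensus sequence: {sorted(bad)}")
    return ConsensusSequence(name=records[0].id, sequence=seq)


@dataclass(frozen=True)
class HaplogroupDefinition:
    name: str
    defining_sites: tuple[tuple[int, str], ...]  # (1-based pos, derived allele)


@dataclass(frozen=True)
class HaplogroupAssignment:
    name: str
    n_ph: int
    n_ph_exp: int
    p_hg: float

    @property
    def reliable(self) -> bool:
        return self.p_hg > 0.90


def build_consensus(
    calls: list[VariantCall],
    pileup: PileupTable,
    ref: CircularReference,
    th: FilterThresholds = FilterThresholds(),
    name: str | None = None,
) -> ConsensusSequence:
    """Assemble the consensus: gaps, fixed alts, IUPAC-ambiguous sites.

    Per position: rd < min_rd -> 'N'; one PASS mismatch with
    hf >= consensus_hf -> its alt base; PASS mismatch(es) all below the
    threshold -> IUPAC code over {ref base} + alt bases; otherwise the
    reference base.  Indels are never applied (length preserved).
    """
    seq = list(ref.sequence)
    rd = pileup.rd
    by_pos: dict[int, list[VariantCall]] = {}
    for c in calls:
        if c.is_pass and c.vtype == "mismatch":
            by_pos.setdefault(c.pos, []).append(c)
    for pos, group in by_pos.items():
        i = pos - 1
        if rd[i] < th.min_rd:
            continue  # gap rule below wins
        fixed = [c for c in group if c.hf >= th.consensus_hf]
        assert len(fixed) <= 1, "two alts with HF>=0.75 at one site: HFs would sum >1"
        if fixed:
            seq[i] = fixed[0].alt_allele
        else:
            alleles = frozenset({ref.sequence[i]} | {c.alt_allele for c in group})
            seq[i] = SET_TO_IUPAC[alleles]
    for i in range(ref.length):
        if rd[i] < th.min_rd:
            seq[i] = "N"
    return ConsensusSequence(name=name or f"{ref.name}_consensus", sequence="".join(seq))


def load_haplogroup_definitions(source) -> list[HaplogroupDefinition]:
    """Read a TSV with header ``haplogroup  position  derived_allele``."""
    if isinstance(source, str):
        handle = open(source)
        close = True
    else:
        handle = source
        close = False
    try:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    finally:
        if close:
            handle.close()
    if not lines:
        return []
    cols = lines[0].lower().split("\t")
    sites: dict[str, list[tuple[int, str]]] = {}
    for ln in lines[1:]:
        row = dict(zip(cols, ln.split("\t")))
        sites.setdefault(row["haplogroup"], []).append(
            (int(row["position"]), row["derived_allele"].upper())
        )
    return [
        HaplogroupDefinition(name=name, defining_sites=tuple(sorted(s)))
        for name, s in sorted(sites.items())
    ]


def write_haplogroup_definitions(defs: list[HaplogroupDefinition], handle) -> None:
    handle.write("haplogroup\tposition\tderived_allele\n")
    for d in defs:
        for pos, allele in d.defining_sites:
            handle.write(f"{d.name}\t{pos}\t{allele}\n")


def _matches(consensus_char: str, derived: str) -> bool:
    if consensus_char == "N":
        return False
    return derived in IUPAC_SETS.get(consensus_char, frozenset())


def assign_haplogroup(
    consensus: ConsensusSequence,
    definitions: list[HaplogroupDefinition],
    count_gaps_in_denominator: bool = True,
) -> tuple[HaplogroupAssignment, list[HaplogroupAssignment]]:
    """Score every haplogroup and return (best, full ranking).

    Nph counts defining sites whose consensus character contains the derived
    allele ('N' never matches, but by default still counts in the expected
    denominator — the conservative choice).  Ties break on larger N_ph_exp,
    then lexicographic name.
    """
    if not definitions:
        raise ValueError("haplogroup definitions table is empty")
    L = len(consensus.sequence)
    ranked: list[HaplogroupAssignment] = []
    for d in definitions:
        bad = [p for p, _ in d.defining_sites if not 1 <= p <= L]
        if bad:
            log.warning(
                "rejecting haplogroup definition %s: positions %s exceed sequence "
                "length %d",
                d.name,
                bad,
                L,
            )
            continue
        n_ph = 0
        n_exp = 0
        for pos, allele in d.defining_sites:
            char = consensus.sequence[pos - 1]
            if char == "N" and not count_gaps_in_denominator:
                continue
            n_exp += 1
            if _matches(char, allele):
                n_ph += 1
        ranked.append(
            HaplogroupAssignment(
                name=d.name,
                n_ph=n_ph,
                n_ph_exp=n_exp,
                p_hg=n_ph / n_exp if n_exp else 0.0,
            )
        )
    if not ranked:
        raise ValueError("no valid haplogroup definitions after position checks")
    ranked.sort(key=lambda a: (-a.p_hg, -a.n_ph_exp, a.name))
    return ranked[0], ranked


def write_assignment_table(ranked: list[HaplogroupAssignment], handle) -> None:
    handle.write("haplogroup\tn_ph\tn_ph_exp\tp_hg\treliable\n")
    for a in ranked:
        handle.write(f"{a.name}\t{a.n_ph}\t{a.n_ph_exp}\t{a.p_hg:.4f}\t{a.reliable}\n")
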