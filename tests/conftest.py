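import io

import pytest

from mitohet import reference_from_string, simulate_reference


@pytest.fixture
def tiny_ref():
    """10-bp circular reference for coordinate arithmetic tests."""
    return reference_from_string("tiny", "ACGTACGTAA")


@pytest.fixture
def sim_ref():
    """Deterministic 300-bp reference for pipeline tests."""
    return simulate_reference(300, seed=42)


def sam_line(
    qname="r1",
    flag=0,
    rname="ref",
    pos=1,
    mapq=60,
    cigar="4M",
    rnext="*",
    pnext=0,
    tlen=0,
    seq="ACGT",
    qual=None,
):
    if qual is None:
        qual = "".join(chr(30 + 33) for _ in seq)
    return "\t".join(
        [qname, str(flag), rname, str(pos), str(mapq), cigar, rnext, str(pnext), str(tlen), seq, qual]
    )


def sam_text(ref, lines):
    header = f"@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:{ref.name}\tLN:{ref.length}\n"
    return header + "\n".join(lines) + "\n"
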