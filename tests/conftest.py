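import pytest

from umtcall.panel import AmpliconDef, Hotspot, Panel
from umtcall.reads import ReadRecord

AMP_A_SEQ = "ACGTACGTAACCGGTTACGT"
AMP_B_SEQ = "TTGACCATGGATCCAGTCAA"


def build_panel() -> Panel:
    """Two amplicons with well-separated primer pairs, one hotspot on A."""
    a = AmpliconDef(
        amplicon_id="A",
        chrom="chr1",
        insert_start=101,
        insert_end=120,
        fwd_primer="AAACCCGG",
        rev_primer="GGGTTTCC",
        insert_seq=AMP_A_SEQ,
    )
    b = AmpliconDef(
        amplicon_id="B",
        chrom="chr2",
        insert_start=501,
        insert_end=520,
        fwd_primer="CCCTTTAA",
        rev_primer="TTTAAACC",
        insert_seq=AMP_B_SEQ,
    )
    return Panel(
        amplicons=[a, b],
        hotspots=[Hotspot("chr1", 105, "A", "G", "hs1")],
    )


@pytest.fixture
def panel() -> Panel:
    return build_panel()


def make_read(
    sequence: str,
    umt5: str = "AAAAAA",
    umt3: str = "CCCCCC",
    amplicon_id: str = "A",
    sample: str = "S1",
    read_id: str = "r0",
) -> ReadRecord:
    return ReadRecord(
        read_id=read_id,
        sample=sample,
        amplicon_id=amplicon_id,
        sequence=sequence,
        qualities="I" * len(sequence),
        umt5=umt5,
        umt3=umt3,
    )
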