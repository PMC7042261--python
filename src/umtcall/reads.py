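"""Read parsing: UMT extraction, primer trimming, amplicon assignment.

Raw amplicon reads carry a unique molecular tag (UMT) at each end:

    5'-UMT -- forward primer -- insert -- reverse primer -- 3'-UMT

Both UMTs are excised, primers are matched against the panel to assign
the read to an amplicon (and trimmed), and the insert is retained. Reads
are single-ended and already oriented 5'->3' along the amplicon.

Reads may also be supplied pre-tagged as a TSV dialect
(read_id, sample, amplicon_id, umt5, umt3, insert, qualities) so the
callers can be exercised without FASTQ parsing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .panel import AmpliconDef, Panel

READ_ALPHABET = set("ACGTN")


@dataclass(frozen=True, slots=True)
class ReadStructure:
    """Physical layout of a tagged read: UMT length and primer match budget."""

    umt_length: int = 6
    max_primer_mismatch: int = 2


@dataclass(frozen=True, slots=True)
class ReadRecord:
    """One parsed read: insert sequence/qualities plus its two UMTs.

    ``qualities`` is stored as a Phred+33 string of the same length as
    ``sequence``; :meth:`quality_scores` decodes it.
    """

    read_id: str
    sample: str
    amplicon_id: str
    sequence: str
    qualities: str
    umt5: str
    umt3: str
    primer_trimmed: bool = True

    def quality_scores(self) -> list[int]:
        return [ord(c) - 33 for c in self.qualities]

    def validate(self, umt_length: int = 6) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.read_id}: sequence/qualities length mismatch")
        if len(self.umt5) != umt_length or len(self.umt3) != umt_length:
            raise ValueError(f"{self.read_id}: UMT length != {umt_length}")
        if not set(self.sequence) <= READ_ALPHABET:
            raise ValueError(f"{self.read_id}: non-ACGTN base in sequence")


@dataclass(frozen=True, slots=True)
class RejectedRead:
    read_id: str
    reason: str  # "too_short" | "unassigned"


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def assign_amplicon(
    read_insert: str,
    primer_pair_observed: tuple[str, str],
    panel: Panel,
    max_mismatch: int,
) -> Optional[str]:
    """Assign a read to the unique best-matching amplicon by its primer pair.

    Returns the amplicon_id whose (fwd, rev) primers match the observed
    pair within ``max_mismatch`` total mismatches; ``None`` when no
    amplicon matches or when two amplicons tie at the minimum distance
    (ambiguous assignment is treated as no assignment).
    """
    obs_fwd, obs_rev = primer_pair_observed
    best: Optional[str] = None
    best_d = max_mismatch + 1
    tied = False
    for a in panel.amplicons:
        if len(a.fwd_primer) != len(obs_fwd) or len(a.rev_primer) != len(obs_rev):
            continue
        d = _hamming(obs_fwd, a.fwd_primer) + _hamming(obs_rev, a.rev_primer)
        if d < best_d:
            best, best_d, tied = a.amplicon_id, d, False
        elif d == best_d:
            tied = True
    if best is None or tied:
        return None
    return best


def parse_tagged_read(
    raw_sequence: str,
    raw_qualities: str | list[int],
    structure: ReadStructure,
    panel: Panel,
    read_id: str = "",
    sample: str = "S1",
) -> tuple[Optional[ReadRecord], Optional[RejectedRead]]:
    """Parse one raw read into a :class:`ReadRecord`.

    Exactly one of (record, rejection) is returned non-None. Rejection
    reasons: ``too_short`` (read cannot hold both UMTs, both primers and a
    one-base insert for any amplicon) and ``unassigned`` (no amplicon's
    primer pair matches within the mismatch budget, or the best match is
    ambiguous).
    """
    if isinstance(raw_qualities, list):
        raw_qualities = "".join(chr(q + 33) for q in raw_qualities)
    if len(raw_sequence) != len(raw_qualities):
        raise ValueError(f"{read_id}: sequence/quality length mismatch")
    u = structure.umt_length
    min_primer_span = min(
        len(a.fwd_primer) + len(a.rev_primer) for a in panel.amplicons
    )
    if len(raw_sequence) < 2 * u + min_primer_span + 1:
        return None, RejectedRead(read_id, "too_short")

    umt5 = raw_sequence[:u]
    umt3 = raw_sequence[-u:]
    middle = raw_sequence[u:-u]
    mid_qual = raw_qualities[u:-u]

    # Per-amplicon primer distance: primer lengths differ between amplicons,
    # so the observed primers are re-sliced per candidate.
    best: Optional[AmpliconDef] = None
    best_d = structure.max_primer_mismatch + 1
    tied = False
    for a in panel.amplicons:
        lf, lr = len(a.fwd_primer), len(a.rev_primer)
        if len(middle) < lf + lr + 1:
            continue
        d = _hamming(middle[:lf], a.fwd_primer) + _hamming(middle[-lr:], a.rev_primer)
        if d < best_d:
            best, best_d, tied = a, d, False
        elif d == best_d:
            tied = True
    if best is None or tied:
        return None, RejectedRead(read_id, "unassigned")

    lf, lr = len(best.fwd_primer), len(best.rev_primer)
    record = ReadRecord(
        read_id=read_id,
        sample=sample,
        amplicon_id=best.amplicon_id,
        sequence=middle[lf : len(middle) - lr],
        qualities=mid_qual[lf : len(middle) - lr],
        umt5=umt5,
        umt3=umt3,
        primer_trimmed=True,
    )
    return record, None


def parse_fastq(
    path: str | Path,
    structure: ReadStructure,
    panel: Panel,
    sample: str = "S1",
) -> tuple[list[ReadRecord], list[RejectedRead]]:
    """Parse a Phred+33 FASTQ file of tagged reads.

    Returns (accepted, rejected); every input read lands in exactly one of
    the two lists.
    """
    accepted: list[ReadRecord] = []
    rejected: list[RejectedRead] = []
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            read_id = title.split()[0]
            rec, rej = parse_tagged_read(
                seq, qual, structure, panel, read_id=read_id, sample=sample
            )
            if rec is not None:
                accepted.append(rec)
            else:
                assert rej is not None
                rejected.append(rej)
    return accepted, rejected


def write_rejection_log(rejected: Iterable[RejectedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\treason\n")
        for r in rejected:
            fh.write(f"{r.read_id}\t{r.reason}\n")


TAGGED_TSV_COLUMNS = [
    "read_id",
    "sample",
    "amplicon_id",
    "umt5",
    "umt3",
    "insert",
    "qualities",
]


def read_tagged_tsv(path: str | Path) -> list[ReadRecord]:
    """Read the pre-tagged TSV dialect (header required)."""
    records: list[ReadRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TAGGED_TSV_COLUMNS:
            raise ValueError(
                f"{path}: expected header {TAGGED_TSV_COLUMNS}, got {header}"
            )
        for line in fh:
            f = line.rstrip("\n").split("\t")
            records.append(
                ReadRecord(
                    read_id=f[0],
                    sample=f[1],
                    amplicon_id=f[2],
                    sequence=f[5],
                    qualities=f[6],
                    umt5=f[3],
                    umt3=f[4],
                )
            )
    return records


def write_tagged_tsv(records: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TAGGED_TSV_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.read_id}\t{r.sample}\t{r.amplicon_id}\t{r.umt5}\t{r.umt3}"
                f"\t{r.sequence}\t{r.qualities}\n"
            )
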