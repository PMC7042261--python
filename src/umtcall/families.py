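"""Molecular-family clustering and unanimous consensus.

Reads sharing one (sample, amplicon, 5'-UMT, 3'-UMT) key descend from one
template molecule and form a *molecular family*. A family with at least
``min_family_size`` members (default 2) is *functional* and may contribute
evidence to calling; smaller families are kept for accounting but never
reach the caller.

Consensus is unanimous per position: a family supports an allele at a
position only when every member read carries the identical token there;
any disagreement marks the position AMBIGUOUS, so a family can never
support both the reference and an alternate allele at one position.
PCR/sequencing errors present in a subset of members are thereby
eliminated.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional

from .reads import ReadRecord
from .tokens import Deviations, read_deviations

DEFAULT_MIN_FAMILY_SIZE = 2

AMBIGUOUS = "AMBIGUOUS"


class FamilyKey(NamedTuple):
    sample: str
    amplicon_id: str
    umt5: str
    umt3: str


@dataclass
class MolecularFamily:
    key: FamilyKey
    members: list[ReadRecord]
    functional: bool

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class FamilyConsensus:
    """Sparse per-position consensus of one family against its amplicon insert.

    ``deviations`` maps 0-based insert positions to the unanimous non-reference
    token there; ``ambiguous`` holds positions where members disagree. All
    other positions are unanimously reference. ``failed`` families are
    excluded from tallies (members could not be reconciled to the insert).
    """

    key: FamilyKey
    family_size: int
    insert_length: int
    deviations: dict[int, str] = field(default_factory=dict)
    ambiguous: frozenset[int] = frozenset()
    failed: bool = False
    fail_reason: str = ""

    def allele_at(self, pos0: int, ref: str) -> str:
        """Token at a 0-based insert position, or AMBIGUOUS."""
        if pos0 in self.ambiguous:
            return AMBIGUOUS
        return self.deviations.get(pos0, ref[pos0])


def build_families(
    reads: Iterable[ReadRecord],
    min_family_size: int = DEFAULT_MIN_FAMILY_SIZE,
) -> list[MolecularFamily]:
    """Partition reads into molecular families by exact UMT-pair key.

    Output is sorted by key so downstream results are bit-reproducible.
    The sum of family sizes always equals the number of input reads.
    """
    groups: dict[FamilyKey, list[ReadRecord]] = defaultdict(list)
    for r in reads:
        groups[FamilyKey(r.sample, r.amplicon_id, r.umt5, r.umt3)].append(r)
    return [
        MolecularFamily(key=k, members=groups[k], functional=len(groups[k]) >= min_family_size)
        for k in sorted(groups)
    ]


def merge_umt_neighbors(
    families: list[MolecularFamily],
    max_edit_distance: int,
    min_family_size: int = DEFAULT_MIN_FAMILY_SIZE,
) -> list[MolecularFamily]:
    """Optionally absorb UMT-sequencing-error fragments into larger families.

    With ``max_edit_distance=0`` this is the identity. With 1, a family is
    absorbed into a family at least twice its size (same sample and
    amplicon) whose concatenated UMT pair lies within Hamming distance 1;
    candidates are scanned greedily by descending size with lexicographic
    key tie-break. Off by default throughout the package: exact UMT match
    is the conservative choice.
    """
    if max_edit_distance not in (0, 1):
        raise ValueError("max_edit_distance must be 0 or 1")
    if max_edit_distance == 0:
        return families

    order = sorted(families, key=lambda f: (-f.size, f.key))
    merged: dict[FamilyKey, MolecularFamily] = {}
    for fam in order:
        absorber = None
        for cand in merged.values():
            if cand.key.sample != fam.key.sample:
                continue
            if cand.key.amplicon_id != fam.key.amplicon_id:
                continue
            if cand.size < 2 * fam.size:
                continue
            d = _hamming(cand.key.umt5 + cand.key.umt3, fam.key.umt5 + fam.key.umt3)
            if d <= 1:
                absorber = cand
                break
        if absorber is None:
            merged[fam.key] = MolecularFamily(fam.key, list(fam.members), fam.functional)
        else:
            absorber.members.extend(fam.members)
    out = sorted(merged.values(), key=lambda f: f.key)
    for f in out:
        f.functional = f.size >= min_family_size
    return out


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def family_consensus(
    family: MolecularFamily,
    ref_insert: str,
    max_indel_span: Optional[int] = None,
) -> FamilyConsensus:
    """Unanimous per-position consensus of a family against its insert.

    N handling: N is missing data, not evidence — an N is ignored when the
    remaining members (>=2) agree on the position; otherwise the position
    is AMBIGUOUS. A member whose length differs from the insert by more
    than ``max_indel_span`` (default: half the insert) cannot be
    reconciled and marks the family consensus-failed.
    """
    L = len(ref_insert)
    if max_indel_span is None:
        max_indel_span = L // 2
    for m in family.members:
        if abs(len(m.sequence) - L) > max_indel_span:
            return FamilyConsensus(
                key=family.key,
                family_size=family.size,
                insert_length=L,
                failed=True,
                fail_reason="irreconcilable_length",
            )

    seqs = [m.sequence for m in family.members]
    first = seqs[0]
    if all(s == first for s in seqs):  # fast path: identical members
        devs = read_deviations(ref_insert, first)
        return FamilyConsensus(
            key=family.key,
            family_size=family.size,
            insert_length=L,
            deviations=dict(devs),
        )

    member_devs: list[Deviations] = [read_deviations(ref_insert, s) for s in seqs]
    positions: set[int] = set()
    for devs in member_devs:
        positions.update(p for p, _ in devs)

    consensus: dict[int, str] = {}
    ambiguous: set[int] = set()
    dev_maps = [dict(d) for d in member_devs]
    for pos in positions:
        tokens = [dm.get(pos, ref_insert[pos]) for dm in dev_maps]
        non_n = [t for t in tokens if t != "N"]
        if "N" in tokens:
            if len(non_n) >= 2 and len(set(non_n)) == 1:
                tok = non_n[0]
            else:
                ambiguous.add(pos)
                continue
        else:
            if len(set(tokens)) == 1:
                tok = tokens[0]
            else:
                ambiguous.add(pos)
                continue
        if tok != ref_insert[pos]:
            consensus[pos] = tok
    return FamilyConsensus(
        key=family.key,
        family_size=family.size,
        insert_length=L,
        deviations=consensus,
        ambiguous=frozenset(ambiguous),
    )


def family_size_histogram(families: Iterable[MolecularFamily]) -> dict[int, int]:
    """Histogram of family sizes; the values sum to the number of families."""
    return dict(Counter(f.size for f in families))


def write_family_stats(
    families: Iterable[MolecularFamily],
    consensuses: dict[FamilyKey, FamilyConsensus],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tamplicon\tumt5\tumt3\tsize\tfunctional\tconsensus_failed\n")
        for f in families:
            cons = consensuses.get(f.key)
            failed = cons.failed if cons is not None else ""
            fh.write(
                f"{f.key.sample}\t{f.key.amplicon_id}\t{f.key.umt5}\t{f.key.umt3}"
                f"\t{f.size}\t{f.functional}\t{failed}\n"
            )
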