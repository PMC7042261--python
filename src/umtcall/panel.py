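"""Amplicon panel definitions: amplicons, primers, hotspot lists.

A panel is the static description of a targeted amplicon assay: for each
amplicon, the genomic interval of the inter-primer insert (1-based,
inclusive, VCF convention) and the forward/reverse primer sequences used
to assign reads. Hotspots are user-supplied recurrently mutated alleles
that are granted a lower evidence threshold downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

_DNA = set("ACGT")


@dataclass(frozen=True)
class AmpliconDef:
    """One amplicon: insert coordinates, primer pair, optional insert sequence.

    ``insert_start``/``insert_end`` are 1-based inclusive genomic coordinates
    of the region between the primers. ``insert_seq`` (the reference sequence
    of that region) is required for simulation and for indel-aware calling,
    optional otherwise.
    """

    amplicon_id: str
    chrom: str
    insert_start: int
    insert_end: int
    fwd_primer: str
    rev_primer: str
    pool_id: int = 1
    insert_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.insert_start > self.insert_end:
            raise ValueError(
                f"amplicon {self.amplicon_id}: insert_start > insert_end"
            )
        for name, primer in (("fwd", self.fwd_primer), ("rev", self.rev_primer)):
            if not primer or not set(primer) <= _DNA:
                raise ValueError(
                    f"amplicon {self.amplicon_id}: {name} primer must be "
                    f"non-empty over A/C/G/T, got {primer!r}"
                )
        if self.insert_seq is not None:
            expected = self.insert_end - self.insert_start + 1
            if len(self.insert_seq) != expected:
                raise ValueError(
                    f"amplicon {self.amplicon_id}: insert_seq length "
                    f"{len(self.insert_seq)} != coordinate span {expected}"
                )

    @property
    def insert_length(self) -> int:
        return self.insert_end - self.insert_start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.insert_start <= pos <= self.insert_end


@dataclass(frozen=True)
class Hotspot:
    chrom: str
    pos: int
    ref: str
    alt: str
    label: str = ""


@dataclass
class Panel:
    """A set of amplicons plus a hotspot allele list."""

    amplicons: list[AmpliconDef]
    hotspots: list[Hotspot] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [a.amplicon_id for a in self.amplicons]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate amplicon_id(s): {dupes}")
        for hs in self.hotspots:
            if not any(a.contains(hs.chrom, hs.pos) for a in self.amplicons):
                raise ValueError(
                    f"hotspot {hs.chrom}:{hs.pos} {hs.ref}>{hs.alt} falls "
                    f"outside every amplicon insert"
                )

    def get(self, amplicon_id: str) -> AmpliconDef:
        for a in self.amplicons:
            if a.amplicon_id == amplicon_id:
                return a
        raise KeyError(amplicon_id)

    def amplicon_for(self, chrom: str, pos: int) -> Optional[AmpliconDef]:
        for a in self.amplicons:
            if a.contains(chrom, pos):
                return a
        return None

    def hotspot_set(self) -> set[tuple[str, int, str, str]]:
        return {(h.chrom, h.pos, h.ref, h.alt) for h in self.hotspots}


def load_panel(
    amplicon_table: str | Path, hotspot_table: str | Path | None = None
) -> Panel:
    """Load a panel from tab-separated tables.

    Amplicon table columns (header line starting with ``#`` declares the
    1-based coordinate convention): chrom, insert_start, insert_end,
    amplicon_id, fwd_primer, rev_primer[, pool_id[, insert_seq]].
    Hotspot table columns: chrom, pos, ref, alt[, label].
    """
    amplicons = []
    for lineno, fields in _read_tsv(amplicon_table):
        if len(fields) < 6:
            raise ValueError(
                f"{amplicon_table}:{lineno}: expected >=6 columns, got {len(fields)}"
            )
        pool = int(fields[6]) if len(fields) > 6 and fields[6] else 1
        seq = fields[7] if len(fields) > 7 and fields[7] else None
        amplicons.append(
            AmpliconDef(
                amplicon_id=fields[3],
                chrom=fields[0],
                insert_start=int(fields[1]),
                insert_end=int(fields[2]),
                fwd_primer=fields[4],
                rev_primer=fields[5],
                pool_id=pool,
                insert_seq=seq,
            )
        )
    hotspots: list[Hotspot] = []
    if hotspot_table is not None:
        for lineno, fields in _read_tsv(hotspot_table):
            if len(fields) < 4:
                raise ValueError(
                    f"{hotspot_table}:{lineno}: expected >=4 columns"
                )
            label = fields[4] if len(fields) > 4 else ""
            hotspots.append(
                Hotspot(fields[0], int(fields[1]), fields[2], fields[3], label)
            )
    try:
        return Panel(amplicons=amplicons, hotspots=hotspots)
    except ValueError as exc:
        raise ValueError(f"panel validation failed: {exc}") from exc


def write_panel(panel: Panel, amplicon_path: str | Path) -> None:
    with open(amplicon_path, "w") as fh:
        fh.write(
            "#chrom\tinsert_start\tinsert_end\tamplicon_id\tfwd_primer\t"
            "rev_primer\tpool_id\tinsert_seq\t(coordinates 1-based inclusive)\n"
        )
        for a in panel.amplicons:
            fh.write(
                f"{a.chrom}\t{a.insert_start}\t{a.insert_end}\t{a.amplicon_id}"
                f"\t{a.fwd_primer}\t{a.rev_primer}\t{a.pool_id}"
                f"\t{a.insert_seq or ''}\n"
            )


def _read_tsv(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")
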