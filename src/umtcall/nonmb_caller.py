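"""Conventional read-level (non-molecular-barcode) variant calling.

The comparison baseline: UMTs are ignored entirely — every read counts
once, PCR duplicates included, as in conventional amplicon analysis. A
tumor call passes when it has >= 10 supporting reads, >= 20x depth, is not
a common SNP, and (when a matched normal is supplied) shows at most
negligible evidence in the normal ("confident somatic": normal alternate
reads <= 1 and normal VAF <= 2% by default; the vendor semantics are not
public, so both thresholds are configuration).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .mb_caller import Allele, VafValue, Verdict, molecular_vaf
from .panel import AmpliconDef, Panel
from .reads import ReadRecord
from .tokens import read_deviations, token_alleles


def read_level_vaf(alt_reads: int, depth: int) -> VafValue:
    """Read-level VAF: alternate reads / read depth (0 when uncovered)."""
    return molecular_vaf(alt_reads, depth)


@dataclass
class RawTally:
    """Read-level allele counts at one genomic position (UMTs ignored)."""

    chrom: str
    pos: int
    ref_base: str
    depth: int = 0
    alt: dict[Allele, int] = field(default_factory=dict)


@dataclass
class NonMBFilterConfig:
    min_alt_reads: int = 10
    min_depth: int = 20
    common_snp_positions: set[tuple[str, int]] = field(default_factory=set)
    max_normal_alt_reads: int = 1
    max_normal_vaf: float = 0.02
    min_vaf: float = 0.0  # optional operating VAF floor (e.g. 0.05 in plasma)

    def __post_init__(self) -> None:
        for name in ("min_alt_reads", "min_depth", "max_normal_alt_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def tally_reads(
    reads: Iterable[ReadRecord], amplicon: AmpliconDef
) -> list[RawTally]:
    """Sparse read-level tallies over an amplicon insert.

    Reads whose length cannot be reconciled with the insert are skipped
    from per-position counts but a read-depth is maintained from all reads.
    """
    if amplicon.insert_seq is None:
        raise ValueError(f"amplicon {amplicon.amplicon_id} has no insert sequence")
    ref_seq = amplicon.insert_seq
    depth = 0
    per_pos: dict[int, dict[Allele, int]] = defaultdict(dict)
    per_pos_nonref: dict[int, int] = defaultdict(int)
    for r in reads:
        depth += 1
        for pos0, token in read_deviations(ref_seq, r.sequence):
            per_pos_nonref[pos0] += 1
            parsed = token_alleles(pos0, token, ref_seq)
            if parsed is None:
                continue
            _, ref_a, alt_a, vclass = parsed
            allele = Allele(ref_a, alt_a, vclass)
            per_pos[pos0][allele] = per_pos[pos0].get(allele, 0) + 1
    return [
        RawTally(
            chrom=amplicon.chrom,
            pos=amplicon.insert_start + pos0,
            ref_base=ref_seq[pos0],
            depth=depth,
            alt=dict(per_pos[pos0]),
        )
        for pos0 in sorted(per_pos)
    ]


@dataclass
class RawVariantCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str
    alt_reads: int
    depth: int
    vaf: float
    normal_alt_reads: Optional[int]
    normal_depth: Optional[int]
    verdicts: list[Verdict] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(v.passed for v in self.verdicts)

    @property
    def filter_field(self) -> str:
        for v in self.verdicts:
            if not v.passed:
                return v.name
        return "PASS"


def call_raw_variants(
    tumor: Iterable[RawTally],
    normal: Optional[Iterable[RawTally]],
    cfg: NonMBFilterConfig,
) -> list[RawVariantCall]:
    """Tumor(-normal) read-level calling with the conventional filter set.

    ``normal=None`` runs tumor-only (the confident-somatic check is
    skipped). When a normal is supplied but lacks the locus, the call is
    marked ``no_normal`` and cannot PASS.
    """
    normal_by_locus: Optional[dict[tuple[str, int], RawTally]] = None
    if normal is not None:
        normal_by_locus = {(t.chrom, t.pos): t for t in normal}

    calls: list[RawVariantCall] = []
    for t in tumor:
        for allele, n_alt in t.alt.items():
            vaf = read_level_vaf(n_alt, t.depth)
            verdicts = [
                Verdict("min_alt_reads", n_alt >= cfg.min_alt_reads),
                Verdict("min_depth", t.depth >= cfg.min_depth),
                Verdict("common_snp", (t.chrom, t.pos) not in cfg.common_snp_positions),
            ]
            n_alt_normal: Optional[int] = None
            n_depth_normal: Optional[int] = None
            if normal_by_locus is not None:
                nt = normal_by_locus.get((t.chrom, t.pos))
                if nt is None:
                    verdicts.append(Verdict("no_normal", False))
                else:
                    n_alt_normal = nt.alt.get(allele, 0)
                    n_depth_normal = nt.depth
                    nvaf = read_level_vaf(n_alt_normal, nt.depth).fraction
                    verdicts.append(
                        Verdict(
                            "confident_somatic",
                            n_alt_normal <= cfg.max_normal_alt_reads
                            and nvaf <= cfg.max_normal_vaf,
                        )
                    )
            if cfg.min_vaf > 0:
                verdicts.append(Verdict("min_vaf", vaf.fraction >= cfg.min_vaf))
            calls.append(
                RawVariantCall(
                    chrom=t.chrom,
                    pos=t.pos,
                    ref=allele.ref,
                    alt=allele.alt,
                    vclass=allele.vclass,
                    alt_reads=n_alt,
                    depth=t.depth,
                    vaf=vaf.fraction,
                    normal_alt_reads=n_alt_normal,
                    normal_depth=n_depth_normal,
                    verdicts=verdicts,
                )
            )
    calls.sort(key=lambda c: (c.chrom, c.pos, c.alt))
    return calls


RAW_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=umtcall-nonmb
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=AO,Number=1,Type=Integer,Description="Alternate-allele read count">
##INFO=<ID=VAF,Number=1,Type=Float,Description="Read-level variant allele fraction">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_raw_vcf(calls: Sequence[RawVariantCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(RAW_VCF_HEADER)
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\t{c.filter_field}\t"
                f"DP={c.depth};AO={c.alt_reads};VAF={c.vaf:.6g}\n"
            )


def raw_pipeline(
    tumor_reads: Iterable[ReadRecord],
    normal_reads: Optional[Iterable[ReadRecord]],
    panel: Panel,
    cfg: NonMBFilterConfig,
) -> list[RawVariantCall]:
    """Read-level calling straight from parsed reads."""
    by_amp: dict[str, list[ReadRecord]] = defaultdict(list)
    for r in tumor_reads:
        by_amp[r.amplicon_id].append(r)
    tumor_tallies: list[RawTally] = []
    for amp_id in sorted(by_amp):
        tumor_tallies.extend(tally_reads(by_amp[amp_id], panel.get(amp_id)))
    normal_tallies: Optional[list[RawTally]] = None
    if normal_reads is not None:
        by_amp_n: dict[str, list[ReadRecord]] = defaultdict(list)
        for r in normal_reads:
            by_amp_n[r.amplicon_id].append(r)
        normal_tallies = []
        for amp_id in sorted(by_amp_n):
            normal_tallies.extend(tally_reads(by_amp_n[amp_id], panel.get(amp_id)))
    return call_raw_variants(tumor_tallies, normal_tallies, cfg)
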