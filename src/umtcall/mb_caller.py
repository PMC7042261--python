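"""Molecular-barcode (MB) variant calling from functional-family consensuses.

Evidence is counted in *molecules*: each functional family contributes at
most one count per locus, and only when its members are unanimous. A
candidate allele is scored by

* its alternate functional-family count (``FAO``),
* the molecular VAF ``FAO / FDP`` where ``FDP`` is the functional-family
  depth at the locus (families that are AMBIGUOUS at the position stay in
  the denominator — a conservative choice), and
* a one-sided exact binomial tail p-value against a configurable
  background error rate: ``P(X >= FAO | n = FDP, p = background)``.

The filter cascade applies, in order: per-class supporting-family minima
(SNV and hotspot 2, INDEL 6), alternate allele count >= 2, common-SNP
exclusion, p-value < 0.02, INDEL evidence (VAF >= 0.002 and > 3 mutated
alleles), non-hotspot mutated-allele count > 3, a family-size floor for
homopolymer indels, and — in tumor context only — a molecular VAF cutoff
of 0.005. Every applicable verdict is recorded even after the first
failure, and a call is PASS only when all applicable verdicts pass.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import yaml
from scipy.stats import binom

from .families import FamilyConsensus
from .panel import AmpliconDef, Panel
from .tokens import token_alleles


# ---------------------------------------------------------------------------
# VAF arithmetic

class VafValue(NamedTuple):
    fraction: float
    no_coverage: bool

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def molecular_vaf(alt_count: int, depth: int) -> VafValue:
    """Molecular VAF: alternate families / functional-family depth.

    Zero depth yields 0 flagged ``no_coverage`` rather than an error, so
    uncovered loci can be reported.
    """
    if depth < 0 or alt_count < 0:
        raise ValueError("counts must be non-negative")
    if alt_count > depth:
        raise ValueError(f"alt_count {alt_count} exceeds depth {depth}")
    if depth == 0:
        return VafValue(0.0, True)
    return VafValue(alt_count / depth, False)


def format_vaf_percent(fraction: float) -> str:
    """Render a VAF fraction as a percentage at reporting precision.

    Two decimal places; values that would round to 0.00 but are non-zero
    fall back to two significant figures (e.g. 9/249,780 -> "0.0036").
    """
    pct = 100.0 * fraction
    s = f"{pct:.2f}"
    if s == "0.00" and pct > 0:
        return f"{pct:.2g}"
    return s


def background_pvalue(alt_count: int, depth: int, error_rate: float) -> float:
    """One-sided exact binomial tail: P(X >= alt_count | n=depth, p=error_rate).

    Monotone non-increasing in ``alt_count`` at fixed depth. Zero depth
    (or zero alternate count) is maximally unsurprising: p = 1.
    """
    if not (0.0 < error_rate < 1.0):
        raise ValueError("error_rate must lie in (0, 1)")
    if alt_count < 0 or depth < 0 or alt_count > depth:
        raise ValueError("require 0 <= alt_count <= depth")
    if depth == 0 or alt_count == 0:
        return 1.0
    return float(binom.sf(alt_count - 1, depth, error_rate))


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class MBFilterConfig:
    """Thresholds of the MB calling workflow.

    Counts are molecular (functional families) throughout. The
    ``background_error_rate`` is the per-family per-allele rate of the
    binomial null; a per-substitution-class override (e.g. ``{"C>T": 3e-4}``)
    captures elevated deamination classes.
    """

    min_family_size: int = 2
    min_snp_supporting_families: int = 2
    min_hotspot_supporting_families: int = 2
    min_indel_supporting_families: int = 6
    homopolymer_indel_family_size: int = 2
    min_alt_allele_count: int = 2
    max_p_value: float = 0.02
    min_indel_vaf: float = 0.002
    min_indel_alt_count: int = 4  # excludes <= 3 mutated alleles
    min_nonhotspot_alt_count: int = 4  # excludes <= 3 mutated alleles
    tumor_vaf_cutoff: float = 0.005
    background_error_rate: float = 1e-4
    background_error_rate_by_class: dict[str, float] = field(default_factory=dict)
    common_snp_positions: set[tuple[str, int]] = field(default_factory=set)
    homopolymer_min_run: int = 4

    def __post_init__(self) -> None:
        if not (0.0 < self.max_p_value < 1.0):
            raise ValueError("max_p_value must lie in (0, 1)")
        if not (0.0 < self.background_error_rate < 1.0):
            raise ValueError("background_error_rate must lie in (0, 1)")
        for name in (
            "min_family_size",
            "min_snp_supporting_families",
            "min_hotspot_supporting_families",
            "min_indel_supporting_families",
            "min_alt_allele_count",
            "min_indel_alt_count",
            "min_nonhotspot_alt_count",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def error_rate_for(self, ref: str, alt: str) -> float:
        if len(ref) == 1 and len(alt) == 1:
            return self.background_error_rate_by_class.get(
                f"{ref}>{alt}", self.background_error_rate
            )
        return self.background_error_rate

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MBFilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "common_snp_positions" in data:
            data["common_snp_positions"] = {
                (str(c), int(p)) for c, p in data["common_snp_positions"]
            }
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: v
            for k, v in self.__dict__.items()
            if k != "common_snp_positions"
        }
        data["common_snp_positions"] = sorted(
            [list(t) for t in self.common_snp_positions]
        )
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Locus tallies

class Allele(NamedTuple):
    ref: str
    alt: str
    vclass: str  # SNV | INS | DEL


@dataclass
class AltEvidence:
    families: int = 0
    min_family_size: int = 0  # smallest supporting family

    def add(self, family_size: int) -> None:
        self.families += 1
        if self.min_family_size == 0 or family_size < self.min_family_size:
            self.min_family_size = family_size


@dataclass
class LocusTally:
    """Molecular allele counts at one genomic position.

    ``family_depth`` counts every non-failed functional family covering the
    position, including families AMBIGUOUS there; the per-allele counts sum
    to at most the depth.
    """

    chrom: str
    pos: int  # 1-based genomic
    ref_base: str
    family_depth: int = 0
    ref_families: int = 0
    ambiguous_families: int = 0
    alt: dict[Allele, AltEvidence] = field(default_factory=dict)
    read_depth: Optional[int] = None


def tally_locus(
    consensuses: Iterable[FamilyConsensus],
    amplicon: AmpliconDef,
    pos: int,
) -> LocusTally:
    """Tally functional-family support at one genomic position.

    Only unanimous families support an allele; AMBIGUOUS families add to
    depth only. A position outside the amplicon yields an empty tally with
    depth 0.
    """
    ref_seq = _require_insert(amplicon)
    tally = LocusTally(chrom=amplicon.chrom, pos=pos, ref_base="N")
    if not amplicon.contains(amplicon.chrom, pos):
        return tally
    pos0 = pos - amplicon.insert_start
    tally.ref_base = ref_seq[pos0]
    for cons in consensuses:
        if cons.failed:
            continue
        tally.family_depth += 1
        if pos0 in cons.ambiguous:
            tally.ambiguous_families += 1
            continue
        token = cons.deviations.get(pos0)
        if token is None:
            tally.ref_families += 1
            continue
        parsed = token_alleles(pos0, token, ref_seq)
        if parsed is None:  # '*' spanning deletion or N: depth only
            tally.ambiguous_families += 1
            continue
        _, ref_a, alt_a, vclass = parsed
        allele = Allele(ref_a, alt_a, vclass)
        tally.alt.setdefault(allele, AltEvidence()).add(cons.family_size)
    return tally


def tally_amplicon(
    consensuses: Sequence[FamilyConsensus], amplicon: AmpliconDef
) -> list[LocusTally]:
    """Sparse tallies for every position of an amplicon with alternate support.

    Equivalent to calling :func:`tally_locus` at each position, but walks
    each consensus's deviation list once.
    """
    ref_seq = _require_insert(amplicon)
    live = [c for c in consensuses if not c.failed]
    depth = len(live)
    per_pos_alt: dict[int, dict[Allele, AltEvidence]] = defaultdict(dict)
    per_pos_nonref: dict[int, int] = defaultdict(int)
    per_pos_amb: dict[int, int] = defaultdict(int)
    for cons in live:
        for pos0 in cons.ambiguous:
            per_pos_amb[pos0] += 1
            per_pos_nonref[pos0] += 1
        for pos0, token in cons.deviations.items():
            per_pos_nonref[pos0] += 1
            parsed = token_alleles(pos0, token, ref_seq)
            if parsed is None:
                per_pos_amb[pos0] += 1
                continue
            _, ref_a, alt_a, vclass = parsed
            allele = Allele(ref_a, alt_a, vclass)
            per_pos_alt[pos0].setdefault(allele, AltEvidence()).add(
                cons.family_size
            )
    tallies = []
    for pos0 in sorted(per_pos_alt):
        tally = LocusTally(
            chrom=amplicon.chrom,
            pos=amplicon.insert_start + pos0,
            ref_base=ref_seq[pos0],
            family_depth=depth,
            ref_families=depth - per_pos_nonref[pos0],
            ambiguous_families=per_pos_amb[pos0],
            alt=per_pos_alt[pos0],
        )
        tallies.append(tally)
    return tallies


def _require_insert(amplicon: AmpliconDef) -> str:
    if amplicon.insert_seq is None:
        raise ValueError(
            f"amplicon {amplicon.amplicon_id} has no insert sequence; "
            f"indel-aware tallying requires one"
        )
    return amplicon.insert_seq


# ---------------------------------------------------------------------------
# Calls and the filter cascade

class Verdict(NamedTuple):
    name: str
    passed: bool


@dataclass
class MBVariantCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str  # SNV | INS | DEL
    hotspot: bool
    homopolymer: bool
    alt_family_count: int
    family_depth: int
    min_supporting_family_size: int
    vaf: float
    p_value: float
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


def apply_mb_filters(
    call: MBVariantCall, cfg: MBFilterConfig, context: str
) -> MBVariantCall:
    """Populate the ordered verdict list of a draft call.

    ``context`` is ``"tumor"`` or ``"plasma"``; the molecular-VAF cutoff
    applies only to tumor calling.
    """
    if call.vclass not in ("SNV", "INS", "DEL"):
        raise ValueError(f"unknown variant class {call.vclass!r}")
    if context not in ("tumor", "plasma"):
        raise ValueError(f"context must be tumor or plasma, got {context!r}")
    is_indel = call.vclass in ("INS", "DEL")
    verdicts: list[Verdict] = []

    if call.hotspot:
        min_fam = cfg.min_hotspot_supporting_families
    elif is_indel:
        min_fam = cfg.min_indel_supporting_families
    else:
        min_fam = cfg.min_snp_supporting_families
    verdicts.append(Verdict("min_supporting_families", call.alt_family_count >= min_fam))
    verdicts.append(
        Verdict("min_alt_allele_count", call.alt_family_count >= cfg.min_alt_allele_count)
    )
    verdicts.append(
        Verdict("common_snp", (call.chrom, call.pos) not in cfg.common_snp_positions)
    )
    verdicts.append(Verdict("max_p_value", call.p_value < cfg.max_p_value))
    if is_indel:
        verdicts.append(
            Verdict(
                "indel_evidence",
                call.vaf >= cfg.min_indel_vaf
                and call.alt_family_count >= cfg.min_indel_alt_count,
            )
        )
    if not call.hotspot:
        verdicts.append(
            Verdict(
                "nonhotspot_alt_count",
                call.alt_family_count >= cfg.min_nonhotspot_alt_count,
            )
        )
    if is_indel and call.homopolymer:
        verdicts.append(
            Verdict(
                "homopolymer_family_size",
                call.min_supporting_family_size >= cfg.homopolymer_indel_family_size,
            )
        )
    if context == "tumor":
        verdicts.append(Verdict("tumor_vaf", call.vaf >= cfg.tumor_vaf_cutoff))
    call.verdicts = verdicts
    return call


def homopolymer_context(insert_seq: str, pos0: int, min_run: int) -> bool:
    """True when the reference run adjacent to an indel anchor is >= min_run.

    The run examined starts at the base immediately following the anchor
    (where the inserted/deleted bases sit in VCF-anchored notation).
    """
    i = pos0 + 1
    if i >= len(insert_seq):
        return False
    base = insert_seq[i]
    run = 0
    while i < len(insert_seq) and insert_seq[i] == base:
        run += 1
        i += 1
    return run >= min_run


def call_variants(
    tallies: Iterable[LocusTally],
    panel: Panel,
    cfg: MBFilterConfig,
    context: str = "tumor",
) -> list[MBVariantCall]:
    """Turn locus tallies into filtered variant calls.

    One call per (locus, alternate allele) with at least one supporting
    family; output sorted by (chrom, pos, alt) for reproducibility.
    """
    hotspots = panel.hotspot_set()
    calls: list[MBVariantCall] = []
    for tally in tallies:
        amp = panel.amplicon_for(tally.chrom, tally.pos)
        for allele, ev in tally.alt.items():
            vaf = molecular_vaf(ev.families, tally.family_depth)
            pval = background_pvalue(
                ev.families,
                tally.family_depth,
                cfg.error_rate_for(allele.ref, allele.alt),
            )
            is_indel = allele.vclass in ("INS", "DEL")
            homopol = False
            if is_indel and amp is not None and amp.insert_seq is not None:
                homopol = homopolymer_context(
                    amp.insert_seq, tally.pos - amp.insert_start, cfg.homopolymer_min_run
                )
            call = MBVariantCall(
                chrom=tally.chrom,
                pos=tally.pos,
                ref=allele.ref,
                alt=allele.alt,
                vclass=allele.vclass,
                hotspot=(tally.chrom, tally.pos, allele.ref, allele.alt) in hotspots,
                homopolymer=homopol,
                alt_family_count=ev.families,
                family_depth=tally.family_depth,
                min_supporting_family_size=ev.min_family_size,
                vaf=vaf.fraction,
                p_value=pval,
            )
            calls.append(apply_mb_filters(call, cfg, context))
    calls.sort(key=lambda c: (c.chrom, c.pos, c.alt))
    return calls


def rescue_report(
    calls: Iterable[MBVariantCall],
    loci: Iterable[tuple[str, int, str, str]],
) -> list[MBVariantCall]:
    """Sub-threshold evidence at externally nominated loci.

    Mirrors manual review of plasma at loci already mutated in the paired
    tumor: returns the non-PASS calls among ``loci`` that still carry at
    least one supporting family, so they can be inspected rather than
    silently dropped.
    """
    wanted = set(loci)
    return [
        c
        for c in calls
        if not c.passed
        and c.alt_family_count >= 1
        and (c.chrom, c.pos, c.ref, c.alt) in wanted
    ]


# ---------------------------------------------------------------------------
# VCF output

VCF_HEADER = """\
##fileformat=VCFv4.2
##source=umtcall-mb
##INFO=<ID=FDP,Number=1,Type=Integer,Description="Functional family depth">
##INFO=<ID=FAO,Number=1,Type=Integer,Description="Alternate-allele functional family count">
##INFO=<ID=MVAF,Number=1,Type=Float,Description="Molecular variant allele fraction">
##INFO=<ID=PV,Number=1,Type=Float,Description="One-sided binomial background p-value">
##INFO=<ID=HS,Number=0,Type=Flag,Description="Hotspot allele">
##INFO=<ID=VCLASS,Number=1,Type=String,Description="Variant class (SNV/INS/DEL)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(calls: Sequence[MBVariantCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for c in calls:
            info = (
                f"FDP={c.family_depth};FAO={c.alt_family_count};"
                f"MVAF={c.vaf:.6g};PV={c.p_value:.6g};VCLASS={c.vclass}"
            )
            if c.hotspot:
                info += ";HS"
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\t"
                f"{c.filter_field}\t{info}\n"
            )
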