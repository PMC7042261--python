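"""Evaluation of callers against truth or against each other.

Detection tables follow the serial-dilution layout (one row per engineered
variant, one column per expected-VAF level, cells carry the observed VAF
in percent or ND for "not detected"). VAF concordance between two methods
is summarized by R-squared, the squared Pearson correlation of the paired
VAFs. The limit of detection (LoD) of a caller on a ladder is defined here
as the smallest VAF level at which at least half of seeded replicates
yield a PASS call for the spiked variant — a replicate-based, strictly
stronger reading of single-run detection claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, Sequence

from scipy.stats import pearsonr

from .mb_caller import format_vaf_percent
from .simulate import SimScenario, TrueVariant, scenario_with_seed

ND = "ND"


class _CallLike(Protocol):
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float

    @property
    def passed(self) -> bool: ...


def _pass_vafs(calls: Sequence[_CallLike]) -> dict[tuple[str, int, str, str], float]:
    return {
        (c.chrom, c.pos, c.ref, c.alt): c.vaf for c in calls if c.passed
    }


@dataclass
class DetectionTable:
    variants: list[TrueVariant]
    levels: list[float]  # expected VAF fractions, ladder order
    cells: dict[tuple[tuple[str, int, str, str], float], str] = field(
        default_factory=dict
    )

    def cell(self, variant: TrueVariant, level: float) -> str:
        return self.cells[(variant[:4], level)]

    def to_tsv(self) -> str:
        header = "variant\t" + "\t".join(
            format_vaf_percent(lv) + "%" for lv in self.levels
        )
        rows = [header]
        for v in self.variants:
            cells = [self.cell(v, lv) for lv in self.levels]
            rows.append(f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}\t" + "\t".join(cells))
        return "\n".join(rows) + "\n"


def detection_table(
    calls_by_level: dict[float, Sequence[_CallLike]],
    truth_variants: Sequence[TrueVariant],
) -> DetectionTable:
    """Observed-VAF-or-ND table across a dilution ladder.

    Every level must be probed for the same variant set; a PASS call is
    matched to truth by exact (chrom, pos, ref, alt).
    """
    levels = sorted(calls_by_level)
    table = DetectionTable(variants=list(truth_variants), levels=levels)
    for lv in levels:
        found = _pass_vafs(calls_by_level[lv])
        for v in truth_variants:
            key = v[:4]
            table.cells[(key, lv)] = (
                format_vaf_percent(found[key]) if key in found else ND
            )
    return table


@dataclass
class ConcordanceResult:
    r_squared: float
    n: int
    pairs: list[tuple[float, float]]


def vaf_concordance(pairs: Sequence[tuple[float, float]]) -> ConcordanceResult:
    """Squared Pearson correlation of paired VAF measurements.

    Symmetric in the two methods. Fewer than two pairs, or a constant
    vector, leaves the correlation undefined and raises.
    """
    if len(pairs) < 2:
        raise ValueError("concordance needs at least 2 pairs")
    x = [p[0] for p in pairs]
    y = [p[1] for p in pairs]
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise ValueError("concordance undefined for a constant VAF vector")
    r = pearsonr(x, y).statistic
    return ConcordanceResult(r_squared=float(r * r), n=len(pairs), pairs=list(pairs))


@dataclass
class LodResult:
    detection_frequency: dict[float, float]  # VAF level -> fraction detected
    lod: Optional[float]  # smallest level with frequency >= 0.5
    replicates: int


def lod_ladder(
    caller: Callable[[SimScenario], Sequence[_CallLike]],
    scenarios: Sequence[SimScenario],
    replicates: int,
    seed: int,
    detection_threshold: float = 0.5,
) -> LodResult:
    """Replicate detection frequency per ladder level and the resulting LoD.

    Each scenario is re-run ``replicates`` times with derived seeds; a
    replicate scores the fraction of its truth variants recovered as PASS
    calls (a variant-free scenario scores 1 when any PASS call appears, so
    the frequency reads as a false-positive rate).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    freq: dict[float, float] = {}
    for i, scenario in enumerate(scenarios):
        level = max((v.vaf for v in scenario.truth), default=0.0)
        total = 0.0
        for rep in range(replicates):
            calls = caller(scenario_with_seed(scenario, seed + 1000 * i + rep))
            found = _pass_vafs(calls)
            spiked = [v for v in scenario.truth if v.vaf > 0]
            if spiked:
                total += sum(v[:4] in found for v in spiked) / len(spiked)
            else:
                total += 1.0 if found else 0.0
        freq[level] = total / replicates
    detected_levels = [
        lv for lv, f in freq.items() if lv > 0 and f >= detection_threshold
    ]
    return LodResult(
        detection_frequency=freq,
        lod=min(detected_levels) if detected_levels else None,
        replicates=replicates,
    )
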