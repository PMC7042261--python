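"""End-to-end orchestration: reads -> families -> consensus -> calls."""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Optional

from .families import (
    FamilyConsensus,
    MolecularFamily,
    build_families,
    family_consensus,
    merge_umt_neighbors,
)
from .mb_caller import LocusTally, MBFilterConfig, MBVariantCall, call_variants, tally_amplicon
from .panel import Panel
from .reads import ReadRecord


def mb_tallies(
    reads: Iterable[ReadRecord],
    panel: Panel,
    cfg: MBFilterConfig,
    merge_distance: int = 0,
    stats: Optional[dict] = None,
) -> list[LocusTally]:
    """Molecular tallies from tagged reads.

    Families are built per amplicon by exact UMT-pair key (optionally with
    distance-1 UMT merging), only functional families are consensus-called,
    and only non-failed consensuses reach the tallies.
    """
    by_amp: dict[str, list[ReadRecord]] = defaultdict(list)
    n_reads = 0
    for r in reads:
        by_amp[r.amplicon_id].append(r)
        n_reads += 1
    tallies: list[LocusTally] = []
    n_families = n_functional = 0
    for amp_id in sorted(by_amp):
        amp = panel.get(amp_id)
        families: list[MolecularFamily] = build_families(
            by_amp[amp_id], cfg.min_family_size
        )
        if merge_distance:
            families = merge_umt_neighbors(
                families, merge_distance, cfg.min_family_size
            )
        n_families += len(families)
        consensuses: list[FamilyConsensus] = []
        for fam in families:
            if not fam.functional:
                continue
            n_functional += 1
            consensuses.append(family_consensus(fam, amp.insert_seq))
        tallies.extend(tally_amplicon(consensuses, amp))
    if stats is not None:
        stats.update(
            reads=n_reads, families=n_families, functional_families=n_functional
        )
    return tallies


def mb_call_reads(
    reads: Iterable[ReadRecord],
    panel: Panel,
    cfg: MBFilterConfig,
    context: str = "tumor",
    merge_distance: int = 0,
    stats: Optional[dict] = None,
) -> list[MBVariantCall]:
    """Full MB pipeline: cluster, consensus, tally, filter."""
    tallies = mb_tallies(reads, panel, cfg, merge_distance, stats)
    calls = call_variants(tallies, panel, cfg, context)
    if stats is not None:
        stats["calls"] = len(calls)
        stats["pass_calls"] = sum(c.passed for c in calls)
    return calls
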