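"""Synthetic tagged-amplicon reads with known truth.

The generative model mirrors a dual-UMT amplicon library:

1. *Template sampling* — each amplicon receives ``round(input_mass_ng x
   copies_per_ng)`` template molecules (default 303 haploid genome
   equivalents per ng, i.e. 3.3 pg per haploid genome); for each truth
   variant, the number of mutant molecules is Binomial(total, VAF).
2. *Tagging* — every molecule gets a random 5'/3' UMT pair, sampled
   without replacement over the pair space so each molecule is uniquely
   tagged (the working assumption of dual-tag chemistry).
3. *Heritable noise* — optional FFPE-style C->T deamination and
   lineage-level PCR errors are drawn once per molecule and inherited by
   all of its reads; this is the error class that can survive consensus.
4. *Sequencing* — each molecule emits k reads, k ~ Poisson(mean 6)
   truncated to >= 1, each with i.i.d. per-base substitution errors
   (default 1e-3/base), targets uniform over the three non-template bases.

Scenario presets reproduce a serial-dilution ladder (eight EGFR-style
variants at 0.1-5% expected VAF, constant 20 ng input) and single-variant
plasma spikes at arbitrary molecule counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .panel import AmpliconDef, Hotspot, Panel
from .reads import ReadRecord

DILUTION_LADDER = (0.001, 0.0025, 0.005, 0.01, 0.025, 0.05)
COPIES_PER_NG = 303  # haploid genome equivalents per ng (3.3 pg/genome)

_BASES = "ACGT"
_OTHER = {b: _BASES.replace(b, "") for b in _BASES}


class TrueVariant(NamedTuple):
    chrom: str
    pos: int  # 1-based genomic, VCF-style anchored for indels
    ref: str
    alt: str
    vaf: float


@dataclass
class SimScenario:
    """Generative description of one simulated library."""

    panel: Panel
    truth: list[TrueVariant]
    seed: int
    sample: str = "SIM"
    input_mass_ng: float = 20.0
    copies_per_ng: float = COPIES_PER_NG
    pcr_error_rate: float = 1e-6  # heritable, per base per molecule lineage
    seq_error_rate: float = 1e-3  # i.i.d. per base per read
    reads_per_molecule_mean: float = 6.0  # truncated Poisson, >= 1
    ffpe_deamination_rate: float = 0.0  # C->T per template C (FFPE preset 3e-4)
    umt_length: int = 6

    def __post_init__(self) -> None:
        for v in self.truth:
            if not (0.0 <= v.vaf <= 1.0):
                raise ValueError(f"true VAF out of [0,1]: {v}")
        for name in ("pcr_error_rate", "seq_error_rate"):
            if not (0.0 <= getattr(self, name) < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if not (0.0 <= self.ffpe_deamination_rate <= 1.0):
            raise ValueError("ffpe_deamination_rate must lie in [0, 1]")
        if self.copies_per_ng <= 0:
            raise ValueError("copies_per_ng must be positive")

    @property
    def molecules_per_amplicon(self) -> int:
        return round(self.input_mass_ng * self.copies_per_ng)


@dataclass
class GroundTruthVariant:
    variant: TrueVariant
    mutant_molecules: int
    total_molecules: int


@dataclass
class Molecule:
    molecule_id: int
    amplicon_id: str
    template: str  # insert sequence after variant + heritable errors
    is_mutant: bool
    umt5: str
    umt3: str


@dataclass
class GroundTruth:
    variants: list[GroundTruthVariant]
    read_molecule: list[int] = field(default_factory=list)  # parallel to reads
    read_error_positions: dict[int, tuple[int, ...]] = field(default_factory=dict)

    def validate(self, n_molecules: int) -> None:
        for gv in self.variants:
            assert gv.mutant_molecules <= gv.total_molecules
        assert all(0 <= m < n_molecules for m in self.read_molecule)


def apply_variant(insert_seq: str, insert_start: int, v: TrueVariant) -> str:
    """Apply a VCF-style (pos, ref, alt) edit to an amplicon insert."""
    pos0 = v.pos - insert_start
    if pos0 < 0 or pos0 + len(v.ref) > len(insert_seq):
        raise ValueError(f"variant {v} outside amplicon insert")
    if insert_seq[pos0 : pos0 + len(v.ref)] != v.ref:
        raise ValueError(
            f"variant {v}: reference allele mismatch "
            f"(insert has {insert_seq[pos0:pos0 + len(v.ref)]!r})"
        )
    return insert_seq[:pos0] + v.alt + insert_seq[pos0 + len(v.ref) :]


def _int_to_kmer(values: np.ndarray, k: int) -> list[str]:
    out = []
    for v in values:
        s = []
        for _ in range(k):
            s.append(_BASES[v & 3])
            v >>= 2
        out.append("".join(s))
    return out


def _unique_umt_pairs(
    rng: np.random.Generator, n: int, umt_length: int
) -> tuple[list[str], list[str]]:
    """n distinct UMT pairs; each pair uniquely tags one molecule."""
    space = 4 ** (2 * umt_length)
    if n > space:
        raise ValueError("more molecules than UMT pair space")
    seen: set[int] = set()
    codes: list[int] = []
    while len(codes) < n:
        batch = rng.integers(0, space, size=(n - len(codes)) + 16)
        for c in batch.tolist():
            if c not in seen:
                seen.add(c)
                codes.append(c)
                if len(codes) == n:
                    break
    arr = np.asarray(codes, dtype=np.int64)
    mask = (1 << (2 * umt_length)) - 1
    umt5 = _int_to_kmer(arr & mask, umt_length)
    umt3 = _int_to_kmer(arr >> (2 * umt_length), umt_length)
    return umt5, umt3


def draw_molecules(
    scenario: SimScenario, rng: Optional[np.random.Generator] = None
) -> tuple[list[Molecule], list[GroundTruthVariant]]:
    """Sample tagged template molecules for every amplicon of the panel.

    Mutant molecule counts are Binomial(total, VAF) per truth variant;
    variants sharing an amplicon occupy disjoint molecules (their VAFs
    must sum to <= 1).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    n_total = scenario.molecules_per_amplicon
    molecules: list[Molecule] = []
    gt: list[GroundTruthVariant] = []
    mol_id = 0
    for amp in scenario.panel.amplicons:
        if amp.insert_seq is None:
            raise ValueError(f"amplicon {amp.amplicon_id} has no insert sequence")
        amp_variants = [
            v for v in scenario.truth if amp.contains(v.chrom, v.pos)
        ]
        if sum(v.vaf for v in amp_variants) > 1.0:
            raise ValueError(
                f"true VAFs on amplicon {amp.amplicon_id} sum to > 1"
            )
        counts = [int(rng.binomial(n_total, v.vaf)) for v in amp_variants]
        if sum(counts) > n_total:
            raise ValueError(
                f"sampled mutant molecules exceed total on {amp.amplicon_id}"
            )
        umt5s, umt3s = _unique_umt_pairs(rng, n_total, scenario.umt_length)
        templates = [amp.insert_seq] * n_total
        mutant = [False] * n_total
        slot = 0
        for v, c in zip(amp_variants, counts):
            mut_template = apply_variant(amp.insert_seq, amp.insert_start, v)
            for _ in range(c):
                templates[slot] = mut_template
                mutant[slot] = True
                slot += 1
            gt.append(GroundTruthVariant(v, c, n_total))
        templates = _heritable_noise(templates, scenario, rng)
        for i in range(n_total):
            molecules.append(
                Molecule(
                    molecule_id=mol_id,
                    amplicon_id=amp.amplicon_id,
                    template=templates[i],
                    is_mutant=mutant[i],
                    umt5=umt5s[i],
                    umt3=umt3s[i],
                )
            )
            mol_id += 1
    return molecules, gt


def _heritable_noise(
    templates: list[str], scenario: SimScenario, rng: np.random.Generator
) -> list[str]:
    """FFPE deamination and lineage-level PCR errors, once per molecule."""
    out = templates
    if scenario.ffpe_deamination_rate > 0.0:
        out = list(out)
        for i, t in enumerate(out):
            c_pos = [j for j, b in enumerate(t) if b == "C"]
            if not c_pos:
                continue
            hits = rng.random(len(c_pos)) < scenario.ffpe_deamination_rate
            if hits.any():
                s = list(t)
                for j, hit in zip(c_pos, hits):
                    if hit:
                        s[j] = "T"
                out[i] = "".join(s)
    if scenario.pcr_error_rate > 0.0:
        out = list(out)
        lengths = np.array([len(t) for t in out])
        n_err = rng.binomial(lengths, scenario.pcr_error_rate)
        for i in np.nonzero(n_err)[0]:
            out[i] = _substitute(out[i], int(n_err[i]), rng)[0]
    return out


def _substitute(
    seq: str, n_err: int, rng: np.random.Generator
) -> tuple[str, tuple[int, ...]]:
    positions = rng.choice(len(seq), size=n_err, replace=False)
    s = list(seq)
    for p in positions:
        s[p] = _OTHER[s[p]][rng.integers(0, 3)]
    return "".join(s), tuple(int(p) for p in sorted(positions))


def amplify_and_sequence(
    molecules: Sequence[Molecule],
    scenario: SimScenario,
    rng: Optional[np.random.Generator] = None,
    truth: Optional[GroundTruth] = None,
) -> list[ReadRecord]:
    """Emit sequencing reads: k per molecule (truncated Poisson), i.i.d. errors."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed + 1)
    n = len(molecules)
    if n == 0:
        return []
    k = rng.poisson(scenario.reads_per_molecule_mean, n)
    while True:  # truncate at >= 1 by resampling zeros
        zeros = k == 0
        if not zeros.any():
            break
        k[zeros] = rng.poisson(scenario.reads_per_molecule_mean, int(zeros.sum()))

    reads: list[ReadRecord] = []
    qual_cache: dict[int, str] = {}
    read_idx = 0
    e = scenario.seq_error_rate
    for mol, ki in zip(molecules, k.tolist()):
        L = len(mol.template)
        qual = qual_cache.get(L)
        if qual is None:
            qual = qual_cache[L] = "I" * L
        if e > 0.0:
            errs = rng.binomial(L, e, ki)
        else:
            errs = np.zeros(ki, dtype=int)
        for j in range(ki):
            if errs[j] == 0:
                seq = mol.template
            else:
                seq, err_pos = _substitute(mol.template, int(errs[j]), rng)
                if len(seq) != L:  # pragma: no cover
                    raise AssertionError
                if truth is not None:
                    truth.read_error_positions[read_idx] = err_pos
            reads.append(
                ReadRecord(
                    read_id=f"r{read_idx}",
                    sample=scenario.sample,
                    amplicon_id=mol.amplicon_id,
                    sequence=seq,
                    qualities=qual if len(seq) == L else "I" * len(seq),
                    umt5=mol.umt5,
                    umt3=mol.umt3,
                )
            )
            if truth is not None:
                truth.read_molecule.append(mol.molecule_id)
            read_idx += 1
    return reads


@dataclass
class SimResult:
    scenario: SimScenario
    molecules: list[Molecule]
    reads: list[ReadRecord]
    truth: GroundTruth


def simulate_scenario(scenario: SimScenario) -> SimResult:
    """Run the full generative model from one seed."""
    rng = np.random.default_rng(scenario.seed)
    molecules, gt_variants = draw_molecules(scenario, rng)
    truth = GroundTruth(variants=gt_variants)
    reads = amplify_and_sequence(molecules, scenario, rng, truth=truth)
    return SimResult(scenario=scenario, molecules=molecules, reads=reads, truth=truth)


# ---------------------------------------------------------------------------
# Scenario presets

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


def _variant_round_trips(amp: AmpliconDef, v: TrueVariant) -> bool:
    """The mutant template must tokenize back to exactly (pos, ref, alt)."""
    from .tokens import read_deviations, token_alleles

    mutant = apply_variant(amp.insert_seq, amp.insert_start, v)
    devs = read_deviations(amp.insert_seq, mutant)
    alleles = []
    for pos0, tok in devs:
        parsed = token_alleles(pos0, tok, amp.insert_seq)
        if parsed is not None:
            pos0a, ref_a, alt_a, _ = parsed
            alleles.append((amp.insert_start + pos0a, ref_a, alt_a))
    return alleles == [(v.pos, v.ref, v.alt)]


def make_dilution_panel(
    seed: int = 0,
    insert_length: int = 50,
    primer_length: int = 18,
) -> tuple[Panel, list[TrueVariant]]:
    """Synthetic stand-in for an eight-variant EGFR dilution panel.

    Eight single-variant amplicons: six SNVs, one 15-bp deletion and one
    9-bp insertion (the long-insertion analogue). Sequences are random but
    seeded, and regenerated until each variant's mutant template tokenizes
    back to exactly its (pos, ref, alt) — no alignment ambiguity. VAFs on
    the returned variants are placeholders (0); scenario builders set them.
    """
    rng = np.random.default_rng(seed)
    specs = [  # (name, kind, event length)
        ("EGFR_L858R", "SNV", 1),
        ("EGFR_dE746_A750", "DEL", 15),
        ("EGFR_T790M", "SNV", 1),
        ("EGFR_insASV", "INS", 9),
        ("EGFR_L861Q", "SNV", 1),
        ("EGFR_G719S", "SNV", 1),
        ("EGFR_C797S", "SNV", 1),
        ("EGFR_S768I", "SNV", 1),
    ]
    amplicons: list[AmpliconDef] = []
    variants: list[TrueVariant] = []
    start = 1000
    for i, (name, kind, span) in enumerate(specs):
        for _ in range(100):  # retry until unambiguous
            seq = _random_seq(rng, insert_length)
            anchor0 = insert_length // 3
            amp = AmpliconDef(
                amplicon_id=name,
                chrom="chr7",
                insert_start=start,
                insert_end=start + insert_length - 1,
                fwd_primer=_random_seq(rng, primer_length),
                rev_primer=_random_seq(rng, primer_length),
                pool_id=1 + i % 2,
                insert_seq=seq,
            )
            pos = start + anchor0
            if kind == "SNV":
                ref = seq[anchor0]
                alt = _OTHER[ref][int(rng.integers(0, 3))]
            elif kind == "DEL":
                ref = seq[anchor0 : anchor0 + span + 1]
                alt = ref[0]
            else:  # INS
                ref = seq[anchor0]
                alt = ref + _random_seq(rng, span)
            v = TrueVariant(amp.chrom, pos, ref, alt, 0.0)
            if _variant_round_trips(amp, v):
                amplicons.append(amp)
                variants.append(v)
                break
        else:  # pragma: no cover
            raise RuntimeError(f"could not place variant {name}")
        start += insert_length + 200
    hotspots = [Hotspot(v.chrom, v.pos, v.ref, v.alt, specs[i][0]) for i, v in enumerate(variants)]
    return Panel(amplicons=amplicons, hotspots=hotspots), variants


def serial_dilution_scenarios(
    panel: Panel,
    variants: Sequence[TrueVariant],
    seed: int,
    ladder: Sequence[float] = DILUTION_LADDER,
    **overrides,
) -> list[SimScenario]:
    """One scenario per ladder VAF, all variants spiked at that level.

    Total input is held constant (20 ng default, ~6,060 genome
    equivalents); scenario i derives its seed as ``seed + i``.
    """
    scenarios = []
    for i, vaf in enumerate(ladder):
        truth = [v._replace(vaf=vaf) for v in variants]
        scenarios.append(
            SimScenario(panel=panel, truth=truth, seed=seed + i, **overrides)
        )
    return scenarios


def make_plasma_panel(
    seed: int = 7, insert_length: int = 30, primer_length: int = 18
) -> tuple[Panel, TrueVariant]:
    """Single-amplicon cfDNA panel with one non-hotspot SNV mid-insert."""
    rng = np.random.default_rng(seed)
    seq = _random_seq(rng, insert_length)
    amp = AmpliconDef(
        amplicon_id="CF1",
        chrom="chr12",
        insert_start=25245000,
        insert_end=25245000 + insert_length - 1,
        fwd_primer=_random_seq(rng, primer_length),
        rev_primer=_random_seq(rng, primer_length),
        insert_seq=seq,
    )
    anchor0 = insert_length // 2
    ref = seq[anchor0]
    alt = _OTHER[ref][int(rng.integers(0, 3))]
    variant = TrueVariant(amp.chrom, amp.insert_start + anchor0, ref, alt, 0.0)
    return Panel(amplicons=[amp]), variant


def plasma_scenario(
    true_vaf: float,
    n_molecules: int,
    seed: int,
    panel: Optional[Panel] = None,
    variant: Optional[TrueVariant] = None,
    **overrides,
) -> SimScenario:
    """A single-variant cfDNA spike at an exact template molecule count."""
    if panel is None or variant is None:
        panel, variant = make_plasma_panel()
    return SimScenario(
        panel=panel,
        truth=[variant._replace(vaf=true_vaf)],
        seed=seed,
        input_mass_ng=n_molecules / COPIES_PER_NG,
        **overrides,
    )


def error_only_scenario(
    n_molecules: int,
    seed: int,
    seq_error_rate: float,
    panel: Optional[Panel] = None,
    **overrides,
) -> SimScenario:
    """No true variant: every call is a false call (specificity probe)."""
    if panel is None:
        panel, _ = make_plasma_panel()
    return SimScenario(
        panel=panel,
        truth=[],
        seed=seed,
        input_mass_ng=n_molecules / COPIES_PER_NG,
        seq_error_rate=seq_error_rate,
        **overrides,
    )


# ---------------------------------------------------------------------------
# Output writers

def write_fastq(
    reads: Sequence[ReadRecord], panel: Panel, path: str | Path
) -> None:
    """Reconstruct raw tagged reads (UMT5+fwd+insert+rev+UMT3) as FASTQ."""
    amps = {a.amplicon_id: a for a in panel.amplicons}
    with open(path, "w") as fh:
        for r in reads:
            a = amps[r.amplicon_id]
            raw = r.umt5 + a.fwd_primer + r.sequence + a.rev_primer + r.umt3
            qual = (
                "I" * len(r.umt5)
                + "I" * len(a.fwd_primer)
                + r.qualities
                + "I" * len(a.rev_primer)
                + "I" * len(r.umt3)
            )
            fh.write(f"@{r.read_id}\n{raw}\n+\n{qual}\n")


TRUTH_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=umtcall-simulator
##INFO=<ID=TRUE_VAF,Number=1,Type=Float,Description="Simulated true variant allele fraction">
##INFO=<ID=MUT_MOL,Number=1,Type=Integer,Description="Sampled mutant template molecules">
##INFO=<ID=TOT_MOL,Number=1,Type=Integer,Description="Total template molecules on the amplicon">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_truth(
    truth_variants: Sequence[GroundTruthVariant],
    vcf_path: str | Path,
    tsv_path: Optional[str | Path] = None,
) -> None:
    ordered = sorted(truth_variants, key=lambda g: (g.variant.chrom, g.variant.pos))
    with open(vcf_path, "w") as fh:
        fh.write(TRUTH_VCF_HEADER)
        for g in ordered:
            v = g.variant
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                f"TRUE_VAF={v.vaf:.6g};MUT_MOL={g.mutant_molecules};"
                f"TOT_MOL={g.total_molecules}\n"
            )
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\ttrue_vaf\tmutant_molecules\ttotal_molecules\n")
            for g in ordered:
                v = g.variant
                fh.write(
                    f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.vaf:.6g}"
                    f"\t{g.mutant_molecules}\t{g.total_molecules}\n"
                )


def scenario_with_seed(scenario: SimScenario, seed: int) -> SimScenario:
    return replace(scenario, seed=seed)
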