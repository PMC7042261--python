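import numpy as np
import pytest

from umtcall.simulate import (
    SimScenario,
    TrueVariant,
    amplify_and_sequence,
    apply_variant,
    draw_molecules,
    error_only_scenario,
    make_dilution_panel,
    make_plasma_panel,
    plasma_scenario,
    serial_dilution_scenarios,
    simulate_scenario,
    write_fastq,
    write_truth,
)

from .conftest import build_panel

VARIANT = TrueVariant("chr1", 105, "A", "G", 0.1)


def _scenario(**kw):
    kw.setdefault("panel", build_panel())
    kw.setdefault("truth", [VARIANT])
    kw.setdefault("seed", 1)
    kw.setdefault("input_mass_ng", 100 / 303)
    return SimScenario(**kw)


def test_input_mass_converts_to_genome_equivalents():
    sc = _scenario(input_mass_ng=20.0)
    assert sc.molecules_per_amplicon == 6060  # 20 ng x 303 copies/ng
    molecules, _ = draw_molecules(_scenario())
    per_amp = {}
    for m in molecules:
        per_amp[m.amplicon_id] = per_amp.get(m.amplicon_id, 0) + 1
    assert per_amp == {"A": 100, "B": 100}


def test_vaf_zero_never_yields_mutant_molecules():
    sc = _scenario(truth=[VARIANT._replace(vaf=0.0)])
    molecules, gt = draw_molecules(sc)
    assert gt[0].mutant_molecules == 0
    assert not any(m.is_mutant for m in molecules)


def test_mutant_count_is_binomial_in_expectation():
    """Empirical mean of Binomial(n, v) draws within 3 s.e. of n*v."""
    n, v, seeds = 1000, 0.05, 150
    counts = []
    for s in range(seeds):
        sc = _scenario(
            truth=[VARIANT._replace(vaf=v)], seed=s, input_mass_ng=n / 303
        )
        counts.append(draw_molecules(sc)[1][0].mutant_molecules)
    se = np.sqrt(n * v * (1 - v) / seeds)
    assert abs(np.mean(counts) - n * v) < 3 * se


def test_umt_pairs_uniquely_tag_molecules():
    molecules, _ = draw_molecules(_scenario(input_mass_ng=2000 / 303))
    pairs = {(m.amplicon_id, m.umt5, m.umt3) for m in molecules}
    assert len(pairs) == len(molecules)


def test_zero_error_reads_equal_their_template():
    sc = _scenario(seq_error_rate=0.0, pcr_error_rate=0.0)
    res = simulate_scenario(sc)
    by_id = {m.molecule_id: m for m in res.molecules}
    assert len(res.truth.read_molecule) == len(res.reads)
    for read, mol_id in zip(res.reads, res.truth.read_molecule):
        assert read.sequence == by_id[mol_id].template
    assert all(len(m.template) >= 1 for m in res.molecules)


def test_every_molecule_emits_at_least_one_read():
    res = simulate_scenario(_scenario(reads_per_molecule_mean=1.0))
    assert set(res.truth.read_molecule) == {m.molecule_id for m in res.molecules}


def test_sequencing_error_rate_recovers_binomial_mean():
    """At e=0.5 over a 20-base insert, mean mismatches per read ~ Binomial(20, .5)."""
    sc = _scenario(seq_error_rate=0.5, reads_per_molecule_mean=6.0, seed=9)
    res = simulate_scenario(sc)
    templates = {m.molecule_id: m.template for m in res.molecules}
    mismatches = [
        sum(a != b for a, b in zip(r.sequence, templates[mid]))
        for r, mid in zip(res.reads, res.truth.read_molecule)
    ]
    n_reads, L, e = len(mismatches), 20, 0.5
    se = np.sqrt(L * e * (1 - e) / n_reads)
    assert abs(np.mean(mismatches) - L * e) < 3 * se


def test_full_deamination_converts_all_template_C_to_T():
    sc = _scenario(ffpe_deamination_rate=1.0, seq_error_rate=0.0, truth=[])
    res = simulate_scenario(sc)
    for r in res.reads:
        assert "C" not in r.sequence


def test_identical_seed_gives_bit_identical_fastq(tmp_path):
    panel = build_panel()
    paths = []
    for name in ("a.fastq", "b.fastq"):
        res = simulate_scenario(_scenario(seed=77))
        p = tmp_path / name
        write_fastq(res.reads, panel, p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_apply_variant_checks_reference():
    seq = "ACGTACGT"
    assert apply_variant(seq, 101, TrueVariant("c", 103, "G", "T", 0.1)) == "ACTTACGT"
    assert apply_variant(seq, 101, TrueVariant("c", 103, "GT", "G", 0.1)) == "ACGACGT"
    with pytest.raises(ValueError, match="mismatch"):
        apply_variant(seq, 101, TrueVariant("c", 103, "A", "T", 0.1))
    with pytest.raises(ValueError, match="outside"):
        apply_variant(seq, 101, TrueVariant("c", 120, "A", "T", 0.1))


def test_vaf_ladder_summing_above_one_rejected():
    panel = build_panel()
    truth = [
        TrueVariant("chr1", 105, "A", "G", 0.6),
        TrueVariant("chr1", 108, "T", "C", 0.6),
    ]
    sc = SimScenario(panel=panel, truth=truth, seed=1, input_mass_ng=50 / 303)
    with pytest.raises(ValueError, match="sum to > 1"):
        draw_molecules(sc)


def test_serial_dilution_scenarios_follow_the_ladder():
    panel, variants = make_dilution_panel(seed=3)
    scens = serial_dilution_scenarios(panel, variants, seed=50)
    assert [s.truth[0].vaf for s in scens] == [0.001, 0.0025, 0.005, 0.01, 0.025, 0.05]
    assert all(len(s.truth) == 8 for s in scens)
    assert [s.seed for s in scens] == [50 + i for i in range(6)]
    assert all(s.molecules_per_amplicon == 6060 for s in scens)
    # 0.1% of 6,060 molecules: ~6 expected mutant copies per variant
    assert scens[0].truth[0].vaf * scens[0].molecules_per_amplicon == pytest.approx(6.06)


def test_dilution_panel_variant_classes():
    _, variants = make_dilution_panel(seed=3)
    classes = sorted(
        ("SNV" if len(v.ref) == len(v.alt) == 1 else "DEL" if len(v.ref) > 1 else "INS")
        for v in variants
    )
    assert classes.count("SNV") == 6 and classes.count("DEL") == 1
    assert classes.count("INS") == 1


def test_plasma_scenario_hits_exact_molecule_count():
    sc = plasma_scenario(0.0017, 20000, seed=4)
    assert sc.molecules_per_amplicon == 20000
    assert sc.truth[0].vaf == 0.0017
    sc0 = error_only_scenario(500, seed=4, seq_error_rate=0.005)
    assert sc0.truth == [] and sc0.molecules_per_amplicon == 500


def test_write_truth_round_trips_through_pysam(tmp_path):
    pysam = pytest.importorskip("pysam")
    res = simulate_scenario(_scenario())
    vcf_path = tmp_path / "truth.vcf"
    write_truth(res.truth.variants, vcf_path, tmp_path / "truth.tsv")
    records = list(pysam.VariantFile(str(vcf_path)))
    assert len(records) == 1
    rec = records[0]
    assert (rec.chrom, rec.pos, rec.ref, rec.alts[0]) == ("chr1", 105, "A", "G")
    assert rec.info["TRUE_VAF"] == pytest.approx(0.1)


def test_write_truth_empty_and_sorted(tmp_path):
    write_truth([], tmp_path / "empty.vcf")
    lines = (tmp_path / "empty.vcf").read_text().splitlines()
    assert all(l.startswith("#") for l in lines)
    panel, variants = make_dilution_panel(seed=3)
    sc = serial_dilution_scenarios(panel, variants, seed=5, ladder=[0.05])[0]
    _, gt = draw_molecules(sc)
    write_truth(gt, tmp_path / "eight.vcf")
    body = [
        l for l in (tmp_path / "eight.vcf").read_text().splitlines()
        if not l.startswith("#")
    ]
    positions = [int(l.split("\t")[1]) for l in body]
    assert len(body) == 8 and positions == sorted(positions)
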