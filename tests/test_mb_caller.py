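import math
from fractions import Fraction

import pytest

from umtcall.families import FamilyConsensus, FamilyKey
from umtcall.mb_caller import (
    Allele,
    MBFilterConfig,
    MBVariantCall,
    apply_mb_filters,
    background_pvalue,
    call_variants,
    format_vaf_percent,
    homopolymer_context,
    molecular_vaf,
    tally_amplicon,
    tally_locus,
)

from .conftest import AMP_A_SEQ


# ---------------------------------------------------------------------------
# VAF arithmetic

@pytest.mark.parametrize(
    "alt,depth,printed",
    [
        (9, 249780, "0.0036"),
        (2145, 236446, "0.91"),
        (4, 3053, "0.13"),
        (6, 9859, "0.06"),
    ],
)
def test_vaf_reproduces_printed_conversions(alt, depth, printed):
    vaf = molecular_vaf(alt, depth)
    assert not vaf.no_coverage
    assert math.isclose(vaf.fraction, alt / depth)
    assert format_vaf_percent(vaf.fraction) == printed


def test_vaf_edge_cases():
    assert molecular_vaf(0, 1000).fraction == 0.0
    zero = molecular_vaf(0, 0)
    assert zero.fraction == 0.0 and zero.no_coverage
    with pytest.raises(ValueError, match="exceeds"):
        molecular_vaf(5, 4)
    with pytest.raises(ValueError):
        molecular_vaf(-1, 4)


# ---------------------------------------------------------------------------
# Background p-value vs an independent exact-summation oracle

def oracle_binomial_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) by exact big-integer summation of the complement.

    The float ``p`` is an exact binary rational pn/pd, so every pmf term
    C(n,i) p^i (1-p)^(n-i) is an exact integer over pd^n; the complement
    sum for i < k is accumulated exactly and the tail rounded to float at
    the very end. Practical for the small k of a background-noise tail.
    """
    if k <= 0:
        return 1.0
    frac_p = Fraction(p)
    pn, pd = frac_p.numerator, frac_p.denominator
    qn = pd - pn  # (1-p) numerator over the same pd
    qpow = qn**n
    total = 0  # complement numerator over denominator pd^n
    ppow = 1
    for i in range(k):
        if i > 0:
            qpow //= qn
            ppow *= pn
        total += math.comb(n, i) * ppow * qpow
    num, den = pd**n - total, pd**n
    # round to float without Fraction's gcd normalization of huge ints
    shift = den.bit_length() - num.bit_length() + 80
    return math.ldexp((num << shift) // den, -shift)


@pytest.mark.parametrize(
    "k,n,p",
    [
        (1, 10, 0.01),
        (3, 50, 0.1),
        (4, 3053, 1e-3),
        (2, 500, 1e-4),
        (17, 100000, 1e-4),
        (30, 100000, 1e-4),
        (5, 100000, 1e-5),
    ],
)
def test_pvalue_matches_exact_summation_oracle(k, n, p):
    assert background_pvalue(k, n, p) == pytest.approx(
        oracle_binomial_tail(k, n, p), rel=1e-12
    )


def test_pvalue_frozen_exact_value():
    # exact rational tail sum for (4, 3053, 1e-3), computed independently
    assert background_pvalue(4, 3053, 1e-3) == pytest.approx(
        0.36464641088844174, rel=1e-12
    )


def test_pvalue_closed_forms_and_edges():
    assert background_pvalue(0, 100, 0.01) == 1.0
    assert background_pvalue(0, 0, 0.5) == 1.0  # zero depth
    for n, e in [(3, 0.2), (7, 0.01)]:
        assert background_pvalue(n, n, e) == pytest.approx(e**n, rel=1e-12)
    with pytest.raises(ValueError):
        background_pvalue(2, 1, 0.1)
    with pytest.raises(ValueError):
        background_pvalue(1, 10, 0.0)


def test_pvalue_monotone_nonincreasing_in_alt_count():
    vals = [background_pvalue(k, 1000, 1e-3) for k in range(0, 20)]
    assert all(a >= b for a, b in zip(vals, vals[1:]))


# ---------------------------------------------------------------------------
# Locus tallies

KEY = FamilyKey("S1", "A", "AAAAAA", "CCCCCC")


def _cons(deviations=None, ambiguous=(), size=3, failed=False):
    return FamilyConsensus(
        key=KEY,
        family_size=size,
        insert_length=len(AMP_A_SEQ),
        deviations=deviations or {},
        ambiguous=frozenset(ambiguous),
        failed=failed,
    )


def test_tally_counts_unanimous_families(panel):
    amp = panel.get("A")
    cons = [_cons() for _ in range(97)] + [_cons({4: "G"}) for _ in range(3)]
    tally = tally_locus(cons, amp, pos=105)  # pos0 = 4, ref A
    assert tally.family_depth == 100
    assert tally.ref_families == 97
    assert tally.alt[Allele("A", "G", "SNV")].families == 3


def test_tally_ambiguous_families_add_depth_only(panel):
    amp = panel.get("A")
    cons = [_cons() for _ in range(9)] + [_cons(ambiguous=[4])]
    tally = tally_locus(cons, amp, pos=105)
    assert tally.family_depth == 10
    assert tally.ref_families == 9
    assert not tally.alt and tally.ambiguous_families == 1


def test_tally_empty_and_out_of_range(panel):
    amp = panel.get("A")
    assert tally_locus([], amp, pos=105).family_depth == 0
    assert tally_locus([_cons()], amp, pos=999).family_depth == 0


def test_tally_amplicon_matches_per_locus_tally(panel):
    amp = panel.get("A")
    cons = (
        [_cons() for _ in range(5)]
        + [_cons({4: "G"}, size=2) for _ in range(2)]
        + [_cons({7: "A"}), _cons(ambiguous=[4]), _cons(failed=True)]
    )
    tallies = {t.pos: t for t in tally_amplicon(cons, amp)}
    assert set(tallies) == {105, 108}
    per_locus = tally_locus([c for c in cons], amp, 105)
    assert tallies[105].family_depth == per_locus.family_depth == 9
    assert tallies[105].alt == per_locus.alt
    assert tallies[105].ambiguous_families == per_locus.ambiguous_families


def test_tally_spanning_deletion_token_adds_depth_only(panel):
    amp = panel.get("A")
    cons = [_cons({4: f"{AMP_A_SEQ[4]}-3", 5: "*", 6: "*", 7: "*"})] + [_cons()] * 3
    t_anchor = tally_locus(cons, amp, 105)
    assert t_anchor.alt[Allele(AMP_A_SEQ[4:8], AMP_A_SEQ[4], "DEL")].families == 1
    t_span = tally_locus(cons, amp, 106)
    assert t_span.family_depth == 4 and not t_span.alt


# ---------------------------------------------------------------------------
# Filter cascade

def _draft(
    vclass="SNV",
    hotspot=False,
    homopolymer=False,
    alt_families=4,
    depth=3053,
    vaf=None,
    p_value=None,
    min_fam_size=2,
    error_rate=1e-4,
):
    vaf = vaf if vaf is not None else alt_families / depth
    p = (
        p_value
        if p_value is not None
        else background_pvalue(alt_families, depth, error_rate)
    )
    return MBVariantCall(
        chrom="chr1",
        pos=105,
        ref="A",
        alt="G",
        vclass=vclass,
        hotspot=hotspot,
        homopolymer=homopolymer,
        alt_family_count=alt_families,
        family_depth=depth,
        min_supporting_family_size=min_fam_size,
        vaf=vaf,
        p_value=p,
    )


def _verdict(call, name):
    return {v.name: v.passed for v in call.verdicts}[name]


def test_plasma_low_vaf_snv_with_four_families_passes():
    """4 supporting molecules out of 3,053 (0.13%) survives plasma filtering."""
    call = apply_mb_filters(_draft(), MBFilterConfig(), context="plasma")
    assert call.passed and call.filter_field == "PASS"
    assert format_vaf_percent(call.vaf) == "0.13"


def test_nonhotspot_snv_with_three_alleles_fails():
    call = apply_mb_filters(_draft(alt_families=3), MBFilterConfig(), "plasma")
    assert not call.passed
    assert not _verdict(call, "nonhotspot_alt_count")


def test_indel_with_five_families_fails_supporting_minimum():
    call = apply_mb_filters(
        _draft(vclass="INS", hotspot=False, alt_families=5), MBFilterConfig(), "plasma"
    )
    assert not _verdict(call, "min_supporting_families")
    # 6 supporting families meet the INDEL minimum
    ok = apply_mb_filters(
        _draft(vclass="INS", alt_families=6), MBFilterConfig(), "plasma"
    )
    assert _verdict(ok, "min_supporting_families")


def test_hotspot_snv_below_tumor_vaf_cutoff_fails_in_tumor_only():
    draft = _draft(hotspot=True, alt_families=2, depth=500, vaf=0.004)
    tumor = apply_mb_filters(draft, MBFilterConfig(), "tumor")
    assert not _verdict(tumor, "tumor_vaf") and not tumor.passed
    plasma = apply_mb_filters(_draft(hotspot=True, alt_families=2, depth=500, vaf=0.004), MBFilterConfig(), "plasma")
    assert "tumor_vaf" not in {v.name for v in plasma.verdicts}


def test_common_snp_and_pvalue_filters():
    cfg = MBFilterConfig(common_snp_positions={("chr1", 105)})
    call = apply_mb_filters(_draft(), cfg, "plasma")
    assert not _verdict(call, "common_snp")
    noisy = apply_mb_filters(_draft(p_value=0.5), MBFilterConfig(), "plasma")
    assert not _verdict(noisy, "max_p_value")


def test_indel_evidence_thresholds():
    cfg = MBFilterConfig()
    low_vaf = apply_mb_filters(
        _draft(vclass="DEL", alt_families=8, depth=8000, vaf=0.001), cfg, "plasma"
    )
    assert not _verdict(low_vaf, "indel_evidence")
    few = apply_mb_filters(
        _draft(vclass="DEL", alt_families=3, depth=800), cfg, "plasma"
    )
    assert not _verdict(few, "indel_evidence")


def test_homopolymer_indel_family_size_floor():
    cfg = MBFilterConfig(homopolymer_indel_family_size=3)
    call = apply_mb_filters(
        _draft(vclass="DEL", alt_families=6, homopolymer=True, min_fam_size=2),
        cfg,
        "plasma",
    )
    assert not _verdict(call, "homopolymer_family_size")


def test_unknown_class_and_context_rejected():
    with pytest.raises(ValueError, match="class"):
        apply_mb_filters(_draft(vclass="MNV"), MBFilterConfig(), "plasma")
    with pytest.raises(ValueError, match="context"):
        apply_mb_filters(_draft(), MBFilterConfig(), "serum")


def test_all_applicable_verdicts_recorded_after_failure():
    call = apply_mb_filters(_draft(alt_families=1, depth=100), MBFilterConfig(), "tumor")
    names = [v.name for v in call.verdicts]
    assert names == [
        "min_supporting_families",
        "min_alt_allele_count",
        "common_snp",
        "max_p_value",
        "nonhotspot_alt_count",
        "tumor_vaf",
    ]


def test_filter_cascade_monotone_in_alt_family_count():
    """Adding supporting molecules (all else fixed) never flips PASS to FAIL."""
    cfg = MBFilterConfig()
    for context in ("tumor", "plasma"):
        for vclass in ("SNV", "DEL"):
            prev_pass = False
            for alt in range(0, 60):
                call = apply_mb_filters(
                    _draft(vclass=vclass, alt_families=alt, depth=2000),
                    cfg,
                    context,
                )
                if prev_pass:
                    assert call.passed, f"{context}/{vclass} flipped at {alt}"
                prev_pass = call.passed


def test_homopolymer_context_detection():
    #            0123456789
    seq = "ATCGGGGACT"
    assert homopolymer_context(seq, 2, min_run=4)  # GGGG follows pos 2
    assert not homopolymer_context(seq, 3, min_run=4)  # GGG after pos 3
    assert not homopolymer_context(seq, 9, min_run=1)  # anchor at last base


def test_call_variants_orders_and_flags_hotspots(panel):
    amp = panel.get("A")
    cons = [_cons() for _ in range(200)] + [_cons({4: "G"})] * 5 + [
        _cons({7: "C"})
    ] * 4
    tallies = tally_amplicon(cons, amp)
    calls = call_variants(tallies, panel, MBFilterConfig(), context="plasma")
    assert [(c.pos, c.alt) for c in calls] == [(105, "G"), (108, "C")]
    assert calls[0].hotspot and not calls[1].hotspot
    assert all(c.passed for c in calls)
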