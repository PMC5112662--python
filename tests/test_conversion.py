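"""Conversion-signature detection: identity windows, tracts, region contrast."""

import math

import numpy as np
import pytest

from pairedrec.codon import CodonAlignment
from pairedrec.conversion import (
    StrandRegionSet,
    check_exon_restriction,
    codon_to_genomic,
    detect_conversion_tracts,
    percent_identity_windows,
    region_contrast,
)
from pairedrec.simulate import apply_conversion, evolve_codon_sequence, random_coding_sequence

SYN_PAIR = ("GTT", "GTA")  # Val/Val: one synonymous difference
IDENT = ("AAA", "AAA")


def _alignment_from_pattern(pattern: str) -> CodonAlignment:
    """'s' codons carry a synonymous difference, '.' are identical."""
    a = "".join(SYN_PAIR[0] if c == "s" else IDENT[0] for c in pattern)
    b = "".join(SYN_PAIR[1] if c == "s" else IDENT[1] for c in pattern)
    return CodonAlignment(a, b)


# --- percent identity windows -------------------------------------------------


def test_identity_windows_identical_pair():
    wins = percent_identity_windows("ACGT" * 250, "ACGT" * 250, window=100, step=25)
    assert all(w.identity == 100.0 for w in wins)
    assert wins[0].start == 0 and wins[-1].end == 1000


def test_identity_windows_alternating_mismatch():
    a = "AC" * 200
    b = "AG" * 200  # every second column mismatches
    wins = percent_identity_windows(a, b, window=100, step=50)
    assert all(w.identity == pytest.approx(50.0) for w in wins)


def test_identity_windows_matches_direct_recount(rng):
    bases = "ACGT"
    a = "".join(bases[i] for i in rng.integers(0, 4, 500))
    b = "".join(bases[i] for i in rng.integers(0, 4, 500))
    wins = percent_identity_windows(a, b, window=80, step=40)
    for w in wins:
        seg_a, seg_b = a[w.start : w.end], b[w.start : w.end]
        matches = sum(x == y for x, y in zip(seg_a, seg_b))
        assert w.identity == pytest.approx(100 * matches / len(seg_a))


def test_identity_windows_gap_handling_and_short_alignment():
    wins = percent_identity_windows("AAA------A", "AAACCCCCCA", window=100, step=10)
    assert len(wins) == 1  # window longer than alignment: single window
    assert wins[0].comparable == 4
    assert wins[0].identity == 100.0
    assert wins[0].low_coverage


# --- tract detection ----------------------------------------------------------


def test_identical_pair_not_assessable():
    scan = detect_conversion_tracts(CodonAlignment("AAA" * 30, "AAA" * 30), reps=199)
    assert scan.status == "not_assessable"


def test_tract_detected_in_constructed_alignment():
    # dense synonymous differences except a clean 24-codon run
    pattern = "s.s.ss.s.s" * 3 + "." * 24 + "s.ss.s.s.s" * 3
    scan = detect_conversion_tracts(_alignment_from_pattern(pattern), min_len=15,
                                    reps=999, seed=1)
    assert scan.status == "ok"
    assert len(scan.tracts) == 1
    tract = scan.tracts[0]
    assert tract.start == 30 and tract.end == 54
    assert tract.syn_inside == 0
    assert 0 < tract.pvalue <= 0.05


def test_tract_detection_swap_invariant():
    pattern = "s.s.ss.s.s" * 3 + "." * 24 + "s.ss.s.s.s" * 3
    aln = _alignment_from_pattern(pattern)
    s1 = detect_conversion_tracts(aln, reps=499, seed=5)
    s2 = detect_conversion_tracts(aln.swapped(), reps=499, seed=5)
    assert [(t.start, t.end, t.pvalue) for t in s1.tracts] == [
        (t.start, t.end, t.pvalue) for t in s2.tracts
    ]


def test_tract_detection_seeded_determinism():
    pattern = "s." * 30 + "." * 20 + ".s" * 25
    aln = _alignment_from_pattern(pattern)
    s1 = detect_conversion_tracts(aln, reps=499, seed=11)
    s2 = detect_conversion_tracts(aln, reps=499, seed=11)
    assert [(t.start, t.pvalue) for t in s1.tracts] == [(t.start, t.pvalue) for t in s2.tracts]


def test_simulated_conversion_recovered(rng):
    anc = random_coding_sequence(150, rng)
    a = evolve_codon_sequence(anc, 0.2, 0.5, rng)
    b = apply_conversion(evolve_codon_sequence(anc, 0.2, 0.5, rng), a, (55, 95))
    scan = detect_conversion_tracts(CodonAlignment(a, b), min_len=15, reps=999, seed=0)
    assert scan.status == "ok"
    assert any(t.overlaps(55, 95) for t in scan.tracts)


def test_add_one_pvalues_bounded():
    pattern = "s." * 40 + "." * 30
    scan = detect_conversion_tracts(_alignment_from_pattern(pattern), reps=199, seed=0)
    for t in scan.tracts:
        assert 1 / 200 <= t.pvalue <= 1.0


def test_few_reps_warns():
    pattern = "s." * 40
    with pytest.warns(UserWarning):
        detect_conversion_tracts(_alignment_from_pattern(pattern), reps=50, seed=0)


# --- exon restriction ---------------------------------------------------------


def test_exon_restriction_cases():
    exon = (1000, 1321)
    # tract spanning the whole exon (incl. splice dinucleotides) -> true
    conc = check_exon_restriction((998, 1323), exon, slack=10)
    assert conc.exon_restricted
    # tract covering half the exon -> false
    assert not check_exon_restriction((1000, 1160), exon, slack=10).exon_restricted
    # tract extending 200 nt into the intron -> false
    assert not check_exon_restriction((998, 1521), exon, slack=10).exon_restricted
    # tract entirely outside -> false with note
    conc = check_exon_restriction((2000, 2100), exon, slack=10)
    assert not conc.exon_restricted and "outside" in conc.note


def test_codon_to_genomic_strand_aware():
    assert codon_to_genomic((0, 10), 1000, 1321, "+") == (1000, 1030)
    assert codon_to_genomic((0, 10), 1000, 1321, "-") == (1291, 1321)


# --- region contrast ----------------------------------------------------------


def test_region_contrast_uniform_null():
    # nonsynonymous differences spread uniformly: ratio ~= 1, p not small
    a = ("GAT" + "AAA") * 30  # Asp vs Ala at every second codon
    b = ("GCT" + "AAA") * 30
    aln = CodonAlignment(a, b)
    regions = StrandRegionSet({"r1": (10, 25), "r2": (40, 50)})
    rc = region_contrast(aln, regions, reps=499, seed=0)
    assert rc.ratio == pytest.approx(1.0, abs=0.35)
    assert rc.pvalue > 0.05


def test_region_contrast_all_inside_extreme():
    pattern_a = "AAA" * 10 + "GAT" * 10 + "AAA" * 10
    pattern_b = "AAA" * 10 + "GCT" * 10 + "AAA" * 10
    aln = CodonAlignment(pattern_a, pattern_b)
    rc = region_contrast(aln, StrandRegionSet({"w": (10, 20)}), reps=199, seed=0)
    assert rc.nd_outside == 0
    assert math.isinf(rc.ratio)
    assert rc.pvalue <= 1 / 200 + 1e-12


def test_region_contrast_power_on_selected_window(rng):
    om = np.full(150, 0.2)
    om[60:85] = 2.0
    anc = random_coding_sequence(150, rng)
    a = evolve_codon_sequence(anc, 0.15, om, rng)
    b = evolve_codon_sequence(anc, 0.15, om, rng)
    rc = region_contrast(CodonAlignment(a, b), StrandRegionSet({"w": (60, 85)}),
                         reps=499, seed=1)
    assert rc.ratio > 1


def test_region_contrast_no_nonsyn_undefined():
    a = "GTT" * 30
    b = "GTA" * 30  # only synonymous differences
    rc = region_contrast(CodonAlignment(a, b), StrandRegionSet({"w": (5, 15)}),
                         reps=99, seed=0)
    assert math.isnan(rc.ratio)


def test_region_set_validation():
    with pytest.raises(ValueError):
        StrandRegionSet({"a": (0, 10), "b": (5, 15)})  # overlap
    with pytest.raises(ValueError):
        region_contrast(
            CodonAlignment("AAA" * 4, "AAA" * 4), StrandRegionSet({"a": (0, 3)}), reps=9
        )
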