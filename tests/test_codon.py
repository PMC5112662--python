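"""NG86 site/difference counting against independent enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from pairedrec.codon import (
    CodonAlignment,
    NoComparableCodonsError,
    SENSE_CODONS,
    STOP_CODONS,
    count_differences,
    count_sites,
    cumulative_profile,
    edit_alignment,
    jukes_cantor,
    pairwise_dnds,
)

BASES = "ACGT"


# --- independent oracles (Biopython translation, explicit recursion) ----------


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_sites(codon: str) -> float:
    """Synonymous site count by direct mutant enumeration."""
    s = 0.0
    for pos in range(3):
        fates = []
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if translate(mut) == "*":
                continue
            fates.append(translate(mut) == translate(codon))
        if fates:
            s += sum(fates) / len(fates)
    return s


def oracle_differences(a: str, b: str) -> tuple[float, float]:
    """Pathway average by recursive stepping (stop-free paths)."""

    def paths(cur: str, remaining: tuple[int, ...], allow_stops: bool):
        if not remaining:
            yield (0, 0)
            return
        for i, pos in enumerate(remaining):
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if translate(nxt) == "*" and not allow_stops:
                continue
            step_syn = translate(nxt) == translate(cur) and "*" not in (
                translate(nxt),
                translate(cur),
            )
            for sd, nd in paths(nxt, remaining[:i] + remaining[i + 1 :], allow_stops):
                yield (sd + step_syn, nd + (not step_syn))

    diff = tuple(i for i in range(3) if a[i] != b[i])
    found = list(paths(a, diff, False))
    if not found:
        found = list(paths(a, diff, True))
    if not found:
        return (0.0, 0.0)
    return (
        sum(p[0] for p in found) / len(found),
        sum(p[1] for p in found) / len(found),
    )


def random_sense_sequence(n_codons: int, rng) -> str:
    return "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, size=n_codons))


# --- site counting ------------------------------------------------------------


@pytest.mark.parametrize(
    "codon,S", [("TTT", 1 / 3), ("CTT", 1.0), ("TGG", 0.0)]
)
def test_site_counts_worked_examples(codon, S):
    sc = count_sites(codon)
    assert sc.S == pytest.approx(S)
    assert sc.N == pytest.approx(3 - S)


def test_site_counts_match_oracle_for_all_sense_codons():
    for codon in SENSE_CODONS:
        sc = count_sites(codon)
        assert sc.S == pytest.approx(oracle_sites(codon), abs=1e-12), codon
        assert sc.S + sc.N == pytest.approx(3.0)


@pytest.mark.parametrize("codon", sorted(STOP_CODONS))
def test_stop_codons_rejected(codon):
    with pytest.raises(ValueError):
        count_sites(codon)
    with pytest.raises(ValueError):
        count_differences(codon, "AAA")


# --- pathway difference counting ----------------------------------------------


@pytest.mark.parametrize(
    "a,b,sd,nd",
    [
        ("GTT", "GTA", 1.0, 0.0),  # Val->Val, single synonymous step
        ("TTT", "GTA", 0.5, 1.5),  # two pathways averaged
        ("AAA", "AAA", 0.0, 0.0),
    ],
)
def test_difference_worked_examples(a, b, sd, nd):
    assert count_differences(a, b) == pytest.approx((sd, nd))


def test_differences_match_oracle_and_hamming_for_all_codon_pairs():
    """Exhaustive 61x61 check: pathway oracle equality and Sd+Nd = Hamming."""
    for a, b in itertools.product(SENSE_CODONS, repeat=2):
        sd, nd = count_differences(a, b)
        osd, ond = oracle_differences(a, b)
        assert sd == pytest.approx(osd, abs=1e-12), (a, b)
        assert nd == pytest.approx(ond, abs=1e-12), (a, b)
        assert sd + nd == pytest.approx(sum(x != y for x, y in zip(a, b)))


# --- Jukes-Cantor ---------------------------------------------------------------


def test_jukes_cantor_domain():
    assert jukes_cantor(0.0) == 0.0
    assert jukes_cantor(0.7499) > 5  # near saturation, large but finite
    assert math.isnan(jukes_cantor(0.75))
    with pytest.raises(ValueError):
        jukes_cantor(-0.1)


def test_jukes_cantor_monotone():
    ps = np.linspace(0, 0.74, 50)
    ds = [jukes_cantor(p) for p in ps]
    assert all(x < y for x, y in zip(ds, ds[1:]))


# --- alignment editing ----------------------------------------------------------


def test_edit_alignment_identity_and_gap_removal():
    aln = edit_alignment("ATGAAA", "ATGAAA")
    assert aln.n_codons == 2 and aln.dropped_columns == 0
    aln = edit_alignment("ATG---AAA", "ATGCCCAAA")
    assert aln.n_codons == 2 and aln.dropped_columns == 1


def test_edit_alignment_errors():
    with pytest.raises(ValueError):
        edit_alignment("ATGAAAA", "ATGAAAA")  # frame-shifted (not codon-sized)
    with pytest.raises(NoComparableCodonsError):
        edit_alignment("---", "AAA")
    with pytest.raises(ValueError):
        edit_alignment("AAA", "AAAA")  # unequal lengths


def test_edit_alignment_drops_ambiguity_and_stop_columns():
    aln = edit_alignment("ATGNNNAAA", "ATGCCCTAA")  # N column + stop column
    assert aln.n_codons == 1 and aln.dropped_columns == 2


# --- pairwise dN/dS -------------------------------------------------------------


def test_identical_sequences_have_undefined_ratio():
    aln = CodonAlignment("ATGGCT", "ATGGCT")
    res = pairwise_dnds(aln)
    assert res.dN == 0 and res.dS == 0
    assert not res.defined
    assert "dS_zero" in res.flags


def test_pairwise_dnds_matches_bruteforce_on_random_pairs(rng):
    """Oracle equivalence: re-derive S, N, Sd, Nd and JC from scratch."""
    for _ in range(5):
        a = random_sense_sequence(50, rng)
        b = random_sense_sequence(50, rng)
        res = pairwise_dnds(CodonAlignment(a, b))
        S = N = Sd = Nd = 0.0
        for i in range(0, 150, 3):
            ca, cb = a[i : i + 3], b[i : i + 3]
            sa, sb = oracle_sites(ca), oracle_sites(cb)
            S += (sa + sb) / 2
            N += (3 - sa + 3 - sb) / 2
            d = oracle_differences(ca, cb)
            Sd += d[0]
            Nd += d[1]
        assert res.S == pytest.approx(S, abs=1e-9)
        assert res.N == pytest.approx(N, abs=1e-9)
        assert res.Sd == pytest.approx(Sd, abs=1e-9)
        assert res.Nd == pytest.approx(Nd, abs=1e-9)
        if res.defined:
            dS = -0.75 * math.log(1 - 4 * (Sd / S) / 3)
            dN = -0.75 * math.log(1 - 4 * (Nd / N) / 3)
            assert res.ratio == pytest.approx(dN / dS, abs=1e-9)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_pairwise_dnds_symmetric(seed):
    rng = np.random.default_rng(seed)
    a = random_sense_sequence(20, rng)
    b = random_sense_sequence(20, rng)
    r1 = pairwise_dnds(CodonAlignment(a, b))
    r2 = pairwise_dnds(CodonAlignment(b, a))
    assert r1.S == pytest.approx(r2.S)
    assert r1.Sd == pytest.approx(r2.Sd)
    assert (math.isnan(r1.ratio) and math.isnan(r2.ratio)) or r1.ratio == pytest.approx(
        r2.ratio
    )


# --- cumulative profiles --------------------------------------------------------


def test_cumulative_profile_properties(rng):
    a = random_sense_sequence(40, rng)
    b = random_sense_sequence(40, rng)
    aln = CodonAlignment(a, b)
    prof = cumulative_profile(aln)
    res = pairwise_dnds(aln)
    assert np.all(np.diff(prof.cum_sd) >= 0)
    assert np.all(np.diff(prof.cum_nd) >= 0)
    assert prof.cum_sd[-1] == pytest.approx(res.Sd)
    assert prof.cum_nd[-1] == pytest.approx(res.Nd)


def test_cumulative_profile_single_step():
    # identical 20-codon sequences except a synonymous change at codon 10
    base = "GTT" * 20
    other = base[:27] + "GTA" + base[30:]
    prof = cumulative_profile(CodonAlignment(base, other))
    assert prof.cum_nd[-1] == 0
    assert prof.cum_sd[8] == 0 and prof.cum_sd[9] == 1 and prof.cum_sd[-1] == 1


def test_cumulative_profile_identical_is_zero():
    prof = cumulative_profile(CodonAlignment("ATGGCT", "ATGGCT"))
    assert prof.cum_sd[-1] == 0 and prof.cum_nd[-1] == 0
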