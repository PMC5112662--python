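"""Synonymous / nonsynonymous substitution statistics on codon alignments.

Implements the pathway-counting method of Nei & Gojobori (1986): fractional
synonymous (S) and nonsynonymous (N) site counts per codon, substitution
differences averaged over all mutational pathways between two codons, the
Jukes-Cantor multiple-hit correction, and the pairwise dN/dS ratio.  A
cumulative per-codon profile of synonymous and nonsynonymous differences
along the alignment is the substrate for gene-conversion tract detection:
stretches of codons without synonymous change show up as flat segments of
the synonymous curve.

All computations use the standard genetic code.  Mutational pathways that
pass through a stop codon are excluded from the pathway average; in the
degenerate case where every pathway passes through a stop, pathways are
re-admitted with stop-involving steps counted as nonsynonymous.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "BASES",
    "GENETIC_CODE",
    "STOP_CODONS",
    "SENSE_CODONS",
    "SiteCounts",
    "CodonAlignment",
    "DnDsResult",
    "CumulativeProfile",
    "NoComparableCodonsError",
    "edit_alignment",
    "count_sites",
    "count_differences",
    "jukes_cantor",
    "pairwise_dnds",
    "per_codon_differences",
    "cumulative_profile",
]

BASES = "ACGT"

_STANDARD_TABLE = unambiguous_dna_by_id[1]
#: codon -> one-letter amino acid, stop codons excluded
GENETIC_CODE: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD_TABLE.stop_codons)
#: the 61 sense codons of the standard code, sorted
SENSE_CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))


class NoComparableCodonsError(ValueError):
    """Raised when gap/ambiguity editing removes every codon column."""


def _check_sense(codon: str) -> str:
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} is not a valid input")
    if codon not in GENETIC_CODE:
        raise ValueError(f"{codon!r} is not an unambiguous DNA codon")
    return codon


@dataclass(frozen=True)
class SiteCounts:
    """Fractional synonymous (S) and nonsynonymous (N) site counts.

    Per codon S + N = 3 exactly: each nucleotide position contributes the
    fraction of its non-stop single-base changes that are synonymous.
    """

    S: float
    N: float

    def __add__(self, other: "SiteCounts") -> "SiteCounts":
        return SiteCounts(self.S + other.S, self.N + other.N)


@lru_cache(maxsize=None)
def count_sites(codon: str) -> SiteCounts:
    """Fractional synonymous/nonsynonymous sites of one sense codon.

    For each of the three positions, the synonymous fraction among the
    non-stop single-base changes is that position's synonymous site
    contribution.  Changes that would create a stop codon are removed
    from the denominator (the SNAP convention).
    """
    codon = _check_sense(codon)
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        total = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            total += 1
            if GENETIC_CODE[mutant] == aa:
                syn += 1
        if total:
            s += syn / total
    return SiteCounts(S=s, N=3.0 - s)


@lru_cache(maxsize=None)
def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) between two sense codons.

    With k differing positions, all k! orderings of the single-base steps
    are enumerated; each step is classified synonymous or nonsynonymous
    and counts are averaged over pathways with equal weight.  Pathways
    whose intermediate codons are stops are excluded; if that excludes
    every pathway, all are re-admitted with stop steps counted as
    nonsynonymous.  Sd + Nd equals the nucleotide Hamming distance.
    """
    a = _check_sense(codon_a)
    b = _check_sense(codon_b)
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return (0.0, 0.0)

    def enumerate_paths(allow_stops: bool) -> list[tuple[int, int]]:
        paths = []
        for order in itertools.permutations(diff_pos):
            cur = a
            sd = nd = 0
            valid = True
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                if nxt in STOP_CODONS and not allow_stops:
                    valid = False
                    break
                if nxt in STOP_CODONS or cur in STOP_CODONS:
                    nd += 1  # stop-involving step: nonsynonymous by convention
                elif GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if valid:
                paths.append((sd, nd))
        return paths

    paths = enumerate_paths(allow_stops=False)
    if not paths:
        paths = enumerate_paths(allow_stops=True)
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return (sd, nd)


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor corrected distance -(3/4) ln(1 - 4p/3).

    Returns ``nan`` when ``p >= 3/4`` (saturated, correction undefined)
    so that downstream code can flag rather than abort.
    """
    if p < 0:
        raise ValueError("proportion of differences must be >= 0")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class CodonAlignment:
    """A gap-edited pairwise codon alignment.

    Both sequences are uppercase A/C/G/T of equal length divisible by 3
    with no stop codons; ``dropped_columns`` records how many codon
    columns were removed by gap/ambiguity/stop editing.
    """

    seq_a: str
    seq_b: str
    id_a: str = "seq_a"
    id_b: str = "seq_b"
    dropped_columns: int = 0

    def __post_init__(self) -> None:
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences must have equal length")
        if len(self.seq_a) % 3:
            raise ValueError("alignment length is not a multiple of 3")
        for ca, cb in self.codons():
            _check_sense(ca)
            _check_sense(cb)

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codons(self):
        """Yield (codon_a, codon_b) column pairs."""
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]

    def swapped(self) -> "CodonAlignment":
        return CodonAlignment(self.seq_b, self.seq_a, self.id_b, self.id_a, self.dropped_columns)


def edit_alignment(
    raw_a: str,
    raw_b: str,
    id_a: str = "seq_a",
    id_b: str = "seq_b",
    frame: int = 0,
) -> CodonAlignment:
    """Edit a gapped codon-aware pairwise alignment into a CodonAlignment.

    Every codon column containing a gap, an ambiguity symbol, or a stop
    codon in either sequence is dropped and counted.  ``frame`` trims
    leading alignment columns before codon chunking; the remaining
    length must be a multiple of 3.
    """
    if len(raw_a) != len(raw_b):
        raise ValueError("aligned sequences must have equal length")
    a = raw_a[frame:].upper()
    b = raw_b[frame:].upper()
    if len(a) % 3:
        raise ValueError("alignment length minus frame is not a multiple of 3")
    kept_a: list[str] = []
    kept_b: list[str] = []
    dropped = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if any(c not in BASES for c in ca + cb) or ca in STOP_CODONS or cb in STOP_CODONS:
            dropped += 1
            continue
        kept_a.append(ca)
        kept_b.append(cb)
    if not kept_a:
        raise NoComparableCodonsError("no comparable codons after gap editing")
    return CodonAlignment("".join(kept_a), "".join(kept_b), id_a, id_b, dropped)


@dataclass
class DnDsResult:
    """Pairwise NG86 dN/dS summary.

    ``ratio`` is ``nan`` (with an explanatory flag) when dS is zero or a
    rate is saturated; downstream ranking treats it as not comparable.
    """

    id_a: str
    id_b: str
    n_codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    dS: float
    dN: float
    ratio: float
    flags: list[str] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ratio)

    def to_dict(self) -> dict:
        return {
            "id_a": self.id_a,
            "id_b": self.id_b,
            "codons": self.n_codons,
            "Sd": round(self.Sd, 4),
            "Nd": round(self.Nd, 4),
            "S": round(self.S, 4),
            "N": round(self.N, 4),
            "ps": round(self.ps, 4),
            "pn": round(self.pn, 4),
            "dS": round(self.dS, 4) if not math.isnan(self.dS) else "NA",
            "dN": round(self.dN, 4) if not math.isnan(self.dN) else "NA",
            "dNdS": round(self.ratio, 4) if self.defined else "NA",
            "flags": ";".join(self.flags) or ".",
        }


def per_codon_differences(aln: CodonAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Per-codon-column pathway-averaged (Sd, Nd) arrays."""
    sd = np.empty(aln.n_codons)
    nd = np.empty(aln.n_codons)
    for i, (ca, cb) in enumerate(aln.codons()):
        sd[i], nd[i] = count_differences(ca, cb)
    return sd, nd


def pairwise_dnds(aln: CodonAlignment) -> DnDsResult:
    """NG86 pairwise dN/dS with Jukes-Cantor correction.

    Site totals are averaged over the two sequences; ps = Sd/S and
    pn = Nd/N are corrected with :func:`jukes_cantor`.  The result is
    symmetric in the two sequences.
    """
    s_a = sum(count_sites(ca).S for ca, _ in aln.codons())
    s_b = sum(count_sites(cb).S for _, cb in aln.codons())
    S = 0.5 * (s_a + s_b)
    N = 3.0 * aln.n_codons - S
    sd_arr, nd_arr = per_codon_differences(aln)
    Sd = float(sd_arr.sum())
    Nd = float(nd_arr.sum())
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    dS = jukes_cantor(ps)
    dN = jukes_cantor(pn)
    flags: list[str] = []
    if math.isnan(dS):
        flags.append("saturated_dS")
    if math.isnan(dN):
        flags.append("saturated_dN")
    if dS == 0.0:
        flags.append("dS_zero")
    if flags:
        ratio = math.nan
        if "dS_zero" in flags:
            flags.append("ratio_undefined")
    else:
        ratio = dN / dS
    return DnDsResult(
        id_a=aln.id_a,
        id_b=aln.id_b,
        n_codons=aln.n_codons,
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        ps=ps,
        pn=pn,
        dS=dS,
        dN=dN,
        ratio=ratio,
        flags=flags,
    )


@dataclass
class CumulativeProfile:
    """Running sums of synonymous/nonsynonymous differences along codons.

    ``cum_sd[i]`` / ``cum_nd[i]`` are the cumulative counts from codon 1
    through codon i+1; both series are monotone non-decreasing and end at
    the alignment totals of :class:`DnDsResult`.
    """

    id_a: str
    id_b: str
    sd: np.ndarray
    nd: np.ndarray

    @property
    def cum_sd(self) -> np.ndarray:
        return np.cumsum(self.sd)

    @property
    def cum_nd(self) -> np.ndarray:
        return np.cumsum(self.nd)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "codon_index": np.arange(1, len(self.sd) + 1),
                "cum_Sd": np.round(self.cum_sd, 4),
                "cum_Nd": np.round(self.cum_nd, 4),
            }
        )


def cumulative_profile(aln: CodonAlignment) -> CumulativeProfile:
    """Cumulative synonymous/nonsynonymous substitution profile."""
    sd, nd = per_codon_differences(aln)
    return CumulativeProfile(aln.id_a, aln.id_b, sd, nd)
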