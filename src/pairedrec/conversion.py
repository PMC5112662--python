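"""Gene-conversion / recombination signature detection.

Two complementary views are provided:

* a sliding-window percent-identity track over a gapped pairwise genomic
  alignment (a percent-identity-plot in the PipMaker tradition), which
  exposes conversion as a block of near-100% identity confined to an exon
  against a background of diverged introns; and

* codon-level tract detection on an edited codon alignment: a converted
  tract is homogenised between donor and acceptor, so synonymous
  substitutions -- which accumulate clock-like under purifying selection --
  are absent inside it.  Candidate tracts are maximal runs of codons with
  zero synonymous difference; their significance is assessed by permuting
  codon columns (which are exchangeable under uniform divergence) and
  asking how often the longest zero-synonymous run is at least as long as
  the observed tract.  Permutation p-values use the add-one rule
  (b + 1) / (B + 1) and therefore lie in (0, 1].

Exon-boundary concordance asks whether a tract's limits coincide (within
a slack) with the exon limits extended by the 2-nt splice dinucleotides,
the hallmark of conversion restricted to a single exon.  A region
contrast compares nonsynonymous substitution density inside a named set
of codon intervals (e.g. the CC'C''FG beta-strand face of an IgV domain)
against the remainder, again with a one-sided permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codon import CodonAlignment, per_codon_differences

__all__ = [
    "IdentityWindow",
    "ConversionTract",
    "TractScan",
    "BoundaryConcordance",
    "StrandRegionSet",
    "RegionContrast",
    "percent_identity_windows",
    "detect_conversion_tracts",
    "check_exon_restriction",
    "region_contrast",
    "codon_to_genomic",
]


@dataclass
class IdentityWindow:
    """Percent identity of one sliding window (0-based, half-open)."""

    start: int
    end: int
    identity: float  # percent, 0-100; nan when no comparable columns
    comparable: int  # aligned non-gap columns in the window
    low_coverage: bool  # fewer than 50% comparable columns


def percent_identity_windows(
    aligned_a: str,
    aligned_b: str,
    window: int = 100,
    step: int = 25,
) -> list[IdentityWindow]:
    """Sliding-window percent identity over a gapped pairwise alignment.

    Identity is matches / aligned non-gap columns per window; windows
    with fewer than 50% comparable columns are flagged.  A window longer
    than the alignment yields a single whole-alignment window.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    if not (window >= step >= 1):
        raise ValueError("require window >= step >= 1")
    a = aligned_a.upper()
    b = aligned_b.upper()
    length = len(a)
    if window >= length:
        starts = [0]
        window = length
    else:
        starts = list(range(0, length - window + 1, step))
    out: list[IdentityWindow] = []
    comparable_mask = np.array([x != "-" and y != "-" for x, y in zip(a, b)])
    match_mask = np.array([x == y for x, y in zip(a, b)]) & comparable_mask
    comp_cum = np.concatenate([[0], np.cumsum(comparable_mask)])
    match_cum = np.concatenate([[0], np.cumsum(match_mask)])
    for s in starts:
        e = s + window
        comp = int(comp_cum[e] - comp_cum[s])
        match = int(match_cum[e] - match_cum[s])
        identity = 100.0 * match / comp if comp else float("nan")
        out.append(
            IdentityWindow(
                start=s,
                end=e,
                identity=identity,
                comparable=comp,
                low_coverage=comp < 0.5 * window,
            )
        )
    return out


@dataclass
class ConversionTract:
    """A codon interval depleted of synonymous substitutions.

    Coordinates are 0-based half-open on the edited codon alignment.
    """

    start: int
    end: int
    length: int
    nuc_diffs_inside: int
    syn_inside: float
    pvalue: float
    genomic_interval: tuple[int, int] | None = None

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class TractScan:
    """Result of a conversion-tract scan on one codon alignment."""

    status: str  # "ok" | "not_assessable"
    tracts: list[ConversionTract] = field(default_factory=list)
    longest_run: int = 0
    total_syn: float = 0.0
    total_diffs: float = 0.0
    note: str = ""


def _zero_runs(indicator: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of False values as (start, end) half-open intervals."""
    runs = []
    start = None
    for i, hit in enumerate(indicator):
        if not hit:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(indicator)))
    return runs


def _longest_zero_run_rows(matrix: np.ndarray) -> np.ndarray:
    """Longest run of zeros per row of a boolean matrix."""
    n_rows, n_cols = matrix.shape
    best = np.zeros(n_rows, dtype=int)
    cur = np.zeros(n_rows, dtype=int)
    for j in range(n_cols):
        col = matrix[:, j]
        cur = np.where(col, 0, cur + 1)
        best = np.maximum(best, cur)
    return best


def detect_conversion_tracts(
    aln: CodonAlignment,
    min_len: int = 15,
    reps: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> TractScan:
    """Detect codon tracts with zero synonymous substitutions.

    Candidate tracts are maximal zero-synonymous codon runs of at least
    ``min_len`` codons.  Each candidate's p-value is the add-one fraction
    of seeded codon-column permutations whose longest zero-synonymous
    run is >= the candidate's length; candidates with p <= ``alpha`` are
    reported.  Alignments without any synonymous difference (or without
    any difference at all) are "not assessable".  Detection is invariant
    to swapping the two sequences.
    """
    if reps < 100:
        import warnings

        warnings.warn("fewer than 100 permutations gives coarse p-values", stacklevel=2)
    sd, nd = per_codon_differences(aln)
    total_syn = float(sd.sum())
    total_diffs = float(sd.sum() + nd.sum())
    if total_diffs == 0:
        return TractScan("not_assessable", note="no differences in alignment",
                         total_syn=0.0, total_diffs=0.0)
    if total_syn == 0:
        return TractScan("not_assessable", note="no synonymous differences in alignment",
                         total_syn=0.0, total_diffs=total_diffs)
    indicator = sd > 0
    runs = [(s, e) for s, e in _zero_runs(indicator) if e - s >= min_len]
    longest = max((e - s for s, e in _zero_runs(indicator)), default=0)
    if not runs:
        return TractScan("ok", tracts=[], longest_run=longest,
                         total_syn=total_syn, total_diffs=total_diffs)

    rng = np.random.default_rng(seed)
    perm = np.empty((reps, len(indicator)), dtype=bool)
    for r in range(reps):
        perm[r] = indicator[rng.permutation(len(indicator))]
    null_longest = _longest_zero_run_rows(perm)

    tracts = []
    for s, e in runs:
        length = e - s
        b = int(np.sum(null_longest >= length))
        p = (b + 1) / (reps + 1)
        if p <= alpha:
            nt_a = aln.seq_a[3 * s : 3 * e]
            nt_b = aln.seq_b[3 * s : 3 * e]
            nuc_diffs = sum(x != y for x, y in zip(nt_a, nt_b))
            tracts.append(
                ConversionTract(
                    start=s,
                    end=e,
                    length=length,
                    nuc_diffs_inside=nuc_diffs,
                    syn_inside=float(sd[s:e].sum()),
                    pvalue=p,
                )
            )
    return TractScan("ok", tracts=tracts, longest_run=longest,
                     total_syn=total_syn, total_diffs=total_diffs)


def codon_to_genomic(
    codon_interval: tuple[int, int],
    exon_start: int,
    exon_end: int,
    strand: str = "+",
) -> tuple[int, int]:
    """Map a codon interval on a single exon to genomic coordinates.

    Assumes the codon alignment covers the exon from its first coding
    base without dropped columns (valid for gapless exon alignments);
    strand-aware: on '-' the first codon sits at the exon's genomic end.
    """
    s, e = codon_interval
    if strand == "+":
        return (exon_start + 3 * s, exon_start + 3 * e)
    return (exon_end - 3 * e, exon_end - 3 * s)


@dataclass
class BoundaryConcordance:
    """Whether a tract's limits coincide with exon limits (plus splice sites)."""

    tract: ConversionTract
    exon: tuple[int, int]
    exon_restricted: bool
    note: str = ""


def check_exon_restriction(
    tract_genomic: tuple[int, int],
    exon: tuple[int, int],
    slack: int = 10,
    tract: ConversionTract | None = None,
) -> BoundaryConcordance:
    """Test whether a tract is restricted to one exon.

    The exon is extended by the 2-nt splice dinucleotides on both sides;
    the flag is true iff both tract limits lie within ``slack`` nt of the
    extended exon limits.  A tract not overlapping the exon at all is
    flagged false with a note.
    """
    if slack < 0:
        raise ValueError("slack must be >= 0")
    ts, te = tract_genomic
    ext_start, ext_end = exon[0] - 2, exon[1] + 2
    placeholder = tract if tract is not None else ConversionTract(
        start=ts, end=te, length=te - ts, nuc_diffs_inside=0, syn_inside=0.0,
        pvalue=float("nan"), genomic_interval=tract_genomic,
    )
    if te <= exon[0] or ts >= exon[1]:
        return BoundaryConcordance(placeholder, exon, False, "tract outside exon")
    concordant = abs(ts - ext_start) <= slack and abs(te - ext_end) <= slack
    return BoundaryConcordance(placeholder, exon, concordant)


@dataclass
class StrandRegionSet:
    """Named, non-overlapping codon intervals (0-based half-open).

    Typically the C, C', C'', F and G beta-strands of the IgV fold whose
    face binds pathogen adhesins; the remainder of the alignment is the
    implicit complement.
    """

    regions: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        ivs = sorted(self.regions.values())
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError("region intervals overlap")
        for s, e in ivs:
            if s < 0 or e <= s:
                raise ValueError("bad region interval")

    def mask(self, n_codons: int) -> np.ndarray:
        m = np.zeros(n_codons, dtype=bool)
        for s, e in self.regions.values():
            if e > n_codons:
                raise ValueError("region extends beyond alignment")
            m[s:e] = True
        return m


@dataclass
class RegionContrast:
    """Nonsynonymous substitution density inside vs outside a region set."""

    nd_inside: float
    nd_outside: float
    codons_inside: int
    codons_outside: int
    ratio: float  # per-codon density ratio inside/outside; nan if undefined
    pvalue: float  # one-sided permutation p for enrichment inside


def region_contrast(
    aln: CodonAlignment,
    regions: StrandRegionSet,
    reps: int = 999,
    seed: int = 0,
) -> RegionContrast:
    """Contrast nonsynonymous density inside vs outside named regions.

    The statistic is the mean per-codon nonsynonymous difference count
    inside the region set; the null shuffles codon labels (seeded).
    One-sided add-one p-value for enrichment inside.
    """
    mask = regions.mask(aln.n_codons)
    n_in = int(mask.sum())
    n_out = int((~mask).sum())
    if n_in < 3 or n_out < 3:
        raise ValueError("need >= 3 codons inside and outside the region set")
    _, nd = per_codon_differences(aln)
    nd_in = float(nd[mask].sum())
    nd_out = float(nd[~mask].sum())
    if nd_in + nd_out == 0:
        return RegionContrast(0.0, 0.0, n_in, n_out, float("nan"), float("nan"))
    dens_in = nd_in / n_in
    dens_out = nd_out / n_out
    ratio = dens_in / dens_out if dens_out > 0 else float("inf")
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(reps):
        perm_nd = nd[rng.permutation(len(nd))]
        if perm_nd[mask].sum() / n_in >= dens_in - 1e-12:
            b += 1
    p = (b + 1) / (reps + 1)
    return RegionContrast(nd_in, nd_out, n_in, n_out, ratio, p)
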