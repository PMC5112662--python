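"""Gene-model annotation for tandem receptor clusters.

Covers the rules used to delimit and classify genes in a receptor
cluster: merging of N-domain (IgV-like) exon runs into genes, counting
of distinct N exons at a divergence threshold, pseudogene calling from
internal stop codons and defective splice dinucleotides, scanning of
cytoplasmic tails for tyrosine-based signaling motifs (ITIM, ITSM, ITAM
and ITAM-like), and enumeration of oppositely oriented
inhibitory/activating gene pairs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import Align
from Bio.Seq import Seq

__all__ = [
    "Exon",
    "GeneModel",
    "SignalingMotif",
    "PseudogeneCall",
    "DEFAULT_MOTIF_PATTERNS",
    "scan_motifs",
    "classify_motifs",
    "call_pseudogene",
    "cluster_n_exons",
    "merge_exons_to_genes",
    "orientation_pairs",
]

EXON_KINDS = ("leader", "N", "IgC", "TM", "cytoplasmic", "other")


@dataclass
class Exon:
    """One exon, 0-based half-open genomic coordinates."""

    start: int
    end: int
    kind: str = "other"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("exon end must exceed start")
        if self.kind not in EXON_KINDS:
            raise ValueError(f"unknown exon kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """A gene: ordered exons on a chromosome strand.

    ``exons`` are ordered 5'->3' on the coding strand (i.e. by ascending
    genomic coordinate on '+', descending on '-').  ``homeolog`` tags
    the L or S copy of an allotetraploid locus; ``anchoring`` carries
    the supplied membrane-anchoring annotation (TM | GPI | secreted).
    """

    id: str
    chromosome: str
    strand: str
    exons: list[Exon]
    subgroup: str = ""
    homeolog: str = ""  # "L" | "S" | ""
    anchoring: str = ""  # "TM" | "GPI" | "secreted" | ""
    species: str = ""
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        coords = [(e.start, e.end) for e in self.exons]
        for (s1, e1), (s2, e2) in zip(sorted(coords), sorted(coords)[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in gene {self.id}")
        genomic_order = sorted(coords) if self.strand == "+" else sorted(coords, reverse=True)
        if coords != genomic_order:
            raise ValueError(f"exons of gene {self.id} not ordered 5'->3' on coding strand")

    def exons_of_kind(self, kind: str) -> list[Exon]:
        return [e for e in self.exons if e.kind == kind]

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)

    def exon_coding_seq(self, exon: Exon, chromosome_seq: str) -> str:
        """Exon sequence in coding (5'->3' mRNA) orientation."""
        raw = chromosome_seq[exon.start : exon.end].upper()
        return str(Seq(raw).reverse_complement()) if self.strand == "-" else raw


# --- signaling-motif scanning -------------------------------------------------

#: Regular-expression consensi for tyrosine-based signaling motifs.  The
#: ITAM-like class is two Yxx[ILV] modules at non-canonical spacing (3-5
#: or 13-20 residues between modules), or a lone Yxx[ILV] module in a
#: tail without any ITIM.  Patterns are configurable; these defaults are
#: the canonical consensi.
DEFAULT_MOTIF_PATTERNS: dict[str, str] = {
    "ITIM": r"[ILVS].Y..[ILV]",
    "ITSM": r"T.Y..[VI]",
    "ITAM": r"Y..[LI].{6,12}Y..[LI]",
    "ITAM-like": r"Y..[ILV].{3,5}Y..[ILV]|Y..[ILV].{13,20}Y..[ILV]",
    "_module": r"Y..[ILV]",
}


@dataclass
class SignalingMotif:
    """One motif hit in a cytoplasmic peptide (0-based offset)."""

    kind: str  # ITIM | ITSM | ITAM | ITAM-like
    offset: int
    peptide: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.offset, self.offset + len(self.peptide))


def _finditer_overlapping(pattern: str, seq: str):
    """All (possibly overlapping) matches as (start, matched_text)."""
    regex = re.compile(f"(?=({pattern}))")
    for m in regex.finditer(seq):
        yield m.start(), m.group(1)


def scan_motifs(
    peptide: str,
    patterns: dict[str, str] | None = None,
) -> list[SignalingMotif]:
    """Scan a cytoplasmic peptide for tyrosine-based signaling motifs.

    Overlapping matches are found for every configured pattern;
    precedence ITAM > ITAM-like > ITIM/ITSM is applied per overlapping
    site, so the constituent Yxx[LI] modules of an ITAM are not reported
    again as lone motifs.  A lone Yxx[ILV] module counts as ITAM-like
    only when no ITIM matches the tail.
    """
    peptide = peptide.upper()
    if not peptide:
        return []
    pats = dict(DEFAULT_MOTIF_PATTERNS)
    if patterns:
        pats.update(patterns)

    itam = [SignalingMotif("ITAM", s, m) for s, m in _finditer_overlapping(pats["ITAM"], peptide)]
    taken = [m.span for m in itam]

    def free(start: int, text: str) -> bool:
        end = start + len(text)
        return all(end <= s or e <= start for s, e in taken)

    itam_like = [
        SignalingMotif("ITAM-like", s, m)
        for s, m in _finditer_overlapping(pats["ITAM-like"], peptide)
        if free(s, m)
    ]
    taken += [m.span for m in itam_like]
    itim = [
        SignalingMotif("ITIM", s, m)
        for s, m in _finditer_overlapping(pats["ITIM"], peptide)
        if free(s, m)
    ]
    itsm = [
        SignalingMotif("ITSM", s, m)
        for s, m in _finditer_overlapping(pats["ITSM"], peptide)
        if free(s, m)
    ]
    hits = itam + itam_like + itim + itsm
    if not itim and not itam and not itam_like:
        # lone Yxx[ILV] module in an ITIM-free tail: ITAM-like stand-in
        hits += [
            SignalingMotif("ITAM-like", s, m)
            for s, m in _finditer_overlapping(pats["_module"], peptide)
        ]
    return sorted(hits, key=lambda m: (m.offset, m.kind))


def classify_motifs(motifs: list[SignalingMotif]) -> str:
    """Gene-level signaling class from its motif hits.

    inhibitory = ITIM (with or without ITSM) and no ITAM/ITAM-like;
    activating = ITAM or ITAM-like; both present -> "ambiguous"
    (excluded from pairing); neither -> "none".
    """
    kinds = {m.kind for m in motifs}
    inhibitory = "ITIM" in kinds
    activating = bool(kinds & {"ITAM", "ITAM-like"})
    if inhibitory and activating:
        return "ambiguous"
    if inhibitory:
        return "inhibitory"
    if activating:
        return "activating"
    return "none"


# --- pseudogene calling -------------------------------------------------------


@dataclass
class PseudogeneCall:
    gene_id: str
    status: str  # "intact" | "pseudogene"
    reasons: list[str] = field(default_factory=list)


def call_pseudogene(
    gene: GeneModel,
    chromosome_seq: str,
    allow_gc_donor: bool = False,
) -> PseudogeneCall:
    """Call a gene a pseudogene from its N exons and flanking splice sites.

    A gene is a pseudogene iff any N exon contains an in-frame stop
    codon, or an intron flanking an N exon lacks the canonical GT donor
    / AG acceptor dinucleotides (strand-aware; GC donors accepted only
    when ``allow_gc_donor``).  N-exon reading frame is taken as frame 0
    from the exon start unless the gene carries a ``frame`` attribute.
    """
    from .codon import STOP_CODONS

    reasons: list[str] = []
    n_exons = gene.exons_of_kind("N")
    if not n_exons:
        raise ValueError(f"gene {gene.id} has no N exon")
    for exon in n_exons:
        if exon.start < 0 or exon.end > len(chromosome_seq):
            raise ValueError(f"exon of {gene.id} outside chromosome bounds")
        coding = gene.exon_coding_seq(exon, chromosome_seq)
        frame = int(gene.attrs.get("frame", 0))
        for i in range(frame, len(coding) - 2, 3):
            if coding[i : i + 3] in STOP_CODONS:
                reasons.append("internal stop")
                break
    # introns flanking N exons, in transcription order
    donors_ok = ("GT", "GC") if allow_gc_donor else ("GT",)
    for prev, nxt in zip(gene.exons, gene.exons[1:]):
        if prev.kind != "N" and nxt.kind != "N":
            continue
        if gene.strand == "+":
            intron = chromosome_seq[prev.end : nxt.start].upper()
        else:
            raw = chromosome_seq[nxt.end : prev.start].upper()
            intron = str(Seq(raw).reverse_complement())
        if len(intron) < 4:
            reasons.append("bad splice donor")
            continue
        if intron[:2] not in donors_ok:
            reasons.append("bad splice donor")
        if intron[-2:] != "AG":
            reasons.append("bad splice acceptor")
    reasons = sorted(set(reasons))
    return PseudogeneCall(gene.id, "pseudogene" if reasons else "intact", reasons)


# --- N-exon clustering and gene merging ---------------------------------------


def _global_nt_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def pairwise_divergence(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """1 - identity over aligned non-gap columns of a global alignment."""
    if aligner is None:
        aligner = _global_nt_aligner()
    alignment = aligner.align(a.upper(), b.upper())[0]
    sa, sb = str(alignment[0]), str(alignment[1])
    comparable = matches = 0
    for x, y in zip(sa, sb):
        if x == "-" or y == "-":
            continue
        comparable += 1
        matches += x == y
    if comparable == 0:
        raise ValueError("no comparable columns in alignment")
    return 1.0 - matches / comparable


def cluster_n_exons(
    n_exon_seqs: dict[str, str] | list[str],
    divergence_threshold: float = 0.01,
) -> list[list[str]]:
    """Single-linkage clusters of N-exon sequences at a divergence cutoff.

    Sequences within ``divergence_threshold`` of each other (directly or
    transitively) form one "distinct exon"; the number of clusters is
    the distinct-exon count used for gene-number estimates.  The result
    is invariant to input order (clusters and members sorted by label).
    """
    if isinstance(n_exon_seqs, list):
        n_exon_seqs = {f"exon{i+1}": s for i, s in enumerate(n_exon_seqs)}
    labels = sorted(n_exon_seqs)
    if not labels:
        return []
    parent = {lab: lab for lab in labels}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    aligner = _global_nt_aligner()
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            if pairwise_divergence(n_exon_seqs[la], n_exon_seqs[lb], aligner) <= divergence_threshold:
                parent[find(lb)] = find(la)
    clusters: dict[str, list[str]] = {}
    for lab in labels:
        clusters.setdefault(find(lab), []).append(lab)
    return sorted((sorted(v) for v in clusters.values()), key=lambda c: c[0])


def merge_exons_to_genes(exon_kinds: list[str]) -> list[list[int]]:
    """Group ordered locus exons into genes.

    Consecutive N exons with no non-N exon between them belong to one
    gene; an N exon following a non-N (non-leader) exon starts a new
    gene, as does a leader exon.  Returns the exon-index groups; groups
    without an N exon are merged into the preceding gene.  The gene
    count never exceeds the number of N-exon runs.
    """
    groups: list[list[int]] = []
    current: list[int] = []
    seen_n = False
    seen_non_n_after = False
    for i, kind in enumerate(exon_kinds):
        new_gene = False
        if current:
            if kind == "leader":
                new_gene = True
            elif kind == "N" and seen_n and seen_non_n_after:
                new_gene = True
        if new_gene:
            groups.append(current)
            current = []
            seen_n = False
            seen_non_n_after = False
        current.append(i)
        if kind == "N":
            seen_n = True
            seen_non_n_after = False
        elif seen_n:
            seen_non_n_after = True
    if current:
        groups.append(current)
    # merge N-less groups into predecessor
    merged: list[list[int]] = []
    for g in groups:
        if merged and not any(exon_kinds[i] == "N" for i in g):
            merged[-1].extend(g)
        else:
            merged.append(g)
    return [g for g in merged if any(exon_kinds[i] == "N" for i in g)]


# --- transcriptional-orientation pairing --------------------------------------


def orientation_pairs(
    genes: list[GeneModel],
    motif_class: dict[str, str],
) -> list[tuple[str, str, int]]:
    """Oppositely oriented inhibitory/activating gene pairs.

    All (inhibitory, activating) pairs on opposite strands of the same
    chromosome and subgroup, ordered by genomic distance between gene
    midpoints.  Motif classes come from :func:`classify_motifs`.
    """
    pairs: list[tuple[str, str, int]] = []
    inhib = [g for g in genes if motif_class.get(g.id) == "inhibitory"]
    activ = [g for g in genes if motif_class.get(g.id) == "activating"]
    for gi in inhib:
        for ga in activ:
            if gi.chromosome != ga.chromosome or gi.subgroup != ga.subgroup:
                continue
            if gi.strand == ga.strand:
                continue
            mid_i = (gi.start + gi.end) // 2
            mid_a = (ga.start + ga.end) // 2
            pairs.append((gi.id, ga.id, abs(mid_i - mid_a)))
    return sorted(pairs, key=lambda p: (p[2], p[0], p[1]))
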