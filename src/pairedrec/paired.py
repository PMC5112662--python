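"""Paired-receptor classification and locus-level comparisons.

Integrates motif classes, N-domain identity, transcriptional orientation
and dN/dS into three headline analyses:

* identification of paired receptors -- an inhibitory (ITIM-bearing)
  gene and one or more activating (ITAM/ITAM-like) genes with highly
  similar N domains and opposite transcriptional orientation in the
  same subgroup cluster;
* ranking of ortholog/homeolog pairs by dN/dS, flagging whether
  inhibitory-receptor pairs occupy the top ranks (the signature of
  pathogen-driven diversifying selection); and
* comparison of two homeologous loci of an allotetraploid: per-gene
  retention/loss fates, the loss fraction, and whether any complete
  paired-receptor pair survives at each locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .annotation import GeneModel
from .codon import DnDsResult
from .phylo import OrthologyCall, protein_identity

__all__ = [
    "PairedReceptorPair",
    "SelectionRanking",
    "LocusComparison",
    "identify_paired_receptors",
    "rank_selection",
    "compare_homeologous_loci",
]


@dataclass
class PairedReceptorPair:
    inhibitory: str
    activating: str
    identity_pct: float
    subgroup: str
    orientation_opposed: bool
    genomic_distance: int
    evidence: list[str] = field(default_factory=list)


def identify_paired_receptors(
    genes: list[GeneModel],
    motif_class: dict[str, str],
    n_domain_peptides: dict[str, str],
    identity_threshold: float = 80.0,
) -> list[PairedReceptorPair]:
    """Identify paired-receptor gene pairs.

    A pair requires (i) opposing motif classes (one inhibitory, one
    activating), (ii) N-domain amino-acid identity >= the threshold
    (default 80%, the lower edge of the identity range observed for
    paired receptors), and (iii) opposite transcriptional orientation on
    the same chromosome and subgroup.  One inhibitory gene may pair with
    several activating genes.  Genes with ambiguous motif class are
    excluded.  Genomic distance is reported but not filtered on.
    """
    by_id = {g.id: g for g in genes}
    pairs: list[PairedReceptorPair] = []
    inhib = sorted(g.id for g in genes if motif_class.get(g.id) == "inhibitory")
    activ = sorted(g.id for g in genes if motif_class.get(g.id) == "activating")
    for gi_id in inhib:
        gi = by_id[gi_id]
        for ga_id in activ:
            ga = by_id[ga_id]
            if gi.chromosome != ga.chromosome or gi.subgroup != ga.subgroup:
                continue
            if gi.strand == ga.strand:
                continue
            if gi_id not in n_domain_peptides or ga_id not in n_domain_peptides:
                continue
            ident = protein_identity(n_domain_peptides[gi_id], n_domain_peptides[ga_id])
            if ident < identity_threshold:
                continue
            dist = abs((gi.start + gi.end) // 2 - (ga.start + ga.end) // 2)
            pairs.append(
                PairedReceptorPair(
                    inhibitory=gi_id,
                    activating=ga_id,
                    identity_pct=ident,
                    subgroup=gi.subgroup,
                    orientation_opposed=True,
                    genomic_distance=dist,
                )
            )
    return sorted(pairs, key=lambda p: (p.subgroup, p.inhibitory, p.activating))


@dataclass
class SelectionRanking:
    """Ortholog/homeolog pairs ordered by descending dN/dS."""

    order: list[str]  # pair keys, undefined ratios last
    ratios: dict[str, float]
    motif_class: dict[str, str]
    undefined: list[str]
    inhibitory_top: bool
    warning: str = ""


def rank_selection(
    dnds_results: dict[str, DnDsResult],
    motif_class: dict[str, str],
) -> SelectionRanking:
    """Rank gene pairs by dN/dS, undefined ratios last.

    Ties are broken by pair label for a stable order.  The
    ``inhibitory_top`` flag records whether the top-ranked defined pair
    involves an inhibitory (ITIM) receptor.
    """
    defined = {k: r.ratio for k, r in dnds_results.items() if r.defined}
    undefined = sorted(k for k, r in dnds_results.items() if not r.defined)
    order = sorted(defined, key=lambda k: (-defined[k], k)) + undefined
    warning = ""
    if not defined:
        warning = "no defined dN/dS ratios"
    top_inhibitory = bool(defined) and motif_class.get(order[0]) == "inhibitory"
    return SelectionRanking(
        order=order,
        ratios={k: (defined[k] if k in defined else math.nan) for k in order},
        motif_class=motif_class,
        undefined=undefined,
        inhibitory_top=top_inhibitory,
        warning=warning,
    )


@dataclass
class LocusComparison:
    """Retention/loss accounting between two homeologous loci."""

    fates: dict[str, str]  # gene id (locus A) -> "retained" | "lost-from-b"
    gained_in_b: list[str]
    loss_fraction: float
    retention_fraction: float
    by_subgroup: dict[str, dict[str, int]]
    by_motif_class: dict[str, dict[str, int]]
    paired_pair_survives_a: bool
    paired_pair_survives_b: bool


def compare_homeologous_loci(
    locus_a: list[GeneModel],
    locus_b: list[GeneModel],
    orthology: list[OrthologyCall],
    motif_class: dict[str, str] | None = None,
    pairs_a: list[PairedReceptorPair] | None = None,
    pairs_b: list[PairedReceptorPair] | None = None,
) -> LocusComparison:
    """Compare gene complements of two homeologous loci.

    Every locus-A gene receives exactly one fate: "retained" when a
    homeolog call links it to a locus-B gene, otherwise "lost-from-b".
    Locus-B genes without a partner are "gained-in-b" (e.g. post-
    duplication copies).  Loss fraction + retention fraction = 1 over
    locus A.  Per-subgroup and per-motif-class retention tables and
    paired-receptor survival flags are included.
    """
    motif_class = motif_class or {}
    ids_a = {g.id for g in locus_a}
    ids_b = {g.id for g in locus_b}
    partner: dict[str, str] = {}
    for call in orthology:
        if call.relation != "homeolog":
            continue
        if call.gene_a in ids_a and call.gene_b in ids_b:
            partner[call.gene_a] = call.gene_b
        elif call.gene_b in ids_a and call.gene_a in ids_b:
            partner[call.gene_b] = call.gene_a
    fates = {g.id: ("retained" if g.id in partner else "lost-from-b")
             for g in sorted(locus_a, key=lambda g: g.id)}
    matched_b = set(partner.values())
    gained = sorted(ids_b - matched_b)
    n = len(locus_a)
    lost = sum(f == "lost-from-b" for f in fates.values())
    loss_fraction = lost / n if n else 0.0

    def breakdown(keyfun) -> dict[str, dict[str, int]]:
        table: dict[str, dict[str, int]] = {}
        for g in locus_a:
            key = keyfun(g)
            row = table.setdefault(key, {"retained": 0, "lost-from-b": 0})
            row[fates[g.id]] += 1
        return table

    by_subgroup = breakdown(lambda g: g.subgroup or "unassigned")
    by_motif = breakdown(lambda g: motif_class.get(g.id, "none"))
    return LocusComparison(
        fates=fates,
        gained_in_b=gained,
        loss_fraction=loss_fraction,
        retention_fraction=1.0 - loss_fraction,
        by_subgroup=by_subgroup,
        by_motif_class=by_motif,
        paired_pair_survives_a=bool(pairs_a),
        paired_pair_survives_b=bool(pairs_b),
    )
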