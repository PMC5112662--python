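"""Motif scanning, pseudogene calling, exon clustering and gene merging."""

import pytest
from Bio.Seq import Seq

from pairedrec.annotation import (
    Exon,
    GeneModel,
    call_pseudogene,
    classify_motifs,
    cluster_n_exons,
    merge_exons_to_genes,
    orientation_pairs,
    scan_motifs,
)

# --- motif scanning -----------------------------------------------------------


def test_single_itim():
    hits = scan_motifs("AASVYAQLAA")
    assert [(m.kind, m.offset) for m in hits] == [("ITIM", 2)]


def test_canonical_itam_suppresses_constituent_modules():
    hits = scan_motifs("YEGLAAAAAAAYSEI")
    assert [m.kind for m in hits] == ["ITAM"]
    assert hits[0].offset == 0


def test_itim_and_itsm_both_reported_where_both_match():
    # TAYAGV holds an ITSM (TxYxx[VI]); VAYAGL holds an ITIM ([ILVS]xYxx[ILV])
    hits = scan_motifs("TAYAGVAYAGL")
    kinds = {m.kind for m in hits}
    assert "ITSM" in kinds and "ITIM" in kinds


def test_lone_module_is_itam_like_only_without_itim():
    # an isolated YxxL module in an ITIM-free tail
    hits = scan_motifs("AAAYEGLAAA")
    assert [m.kind for m in hits] == ["ITAM-like"]
    # the same module next to an ITIM is not promoted
    hits = scan_motifs("AASVYAQLAAA")
    assert {m.kind for m in hits} == {"ITIM"}


def test_empty_sequence():
    assert scan_motifs("") == []


def test_motif_offsets_shift_with_prefix():
    base = "AASVYAQLAA"
    shifted = scan_motifs("GG" + base)
    original = scan_motifs(base)
    assert [(m.kind, m.offset - 2) for m in shifted] == [
        (m.kind, m.offset) for m in original
    ]


def test_classification_rules():
    assert classify_motifs(scan_motifs("AASVYAQLAA")) == "inhibitory"
    assert classify_motifs(scan_motifs("YEGLAAAAAAAYSEI")) == "activating"
    assert classify_motifs(scan_motifs("AASVYAQLAAGGYEGLAAAAAAAYSEI")) == "ambiguous"
    assert classify_motifs(scan_motifs("GGGAAA")) == "none"


# --- pseudogene calling -------------------------------------------------------


def _gene_on(chrom: str, strand: str, exons):
    return GeneModel("g1", "chr1", strand, [Exon(*e) for e in exons])


def test_intact_gene_with_canonical_splice_sites():
    # leader(0,6) intron GT..AG N(16,25)
    chrom = "ATGAAA" + "GT" + "TTTT" + "AG" + "GCTGCTGCT" + "AAAA"
    gene = _gene_on(chrom, "+", [(0, 6, "leader"), (14, 23, "N")])
    call = call_pseudogene(gene, chrom)
    assert call.status == "intact" and call.reasons == []


def test_internal_stop_is_pseudogene():
    chrom = "ATGAAA" + "GT" + "TTTT" + "AG" + "GCTTAAGCT" + "AAAA"
    gene = _gene_on(chrom, "+", [(0, 6, "leader"), (14, 23, "N")])
    call = call_pseudogene(gene, chrom)
    assert call.status == "pseudogene" and "internal stop" in call.reasons


def test_bad_splice_sites_are_pseudogene():
    chrom = "ATGAAA" + "CC" + "TTTT" + "CC" + "GCTGCTGCT" + "AAAA"
    gene = _gene_on(chrom, "+", [(0, 6, "leader"), (14, 23, "N")])
    call = call_pseudogene(gene, chrom)
    assert call.status == "pseudogene"
    assert set(call.reasons) == {"bad splice donor", "bad splice acceptor"}


def test_minus_strand_gene_uses_reverse_complement_signals():
    plus_chrom = "ATGAAA" + "GT" + "TTTT" + "AG" + "GCTGCTGCT" + "AAAA"
    rc = str(Seq(plus_chrom).reverse_complement())
    L = len(plus_chrom)
    # exon coordinates mirrored; exon order stays 5'->3' on the coding strand
    gene = GeneModel(
        "g1",
        "chr1",
        "-",
        [Exon(L - 6, L, "leader"), Exon(L - 23, L - 14, "N")],
    )
    call = call_pseudogene(gene, rc)
    assert call.status == "intact"
    # the same gene evaluated as if plus-strand fails the splice check
    naive = GeneModel("g1", "chr1", "+", [Exon(L - 23, L - 14, "N"), Exon(L - 6, L, "leader")])
    assert call_pseudogene(naive, rc).status == "pseudogene"


def test_reverse_complement_invariance(small_family):
    """Pseudogene calls are unchanged on the reverse-complemented chromosome."""
    locus = small_family.loci[0]
    chrom = locus.sequence
    rc = str(Seq(chrom).reverse_complement())
    L = len(chrom)
    for gene in locus.genes[:4]:
        call = call_pseudogene(gene, chrom)
        flipped = GeneModel(
            gene.id,
            gene.chromosome,
            "-" if gene.strand == "+" else "+",
            [Exon(L - e.end, L - e.start, e.kind) for e in gene.exons],
            species=gene.species,
        )
        assert call_pseudogene(flipped, rc).status == call.status


def test_exon_out_of_bounds_is_hard_error():
    gene = _gene_on("ATG", "+", [(0, 9, "N")])
    with pytest.raises(ValueError):
        call_pseudogene(gene, "ATG")


# --- N-exon clustering --------------------------------------------------------


def test_cluster_n_exons_divergence_threshold():
    base = "ATGGCTGCAACCGGTTCA" * 17  # 306 nt
    one_diff = "C" + base[1:]  # ~0.33% divergence: same cluster
    ten_diff = "".join(
        ("C" if base[i] == "A" else "A") if i % 30 == 0 else base[i] for i in range(len(base))
    )  # ~3.3% divergence: distinct
    clusters = cluster_n_exons({"e1": base, "e2": one_diff, "e3": ten_diff}, 0.01)
    assert len(clusters) == 2
    assert ["e1", "e2"] in clusters
    assert clusters == cluster_n_exons({"e3": ten_diff, "e2": one_diff, "e1": base}, 0.01)


def test_cluster_identical_duplicates_and_empty():
    assert len(cluster_n_exons(["AAA" * 50, "AAA" * 50])) == 1
    assert cluster_n_exons([]) == []


# --- exon-run merging ---------------------------------------------------------


@pytest.mark.parametrize(
    "kinds,n_genes",
    [
        (["N", "N", "IgC", "TM"], 1),
        (["N", "IgC", "N", "TM"], 2),
        ([], 0),
        (["leader", "N", "IgC", "leader", "N", "TM"], 2),
        (["N"], 1),
        (["IgC", "TM"], 0),
    ],
)
def test_merge_exons_to_genes(kinds, n_genes):
    groups = merge_exons_to_genes(kinds)
    assert len(groups) == n_genes
    # never more genes than N-exon runs
    runs = sum(
        1 for i, k in enumerate(kinds) if k == "N" and (i == 0 or kinds[i - 1] != "N")
    )
    assert len(groups) <= runs or runs == 0


# --- orientation pairing ------------------------------------------------------


def _simple_gene(gid, strand, start, subgroup="group1"):
    return GeneModel(
        gid,
        "chr1",
        strand,
        [Exon(start, start + 300, "N")] if strand == "+" else [Exon(start, start + 300, "N")],
        subgroup=subgroup,
    )


def test_orientation_pairs_rules():
    genes = [
        _simple_gene("inh", "+", 0),
        _simple_gene("act", "-", 1000),
        _simple_gene("act2", "+", 2000),
        _simple_gene("inh2", "-", 3000, subgroup="group2"),
    ]
    classes = {"inh": "inhibitory", "act": "activating", "act2": "activating",
               "inh2": "inhibitory"}
    pairs = orientation_pairs(genes, classes)
    # only the opposite-strand, same-subgroup inhibitory/activating combination
    assert [(p[0], p[1]) for p in pairs] == [("inh", "act")]
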