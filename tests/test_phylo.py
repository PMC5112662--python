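"""Distances, neighbor joining, bootstrap, subgroups and orthology calls."""

import math

import numpy as np
import pytest

from pairedrec.phylo import (
    DistanceMatrix,
    assign_subgroups,
    bootstrap_support,
    call_orthologs,
    distance_matrix_from_sequences,
    exhaustive_ls_tree,
    neighbor_joining,
    protein_distance,
    random_additive_matrix,
    tree_bipartitions,
)

# --- protein distances --------------------------------------------------------


def test_protein_distance_identical():
    d = protein_distance("MKLVINS", "MKLVINS")
    assert d.p == 0 and d.distance == 0 and d.identity_pct == 100


def test_protein_distance_closed_form():
    a = "A" * 90 + "KRDEWFHPQM"
    b = "A" * 90 + "RKEDFWHPQM"  # 6 mismatched columns out of 100
    d = protein_distance(a, b)
    assert d.p == pytest.approx(0.06)
    assert d.distance == pytest.approx(-math.log(0.94))
    assert protein_distance(a, b, model="p").distance == pytest.approx(0.06)


def test_protein_distance_matches_hand_recount(rng):
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    a = "".join(rng.choice(aas, 80))
    b = "".join(rng.choice(aas, 80))
    d = protein_distance(a, b, model="p")
    # equal length, high-divergence random pair: alignment may introduce
    # gaps, so recount on the alignment's comparable columns definitionally
    assert d.identity_pct == pytest.approx(100 * (1 - d.p))
    assert 0 <= d.p < 1


# --- distance matrix ----------------------------------------------------------


def test_distance_matrix_validation():
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[1.0, 0.0], [0.0, 0.0]]))  # bad diagonal


# --- neighbor joining ---------------------------------------------------------


def test_nj_three_taxa_closed_form():
    # three-point formulas: d_ab=3, d_ac=4, d_bc=5 -> la=1, lb=2, lc=3
    dm = DistanceMatrix(["a", "b", "c"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]]))
    tree = neighbor_joining(dm)
    lengths = {}

    def walk(node):
        for child, ln in node.children:
            if child.is_leaf:
                lengths[child.label] = lengths.get(child.label, 0) + ln
            walk(child)

    walk(tree)
    assert lengths["a"] == pytest.approx(1.0)
    assert lengths["b"] == pytest.approx(2.0)
    assert lengths["c"] == pytest.approx(3.0)


def test_nj_recovers_additive_topology():
    for seed in range(30):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        dm, true_splits = random_additive_matrix([f"t{i}" for i in range(n)], rng)
        assert tree_bipartitions(neighbor_joining(dm)) == true_splits


def test_nj_agrees_with_scikit_bio_on_additive_input():
    skbio = pytest.importorskip("skbio")
    from skbio.tree import nj as sk_nj

    rng = np.random.default_rng(5)
    dm, _ = random_additive_matrix([f"t{i}" for i in range(8)], rng)
    sk_tree = sk_nj(skbio.DistanceMatrix(dm.matrix, ids=dm.labels))
    anchor = min(dm.labels)
    sk_splits = set()
    for node in sk_tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(dm.labels) - 1:
            if anchor in side:
                side = frozenset(dm.labels) - side
            sk_splits.add(side)
    assert sk_splits == tree_bipartitions(neighbor_joining(dm))


def test_nj_matches_least_squares_oracle_mostly():
    agree = 0
    for seed in range(30):
        rng = np.random.default_rng(10_000 + seed)
        dm, _ = random_additive_matrix([f"t{i}" for i in range(5)], rng)
        noise = rng.uniform(0.95, 1.05, size=dm.matrix.shape)
        m = dm.matrix * (noise + noise.T) / 2
        np.fill_diagonal(m, 0)
        noisy = DistanceMatrix(dm.labels, m)
        agree += tree_bipartitions(neighbor_joining(noisy)) == exhaustive_ls_tree(noisy)
    assert agree >= 27  # >= 90% on noisy matrices


def test_nj_rejects_small_or_asymmetric_input():
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


def test_nj_branch_lengths_non_negative():
    rng = np.random.default_rng(3)
    dm, _ = random_additive_matrix([f"t{i}" for i in range(7)], rng)
    m = dm.matrix + rng.uniform(0, 0.3, dm.matrix.shape)
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    tree = neighbor_joining(DistanceMatrix(dm.labels, m))

    def walk(node):
        for child, ln in node.children:
            assert ln >= 0
            walk(child)

    walk(tree)


# --- bootstrap ----------------------------------------------------------------


def _two_clade_alignment(rng):
    aln = {}
    for i in range(4):
        aln[f"a{i}"] = "A" * 30 + "".join(rng.choice(list("ACDE"), 10))
    for i in range(4):
        aln[f"b{i}"] = "W" * 30 + "".join(rng.choice(list("ACDE"), 10))
    return aln


def test_bootstrap_saturated_signal(rng):
    aln = _two_clade_alignment(rng)
    tree, support = bootstrap_support(aln, reps=100, seed=1)
    clade = frozenset(f"b{i}" for i in range(4))
    assert support[clade] == pytest.approx(100.0)
    assert all(0 <= v <= 100 for v in support.values())


def test_bootstrap_seeded_determinism(rng):
    aln = _two_clade_alignment(rng)
    _, s1 = bootstrap_support(aln, reps=50, seed=9)
    _, s2 = bootstrap_support(aln, reps=50, seed=9)
    assert s1 == s2


def test_bootstrap_random_alignment_low_support(rng):
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    aln = {f"s{i}": "".join(rng.choice(aas, 60)) for i in range(8)}
    _, support = bootstrap_support(aln, reps=100, seed=2)
    assert np.mean(list(support.values())) < 70


# --- subgroup assignment ------------------------------------------------------


def test_assign_subgroups_two_ancient_clades(small_family):
    truth = small_family.truth
    peps = {}
    from Bio.Seq import Seq

    for name, nt in small_family.n_exons.items():
        if truth.genes[name]["species"] == "A" and not truth.genes[name]["pseudogene"]:
            peps[name] = str(Seq(nt).translate())
    sub = assign_subgroups(peps)
    assert sub.split_found
    groups = {frozenset(sub.group1), frozenset(sub.group2)}
    want = {
        frozenset(n for n in peps if truth.genes[n]["subgroup"] == "group1"),
        frozenset(n for n in peps if truth.genes[n]["subgroup"] == "group2"),
    }
    assert groups == want
    # between-group identity stays below within-group identity
    assert sub.between_identity[1] < sub.within_identity[0]


def test_assign_subgroups_near_identical_flags_no_split():
    seqs = {f"s{i}": "MKLVINSEQARND" for i in range(5)}
    sub = assign_subgroups(seqs)
    assert not sub.split_found


def test_assign_subgroups_order_invariant():
    rng = np.random.default_rng(0)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    g1 = {f"x{i}": "MKL" * 20 + "".join(rng.choice(aas, 6)) for i in range(4)}
    g2 = {f"y{i}": "WFP" * 20 + "".join(rng.choice(aas, 6)) for i in range(4)}
    seqs = {**g1, **g2}
    s1 = assign_subgroups(seqs)
    s2 = assign_subgroups(dict(reversed(list(seqs.items()))))
    assert (s1.group1, s1.group2) == (s2.group1, s2.group2)


# --- orthology ----------------------------------------------------------------


def _labelled_matrix(entries, labels):
    n = len(labels)
    m = np.zeros((n, n))
    idx = {lab: i for i, lab in enumerate(labels)}
    for (a, b), d in entries.items():
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = d
    return DistanceMatrix(labels, m)


def test_reciprocal_best_hits_are_orthologs_and_symmetric():
    labels = ["a1", "a2", "b1", "b2"]
    dm = _labelled_matrix(
        {("a1", "b1"): 0.1, ("a2", "b2"): 0.1, ("a1", "b2"): 0.9,
         ("a2", "b1"): 0.9, ("a1", "a2"): 0.8, ("b1", "b2"): 0.8},
        labels,
    )
    species = {"a1": "X", "a2": "X", "b1": "Y", "b2": "Y"}
    calls = call_orthologs({l: "M" for l in labels}, species, dm=dm)
    orth = {(c.gene_a, c.gene_b) for c in calls if c.relation == "ortholog"}
    assert orth == {("a1", "b1"), ("a2", "b2")}


def test_one_to_two_duplication_grouped_as_co_orthologs():
    # b1/b1x duplicated after speciation: both pair with a1
    labels = ["a1", "a2", "b1", "b1x", "b2"]
    dm = _labelled_matrix(
        {("a1", "b1"): 0.20, ("a1", "b1x"): 0.22, ("b1", "b1x"): 0.05,
         ("a2", "b2"): 0.2, ("a1", "a2"): 0.9, ("a1", "b2"): 0.9,
         ("a2", "b1"): 0.9, ("a2", "b1x"): 0.9, ("b1", "b2"): 0.9,
         ("b1x", "b2"): 0.9},
        labels,
    )
    species = {"a1": "X", "a2": "X", "b1": "Y", "b1x": "Y", "b2": "Y"}
    calls = call_orthologs({l: "M" for l in labels}, species, dm=dm)
    orth = {(c.gene_a, c.gene_b) for c in calls if c.relation == "ortholog"}
    assert ("a1", "b1") in orth and ("a1", "b1x") in orth
    par = {tuple(sorted((c.gene_a, c.gene_b))) for c in calls if c.relation == "paralog"}
    assert ("b1", "b1x") in par


def test_single_species_yields_paralogs_only():
    labels = ["a1", "a2", "a3"]
    dm = _labelled_matrix({("a1", "a2"): 0.1, ("a1", "a3"): 0.8, ("a2", "a3"): 0.8}, labels)
    calls = call_orthologs({l: "M" for l in labels}, {l: "X" for l in labels}, dm=dm)
    assert all(c.relation == "paralog" for c in calls)
    assert {(c.gene_a, c.gene_b) for c in calls} == {("a1", "a2")}


def test_homeologs_called_across_ls_tags():
    labels = ["bL1", "bL2", "bS1"]
    dm = _labelled_matrix({("bL1", "bS1"): 0.1, ("bL2", "bS1"): 0.7,
                           ("bL1", "bL2"): 0.6}, labels)
    tags = {"bL1": "L", "bL2": "L", "bS1": "S"}
    calls = call_orthologs({l: "M" for l in labels}, {l: "B" for l in labels},
                           tags=tags, dm=dm)
    hom = {(c.gene_a, c.gene_b) for c in calls if c.relation == "homeolog"}
    assert hom == {("bL1", "bS1")}
    # cross-tag pairs are never reported as paralogs
    assert not any(
        c.relation == "paralog" and tags[c.gene_a] != tags[c.gene_b] for c in calls
    )
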