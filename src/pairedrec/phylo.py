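"""Distance-based grouping of receptor N-domain amino-acid sequences.

Pairwise distances (p-distance and Poisson-corrected) are computed on
global pairwise alignments, trees are built with neighbor joining
(Saitou & Nei 1987) with deterministic tie-breaking, bipartition support
comes from column-resampling bootstrap, and ortholog / paralog /
homeolog relations are called by reciprocal-best-hit logic on the
distance matrix.  Subgroup assignment cuts the NJ tree at its longest
internal edge, which separates anciently diverged clades such as the
group 1 / group 2 split of the amphibian Ceacam family.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "OrthologyCall",
    "SubgroupAssignment",
    "protein_distance",
    "protein_identity",
    "distance_matrix_from_sequences",
    "neighbor_joining",
    "tree_bipartitions",
    "bootstrap_support",
    "assign_subgroups",
    "call_orthologs",
    "random_additive_matrix",
    "exhaustive_ls_tree",
]


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


@dataclass
class ProteinDistance:
    p: float
    distance: float
    identity_pct: float
    comparable: int


def protein_distance(
    a: str,
    b: str,
    model: str = "poisson",
    aligner: Align.PairwiseAligner | None = None,
) -> ProteinDistance:
    """Distance between two amino-acid sequences after global alignment.

    Gap columns are dropped; p = mismatches / compared columns;
    the Poisson correction is -ln(1 - p).  Percent identity
    100 (1 - p) is reported alongside.
    """
    if model not in ("p", "poisson"):
        raise ValueError("model must be 'p' or 'poisson'")
    if aligner is None:
        aligner = _protein_aligner()
    aln = aligner.align(a.upper(), b.upper())[0]
    sa, sb = str(aln[0]), str(aln[1])
    comparable = mismatches = 0
    for x, y in zip(sa, sb):
        if x == "-" or y == "-":
            continue
        comparable += 1
        mismatches += x != y
    if comparable == 0:
        raise ValueError("no comparable columns between sequences")
    p = mismatches / comparable
    if model == "p":
        d = p
    else:
        # saturate at a large finite value when no residues match so that
        # downstream tree building stays numerically well behaved
        d = -math.log(1.0 - p) if p < 1.0 else 10.0
    return ProteinDistance(p=p, distance=d, identity_pct=100.0 * (1.0 - p), comparable=comparable)


def protein_identity(a: str, b: str) -> float:
    """Percent identity of two globally aligned amino-acid sequences."""
    return protein_distance(a, b, model="p").identity_pct


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with sorted labels."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.matrix < -1e-12).any():
            raise ValueError("negative distances")

    def get(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[ia, ib])


def distance_matrix_from_sequences(
    seqs: dict[str, str],
    model: str = "poisson",
) -> DistanceMatrix:
    """All-vs-all protein distance matrix (labels sorted)."""
    labels = sorted(seqs)
    n = len(labels)
    m = np.zeros((n, n))
    aligner = _protein_aligner()
    for i in range(n):
        for j in range(i + 1, n):
            d = protein_distance(seqs[labels[i]], seqs[labels[j]], model, aligner).distance
            m[i, j] = m[j, i] = d
    return DistanceMatrix(labels, m)


# --- trees --------------------------------------------------------------------


class TreeNode:
    """Minimal rooted representation of an unrooted tree.

    ``children`` holds (child, branch_length) pairs; leaves carry a
    label.  The root is an arbitrary internal node.
    """

    __slots__ = ("label", "children")

    def __init__(self, label: str | None = None, children=None):
        self.label = label
        self.children: list[tuple[TreeNode, float]] = children or []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self) -> str:
        return self._newick_part() + ";"

    def _newick_part(self) -> str:
        if self.is_leaf:
            return self.label
        inner = ",".join(
            f"{child._newick_part()}:{length:.6f}" for child, length in self.children
        )
        return f"({inner})"


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a distance matrix.

    Standard agglomeration; negative branch lengths are clamped to zero
    with the deficit moved to the sister branch; ties in the Q criterion
    are broken deterministically by label order.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 labels")
    order = sorted(range(n), key=lambda i: dm.labels[i])
    nodes: list[TreeNode] = [TreeNode(dm.labels[i]) for i in order]
    d = dm.matrix[np.ix_(order, order)].copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # deterministic tie-break: first (i, j) in creation/label order
        ii, jj = map(int, np.argwhere(np.isclose(q, qmin, atol=1e-12))[0])
        i, j = active[ii], active[jj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ii] - r[jj]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_dist = np.zeros(d.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_dist[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_dist
        d[:-1, -1] = new_dist
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]

    i, j = active
    dij = max(d[i, j], 0.0)
    a, b = nodes[i], nodes[j]
    if not a.is_leaf:
        a.children.append((b, dij))
        return a
    if not b.is_leaf:
        b.children.append((a, dij))
        return b
    return TreeNode(children=[(a, dij / 2), (b, dij / 2)])


def tree_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each encoded as its canonical side.

    The canonical side is the one *not* containing the lexicographically
    smallest leaf, so two trees over the same leaf set can be compared
    by set equality.
    """
    all_leaves = frozenset(tree.leaves())
    anchor = min(all_leaves)
    splits: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.label])
        below = frozenset()
        for child, _ in node.children:
            child_leaves = walk(child)
            if 1 < len(child_leaves) < len(all_leaves) - 1:
                side = child_leaves if anchor not in child_leaves else all_leaves - child_leaves
                splits.add(side)
            below |= child_leaves
        return below

    walk(tree)
    return splits


def _hamming_distance_matrix(rows: np.ndarray, labels: list[str], model: str) -> DistanceMatrix:
    """Distance matrix from aligned residue rows (gaps excluded pairwise)."""
    n = len(labels)
    m = np.zeros((n, n))
    gap = rows == "-"
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            comp = int(ok.sum())
            p = float((rows[i][ok] != rows[j][ok]).sum()) / comp if comp else 0.0
            if model == "poisson":
                d = -math.log(1.0 - p) if p < 1.0 else 10.0
            else:
                d = p
            m[i, j] = m[j, i] = d
    return DistanceMatrix(labels, m)


def bootstrap_support(
    alignment: dict[str, str],
    reps: int = 200,
    seed: int = 0,
    model: str = "poisson",
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """NJ tree with bootstrap bipartition support.

    Columns of the multiple alignment are resampled with replacement
    ``reps`` times (seeded); support for each bipartition of the full
    tree is the percentage of replicate NJ trees containing it.
    """
    labels = sorted(alignment)
    lengths = {len(alignment[l]) for l in labels}
    if len(lengths) != 1:
        raise ValueError("alignment rows must have equal length")
    ncol = lengths.pop()
    rows = np.array([list(alignment[l].upper()) for l in labels])
    base_tree = neighbor_joining(_hamming_distance_matrix(rows, labels, model))
    base_splits = tree_bipartitions(base_tree)
    counts = {s: 0 for s in base_splits}
    rng = np.random.default_rng(seed)
    for _ in range(reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_tree = neighbor_joining(_hamming_distance_matrix(rows[:, cols], labels, model))
        for s in tree_bipartitions(rep_tree):
            if s in counts:
                counts[s] += 1
    support = {s: 100.0 * c / reps for s, c in counts.items()}
    return base_tree, support


# --- subgroup assignment ------------------------------------------------------


@dataclass
class SubgroupAssignment:
    """Two-way split of sequences at the longest internal NJ edge."""

    group1: list[str]
    group2: list[str]
    split_found: bool
    split_edge_length: float
    within_identity: tuple[float, float]  # (min, max) percent within groups
    between_identity: tuple[float, float]  # (min, max) percent between groups


def assign_subgroups(
    seqs: dict[str, str],
    min_split_edge: float = 0.1,
    model: str = "poisson",
) -> SubgroupAssignment:
    """Split sequences into two subgroups by the longest internal NJ edge.

    If no internal edge reaches ``min_split_edge`` (near-identical
    input) the assignment is flagged as "no split" with everything in
    group1.  Group 1 is the side containing the lexicographically
    smallest label, so the split is invariant to input order.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    dm = distance_matrix_from_sequences(seqs, model)
    identity = {}
    aligner = _protein_aligner()
    labels = sorted(seqs)
    for a, b in itertools.combinations(labels, 2):
        identity[(a, b)] = protein_distance(seqs[a], seqs[b], "p", aligner).identity_pct
    if len(seqs) < 4:
        # NJ has no internal edge; fall back to farthest-pair split
        best = max(identity, key=lambda k: dm.get(*k))
        split_len = dm.get(*best)
        if split_len < min_split_edge:
            return SubgroupAssignment(labels, [], False, split_len,
                                      _rng_range(identity.values()), (math.nan, math.nan))
        g2 = [best[1]] if best[0] == labels[0] else [best[0]]
        g1 = [l for l in labels if l not in g2]
        return _finish_assignment(g1, g2, split_len, identity)

    tree = neighbor_joining(dm)
    all_leaves = set(labels)
    best_edge: tuple[float, frozenset[str]] | None = None

    def walk(node: TreeNode) -> set[str]:
        nonlocal best_edge
        if node.is_leaf:
            return {node.label}
        below = set()
        for child, length in node.children:
            child_leaves = walk(child)
            if 1 < len(child_leaves) < len(all_leaves) - 1:  # internal edge
                if best_edge is None or length > best_edge[0]:
                    best_edge = (length, frozenset(child_leaves))
            below |= child_leaves
        return below

    walk(tree)
    if best_edge is None or best_edge[0] < min_split_edge:
        length = best_edge[0] if best_edge else 0.0
        return SubgroupAssignment(labels, [], False, length,
                                  _rng_range(identity.values()), (math.nan, math.nan))
    side = set(best_edge[1])
    other = all_leaves - side
    g1, g2 = (side, other) if labels[0] in side else (other, side)
    return _finish_assignment(sorted(g1), sorted(g2), best_edge[0], identity)


def _rng_range(values) -> tuple[float, float]:
    vals = list(values)
    return (min(vals), max(vals)) if vals else (math.nan, math.nan)


def _finish_assignment(g1, g2, split_len, identity) -> SubgroupAssignment:
    within = [v for (a, b), v in identity.items()
              if (a in g1) == (b in g1)]
    between = [v for (a, b), v in identity.items()
               if (a in g1) != (b in g1)]
    return SubgroupAssignment(
        group1=list(g1),
        group2=list(g2),
        split_found=True,
        split_edge_length=split_len,
        within_identity=_rng_range(within),
        between_identity=_rng_range(between),
    )


# --- orthology ----------------------------------------------------------------


@dataclass
class OrthologyCall:
    """A pairwise relation between genes.

    relation: "ortholog" (across species), "paralog" (within-species
    mutual nearest neighbours closer than any cross-species sequence) or
    "homeolog" (across L/S locus tags within an allotetraploid species).
    """

    gene_a: str
    species_a: str
    gene_b: str
    species_b: str
    relation: str
    distance: float
    support: float | None = None
    reciprocal: bool = True
    tie: bool = False


def _best_hit(dm: DistanceMatrix, gene: str, candidates: list[str]) -> tuple[str, float, bool]:
    dists = [(dm.get(gene, c), c) for c in candidates]
    dmin = min(d for d, _ in dists)
    hits = sorted(c for d, c in dists if abs(d - dmin) <= 1e-12)
    return hits[0], dmin, len(hits) > 1


def call_orthologs(
    seqs: dict[str, str],
    species: dict[str, str],
    tags: dict[str, str] | None = None,
    model: str = "poisson",
    dm: DistanceMatrix | None = None,
) -> list[OrthologyCall]:
    """Ortholog / paralog / homeolog calls from pairwise distances.

    * ortholog: reciprocal best cross-species hit; when a recent
      duplication makes the relation one-to-two, the non-reciprocal
      duplicate is still called an ortholog if its within-species
      nearest neighbour is closer than the cross-species hit
      (co-ortholog grouping).
    * paralog: within-species mutual nearest neighbours that are closer
      to each other than either is to any cross-species sequence.
    * homeolog: reciprocal best hit across L/S locus tags within one
      (allotetraploid) species.

    Ties are broken by label order and flagged.
    """
    tags = tags or {}
    if dm is None:
        dm = distance_matrix_from_sequences(seqs, model)
    labels = dm.labels
    by_species: dict[str, list[str]] = {}
    for lab in labels:
        by_species.setdefault(species[lab], []).append(lab)
    calls: list[OrthologyCall] = []

    # Orthologs across species pairs.  Genes of an allotetraploid are
    # partitioned by their L/S locus tag and reciprocal-best-hit calling
    # runs against each tag group separately: the diploid relative is
    # compared with each homeologous locus on its own, so both the L and
    # the S copy can be recovered as (co-)orthologs.
    def _tag_groups(gene_list: list[str]) -> list[list[str]]:
        groups: dict[str, list[str]] = {}
        for g in gene_list:
            groups.setdefault(tags.get(g, ""), []).append(g)
        return [groups[k] for k in sorted(groups)]

    def _rbh(genes_a: list[str], genes_b: list[str], sp_a: str, sp_b: str) -> None:
        best_ab = {a: _best_hit(dm, a, genes_b) for a in genes_a}
        best_ba = {b: _best_hit(dm, b, genes_a) for b in genes_b}

        def co_ortholog(x: str, pool: list[str], w: str, d_cross: float,
                        d_pair: float) -> bool:
            # x is accepted as a co-ortholog if it is a recent duplicate
            # of the reciprocal partner w: x's within-group nearest
            # neighbour is w, and the duplication is more recent than
            # the speciation (d(x, w) below both cross-species distances)
            if len(pool) < 2:
                return False
            near, d_xw, _ = _best_hit(dm, x, [g for g in pool if g != x])
            return near == w and d_xw < d_cross and d_xw < d_pair

        seen: set[tuple[str, str]] = set()
        for a, (b, d_ab, tie_a) in best_ab.items():
            reciprocal = best_ba[b][0] == a
            accept = reciprocal
            if not reciprocal:
                w = best_ba[b][0]
                if best_ab[w][0] == b:
                    accept = co_ortholog(a, genes_a, w, d_ab, dm.get(w, b))
            if accept and (a, b) not in seen:
                seen.add((a, b))
                calls.append(OrthologyCall(a, sp_a, b, sp_b, "ortholog", d_ab,
                                           reciprocal=reciprocal, tie=tie_a))
        for b, (a, d_ba, tie_b) in best_ba.items():
            if best_ab[a][0] == b:
                continue  # reciprocal pair already emitted
            w = best_ab[a][0]
            if best_ba[w][0] == a and co_ortholog(b, genes_b, w, d_ba, dm.get(a, w)):
                if (a, b) not in seen:
                    seen.add((a, b))
                    calls.append(OrthologyCall(a, sp_a, b, sp_b, "ortholog", d_ba,
                                               reciprocal=False, tie=tie_b))

    for sp_a, sp_b in itertools.combinations(sorted(by_species), 2):
        for group_a in _tag_groups(by_species[sp_a]):
            for group_b in _tag_groups(by_species[sp_b]):
                _rbh(group_a, group_b, sp_a, sp_b)

    # paralog groups within species
    for sp, genes in sorted(by_species.items()):
        others = [g for g in labels if species[g] != sp]
        for a, b in itertools.combinations(sorted(genes), 2):
            ta, tb = tags.get(a, ""), tags.get(b, "")
            if ta and tb and ta != tb:
                continue  # cross-tag pairs are homeolog candidates, not paralogs
            rest_a = [g for g in genes if g != a]
            rest_b = [g for g in genes if g != b]
            if not rest_a or not rest_b:
                continue
            hit_a, d_a, _ = _best_hit(dm, a, rest_a)
            hit_b, d_b, _ = _best_hit(dm, b, rest_b)
            if hit_a != b or hit_b != a:
                continue
            if others:
                _, cross_a, _ = _best_hit(dm, a, others)
                _, cross_b, _ = _best_hit(dm, b, others)
                if d_a >= cross_a or d_b >= cross_b:
                    continue
            calls.append(OrthologyCall(a, sp, b, sp, "paralog", dm.get(a, b)))

    # homeologs across L/S tags within each species carrying tags
    for sp, genes in sorted(by_species.items()):
        l_genes = sorted(g for g in genes if tags.get(g) == "L")
        s_genes = sorted(g for g in genes if tags.get(g) == "S")
        if not l_genes or not s_genes:
            continue
        for a in l_genes:
            b, d_ab, tie = _best_hit(dm, a, s_genes)
            back, _, _ = _best_hit(dm, b, l_genes)
            if back == a:
                calls.append(OrthologyCall(a, sp, b, sp, "homeolog", d_ab, tie=tie))
    return calls


# --- oracles / generators for validation --------------------------------------


def random_additive_matrix(
    labels: list[str],
    rng: np.random.Generator,
    min_branch: float = 0.05,
    max_branch: float = 1.0,
) -> tuple[DistanceMatrix, set[frozenset[str]]]:
    """Random binary tree -> additive distance matrix and its bipartitions.

    Used to validate that NJ recovers the generating topology exactly on
    additive input.
    """
    labels = sorted(labels)
    nodes = [TreeNode(l) for l in labels]
    lengths: dict[int, float] = {}

    def blen() -> float:
        return float(rng.uniform(min_branch, max_branch))

    pool = nodes[:]
    while len(pool) > 3:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        a, b = pool[int(i)], pool[int(j)]
        pool = [x for x in pool if x not in (a, b)]
        pool.append(TreeNode(children=[(a, blen()), (b, blen())]))
    root = TreeNode(children=[(x, blen()) for x in pool])

    # leaf-to-leaf path lengths
    paths: dict[str, dict[str, float]] = {}

    def collect(node: TreeNode, acc: float, table: dict[str, float]):
        if node.is_leaf:
            table[node.label] = acc
            return
        for child, length in node.children:
            collect(child, acc + length, table)

    def walk(node: TreeNode):
        for child, length in node.children:
            walk(child)
        # distances through this node between child subtrees
        tables = []
        for child, length in node.children:
            t: dict[str, float] = {}
            collect(child, length, t)
            tables.append(t)
        for t1, t2 in itertools.combinations(tables, 2):
            for l1, d1 in t1.items():
                for l2, d2 in t2.items():
                    paths.setdefault(l1, {})[l2] = d1 + d2
                    paths.setdefault(l2, {})[l1] = d1 + d2

    walk(root)
    n = len(labels)
    m = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                m[i, j] = paths[a][b]
    return DistanceMatrix(labels, m), tree_bipartitions(root)


def _enumerate_unrooted_topologies(labels: list[str]):
    """Yield every unrooted binary topology as (edges, leaf_node_ids).

    Nodes are integers; leaves 0..n-1 map to sorted labels.  Trees are
    grown by attaching each new leaf to every existing edge (the
    standard (2n-5)!! enumeration).
    """
    labels = sorted(labels)
    n = len(labels)
    if n < 3:
        raise ValueError("need >= 3 labels")
    base_edges = [(0, n), (1, n), (2, n)]
    stack = [(base_edges, 3, n + 1)]
    while stack:
        edges, next_leaf, next_internal = stack.pop()
        if next_leaf == n:
            yield edges
            continue
        for k, (u, v) in enumerate(edges):
            new_edges = edges[:k] + edges[k + 1 :]
            w = next_internal
            new_edges = new_edges + [(u, w), (v, w), (next_leaf, w)]
            stack.append((new_edges, next_leaf + 1, next_internal + 1))


def _splits_from_edges(edges, n_leaves: int, labels: list[str]) -> set[frozenset[str]]:
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    anchor = labels[0]
    splits = set()
    for u, v in edges:
        # leaves on v's side when edge (u, v) removed
        seen = {u, v}
        stack = [v]
        side = set()
        while stack:
            x = stack.pop()
            if x < n_leaves:
                side.add(labels[x])
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 1 < len(side) < n_leaves - 1:
            if anchor in side:
                side = set(labels) - side
            splits.add(frozenset(side))
    return splits


def exhaustive_ls_tree(dm: DistanceMatrix) -> set[frozenset[str]]:
    """Best-fitting topology by exhaustive ordinary least squares.

    Enumerates all unrooted binary topologies (practical for <= 7
    taxa), fits branch lengths by unconstrained OLS on the path/edge
    incidence matrix, and returns the bipartitions of the topology with
    the smallest residual sum of squares.  Serves as an independent
    oracle for neighbor joining.
    """
    labels = dm.labels
    n = len(labels)
    pairs = list(itertools.combinations(range(n), 2))
    y = np.array([dm.matrix[i, j] for i, j in pairs])
    best = None
    for edges in _enumerate_unrooted_topologies(labels):
        adj: dict[int, list[tuple[int, int]]] = {}
        for e_idx, (u, v) in enumerate(edges):
            adj.setdefault(u, []).append((v, e_idx))
            adj.setdefault(v, []).append((u, e_idx))
        A = np.zeros((len(pairs), len(edges)))
        for row, (i, j) in enumerate(pairs):
            # path from leaf i to leaf j
            stack = [(i, [])]
            seen = {i}
            while stack:
                x, path = stack.pop()
                if x == j:
                    for e_idx in path:
                        A[row, e_idx] = 1.0
                    break
                for y_node, e_idx in adj[x]:
                    if y_node not in seen:
                        seen.add(y_node)
                        stack.append((y_node, path + [e_idx]))
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        sse = float(np.sum((A @ coef - y) ** 2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, edges)
    return _splits_from_edges(best[1], n, labels)
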