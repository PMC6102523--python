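"""Neighbor-joining phylogeny of the protein family, with bootstrap support.

The tree is inferred from a consumed protein multiple alignment (the family's
long, variable N-terminal regions make pairwise deletion the safer choice for
distances). Supports are percentages of bootstrap replicates containing each
bipartition, reported as integers the way tree figures print them.
Subfamilies (PG1beta-like, BNM2-like, BURPIII, BURPIV) are assigned from the
topology using user-supplied seed members per subfamily.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import SeqIO


@dataclass
class ProteinAlignment:
    """Equal-length gapped amino-acid rows keyed by unique ids."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len(self.ids) < 2:
            raise ValueError("alignment needs >= 2 rows")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in alignment")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise ValueError("rows have unequal lengths")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_fasta(cls, path) -> "ProteinAlignment":
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(ids=ids, rows=rows)

    def subset(self, keep_ids) -> "ProteinAlignment":
        keep = set(keep_ids)
        pairs = [(i, r) for i, r in zip(self.ids, self.rows) if i in keep]
        return ProteinAlignment(ids=[p[0] for p in pairs], rows=[p[1] for p in pairs])


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    saturated: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")


@dataclass
class PhyloTree:
    """A dendropy tree plus the processing log (clamped branches etc.)."""

    tree: dendropy.Tree
    log: list[str] = field(default_factory=list)

    @property
    def leaf_labels(self) -> set[str]:
        return {lf.taxon.label for lf in self.tree.leaf_node_iter()}

    def newick(self) -> str:
        """Newick with integer support values as internal node labels."""
        return self.tree.as_string(
            schema="newick", suppress_rooting=True
        ).strip()

    def bipartitions(self) -> set[frozenset]:
        return tree_bipartitions(self.tree)


GAPS = frozenset("-.")


def _pairwise_p(row_i: str, row_j: str) -> tuple[int, int]:
    """(mismatches, compared) over columns ungapped in both rows."""
    mism = comp = 0
    for a, b in zip(row_i, row_j):
        if a in GAPS or b in GAPS or a == "X" or b == "X":
            continue
        comp += 1
        if a != b:
            mism += 1
    return mism, comp


def protein_distance(aln: ProteinAlignment, model: str = "poisson") -> DistanceMatrix:
    """Pairwise-deletion p-distance or its Poisson correction -ln(1-p).

    A pair whose Poisson correction saturates (p >= 1, i.e. no shared
    residues identical) is capped just below saturation and flagged.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    n = len(aln.ids)
    d = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            mism, comp = _pairwise_p(aln.rows[i], aln.rows[j])
            if comp == 0:
                raise ValueError(
                    f"no comparable columns between {aln.ids[i]} and {aln.ids[j]}"
                )
            p = mism / comp
            if model == "p":
                dist = p
            else:
                if p >= 1.0:
                    saturated.append((aln.ids[i], aln.ids[j]))
                    p = 1.0 - 1.0 / (2 * comp)  # cap: under half a residue shy
                dist = -np.log1p(-p)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(ids=list(aln.ids), d=d, saturated=saturated)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; negative branch lengths clamped to 0."""
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    log: list[str] = []
    # active nodes: newick fragments with accumulated subtree strings
    labels = {i: _quote(dm.ids[i]) for i in range(n)}
    D = {(i, j): dm.d[i, j] for i in range(n) for j in range(n)}
    active = list(range(n))
    nxt = n

    def clamp(x, what):
        if x < 0:
            log.append(f"clamped negative branch length {x:.6g} at {what}")
            return 0.0
        return x

    while len(active) > 2:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best, bi, bj = None, None, None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best - 1e-12:
                    best, bi, bj = q, i, j
        i, j = bi, bj
        dij = D[i, j]
        vi = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        vj = dij - vi
        vi = clamp(vi, f"join({labels[i]})")
        vj = clamp(vj, f"join({labels[j]})")
        labels[nxt] = f"({labels[i]}:{vi:.10g},{labels[j]}:{vj:.10g})"
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (D[i, k] + D[j, k] - dij)
            D[nxt, k] = D[k, nxt] = dk
        D[nxt, nxt] = 0.0
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1

    i, j = active
    v = clamp(D[i, j], "final join")
    newick = f"({labels[i]}:0,{labels[j]}:{v:.10g});"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return PhyloTree(tree=tree, log=log)


def _quote(label: str) -> str:
    if any(c in label for c in "(),:;[] '\t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of the smaller side's labels
    (ties broken lexicographically) — an unrooted, label-based encoding."""
    all_labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_labels - side
        if len(side) < 2 or len(other) < 2:
            continue  # trivial split
        canon = min(side, other, key=lambda s: (len(s), sorted(s)))
        out.add(canon)
    return out


def bootstrap_support(
    aln: ProteinAlignment,
    n_reps: int,
    seed: int,
    model: str = "poisson",
) -> PhyloTree:
    """NJ tree from the full alignment with bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; the support of
    each internal edge is the integer percentage of replicate trees that
    contain the same bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    main = nj_tree(protein_distance(aln, model=model))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    L = aln.length
    for _ in range(n_reps):
        cols = np.sort(rng.integers(0, L, size=L))
        rows = ["".join(r[c] for c in cols) for r in aln.rows]
        rep_aln = ProteinAlignment(ids=list(aln.ids), rows=rows)
        try:
            rep_tree = nj_tree(protein_distance(rep_aln, model=model))
        except ValueError:
            continue  # replicate with an incomparable pair: skipped
        for bp in tree_bipartitions(rep_tree.tree):
            counts[bp] = counts.get(bp, 0) + 1
    all_labels = frozenset(aln.ids)
    for node in main.tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_labels - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), sorted(s)))
        support = int(round(100.0 * counts.get(canon, 0) / n_reps))
        node.label = str(support)
    return main


SUBFAMILY_LABELS = ("PG1β-like", "BNM2-like", "BURPIII", "BURPIV")


def assign_subfamilies(
    tree: PhyloTree | dendropy.Tree,
    seeds: dict[str, list[str]],
) -> dict[str, str]:
    """Label every leaf by seeded clade membership.

    Each leaf gets the label of the smallest non-root clade containing it and
    at least one seed; when that clade holds seeds of several labels, the
    majority label wins (ties broken lexicographically). Leaves never sharing
    a non-root clade with a seed are 'unassigned'.

    NJ trees are arbitrarily rooted, which can leave one group paraphyletic
    in the rooted representation; when branch lengths are available the tree
    is midpoint-rooted first so clades are read off a stable rooting.
    """
    t = tree.tree if isinstance(tree, PhyloTree) else tree
    if all(
        nd.edge.length is not None
        for nd in t.preorder_node_iter()
        if nd.parent_node is not None
    ):
        t = t.clone(depth=1)
        try:
            t.reroot_at_midpoint(update_bipartitions=False)
        except Exception:  # degenerate lengths: keep the original rooting
            pass
    leaf_labels = {lf.taxon.label for lf in t.leaf_node_iter()}
    seed_of: dict[str, str] = {}
    for label, members in seeds.items():
        if not members:
            raise ValueError(f"subfamily {label!r} has no seed members")
        for m in members:
            if m not in leaf_labels:
                raise ValueError(f"seed id {m!r} not on the tree")
            seed_of[m] = label

    assignment: dict[str, str] = {}
    for leaf in t.leaf_node_iter():
        name = leaf.taxon.label
        if name in seed_of:
            assignment[name] = seed_of[name]
            continue
        node = leaf.parent_node
        label = "unassigned"
        while node is not None and node.parent_node is not None:
            clade_seeds = [
                seed_of[lf.taxon.label]
                for lf in node.leaf_iter()
                if lf.taxon.label in seed_of
            ]
            if clade_seeds:
                votes: dict[str, int] = {}
                for s in clade_seeds:
                    votes[s] = votes.get(s, 0) + 1
                top = max(votes.values())
                label = min(k for k, v in votes.items() if v == top)
                break
            node = node.parent_node
        assignment[name] = label
    return assignment


def path_length_matrix(tree: PhyloTree | dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf patristic distances (for additivity checks)."""
    t = tree.tree if isinstance(tree, PhyloTree) else tree
    pdm = t.phylogenetic_distance_matrix()
    taxa = sorted(t.taxon_namespace, key=lambda x: x.label)
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return [tx.label for tx in taxa], out
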