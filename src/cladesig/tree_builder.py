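"""Distance-based phylogeny: p/Poisson distances, neighbor joining,
midpoint rooting, column-resampling bootstrap and Robinson-Foulds
comparison.

Trees are :class:`dendropy.Tree` objects throughout.  The built-in
neighbor-joining path is a deterministic stand-in for external
maximum-likelihood inference; externally computed newick trees can be
imported via :mod:`cladesig.sequence_io`.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np

from ._align import GAP
from .msa_pipeline import Msa, Supermatrix
from .sequence_io import SequenceRecord

logger = logging.getLogger(__name__)

PhyloTree = dendropy.Tree


class DistanceMatrix:
    """Symmetric non-negative distances over an ordered taxon list."""

    def __init__(self, taxa: list[str], d: np.ndarray):
        d = np.asarray(d, dtype=float)
        if d.shape != (len(taxa), len(taxa)):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(d)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        self.taxa = list(taxa)
        self.d = d

    def __getitem__(self, pair) -> float:
        i = self.taxa.index(pair[0])
        j = self.taxa.index(pair[1])
        return float(self.d[i, j])


def _rows_and_labels(msa) -> tuple[list[str], list[str]]:
    if isinstance(msa, (Msa, Supermatrix)):
        records = msa.records
    else:
        records = list(msa)
    taxa = [r.taxon for r in records]
    if len(set(taxa)) != len(taxa):
        taxa = [r.id for r in records]
    return [r.residues for r in records], taxa


def distance_matrix(msa, model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gap columns.

    model 'p': mismatch fraction over comparable columns;
    model 'poisson': d = -ln(1 - p) (multiple-hit corrected).
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    rows, taxa = _rows_and_labels(msa)
    if len(rows) < 3:
        raise ValueError("need at least 3 rows for a distance matrix")
    mat = np.frombuffer("".join(rows).encode(), dtype=np.uint8)
    mat = mat.reshape(len(rows), -1)
    gap = mat == ord(GAP)
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            total = int(ok.sum())
            if total == 0:
                raise ValueError(
                    f"no comparable columns between {taxa[i]!r} and "
                    f"{taxa[j]!r}")
            p = float(np.sum(mat[i, ok] != mat[j, ok])) / total
            if model == "p":
                d[i, j] = d[j, i] = p
            else:
                if p >= 1.0:
                    raise ValueError(
                        f"p-distance {p} >= 1 between {taxa[i]!r} and "
                        f"{taxa[j]!r}; Poisson correction undefined")
                d[i, j] = d[j, i] = -np.log(1.0 - p)
    return DistanceMatrix(taxa, d)


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Canonical Saitou-Nei NJ with the Studier-Keppler Q criterion.

    Ties in Q are broken by the lexicographically smallest active-node
    index pair (leaves in input taxon order, then internal nodes in
    creation order).  Negative branch lengths are clamped to zero and
    the deficit logged.
    """
    n0 = len(D.taxa)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    ns = dendropy.TaxonNamespace(D.taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = False
    nodes: list[dendropy.Node] = []
    for label in D.taxa:
        node = dendropy.Node()
        node.taxon = ns.get_taxon(label)
        nodes.append(node)
    d = D.d.copy()
    active = list(range(n0))
    clamped = 0.0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += -x
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = np.min(Q)
        ii, jj = min((a, b) for a in range(m) for b in range(m)
                     if a < b and Q[a, b] <= best + 1e-12)
        i, j = active[ii], active[jj]
        li = 0.5 * sub[ii, jj] + (r[ii] - r[jj]) / (2 * (m - 2))
        lj = sub[ii, jj] - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = clamp(li)
        parent.add_child(nodes[j])
        nodes[j].edge.length = clamp(lj)
        # distances from the new node to the remaining actives
        new_row = np.zeros(d.shape[0] + 1)
        for kk in range(m):
            k = active[kk]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]
    # final three nodes joined at the unrooted trifurcating pseudo-root
    a, b, c = active
    root = dendropy.Node()
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        root.add_child(node)
        node.edge.length = clamp(length)
    tree.seed_node = root
    if clamped > 0:
        logger.info("clamped negative NJ branch lengths; total deficit %.6g",
                    clamped)
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def _leaf_path(u, v):
    """Edges on the path from leaf u to leaf v, each as
    (edge, towards_parent: bool) in walking order."""
    u_anc = [u] + list(u.ancestor_iter())
    u_set = set(id(n) for n in u_anc)
    v_anc = [v] + list(v.ancestor_iter())
    mrca = next(n for n in v_anc if id(n) in u_set)
    path = []
    node = u
    while node is not mrca:
        path.append((node.edge, True))
        node = node.parent_node
    down = []
    node = v
    while node is not mrca:
        down.append((node.edge, False))
        node = node.parent_node
    return path + down[::-1]


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root a branch-length tree at the midpoint of its longest
    leaf-to-leaf path.

    The root always bifurcates: when the midpoint falls exactly on an
    internal node, the root is placed on the adjacent path edge with a
    zero-length segment.  The two farthest leaves end up equidistant
    from the root (to 1e-9).
    """
    lengths = [e.length or 0.0 for e in tree.preorder_edge_iter()
               if e.head_node is not tree.seed_node]
    if not any(l > 0 for l in lengths):
        raise ValueError("cannot midpoint-root a tree with all-zero "
                         "branch lengths")
    t = tree.clone(depth=1)
    pdm = t.phylogenetic_distance_matrix()
    leaves = sorted(t.leaf_node_iter(), key=lambda n: n.taxon.label)
    best = (-1.0, None, None)
    for i, u in enumerate(leaves):
        for v in leaves[i + 1:]:
            duv = pdm.distance(u.taxon, v.taxon)
            if duv > best[0] + 1e-15:
                best = (duv, u, v)
    dmax, u, v = best
    half = dmax / 2.0
    acc = 0.0
    for edge, towards_parent in _leaf_path(u, v):
        length = edge.length or 0.0
        if acc + length >= half - 1e-12:
            offset = half - acc  # from the u-side end of this edge
            head_part = offset if towards_parent else length - offset
            break
        acc += length
    parent = edge.tail_node
    child = edge.head_node
    tail_part = (edge.length or 0.0) - head_part
    new_node = dendropy.Node()
    parent.add_child(new_node)
    parent.remove_child(child)
    new_node.add_child(child)
    child.edge.length = head_part
    new_node.edge.length = tail_part
    _reroot_at(t, new_node)
    t.is_rooted = True
    return t


def _reroot_at(t: PhyloTree, node) -> None:
    """Make ``node`` the seed by reversing its ancestor chain,
    preserving every edge length; degree-two relics are spliced out."""
    path = [node] + list(node.ancestor_iter())
    lens = [p.edge.length for p in path[:-1]]
    for k in range(len(path) - 1):
        path[k + 1].remove_child(path[k])
    for k in range(len(path) - 1, 0, -1):
        path[k - 1].add_child(path[k])
        path[k].edge.length = lens[k - 1]
    t.seed_node = node
    node.edge.length = None
    node.parent_node = None
    t.suppress_unifurcations()


def _bipartitions(tree: PhyloTree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical frozensets of leaf labels
    (the side not containing the alphabetically first leaf)."""
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    ref = min(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        side = leaves - below if ref in below else below
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(frozenset(side))
    return out


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds distance: bipartitions present in exactly one
    tree."""
    l1 = {leaf.taxon.label for leaf in t1.leaf_node_iter()}
    l2 = {leaf.taxon.label for leaf in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only-in-first={sorted(l1 - l2)}, "
            f"only-in-second={sorted(l2 - l1)}")
    return len(_bipartitions(t1) ^ _bipartitions(t2))


def bootstrap_support(matrix_source: Supermatrix | Msa, replicates: int,
                      seed: int, model: str = "poisson") -> PhyloTree:
    """NJ tree with bipartition supports from column-resampling
    replicates.

    Columns are resampled with replacement per replicate; the support of
    each internal edge of the full-data NJ tree is the fraction of
    replicate trees containing its bipartition.  Deterministic given
    ``seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows, taxa = _rows_and_labels(matrix_source)
    base = neighbor_joining(distance_matrix(matrix_source, model=model))
    mat = np.frombuffer("".join(rows).encode(), dtype=np.uint8)
    mat = mat.reshape(len(rows), -1)
    length = mat.shape[1]
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in _bipartitions(base)}
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        res = mat[:, cols]
        rep_rows = [res[i].tobytes().decode() for i in range(len(rows))]
        rep = [SequenceRecord(t, t, s) for t, s in zip(taxa, rep_rows)]
        rep_tree = neighbor_joining(distance_matrix(rep, model=model))
        rep_bps = _bipartitions(rep_tree)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    leaves = set(taxa)
    ref = min(leaves)
    for node in base.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        side = leaves - below if ref in below else below
        key = frozenset(side)
        if key in counts:
            support = counts[key] / replicates
            node.label = f"{support:.3f}"
            node.support = support
    return base
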