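"""Distance-based tree reconstruction and tree utilities.

Trees are :class:`dendropy.Tree` objects (unrooted; an internal node of
degree three serves as the drawing root).  Bootstrap supports are stored as
internal node labels, formatted as percentages with one decimal.

Provided here:

* Saitou-Nei Neighbor-Joining with a deterministic tie-break (the first pair
  in row-major matrix order among Q-criterion minima), negative branch-length
  estimates clamped to zero.  NJ is exact on additive matrices.
* Strict majority-rule consensus: the consensus contains exactly the
  bipartitions occurring in more than ``threshold`` of the input trees (no
  greedy completion), each annotated with its occurrence percentage.
* Fixed-topology branch-length fitting by non-negative weighted least
  squares with Fitch-Margoliash weights 1/d^2 — the tree-search-free variant
  of the Fitch-Margoliash method, used to put branch lengths on a consensus
  topology.
* Newick read/write, label-based bipartition sets, Robinson-Foulds distance.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import dendropy
import numpy as np
from scipy.optimize import nnls

from .distance import DistanceMatrix

__all__ = [
    "neighbor_joining",
    "majority_consensus",
    "fit_branch_lengths",
    "annotate_supports",
    "tree_to_newick",
    "parse_newick",
    "tree_splits",
    "robinson_foulds",
    "leaf_labels",
    "get_supports",
]

PhyloTree = dendropy.Tree


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    """The set of leaf (taxon) labels of a tree."""
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def _node_leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def _canonical(side: frozenset[str], all_labels: frozenset[str], ref: str) -> frozenset[str]:
    """Canonical key of a bipartition: the side not containing ``ref``."""
    return all_labels - side if ref in side else side


def tree_splits(tree: dendropy.Tree) -> frozenset[frozenset[str]]:
    """Non-trivial bipartitions of an (un)rooted tree, as label sets.

    Each split is keyed by the side that does not contain the
    lexicographically smallest leaf label, so splits compare across trees
    regardless of rooting or taxon-namespace identity.
    """
    labels = leaf_labels(tree)
    n = len(labels)
    ref = min(labels)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = _node_leafset(node)
        if 2 <= len(below) <= n - 2:
            splits.add(_canonical(below, labels, ref))
    return frozenset(splits)


def robinson_foulds(a: dendropy.Tree, b: dendropy.Tree) -> int:
    """Number of bipartitions present in exactly one of the two trees."""
    la, lb = leaf_labels(a), leaf_labels(b)
    if la != lb:
        raise ValueError(
            f"leaf sets differ: {sorted(la - lb)} only in first, "
            f"{sorted(lb - la)} only in second"
        )
    return len(tree_splits(a) ^ tree_splits(b))


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei Neighbor-Joining on a labeled distance matrix.

    Iteratively joins the pair minimizing the Q criterion
    Q_ij = (m-2) d_ij - r_i - r_j; ties go to the first (i, j) in row-major
    order, so the result is deterministic.  Negative branch-length estimates
    are clamped to zero.  Returns an unrooted tree whose seed node has
    degree three (for n > 3 taxa; exactly three for n == 3).
    """
    n = dm.n
    if n < 3:
        raise ValueError(f"neighbor joining needs >= 3 taxa, got {n}")
    if not np.all(np.isfinite(dm.values)):
        raise ValueError("distance matrix contains non-finite entries")
    tns = dendropy.TaxonNamespace(list(dm.labels))
    cur_nodes = [dendropy.Node(taxon=tns.get_taxon(lab)) for lab in dm.labels]
    D = dm.values.astype(np.float64).copy()
    while len(cur_nodes) > 3:
        m = len(cur_nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = divmod(int(np.argmin(Q)), m)
        if i > j:  # symmetric matrix: row-major argmin already gives i < j
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        parent.add_child(cur_nodes[i])
        cur_nodes[i].edge.length = max(li, 0.0)
        parent.add_child(cur_nodes[j])
        cur_nodes[j].edge.length = max(lj, 0.0)
        merged = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [x for x in range(m) if x != i and x != j]
        newD = np.zeros((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = merged[keep]
        newD[:-1, -1] = merged[keep]
        cur_nodes = [cur_nodes[x] for x in keep] + [parent]
        D = newD
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = (
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    )
    center = dendropy.Node()
    for node, length in zip(cur_nodes, lengths):
        center.add_child(node)
        node.edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def majority_consensus(
    trees: list[dendropy.Tree],
    threshold: float = 0.5,
) -> dendropy.Tree:
    """Strict majority-rule consensus of trees over one leaf set.

    The consensus contains exactly the bipartitions occurring in strictly
    more than ``threshold`` (a fraction, >= 0.5) of the input trees; each
    retained internal edge is labeled with its occurrence percentage.  No
    branch lengths are assigned (fit them with :func:`fit_branch_lengths`).
    """
    if not trees:
        raise ValueError("need at least one tree")
    if not 0.5 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0.5, 1), got {threshold}")
    labels = leaf_labels(trees[0])
    counts: dict[frozenset[str], int] = {}
    for idx, t in enumerate(trees):
        lt = leaf_labels(t)
        if lt != labels:
            raise ValueError(f"tree {idx} has a different leaf set than tree 0")
        for split in tree_splits(t):
            counts[split] = counts.get(split, 0) + 1
    b = len(trees)
    retained = {s: c for s, c in counts.items() if c / b > threshold}
    newick = _build_consensus_newick(labels, retained, b)
    tree = parse_newick(newick)
    tree.is_rooted = False
    return tree


def _quote_label(label: str) -> str:
    if any(ch in label for ch in "()[]{}:;,= \t\n'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _build_consensus_newick(
    labels: frozenset[str],
    retained: dict[frozenset[str], int],
    n_trees: int,
) -> str:
    taxa = sorted(labels)
    # majority splits are pairwise compatible; as clusters all excluding the
    # reference taxon they are nested or disjoint, hence form a hierarchy
    clusters = sorted(retained, key=lambda s: (-len(s), tuple(sorted(s))))
    parent: dict[int, int | None] = {}
    for idx, c in enumerate(clusters):
        parent[idx] = None
        for pidx in range(idx):  # earlier entries are at least as large
            if c <= clusters[pidx]:
                parent[idx] = pidx  # last superset found is the smallest
    leaf_home: dict[str, int | None] = {}
    for taxon in taxa:
        home: int | None = None
        for idx, c in enumerate(clusters):
            if taxon in c:
                home = idx
        leaf_home[taxon] = home

    children: dict[int | None, list[int]] = {None: []}
    for idx in range(len(clusters)):
        children.setdefault(parent[idx], []).append(idx)
        children.setdefault(idx, [])
    attached: dict[int | None, list[str]] = {None: []}
    for taxon in taxa:
        attached.setdefault(leaf_home[taxon], []).append(taxon)

    def render(idx: int | None) -> str:
        parts = [_quote_label(t) for t in attached.get(idx, [])]
        parts += [render(ch) for ch in children.get(idx, [])]
        inner = "(" + ",".join(parts) + ")"
        if idx is None:
            return inner + ";"
        pct = 100.0 * retained[clusters[idx]] / n_trees
        return inner + f"{pct:.1f}"

    return render(None)


def annotate_supports(
    tree: dendropy.Tree,
    replicate_trees: list[dendropy.Tree],
) -> dendropy.Tree:
    """Label each internal edge of ``tree`` with its bootstrap percentage.

    The percentage is the fraction of ``replicate_trees`` containing the same
    bipartition.  Returns an annotated clone; the input is untouched.
    """
    labels = leaf_labels(tree)
    ref = min(labels)
    n = len(labels)
    counts: dict[frozenset[str], int] = {}
    for t in replicate_trees:
        for split in tree_splits(t):
            counts[split] = counts.get(split, 0) + 1
    b = len(replicate_trees)
    out = tree.clone(depth=1)
    for node in out.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = _node_leafset(node)
        if 2 <= len(below) <= n - 2:
            key = _canonical(below, labels, ref)
            node.label = f"{100.0 * counts.get(key, 0) / b:.1f}"
    return out


def fit_branch_lengths(
    topology: dendropy.Tree,
    dm: DistanceMatrix,
    min_weight_distance: float = 0.0,
) -> dendropy.Tree:
    """Fit branch lengths on a fixed topology by weighted least squares.

    Minimizes sum_{i<j} (d_ij - p_ij)^2 / d_ij^2 over non-negative edge
    lengths, where p_ij is the path length between leaves i and j on the
    tree (the Fitch-Margoliash criterion with its topology fixed).  Pairs at
    distance zero get unit weight (with a warning).  Polytomies are accepted
    (fewer edges to fit).  Returns a new tree; supports and topology are
    preserved.
    """
    if leaf_labels(topology) != frozenset(dm.labels):
        raise ValueError("topology leaf set does not match distance matrix labels")
    tree = topology.clone(depth=1)
    seed_children = tree.seed_node.child_nodes()
    if len(seed_children) == 2 and len(dm.labels) > 2:
        tree.deroot()  # basal bifurcation duplicates one edge; collapse it

    edge_nodes = [
        nd for nd in tree.preorder_node_iter() if nd.parent_node is not None
    ]
    edge_sides = [_node_leafset(nd) for nd in edge_nodes]
    idx = {label: i for i, label in enumerate(dm.labels)}
    pairs = list(combinations(dm.labels, 2))
    A = np.zeros((len(pairs), len(edge_nodes)))
    d = np.zeros(len(pairs))
    w = np.ones(len(pairs))
    zero_pairs = 0
    for p, (u, v) in enumerate(pairs):
        d[p] = dm.values[idx[u], idx[v]]
        if d[p] > min_weight_distance:
            w[p] = 1.0 / d[p] ** 2
        else:
            zero_pairs += 1
        for e, side in enumerate(edge_sides):
            if (u in side) != (v in side):
                A[p, e] = 1.0
    if zero_pairs:
        warnings.warn(
            f"{zero_pairs} taxon pair(s) at distance zero; using unit weight "
            "for them in the least-squares fit",
            stacklevel=2,
        )
    sw = np.sqrt(w)
    lengths, _ = nnls(A * sw[:, None], d * sw)
    for nd, length in zip(edge_nodes, lengths):
        nd.edge.length = float(length)
    return tree


def tree_to_newick(tree: dendropy.Tree, include_supports: bool = False) -> str:
    """Serialize as Newick (6 significant digits on branch lengths).

    With ``include_supports`` the internal node labels (bootstrap
    percentages) are written as standard internal Newick labels.
    """
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_internal_node_labels=not include_supports,
        real_value_format_specifier=".6g",
    )


def trees_to_nexus(trees: list[dendropy.Tree]) -> str:
    """Serialize trees as a NEXUS trees block (for tree viewers)."""
    tns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(taxon_namespace=tns)
    for t in trees:
        tl.append(parse_newick(tree_to_newick(t, include_supports=True)))
    return tl.as_string(schema="nexus")


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string; numeric internal labels are kept as supports."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"newick parse error: {exc}") from None
    return tree


def get_supports(tree: dendropy.Tree) -> dict[frozenset[str], float]:
    """Bootstrap percentages per bipartition, read from internal labels."""
    labels = leaf_labels(tree)
    ref = min(labels)
    n = len(labels)
    supports: dict[frozenset[str], float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf() or node.label is None:
            continue
        try:
            value = float(node.label)
        except ValueError:
            continue
        below = _node_leafset(node)
        if 2 <= len(below) <= n - 2:
            supports[_canonical(below, labels, ref)] = value
    return supports
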