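"""Synthetic data generators for testing and benchmarking the method.

Three generators cover everything the test and acceptance suites need
without any downloads:

* i.i.d. random nucleotide sequences with controlled length and GC content;
* random additive trees together with their exact path-length matrices (the
  oracle on which Neighbor-Joining is provably exact);
* sequence sets evolved along a known tree under a Jukes-Cantor-like i.i.d.
  substitution process, so topology recovery can be scored against a known
  truth.  The per-site substitution probability across a branch of length t
  is 1 - exp(-rate * t).

The substitution process deliberately omits indels, repeats and regional GC
structure: the method under test consumes k-mer composition only, and an
i.i.d. process already produces the graded compositional divergence the
method must resolve.  EST-like inputs (short reads, optional poly-A tails)
are emulated by :func:`make_est_records`.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .distance import DistanceMatrix
from .seqio import SequenceRecord
from .tree import parse_newick

__all__ = [
    "SimScenario",
    "random_sequence",
    "random_additive_tree",
    "evolve_sequences",
    "two_clade_scenario",
    "make_est_records",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimScenario:
    """A known-truth simulation: tree, root length, substitution rate, seed."""

    tree: dendropy.Tree
    root_length: int
    rate: float  # expected substitutions per site per unit branch length
    seed: int
    gc: float = 0.5


def random_sequence(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """I.i.d. random A/C/G/T sequence with expected GC fraction ``gc``."""
    if length < 0:
        raise ValueError("length must be >= 0")
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must be in [0, 1], got {gc}")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A, C, G, T
    codes = rng.choice(4, size=length, p=probs)
    return _BASES[codes].tobytes().decode("ascii")


def random_additive_tree(
    n_taxa: int,
    seed: int = 0,
    length_range: tuple[float, float] = (0.1, 1.0),
) -> tuple[dendropy.Tree, DistanceMatrix]:
    """Random binary topology with random branch lengths and its exact
    path-length matrix.

    The returned matrix is additive by construction (entries are tree path
    lengths computed independently of any reconstruction code), so it serves
    as an oracle: NJ must recover the topology and all branch lengths.
    """
    if n_taxa < 4:
        raise ValueError(f"need at least 4 taxa, got {n_taxa}")
    rng = np.random.default_rng(seed)
    labels = [f"T{i + 1}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(labels)
    center = dendropy.Node()
    for lab in labels[:3]:
        center.add_child(dendropy.Node(taxon=tns.get_taxon(lab)))
    attachable = list(center.child_nodes())  # nodes whose parent edge can split
    for lab in labels[3:]:
        target = attachable[int(rng.integers(len(attachable)))]
        parent = target.parent_node
        mid = dendropy.Node()
        parent.remove_child(target)
        parent.add_child(mid)
        mid.add_child(target)
        leaf = dendropy.Node(taxon=tns.get_taxon(lab))
        mid.add_child(leaf)
        attachable.extend([mid, leaf])
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    lo, hi = length_range
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(rng.uniform(lo, hi))

    # exact leaf-to-leaf path lengths via cumulative distances to the root
    up: dict[str, dict[int, float]] = {}
    for leaf in tree.leaf_node_iter():
        cum, node, dist = {}, leaf, 0.0
        while node is not None:
            cum[id(node)] = dist
            if node.parent_node is not None:
                dist += node.edge.length
            node = node.parent_node
        up[leaf.taxon.label] = cum
    values = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(labels):
        for j in range(i + 1, n_taxa):
            b = labels[j]
            common = up[a].keys() & up[b].keys()
            d = min(up[a][c] + up[b][c] for c in common)
            values[i, j] = values[j, i] = d
    return tree, DistanceMatrix(labels=tuple(labels), values=values, metric="additive")


def _mutate(codes: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability p, to a uniform different base."""
    out = codes.copy()
    mask = rng.random(codes.size) < p
    n_mut = int(mask.sum())
    if n_mut:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n_mut)) % 4
    return out


def evolve_sequences(scn: SimScenario) -> list[tuple[str, str]]:
    """Evolve sequences down the scenario tree; returns (label, sequence)
    per leaf, in tree traversal order."""
    if scn.rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(scn.seed)
    probs = [(1 - scn.gc) / 2, scn.gc / 2, scn.gc / 2, (1 - scn.gc) / 2]
    root = rng.choice(4, size=scn.root_length, p=probs).astype(np.uint8)
    seqs: dict[int, np.ndarray] = {id(scn.tree.seed_node): root}
    leaves: list[tuple[str, str]] = []
    for node in scn.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        length = node.edge.length if node.edge.length is not None else 0.0
        p = 1.0 - float(np.exp(-scn.rate * length))
        codes = _mutate(seqs[id(node.parent_node)], p, rng)
        seqs[id(node)] = codes
        if node.is_leaf():
            leaves.append((node.taxon.label, _BASES[codes].tobytes().decode("ascii")))
    return leaves


_TWO_CLADE_NEWICK = (
    "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
)


def two_clade_scenario(
    seed: int,
    root_length: int = 50_000,
    rate: float = 0.03,
    gc: float = 0.5,
) -> SimScenario:
    """Preset: eight taxa on a balanced tree with two four-taxon clades.

    Unit branch lengths with ``rate`` expected substitutions per site per
    unit length, i.e. roughly 3% divergence per branch at the default — close
    relatives with clearly structured signal.
    """
    return SimScenario(
        tree=parse_newick(_TWO_CLADE_NEWICK),
        root_length=root_length,
        rate=rate,
        seed=seed,
        gc=gc,
    )


def make_est_records(
    seq: str,
    read_length: int,
    rng: np.random.Generator,
    polya_mean: float = 0.0,
    label_prefix: str = "read",
) -> list[SequenceRecord]:
    """Chop a sequence into EST-like reads, optionally appending poly-A tails.

    Tail lengths are geometric with mean ``polya_mean`` (0 disables tails).
    Leftover cDNA poly-A tails are the real-data artifact that inflates the
    two homopolymer FCGR cells; this generator exists to exercise the
    masking rule against a known truth.
    """
    records = []
    for i, start in enumerate(range(0, len(seq), read_length)):
        read = seq[start : start + read_length]
        if not read:
            continue
        if polya_mean > 0:
            tail = int(rng.geometric(1.0 / polya_mean))
            read += "A" * tail
        records.append(SequenceRecord(f"{label_prefix}{i + 1}", read))
    return records
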