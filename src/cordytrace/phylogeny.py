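"""Minimal distance-based tree machinery for clade-map generation.

This module exists so the pipeline can derive clade maps for core-region
delimitation on new (e.g. synthetic) datasets without external tree software:
uncorrected p-distances between aligned haplotype sequences, Saitou-Nei
neighbor joining with a deterministic tie rule, nonparametric bootstrap over
alignment columns, and leaf-set extraction of the minimal clade spanning a
set of seed haplotypes.  Model-based phylogenetics (ML, Bayesian inference)
is deliberately out of scope; published clade memberships for real data are
consumed as configuration by :mod:`cordytrace.core_regions`.

Haplotype sequences of one marker share a common length in this system, so
an alignment step is not provided; unequal lengths are rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np

ACGT = frozenset("ACGT")


def p_distance(seq_a: str, seq_b: str) -> float:
    """Uncorrected proportion of differing sites between two aligned sequences.

    Sites where either sequence carries a non-ACGT character (ambiguity codes,
    gaps) are excluded from both numerator and denominator.  Raises when the
    lengths differ or no comparable site remains.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("p-distance requires equal-length (aligned) sequences")
    a, b = seq_a.upper(), seq_b.upper()
    compared = mismatches = 0
    for x, y in zip(a, b):
        if x in ACGT and y in ACGT:
            compared += 1
            mismatches += x != y
    if compared == 0:
        raise ValueError("no comparable ACGT sites between the two sequences")
    return mismatches / compared


@dataclass(frozen=True)
class DistanceMatrix:
    """A labelled symmetric distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError("matrix shape does not match the label count")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (d < -1e-12).any():
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "d", d)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])


def distance_matrix(labeled_seqs: Sequence[tuple[str, str]]) -> DistanceMatrix:
    """All-pairs p-distance matrix of labelled, aligned sequences."""
    labels = tuple(lab for lab, _ in labeled_seqs)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(labeled_seqs[i][1], labeled_seqs[j][1])
    return DistanceMatrix(labels=labels, d=d)


class UnrootedTree:
    """An unrooted tree with labelled leaves and nonnegative edge lengths."""

    def __init__(self) -> None:
        self._adj: dict[int, dict[int, float]] = {}
        self._leaf_label: dict[int, str] = {}
        self._next_id = 0
        #: True when any negative NJ branch length was clamped to zero.
        self.clamped_negative_lengths = False

    def add_node(self, label: Optional[str] = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self._adj[nid] = {}
        if label is not None:
            self._leaf_label[nid] = label
        return nid

    def add_edge(self, a: int, b: int, length: float) -> None:
        if length < 0:
            self.clamped_negative_lengths = True
            length = 0.0
        self._adj[a][b] = length
        self._adj[b][a] = length

    @property
    def leaves(self) -> dict[int, str]:
        return dict(self._leaf_label)

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(self._leaf_label.values())

    def neighbors(self, nid: int) -> dict[int, float]:
        return dict(self._adj[nid])

    def edges(self) -> list[tuple[int, int, float]]:
        out = []
        for a, nbrs in self._adj.items():
            for b, length in nbrs.items():
                if a < b:
                    out.append((a, b, length))
        return out

    def _node_of(self, label: str) -> int:
        for nid, lab in self._leaf_label.items():
            if lab == label:
                return nid
        raise KeyError(label)

    def path_length(self, label_a: str, label_b: str) -> float:
        """Sum of edge lengths along the unique path between two leaves."""
        start, goal = self._node_of(label_a), self._node_of(label_b)
        stack = [(start, 0.0, -1)]
        while stack:
            node, dist, parent = stack.pop()
            if node == goal:
                return dist
            for nbr, length in self._adj[node].items():
                if nbr != parent:
                    stack.append((nbr, dist + length, node))
        raise ValueError("tree is disconnected")

    def _split(self, a: int, b: int) -> frozenset[str]:
        """Leaf labels on the ``a`` side of edge (a, b)."""
        labels = set()
        stack = [(a, b)]
        while stack:
            node, parent = stack.pop()
            if node in self._leaf_label:
                labels.add(self._leaf_label[node])
            for nbr in self._adj[node]:
                if nbr != parent:
                    stack.append((nbr, node))
        return frozenset(labels)

    def bipartitions(self, include_trivial: bool = False) -> set[frozenset[str]]:
        """Canonical leaf bipartitions, one frozenset per edge.

        Each edge splits the leaves in two; the canonical representative is
        the side *not* containing the lexicographically smallest leaf label.
        Trivial splits (single leaf vs rest) are excluded by default.
        """
        anchor = min(self.leaf_labels)
        out = set()
        for a, b, _ in self.edges():
            side = self._split(a, b)
            if anchor in side:
                side = self.leaf_labels - side
            if include_trivial or 1 < len(side) < len(self.leaf_labels) - 1:
                out.add(frozenset(side))
        return out

    def to_dendropy(self) -> dendropy.Tree:
        """Convert to a dendropy tree (arbitrarily rooted at an internal node)."""
        taxa = dendropy.TaxonNamespace(sorted(self.leaf_labels))
        tree = dendropy.Tree(taxon_namespace=taxa)
        internal = [n for n in self._adj if n not in self._leaf_label]
        root = internal[0] if internal else next(iter(self._adj))
        node_map = {root: tree.seed_node}
        stack = [(root, -1)]
        while stack:
            node, parent = stack.pop()
            for nbr, length in self._adj[node].items():
                if nbr == parent:
                    continue
                child = node_map[node].new_child(edge_length=length)
                if nbr in self._leaf_label:
                    child.taxon = taxa.get_taxon(self._leaf_label[nbr])
                node_map[nbr] = child
                stack.append((nbr, node))
        return tree

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(schema="newick").strip()


def neighbor_joining(m: DistanceMatrix) -> UnrootedTree:
    """Saitou-Nei neighbor joining, deterministic given the label set.

    Ties in the Q-criterion are broken by the lexicographically smallest
    (cluster key) pair, where a cluster's key is the smallest leaf label it
    contains; the result therefore does not depend on input order.  Negative
    branch lengths are clamped to zero (flagged on the tree).  On an additive
    distance matrix the produced tree reproduces all pairwise path lengths.
    """
    n = len(m.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    tree = UnrootedTree()
    # active clusters: key -> (node id, index into the working matrix)
    nodes = {lab: tree.add_node(lab) for lab in m.labels}
    keys = list(m.labels)
    d = {a: {b: m.d[i, j] for j, b in enumerate(keys)} for i, a in enumerate(keys)}

    while len(keys) > 3:
        r = {a: sum(d[a][b] for b in keys if b != a) for a in keys}
        best: Optional[tuple] = None
        for a in keys:
            for b in keys:
                if a >= b:
                    continue
                q = (len(keys) - 2) * d[a][b] - r[a] - r[b]
                cand = (q, a, b)
                if best is None or cand < best:
                    best = cand
        _, a, b = best
        la = 0.5 * d[a][b] + (r[a] - r[b]) / (2 * (len(keys) - 2))
        lb = d[a][b] - la
        new = tree.add_node()
        tree.add_edge(nodes[a], new, la)
        tree.add_edge(nodes[b], new, lb)
        newkey = min(a, b)
        newd = {}
        for c in keys:
            if c in (a, b):
                continue
            newd[c] = 0.5 * (d[a][c] + d[b][c] - d[a][b])
        for c, dist in newd.items():
            d[c][newkey] = dist
        keys = [k for k in keys if k not in (a, b)] + [newkey]
        keys.sort()
        d[newkey] = newd
        nodes[newkey] = new

    a, b, c = keys
    center = tree.add_node()
    tree.add_edge(nodes[a], center, 0.5 * (d[a][b] + d[a][c] - d[b][c]))
    tree.add_edge(nodes[b], center, 0.5 * (d[a][b] + d[b][c] - d[a][c]))
    tree.add_edge(nodes[c], center, 0.5 * (d[a][c] + d[b][c] - d[a][b]))
    return tree


def bootstrap_support(
    labeled_seqs: Sequence[tuple[str, str]],
    n_reps: int,
    seed: int,
) -> dict[frozenset[str], float]:
    """Column-resampling bootstrap support for NJ bipartitions.

    Alignment columns are resampled with replacement ``n_reps`` times; the
    support of a bipartition is the fraction of replicate NJ trees containing
    it.  Deterministic given ``seed`` and invariant to leaf order (the NJ tie
    rule depends on labels, and the resampled columns depend only on the
    seed).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    lengths = {len(s) for _, s in labeled_seqs}
    if len(lengths) != 1:
        raise ValueError("bootstrap requires aligned equal-length sequences")
    length = lengths.pop()
    ordered = sorted(labeled_seqs)  # leaf-order invariance
    arr = np.array([list(s) for _, s in ordered])
    labels = [lab for lab, _ in ordered]
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        rep = [(lab, "".join(row)) for lab, row in zip(labels, arr[:, cols])]
        tree = neighbor_joining(distance_matrix(rep))
        for bip in tree.bipartitions():
            counts[bip] = counts.get(bip, 0) + 1
    return {bip: c / n_reps for bip, c in counts.items()}


def extract_clade(
    tree: UnrootedTree,
    seed_codes: Iterable[str],
    outgroup: Optional[str] = None,
) -> frozenset[str]:
    """Smallest leaf set containing all seeds on one side of some edge.

    In an unrooted tree a clade is defined relative to an edge cut: the
    returned set is the minimal edge-side leaf superset of ``seed_codes``
    (excluding a designated outgroup leaf when given).  When the seeds
    straddle every edge the whole leaf set is returned with a warning.
    """
    seeds = frozenset(seed_codes)
    if not seeds:
        raise ValueError("at least one seed haplotype is required")
    if not seeds <= tree.leaf_labels:
        raise ValueError(f"seeds not in tree: {sorted(seeds - tree.leaf_labels)}")
    if outgroup is not None and outgroup not in tree.leaf_labels:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    best: Optional[frozenset[str]] = None
    for a, b, _ in tree.edges():
        for side in (tree._split(a, b), tree._split(b, a)):
            if not seeds <= side:
                continue
            if outgroup is not None and outgroup in side:
                continue
            if best is None or (len(side), sorted(side)) < (len(best), sorted(best)):
                best = side
    if best is None:
        warnings.warn(
            "seed haplotypes straddle every edge; returning all leaves",
            stacklevel=2,
        )
        return tree.leaf_labels
    return best
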