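"""Synthetic tree landscapes and manifold samples for testing and calibration.

The bootstrap tree sets this kind of analysis consumes have a
characteristic structure: each data partition contributes a cluster of
topologically similar trees, and partitions with fewer informative
characters (shorter genes) produce more widely scattered clusters.  The
generator here reproduces exactly that distributional shape without any
tree inference: each partition gets a center topology, and member trees
are produced by a Poisson number of random NNI (nearest-neighbor
interchange) moves away from the center, with the expected number of
moves inversely proportional to the partition-length proxy L_g.

Two modes mirror the two study designs:

* ``clustered`` — every partition has its own independent random center
  (well-separated clusters, the real-data case);
* ``null`` — all partitions share one center, so between-partition
  spread matches within-partition spread (the shuffled-columns control).

``sample_manifold`` provides Euclidean point clouds of known intrinsic
dimension (segment, square, cube, Gaussian, swiss roll) as ground truth
for the dimensionality estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .distances import DistanceMatrix
from .trees import TreeSet

__all__ = [
    "LandscapeSimSpec",
    "random_tree",
    "nni_move",
    "simulate_landscape",
    "sample_manifold",
]


# ---------------------------------------------------------------------------
# unrooted binary topologies as adjacency maps {node: set(neighbors)};
# leaves are 0..n_taxa-1, internal nodes n_taxa..2*n_taxa-3

def _random_topology(n_taxa, rng):
    """Uniform random unrooted binary topology by sequential random leaf
    attachment (each of the (2n-5)!! topologies is equally likely)."""
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    nxt = n_taxa  # next internal node id
    adj = {i: set() for i in range(3)}
    adj[nxt] = {0, 1, 2}
    for i in range(3):
        adj[i] = {nxt}
    edges = [(0, nxt), (1, nxt), (2, nxt)]
    nxt += 1
    for leaf in range(3, n_taxa):
        a, b = edges[rng.integers(len(edges))]
        m = nxt
        nxt += 1
        adj[a].remove(b)
        adj[b].remove(a)
        adj[m] = {a, b, leaf}
        adj[a].add(m)
        adj[b].add(m)
        adj[leaf] = {m}
        edges.remove((a, b))
        edges.extend([(a, m), (b, m), (leaf, m)])
    return adj


def _internal_edges(adj):
    return [(u, v) for u in adj for v in adj[u]
            if u < v and len(adj[u]) > 1 and len(adj[v]) > 1]


def _nni(adj, rng):
    """One random nearest-neighbor interchange, in place."""
    candidates = _internal_edges(adj)
    if not candidates:
        return adj
    u, v = candidates[rng.integers(len(candidates))]
    a = list(adj[u] - {v})[rng.integers(2)]
    b = list(adj[v] - {u})[rng.integers(2)]
    adj[u].remove(a)
    adj[a].remove(u)
    adj[v].remove(b)
    adj[b].remove(v)
    adj[u].add(b)
    adj[b].add(u)
    adj[v].add(a)
    adj[a].add(v)
    return adj


def _copy_adj(adj):
    return {k: set(v) for k, v in adj.items()}


def _taxon_labels(n_taxa):
    width = len(str(n_taxa - 1))
    return [f"t{i:0{width}d}" for i in range(n_taxa)]


def _to_newick(adj, labels):
    leaves = sorted(k for k in adj if len(adj[k]) == 1)
    root = next(iter(adj[leaves[0]]))

    def rec(node, parent):
        if len(adj[node]) == 1:
            return labels[node]
        parts = [rec(c, node) for c in sorted(adj[node] - {parent if parent is not None else -1})]
        return "(" + ",".join(parts) + ")"

    return rec(root, None) + ";"


def _parse(newick, taxon_namespace):
    return dendropy.Tree.get(data=newick, schema="newick",
                             taxon_namespace=taxon_namespace)


def random_tree(n_taxa, seed):
    """A uniform random unrooted binary topology as a dendropy Tree."""
    rng = np.random.default_rng(seed)
    adj = _random_topology(n_taxa, rng)
    labels = _taxon_labels(n_taxa)
    return _parse(_to_newick(adj, labels), dendropy.TaxonNamespace(labels))


def nni_move(tree_or_adj, seed):
    """One random NNI applied to a dendropy tree (returns a new tree)."""
    rng = np.random.default_rng(seed)
    if isinstance(tree_or_adj, dict):
        return _nni(_copy_adj(tree_or_adj), rng)
    tree = tree_or_adj
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    adj = _adj_from_tree(tree, labels)
    adj = _nni(adj, rng)
    return _parse(_to_newick(adj, labels), tree.taxon_namespace)


def _adj_from_tree(tree, labels):
    index = {lab: i for i, lab in enumerate(labels)}
    nxt = [len(labels)]
    adj = {}
    ids = {}

    def node_id(node):
        if node not in ids:
            if node.is_leaf():
                ids[node] = index[node.taxon.label]
            else:
                ids[node] = nxt[0]
                nxt[0] += 1
            adj.setdefault(ids[node], set())
        return ids[node]

    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        a, b = node_id(edge.tail_node), node_id(edge.head_node)
        adj[a].add(b)
        adj[b].add(a)
    # suppress a degree-2 root so the topology is properly unrooted
    for k in list(adj):
        if len(adj[k]) == 2:
            x, y = adj.pop(k)
            adj[x].discard(k)
            adj[y].discard(k)
            adj[x].add(y)
            adj[y].add(x)
    return adj


@dataclass
class LandscapeSimSpec:
    """Conditions for a synthetic landscape.

    ``partitions`` lists (label, length_proxy L_g, n_trees) triples; the
    expected NNI moves per tree in partition g is nni_scale / L_g, so
    longer partitions yield tighter clusters.  The default nni_scale of
    200 makes partition lengths in the few-hundreds-to-few-thousands
    range (the scale of real gene partitions) span rates from ~2 down
    to ~0.1 moves per tree.
    """

    n_taxa: int
    partitions: list
    base_seed: int = 0
    nni_scale: float = 200.0
    mode: str = "clustered"

    def __post_init__(self):
        if self.n_taxa < 8:
            raise ValueError("need n_taxa >= 8")
        for lab, L, m in self.partitions:
            if L <= 0 or m < 2:
                raise ValueError(f"partition {lab!r}: need L > 0 and n_trees >= 2")
        if self.mode not in ("clustered", "null"):
            raise ValueError("mode must be 'clustered' or 'null'")


def simulate_landscape(spec):
    """Generate a TreeSet with the partition-cluster structure of ``spec``."""
    labels = _taxon_labels(spec.n_taxa)
    ns = dendropy.TaxonNamespace(labels)
    rng = np.random.default_rng(spec.base_seed)
    shared_center = _random_topology(spec.n_taxa, rng) if spec.mode == "null" else None
    trees, partition_of = [], []
    for lab, L, m in spec.partitions:
        center = shared_center if shared_center is not None else _random_topology(spec.n_taxa, rng)
        rate = spec.nni_scale / L
        for _ in range(m):
            adj = _copy_adj(center)
            for _ in range(rng.poisson(rate)):
                _nni(adj, rng)
            trees.append(_parse(_to_newick(adj, labels), ns))
            partition_of.append(str(lab))
    return TreeSet(trees=trees, leaf_labels=tuple(sorted(labels)),
                   partition_of=partition_of, source_files=["<simulated>"])


MANIFOLD_KINDS = ("segment", "square", "cube", "gaussian_d", "swiss_roll")


def sample_manifold(kind, n, d=None, seed=0, ambient_dim=None):
    """i.i.d. samples from a unit-scale manifold of known dimension.

    Returns (points, DistanceMatrix) with Euclidean distances; the point
    coordinates are the ground truth for embedding-recovery tests.
    ``ambient_dim`` embeds the sample in a higher-dimensional space via a
    random rotation (the distances are unchanged).
    """
    if n < 10:
        raise ValueError("need n >= 10 samples")
    rng = np.random.default_rng(seed)
    if kind == "segment":
        pts = rng.uniform(0, 1, size=(n, 1))
    elif kind == "square":
        pts = rng.uniform(0, 1, size=(n, 2))
    elif kind == "cube":
        pts = rng.uniform(0, 1, size=(n, 3))
    elif kind == "gaussian_d":
        if d is None:
            raise ValueError("gaussian_d needs d")
        pts = rng.standard_normal((n, d))
    elif kind == "swiss_roll":
        t = rng.uniform(1.5 * np.pi, 4.5 * np.pi, size=n)
        h = rng.uniform(0, 10, size=n)
        pts = np.column_stack([t * np.cos(t), h, t * np.sin(t)]) / (4.5 * np.pi)
    else:
        raise ValueError(f"unknown manifold kind {kind!r}; choose from {MANIFOLD_KINDS}")
    if ambient_dim is not None:
        if ambient_dim < pts.shape[1]:
            raise ValueError("ambient_dim must be >= intrinsic dimension")
        padded = np.zeros((n, ambient_dim))
        padded[:, : pts.shape[1]] = pts
        Q, _ = np.linalg.qr(rng.standard_normal((ambient_dim, ambient_dim)))
        pts = padded @ Q
    dm = DistanceMatrix(squareform(pdist(pts)), metric_name=f"euclidean_{kind}")
    return pts, dm
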