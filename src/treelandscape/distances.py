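"""Robinson-Foulds distance matrices over tree sets.

The RF distance between two unrooted trees on the same leaves is the
number of bipartitions (splits) present in one tree but not the other —
the size of the symmetric difference of their split sets.  It is reported
unnormalized (raw split count); dividing by the maximum 2(n-3) is
available via ``normalize=True``.

Distance matrices read from or written to disk use either a full square
CSV (header row of tree ids) or a PHYLIP-style lower-triangular
whitespace format; the reader auto-detects the format, so externally
computed metrics can be fed to the downstream embedding machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trees import TreeSetError, bipartitions

__all__ = [
    "DistanceMatrix",
    "rf",
    "rf_matrix",
    "read_distance_matrix",
    "write_distance_matrix",
]


@dataclass
class DistanceMatrix:
    """A symmetric N x N dissimilarity matrix with per-row partition labels."""

    delta: np.ndarray
    labels: list = field(default_factory=list)
    metric_name: str = "rf"

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float)
        d = self.delta
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError(f"distance matrix must be square, got shape {d.shape}")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(d < 0):
            raise ValueError("distances must be nonnegative")
        if not self.labels:
            self.labels = [str(i) for i in range(d.shape[0])]
        if len(self.labels) != d.shape[0]:
            raise ValueError("labels must align with matrix rows")

    @property
    def n(self):
        return self.delta.shape[0]


def rf(tree_a, tree_b, leaf_labels=None, normalize=False):
    """Robinson-Foulds distance between two trees on the same leaf set.

    |B(a) symmetric-difference B(b)| over non-trivial splits; an even
    nonnegative integer bounded by 2(n - 3) for binary trees.
    """
    la = sorted(l.taxon.label for l in tree_a.leaf_node_iter())
    lb = sorted(l.taxon.label for l in tree_b.leaf_node_iter())
    if la != lb:
        raise TreeSetError(
            "leaf-set mismatch: "
            f"{sorted(set(la).symmetric_difference(lb))}"
        )
    if leaf_labels is None:
        leaf_labels = tuple(la)
    sa = bipartitions(tree_a, leaf_labels)
    sb = bipartitions(tree_b, leaf_labels)
    d = len(sa.symmetric_difference(sb))
    if normalize:
        d = d / (2 * (len(leaf_labels) - 3))
    return d


def rf_matrix(ts, normalize=False):
    """All-pairs RF distance matrix of a TreeSet.

    Split sets are encoded once per tree; each of the N(N-1)/2 pairs then
    costs one integer-set intersection:
    |A ^ B| = |A| + |B| - 2|A & B|.
    """
    n_trees = len(ts)
    if n_trees < 2:
        raise TreeSetError("need at least 2 trees")
    splits = [bipartitions(t, ts.leaf_labels) for t in ts.trees]
    sizes = [len(s) for s in splits]
    delta = np.zeros((n_trees, n_trees))
    for i in range(n_trees):
        si = splits[i]
        for j in range(i + 1, n_trees):
            d = sizes[i] + sizes[j] - 2 * len(si & splits[j])
            delta[i, j] = delta[j, i] = d
    if normalize:
        delta /= 2 * (ts.n_leaves - 3)
    return DistanceMatrix(delta, labels=list(ts.partition_of),
                          metric_name="rf_normalized" if normalize else "rf")


def write_distance_matrix(dm, path, fmt="csv"):
    """Write a DistanceMatrix as square CSV (default) or PHYLIP lower-triangular."""
    d = dm.delta
    n = d.shape[0]
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write(",".join(f"t{i}" for i in range(n)) + "\n")
            for i in range(n):
                fh.write(",".join(repr(float(x)) for x in d[i]) + "\n")
    elif fmt == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{n}\n")
            for i in range(n):
                row = " ".join(repr(float(x)) for x in d[i, :i])
                fh.write(f"t{i} {row}".rstrip() + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r} (use 'csv' or 'phylip')")


def read_distance_matrix(path, labels=None, metric_name="external"):
    """Read a distance matrix, auto-detecting square CSV vs PHYLIP lower-triangular.

    A first line consisting of a single integer marks the PHYLIP format
    (row i carries a name and i strictly-lower entries); anything else is
    parsed as a square CSV whose first row is a header of tree ids.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path!r} is empty")
    first = lines[0].split()
    if len(first) == 1 and first[0].isdigit():
        n = int(first[0])
        if len(lines) != n + 1:
            raise ValueError(f"{path!r}: expected {n} rows, found {len(lines) - 1}")
        d = np.zeros((n, n))
        for i, line in enumerate(lines[1:]):
            parts = line.split()
            vals = parts[1:]  # leading token is the row name
            if len(vals) != i:
                raise ValueError(
                    f"{path!r} row {i}: expected {i} lower-triangular entries, "
                    f"got {len(vals)}"
                )
            for j, v in enumerate(vals):
                d[i, j] = d[j, i] = float(v)
    else:
        header = lines[0].split(",")
        n = len(header)
        rows = lines[1:]
        if len(rows) != n:
            raise ValueError(f"{path!r}: header has {n} columns but {len(rows)} data rows")
        d = np.array([[float(v) for v in row.split(",")] for row in rows])
    return DistanceMatrix(d, labels=labels or [], metric_name=metric_name)
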