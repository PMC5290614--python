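"""Reading, writing and canonicalizing sets of phylogenetic trees.

A tree landscape is built from a collection of trees that all share one
leaf-label set (typically the union of bootstrap trees from several data
partitions of a single alignment).  Trees are treated as *unrooted*
throughout: rooted Newick input is accepted, but every topology is reduced
to its set of non-trivial bipartitions (splits), which is the
representation all downstream distance computations consume.

Splits are encoded as integer bitmasks over a fixed, lexicographically
sorted leaf ordering, normalized so that the bit of the first leaf is
always 0.  Set operations on splits are then exact integer comparisons.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "TreeSet",
    "TreeSetError",
    "read_treeset",
    "write_treeset",
    "bipartitions",
    "read_partition_table",
    "write_partition_table",
]


class TreeSetError(ValueError):
    """Raised for malformed input tree sets (parse errors, leaf-set mismatches)."""


@dataclass
class TreeSet:
    """A labeled collection of trees on a single leaf set.

    Attributes
    ----------
    trees : list of dendropy.Tree
        The topologies, in input order.  Branch lengths, if present, are
        parsed but ignored by the topology-only pipeline.
    leaf_labels : tuple of str
        The shared taxon names, lexicographically sorted.  This ordering
        defines the global bit positions used by :func:`bipartitions`.
    partition_of : list of str
        Partition label of each tree (``partition_of[i]`` labels
        ``trees[i]``).
    source_files : list of str
        Provenance: the files each tree came from.
    """

    trees: list
    leaf_labels: tuple
    partition_of: list
    source_files: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.trees) != len(self.partition_of):
            raise TreeSetError(
                "partition_of must label every tree: "
                f"{len(self.trees)} trees vs {len(self.partition_of)} labels"
            )

    def __len__(self):
        return len(self.trees)

    @property
    def n_leaves(self):
        return len(self.leaf_labels)

    @property
    def partition_labels(self):
        """Distinct partition labels in first-appearance order."""
        seen = []
        for lab in self.partition_of:
            if lab not in seen:
                seen.append(lab)
        return seen


def _leaf_set(tree):
    return frozenset(l.taxon.label for l in tree.leaf_node_iter())


def read_treeset(paths, labels=None):
    """Read one or more Newick files into a single :class:`TreeSet`.

    Each file contributes one data partition; trees are concatenated in
    file order.  Partition labels default to the file basename (without
    extension) and may be overridden with ``labels``.

    All trees must share an identical leaf-label set; a mismatch raises
    :class:`TreeSetError` naming the offending labels.
    """
    paths = [str(p) for p in paths]
    if labels is not None and len(labels) != len(paths):
        raise TreeSetError(
            f"got {len(labels)} labels for {len(paths)} files"
        )
    trees, partition_of, sources = [], [], []
    for fi, path in enumerate(paths):
        label = labels[fi] if labels is not None else os.path.splitext(os.path.basename(path))[0]
        # Separate taxon namespaces per file: leaf-set agreement is checked
        # explicitly below so mismatches produce a precise error message.
        try:
            tl = dendropy.TreeList.get(path=path, schema="newick")
        except Exception as exc:  # dendropy raises several error types
            raise TreeSetError(f"malformed Newick in {path!r}: {exc}") from exc
        if len(tl) == 0:
            raise TreeSetError(f"no trees found in {path!r}")
        for ti, tree in enumerate(tl):
            if any(leaf.taxon is None for leaf in tree.leaf_node_iter()):
                raise TreeSetError(f"unlabeled leaf in {path!r}, tree {ti}")
            trees.append(tree)
            partition_of.append(label)
            sources.append(path)

    ref = _leaf_set(trees[0])
    for i, tree in enumerate(trees[1:], start=1):
        ls = _leaf_set(tree)
        if ls != ref:
            diff = sorted(ls.symmetric_difference(ref))
            raise TreeSetError(
                f"leaf-set mismatch in {sources[i]!r} (tree index {i}): "
                f"labels not shared by all trees: {diff}"
            )
    ts = TreeSet(
        trees=trees,
        leaf_labels=tuple(sorted(ref)),
        partition_of=partition_of,
        source_files=list(dict.fromkeys(paths)),
    )
    if len(ts) < 2:
        raise TreeSetError(f"a TreeSet needs at least 2 trees, got {len(ts)}")
    return ts


def write_treeset(ts, trees_path, labels_path=None):
    """Write all trees to one Newick file and, optionally, the partition table."""
    with open(trees_path, "w") as fh:
        for tree in ts.trees:
            fh.write(tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n")
    if labels_path is not None:
        write_partition_table(ts.partition_of, labels_path)


def read_partition_table(path):
    """Read a TSV with columns ``tree_index`` (0-based) and ``partition_label``.

    Returns a list mapping tree index -> label.  A header row is optional.
    """
    entries = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TreeSetError(
                    f"{path!r} line {lineno + 1}: expected 2 tab-separated columns"
                )
            if lineno == 0 and not parts[0].isdigit():
                continue  # header
            entries[int(parts[0])] = parts[1]
    n = len(entries)
    if sorted(entries) != list(range(n)):
        raise TreeSetError(f"{path!r}: tree indices must cover 0..{n - 1} exactly")
    return [entries[i] for i in range(n)]


def write_partition_table(partition_of, path):
    with open(path, "w") as fh:
        fh.write("tree_index\tpartition_label\n")
        for i, lab in enumerate(partition_of):
            fh.write(f"{i}\t{lab}\n")


def _leaf_bit_map(leaf_labels):
    return {lab: 1 << i for i, lab in enumerate(leaf_labels)}


def bipartitions(tree, leaf_labels=None):
    """The set of non-trivial splits of an unrooted topology, as bitmasks.

    Each internal edge of the unrooted tree cuts the leaves into two sides;
    the split is recorded as the bitmask of one side over the (sorted)
    ``leaf_labels`` ordering, complemented if necessary so the bit of the
    first leaf is 0.  Trivial splits (one side a single leaf) are omitted,
    so a binary unrooted tree on n leaves yields n - 3 splits and
    polytomies yield fewer.

    Parameters
    ----------
    tree : dendropy.Tree
    leaf_labels : tuple of str, optional
        Global leaf ordering; defaults to the sorted labels of this tree.
        Pass the TreeSet's ordering when comparing across trees.

    Returns
    -------
    frozenset of int
    """
    labels_here = sorted(l.taxon.label for l in tree.leaf_node_iter())
    if leaf_labels is None:
        leaf_labels = tuple(labels_here)
    elif sorted(leaf_labels) != labels_here:
        raise TreeSetError("tree leaf labels do not match the supplied ordering")
    n = len(leaf_labels)
    if n < 4:
        raise TreeSetError(f"no non-trivial splits on {n} < 4 leaves")
    bit = _leaf_bit_map(leaf_labels)
    full = (1 << n) - 1

    # Postorder accumulation of the leaf mask below each node; rooted
    # presentation is irrelevant because masks are complement-normalized
    # and collected into a set (a degree-2 root contributes duplicates).
    mask_below = {}
    splits = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            mask_below[node] = bit[node.taxon.label]
            continue
        m = 0
        for child in node.child_nodes():
            m |= mask_below[child]
        mask_below[node] = m
        if m == full:
            continue
        size = m.bit_count()
        if size < 2 or size > n - 2:
            continue
        if m & 1:
            m ^= full
        splits.add(m)
    return frozenset(splits)
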