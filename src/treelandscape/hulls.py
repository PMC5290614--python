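"""Convex-hull summaries of partition clusters in an embedded landscape.

Each data partition's embedded points are enclosed in a convex hull so
that the size and relative position of gene-tree clusters can be read
off a single landscape, and so that landscapes from different taxon sets
with matching partitions can be compared.  Two supporting operations
keep the hulls legible:

* **Outlier pruning** — a point is removed when excluding it drops the
  variance of the pairwise distances among the partition's points by
  more than a threshold fraction tau (default 0.01); pruning iterates
  greedily, largest drop first.
* **Separation** — hulls near the origin are revealed by translating
  each group rigidly by a distance s along the direction from the
  centroid of all points to the group centroid.  Within-group distances
  are preserved exactly, so hull shapes are unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

__all__ = [
    "GroupHull",
    "HullSummary",
    "prune_outliers",
    "convex_hull",
    "separate_hulls",
    "hull_summary",
]


@dataclass
class GroupHull:
    label: str
    retained: np.ndarray          # indices into the full embedding
    removed: np.ndarray
    points: np.ndarray            # retained coordinates (post-translation)
    facets: np.ndarray | None     # vertex-index triples/pairs into `points`
    centroid: np.ndarray
    degenerate: bool = False


@dataclass
class HullSummary:
    groups: list
    global_centroid: np.ndarray
    tau: float = 0.01
    separation: float = 0.0

    def group(self, label):
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(label)


def _pairwise_variance(points):
    if len(points) < 2:
        return 0.0
    return float(np.var(pdist(points)))


def prune_outliers(points, tau=0.01, centroid_based=False, absolute=False):
    """Iteratively remove points whose exclusion drops the distance variance.

    At each step let v be the variance of all pairwise Euclidean
    distances among the current points and v_q the same variance with
    point q's pairs excluded.  If the largest decrease exceeds the
    threshold — relative, (v - v_q)/v > tau, by default; absolute,
    v - v_q > tau, with ``absolute=True`` — that point is removed (ties
    toward the lowest index) and the step repeats.  ``centroid_based``
    uses the variance of distances to the group centroid instead.

    Returns (retained_indices, removed_indices).  Groups that would
    shrink below 3 points stop pruning; an all-coincident group (v = 0)
    removes nothing.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 points to prune")
    if tau <= 0:
        raise ValueError("tau must be positive")
    alive = list(range(n))
    removed = []

    def variance(idx):
        sub = pts[idx]
        if centroid_based:
            c = sub.mean(axis=0)
            return float(np.var(np.linalg.norm(sub - c, axis=1)))
        return _pairwise_variance(sub)

    while len(alive) > 3:
        v = variance(alive)
        if v <= 0:
            break
        best_q, best_drop = None, -np.inf
        for pos, q in enumerate(alive):
            rest = alive[:pos] + alive[pos + 1:]
            drop = v - variance(rest)
            if not absolute:
                drop = drop / v
            if drop > best_drop + 1e-15:
                best_q, best_drop = q, drop
        if best_drop > tau:
            alive.remove(best_q)
            removed.append(best_q)
        else:
            break
    return np.array(alive, dtype=int), np.array(removed, dtype=int)


def convex_hull(points, p=None):
    """Hull facets of a point set; degenerate sets fall back gracefully.

    Returns (facets, degenerate): facets is an array of vertex-index
    simplices into ``points`` (None when fewer than 3 points), and
    degenerate is True when the points do not span the ambient dimension
    (collinear / coplanar), in which case the hull is computed in the
    spanned subspace.
    """
    pts = np.asarray(points, dtype=float)
    if p is None:
        p = pts.shape[1]
    if len(pts) < 3:
        return None, True
    try:
        hull = ConvexHull(pts)
        return hull.simplices.copy(), False
    except QhullError:
        pass
    # rank-deficient: project onto the affine subspace actually spanned
    c = pts.mean(axis=0)
    U, s, Vt = np.linalg.svd(pts - c, full_matrices=False)
    rank = int(np.sum(s > 1e-9 * max(s[0], 1e-30)))
    if rank < 1:
        return None, True
    proj = (pts - c) @ Vt[:rank].T
    if rank == 1:
        o = np.argsort(proj[:, 0])
        return np.array([[o[0], o[-1]]]), True
    try:
        hull = ConvexHull(proj)
        return hull.simplices.copy(), True
    except QhullError:
        return None, True


def hull_summary(X, labels, tau=0.01, centroid_based=False, absolute=False):
    """Prune and hull each partition's points of an embedding."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    groups = []
    for lab in dict.fromkeys(labels.tolist()):
        idx = np.flatnonzero(labels == lab)
        pts = X[idx]
        if len(idx) >= 3:
            keep_local, drop_local = prune_outliers(
                pts, tau=tau, centroid_based=centroid_based, absolute=absolute)
        else:
            keep_local = np.arange(len(idx))
            drop_local = np.array([], dtype=int)
        kept = pts[keep_local]
        facets, degen = convex_hull(kept) if len(kept) >= 3 else (None, True)
        groups.append(GroupHull(
            label=str(lab), retained=idx[keep_local], removed=idx[drop_local],
            points=kept, facets=facets, centroid=kept.mean(axis=0),
            degenerate=degen,
        ))
    all_retained = np.vstack([g.points for g in groups])
    return HullSummary(groups=groups, global_centroid=all_retained.mean(axis=0),
                       tau=tau, separation=0.0)


def separate_hulls(summary, s):
    """Translate each group rigidly away from the overall centroid by s.

    Groups move along the unit vector from the global centroid to their
    own centroid; a group sitting exactly on the global centroid stays
    put.  The move is rigid: within-group pairwise distances are
    preserved (to floating-point roundoff) and the translation is
    reversible.
    """
    if s < 0:
        raise ValueError("separation distance must be >= 0")
    c = summary.global_centroid
    new_groups = []
    for g in summary.groups:
        direction = g.centroid - c
        norm = np.linalg.norm(direction)
        shift = np.zeros_like(c) if (norm == 0 or s == 0) else s * direction / norm
        new_groups.append(GroupHull(
            label=g.label, retained=g.retained, removed=g.removed,
            points=g.points + shift, facets=g.facets,
            centroid=g.centroid + shift, degenerate=g.degenerate,
        ))
    return HullSummary(groups=new_groups, global_centroid=c,
                       tau=summary.tau, separation=summary.separation + s)


def summary_to_dict(summary):
    return {
        "tau": summary.tau,
        "separation": summary.separation,
        "global_centroid": summary.global_centroid.tolist(),
        "groups": [
            {
                "label": g.label,
                "retained": g.retained.tolist(),
                "removed": g.removed.tolist(),
                "centroid": g.centroid.tolist(),
                "facets": None if g.facets is None else g.facets.tolist(),
                "degenerate": bool(g.degenerate),
            }
            for g in summary.groups
        ],
    }


def plot_hulls(summary, path, title=None):
    """Render 2D or 3D hulls to a static image (PNG/SVG) via matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dim = len(summary.global_centroid)
    fig = plt.figure(figsize=(7, 6))
    if dim >= 3:
        ax = fig.add_subplot(111, projection="3d")
    else:
        ax = fig.add_subplot(111)
    cmap = plt.get_cmap("tab10")
    for gi, g in enumerate(summary.groups):
        color = cmap(gi % 10)
        pts = g.points
        if dim >= 3:
            ax.scatter(pts[:, 0], pts[:, 1], pts[:, 2], s=8, color=color, label=g.label)
            if g.facets is not None and not g.degenerate:
                from mpl_toolkits.mplot3d.art3d import Poly3DCollection
                polys = [pts[f] for f in g.facets]
                ax.add_collection3d(Poly3DCollection(polys, alpha=0.15, facecolor=color))
        else:
            ax.scatter(pts[:, 0], pts[:, 1], s=8, color=color, label=g.label)
            if g.facets is not None and not g.degenerate:
                for f in g.facets:
                    seg = pts[f]
                    ax.plot(seg[:, 0], seg[:, 1], color=color, lw=1)
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
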