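"""Trajectory clustering in the PC1–PC2 plane and branch classification.

Whole trajectories (not their means) are compared: the plane is partitioned
into a shared 10 × 10 grid over the pooled projections, each trajectory
becomes an occupancy count grid, and the Bhattacharyya coefficient

    BC(p, q) = Σ_i √(p_i · q_i)        (counts, so 0 ≤ BC ≤ N)

measures the overlap between two trajectories with N frames each.  N − BC is
the inter-trajectory distance; it is 0 iff the grids are identical and N for
disjoint supports, but it is not a metric (no triangle inequality).  The
distance matrix is clustered with UPGMA (average linkage over the original
distances), which yields an ultrametric rooted tree, serialized as Newick.

Classification reads the tree relative to the wild type: the root splits the
leaves into the WT-side subtree and a far subtree, the far subtree splits
once more, and the "distal" branch — the one whose members lie farthest from
the WT — is called affected (rule ``distal_affected``), or everything outside
the WT-containing branch is called affected (rule ``proximal_unaffected``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "CountGrid",
    "DistanceMatrix",
    "TreeNode",
    "grid_histogram",
    "bhattacharyya_distance_matrix",
    "upgma",
    "write_newick",
    "read_newick",
    "cophenetic_distances",
    "classify_by_branch",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    x_min: float
    x_max: float
    y_min: float
    y_max: float
    nx: int = 10
    ny: int = 10

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("grid bounds must have positive extent")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one bin per axis")

    @property
    def x_edges(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.nx + 1)

    @property
    def y_edges(self) -> np.ndarray:
        return np.linspace(self.y_min, self.y_max, self.ny + 1)


@dataclass
class CountGrid:
    variant: str
    counts: np.ndarray  # (nx, ny) non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or (self.counts < 0).any():
            raise ValueError("counts must be a non-negative 2-D array")

    @property
    def N(self) -> int:
        return int(self.counts.sum())


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if np.isnan(self.values).any() or (self.values < -1e-9).any():
            raise ValueError("distances must be finite and non-negative")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("distance matrix must have a zero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def distance(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def _split_projections(projections) -> dict[str, np.ndarray]:
    if isinstance(projections, pd.DataFrame):
        cols = ["PC1", "PC2"] if "PC1" in projections.columns else list(projections.columns[:2])
        return {
            str(vid): sub[cols].to_numpy(dtype=float)
            for vid, sub in projections.groupby(level="variant", sort=False)
        }
    return {str(k): np.asarray(v, dtype=float)[:, :2] for k, v in projections.items()}


def grid_histogram(
    projections, nx: int = 10, ny: int = 10
) -> tuple[GridSpec, dict[str, CountGrid]]:
    """Occupancy count grids over a common partition of the PC1–PC2 plane.

    Bounds are the global min/max over the pooled points of *all* variants —
    the histograms must share bins for the overlap coefficient to mean
    anything.  Bins are half-open with the top/right edge closed, so every
    point is counted exactly once.
    """
    pts = _split_projections(projections)
    if not pts or any(len(v) == 0 for v in pts.values()):
        raise ValueError("every variant needs at least one projected point")
    pooled = np.vstack(list(pts.values()))
    lo, hi = pooled.min(axis=0), pooled.max(axis=0)
    for ax in (0, 1):
        if hi[ax] <= lo[ax]:
            eps = max(abs(lo[ax]), 1.0) * 1e-9
            lo[ax] -= eps
            hi[ax] += eps
            warnings.warn(f"degenerate bounds on axis {ax}; expanded by epsilon")
    spec = GridSpec(float(lo[0]), float(hi[0]), float(lo[1]), float(hi[1]), nx, ny)
    grids = {}
    for vid, xy in pts.items():
        counts, _, _ = np.histogram2d(
            xy[:, 0], xy[:, 1], bins=[spec.x_edges, spec.y_edges]
        )
        grids[vid] = CountGrid(vid, counts.astype(int))
    return spec, grids


def bhattacharyya_distance_matrix(grids: list[CountGrid]) -> DistanceMatrix:
    """Pairwise N − BC distances between occupancy grids of equal N."""
    if len(grids) < 2:
        raise ValueError("need at least two grids")
    Ns = {g.N for g in grids}
    if len(Ns) != 1:
        raise ValueError(f"grids have unequal totals {sorted(Ns)}; distances incomparable")
    N = Ns.pop()
    labels = [g.variant for g in grids]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate grid labels")
    flat = np.stack([np.sqrt(g.counts.astype(float).ravel()) for g in grids])
    bc = flat @ flat.T  # BC(p,q) = Σ √p_i √q_i
    d = N - bc
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    return DistanceMatrix(labels, (d + d.T) / 2.0)


# -- UPGMA --------------------------------------------------------------------


@dataclass(frozen=True)
class TreeNode:
    """Rooted ultrametric tree node; leaves have height 0."""

    height: float
    label: str | None = None
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Unweighted pair-group clustering with arithmetic mean.

    Inter-cluster distance is the mean over all cross pairs of the original
    distances; the merge height is half the merge distance, so the tree is
    ultrametric by construction.  Tied merges are broken by the lexicographic
    order of the clusters' representative (smallest) labels, making the tree
    deterministic.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least two labels")
    D = dm.values
    clusters: dict[int, dict] = {
        i: {"members": [i], "node": TreeNode(0.0, label=dm.labels[i]), "rep": dm.labels[i]}
        for i in range(n)
    }
    next_id = n
    while len(clusters) > 1:
        best = None
        ids = sorted(clusters)
        for ii, a in enumerate(ids):
            for b in ids[ii + 1:]:
                ma, mb = clusters[a]["members"], clusters[b]["members"]
                d = D[np.ix_(ma, mb)].mean()
                reps = tuple(sorted((clusters[a]["rep"], clusters[b]["rep"])))
                key = (d, reps)
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _), a, b = best
        ca, cb = clusters.pop(a), clusters.pop(b)
        # deterministic child order: representative label
        kids = sorted((ca, cb), key=lambda c: c["rep"])
        node = TreeNode(
            height=d / 2.0,
            children=tuple(c["node"] for c in kids),
        )
        clusters[next_id] = {
            "members": ca["members"] + cb["members"],
            "node": node,
            "rep": min(ca["rep"], cb["rep"]),
        }
        next_id += 1
    return next(iter(clusters.values()))["node"]


def write_newick(tree: TreeNode) -> str:
    """Newick string with branch lengths (parseable by standard readers)."""

    def _fmt(node: TreeNode, parent_height: float) -> str:
        bl = parent_height - node.height
        if node.is_leaf:
            return f"{node.label}:{bl:g}"
        inner = ",".join(_fmt(c, node.height) for c in node.children)
        return f"({inner}):{bl:g}"

    if tree.is_leaf:
        return f"{tree.label};"
    inner = ",".join(_fmt(c, tree.height) for c in tree.children)
    return f"({inner});"


def read_newick(text: str) -> TreeNode:
    """Parse a Newick string (with branch lengths) back into an ultrametric
    :class:`TreeNode`; node heights are recovered from leaf depths."""
    import dendropy

    dtree = dendropy.Tree.get(data=text, schema="newick")

    def _depths(node, depth, out):
        for ch in node.child_nodes():
            _depths(ch, depth + (ch.edge.length or 0.0), out)
        if node.is_leaf():
            out[node] = depth
        return out

    leaf_depths = _depths(dtree.seed_node, 0.0, {})
    root_height = max(leaf_depths.values())

    def _convert(node, depth) -> TreeNode:
        if node.is_leaf():
            return TreeNode(0.0, label=node.taxon.label.replace(" ", "_"))
        kids = tuple(
            _convert(ch, depth + (ch.edge.length or 0.0)) for ch in node.child_nodes()
        )
        return TreeNode(root_height - depth, children=kids)

    return _convert(dtree.seed_node, 0.0)


def cophenetic_distances(tree: TreeNode) -> pd.DataFrame:
    """Leaf-pair distances implied by the tree (2 × merge height)."""
    leaves = tree.leaves()
    idx = {l: i for i, l in enumerate(leaves)}
    M = np.zeros((len(leaves), len(leaves)))

    def _walk(node: TreeNode) -> list[str]:
        if node.is_leaf:
            return [node.label]
        groups = [_walk(c) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        M[idx[a], idx[b]] = M[idx[b], idx[a]] = 2.0 * node.height
        return [l for g in groups for l in g]

    _walk(tree)
    return pd.DataFrame(M, index=leaves, columns=leaves)


def classify_by_branch(
    tree: TreeNode,
    wt_label: str,
    rule: str = "distal_affected",
    *,
    distances: DistanceMatrix | None = None,
) -> dict[str, str]:
    """Binary affected/unaffected calls from the tree topology.

    The root separates the WT-side subtree from the far subtree; splitting
    the far subtree once more yields three branches in total.  The distal
    branch is the one maximizing the mean distance of its members to the
    wild type — measured on the original distance matrix when provided
    (cophenetic distances cannot distinguish the two far branches, which sit
    at the same root height), otherwise on cophenetic distances with
    deterministic tie-breaking.

    ``distal_affected``: distal-branch members are affected, all others
    unaffected.  ``proximal_unaffected``: WT-branch members are unaffected,
    all others affected.  The WT itself is excluded from the output.
    """
    if rule not in ("distal_affected", "proximal_unaffected"):
        raise ValueError(f"unknown rule {rule!r}")
    leaves = tree.leaves()
    if wt_label not in leaves:
        raise ValueError(f"wild type {wt_label!r} is not a leaf of the tree")
    if len(leaves) < 4:
        raise ValueError("need at least 4 leaves to classify")
    if tree.is_leaf or len(tree.children) != 2:
        raise ValueError("rooted binary tree required")
    c1, c2 = tree.children
    if wt_label in c1.leaves():
        wt_side, far = c1, c2
    else:
        wt_side, far = c2, c1
    wt_branch = set(wt_side.leaves())
    if far.is_leaf:
        warnings.warn("far subtree is a single leaf; branches degenerate")
        branches = [wt_branch, {far.label}, set()]
    else:
        branches = [wt_branch, set(far.children[0].leaves()), set(far.children[1].leaves())]

    coph = cophenetic_distances(tree)

    def _mean_dist_to_wt(branch: set[str]) -> float:
        members = sorted(branch - {wt_label})
        if not members:
            return -np.inf
        if distances is not None:
            return float(np.mean([distances.distance(wt_label, m) for m in members]))
        return float(coph.loc[wt_label, members].mean())

    scored = sorted(
        (b for b in branches if b),
        key=lambda b: (-_mean_dist_to_wt(b), sorted(b - {wt_label}) or [""]),
    )
    distal = scored[0]
    calls: dict[str, str] = {}
    for leaf in leaves:
        if leaf == wt_label:
            continue
        if rule == "distal_affected":
            calls[leaf] = "affected" if leaf in distal else "unaffected"
        else:
            calls[leaf] = "unaffected" if leaf in wt_branch else "affected"
    return calls
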