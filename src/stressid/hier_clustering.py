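"""Two-phase hierarchical clustering: divide, then agglomerate.

The dividing phase recursively cuts a class in two at a histogram valley of
one of its dimensions, producing a binary split tree whose leaves may
over-segment the data.  The agglomerating phase walks that tree bottom-up,
deepest splits first, re-merging sibling subclasses whose union no longer
admits a valid split.

Split selection
---------------
For every dimension the class's values are binned into ``B`` equal-width
bins over the class's own range.  A candidate split is an interior local
minimum (valley) of the moving-average-smoothed counts that is

* below the class's mean per-bin count ``n / B``, and
* significantly below both flanking peaks: ``min(peak_l, peak_r) - valley``
  must exceed ``valley_z * sqrt(min(peak_l, peak_r))``, a Poisson-noise
  yardstick that rejects sampling dips in unimodal data.

The threshold ``h`` is the median of the values inside the valley bin, and
the cut sends ``value <= h`` left and ``value > h`` right.  A candidate is
valid only if each resulting subclass keeps a peak of its own: its maximum
bin count (on the parent's bin edges) must exceed ``n / B``.  Among valid
candidates the deepest valley wins; ties break toward the lowest dimension
index, then the lowest bin index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data_model import Dataset, Partition

__all__ = [
    "Histogram",
    "SplitPosition",
    "ClusterConfig",
    "ClusterNode",
    "ClusterTree",
    "build_histogram",
    "find_split",
    "split_class",
    "dividing_phase",
    "merge_condition",
    "agglomerating_phase",
    "cluster",
    "tree_to_json",
    "tree_to_dot",
]


@dataclass(frozen=True)
class Histogram:
    """Equal-width histogram of one dimension of one class.

    ``dim`` is 1-based.  ``medians`` holds the median value inside each bin
    (NaN for empty bins).  ``degenerate`` flags an all-identical column, in
    which case there is a single effective bin.
    """

    dim: int
    edges: np.ndarray
    counts: np.ndarray
    medians: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and np.any(np.diff(self.edges) <= 0):
            raise ValueError("histogram edges must be strictly increasing")


@dataclass(frozen=True)
class SplitPosition:
    """A cut ``(dim, threshold)``: dimension index (1-based) and the value
    ``h`` splitting the class into ``<= h`` and ``> h`` sides."""

    dim: int
    threshold: float
    bin_index: int


@dataclass(frozen=True)
class ClusterConfig:
    """Tuning knobs for both phases.

    ``seed`` is recorded for provenance only; the algorithm is
    deterministic.
    """

    bins: int = 16
    min_cluster_size: int = 2
    smoothing_window: int = 3
    valley_z: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd integer")
        if self.valley_z < 0:
            raise ValueError("valley_z must be >= 0")


@dataclass(eq=False)
class ClusterNode:
    """One node of the binary split tree.

    ``split_level`` is 1 at the root and increases by one per split.  The
    display ``tag`` follows the level-digit scheme ("1", "12", "123", ...);
    the tree structure itself is authoritative.
    """

    members: tuple[str, ...]
    split_level: int
    parent: Optional["ClusterNode"] = None
    children: tuple["ClusterNode", "ClusterNode"] | None = None
    split: SplitPosition | None = None
    merged: bool = False

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def tag(self) -> str:
        return "".join(str(level) for level in range(1, self.split_level + 1))

    def leaves(self) -> list["ClusterNode"]:
        if self.is_leaf:
            return [self]
        out: list[ClusterNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def set_children(self, left: "ClusterNode", right: "ClusterNode") -> None:
        if not left.members or not right.members:
            raise ValueError("children must be non-empty")
        if set(left.members) | set(right.members) != set(self.members) or set(
            left.members
        ) & set(right.members):
            raise ValueError("children must partition the parent's members")
        left.parent = right.parent = self
        self.children = (left, right)


@dataclass
class ClusterTree:
    """Binary split tree over a dataset; leaves partition the samples."""

    root: ClusterNode
    dataset: Dataset

    @property
    def max_level(self) -> int:
        return max(leaf.split_level for leaf in self.root.leaves())

    def leaves(self) -> list[ClusterNode]:
        return self.root.leaves()

    def partition(self) -> Partition:
        part = Partition([leaf.members for leaf in self.leaves()])
        part.validate_against(self.dataset)
        return part


# ---------------------------------------------------------------------------
# histogram machinery
# ---------------------------------------------------------------------------

def _column(class_members: Dataset | np.ndarray, dim: int) -> np.ndarray:
    values = (
        class_members.values
        if isinstance(class_members, Dataset)
        else np.asarray(class_members, dtype=float)
    )
    if values.ndim != 2:
        raise ValueError("expected a 2-D score matrix")
    if not 1 <= dim <= values.shape[1]:
        raise ValueError(f"dimension {dim} out of range 1..{values.shape[1]}")
    return values[:, dim - 1]


def build_histogram(
    class_members: Dataset | np.ndarray, dim: int, bins: int
) -> Histogram:
    """Equal-width histogram of dimension ``dim`` (1-based) of a class.

    Bins cover the class's own ``[min, max]``; the last bin is right-closed
    so every sample is counted exactly once.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    vals = _column(class_members, dim)
    if vals.size == 0:
        raise ValueError("cannot build a histogram of an empty class")
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        return Histogram(
            dim=dim,
            edges=np.array([lo, hi]),
            counts=np.array([vals.size]),
            medians=np.array([lo]),
            degenerate=True,
        )
    edges = np.linspace(lo, hi, bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    medians = np.full(bins, np.nan)
    for b in range(bins):
        in_bin = _bin_mask(vals, edges, b)
        if in_bin.any():
            medians[b] = float(np.median(vals[in_bin]))
    return Histogram(dim=dim, edges=edges, counts=counts, medians=medians)


def _bin_mask(vals: np.ndarray, edges: np.ndarray, b: int) -> np.ndarray:
    last = b == len(edges) - 2
    upper = vals <= edges[b + 1] if last else vals < edges[b + 1]
    return (vals >= edges[b]) & upper


def _smooth(counts: np.ndarray, window: int) -> np.ndarray:
    counts = counts.astype(float)
    if window <= 1 or counts.size < 3:
        return counts
    pad = window // 2
    padded = np.pad(counts, pad, mode="edge")
    return np.convolve(padded, np.ones(window) / window, mode="valid")


# ---------------------------------------------------------------------------
# dividing phase
# ---------------------------------------------------------------------------

def find_split(
    class_members: Dataset | np.ndarray, config: ClusterConfig | None = None
) -> SplitPosition | None:
    """Best valid split of a class, or ``None`` if no candidate qualifies.

    See the module docstring for the candidate and validity rules.  Absence
    of a split is a normal outcome, not an error.
    """
    config = config or ClusterConfig()
    values = (
        class_members.values
        if isinstance(class_members, Dataset)
        else np.atleast_2d(np.asarray(class_members, dtype=float))
    )
    n, d = values.shape
    if n < 2 * config.min_cluster_size:
        return None
    B = config.bins
    mean_parent = n / B
    best: tuple | None = None
    for dim in range(1, d + 1):
        hist = build_histogram(values, dim, B)
        if hist.degenerate:
            continue
        vals = values[:, dim - 1]
        smoothed = _smooth(hist.counts, config.smoothing_window)
        for b in range(1, B - 1):
            if not _is_valley(smoothed, b):
                continue
            peak_l = smoothed[:b].max()
            peak_r = smoothed[b + 1:].max()
            peak_min = min(peak_l, peak_r)
            if smoothed[b] >= mean_parent:
                continue
            if peak_min - smoothed[b] <= config.valley_z * np.sqrt(peak_min):
                continue
            h = hist.medians[b]
            if np.isnan(h):  # empty valley bin: cut at its midpoint
                h = 0.5 * (hist.edges[b] + hist.edges[b + 1])
            left = vals <= h
            n1 = int(left.sum())
            n2 = n - n1
            if n1 < config.min_cluster_size or n2 < config.min_cluster_size:
                continue
            ok = True
            for mask in (left, ~left):
                sub_counts, _ = np.histogram(vals[mask], bins=hist.edges)
                if sub_counts.max() <= mean_parent:
                    ok = False
                    break
            if not ok:
                continue
            depth = peak_min - smoothed[b]
            key = (depth, -dim, -b)
            if best is None or key > best[0]:
                best = (key, SplitPosition(dim=dim, threshold=float(h), bin_index=b))
    return None if best is None else best[1]


def _is_valley(smoothed: np.ndarray, b: int) -> bool:
    return (
        smoothed[b] <= smoothed[b - 1]
        and smoothed[b] <= smoothed[b + 1]
        and (smoothed[b] < smoothed[b - 1] or smoothed[b] < smoothed[b + 1])
    )


def split_class(
    class_members: Dataset, pos: SplitPosition
) -> tuple[Dataset, Dataset]:
    """Cut a class at ``pos``: samples with value ``<= h`` in the split
    dimension go left, the rest right.  Both sides must be non-empty."""
    vals = _column(class_members, pos.dim)
    left = vals <= pos.threshold
    n1 = int(left.sum())
    if n1 == 0 or n1 == len(vals):
        raise ValueError(
            f"empty subclass: threshold {pos.threshold} in dim {pos.dim} "
            "does not separate the class"
        )
    idx = np.arange(len(vals))
    return class_members.take(idx[left]), class_members.take(idx[~left])


def dividing_phase(ds: Dataset, config: ClusterConfig | None = None) -> ClusterTree:
    """Recursively split the dataset until no leaf admits a valid split."""
    if ds.n == 0:
        raise ValueError("empty dataset")
    config = config or ClusterConfig()
    id_row = {sid: i for i, sid in enumerate(ds.ids)}
    root = ClusterNode(members=tuple(ds.ids), split_level=1)
    queue: list[ClusterNode] = [root]
    while queue:
        node = queue.pop(0)
        rows = [id_row[sid] for sid in node.members]
        sub = ds.values[rows]
        pos = find_split(sub, config)
        if pos is None:
            continue
        vals = sub[:, pos.dim - 1]
        left_mask = vals <= pos.threshold
        left_ids = tuple(sid for sid, m in zip(node.members, left_mask) if m)
        right_ids = tuple(sid for sid, m in zip(node.members, left_mask) if not m)
        node.split = pos
        left = ClusterNode(members=left_ids, split_level=node.split_level + 1)
        right = ClusterNode(members=right_ids, split_level=node.split_level + 1)
        node.set_children(left, right)
        queue.append(left)
        queue.append(right)
    return ClusterTree(root=root, dataset=ds)


# ---------------------------------------------------------------------------
# agglomerating phase
# ---------------------------------------------------------------------------

def merge_condition(
    ds: Dataset,
    c1: ClusterNode,
    c2: ClusterNode,
    config: ClusterConfig | None = None,
) -> bool:
    """Two sibling subclasses merge iff their union cannot be re-split.

    Symmetric in its arguments: the union of members is tested with the same
    dividing criterion used to create the tree.
    """
    config = config or ClusterConfig()
    union = dict.fromkeys(c1.members)
    union.update(dict.fromkeys(c2.members))
    id_row = {sid: i for i, sid in enumerate(ds.ids)}
    rows = [id_row[sid] for sid in union]
    return find_split(ds.values[rows], config) is None


def agglomerating_phase(
    tree: ClusterTree, config: ClusterConfig | None = None
) -> Partition:
    """Bottom-up merge pass over a split tree.

    Sibling pairs are examined in strictly decreasing split-level order
    (deepest first).  A pair that meets the merge condition collapses into
    its parent, which then becomes a candidate leaf one level up; a pair
    that does not is sealed and its two nodes stand in for the parent from
    then on.  The pass ends at the root; the surviving leaves form the
    partition.
    """
    config = config or ClusterConfig()
    ds = tree.dataset
    max_level = tree.max_level
    sealed: set[int] = set()
    for level in range(max_level, 1, -1):
        parents = _mergeable_parents(tree.root, level, sealed)
        for parent in parents:
            left, right = parent.children
            if merge_condition(ds, left, right, config):
                parent.children = None
                parent.split = None
                parent.merged = True
            else:
                sealed.add(id(parent))
    return tree.partition()


def _mergeable_parents(
    node: ClusterNode, level: int, sealed: set[int]
) -> list[ClusterNode]:
    """Internal nodes (in creation order) whose children are both leaves at
    ``level`` and which have not been sealed by a refused merge."""
    if node.is_leaf:
        return []
    out: list[ClusterNode] = []
    left, right = node.children
    if (
        left.is_leaf
        and right.is_leaf
        and left.split_level == level
        and id(node) not in sealed
    ):
        out.append(node)
    out.extend(_mergeable_parents(left, level, sealed))
    out.extend(_mergeable_parents(right, level, sealed))
    return out


def cluster(
    ds: Dataset, config: ClusterConfig | None = None
) -> tuple[Partition, ClusterTree]:
    """Full pipeline: dividing phase followed by the agglomerating phase.

    Deterministic: identical ``(dataset, config)`` give identical output.
    """
    config = config or ClusterConfig()
    tree = dividing_phase(ds, config)
    partition = agglomerating_phase(tree, config)
    return partition, tree


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def _node_to_dict(node: ClusterNode) -> dict:
    out: dict = {
        "split_level": node.split_level,
        "tag": node.tag,
        "size": len(node.members),
    }
    if node.is_leaf:
        out["members"] = list(node.members)
        if node.merged:
            out["merged"] = True
    else:
        out["split"] = {
            "dim": node.split.dim,
            "threshold": node.split.threshold,
            "bin_index": node.split.bin_index,
        }
        out["children"] = [_node_to_dict(c) for c in node.children]
    return out


def tree_to_json(tree: ClusterTree, indent: int | None = 2) -> str:
    """Nested-JSON rendering of the split tree."""
    return json.dumps(_node_to_dict(tree.root), indent=indent)


def tree_to_dot(tree: ClusterTree) -> str:
    """GraphViz DOT rendering of the split tree (display only)."""
    lines = ["digraph split_tree {", "  node [shape=box];"]
    counter = [0]

    def walk(node: ClusterNode) -> int:
        my_id = counter[0]
        counter[0] += 1
        label = f"{node.tag}\\nn={len(node.members)}"
        if node.split is not None:
            label += f"\\ndim {node.split.dim} <= {node.split.threshold:.3g}"
        lines.append(f'  n{my_id} [label="{label}"];')
        if not node.is_leaf:
            for child in node.children:
                child_id = walk(child)
                lines.append(f"  n{my_id} -> n{child_id};")
        return my_id

    walk(tree.root)
    lines.append("}")
    return "\n".join(lines)
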