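"""Dynamic hybrid cutting of a hierarchical clustering tree.

Walks the merge sequence of an (average-linkage) dendrogram bottom-up and
closes a branch as a cluster when it is large enough, has a tightly merging
core, and joins the rest of the tree far above that core. The stringency of
the core-tightness and gap criteria is controlled by ``deep_split`` (0-4;
larger = more, smaller clusters), using the published parameterization
maxCoreScatter in {0.64, 0.73, 0.82, 0.91, 0.95} and
minGap = 0.75 * (1 - maxCoreScatter), both taken relative to the height
range between the 5th-percentile merge and the cut height.

Genes that only attach to a branch near the top of the tree (above the
absolute core-scatter limit) are trimmed from the cluster; a trimmed cluster
falling below ``min_cluster_size`` is discarded entirely. This keeps
background genes that glue onto a genuine branch late, and undersized planted
blocks padded with noise, out of the labelled modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

_MAX_CORE_SCATTER = (0.64, 0.73, 0.82, 0.91, 0.95)


@dataclass
class _Branch:
    members: list[int] = field(default_factory=list)
    attach_heights: list[float] = field(default_factory=list)
    basic: bool = True


def _core_size(branch_size: int, min_cluster_size: int) -> int:
    base = min_cluster_size // 2 + 1
    if base < branch_size:
        return int(base + math.sqrt(branch_size - base))
    return branch_size


def _core_scatter(branch: _Branch, min_cluster_size: int) -> float:
    h = np.sort(np.asarray(branch.attach_heights))
    core = _core_size(len(h), min_cluster_size)
    return float(h[:core].mean())


def _qualifies(
    branch: _Branch,
    attach_height: float,
    min_cluster_size: int,
    max_abs_core_scatter: float,
    min_abs_gap: float,
) -> bool:
    if not branch.basic or len(branch.members) < min_cluster_size:
        return False
    scatter = _core_scatter(branch, min_cluster_size)
    if scatter > max_abs_core_scatter:
        return False
    return (attach_height - scatter) > min_abs_gap


def cut_tree_hybrid(
    linkage: np.ndarray,
    min_cluster_size: int = 50,
    deep_split: int = 3,
    cut_height: float | None = None,
) -> np.ndarray:
    """Cluster labels (0 = unassigned) for the leaves of a scipy linkage.

    Parameters
    ----------
    linkage : (n-1, 4) scipy linkage matrix, heights non-decreasing
        (guaranteed for average linkage).
    min_cluster_size : minimum number of leaves for a cluster.
    deep_split : 0-4 sensitivity of branch splitting.
    cut_height : heights above this never join branches; default is 99% of
        the maximum merge height.
    """
    if not 0 <= deep_split <= 4:
        raise ValueError("deep_split must be in 0..4")
    linkage = np.asarray(linkage, dtype=float)
    n = linkage.shape[0] + 1
    if n < 2:
        return np.zeros(n, dtype=int)
    heights = linkage[:, 2]
    if cut_height is None:
        cut_height = 0.99 * float(heights.max())
    ref_height = float(np.quantile(heights, 0.05))
    span = max(cut_height - ref_height, 1e-12)
    max_core_scatter = _MAX_CORE_SCATTER[deep_split]
    min_gap = 0.75 * (1.0 - max_core_scatter)
    max_abs_core_scatter = ref_height + max_core_scatter * span
    min_abs_gap = min_gap * span

    nodes: dict[int, _Branch] = {}
    clusters: list[_Branch] = []

    def close(branch: _Branch, attach: float) -> None:
        if _qualifies(branch, attach, min_cluster_size, max_abs_core_scatter, min_abs_gap):
            clusters.append(branch)

    def get(idx: int, h: float) -> _Branch:
        if idx < n:
            return _Branch(members=[idx], attach_heights=[h])
        return nodes[idx]

    for k in range(n - 1):
        a, b = int(linkage[k, 0]), int(linkage[k, 1])
        h = float(heights[k])
        ba, bb = get(a, h), get(b, h)
        if h > cut_height:
            # branches never join above the cut; finalize both sides
            for br in (ba, bb):
                if len(br.members) > 1:
                    close(br, cut_height)
            nodes[n + k] = _Branch(
                members=ba.members + bb.members,
                attach_heights=ba.attach_heights + bb.attach_heights,
                basic=False,
            )
            nodes.pop(a, None)
            nodes.pop(b, None)
            continue

        singles = (len(ba.members) == 1, len(bb.members) == 1)
        if all(singles):
            merged = _Branch(members=ba.members + bb.members, attach_heights=[h, h])
        elif any(singles):
            leaf, branch = (ba, bb) if singles[0] else (bb, ba)
            branch.members.append(leaf.members[0])
            branch.attach_heights.append(h)
            merged = branch
        else:
            qa = _qualifies(ba, h, min_cluster_size, max_abs_core_scatter, min_abs_gap)
            qb = _qualifies(bb, h, min_cluster_size, max_abs_core_scatter, min_abs_gap)
            if qa and qb:
                # two complete clusters meet: close both; the join itself is
                # no longer a cluster candidate (eigengene merging downstream
                # re-unites over-split branches)
                clusters.append(ba)
                clusters.append(bb)
                merged = _Branch(
                    members=ba.members + bb.members,
                    attach_heights=ba.attach_heights + bb.attach_heights,
                    basic=False,
                )
            elif not (ba.basic and bb.basic):
                # joining a composite that already closed clusters: a basic
                # side may still end here as a cluster of its own
                if qa:
                    clusters.append(ba)
                if qb:
                    clusters.append(bb)
                merged = _Branch(
                    members=ba.members + bb.members,
                    attach_heights=ba.attach_heights + bb.attach_heights,
                    basic=False,
                )
            else:
                # at most one side qualifies: absorb and keep growing; noise
                # absorbed near the top is trimmed when the branch closes
                merged = _Branch(
                    members=ba.members + bb.members,
                    attach_heights=ba.attach_heights + bb.attach_heights,
                )
        nodes[n + k] = merged
        nodes.pop(a, None)
        nodes.pop(b, None)

    # whatever survives to the root may still be a cluster
    for br in nodes.values():
        if len(br.members) > 1:
            close(br, cut_height)

    labels = np.zeros(n, dtype=int)
    next_label = 1
    for br in clusters:
        members = np.asarray(br.members)
        attach = np.asarray(br.attach_heights)
        keep = members[attach <= max_abs_core_scatter]
        if len(keep) < min_cluster_size:
            continue
        free = keep[labels[keep] == 0]
        if len(free) < min_cluster_size:
            continue
        labels[free] = next_label
        next_label += 1
    return labels
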