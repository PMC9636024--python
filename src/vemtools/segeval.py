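"""Skeleton-based segmentation evaluation and consensus building.

Candidate neurite segmentations are scored against ground-truth skeletons
(edge accuracy: every skeleton edge is correct, split, merged or omitted),
screened for merge errors with annotated point pairs lying in different
but adjacent neurites, combined by oversegmentation consensus (segments =
connected regions where two segmentations agree on co-membership), cleaned
by filling enclosed background and absorbing fully contained segments, and
finally the best-performing pair of candidates is selected to form the
base segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage
from skimage import measure

from .skeleton import Skeleton
from .volume import Volume, connectivity_struct, _relabel_first_encounter

__all__ = [
    "EdgeAccuracyResult",
    "PairSeparationResult",
    "edge_accuracy",
    "pair_separation_count",
    "oversegmentation_consensus",
    "postprocess_segments",
    "select_checkpoint_pair",
]


@dataclass
class EdgeAccuracyResult:
    n_correct: int
    n_split: int
    n_merged: int
    n_omitted: int
    accuracy: float
    per_skeleton: dict[int, float]
    edge_classes: list[tuple[int, int, int, str]] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return self.n_correct + self.n_split + self.n_merged + self.n_omitted


@dataclass
class PairSeparationResult:
    n_separated: int
    merged_pairs: list[int]
    uninformative_pairs: list[int]


def _node_labels(skel: Skeleton, seg: Volume) -> dict[int, int]:
    ids = sorted(skel.nodes)
    if not ids:
        return {}
    idx = seg.world_to_index(skel.positions(ids))
    bad = [
        ids[i]
        for i in range(len(ids))
        if not all(0 <= idx[i][d] < seg.shape[d] for d in range(3))
    ]
    if bad:
        raise ValueError(f"skeleton nodes outside the volume: {bad[:10]}")
    labels = seg.data[idx[:, 0], idx[:, 1], idx[:, 2]]
    return dict(zip(ids, (int(v) for v in labels)))


def edge_accuracy(
    skeletons: list[Skeleton], seg: Volume, merged_witness: str = "node"
) -> EdgeAccuracyResult:
    """Classify every skeleton edge against a segmentation.

    An edge is *omitted* if either endpoint falls on background, *split* if
    its endpoints carry different nonzero labels, *merged* if the shared
    label also contains a node of a different skeleton, else *correct*.
    Accuracy pools edges over all skeletons; per-skeleton accuracies are
    also reported.  ``merged_witness="component"`` restricts the merge
    witness to the same connected component of the label's voxels.
    """
    node_lab = [_node_labels(s, seg) for s in skeletons]

    if merged_witness == "component":
        # witness key: (label, component id of the node's voxel)
        comp_cache: dict[int, np.ndarray] = {}

        def witness_key(si: int, node: int) -> tuple[int, int]:
            lab = node_lab[si][node]
            if lab not in comp_cache:
                comp_cache[lab], _ = ndimage.label(
                    seg.data == lab, structure=connectivity_struct(26)
                )
            idx = seg.world_to_index(skeletons[si].nodes[node])[0]
            return (lab, int(comp_cache[lab][tuple(idx)]))

    else:

        def witness_key(si: int, node: int) -> tuple[int, int]:
            return (node_lab[si][node], 0)

    # which skeletons place nodes in which witness region
    region_skels: dict[tuple[int, int], set[int]] = {}
    for si, labs in enumerate(node_lab):
        for node, lab in labs.items():
            if lab != 0:
                region_skels.setdefault(witness_key(si, node), set()).add(si)

    counts = {"correct": 0, "split": 0, "merged": 0, "omitted": 0}
    per_skel_counts: dict[int, list[int]] = {}
    classes = []
    for si, skel in enumerate(skeletons):
        ok = tot = 0
        for a, b in sorted(skel.edges):
            la, lb = node_lab[si][a], node_lab[si][b]
            if la == 0 or lb == 0:
                cls = "omitted"
            elif la != lb:
                cls = "split"
            else:
                key = witness_key(si, a)
                cls = "merged" if region_skels.get(key, {si}) - {si} else "correct"
            counts[cls] += 1
            tot += 1
            ok += cls == "correct"
            classes.append((si, a, b, cls))
        per_skel_counts[si] = [ok, tot]

    total = sum(counts.values())
    return EdgeAccuracyResult(
        n_correct=counts["correct"],
        n_split=counts["split"],
        n_merged=counts["merged"],
        n_omitted=counts["omitted"],
        accuracy=counts["correct"] / total if total else 0.0,
        per_skeleton={
            si: (c[0] / c[1] if c[1] else 0.0) for si, c in per_skel_counts.items()
        },
        edge_classes=classes,
    )


def pair_separation_count(
    seg: Volume, pairs: list[tuple[tuple[int, int, int], tuple[int, int, int]]]
) -> PairSeparationResult:
    """Count point pairs whose voxels carry two distinct nonzero segment ids.

    Pairs sharing a nonzero label are merged; pairs touching background are
    uninformative and reported separately.
    """
    n_sep, merged, uninf = 0, [], []
    for i, (p, q) in enumerate(pairs):
        lp = int(seg.data[tuple(p)])
        lq = int(seg.data[tuple(q)])
        if lp == 0 or lq == 0:
            uninf.append(i)
        elif lp == lq:
            merged.append(i)
        else:
            n_sep += 1
    return PairSeparationResult(n_sep, merged, uninf)


def oversegmentation_consensus(segA: Volume, segB: Volume, conn: int = 26) -> Volume:
    """Consensus of two segmentations of the same grid.

    A voxel is foreground iff nonzero in both inputs; output segments are
    the connected components of constant (labelA, labelB) pairs, relabeled
    deterministically in first-encounter raster order.  The result refines
    both inputs.
    """
    if not segA.same_grid(segB):
        raise ValueError("consensus requires segmentations on the same grid")
    a, b = segA.data, segB.data
    fg = (a != 0) & (b != 0)
    pair_code = np.zeros(a.shape, dtype=np.int64)
    if fg.any():
        stacked = np.stack([a[fg], b[fg]], axis=1)
        _, inv = np.unique(stacked, axis=0, return_inverse=True)
        pair_code[fg] = inv.reshape(-1) + 1
    skconn = {6: 1, 18: 2, 26: 3}[conn]
    labels = measure.label(pair_code, background=0, connectivity=skconn)
    return segA.like(_relabel_first_encounter(labels.astype(np.int32)))


def postprocess_segments(seg: Volume, conn_bg: int = 6) -> Volume:
    """Fill enclosed background and absorb fully contained segments.

    Background components not reachable from the volume border (under
    ``conn_bg`` connectivity) whose surrounding voxels all share one label
    are filled with that label.  A segment is absorbed into a neighbour
    when all of its adjacent foreground belongs to that single neighbour
    and none of its adjacent background reaches the border.  Both rules are
    applied iteratively to a fixpoint; the operation is idempotent.
    """
    data = np.asarray(seg.data).copy()
    struct = connectivity_struct(conn_bg, ndim=3)
    changed = True
    while changed:
        changed = False
        bg = data == 0
        bg_lab, n_bg = ndimage.label(bg, structure=struct)
        border_ids = set()
        for sl in (
            bg_lab[0, :, :], bg_lab[-1, :, :],
            bg_lab[:, 0, :], bg_lab[:, -1, :],
            bg_lab[:, :, 0], bg_lab[:, :, -1],
        ):
            border_ids |= set(np.unique(sl))
        border_ids.discard(0)
        # fill interior background surrounded by a single label
        for bi in range(1, n_bg + 1):
            if bi in border_ids:
                continue
            m = bg_lab == bi
            ring = ndimage.binary_dilation(m, structure=struct) & ~m
            labs = set(np.unique(data[ring])) - {0}
            if len(labs) == 1:
                data[m] = labs.pop()
                changed = True
        # absorb segments fully contained in one neighbour: recompute the
        # border-reachable background after filling
        bg = data == 0
        bg_lab, _ = ndimage.label(bg, structure=struct)
        border_reach = np.zeros_like(bg)
        if bg.any():
            edge_seeds = np.zeros_like(bg)
            edge_seeds[0, :, :] = edge_seeds[-1, :, :] = True
            edge_seeds[:, 0, :] = edge_seeds[:, -1, :] = True
            edge_seeds[:, :, 0] = edge_seeds[:, :, -1] = True
            seed_ids = set(np.unique(bg_lab[edge_seeds & bg])) - {0}
            if seed_ids:
                border_reach = np.isin(bg_lab, sorted(seed_ids))
        for lab in [int(l) for l in np.unique(data) if l != 0]:
            m = data == lab
            if m[0, :, :].any() or m[-1, :, :].any() or m[:, 0, :].any() \
                    or m[:, -1, :].any() or m[:, :, 0].any() or m[:, :, -1].any():
                continue  # touches the volume border
            ring = ndimage.binary_dilation(m, structure=struct) & ~m
            if (border_reach & ring).any():
                continue  # has a background path to the outside
            neigh = set(np.unique(data[ring])) - {0, lab}
            if len(neigh) == 1:
                data[m] = neigh.pop()
                changed = True
    return seg.like(data)


def select_checkpoint_pair(
    candidates: list[Volume],
    accuracies: list[float],
    pairs: list[tuple[tuple[int, int, int], tuple[int, int, int]]],
    k: int = 7,
) -> tuple[tuple[int, int], Volume, int]:
    """Choose the candidate pair whose consensus separates the most pairs.

    The top-``k`` candidates by edge accuracy (ties by input order) are
    screened: for every unordered pair the oversegmentation consensus is
    computed and scored by :func:`pair_separation_count`; the argmax pair
    (ties by lexicographic indices) wins.  Returns (indices, consensus,
    separation count).
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate segmentations")
    order = sorted(range(len(candidates)), key=lambda i: (-accuracies[i], i))
    top = sorted(order[:k])
    best = None
    for i, j in combinations(top, 2):
        cons = oversegmentation_consensus(candidates[i], candidates[j])
        n = pair_separation_count(cons, pairs).n_separated
        if best is None or n > best[2]:
            best = ((i, j), cons, n)
    return best
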