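"""Connectome assembly: from detected synapses to a wiring diagram.

Each detected synaptic cleft is mapped onto the agglomerated neurite
segmentation: the two cells with the largest contact within a small
dilation of the cleft become the partners, and the partner with more
vesicle-cloud evidence near the cleft is the presynaptic one (the
automatic analogue of the manual criterion that a vesicle cloud is seen
in the axon).  Ambiguity — missing vesicle evidence, ties, clefts touching
fewer than two cells — is surfaced through flags, never silently
resolved.  Directed edges aggregate synapse counts per (pre, post) cell
pair; cycle detection and shared-partner fractions summarize the wiring
diagram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import Volume

__all__ = [
    "SynapseAssignment",
    "ConnectomeEdge",
    "assign_partners",
    "build_edges",
    "recurrency_check",
    "shared_partner_fraction",
]


@dataclass
class SynapseAssignment:
    cleft_id: int
    pre: int | None
    post: int | None
    partners: tuple[int, int] | None
    contact_voxels: dict[int, int] = field(default_factory=dict)
    vesicle_voxels: dict[int, int] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


@dataclass
class ConnectomeEdge:
    pre: int
    post: int
    n_synapses: int
    cleft_ids: list[int]


def _metric_ball(radius_nm: float, voxel_size) -> np.ndarray:
    ext = [max(int(np.floor(radius_nm / s)), 0) for s in voxel_size]
    ax = [np.arange(-e, e + 1) * s for e, s in zip(ext, voxel_size)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    return gx**2 + gy**2 + gz**2 <= radius_nm**2


def assign_partners(
    cleft_labels: Volume,
    vesicle_labels: Volume,
    seg: Volume,
    dilation_nm: float = 100.0,
) -> list[SynapseAssignment]:
    """Assign pre/post partner cells to every detected cleft.

    Cells with voxels within ``dilation_nm`` of a cleft are ranked by
    contact voxel count (ties by smaller id); the top two are the partners.
    The partner with the larger vesicle-cloud overlap in the same
    neighbourhood is presynaptic; absent or tied evidence leaves the
    direction null with a flag, as does a cleft touching fewer than two
    cells.
    """
    for other in (vesicle_labels, seg):
        if not cleft_labels.same_grid(other):
            raise ValueError("cleft, vesicle and segmentation grids must match")
    cdata = cleft_labels.data
    vdata = np.asarray(vesicle_labels.data) != 0
    sdata = seg.data
    ball = _metric_ball(dilation_nm, cleft_labels.voxel_size)
    pad = [s // 2 for s in ball.shape]
    shape = np.asarray(cdata.shape)

    out = []
    for cid in [int(v) for v in np.unique(cdata) if v != 0]:
        vox = np.argwhere(cdata == cid)
        lo = np.maximum(vox.min(axis=0) - pad, 0)
        hi = np.minimum(vox.max(axis=0) + pad + 1, shape)
        box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        local = cdata[box] == cid
        region = ndimage.binary_dilation(local, structure=ball)
        seg_local = sdata[box]
        ves_local = vdata[box]
        in_region = region & (seg_local != 0)
        cells, counts = np.unique(seg_local[in_region], return_counts=True)
        contact = {int(c): int(n) for c, n in zip(cells, counts)}
        vely = region & ves_local & (seg_local != 0)
        vcells, vcounts = np.unique(seg_local[vely], return_counts=True)
        vesicle = {int(c): int(n) for c, n in zip(vcells, vcounts)}

        flags: list[str] = []
        if len(contact) < 2:
            out.append(
                SynapseAssignment(
                    cid, None, None, None, contact, vesicle, ["unpaired"]
                )
            )
            continue
        ranked = sorted(contact.items(), key=lambda kv: (-kv[1], kv[0]))
        c1, c2 = ranked[0][0], ranked[1][0]
        v1, v2 = vesicle.get(c1, 0), vesicle.get(c2, 0)
        if v1 == v2:
            pre = post = None
            flags.append("no_vesicle_evidence" if v1 == 0 else "tied_vesicle_evidence")
        elif v1 > v2:
            pre, post = c1, c2
        else:
            pre, post = c2, c1
        out.append(
            SynapseAssignment(
                cid, pre, post, (min(c1, c2), max(c1, c2)), contact, vesicle, flags
            )
        )
    return out


def build_edges(
    assignments: list[SynapseAssignment],
) -> tuple[list[ConnectomeEdge], pd.DataFrame, list[SynapseAssignment], list[SynapseAssignment]]:
    """Aggregate directed assignments into connectome edges.

    Returns (edges, address book, undirected assignments, unpaired
    assignments).  The address book lists per-cell incoming and outgoing
    synapse counts.  Synapse count is conserved: edge counts plus
    undirected plus unpaired equals the number of clefts.
    """
    grouped: dict[tuple[int, int], list[int]] = {}
    undirected, unpaired = [], []
    for a in assignments:
        if a.partners is None:
            unpaired.append(a)
        elif a.pre is None:
            undirected.append(a)
        else:
            grouped.setdefault((a.pre, a.post), []).append(a.cleft_id)
    edges = [
        ConnectomeEdge(pre, post, len(cids), sorted(cids))
        for (pre, post), cids in sorted(grouped.items())
    ]
    cells = sorted(
        {e.pre for e in edges}
        | {e.post for e in edges}
        | {c for a in undirected for c in a.partners}
    )
    rows = []
    for c in cells:
        rows.append(
            {
                "cell": c,
                "n_out": sum(e.n_synapses for e in edges if e.pre == c),
                "n_in": sum(e.n_synapses for e in edges if e.post == c),
                "n_undirected": sum(1 for a in undirected if c in a.partners),
            }
        )
    book = pd.DataFrame(rows, columns=["cell", "n_out", "n_in", "n_undirected"])
    return edges, book, undirected, unpaired


def recurrency_check(
    edges: list[ConnectomeEdge], cells: set[int] | None = None
) -> dict:
    """Detect directed cycles and bidirectional pairs in the wiring diagram.

    Restricted to ``cells`` when given.  Returns has_cycle, the list of
    simple cycles and the list of cell pairs connected in both directions.
    """
    g = nx.DiGraph()
    for e in edges:
        if cells is not None and (e.pre not in cells or e.post not in cells):
            continue
        g.add_edge(e.pre, e.post)
    cycles = [tuple(c) for c in nx.simple_cycles(g)]
    bidir = sorted(
        {(min(u, v), max(u, v)) for u, v in g.edges if g.has_edge(v, u) and u != v}
    )
    return {"has_cycle": bool(cycles), "cycles": cycles, "bidirectional_pairs": bidir}


def shared_partner_fraction(
    edges: list[ConnectomeEdge], cell_x: int, cell_y: int, direction: str = "in"
) -> tuple[float | None, dict, list[str]]:
    """Fraction of X's synaptic partners that are also partners of Y.

    ``direction`` is "in" (presynaptic partners) or "out" (postsynaptic
    partners).  Returns the fraction |P(X) ∩ P(Y)| / |P(X)|, a detail dict
    with the symmetric variant, and flags (undefined when X has no
    partners).
    """
    if direction not in ("in", "out"):
        raise ValueError("direction must be 'in' or 'out'")

    def partners(c: int) -> set[int]:
        if direction == "out":
            return {e.post for e in edges if e.pre == c}
        return {e.pre for e in edges if e.post == c}

    px, py = partners(cell_x), partners(cell_y)
    shared = px & py
    detail = {
        "n_x": len(px),
        "n_y": len(py),
        "n_shared": len(shared),
        "fraction_of_y": len(shared) / len(py) if py else None,
        "jaccard": len(shared) / len(px | py) if px | py else None,
    }
    if not px:
        return None, detail, ["cell_x_has_no_partners"]
    return len(shared) / len(px), detail, []
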