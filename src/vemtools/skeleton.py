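"""Neuron skeletons and morphometrics.

Skeletons are forests of 3D nodes (positions in nm) with undirected edges,
per-node annotations (branch/synapse tags) and compartment assignments
(axon / dendrite / soma / unassigned).  They serve both as ground truth for
segmentation evaluation and as the substrate for per-cell morphometry:
path length, branch-point density, synapse density and region-wise
branch-point profiles.  Redundant manual tracings of one cell can be fused
into a consensus skeleton; short fragments around random locations support
local diameter review.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .volume import Volume

__all__ = [
    "Skeleton",
    "MorphometryRow",
    "read_swc",
    "write_swc",
    "path_length",
    "densities",
    "region_branch_profile",
    "consensus_skeleton",
    "sample_fragments",
]

COMPARTMENTS = ("axon", "dendrite", "soma", "unassigned")

# SWC structure-type codes <-> compartments
_SWC_TYPE = {"unassigned": 0, "soma": 1, "axon": 2, "dendrite": 3}
_SWC_TYPE_INV = {0: "unassigned", 1: "soma", 2: "axon", 3: "dendrite"}


@dataclass
class Skeleton:
    """Forest of nodes with nm positions, undirected edges and annotations."""

    nodes: dict[int, np.ndarray] = field(default_factory=dict)
    edges: set[tuple[int, int]] = field(default_factory=set)
    radius: dict[int, float] = field(default_factory=dict)
    annotations: dict[int, set[str]] = field(default_factory=dict)
    compartment: dict[int, str] = field(default_factory=dict)
    cell_id: int | str | None = None

    def add_node(
        self,
        node_id: int,
        position_nm,
        radius: float = 1.0,
        compartment: str = "unassigned",
        tags: set[str] | None = None,
    ) -> None:
        self.nodes[node_id] = np.asarray(position_nm, dtype=float)
        self.radius[node_id] = float(radius)
        self.compartment[node_id] = compartment
        if tags:
            self.annotations[node_id] = set(tags)

    def add_edge(self, a: int, b: int) -> None:
        if a == b:
            raise ValueError("self-edges are not allowed in a skeleton")
        if a not in self.nodes or b not in self.nodes:
            raise KeyError(f"edge ({a}, {b}) references unknown node")
        self.edges.add((min(a, b), max(a, b)))

    def degree(self) -> dict[int, int]:
        deg = {n: 0 for n in self.nodes}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def neighbors(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {n: [] for n in self.nodes}
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        return adj

    def components(self) -> list[set[int]]:
        adj = self.neighbors()
        seen: set[int] = set()
        comps = []
        for start in sorted(self.nodes):
            if start in seen:
                continue
            stack, comp = [start], set()
            while stack:
                n = stack.pop()
                if n in comp:
                    continue
                comp.add(n)
                stack.extend(m for m in adj[n] if m not in comp)
            seen |= comp
            comps.append(comp)
        return comps

    def branch_points(self) -> list[int]:
        """Nodes of degree >= 3, unless explicit 'branch' annotations exist.

        Explicit annotations win over the degree rule when present anywhere
        in the skeleton.
        """
        tagged = [n for n, tags in self.annotations.items() if "branch" in tags]
        if tagged:
            return sorted(tagged)
        deg = self.degree()
        return sorted(n for n, d in deg.items() if d >= 3)

    def positions(self, order: list[int] | None = None) -> np.ndarray:
        ids = order if order is not None else sorted(self.nodes)
        if not ids:
            return np.zeros((0, 3))
        return np.vstack([self.nodes[i] for i in ids])


@dataclass
class MorphometryRow:
    cell_id: int | str | None
    length_um: float
    axon_length_um: float
    dendrite_length_um: float
    n_branch_points: int
    branch_density_per_um: float | None
    n_synapses_in: int
    n_synapses_out: int
    synapse_out_density_per_um: float | None
    flags: list[str] = field(default_factory=list)


def _edge_length_nm(skel: Skeleton, a: int, b: int) -> float:
    return float(np.linalg.norm(skel.nodes[a] - skel.nodes[b]))


def path_length(skel: Skeleton, compartment: str | None = None) -> float:
    """Total Euclidean path length in µm, optionally per compartment.

    An edge counts toward a compartment when both its endpoints carry that
    compartment label.
    """
    total = 0.0
    for a, b in skel.edges:
        if compartment is not None:
            if (
                skel.compartment.get(a, "unassigned") != compartment
                or skel.compartment.get(b, "unassigned") != compartment
            ):
                continue
        total += _edge_length_nm(skel, a, b)
    return total / 1000.0


def densities(skel: Skeleton) -> MorphometryRow:
    """Per-cell morphometry: path lengths, branch and synapse densities.

    Branch density is per µm of total path length; synapse(out) density is
    per µm of axonal path length (synapses without axon length are flagged,
    density left undefined).
    """
    flags: list[str] = []
    total = path_length(skel)
    axon = path_length(skel, "axon")
    dendrite = path_length(skel, "dendrite")
    branches = skel.branch_points()
    syn_in = sum(1 for tags in skel.annotations.values() if "synapse_in" in tags)
    syn_out = sum(1 for tags in skel.annotations.values() if "synapse_out" in tags)

    if total > 0:
        branch_density = len(branches) / total
    else:
        branch_density = None
        if branches:
            flags.append("branch_points_with_zero_length")
    if axon > 0:
        syn_density = syn_out / axon
    else:
        syn_density = None
        if syn_out:
            flags.append("synapses_with_zero_axon_length")

    return MorphometryRow(
        cell_id=skel.cell_id,
        length_um=total,
        axon_length_um=axon,
        dendrite_length_um=dendrite,
        n_branch_points=len(branches),
        branch_density_per_um=branch_density,
        n_synapses_in=syn_in,
        n_synapses_out=syn_out,
        synapse_out_density_per_um=syn_density,
        flags=flags,
    )


def region_branch_profile(
    skel: Skeleton, region_masks: dict[str, Volume]
) -> tuple[dict[str, float], list[str]]:
    """Fraction of a cell's branch points falling in each region mask.

    Counts branch-point nodes whose voxel lies inside each region and
    normalizes by the total branch-point count; branch points outside every
    region go to an ``"unassigned"`` bin.  With zero branch points all
    fractions are undefined and the result is flagged.
    """
    branches = skel.branch_points()
    if not branches:
        return {}, ["no_branch_points"]
    counts = {name: 0 for name in region_masks}
    counts["unassigned"] = 0
    for n in branches:
        pos = skel.nodes[n]
        hit = None
        for name, vol in region_masks.items():
            idx = vol.world_to_index(pos)[0]
            if all(0 <= idx[d] < vol.shape[d] for d in range(3)) and vol.data[tuple(idx)]:
                hit = name
                break
        counts[hit if hit is not None else "unassigned"] += 1
    total = len(branches)
    return {name: c / total for name, c in counts.items()}, []


def consensus_skeleton(
    tracings: list[Skeleton],
    tolerance_nm: float = 1000.0,
    quorum: int | None = None,
) -> tuple[Skeleton, int]:
    """Fuse redundant tracings of one cell into a consensus skeleton.

    A node of any tracing is retained iff at least ``quorum - 1`` *other*
    tracings place a node within ``tolerance_nm`` of it (quorum defaults to
    a majority, ``ceil(n/2)``).  Retained nodes are merged by greedy spatial
    clustering at the same tolerance (cluster centre = mean member
    position); edges are induced from the supporting tracings.  Returns the
    consensus skeleton and its connected-component count.
    """
    if len(tracings) < 2:
        raise ValueError("consensus requires at least 2 tracings")
    n = len(tracings)
    if quorum is None:
        quorum = int(np.ceil(n / 2))

    trees = [cKDTree(t.positions(sorted(t.nodes))) if t.nodes else None for t in tracings]
    id_orders = [sorted(t.nodes) for t in tracings]

    retained: dict[tuple[int, int], np.ndarray] = {}
    for ti, skel in enumerate(tracings):
        for nid in id_orders[ti]:
            pos = skel.nodes[nid]
            support = 1
            for tj in range(n):
                if tj == ti or trees[tj] is None:
                    continue
                if trees[tj].query_ball_point(pos, tolerance_nm):
                    support += 1
            if support >= quorum:
                retained[(ti, nid)] = pos

    # greedy clustering in deterministic (tracing, node id) order
    centers: list[np.ndarray] = []
    members: list[list[np.ndarray]] = []
    assignment: dict[tuple[int, int], int] = {}
    for key in sorted(retained):
        pos = retained[key]
        best, best_d = None, tolerance_nm
        for ci, c in enumerate(centers):
            d = float(np.linalg.norm(pos - c))
            if d <= best_d:
                best, best_d = ci, d
        if best is None:
            centers.append(pos.copy())
            members.append([pos])
            assignment[key] = len(centers) - 1
        else:
            members[best].append(pos)
            centers[best] = np.mean(members[best], axis=0)
            assignment[key] = best

    out = Skeleton(cell_id=tracings[0].cell_id)
    for ci in range(len(centers)):
        center = np.mean(members[ci], axis=0)
        out.add_node(ci, center)
    for ti, skel in enumerate(tracings):
        for a, b in skel.edges:
            ka, kb = (ti, a), (ti, b)
            if ka in assignment and kb in assignment:
                ca, cb = assignment[ka], assignment[kb]
                if ca != cb:
                    out.add_edge(ca, cb)
    return out, len(out.components()) if out.nodes else 0


def sample_fragments(
    skel: Skeleton,
    n: int = 200,
    radius_nm: float = 750.0,
    compartment: str | None = None,
    seed: int = 0,
) -> tuple[list[Skeleton], list[str]]:
    """Sample locations uniformly along path length and cut out fragments.

    Each of ``n`` locations is drawn uniformly along the (compartment-
    filtered) path length; its fragment contains every node within
    ``radius_nm`` of the location plus the induced edges.  Reproducible via
    ``seed``.  A zero-length compartment yields no fragments and a flag.
    """
    flags: list[str] = []
    edges = []
    for a, b in sorted(skel.edges):
        if compartment is not None:
            if (
                skel.compartment.get(a, "unassigned") != compartment
                or skel.compartment.get(b, "unassigned") != compartment
            ):
                continue
        edges.append((a, b, _edge_length_nm(skel, a, b)))
    total = sum(e[2] for e in edges)
    if n == 0:
        return [], flags
    if total == 0 or not edges:
        return [], ["zero_length_compartment"]
    if total < n * 2 * radius_nm:
        flags.append("compartment_shorter_than_requested_sampling")

    rng = np.random.default_rng(seed)
    cum = np.cumsum([e[2] for e in edges])
    picks = np.sort(rng.uniform(0, total, size=n))
    node_ids = sorted(skel.nodes)
    tree = cKDTree(skel.positions(node_ids))

    fragments = []
    for s in picks:
        ei = int(np.searchsorted(cum, s, side="right"))
        ei = min(ei, len(edges) - 1)
        a, b, elen = edges[ei]
        t = 1.0 if elen == 0 else (s - (cum[ei] - elen)) / elen
        loc = skel.nodes[a] + t * (skel.nodes[b] - skel.nodes[a])
        near = tree.query_ball_point(loc, radius_nm)
        keep = {node_ids[i] for i in near}
        frag = Skeleton(cell_id=skel.cell_id)
        for nid in sorted(keep):
            frag.add_node(
                nid,
                skel.nodes[nid],
                skel.radius.get(nid, 1.0),
                skel.compartment.get(nid, "unassigned"),
                skel.annotations.get(nid),
            )
        for a2, b2 in skel.edges:
            if a2 in keep and b2 in keep:
                frag.add_edge(a2, b2)
        fragments.append(frag)
    return fragments, flags


def write_swc(skel: Skeleton, path: str | Path, tags_csv: str | Path | None = None) -> Path:
    """Write a skeleton as SWC (positions in nm); annotations go to a CSV.

    Compartments map to SWC structure types (1 soma, 2 axon, 3 dendrite,
    0 unassigned).  The forest is rooted per component; parents follow a
    depth-first traversal from each component's smallest node id.
    """
    path = Path(path)
    adj = skel.neighbors()
    parent: dict[int, int] = {}
    for comp in skel.components():
        root = min(comp)
        parent[root] = -1
        stack = [root]
        seen = {root}
        while stack:
            u = stack.pop()
            for v in sorted(adj[u], reverse=True):
                if v not in seen:
                    seen.add(v)
                    parent[v] = u
                    stack.append(v)
    with open(path, "w") as f:
        f.write("# SWC positions in nm\n")
        for nid in sorted(skel.nodes):
            x, y, z = skel.nodes[nid]
            stype = _SWC_TYPE.get(skel.compartment.get(nid, "unassigned"), 0)
            r = skel.radius.get(nid, 1.0)
            f.write(f"{nid} {stype} {x:.3f} {y:.3f} {z:.3f} {r:.3f} {parent[nid]}\n")
    if tags_csv is not None and skel.annotations:
        with open(tags_csv, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["node_id", "tag"])
            for nid in sorted(skel.annotations):
                for tag in sorted(skel.annotations[nid]):
                    w.writerow([nid, tag])
    return path


def read_swc(path: str | Path, tags_csv: str | Path | None = None) -> Skeleton:
    """Read an SWC file written by :func:`write_swc` (positions in nm)."""
    skel = Skeleton()
    pending: list[tuple[int, int]] = []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            nid, stype = int(parts[0]), int(parts[1])
            pos = [float(parts[2]), float(parts[3]), float(parts[4])]
            r = float(parts[5])
            par = int(parts[6])
            skel.add_node(nid, pos, r, _SWC_TYPE_INV.get(stype, "unassigned"))
            if par != -1:
                pending.append((nid, par))
    for a, b in pending:
        skel.add_edge(a, b)
    if tags_csv is not None and Path(tags_csv).exists():
        with open(tags_csv) as f:
            for row in csv.DictReader(f):
                nid = int(row["node_id"])
                skel.annotations.setdefault(nid, set()).add(row["tag"])
    return skel
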