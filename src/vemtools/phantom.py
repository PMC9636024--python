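"""Synthetic phantom volumes for pipeline testing.

Real whole-brain vEM datasets are teravoxel-scale; every stage of this
toolkit is instead exercised on desk-scale phantoms that reproduce the
*structural* properties the pipeline assumes: non-overlapping neurite
tubes (down to ~50 nm diameter) following smooth paths, somata each
containing one nucleus, synaptic clefts as thin slabs (25-50 nm, the scale
of a postsynaptic density) between two touching tubes with a vesicle cloud
in the designated presynaptic partner, centerline skeletons, controlled
split/merge oversegmentation errors, and sharp/defocused image textures.

Packing strategy: tubes run along x inside disjoint (y, z) "lane"
corridors, which guarantees a background gap between any two tubes and
makes packing feasible deterministically; somata are placed first by
rejection sampling and block the lanes they shadow.  Synapse pairs occupy
adjacent lanes and their paths are pulled to the shared lane boundary at
the synapse location so the surface gap there equals the cleft thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .skeleton import Skeleton
from .volume import Volume

__all__ = [
    "PhantomSpec",
    "ErrorSpec",
    "PhantomResult",
    "OversegResult",
    "PackingError",
    "make_phantom",
    "make_oversegmentation",
    "make_tube_pair_grid",
    "make_focus_stack",
]


class PackingError(RuntimeError):
    """Requested objects cannot be packed into the volume."""


@dataclass
class PhantomSpec:
    """Parameters of a phantom volume (all physical sizes in nm)."""

    shape: tuple[int, int, int] = (512, 512, 128)
    voxel_size: tuple[float, float, float] = (14.0, 14.0, 25.0)
    n_neurites: int = 8
    neurite_radius_nm: tuple[float, float] = (25.0, 120.0)
    n_somata: int = 2
    soma_radius_nm: tuple[float, float] = (600.0, 900.0)
    nucleus_radius_nm: tuple[float, float] = (250.0, 400.0)
    n_synapses: int = 5
    cleft_thickness_nm: float = 30.0
    vesicle_cloud_radius_nm: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_neurites, self.n_somata, self.n_synapses) < 0:
            raise ValueError("counts must be non-negative")
        for rng_ in (self.neurite_radius_nm, self.soma_radius_nm, self.nucleus_radius_nm):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ValueError(f"invalid radius range {rng_}")
        if self.cleft_thickness_nm <= 0 or self.vesicle_cloud_radius_nm <= 0:
            raise ValueError("cleft/vesicle sizes must be positive")
        if self.n_synapses > 0 and self.n_neurites < 2:
            raise ValueError("synapses require at least 2 neurites")


@dataclass
class ErrorSpec:
    """Planted oversegmentation errors.

    ``split_rate``: probability a true object is cut by a random plane into
    two supervoxels.  ``merge_rate``: probability an adjacent true-object
    pair shares a supervoxel.  ``n_merges`` plants an exact number of
    mergers instead of a rate.  Split decisions use one substream per
    object keyed by (seed, label), so for a fixed seed the set of split
    objects is nested as split_rate grows.
    """

    split_rate: float = 0.0
    merge_rate: float = 0.0
    seed: int = 0
    n_merges: int | None = None
    adjacency_nm: float = 120.0

    def __post_init__(self) -> None:
        if not (0 <= self.split_rate <= 1 and 0 <= self.merge_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")


@dataclass
class PhantomResult:
    truth: Volume
    skeletons: list[Skeleton]
    cleft_labels: Volume
    vesicle_labels: Volume
    cleft_to_pair: dict[int, tuple[int, int]]
    tube_labels: list[int] = field(default_factory=list)
    soma_labels: list[int] = field(default_factory=list)
    nucleus_labels: list[int] = field(default_factory=list)
    nucleus_of_soma: dict[int, int] = field(default_factory=dict)
    synapse_sites: dict[int, tuple[int, int, int]] = field(default_factory=dict)


@dataclass
class OversegResult:
    supervoxels: Volume
    true_graph: set[tuple[int, int]]
    planted_merges: list[tuple[int, int, int, int]]  # (sv_kept, sv_merged, objA, objB)
    adjacent_pairs: list[tuple[int, int]]
    obj_to_svs: dict[int, list[int]]


def _ball_offsets(radius_nm: float, voxel_size) -> np.ndarray:
    """Voxel offsets inside a metric ball of the given nm radius."""
    ext = [max(int(np.floor(radius_nm / s)), 0) for s in voxel_size]
    ax = [np.arange(-e, e + 1) for e in ext]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    d2 = (
        (gx * voxel_size[0]) ** 2
        + (gy * voxel_size[1]) ** 2
        + (gz * voxel_size[2]) ** 2
    )
    sel = d2 <= radius_nm**2
    return np.stack([gx[sel], gy[sel], gz[sel]], axis=1)


def _stamp(mask: np.ndarray, centers: np.ndarray, offsets: np.ndarray) -> None:
    shape = mask.shape
    pts = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    ok = np.all((pts >= 0) & (pts < np.asarray(shape)), axis=1)
    pts = pts[ok]
    mask[pts[:, 0], pts[:, 1], pts[:, 2]] = True


def _paint_ball(vol: np.ndarray, center, radius_nm: float, voxel_size, value: int) -> int:
    offs = _ball_offsets(radius_nm, voxel_size)
    pts = offs + np.asarray(center, dtype=int)
    ok = np.all((pts >= 0) & (pts < np.asarray(vol.shape)), axis=1)
    pts = pts[ok]
    vol[pts[:, 0], pts[:, 1], pts[:, 2]] = value
    return len(pts)


def make_phantom(spec: PhantomSpec) -> PhantomResult:
    """Generate a phantom volume with tubes, somata, synapses and skeletons.

    Deterministic given ``spec.seed``; raises :class:`PackingError` when the
    requested objects cannot be placed.
    """
    rng = np.random.default_rng(spec.seed)
    X, Y, Z = spec.shape
    vs = np.asarray(spec.voxel_size)
    truth = np.zeros(spec.shape, dtype=np.int32)
    cleft = np.zeros(spec.shape, dtype=np.int32)
    vesicle = np.zeros(spec.shape, dtype=np.int32)

    tube_labels = list(range(1, spec.n_neurites + 1))
    soma_labels, nucleus_labels, nucleus_of_soma = [], [], {}

    # --- somata with nuclei (rejection sampling) ------------------------
    soma_centers, soma_radii = [], []
    next_label = spec.n_neurites + 1
    for _ in range(spec.n_somata):
        r = rng.uniform(*spec.soma_radius_nm)
        rn = rng.uniform(*spec.nucleus_radius_nm)
        rn = min(rn, 0.75 * r)  # nucleus strictly inside
        placed = False
        for _attempt in range(200):
            margin = np.ceil(r / vs).astype(int) + 1
            if np.any(margin * 2 + 2 >= np.asarray(spec.shape)):
                break
            c = np.array(
                [rng.integers(m, s - m) for m, s in zip(margin, spec.shape)]
            )
            clear = True
            for c2, r2 in zip(soma_centers, soma_radii):
                if np.linalg.norm((c - c2) * vs) < r + r2 + 2 * vs.max():
                    clear = False
                    break
            if clear:
                placed = True
                break
        if not placed:
            raise PackingError("could not place requested somata")
        soma_lab, nuc_lab = next_label, next_label + 1
        next_label += 2
        _paint_ball(truth, c, r, vs, soma_lab)
        # nucleus centre jittered but kept strictly inside the soma
        max_off = r - rn - vs.max()
        off_nm = rng.uniform(-1, 1, 3)
        off_nm = off_nm / (np.linalg.norm(off_nm) + 1e-9) * rng.uniform(0, max(max_off, 0))
        nc = c + np.round(off_nm / vs).astype(int)
        _paint_ball(truth, nc, rn, vs, nuc_lab)
        soma_centers.append(c)
        soma_radii.append(r)
        soma_labels.append(soma_lab)
        nucleus_labels.append(nuc_lab)
        nucleus_of_soma[soma_lab] = nuc_lab

    # --- lane layout for tubes ------------------------------------------
    r_max_vox_y = int(np.ceil(spec.neurite_radius_nm[1] / vs[1]))
    r_max_vox_z = int(np.ceil(spec.neurite_radius_nm[1] / vs[2]))
    lane_w = 2 * r_max_vox_y + 4
    lane_h = 2 * r_max_vox_z + 4
    ny, nz = Y // lane_w, Z // lane_h
    lanes = [(iy, iz) for iz in range(nz) for iy in range(ny)]

    # lanes shadowed by a soma (in (y, z) projection) are unusable
    soma_occ = np.zeros(spec.shape, dtype=bool)
    for lab in soma_labels:
        soma_occ |= truth == lab
    soma_proj = soma_occ.any(axis=0)  # (y, z)
    free_lanes = []
    for iy, iz in lanes:
        sub = soma_proj[iy * lane_w : (iy + 1) * lane_w, iz * lane_h : (iz + 1) * lane_h]
        if not sub.any():
            free_lanes.append((iy, iz))

    # synapse pairs need adjacent-in-y lane pairs within one z row
    n_pairs = min(spec.n_synapses, spec.n_neurites // 2)
    pair_slots: list[tuple[tuple[int, int], tuple[int, int]]] = []
    used: set[tuple[int, int]] = set()
    free_set = set(free_lanes)
    for iy, iz in free_lanes:
        if len(pair_slots) >= n_pairs:
            break
        if (iy, iz) in used or (iy + 1, iz) not in free_set or (iy + 1, iz) in used:
            continue
        pair_slots.append(((iy, iz), (iy + 1, iz)))
        used |= {(iy, iz), (iy + 1, iz)}
    if len(pair_slots) < n_pairs:
        raise PackingError("not enough adjacent free lanes for synapse pairs")
    single_lanes = [ln for ln in free_lanes if ln not in used]
    n_single = spec.n_neurites - 2 * len(pair_slots)
    if len(single_lanes) < n_single:
        raise PackingError("not enough free lanes for requested neurites")

    # assign tubes to lanes: paired tubes first, then singles
    tube_lane: dict[int, tuple[int, int]] = {}
    pair_of_tubes: list[tuple[int, int]] = []
    t = 0
    for la, lb in pair_slots:
        tube_lane[tube_labels[t]] = la
        tube_lane[tube_labels[t + 1]] = lb
        pair_of_tubes.append((tube_labels[t], tube_labels[t + 1]))
        t += 2
    for lab in tube_labels[t:]:
        tube_lane[lab] = single_lanes.pop(0)

    # synapse -> (pair index, x control index); spread along x
    n_ctrl = max(4, X // 32)
    ctrl_x = np.linspace(0, X - 1, n_ctrl)
    syn_plan: list[tuple[int, int]] = []  # (pair idx, control idx)
    if spec.n_synapses:
        per_pair: dict[int, list[int]] = {i: [] for i in range(len(pair_slots))}
        interior = list(range(1, n_ctrl - 1))
        for s in range(spec.n_synapses):
            pi = s % len(pair_slots)
            avail = [i for i in interior if all(abs(i - j) >= 2 for j in per_pair[pi])]
            if not avail:
                raise PackingError("too many synapses for one tube pair")
            ci = int(rng.choice(avail))
            per_pair[pi].append(ci)
            syn_plan.append((pi, ci))

    # --- rasterize tubes --------------------------------------------------
    tube_radius: dict[int, float] = {}
    tube_path: dict[int, np.ndarray] = {}  # dense centre line, voxel coords
    syn_ctrl_y: dict[tuple[int, int], float] = {}  # (tube, ctrl idx) -> forced y (vox)
    syn_ctrl_z: dict[tuple[int, int], float] = {}
    syn_x_of: dict[int, int] = {}

    for s, (pi, ci) in enumerate(syn_plan):
        a, b = pair_of_tubes[pi]
        (iy_a, iz), (iy_b, _) = pair_slots[pi]
        ra = rng.uniform(*spec.neurite_radius_nm)
        rb = rng.uniform(*spec.neurite_radius_nm)
        tube_radius.setdefault(a, ra)
        tube_radius.setdefault(b, rb)
        boundary_y_nm = (iy_a + 1) * lane_w * vs[1]
        ya = (boundary_y_nm - tube_radius[a] - spec.cleft_thickness_nm / 2) / vs[1]
        yb = (boundary_y_nm + tube_radius[b] + spec.cleft_thickness_nm / 2) / vs[1]
        zc = (iz + 0.5) * lane_h
        syn_ctrl_y[(a, ci)] = ya
        syn_ctrl_y[(b, ci)] = yb
        syn_ctrl_z[(a, ci)] = zc
        syn_ctrl_z[(b, ci)] = zc
        syn_x_of[s] = int(round(ctrl_x[ci]))

    for lab in tube_labels:
        r = tube_radius.setdefault(lab, rng.uniform(*spec.neurite_radius_nm))
        iy, iz = tube_lane[lab]
        rv_y = r / vs[1]
        rv_z = r / vs[2]
        lo_y, hi_y = iy * lane_w + rv_y + 1, (iy + 1) * lane_w - rv_y - 1
        lo_z, hi_z = iz * lane_h + rv_z + 1, (iz + 1) * lane_h - rv_z - 1
        cy = rng.uniform(lo_y, hi_y, size=n_ctrl)
        cz = rng.uniform(lo_z, hi_z, size=n_ctrl)
        for ci in range(n_ctrl):
            if (lab, ci) in syn_ctrl_y:
                cy[ci] = syn_ctrl_y[(lab, ci)]
                cz[ci] = syn_ctrl_z[(lab, ci)]
        sp_y = CubicSpline(ctrl_x, cy)
        sp_z = CubicSpline(ctrl_x, cz)
        xs = np.arange(0, X, 0.5)
        ys = sp_y(xs)
        zs = sp_z(xs)
        # keep the surface inside the lane; at synapse controls the centre
        # may approach the boundary up to half a cleft thickness
        y_min = iy * lane_w + rv_y
        y_max = (iy + 1) * lane_w - rv_y - spec.cleft_thickness_nm / (2 * vs[1])
        if y_max <= y_min:
            y_max = y_min + 1e-6
        ys = np.clip(ys, min(y_min, y_max), max(y_min, y_max))
        zs = np.clip(zs, lo_z - 1, hi_z + 1)
        zs = np.clip(zs, rv_z, Z - 1 - rv_z)
        centers = np.unique(np.round(np.stack([xs, ys, zs], axis=1)).astype(int), axis=0)
        mask = np.zeros(spec.shape, dtype=bool)
        _stamp(mask, centers, _ball_offsets(r, vs))
        if (truth[mask] != 0).any():
            raise PackingError(f"tube {lab} collided with an existing object")
        truth[mask] = lab
        tube_path[lab] = np.stack([xs, ys, zs], axis=1)

    # --- synaptic clefts and vesicle clouds ------------------------------
    cleft_to_pair: dict[int, tuple[int, int]] = {}
    synapse_sites: dict[int, tuple[int, int, int]] = {}
    for s, (pi, ci) in enumerate(syn_plan):
        a, b = pair_of_tubes[pi]
        (iy_a, iz), _ = pair_slots[pi]
        x_s = syn_x_of[s]
        y_c = int(round((iy_a + 1) * lane_w))
        z_c = int(round((iz + 0.5) * lane_h))
        hw = np.ceil(
            np.array([150.0, spec.cleft_thickness_nm + 2 * vs[1], 150.0]) / vs
        ).astype(int) + 2
        lo = np.maximum([x_s - hw[0], y_c - hw[1], z_c - hw[2]], 0)
        hi = np.minimum([x_s + hw[0], y_c + hw[1], z_c + hw[2]], [X, Y, Z])
        box = tuple(slice(int(l), int(h)) for l, h in zip(lo, hi))
        sub = truth[box]
        in_a, in_b = sub == a, sub == b
        if not in_a.any() or not in_b.any():
            raise PackingError(f"synapse {s} lost contact with its tubes")
        da = ndimage.distance_transform_edt(~in_a, sampling=vs)
        db = ndimage.distance_transform_edt(~in_b, sampling=vs)
        slack = spec.cleft_thickness_nm + vs.max()
        for extra in (0.0, vs.max(), 2 * vs.max()):
            cand = (sub == 0) & (da <= slack + extra) & (db <= slack + extra)
            if cand.any():
                lab_c, _ = ndimage.label(cand, structure=np.ones((3, 3, 3), bool))
                # component closest to the box centre
                cc = np.array(cand.shape) / 2
                best, best_d = None, np.inf
                for li in range(1, lab_c.max() + 1):
                    pts = np.argwhere(lab_c == li)
                    d = np.linalg.norm((pts - cc) * vs, axis=1).min()
                    if d < best_d:
                        best, best_d = li, d
                sel = lab_c == best
                dil = ndimage.binary_dilation(sel, structure=np.ones((3, 3, 3), bool))
                touched = set(np.unique(sub[dil])) - {0}
                if touched == {a, b}:
                    cleft_view = cleft[box]
                    cleft_view[sel] = s + 1
                    break
        else:
            raise PackingError(f"could not carve cleft for synapse {s}")
        pre, post = (a, b) if rng.uniform() < 0.5 else (b, a)
        cleft_to_pair[s + 1] = (pre, post)
        synapse_sites[s + 1] = (x_s, y_c, z_c)
        # vesicle cloud: presynaptic voxels near the cleft centroid
        pts = np.argwhere(cleft[box] == s + 1)
        centroid = pts.mean(axis=0) + lo
        # distance of tube voxels to centroid, restricted to a local box
        vr = spec.vesicle_cloud_radius_nm
        vhw = np.ceil(vr / vs).astype(int) + 1
        vlo = np.maximum((centroid - vhw).astype(int), 0)
        vhi = np.minimum((centroid + vhw + 1).astype(int), [X, Y, Z])
        vbox = tuple(slice(int(l), int(h)) for l, h in zip(vlo, vhi))
        vsub = truth[vbox]
        coords = np.argwhere(vsub == pre) + vlo
        if len(coords):
            d = np.linalg.norm((coords - centroid) * vs, axis=1)
            keep = coords[d <= vr]
            vesicle[keep[:, 0], keep[:, 1], keep[:, 2]] = s + 1

    # --- centerline skeletons --------------------------------------------
    skeletons: list[Skeleton] = []
    for lab in tube_labels:
        path = tube_path[lab]
        step = 4  # node every ~2 voxels of dense samples (0.5 vox spacing)
        idx = np.arange(0, len(path), step)
        skel = Skeleton(cell_id=lab)
        prev = None
        for ni, pi_ in enumerate(idx):
            vox = np.round(path[pi_]).astype(int)
            vox = np.clip(vox, 0, np.asarray(spec.shape) - 1)
            pos_nm = vox * vs  # voxel centre => guaranteed inside the tube
            skel.add_node(ni, pos_nm, radius=tube_radius[lab], compartment="axon")
            if prev is not None:
                skel.add_edge(prev, ni)
            prev = ni
        skeletons.append(skel)

    # synapse annotations on the nearest skeleton nodes
    for cid, (pre, post) in cleft_to_pair.items():
        site = np.asarray(synapse_sites[cid]) * vs
        for lab, tag in ((pre, "synapse_out"), (post, "synapse_in")):
            skel = skeletons[tube_labels.index(lab)]
            ids = sorted(skel.nodes)
            pos = skel.positions(ids)
            nearest = ids[int(np.argmin(np.linalg.norm(pos - site, axis=1)))]
            skel.annotations.setdefault(nearest, set()).add(tag)

    mk = lambda arr: Volume(arr, spec.voxel_size)
    return PhantomResult(
        truth=mk(truth),
        skeletons=skeletons,
        cleft_labels=mk(cleft),
        vesicle_labels=mk(vesicle),
        cleft_to_pair=cleft_to_pair,
        tube_labels=tube_labels,
        soma_labels=soma_labels,
        nucleus_labels=nucleus_labels,
        nucleus_of_soma=nucleus_of_soma,
        synapse_sites=synapse_sites,
    )


def _adjacent_pairs(truth: Volume, adjacency_nm: float) -> tuple[
    list[tuple[int, int]], dict[tuple[int, int], tuple[np.ndarray, np.ndarray]]
]:
    """Object pairs whose surfaces come within adjacency_nm, with witness voxels."""
    data = truth.data
    vs = np.asarray(truth.voxel_size)
    labels = [int(l) for l in np.unique(data) if l != 0]
    coords = {l: np.argwhere(data == l) for l in labels}
    boxes = {
        l: (coords[l].min(axis=0), coords[l].max(axis=0)) for l in labels
    }
    pad = np.ceil(adjacency_nm / vs).astype(int) + 1
    pairs, witness = [], {}
    for i, a in enumerate(labels):
        ta = None
        for b in labels[i + 1 :]:
            lo_a, hi_a = boxes[a]
            lo_b, hi_b = boxes[b]
            if np.any(lo_b > hi_a + pad) or np.any(lo_a > hi_b + pad):
                continue
            if ta is None:
                ta = cKDTree(coords[a] * vs)
            pb = coords[b] * vs
            d, idx = ta.query(pb, distance_upper_bound=adjacency_nm + float(vs.max()))
            ok = np.isfinite(d) & (d <= adjacency_nm)
            if ok.any():
                j = int(np.argmin(np.where(ok, d, np.inf)))
                pairs.append((a, b))
                witness[(a, b)] = (coords[a][idx[j]], coords[b][j])
    return pairs, witness


def make_oversegmentation(truth: Volume, err: ErrorSpec) -> OversegResult:
    """Derive a supervoxel oversegmentation with planted split/merge errors.

    With zero rates the partition equals the truth up to relabeling.  Splits
    cut an object by a random axis-aligned plane; merges give one supervoxel
    of each of two adjacent objects a shared id.  ``true_graph`` connects
    supervoxels of the same true object.
    """
    data = truth.data
    labels = [int(l) for l in np.unique(data) if l != 0]
    sv = np.zeros_like(data, dtype=np.int32)
    next_id = 1
    obj_to_svs: dict[int, list[int]] = {}
    true_graph: set[tuple[int, int]] = set()

    for lab in labels:
        sub_rng = np.random.default_rng([err.seed, lab])
        u = sub_rng.uniform()
        axis = int(sub_rng.integers(3))
        vox = np.argwhere(data == lab)
        ids = [next_id]
        if u < err.split_rate:
            vals = np.unique(vox[:, axis])
            if len(vals) >= 2:
                cut = vals[int(sub_rng.integers(1, len(vals)))]
                left = vox[:, axis] < cut
                sv[tuple(vox[left].T)] = next_id
                sv[tuple(vox[~left].T)] = next_id + 1
                ids = [next_id, next_id + 1]
            else:
                sv[tuple(vox.T)] = next_id
        else:
            sv[tuple(vox.T)] = next_id
        next_id += len(ids)
        obj_to_svs[lab] = ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                true_graph.add((ids[i], ids[j]))

    if err.merge_rate == 0 and not err.n_merges:
        pairs, witness = [], {}
    else:
        pairs, witness = _adjacent_pairs(truth, err.adjacency_nm)
    sel_rng = np.random.default_rng([err.seed, 2**20 + 7])
    if err.n_merges is not None:
        if err.n_merges > len(pairs):
            raise ValueError(
                f"requested {err.n_merges} merges but only {len(pairs)} adjacent pairs"
            )
        chosen_idx = sorted(
            sel_rng.choice(len(pairs), size=err.n_merges, replace=False).tolist()
        )
        chosen = [pairs[i] for i in chosen_idx]
    else:
        chosen = [p for p in pairs if sel_rng.uniform() < err.merge_rate]

    planted = []
    for a, b in chosen:
        wa, wb = witness[(a, b)]
        sva = int(sv[tuple(wa)])
        svb = int(sv[tuple(wb)])
        if sva == svb:
            continue
        sv[sv == svb] = sva
        true_graph = {
            tuple(sorted((sva if x == svb else x, sva if y == svb else y)))
            for x, y in true_graph
            if not (x == svb and y == sva) and not (x == sva and y == svb)
        }
        true_graph = {e for e in true_graph if e[0] != e[1]}
        obj_to_svs = {
            k: [sva if i == svb else i for i in v] for k, v in obj_to_svs.items()
        }
        planted.append((sva, svb, a, b))

    return OversegResult(
        supervoxels=truth.like(sv),
        true_graph=true_graph,
        planted_merges=planted,
        adjacent_pairs=pairs,
        obj_to_svs=obj_to_svs,
    )


def make_tube_pair_grid(
    n_pairs: int,
    voxel_size: tuple[float, float, float] = (14.0, 14.0, 25.0),
    tube_len: int = 40,
    radius_vox: int = 2,
    gap_vox: int = 2,
    seed: int = 0,
) -> tuple[Volume, list[tuple[int, int]], list[tuple[tuple[int, int, int], tuple[int, int, int]]]]:
    """Grid of straight adjacent tube pairs for merge-screening experiments.

    Each cell of a (y, z) grid holds two parallel tubes along x separated by
    ``gap_vox`` voxels in y; different cells are far apart, so the adjacency
    graph contains exactly the ``n_pairs`` within-cell pairs.  Returns the
    label volume, the (labelA, labelB) pairs, and one annotated point pair
    per tube pair (a voxel on each tube's centre line at mid-length).
    """
    rng = np.random.default_rng(seed)
    d = 2 * radius_vox + 1
    cell_y = 2 * d + gap_vox + 6
    cell_z = d + 6
    n_cols = int(np.ceil(np.sqrt(n_pairs)))
    n_rows = int(np.ceil(n_pairs / n_cols))
    shape = (tube_len, n_cols * cell_y, n_rows * cell_z)
    data = np.zeros(shape, dtype=np.int32)
    yy, zz = np.mgrid[-radius_vox : radius_vox + 1, -radius_vox : radius_vox + 1]
    disk = np.stack([yy[yy**2 + zz**2 <= radius_vox**2], zz[yy**2 + zz**2 <= radius_vox**2]], 1)

    pairs, points = [], []
    lab = 1
    for p in range(n_pairs):
        col, row = p % n_cols, p // n_cols
        y0 = col * cell_y + 3 + radius_vox
        z0 = row * cell_z + 3 + radius_vox
        y1 = y0 + d + gap_vox  # second tube centre line
        for y_c, l in ((y0, lab), (y1, lab + 1)):
            for dy, dz in disk:
                data[:, y_c + dy, z0 + dz] = l
        pairs.append((lab, lab + 1))
        xm = tube_len // 2 + int(rng.integers(-tube_len // 4, tube_len // 4 + 1))
        points.append(((xm, y0, z0), (xm, y1, z0)))
        lab += 2
    return Volume(data, voxel_size), pairs, points


def make_focus_stack(
    shape: tuple[int, int, int],
    blur_sigmas: tuple[float, ...] = (0.0, 8.0),
    seed: int = 0,
    region_labels: np.ndarray | None = None,
    sharp_sigma_max: float = 1.0,
) -> tuple[Volume, np.ndarray, np.ndarray]:
    """Grayscale stack with sharp and defocused regions plus ground truth.

    A high-contrast binary texture fills the volume; each region (default:
    the two x-halves) is the same texture convolved in-plane with the
    region's Gaussian sigma.  Returns the 8-bit stack, the per-voxel
    ground-truth focus mask (True = in focus, i.e. sigma <=
    ``sharp_sigma_max``) and the region-label array used.
    """
    rng = np.random.default_rng(seed)
    # full-range binary texture with ~2-voxel grain: enough power survives
    # the detector's own smoothing, emulating contrast-normalized EM planes
    gx, gy = (shape[0] + 1) // 2, (shape[1] + 1) // 2
    coarse = (rng.uniform(size=(gx, gy, shape[2])) < 0.5).astype(float) * 255.0
    base = np.repeat(np.repeat(coarse, 2, axis=0), 2, axis=1)[: shape[0], : shape[1], :]
    if region_labels is None:
        region_labels = np.zeros(shape, dtype=np.int32)
        region_labels[shape[0] // 2 :, :, :] = 1
    region_labels = np.asarray(region_labels)
    out = np.zeros(shape, dtype=float)
    focus = np.zeros(shape, dtype=bool)
    for rid, sigma in enumerate(blur_sigmas):
        m = region_labels == rid
        if not m.any():
            continue
        if sigma > 0:
            blurred = ndimage.gaussian_filter(base, sigma=(sigma, sigma, 0))
        else:
            blurred = base
        out[m] = blurred[m]
        focus[m] = sigma <= sharp_sigma_max
    vol = Volume(np.clip(np.round(out), 0, 255).astype(np.uint8))
    return vol, focus, region_labels
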