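import numpy as np
import pytest

from vemtools.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Shared desk-scale phantom: 6 tubes, 1 soma+nucleus, 3 synapses."""
    spec = PhantomSpec(
        shape=(160, 256, 96), n_neurites=6, n_somata=1, n_synapses=3, seed=3
    )
    return make_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def union_find_partition(n_nodes, edges):
    """Independent union-find oracle: node -> canonical component root."""
    parent = list(range(n_nodes))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    roots = {}
    out = [0] * n_nodes
    for i in range(n_nodes):
        r = find(i)
        roots.setdefault(r, min(i, r))
        out[i] = roots[r]
    return out


def mask_partition_oracle(mask, conn):
    """Union-find over neighbour pairs of a binary 3D mask."""
    coords = np.argwhere(mask)
    index = {tuple(c): i for i, c in enumerate(coords)}
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if conn == 6 and order > 1:
                    continue
                if conn == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    edges = []
    for i, c in enumerate(coords):
        for off in offsets:
            nb = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
            j = index.get(nb)
            if j is not None and j > i:
                edges.append((i, j))
    part = union_find_partition(len(coords), edges)
    return {tuple(c): part[i] for i, c in enumerate(coords)}


def partitions_equal(labels_a: dict, labels_b: dict) -> bool:
    """Same grouping regardless of label values."""
    if set(labels_a) != set(labels_b):
        return False
    map_ab, map_ba = {}, {}
    for k in labels_a:
        a, b = labels_a[k], labels_b[k]
        if map_ab.setdefault(a, b) != b or map_ba.setdefault(b, a) != a:
            return False
    return True
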