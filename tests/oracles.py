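"""Brute-force definitional implementations used as independent oracles.

Each function here follows the mathematical definition literally (loops
over voxels and offsets, breadth-first flood fill, direct set counting)
and is kept independent of the package's vectorized implementations.
"""

from collections import deque

import numpy as np


def brute_ball_offsets(radius):
    """All integer offset triples with Euclidean norm <= radius."""
    out = []
    for dx in range(-radius, radius + 1):
        for dy in range(-radius, radius + 1):
            for dz in range(-radius, radius + 1):
                if dx * dx + dy * dy + dz * dz <= radius * radius:
                    out.append((dx, dy, dz))
    return out


def brute_erode(mask, offsets):
    """Voxel kept iff every offset lands inside the grid on foreground."""
    nx, ny, nz = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for x, y, z in np.argwhere(mask):
        ok = True
        for dx, dy, dz in offsets:
            u, v, w = x + dx, y + dy, z + dz
            if not (0 <= u < nx and 0 <= v < ny and 0 <= w < nz) or not mask[u, v, w]:
                ok = False
                break
        out[x, y, z] = ok
    return out


def brute_dilate(mask, offsets):
    """Voxel set iff any offset reaches an input foreground voxel."""
    nx, ny, nz = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for x, y, z in np.argwhere(mask):
        for dx, dy, dz in offsets:
            u, v, w = x + dx, y + dy, z + dz
            if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz:
                out[u, v, w] = True
    return out


def brute_open(mask, offsets):
    return brute_dilate(brute_erode(mask, offsets), offsets)


_NEIGHBOURS = {
    6: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
        for dz in (-1, 0, 1) if abs(dx) + abs(dy) + abs(dz) == 1],
    18: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
         for dz in (-1, 0, 1) if 1 <= abs(dx) + abs(dy) + abs(dz) <= 2],
    26: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
         for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)],
}


def brute_components(mask, connectivity):
    """Flood-fill labelling; labels 1..K in decreasing size order, ties by
    smallest minimum raster (C-order) index."""
    nx, ny, nz = mask.shape
    nbrs = _NEIGHBOURS[connectivity]
    raw = np.zeros(mask.shape, dtype=np.int32)
    comps = []  # (size, first raster index, raw label)
    next_label = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if mask[x, y, z] and raw[x, y, z] == 0:
                    next_label += 1
                    queue = deque([(x, y, z)])
                    raw[x, y, z] = next_label
                    size = 0
                    while queue:
                        cx, cy, cz = queue.popleft()
                        size += 1
                        for dx, dy, dz in nbrs:
                            u, v, w = cx + dx, cy + dy, cz + dz
                            if (0 <= u < nx and 0 <= v < ny and 0 <= w < nz
                                    and mask[u, v, w] and raw[u, v, w] == 0):
                                raw[u, v, w] = next_label
                                queue.append((u, v, w))
                    comps.append((size, (x * ny + y) * nz + z, next_label))
    comps.sort(key=lambda c: (-c[0], c[1]))
    remap = np.zeros(next_label + 1, dtype=np.int32)
    for new, (_, _, old) in enumerate(comps, start=1):
        remap[old] = new
    return remap[raw], np.array([c[0] for c in comps], dtype=np.int64)


def brute_overlap_counts(ref, seg):
    """Direct voxel-loop counting of |Vm|, |Va| and |Vm ∩ Va|."""
    n_ref = n_seg = n_int = 0
    for r, s in zip(ref.ravel(), seg.ravel()):
        if r:
            n_ref += 1
        if s:
            n_seg += 1
        if r and s:
            n_int += 1
    return n_ref, n_seg, n_int
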