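"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and the scipy/scikit-image
primitives) they verify: connected components by explicit BFS flood
fill, Otsu by exhaustive search over every candidate cut, erosion by the
Minkowski definition, covariance by accumulation loops.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def neighbor_offsets(connectivity: int):
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                n_nonzero = sum(1 for d in (dz, dy, dx) if d != 0)
                if connectivity == 6 and n_nonzero > 1:
                    continue
                if connectivity == 18 and n_nonzero > 2:
                    continue
                offsets.append((dz, dy, dx))
    return offsets


def flood_fill_partition(mask: np.ndarray, connectivity: int) -> set[frozenset]:
    """Partition of foreground voxels into connected components (BFS)."""
    offsets = neighbor_offsets(connectivity)
    shape = mask.shape
    seen = np.zeros(shape, dtype=bool)
    components = set()
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        comp = []
        while queue:
            v = queue.popleft()
            comp.append(v)
            for off in offsets:
                w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if all(0 <= w[i] < shape[i] for i in range(3)) and mask[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        components.add(frozenset(comp))
    return components


def label_partition(labels: np.ndarray) -> set[frozenset]:
    """Partition induced by a label image (for comparing against flood fill)."""
    out = set()
    for lab in np.unique(labels):
        if lab == 0:
            continue
        out.add(frozenset(map(tuple, np.argwhere(labels == lab))))
    return out


def exhaustive_otsu(values: np.ndarray, nbins: int = 256) -> float | None:
    """Otsu threshold by trying every candidate cut of a 256-bin histogram."""
    values = np.asarray(values, dtype=np.float64).ravel()
    lo, hi = values.min(), values.max()
    if lo == hi:
        return None
    hist, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    variances = np.full(nbins - 1, -1.0)
    for cut in range(nbins - 1):
        w0 = hist[: cut + 1].sum()
        w1 = hist[cut + 1:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: cut + 1] * centers[: cut + 1]).sum() / w0
        mu1 = (hist[cut + 1:] * centers[cut + 1:]).sum() / w1
        variances[cut] = w0 * w1 * (mu0 - mu1) ** 2
    # ties (plateaus over empty bins) resolve to the lowest threshold,
    # with a relative tolerance absorbing summation round-off
    best_cut = int(np.flatnonzero(variances >= variances.max() * (1 - 1e-9))[0])
    return float(edges[best_cut + 1])


def ball_offsets(radius: int):
    offs = []
    for dz in range(-radius, radius + 1):
        for dy in range(-radius, radius + 1):
            for dx in range(-radius, radius + 1):
                if dz * dz + dy * dy + dx * dx <= radius * radius:
                    offs.append((dz, dy, dx))
    return offs


def minkowski_erosion(mask: np.ndarray, radius: int) -> np.ndarray:
    """Erosion per the Minkowski definition: a voxel survives iff every
    structuring-element translate stays in the foreground (outside = background)."""
    out = np.ones_like(mask)
    for offset in ball_offsets(radius):
        # shifted[v] = mask[v + s], with out-of-bounds reading as background
        shifted = np.zeros_like(mask)
        src = [slice(max(0, d), mask.shape[i] + min(0, d)) for i, d in enumerate(offset)]
        dst = [slice(max(0, -d), mask.shape[i] + min(0, -d)) for i, d in enumerate(offset)]
        shifted[tuple(dst)] = mask[tuple(src)]
        out &= shifted
    return out


def covariance_by_loops(coords: np.ndarray, spacing) -> np.ndarray:
    """3x3 covariance of voxel coordinates in physical units, accumulated
    element by element, with the voxel-as-box diagonal term."""
    n = len(coords)
    pts = [tuple(c * s for c, s in zip(row, spacing)) for row in coords]
    mean = [sum(p[i] for p in pts) / n for i in range(3)]
    cov = np.zeros((3, 3))
    for p in pts:
        for i in range(3):
            for j in range(3):
                cov[i, j] += (p[i] - mean[i]) * (p[j] - mean[j])
    cov /= n
    for i in range(3):
        cov[i, i] += spacing[i] ** 2 / 12.0
    return cov
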