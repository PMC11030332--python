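"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written along a different code path than
the package: per-offset scans instead of distance transforms, an
order-independent Jacobi fixed point instead of ordered sweeps, and
graph Dijkstra via scipy.sparse.csgraph.  Oracles are only run on tiny
inputs.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph


def ball_offsets(radius: int) -> np.ndarray:
    r = int(radius)
    g = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1].reshape(3, -1).T
    return g[(g**2).sum(axis=1) <= r * r]


def _shift(arr: np.ndarray, dz: int, dy: int, dx: int, fill: bool) -> np.ndarray:
    """arr translated by (dz, dy, dx), padding with ``fill``."""
    out = np.full_like(arr, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, d in enumerate((dz, dy, dx)):
        n = arr.shape[ax]
        if abs(d) >= n:
            return out
        if d >= 0:
            src[ax] = slice(0, n - d)
            dst[ax] = slice(d, n)
        else:
            src[ax] = slice(-d, n)
            dst[ax] = slice(0, n + d)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def brute_dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    """Per-offset ball scan: active iff some active voxel within the ball."""
    out = np.zeros_like(mask)
    for dz, dy, dx in ball_offsets(radius):
        out |= _shift(mask, dz, dy, dx, fill=False)
    return out


def brute_erode(mask: np.ndarray, radius: int) -> np.ndarray:
    """Active iff the whole ball is active; out-of-domain counts background."""
    out = np.ones_like(mask)
    for dz, dy, dx in ball_offsets(radius):
        out &= _shift(mask, dz, dy, dx, fill=False)
    return out


def brute_close(mask: np.ndarray, radius: int) -> np.ndarray:
    """Unbounded-domain closing: pad so the dilation is never clipped."""
    r = int(radius)
    padded = np.pad(mask, r, constant_values=False)
    closed = brute_erode(brute_dilate(padded, r), r)
    return closed[r:-r, r:-r, r:-r] if r else closed


def brute_open(mask: np.ndarray, radius: int) -> np.ndarray:
    return brute_dilate(brute_erode(mask, radius), radius)


def brute_surface(mask: np.ndarray) -> np.ndarray:
    """Active voxels with an inactive 6-neighbor (outside counts inactive)."""
    out = np.zeros_like(mask)
    for z, y, x in np.argwhere(mask):
        on_surface = False
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nz, ny, nx = z + dz, y + dy, x + dx
            if not (
                0 <= nz < mask.shape[0]
                and 0 <= ny < mask.shape[1]
                and 0 <= nx < mask.shape[2]
            ) or not mask[nz, ny, nx]:
                on_surface = True
                break
        out[z, y, x] = on_surface
    return out


_OFFSETS = {
    6: [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if abs(dz) + abs(dy) + abs(dx) == 1],
    18: [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
         if 0 < abs(dz) + abs(dy) + abs(dx) <= 2],
    26: [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
         if (dz, dy, dx) != (0, 0, 0)],
}


def flood_fill_labels(mask: np.ndarray, connectivity: int = 26) -> list[set]:
    """BFS flood fill; returns the partition as a list of coordinate sets."""
    offsets = _OFFSETS[connectivity]
    seen = np.zeros_like(mask)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp = {start}
        seen[start] = True
        stack = [start]
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                nz, ny, nx = z + dz, y + dy, x + dx
                if (
                    0 <= nz < mask.shape[0]
                    and 0 <= ny < mask.shape[1]
                    and 0 <= nx < mask.shape[2]
                    and mask[nz, ny, nx]
                    and not seen[nz, ny, nx]
                ):
                    seen[nz, ny, nx] = True
                    comp.add((nz, ny, nx))
                    stack.append((nz, ny, nx))
        comps.append(comp)
    return comps


def brute_threshold(values: np.ndarray, fg_percent: float):
    """Exhaustive scan over unique intensities; returns (threshold, fraction)."""
    n = values.size
    best = None
    for t in np.unique(values):
        frac = float((values > t).sum()) / n
        err = abs(frac - fg_percent)
        if best is None or err < best[0] - 1e-15 or (abs(err - best[0]) <= 1e-15 and frac < best[2]):
            best = (err, float(t), frac)
    return best[1], best[2]


def eikonal_jacobi(mask: np.ndarray, seed_zero: np.ndarray, spacing, tol=1e-9, max_iter=100000):
    """Order-independent fixed point of the solver's local update.

    The local update is min(Godunov 6-neighbor upwind eikonal update,
    26-neighbor direct step candidates).  All voxels are updated
    simultaneously from the previous iterate (Jacobi), so no sweep
    ordering is involved; iterate until no value changes by more than
    ``tol``.  ``seed_zero`` is a boolean array of zero-value voxels.
    """
    hz, hy, hx = spacing
    dist = np.full(mask.shape, np.inf)
    dist[seed_zero & mask] = 0.0

    def axis_min(d, axis):
        lo = np.full(mask.shape, np.inf)
        hi = np.full(mask.shape, np.inf)
        sl_lo_dst = [slice(None)] * 3
        sl_lo_src = [slice(None)] * 3
        sl_lo_dst[axis] = slice(1, None)
        sl_lo_src[axis] = slice(None, -1)
        lo[tuple(sl_lo_dst)] = np.where(mask[tuple(sl_lo_src)], d[tuple(sl_lo_src)], np.inf)
        sl_hi_dst = [slice(None)] * 3
        sl_hi_src = [slice(None)] * 3
        sl_hi_dst[axis] = slice(None, -1)
        sl_hi_src[axis] = slice(1, None)
        hi[tuple(sl_hi_dst)] = np.where(mask[tuple(sl_hi_src)], d[tuple(sl_hi_src)], np.inf)
        return np.minimum(lo, hi)

    h = np.array([hz, hy, hx])
    for _ in range(max_iter):
        a = np.stack([axis_min(dist, ax) for ax in range(3)], axis=-1)  # (...,3)
        order = np.argsort(a, axis=-1)
        a_sorted = np.take_along_axis(a, order, axis=-1)
        h_sorted = np.take_along_axis(
            np.broadcast_to(h, a.shape), order, axis=-1
        )
        # k=1
        u = a_sorted[..., 0] + h_sorted[..., 0]
        # k=2 where u exceeds the second neighbor value
        w0 = 1.0 / h_sorted[..., 0] ** 2
        w1 = 1.0 / h_sorted[..., 1] ** 2
        with np.errstate(invalid="ignore"):
            need2 = u > a_sorted[..., 1]
            A = w0 + w1
            B = w0 * a_sorted[..., 0] + w1 * a_sorted[..., 1]
            C = w0 * a_sorted[..., 0] ** 2 + w1 * a_sorted[..., 1] ** 2 - 1.0
            disc = np.maximum(B * B - A * C, 0.0)
            u2 = (B + np.sqrt(disc)) / A
            u = np.where(need2 & np.isfinite(a_sorted[..., 1]), u2, u)
            # k=3
            need3 = u > a_sorted[..., 2]
            w2 = 1.0 / h_sorted[..., 2] ** 2
            A3 = A + w2
            B3 = B + w2 * a_sorted[..., 2]
            C3 = C + w2 * a_sorted[..., 2] ** 2
            disc3 = np.maximum(B3 * B3 - A3 * C3, 0.0)
            u3 = (B3 + np.sqrt(disc3)) / A3
            u = np.where(need2 & need3 & np.isfinite(a_sorted[..., 2]), u3, u)
        # direct 26-neighbor step candidates
        for dz, dy, dx in _OFFSETS[26]:
            w = float(np.sqrt((dz * hz) ** 2 + (dy * hy) ** 2 + (dx * hx) ** 2))
            shifted = np.where(mask, dist, np.inf)
            shifted = np.roll(shifted, (dz, dy, dx), axis=(0, 1, 2))
            # roll wraps around; blank the wrapped borders
            if dz > 0:
                shifted[:dz] = np.inf
            elif dz < 0:
                shifted[dz:] = np.inf
            if dy > 0:
                shifted[:, :dy] = np.inf
            elif dy < 0:
                shifted[:, dy:] = np.inf
            if dx > 0:
                shifted[:, :, :dx] = np.inf
            elif dx < 0:
                shifted[:, :, dx:] = np.inf
            u = np.minimum(u, shifted + w)
        new = np.where(mask & (dist > 0), np.minimum(dist, u), dist)
        new[~mask] = np.inf
        new[seed_zero & mask] = 0.0
        finite = np.isfinite(dist) | np.isfinite(new)
        with np.errstate(invalid="ignore"):
            delta = np.where(
                np.isfinite(dist) & np.isfinite(new),
                np.abs(dist - new),
                np.where(finite, np.inf, 0.0),
            )
        dist = new
        if delta.max() <= tol:
            break
    return dist


def dijkstra26(mask: np.ndarray, seed_zero: np.ndarray, spacing) -> np.ndarray:
    """26-neighbor graph distance (Euclidean edge weights) from seed voxels."""
    coords = np.argwhere(mask)
    index = -np.ones(mask.shape, np.int64)
    index[tuple(coords.T)] = np.arange(len(coords))
    h = np.asarray(spacing)
    rows, cols, data = [], [], []
    for dz, dy, dx in _OFFSETS[26]:
        shifted = coords + (dz, dy, dx)
        sel = np.where(np.all((shifted >= 0) & (shifted < mask.shape), axis=1))[0]
        sel = sel[mask[tuple(shifted[sel].T)]]
        w = float(np.linalg.norm(np.array([dz, dy, dx]) * h))
        rows.extend(index[tuple(coords[sel].T)])
        cols.extend(index[tuple(shifted[sel].T)])
        data.extend([w] * len(sel))
    n = len(coords)
    graph = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    sources = index[seed_zero & mask]
    sources = sources[sources >= 0]
    if len(sources) == 0:
        return np.full(mask.shape, np.inf)
    d = csgraph.dijkstra(graph, directed=False, indices=sources).min(axis=0)
    out = np.full(mask.shape, np.inf)
    out[tuple(coords.T)] = d
    return out
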