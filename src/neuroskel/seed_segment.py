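"""Soma (seed) detection by surface extraction, closing and opening.

Somas are large and roughly spherical, and with surface-only labeling the
image describes *shells*.  The detector therefore works on the surface
representation of the foreground mask:

    extract_surface -> close(close_radius) -> open(open_radius)
    -> connected components (26) -> size filter

Closing fills the hollow cell bodies (the closing radius must reach the
cavity radius, i.e. about the soma radius minus the shell thickness);
opening removes the thin tubular branches.  What survives are solid
soma-shaped blobs, split into instances, each summarized by its centroid
(mean voxel position, um) and equivalent-sphere radius.

Defaults (close 7, open 3) are tied to the phantom soma geometry used
throughout the test-suite: soma radii 6–8.5 um with a 2-voxel shell, so
cavities are at most 6.5 um; branches are at most 2 um in radius.  The
size filter defaults to the volume of the opening ball — anything smaller
survived opening only as an artifact — and can be disabled
(``min_voxels=0``) to reproduce a high-recall / low-precision regime
where filtering is deferred to a human.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sparse_grid
from .sparse_grid import SparseMask

__all__ = ["SeedInstance", "SeedSet", "segment_seeds", "seed_radius", "write_seeds", "read_seeds"]


@dataclass
class SeedInstance:
    """One detected soma: its voxels, surface, centroid (um) and radius (um)."""

    id: int
    voxels: np.ndarray  # (N, 3) int voxel coords of the solid instance
    surface: np.ndarray  # (M, 3) int voxel coords of the instance surface
    centroid_um: tuple[float, float, float]  # (z, y, x)
    radius_um: float

    @property
    def voxel_count(self) -> int:
        return len(self.voxels)


@dataclass
class SeedSet:
    """Instance-labeled somas; surfaces are pairwise disjoint."""

    instances: list[SeedInstance]
    domain_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self):
        return iter(self.instances)

    def surface_mask(self) -> SparseMask:
        """Union of all instance surfaces as a mask over the domain."""
        data = np.zeros(self.domain_shape, bool)
        for inst in self.instances:
            data[inst.surface[:, 0], inst.surface[:, 1], inst.surface[:, 2]] = True
        return SparseMask(data, self.voxel_size)


def seed_radius(voxel_count: int, voxel_size: tuple[float, float, float]) -> float:
    """Radius (um) of the sphere whose volume equals the instance volume."""
    if voxel_count < 1:
        raise ValueError("voxel_count must be >= 1")
    vol = voxel_count * voxel_size[0] * voxel_size[1] * voxel_size[2]
    return (3.0 * vol / (4.0 * math.pi)) ** (1.0 / 3.0)


def default_min_voxels(open_radius: int) -> int:
    """Volume of the opening ball: the smallest blob opening can preserve."""
    return len(sparse_grid.ball_offsets(open_radius))


def segment_seeds(
    mask: SparseMask,
    close_radius: int = 7,
    open_radius: int = 3,
    min_voxels: int | None = None,
) -> SeedSet:
    """Locate and instance-label somas in a foreground mask.

    ``min_voxels=None`` applies the default size filter
    (:func:`default_min_voxels`); pass 0 to keep every component.
    An empty mask yields an empty SeedSet.
    """
    if close_radius < 1 or open_radius < 1:
        raise ValueError("close_radius and open_radius must be >= 1")
    if min_voxels is None:
        min_voxels = default_min_voxels(open_radius)
    if min_voxels < 0:
        raise ValueError("min_voxels must be >= 0")

    surface = sparse_grid.extract_surface(mask)
    closed = sparse_grid.close(surface, close_radius)
    opened = sparse_grid.open_(closed, open_radius)
    labelled = sparse_grid.connected_components(opened, connectivity=26)

    vs = np.asarray(mask.voxel_size)
    instances: list[SeedInstance] = []
    next_id = 1
    for label in range(1, labelled.n_labels + 1):
        comp = labelled.mask_of(label)
        voxels = comp.coords()
        if len(voxels) < min_voxels:
            continue
        surf = sparse_grid.extract_surface(comp).coords()
        centroid = tuple((voxels.mean(axis=0) * vs).tolist())
        instances.append(
            SeedInstance(
                id=next_id,
                voxels=voxels,
                surface=surf,
                centroid_um=centroid,  # type: ignore[arg-type]
                radius_um=seed_radius(len(voxels), mask.voxel_size),
            )
        )
        next_id += 1
    return SeedSet(instances, mask.domain_shape, mask.voxel_size)


_SEED_COLUMNS = ["id", "z_um", "y_um", "x_um", "radius_um", "voxel_count"]


def write_seeds(seeds: SeedSet, path) -> None:
    """Write seeds as CSV: ``id,z_um,y_um,x_um,radius_um,voxel_count``."""
    rows = [
        (s.id, s.centroid_um[0], s.centroid_um[1], s.centroid_um[2], s.radius_um, s.voxel_count)
        for s in seeds
    ]
    pd.DataFrame(rows, columns=_SEED_COLUMNS).to_csv(path, index=False)


def read_seeds(path) -> pd.DataFrame:
    """Read a seed CSV (header required; centroid coordinates in um)."""
    df = pd.read_csv(path)
    missing = [c for c in _SEED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"seed CSV {path} missing columns: {missing}")
    return df
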