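"""Spatial static dielectric permittivity maps.

The protein interior is partitioned into four discrete permittivity layers
(eps 3, 5, 10, 20) driven by the local density of polar side-chain O/N
atoms; the lipid bilayer is an implicit slab with a low-permittivity acyl
core (eps 2.0 or 2.5) flanked by headgroup bands (eps 20 or 40); everything
else is aqueous solvent with eps 81 and a Debye screening term set by the
ionic strength.  Maps rasterize onto regular grids at any spacing, which is
what the focused Poisson-Boltzmann runs rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .structure_io import ParameterizedStructure

__all__ = [
    "GridSpec",
    "MembraneSlab",
    "DielectricMap",
    "DielectricScene",
    "REGION_SOLVENT",
    "REGION_MEMBRANE_CORE",
    "REGION_MEMBRANE_HEAD",
    "protein_region_label",
    "polar_density",
    "default_density_mapping",
    "build_eps_map",
    "apply_membrane",
    "uniform_map",
    "grid_from_structure",
    "write_dx",
]

PROTEIN_LEVELS = (3.0, 5.0, 10.0, 20.0)
REGION_SOLVENT = 0
# protein layers are regions 1..n_levels (1 -> eps 3, ... 4 -> eps 20)
REGION_MEMBRANE_CORE = 101
REGION_MEMBRANE_HEAD = 102

REGION_NAMES = {
    REGION_SOLVENT: "solvent",
    1: "protein_layer_3",
    2: "protein_layer_5",
    3: "protein_layer_10",
    4: "protein_layer_20",
    REGION_MEMBRANE_CORE: "membrane_core",
    REGION_MEMBRANE_HEAD: "membrane_head",
}


def protein_region_label(level_index: int) -> int:
    return level_index + 1


@dataclass(frozen=True)
class GridSpec:
    """Regular node-centred grid: node (i,j,k) sits at origin + h*(i,j,k)."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(d < 2 for d in self.dims):
            raise ValueError("grid needs at least 2 nodes per axis")

    @property
    def upper(self) -> np.ndarray:
        return np.asarray(self.origin) + self.spacing * (np.asarray(self.dims) - 1)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o = np.asarray(self.origin)
        return tuple(o[i] + self.spacing * np.arange(self.dims[i]) for i in range(3))

    def contains(self, points: np.ndarray, pad: float = 0.0) -> bool:
        points = np.atleast_2d(points)
        lo = np.asarray(self.origin) + pad
        hi = self.upper - pad
        return bool(np.all(points >= lo) and np.all(points <= hi))


def grid_from_structure(
    structure: ParameterizedStructure, spacing: float = 0.5, margin: float = 15.0
) -> GridSpec:
    """Box enclosing all atoms plus ``margin`` per side (default mid-range of
    the 10-17 A margins customary for protein PB grids)."""
    pos = structure.positions
    lo = pos.min(axis=0) - margin
    hi = pos.max(axis=0) + margin
    dims = tuple(int(math.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
    return GridSpec(origin=tuple(lo), spacing=spacing, dims=dims)


@dataclass(frozen=True)
class MembraneSlab:
    """Implicit bilayer slab normal to z: acyl core between core_zmin and
    core_zmax, headgroup bands of ``headgroup_thickness`` per leaflet."""

    core_zmin: float
    core_zmax: float
    headgroup_thickness: float = 8.0
    eps_core: float = 2.0
    eps_head: float = 20.0

    def __post_init__(self):
        if self.core_zmin >= self.core_zmax:
            raise ValueError("core_zmin must be below core_zmax")
        if self.eps_core >= self.eps_head:
            raise ValueError("eps_core must be below eps_head")


@dataclass
class DielectricMap:
    grid: GridSpec
    eps: np.ndarray
    region_labels: np.ndarray
    eps_solvent: float = 81.0
    ionic_strength: float = 0.2
    scene: "DielectricScene | None" = None

    def __post_init__(self):
        if np.any(self.eps < 1.0):
            raise ValueError("permittivity below 1")
        if self.eps.shape != tuple(self.grid.dims) or self.region_labels.shape != self.eps.shape:
            raise ValueError("eps/label arrays do not match grid dims")

    @property
    def protein_mask(self) -> np.ndarray:
        return (self.region_labels >= 1) & (self.region_labels <= len(PROTEIN_LEVELS))

    @property
    def solvent_mask(self) -> np.ndarray:
        return self.region_labels == REGION_SOLVENT

    def refine(self, grid: GridSpec) -> "DielectricMap":
        """Re-rasterize at another grid (used by PB focusing).

        Falls back to nearest-neighbour resampling when the map was not built
        from a scene (e.g. loaded from file).
        """
        if self.scene is not None:
            return self.scene.rasterize(grid)
        ax = self.grid.axes()
        idx = []
        for i, axis in enumerate(grid.axes()):
            j = np.clip(np.round((axis - ax[i][0]) / self.grid.spacing).astype(int), 0, self.grid.dims[i] - 1)
            idx.append(j)
        ii, jj, kk = np.meshgrid(*idx, indexing="ij")
        return DielectricMap(
            grid=grid,
            eps=self.eps[ii, jj, kk],
            region_labels=self.region_labels[ii, jj, kk],
            eps_solvent=self.eps_solvent,
            ionic_strength=self.ionic_strength,
        )


def default_density_mapping(density: np.ndarray | float) -> np.ndarray | float:
    """Piecewise-linear monotone map from polar side-chain O/N density
    (atoms/A^3, 5 A kernel) to a continuous permittivity.

    Breakpoints are chosen so hydrophobic interiors (density ~0) land in the
    eps-3 layer, typical buried-polar densities in eps 5-10, and densely
    polar solvated loops in the eps-20 layer.
    """
    x = np.asarray(density, dtype=float)
    xp = [0.0, 0.002, 0.005, 0.010, 0.020]
    fp = [2.0, 4.0, 7.5, 15.0, 25.0]
    return np.interp(x, xp, fp)


def polar_density(
    structure: ParameterizedStructure,
    point: np.ndarray,
    kernel_radius: float = 5.0,
) -> float:
    """Local density of polar side-chain O/N atoms at ``point`` (atoms/A^3):
    hard-sphere count within ``kernel_radius`` over the kernel volume."""
    if kernel_radius <= 0:
        raise ValueError("kernel_radius must be positive")
    idx = structure.polar_sidechain_indices()
    if len(idx) == 0:
        return 0.0
    pos = structure.positions[idx]
    d2 = np.sum((pos - np.asarray(point, dtype=float)) ** 2, axis=1)
    count = int(np.sum(d2 <= kernel_radius**2))
    return count / (4.0 / 3.0 * math.pi * kernel_radius**3)


def _quantize_levels(eps_cont: np.ndarray, levels: Sequence[float]) -> np.ndarray:
    """Index of nearest level; ties break upward (toward higher screening)."""
    levels = np.asarray(sorted(levels), dtype=float)
    mids = 0.5 * (levels[:-1] + levels[1:])
    return np.searchsorted(mids, eps_cont, side="right")


def _ball_footprint(radius_cells: float) -> np.ndarray:
    r = int(math.floor(radius_cells))
    if r < 1:
        return np.ones((1, 1, 1), dtype=bool)
    ax = np.arange(-r, r + 1)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    return X**2 + Y**2 + Z**2 <= radius_cells**2


@dataclass
class DielectricScene:
    """Everything needed to rasterize the permittivity field at any grid."""

    structure: ParameterizedStructure
    mapping: Callable[[np.ndarray], np.ndarray] = default_density_mapping
    levels: tuple[float, ...] = PROTEIN_LEVELS
    kernel_radius: float = 5.0
    probe_radius: float = 1.4
    eps_solvent: float = 81.0
    ionic_strength: float = 0.2
    slab: MembraneSlab | None = None

    def rasterize(self, grid: GridSpec) -> DielectricMap:
        h = grid.spacing
        axes = grid.axes()
        inside = self._protein_mask(grid)
        labels = np.full(grid.dims, REGION_SOLVENT, dtype=np.int16)
        eps = np.full(grid.dims, float(self.eps_solvent))

        if inside.any():
            pts = np.argwhere(inside)
            coords = np.asarray(grid.origin) + h * pts
            rho = self._density_at(coords)
            eps_cont = np.asarray(self.mapping(rho), dtype=float)
            if np.any(eps_cont < 1.0):
                raise ValueError("density->eps mapping returned permittivity < 1")
            level_idx = _quantize_levels(eps_cont, self.levels)
            labels[tuple(pts.T)] = level_idx + 1
            eps[tuple(pts.T)] = np.asarray(sorted(self.levels))[level_idx]

        dmap = DielectricMap(
            grid=grid,
            eps=eps,
            region_labels=labels,
            eps_solvent=self.eps_solvent,
            ionic_strength=self.ionic_strength,
            scene=self,
        )
        if self.slab is not None:
            # focused sub-grids may lie entirely outside the slab
            dmap = apply_membrane(dmap, self.slab, _rebuild_scene=False, strict=False)
            dmap.scene = self
        return dmap

    def _protein_mask(self, grid: GridSpec) -> np.ndarray:
        """Voxel inside any atom sphere, then closed by a 1.4 A rolling probe
        (dilation+erosion), approximating the solvent-excluded surface."""
        h = grid.spacing
        mask = np.zeros(grid.dims, dtype=bool)
        origin = np.asarray(grid.origin)
        st = self.structure
        radii = st.radii
        if np.any(~np.isfinite(radii)):
            raise ValueError("structure must have radii assigned before mapping")
        for pos, r in zip(st.positions, radii):
            if r <= 0:
                continue
            lo = np.maximum(np.floor((pos - r - origin) / h).astype(int), 0)
            hi = np.minimum(np.ceil((pos + r - origin) / h).astype(int) + 1, grid.dims)
            if np.any(lo >= hi):
                continue
            sl = tuple(slice(lo[i], hi[i]) for i in range(3))
            sub = np.meshgrid(
                *(origin[i] + h * np.arange(lo[i], hi[i]) for i in range(3)), indexing="ij"
            )
            d2 = sum((sub[i] - pos[i]) ** 2 for i in range(3))
            mask[sl] |= d2 <= r**2
        if self.probe_radius > 0 and mask.any():
            foot = _ball_footprint(self.probe_radius / h)
            mask = ndimage.binary_closing(mask, structure=foot)
        return mask

    def _density_at(self, coords: np.ndarray) -> np.ndarray:
        idx = self.structure.polar_sidechain_indices()
        if len(idx) == 0:
            return np.zeros(len(coords))
        tree = cKDTree(self.structure.positions[idx])
        counts = tree.query_ball_point(coords, r=self.kernel_radius, return_length=True)
        return counts / (4.0 / 3.0 * math.pi * self.kernel_radius**3)


def build_eps_map(
    structure: ParameterizedStructure,
    grid: GridSpec,
    mapping: Callable[[np.ndarray], np.ndarray] | None = None,
    levels: Sequence[float] = PROTEIN_LEVELS,
    kernel_radius: float = 5.0,
    probe_radius: float = 1.4,
    eps_solvent: float = 81.0,
    ionic_strength: float = 0.2,
    slab: MembraneSlab | None = None,
) -> DielectricMap:
    """Build the layered permittivity map for a parameterized structure."""
    scene = DielectricScene(
        structure=structure,
        mapping=mapping or default_density_mapping,
        levels=tuple(levels),
        kernel_radius=kernel_radius,
        probe_radius=probe_radius,
        eps_solvent=eps_solvent,
        ionic_strength=ionic_strength,
        slab=slab,
    )
    return scene.rasterize(grid)


def apply_membrane(
    dmap: DielectricMap, slab: MembraneSlab, _rebuild_scene: bool = True, strict: bool = True
) -> DielectricMap:
    """Overlay the membrane slab on non-protein voxels (protein wins)."""
    zlo, zhi = dmap.grid.origin[2], dmap.grid.upper[2]
    if slab.core_zmax < zlo or slab.core_zmin > zhi:
        if strict:
            raise ValueError("membrane slab lies outside the grid box")
        return dmap
    z = dmap.grid.axes()[2]
    core = (z >= slab.core_zmin) & (z <= slab.core_zmax)
    head = (
        (z >= slab.core_zmin - slab.headgroup_thickness)
        & (z <= slab.core_zmax + slab.headgroup_thickness)
        & ~core
    )
    eps = dmap.eps.copy()
    labels = dmap.region_labels.copy()
    free = ~dmap.protein_mask
    core3 = free & core[None, None, :]
    head3 = free & head[None, None, :]
    eps[core3] = slab.eps_core
    labels[core3] = REGION_MEMBRANE_CORE
    eps[head3] = slab.eps_head
    labels[head3] = REGION_MEMBRANE_HEAD
    scene = None
    if _rebuild_scene and dmap.scene is not None:
        scene = replace(dmap.scene, slab=slab)
    return DielectricMap(
        grid=dmap.grid,
        eps=eps,
        region_labels=labels,
        eps_solvent=dmap.eps_solvent,
        ionic_strength=dmap.ionic_strength,
        scene=scene,
    )


@dataclass
class _UniformScene:
    """Degenerate scene: homogeneous medium, all-solvent labels."""

    eps: float
    ionic_strength: float

    def rasterize(self, grid: GridSpec) -> DielectricMap:
        return DielectricMap(
            grid=grid,
            eps=np.full(grid.dims, float(self.eps)),
            region_labels=np.full(grid.dims, REGION_SOLVENT, dtype=np.int16),
            eps_solvent=self.eps,
            ionic_strength=self.ionic_strength,
            scene=self,
        )


def uniform_map(grid: GridSpec, eps: float, ionic_strength: float = 0.0) -> DielectricMap:
    """Homogeneous medium (labelled solvent everywhere) -- the closed-form
    Coulomb/Debye oracle geometry."""
    return _UniformScene(eps=eps, ionic_strength=ionic_strength).rasterize(grid)


def write_dx(dmap_or_grid, array: np.ndarray | None = None, path: str | Path = "map.dx") -> None:
    """Export a scalar grid as OpenDX (APBS/DelPhi-compatible) via gridData."""
    from gridData import Grid

    if array is None:
        grid, array = dmap_or_grid.grid, dmap_or_grid.eps
    else:
        grid = dmap_or_grid
    g = Grid(array, origin=np.asarray(grid.origin), delta=[grid.spacing] * 3)
    g.export(str(path), file_format="dx")
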