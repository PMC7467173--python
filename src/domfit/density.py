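"""Density maps: MRC/CCP4 I/O, resampling, composite construction,
map simulation from coordinates, masking and search-point selection.

Grid convention
---------------
A :class:`DensityMap` stores its grid indexed ``[ix, iy, iz]`` in
right-handed xyz order. ``origin`` is the Å position of the grid
*corner*: the center of voxel ``(0, 0, 0)`` sits at
``origin + voxel_size / 2``, and in general the center of voxel
``(i, j, k)`` is ``origin + (i + 0.5, j + 0.5, k + 0.5) * voxel_size``.

Files are written as MRC2014 mode-2 (float32) with the grid origin in
the ORIGIN header words; files whose axis order differs from xyz
(MAPC/MAPR/MAPS permuted) are canonicalized on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import (
    DegenerateMapError,
    EmptyOverlapError,
    FormatError,
    GridMismatchError,
    UndersamplingError,
)

__all__ = [
    "DensityMap",
    "SearchPoints",
    "read_map",
    "write_map",
    "resample",
    "normalize_map",
    "histogram_match",
    "composite",
    "sigma_from_resolution",
    "simulate_map",
    "simulate_on_grid",
    "mask_out",
    "select_search_points",
]


@dataclass
class DensityMap:
    """A 3D scalar field on a regular grid.

    Parameters
    ----------
    grid : ndarray, shape (nx, ny, nz)
        Density values in xyz axis order.
    voxel_size : array-like of 3 floats
        Å per voxel along x, y, z; all positive.
    origin : array-like of 3 floats
        Å position of the grid corner (see module docstring).
    metadata : dict
        Free-form provenance (e.g. the Gaussian width convention used
        by :func:`simulate_map`).
    """

    grid: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise ValueError("grid must be 3D with all dimensions >= 1")
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be positive on all axes")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3).copy()

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def voxel_center(self, index: np.ndarray) -> np.ndarray:
        """Å position of the center(s) of voxel index(es) (..., 3)."""
        return self.origin + (np.asarray(index, dtype=float) + 0.5) * self.voxel_size

    def fractional_index(self, position: np.ndarray) -> np.ndarray:
        """Continuous voxel index of Å position(s); voxel centers map to integers."""
        return (np.asarray(position, dtype=float) - self.origin) / self.voxel_size - 0.5

    def voxel_centers(self) -> np.ndarray:
        """All voxel centers, shape (nx, ny, nz, 3)."""
        axes = [
            self.origin[d] + (np.arange(self.shape[d]) + 0.5) * self.voxel_size[d]
            for d in range(3)
        ]
        g = np.meshgrid(*axes, indexing="ij")
        return np.stack(g, axis=-1)

    @property
    def extent_min(self) -> np.ndarray:
        return self.origin.copy()

    @property
    def extent_max(self) -> np.ndarray:
        return self.origin + np.array(self.shape) * self.voxel_size

    def copy(self) -> "DensityMap":
        return DensityMap(
            self.grid.copy(), self.voxel_size.copy(), self.origin.copy(),
            dict(self.metadata),
        )

    def same_grid(self, other: "DensityMap", atol: float = 1e-4) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def interpolate(self, positions: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at Å positions (N, 3); 0 outside."""
        idx = self.fractional_index(np.atleast_2d(positions))
        return ndimage.map_coordinates(
            self.grid.astype(float), idx.T, order=1, mode="constant", cval=0.0
        )


@dataclass
class SearchPoints:
    """High-density candidate translations for docking.

    ``points`` are voxel centers ordered by non-increasing density with
    all pairwise distances strictly greater than the separation used to
    build them; ``indices`` are the corresponding integer voxel indices.
    """

    points: np.ndarray      # (N, 3) Å
    densities: np.ndarray   # (N,)
    indices: np.ndarray     # (N, 3) int voxel indices
    min_separation: float = 0.0

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# file I/O (gemmi)
# ---------------------------------------------------------------------------

def read_map(path: str | Path) -> DensityMap:
    """Read an MRC2014/CCP4 map, canonicalizing axis order to xyz.

    The ORIGIN header is honored when set; otherwise the origin is
    reconstructed from the start indices (NXSTART etc.) and voxel size.
    Only orthogonal cells (90/90/90) are supported.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot read map {path}: {exc}") from exc
    cell = m.grid.unit_cell
    if not (
        abs(cell.alpha - 90) < 1e-3
        and abs(cell.beta - 90) < 1e-3
        and abs(cell.gamma - 90) < 1e-3
    ):
        raise FormatError(f"non-orthogonal cell in {path}; skewed maps unsupported")
    origin = np.array(
        [m.header_float(50), m.header_float(51), m.header_float(52)], dtype=float
    )
    nstart = np.array(
        [m.header_i32(5), m.header_i32(6), m.header_i32(7)], dtype=float
    )
    m.setup(0.0, gemmi.MapSetup.ReorderOnly)
    grid = np.array(m.grid, copy=True)
    voxel = np.array(m.grid.spacing, dtype=float)
    if np.any(voxel <= 0):
        raise FormatError(f"non-positive voxel size in {path}")
    if np.all(origin == 0) and np.any(nstart != 0):
        origin = nstart * voxel
    return DensityMap(grid, voxel, origin, metadata={"source": str(path)})


def write_map(density: DensityMap, path: str | Path) -> None:
    """Write as MRC2014 mode-2 (float32), xyz axis order, P1 cell."""
    arr = np.ascontiguousarray(density.grid, dtype=np.float32)
    nx, ny, nz = arr.shape
    vx, vy, vz = density.voxel_size
    cell = gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90.0, 90.0, 90.0)
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(arr, cell, gemmi.SpaceGroup("P1"))
    m.update_ccp4_header()
    for word, value in zip((50, 51, 52), density.origin):
        m.set_header_float(word, float(value))
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# resampling and composite construction
# ---------------------------------------------------------------------------

def resample(source: DensityMap, target: DensityMap) -> DensityMap:
    """Interpolate ``source`` onto ``target``'s grid (trilinear).

    Voxels of the target grid outside the source extent become 0.
    Raises :class:`EmptyOverlapError` when the two boxes are disjoint.
    """
    lo = np.maximum(source.extent_min, target.extent_min)
    hi = np.minimum(source.extent_max, target.extent_max)
    if np.any(lo >= hi):
        raise EmptyOverlapError("source and target grids do not overlap")
    centers = target.voxel_centers().reshape(-1, 3)
    vals = source.interpolate(centers).reshape(target.shape)
    return DensityMap(
        vals, target.voxel_size.copy(), target.origin.copy(),
        metadata={"resampled_from": source.metadata.get("source", "<memory>")},
    )


def normalize_map(density: DensityMap) -> DensityMap:
    """Affine rescale to [0, 1]; rank order of voxels is preserved."""
    lo, hi = float(density.grid.min()), float(density.grid.max())
    if hi <= lo:
        raise DegenerateMapError("cannot normalize a constant map")
    out = density.copy()
    out.grid = (density.grid.astype(float) - lo) / (hi - lo)
    return out


def histogram_match(source: DensityMap, reference: DensityMap) -> DensityMap:
    """Remap ``source`` values so their empirical distribution matches
    ``reference``'s (quantile mapping with linear interpolation).

    Voxel rank order within the source is preserved (ties broken by a
    stable ordering), so Spearman correlation with the input is 1.
    """
    src = source.grid.astype(float).ravel()
    ref = np.sort(reference.grid.astype(float).ravel())
    if ref[0] == ref[-1]:
        raise DegenerateMapError("reference map is constant")
    if src.min() == src.max():
        raise DegenerateMapError("source map is constant")
    order = np.argsort(src, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(src.size)
    # quantile of each source voxel -> value at that quantile of reference
    q = ranks / (src.size - 1)
    ref_q = np.linspace(0.0, 1.0, ref.size)
    matched = np.interp(q, ref_q, ref)
    out = source.copy()
    out.grid = matched.reshape(source.shape)
    return out


def composite(maps: list[DensityMap]) -> DensityMap:
    """Density-weighted average of aligned maps on a common grid.

    Each input is first normalized to [0, 1]; per voxel the output is
    ``sum_i d_i^2 / sum_i d_i`` (each map's weight proportional to its
    own density there), and 0 where every map is 0.
    """
    if len(maps) < 2:
        raise ValueError("composite requires at least 2 maps")
    first = maps[0]
    for m in maps[1:]:
        if not first.same_grid(m):
            raise GridMismatchError("composite inputs must share one grid")
    stack = []
    for m in maps:
        g = normalize_map(m).grid
        stack.append(np.clip(g, 0.0, None))
    d = np.stack(stack)
    denom = d.sum(axis=0)
    numer = (d * d).sum(axis=0)
    out_grid = np.divide(numer, denom, out=np.zeros_like(denom), where=denom > 0)
    return DensityMap(
        out_grid, first.voxel_size.copy(), first.origin.copy(),
        metadata={"composite_of": len(maps)},
    )


# ---------------------------------------------------------------------------
# simulation from coordinates
# ---------------------------------------------------------------------------

def sigma_from_resolution(resolution: float) -> float:
    """Gaussian width (Å) for a nominal resolution: sigma = res / (pi*sqrt(2))."""
    return resolution / (np.pi * np.sqrt(2.0))


def _coords_weights(obj, weights=None):
    """Accept a Domain, a biotite AtomArray, or a plain (N, 3) array."""
    if hasattr(obj, "atoms") and hasattr(obj, "label"):      # Domain
        from .structure import atom_weights

        coords = np.asarray(obj.atoms.coord, dtype=float)
        w = atom_weights(obj.atoms) if weights is None else np.asarray(weights, float)
    elif hasattr(obj, "coord"):                               # AtomArray
        from .structure import atom_weights

        coords = np.asarray(obj.coord, dtype=float)
        w = atom_weights(obj) if weights is None else np.asarray(weights, float)
    else:
        coords = np.atleast_2d(np.asarray(obj, dtype=float))
        w = np.ones(len(coords)) if weights is None else np.asarray(weights, float)
    if coords.shape[0] == 0:
        raise ValueError("no atoms to simulate")
    return coords, w


def simulate_on_grid(
    structure,
    template: DensityMap,
    resolution: float,
    weights=None,
    truncate: float = 4.0,
) -> DensityMap:
    """Accumulate atomic Gaussians onto an existing grid geometry.

    Each atom adds a separable 3D Gaussian of width
    ``sigma_from_resolution(resolution)`` scaled so that its full grid
    sum equals the atomic weight; tails are truncated at
    ``truncate * sigma`` and contributions falling outside the grid are
    clipped. Grid values approximate ``sum of weights`` when the grid
    covers all atoms with ~3 sigma of padding.
    """
    coords, w = _coords_weights(structure, weights)
    if resolution < 2.0 * float(np.max(template.voxel_size)):
        raise UndersamplingError(
            f"resolution {resolution} Å < 2x voxel size "
            f"{np.max(template.voxel_size)} Å"
        )
    sigma = sigma_from_resolution(resolution)
    out = np.zeros(template.shape, dtype=float)
    shape = np.array(template.shape)
    vox = template.voxel_size
    origin = template.origin
    half = truncate * sigma
    norm1d = vox / (np.sqrt(2.0 * np.pi) * sigma)   # per-axis normalization
    if out.size <= 150_000:
        # separable fast path: full-length 1D profiles per atom, combined
        # with one einsum; identical values to the per-atom box loop
        profs = []
        for d in range(3):
            centers = origin[d] + (np.arange(shape[d]) + 0.5) * vox[d]
            u = (centers[None, :] - coords[:, d, None]) / sigma
            g = norm1d[d] * np.exp(-0.5 * u * u)
            g[np.abs(u) > truncate] = 0.0
            profs.append(g)
        profs[0] = profs[0] * w[:, None]
        na, ni = profs[0].shape
        nj, nk = profs[1].shape[1], profs[2].shape[1]
        pair = (profs[0][:, :, None] * profs[1][:, None, :]).reshape(na, ni * nj)
        out = (pair.T @ profs[2]).reshape(ni, nj, nk)
        return DensityMap(
            out, template.voxel_size.copy(), template.origin.copy(),
            metadata={
                "simulated": True,
                "resolution": resolution,
                "sigma": sigma,
                "sigma_convention": "resolution/(pi*sqrt(2))",
                "truncate_sigma": truncate,
            },
        )
    for a, wa in zip(coords, w):
        lo = np.floor((a - half - origin) / vox - 0.5).astype(int)
        hi = np.ceil((a + half - origin) / vox - 0.5).astype(int)
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, shape - 1)
        if np.any(lo > hi):
            continue
        g1 = []
        for d in range(3):
            centers = origin[d] + (np.arange(lo[d], hi[d] + 1) + 0.5) * vox[d]
            u = (centers - a[d]) / sigma
            g = norm1d[d] * np.exp(-0.5 * u * u)
            g[np.abs(u) > truncate] = 0.0
            g1.append(g)
        block = wa * g1[0][:, None, None] * g1[1][None, :, None] * g1[2][None, None, :]
        out[lo[0]: hi[0] + 1, lo[1]: hi[1] + 1, lo[2]: hi[2] + 1] += block
    result = DensityMap(
        out, template.voxel_size.copy(), template.origin.copy(),
        metadata={
            "simulated": True,
            "resolution": resolution,
            "sigma": sigma,
            "sigma_convention": "resolution/(pi*sqrt(2))",
            "truncate_sigma": truncate,
        },
    )
    return result


def simulate_map(
    structure,
    resolution: float,
    voxel_size: float = 2.0,
    padding: float = 10.0,
    weights=None,
    truncate: float = 4.0,
) -> DensityMap:
    """Simulate a density map from coordinates on a fresh grid.

    The grid covers the atomic coordinates plus ``padding`` Å on every
    side. See :func:`simulate_on_grid` for the Gaussian convention.
    """
    coords, w = _coords_weights(structure, weights)
    vox = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    if resolution < 2.0 * float(np.max(vox)):
        raise UndersamplingError(
            f"resolution {resolution} Å < 2x voxel size {np.max(vox)} Å"
        )
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    shape = np.maximum(np.ceil((hi - lo) / vox).astype(int), 1)
    template = DensityMap(np.zeros(shape, dtype=float), vox, lo)
    return simulate_on_grid(
        coords, template, resolution, weights=w, truncate=truncate
    )


# ---------------------------------------------------------------------------
# masking and search points
# ---------------------------------------------------------------------------

def _mask_indices_near(density: DensityMap, coords: np.ndarray, radius: float):
    """Boolean grid: voxel centers within ``radius`` Å of any coordinate."""
    coords = np.atleast_2d(coords)
    mask = np.zeros(density.shape, dtype=bool)
    shape = np.array(density.shape)
    vox = density.voxel_size
    origin = density.origin
    lo_all = np.floor((coords.min(axis=0) - radius - origin) / vox - 0.5).astype(int)
    hi_all = np.ceil((coords.max(axis=0) + radius - origin) / vox - 0.5).astype(int)
    lo_all = np.maximum(lo_all, 0)
    hi_all = np.minimum(hi_all, shape - 1)
    if np.any(lo_all > hi_all):
        return mask
    idx = np.stack(
        np.meshgrid(
            *[np.arange(lo_all[d], hi_all[d] + 1) for d in range(3)], indexing="ij"
        ),
        axis=-1,
    ).reshape(-1, 3)
    centers = density.voxel_center(idx)
    tree = cKDTree(coords)
    dists, _ = tree.query(centers, k=1, distance_upper_bound=radius)
    near = np.isfinite(dists)
    sel = idx[near]
    mask[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return mask


def mask_out(density: DensityMap, structure, radius: float = 3.0) -> DensityMap:
    """Zero out voxels within ``radius`` Å of any atom; idempotent."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    coords, _ = _coords_weights(structure)
    out = density.copy()
    mask = _mask_indices_near(density, coords, radius)
    out.grid = np.where(mask, 0.0, density.grid.astype(float))
    return out


def select_search_points(
    density: DensityMap, n_points: int = 50_000, min_separation: float = 2.0
) -> SearchPoints:
    """Greedy selection of high-density, well-separated voxel centers.

    Voxel centers are visited in order of strictly decreasing density
    (ties broken by flat voxel index, stable); a candidate is accepted
    iff it lies more than ``min_separation`` Å from every previously
    accepted point, until ``n_points`` are found or candidates run out.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    flat = density.grid.astype(float).ravel()
    order = np.argsort(-flat, kind="stable")
    shape = density.shape
    all_idx = np.stack(np.unravel_index(order, shape), axis=-1)
    centers = density.voxel_center(all_idx)

    accepted_pts: list[np.ndarray] = []
    accepted_idx: list[np.ndarray] = []
    accepted_dens: list[float] = []
    if min_separation <= 0:
        take = min(n_points, len(order))
        pts = centers[:take]
        return SearchPoints(
            pts, flat[order[:take]], all_idx[:take], min_separation
        )
    # spatial hash with cell size = min_separation: any conflicting accepted
    # point must be in one of the 27 neighboring cells
    cell = float(min_separation)
    grid_hash: dict[tuple, list[int]] = {}
    msep2 = min_separation * min_separation
    for pos, vidx, dens in zip(centers, all_idx, flat[order]):
        key = tuple((pos // cell).astype(int))
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    nb = (key[0] + dx, key[1] + dy, key[2] + dz)
                    for j in grid_hash.get(nb, ()):
                        diff = accepted_pts[j] - pos
                        if diff @ diff <= msep2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            grid_hash.setdefault(key, []).append(len(accepted_pts))
            accepted_pts.append(pos)
            accepted_idx.append(vidx)
            accepted_dens.append(float(dens))
            if len(accepted_pts) >= n_points:
                break
    return SearchPoints(
        np.array(accepted_pts).reshape(-1, 3),
        np.array(accepted_dens),
        np.array(accepted_idx).reshape(-1, 3).astype(int),
        min_separation,
    )
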