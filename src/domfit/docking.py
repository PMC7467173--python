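"""Six-dimensional rigid-body docking of one domain into a density map.

The search enumerates a quasi-uniform rotation grid against a set of
pre-selected high-density translation points. For each rotation the
overlap score at *every* candidate point is obtained at once by FFT
cross-correlation of the map with the simulated (rotated, centered)
domain density — mathematically identical to simulating the posed
domain at each point and summing voxel products, because the candidate
points are voxel centers and the Gaussian simulation is
translation-equivariant on the grid. The top candidates are then
rigid-body refined against a masked real-space correlation, pruned for
redundancy, and ranked.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial.transform import Rotation

from .config import RunConfig
from .density import (
    DensityMap,
    SearchPoints,
    select_search_points,
    sigma_from_resolution,
    simulate_on_grid,
)
from .errors import EmptyMaskError
from .structure import Domain, Placement, apply_placement

__all__ = [
    "RotationSet",
    "DockResult",
    "build_rotation_grid",
    "coarse_search",
    "masked_rsc",
    "refine_placements",
    "prune_redundant",
    "dock_domain",
]


# ---------------------------------------------------------------------------
# rotation grid
# ---------------------------------------------------------------------------

@dataclass
class RotationSet:
    """Quasi-uniform covering of SO(3); contains the identity."""

    rotations: np.ndarray      # (N, 3, 3)
    angular_step: float        # degrees

    def __len__(self) -> int:
        return len(self.rotations)


def _super_fibonacci(n: int) -> np.ndarray:
    """Deterministic quasi-uniform quaternions (super-Fibonacci spiral)."""
    phi = np.sqrt(2.0)
    psi = 1.533751168755204288118041
    i = np.arange(n) + 0.5
    t = i / n
    d = 2.0 * np.pi * i
    r = np.sqrt(t)
    big_r = np.sqrt(1.0 - t)
    alpha = d / phi
    beta = d / psi
    return np.stack(
        [
            r * np.sin(alpha),
            r * np.cos(alpha),
            big_r * np.sin(beta),
            big_r * np.cos(beta),
        ],
        axis=1,
    )


def build_rotation_grid(angular_step: float) -> RotationSet:
    """Rotation set with nearest-neighbor geodesic spacing <= step (deg).

    The size is 4x the ideal sphere-covering count for the requested
    step, which empirically keeps both the nearest-neighbor spacing and
    the covering radius of the super-Fibonacci set below the step. The
    identity rotation is always included.
    """
    if not (0 < angular_step <= 180):
        raise ValueError("angular_step must be in (0, 180] degrees")
    half = np.radians(angular_step) / 2.0
    ideal = np.pi / (2 * half - np.sin(2 * half))
    n = max(int(np.ceil(4.0 * ideal)), 4)
    quats = _super_fibonacci(n)
    mats = Rotation.from_quat(quats).as_matrix()  # (x, y, z, w) order is fine: set is symmetric
    mats = np.concatenate([np.eye(3)[None], mats], axis=0)
    return RotationSet(rotations=mats, angular_step=float(angular_step))


# ---------------------------------------------------------------------------
# coarse FFT search
# ---------------------------------------------------------------------------

class _FFTCorrelator:
    """Cross-correlate one fixed map with many kernels of a fixed shape."""

    def __init__(self, grid: np.ndarray, kernel_shape: tuple[int, int, int]):
        from scipy import fft as sfft

        self.map_shape = grid.shape
        self.kernel_shape = kernel_shape
        full = [m + k - 1 for m, k in zip(self.map_shape, kernel_shape)]
        # pad to FFT-friendly sizes; extra zero padding cannot alias the
        # linear-correlation region
        self.full = tuple(sfft.next_fast_len(n) for n in full)
        self._sfft = sfft
        self._fmap = sfft.rfftn(grid, s=self.full)

    def correlate(self, kernel: np.ndarray) -> np.ndarray:
        """Return corr[v] = sum_s kernel[s] * map[v + s - center] ('same' size)."""
        return self.correlate_batch(kernel[None])[0]

    def correlate_batch(self, kernels: np.ndarray) -> np.ndarray:
        """Correlate a stack of kernels (n, *kernel_shape) in one pass."""
        sfft = self._sfft
        rev = kernels[:, ::-1, ::-1, ::-1]
        fk = sfft.rfftn(rev, s=self.full, axes=(1, 2, 3))
        out = sfft.irfftn(self._fmap[None] * fk, s=self.full, axes=(1, 2, 3))
        # 'same' slice centered on the map (odd kernels only)
        sl = (slice(None),) + tuple(
            slice((k - 1) // 2, (k - 1) // 2 + m)
            for k, m in zip(self.kernel_shape, self.map_shape)
        )
        return out[sl]


def _centered_kernel(
    coords_local: np.ndarray,
    weights: np.ndarray,
    voxel_size: np.ndarray,
    resolution: float,
    truncate: float,
) -> tuple[DensityMap, int]:
    """Simulate centered local coordinates on a grid congruent with the map.

    The kernel grid has odd dimensions 2S+1 with the center voxel's
    center at the local origin, so integer-shift correlation against the
    map reproduces per-pose simulation exactly.
    """
    sigma = sigma_from_resolution(resolution)
    reach = np.abs(coords_local).max(axis=0) + truncate * sigma
    half = np.ceil(reach / voxel_size - 0.5).astype(int) + 1
    shape = 2 * half + 1
    origin = -(half + 0.5) * voxel_size
    template = DensityMap(np.zeros(shape), voxel_size.copy(), origin)
    k = simulate_on_grid(
        coords_local, template, resolution, weights=weights, truncate=truncate
    )
    return k, half


def coarse_search(
    domain: Domain,
    density: DensityMap,
    points: SearchPoints,
    rotations: RotationSet,
    resolution: float = 10.0,
    weights=None,
    normalize: bool = False,
    keep: int | None = None,
    truncate: float = 4.0,
) -> list[Placement]:
    """Score every (rotation, point) pose by model/map density overlap.

    The score is the voxel sum of (simulated posed density, mean-
    subtracted within its own footprint) times the map. With
    ``normalize`` the score is divided by the rotation's mean-subtracted
    self-overlap norm. Returns placements sorted by descending score
    (ties broken by rotation-then-point enumeration order); ``keep``
    caps the number materialized.
    """
    if len(points) == 0:
        raise ValueError("no search points")
    from .structure import atom_weights

    coords = domain.coords
    w = atom_weights(domain.atoms) if weights is None else np.asarray(weights, float)
    centroid = domain.centroid
    local = coords - centroid
    grid = density.grid.astype(float)
    vox = density.voxel_size
    pad = truncate * sigma_from_resolution(resolution)

    # per-rotation kernels are cropped to the rotated bounding box; the
    # per-axis half-sizes are rounded up to a small set of buckets so
    # batched FFT plans (one per kernel shape) can be reused
    rot_all = rotations.rotations
    rotated = [local @ R.T for R in rot_all]
    halves = np.empty((len(rot_all), 3), dtype=int)
    for i, rl in enumerate(rotated):
        h = np.ceil((np.abs(rl).max(axis=0) + pad) / vox - 0.5).astype(int) + 1
        halves[i] = ((h + 2) // 3) * 3  # bucket in steps of 3 voxels
    correlators: dict[tuple, _FFTCorrelator] = {}

    vidx = points.indices
    n_rot = len(rot_all)
    scores = np.empty((n_rot, len(points)), dtype=float)
    batch = 24
    shape_groups: dict[tuple, list[int]] = {}
    for i in range(n_rot):
        shape_groups.setdefault(tuple(halves[i]), []).append(i)
    for members in shape_groups.values():
        for g0 in range(0, len(members), batch):
            group = members[g0: g0 + batch]
            half = halves[group[0]]
            shape = tuple(2 * half + 1)
            origin = -(half + 0.5) * vox
            template = DensityMap(np.zeros(shape), vox.copy(), origin)
            key = shape
            if key not in correlators:
                correlators[key] = _FFTCorrelator(grid, shape)
            corr = correlators[key]
            nb = len(group)
            stack = np.empty((2 * nb,) + shape)
            means = np.empty(nb)
            norms = np.ones(nb)
            for i, ri in enumerate(group):
                kernel = simulate_on_grid(
                    rotated[ri], template, resolution, weights=w, truncate=truncate
                ).grid
                support = kernel > 0
                n_support = support.sum()
                means[i] = kernel.sum() / n_support if n_support else 0.0
                stack[i] = kernel
                stack[nb + i] = support
                if normalize:
                    nrm = np.sqrt(((kernel - means[i] * support) ** 2).sum())
                    norms[i] = nrm if nrm > 0 else 1.0
            c = corr.correlate_batch(stack)
            s = c[:nb] - means[:, None, None, None] * c[nb:]
            if normalize:
                s = s / norms[:, None, None, None]
            scores[group] = s[:, vidx[:, 0], vidx[:, 1], vidx[:, 2]]

    flat = scores.ravel()
    if keep is not None and keep < flat.size:
        cand = np.argpartition(-flat, keep - 1)[:keep]
        cand = cand[np.lexsort((cand, -flat[cand]))]
    else:
        cand = np.lexsort((np.arange(flat.size), -flat))
    placements = []
    for j in cand:
        ri, pi = divmod(int(j), len(points))
        placements.append(
            Placement(
                rotation=rotations.rotations[ri],
                translation=points.points[pi] - centroid,
                coarse_score=float(flat[j]),
                label=domain.label,
            )
        )
    return placements


# ---------------------------------------------------------------------------
# masked real-space correlation and refinement
# ---------------------------------------------------------------------------

def _mask_voxel_indices(
    density: DensityMap, coords: np.ndarray, mask_radius: float
) -> np.ndarray:
    from .density import _mask_indices_near

    mask = _mask_indices_near(density, coords, mask_radius)
    return np.argwhere(mask)


def _simulate_at_voxels(
    coords: np.ndarray,
    weights: np.ndarray,
    density: DensityMap,
    vox_idx: np.ndarray,
    resolution: float,
    truncate: float = 4.0,
) -> np.ndarray:
    """Simulated density values at specific map voxels (exact subgrid)."""
    sigma = sigma_from_resolution(resolution)
    vox = density.voxel_size
    lo = np.floor(
        (coords.min(axis=0) - truncate * sigma - density.origin) / vox - 0.5
    ).astype(int) - 1
    hi = np.ceil(
        (coords.max(axis=0) + truncate * sigma - density.origin) / vox - 0.5
    ).astype(int) + 1
    lo = np.minimum(lo, vox_idx.min(axis=0))
    hi = np.maximum(hi, vox_idx.max(axis=0))
    shape = hi - lo + 1
    sub_origin = density.origin + lo * vox
    template = DensityMap(np.zeros(shape), vox.copy(), sub_origin)
    sub = simulate_on_grid(
        coords, template, resolution, weights=weights, truncate=truncate
    ).grid
    rel = vox_idx - lo
    return sub[rel[:, 0], rel[:, 1], rel[:, 2]]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.clip(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb), -1, 1))


def masked_rsc(
    domain_pose: Domain,
    density: DensityMap,
    mask_radius: float = 4.0,
    resolution: float = 10.0,
) -> float:
    """Pearson correlation of simulated pose density with the map,
    restricted to voxels within ``mask_radius`` Å of the pose's atoms."""
    from .structure import atom_weights

    coords = domain_pose.coords
    vox_idx = _mask_voxel_indices(density, coords, mask_radius)
    if len(vox_idx) == 0:
        raise EmptyMaskError("no map voxels within mask radius of the pose")
    sim = _simulate_at_voxels(
        coords, atom_weights(domain_pose.atoms), density, vox_idx, resolution
    )
    obs = density.grid[vox_idx[:, 0], vox_idx[:, 1], vox_idx[:, 2]].astype(float)
    return _pearson(sim, obs)


def refine_placements(
    domain: Domain,
    candidates: list[Placement],
    density: DensityMap,
    n_refine: int = 1000,
    mask_radius: float = 4.0,
    resolution: float = 10.0,
    maxiter: int = 2,
) -> list[Placement]:
    """Locally optimize the 6 rigid-body parameters of the top candidates.

    Candidates are taken in order (they arrive sorted by coarse score).
    During optimization the correlation mask is fixed at the starting
    pose; the returned ``refined_score`` is re-evaluated with a fresh
    mask at the final pose, and a move is kept only if it does not lower
    that honest score — so the refined score never falls below the
    starting masked RSC.
    """
    from .structure import atom_weights

    out: list[Placement] = []
    w = atom_weights(domain.atoms)
    coords = domain.coords
    centroid = domain.centroid
    for cand in candidates[: min(n_refine, len(candidates))]:
        start_pose = cand.apply(coords, centroid)
        vox_idx = _mask_voxel_indices(density, start_pose, mask_radius)
        if len(vox_idx) == 0:
            refined = Placement(
                cand.rotation, cand.translation, cand.coarse_score,
                refined_score=-1.0, label=cand.label, model_index=cand.model_index,
            )
            out.append(refined)
            continue
        obs = density.grid[vox_idx[:, 0], vox_idx[:, 1], vox_idx[:, 2]].astype(float)

        def objective(params: np.ndarray) -> float:
            d_rot = Rotation.from_rotvec(params[:3]).as_matrix()
            pose = (coords - centroid) @ (d_rot @ cand.rotation).T
            pose = pose + centroid + cand.translation + params[3:]
            sim = _simulate_at_voxels(pose, w, density, vox_idx, resolution)
            return -_pearson(sim, obs)

        x0 = np.zeros(6)
        direc = np.diag([0.05, 0.05, 0.05, 0.5, 0.5, 0.5])
        res = optimize.minimize(
            objective, x0, method="Powell",
            options={"maxiter": maxiter, "xtol": 1e-3, "ftol": 1e-4, "direc": direc},
        )
        d_rot = Rotation.from_rotvec(res.x[:3]).as_matrix()
        new = Placement(
            rotation=d_rot @ cand.rotation,
            translation=cand.translation + res.x[3:],
            coarse_score=cand.coarse_score,
            label=cand.label,
            model_index=cand.model_index,
        )
        start_score = masked_rsc(
            apply_placement(domain, cand), density, mask_radius, resolution
        )
        new_score = masked_rsc(
            apply_placement(domain, new), density, mask_radius, resolution
        )
        if new_score >= start_score:
            new.refined_score = new_score
            out.append(new)
        else:
            kept = Placement(
                cand.rotation, cand.translation, cand.coarse_score,
                refined_score=start_score, label=cand.label,
                model_index=cand.model_index,
            )
            out.append(kept)
    out.sort(key=lambda p: -p.refined_score)
    return out


# ---------------------------------------------------------------------------
# redundancy pruning and the full pipeline
# ---------------------------------------------------------------------------

def ca_rmsd_between_placements(
    domain: Domain, a: Placement, b: Placement
) -> float:
    """CA-RMSD (no superposition) between two poses of the same domain."""
    ca = domain.ca_coords
    if len(ca) == 0:
        ca = domain.coords
    centroid = domain.centroid
    return float(
        np.sqrt(((a.apply(ca, centroid) - b.apply(ca, centroid)) ** 2).sum(axis=1).mean())
    )


@dataclass
class DockResult:
    """Ranked, pruned placements of one domain with the parameters used."""

    label: str
    placements: list[Placement]
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "params": self.params,
            "placements": [p.to_dict() for p in self.placements],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "DockResult":
        d = json.loads(Path(path).read_text())
        return cls(
            label=d["label"],
            placements=[Placement.from_dict(p) for p in d["placements"]],
            params=d.get("params", {}),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.placements:
            row = p.to_dict()
            rot = row.pop("rotation")
            trans = row.pop("translation")
            for i, v in enumerate(rot):
                row[f"r{i // 3}{i % 3}"] = v
            for ax, v in zip("xyz", trans):
                row[f"t{ax}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


def prune_redundant(
    domain: Domain,
    placements: list[Placement],
    rms_cutoff: float = 11.0,
    n_keep: int = 200,
    params: dict | None = None,
) -> DockResult:
    """Greedy redundancy filter: walk placements by descending refined
    score (stable in input order on ties) and keep one iff its CA-RMSD
    to every kept placement exceeds ``rms_cutoff``; stop at ``n_keep``."""
    order = sorted(
        range(len(placements)),
        key=lambda i: (-(placements[i].refined_score or -np.inf), i),
    )
    kept: list[Placement] = []
    for i in order:
        p = placements[i]
        if all(
            ca_rmsd_between_placements(domain, p, q) > rms_cutoff for q in kept
        ):
            kept.append(p)
            if len(kept) >= n_keep:
                break
    for rank, p in enumerate(kept):
        p.rank = rank
    return DockResult(label=domain.label, placements=kept, params=params or {})


def dock_domain(
    domain: Domain,
    density: DensityMap,
    config: RunConfig | None = None,
    resolution: float = 10.0,
    points: SearchPoints | None = None,
    rotations: RotationSet | None = None,
    **overrides,
) -> DockResult:
    """Full docking pipeline: search points -> coarse FFT search ->
    masked-RSC rigid-body refinement -> redundancy pruning.

    ``points``/``rotations`` may be passed in to share them across
    domains docked into the same map. ``overrides`` replace individual
    RunConfig fields for this call.
    """
    cfg = config or RunConfig()
    if overrides:
        cfg = RunConfig.from_dict({**cfg.to_dict(), **overrides})
    if points is None:
        points = select_search_points(density, cfg.n_points, cfg.min_separation)
    if rotations is None:
        rotations = build_rotation_grid(cfg.rot_step)
    coarse = coarse_search(
        domain, density, points, rotations,
        resolution=resolution, normalize=cfg.normalize_coarse, keep=cfg.n_refine,
    )
    refined = refine_placements(
        domain, coarse, density,
        n_refine=cfg.n_refine, mask_radius=cfg.mask_radius, resolution=resolution,
    )
    params = {
        "n_points": cfg.n_points,
        "min_separation": cfg.min_separation,
        "rot_step": cfg.rot_step,
        "n_refine": cfg.n_refine,
        "rms_cutoff": cfg.rms_cutoff,
        "n_keep": cfg.n_keep,
        "mask_radius": cfg.mask_radius,
        "resolution": resolution,
        "normalize_coarse": cfg.normalize_coarse,
        "config_hash": cfg.config_hash,
    }
    return prune_redundant(
        domain, refined, cfg.rms_cutoff, cfg.n_keep, params=params
    )
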