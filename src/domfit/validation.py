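"""Model-versus-data validation statistics.

Covers the standard integrative-modelling report at intermediate
resolution: model-map Fourier shell correlation (with threshold
crossings read off in Å), per-domain masked real-space correlation with
best-versus-second-best gaps, cross-link satisfaction tables at a CA-CA
threshold, and interface-residue classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .density import DensityMap
from .docking import DockResult, masked_rsc
from .errors import GridMismatchError, MappingError
from .structure import Domain, Structure

__all__ = [
    "FSCCurve",
    "fsc_curve",
    "real_space_correlation",
    "rsc_gap",
    "crosslink_satisfaction",
    "interface_residues",
    "ValidationReport",
]


@dataclass
class FSCCurve:
    """Fourier shell correlation per spatial-frequency shell."""

    frequencies: np.ndarray   # 1/Å, strictly increasing shell centers
    correlations: np.ndarray  # in [-1, 1]

    def resolution_at(self, threshold: float = 0.5) -> float:
        """Resolution (Å) of the first downward crossing of ``threshold``
        (linear interpolation); inf if the curve never drops below it."""
        f, c = self.frequencies, self.correlations
        for i in range(1, len(c)):
            if c[i - 1] >= threshold > c[i]:
                # interpolate frequency at the crossing
                t = (c[i - 1] - threshold) / (c[i - 1] - c[i])
                freq = f[i - 1] + t * (f[i] - f[i - 1])
                return float(1.0 / freq) if freq > 0 else np.inf
        return np.inf

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frequency": self.frequencies, "fsc": self.correlations}
        )


def fsc_curve(map_a: DensityMap, map_b: DensityMap, n_shells: int = 20) -> FSCCurve:
    """Fourier shell correlation between two maps on the same grid.

    Voxels are binned into ``n_shells`` concentric shells of spatial
    frequency up to Nyquist; per shell the correlation is
    ``Re(sum F_a conj(F_b)) / sqrt(sum |F_a|^2 sum |F_b|^2)``. The
    zero-frequency shell of two non-empty maps correlates to 1. The
    curve is symmetric in its arguments and invariant to positive
    scaling of either map.
    """
    if map_a.shape != map_b.shape or not np.allclose(
        map_a.voxel_size, map_b.voxel_size, atol=1e-6
    ):
        raise GridMismatchError("FSC requires identical grids")
    fa = np.fft.fftn(map_a.grid.astype(float))
    fb = np.fft.fftn(map_b.grid.astype(float))
    freqs = [
        np.fft.fftfreq(n, d=v)
        for n, v in zip(map_a.shape, map_a.voxel_size)
    ]
    kx, ky, kz = np.meshgrid(*freqs, indexing="ij")
    kmag = np.sqrt(kx**2 + ky**2 + kz**2)
    nyquist = 0.5 / np.max(map_a.voxel_size)
    edges = np.linspace(0.0, nyquist, n_shells + 1)
    which = np.digitize(kmag.ravel(), edges) - 1
    num = (fa * np.conj(fb)).real.ravel()
    pa = (np.abs(fa) ** 2).ravel()
    pb = (np.abs(fb) ** 2).ravel()
    centers, corrs = [], []
    for s in range(n_shells):
        sel = which == s
        if not sel.any():
            continue
        denom = np.sqrt(pa[sel].sum() * pb[sel].sum())
        corrs.append(num[sel].sum() / denom if denom > 0 else 0.0)
        centers.append(0.5 * (edges[s] + edges[s + 1]))
    return FSCCurve(np.asarray(centers), np.clip(np.asarray(corrs), -1, 1))


def real_space_correlation(
    domain_pose: Domain,
    density: DensityMap,
    mask_radius: float = 4.0,
    resolution: float = 10.0,
) -> float:
    """Masked real-space correlation of a posed model with the map
    (identical semantics to the docking stage's masked RSC)."""
    return masked_rsc(domain_pose, density, mask_radius, resolution)


def rsc_gap(result: DockResult) -> float:
    """Best minus second-best refined score of a dock result (a large
    gap indicates an unambiguous placement); inf with < 2 placements."""
    scores = [p.refined_score for p in result.placements if p.refined_score is not None]
    if len(scores) < 2:
        return np.inf
    ordered = sorted(scores, reverse=True)
    return float(ordered[0] - ordered[1])


def crosslink_satisfaction(
    model: Structure,
    crosslinks,
    threshold: float | None = None,
    domain_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-link satisfaction table.

    One row per cross-link with its CA-CA distance in the model, a
    ``status`` of satisfied / violated / unmapped (endpoint residue
    absent from the model; excluded from satisfaction denominators) and,
    when a domain table (columns label,chain,start,end) is supplied, an
    ``inter_domain`` flag for links spanning two different domains.
    """
    ca_mask = model.atom_name == "CA"
    ca = model.coord[ca_mask]
    chains = model.chain_id[ca_mask]
    res = model.res_id[ca_mask]
    index = {(str(c), int(r)): i for i, (c, r) in enumerate(zip(chains, res))}

    def domain_of(chain: str, resnum: int):
        if domain_table is None:
            return None
        hit = domain_table[
            (domain_table["chain"].astype(str) == chain)
            & (domain_table["start"] <= resnum)
            & (domain_table["end"] >= resnum)
        ]
        return str(hit.iloc[0]["label"]) if len(hit) else None

    rows = []
    for link in crosslinks:
        thr = threshold if threshold is not None else link.threshold
        key_a = (link.chain_a, link.res_a)
        key_b = (link.chain_b, link.res_b)
        ia, ib = index.get(key_a), index.get(key_b)
        if ia is None or ib is None:
            dist, status = np.nan, "unmapped"
        else:
            dist = float(np.linalg.norm(ca[ia] - ca[ib]))
            status = "satisfied" if dist <= thr else "violated"
        dom_a = domain_of(*key_a)
        dom_b = domain_of(*key_b)
        inter = (
            None
            if domain_table is None
            else (
                link.chain_a != link.chain_b
                or (dom_a is not None and dom_b is not None and dom_a != dom_b)
            )
        )
        rows.append(
            {
                "chain_a": link.chain_a, "res_a": link.res_a,
                "chain_b": link.chain_b, "res_b": link.res_b,
                "threshold": thr, "distance": dist, "status": status,
                "domain_a": dom_a, "domain_b": dom_b, "inter_domain": inter,
            }
        )
    return pd.DataFrame(rows)


def satisfaction_summary(table: pd.DataFrame) -> dict:
    """Counts from a cross-link table: satisfied + violated + unmapped
    equals the number of input links."""
    n_sat = int((table["status"] == "satisfied").sum())
    n_vio = int((table["status"] == "violated").sum())
    n_unm = int((table["status"] == "unmapped").sum())
    mapped = n_sat + n_vio
    out = {
        "n_links": len(table),
        "satisfied": n_sat,
        "violated": n_vio,
        "unmapped": n_unm,
        "fraction_satisfied": n_sat / mapped if mapped else np.nan,
    }
    if "inter_domain" in table and table["inter_domain"].notna().any():
        inter = table[(table["inter_domain"] == True) & (table["status"] != "unmapped")]  # noqa: E712
        out["inter_domain_total"] = len(inter)
        out["inter_domain_satisfied"] = int((inter["status"] == "satisfied").sum())
    return out


def interface_residues(
    poses: list[Domain], cutoff: float = 5.0
) -> pd.DataFrame:
    """Residues with any atom within ``cutoff`` Å of another domain.

    Returns one row per (domain, residue) flagged as interface, with
    the closest partner domain. Symmetric in the two partners; an empty
    table for cutoff <= 0 or non-touching domains.
    """
    rows = []
    if cutoff <= 0 or len(poses) < 2:
        return pd.DataFrame(columns=["domain", "chain", "res_id", "partner"])
    trees = [cKDTree(p.coords) for p in poses]
    for i, pose in enumerate(poses):
        res_ids = pose.atoms.res_id
        flagged: dict[int, str] = {}
        for j, other in enumerate(poses):
            if i == j:
                continue
            d, _ = trees[j].query(pose.coords, k=1, distance_upper_bound=cutoff)
            near = np.isfinite(d)
            for rid in np.unique(res_ids[near]):
                flagged.setdefault(int(rid), other.label)
        for rid, partner in sorted(flagged.items()):
            rows.append(
                {
                    "domain": pose.label, "chain": pose.chain_id,
                    "res_id": rid, "partner": partner,
                }
            )
    return pd.DataFrame(rows, columns=["domain", "chain", "res_id", "partner"])


@dataclass
class ValidationReport:
    """Aggregate report: per-domain RSC (+gap), cross-links, FSC."""

    domain_rsc: pd.DataFrame = field(default_factory=pd.DataFrame)
    crosslink_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    crosslink_summary: dict = field(default_factory=dict)
    fsc_resolution: float | None = None
    interface: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "domain_rsc": self.domain_rsc.to_dict(orient="records"),
            "crosslink_summary": self.crosslink_summary,
            "fsc_resolution_at_0.5": self.fsc_resolution,
            "n_interface_residues": len(self.interface),
        }

    def save(self, path: str | Path) -> None:
        import json

        Path(path).write_text(json.dumps(self.to_dict(), indent=1, default=str))
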