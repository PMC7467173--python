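"""Synthetic multi-domain complexes with known ground truth.

The generator emulates the regime the assembly method is built for:
compact multi-domain complexes observed at ~10 Å resolution, where
individual domains are rigid, linkers are unmodeled, and cross-links
report noisy CA-CA proximity. Domains are idealized CA/CB helical
bundles (canonical α-helix CA geometry: 2.3 Å radius, 1.5 Å rise,
100° turn per residue), packed without clashes; everything is a pure
function of its seed and parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .assembly import CrossLink
from .density import DensityMap, simulate_map
from .errors import PackingError
from .structure import Domain, Placement, apply_placement

__all__ = [
    "ToyComplex",
    "make_helix_bundle_domain",
    "make_toy_complex",
    "make_decoys",
    "make_crosslinks",
]

# canonical α-helix CA parameters
_HELIX_RADIUS = 2.3      # Å
_HELIX_RISE = 1.5        # Å per residue
_HELIX_TURN = 100.0      # degrees per residue
_CLASH_DIST = 5.0        # Å minimum inter-domain CA-CA distance when packing


def _helix_ca(n_res: int) -> np.ndarray:
    i = np.arange(n_res)
    ang = np.radians(_HELIX_TURN) * i
    return np.stack(
        [_HELIX_RADIUS * np.cos(ang), _HELIX_RADIUS * np.sin(ang), _HELIX_RISE * i],
        axis=1,
    )


def make_helix_bundle_domain(
    n_res: int,
    label: str = "dom",
    chain_id: str = "A",
    res_start: int = 1,
    n_helices: int = 4,
    spacing: float = 9.0,
    with_cb: bool = True,
    rng: np.random.Generator | None = None,
) -> Domain:
    """An idealized antiparallel helical bundle, CA (+CB) only, centered
    on its centroid. Residue numbering starts at ``res_start``.

    Helix lengths and positions are jittered (deterministically from
    ``rng``) so the bundle has no rotational pseudo-symmetry — real
    domains are asymmetric, and symmetric shapes would make rigid-body
    poses degenerate at low resolution.
    """
    rng = rng or np.random.default_rng(0)
    frac = 1.0 + rng.uniform(-0.25, 0.25, size=n_helices)
    lengths = np.maximum((n_res * frac / frac.sum()).astype(int), 4)
    lengths[-1] += n_res - lengths.sum()
    ca = []
    for h in range(n_helices):
        c = _helix_ca(int(lengths[h]))
        if h % 2:
            c = c[:, [1, 0, 2]] * np.array([1.0, 1.0, -1.0])
            c[:, 2] -= c[:, 2].min()
        jitter = rng.uniform(-1.5, 1.5, size=2)
        z_off = rng.uniform(-2.0, 2.0)
        c = c + np.array(
            [spacing * (h % 2) + jitter[0], spacing * (h // 2) + jitter[1], z_off]
        )
        ca.append(c)
    ca = np.concatenate(ca)
    ca -= ca.mean(axis=0)
    n = len(ca)
    if with_cb:
        # CB pseudo-atoms 1.5 Å radially outward from the local helix axis
        axis_pts = ca.copy()
        axis_pts[:, :2] = 0
        out_dir = ca - axis_pts
        nrm = np.linalg.norm(out_dir, axis=1, keepdims=True)
        nrm[nrm < 1e-6] = 1.0
        cb = ca + 1.5 * out_dir / nrm
        coords = np.empty((2 * n, 3))
        coords[0::2] = ca
        coords[1::2] = cb
        atom_names = np.empty(2 * n, dtype="<U3")
        atom_names[0::2] = "CA"
        atom_names[1::2] = "CB"
        res_ids = np.repeat(np.arange(res_start, res_start + n), 2)
    else:
        coords = ca
        atom_names = np.full(n, "CA", dtype="<U3")
        res_ids = np.arange(res_start, res_start + n)
    na = len(coords)
    atoms = struc.AtomArray(na)
    atoms.coord = coords.astype(np.float32)
    atoms.chain_id = np.full(na, chain_id)
    atoms.res_id = res_ids
    atoms.res_name = np.full(na, "ALA")
    atoms.atom_name = atom_names
    atoms.element = np.full(na, "C")
    atoms.hetero = np.zeros(na, bool)
    return Domain(
        label=label, chain_id=chain_id,
        res_start=res_start, res_end=res_start + n - 1, atoms=atoms,
    )


@dataclass
class ToyComplex:
    """A synthetic complex with exact ground truth.

    ``domains`` hold library (centered) coordinates; applying
    ``true_placements[label]`` reproduces the assembled structure's
    coordinates exactly.
    """

    domains: list[Domain]
    true_placements: dict[str, Placement]
    crosslinks: list[CrossLink] = field(default_factory=list)
    seed: int = 0
    linker_length: int = 10

    @property
    def structure(self) -> struc.AtomArray:
        arrays = [
            apply_placement(d, self.true_placements[d.label]).atoms
            for d in self.domains
        ]
        out = arrays[0]
        for a in arrays[1:]:
            out = out + a
        return out

    @property
    def domain_table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "label": d.label, "chain": d.chain_id,
                    "start": d.res_start, "end": d.res_end,
                }
                for d in self.domains
            ]
        )

    def simulated_map(
        self, resolution: float = 10.0, voxel_size: float | None = None,
        padding: float = 12.0,
    ) -> DensityMap:
        if voxel_size is None:
            voxel_size = resolution / 3.0
        return simulate_map(
            self.structure, resolution, voxel_size=voxel_size, padding=padding
        )

    def truth_dict(self) -> dict:
        return {
            "seed": self.seed,
            "linker_length": self.linker_length,
            "placements": {
                lbl: pl.to_dict() for lbl, pl in self.true_placements.items()
            },
        }


def make_toy_complex(
    n_domains: int = 4,
    residues_per_domain: int = 60,
    seed: int = 0,
    linker_length: int = 10,
    with_cb: bool = True,
    max_tries: int = 200,
) -> ToyComplex:
    """Generate a packed multi-domain complex with known placements.

    Domains are consecutive segments of one chain separated by
    ``linker_length`` unmodeled residues. Each domain gets a random
    orientation and a position near the growing complex such that no
    inter-domain CA pair comes closer than 5 Å while staying compact
    (every domain touches the rest within linker reach).
    """
    if n_domains < 1:
        raise ValueError("n_domains must be >= 1")
    rng = np.random.default_rng(seed)
    domains = []
    start = 1
    for d in range(n_domains):
        dom = make_helix_bundle_domain(
            residues_per_domain, label=f"D{d}", chain_id="A",
            res_start=start, with_cb=with_cb, rng=rng,
        )
        dom.n_link_prev = linker_length if d > 0 else 0
        dom.n_link_next = linker_length if d < n_domains - 1 else 0
        domains.append(dom)
        start += residues_per_domain + linker_length

    placements: dict[str, Placement] = {}
    placed_ca: list[np.ndarray] = []
    placed_all: list[np.ndarray] = []
    anchors: list[np.ndarray] = []
    # rough bundle radius to set packing distances
    radius = np.linalg.norm(domains[0].ca_coords, axis=1).max()
    # the linker between adjacent domains must remain closable with
    # slack to spare (pairwise optimization may later slide domains by
    # up to ~5 Å); keep the terminal gap well inside 3.5 Å per residue
    max_gap = linker_length * 3.5 - 2.0
    for d, dom in enumerate(domains):
        ok = False
        for _ in range(max_tries):
            rot = Rotation.random(random_state=rng).as_matrix()
            if d == 0:
                trans = np.zeros(3)
            else:
                anchor = anchors[d - 1]
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                dist = 2 * radius + rng.uniform(-4.0, 2.0)
                trans = anchor + direction * dist
            pl = Placement(rot, trans)
            coords = pl.apply(dom.coords, dom.centroid)
            ca = pl.apply(dom.ca_coords, dom.centroid)
            if placed_ca:
                all_prev = np.concatenate(placed_all)
                dmin = cKDTree(all_prev).query(coords, k=1)[0].min()
                if dmin < _CLASH_DIST or dmin > 2.5 * radius:
                    continue
                # chain continuity: previous C-terminus near this N-terminus
                order_prev = np.argsort(domains[d - 1].ca_res_ids)
                prev_cterm = placed_ca[d - 1][order_prev[-1]]
                order_this = np.argsort(dom.ca_res_ids)
                gap = np.linalg.norm(prev_cterm - ca[order_this[0]])
                if gap > max_gap:
                    continue
            placements[dom.label] = pl
            placed_ca.append(ca)
            placed_all.append(coords)
            anchors.append(trans)
            ok = True
            break
        if not ok:
            raise PackingError(
                f"could not place domain {dom.label} after {max_tries} tries"
            )
    return ToyComplex(
        domains=domains, true_placements=placements,
        seed=seed, linker_length=linker_length,
    )


def make_decoys(
    toy: ToyComplex,
    n_decoys_per_domain: int = 3,
    seed: int = 0,
    min_rmsd: float = 5.0,
    max_tries: int = 200,
) -> tuple[dict[str, list[Placement]], dict[str, int]]:
    """Candidate placement lists: the truth plus randomized decoys.

    Decoys are random orientations translated to positions near other
    domains' true locations (i.e. regions that genuinely contain
    density), each at least ``min_rmsd`` CA-RMSD from the truth. The
    returned order is shuffled; the second dict maps each label to the
    index of the true placement in its list.
    """
    rng = np.random.default_rng(seed)
    centers = np.array(
        [
            pl.apply(d.ca_coords, d.centroid).mean(axis=0)
            for d, pl in ((d, toy.true_placements[d.label]) for d in toy.domains)
        ]
    )
    candidates: dict[str, list[Placement]] = {}
    truth_index: dict[str, int] = {}
    for di, d in enumerate(toy.domains):
        truth = toy.true_placements[d.label]
        ca = d.ca_coords
        cen = d.centroid
        true_ca = truth.apply(ca, cen)
        other_centers = np.delete(centers, di, axis=0)
        decoys: list[Placement] = []
        tries = 0
        while len(decoys) < n_decoys_per_domain and tries < max_tries:
            tries += 1
            rot = Rotation.random(random_state=rng).as_matrix()
            if len(other_centers):
                target = other_centers[rng.integers(0, len(other_centers))]
            else:
                target = centers[0] + rng.normal(scale=15.0, size=3)
            trans = target + rng.normal(scale=4.0, size=3) - cen
            pl = Placement(rot, trans)
            rmsd = float(np.sqrt(((pl.apply(ca, cen) - true_ca) ** 2).sum(1).mean()))
            if rmsd >= min_rmsd:
                decoys.append(pl)
        pls = [truth] + decoys
        order = rng.permutation(len(pls))
        candidates[d.label] = [pls[i] for i in order]
        truth_index[d.label] = int(np.flatnonzero(order == 0)[0])
    return candidates, truth_index


def make_crosslinks(
    toy: ToyComplex,
    n_links: int = 20,
    violation_rate: float = 0.0,
    seed: int = 0,
    threshold: float = 30.0,
    max_tries: int = 10000,
) -> list[CrossLink]:
    """Sample synthetic cross-links against the ground-truth structure.

    A ``1 - violation_rate`` fraction is drawn from inter-domain residue
    pairs with true CA-CA distance <= threshold (satisfied links); the
    rest from pairs beyond the threshold (emulating links from flexible
    or disordered regions). Deterministic for a fixed seed.
    """
    if not 0 <= violation_rate <= 1:
        raise ValueError("violation_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    posed = [
        apply_placement(d, toy.true_placements[d.label]) for d in toy.domains
    ]
    ca = [p.ca_coords for p in posed]
    ids = [p.ca_res_ids for p in posed]
    n_dom = len(posed)
    if n_dom < 2:
        raise ValueError("cross-links need at least 2 domains")
    n_bad = int(round(violation_rate * n_links))
    links: list[CrossLink] = []
    seen = set()
    for want_violated, count in ((False, n_links - n_bad), (True, n_bad)):
        made = 0
        tries = 0
        while made < count and tries < max_tries:
            tries += 1
            i, j = rng.choice(n_dom, size=2, replace=False)
            ri = rng.integers(0, len(ids[i]))
            rj = rng.integers(0, len(ids[j]))
            d = float(np.linalg.norm(ca[i][ri] - ca[j][rj]))
            good = d <= threshold
            if good == want_violated:
                continue
            key = (int(ids[i][ri]), int(ids[j][rj]))
            if key in seen or key[::-1] in seen:
                continue
            seen.add(key)
            links.append(
                CrossLink("A", key[0], "A", key[1], threshold)
            )
            made += 1
    return links


def save_fixture(toy: ToyComplex, out_dir: str | Path, resolution: float = 10.0):
    """Write model.pdb, truth.json, map.mrc, crosslinks.csv to a directory."""
    from .assembly import write_crosslinks
    from .density import write_map
    from .structure import write_structure

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_structure(toy.structure, out / "model.pdb")
    (out / "truth.json").write_text(json.dumps(toy.truth_dict(), indent=1))
    write_map(toy.simulated_map(resolution), out / "map.mrc")
    toy.domain_table.to_csv(out / "domains.csv", index=False)
    if toy.crosslinks:
        write_crosslinks(toy.crosslinks, out / "crosslinks.csv")
    return out
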