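"""Combinatorial assembly of docked domains by Monte Carlo simulated
annealing.

Each domain (or group of mutually exclusive alternative domains covering
the same sequence) is an assignment *slot* holding a list of candidate
placements plus the explicit option of being NOT_FOUND (absent from the
map). A state assigns one option per slot and is scored by four terms,
lower is better:

* density fit: ``w_dens * sum(-RSC_i)`` over placed domains,
* linker closability: a flat-bottom quadratic penalty on the gap
  between chain-adjacent domains relative to what the unmodeled linker
  can span,
* coarse-grained interface energy: a CB contact-well potential with
  soft-sphere repulsion, evaluated as combined-minus-separated energy
  after a pairwise interface optimization (slide into contact, clash
  trimming),
* cross-link restraints: a bounded flat-bottom penalty per link beyond
  its CA-CA threshold.

The weighted-term layout and default multipliers (260 / 1000 / 150 /
30000) follow the published protocol; annealing runs many short
independent trajectories, and the top distinct final states decide
which domains have converged and are frozen; their density is removed
and the remaining domains are redocked for the next round.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import AnnealSchedule, RunConfig
from .density import DensityMap, mask_out, select_search_points
from .docking import build_rotation_grid, dock_domain, masked_rsc
from .errors import NoAxisError
from .structure import Domain, Placement, apply_placement, assign_secondary_structure

__all__ = [
    "NOT_FOUND",
    "CrossLink",
    "AssemblyState",
    "read_crosslinks",
    "write_crosslinks",
    "slide_into_contact",
    "clash_score",
    "per_residue_clash",
    "trim_clashing_residues",
    "split_subdomains",
    "centroid_energy",
    "proximity_score",
    "crosslink_penalty",
    "AssemblyProblem",
    "total_score",
    "mcsa_sample",
    "assess_convergence",
    "iterative_assemble",
    "assembled_structure",
]

NOT_FOUND = -1


@dataclass(frozen=True)
class CrossLink:
    """One residue pair restrained by a cross-linker (CA-CA threshold)."""

    chain_a: str
    res_a: int
    chain_b: str
    res_b: int
    threshold: float = 30.0

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if (self.chain_a, self.res_a) == (self.chain_b, self.res_b):
            raise ValueError("cross-link endpoints must be distinct residues")


def read_crosslinks(path: str | Path, default_threshold: float = 30.0) -> list[CrossLink]:
    """Read a cross-link CSV: chain_a,res_a,chain_b,res_b[,threshold]."""
    df = pd.read_csv(path)
    links = []
    for row in df.itertuples():
        thr = getattr(row, "threshold", default_threshold)
        links.append(
            CrossLink(
                str(row.chain_a), int(row.res_a),
                str(row.chain_b), int(row.res_b), float(thr),
            )
        )
    return links


def write_crosslinks(links: list[CrossLink], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "chain_a": l.chain_a, "res_a": l.res_a,
                "chain_b": l.chain_b, "res_b": l.res_b,
                "threshold": l.threshold,
            }
            for l in links
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pairwise interface geometry
# ---------------------------------------------------------------------------

def slide_into_contact(
    pose_a: Domain,
    pose_b: Domain,
    max_shift: float = 5.0,
    contact_dist: float = 8.0,
    clash_dist: float = 4.0,
    step: float = 0.1,
) -> tuple[Domain, Domain, bool]:
    """Slide both domains along their inter-centroid axis into contact.

    Searches signed total displacements up to ``max_shift`` (smallest
    first, split equally between the two domains) for a geometry that is
    in contact (some inter-domain CA pair closer than ``contact_dist``)
    but clash-free (no CA pair closer than ``clash_dist``). Returns the
    two (possibly shifted) poses and a success flag; when the condition
    cannot be met within ``max_shift`` the inputs come back unchanged.
    """
    ca_a, ca_b = pose_a.ca_coords, pose_b.ca_coords
    if len(ca_a) == 0 or len(ca_b) == 0:
        return pose_a, pose_b, False
    axis = pose_b.centroid - pose_a.centroid
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise NoAxisError("coincident centroids: no slide axis")
    u = axis / norm

    # pair vectors for every CA pair that could come within reach
    reach = contact_dist + max_shift + 1.0
    tree_a = cKDTree(ca_a)
    pairs = tree_a.query_ball_tree(cKDTree(ca_b), reach)
    vecs = [ca_b[j] - ca_a[i] for i, js in enumerate(pairs) for j in js]
    if not vecs:
        return pose_a, pose_b, False
    v = np.asarray(vecs)
    shifts = np.arange(0.0, max_shift + 1e-9, step)
    signed = np.empty(2 * len(shifts) - 1)
    signed[0] = 0.0
    signed[1::2] = shifts[1:]
    signed[2::2] = -shifts[1:]
    for s in signed:
        d = np.linalg.norm(v + s * u, axis=1)
        if d.min() >= clash_dist and d.min() < contact_dist:
            if abs(s) < 1e-12:
                return pose_a, pose_b, True
            a2, b2 = pose_a.copy(), pose_b.copy()
            a2.atoms.coord = (pose_a.coords - 0.5 * s * u).astype(a2.atoms.coord.dtype)
            b2.atoms.coord = (pose_b.coords + 0.5 * s * u).astype(b2.atoms.coord.dtype)
            return a2, b2, True
    return pose_a, pose_b, False


def _inter_pairs(coords_a, coords_b, cutoff):
    tree = cKDTree(coords_a)
    dist = tree.sparse_distance_matrix(
        cKDTree(coords_b), cutoff, output_type="coo_matrix"
    )
    return dist.row, dist.col, dist.data


def clash_score(pose_a: Domain, pose_b: Domain, clash_dist: float = 4.0) -> float:
    """Soft-sphere repulsion between two posed domains.

    Sum over inter-domain atom pairs closer than ``clash_dist`` of
    ``((clash_dist - d) / clash_dist)**2``: zero when nothing
    penetrates, growing quadratically with penetration depth, and
    monotonically non-increasing as the domains separate.
    """
    _, _, d = _inter_pairs(pose_a.coords, pose_b.coords, clash_dist)
    if len(d) == 0:
        return 0.0
    return float((((clash_dist - d) / clash_dist) ** 2).sum())


def per_residue_clash(
    pose_a: Domain, pose_b: Domain, clash_dist: float = 4.0
) -> tuple[dict[int, float], dict[int, float]]:
    """Per-residue share of the pair clash score (each pair's
    contribution is attributed to the residue on each side)."""
    ia, ib, d = _inter_pairs(pose_a.coords, pose_b.coords, clash_dist)
    contrib_a: dict[int, float] = {}
    contrib_b: dict[int, float] = {}
    res_a = pose_a.atoms.res_id
    res_b = pose_b.atoms.res_id
    for i, j, dist in zip(ia, ib, d):
        c = ((clash_dist - dist) / clash_dist) ** 2
        contrib_a[int(res_a[i])] = contrib_a.get(int(res_a[i]), 0.0) + c
        contrib_b[int(res_b[j])] = contrib_b.get(int(res_b[j]), 0.0) + c
    return contrib_a, contrib_b


def _exposed_residues(pose: Domain, radius: float, max_neighbors: int) -> set[int]:
    """Residues with fewer than ``max_neighbors`` CA atoms within
    ``radius`` Å in their own domain (surface-exposure test)."""
    ca = pose.ca_coords
    ids = pose.ca_res_ids
    if len(ca) == 0:
        return set()
    tree = cKDTree(ca)
    counts = tree.query_ball_point(ca, radius, return_length=True) - 1
    return {int(r) for r, c in zip(ids, counts) if c < max_neighbors}


def trim_clashing_residues(
    pose_a: Domain,
    pose_b: Domain,
    sse_a: np.ndarray,
    sse_b: np.ndarray,
    config: RunConfig | None = None,
) -> tuple[Domain, Domain]:
    """Remove severely clashing loop residues that are surface-exposed.

    Only acts when the pair clash score exceeds the severe-clash
    threshold. A residue is removed iff (its share of the clash score
    exceeds the per-residue threshold) AND (it is a loop, label L) AND
    (it is exposed: fewer than 10 CA atoms within 12 Å in its own
    domain). Inputs are not modified.
    """
    cfg = config or RunConfig()
    if clash_score(pose_a, pose_b, cfg.clash_dist) <= cfg.severe_clash_threshold:
        return pose_a, pose_b
    ca_contrib, cb_contrib = per_residue_clash(pose_a, pose_b, cfg.clash_dist)
    out = []
    for pose, sse, contrib in (
        (pose_a, sse_a, ca_contrib), (pose_b, sse_b, cb_contrib)
    ):
        exposed = _exposed_residues(pose, cfg.exposure_radius, cfg.exposure_max_neighbors)
        res_ids = pose.residue_ids
        sse_of = {int(r): s for r, s in zip(res_ids, sse)}
        doomed = {
            r
            for r, c in contrib.items()
            if c > cfg.per_residue_clash_threshold
            and sse_of.get(r, "L") == "L"
            and r in exposed
        }
        if doomed and len(doomed) < len(res_ids):
            keep = ~np.isin(pose.atoms.res_id, sorted(doomed))
            trimmed = pose.copy()
            trimmed.atoms = pose.atoms[keep].copy()
            out.append(trimmed)
        else:
            out.append(pose)
    return out[0], out[1]


def split_subdomains(
    domain: Domain,
    min_subdomain_size: int = 20,
    contact_cutoff: float = 8.0,
    split_threshold: float = 0.28,
) -> list[Domain]:
    """Partition a domain into compact sequence-contiguous subdomains.

    Recursive contact-map bipartitioning: for every sequence cut point
    the inter-segment CA contact count is normalized by the geometric
    mean of the intra-segment contact counts; the best cut is applied if
    that normalized score falls below ``split_threshold`` and both
    segments keep at least ``min_subdomain_size`` residues. Segments
    that are not themselves compact (fewer internal contacts than half
    their residue count — e.g. a bare extended linker) are merged into
    the neighboring segment they contact most. Domains shorter than 40
    residues are returned unsplit; the returned segments are disjoint,
    sequence-ordered and cover the domain's residues exactly.
    """
    segments = _bipartition(domain, min_subdomain_size, contact_cutoff,
                            split_threshold)
    if len(segments) == 1:
        return segments

    def n_contacts(coords_a, coords_b=None):
        tree = cKDTree(coords_a)
        if coords_b is None:
            p = tree.query_pairs(contact_cutoff, output_type="ndarray")
            if len(p) == 0:
                return 0
            return int(np.sum(np.abs(p[:, 0] - p[:, 1]) > 2))
        return int(tree.count_neighbors(cKDTree(coords_b), contact_cutoff))

    changed = True
    while changed and len(segments) > 1:
        changed = False
        for i, seg in enumerate(segments):
            ca = seg.ca_coords
            intra = n_contacts(ca)
            if intra >= 0.5 * len(ca):
                continue
            # merge the floppy segment into its better-connected neighbor
            left = n_contacts(ca, segments[i - 1].ca_coords) if i > 0 else -1
            right = (
                n_contacts(ca, segments[i + 1].ca_coords)
                if i < len(segments) - 1 else -1
            )
            j = i - 1 if left >= right else i + 1
            lo = min(seg.res_start, segments[j].res_start)
            hi = max(seg.res_end, segments[j].res_end)
            mask = (domain.atoms.res_id >= lo) & (domain.atoms.res_id <= hi)
            merged = Domain(
                label=f"{domain.label}.{lo}-{hi}", chain_id=domain.chain_id,
                res_start=lo, res_end=hi, atoms=domain.atoms[mask].copy(),
            )
            segments[min(i, j)] = merged
            del segments[max(i, j)]
            changed = True
            break
    return segments


def _bipartition(domain, min_subdomain_size, contact_cutoff, split_threshold):
    ca = domain.ca_coords
    ids = domain.ca_res_ids
    n = len(ca)
    if n < max(2 * min_subdomain_size, 40):
        return [domain]
    tree = cKDTree(ca)
    pairs = tree.query_pairs(contact_cutoff, output_type="ndarray")
    pairs = pairs[np.abs(pairs[:, 0] - pairs[:, 1]) > 2]   # skip trivial neighbors
    if len(pairs) == 0:
        return [domain]
    best_k, best_q = None, np.inf
    for k in range(min_subdomain_size, n - min_subdomain_size + 1):
        left = pairs < k
        inter = np.sum(left[:, 0] ^ left[:, 1])
        intra_a = np.sum(left[:, 0] & left[:, 1])
        intra_b = np.sum(~left[:, 0] & ~left[:, 1])
        if intra_a == 0 or intra_b == 0:
            continue
        q = inter / np.sqrt(intra_a * intra_b)
        if q < best_q:
            best_q, best_k = q, k
    if best_k is None or best_q >= split_threshold:
        return [domain]
    cut_res = int(ids[best_k])
    sub = []
    for lo, hi, tag in (
        (domain.res_start, cut_res - 1, "a"),
        (cut_res, domain.res_end, "b"),
    ):
        mask = (domain.atoms.res_id >= lo) & (domain.atoms.res_id <= hi)
        seg = Domain(
            label=f"{domain.label}.{tag}", chain_id=domain.chain_id,
            res_start=lo, res_end=hi, atoms=domain.atoms[mask].copy(),
        )
        sub.extend(
            _bipartition(seg, min_subdomain_size, contact_cutoff, split_threshold)
        )
    return sub


# ---------------------------------------------------------------------------
# score terms
# ---------------------------------------------------------------------------

def _residue_bead_coords(pose: Domain) -> np.ndarray:
    """One interaction bead per residue: CB when present, else CA."""
    atoms = pose.atoms
    coords = pose.coords
    is_cb = atoms.atom_name == "CB"
    is_ca = atoms.atom_name == "CA"
    beads = []
    for rid in pose.residue_ids:
        sel = atoms.res_id == rid
        if (sel & is_cb).any():
            beads.append(coords[sel & is_cb][0])
        elif (sel & is_ca).any():
            beads.append(coords[sel & is_ca][0])
        else:
            beads.append(coords[sel].mean(axis=0))
    return np.asarray(beads)


def _contact_well_energy(
    beads_a: np.ndarray,
    beads_b: np.ndarray,
    well_depth: float = 0.05,
    rep_scale: float = 10.0,
) -> float:
    """Residue-level interface potential: an attractive well of depth
    ``well_depth`` for bead-bead distances in 5-8 Å (linear ramps over
    4-5 and 8-9 Å) plus quadratic soft-sphere repulsion below 4 Å.

    The well depth is scaled so a typical genuine two-domain interface
    (tens of contacts) scores a few negative units, commensurate with
    the published weight magnitudes for this term.
    """
    _, _, d = _inter_pairs(beads_a, beads_b, 9.0)
    if len(d) == 0:
        return 0.0
    e = np.zeros_like(d)
    well = (d >= 5.0) & (d <= 8.0)
    e[well] = -well_depth
    ramp_in = (d >= 4.0) & (d < 5.0)
    e[ramp_in] = -well_depth * (d[ramp_in] - 4.0)
    ramp_out = (d > 8.0) & (d <= 9.0)
    e[ramp_out] = -well_depth * (9.0 - d[ramp_out])
    rep = d < 4.0
    e[rep] = rep_scale * ((4.0 - d[rep]) / 4.0) ** 2
    return float(e.sum())


def centroid_energy(
    pose_a: Domain,
    pose_b: Domain,
    well_depth: float = 0.05,
    rep_scale: float = 10.0,
) -> float:
    """Coarse-grained interface energy: E(combined) - E(separated).

    The separated reference translates the second domain 200 Å away and
    re-evaluates the same potential (zero there), so a favorable
    interface is negative and inter-penetration strongly positive.
    """
    beads_a = _residue_bead_coords(pose_a)
    beads_b = _residue_bead_coords(pose_b)
    combined = _contact_well_energy(beads_a, beads_b, well_depth, rep_scale)
    separated = _contact_well_energy(
        beads_a, beads_b + np.array([200.0, 0.0, 0.0]), well_depth, rep_scale
    )
    return combined - separated


def proximity_score(
    pose_a: Domain,
    pose_b: Domain,
    n_link: int | None = None,
    per_residue_span: float = 3.5,
    base_offset: float = 4.0,
) -> float:
    """Linker-closability penalty for chain-adjacent domains.

    ``gap`` is the distance from the C-terminal CA of the
    sequence-earlier domain to the N-terminal CA of the later one; the
    penalty is zero up to ``n_link * per_residue_span + base_offset``
    and quadratic beyond. Pairs on different chains score 0.
    """
    first, second = (
        (pose_a, pose_b) if pose_a.res_start <= pose_b.res_start else (pose_b, pose_a)
    )
    if first.chain_id != second.chain_id:
        return 0.0
    if n_link is None:
        # chain-adjacent means the second domain follows directly after
        # the first's linker; other same-chain pairs carry no penalty
        seq_gap = second.res_start - first.res_end - 1
        if seq_gap < 0 or seq_gap != first.n_link_next:
            return 0.0
        n_link = first.n_link_next
    ca_first, ca_second = first.ca_coords, second.ca_coords
    if len(ca_first) == 0 or len(ca_second) == 0:
        return 0.0
    order_f = np.argsort(first.ca_res_ids)
    order_s = np.argsort(second.ca_res_ids)
    gap = float(np.linalg.norm(ca_first[order_f[-1]] - ca_second[order_s[0]]))
    closable = n_link * per_residue_span + base_offset
    return 0.0 if gap <= closable else (gap - closable) ** 2


def crosslink_penalty(
    distance: float, threshold: float = 30.0, slope: float = 1.0, cap: float = 30.0
) -> float:
    """Flat-bottom bounded penalty for one cross-link distance."""
    if distance <= threshold:
        return 0.0
    return float(min(slope * (distance - threshold), cap))


# ---------------------------------------------------------------------------
# the assembly problem: slots, options, cached terms
# ---------------------------------------------------------------------------

@dataclass
class _Option:
    """One candidate pose of one domain variant within a slot."""

    variant: int            # index into the slot's domain variants
    placement: Placement
    pose: Domain
    rsc: float


@dataclass
class _Slot:
    """An assignment slot: mutually exclusive domain variants sharing
    one choice among candidate placements (or NOT_FOUND)."""

    name: str
    variants: list[Domain]
    options: list[_Option]
    frozen: bool = False
    frozen_option: int = NOT_FOUND


@dataclass
class AssemblyState:
    """One assignment of options to slots with its score breakdown."""

    assignment: np.ndarray            # option index per slot, or NOT_FOUND
    total_score: float
    breakdown: dict
    frozen: np.ndarray | None = None
    labels: list[str] | None = None
    multiplicity: int = 1             # trajectories ending in this state

    def to_dict(self) -> dict:
        return {
            "assignment": [int(a) for a in self.assignment],
            "labels": self.labels,
            "total_score": float(self.total_score),
            "breakdown": {k: float(v) for k, v in self.breakdown.items()},
            "frozen": None if self.frozen is None else [bool(f) for f in self.frozen],
        }


class AssemblyProblem:
    """Precomputed option scores and pairwise term caches.

    Building the problem performs, for every pair of options of
    different slots, the pairwise interface optimization (slide into
    contact within ``max_shift``, then clash-residue trimming when the
    pair is still severely clashing) and caches the interface energy,
    linker proximity penalty, cross-link penalties and a clash flag.
    The cache is symmetric by construction. ``frozen`` pins named slots
    to a specific (domain, placement) before the tables are built.
    """

    def __init__(
        self,
        domains: list[Domain],
        candidates: dict[str, list[Placement]],
        density: DensityMap,
        crosslinks: list[CrossLink] | None = None,
        config: RunConfig | None = None,
        resolution: float = 10.0,
        frozen: dict[str, tuple[Domain, Placement, int]] | None = None,
    ):
        self.cfg = config or RunConfig()
        self.density = density
        self.resolution = resolution
        self.crosslinks = crosslinks or []
        self.slots = self._build_slots(domains, candidates)
        if frozen:
            for slot in self.slots:
                if slot.name in frozen:
                    slot.frozen = True
                    slot.frozen_option = _match_option(slot, frozen[slot.name])
        self._score_options()
        self._build_pair_cache()
        self._build_tables()

    # -- construction ----------------------------------------------------
    def _build_slots(self, domains, candidates) -> list[_Slot]:
        # union-find over domains sharing > exclusive_overlap of residues
        parent = list(range(len(domains)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(domains)):
            for j in range(i + 1, len(domains)):
                if (
                    domains[i].shared_residue_fraction(domains[j])
                    > self.cfg.exclusive_overlap
                ):
                    parent[find(i)] = find(j)
        groups: dict[int, list[int]] = {}
        for i in range(len(domains)):
            groups.setdefault(find(i), []).append(i)
        slots = []
        for members in groups.values():
            variants = [domains[i] for i in members]
            options = []
            for vi, dom in enumerate(variants):
                for pl in candidates.get(dom.label, []):
                    options.append(
                        _Option(
                            variant=vi, placement=pl,
                            pose=apply_placement(dom, pl), rsc=0.0,
                        )
                    )
            name = "|".join(v.label for v in variants)
            slots.append(_Slot(name=name, variants=variants, options=options))
        slots.sort(key=lambda s: s.name)
        return slots

    def _score_options(self) -> None:
        for slot in self.slots:
            for opt in slot.options:
                try:
                    opt.rsc = masked_rsc(
                        opt.pose, self.density,
                        self.cfg.mask_radius, self.resolution,
                    )
                except Exception:
                    opt.rsc = 0.0   # pose outside the map: no density support

    def _optimize_pair(self, pose_a: Domain, pose_b: Domain, sse_a, sse_b):
        cfg = self.cfg
        a2, b2, _ = slide_into_contact(
            pose_a, pose_b, cfg.max_shift, cfg.contact_dist, cfg.clash_dist
        )
        if clash_score(a2, b2, cfg.clash_dist) > cfg.severe_clash_threshold:
            a2, b2 = trim_clashing_residues(a2, b2, sse_a, sse_b, cfg)
        return a2, b2

    def _build_pair_cache(self) -> None:
        self._sse = [
            [assign_secondary_structure(v) for v in slot.variants]
            for slot in self.slots
        ]
        n = len(self.slots)
        self.pair_cache: dict[tuple, dict] = {}
        for i in range(n):
            for j in range(i + 1, n):
                for p, op in enumerate(self.slots[i].options):
                    for q, oq in enumerate(self.slots[j].options):
                        self.pair_cache[(i, p, j, q)] = self._pair_terms(
                            i, p, j, q, op, oq
                        )

    def pair_entry(self, i: int, p: int, j: int, q: int) -> dict:
        """Symmetric access to the pairwise term cache."""
        if i > j:
            i, j, p, q = j, i, q, p
        return self.pair_cache[(i, p, j, q)]

    def _pair_terms(self, i, p, j, q, op: _Option, oq: _Option) -> dict:
        cfg = self.cfg
        pose_a, pose_b = op.pose, oq.pose
        # cheap reject: domains whose envelopes cannot touch need no
        # interface optimization
        gap = np.linalg.norm(pose_a.centroid - pose_b.centroid)
        radius_a = np.linalg.norm(pose_a.coords - pose_a.centroid, axis=1).max()
        radius_b = np.linalg.norm(pose_b.coords - pose_b.centroid, axis=1).max()
        near = gap < radius_a + radius_b + cfg.contact_dist + cfg.max_shift
        if near:
            a2, b2 = self._optimize_pair(
                pose_a, pose_b, self._sse[i][op.variant], self._sse[j][oq.variant]
            )
            energy = centroid_energy(a2, b2)
            clash = clash_score(a2, b2, cfg.clash_dist) > cfg.severe_clash_threshold
        else:
            a2, b2 = pose_a, pose_b
            energy = 0.0
            clash = False
        prox = proximity_score(
            a2, b2, per_residue_span=cfg.per_residue_span,
            base_offset=cfg.linker_base_offset,
        )
        # pairs that remain severely clashing after the interface
        # optimization are screened out with a large positive energy
        gated = cfg.clash_energy_penalty if clash else energy
        return {
            "centroid_energy": gated,
            "centroid_energy_raw": energy,
            "proximity": prox,
            "clash": clash,
        }

    # -- cross-link mapping ----------------------------------------------
    def _locate(self, opt: _Option, chain: str, res: int):
        """CA coordinate of (chain, res) in an option's pose, or None."""
        pose = opt.pose
        if pose.chain_id != chain:
            return None
        sel = (pose.atoms.res_id == res) & (pose.atoms.atom_name == "CA")
        if not sel.any():
            return None
        return pose.coords[sel][0]

    def _locate_slot(self, chain: str, res: int):
        """First slot containing (chain, res), with per-option CA coords."""
        for si, slot in enumerate(self.slots):
            coords = [self._locate(opt, chain, res) for opt in slot.options]
            if any(c is not None for c in coords):
                return si, coords
        return None, None

    def _build_tables(self) -> None:
        """Collapse every term into per-slot vectors (t1) and per-pair
        matrices (t2) indexed by padded option index (kmax = NOT_FOUND),
        so each MC move costs a handful of table lookups."""
        cfg = self.cfg
        w = cfg.weights
        n = len(self.slots)
        self.n_options = np.array([len(s.options) for s in self.slots], dtype=int)
        kmax = int(self.n_options.max()) if n else 0
        self.kmax = kmax
        self.t1 = np.full((n, kmax + 1), np.inf)
        for i, slot in enumerate(self.slots):
            for k, opt in enumerate(slot.options):
                self.t1[i, k] = w.w_dens * (-opt.rsc)
            self.t1[i, kmax] = cfg.not_found_offset
        self.t2 = np.zeros((n, n, kmax + 1, kmax + 1))
        for (i, p, j, q), entry in self.pair_cache.items():
            v = (
                w.w_centroid_energy * entry["centroid_energy"]
                + w.w_proximity * entry["proximity"]
            )
            self.t2[i, j, p, q] = v
            self.t2[j, i, q, p] = v

        # cross-links: each link lives on one slot (intra) or one slot
        # pair (inter); endpoints not present anywhere are unmapped
        self._links: list[tuple[CrossLink, int, int]] = []
        wx = w.w_distance_constraint
        miss = cfg.crosslink_missing_penalty
        for link in self.crosslinks:
            sa, coords_a = self._locate_slot(link.chain_a, link.res_a)
            sb, coords_b = self._locate_slot(link.chain_b, link.res_b)
            if sa is None or sb is None:
                continue
            self._links.append((link, sa, sb))
            if sa == sb:
                for k in range(self.n_options[sa]):
                    ca, cb = coords_a[k], coords_b[k]
                    if ca is None or cb is None:
                        pen = miss
                    else:
                        pen = crosslink_penalty(
                            float(np.linalg.norm(ca - cb)),
                            link.threshold, cfg.crosslink_slope, cfg.crosslink_cap,
                        )
                    self.t1[sa, k] += wx * pen
                self.t1[sa, kmax] += wx * miss
            else:
                ka_list = list(range(self.n_options[sa])) + [kmax]
                kb_list = list(range(self.n_options[sb])) + [kmax]
                for ka in ka_list:
                    for kb in kb_list:
                        ca = coords_a[ka] if ka != kmax else None
                        cb = coords_b[kb] if kb != kmax else None
                        if ca is None or cb is None:
                            pen = miss
                        else:
                            pen = crosslink_penalty(
                                float(np.linalg.norm(ca - cb)),
                                link.threshold, cfg.crosslink_slope,
                                cfg.crosslink_cap,
                            )
                        self.t2[sa, sb, ka, kb] += wx * pen
                        self.t2[sb, sa, kb, ka] += wx * pen

    # -- scoring ----------------------------------------------------------
    def _padded(self, assignment: np.ndarray) -> np.ndarray:
        a = np.asarray(assignment, dtype=int).copy()
        a[a == NOT_FOUND] = self.kmax
        return a

    def score(self, assignment) -> float:
        """Fast table-based total score of one assignment."""
        a = self._padded(assignment)
        n = len(self.slots)
        total = float(self.t1[np.arange(n), a].sum())
        for i in range(n):
            for j in range(i + 1, n):
                total += self.t2[i, j, a[i], a[j]]
        return total

    def state(self, assignment) -> AssemblyState:
        """Full state with a per-term breakdown; the weighted sum of the
        breakdown equals the total score to numerical precision."""
        cfg = self.cfg
        w = cfg.weights
        a = np.asarray(assignment, dtype=int)
        dens = prox = cent = 0.0
        n_not_found = 0
        for i, slot in enumerate(self.slots):
            if a[i] == NOT_FOUND:
                n_not_found += 1
            else:
                dens += -slot.options[a[i]].rsc
        for i in range(len(self.slots)):
            for j in range(i + 1, len(self.slots)):
                if a[i] == NOT_FOUND or a[j] == NOT_FOUND:
                    continue
                entry = self.pair_entry(i, int(a[i]), j, int(a[j]))
                cent += entry["centroid_energy"]
                prox += entry["proximity"]
        constr = self._constraint_total(a)
        total = (
            w.w_dens * dens
            + w.w_centroid_energy * cent
            + w.w_proximity * prox
            + w.w_distance_constraint * constr
            + n_not_found * cfg.not_found_offset
        )
        return AssemblyState(
            assignment=a.copy(),
            total_score=total,
            breakdown={
                "dens": dens,
                "centroid_energy": cent,
                "proximity": prox,
                "distance_constraint": constr,
                "n_not_found": n_not_found,
            },
            labels=[s.name for s in self.slots],
        )

    def _constraint_total(self, assignment: np.ndarray) -> float:
        """Unweighted cross-link penalty total for one assignment."""
        cfg = self.cfg
        total = 0.0
        for link, sa, sb in self._links:
            ka = assignment[sa]
            kb = assignment[sb]
            ca = (
                self._locate(self.slots[sa].options[ka], link.chain_a, link.res_a)
                if ka != NOT_FOUND else None
            )
            cb = (
                self._locate(self.slots[sb].options[kb], link.chain_b, link.res_b)
                if kb != NOT_FOUND else None
            )
            if ca is not None and cb is not None:
                total += crosslink_penalty(
                    float(np.linalg.norm(ca - cb)),
                    link.threshold, cfg.crosslink_slope, cfg.crosslink_cap,
                )
            else:
                total += cfg.crosslink_missing_penalty
        return total

    def enumerate_states(self) -> list[AssemblyState]:
        """Exhaustive enumeration of all assignments (small problems)."""
        from itertools import product

        ranges = [
            list(range(self.n_options[i])) + [NOT_FOUND]
            for i in range(len(self.slots))
        ]
        states = [self.state(np.array(a)) for a in product(*ranges)]
        states.sort(key=lambda s: s.total_score)
        return states


def total_score(problem: AssemblyProblem, assignment) -> AssemblyState:
    """Score one assignment (NOT_FOUND = -1 for unplaced slots)."""
    return problem.state(np.asarray(assignment, dtype=int))


# ---------------------------------------------------------------------------
# Monte Carlo simulated annealing
# ---------------------------------------------------------------------------

def mcsa_sample(
    problem: AssemblyProblem,
    schedule: AnnealSchedule | None = None,
    top_k: int = 10,
) -> list[AssemblyState]:
    """Anneal many independent trajectories; return top distinct finals.

    Every step picks one random unfrozen slot per trajectory and
    proposes a uniformly random alternative option (including
    NOT_FOUND), accepted by the Metropolis criterion at the current kT,
    which decays geometrically from ``kT_start`` to ``kT_end`` over the
    run. Trajectories are vectorized; results are reproducible for a
    fixed schedule seed.
    """
    sched = schedule or problem.cfg.schedule
    rng = np.random.default_rng(sched.seed)
    n_slots = len(problem.slots)
    n_traj = sched.n_trajectories
    kmax = problem.kmax
    n_opt = problem.n_options
    frozen = np.array([s.frozen for s in problem.slots])
    movable = ~frozen & (n_opt > 0)
    free_slots = np.flatnonzero(movable)
    if len(free_slots) == 0:
        a = np.array(
            [s.frozen_option if s.frozen else NOT_FOUND for s in problem.slots]
        )
        return [problem.state(a)]

    a = np.empty((n_traj, n_slots), dtype=np.int64)
    for i, slot in enumerate(problem.slots):
        if slot.frozen:
            a[:, i] = slot.frozen_option if slot.frozen_option != NOT_FOUND else kmax
        elif n_opt[i] == 0:
            a[:, i] = kmax
        else:
            draw = rng.integers(0, n_opt[i] + 1, size=n_traj)
            a[:, i] = np.where(draw == n_opt[i], kmax, draw)

    t1, t2 = problem.t1, problem.t2
    idx_slots = np.arange(n_slots)
    scores = t1[idx_slots, a].sum(axis=1)
    for i in range(n_slots):
        for j in range(i + 1, n_slots):
            scores += t2[i, j, a[:, i], a[:, j]]

    n_steps = sched.n_steps
    if n_steps > 1 and sched.kT_start != sched.kT_end:
        kts = sched.kT_start * (
            (sched.kT_end / sched.kT_start) ** (np.arange(n_steps) / (n_steps - 1))
        )
    else:
        kts = np.full(n_steps, sched.kT_end)

    traj = np.arange(n_traj)
    for step in range(n_steps):
        d = free_slots[rng.integers(0, len(free_slots), size=n_traj)]
        cur = a[traj, d]
        n_real = n_opt[d]
        # uniform over the n_real alternatives (other options + NOT_FOUND)
        prop = rng.integers(0, n_real)
        cur_real = np.where(cur == kmax, n_real, cur)
        prop = np.where(prop >= cur_real, prop + 1, prop)
        prop = np.where(prop >= n_real + 1, kmax, prop)
        prop = np.where(prop == n_real, kmax, prop)
        delta = t1[d, prop] - t1[d, cur]
        inter = (
            t2[d[:, None], idx_slots[None, :], prop[:, None], a]
            - t2[d[:, None], idx_slots[None, :], cur[:, None], a]
        )
        inter[traj, d] = 0.0
        delta = delta + inter.sum(axis=1)
        kt = kts[step]
        accept = delta <= 0
        hot = ~accept
        if kt > 0 and hot.any():
            accept[hot] = rng.random(hot.sum()) < np.exp(
                -np.clip(delta[hot] / kt, 0.0, 700.0)
            )
        a[traj[accept], d[accept]] = prop[accept]
        scores[accept] += delta[accept]

    order = np.argsort(scores, kind="stable")
    counts: dict[tuple, int] = {}
    for t in range(n_traj):
        key = tuple(a[t])
        counts[key] = counts.get(key, 0) + 1
    seen = set()
    out: list[AssemblyState] = []
    for t in order:
        key = tuple(a[t])
        if key in seen:
            continue
        seen.add(key)
        assignment = np.where(a[t] == kmax, NOT_FOUND, a[t])
        st = problem.state(assignment)
        st.multiplicity = counts[key]
        out.append(st)
        if len(out) >= top_k:
            break
    return out


def assess_convergence(
    problem: AssemblyProblem,
    top_states: list[AssemblyState],
    rms_tolerance: float = 5.0,
    n_votes: int = 10,
) -> dict[int, int]:
    """Freeze decisions from the top sampled states.

    Votes come from the ``n_votes`` best-scoring trajectory endpoints:
    distinct states are taken best-first, each contributing up to its
    multiplicity (1 for externally constructed state lists). A slot is
    frozen iff one placement — counting placements of the same domain
    variant within ``rms_tolerance`` CA-RMSD of each other as the same
    — holds strictly more than half of the votes. Returns {slot index:
    representative option index}, the representative taken from the
    best-scoring state in the majority cluster.
    """
    frozen: dict[int, int] = {}
    if not top_states:
        return frozen
    votes: list[tuple[AssemblyState, int]] = []
    remaining = n_votes
    for st in top_states:
        take = min(max(int(st.multiplicity), 1), remaining)
        votes.append((st, take))
        remaining -= take
        if remaining <= 0:
            break
    total_votes = sum(v for _, v in votes)
    for si, slot in enumerate(problem.slots):
        if slot.frozen:
            continue
        placed = [
            (int(st.assignment[si]), v)
            for st, v in votes
            if int(st.assignment[si]) != NOT_FOUND
        ]
        if not placed:
            continue
        clusters: list[list[tuple[int, int]]] = []
        for k, v in placed:
            for cl in clusters:
                if _option_rmsd(slot, k, cl[0][0]) < rms_tolerance:
                    cl.append((k, v))
                    break
            else:
                clusters.append([(k, v)])
        best = max(clusters, key=lambda cl: sum(v for _, v in cl))
        if sum(v for _, v in best) > total_votes / 2:
            frozen[si] = best[0][0]   # states arrive best-first
    return frozen


def _option_rmsd(slot: _Slot, k1: int, k2: int) -> float:
    o1, o2 = slot.options[k1], slot.options[k2]
    if o1.variant != o2.variant:
        return np.inf
    c1, c2 = o1.pose.ca_coords, o2.pose.ca_coords
    if len(c1) == 0 or len(c1) != len(c2):
        return np.inf
    return float(np.sqrt(((c1 - c2) ** 2).sum(axis=1).mean()))


def _match_option(slot: _Slot, target: tuple[Domain, Placement, int]) -> int:
    """Find (or append) the option matching a frozen placement."""
    dom, placement, variant = target
    for k, opt in enumerate(slot.options):
        if (
            opt.variant == variant
            and np.allclose(opt.placement.rotation, placement.rotation, atol=1e-9)
            and np.allclose(opt.placement.translation, placement.translation, atol=1e-9)
        ):
            return k
    slot.options.append(
        _Option(
            variant=variant, placement=placement,
            pose=apply_placement(dom, placement), rsc=0.0,
        )
    )
    return len(slot.options) - 1


# ---------------------------------------------------------------------------
# iterative freeze / density-removal / redock loop
# ---------------------------------------------------------------------------

def iterative_assemble(
    domains: list[Domain],
    density: DensityMap,
    crosslinks: list[CrossLink] | None = None,
    config: RunConfig | None = None,
    resolution: float = 10.0,
    candidates: dict[str, list[Placement]] | None = None,
    max_rounds: int = 5,
) -> tuple[AssemblyState, AssemblyProblem, list[dict]]:
    """Assemble domains with iterative freezing and redocking.

    Rounds of MC-SA sampling alternate with convergence assessment:
    slots whose placement recurs in a majority of the top states are
    frozen, the density they occupy is removed from the working map,
    unfrozen domains are redocked into the remaining density, and
    sampling repeats. Stops when a round freezes nothing new or
    ``max_rounds`` is reached. Returns (final best state, the problem
    it was scored on, per-round log).
    """
    cfg = config or RunConfig()
    if candidates is None:
        rotations = build_rotation_grid(cfg.rot_step)
        points = select_search_points(density, cfg.n_points, cfg.min_separation)
        candidates = {
            d.label: dock_domain(
                d, density, cfg, resolution=resolution,
                points=points, rotations=rotations,
            ).placements
            for d in domains
        }
    else:
        candidates = dict(candidates)
    work_map = density
    frozen_state: dict[str, tuple[Domain, Placement, int]] = {}
    log: list[dict] = []
    problem = None
    best_states = None
    for round_no in range(1, max_rounds + 1):
        sched = replace(cfg.schedule, seed=cfg.schedule.seed + round_no)
        problem = AssemblyProblem(
            domains, candidates, work_map, crosslinks, cfg, resolution,
            frozen=frozen_state,
        )
        best_states = mcsa_sample(problem, sched)
        newly = assess_convergence(problem, best_states, cfg.convergence_rms)
        log.append(
            {
                "round": round_no,
                "best_score": float(best_states[0].total_score),
                "n_frozen_before": len(frozen_state),
                "newly_frozen": {
                    problem.slots[si].name: int(k) for si, k in newly.items()
                },
            }
        )
        if not newly:
            break
        for si, k in newly.items():
            slot = problem.slots[si]
            opt = slot.options[k]
            frozen_state[slot.name] = (
                slot.variants[opt.variant], opt.placement, opt.variant,
            )
        if len(frozen_state) == len(problem.slots):
            continue   # one more round to confirm no further change
        # remove frozen density, then redock the unfrozen domains
        work_map = density
        frozen_labels = set()
        for dom, pl, _ in frozen_state.values():
            posed = apply_placement(dom, pl)
            work_map = mask_out(work_map, posed.atoms, cfg.mask_out_radius)
            frozen_labels.add(dom.label)
        rotations = build_rotation_grid(cfg.rot_step)
        points = select_search_points(work_map, cfg.n_points, cfg.min_separation)
        for d in domains:
            if d.label not in frozen_labels:
                candidates[d.label] = dock_domain(
                    d, work_map, cfg, resolution=resolution,
                    points=points, rotations=rotations,
                ).placements

    final = best_states[0]
    assignment = final.assignment.copy()
    for si, slot in enumerate(problem.slots):
        if slot.frozen:
            assignment[si] = slot.frozen_option
    final = problem.state(assignment)
    final.frozen = np.array([s.frozen for s in problem.slots])
    return final, problem, log


def assembled_structure(problem: AssemblyProblem, state: AssemblyState):
    """Concatenate the posed atoms of all placed slots into one model."""
    arrays = []
    for si, slot in enumerate(problem.slots):
        k = int(state.assignment[si])
        if k == NOT_FOUND:
            continue
        arrays.append(slot.options[k].pose.atoms)
    if not arrays:
        return None
    out = arrays[0]
    for arr in arrays[1:]:
        out = out + arr
    return out
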