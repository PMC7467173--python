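"""Atomic structures and rigid-body domains.

Structures are held as :class:`biotite.structure.AtomArray`; domains are
contiguous residue ranges carved from one chain and treated as rigid
bodies by docking and assembly. Secondary structure is assigned with a
CA-geometry heuristic (P-SEA, as implemented in biotite), which is all
the clash-trimming rule needs and works for CA-only models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io import pdb as io_pdb
from biotite.structure.io import pdbx as io_pdbx

from .errors import EmptyDomainError, FormatError, InvalidRotationError

__all__ = [
    "Structure",
    "Domain",
    "Placement",
    "read_structure",
    "write_structure",
    "atom_weights",
    "extract_domain",
    "assign_secondary_structure",
    "apply_placement",
    "identity_placement",
    "read_domain_table",
    "domains_from_table",
]

Structure = struc.AtomArray

# monoisotopic-ish masses for the elements that occur in protein models
_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971,
}


def atom_weights(atoms: Structure) -> np.ndarray:
    """Atomic weight per atom (element mass; 12.0 for unknown elements)."""
    return np.array(
        [_MASSES.get(str(e).upper(), 12.0) for e in atoms.element], dtype=float
    )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_structure(path: str | Path) -> Structure:
    """Read a PDB or mmCIF file into an AtomArray (first model)."""
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix in (".cif", ".mmcif", ".pdbx"):
            f = io_pdbx.CIFFile.read(str(path))
            arr = io_pdbx.get_structure(f, model=1)
        else:
            f = io_pdb.PDBFile.read(str(path))
            arr = f.get_structure(model=1)
    except Exception as exc:  # biotite raises several parse error types
        raise FormatError(f"cannot parse structure {path}: {exc}") from exc
    return arr


def write_structure(atoms: Structure, path: str | Path) -> None:
    """Write an AtomArray as PDB or mmCIF, chosen by file extension."""
    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif", ".pdbx"):
        f = io_pdbx.CIFFile()
        io_pdbx.set_structure(f, atoms)
        f.write(str(path))
    else:
        f = io_pdb.PDBFile()
        f.set_structure(atoms)
        f.write(str(path))


# ---------------------------------------------------------------------------
# domains
# ---------------------------------------------------------------------------

@dataclass
class Domain:
    """A contiguous-residue rigid body carved from one chain.

    ``n_link_prev``/``n_link_next`` count unmodeled linker residues to
    the chain-adjacent domains (from sequence numbering gaps); they set
    how far apart two adjacent domains may be placed while remaining
    closable by a rebuilt linker.
    """

    label: str
    chain_id: str
    res_start: int
    res_end: int
    atoms: Structure
    n_link_prev: int = 0
    n_link_next: int = 0

    def __post_init__(self) -> None:
        if self.res_end < self.res_start:
            raise ValueError("residue_range must be non-empty")
        if self.atoms.array_length() == 0:
            raise EmptyDomainError(f"domain {self.label} has no atoms")

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.atoms.coord, dtype=float)

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    @property
    def ca_mask(self) -> np.ndarray:
        return self.atoms.atom_name == "CA"

    @property
    def ca_coords(self) -> np.ndarray:
        return self.coords[self.ca_mask]

    @property
    def ca_res_ids(self) -> np.ndarray:
        return self.atoms.res_id[self.ca_mask]

    @property
    def residue_ids(self) -> np.ndarray:
        return np.unique(self.atoms.res_id)

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def copy(self) -> "Domain":
        return replace(self, atoms=self.atoms.copy())

    def shared_residue_fraction(self, other: "Domain") -> float:
        """Fraction of the smaller domain's residues shared with ``other``."""
        if self.chain_id != other.chain_id:
            return 0.0
        a, b = set(self.residue_ids.tolist()), set(other.residue_ids.tolist())
        if not a or not b:
            return 0.0
        return len(a & b) / min(len(a), len(b))


def extract_domain(
    structure: Structure, chain: str, start: int, end: int, label: str = ""
) -> Domain:
    """Carve residues [start, end] (inclusive) of one chain as a Domain."""
    sel = (
        (structure.chain_id == chain)
        & (structure.res_id >= start)
        & (structure.res_id <= end)
    )
    atoms = structure[sel]
    if atoms.array_length() == 0:
        raise EmptyDomainError(
            f"no residues in chain {chain} range {start}-{end}"
        )
    return Domain(
        label=label or f"{chain}_{start}-{end}",
        chain_id=chain, res_start=start, res_end=end, atoms=atoms.copy(),
    )


# ---------------------------------------------------------------------------
# secondary structure (CA-geometry heuristic)
# ---------------------------------------------------------------------------

_SSE_MAP = {"a": "H", "b": "E", "c": "L"}


def assign_secondary_structure(domain: Domain) -> np.ndarray:
    """Per-residue secondary structure in {H, E, L}.

    Uses the P-SEA CA-distance/angle criteria; fragments too short for
    any helix/strand call (fewer than 5 CA atoms) are labeled all-L, as
    are residues lacking a CA atom.
    """
    n_res = domain.n_residues
    labels = np.full(n_res, "L", dtype="<U1")
    ca = domain.atoms[domain.ca_mask]
    if ca.array_length() < 5:
        return labels
    try:
        sse = struc.annotate_sse(ca)
    except Exception:
        return labels
    ca_ids = ca.res_id
    id_to_pos = {rid: i for i, rid in enumerate(domain.residue_ids)}
    for rid, s in zip(ca_ids, sse):
        labels[id_to_pos[int(rid)]] = _SSE_MAP.get(str(s), "L")
    return labels


# ---------------------------------------------------------------------------
# rigid placements
# ---------------------------------------------------------------------------

@dataclass
class Placement:
    """One rigid-body pose of a domain.

    The pose maps library coordinates ``x`` (centroid ``c``) to
    ``R @ (x - c) + c + t``: rotation about the domain centroid followed
    by translation.
    """

    rotation: np.ndarray              # (3, 3), orthonormal det +1
    translation: np.ndarray           # (3,) Å
    coarse_score: float | None = None
    refined_score: float | None = None
    rank: int | None = None
    model_index: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    def apply(self, coords: np.ndarray, centroid: np.ndarray) -> np.ndarray:
        c = np.asarray(centroid, dtype=float)
        return (np.asarray(coords, dtype=float) - c) @ self.rotation.T + c + self.translation

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "model_index": self.model_index,
            "rotation": [float(v) for v in self.rotation.ravel()],
            "translation": [float(v) for v in self.translation],
            "coarse_score": None if self.coarse_score is None else float(self.coarse_score),
            "refined_score": None if self.refined_score is None else float(self.refined_score),
            "rank": self.rank,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Placement":
        return cls(
            rotation=np.array(d["rotation"], dtype=float).reshape(3, 3),
            translation=np.array(d["translation"], dtype=float),
            coarse_score=d.get("coarse_score"),
            refined_score=d.get("refined_score"),
            rank=d.get("rank"),
            model_index=d.get("model_index", 0),
            label=d.get("label", ""),
        )


def identity_placement() -> Placement:
    return Placement(rotation=np.eye(3), translation=np.zeros(3))


def _check_rotation(R: np.ndarray, tol: float = 1e-6) -> None:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=tol):
        raise InvalidRotationError("rotation matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise InvalidRotationError("rotation matrix has det -1 (reflection)")


def apply_placement(domain: Domain, placement: Placement) -> Domain:
    """Return a posed copy of ``domain``; the input is untouched."""
    _check_rotation(placement.rotation)
    posed = domain.copy()
    posed.atoms.coord = placement.apply(
        domain.coords, domain.centroid
    ).astype(posed.atoms.coord.dtype)
    return posed


# ---------------------------------------------------------------------------
# domain definition tables
# ---------------------------------------------------------------------------

def read_domain_table(path: str | Path) -> pd.DataFrame:
    """Domain definition CSV with columns label,chain,start,end."""
    df = pd.read_csv(path)
    required = {"label", "chain", "start", "end"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"domain table must have columns {sorted(required)}; got {list(df.columns)}"
        )
    return df


def domains_from_table(structure: Structure, table: pd.DataFrame) -> list[Domain]:
    """Carve the domains of a definition table and fill in linker counts.

    Linker counts are sequence-numbering gaps between chain-adjacent
    domains (0 when ranges abut or overlap).
    """
    domains = [
        extract_domain(structure, str(r.chain), int(r.start), int(r.end), str(r.label))
        for r in table.itertuples()
    ]
    by_chain: dict[str, list[Domain]] = {}
    for d in domains:
        by_chain.setdefault(d.chain_id, []).append(d)
    for chain_domains in by_chain.values():
        chain_domains.sort(key=lambda d: (d.res_start, d.res_end))
        for prev, nxt in zip(chain_domains, chain_domains[1:]):
            gap = max(0, nxt.res_start - prev.res_end - 1)
            prev.n_link_next = gap
            nxt.n_link_prev = gap
    return domains
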