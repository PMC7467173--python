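"""Run configuration: every tunable of the pipeline in one place.

Defaults follow the published protocol where it states a value
(search-point count and spacing, refinement depth, redundancy cutoff,
solution count, slide limit, cross-link threshold, score weights and
annealing schedule); the remaining constants are this package's own
calibrated choices and are documented in the methods note.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class ScoreWeights:
    """Multipliers of the four assembly score terms (dimensionless)."""

    w_dens: float = 260.0
    w_proximity: float = 1000.0
    w_centroid_energy: float = 150.0
    w_distance_constraint: float = 30000.0


@dataclass
class AnnealSchedule:
    """Monte Carlo simulated-annealing schedule.

    ``kT`` decays geometrically from ``kT_start`` to ``kT_end`` over
    ``n_steps``; ``n_trajectories`` independent runs are performed.
    """

    n_steps: int = 200_000
    kT_start: float = 100.0
    kT_end: float = 1.0
    n_trajectories: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not (self.kT_start >= self.kT_end > 0):
            raise ValueError("require kT_start >= kT_end > 0")


@dataclass
class RunConfig:
    """All tunables of the docking/assembly pipeline with their defaults."""

    # docking (6D search)
    n_points: int = 50_000            # high-density translation candidates
    min_separation: float = 2.0       # Å between search points
    rot_step: float = 15.0            # degrees, SO(3) grid spacing
    n_refine: int = 1000              # candidates passed to rigid-body refinement
    rms_cutoff: float = 11.0          # Å CA-RMSD redundancy cutoff
    n_keep: int = 200                 # placements kept per domain
    mask_radius: float = 4.0          # Å mask around atoms for masked RSC
    normalize_coarse: bool = False    # divide coarse score by rotation self-overlap

    # map simulation
    sigma_convention: str = "resolution/(pi*sqrt(2))"
    mask_out_radius: float = 3.0      # Å, density removal around frozen domains

    # assembly geometry
    max_shift: float = 5.0            # Å, pairwise slide-into-contact limit
    contact_dist: float = 8.0         # Å CA-CA defining "in contact"
    clash_dist: float = 4.0           # Å CA-CA soft-sphere contact radius
    severe_clash_threshold: float = 3.0   # pairwise clash score gating trimming
    per_residue_clash_threshold: float = 0.25
    clash_energy_penalty: float = 50.0    # interface energy assigned to pairs
                                          # still clashing after optimization
    exposure_max_neighbors: int = 10  # CA neighbors within exposure_radius
    exposure_radius: float = 12.0     # Å
    min_subdomain_size: int = 20      # residues, for contact-map splitting

    # assembly score terms
    crosslink_threshold: float = 30.0   # Å CA-CA
    crosslink_slope: float = 1.0        # penalty per Å beyond threshold
    crosslink_cap: float = 30.0         # penalty bound per link
    crosslink_missing_penalty: float = 0.0  # for links touching NOT_FOUND
    per_residue_span: float = 3.5       # Å per linker residue (closability)
    linker_base_offset: float = 4.0     # Å added to closable gap
    not_found_offset: float = 0.0       # score of leaving a domain unplaced
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    convergence_rms: float = 5.0        # Å, placements counted as "same"
    exclusive_overlap: float = 0.20     # shared-residue fraction making domains alternatives

    seed: int = 0

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "weights" in d and isinstance(d["weights"], dict):
            d["weights"] = ScoreWeights(**d["weights"])
        if "schedule" in d and isinstance(d["schedule"], dict):
            d["schedule"] = AnnealSchedule(**d["schedule"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        """Stable short hash identifying this configuration."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]
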