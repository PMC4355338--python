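"""Synthetic isoform families and toy site structures with known truth.

The family generator emulates the anatomy of a real isoform family's
active site: a reference sequence; a small invariant (catalytic) core —
the analogue of the zinc-coordinating histidines; a few planted
highly-variable positions with controlled residue alphabets — the analogue
of the selective-pocket rim; and independent background substitution
everywhere else. Defaults mirror the carbonic anhydrase study family:
12 members, 260 residues (the alpha-CA domain scale), background
substitution probability 0.05 per site.

The structure generator places one C-alpha per residue on a sphere at a
planted distance from a metal at the origin, puts ligand atoms 3 A from
each planted contact residue, then applies an optional rigid motion and
Gaussian coordinate noise. Truth records retain everything planted so
recovery can be asserted exactly.

All randomness flows through one seeded numpy Generator per call; the same
seed gives byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .alignment import AMINO_ACIDS, IsoformSequence
from .structure import Atom, SiteStructure


@dataclass
class FamilyConfig:
    n_isoforms: int = 12
    length: int = 260
    background_rate: float = 0.05
    invariant_positions: frozenset[int] = frozenset()  # 1-based
    # 1-based position -> residue alphabet drawn uniformly with replacement
    variable_positions: dict[int, str] = field(default_factory=dict)
    # (member index, 1-based position after which to insert, length)
    insertion: tuple[int, int, int] | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.background_rate <= 1.0:
            raise ValueError("background rate must be in [0, 1]")
        special = set(self.invariant_positions) | set(self.variable_positions)
        if set(self.invariant_positions) & set(self.variable_positions):
            raise ValueError("invariant and variable positions must be disjoint")
        if any(not 1 <= p <= self.length for p in special):
            raise ValueError("special positions must lie within the sequence")


@dataclass
class FamilyTruth:
    reference: str
    invariant_positions: list[int]
    # position -> list of realized residues, one per member
    planted: dict[int, list[str]]
    insertion: tuple[int, int, int] | None


def generate_family(cfg: FamilyConfig) -> tuple[list[IsoformSequence], FamilyTruth]:
    """Draw a family and its truth record; reproducible from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    aa = np.array(list(AMINO_ACIDS))
    ref = rng.choice(aa, size=cfg.length)
    invariant = sorted(cfg.invariant_positions)
    planted: dict[int, list[str]] = {p: [] for p in cfg.variable_positions}
    members = []
    for k in range(cfg.n_isoforms):
        seq = ref.copy()
        for p0 in range(cfg.length):
            pos = p0 + 1
            if pos in cfg.invariant_positions:
                continue
            if pos in cfg.variable_positions:
                choice = rng.choice(list(cfg.variable_positions[pos]))
                seq[p0] = choice
                planted[pos].append(str(choice))
                continue
            if rng.random() < cfg.background_rate:
                others = [c for c in AMINO_ACIDS if c != seq[p0]]
                seq[p0] = rng.choice(others)
        residues = "".join(seq)
        if cfg.insertion is not None and cfg.insertion[0] == k:
            _, after, ins_len = cfg.insertion
            insert = "".join(rng.choice(aa, size=ins_len))
            residues = residues[:after] + insert + residues[after:]
        members.append(IsoformSequence(f"ISO{k + 1:02d}", residues))
    truth = FamilyTruth("".join(ref), invariant, planted, cfg.insertion)
    return members, truth


@dataclass
class StructureConfig:
    # 1-based residue number -> distance (A) of its C-alpha from the metal
    residue_distances: dict[int, float] = field(default_factory=dict)
    # residue numbers that receive a ligand atom 3 A away
    contact_positions: frozenset[int] = frozenset()
    rotation_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    rotation_angle: float = 0.0  # radians
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(d <= 0 for d in self.residue_distances.values()):
            raise ValueError("residue distances must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if not set(self.contact_positions) <= set(self.residue_distances):
            raise ValueError("contact positions must be placed residues")


@dataclass
class StructureTruth:
    rotation: list[list[float]]
    translation: list[float]
    residue_distances: dict[int, float]
    contact_positions: list[int]


def _rotation_matrix(axis, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    cc = 1.0 - c
    return np.array(
        [
            [c + x * x * cc, x * y * cc - z * s, x * z * cc + y * s],
            [y * x * cc + z * s, c + y * y * cc, y * z * cc - x * s],
            [z * x * cc - y * s, z * y * cc + x * s, c + z * z * cc],
        ]
    )


def generate_toy_structure(cfg: StructureConfig) -> tuple[SiteStructure, StructureTruth]:
    """Build the toy site, apply the rigid motion and noise, keep the truth."""
    rng = np.random.default_rng(cfg.seed)
    rot = _rotation_matrix(cfg.rotation_axis, cfg.rotation_angle)
    trans = np.asarray(cfg.translation, dtype=float)

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    metal_index = 0
    atoms.append(Atom("ZN", "ZN", "ZN", "A", 9000, 0.0, 0.0, 0.0))
    coords.append(np.zeros(3))
    ligand_indices: list[int] = []
    for resnum in sorted(cfg.residue_distances):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = direction * cfg.residue_distances[resnum]
        atoms.append(Atom("C", "CA", "GLY", "A", resnum, *pos))
        coords.append(pos)
        if resnum in cfg.contact_positions:
            lig = pos + direction * 3.0
            ligand_indices.append(len(atoms))
            atoms.append(Atom("C", "C1", "LIG", "L", 9100 + resnum, *lig))
            coords.append(lig)

    xyz = np.array(coords) @ rot.T + trans
    if cfg.noise_sigma > 0:
        xyz = xyz + rng.normal(scale=cfg.noise_sigma, size=xyz.shape)
    atoms = [
        Atom(a.element, a.name, a.resname, a.chain, a.resnum, *xyz[i])
        for i, a in enumerate(atoms)
    ]
    truth = StructureTruth(
        rot.tolist(),
        trans.tolist(),
        dict(cfg.residue_distances),
        sorted(cfg.contact_positions),
    )
    return SiteStructure("synthetic", atoms, metal_index, ligand_indices), truth


def write_truth(truth, path) -> None:
    """Truth record as JSON beside the generated data file."""
    record = asdict(truth)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=1, default=str)
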