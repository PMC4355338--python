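"""Structural stage: coordinate parsing, rigid-body superposition, and
active-site / ligand-contact extraction.

Structures enter as PDB files (first model, altloc A, hydrogens dropped).
Superposition is the Kabsch least-squares algorithm over matched point
sets — by convention the C-alpha atoms of residues co-present at the same
reference positions. The active site is taken as every residue with a
heavy atom within a cutoff (default 15 A, the scale of the conical
carbonic anhydrase cleft) of the catalytic metal; ligand contacts use a
4.0 A heavy-atom cutoff and feed the selective-pocket contact set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser

from .refmap import ReferenceMap

DEFAULT_SITE_CUTOFF = 15.0  # A, cavity scale: ~15 A wide and deep
DEFAULT_CONTACT_CUTOFF = 4.0  # A, standard heavy-atom contact distance


@dataclass(frozen=True)
class Atom:
    element: str
    name: str
    resname: str
    chain: str
    resnum: int
    x: float
    y: float
    z: float

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class SiteStructure:
    """Flat atom list with an optional designated metal center and ligand."""

    label: str
    atoms: list[Atom]
    metal_index: int | None = None
    ligand_indices: list[int] = field(default_factory=list)

    def coords(self, indices=None) -> np.ndarray:
        atoms = self.atoms if indices is None else [self.atoms[i] for i in indices]
        return np.array([[a.x, a.y, a.z] for a in atoms])

    @property
    def metal(self) -> Atom | None:
        return None if self.metal_index is None else self.atoms[self.metal_index]

    def ca_by_resnum(self) -> dict[tuple[str, int], int]:
        return {
            (a.chain, a.resnum): i
            for i, a in enumerate(self.atoms)
            if a.name == "CA" and a.element != "ZN"
        }


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, proper (det +1)
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def transform(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def read_pdb(path, label: str | None = None) -> SiteStructure:
    """Parse a PDB file into a flat heavy-atom list.

    First model only; alternate locations other than blank/'A' and all
    hydrogens are dropped. A unique zinc HETATM becomes the metal center;
    with several zincs the center is left unset for the caller to choose.
    Non-water hetero residues (excluding the metal) are recorded as ligand
    atoms.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        struct = parser.get_structure(label or "structure", str(path))
    models = list(struct.get_models())
    if not models:
        raise ValueError(f"{path}: no coordinate records")
    atoms: list[Atom] = []
    zinc_indices: list[int] = []
    ligand_indices: list[int] = []
    for chain in models[0]:
        for residue in chain:
            hetflag = residue.id[0]
            for atom in residue.get_unpacked_list():
                if atom.get_altloc() not in (" ", "A", ""):
                    continue
                element = (atom.element or "").upper()
                if element in ("H", "D"):
                    continue
                idx = len(atoms)
                atoms.append(
                    Atom(
                        element,
                        atom.get_name(),
                        residue.get_resname(),
                        chain.id,
                        residue.id[1],
                        *(float(v) for v in atom.coord),
                    )
                )
                if element == "ZN":
                    zinc_indices.append(idx)
                elif hetflag not in (" ",) and hetflag != "W":
                    ligand_indices.append(idx)
    if not atoms:
        raise ValueError(f"{path}: no atoms parsed")
    metal = zinc_indices[0] if len(zinc_indices) == 1 else None
    return SiteStructure(label or str(path), atoms, metal, ligand_indices)


def write_pdb(s: SiteStructure, path) -> None:
    """Fixed-column coordinate dump (debug / synthetic-data output)."""
    hetero = set(s.ligand_indices)
    if s.metal_index is not None:
        hetero.add(s.metal_index)
    with open(path, "w") as fh:
        for i, a in enumerate(s.atoms):
            record = "HETATM" if i in hetero else "ATOM  "
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            fh.write(
                f"{record}{i + 1:5d} {name}{'':1s}{a.resname:>3s} {a.chain}"
                f"{a.resnum:4d}    {a.x:8.3f}{a.y:8.3f}{a.z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n"
            )
        fh.write("END\n")


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of moving onto fixed.

    Proper rotation is enforced (the smallest singular vector's sign is
    flipped when the raw solution is a reflection). Degenerate point sets
    (fewer than 3 points, or collinear) are rejected.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError("point sets differ in shape")
    n = moving.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    mov_mean = moving.mean(axis=0)
    fix_mean = fixed.mean(axis=0)
    a = moving - mov_mean
    b = fixed - fix_mean
    if np.linalg.matrix_rank(a, tol=1e-8) < 2 or np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rotation = vt.T @ correction @ u.T
    translation = fix_mean - rotation @ mov_mean
    moved = moving @ rotation.T + translation
    rmsd = float(np.sqrt(((moved - fixed) ** 2).sum() / n))
    return SuperpositionResult(rotation, translation, rmsd, n)


def superpose_structures(
    moving: SiteStructure,
    fixed: SiteStructure,
    moving_map: dict[int, int] | None = None,
    fixed_map: dict[int, int] | None = None,
) -> SuperpositionResult:
    """Superpose on C-alpha atoms of residues co-present at the same
    reference positions.

    The optional maps take each structure's residue numbers to reference
    positions; by default residue numbers are assumed to already be in
    reference numbering.
    """

    def ca_at_refpos(s: SiteStructure, num_map) -> dict[int, int]:
        out = {}
        for (chain, resnum), idx in s.ca_by_resnum().items():
            ref = resnum if num_map is None else num_map.get(resnum)
            if ref is not None:
                out[ref] = idx
        return out

    mov = ca_at_refpos(moving, moving_map)
    fix = ca_at_refpos(fixed, fixed_map)
    common = sorted(set(mov) & set(fix))
    if len(common) < 3:
        raise ValueError("fewer than 3 matched C-alpha positions")
    return kabsch_superpose(
        moving.coords([mov[p] for p in common]),
        fixed.coords([fix[p] for p in common]),
    )


def site_residues(
    s: SiteStructure,
    center: np.ndarray | None = None,
    cutoff: float = DEFAULT_SITE_CUTOFF,
) -> set[tuple[str, int, str]]:
    """Residues with any heavy atom within cutoff of the (metal) center."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if center is None:
        if s.metal is None:
            raise ValueError("no metal center designated and none supplied")
        center = s.metal.coord
    center = np.asarray(center, dtype=float)
    out = set()
    skip = {s.metal_index} | set(s.ligand_indices)
    for i, a in enumerate(s.atoms):
        if i in skip:
            continue
        if np.linalg.norm(a.coord - center) <= cutoff:
            out.add((a.chain, a.resnum, a.resname))
    return out


@dataclass
class ContactResult:
    positions: set[int]
    unmapped: list[tuple[str, int, str]]


def ligand_contacts(
    s: SiteStructure,
    ligand_indices: list[int] | None = None,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    refmap: ReferenceMap | None = None,
    member: str | None = None,
) -> ContactResult:
    """Reference positions whose residues touch the ligand.

    A residue is a contact when any of its heavy atoms lies within cutoff
    of any ligand atom. With a reference map the structure's residue
    numbers are translated to reference numbering (unmappable residues are
    reported, not fatal); without one, residue numbers are taken as
    reference positions directly.
    """
    if ligand_indices is None:
        ligand_indices = s.ligand_indices
    if not ligand_indices:
        raise ValueError("no ligand atoms")
    lig = s.coords(ligand_indices)
    num_map = None
    if refmap is not None:
        if member is None:
            raise ValueError("member label required with a reference map")
        num_map = refmap.member_to_ref[member]
    skip = {s.metal_index} | set(ligand_indices)
    positions: set[int] = set()
    unmapped: list[tuple[str, int, str]] = []
    touched: set[tuple[str, int, str]] = set()
    for i, a in enumerate(s.atoms):
        if i in skip:
            continue
        if np.min(np.linalg.norm(lig - a.coord, axis=1)) <= cutoff:
            touched.add((a.chain, a.resnum, a.resname))
    for chain, resnum, resname in sorted(touched):
        ref = resnum if num_map is None else num_map.get(resnum)
        if ref is None:
            unmapped.append((chain, resnum, resname))
        else:
            positions.add(ref)
    return ContactResult(positions, unmapped)
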