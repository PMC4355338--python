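"""Reference-numbered residue tables.

Every family member's positions are expressed in the numbering of a chosen
reference sequence (for the carbonic anhydrase family this is CA II
numbering): MSA columns that are non-gap in the reference row are numbered
1..L by the reference's ungapped index, and member residues in those
columns inherit the column's reference position. Member insertions relative
to the reference map to no position and are dropped; member deletions leave
the position absent ('-' in tables).

All positions are 1-based and inclusive; no 0-based index ever surfaces in
files or labels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .alignment import GAP, MultipleAlignment

_LABEL_RE = re.compile(r"^([A-Z\-])(\d+)$")


@dataclass
class ReferenceMap:
    """Per-member mapping reference position -> residue (absent if gapped)."""

    reference: str
    length: int
    members: list[str]
    # members -> {ref position -> residue}
    residues: dict[str, dict[int, str]]
    # members -> {member ungapped position -> ref position}
    member_to_ref: dict[str, dict[int, int]]

    def residue_at(self, member: str, position: int) -> str:
        """Member residue at a reference position, '-' if absent there."""
        return self.residues[member].get(position, GAP)

    def reference_residue(self, position: int) -> str:
        return self.residues[self.reference][position]


@dataclass
class ResidueTable:
    """Isoform x reference-position grid of one-letter residues.

    Row labels carry the reference residue, e.g. "N67". Absent residues
    are stored as '-'; position labels are strictly increasing.
    """

    position_labels: list[str]
    isoforms: list[str]
    grid: list[list[str]]  # rows follow position_labels, columns isoforms

    def __post_init__(self):
        if len(self.grid) != len(self.position_labels):
            raise ValueError("grid row count does not match positions")
        for row in self.grid:
            if len(row) != len(self.isoforms):
                raise ValueError("ragged row in residue table")
        pos = self.positions
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("position labels must be strictly increasing")
        if len(set(pos)) != len(pos):
            raise ValueError("duplicate positions")

    @property
    def positions(self) -> list[int]:
        out = []
        for lab in self.position_labels:
            m = _LABEL_RE.match(lab)
            if not m:
                raise ValueError(f"bad position label {lab!r}")
            out.append(int(m.group(2)))
        return out

    def column(self, isoform: str) -> list[str]:
        k = self.isoforms.index(isoform)
        return [row[k] for row in self.grid]

    def row(self, position: int) -> list[str]:
        i = self.positions.index(position)
        return list(self.grid[i])


def build_reference_map(msa: MultipleAlignment, reference_label: str) -> ReferenceMap:
    """Number MSA columns by the reference row's ungapped index."""
    if reference_label not in msa.labels:
        raise ValueError(f"reference label {reference_label!r} not in alignment")
    ref_row = msa.row(reference_label)
    residues: dict[str, dict[int, str]] = {lab: {} for lab in msa.labels}
    member_to_ref: dict[str, dict[int, int]] = {lab: {} for lab in msa.labels}
    counters = {lab: 0 for lab in msa.labels}
    ref_pos = 0
    for col in range(len(ref_row)):
        ref_gap = ref_row[col] == GAP
        if not ref_gap:
            ref_pos += 1
        for lab in msa.labels:
            c = msa.row(lab)[col]
            if c == GAP:
                continue
            counters[lab] += 1
            if not ref_gap:
                residues[lab][ref_pos] = c
                member_to_ref[lab][counters[lab]] = ref_pos
    return ReferenceMap(reference_label, ref_pos, list(msa.labels), residues, member_to_ref)


def extract_residue_table(refmap: ReferenceMap, positions: list[int]) -> ResidueTable:
    """Residue grid at the given reference positions for every member.

    Row labels are "<reference residue><position>"; absent residues '-' .
    """
    for p in positions:
        if not 1 <= p <= refmap.length:
            raise ValueError(f"position {p} outside reference length {refmap.length}")
    labels = [f"{refmap.reference_residue(p)}{p}" for p in positions]
    grid = [
        [refmap.residue_at(member, p) for member in refmap.members]
        for p in positions
    ]
    return ResidueTable(labels, list(refmap.members), grid)


def read_residue_table(path) -> ResidueTable:
    """Read the residue-table TSV (header of isoform labels, first column of
    position labels). Ragged rows and duplicate positions are rejected."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty residue table {path}")
    header = lines[0].split("\t")
    isoforms = header[1:]
    position_labels, grid = [], []
    for ln in lines[1:]:
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise ValueError(f"ragged row in {path}: {ln!r}")
        position_labels.append(cells[0])
        grid.append(cells[1:])
    return ResidueTable(position_labels, isoforms, grid)


def write_residue_table(table: ResidueTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["position"] + table.isoforms) + "\n")
        for lab, row in zip(table.position_labels, table.grid):
            fh.write("\t".join([lab] + row) + "\n")


def read_positions(path) -> list[int]:
    """Plain positions file: one integer per line; '#' comments allowed."""
    out = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.split("#", 1)[0].strip()
            if ln:
                out.append(int(ln))
    return out
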