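"""Active-site pocket profiling: Kyte-Doolittle hydrophobicity totals,
per-position variability statistics, and conserved / variable / selective
classification.

The scientific picture: across an isoform family the deep, metal-proximal
active-site positions are invariant (the "conserved pocket"), while a few
rim positions vary strongly between isoforms and, when they also contact
bound ligands, form the "selective pocket" that isoform-selective inhibitor
design exploits. For the human carbonic anhydrases those contact positions
are 67, 91 and 131 (CA II numbering), and position 91 is the variability
hot-spot. Overall cleft hydrophobicity — the summed Kyte-Doolittle
hydropathy of the cleft residues — separates isoforms with notably
hydrophobic clefts (CA II ~26, CA IX ~23) from hydrophilic ones (CA IV ~4).

Statistics exclude absent residues ('-'); a column with fewer than two
observed residues is reported but never classified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

from .refmap import ResidueTable

AMINO_ACIDS_20 = set("ACDEFGHIKLMNPQRSTVWY")

#: Positions 67, 91, 131 (reference numbering) — the default ligand-contact
#: gate for selective-pocket membership in the carbonic anhydrase family.
DEFAULT_CONTACT_POSITIONS = frozenset({67, 91, 131})

#: Default cleft-face annotations (reference numbering) for the CA family.
HYDROPHILIC_CLEFT = frozenset({7, 62, 64, 67, 199, 200})
HYDROPHOBIC_CLEFT = frozenset({121, 143, 198, 207, 209})

#: Variability threshold (bits) above which a position counts as variable.
DEFAULT_ENTROPY_THRESHOLD = 1.0


class HydropathyScale(dict):
    """Residue -> signed hydropathy value, complete over the 20 residues."""

    def __init__(self, values: dict[str, float]):
        missing = AMINO_ACIDS_20 - values.keys()
        if missing:
            raise ValueError(f"scale missing residues {sorted(missing)}")
        super().__init__(values)


def _load_bundled_scale() -> HydropathyScale:
    text = resources.files("isopocket.data").joinpath("kyte_doolittle.tsv").read_text()
    values = {}
    for ln in text.splitlines()[1:]:
        if ln.strip():
            res, val = ln.split("\t")
            values[res] = float(val)
    return HydropathyScale(values)


#: The Kyte-Doolittle hydropathy scale (Ile +4.5 ... Arg -4.5).
KYTE_DOOLITTLE = _load_bundled_scale()


def read_hydropathy_scale(path) -> HydropathyScale:
    """Read a 20-line residue/value TSV (header optional)."""
    values = {}
    with open(path) as fh:
        for ln in fh:
            parts = ln.strip().split("\t")
            if len(parts) != 2 or parts[0] == "residue":
                continue
            values[parts[0]] = float(parts[1])
    return HydropathyScale(values)


def hydropathy(residue: str, scale: HydropathyScale = KYTE_DOOLITTLE) -> float:
    if residue not in AMINO_ACIDS_20:
        raise ValueError(f"hydropathy undefined for {residue!r}")
    return scale[residue]


def round_half_away(x: float) -> int:
    """Round to the nearest integer with halves away from zero (8.5 -> 9)."""
    return int(
        Decimal(str(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
        if x >= 0
        else -Decimal(str(-x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class PocketScore:
    """Summed cleft hydropathy for one isoform."""

    isoform: str
    raw: float  # one-decimal sum
    rounded: int  # half-away-from-zero
    contributions: tuple[tuple[str, str, float], ...]  # (pos label, residue, value)


@dataclass
class PositionProfile:
    """Variability statistics for one reference position."""

    position: int
    label: str
    residues: str  # observed residues, table order, '-' excluded
    distinct: int
    entropy_bits: float
    hydropathy_range: float
    cleft: str | None = None  # 'hydrophobic' | 'hydrophilic' | None
    classification: str | None = None


def pocket_hydrophobicity(
    table: ResidueTable,
    isoform: str,
    scale: HydropathyScale = KYTE_DOOLITTLE,
) -> PocketScore:
    """Sum the hydropathy of one isoform's residues over all table positions.

    Rejects columns with an absent residue, naming the position: a cleft
    total over a partial column would not be comparable across isoforms.
    """
    contributions = []
    total = 0.0
    for lab, res in zip(table.position_labels, table.column(isoform)):
        if res not in AMINO_ACIDS_20:
            raise ValueError(f"{isoform}: no standard residue at position {lab}")
        v = scale[res]
        contributions.append((lab, res, v))
        total += v
    raw = round(total, 1)
    return PocketScore(isoform, raw, round_half_away(raw), tuple(contributions))


def score_family(
    table: ResidueTable, scale: HydropathyScale = KYTE_DOOLITTLE
) -> list[PocketScore]:
    return [pocket_hydrophobicity(table, iso, scale) for iso in table.isoforms]


def _observed(table: ResidueTable, position: int) -> list[str]:
    obs = [r for r in table.row(position) if r != "-"]
    if not obs:
        raise ValueError(f"position {position}: no observed residues")
    return obs


def column_distinct(table: ResidueTable, position: int) -> int:
    """Distinct residues at a position, absent cells excluded."""
    return len(set(_observed(table, position)))


def column_entropy(table: ResidueTable, position: int) -> float:
    """Shannon entropy (bits) of the residue distribution at a position."""
    obs = _observed(table, position)
    n = len(obs)
    counts = {r: obs.count(r) for r in set(obs)}
    # + 0.0 normalizes IEEE negative zero on invariant columns
    return -sum((c / n) * math.log2(c / n) for c in counts.values()) + 0.0


def hydropathy_range(
    table: ResidueTable, position: int, scale: HydropathyScale = KYTE_DOOLITTLE
) -> float:
    """Max minus min hydropathy over the residues observed at a position."""
    vals = [hydropathy(r, scale) for r in _observed(table, position)]
    return max(vals) - min(vals)


def build_profiles(
    table: ResidueTable,
    scale: HydropathyScale = KYTE_DOOLITTLE,
    hydrophobic_cleft: frozenset[int] = HYDROPHOBIC_CLEFT,
    hydrophilic_cleft: frozenset[int] = HYDROPHILIC_CLEFT,
) -> list[PositionProfile]:
    """Per-position profiles in table order (classification left unset)."""
    profiles = []
    for lab, pos in zip(table.position_labels, table.positions):
        obs = _observed(table, pos)
        cleft = (
            "hydrophobic"
            if pos in hydrophobic_cleft
            else "hydrophilic"
            if pos in hydrophilic_cleft
            else None
        )
        try:
            hrange = hydropathy_range(table, pos, scale)
        except ValueError:
            hrange = float("nan")  # column contains 'X'
        profiles.append(
            PositionProfile(
                position=pos,
                label=lab,
                residues="".join(obs),
                distinct=column_distinct(table, pos),
                entropy_bits=column_entropy(table, pos),
                hydropathy_range=hrange,
                cleft=cleft,
            )
        )
    return profiles


def classify_positions(
    profiles: list[PositionProfile],
    entropy_threshold: float = DEFAULT_ENTROPY_THRESHOLD,
    contact_positions: frozenset[int] = DEFAULT_CONTACT_POSITIONS,
) -> list[PositionProfile]:
    """Label each profile and return the list ranked by variability.

    conserved: entropy 0 (a single residue across the family).
    variable: entropy >= threshold.
    selective: variable AND a member of the ligand-contact position set —
        composition statistics alone cannot distinguish rim positions that
        ligands actually reach, so the contact set is an explicit input.
    intermediate: between 0 and the threshold.
    Columns with fewer than two observed residues stay unclassified.

    Ranking is by (distinct count, entropy) descending; ties keep input
    order.
    """
    if entropy_threshold < 0:
        raise ValueError("entropy threshold must be non-negative")
    for p in profiles:
        if len(p.residues) < 2:
            p.classification = None
        elif p.entropy_bits == 0.0:
            p.classification = "conserved"
        elif p.entropy_bits >= entropy_threshold:
            p.classification = (
                "selective" if p.position in contact_positions else "variable"
            )
        else:
            p.classification = "intermediate"
    return sorted(
        profiles, key=lambda p: (-p.distinct, -p.entropy_bits)
    )


def conserved_position_count(table: ResidueTable) -> int:
    """Number of table positions with a single observed residue."""
    if not table.position_labels:
        raise ValueError("empty residue table")
    return sum(1 for pos in table.positions if column_distinct(table, pos) == 1)


def selective_positions(profiles: list[PositionProfile]) -> set[int]:
    return {p.position for p in profiles if p.classification == "selective"}


def conserved_positions(profiles: list[PositionProfile]) -> set[int]:
    return {p.position for p in profiles if p.classification == "conserved"}


def write_profiles(profiles: list[PositionProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "position\tlabel\tresidues\tdistinct\tentropy_bits\t"
            "hydropathy_range\tcleft\tclassification\n"
        )
        for p in profiles:
            fh.write(
                f"{p.position}\t{p.label}\t{p.residues}\t{p.distinct}\t"
                f"{p.entropy_bits:.4f}\t{p.hydropathy_range:.1f}\t"
                f"{p.cleft or '.'}\t{p.classification or '.'}\n"
            )


def write_scores(scores: list[PocketScore], path, printed: dict[str, int] | None = None) -> None:
    """Score report TSV; when printed reference totals are supplied, a
    mismatch column flags isoforms whose computed total disagrees."""
    with open(path, "w") as fh:
        header = "isoform\traw_sum\trounded_total"
        if printed is not None:
            header += "\treference_total\tflag"
        fh.write(header + "\n")
        for s in scores:
            line = f"{s.isoform}\t{s.raw:.1f}\t{s.rounded}"
            if printed is not None:
                ref = printed.get(s.isoform)
                flag = "." if ref is None or ref == s.rounded else "MISMATCH"
                line += f"\t{ref if ref is not None else '.'}\t{flag}"
            fh.write(line + "\n")
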