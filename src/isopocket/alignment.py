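"""Sequence families, pairwise global alignment, identity matrices, and a
progressive multiple alignment.

An isoform family is an ordered list of :class:`IsoformSequence`. Pairwise
alignments are global (Needleman-Wunsch) with affine gap penalties, scored
with a substitution matrix (BLOSUM62 by default; 'X' scores 0 against
everything and is never counted as identical). Percent identity uses the
columns where both sequences are non-gap as its denominator, which makes
the value insensitive to terminal-gap conventions.

The multiple alignment is progressive: a UPGMA guide tree is built on the
identity-distance matrix and profiles are merged pairwise, so a gap opened
at an internal node persists to the root ("once a gap, always a gap").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

from . import _gotoh

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
ALPHABET = AMINO_ACIDS + "X"
_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
GAP = "-"


def _load_submatrix(name: str) -> np.ndarray:
    """21x21 score matrix over ALPHABET; X scores 0 against everything."""
    ref = substitution_matrices.load(name)
    sub = np.zeros((21, 21))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            sub[i, j] = ref[a, b]
    return sub


@dataclass(frozen=True)
class IsoformSequence:
    """One protein sequence with its isoform label."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"{self.id!r}: empty sequence")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"{self.id!r}: illegal residue character(s) {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap alignment parameters (ClustalW-like defaults)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self):
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap-extend must not exceed gap-open")

    def submatrix(self) -> np.ndarray:
        return _load_submatrix(self.matrix)


DEFAULT_PARAMS = AlignmentParams()


@dataclass(frozen=True)
class PairwiseAlignment:
    """A scored global alignment of two sequences (gap character '-')."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca == GAP and cb == GAP:
                raise ValueError("gap-gap column in alignment")


@dataclass
class MultipleAlignment:
    """Labelled rows of equal length over residues + '-'."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self):
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("MSA rows differ in length")

    def row(self, label: str) -> str:
        return self.rows[self.labels.index(label)]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


@dataclass
class IdentityMatrix:
    """Pairwise percent identity (one decimal) and conserved-residue counts."""

    labels: list[str]
    identity: np.ndarray
    conserved: np.ndarray


def read_fasta(path) -> list[IsoformSequence]:
    """Read an isoform family from FASTA (wrapped or unwrapped lines).

    Record order is preserved; residues are upper-cased. Duplicate ids and
    illegal residue characters are rejected.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(IsoformSequence(rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs, path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), 60):
                fh.write(s.residues[i : i + 60] + "\n")


def write_msa(msa: MultipleAlignment, path) -> None:
    """Write an MSA as aligned FASTA."""
    with open(path, "w") as fh:
        for label, row in zip(msa.labels, msa.rows):
            fh.write(f">{label}\n")
            for i in range(0, len(row), 60):
                fh.write(row[i : i + 60] + "\n")


def _encode(residues: str) -> np.ndarray:
    return np.array([_INDEX[c] for c in residues], dtype=np.intp)


def global_align(
    a: IsoformSequence,
    b: IsoformSequence,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> PairwiseAlignment:
    """Optimal affine-gap global alignment of two sequences.

    Ties in the dynamic program are broken diagonal > up > left, so the
    returned alignment is deterministic.
    """
    sub = params.submatrix()
    ea, eb = _encode(a.residues), _encode(b.residues)
    score_mat = sub[np.ix_(ea, eb)]
    best, end_state, ptr = _gotoh.gotoh_fill(
        score_mat, params.gap_open, params.gap_extend
    )
    moves = _gotoh.traceback(end_state, ptr, len(ea), len(eb))
    out_a, out_b = [], []
    i = j = 0
    for mv in moves:
        if mv == _gotoh.M:
            out_a.append(a.residues[i])
            out_b.append(b.residues[j])
            i += 1
            j += 1
        elif mv == _gotoh.UP:
            out_a.append(a.residues[i])
            out_b.append(GAP)
            i += 1
        else:
            out_a.append(GAP)
            out_b.append(b.residues[j])
            j += 1
    return PairwiseAlignment(a.id, b.id, "".join(out_a), "".join(out_b), float(best))


def percent_identity(aln: PairwiseAlignment) -> float:
    """100 x identical columns / columns where both rows are non-gap.

    'X' never counts as identical. Reported to one decimal.
    """
    both = ident = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca != GAP and cb != GAP:
            both += 1
            if ca == cb and ca != "X":
                ident += 1
    if both == 0:
        raise ValueError("alignment has no co-aligned (non-gap/non-gap) columns")
    return round(100.0 * ident / both, 1)


def conserved_count(aln: PairwiseAlignment) -> int:
    """Number of alignment columns with identical residues ('X' excluded)."""
    return sum(
        1
        for ca, cb in zip(aln.aligned_a, aln.aligned_b)
        if ca == cb and ca != GAP and ca != "X"
    )


def identity_matrix(
    family: list[IsoformSequence],
    params: AlignmentParams = DEFAULT_PARAMS,
) -> IdentityMatrix:
    """All-pairs identity / conserved-count matrix for a family.

    The diagonal holds 100.0 and the sequence length; the matrix is
    symmetric by construction (each unordered pair is aligned once).
    """
    if len(family) < 2:
        raise ValueError("need at least two sequences")
    n = len(family)
    ident = np.zeros((n, n))
    cons = np.zeros((n, n), dtype=int)
    for i in range(n):
        ident[i, i] = 100.0
        cons[i, i] = len(family[i])
    for i in range(n):
        for j in range(i + 1, n):
            try:
                aln = global_align(family[i], family[j], params)
                pid = percent_identity(aln)
            except ValueError as exc:
                raise ValueError(
                    f"alignment of {family[i].id!r} vs {family[j].id!r} failed: {exc}"
                ) from exc
            ident[i, j] = ident[j, i] = pid
            cons[i, j] = cons[j, i] = conserved_count(aln)
    return IdentityMatrix([s.id for s in family], ident, cons)


def write_identity_matrix(m: IdentityMatrix, path) -> None:
    """TSV with identity % in the lower triangle and conserved counts in the
    upper triangle (diagonal written as '-')."""
    with open(path, "w") as fh:
        fh.write("\t".join([""] + m.labels) + "\n")
        for i, lab in enumerate(m.labels):
            cells = []
            for j in range(len(m.labels)):
                if i == j:
                    cells.append("-")
                elif i > j:
                    cells.append(f"{m.identity[i, j]:.1f}")
                else:
                    cells.append(str(int(m.conserved[i, j])))
            fh.write("\t".join([lab] + cells) + "\n")


# ---------------------------------------------------------------------------
# progressive multiple alignment


def _profile_counts(rows: list[str]) -> np.ndarray:
    """Per-column residue counts over ALPHABET (gaps contribute nothing)."""
    ncol = len(rows[0])
    counts = np.zeros((ncol, 21))
    for row in rows:
        for j, c in enumerate(row):
            if c != GAP:
                counts[j, _INDEX[c]] += 1
    return counts


def _merge_profiles(
    rows_a: list[str],
    rows_b: list[str],
    sub: np.ndarray,
    params: AlignmentParams,
) -> tuple[list[str], list[str]]:
    """Align two profiles; the column-pair score is the expected substitution
    score over all residue pairs (gap pairings score 0)."""
    ca, cb = _profile_counts(rows_a), _profile_counts(rows_b)
    score_mat = (ca @ sub @ cb.T) / (len(rows_a) * len(rows_b))
    _, end_state, ptr = _gotoh.gotoh_fill(
        score_mat, params.gap_open, params.gap_extend
    )
    moves = _gotoh.traceback(end_state, ptr, len(ca), len(cb))
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for mv in moves:
        if mv == _gotoh.M:
            for k, row in enumerate(rows_a):
                out_a[k].append(row[i])
            for k, row in enumerate(rows_b):
                out_b[k].append(row[j])
            i += 1
            j += 1
        elif mv == _gotoh.UP:
            for k, row in enumerate(rows_a):
                out_a[k].append(row[i])
            for k in range(len(rows_b)):
                out_b[k].append(GAP)
            i += 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append(GAP)
            for k, row in enumerate(rows_b):
                out_b[k].append(row[j])
            j += 1
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def progressive_msa(
    family: list[IsoformSequence],
    params: AlignmentParams = DEFAULT_PARAMS,
) -> MultipleAlignment:
    """Progressive multiple alignment guided by a UPGMA tree on the
    pairwise identity-distance matrix.

    Every input is recoverable by removing the gaps from its row.
    """
    from .cladogram import DistanceMatrix, identity_to_distance, upgma

    if len(family) < 2:
        raise ValueError("need at least two sequences")
    if len(family) == 2:
        aln = global_align(family[0], family[1], params)
        return MultipleAlignment(
            [aln.id_a, aln.id_b], [aln.aligned_a, aln.aligned_b]
        )
    sub = params.submatrix()
    dist = identity_to_distance(identity_matrix(family, params))
    tree = upgma(dist)
    by_label = {s.id: s for s in family}

    def build(node) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return [node.label], [by_label[node.label].residues]
        (la, ra), (lb, rb) = build(node.children[0]), build(node.children[1])
        ma, mb = _merge_profiles(ra, rb, sub, params)
        return la + lb, ma + mb

    labels, rows = build(tree.root)
    # restore input ordering
    order = sorted(range(len(labels)), key=lambda k: [s.id for s in family].index(labels[k]))
    return MultipleAlignment([labels[k] for k in order], [rows[k] for k in order])
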