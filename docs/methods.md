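# Methods

This note documents the models, conventions, and parameter choices behind
`isopocket`, in the order the pipeline runs them.

## Pairwise alignment and identity

Global alignment is Needleman–Wunsch with affine gaps (Gotoh three-state
dynamic program). Defaults are BLOSUM62, gap-open 10, gap-extend 0.5 —
ClustalW-like protein defaults — and a gap run of length *k* costs
`open + (k−1)·extend`. All parameters are overridable through
`AlignmentParams`. Published identity values for the CA family were
produced by ClustalW2, whose exact parameterization is not recorded with
the tables; this implementation therefore matches such values
approximately, not bit-exactly, and real-sequence reproduction is an
optional external-data mode (no accessions are bundled).

Conventions, fixed for determinism and stated because they differ between
tools:

- **Tie-breaking**: diagonal > up > left at every DP choice, so the
  reported alignment is unique.
- **Identity denominator**: columns where *both* sequences are non-gap —
  insensitive to terminal-gap handling. Reported to one decimal.
- **Unknown residues** (`X`): substitution score 0 against everything,
  never counted as identical.
- The DP kernel is numba-compiled and shared between sequence-sequence
  and profile-profile alignment (the latter scores a column pair as the
  expected substitution score over residue pairs, gaps contributing 0).

The test suite checks DP scores against exhaustive enumeration of all
global alignments for short peptides, and against Biopython's
`PairwiseAligner` as an independent implementation.

## Progressive multiple alignment and reference numbering

The guide tree is UPGMA on `d = 100 − identity`; profiles are merged
pairwise bottom-up, so a gap opened at an internal node persists ("once a
gap, always a gap"), and de-gapping any row reproduces its input exactly.

Reference numbering is 1-based and inclusive: alignment columns that are
non-gap in the chosen reference row are numbered consecutively by the
reference's ungapped index. Member insertions relative to the reference
map to no position (dropped from tables); deletions leave positions
absent, stored as `-`. Absent cells are excluded from all downstream
statistics rather than treated as a 21st symbol.

## Cladogram

UPGMA (average linkage), merge height = half the merge distance, which
makes the tree ultrametric — convenient for testing (all root-to-leaf
paths equal) and honest about what the tree is: a visualization of the
identity matrix, not a model-based phylogeny. Neighbor-joining would be
the alternative if additive (non-clock) distances mattered; it is noted,
not implemented. Equal-distance merges take the lexicographically
smallest pair of cluster representatives, so topologies are
deterministic.

## Residue tables and the bundled fixtures

The two published CA active-site tables ship as TSV fixtures transcribed
as printed: `table3_active_site` (17 positions × 12 isoforms, the CA II
reference stored as an explicit column so per-position statistics include
it) and `table4_cleft` (9 positions × 11 isoforms). The two tables
overlap but differ in position sets (141 and 204 appear only in the cleft
table) and disagree at a few cells (e.g. position 135 for CA VA); both
are preserved verbatim and no merged "canonical" set is invented. Row
labels such as `V141` are treated as opaque position labels.

## Variability statistics and classification

Per position: distinct-residue count; Shannon entropy in **bits** (base 2
— arbitrary but fixed); hydropathy range = max − min Kyte–Doolittle value
over observed residues (a physicochemical complement to entropy: position
91's range of 9.0 spans Ile to Arg).

Classification: *conserved* iff entropy = 0; *variable* iff entropy ≥
threshold; *selective* = variable ∧ member of the ligand-contact set;
strictly between 0 and the threshold → *intermediate*; columns with fewer
than two observed residues are reported but never classified. The default
threshold is **1.0 bit**: on the bundled active-site table it separates
the four strongly variable positions {67, 91, 131, 135} from the
single-substitution positions (entropy ≈ 0.41 bits for an 11/1 split)
while leaving the eight invariant columns conserved. The contact-set gate
is required because composition alone cannot distinguish position 131
from 135 — their residue count profiles are identical (5/2/2/2/1) — and
the selective-pocket call for 131 rests on structural ligand contacts;
the default contact set is {67, 91, 131} for the CA family, replaceable
by an explicit list or by positions derived from structures via
`ligand_contacts`. Cleft-face annotations (hydrophilic {7, 62, 64, 67,
199, 200}, hydrophobic {121, 143, 198, 207, 209}) are metadata only and
never affect scores; an alternative published hydrophobic-cleft roster
exists (including 91/135/141/202/204, excluding 207), and neither set is
canonical.

Positions are ranked by (distinct count, entropy) descending; on the
bundled table this puts position 91 first — the hot-spot.

## Cleft hydrophobicity

The pocket score is the plain sum of Kyte–Doolittle values over an
isoform's cleft residues; the raw one-decimal sum is always reported next
to the integer total. Rounding is **half away from zero** — required to
turn the raw 8.5 (CA XII) into the published 9. Columns with an absent
residue are rejected (a partial-column total would not be comparable).
Term-by-term summation reproduces 8 of the 11 published totals exactly;
isoforms III, IV, VI disagree by ~1 unit (computed 9/3/6 vs printed
8/4/7). Since no per-residue arithmetic accompanies the published totals,
whether this is a transcription slip in the residue rows or a different
rounding is undecidable; the score report flags these three rather than
special-casing them. The scale is a swappable 20-line TSV so other
hydropathy scales can be substituted.

## Structure stage

PDB files are read through Biopython's parser: first model only, altloc
other than blank/`A` dropped, hydrogens dropped, occupancy/B-factor
parsed but ignored. A unique zinc HETATM is auto-designated the metal
center; with several zincs the caller must choose. Superposition is the
Kabsch algorithm (SVD of the covariance of centered point sets) with the
reflection case handled by flipping the smallest singular vector's sign,
so the rotation is always proper (det +1). Matched atoms for
structure-level superposition are Cα atoms of residues co-present at the
same reference positions. Degenerate inputs (< 3 points or collinear
sets) are rejected. Defaults: site radius 15 Å from the metal (the
cleft's physical scale); ligand-contact cutoff 4.0 Å (a standard
heavy-atom contact distance — no value is published for the family
analysis).

## Synthetic generator

`generate_family` emulates the anatomy the real family's tables show: a
uniform-random reference; an invariant core held fixed (the
zinc-coordinating analogue); planted variable positions drawn uniformly
*with replacement* from per-position alphabets (truth records therefore
store realized, not nominal, compositions); independent background
substitution elsewhere; optionally one planted insertion. Defaults —
chosen once as the study-family scale: 12 members, length 260 (the α-CA
domain), background rate 0.05 per site, which keeps planted-signal
recovery interpretable while providing realistic background variation.
What it does **not** model: tree-structured evolution (members diverge
independently from one reference, so synthetic identity matrices are
star-like), indel processes beyond the single planted insertion, and any
covariation between positions — so passing recovery tests demonstrates
the statistics and plumbing, not performance on phylogenetically
structured real families. `generate_toy_structure` places one Cα per
residue at a planted distance from a metal at the origin, ligand atoms
3 Å outside each planted contact residue, then applies a stated rigid
motion and Gaussian noise. Both generators run off a single seeded numpy
`Generator`; the same seed gives byte-identical output.

The stochastic recovery check runs 100 seeded families at the defaults
with one planted 8-letter variable position and a 3-position invariant
core through the full alignment → mapping → classification pipeline and
requires ≥ 95% joint recovery.

## Pipeline and reports

`run_pipeline` has two modes: sequence mode (FASTA in, all stages) and
fixture mode (a residue-table TSV in, profiling/scoring only — the mode
that reproduces the published-table analysis with no sequence input).
Reports are TSV (identity matrix in the published layout: identities
lower triangle, conserved counts upper), Newick, and a JSON manifest of
inputs, parameters, version and seed. The manifest carries no timestamp
and no output directory, so identical configs yield byte-identical
outputs. Any stage failure aborts, names the stage, and removes partial
outputs.

## Known limitations

- ClustalW2's exact identity values are not reproduced bit-exactly
  (unknown parameters and input records); the supported claim is
  approximate agreement under standard parameters.
- Progressive MSA quality degrades for deep divergence (< ~30% identity);
  no iterative refinement is performed, and families beyond ~100
  sequences are out of scope.
- No mmCIF parsing, cavity-volume computation, docking, or any
  binding-affinity claim: the pocket statistics describe sequence/
  structure variability, not inhibitor potency.
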