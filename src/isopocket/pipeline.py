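"""End-to-end orchestration: sequences -> identity matrix + cladogram ->
reference mapping -> residue table -> position profiles + pocket scores,
with an optional structural stage deriving the ligand-contact set.

Two entry modes exist. Sequence mode starts from a FASTA family and runs
the full alignment pipeline. Fixture mode starts directly from a
residue-table TSV (such as the bundled active-site tables) and runs only
the profiling and scoring stages — this reproduces the published-table
analysis without any sequence input.

A run writes TSV/Newick reports plus a JSON manifest of inputs and
parameters; the manifest carries no timestamp, so identical configs
produce byte-identical output trees. Any stage failure aborts the run,
names the stage, and removes partial outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from . import __version__
from .alignment import (
    AlignmentParams,
    identity_matrix,
    progressive_msa,
    read_fasta,
    write_identity_matrix,
    write_msa,
)
from .cladogram import identity_to_distance, upgma, write_newick
from .profile import (
    DEFAULT_CONTACT_POSITIONS,
    DEFAULT_ENTROPY_THRESHOLD,
    KYTE_DOOLITTLE,
    build_profiles,
    classify_positions,
    read_hydropathy_scale,
    score_family,
    write_profiles,
    write_scores,
)
from .refmap import (
    build_reference_map,
    extract_residue_table,
    read_positions,
    read_residue_table,
    write_residue_table,
)
from .structure import ligand_contacts, read_pdb

BUNDLED_TABLES = ("table3_active_site", "table4_cleft")


def bundled_fixture(name: str) -> Path:
    """Path of a bundled residue-table fixture (name without extension)."""
    if name not in BUNDLED_TABLES:
        raise ValueError(f"unknown bundled table {name!r}; have {BUNDLED_TABLES}")
    return Path(str(resources.files("isopocket.data").joinpath(f"{name}.tsv")))


def bundled_printed_totals() -> dict[str, int]:
    """The published cleft-hydrophobicity totals, for mismatch flagging."""
    text = (
        resources.files("isopocket.data")
        .joinpath("table4_printed_totals.tsv")
        .read_text()
    )
    out = {}
    for ln in text.splitlines()[1:]:
        if ln.strip():
            iso, total = ln.split("\t")
            out[iso] = int(total)
    return out


@dataclass
class RunConfig:
    output_dir: str
    fasta: str | None = None
    reference: str | None = None
    positions: str | None = None  # positions file path
    residue_table: str | None = None  # fixture mode: path or bundled name
    scale: str | None = None  # hydropathy scale TSV, default Kyte-Doolittle
    entropy_threshold: float = DEFAULT_ENTROPY_THRESHOLD
    contacts: str = "default"  # 'default' | 'none' | '67,91,131' | 'structures'
    pdbs: list[str] = field(default_factory=list)
    gap_open: float = 10.0
    gap_extend: float = 0.5
    matrix: str = "BLOSUM62"
    seed: int = 0

    def __post_init__(self):
        if self.entropy_threshold < 0:
            raise ValueError("entropy threshold must be non-negative")
        if self.residue_table is None and self.fasta is None:
            raise ValueError("need either a FASTA family or a residue table")


def read_run_config(path) -> RunConfig:
    """Flat 'key = value' config file ('#' comments; pdbs comma-separated)."""
    kwargs: dict = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.split("#", 1)[0].strip()
            if not ln:
                continue
            if "=" not in ln:
                raise ValueError(f"bad config line {ln!r}")
            key, value = (part.strip() for part in ln.split("=", 1))
            if key in ("entropy_threshold", "gap_open", "gap_extend"):
                kwargs[key] = float(value)
            elif key == "seed":
                kwargs[key] = int(value)
            elif key == "pdbs":
                kwargs[key] = [p.strip() for p in value.split(",") if p.strip()]
            else:
                kwargs[key] = value
    return RunConfig(**kwargs)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _parse_contacts(cfg: RunConfig, log) -> frozenset[int] | None:
    if cfg.contacts == "default":
        return DEFAULT_CONTACT_POSITIONS
    if cfg.contacts == "none":
        return frozenset()
    if cfg.contacts == "structures":
        if not cfg.pdbs:
            raise ValueError("contacts=structures requires pdb paths")
        positions: set[int] = set()
        for path in cfg.pdbs:
            s = read_pdb(path)
            result = ligand_contacts(s)
            positions |= result.positions
            if result.unmapped:
                log(f"  {path}: {len(result.unmapped)} unmappable contact residues")
        return frozenset(positions)
    return frozenset(int(p) for p in cfg.contacts.split(","))


def run_pipeline(cfg: RunConfig, log=lambda msg: None) -> dict[str, str]:
    """Run all stages; returns {report name: path}. See module docstring."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    outputs: dict[str, str] = {}

    def emit(name: str, filename: str) -> Path:
        path = outdir / filename
        written.append(path)
        outputs[name] = str(path)
        return path

    scale = KYTE_DOOLITTLE if cfg.scale is None else read_hydropathy_scale(cfg.scale)
    params = AlignmentParams(cfg.matrix, cfg.gap_open, cfg.gap_extend)
    stage = "configure"
    try:
        stage = "contacts"
        log("deriving contact set")
        contact_set = _parse_contacts(cfg, log)

        if cfg.residue_table is not None:
            stage = "load-table"
            table_path = (
                bundled_fixture(cfg.residue_table)
                if cfg.residue_table in BUNDLED_TABLES
                else Path(cfg.residue_table)
            )
            log(f"fixture mode: loading {table_path}")
            table = read_residue_table(table_path)
        else:
            stage = "read-family"
            log(f"reading family from {cfg.fasta}")
            family = read_fasta(cfg.fasta)
            reference = cfg.reference or family[0].id

            stage = "identity-matrix"
            log(f"aligning {len(family)} sequences pairwise")
            ident = identity_matrix(family, params)
            write_identity_matrix(ident, emit("identity_matrix", "identity_matrix.tsv"))

            stage = "cladogram"
            tree = upgma(identity_to_distance(ident))
            emit("cladogram", "cladogram.nwk").write_text(write_newick(tree) + "\n")

            stage = "msa"
            log("building progressive multiple alignment")
            msa = progressive_msa(family, params)
            write_msa(msa, emit("msa", "msa.fasta"))

            stage = "reference-map"
            refmap = build_reference_map(msa, reference)
            positions = (
                read_positions(cfg.positions)
                if cfg.positions
                else list(range(1, refmap.length + 1))
            )
            table = extract_residue_table(refmap, positions)

        stage = "residue-table"
        write_residue_table(table, emit("residue_table", "residue_table.tsv"))

        stage = "profiles"
        log("profiling positions")
        profiles = classify_positions(
            build_profiles(table, scale),
            cfg.entropy_threshold,
            contact_set if contact_set is not None else frozenset(),
        )
        write_profiles(profiles, emit("profiles", "profiles.tsv"))

        stage = "scores"
        scores = score_family(table, scale)
        write_scores(
            scores,
            emit("pocket_scores", "pocket_scores.tsv"),
            printed=bundled_printed_totals()
            if cfg.residue_table == "table4_cleft"
            else None,
        )

        stage = "manifest"
        manifest = {
            "tool": "isopocket",
            "version": __version__,
            "seed": cfg.seed,
            # output_dir is where the manifest lives; recording it would
            # make otherwise-identical runs differ byte-wise
            "config": {
                k: v
                for k, v in vars(cfg).items()
                if v not in (None, []) and k != "output_dir"
            },
            "contact_set": sorted(contact_set) if contact_set is not None else None,
            "outputs": {k: Path(v).name for k, v in outputs.items()},
        }
        path = emit("manifest", "manifest.json")
        path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
    log("done")
    return outputs
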