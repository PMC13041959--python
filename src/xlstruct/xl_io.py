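"""Readers and writers for every external format the pipeline touches.

Structural models come and go as PDB (``gemmi`` does the heavy lifting),
crosslink spectrum match (CSM) tables as delimited text with a declared
column dialect, sequences as FASTA, chain maps as flat YAML, and distance
restraints in either a docking ``assign``-statement dialect or a plain
whitespace list consumed by fragment-assembly refinement.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

log = logging.getLogger(__name__)

#: 3-letter → 1-letter residue code table (standard amino acids only).
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

CA = "CA"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structural model (author numbering, 1-based residues)."""

    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    position: tuple[float, float, float]
    element: str = ""

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for {self}")


class StructureModel:
    """Multi-chain coordinate container with per-chain derived sequence.

    Holds models from any source (AlphaFold, I-TASSER, docking output,
    synthetic) behind one interface; only alpha-carbons are required,
    other atoms are kept for all-atom distance modes and SASD blocking.
    """

    def __init__(self, model_id: str, atoms: Sequence[AtomRecord]):
        self.model_id = model_id
        self.atoms: list[AtomRecord] = list(atoms)
        self._ca: dict[tuple[str, int], AtomRecord] = {}
        self._residue_names: dict[tuple[str, int], str] = {}
        chains: dict[str, list[int]] = {}
        for a in self.atoms:
            key = (a.chain_id, a.residue_index)
            self._residue_names.setdefault(key, a.residue_name)
            if a.atom_name == CA:
                if key in self._ca:
                    raise ValueError(
                        f"duplicate alpha-carbon for chain {a.chain_id} "
                        f"residue {a.residue_index} in model {model_id!r}"
                    )
                self._ca[key] = a
                chains.setdefault(a.chain_id, []).append(a.residue_index)
        if not self._ca:
            raise ValueError(f"model {model_id!r} has no alpha-carbon atoms")
        self._chain_residues = {c: sorted(r) for c, r in chains.items()}

    # -- chain / residue accessors ------------------------------------

    @property
    def chains(self) -> list[str]:
        return sorted(self._chain_residues)

    def residues(self, chain_id: str) -> list[int]:
        """Residue indices with an alpha-carbon, ascending."""
        try:
            return self._chain_residues[chain_id]
        except KeyError:
            raise KeyError(f"chain {chain_id!r} not in model {self.model_id!r}") from None

    def residue_name(self, chain_id: str, residue_index: int) -> str:
        return self._residue_names[(chain_id, residue_index)]

    def has_residue(self, chain_id: str, residue_index: int) -> bool:
        return (chain_id, residue_index) in self._ca

    def ca(self, chain_id: str, residue_index: int) -> np.ndarray:
        try:
            return np.asarray(self._ca[(chain_id, residue_index)].position)
        except KeyError:
            raise KeyError(
                f"no alpha-carbon at {chain_id}:{residue_index} in model {self.model_id!r}"
            ) from None

    def ca_coords(self, chain_id: str, residue_indices: Iterable[int] | None = None) -> np.ndarray:
        idx = self.residues(chain_id) if residue_indices is None else list(residue_indices)
        return np.array([self.ca(chain_id, i) for i in idx], dtype=float)

    def all_coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def chain_sequences(self) -> dict[str, str]:
        """One-letter sequence per chain, derived from residue names ('X' for unknown)."""
        return {
            c: "".join(THREE_TO_ONE.get(self._residue_names[(c, i)], "X") for i in res)
            for c, res in self._chain_residues.items()
        }

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    model_id: str | None = None) -> "StructureModel":
        """Return a rigidly transformed copy: x' = R @ x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        atoms = [
            dataclasses.replace(a, position=tuple(R @ np.asarray(a.position) + t))
            for a in self.atoms
        ]
        return StructureModel(model_id or self.model_id, atoms)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"StructureModel({self.model_id!r}, chains="
                f"{ {c: len(r) for c, r in self._chain_residues.items()} })")


@dataclass
class ChainMap:
    """Maps protein accessions to model chains.

    ``entries[accession]`` is a list of ``(chain_id, offset)`` pairs; an
    accession mapping to several chains describes a homo-oligomer and all
    candidates are carried downstream for minimum-distance resolution.
    ``offset`` bridges 1-based sequence numbering to author residue
    numbering: ``residue_index = sequence_position + offset``.
    """

    entries: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def chains_for(self, accession: str) -> list[tuple[str, int]]:
        return self.entries.get(accession, [])

    def validate_against(self, model: StructureModel) -> None:
        missing = {
            ch for targets in self.entries.values() for ch, _ in targets
            if ch not in model._chain_residues
        }
        if missing:
            raise ValueError(
                f"chain map references chains absent from model "
                f"{model.model_id!r}: {sorted(missing)}"
            )


@dataclass(frozen=True)
class CSMRecord:
    """One crosslink spectrum match: a spectrum-level identification of a
    crosslinked peptide pair, localized to two sequence positions."""

    csm_id: str
    replicate: str
    protein_a: str
    position_a: int
    protein_b: str
    position_b: int
    score: float | None = None
    passes_fdr: bool = True

    def __post_init__(self) -> None:
        if self.position_a < 1 or self.position_b < 1:
            raise ValueError(f"positions must be >= 1 in CSM {self.csm_id!r}")
        if not self.protein_a or not self.protein_b:
            raise ValueError(f"empty accession in CSM {self.csm_id!r}")


@dataclass(frozen=True)
class Restraint:
    """A single Cα–Cα distance band: target with lower/upper margins (Å)."""

    chain_a: str
    residue_a: int
    atom_a: str
    chain_b: str
    residue_b: int
    atom_b: str
    target: float
    lower_margin: float
    upper_margin: float

    def __post_init__(self) -> None:
        if self.target - self.lower_margin < -1e-9:
            raise ValueError("restraint band extends below zero")


@dataclass
class RestraintSet:
    restraints: list[Restraint]
    dialect: str = "docking-tbl"  # or "refinement-list"


# ---------------------------------------------------------------------------
# crosslink table dialects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TableDialect:
    """Column-name profile of a crosslink export.

    Search engines export CSM tables with vendor-specific headers; a
    dialect names the columns this reader needs so a new export style is
    declared (e.g. from YAML), never hard-coded.
    """

    name: str
    protein_a: str
    position_a: str
    protein_b: str
    position_b: str
    csm_id: str | None = None
    replicate: str | None = None
    score: str | None = None
    passes_fdr: str | None = None
    delimiter: str = "\t"


#: the canonical dialect written by this package's own writers.
CANONICAL_DIALECT = TableDialect(
    name="canonical",
    csm_id="csm_id",
    replicate="replicate",
    protein_a="protein_a",
    position_a="position_a",
    protein_b="protein_b",
    position_b="position_b",
    score="score",
    passes_fdr="passes_fdr",
)


def load_dialect(path: str | Path) -> TableDialect:
    """Load a dialect declaration from a flat YAML mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return TableDialect(**raw)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path, model_id: str | None = None) -> StructureModel:
    """Parse ATOM records of a PDB file into a :class:`StructureModel`.

    The first altloc of each atom is kept; HETATM records are counted and
    ignored.  Raises if no chain contains an alpha-carbon or if a
    duplicate (chain, residue, atom) survives altloc resolution.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_pdb(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    atoms: list[AtomRecord] = []
    seen: set[tuple[str, int, str]] = set()
    n_het = 0
    model = st[0]
    for chain in model:
        for residue in chain:
            if residue.het_flag == "H":
                n_het += 1
                continue
            for atom in residue:
                key = (chain.name, residue.seqid.num, atom.name)
                if key in seen:
                    if atom.altloc:  # keep first altloc only
                        continue
                    raise ValueError(
                        f"{path}: duplicate atom {key} after altloc resolution"
                    )
                seen.add(key)
                atoms.append(AtomRecord(
                    chain_id=chain.name,
                    residue_index=residue.seqid.num,
                    residue_name=residue.name,
                    atom_name=atom.name,
                    position=(atom.pos.x, atom.pos.y, atom.pos.z),
                    element=atom.element.name,
                ))
    if n_het:
        log.info("%s: ignored %d HETATM residues", path, n_het)
    return StructureModel(model_id or path.stem, atoms)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as standard PDB ATOM records (3-decimal coordinates)."""
    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model("1")
    by_chain: dict[str, dict[int, list[AtomRecord]]] = {}
    for a in model.atoms:
        by_chain.setdefault(a.chain_id, {}).setdefault(a.residue_index, []).append(a)
    for chain_id in sorted(by_chain):
        ch = gemmi.Chain(chain_id)
        for resi in sorted(by_chain[chain_id]):
            recs = by_chain[chain_id][resi]
            res = gemmi.Residue()
            res.name = recs[0].residue_name
            res.seqid = gemmi.SeqId(resi, " ")
            for rec in recs:
                at = gemmi.Atom()
                at.name = rec.atom_name
                at.pos = gemmi.Position(*rec.position)
                at.element = gemmi.Element(rec.element or "C")
                res.add_atom(at)
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences keyed by the first token of each FASTA header."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_chain_map(path: str | Path) -> ChainMap:
    """Read a chain map from flat YAML.

    Accepts ``{accession: {chain: A, offset: 0}}`` or, for homo-oligomers,
    ``{accession: [{chain: A, offset: 0}, {chain: B, offset: 0}]}``; a top
    level ``chains:`` key is optional.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if isinstance(raw, dict) and "chains" in raw:
        raw = raw["chains"]
    entries: dict[str, list[tuple[str, int]]] = {}
    for acc, spec in raw.items():
        items = spec if isinstance(spec, list) else [spec]
        entries[acc] = [(str(it["chain"]), int(it.get("offset", 0))) for it in items]
    return ChainMap(entries)


def write_chain_map(chain_map: ChainMap, path: str | Path) -> None:
    raw = {
        acc: [{"chain": c, "offset": o} for c, o in targets]
        for acc, targets in sorted(chain_map.entries.items())
    }
    with open(path, "w") as fh:
        yaml.safe_dump({"chains": raw}, fh, sort_keys=True)


def read_crosslink_table(path: str | Path,
                         dialect: TableDialect = CANONICAL_DIALECT) -> list[CSMRecord]:
    """Read a delimited CSM export into records.

    Rows failing the FDR flag are retained but flagged so summaries can
    include or exclude them.  A malformed position raises, naming the
    1-based data row.
    """
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    required = [dialect.protein_a, dialect.position_a, dialect.protein_b, dialect.position_b]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: dialect {dialect.name!r} expects columns {missing} "
            f"not present in header {list(df.columns)}"
        )
    records: list[CSMRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        try:
            pos_a = int(row_d[dialect.position_a])
            pos_b = int(row_d[dialect.position_b])
        except ValueError as exc:
            raise ValueError(f"{path}: non-integer position in data row {i}") from exc
        score = None
        if dialect.score and row_d.get(dialect.score, "") not in ("", "NA"):
            score = float(row_d[dialect.score])
        passes = True
        if dialect.passes_fdr and row_d.get(dialect.passes_fdr, "") != "":
            passes = str(row_d[dialect.passes_fdr]).strip().lower() in ("1", "true", "yes")
        records.append(CSMRecord(
            csm_id=(row_d.get(dialect.csm_id, "") or f"csm{i}") if dialect.csm_id else f"csm{i}",
            replicate=row_d.get(dialect.replicate, "") if dialect.replicate else "",
            protein_a=row_d[dialect.protein_a],
            position_a=pos_a,
            protein_b=row_d[dialect.protein_b],
            position_b=pos_b,
            score=score,
            passes_fdr=passes,
        ))
    return records


def write_crosslink_table(csms: Sequence[CSMRecord], path: str | Path) -> None:
    """Write CSMs in the canonical dialect (tab-separated)."""
    df = pd.DataFrame([{
        "csm_id": c.csm_id,
        "replicate": c.replicate,
        "protein_a": c.protein_a,
        "position_a": c.position_a,
        "protein_b": c.protein_b,
        "position_b": c.position_b,
        "score": "" if c.score is None else c.score,
        "passes_fdr": c.passes_fdr,
    } for c in csms])
    df.to_csv(path, sep="\t", index=False)


# -- crosslink → model mapping ---------------------------------------------

@dataclass(frozen=True)
class MappedXL:
    """A crosslink resolved onto model residues, or a reason-coded miss.

    ``candidates`` holds every ((chain, residue), (chain, residue)) pair a
    homo-oligomeric chain map admits; downstream measurement keeps the
    minimum-distance candidate.  ``reason`` is ``None`` when mapped, else
    ``"no-chain"`` or ``"no-residue"``.
    """

    xl: object  # UniqueXL; typed loosely to avoid a circular import
    candidates: tuple[tuple[tuple[str, int], tuple[str, int]], ...] = ()
    reason: str | None = None
    non_lysine: bool = False

    @property
    def mapped(self) -> bool:
        return self.reason is None


def map_crosslink(xl, chain_map: ChainMap, model: StructureModel) -> MappedXL:
    """Resolve a unique crosslink's two endpoints onto model residues.

    Unmappable endpoints are a value (reason code), not an error.  When a
    mapped residue is not lysine a warning is issued but the crosslink is
    kept (CSM site localization can be off by one); the result is flagged.
    """
    ends = []
    for acc, pos in (xl.endpoint_a, xl.endpoint_b):
        targets = chain_map.chains_for(acc)
        if not targets:
            return MappedXL(xl=xl, reason="no-chain")
        resolved = [
            (chain, pos + offset) for chain, offset in targets
            if chain in model._chain_residues and model.has_residue(chain, pos + offset)
        ]
        if not resolved:
            return MappedXL(xl=xl, reason="no-residue")
        ends.append(resolved)
    non_lys = False
    for options in ends:
        for chain, resi in options:
            if model.residue_name(chain, resi) != "LYS":
                non_lys = True
                warnings.warn(
                    f"crosslink maps to non-lysine residue "
                    f"{chain}:{resi} ({model.residue_name(chain, resi)})",
                    stacklevel=2,
                )
    candidates = tuple((a, b) for a in ends[0] for b in ends[1])
    return MappedXL(xl=xl, candidates=candidates, non_lysine=non_lys)


# -- restraint output -------------------------------------------------------

def _canonical_restraints(rs: RestraintSet) -> list[Restraint]:
    def canon(r: Restraint) -> Restraint:
        a = (r.chain_a, r.residue_a, r.atom_a)
        b = (r.chain_b, r.residue_b, r.atom_b)
        if b < a:
            return Restraint(r.chain_b, r.residue_b, r.atom_b,
                             r.chain_a, r.residue_a, r.atom_a,
                             r.target, r.lower_margin, r.upper_margin)
        return r
    return sorted((canon(r) for r in rs.restraints),
                  key=lambda r: (r.chain_a, r.residue_a, r.chain_b, r.residue_b))


def format_restraints(rs: RestraintSet) -> str:
    """Render a restraint set in its dialect; byte-stable under input order."""
    if not rs.restraints:
        raise ValueError("refusing to write an empty restraint set")
    lines = []
    for r in _canonical_restraints(rs):
        if rs.dialect == "docking-tbl":
            lines.append(
                f"assign (segid {r.chain_a} and resid {r.residue_a} and name {r.atom_a}) "
                f"(segid {r.chain_b} and resid {r.residue_b} and name {r.atom_b}) "
                f"{r.target:.1f} {r.lower_margin:.1f} {r.upper_margin:.1f}"
            )
        elif rs.dialect == "refinement-list":
            lines.append(f"{r.residue_a} {r.chain_a} {r.residue_b} {r.chain_b} {r.target:.1f}")
        else:
            raise ValueError(f"unknown restraint dialect {rs.dialect!r}")
    return "\n".join(lines) + "\n"


def write_restraints(rs: RestraintSet, path: str | Path,
                     model: StructureModel | None = None) -> None:
    """Write restraints to ``path``; optionally verify selectors against a model."""
    if model is not None:
        for r in rs.restraints:
            for chain, resi in ((r.chain_a, r.residue_a), (r.chain_b, r.residue_b)):
                if not model.has_residue(chain, resi):
                    raise ValueError(f"restraint selector {chain}:{resi} not in model")
    Path(path).write_text(format_restraints(rs))
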