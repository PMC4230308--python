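"""Read PDB coordinate files into a validated structure model.

The model is deliberately small: ordered atoms grouped into residues,
residues grouped into one Structure. Hydrogens are dropped on read
(contact inference is heavy-atom based), alternate locations are resolved
to a single coordinate set, and every residue is classified as polymer,
ligand, solvent, ion or other-het. Author residue numbering — not serial
index — keys all downstream matching, because cross-structure comparisons
match residues by their sequence number.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import EmptyStructureError, InputError

logger = logging.getLogger(__name__)

#: Peptide backbone atom names; needed by the adjacent-backbone contact filter.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Water residue names mapped to kind="solvent".
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

#: Common crystallographic ions and additives mapped to kind="ion".
ION_NAMES = frozenset({
    "NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "CU", "NI", "CO",
    "SO4", "PO4", "GOL", "EDO", "ACT", "PEG", "CD", "BR", "IOD",
})

_STANDARD_AA = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
})


@dataclass(frozen=True)
class Atom:
    """A heavy atom with Cartesian coordinates in Angstrom."""

    name: str
    element: str
    coords: tuple[float, float, float]
    altloc: str = ""
    is_backbone: bool = False

    def __post_init__(self):
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}: {self.coords}")


@dataclass
class Residue:
    """One residue (or het group) identified by author numbering.

    kind is one of {"polymer", "ligand", "solvent", "ion", "other-het"}.
    (chain_id, seq_number, insertion_code) is unique within a Structure.
    """

    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    kind: str = "polymer"

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def __repr__(self) -> str:  # compact, for logs
        return f"<Residue {self.chain_id}:{self.res_name}{self.seq_number}{self.insertion_code} {self.kind}>"


@dataclass
class Structure:
    """Ordered residues from one coordinate file."""

    structure_id: str
    residues: list[Residue]
    source_path: str = ""

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.kind == "polymer"]

    def ligand_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.kind == "ligand"]

    def validate(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate residue keys in structure")
        if not self.polymer_residues():
            raise EmptyStructureError(f"{self.structure_id}: no polymer residues")


def _resolve_altlocs(atoms: list[gemmi.Atom], policy: str) -> list[gemmi.Atom]:
    """Keep a single alternate location per atom name.

    "highest_occupancy" keeps the highest-occupancy conformer, ties broken
    by altloc label order; "first" keeps the first conformer encountered.
    """
    if policy not in ("highest_occupancy", "first"):
        raise ValueError(f"unknown altloc policy {policy!r}")
    by_name: dict[str, list[gemmi.Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for name in order:
        group = by_name[name]
        if len(group) == 1 or policy == "first":
            kept.append(group[0])
        else:
            kept.append(max(group, key=lambda a: (a.occ, -ord(a.altloc or " "))))
    return kept


def _classify(res_name: str) -> str:
    if res_name in _STANDARD_AA:
        return "polymer"
    if res_name in WATER_NAMES:
        return "solvent"
    if res_name in ION_NAMES:
        return "ion"
    return "other-het"


def read_pdb(path: str, altloc_policy: str = "highest_occupancy",
             structure_id: str | None = None) -> Structure:
    """Parse a PDB file into a Structure, dropping hydrogens.

    Parameters
    ----------
    path : str
        PDB coordinate file (ATOM/HETATM records, wwPDB v3.3 columns).
    altloc_policy : str
        "highest_occupancy" (default) or "first"; how alternate locations
        collapse to one coordinate set.
    structure_id : str, optional
        Identifier for provenance; defaults to the file stem.

    Only the first model of a multi-model file is read. Residues are
    classified by name (standard amino acids -> polymer, waters -> solvent,
    known ions/additives -> ion, everything else -> other-het); declare
    ligands afterwards with :func:`classify_het_groups`.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, OSError) as exc:
        raise InputError(f"cannot read PDB file {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models in file")
    model = st[0]

    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            heavy = [a for a in res if a.element.name not in ("H", "D")]
            if not heavy:
                continue
            kept = _resolve_altlocs(heavy, altloc_policy)
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name.upper(),
                    coords=(a.pos.x, a.pos.y, a.pos.z),
                    altloc=a.altloc or "",
                    is_backbone=a.name in BACKBONE_ATOMS,
                )
                for a in kept
            ]
            residues.append(
                Residue(
                    chain_id=chain.name,
                    seq_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    res_name=res.name,
                    atoms=atoms,
                    kind=_classify(res.name),
                )
            )

    if not residues:
        raise EmptyStructureError(f"{path}: zero parsed atoms")
    sid = structure_id if structure_id is not None else Path(path).stem
    return Structure(structure_id=sid, residues=residues, source_path=str(path))


def trim_to_segments(s: Structure, segments: list[tuple[str, int, int]]) -> Structure:
    """Restrict a Structure to the union of (chain, start, end) segments.

    Boundaries are author numbering, inclusive on both ends. Only polymer
    residues are filtered; all ligand residues are kept so that a later
    ligand-inclusive analysis still sees them. A segment matching zero
    residues logs a warning but is not an error.
    """
    if not segments:
        raise ValueError("segments must be non-empty")

    def in_segments(r: Residue) -> bool:
        return any(r.chain_id == c and lo <= r.seq_number <= hi for c, lo, hi in segments)

    for c, lo, hi in segments:
        if not any(r.chain_id == c and lo <= r.seq_number <= hi for r in s.residues):
            logger.warning("segment (%s, %d, %d) matches no residues", c, lo, hi)

    kept = [r for r in s.residues if r.kind == "ligand" or (r.kind == "polymer" and in_segments(r))]
    return Structure(structure_id=s.structure_id, residues=kept, source_path=s.source_path)


def classify_het_groups(s: Structure, ligand_names: set[str]) -> Structure:
    """Mark declared het groups as ligands; re-assert solvent/ion rules.

    Residues whose res_name is in ``ligand_names`` get kind="ligand".
    Waters become solvent, known ions become ion, and undeclared het
    groups stay other-het (excluded from the network by default). Ligand
    names absent from the structure trigger a warning listing them.
    """
    present = {r.res_name for r in s.residues}
    missing = sorted(set(ligand_names) - present)
    if missing:
        warnings.warn(f"declared ligand names not found in {s.structure_id}: {', '.join(missing)}")

    out = []
    for r in s.residues:
        if r.res_name in ligand_names:
            out.append(replace_kind(r, "ligand"))
        elif r.res_name in WATER_NAMES:
            out.append(replace_kind(r, "solvent"))
        elif r.kind != "polymer" and r.res_name in ION_NAMES:
            out.append(replace_kind(r, "ion"))
        else:
            out.append(r)
    return Structure(structure_id=s.structure_id, residues=out, source_path=s.source_path)


def replace_kind(r: Residue, kind: str) -> Residue:
    return Residue(chain_id=r.chain_id, seq_number=r.seq_number,
                   insertion_code=r.insertion_code, res_name=r.res_name,
                   atoms=r.atoms, kind=kind)


def select_chain(s: Structure, chain_id: str) -> Structure:
    """Keep one receptor chain (plus its ligands); drop fusion partners."""
    kept = [r for r in s.residues if r.chain_id == chain_id]
    return Structure(structure_id=s.structure_id, residues=kept, source_path=s.source_path)
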