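"""Detect non-covalent interatomic contacts and apply the edge filters.

Two contact criteria are supported, both acting on heavy atoms only:

``distance_cutoff``
    A pair of atoms is in contact when their distance is at most a fixed
    cutoff (default 4.5 A).

``csu_like``
    A pair is in contact when their solvent-extended van der Waals spheres
    overlap: d <= r_vdw(a) + r_vdw(b) + 2 * probe_radius. This is a
    documented approximation of the excluded-solvent-accessible-surface
    criterion of the CSU program; it ignores occlusion by third atoms, so
    results on real structures are labeled with the criterion used.

After detection, filters remove the contacts that do not represent
non-covalent residue-residue interactions: intra-residue pairs,
backbone-backbone pairs between sequence-adjacent residues (the peptide
bond and its neighborhood), and, optionally, disulfide SG-SG pairs.
Side-chain contacts between adjacent residues are genuine interactions
and are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import RadiusLookupError
from .structure_io import Residue, Structure

#: Bondi van der Waals radii (A) for the elements common in protein/ligand
#: heavy atoms; anything else falls back to the carbon radius unless the
#: fallback is disabled.
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}

DEFAULT_VDW_FALLBACK = 1.70


@dataclass
class ContactCriterion:
    """Parameters of the interatomic contact test.

    mode : {"csu_like", "distance_cutoff"}
    probe_radius : solvent probe radius in A (csu_like mode), default 1.4.
    cutoff : fixed distance threshold in A (distance_cutoff mode), default 4.5.
    vdw_radii : element -> radius map; fallback used for unknown elements,
        or a RadiusLookupError if fallback is None.
    """

    mode: str = "csu_like"
    probe_radius: float = 1.4
    cutoff: float = 4.5
    vdw_radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VDW_RADII))
    fallback_radius: float | None = DEFAULT_VDW_FALLBACK

    def __post_init__(self):
        if self.mode not in ("csu_like", "distance_cutoff"):
            raise ValueError(f"unknown contact mode {self.mode!r}")
        if self.cutoff <= 0 or self.probe_radius <= 0:
            raise ValueError("cutoff and probe_radius must be positive")
        if any(r <= 0 for r in self.vdw_radii.values()):
            raise ValueError("van der Waals radii must be positive")

    def radius(self, element: str) -> float:
        r = self.vdw_radii.get(element.upper())
        if r is None:
            if self.fallback_radius is None:
                raise RadiusLookupError(
                    f"no van der Waals radius for element {element!r} and no fallback configured")
            return self.fallback_radius
        return r

    def threshold(self, elem_a: str, elem_b: str) -> float:
        """Pairwise contact distance threshold in A."""
        if self.mode == "distance_cutoff":
            return self.cutoff
        return self.radius(elem_a) + self.radius(elem_b) + 2.0 * self.probe_radius

    @property
    def tag(self) -> str:
        if self.mode == "distance_cutoff":
            return f"distance_cutoff:{self.cutoff:g}"
        return f"csu_like:probe={self.probe_radius:g}"


@dataclass(frozen=True)
class AtomContact:
    """One detected interatomic contact, stored with a canonical pair order."""

    residue_a: tuple[str, int, str]
    residue_b: tuple[str, int, str]
    atom_a: str
    atom_b: str
    distance: float
    criterion: str


def _eligible_residues(s: Structure) -> list[Residue]:
    return [r for r in s.residues if r.kind in ("polymer", "ligand")]


def _flatten(residues: list[Residue]):
    coords, owner, names, elements = [], [], [], []
    for i, r in enumerate(residues):
        for a in r.atoms:
            coords.append(a.coords)
            owner.append(i)
            names.append(a.name)
            elements.append(a.element)
    return np.asarray(coords, dtype=float), np.asarray(owner), names, elements


def _canonical(res_i: Residue, res_j: Residue, name_i: str, name_j: str,
               dist: float, tag: str) -> AtomContact:
    if res_j.key < res_i.key:
        res_i, res_j = res_j, res_i
        name_i, name_j = name_j, name_i
    return AtomContact(residue_a=res_i.key, residue_b=res_j.key,
                       atom_a=name_i, atom_b=name_j,
                       distance=float(dist), criterion=tag)


def detect_atomic_contacts(s: Structure, crit: ContactCriterion) -> list[AtomContact]:
    """Find all heavy-atom pairs satisfying the contact criterion.

    Atoms of polymer and ligand residues are eligible; waters, ions and
    undeclared het groups never enter. A k-d tree restricts candidate
    pairs to those within the largest possible pairwise threshold, making
    detection subquadratic in atom count; the exact per-pair threshold is
    then applied. Intra-residue pairs are skipped here already (they can
    never become edges) but the full filtering contract lives in
    :func:`filter_contacts`.
    """
    residues = _eligible_residues(s)
    coords, owner, names, elements = _flatten(residues)
    if len(coords) < 2:
        return []

    if crit.mode == "distance_cutoff":
        r_max = crit.cutoff
    else:
        radii = np.array([crit.radius(e) for e in elements])
        r_max = 2.0 * radii.max() + 2.0 * crit.probe_radius

    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=r_max, output_type="ndarray")

    contacts: list[AtomContact] = []
    for i, j in pairs:
        if owner[i] == owner[j]:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d <= crit.threshold(elements[i], elements[j]):
            contacts.append(_canonical(residues[owner[i]], residues[owner[j]],
                                       names[i], names[j], d, crit.tag))
    contacts.sort(key=lambda c: (c.residue_a, c.residue_b, c.atom_a, c.atom_b))
    return contacts


def detect_atomic_contacts_bruteforce(s: Structure, crit: ContactCriterion) -> list[AtomContact]:
    """All-pairs reference detector; quadratic, used as a test oracle."""
    residues = _eligible_residues(s)
    coords, owner, names, elements = _flatten(residues)
    contacts: list[AtomContact] = []
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            if owner[i] == owner[j]:
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d <= crit.threshold(elements[i], elements[j]):
                contacts.append(_canonical(residues[owner[i]], residues[owner[j]],
                                           names[i], names[j], d, crit.tag))
    contacts.sort(key=lambda c: (c.residue_a, c.residue_b, c.atom_a, c.atom_b))
    return contacts


def filter_contacts(contacts: list[AtomContact], s: Structure,
                    remove_disulfides: bool = True,
                    disulfide_cutoff: float = 2.5) -> list[AtomContact]:
    """Screen out covalent and trivial contacts.

    Removes (1) intra-residue pairs, (2) backbone-backbone pairs between
    sequence-adjacent residues of the same chain (|delta seq| == 1; a gap
    in author numbering is a chain break, so the filter never fires across
    one), and (3) Cys SG-SG pairs closer than ``disulfide_cutoff`` when
    ``remove_disulfides`` (covalent disulfide bridges). Side-chain
    contacts between adjacent residues survive.
    """
    by_key = {r.key: r for r in s.residues}
    backbone_names = {r.key: {a.name for a in r.atoms if a.is_backbone} for r in s.residues}

    out = []
    for c in contacts:
        if c.residue_a == c.residue_b:
            continue
        ra, rb = by_key[c.residue_a], by_key[c.residue_b]
        adjacent = (ra.chain_id == rb.chain_id
                    and ra.kind == "polymer" and rb.kind == "polymer"
                    and abs(ra.seq_number - rb.seq_number) == 1
                    and ra.insertion_code == "" and rb.insertion_code == "")
        if adjacent and c.atom_a in backbone_names[c.residue_a] and c.atom_b in backbone_names[c.residue_b]:
            continue
        if (remove_disulfides
                and ra.res_name == "CYS" and rb.res_name == "CYS"
                and c.atom_a == "SG" and c.atom_b == "SG"
                and c.distance < disulfide_cutoff):
            continue
        out.append(c)
    return out


def write_contacts_tsv(contacts: list[AtomContact], s: Structure, path: str) -> None:
    """Write the contact list as TSV (one atomic contact per row)."""
    by_key = {r.key: r for r in s.residues}
    with open(path, "w") as fh:
        fh.write("chain_a\tseq_a\tresname_a\tatom_a\tchain_b\tseq_b\tresname_b\tatom_b\tdistance_A\tcriterion\n")
        for c in contacts:
            ra, rb = by_key[c.residue_a], by_key[c.residue_b]
            fh.write(f"{ra.chain_id}\t{ra.seq_number}\t{ra.res_name}\t{c.atom_a}\t"
                     f"{rb.chain_id}\t{rb.seq_number}\t{rb.res_name}\t{c.atom_b}\t"
                     f"{c.distance:.3f}\t{c.criterion}\n")
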