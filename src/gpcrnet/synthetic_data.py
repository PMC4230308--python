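"""Synthetic structures with known ground truth for end-to-end testing.

Three generators:

- :func:`write_toy_pdb` realises a designed residue adjacency graph as a
  PDB file of single-atom pseudo-residues, placed so that exactly the
  designed pairs fall within contact range. The placement is found by
  seeded penalty minimisation and verified post hoc against the design;
  an unrealisable design raises, never passes silently.
- :func:`write_bundle_pdb` emits a seven-helix bundle of C-beta-like
  pseudo-atoms whose inter-helix packing is densest at mid-height (the
  "knot") and flares out at both ends — the qualitative architecture of
  a GPCR transmembrane bundle — optionally with a small-molecule ligand
  pseudo-residue touching designated pocket residues at one mouth.
- :func:`random_graph` draws seeded connected Erdos-Renyi graphs for
  oracle testing of the centrality code.

Toy pseudo-residues are numbered with a stride of 2 by default so that no
two are sequence-adjacent and the adjacent-backbone contact filter never
fires on them; the filter logic is exercised separately by two-residue
full-backbone fixtures in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import networkx as nx
import numpy as np
from scipy.optimize import minimize

from .errors import GenerationError

_AA_CYCLE = ["ALA", "GLY", "SER", "LEU", "VAL", "THR", "ILE", "PRO"]


@dataclass
class ToyDesign:
    """A target residue adjacency graph plus the spacings that realise it.

    target_adjacency holds 0-based residue index pairs. Edges are placed
    at ``spacing_contact`` Angstrom, non-edges at ``spacing_noncontact``
    or farther, so any detection cutoff strictly between the two spacings
    (with a 5% safety margin on each side) recovers the design exactly.
    The default spacings bracket the default 4.5 A detection cutoff;
    pushing non-contacts much past the contact spacing becomes
    geometrically infeasible (the two diagonals of a chordless 4-cycle
    with sides s average at most s * sqrt(2), and a 2-path bounds its
    endpoints at two contact spacings).
    """

    n_residues: int
    target_adjacency: frozenset
    spacing_contact: float = 4.0
    spacing_noncontact: float = 5.5
    seed: int = 0
    seq_numbers: tuple | None = None   # author numbering; default 1, 3, 5, ...
    res_names: tuple | None = None
    chain_id: str = "A"
    ligand_touches: tuple = ()         # residue indices the ligand must contact

    def __post_init__(self):
        if self.spacing_contact >= self.spacing_noncontact:
            raise ValueError("spacing_contact must be smaller than spacing_noncontact")
        self.target_adjacency = frozenset(
            (min(i, j), max(i, j)) for i, j in self.target_adjacency)
        for i, j in self.target_adjacency:
            if not (0 <= i < self.n_residues and 0 <= j < self.n_residues) or i == j:
                raise ValueError(f"adjacency pair ({i}, {j}) out of range")

    def seqs(self) -> list[int]:
        if self.seq_numbers is not None:
            if len(self.seq_numbers) != self.n_residues:
                raise ValueError("seq_numbers length mismatch")
            return list(self.seq_numbers)
        return [2 * i + 1 for i in range(self.n_residues)]

    def names(self) -> list[str]:
        if self.res_names is not None:
            return list(self.res_names)
        return [_AA_CYCLE[i % len(_AA_CYCLE)] for i in range(self.n_residues)]


def fig1_design() -> ToyDesign:
    """The five-residue design whose graph reproduces the worked example.

    Nodes Val 86, Asp 113, Phe 289, Asn 312, Tyr 316 with edges
    Val86-Asp113, Val86-Tyr316, Asp113-Tyr316, Phe289-Asn312,
    Asn312-Tyr316 — the unique labeled 5-node edge set whose closeness
    vector rounds to (0.57, 0.57, 0.44, 0.67, 0.80).
    """
    return ToyDesign(
        n_residues=5,
        target_adjacency=frozenset({(0, 1), (0, 4), (2, 3), (3, 4), (1, 4)}),
        seq_numbers=(86, 113, 289, 312, 316),
        res_names=("VAL", "ASP", "PHE", "ASN", "TYR"),
    )


def _embed(d: ToyDesign, margin_frac: float = 0.05,
           max_restarts: int = 40) -> np.ndarray:
    """Find 3-D coordinates realising the design; raise GenerationError on failure.

    Minimises a smooth penalty: edges are pulled to spacing_contact,
    non-edge pairs are pushed beyond spacing_noncontact (with margin).
    Seeded random restarts; the result is verified against the design.
    """
    n = d.n_residues
    s_c, s_nc = d.spacing_contact, d.spacing_noncontact
    edges = sorted(d.target_adjacency)
    nonedges = [(i, j) for i in range(n) for j in range(i + 1, n)
                if (i, j) not in d.target_adjacency]
    push_to = s_nc * (1 + margin_frac)

    def objective(x):
        p = x.reshape(n, 3)
        f = 0.0
        grad = np.zeros_like(p)
        for i, j in edges:
            v = p[i] - p[j]
            dist = max(np.linalg.norm(v), 1e-9)
            f += (dist - s_c) ** 2
            gv = 2 * (dist - s_c) * v / dist
            grad[i] += gv
            grad[j] -= gv
        for i, j in nonedges:
            v = p[i] - p[j]
            dist = max(np.linalg.norm(v), 1e-9)
            if dist < push_to:
                f += (dist - push_to) ** 2
                gv = 2 * (dist - push_to) * v / dist
                grad[i] += gv
                grad[j] -= gv
        return f, grad.ravel()

    rng = np.random.default_rng(d.seed)
    for _ in range(max_restarts):
        x0 = rng.normal(scale=0.6 * s_nc * max(1.0, n ** (1 / 3)), size=3 * n)
        res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 2000})
        p = res.x.reshape(n, 3)
        if _verify(d, p, margin_frac):
            return p
    raise GenerationError(
        f"could not realise design (n={n}, {len(edges)} edges) as geometry "
        f"matching the target adjacency after {max_restarts} restarts")


def _verify(d: ToyDesign, p: np.ndarray, margin_frac: float = 0.05) -> bool:
    """Post-hoc check: the geometric contact map equals the target."""
    n = d.n_residues
    lo = d.spacing_contact * (1 + margin_frac)
    hi = d.spacing_noncontact * (1 - margin_frac)
    for i in range(n):
        for j in range(i + 1, n):
            dist = float(np.linalg.norm(p[i] - p[j]))
            if (i, j) in d.target_adjacency:
                if dist > lo:
                    return False
            elif dist < hi:
                return False
    return True


def _new_pdb_structure(name: str) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model("1")
    model.add_chain(gemmi.Chain("A"))
    st.add_model(model)
    return st


def _add_residue(chain: gemmi.Chain, seq: int, res_name: str,
                 atoms: list[tuple[str, str, np.ndarray]], het: bool = False) -> None:
    res = gemmi.Residue()
    res.name = res_name
    res.seqid = gemmi.SeqId(seq, " ")
    res.het_flag = "H" if het else "A"
    for atom_name, element, xyz in atoms:
        a = gemmi.Atom()
        a.name = atom_name
        a.element = gemmi.Element(element)
        a.pos = gemmi.Position(*map(float, xyz))
        a.occ = 1.0
        res.add_atom(a)
    chain.add_residue(res)


def write_toy_pdb(d: ToyDesign, path: str) -> np.ndarray:
    """Realise a ToyDesign as a PDB file; returns the coordinates used.

    Each residue is one carbon pseudo-atom named CA. The file round-trips
    through the reading/contact/graph stages to exactly the designed
    adjacency for any distance cutoff between the two spacings.

    When ``ligand_touches`` is set, a HETATM pseudo-residue LIG is added
    with one atom per touched residue, each placed just inside contact
    range of its target and verified to stay beyond non-contact range of
    every other residue; failure to realise that raises GenerationError.
    """
    coords = _embed(d)
    st = _new_pdb_structure("toy")
    chain = st[0]["A"]
    for i, (seq, name) in enumerate(zip(d.seqs(), d.names())):
        _add_residue(chain, seq, name, [("CA", "C", coords[i])])
    if d.ligand_touches:
        lig_atoms = _place_ligand(d, coords)
        _add_residue(chain, 999, "LIG",
                     [(f"C{k + 1}", "C", xyz) for k, xyz in enumerate(lig_atoms)],
                     het=True)
    st.setup_entities()
    st.write_pdb(str(path))
    return coords


def _place_ligand(d: ToyDesign, coords: np.ndarray,
                  margin_frac: float = 0.05) -> list[np.ndarray]:
    """One ligand atom per touched residue, contacting only that residue."""
    offset = d.spacing_contact - 0.5
    lo = d.spacing_contact * (1 + margin_frac)
    hi = d.spacing_noncontact * (1 - margin_frac)
    centroid = coords.mean(axis=0)
    rng = np.random.default_rng(d.seed + 7919)
    atoms = []
    for i in d.ligand_touches:
        directions = [coords[i] - centroid]
        directions += [rng.normal(size=3) for _ in range(200)]
        placed = None
        for v in directions:
            norm = np.linalg.norm(v)
            if norm < 1e-9:
                continue
            xyz = coords[i] + offset * v / norm
            dists = np.linalg.norm(coords - xyz, axis=1)
            if dists[i] <= lo and all(dist >= hi for j, dist in enumerate(dists) if j != i):
                placed = xyz
                break
        if placed is None:
            raise GenerationError(
                f"cannot place a ligand atom touching only residue index {i}")
        atoms.append(placed)
    return atoms


def random_toy_design(seed: int, n_min: int = 4, n_max: int = 8,
                      extra_edges: int = 2, max_degree: int = 4) -> ToyDesign:
    """A seeded random sparse connected design (random tree + extra edges).

    Degree is capped at ``max_degree``: around a hub, non-adjacent leaves
    must stay mutually beyond the non-contact spacing, and no more than
    four such directions fit in 3-D at the default spacings. Designs in
    which two non-adjacent residues share three or more common neighbors
    (K_{2,3} subgraphs) are redrawn — that motif has essentially no
    realisation volume at the default spacings.
    """
    for attempt in range(50):
        rng = np.random.default_rng((seed, attempt))
        n = int(rng.integers(n_min, n_max + 1))
        edges: set[tuple[int, int]] = set()
        degree = [0] * n

        def add(i: int, j: int) -> bool:
            if degree[i] >= max_degree or degree[j] >= max_degree:
                return False
            edges.add((min(i, j), max(i, j)))
            degree[i] += 1
            degree[j] += 1
            return True

        for i in range(1, n):  # random tree, connected by construction
            parents = [j for j in range(i) if degree[j] < max_degree]
            add(int(rng.choice(parents)), i)
        candidates = [(i, j) for i in range(n) for j in range(i + 1, n)
                      if (i, j) not in edges]
        rng.shuffle(candidates)
        wanted = int(rng.integers(0, extra_edges + 1))
        for i, j in candidates:
            if wanted == 0:
                break
            if add(i, j):
                wanted -= 1

        nbrs = {i: set() for i in range(n)}
        for i, j in edges:
            nbrs[i].add(j)
            nbrs[j].add(i)
        tight = any(len(nbrs[i] & nbrs[j]) >= 3
                    for i in range(n) for j in range(i + 1, n)
                    if (i, j) not in edges)
        if not tight:
            return ToyDesign(n_residues=n, target_adjacency=frozenset(edges), seed=seed)
    raise GenerationError(f"no embeddable random design found for seed {seed}")


def star_pocket_design() -> ToyDesign:
    """A hub-and-spokes design with a ligand touching the three spokes.

    Residue 0 is the hub; residues 1-3 connect only through it. The
    ligand contacts the three peripheral residues, shortcutting every
    peripheral-peripheral path — the minimal fixture on which a ligand
    measurably reshapes closeness.
    """
    return ToyDesign(
        n_residues=4,
        target_adjacency=frozenset({(0, 1), (0, 2), (0, 3)}),
        ligand_touches=(1, 2, 3),
    )


@dataclass
class BundleDesign:
    """A seven-helix bundle with a tight mid-height core and flared ends.

    Helices stand on a circle around the z axis; the circle radius varies
    with height: minimal (``r_knot``) at mid-height, growing to ``r_end``
    at both mouths following a parabolic profile — a bow-tie silhouette.
    Residues are single C-beta-like pseudo-atoms on an ideal helical
    path (1.5 A rise and 100 degrees twist per residue). Consecutive
    helices run antiparallel, as in a serpentine membrane topology.

    ``ligand_sites`` designates (helix, residue_index) pocket positions at
    which a ligand pseudo-atom is dropped 3.5 A inward, producing one
    multi-atom het residue (name LIG) in contact with those residues.
    """

    n_helices: int = 7
    residues_per_helix: int = 30
    rise: float = 1.5
    twist_deg: float = 100.0
    r_local: float = 1.5
    r_knot: float = 5.0
    r_end: float = 12.0
    ligand_sites: tuple = ()
    ligand_offset: float = 3.5
    seed: int = 0

    def radial_profile(self, t: float) -> float:
        """Bundle circle radius at fractional height t in [0, 1]."""
        r = self.r_knot + (self.r_end - self.r_knot) * (2.0 * t - 1.0) ** 2
        if r <= 0:
            raise ValueError("radial profile must stay positive")
        return r

    def __post_init__(self):
        if self.r_knot <= 0 or self.r_end <= 0:
            raise ValueError("radii must be positive")
        mids = [self.radial_profile(t) for t in np.linspace(1 / 3, 2 / 3, 7)]
        if min(self.radial_profile(t) for t in np.linspace(0, 1, 31)) < min(mids) - 1e-9:
            raise ValueError("radial profile minimum must lie in the middle third")

    def coordinates(self) -> dict:
        """(helix, residue_index) -> xyz for every pseudo-residue."""
        m = self.residues_per_helix
        omega = math.radians(self.twist_deg)
        coords = {}
        for h in range(self.n_helices):
            phi = 2.0 * math.pi * h / self.n_helices
            down = h % 2 == 1
            for i in range(m):
                t = i / (m - 1)
                if down:
                    t = 1.0 - t
                z = t * (m - 1) * self.rise
                rho = self.radial_profile(t)
                ang = omega * i + 0.7 * h  # per-helix phase offset
                radial = rho + self.r_local * math.cos(ang)
                tangent = self.r_local * math.sin(ang)
                x = radial * math.cos(phi) - tangent * math.sin(phi)
                y = radial * math.sin(phi) + tangent * math.cos(phi)
                coords[(h, i)] = np.array([x, y, z])
        return coords

    def seq_number(self, helix: int, i: int) -> int:
        """Author numbering: helix h occupies a contiguous 100-block."""
        return 100 * helix + i + 1


def write_bundle_pdb(d: BundleDesign, path: str) -> None:
    """Write the bundle (plus optional ligand) as a PDB file.

    Pseudo-atoms are named CB (side-chain-like), so contacts between
    sequence-adjacent residues survive the backbone filter and each helix
    is chained together; inter-helix contacts are dense only near the
    knot. The ligand, when present, is a single HETATM residue LIG with
    one atom per designated pocket site, placed toward the bundle axis.
    """
    coords = d.coordinates()
    st = _new_pdb_structure("bundle")
    chain = st[0]["A"]
    for h in range(d.n_helices):
        for i in range(d.residues_per_helix):
            seq = d.seq_number(h, i)
            name = _AA_CYCLE[(h + i) % len(_AA_CYCLE)]
            _add_residue(chain, seq, name, [("CB", "C", coords[(h, i)])])
    if d.ligand_sites:
        atoms = []
        for k, (h, i) in enumerate(d.ligand_sites):
            xyz = coords[(h, i)].copy()
            inward = -xyz[:2] / max(np.linalg.norm(xyz[:2]), 1e-9)
            xyz[:2] += d.ligand_offset * inward
            atoms.append((f"C{k + 1}", "C", xyz))
        _add_residue(chain, 999, "LIG", atoms, het=True)
    st.setup_entities()
    st.write_pdb(str(path))


def pocket_bundle_design() -> BundleDesign:
    """The default bundle with a ligand bound at the extracellular mouth.

    The three designated pocket residues sit at the mouth-side ends of
    three different helices, so the ligand bridges helices that are
    otherwise connected only through the knot — the situation in which
    a bound ligand lends centrality to its pocket.
    """
    return BundleDesign(ligand_sites=((0, 29), (2, 29), (4, 29)))


def random_graph(n: int, p: float, seed: int, max_retries: int = 200) -> nx.Graph:
    """A seeded connected Erdos-Renyi graph, resampled until connected."""
    if n < 2 or not 0 < p <= 1:
        raise ValueError("need n >= 2 and 0 < p <= 1")
    for attempt in range(max_retries):
        g = nx.gnp_random_graph(n, p, seed=seed * 100003 + attempt)
        if nx.is_connected(g):
            g.graph["structure_id"] = f"er_n{n}_p{p}_s{seed}"
            return g
    raise GenerationError(f"no connected G({n}, {p}) found in {max_retries} draws")
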