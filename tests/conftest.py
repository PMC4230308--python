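"""Shared fixtures and independent oracles for the test suite."""

import math

import networkx as nx
import numpy as np
import pytest

from gpcrnet.structure_io import Atom, Residue, Structure


def make_structure(spec, structure_id="test"):
    """Build a Structure from (chain, seq, res_name, kind, atoms) tuples.

    atoms: list of (atom_name, element, (x, y, z)).
    """
    residues = []
    for chain, seq, res_name, kind, atoms in spec:
        residues.append(Residue(
            chain_id=chain, seq_number=seq, insertion_code="", res_name=res_name,
            atoms=[Atom(name=n, element=e, coords=tuple(map(float, xyz)),
                        is_backbone=n in {"N", "CA", "C", "O", "OXT"})
                   for n, e, xyz in atoms],
            kind=kind,
        ))
    return Structure(structure_id=structure_id, residues=residues)


def floyd_warshall_closeness(g: nx.Graph) -> dict:
    """Independent all-pairs closeness oracle via min-plus matrix updates.

    Shares no code path with the BFS implementation under test.
    """
    nodes = sorted(g.nodes(), key=str)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for a, b in g.edges():
        dist[idx[a], idx[b]] = dist[idx[b], idx[a]] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, k:k + 1] + dist[k:k + 1, :])
    out = {}
    for v, i in idx.items():
        row = np.delete(dist[i], i)
        out[v] = 0.0 if np.isinf(row).any() else (n - 1) / row.sum()
    return out


@pytest.fixture(scope="session")
def fig1_graph():
    """The five-residue worked-example graph, nodes keyed by seq number."""
    g = nx.Graph(structure_id="fig1")
    edges = [(86, 113), (86, 316), (113, 316), (289, 312), (312, 316)]
    g.add_nodes_from([86, 113, 289, 312, 316])
    g.add_edges_from(edges)
    return g


@pytest.fixture(scope="session")
def dipeptide():
    """Two sequence-adjacent residues with full backbones plus CB atoms.

    Geometry places the peptide C(1)-N(2) pair and the CB(1)-CB(2) pair
    both within 4.5 A, so the adjacency filter's backbone/side-chain
    distinction is observable.
    """
    return make_structure([
        ("A", 1, "ALA", "polymer", [
            ("N", "N", (0.0, 0.0, 0.0)),
            ("CA", "C", (1.5, 0.0, 0.0)),
            ("C", "C", (2.2, 1.3, 0.0)),
            ("O", "O", (1.6, 2.3, 0.0)),
            ("CB", "C", (2.2, -1.3, 0.0)),
        ]),
        ("A", 2, "ALA", "polymer", [
            ("N", "N", (3.5, 1.3, 0.0)),
            ("CA", "C", (4.4, 2.4, 0.0)),
            ("C", "C", (5.8, 1.9, 0.0)),
            ("O", "O", (6.1, 0.7, 0.0)),
            ("CB", "C", (4.4, -2.4, 3.0)),
        ]),
    ])
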