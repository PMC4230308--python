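"""Shortest-path connectivity distances and closeness-centrality.

The connectivity distance d(x, y) between two residues is the number of
edges on the shortest path between their nodes — not a physical distance.
Closeness-centrality of node x in a graph with node set U of size n is

    C(x) = (n - 1) / sum_{y in U, y != x} d(x, y)

so C is 1 exactly when x is directly connected to every other node, and
decreases as x sits farther (in graph terms) from the rest. Because all
edges have unit length, breadth-first search computes the same distances
Dijkstra's algorithm would, exactly.

When the graph is disconnected some d(x, y) are infinite; under the
default convention C(x) = 0 for every node with an unreachable partner,
and a warning names the components. The "wasserman_faust" alternative
restricts the sum to x's component and scales by
(n_reachable - 1)^2 / ((n - 1) * sum d).
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field

import networkx as nx

from .errors import GraphTooSmallError

INFINITY = math.inf


@dataclass
class CentralityTable:
    """Per-node closeness values with provenance."""

    structure_id: str
    ligand_included: bool
    n: int
    values: dict = field(default_factory=dict)
    distances: dict | None = None

    def residue_values(self, exclude=()) -> dict:
        """Values restricted to keys not in ``exclude`` (e.g. the ligand node)."""
        excl = set(exclude)
        return {k: v for k, v in self.values.items() if k not in excl}


def shortest_path_lengths(g: nx.Graph, source) -> dict:
    """BFS geodesic edge counts from ``source`` to every node of ``g``.

    Unreachable nodes map to ``math.inf``. Raises KeyError for an unknown
    source.
    """
    if source not in g:
        raise KeyError(f"source node {source!r} not in graph")
    dist = {node: INFINITY for node in g.nodes()}
    dist[source] = 0
    q = deque([source])
    while q:
        u = q.popleft()
        du = dist[u]
        for v in g[u]:
            if dist[v] is INFINITY or dist[v] > du + 1:
                dist[v] = du + 1
                q.append(v)
    return dist


def closeness_centrality(g: nx.Graph, disconnected: str = "zero",
                         keep_distances: bool = False) -> CentralityTable:
    """Closeness C(x) = (n-1) / sum_y d(x, y) for every node x.

    Parameters
    ----------
    g : the residue graph (metadata read from ``g.graph`` when present).
    disconnected : {"zero", "wasserman_faust"}
        "zero" (default): any node with an unreachable partner gets C = 0
        and a warning names the components. "wasserman_faust": restrict to
        the node's component with the (n_r - 1)^2 / ((n - 1) * sum d)
        scaling.
    keep_distances : also store the full distance map in the table.
    """
    if disconnected not in ("zero", "wasserman_faust"):
        raise ValueError(f"unknown disconnected convention {disconnected!r}")
    n = g.number_of_nodes()
    if n < 2:
        raise GraphTooSmallError(f"closeness undefined for n={n} (< 2 nodes)")

    values: dict = {}
    distances: dict = {}
    any_unreachable = False
    for x in g.nodes():
        dist = shortest_path_lengths(g, x)
        if keep_distances:
            for y, d in dist.items():
                distances[(x, y)] = d
        reach = [d for y, d in dist.items() if y != x and d is not INFINITY and not math.isinf(d)]
        n_r = len(reach) + 1
        total = sum(reach)
        if n_r < n:
            any_unreachable = True
            if disconnected == "zero" or total == 0:
                values[x] = 0.0
                continue
            values[x] = (n_r - 1) ** 2 / ((n - 1) * total)
        else:
            values[x] = (n - 1) / total

    if any_unreachable:
        comps = [sorted(c) for c in nx.connected_components(g)]
        warnings.warn(
            f"graph is disconnected ({len(comps)} components: "
            f"{[len(c) for c in comps]} nodes); closeness uses the "
            f"{disconnected!r} convention")

    return CentralityTable(
        structure_id=g.graph.get("structure_id", ""),
        ligand_included=bool(g.graph.get("ligand_included", False)),
        n=n,
        values=values,
        distances=distances if keep_distances else None,
    )


def parse_centrality_tsv(path: str) -> CentralityTable:
    """Read a table written by :func:`write_centrality_tsv`."""
    values: dict = {}
    meta = {"structure_id": "", "ligand_included": False}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if parts[0] == "structure_id" and len(parts) > 1:
                    meta["structure_id"] = parts[1]
                if parts[0] == "ligand_included" and len(parts) > 1:
                    meta["ligand_included"] = parts[1] == "True"
                continue
            if line.startswith("node_key"):
                continue
            key_txt, _name, _bw, val = line.rstrip("\n").split("\t")
            chain, rest = key_txt.split(":")
            seq = int("".join(ch for ch in rest if ch.isdigit() or ch == "-"))
            icode = "".join(ch for ch in rest if ch.isalpha())
            values[(chain, seq, icode)] = float(val)
    return CentralityTable(structure_id=meta["structure_id"],
                           ligand_included=meta["ligand_included"],
                           n=len(values), values=values)


def write_centrality_tsv(table: CentralityTable, path: str, s=None, scheme=None,
                         header_lines=None) -> None:
    """Write node_key, res_name, bw_id, closeness as TSV.

    ``s`` (Structure) supplies residue names; ``scheme`` (BWScheme) the
    Ballesteros-Weinstein labels; both optional. ``header_lines`` are
    emitted first as '#' comments (provenance).
    """
    from .annotation import assign_bw  # local import avoids a cycle
    by_key = {r.key: r for r in s.residues} if s is not None else {}
    with open(path, "w") as fh:
        fh.write(f"# structure_id\t{table.structure_id}\n")
        fh.write(f"# ligand_included\t{table.ligand_included}\n")
        fh.write(f"# n_nodes\t{table.n}\n")
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("node_key\tres_name\tbw_id\tcloseness\n")
        for key in sorted(table.values):
            chain, seq, icode = key
            r = by_key.get(key)
            name = r.res_name if r is not None else ("LIG" if chain == "LIG" else "")
            bw = assign_bw(seq, scheme) if (scheme is not None and chain != "LIG") else ""
            fh.write(f"{chain}:{seq}{icode}\t{name}\t{bw}\t{table.values[key]:.6f}\n")
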