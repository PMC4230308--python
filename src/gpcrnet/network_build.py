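"""Aggregate filtered atomic contacts into the residue interaction graph.

A residue-residue interaction is always one edge, regardless of how many
atomic contacts exist between the two residues. Every polymer residue of
the (trimmed) structure is a node even when isolated — the closeness
formula's n counts all analyzed residues, so dropping isolates would
silently change every value. The co-crystallized ligand, when included,
collapses to a single extra node connected to every residue that touches
any of its atoms.
"""

from __future__ import annotations

import networkx as nx

from .contact_detection import AtomContact
from .errors import LigandMissingError
from .structure_io import Structure

#: Node key of the merged ligand pseudo-residue.
LIGAND_NODE = ("LIG", 0, "")


def build_residue_graph(contacts: list[AtomContact], s: Structure,
                        include_ligand: bool = False,
                        merge_ligands: bool = True) -> nx.Graph:
    """Build the unweighted simple residue graph.

    Parameters
    ----------
    contacts : filtered atomic contacts (see ``filter_contacts``).
    s : the trimmed structure supplying the node set.
    include_ligand : add the ligand node(s) and their edges; requires at
        least one residue of kind="ligand", else LigandMissingError.
    merge_ligands : with multiple ligand residues, merge them all into the
        single LIGAND_NODE (default); if False each ligand residue becomes
        its own node.

    Node keys are residue keys ``(chain_id, seq_number, insertion_code)``;
    the merged ligand is ``LIGAND_NODE``. Graph metadata records the
    structure id, whether the ligand is included, and the covalent-anchor
    note is the caller's concern (edge presence only requires contacts).
    """
    polymer_keys = {r.key for r in s.polymer_residues()}
    ligand_keys = {r.key for r in s.ligand_residues()}
    if include_ligand and not ligand_keys:
        raise LigandMissingError(f"{s.structure_id}: ligand requested but no ligand residues present")

    g = nx.Graph(structure_id=s.structure_id, ligand_included=include_ligand)
    g.add_nodes_from(sorted(polymer_keys))

    def node_of(key):
        if key in polymer_keys:
            return key
        if key in ligand_keys and include_ligand:
            return LIGAND_NODE if merge_ligands else key
        return None  # ligand excluded, or solvent/ion/other-het leakage

    if include_ligand:
        if merge_ligands:
            g.add_node(LIGAND_NODE)
        else:
            g.add_nodes_from(sorted(ligand_keys))

    for c in contacts:
        a, b = node_of(c.residue_a), node_of(c.residue_b)
        if a is None or b is None or a == b:
            continue
        g.add_edge(a, b)
    if contacts and g.graph.get("criterion") is None:
        g.graph["criterion"] = contacts[0].criterion
    return g


def write_edge_list_tsv(g: nx.Graph, path: str) -> None:
    def fmt(key):
        chain, seq, icode = key
        return f"{chain}:{seq}{icode}"
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\n")
        for a, b in sorted(g.edges()):
            fh.write(f"{fmt(a)}\t{fmt(b)}\n")


def write_node_table_tsv(g: nx.Graph, s: Structure, path: str) -> None:
    by_key = {r.key: r for r in s.residues}
    with open(path, "w") as fh:
        fh.write("node_key\tres_name\tkind\n")
        for key in sorted(g.nodes()):
            chain, seq, icode = key
            if key == LIGAND_NODE:
                names = sorted({r.res_name for r in s.ligand_residues()})
                fh.write(f"LIG\t{'+'.join(names)}\tligand\n")
            else:
                r = by_key[key]
                fh.write(f"{chain}:{seq}{icode}\t{r.res_name}\t{r.kind}\n")
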