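"""The fixture generators: toy designs, the helix bundle, random graphs."""

import networkx as nx
import numpy as np
import pytest

from gpcrnet import (
    ContactCriterion,
    GenerationError,
    build_residue_graph,
    classify_het_groups,
    closeness_centrality,
    detect_atomic_contacts,
    filter_contacts,
    read_pdb,
)
from gpcrnet.synthetic_data import (
    BundleDesign,
    ToyDesign,
    fig1_design,
    pocket_bundle_design,
    random_graph,
    random_toy_design,
    write_bundle_pdb,
    write_toy_pdb,
)

CRIT = ContactCriterion(mode="distance_cutoff", cutoff=4.5)


def recovered_adjacency(design, path):
    """Run the reading/contact/graph stages and map edges back to indices."""
    s = read_pdb(path)
    contacts = filter_contacts(detect_atomic_contacts(s, CRIT), s)
    g = build_residue_graph(contacts, s)
    index = {("A", seq, ""): i for i, seq in enumerate(design.seqs())}
    return frozenset((min(index[a], index[b]), max(index[a], index[b]))
                     for a, b in g.edges())


def test_colinear_path_design(tmp_path):
    """A 3-chain A-B-C recovers edges {AB, BC} but not AC."""
    design = ToyDesign(n_residues=3, target_adjacency=frozenset({(0, 1), (1, 2)}))
    path = tmp_path / "path.pdb"
    write_toy_pdb(design, path)
    assert recovered_adjacency(design, path) == frozenset({(0, 1), (1, 2)})


def test_empty_adjacency_zero_edges(tmp_path):
    design = ToyDesign(n_residues=4, target_adjacency=frozenset())
    path = tmp_path / "empty.pdb"
    write_toy_pdb(design, path)
    assert recovered_adjacency(design, path) == frozenset()


def test_fig1_design_recovers_worked_example(tmp_path):
    design = fig1_design()
    path = tmp_path / "fig1.pdb"
    write_toy_pdb(design, path)
    s = read_pdb(path)
    contacts = filter_contacts(detect_atomic_contacts(s, CRIT), s)
    g = build_residue_graph(contacts, s)
    assert sorted((a[1], b[1]) for a, b in
                  (sorted(e, key=lambda k: k[1]) for e in g.edges())) == [
        (86, 113), (86, 316), (113, 316), (289, 312), (312, 316)]
    t = closeness_centrality(g)
    rounded = {key[1]: round(v, 2) for key, v in t.values.items()}
    assert rounded == {86: 0.57, 113: 0.57, 289: 0.44, 312: 0.67, 316: 0.80}


@pytest.mark.parametrize("seed", range(25))
def test_round_trip_random_designs(tmp_path, seed):
    design = random_toy_design(seed + 1000)
    path = tmp_path / "toy.pdb"
    write_toy_pdb(design, path)
    assert recovered_adjacency(design, path) == design.target_adjacency


def test_generator_is_deterministic(tmp_path):
    d1, d2 = random_toy_design(42), random_toy_design(42)
    assert d1.target_adjacency == d2.target_adjacency
    p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
    c1 = write_toy_pdb(d1, p1)
    c2 = write_toy_pdb(d2, p2)
    np.testing.assert_array_equal(c1, c2)
    assert p1.read_bytes() == p2.read_bytes()


def test_unembeddable_design_raises(tmp_path):
    """A chordless 4-cycle with 8 A non-contacts cannot exist in 3-D:
    both diagonals would need to exceed sqrt(2) times the side length."""
    design = ToyDesign(n_residues=4,
                       target_adjacency=frozenset({(0, 1), (1, 2), (2, 3), (0, 3)}),
                       spacing_noncontact=8.0)
    with pytest.raises(GenerationError):
        write_toy_pdb(design, tmp_path / "bad.pdb")


def test_invalid_spacings_rejected():
    with pytest.raises(ValueError):
        ToyDesign(n_residues=2, target_adjacency=frozenset(),
                  spacing_contact=6.0, spacing_noncontact=5.0)


class TestBundle:
    def test_default_bundle_is_connected(self, tmp_path):
        path = tmp_path / "bundle.pdb"
        write_bundle_pdb(BundleDesign(), path)
        s = read_pdb(path)
        assert len(s.polymer_residues()) == 7 * 30
        g = build_residue_graph(filter_contacts(detect_atomic_contacts(s, CRIT), s), s)
        assert nx.is_connected(g)

    def test_knot_enrichment_mid_helix(self, tmp_path):
        """Per-helix closeness peaks in the middle third: the knot."""
        d = BundleDesign()
        path = tmp_path / "bundle.pdb"
        write_bundle_pdb(d, path)
        s = read_pdb(path)
        g = build_residue_graph(filter_contacts(detect_atomic_contacts(s, CRIT), s), s)
        t = closeness_centrality(g)
        m = d.residues_per_helix
        for h in range(d.n_helices):
            values = [t.values[("A", d.seq_number(h, i), "")] for i in range(m)]
            imax = int(np.argmax(values))
            assert m // 3 <= imax < m - m // 3

    def test_flat_profile_control(self, tmp_path):
        """With no knot (flat radial profile) the engineered enrichment's
        precondition is absent: inter-helix contact density is uniform in
        height rather than concentrated mid-bundle."""
        d = BundleDesign(r_end=BundleDesign().r_knot)
        assert d.radial_profile(0.0) == d.radial_profile(0.5)
        path = tmp_path / "flat.pdb"
        write_bundle_pdb(d, path)
        s = read_pdb(path)
        g = build_residue_graph(filter_contacts(detect_atomic_contacts(s, CRIT), s), s)
        assert nx.is_connected(g)
        closeness_centrality(g)  # well-defined; no mid-helix claim made

    def test_pocket_bundle_ligand_flags_designated_residues(self, tmp_path):
        d = pocket_bundle_design()
        path = tmp_path / "pocket.pdb"
        write_bundle_pdb(d, path)
        s = classify_het_groups(read_pdb(path), {"LIG"})
        from gpcrnet import ligand_effect
        report, _, _ = ligand_effect(s, CRIT)
        flagged = set(report.flagged())
        designated = {("A", d.seq_number(h, i), "") for h, i in d.ligand_sites}
        assert designated <= flagged


class TestRandomGraph:
    def test_minimal_case(self):
        g = random_graph(2, 1.0, seed=0)
        t = closeness_centrality(g)
        assert all(v == pytest.approx(1.0) for v in t.values.values())

    def test_deterministic_under_seed(self):
        g1 = random_graph(30, 0.2, seed=7)
        g2 = random_graph(30, 0.2, seed=7)
        assert set(g1.edges()) == set(g2.edges())

    def test_always_connected(self):
        for seed in range(20):
            assert nx.is_connected(random_graph(25, 0.15, seed=seed))

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            random_graph(1, 0.5, seed=0)
        with pytest.raises(ValueError):
            random_graph(5, 0.0, seed=0)
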