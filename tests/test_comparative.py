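"""High-centrality sets, activation deltas and ligand-presence deltas."""

import math

import pytest

from gpcrnet import (
    CentralityTable,
    ContactCriterion,
    classify_het_groups,
    delta_centrality,
    high_centrality_set,
    ligand_effect,
    read_pdb,
)
from gpcrnet.errors import LigandMissingError
from gpcrnet.network_build import LIGAND_NODE
from gpcrnet.synthetic_data import ToyDesign, star_pocket_design, write_toy_pdb

from conftest import make_structure


def _table(values, structure_id="t", ligand=False):
    keyed = {("A", 10 * (i + 1), ""): v for i, v in enumerate(values)}
    return CentralityTable(structure_id=structure_id, ligand_included=ligand,
                           n=len(keyed), values=keyed)


class TestHighCentrality:
    def test_mean_plus_sd_cutoff(self):
        report = high_centrality_set(_table([0.1, 0.2, 0.3]), k=1.0)
        assert report.mean == pytest.approx(0.2)
        assert report.sd == pytest.approx(0.1)  # sample sd
        assert report.cutoff_high == pytest.approx(0.3)
        assert report.flagged() == [("A", 30, "")]  # inclusive >=

    def test_large_k_flags_nothing(self):
        report = high_centrality_set(_table([0.1, 0.2, 0.3]), k=2.5)
        assert report.cutoff_high == pytest.approx(0.45)
        assert report.flagged() == []

    def test_all_equal_all_flagged(self):
        """sd = 0 makes the cutoff the mean; inclusive >= flags everything."""
        report = high_centrality_set(_table([0.4, 0.4, 0.4]), k=1.0)
        assert len(report.flagged()) == 3

    def test_ligand_node_excluded_from_statistic(self):
        t = _table([0.1, 0.2, 0.3], ligand=True)
        t.values[LIGAND_NODE] = 0.99
        report = high_centrality_set(t, k=1.0)
        assert report.mean == pytest.approx(0.2)
        assert LIGAND_NODE not in dict(report.per_residue)


class TestDeltaCentrality:
    def test_identical_tables_flag_nothing(self):
        t = _table([0.1, 0.2, 0.3])
        report = delta_centrality(t, _table([0.1, 0.2, 0.3], "u"))
        assert all(v == 0.0 for v, _ in report.per_residue.values())
        assert report.flagged() == []

    def test_hand_computed_sd_flags(self):
        a = _table([0.30, 0.20, 0.10, 0.20, 0.20], "a")
        b = _table([0.20, 0.20, 0.20, 0.20, 0.20], "b")
        report = delta_centrality(a, b, k=1.0)
        # deltas {+0.1, 0, -0.1, 0, 0}: mean 0, sample sd sqrt(0.02/4)
        assert report.mean == pytest.approx(0.0)
        assert report.sd == pytest.approx(math.sqrt(0.005))
        assert report.flagged() == [("A", 10, ""), ("A", 30, "")]

    def test_unmatched_residues_listed_not_counted(self):
        a = _table([0.1, 0.2, 0.3, 0.4], "a")
        b = _table([0.1, 0.2, 0.3], "b")
        report = delta_centrality(a, b)
        assert report.unmatched == [("A", 40, "")]
        assert len(report.per_residue) == 3

    def test_too_few_shared_residues_errors(self):
        a = _table([0.1], "a")
        b = _table([0.2], "b")
        with pytest.raises(ValueError, match="shared"):
            delta_centrality(a, b)

    def test_flags_reproducible_from_thresholds(self):
        a = _table([0.31, 0.18, 0.11, 0.22, 0.27], "a")
        b = _table([0.20, 0.21, 0.19, 0.20, 0.22], "b")
        report = delta_centrality(a, b, k=1.0)
        recomputed = report.recompute_flags()
        assert recomputed == {k: f for k, (_, f) in report.per_residue.items()}


@pytest.fixture(scope="module")
def star(tmp_path_factory):
    path = tmp_path_factory.mktemp("star") / "star.pdb"
    write_toy_pdb(star_pocket_design(), path)
    return classify_het_groups(read_pdb(path), {"LIG"})


class TestLigandEffect:
    crit = ContactCriterion(mode="distance_cutoff", cutoff=4.5)

    def test_star_oracle_values(self, star):
        """Frozen brute-force closeness for the hub-and-spokes fixture.

        Without the ligand (star on 4 nodes): hub 3/3 = 1, spokes
        3/(1+2+2) = 0.6. With the ligand bridging the three spokes
        (n = 5): hub 4/5, spokes 4/(1+2+2+1) = 2/3, ligand 4/5.
        """
        report, t_with, t_without = ligand_effect(star, self.crit)
        hub = ("A", 1, "")
        spokes = [("A", 3, ""), ("A", 5, ""), ("A", 7, "")]
        assert t_without.values[hub] == pytest.approx(1.0)
        assert t_with.values[hub] == pytest.approx(4 / 5)
        assert t_with.values[LIGAND_NODE] == pytest.approx(4 / 5)
        for sp in spokes:
            assert t_without.values[sp] == pytest.approx(3 / 5)
            assert t_with.values[sp] == pytest.approx(2 / 3)
            assert report.per_residue[sp][0] == pytest.approx(2 / 3 - 3 / 5)

    def test_star_max_delta_is_ligand_contacting(self, star):
        report, _, _ = ligand_effect(star, self.crit)
        spokes = {("A", 3, ""), ("A", 5, ""), ("A", 7, "")}
        best = max(report.per_residue, key=lambda k: report.per_residue[k][0])
        assert best in spokes

    def test_ligand_node_excluded_from_deltas(self, star):
        report, _, _ = ligand_effect(star, self.crit)
        assert LIGAND_NODE not in report.per_residue

    def test_pocket_fixture_flags_stay_local(self, tmp_path):
        """Ligand touching 2 residues of a 6-path: flagged residues lie in
        the pocket or among its first-degree neighbors."""
        design = ToyDesign(
            n_residues=6,
            target_adjacency=frozenset({(i, i + 1) for i in range(5)}),
            ligand_touches=(2, 3),
        )
        path = tmp_path / "pocket.pdb"
        write_toy_pdb(design, path)
        s = classify_het_groups(read_pdb(path), {"LIG"})
        report, _, _ = ligand_effect(s, self.crit, k=1.0)
        seqs = design.seqs()
        pocket = {("A", seqs[2], ""), ("A", seqs[3], "")}
        neighbors = {("A", seqs[1], ""), ("A", seqs[4], "")}
        assert set(report.flagged()) <= pocket | neighbors
        assert set(report.flagged()) & pocket

    def test_no_ligand_errors(self, tmp_path):
        path = tmp_path / "bare.pdb"
        write_toy_pdb(ToyDesign(n_residues=3,
                                target_adjacency=frozenset({(0, 1), (1, 2)})), path)
        s = read_pdb(path)
        with pytest.raises(LigandMissingError):
            ligand_effect(s, self.crit)
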