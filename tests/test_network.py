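"""Constraint-network construction: hydrogen bonds, tethers, bars."""

import math

import numpy as np
import pytest

from hcnflex.network import (Bar, ConstraintNetwork, HBondParams,
                             build_network, covalent_bonds,
                             detect_hydrogen_bonds,
                             detect_hydrophobic_tethers, hbond_energy,
                             _adjacency, _angle, _angular_factor,
                             _hybridization)
from hcnflex.synth import _build_polyala_helix

from conftest import bare_atom_snapshot, chains_to_snapshot


class TestHBondEnergy:
    def test_radial_minimum_is_minus_v0(self):
        # at d = d0 with unit angular factor the 12-10 well bottoms at -8
        assert hbond_energy(2.8, 1.0) == pytest.approx(-8.0, abs=1e-12)

    def test_energy_positive_at_short_range(self):
        assert hbond_energy(2.0, 1.0) > 0

    def test_no_bond_beyond_distance_screen(self, ideal_helix_snapshot):
        snap = ideal_helix_snapshot.copy()
        # stretch the helix along its axis so every D-A pair exceeds 6 A
        snap.coords = snap.coords * 3.0
        assert detect_hydrogen_bonds(snap) == []

    def test_helix_bonds_match_brute_force_enumeration(
            self, ideal_helix_snapshot):
        """Independent O(n^3)-style scan over all D-H...A triples."""
        snap = ideal_helix_snapshot
        cov = covalent_bonds(snap)
        got = {(b.donor, b.acceptor): b.E_HB
               for b in detect_hydrogen_bonds(snap, covalent=cov)}

        p = HBondParams()
        adj = _adjacency(snap, cov)
        is_h = snap.element == "H"
        polar = np.isin(snap.element, ("N", "O", "S"))
        expected = {}
        for d in np.nonzero(polar)[0]:
            hyds = [j for j in adj[d] if is_h[j]]
            if not hyds:
                continue
            for a in np.nonzero(polar)[0]:
                if a == d or a in adj[d] or (adj[d] & adj[a]):
                    continue
                el = snap.element[a]
                has_h = any(is_h[j] for j in adj[a])
                heavy_deg = sum(1 for j in adj[a] if not is_h[j])
                if not (el in ("O", "S")
                        or (el == "N" and not has_h and heavy_deg <= 2)):
                    continue
                dda = np.linalg.norm(snap.coords[d] - snap.coords[a])
                if dda > p.max_da:
                    continue
                best = None
                for h in hyds:
                    if np.linalg.norm(snap.coords[h] - snap.coords[a]) > p.max_ha:
                        continue
                    if _angle(snap.coords[d], snap.coords[h],
                              snap.coords[a]) < p.min_dha_deg:
                        continue
                    f = _angular_factor(snap, adj, int(d), int(h), int(a),
                                        _hybridization(snap, adj, int(d)),
                                        _hybridization(snap, adj, int(a)))
                    e = hbond_energy(dda, f)
                    if best is None or e < best:
                        best = e
                if best is not None and best < 0:
                    expected[(int(d), int(a))] = best
        assert set(got) == set(expected)
        for key in got:
            assert got[key] == pytest.approx(expected[key], abs=1e-9)


class TestHydrophobicTethers:
    def test_carbon_pair_inside_cutoff(self):
        snap = bare_atom_snapshot([[0, 0, 0], [3.60, 0, 0]], "CC")
        tethers = detect_hydrophobic_tethers(snap)
        assert len(tethers) == 1 and tethers[0].distance == pytest.approx(3.6)

    def test_carbon_pair_boundary_inclusive(self):
        snap = bare_atom_snapshot([[0, 0, 0], [3.65, 0, 0]], "CC")
        assert len(detect_hydrophobic_tethers(snap)) == 1

    def test_carbon_sulfur_pair_outside_cutoff(self):
        snap = bare_atom_snapshot([[0, 0, 0], [3.80, 0, 0]], "CS")
        assert detect_hydrophobic_tethers(snap) == []

    def test_carbon_sulfur_boundary_inclusive(self):
        snap = bare_atom_snapshot([[0, 0, 0], [3.75, 0, 0]], "CS")
        assert len(detect_hydrophobic_tethers(snap)) == 1

    def test_random_cloud_matches_brute_force(self):
        rng = np.random.default_rng(5)
        elements = rng.choice(list("CS"), size=30)
        coords = rng.uniform(0, 12, size=(30, 3))
        snap = bare_atom_snapshot(coords, elements)
        got = {(t.atom_a, t.atom_b) for t in detect_hydrophobic_tethers(snap)}
        radii = {"C": 1.7, "S": 1.8}
        expected = set()
        for i in range(30):
            for j in range(i + 1, 30):
                cut = radii[elements[i]] + radii[elements[j]] + 0.25
                if np.linalg.norm(coords[i] - coords[j]) <= cut:
                    expected.add((i, j))
        assert got == expected

    def test_symmetric_and_order_independent(self):
        rng = np.random.default_rng(6)
        coords = rng.uniform(0, 8, size=(12, 3))
        snap_fwd = bare_atom_snapshot(coords, "C" * 12)
        snap_rev = bare_atom_snapshot(coords[::-1], "C" * 12)
        fwd = {frozenset((t.atom_a, t.atom_b))
               for t in detect_hydrophobic_tethers(snap_fwd)}
        rev = {frozenset((11 - t.atom_a, 11 - t.atom_b))
               for t in detect_hydrophobic_tethers(snap_rev)}
        assert fwd == rev

    def test_polar_bonded_carbons_excluded_by_default(
            self, ideal_helix_snapshot):
        # backbone CA / carbonyl C are bonded to N/O: no tethers in an
        # isolated poly-Ala helix unless the apolar filter is lifted
        assert detect_hydrophobic_tethers(ideal_helix_snapshot) == []
        assert len(detect_hydrophobic_tethers(
            ideal_helix_snapshot, apolar_only=False)) > 0


class TestBuildNetwork:
    def _fake_bond(self, e):
        from hcnflex.network import HydrogenBond
        return HydrogenBond(donor=0, hydrogen=1, acceptor=5, E_HB=e)

    def test_cutoff_threshold_filter(self, ideal_helix_snapshot):
        bonds = [self._fake_bond(e) for e in (-0.5, -2.0, -3.0)]
        net = build_network(ideal_helix_snapshot, bonds, [], E_cut=-1.0)
        assert sum(1 for b in net.bars if b.kind == "hbond") == 2

    def test_zero_cutoff_keeps_all(self, ideal_helix_snapshot):
        bonds = [self._fake_bond(e) for e in (-0.5, -2.0, -3.0)]
        net = build_network(ideal_helix_snapshot, bonds, [], E_cut=0.0)
        assert sum(1 for b in net.bars if b.kind == "hbond") == 3

    def test_positive_cutoff_rejected(self, ideal_helix_snapshot):
        with pytest.raises(ValueError):
            build_network(ideal_helix_snapshot, [], [], E_cut=0.5)

    def test_dipeptide_bar_multiplicities_match_hand_count(self):
        snap = chains_to_snapshot([_build_polyala_helix(2)])
        net = build_network(snap, [], [], E_cut=0.0)
        # residue 1 (N CA HA CB C O): N-CA, CA-C, CA-CB, CA-HA rotatable;
        # C=O locked.  residue 2 adds N-H; peptide C-N locked.
        by_kind = {}
        for b in net.bars:
            by_kind.setdefault((b.kind, b.multiplicity), 0)
            by_kind[(b.kind, b.multiplicity)] += 1
        assert by_kind[("covalent-locked", 6)] == 3    # 2x C=O + peptide
        assert by_kind[("covalent-rotatable", 5)] == 9

    def test_monotone_filtration(self, ideal_helix_snapshot):
        snap = ideal_helix_snapshot
        cov = covalent_bonds(snap)
        bonds = detect_hydrogen_bonds(snap, covalent=cov)
        assert bonds, "helix fixture must contain hydrogen bonds"
        prev = None
        for e_cut in (-6.0, -4.0, -2.0, -0.1):
            net = build_network(snap, bonds, [], E_cut=e_cut, covalent=cov)
            cur = {(b.atom_a, b.atom_b) for b in net.bars if b.kind == "hbond"}
            if prev is not None:
                assert prev <= cur
            prev = cur

    def test_nonstandard_residue_named_in_error(self, ideal_helix_snapshot):
        snap = ideal_helix_snapshot.copy()
        snap.residue_name[:] = "XQZ"
        with pytest.raises(ValueError, match="XQZ"):
            covalent_bonds(snap)

    def test_edge_list_round_trip(self, tmp_path, ideal_helix_snapshot):
        snap = ideal_helix_snapshot
        cov = covalent_bonds(snap)
        bonds = detect_hydrogen_bonds(snap, covalent=cov)
        net = build_network(snap, bonds, [], E_cut=-0.1, covalent=cov)
        path = tmp_path / "edges.tsv"
        net.to_edgelist(path)
        back = ConstraintNetwork.from_edgelist(path, net.n_bodies, net.E_cut)
        assert [(b.atom_a, b.atom_b, b.multiplicity, b.kind) for b in back.bars] \
            == [(b.atom_a, b.atom_b, b.multiplicity, b.kind) for b in net.bars]

    def test_invalid_multiplicity_rejected(self):
        with pytest.raises(ValueError, match="multiplicity"):
            ConstraintNetwork(n_bodies=2, bars=[Bar(0, 1, 3, "hbond", -1.0)])


def test_detection_is_deterministic(ideal_helix_snapshot):
    a = detect_hydrogen_bonds(ideal_helix_snapshot)
    b = detect_hydrogen_bonds(ideal_helix_snapshot)
    assert a == b
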