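"""Pebble game, dilution, stability maps and energies."""

import numpy as np
import pytest

from hcnflex.network import (Bar, ConstraintNetwork, build_network,
                             covalent_bonds, detect_hydrogen_bonds,
                             detect_hydrophobic_tethers)
from hcnflex.rigidity import (default_ecut_grid, delta_stability, dilute,
                              pebble_game, region_average, residue_contacts,
                              stability_map, stability_profile,
                              StabilityMap)

from _oracles import random_network, rank_oracle, welch_p
from conftest import bare_atom_snapshot


def _net(n, bars):
    kinds = {2: "hydrophobic", 5: "covalent-rotatable", 6: "covalent-locked"}
    return ConstraintNetwork(
        n_bodies=n, bars=[Bar(u, v, m, kinds[m]) for u, v, m in bars])


class TestPebbleGame:
    def test_single_body(self):
        dec = pebble_game(_net(1, []))
        assert dec.n_clusters == 1 and dec.floppy_modes == 0

    def test_two_bodies_six_bars_locked(self):
        dec = pebble_game(_net(2, [(0, 1, 6)]))
        assert dec.n_clusters == 1 and dec.floppy_modes == 0

    def test_two_bodies_five_bars_hinge(self):
        dec = pebble_game(_net(2, [(0, 1, 5)]))
        assert dec.n_clusters == 2 and dec.floppy_modes == 1

    def test_matches_rank_oracle_on_random_networks(self):
        rng = np.random.default_rng(123)
        for _ in range(120):
            n, bars = random_network(rng, max_bodies=10)
            dec = pebble_game(_net(n, bars))
            floppy, labels = rank_oracle(n, bars, rng)
            assert dec.floppy_modes == floppy
            assert dec.cluster_of.tolist() == labels

    def test_insertion_order_invariance(self):
        rng = np.random.default_rng(4)
        n, bars = random_network(rng)
        dec1 = pebble_game(_net(n, bars))
        for _ in range(5):
            perm = [bars[i] for i in rng.permutation(len(bars))]
            dec2 = pebble_game(_net(n, perm))
            assert dec1.cluster_of.tolist() == dec2.cluster_of.tolist()
            assert dec1.floppy_modes == dec2.floppy_modes

    def test_adding_a_bar_never_relaxes_the_network(self):
        """The independent-constraint count (rank) never drops when a bar
        is added; equivalently 6V - 6 - rank never increases.  (The
        per-component floppy count can grow by bridging two components,
        which converts trivial motions into internal ones.)"""
        import networkx as nx
        rng = np.random.default_rng(77)

        def rank_of(n, bars):
            dec = pebble_game(_net(n, bars))
            g = nx.Graph()
            g.add_nodes_from(range(n))
            g.add_edges_from((u, v) for u, v, _ in bars)
            c = nx.number_connected_components(g)
            return 6 * n - 6 * c - dec.floppy_modes

        for _ in range(30):
            n, bars = random_network(rng)
            base = rank_of(n, bars)
            u, v = rng.choice(n, size=2, replace=False)
            more = bars + [(int(u), int(v), int(rng.choice([2, 5, 6])))]
            assert rank_of(n, more) >= base


@pytest.fixture(scope="module")
def helix_with_interactions(request):
    from hcnflex.synth import _build_polyala_helix
    from conftest import chains_to_snapshot
    snap = chains_to_snapshot([_build_polyala_helix(14)])
    cov = covalent_bonds(snap)
    hb = detect_hydrogen_bonds(snap, covalent=cov)
    te = detect_hydrophobic_tethers(snap, covalent=cov)
    return snap, cov, hb, te


class TestDilution:
    def test_single_value_grid_equals_direct_game(self, helix_with_interactions):
        snap, cov, hb, te = helix_with_interactions
        dil = dilute(snap, hb, te, [-1.0], covalent=cov)
        assert len(dil) == 1
        direct = pebble_game(build_network(snap, hb, te, -1.0, covalent=cov))
        assert dil[0].cluster_of.tolist() == direct.cluster_of.tolist()
        assert dil[0].floppy_modes == direct.floppy_modes

    def test_empty_grid_rejected(self, helix_with_interactions):
        snap, cov, hb, te = helix_with_interactions
        with pytest.raises(ValueError):
            dilute(snap, hb, te, [], covalent=cov)

    def test_cluster_count_nondecreasing_as_cutoff_drops(
            self, helix_with_interactions):
        snap, cov, hb, te = helix_with_interactions
        dil = dilute(snap, hb, te, default_ecut_grid(), covalent=cov)
        counts = [d.n_clusters for d in dil]  # grid order: -0.1 ... -6.0
        assert counts == sorted(counts)

    def test_partition_only_refines(self, helix_with_interactions):
        snap, cov, hb, te = helix_with_interactions
        dil = dilute(snap, hb, te, default_ecut_grid(), covalent=cov)
        for weak, strong in zip(dil[:-1], dil[1:]):
            # every cluster at the stronger (more negative) cutoff must be
            # contained in one cluster at the weaker cutoff
            for cid in range(strong.n_clusters):
                members = strong.cluster_members(cid)
                assert len(set(weak.cluster_of[members])) == 1

    def test_incremental_equals_independent_recomputation(
            self, helix_with_interactions):
        snap, cov, hb, te = helix_with_interactions
        grid = default_ecut_grid(-0.5, -5.0, 0.5)
        dil = dilute(snap, hb, te, grid, covalent=cov)
        for e_cut, dec in zip(grid, dil):
            direct = pebble_game(
                build_network(snap, hb, te, float(e_cut), covalent=cov))
            assert dec.cluster_of.tolist() == direct.cluster_of.tolist()
            assert dec.floppy_modes == direct.floppy_modes


class TestStabilityMap:
    def test_contact_boundary_inclusive_at_4_5(self):
        snap = bare_atom_snapshot([[0, 0, 0], [4.5, 0, 0], [20, 0, 0]], "CCC")
        contacts = residue_contacts(snap)
        assert (0, 1) in contacts and (0, 2) not in contacts

    def test_always_corigid_pair_gets_grid_minimum(self, helix_with_interactions):
        snap, cov, hb, te = helix_with_interactions
        grid = default_ecut_grid()  # -0.1 .. -6.0
        dil = dilute(snap, hb, te, grid, covalent=cov)
        sm = stability_map(dil, snap)
        # covalently bonded neighbours stay in one cluster at every cutoff?
        # at least: any pair co-rigid at the strongest cutoff carries -6.0
        strong = dil[-1]
        heavy = snap.is_heavy
        for (i, j), rc in sm.rc.items():
            ci = set(strong.cluster_of[(snap.residue_index == i) & heavy])
            cj = set(strong.cluster_of[(snap.residue_index == j) & heavy])
            if ci & cj:
                assert rc == pytest.approx(-6.0)

    def test_sentinel_one_step_above_grid_maximum(self, helix_with_interactions):
        snap, cov, hb, te = helix_with_interactions
        dil = dilute(snap, hb, te, default_ecut_grid(), covalent=cov)
        sm = stability_map(dil, snap)
        assert sm.sentinel == pytest.approx(0.0)

    def test_matches_brute_force_pair_cutoff_scan(self, helix_with_interactions):
        snap, cov, hb, te = helix_with_interactions
        grid = default_ecut_grid(-0.5, -4.0, 0.5)
        dil = dilute(snap, hb, te, grid, covalent=cov)
        sm = stability_map(dil, snap)
        heavy = snap.is_heavy
        for (i, j), rc in sm.rc.items():
            found = None
            for dec in sorted(dil, key=lambda d: d.E_cut):  # most negative up
                ci = set(dec.cluster_of[(snap.residue_index == i) & heavy])
                cj = set(dec.cluster_of[(snap.residue_index == j) & heavy])
                if ci & cj:
                    found = dec.E_cut
                    break
            expected = found if found is not None else sm.sentinel
            assert rc == pytest.approx(expected)


class TestStabilityProfile:
    def test_two_contact_residue(self):
        sm = StabilityMap(n_residues=3,
                          rc={(0, 1): -2.0, (0, 2): -4.0}, sentinel=0.0)
        prof = stability_profile(sm)
        assert prof.E_i[0] == pytest.approx(-3.0)

    def test_isolated_residue_is_zero(self):
        sm = StabilityMap(n_residues=3, rc={(0, 1): -2.0}, sentinel=0.0)
        assert stability_profile(sm).E_i[2] == 0.0

    def test_pair_halving_identity_on_random_map(self):
        rng = np.random.default_rng(11)
        rc = {}
        for _ in range(200):
            i, j = sorted(rng.choice(40, size=2, replace=False))
            rc[(int(i), int(j))] = float(-rng.uniform(0.1, 6.0))
        prof = stability_profile(StabilityMap(n_residues=40, rc=rc))
        assert prof.E_i.sum() == pytest.approx(prof.E_total, abs=1e-9)


class TestDeltaStability:
    def test_identical_groups_all_zero(self):
        rng = np.random.default_rng(2)
        group = rng.normal(size=(4, 10))
        delta = delta_stability(group, group.copy())
        assert np.all(delta.dE_i == 0)
        assert not delta.significant_i.any()

    def test_planted_shift_detected_as_destabilization(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(0.0, 0.01, size=(6, 5))
        con = ref + 5.5  # construct higher E_i => dE = ref - con = -5.5
        delta = delta_stability(ref, con)
        assert np.allclose(delta.dE_i, -5.5, atol=0.05)
        assert delta.significant_i.all()

    def test_p_values_match_direct_welch_formula(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(0, 1, size=(8, 6))
        con = rng.normal(0.5, 2, size=(10, 6))
        delta = delta_stability(ref, con)
        for r in range(6):
            assert delta.p_i[r] == pytest.approx(
                welch_p(ref[:, r], con[:, r]), abs=1e-9)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            delta_stability(np.zeros((1, 4)), np.zeros((3, 4)))


class TestRegionAverage:
    def _delta(self, values):
        from hcnflex.rigidity import DeltaStability
        v = np.asarray(values, dtype=float)
        return DeltaStability(dE_i=v, dE_i_raw=v, p_i=np.zeros_like(v),
                              significant_i=np.ones_like(v, dtype=bool))

    def test_single_residue_region(self):
        m, sd = region_average(self._delta([1.0, -2.5, 3.0]), [1])
        assert m == -2.5 and sd == 0.0

    def test_all_zero_map(self):
        m, _ = region_average(self._delta(np.zeros(5)), range(5))
        assert m == 0.0

    def test_matches_independent_mean_sd(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=20)
        region = [2, 5, 7, 11]
        m, sd = region_average(self._delta(vals), region)
        assert m == pytest.approx(vals[region].mean())
        assert sd == pytest.approx(vals[region].std())

    def test_out_of_range_region_rejected(self):
        with pytest.raises(ValueError):
            region_average(self._delta(np.zeros(5)), [7])
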