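"""Rotamer placement, hydrogen-bond detection and the MC network search."""

import math

import numpy as np
import pytest

from bundleforge.geometry import Transform
from bundleforge.hbnet import (
    HBondCriteria,
    NetworkConstraints,
    SearchSetupError,
    build_search_index,
    detect_hbonds,
    mc_network_search,
    network_satisfaction,
    select_network_sets,
)
from bundleforge.register import assign_register, build_search_mask
from bundleforge.rotamers import (
    DEFAULT_ALLOWED,
    RotamerError,
    build_sidechain,
    chi_grids,
    enumerate_rotamers,
)


def brute_force_hbonds(placements, criteria=HBondCriteria()):
    """Independent all-pairs oracle: plain double loops, no spatial index."""

    def angle(a, b, c):
        v1, v2 = a - b, c - b
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))

    found = set()
    for di, dp in enumerate(placements):
        for ai, ap in enumerate(placements):
            if di == ai:
                continue
            for datom, dbase in dp.donors:
                for aatom, abase in ap.acceptors:
                    d = float(np.linalg.norm(dp.atom(datom) - ap.atom(aatom)))
                    if not criteria.min_distance <= d <= criteria.max_distance:
                        continue
                    if angle(dp.atom(dbase), dp.atom(datom), ap.atom(aatom)) < criteria.min_donor_angle:
                        continue
                    if angle(ap.atom(abase), ap.atom(aatom), dp.atom(datom)) < criteria.min_acceptor_angle:
                        continue
                    found.add((di, datom, ai, aatom))
    return found


class TestRotamers:
    def test_serine_base_grid_has_3_rotamers(self, trimer35):
        rots = enumerate_rotamers(
            trimer35, ("A", 10), allowed_types=("SER",), clash_check=False
        )
        assert len(rots) == 3
        assert {r.chis[0] for r in rots} == {-60.0, 60.0, 180.0}

    def test_serine_extra_grid_has_9_rotamers(self, trimer35):
        rots = enumerate_rotamers(
            trimer35, ("A", 10), allowed_types=("SER",), extra=True, clash_check=False
        )
        assert len(rots) == 9

    def test_default_alphabet_excludes_lys_arg(self):
        assert set(DEFAULT_ALLOWED) == {
            "SER", "THR", "ASN", "GLN", "HIS", "TYR", "TRP", "ASP", "GLU",
        }
        assert "LYS" not in DEFAULT_ALLOWED and "ARG" not in DEFAULT_ALLOWED

    def test_lys_arg_available_by_explicit_request(self, trimer35):
        rots = enumerate_rotamers(
            trimer35, ("A", 10), allowed_types=("LYS",), clash_check=False
        )
        assert len(rots) == 3**4
        assert all("NZ" in r.atom_names for r in rots)

    def test_unknown_type_rejected(self, trimer35):
        with pytest.raises(RotamerError):
            enumerate_rotamers(trimer35, ("A", 10), allowed_types=("XXX",))

    def test_chi_counts_per_type(self):
        expected = {"SER": 1, "THR": 1, "ASN": 2, "GLN": 3, "GLU": 3, "TYR": 2}
        for res, n in expected.items():
            assert len(chi_grids(res)) == n

    def test_sidechain_geometry_bond_lengths(self, trimer35):
        i = np.flatnonzero((trimer35.chain_ids == "A") & (trimer35.res_ids == 10))[0]
        n, ca, cb = (trimer35.coords[i, k] for k in (0, 1, 4))
        names, xyz = build_sidechain(n, ca, cb, "SER", (-60.0,))
        og = xyz[names.index("OG")]
        assert np.linalg.norm(og - cb) == pytest.approx(1.417, abs=1e-9)

    def test_clash_filter_removes_core_pointing_rotamers(self, trimer35):
        free = enumerate_rotamers(
            trimer35, ("A", 10), allowed_types=("TRP",), clash_check=False
        )
        filtered = enumerate_rotamers(trimer35, ("A", 10), allowed_types=("TRP",))
        assert len(filtered) < len(free)


class TestDetectHbonds:
    def test_constructed_pair_within_cutoffs(self, trimer35):
        # a serine donating to a glutamate: accept iff geometry says so, and
        # the vectorized detector must agree with the brute-force oracle
        rots_a = enumerate_rotamers(trimer35, ("A", 17), allowed_types=("SER",), extra=True)
        rots_b = enumerate_rotamers(trimer35, ("B", 17), allowed_types=("GLU",), extra=True)
        placements = rots_a + rots_b
        fast = {
            (h.donor_placement, h.donor_atom, h.acceptor_placement, h.acceptor_atom)
            for h in detect_hbonds(placements)
        }
        assert fast == brute_force_hbonds(placements)

    def test_distant_pair_rejected(self, trimer35):
        rots_a = enumerate_rotamers(trimer35, ("A", 8), allowed_types=("SER",))
        rots_b = enumerate_rotamers(trimer35, ("B", 29), allowed_types=("SER",))
        bonds = detect_hbonds(rots_a + rots_b)
        assert bonds == []

    def test_matches_oracle_on_random_fixtures(self, trimer35):
        rng = np.random.default_rng(11)
        positions = [
            (c, int(r))
            for c in "ABC"
            for r in rng.integers(6, 30, size=3)
        ]
        for trial in range(20):
            picks = rng.choice(len(positions), size=4, replace=False)
            placements = []
            for k in picks:
                rots = enumerate_rotamers(
                    trimer35,
                    positions[k],
                    allowed_types=(str(rng.choice(DEFAULT_ALLOWED)),),
                    extra=True,
                )
                if rots:
                    placements.append(rots[int(rng.integers(len(rots)))])
            fast = {
                (h.donor_placement, h.donor_atom, h.acceptor_placement, h.acceptor_atom)
                for h in detect_hbonds(placements)
            }
            assert fast == brute_force_hbonds(placements)

    def test_empty_input_gives_empty_output(self):
        assert detect_hbonds([]) == []


@pytest.fixture(scope="module")
def triad_search(planted_triad_fixture):
    model = planted_triad_fixture.model
    mask = build_search_mask(assign_register(model), "NPPPN")
    index = build_search_index(
        model,
        mask.positions(),
        allowed_types=("SER", "THR", "ASN"),
        extra_rotamers=True,
    )
    return model, mask, index


class TestMcNetworkSearch:
    def test_recovers_planted_triad_within_1000_trials(self, triad_search):
        model, mask, index = triad_search
        nets = mc_network_search(
            model,
            mask,
            NetworkConstraints(min_residues=3),
            trials=1000,
            seed=0,
            allowed_types=("SER", "THR", "ASN"),
            index=index,
        )
        assert any(len(n) >= 3 and len(n.chains) == 3 for n in nets)

    def test_deterministic_given_seed(self, triad_search):
        model, mask, index = triad_search
        kwargs = dict(
            constraints=NetworkConstraints(min_residues=3),
            trials=300,
            seed=5,
            allowed_types=("SER", "THR", "ASN"),
            index=index,
        )
        first = mc_network_search(model, mask, **kwargs)
        second = mc_network_search(model, mask, **kwargs)
        assert [n.residue_map for n in first] == [n.residue_map for n in second]

    def test_more_trials_never_lose_networks(self, triad_search):
        model, mask, index = triad_search
        kwargs = dict(
            constraints=NetworkConstraints(min_residues=3),
            seed=1,
            allowed_types=("SER", "THR", "ASN"),
            index=index,
        )
        few = mc_network_search(model, mask, trials=200, **kwargs)
        many = mc_network_search(model, mask, trials=800, **kwargs)
        assert {n.residue_map for n in few} <= {n.residue_map for n in many}

    def test_all_nonpolar_mask_raises(self, trimer35):
        mask = build_search_mask(assign_register(trimer35), "NNNNN")
        with pytest.raises(SearchSetupError):
            mc_network_search(trimer35, mask, trials=10, seed=0)

    def test_impossible_constraints_reported_before_search(self, triad_search):
        model, mask, _ = triad_search
        n_positions = len(mask.positions())
        with pytest.raises(SearchSetupError):
            mc_network_search(
                model,
                mask,
                NetworkConstraints(min_residues=n_positions + 1),
                trials=10,
                seed=0,
            )

    def test_networks_connected_and_span_required_chains(self, triad_search):
        model, mask, index = triad_search
        nets = mc_network_search(
            model,
            mask,
            NetworkConstraints(min_residues=3),
            trials=500,
            seed=2,
            allowed_types=("SER", "THR", "ASN"),
            index=index,
        )
        for net in nets:
            assert net.chains >= {"A", "B", "C"}
            # connectivity: every placement participates in >= 1 bond and a
            # union-find over the bonds yields a single component
            parent = list(range(len(net.placements)))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for hb in net.hbonds:
                if hb.donor_placement >= 0 and hb.acceptor_placement >= 0:
                    parent[find(hb.donor_placement)] = find(hb.acceptor_placement)
            assert len({find(i) for i in range(len(net.placements))}) == 1

    def test_search_invariant_under_rigid_motion(self, planted_triad_fixture):
        model = planted_triad_fixture.model
        mask = build_search_mask(assign_register(model), "NPPPN")
        kwargs = dict(
            constraints=NetworkConstraints(min_residues=3),
            trials=150,
            seed=3,
            allowed_types=("SER", "ASN"),
        )
        base = mc_network_search(model, mask, **kwargs)
        t = Transform.rotation_about_axis([1, 0, 1], 45.0, point=[2, -1, 3])
        moved_model = model.transformed(t)
        moved_mask = build_search_mask(
            assign_register(
                moved_model,
                axis_point=t.apply(np.zeros(3)),
                axis_dir=t.rotation @ np.array([0.0, 0.0, 1.0]),
            ),
            "NPPPN",
        )
        moved = mc_network_search(moved_model, moved_mask, **kwargs)
        assert {n.residue_map for n in base} == {n.residue_map for n in moved}


class TestSatisfactionAndSets:
    def test_fully_bonded_network_passes(self, triad_search, planted_triad_fixture):
        model, mask, index = triad_search
        nets = mc_network_search(
            model,
            mask,
            NetworkConstraints(min_residues=3),
            trials=1000,
            seed=0,
            allowed_types=("SER", "THR", "ASN"),
            index=index,
        )
        fractions = [network_satisfaction(n, model)[0] for n in nets]
        assert all(0.0 <= f <= 1.0 for f in fractions)
        assert any(f > 0.5 for f in fractions)

    def test_exposed_atoms_count_satisfied(self, trimer35):
        # a lone surface serine with no partner: satisfied iff outside the
        # burial radius
        ann = assign_register(trimer35)
        surface_res = int(
            trimer35.res_ids[(trimer35.chain_ids == "A") & (ann.letters == "f")][2]
        )
        rots = enumerate_rotamers(
            trimer35, ("A", surface_res), allowed_types=("SER",)
        )
        from bundleforge.hbnet import Network

        net = Network([rots[0]], [], frozenset({"A"}), 0)
        frac_tight, _ = network_satisfaction(net, trimer35, burial_radius=50.0)
        frac_loose, ok = network_satisfaction(net, trimer35, burial_radius=5.0)
        assert frac_tight == 0.0  # buried and unpartnered
        assert frac_loose == 1.0 and ok  # exposed counts satisfied

    def test_select_network_sets_enforces_disjointness_and_aromatics(self):
        from bundleforge.hbnet import Network
        from bundleforge.rotamers import RotamerPlacement

        def fake(chain, res, rtype):
            return RotamerPlacement(
                chain, res, rtype, (), (), np.zeros((0, 3)), (), (), np.zeros(3)
            )

        n1 = Network([fake("A", 1, "TYR"), fake("B", 1, "SER")], [], frozenset("AB"), 1)
        n2 = Network([fake("A", 8, "TRP"), fake("C", 8, "SER")], [], frozenset("AC"), 1)
        n3 = Network([fake("A", 1, "ASN"), fake("C", 15, "SER")], [], frozenset("AC"), 0)
        cons = NetworkConstraints(networks_required=2, min_aromatics_total=2)
        sets = select_network_sets([n1, n2, n3], cons)
        assert (n1, n2) in sets
        # n1 and n3 share position A/1 -> excluded; n2+n3 lack aromatics
        assert all(not (n1 in s and n3 in s) for s in sets)
        assert (n2, n3) not in sets
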