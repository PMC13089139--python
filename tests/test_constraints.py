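"""Flat-bottom restraints, constraint-set builders and per-ligand scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from carbdock import constraints as ct
from carbdock import intermediates as im
from carbdock.constraints import ConstraintSet, FlatBottomRestraint


def make_geometry(**bodies):
    """Geometry dict from {body: {atom: xyz}} mappings."""
    out = {}
    for body, atoms in bodies.items():
        names = list(atoms)
        coords = np.array([atoms[n] for n in names], dtype=float)
        out[body] = (coords, {n: i for i, n in enumerate(names)})
    return out


class TestFlatBottomPenalty:
    def test_zero_inside_flat_bottom(self):
        r = FlatBottomRestraint("distance", (("a", "x"), ("b", "y")),
                                1.6, 2.6, 0.3)
        for v in (1.6, 2.0, 2.6):
            assert r.penalty_of(v) == 0.0

    def test_penalty_at_edge_plus_sd_is_weight(self):
        r = FlatBottomRestraint("distance", (("a", "x"), ("b", "y")),
                                1.6, 2.6, 0.3, weight=1.0)
        assert r.penalty_of(2.6 + 0.3) == pytest.approx(1.0)
        assert r.penalty_of(1.6 - 0.3) == pytest.approx(1.0)
        r2 = FlatBottomRestraint("distance", (("a", "x"), ("b", "y")),
                                 1.6, 2.6, 0.3, weight=2.5)
        assert r2.penalty_of(2.9) == pytest.approx(2.5)

    def test_penalty_continuous_at_edges(self):
        r = FlatBottomRestraint("distance", (("a", "x"), ("b", "y")),
                                1.0, 2.0, 0.5)
        eps = 1e-9
        assert r.penalty_of(2.0 + eps) < 1e-12
        assert r.penalty_of(1.0 - eps) < 1e-12

    @given(st.floats(0.0, 10.0))
    @settings(max_examples=200, deadline=None)
    def test_quadratic_outside_matches_closed_form(self, x):
        r = FlatBottomRestraint("distance", (("a", "x"), ("b", "y")),
                                2.0, 4.0, 0.5, weight=1.3)
        if x < 2.0:
            expected = 1.3 * ((2.0 - x) / 0.5) ** 2
        elif x > 4.0:
            expected = 1.3 * ((x - 4.0) / 0.5) ** 2
        else:
            expected = 0.0
        assert r.penalty_of(x) == pytest.approx(expected, rel=1e-12)

    def test_measure_distance_and_angle(self):
        geom = make_geometry(
            a={"C": [0, 0, 0], "H": [1.0, 0, 0]},
            b={"O": [3.0, 0, 0]},
        )
        dist = FlatBottomRestraint("distance", (("a", "H"), ("b", "O")),
                                   0, 10, 1)
        assert dist.measure(geom) == pytest.approx(2.0)
        ang = FlatBottomRestraint(
            "angle", (("a", "C"), ("a", "H"), ("b", "O")), 0, 180, 1)
        assert ang.measure(geom) == pytest.approx(180.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            FlatBottomRestraint("distance", (("a", "x"), ("b", "y")),
                                3.0, 2.0, 0.5)
        with pytest.raises(ValueError):
            FlatBottomRestraint("distance", (("a", "x"), ("b", "y")),
                                1.0, 2.0, 0.0)
        with pytest.raises(ValueError):
            FlatBottomRestraint("angle", (("a", "x"), ("b", "y")),
                                0.0, 90.0, 5.0)


class TestBuilders:
    def test_species_a_two_anchors_gives_ten_sets(self, species_a):
        sites = im.enumerate_deprotonation_sites(species_a)
        sets = ct.build_deprotonation_sets(
            species_a, sites,
            {"O": ("receptor", "BASE.O"), "H": ("receptor", "BASE.H")},
            [("OT1", ("pp_mg", "OT1")), ("OT3", ("pp_mg", "OT3"))],
        )
        assert len(sets) == 10
        assert len({cs.set_id for cs in sets}) == 10
        assert all(len(cs.restraints) == 3 for cs in sets)
        hypotheses = {cs.product_hypothesis.product_id for cs in sets}
        assert hypotheses == {"7", "8", "10"}

    def test_one_site_one_anchor_single_set(self, toy_cation):
        g, _ = toy_cation
        sites = im.enumerate_deprotonation_sites(g)[:1]
        sets = ct.build_deprotonation_sets(
            g, sites,
            {"O": ("receptor", "BASE.O"), "H": ("receptor", "BASE.H")},
            [("OT1", ("pp_mg", "OT1"))],
        )
        assert len(sets) == 1
        assert len(sets[0].restraints) == 3

    @given(n_h=st.lists(st.integers(1, 3), min_size=1, max_size=3),
           n_anchors=st.integers(1, 3))
    @settings(max_examples=25, deadline=None)
    def test_cardinality_is_sites_times_anchors(self, n_h, n_anchors):
        from carbdock.synthetic_data import make_toy_cation

        g, _ = make_toy_cation(n_h)
        sites = im.enumerate_deprotonation_sites(g)
        anchors = [(f"A{k}", ("pp_mg", f"OT{k}")) for k in range(n_anchors)]
        sets = ct.build_deprotonation_sets(
            g, sites,
            {"O": ("receptor", "BASE.O"), "H": ("receptor", "BASE.H")},
            anchors,
        )
        assert len(sets) == sum(n_h) * n_anchors
        assert len({cs.set_id for cs in sets}) == len(sets)

    def test_water_constraints_reactive_vs_loose(self):
        r6a = ct.build_water_constraints("6a", reactive=True)
        r6b = ct.build_water_constraints("6b", reactive=True)
        l6a = ct.build_water_constraints("6a", reactive=False)
        dist = {r.kind: r for r in r6a}["distance"]
        dist_b = {r.kind: r for r in r6b}["distance"]
        assert (dist.lower, dist.upper) == (dist_b.lower, dist_b.upper)
        face = {r.kind: r for r in r6a}["face_angle"]
        face_b = {r.kind: r for r in r6b}["face_angle"]
        assert face.face_sign == -face_b.face_sign
        loose_dist = {r.kind: r for r in l6a}["distance"]
        assert loose_dist.upper > dist.upper

    def test_wt_mechanism_same_for_both_species(self):
        ra = ct.build_wt_mechanism_constraints("A")
        rb = ct.build_wt_mechanism_constraints("B")
        assert ra == rb
        assert ra[0].members[0] == ("carbocation", "C7")
        # flat-bottom interior: 4.5 A scores zero
        assert ra[0].penalty_of(4.5) == 0.0
        with pytest.raises(ValueError):
            ct.build_wt_mechanism_constraints("C")


class TestLigandScore:
    def test_all_satisfied_scores_zero_for_every_ligand(self):
        geom = make_geometry(
            receptor={"BASE.O": [0, 0, 0]},
            carbocation={"C7": [3.0, 0, 0], "H7A": [2.0, 0, 0],
                         "C16": [0, 3.5, 0]},
            pp_mg={"OT1": [0, 0.5, 0]},
        )
        cs = ConstraintSet("s", [
            FlatBottomRestraint(
                "distance", (("receptor", "BASE.O"), ("carbocation", "H7A")),
                1.6, 2.6, 0.3),
            FlatBottomRestraint(
                "angle", (("carbocation", "C7"), ("carbocation", "H7A"),
                          ("receptor", "BASE.O")), 120, 180, 20),
            FlatBottomRestraint(
                "distance", (("carbocation", "C16"), ("pp_mg", "OT1")),
                2.5, 4.5, 0.5),
        ])
        for body in ("carbocation", "pp_mg"):
            assert ct.ligand_constraint_score(geom, cs, body) == 0.0

    def test_edge_plus_sd_fails_strict_below_one(self):
        # bounds chosen exactly representable so upper + sd evaluates to 1.0
        geom = make_geometry(
            receptor={"BASE.O": [0, 0, 0]},
            carbocation={"H7A": [2.75, 0, 0]},  # upper 2.5 + sd 0.25
        )
        cs = ConstraintSet("s", [FlatBottomRestraint(
            "distance", (("receptor", "BASE.O"), ("carbocation", "H7A")),
            1.5, 2.5, 0.25)])
        score = ct.ligand_constraint_score(geom, cs, "carbocation")
        assert score == pytest.approx(1.0)
        assert not score < 1.0

    def test_random_geometries_match_piecewise_oracle(self, rng):
        for _ in range(50):
            pts = rng.normal(0.0, 3.0, (3, 3))
            geom = make_geometry(
                receptor={"O": pts[0]},
                carbocation={"C": pts[1], "H": pts[2]},
            )
            cs = ConstraintSet("s", [
                FlatBottomRestraint(
                    "distance", (("receptor", "O"), ("carbocation", "H")),
                    1.6, 2.6, 0.3),
                FlatBottomRestraint(
                    "angle", (("carbocation", "C"), ("carbocation", "H"),
                              ("receptor", "O")), 120, 180, 20),
            ])
            # brute-force numeric re-evaluation of each piecewise term
            d = float(np.linalg.norm(pts[2] - pts[0]))
            expected = 0.0
            if d < 1.6:
                expected += ((1.6 - d) / 0.3) ** 2
            elif d > 2.6:
                expected += ((d - 2.6) / 0.3) ** 2
            v1 = pts[1] - pts[2]
            v2 = pts[0] - pts[2]
            cosang = np.dot(v1, v2) / np.linalg.norm(v1) / np.linalg.norm(v2)
            ang = math.degrees(math.acos(np.clip(cosang, -1, 1)))
            if ang < 120:
                expected += ((120 - ang) / 20) ** 2
            got = ct.ligand_constraint_score(geom, cs, "carbocation")
            assert got == pytest.approx(expected, abs=1e-8)

    def test_unresolved_selector_names_the_atom(self):
        geom = make_geometry(receptor={"O": [0, 0, 0]})
        cs = ConstraintSet("s", [FlatBottomRestraint(
            "distance", (("receptor", "O"), ("carbocation", "H99")),
            0, 1, 1)])
        with pytest.raises(ct.SelectorError, match="carbocation"):
            ct.ligand_constraint_score(geom, cs, "carbocation")


class TestSerialization:
    def build_sets(self, species_a):
        sites = im.enumerate_deprotonation_sites(species_a)
        sets = ct.build_deprotonation_sets(
            species_a, sites,
            {"O": ("receptor", "BASE.O"), "H": ("receptor", "BASE.H")},
            [("OT1", ("pp_mg", "OT1")), ("OT3", ("pp_mg", "OT3"))],
        )
        sets[0] = sets[0].with_restraints(
            ct.build_water_constraints("6b", reactive=False),
            water_mode="loose_6b")
        return sets

    def test_text_round_trip(self, tmp_path, species_a):
        sets = self.build_sets(species_a)
        path = tmp_path / "sets.cst"
        ct.write_constraint_text(sets, path)
        back = ct.read_constraint_text(path)
        assert [cs.set_id for cs in back] == [cs.set_id for cs in sets]
        assert [cs.water_mode for cs in back] == \
            [cs.water_mode for cs in sets]
        for a, b in zip(sets, back):
            assert a.restraints == b.restraints

    def test_json_round_trip(self, tmp_path, species_a):
        sets = self.build_sets(species_a)
        path = tmp_path / "sets.json"
        ct.sets_to_json(sets, path)
        back = ct.sets_from_json(path)
        for a, b in zip(sets, back):
            assert a.restraints == b.restraints
            assert a.set_id == b.set_id
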