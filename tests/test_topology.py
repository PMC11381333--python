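"""Entanglement detection (Gauss linking number, triangle-fan piercing)
and restrained link removal."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cgrna.fixtures import (
    circle_ring,
    double_wound_rings,
    hopf_rings,
    interpenetrating_beads,
    linked_hairpin_stem_beads,
    random_ring_pair,
    unlinked_rings,
)
from cgrna.ss_graph import parse_dotbracket
from cgrna.topology import (
    GeometryError,
    OpenProbe,
    Ring,
    UntangleParams,
    beads_from_structure,
    build_rings,
    check_after_refinement,
    detect_links,
    gauss_linking_number,
    piercing_count,
    remove_links,
    _flatten_beads,
)


def projection_linking_oracle(a: Ring, b: Ring, direction=None):
    """Independent oracle: half the signed crossing count of a generic
    planar projection, with over/under from depth along the projection."""
    d = np.array([0.23, 0.41, 0.88]) if direction is None else np.asarray(direction)
    d = d / np.linalg.norm(d)
    u = np.cross(d, [1.0, 0.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(d, u)

    def project(ring):
        verts = ring.vertices
        return np.column_stack([verts @ u, verts @ v]), verts @ d

    pa, za = project(a)
    pb, zb = project(b)
    total = 0
    na, nb = len(pa), len(pb)
    for i in range(na):
        a1, a2 = pa[i], pa[(i + 1) % na]
        z1, z2 = za[i], za[(i + 1) % na]
        for j in range(nb):
            b1, b2 = pb[j], pb[(j + 1) % nb]
            w1, w2 = zb[j], zb[(j + 1) % nb]
            r = a2 - a1
            s = b2 - b1
            cross2 = lambda p, q: p[0] * q[1] - p[1] * q[0]
            denom = cross2(r, s)
            if abs(denom) < 1e-14:
                continue
            t = cross2(b1 - a1, s) / denom
            w = cross2(b1 - a1, r) / denom
            if not (0 < t < 1 and 0 < w < 1):
                continue
            depth_a = z1 + t * (z2 - z1)
            depth_b = w1 + w * (w2 - w1)
            sign = np.sign(denom) * (1 if depth_a > depth_b else -1)
            total += sign
    return total / 2.0


class TestGaussLinkingNumber:
    def test_separated_coplanar_rings_zero(self):
        a, b = unlinked_rings(separation=50.0, radius=1.0)
        L = gauss_linking_number(a, b)
        assert round(L) == 0
        assert abs(L - round(L)) < 0.05

    def test_hopf_link(self):
        a, b = hopf_rings()
        assert abs(gauss_linking_number(a, b)) == pytest.approx(1.0, abs=1e-6)

    def test_double_winding_with_projection_oracle(self):
        a, b = double_wound_rings()
        L = gauss_linking_number(a, b)
        assert abs(round(L)) == 2
        assert projection_linking_oracle(a, b) == pytest.approx(round(L), abs=1e-9)

    def test_hopf_projection_oracle(self):
        a, b = hopf_rings()
        assert projection_linking_oracle(a, b) == pytest.approx(
            round(gauss_linking_number(a, b)), abs=1e-9
        )

    def test_touching_rings_error(self):
        a = circle_ring("a", (0, 0, 0), (0, 0, 1), 5.0, 16)
        b = Ring("b", a.vertices + np.array([0, 0, 1e-8]), "stem")
        with pytest.raises(GeometryError):
            gauss_linking_number(a, b)

    def test_antisymmetric_under_reversal(self):
        rng = np.random.default_rng(2)
        a, b = random_ring_pair(rng)
        L = gauss_linking_number(a, b)
        rev = Ring(b.id, b.vertices[::-1].copy(), b.kind)
        assert gauss_linking_number(a, rev) == pytest.approx(-L, abs=1e-9)

    def test_rigid_motion_and_cyclic_invariance(self):
        rng = np.random.default_rng(4)
        a, b = random_ring_pair(rng)
        L = gauss_linking_number(a, b)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(size=3) * 10
        am = Ring(a.id, a.vertices @ rot.T + shift, a.kind)
        bm = Ring(b.id, b.vertices @ rot.T + shift, b.kind)
        assert gauss_linking_number(am, bm) == pytest.approx(L, abs=1e-9)
        brolled = Ring(b.id, np.roll(b.vertices, 7, axis=0), b.kind)
        assert gauss_linking_number(a, brolled) == pytest.approx(L, abs=1e-9)

    def test_discretization_stability(self):
        """64- vs 256-gon versions of smooth curves agree within 0.02."""
        for maker in (hopf_rings, unlinked_rings):
            a64, b64 = maker(n=64)
            a256, b256 = maker(n=256)
            assert abs(
                gauss_linking_number(a64, b64) - gauss_linking_number(a256, b256)
            ) < 0.02


class TestPiercing:
    def test_segment_through_centroid(self):
        ring = circle_ring("r", (0, 0, 0), (0, 0, 1), 5.0, 32, phase=0.1)
        probe = OpenProbe("p", np.array([[0.3, 0.2, -4.0], [0.3, 0.2, 4.0]]), "x")
        net, gross = piercing_count(probe, ring)
        assert (abs(net), gross) == (1, 1)

    def test_far_segment(self):
        ring = circle_ring("r", (0, 0, 0), (0, 0, 1), 5.0, 32)
        probe = OpenProbe("p", np.array([[40.0, 0, -4.0], [40.0, 0, 4.0]]), "x")
        assert piercing_count(probe, ring) == (0, 0)

    def test_agreement_with_gauss_on_random_pairs(self):
        """Linked verdicts from net piercings and from the rounded linking
        number agree on a seeded random suite."""
        rng = np.random.default_rng(11)
        for _ in range(40):
            a, b = random_ring_pair(rng)
            L = round(gauss_linking_number(a, b))
            net_ab, gross_ab = piercing_count(a, b)
            net_ba, gross_ba = piercing_count(b, a)
            net = net_ab if abs(net_ab) >= abs(net_ba) else net_ba
            assert (net != 0) == (L != 0)
            assert gross_ab >= abs(net_ab) and gross_ba >= abs(net_ba)
            # net counts are consistent with the linking number magnitude
            if L != 0:
                assert abs(net) >= abs(L) - 0 or abs(net) == abs(L)


class TestBuildRings:
    def test_hairpin_structure(self):
        graph = parse_dotbracket("GCAAAGC", "((...))")
        rng = np.random.default_rng(0)
        beads = {
            r: {"P": rng.normal(size=3) * 10, "S": rng.normal(size=3) * 10}
            for r in range(1, 8)
        }
        rings, probes = build_rings(beads, graph)
        assert sorted(r.kind for r in rings) == ["hairpin", "stem"]
        assert probes == []

    def test_junction_ring_present(self, junction_graph):
        rng = np.random.default_rng(1)
        beads = {
            r: {"P": rng.normal(size=3) * 20, "S": rng.normal(size=3) * 20}
            for r in range(1, 25)
        }
        rings, _probes = build_rings(beads, junction_graph)
        assert sum(r.kind == "junction" for r in rings) == 1

    def test_vertex_multiset_oracle(self):
        graph = parse_dotbracket("GCAAAGC", "((...))")
        rng = np.random.default_rng(2)
        beads = {
            r: {"P": rng.normal(size=3) * 10, "S": rng.normal(size=3) * 10}
            for r in range(1, 8)
        }
        rings, _ = build_rings(beads, graph)
        hairpin = next(r for r in rings if r.kind == "hairpin")
        # loop residues 3,4,5 plus closing-pair residues 2 and 6
        expected = [beads[r][role] for r in (2, 3, 4, 5, 6) for role in ("P", "S")]
        assert sorted(map(tuple, hairpin.vertices)) == sorted(
            map(tuple, np.array(expected))
        )

    def test_interior_loop_probes(self, two_stem_graph):
        rng = np.random.default_rng(3)
        beads = {
            r: {"P": rng.normal(size=3) * 30, "S": rng.normal(size=3) * 30}
            for r in range(1, 25)
        }
        rings, probes = build_rings(beads, two_stem_graph)
        assert sum(p.kind == "internal_loop_strand" for p in probes) == 2

    def test_missing_beads_error(self):
        graph = parse_dotbracket("GCAAAGC", "((...))")
        with pytest.raises(ValueError, match="missing beads"):
            build_rings({1: {"P": np.zeros(3), "S": np.ones(3)}}, graph)


class TestDetectLinks:
    def test_clean_two_helix(self):
        beads, graph, _seq, _dbn = linked_hairpin_stem_beads()
        # move the second arm far away: everything clean
        far = {
            r: {k: v + (np.array([200.0, 0, 0]) if r >= 8 else 0) for k, v in d.items()}
            for r, d in beads.items()
        }
        assert detect_links(far, graph, "both").is_clean()

    def test_threaded_stem_linked_both_methods(self):
        beads, graph, _seq, _dbn = linked_hairpin_stem_beads()
        for method in ("pierce", "gauss", "both"):
            report = detect_links(beads, graph, method)
            pair = next(
                p
                for p in report.pairs
                if {p.id_a, p.id_b} == {"s1", "h0"}
            )
            assert pair.verdict == "linked"

    def test_interpenetration_pierce_only(self):
        """Net-zero double crossing: invisible to the Gauss integral,
        flagged as interpenetrating by the piercing detector."""
        beads, graph, _seq, _dbn = interpenetrating_beads()
        pierce = detect_links(beads, graph, "pierce")
        pair = next(
            p for p in pierce.pairs if {p.id_a, p.id_b} == {"s1", "h0"}
        )
        assert pair.verdict == "interpenetrating"
        assert pair.gross_piercings > 0 and pair.net_piercings == 0
        gauss = detect_links(beads, graph, "gauss")
        assert gauss.is_clean()


class TestRemoveLinks:
    def test_already_clean_unchanged(self):
        beads, graph, _seq, _dbn = interpenetrating_beads()
        clean_report = detect_links(
            {
                r: {k: v + np.array([0.0, 0, 500.0 * (r >= 8)]) for k, v in d.items()}
                for r, d in beads.items()
            },
            graph,
            "both",
        )
        new_beads, ok = remove_links(beads, graph, clean_report)
        assert ok
        assert new_beads is beads

    def test_untangles_linked_fixture(self):
        beads, graph, _seq, _dbn = linked_hairpin_stem_beads()
        report = detect_links(beads, graph, "pierce")
        new_beads, ok = remove_links(
            beads, graph, report, UntangleParams(), np.random.default_rng(1)
        )
        assert ok
        assert check_after_refinement(new_beads, graph).is_clean()

    def test_connectivity_preserved(self):
        beads, graph, _seq, _dbn = linked_hairpin_stem_beads()
        report = detect_links(beads, graph, "pierce")
        new_beads, _ok = remove_links(
            beads, graph, report, UntangleParams(), np.random.default_rng(2)
        )
        _k0, c0 = _flatten_beads(beads)
        _k1, c1 = _flatten_beads(new_beads)
        d0 = np.linalg.norm(np.diff(c0, axis=0), axis=1)
        d1 = np.linalg.norm(np.diff(c1, axis=0), axis=1)
        assert np.all(d1 >= 0.5 * d0 - 1e-9)
        assert np.all(d1 <= 2.0 * d0 + 1e-9)


class TestCheckAfterRefinement:
    def test_idempotent_on_unmodified_fixture(self):
        beads, graph, _seq, _dbn = linked_hairpin_stem_beads()
        r1 = check_after_refinement(beads, graph)
        r2 = detect_links(beads, graph, "both")
        assert [(p.id_a, p.id_b, p.verdict) for p in r1.pairs] == [
            (p.id_a, p.id_b, p.verdict) for p in r2.pairs
        ]

    def test_methods_agree_on_random_suite(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            a, b = random_ring_pair(rng)
            L = round(gauss_linking_number(a, b))
            net_ab, _ = piercing_count(a, b)
            net_ba, _ = piercing_count(b, a)
            net = net_ab if abs(net_ab) >= abs(net_ba) else net_ba
            assert (L != 0) == (net != 0)


def test_beads_from_structure(two_stem_system):
    graph, _lib, structure = two_stem_system
    beads = beads_from_structure(structure)
    assert set(beads) == set(range(1, graph.n_residues + 1))
    assert all({"P", "S"} <= set(d) for d in beads.values())
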