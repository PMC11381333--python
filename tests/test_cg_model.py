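"""Rigid helix geometry: virtual points, assembly, closure, clashes."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cgrna.cg_model import (
    AssemblyError,
    FragmentTransform,
    HelixParams,
    StemGeometry,
    assemble_structure,
    closure_deviation,
    detect_clashes,
    element_signature,
    exact_closing_fragment,
    make_pose,
    pose_inverse,
    read_cg_pdb,
    stem_virtual_points,
    write_cg_pdb,
)
from cgrna.fixtures import toy_junction_system
from cgrna.fragments import generate_synthetic_library

from conftest import feasible_structure

PARAMS = HelixParams()


def canonical_stem(n_bp, params=PARAMS):
    return StemGeometry(
        start=np.zeros(3),
        end=np.array([0.0, 0.0, params.rise * n_bp]),
        twist_ref=np.array([1.0, 0.0, 0.0]),
        n_bp=n_bp,
    )


class TestStemVirtualPoints:
    def test_single_bp_three_points(self):
        """One base pair: 3 roles x 2 residues at the template radial
        offsets from the axis."""
        pts = stem_virtual_points(canonical_stem(1), "three_points")
        assert len(pts) == 6
        radii = {p.role: np.hypot(p.xyz[0], p.xyz[1]) for p in pts}
        assert radii["P"] == pytest.approx(PARAMS.r_backbone)
        assert radii["S"] == pytest.approx(PARAMS.r_sugar)
        assert radii["B"] == pytest.approx(PARAMS.r_base)

    def test_constant_twist_increment(self):
        """Each base pair contributes the same rotation about the axis."""
        pts = stem_virtual_points(canonical_stem(10), "three_points")
        backbone_s1 = [p.xyz for p in pts if p.role == "P" and p.residue <= 10]
        angles = [np.arctan2(p[1], p[0]) for p in backbone_s1]
        increments = np.diff(np.unwrap(angles))
        assert np.allclose(increments, PARAMS.twist, atol=1e-9)

    def test_constant_rise(self):
        pts = stem_virtual_points(canonical_stem(10), "one_point")
        z_s1 = [p.xyz[2] for p in pts if p.residue <= 10]
        assert np.allclose(np.diff(z_s1), PARAMS.rise, atol=1e-12)

    def test_one_point_count(self):
        assert len(stem_virtual_points(canonical_stem(7), "one_point")) == 14


class TestAssembly:
    def test_root_canonical_pose(self, hairpin_graph):
        lib = generate_synthetic_library([("hairpin", (3,))], 1, seed=0)
        structure = assemble_structure(
            hairpin_graph,
            {"h0": lib.entries[("hairpin", (3,))][0]},
            {"s0": 2},
        )
        geo = structure.stem_geometries["s0"]
        assert np.allclose(geo.start, 0.0)
        assert np.allclose(geo.axis, [0, 0, 1])
        assert np.allclose(geo.twist_ref, [1, 0, 0])

    def test_identity_fragment_collinear(self, two_stem_graph):
        """An interior-loop fragment with identity rotation and translation
        (0,0,t) places the second stem on the same axis, offset by t."""
        t = 7.0
        frag_i = FragmentTransform(
            np.eye(3), np.array([0.0, 0.0, t]), ("interior_loop", (2, 2))
        )
        frag_h = FragmentTransform(np.eye(3), np.zeros(3), ("hairpin", (4,)))
        structure = assemble_structure(
            two_stem_graph,
            {"i0": frag_i, "h0": frag_h},
            {"s0": 4, "s1": 4},
        )
        g0, g1 = structure.stem_geometries["s0"], structure.stem_geometries["s1"]
        # collinear: s1's axis is parallel to z, start on the z axis
        assert np.allclose(np.abs(g1.axis), [0, 0, 1])
        assert np.allclose(g1.start[:2], 0.0, atol=1e-12)
        assert g1.start[2] == pytest.approx(PARAMS.rise * 4 + t)

    def test_signature_mismatch_named(self, two_stem_graph):
        bad = FragmentTransform(np.eye(3), np.zeros(3), ("interior_loop", (1, 1)))
        frag_h = FragmentTransform(np.eye(3), np.zeros(3), ("hairpin", (4,)))
        with pytest.raises(AssemblyError, match="i0"):
            assemble_structure(
                two_stem_graph, {"i0": bad, "h0": frag_h}, {"s0": 4, "s1": 4}
            )

    def test_matrix_chain_oracle(self, two_stem_system):
        """Stem poses equal the brute-force product of the attachment and
        fragment matrices along the tree path, composed independently."""
        graph, lib, structure = two_stem_system
        params = structure.params
        # independent composition: root pose * end-frame * fragment * flip
        frag = structure.fragment_assignment["i0"].matrix
        len0 = params.rise * 4
        end_frame = make_pose(np.eye(3), np.array([0, 0, len0]))
        flip = make_pose(np.diag([1.0, -1.0, -1.0]), np.zeros(3))
        expected = np.eye(4) @ end_frame @ frag @ pose_inverse(flip)
        assert np.allclose(structure.stem_geometries["s1"].pose, expected, atol=1e-9)

    def test_point_count_identity(self, two_stem_system):
        graph, lib, structure = two_stem_system
        assert len(structure.virtual_points("three_points")) == 3 * graph.n_residues
        assert len(structure.virtual_points("one_point")) == graph.n_residues


class TestClosureDeviation:
    @pytest.fixture
    def junction_structure(self):
        graph, lib, assignment = toy_junction_system(seed=2)
        stem_params = {s.id: len(s.strands[0]) for s in graph.stems}
        structure = assemble_structure(graph, assignment, stem_params)
        broken = next(e for e in graph.elements if e.broken)
        return structure, broken

    def test_identity_cycle_zero(self, junction_structure):
        structure, broken = junction_structure
        closing = exact_closing_fragment(structure, broken.id)
        dev = closure_deviation(structure, broken.id, closing)
        assert dev.translation == pytest.approx(0.0, abs=1e-9)
        assert dev.scalar == pytest.approx(0.0, abs=1e-5)

    def test_translated_cycle(self, junction_structure):
        """Translating the recomposed pose by 3 A gives translation = 3,
        rotation = 0."""
        structure, broken = junction_structure
        closing = exact_closing_fragment(structure, broken.id)
        shifted = FragmentTransform(
            closing.rotation,
            closing.translation + np.array([3.0, 0.0, 0.0]),
            closing.signature,
        )
        dev = closure_deviation(structure, broken.id, shifted)
        assert dev.translation == pytest.approx(3.0, abs=1e-9)
        assert dev.rotation == pytest.approx(0.0, abs=1e-5)

    def test_random_fragment_matches_recomposition_oracle(self, junction_structure):
        structure, broken = junction_structure
        rng = np.random.default_rng(7)
        frag = FragmentTransform(
            Rotation.random(rng=rng).as_matrix(),
            rng.normal(size=3) * 5,
            element_signature(broken),
        )
        dev = closure_deviation(structure, broken.id, frag)
        # independent recomposition of the predicted pose
        params = structure.params
        (from_stem, side_f), (to_stem, side_t) = broken.connections
        geo_from = structure.stem_geometries[from_stem]
        geo_to = structure.stem_geometries[to_stem]
        flip = make_pose(np.diag([1.0, -1.0, -1.0]), np.zeros(3))

        def frame(geo, side):
            rel = (
                make_pose(np.eye(3), np.array([0, 0, params.rise * geo.n_bp]))
                if side == "end"
                else flip
            )
            return geo.pose @ rel

        pred = frame(geo_from, side_f) @ frag.matrix @ pose_inverse(
            flip
            if side_t == "start"
            else make_pose(np.eye(3), np.array([0, 0, params.rise * geo_to.n_bp]))
        )
        placed = geo_to.pose
        t_expected = np.linalg.norm(pred[:3, 3] - placed[:3, 3])
        assert dev.translation == pytest.approx(t_expected, abs=1e-9)
        cos = (np.trace(placed[:3, :3].T @ pred[:3, :3]) - 1) / 2
        ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
        assert dev.rotation == pytest.approx(ang, abs=1e-6)


class TestClashes:
    def test_far_apart_clean(self, two_stem_graph):
        frag_i = FragmentTransform(
            np.eye(3), np.array([0.0, 0.0, 100.0]), ("interior_loop", (2, 2))
        )
        frag_h = FragmentTransform(np.eye(3), np.zeros(3), ("hairpin", (4,)))
        structure = assemble_structure(
            two_stem_graph, {"i0": frag_i, "h0": frag_h}, {"s0": 4, "s1": 4}
        )
        # only stem-stem pairs are relevant: loops interpolate between them
        clashes = [
            c
            for c in detect_clashes(structure, 4.0)
            if {c[0].element_id, c[1].element_id} == {"s0", "s1"}
        ]
        assert clashes == []

    def test_coincident_stems_all_pairs(self, two_stem_graph):
        """Identical stem geometry: every cross-stem point pair within the
        cutoff is reported."""
        frag_i = FragmentTransform(
            np.diag([1.0, -1.0, -1.0]),
            np.array([0.0, 0.0, -PARAMS.rise * 4]),
            ("interior_loop", (2, 2)),
        )
        frag_h = FragmentTransform(np.eye(3), np.zeros(3), ("hairpin", (4,)))
        structure = assemble_structure(
            two_stem_graph, {"i0": frag_i, "h0": frag_h}, {"s0": 4, "s1": 4}
        )
        g0, g1 = structure.stem_geometries["s0"], structure.stem_geometries["s1"]
        assert np.allclose(g0.start, g1.start) and np.allclose(g0.end, g1.end)
        clashes = detect_clashes(structure, 4.0)
        assert any({c[0].element_id, c[1].element_id} == {"s0", "s1"} for c in clashes)

    def test_brute_force_oracle(self, two_stem_system):
        graph, lib, structure = two_stem_system
        cutoff = 6.0
        reported = {
            (a.residue, a.role, b.residue, b.role)
            for a, b, _ in detect_clashes(structure, cutoff)
        }
        pts = structure.virtual_points("three_points")
        adj = graph.adjacency
        expected = set()
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                a, b = pts[i], pts[j]
                if a.element_id == b.element_id:
                    continue
                if b.element_id in adj[a.element_id]:
                    continue
                if np.linalg.norm(np.asarray(a.xyz) - np.asarray(b.xyz)) < cutoff:
                    key = (a.residue, a.role, b.residue, b.role)
                    expected.add(key)
        assert reported == expected


class TestRigidMotionEquivariance:
    def test_points_and_invariants(self, two_stem_system):
        graph, lib, structure = two_stem_system
        rng = np.random.default_rng(3)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(size=3) * 20
        pose = make_pose(rot, shift)
        stem_params = {s.id: len(s.strands[0]) for s in graph.stems}
        moved = assemble_structure(
            graph, structure.fragment_assignment, stem_params, root_pose=pose
        )
        p0 = structure.point_array("three_points")
        p1 = moved.point_array("three_points")
        assert np.allclose(p1, p0 @ rot.T + shift, atol=1e-9)
        c0 = {(a.residue, a.role, b.residue, b.role) for a, b, _ in detect_clashes(structure, 5.0)}
        c1 = {(a.residue, a.role, b.residue, b.role) for a, b, _ in detect_clashes(moved, 5.0)}
        assert c0 == c1


def test_pdb_roundtrip(tmp_path, two_stem_system):
    graph, lib, structure = two_stem_system
    path = tmp_path / "cg.pdb"
    write_cg_pdb(path, structure)
    points = read_cg_pdb(path)
    assert len(points) == 3 * graph.n_residues
    orig = structure.virtual_points("three_points")
    for a, b in zip(orig, points):
        assert a.residue == b.residue and a.role == b.role
        assert np.allclose(a.xyz, b.xyz, atol=1e-3)  # PDB precision
    # byte-stable second write
    path2 = tmp_path / "cg2.pdb"
    write_cg_pdb(path2, points)
    assert path.read_bytes() == path2.read_bytes()
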