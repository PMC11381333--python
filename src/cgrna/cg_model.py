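"""Rigid helix-level coarse-grained geometry.

A stem (A-form duplex) is a rigid body parametrized by its axis, its length
in base pairs and the orientation of the minor groove at its first base pair
(``twist_ref``).  Assuming every base pair contributes equally to the helix
rotation, per-residue *virtual* points (backbone phosphate, sugar, base) are
reconstructed on the fly from this parametrization and never stored.

Loop elements (hairpins, interior loops, multiloop segments) are rigid
transforms between the attachment frames of the stems they connect; a 3D
structure is assembled by composing these transforms along the spanning tree
of the element graph rooted at one stem.  Around each closed junction the
composition of transforms must return to the starting stem: the *closure
deviation* measures how far the fragment assigned to the broken segment is
from closing the cycle exactly.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .ss_graph import ElementGraph, Junction

__all__ = [
    "HelixParams",
    "StemGeometry",
    "FragmentTransform",
    "CGStructure",
    "ClosureDeviation",
    "VirtualPoint",
    "make_pose",
    "pose_inverse",
    "rotation_angle",
    "stem_virtual_points",
    "assemble_structure",
    "closure_deviation",
    "detect_clashes",
    "element_signature",
    "write_cg_pdb",
    "read_cg_pdb",
]

_ORTHO_TOL = 1e-9


def make_pose(rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Build a 4x4 homogeneous pose from a 3x3 rotation and a 3-vector."""
    pose = np.eye(4)
    pose[:3, :3] = rotation
    pose[:3, 3] = translation
    return pose


def pose_inverse(pose: np.ndarray) -> np.ndarray:
    rot = pose[:3, :3]
    inv = np.eye(4)
    inv[:3, :3] = rot.T
    inv[:3, 3] = -rot.T @ pose[:3, 3]
    return inv


def rotation_angle(rotation: np.ndarray) -> float:
    """Angle (radians, in [0, pi]) of a proper rotation matrix."""
    cos = (np.trace(rotation) - 1.0) / 2.0
    return float(np.arccos(np.clip(cos, -1.0, 1.0)))


def _check_rotation(rotation: np.ndarray, tol: float = _ORTHO_TOL) -> None:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {rotation.shape}")
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=tol * 100):
        raise ValueError("rotation matrix is not orthonormal")
    if not np.isclose(np.linalg.det(rotation), 1.0, atol=tol * 100):
        raise ValueError("rotation matrix is not proper (det != 1)")


@dataclass(frozen=True)
class HelixParams:
    """A-form helix constants and coarse-grained point offsets (Angstrom).

    ``twist_deg``/``rise`` set the per-base-pair helical step; the radial
    offsets place the backbone (P), sugar (C1' proxy) and base virtual
    points away from the helix axis.  ``strand_angle_deg`` is the angular
    offset of the second strand's residue around the axis, which fixes the
    width of the grooves.  ``loop_spacing`` is the per-residue spacing used
    for terminal single strands.
    """

    twist_deg: float = 32.7
    rise: float = 2.81
    r_backbone: float = 9.4
    r_sugar: float = 8.5
    r_base: float = 4.0
    strand_angle_deg: float = 150.0
    loop_spacing: float = 5.9

    @property
    def twist(self) -> float:
        return np.deg2rad(self.twist_deg)

    @property
    def strand_angle(self) -> float:
        return np.deg2rad(self.strand_angle_deg)


@dataclass(frozen=True)
class StemGeometry:
    """Rigid placement of one stem: axis endpoints + minor-groove reference.

    ``start`` is the axis point at the outer (5' of strand 1) face, ``end``
    the exit point past the last base pair; ``twist_ref`` is a unit vector
    orthogonal to the axis giving the groove orientation at ``start``.
    """

    start: np.ndarray
    end: np.ndarray
    twist_ref: np.ndarray
    n_bp: int

    def __post_init__(self):
        start = np.asarray(self.start, dtype=float)
        end = np.asarray(self.end, dtype=float)
        twist_ref = np.asarray(self.twist_ref, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        object.__setattr__(self, "twist_ref", twist_ref)
        if np.linalg.norm(end - start) <= 0:
            raise ValueError("stem has zero length: |end - start| must be > 0")
        if abs(np.linalg.norm(twist_ref) - 1.0) > 1e-6:
            raise ValueError("twist_ref must be a unit vector")
        axis = (end - start) / np.linalg.norm(end - start)
        if abs(np.dot(axis, twist_ref)) > 1e-6:
            raise ValueError("twist_ref must be orthogonal to the stem axis")

    @property
    def axis(self) -> np.ndarray:
        d = self.end - self.start
        return d / np.linalg.norm(d)

    @property
    def pose(self) -> np.ndarray:
        """4x4 pose: x = twist_ref, z = axis, origin = start."""
        z = self.axis
        x = self.twist_ref
        y = np.cross(z, x)
        return make_pose(np.column_stack([x, y, z]), self.start)

    @classmethod
    def from_pose(cls, pose: np.ndarray, n_bp: int, params: HelixParams) -> "StemGeometry":
        start = pose[:3, 3].copy()
        axis = pose[:3, 2]
        return cls(
            start=start,
            end=start + axis * params.rise * n_bp,
            twist_ref=pose[:3, 0].copy(),
            n_bp=n_bp,
        )


@dataclass(frozen=True)
class FragmentTransform:
    """Rigid transform carried by a loop fragment.

    Maps the attachment frame of the 5' stem to the attachment frame of the
    3' stem of the element the fragment is assigned to.  ``signature`` keys
    the fragment to compatible elements: (element kind, per-strand
    unpaired-length tuple).
    """

    rotation: np.ndarray
    translation: np.ndarray
    signature: tuple
    source_id: str = ""

    def __post_init__(self):
        rotation = np.asarray(self.rotation, dtype=float)
        translation = np.asarray(self.translation, dtype=float)
        _check_rotation(rotation)
        object.__setattr__(self, "rotation", rotation)
        object.__setattr__(self, "translation", translation)
        sig = (self.signature[0], tuple(self.signature[1]))
        object.__setattr__(self, "signature", sig)

    @property
    def matrix(self) -> np.ndarray:
        return make_pose(self.rotation, self.translation)


@dataclass(frozen=True)
class ClosureDeviation:
    """Mismatch between a stem's placed pose and its pose recomputed around
    a junction cycle: translation (Angstrom), rotation (degrees) and the
    combined scalar translation + w * rotation_in_radians."""

    translation: float
    rotation: float
    scalar: float


Closure_W_DEFAULT = 10.0  # Angstrom per radian in the combined scalar

VirtualPoint = namedtuple("VirtualPoint", ["element_id", "residue", "role", "xyz"])


def element_signature(element) -> tuple:
    """(kind, per-strand unpaired-length tuple) fragment key of an element."""
    return (element.kind, tuple(len(s) for s in element.strands))


@dataclass
class CGStructure:
    """Assembled coarse-grained structure: element graph + rigid placement."""

    graph: ElementGraph
    stem_geometries: dict[str, StemGeometry]
    fragment_assignment: dict[str, FragmentTransform]
    params: HelixParams = field(default_factory=HelixParams)
    closure_weight: float = Closure_W_DEFAULT

    def virtual_points(self, mode: str = "three_points") -> list[VirtualPoint]:
        return structure_virtual_points(self, mode)

    def point_array(self, mode: str = "three_points") -> np.ndarray:
        pts = self.virtual_points(mode)
        return np.array([p.xyz for p in pts])


# ---------------------------------------------------------------------------
# Virtual points

_ROLE_RADII = {"P": "r_backbone", "S": "r_sugar", "B": "r_base"}


def stem_virtual_points(
    stem: StemGeometry,
    mode: str = "three_points",
    params: HelixParams | None = None,
    strands: tuple | None = None,
) -> list[VirtualPoint]:
    """Per-residue virtual points of one stem.

    Base pair ``k`` sits at axial offset ``rise * (k + 1/2)`` and its frame
    is rotated by ``k * twist`` about the axis relative to ``twist_ref``;
    every base pair therefore contributes the same rotation increment.
    ``strands`` optionally supplies the (strand1, strand2) residue index
    lists; defaults to 1..n and 2n..n+1.
    """
    params = params or HelixParams()
    if mode not in ("one_point", "three_points"):
        raise ValueError(f"unknown mode {mode!r}")
    n = stem.n_bp
    if strands is None:
        strands = (tuple(range(1, n + 1)), tuple(range(n + 1, 2 * n + 1)))
    s1, s2 = strands
    pose = stem.pose
    x, y, z = pose[:3, 0], pose[:3, 1], pose[:3, 2]
    roles = ("P", "S", "B") if mode == "three_points" else ("S",)
    out: list[VirtualPoint] = []
    for k in range(n):
        center = stem.start + z * params.rise * (k + 0.5)
        for strand_idx, res in ((0, s1[k]), (1, s2[n - 1 - k])):
            theta = k * params.twist + (params.strand_angle if strand_idx else 0.0)
            u = np.cos(theta) * x + np.sin(theta) * y
            for role in roles:
                r = getattr(params, _ROLE_RADII[role])
                out.append(VirtualPoint("", res, role, center + r * u))
    return out


def _stem_anchor_points(structure: CGStructure) -> dict[int, np.ndarray]:
    """Backbone virtual point of every paired residue (loop anchors)."""
    anchors: dict[int, np.ndarray] = {}
    for stem in structure.graph.stems:
        geo = structure.stem_geometries[stem.id]
        for vp in stem_virtual_points(geo, "three_points", structure.params, stem.strands):
            if vp.role == "P":
                anchors[vp.residue] = vp.xyz
    return anchors


def _loop_strand_points(
    structure: CGStructure,
    element,
    strand: tuple,
    anchors: dict[int, np.ndarray],
    mode: str,
) -> list[VirtualPoint]:
    """Straight-line interpolation of loop residues between their flanking
    paired anchors; terminal strands extend outward from their one anchor."""
    if not strand:
        return []
    params = structure.params
    first, last = strand[0], strand[-1]
    a = anchors.get(first - 1)
    b = anchors.get(last + 1)
    m = len(strand)
    if a is None and b is None:  # no paired neighbors: degenerate, skip
        return []
    if a is None:  # 5' terminal strand: extend backwards from b
        stem_id, side = element.connections[0]
        geo = structure.stem_geometries[stem_id]
        out_dir = -geo.axis if side == "start" else geo.axis
        positions = [b + out_dir * params.loop_spacing * (m - i) for i in range(m)]
    elif b is None:  # 3' terminal strand: extend forwards from a
        stem_id, side = element.connections[0]
        geo = structure.stem_geometries[stem_id]
        out_dir = -geo.axis if side == "start" else geo.axis
        positions = [a + out_dir * params.loop_spacing * (i + 1) for i in range(m)]
    else:
        positions = [a + (b - a) * (i + 1) / (m + 1) for i in range(m)]

    # Deterministic lateral direction for sugar/base offsets: component of
    # the first connected stem's twist_ref orthogonal to the strand direction.
    stem_id, _side = element.connections[0]
    geo = structure.stem_geometries[stem_id]
    d = (positions[-1] - positions[0]) if m > 1 else geo.axis
    nd = np.linalg.norm(d)
    d = d / nd if nd > 1e-9 else geo.axis
    u = geo.twist_ref - np.dot(geo.twist_ref, d) * d
    nu = np.linalg.norm(u)
    u = u / nu if nu > 1e-9 else np.cross(d, geo.axis)

    out: list[VirtualPoint] = []
    for res, pos in zip(strand, positions):
        if mode == "one_point":
            out.append(VirtualPoint(element.id, res, "S", pos))
        else:
            out.append(VirtualPoint(element.id, res, "P", pos))
            out.append(VirtualPoint(element.id, res, "S", pos + 1.0 * u))
            out.append(VirtualPoint(element.id, res, "B", pos + 2.5 * u))
    return out


def structure_virtual_points(structure: CGStructure, mode: str = "three_points") -> list[VirtualPoint]:
    """All virtual points of the assembled structure, ordered by residue.

    ``three_points`` emits exactly 3 points (P, S, B) per residue over the
    whole molecule; ``one_point`` emits 1 (the sugar / C1' proxy).
    """
    if mode not in ("one_point", "three_points"):
        raise ValueError(f"unknown mode {mode!r}")
    out: list[VirtualPoint] = []
    anchors = _stem_anchor_points(structure)
    for element in structure.graph.elements:
        if element.kind == "stem":
            geo = structure.stem_geometries[element.id]
            for vp in stem_virtual_points(geo, mode, structure.params, element.strands):
                out.append(VirtualPoint(element.id, vp.residue, vp.role, vp.xyz))
        else:
            for strand in element.strands:
                out.extend(_loop_strand_points(structure, element, strand, anchors, mode))
    out.sort(key=lambda p: (p.residue, "PSB".index(p.role)))
    return out


# ---------------------------------------------------------------------------
# Assembly

_FLIP = np.diag([1.0, -1.0, -1.0])  # 180 degrees about x: reverses the axis


def _attachment_frame_rel(side: str, stem_len: float) -> np.ndarray:
    """Attachment frame of a stem side, relative to the stem pose.

    The frame's +z points outward, away from the stem body: at the ``end``
    side it is translated to the stem exit point; at the ``start`` side it
    is flipped about x so +z = -axis.
    """
    if side == "end":
        return make_pose(np.eye(3), np.array([0.0, 0.0, stem_len]))
    if side == "start":
        return make_pose(_FLIP, np.zeros(3))
    raise ValueError(f"unknown side {side!r}")


def _attachment_frame(structure_or_pose, geo: StemGeometry, side: str, params: HelixParams) -> np.ndarray:
    return geo.pose @ _attachment_frame_rel(side, params.rise * geo.n_bp)


class AssemblyError(ValueError):
    pass


def assemble_structure(
    graph: ElementGraph,
    assignment: dict[str, FragmentTransform],
    stem_params: dict[str, int],
    root_stem: str | None = None,
    params: HelixParams | None = None,
    root_pose: np.ndarray | None = None,
    closure_weight: float = Closure_W_DEFAULT,
) -> CGStructure:
    """Place every stem by composing fragment transforms along the spanning
    tree of the element graph (broken segments excluded).

    The root stem sits at the canonical pose (start at the origin, axis +z,
    twist_ref +x) unless ``root_pose`` overrides it.  Raises
    :class:`AssemblyError` when an assigned fragment's signature does not
    match its element, or a required assignment is missing.
    """
    params = params or HelixParams()
    stems = [e.id for e in graph.stems]
    if not stems:
        raise AssemblyError("graph has no stems")
    root = root_stem or stems[0]
    if root not in stem_params:
        raise AssemblyError(f"no n_bp given for root stem {root}")

    for element in graph.elements:
        if element.kind == "stem" or element.broken:
            continue
        frag = assignment.get(element.id)
        if frag is None:
            raise AssemblyError(f"no fragment assigned to element {element.id}")
        if frag.signature != element_signature(element):
            raise AssemblyError(
                f"fragment signature {frag.signature} does not match element "
                f"{element.id} with signature {element_signature(element)}"
            )

    poses: dict[str, np.ndarray] = {root: root_pose.copy() if root_pose is not None else np.eye(4)}
    geometries: dict[str, StemGeometry] = {
        root: StemGeometry.from_pose(poses[root], stem_params[root], params)
    }

    # BFS over connector elements (non-broken, two attachment points).
    stack = [root]
    while stack:
        a = stack.pop()
        geo_a = geometries[a]
        for loop_id in graph.adjacency[a]:
            loop = graph.element(loop_id)
            if loop.kind == "stem" or loop.broken or len(loop.connections) != 2:
                continue
            (from_stem, side_f), (to_stem, side_t) = loop.connections
            b = to_stem if from_stem == a else from_stem
            if b in poses:
                continue
            frag = assignment[loop_id].matrix
            len_b = params.rise * stem_params[b]
            if from_stem == a:
                f_a = _attachment_frame(None, geo_a, side_f, params)
                pose_b = f_a @ frag @ pose_inverse(_attachment_frame_rel(side_t, len_b))
            else:
                f_a = _attachment_frame(None, geo_a, side_t, params)
                pose_b = f_a @ pose_inverse(frag) @ pose_inverse(
                    _attachment_frame_rel(side_f, len_b)
                )
            poses[b] = pose_b
            geometries[b] = StemGeometry.from_pose(pose_b, stem_params[b], params)
            stack.append(b)

    missing = set(stems) - set(geometries)
    if missing:
        raise AssemblyError(f"stems not reachable from root: {sorted(missing)}")

    return CGStructure(
        graph=graph,
        stem_geometries=geometries,
        fragment_assignment=dict(assignment),
        params=params,
        closure_weight=closure_weight,
    )


# ---------------------------------------------------------------------------
# Multiloop closure

def _find_junction(graph: ElementGraph, multiloop_id: str) -> Junction:
    for junction in graph.junctions:
        if multiloop_id in junction.segments:
            return junction
    raise KeyError(f"no closed junction contains segment {multiloop_id!r}")


def closure_deviation(
    structure: CGStructure,
    multiloop_id: str,
    broken_fragment: FragmentTransform,
) -> ClosureDeviation:
    """Deviation between a junction stem's placed pose and the pose implied
    by closing the junction cycle through ``broken_fragment``.

    All junction stems except the one across the broken segment are placed
    by the spanning tree; composing the broken fragment from the placed 5'
    stem therefore recomputes the pose of the stem reached by going the rest
    of the way around the junction.  A zero deviation means the cycle of
    transforms composes exactly to the identity.
    """
    graph = structure.graph
    junction = _find_junction(graph, multiloop_id)
    broken = [s for s in junction.segments if graph.element(s).broken]
    if not broken:
        raise KeyError(f"junction of {multiloop_id!r} has no broken segment")
    seg = graph.element(broken[0])
    if broken_fragment.signature != element_signature(seg):
        raise AssemblyError(
            f"fragment signature {broken_fragment.signature} does not match "
            f"broken segment {seg.id} with signature {element_signature(seg)}"
        )
    (from_stem, side_f), (to_stem, side_t) = seg.connections
    params = structure.params
    geo_from = structure.stem_geometries[from_stem]
    geo_to = structure.stem_geometries[to_stem]
    len_to = params.rise * geo_to.n_bp
    f_from = _attachment_frame(None, geo_from, side_f, params)
    pred = f_from @ broken_fragment.matrix @ pose_inverse(
        _attachment_frame_rel(side_t, len_to)
    )
    placed = geo_to.pose
    delta_t = float(np.linalg.norm(pred[:3, 3] - placed[:3, 3]))
    ang = rotation_angle(placed[:3, :3].T @ pred[:3, :3])
    scalar = delta_t + structure.closure_weight * ang
    return ClosureDeviation(
        translation=delta_t, rotation=float(np.rad2deg(ang)), scalar=float(scalar)
    )


def exact_closing_fragment(structure: CGStructure, multiloop_id: str) -> FragmentTransform:
    """The fragment that would close a junction's broken segment exactly
    (zero closure deviation) given the current stem placement."""
    graph = structure.graph
    junction = _find_junction(graph, multiloop_id)
    seg = next(
        graph.element(s) for s in junction.segments if graph.element(s).broken
    )
    (from_stem, side_f), (to_stem, side_t) = seg.connections
    params = structure.params
    geo_from = structure.stem_geometries[from_stem]
    geo_to = structure.stem_geometries[to_stem]
    f_from = _attachment_frame(None, geo_from, side_f, params)
    frag_mat = (
        pose_inverse(f_from)
        @ geo_to.pose
        @ _attachment_frame_rel(side_t, params.rise * geo_to.n_bp)
    )
    return FragmentTransform(
        rotation=frag_mat[:3, :3],
        translation=frag_mat[:3, 3],
        signature=element_signature(seg),
        source_id="planted-closure",
    )


# ---------------------------------------------------------------------------
# Clash detection

def detect_clashes(
    structure: CGStructure,
    cutoff: float = 4.0,
    mode: str = "three_points",
) -> list[tuple[VirtualPoint, VirtualPoint, float]]:
    """All pairs of virtual points from non-adjacent elements closer than
    ``cutoff``.  Elements adjacent in the element graph (a loop and its
    flanking stems) are exempt, as are within-element pairs.  An empty list
    means the structure is clash-free."""
    points = structure.virtual_points(mode)
    if not points:
        return []
    xyz = np.array([p.xyz for p in points])
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    adj = structure.graph.adjacency
    out = []
    for ia, ib in pairs:
        pa, pb = points[ia], points[ib]
        if pa.element_id == pb.element_id:
            continue
        if pb.element_id in adj.get(pa.element_id, ()):
            continue
        dist = float(np.linalg.norm(np.asarray(pa.xyz) - np.asarray(pb.xyz)))
        if dist < cutoff:
            out.append((pa, pb, dist))
    return out


# ---------------------------------------------------------------------------
# PDB I/O (one pseudo-atom per virtual point)

def write_cg_pdb(path, structure_or_points, mode: str = "three_points") -> None:
    """Write virtual points as a pseudo-atom PDB (names P/S/B, chain A)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    if isinstance(structure_or_points, CGStructure):
        points = structure_or_points.virtual_points(mode)
    else:
        points = list(structure_or_points)
    arr = struc.AtomArray(len(points))
    arr.coord = np.array([p.xyz for p in points])
    arr.chain_id = np.array(["A"] * len(points))
    arr.res_id = np.array([p.residue for p in points])
    arr.res_name = np.array(["N"] * len(points))
    arr.atom_name = np.array([p.role for p in points])
    arr.element = np.array(["P" if p.role == "P" else "C" for p in points])
    arr.hetero = np.array([True] * len(points))
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def read_cg_pdb(path) -> list[VirtualPoint]:
    """Read pseudo-atom PDB back into virtual points (element ids unset)."""
    import biotite.structure.io.pdb as pdb

    arr = pdb.PDBFile.read(str(path)).get_structure(model=1)
    return [
        VirtualPoint("", int(arr.res_id[i]), str(arr.atom_name[i]), arr.coord[i].astype(float))
        for i in range(arr.array_length())
    ]
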