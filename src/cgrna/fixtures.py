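"""Seeded synthetic fixtures.

Every study input used by the tests and the command-line pipeline is
generated here programmatically: topological test cases built from bead
geometry (Hopf-linked rings, a stem threaded through a hairpin, an
interpenetrating pair with zero net crossings), a three-way junction with a
planted closing fragment, and a two-stem sampling system whose target PDD
is computed from a planted fragment assignment.  All cases are bitwise
reproducible for a given seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .cg_model import (
    HelixParams,
    assemble_structure,
    detect_clashes,
    element_signature,
    exact_closing_fragment,
    write_cg_pdb,
    VirtualPoint,
)
from .fragments import (
    FragmentLibrary,
    generate_synthetic_library,
    lookup_fragments,
    save_library,
)
from .pdd import compute_pdd, extract_points, write_pdd
from .ss_graph import parse_dotbracket, write_dbn
from .topology import Ring

__all__ = [
    "FixtureSpec",
    "circle_ring",
    "hopf_rings",
    "unlinked_rings",
    "double_wound_rings",
    "random_ring_pair",
    "linked_hairpin_stem_beads",
    "interpenetrating_beads",
    "toy_junction_system",
    "planted_sampling_system",
    "generate_fixture",
    "CASES",
]

CASES = (
    "hopf",
    "unlinked_rings",
    "linked_hairpin_stem",
    "interpenetrating_pair",
    "toy_junction",
    "planted_sampling",
    "synthetic_library",
)


@dataclass(frozen=True)
class FixtureSpec:
    case: str
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.case not in CASES:
            raise ValueError(f"unknown fixture case {self.case!r}; choose from {CASES}")


# ---------------------------------------------------------------------------
# Ring-level topology cases

def circle_ring(
    ring_id: str,
    center,
    normal,
    radius: float = 10.0,
    n: int = 64,
    phase: float = 0.0,
    kind: str = "hairpin",
) -> Ring:
    """Regular n-gon ring in the plane orthogonal to ``normal``."""
    center = np.asarray(center, float)
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    # deterministic in-plane basis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, normal)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    angles = phase + 2 * np.pi * np.arange(n) / n
    verts = center + radius * (
        np.cos(angles)[:, None] * u + np.sin(angles)[:, None] * v
    )
    return Ring(ring_id, verts, kind)


def hopf_rings(radius: float = 10.0, n: int = 64) -> tuple[Ring, Ring]:
    """Canonical Hopf link: two orthogonal circles through each other's
    centers; |L| = 1."""
    # small phases break the exact vertex/centroid coincidences of the
    # perfectly symmetric configuration without changing the topology
    a = circle_ring("ring_a", (0, 0, 0), (0, 0, 1), radius, n, phase=0.21)
    b = circle_ring("ring_b", (radius, 0, 0), (0, 1, 0), radius, n, phase=0.37)
    return a, b


def unlinked_rings(separation: float = 50.0, radius: float = 1.0, n: int = 64) -> tuple[Ring, Ring]:
    """Two separated coplanar rings; L = 0."""
    a = circle_ring("ring_a", (0, 0, 0), (0, 0, 1), radius, n)
    b = circle_ring("ring_b", (separation, 0, 0), (0, 0, 1), radius, n)
    return a, b


def double_wound_rings(radius: float = 10.0, n: int = 128) -> tuple[Ring, Ring]:
    """A closed curve winding twice through a circle; |L| = 2.

    The second curve is a (2, 1) torus-style loop around a section of the
    first ring's tube: it passes through the circle's disk twice in the
    same direction.
    """
    a = circle_ring("ring_a", (0, 0, 0), (0, 0, 1), radius, n)
    # curve b: winds twice through the disk of a, around the ring tube near
    # the point (radius, 0, 0); parametrize a double loop in the xz-plane
    # around that point, with a slow drift in y to keep it a simple closed
    # curve.
    t = 2 * np.pi * np.arange(n) / n
    r_tube = 3.0
    verts = np.column_stack(
        [
            radius + r_tube * np.cos(2 * t),
            0.8 * np.sin(t),
            r_tube * np.sin(2 * t),
        ]
    )
    b = Ring("ring_b", verts, "stem")
    return a, b


def random_ring_pair(
    rng: np.random.Generator,
    n: int = 32,
    radius_range: tuple[float, float] = (4.0, 12.0),
    box: float = 12.0,
    min_separation: float = 0.5,
    max_tries: int = 200,
) -> tuple[Ring, Ring]:
    """Two random circular rings with all cross vertices farther apart than
    ``min_separation``; linked with appreciable probability."""
    for _ in range(max_tries):
        rings = []
        for idx in range(2):
            center = rng.uniform(-box / 2, box / 2, size=3) if idx else np.zeros(3)
            normal = rng.normal(size=3)
            radius = rng.uniform(*radius_range)
            phase = rng.uniform(0, 2 * np.pi)
            rings.append(
                circle_ring(f"ring_{'ab'[idx]}", center, normal, radius, n, phase)
            )
        a, b = rings
        dmin = np.min(
            np.linalg.norm(a.vertices[:, None, :] - b.vertices[None, :, :], axis=-1)
        )
        if dmin > min_separation:
            return a, b
    raise RuntimeError("could not generate a separated ring pair")


# ---------------------------------------------------------------------------
# Bead-level graph cases

_LINKED_DBN = ("GGAAACCAGGAAACC", "((...)).((...))")


def _place_on_circle(beads, residues, center, normal, radius, phase=0.0):
    ring = circle_ring("tmp", center, normal, radius, 2 * len(residues), phase)
    k = 0
    for res in residues:
        beads.setdefault(res, {})["P"] = ring.vertices[k]
        beads[res]["S"] = ring.vertices[k + 1]
        k += 2


def linked_hairpin_stem_beads() -> tuple[dict, object, str, str]:
    """A stem threaded through a hairpin ring (a genuine link, |L| = 1).

    Returns (beads, graph, sequence, structure).  Hairpin h0's ring is a
    circle of radius 8 in the xy-plane at the origin; stem s1's ring is an
    elongated rectangle along z passing through the circle's center.
    """
    seq, dbn = _LINKED_DBN
    graph = parse_dotbracket(seq, dbn)
    beads: dict[int, dict[str, np.ndarray]] = {}
    # h0 ring: residues 2..6 (closing pair 2,6 + loop 3,4,5) on a circle
    _place_on_circle(beads, [2, 3, 4, 5, 6], (0, 0, 0), (0, 0, 1), 8.0, phase=0.3)
    # s0 outer residues 1,7 just outside the circle, hugging residues 2,6
    outer = circle_ring("tmp", (0, 0, 0), (0, 0, 1), 10.4, n=10, phase=0.3)
    beads[1] = {"P": outer.vertices[0], "S": outer.vertices[1]}
    beads[7] = {"P": outer.vertices[8], "S": outer.vertices[9]}
    # m0 (residue 8) on the way towards the stem
    beads[8] = {"P": np.array([12.0, -4.0, 6.0]), "S": np.array([11.0, -4.5, 7.0])}
    # s1 ring: one strand down through the hairpin disk near its center,
    # the other strand back up OUTSIDE the circle: a genuine link
    beads[9] = {"P": np.array([0.0, 0.3, 9.0]), "S": np.array([0.0, 0.3, 5.0])}
    beads[10] = {"P": np.array([0.0, 0.3, 1.0]), "S": np.array([0.0, 0.3, -3.0])}
    beads[14] = {"P": np.array([12.0, -0.3, -3.0]), "S": np.array([12.0, -0.3, 1.0])}
    beads[15] = {"P": np.array([12.0, -0.3, 5.0]), "S": np.array([12.0, -0.3, 9.0])}
    # h1 loop (11,12,13) below the stem, far from the hairpin circle
    _place_on_circle(beads, [11, 12, 13], (6.0, 0, -8.0), (0, 0, 1), 3.0)
    return beads, graph, seq, dbn


def interpenetrating_beads() -> tuple[dict, object, str, str]:
    """A stem dipping twice through a hairpin's surface with opposite
    crossing directions: gross piercings > 0 but net = 0 and L = 0 — seen
    by the piercing detector only."""
    seq, dbn = _LINKED_DBN
    graph = parse_dotbracket(seq, dbn)
    beads: dict[int, dict[str, np.ndarray]] = {}
    _place_on_circle(beads, [2, 3, 4, 5, 6], (0, 0, 0), (0, 0, 1), 8.0, phase=0.3)
    beads[1] = {"P": np.array([10.0, 1.0, 0.0]), "S": np.array([10.5, 0.2, 0.0])}
    beads[7] = {"P": np.array([10.0, -1.0, 0.0]), "S": np.array([10.5, -2.0, 0.0])}
    beads[8] = {"P": np.array([12.0, -4.0, 6.0]), "S": np.array([11.0, -4.5, 7.0])}
    # U-shaped stem ring in the xz-plane: down at x=2.5, up at x=5.0 — both
    # crossings of the hairpin disk, with opposite signs
    beads[9] = {"P": np.array([2.5, 0.4, 7.0]), "S": np.array([2.5, 0.4, 3.0])}
    beads[10] = {"P": np.array([2.5, 0.4, -1.0]), "S": np.array([2.5, 0.4, -5.0])}
    beads[14] = {"P": np.array([5.0, 0.4, -5.0]), "S": np.array([5.0, 0.4, -1.0])}
    beads[15] = {"P": np.array([5.0, 0.4, 3.0]), "S": np.array([5.0, 0.4, 7.0])}
    _place_on_circle(beads, [11, 12, 13], (3.75, 0.4, -9.0), (0, 0, 1), 2.0)
    return beads, graph, seq, dbn


# ---------------------------------------------------------------------------
# Sampling systems

_JUNCTION_DBN = ("GGAAGGAAACCAAGGAAACCAACC", "((..((...))..((...))..))")
_TWO_STEM_DBN = ("GGGGAAGGGGAAAACCCCAACCCC", "((((..((((....))))..))))")


def toy_junction_system(seed: int = 0, n_decoys: int = 8):
    """Three-way junction with a planted, exactly closing fragment.

    Returns (graph, library, planted_assignment).  The two sampled junction
    segments get library fragments; the broken segment's exactly closing
    fragment is computed from the resulting stem placement and planted into
    the library among random decoys.
    """
    seq, dbn = _JUNCTION_DBN
    graph = parse_dotbracket(seq, dbn)
    sigs = sorted(
        {element_signature(e) for e in graph.elements if e.kind != "stem"}
    )
    lib = generate_synthetic_library(sigs, n_decoys, seed=seed)
    stem_params = {s.id: len(s.strands[0]) for s in graph.stems}
    rng = np.random.default_rng(seed + 1)
    movable = [e for e in graph.elements if e.kind != "stem" and not e.broken]
    broken = next(e for e in graph.elements if e.broken)
    for _ in range(500):
        assignment = {
            e.id: lookup_fragments(lib, element_signature(e))[
                rng.integers(n_decoys)
            ]
            for e in movable
        }
        structure = assemble_structure(graph, assignment, stem_params)
        if not detect_clashes(structure, 4.0):
            break
    closing = exact_closing_fragment(structure, broken.id)
    lib.add(closing)
    assignment[broken.id] = closing
    return graph, lib, assignment


def planted_sampling_system(seed: int = 0, n_decoys: int = 12):
    """Two stems joined by an interior loop; the target PDD is computed
    from a planted library fragment.

    Returns (graph, library, planted_structure, target).  Every library
    entry is a candidate; the planted one is simply a designated member
    whose assembled structure generates the target curve.
    """
    seq, dbn = _TWO_STEM_DBN
    graph = parse_dotbracket(seq, dbn)
    sigs = sorted(
        {element_signature(e) for e in graph.elements if e.kind != "stem"}
    )
    lib = generate_synthetic_library(sigs, n_decoys, seed=seed)
    stem_params = {s.id: len(s.strands[0]) for s in graph.stems}
    interior = next(e for e in graph.elements if e.kind == "interior_loop")
    hairpin = next(e for e in graph.elements if e.kind == "hairpin")
    hp_frag = lookup_fragments(lib, element_signature(hairpin))[0]
    planted_structure = None
    for frag in lookup_fragments(lib, element_signature(interior)):
        assignment = {interior.id: frag, hairpin.id: hp_frag}
        structure = assemble_structure(graph, assignment, stem_params)
        if not detect_clashes(structure, 4.0):
            planted_structure = structure
            break
    if planted_structure is None:
        raise RuntimeError("no clash-free planted assignment found")
    points = extract_points(planted_structure, "three_points")
    target = compute_pdd(points, bin_width=1.0)
    return graph, lib, planted_structure, target


def interstem_distance(structure) -> float:
    """Distance between the two stems' axis midpoints (recovery metric)."""
    geos = list(structure.stem_geometries.values())
    mids = [0.5 * (g.start + g.end) for g in geos]
    return float(np.linalg.norm(mids[0] - mids[1]))


# ---------------------------------------------------------------------------
# File emission

def _beads_to_points(beads) -> list[VirtualPoint]:
    pts = []
    for res in sorted(beads):
        for role in ("P", "S"):
            if role in beads[res]:
                pts.append(VirtualPoint("", res, role, np.asarray(beads[res][role])))
    return pts


def _rings_to_beads(*rings: Ring) -> tuple[dict, object, str, str]:
    """Embed standalone rings as consecutive hairpins of a synthetic graph
    so they can round-trip through the PDB + dbn file interface."""
    seqs, dbns, beads = [], [], {}
    offset = 0
    for ring in rings:
        n_res = len(ring.vertices) // 2
        # hairpin of n_res residues: closing pair + loop
        loop = n_res - 2
        seqs.append("G" + "A" * loop + "C")
        dbns.append("(" + "." * loop + ")")
        residues = list(range(offset + 1, offset + n_res + 1))
        for k, res in enumerate(residues):
            beads[res] = {
                "P": ring.vertices[2 * k],
                "S": ring.vertices[2 * k + 1],
            }
        offset += n_res
        # linker residue between rings
    seq = "A".join(seqs)
    dbn = ".".join(dbns)
    # place linker beads midway between ring centroids
    graph = parse_dotbracket(seq, dbn)
    res_set = {r for r in beads}
    centers = [r.centroid for r in rings]
    mid = np.mean(centers, axis=0) + np.array([0.0, 0.0, 60.0])
    next_linker = 0
    for r in range(1, len(seq) + 1):
        if r not in res_set:
            beads[r] = {
                "P": mid + np.array([2.0 * next_linker, 0, 0]),
                "S": mid + np.array([2.0 * next_linker + 1.0, 0, 0]),
            }
            next_linker += 1
    return beads, graph, seq, dbn


def generate_fixture(spec: FixtureSpec, out_dir) -> dict:
    """Write a fixture case to disk; returns the manifest dictionary.

    Emits self-describing files (.dbn, CG-PDB beads, library JSON, target
    PDD, as applicable to the case) plus ``manifest.json`` recording the
    case, seed and parameters.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest = {"case": spec.case, "seed": spec.seed, "params": dict(spec.params)}
    files: dict[str, str] = {}

    def path(name):
        files[name] = name
        return os.path.join(out_dir, name)

    if spec.case in ("hopf", "unlinked_rings"):
        rings = hopf_rings() if spec.case == "hopf" else unlinked_rings(radius=10.0)
        beads, graph, seq, dbn = _rings_to_beads(*rings)
        write_dbn(path("structure.dbn"), seq, dbn, name=spec.case)
        write_cg_pdb(path("beads.pdb"), _beads_to_points(beads))
    elif spec.case == "linked_hairpin_stem":
        beads, graph, seq, dbn = linked_hairpin_stem_beads()
        write_dbn(path("structure.dbn"), seq, dbn, name=spec.case)
        write_cg_pdb(path("beads.pdb"), _beads_to_points(beads))
    elif spec.case == "interpenetrating_pair":
        beads, graph, seq, dbn = interpenetrating_beads()
        write_dbn(path("structure.dbn"), seq, dbn, name=spec.case)
        write_cg_pdb(path("beads.pdb"), _beads_to_points(beads))
    elif spec.case == "toy_junction":
        graph, lib, assignment = toy_junction_system(spec.seed)
        seq, dbn = _JUNCTION_DBN
        write_dbn(path("structure.dbn"), seq, dbn, name=spec.case)
        save_library(path("library.json"), lib)
    elif spec.case == "planted_sampling":
        graph, lib, planted, target = planted_sampling_system(spec.seed)
        seq, dbn = _TWO_STEM_DBN
        write_dbn(path("structure.dbn"), seq, dbn, name=spec.case)
        save_library(path("library.json"), lib)
        write_pdd(path("target.pdd"), target, comment="planted-structure PDD")
        write_cg_pdb(path("planted.pdb"), planted)
        manifest["planted_interstem_distance"] = interstem_distance(planted)
    elif spec.case == "synthetic_library":
        sigs = spec.params.get(
            "signatures", [("interior_loop", (2, 2)), ("hairpin", (4,))]
        )
        n = spec.params.get("n_per_signature", 10)
        lib = generate_synthetic_library(
            [(s[0], tuple(s[1])) for s in sigs], n, seed=spec.seed
        )
        save_library(path("library.json"), lib)

    manifest["files"] = files
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
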