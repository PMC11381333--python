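"""Secondary-structure element graph.

Parses dot-bracket notation into the coarse-grained element decomposition
used throughout the package: stems (helical duplexes), hairpin loops,
interior loops (including bulges), multiloop segments (junction strands and
exterior-loop strands between top-level stems) and 5'/3' terminal strands.

Each closed multiloop (junction) carries exactly one *broken* segment: once
every other strand of the junction has been assigned a 3D fragment, the
broken strand has no remaining degrees of freedom and its fragment is fitted
rather than sampled.  Residue numbering is 1-based, single chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

__all__ = [
    "Element",
    "Junction",
    "ElementGraph",
    "ParseError",
    "PseudoknotError",
    "parse_dotbracket",
    "assign_broken_segments",
    "element_residues",
    "to_dotbracket",
    "read_dbn",
    "write_dbn",
    "graph_to_json",
    "graph_from_json",
]

KINDS = (
    "stem",
    "hairpin",
    "interior_loop",
    "multiloop_segment",
    "fiveprime",
    "threeprime",
)

_PSEUDOKNOT_CHARS = set("[]{}<>") | set("abcdefghijklmnopqrstuvwxyz") | set(
    "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
)


class ParseError(ValueError):
    """Malformed dot-bracket input (unbalanced brackets, bad characters)."""


class PseudoknotError(ValueError):
    """Input uses pseudoknot bracket alphabets, which are unsupported."""


@dataclass(frozen=True)
class Element:
    """One secondary-structure element.

    ``strands`` holds 1-based residue indices, one strictly increasing list
    per strand (stems have two; interior loops two, either possibly empty on
    one side only via bulges being single-strand... interior loops always
    have two entries, one of which may be empty for a bulge; single-strand
    elements have one entry, possibly empty for zero-length multiloop
    segments).  ``connections`` lists ``(stem_id, side)`` attachment points
    in 5'->3' traversal order, where ``side`` is ``"start"`` (outer face of
    an enclosed stem) or ``"end"`` (enclosed face).
    """

    id: str
    kind: str
    strands: tuple[tuple[int, ...], ...]
    connections: tuple[tuple[str, str], ...] = ()
    broken: bool = False

    @property
    def residues(self) -> tuple[int, ...]:
        return tuple(r for strand in self.strands for r in strand)


@dataclass(frozen=True)
class Junction:
    """A closed multiloop: stems and segments in 5'->3' cycle order.

    The cycle is ``stems[0] -(segments[0])- stems[1] - ... -(segments[-1])-
    stems[0]`` where ``stems[0]`` is the enclosing (closing) stem.
    """

    stems: tuple[str, ...]
    segments: tuple[str, ...]


@dataclass(frozen=True)
class ElementGraph:
    elements: tuple[Element, ...]
    adjacency: dict[str, tuple[str, ...]]
    n_residues: int
    junctions: tuple[Junction, ...] = ()
    _index: dict[str, Element] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "_index", {e.id: e for e in self.elements})

    def element(self, element_id: str) -> Element:
        try:
            return self._index[element_id]
        except KeyError:
            raise KeyError(f"no element with id {element_id!r}") from None

    def elements_of_kind(self, kind: str) -> list[Element]:
        return [e for e in self.elements if e.kind == kind]

    @property
    def stems(self) -> list[Element]:
        return self.elements_of_kind("stem")


def _pair_table(structure: str) -> list[int]:
    """Return 1-based pair table; pt[i] = partner of i, 0 if unpaired."""
    n = len(structure)
    pt = [0] * (n + 1)
    stack: list[int] = []
    for pos, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ParseError(f"unbalanced ')' at position {pos}")
            opener = stack.pop()
            pt[opener] = pos
            pt[pos] = opener
        elif ch == ".":
            continue
        elif ch in _PSEUDOKNOT_CHARS:
            raise PseudoknotError(
                f"pseudoknot bracket {ch!r} at position {pos} is unsupported"
            )
        else:
            raise ParseError(f"invalid character {ch!r} at position {pos}")
    if stack:
        raise ParseError(f"unbalanced '(' at position {stack[-1]}")
    return pt


def parse_dotbracket(sequence: str, structure: str) -> ElementGraph:
    """Parse a dot-bracket string into an :class:`ElementGraph`.

    Element ids are assigned deterministically in 5'->3' discovery order
    within each kind (``s0, s1, ...``, ``h0, ...``, ``i0, ...``, ``m0, ...``,
    ``f0``, ``t0``).  Broken multiloop segments are designated by
    :func:`assign_broken_segments` before returning.
    """
    if len(sequence) != len(structure):
        raise ParseError(
            f"sequence length {len(sequence)} != structure length {len(structure)}"
        )
    if not structure:
        raise ParseError("empty structure")
    pt = _pair_table(structure)
    n = len(structure)

    # Maximal stems: runs of stacked pairs.
    stems: list[tuple[list[int], list[int]]] = []  # (strand1 5'->3', strand2 5'->3')
    seen = [False] * (n + 1)
    for i in range(1, n + 1):
        j = pt[i]
        if j > i and not seen[i]:
            s1 = [i]
            s2 = [j]
            k, l = i, j
            while k + 1 <= n and pt[k + 1] == l - 1 and l - 1 > k + 1:
                k += 1
                l -= 1
                s1.append(k)
                s2.append(l)
            for r in s1 + s2:
                seen[r] = True
            stems.append((s1, sorted(s2)))

    stems.sort(key=lambda s: s[0][0])
    stem_ids = {idx: f"s{idx}" for idx in range(len(stems))}
    # residue -> stem index for outer/inner lookup
    outer_open = {s[0][0]: idx for idx, s in enumerate(stems)}   # i1
    outer_close = {s[1][-1]: idx for idx, s in enumerate(stems)}  # j2

    elements: list[Element] = [
        Element(
            id=stem_ids[idx],
            kind="stem",
            strands=(tuple(s1), tuple(s2)),
        )
        for idx, (s1, s2) in enumerate(stems)
    ]

    loops: list[dict] = []  # staged non-stem elements with sort keys
    junctions_raw: list[tuple[list[str], list[int]]] = []  # (stem ids cycle, loop stage idxs)

    def stage(kind, strands, connections, key):
        loops.append(
            {"kind": kind, "strands": strands, "connections": connections, "key": key}
        )
        return len(loops) - 1

    # Interior of each stem: walk from inner 5' end to inner 3' end.
    for idx, (s1, s2) in enumerate(stems):
        i2, j1 = s1[-1], s2[0]
        inner: list[int] = []  # inner stem indices, 5'->3'
        runs: list[list[int]] = [[]]  # unpaired runs between inner stems
        p = i2 + 1
        while p < j1:
            if pt[p]:
                inner.append(outer_open[p])
                runs.append([])
                p = pt[p] + 1
            else:
                runs[-1].append(p)
                p += 1
        sid = stem_ids[idx]
        if not inner:
            stage("hairpin", (tuple(runs[0]),), ((sid, "end"),), runs[0][0] if runs[0] else i2 + 0.5)
        elif len(inner) == 1:
            iid = stem_ids[inner[0]]
            stage(
                "interior_loop",
                (tuple(runs[0]), tuple(runs[1])),
                ((sid, "end"), (iid, "start")),
                (runs[0][0] if runs[0] else i2 + 0.5),
            )
        else:
            cyc = [sid] + [stem_ids[t] for t in inner]
            stage_idxs = []
            k = len(inner)
            for t in range(k + 1):
                if t == 0:
                    conns = ((sid, "end"), (stem_ids[inner[0]], "start"))
                    prev_res = i2
                elif t < k:
                    conns = ((stem_ids[inner[t - 1]], "start"), (stem_ids[inner[t]], "start"))
                    prev_res = stems[inner[t - 1]][1][-1]
                else:
                    conns = ((stem_ids[inner[-1]], "start"), (sid, "end"))
                    prev_res = stems[inner[-1]][1][-1]
                key = runs[t][0] if runs[t] else prev_res + 0.5
                stage_idxs.append(stage("multiloop_segment", (tuple(runs[t]),), conns, key))
            junctions_raw.append((cyc, stage_idxs))

    # Exterior loop: leading / trailing strands and inter-stem segments.
    top: list[int] = []  # top-level stem indices 5'->3'
    runs = [[]]
    p = 1
    while p <= n:
        if pt[p]:
            top.append(outer_open[p])
            runs.append([])
            p = pt[p] + 1
        else:
            runs[-1].append(p)
            p += 1
    if top:
        if runs[0]:
            stage("fiveprime", (tuple(runs[0]),), ((stem_ids[top[0]], "start"),), runs[0][0])
        for t in range(1, len(top)):
            prev_res = stems[top[t - 1]][1][-1]
            key = runs[t][0] if runs[t] else prev_res + 0.5
            stage(
                "multiloop_segment",
                (tuple(runs[t]),),
                ((stem_ids[top[t - 1]], "start"), (stem_ids[top[t]], "start")),
                key,
            )
        if runs[-1]:
            stage(
                "threeprime",
                (tuple(runs[-1]),),
                ((stem_ids[top[-1]], "start"),),
                runs[-1][0],
            )
    else:
        raise ParseError("structure contains no base pairs; nothing to model")

    # Assign ids per kind in 5'->3' order of the staged sort key.
    counters = {k: 0 for k in KINDS}
    order = sorted(range(len(loops)), key=lambda i: loops[i]["key"])
    ids = [None] * len(loops)
    prefix = {"hairpin": "h", "interior_loop": "i", "multiloop_segment": "m",
              "fiveprime": "f", "threeprime": "t"}
    for i in order:
        kind = loops[i]["kind"]
        ids[i] = f"{prefix[kind]}{counters[kind]}"
        counters[kind] += 1
    for i, stg in enumerate(loops):
        elements.append(
            Element(id=ids[i], kind=stg["kind"], strands=stg["strands"],
                    connections=stg["connections"])
        )

    junctions = tuple(
        Junction(stems=tuple(cyc), segments=tuple(ids[i] for i in seg_idxs))
        for cyc, seg_idxs in junctions_raw
    )

    adjacency: dict[str, list[str]] = {e.id: [] for e in elements}
    for e in elements:
        for stem_id, _side in e.connections:
            if stem_id not in adjacency[e.id]:
                adjacency[e.id].append(stem_id)
            if e.id not in adjacency[stem_id]:
                adjacency[stem_id].append(e.id)

    graph = ElementGraph(
        elements=tuple(elements),
        adjacency={k: tuple(v) for k, v in adjacency.items()},
        n_residues=n,
        junctions=junctions,
    )
    return assign_broken_segments(graph)


def _segment_sort_key(graph: ElementGraph, seg_id: str) -> float:
    """5'-most position of a segment; gap position for empty segments."""
    seg = graph.element(seg_id)
    if seg.strands[0]:
        return float(seg.strands[0][0])
    # gap position: just after the 3'-most residue of the preceding stem side
    from_stem, side = seg.connections[0]
    stem = graph.element(from_stem)
    s1, s2 = stem.strands
    res = s1[-1] if side == "end" else s2[-1]
    return res + 0.5


def assign_broken_segments(graph: ElementGraph) -> ElementGraph:
    """Flag exactly one broken segment per closed junction.

    Convention: within each junction the segment whose 5'-most position is
    largest is broken.  This is deterministic and restores a spanning tree
    of the element graph (removing one edge per junction cycle).
    """
    broken_ids = set()
    for junc in graph.junctions:
        broken_ids.add(max(junc.segments, key=lambda s: _segment_sort_key(graph, s)))
    elements = tuple(
        replace(e, broken=(e.id in broken_ids)) for e in graph.elements
    )
    return ElementGraph(
        elements=elements,
        adjacency=graph.adjacency,
        n_residues=graph.n_residues,
        junctions=graph.junctions,
    )


def element_residues(graph: ElementGraph, element_id: str) -> list[list[int]]:
    """Strand-resolved residue lists of one element."""
    return [list(s) for s in graph.element(element_id).strands]


def to_dotbracket(graph: ElementGraph) -> str:
    """Regenerate the dot-bracket string from the element graph."""
    chars = ["."] * graph.n_residues
    for stem in graph.stems:
        s1, s2 = stem.strands
        for r in s1:
            chars[r - 1] = "("
        for r in s2:
            chars[r - 1] = ")"
    return "".join(chars)


# ---------------------------------------------------------------------------
# File formats

def read_dbn(path) -> tuple[str, str, ElementGraph]:
    """Read a .dbn file (optional '>' header, sequence line, structure line)."""
    lines = [ln.strip() for ln in open(path) if ln.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if len(lines) < 2:
        raise ParseError(f"{path}: expected sequence and structure lines")
    sequence, structure = lines[0], lines[1]
    return sequence, structure, parse_dotbracket(sequence, structure)


def write_dbn(path, sequence: str, structure: str, name: str = "cgrna") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n{sequence}\n{structure}\n")


def graph_to_json(graph: ElementGraph) -> str:
    payload = {
        "n_residues": graph.n_residues,
        "elements": [
            {
                "id": e.id,
                "kind": e.kind,
                "strands": [list(s) for s in e.strands],
                "connections": [list(c) for c in e.connections],
                "broken": e.broken,
            }
            for e in graph.elements
        ],
        "adjacency": {k: list(v) for k, v in graph.adjacency.items()},
        "junctions": [
            {"stems": list(j.stems), "segments": list(j.segments)}
            for j in graph.junctions
        ],
    }
    return json.dumps(payload, indent=1)


def graph_from_json(text: str) -> ElementGraph:
    payload = json.loads(text)
    elements = tuple(
        Element(
            id=e["id"],
            kind=e["kind"],
            strands=tuple(tuple(s) for s in e["strands"]),
            connections=tuple(tuple(c) for c in e["connections"]),
            broken=e["broken"],
        )
        for e in payload["elements"]
    )
    return ElementGraph(
        elements=elements,
        adjacency={k: tuple(v) for k, v in payload["adjacency"].items()},
        n_residues=payload["n_residues"],
        junctions=tuple(
            Junction(stems=tuple(j["stems"]), segments=tuple(j["segments"]))
            for j in payload["junctions"]
        ),
    )
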