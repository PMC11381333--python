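import numpy as np
import pytest

from cgrna.cg_model import assemble_structure, detect_clashes, element_signature
from cgrna.fragments import generate_synthetic_library, lookup_fragments
from cgrna.ss_graph import parse_dotbracket


def random_dotbracket(rng, max_depth=3):
    """Random valid non-pseudoknotted dot-bracket string (with >=2 bp stems
    and >=3 nt hairpin loops, the shapes the element model supports)."""

    def unit(depth):
        kind = rng.integers(3) if depth < max_depth else 2
        n_bp = int(rng.integers(2, 5))
        if kind == 2:  # hairpin
            loop = int(rng.integers(3, 7))
            return "(" * n_bp + "." * loop + ")" * n_bp
        if kind == 1:  # interior loop around a nested unit
            l5 = int(rng.integers(0, 4))
            l3 = int(rng.integers(0, 4))
            if l5 == 0 and l3 == 0:
                l5 = 1
            return "(" * n_bp + "." * l5 + unit(depth + 1) + "." * l3 + ")" * n_bp
        # multiloop with 2-3 branches
        k = int(rng.integers(2, 4))
        parts = []
        for _ in range(k):
            parts.append("." * int(rng.integers(0, 3)) + unit(depth + 1))
        return (
            "(" * n_bp
            + "".join(parts)
            + "." * int(rng.integers(0, 3))
            + ")" * n_bp
        )

    s = "." * int(rng.integers(0, 3)) + unit(0) + "." * int(rng.integers(0, 3))
    return s


@pytest.fixture
def hairpin_graph():
    return parse_dotbracket("GCAAAGC", "((...))")


@pytest.fixture
def junction_graph():
    return parse_dotbracket("G" * 24, "((..((...))..((...))..))")


@pytest.fixture
def two_stem_graph():
    return parse_dotbracket("GGGGAAGGGGAAAACCCCAACCCC", "((((..((((....))))..))))")


def feasible_structure(graph, lib, rng, max_tries=200):
    """Clash-free assembly with random library fragments."""
    stem_params = {s.id: len(s.strands[0]) for s in graph.stems}
    movable = [e for e in graph.elements if e.kind != "stem" and not e.broken]
    for _ in range(max_tries):
        assignment = {}
        for e in movable:
            pool = lookup_fragments(lib, element_signature(e))
            assignment[e.id] = pool[rng.integers(len(pool))]
        structure = assemble_structure(graph, assignment, stem_params)
        if not detect_clashes(structure, 4.0):
            return structure
    raise RuntimeError("no feasible structure found")


@pytest.fixture
def two_stem_system(two_stem_graph):
    """Graph + library + one feasible structure for the two-stem toy."""
    sigs = sorted(
        {
            element_signature(e)
            for e in two_stem_graph.elements
            if e.kind != "stem"
        }
    )
    lib = generate_synthetic_library(sigs, 12, seed=5)
    rng = np.random.default_rng(11)
    structure = feasible_structure(two_stem_graph, lib, rng)
    return two_stem_graph, lib, structure
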