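"""Fragment library: storage, synthetic generation and broken-segment fit.

A fragment is the rigid transform a loop element imposes between the
attachment frames of its flanking stems.  Libraries key fragments by the
element *signature* (kind, per-strand unpaired-length tuple), so any loop
with the same strand lengths can draw from the same pool.  The bundled
generator produces synthetic libraries with uniformly random orientations;
it stands in for fragment extraction from solved structures, which is out
of scope here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .cg_model import (
    CGStructure,
    ClosureDeviation,
    FragmentTransform,
    closure_deviation,
    element_signature,
)

__all__ = [
    "FragmentLibrary",
    "EmptySignatureError",
    "generate_synthetic_library",
    "lookup_fragments",
    "assign_broken_fragment",
    "signature_to_str",
    "signature_from_str",
    "library_to_json",
    "library_from_json",
    "save_library",
    "load_library",
]


class EmptySignatureError(KeyError):
    """No fragments stored under the requested signature."""


@dataclass
class FragmentLibrary:
    entries: dict[tuple, list[FragmentTransform]] = field(default_factory=dict)
    seed: int | None = None
    provenance: str = ""

    def add(self, fragment: FragmentTransform) -> None:
        self.entries.setdefault(fragment.signature, []).append(fragment)

    def signatures(self) -> list[tuple]:
        return list(self.entries)

    def __len__(self) -> int:
        return sum(len(v) for v in self.entries.values())


def signature_to_str(signature: tuple) -> str:
    kind, lengths = signature
    return f"{kind}:{','.join(str(x) for x in lengths)}"


def signature_from_str(text: str) -> tuple:
    kind, _, lengths = text.partition(":")
    lens = tuple(int(x) for x in lengths.split(",")) if lengths else ()
    return (kind, lens)


def generate_synthetic_library(
    signatures,
    n_per_signature: int,
    seed: int,
    norm_range: tuple[float, float] = (3.0, 25.0),
) -> FragmentLibrary:
    """Seeded synthetic fragment library.

    Rotations are uniform over SO(3); translation directions uniform on the
    sphere with norms uniform in ``norm_range`` (default 3-25 Angstrom,
    spanning tight bulges to extended loops).
    """
    signatures = list(signatures)
    if not signatures:
        raise ValueError("signature list must not be empty")
    if n_per_signature < 1:
        raise ValueError("n_per_signature must be >= 1")
    lo, hi = norm_range
    rng = np.random.default_rng(seed)
    lib = FragmentLibrary(seed=seed, provenance=f"synthetic(seed={seed})")
    for sig in signatures:
        sig = (sig[0], tuple(sig[1]))
        for k in range(n_per_signature):
            rot = Rotation.random(rng=rng).as_matrix()
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            norm = rng.uniform(lo, hi)
            lib.add(
                FragmentTransform(
                    rotation=rot,
                    translation=direction * norm,
                    signature=sig,
                    source_id=f"syn-{signature_to_str(sig)}-{k}",
                )
            )
    return lib


def lookup_fragments(lib: FragmentLibrary, signature: tuple) -> list[FragmentTransform]:
    """All fragments stored under a signature, in stable insertion order."""
    signature = (signature[0], tuple(signature[1]))
    entries = lib.entries.get(signature)
    if not entries:
        raise EmptySignatureError(
            f"no fragments for signature {signature_to_str(signature)}; "
            "sampling cannot proceed for this element"
        )
    return list(entries)


def assign_broken_fragment(
    structure: CGStructure,
    lib: FragmentLibrary,
    multiloop_id: str,
) -> tuple[FragmentTransform, ClosureDeviation]:
    """Best-fit fragment for a junction's broken segment.

    Scans every library fragment with the broken segment's signature and
    returns the one minimizing the closure deviation scalar, ties broken by
    ``source_id``.  Raises :class:`EmptySignatureError` when the library has
    no candidates.
    """
    graph = structure.graph
    for junction in graph.junctions:
        if multiloop_id in junction.segments:
            seg = next(
                graph.element(s) for s in junction.segments if graph.element(s).broken
            )
            break
    else:
        raise KeyError(f"no closed junction contains segment {multiloop_id!r}")
    candidates = lookup_fragments(lib, element_signature(seg))
    best = min(
        candidates,
        key=lambda f: (closure_deviation(structure, seg.id, f).scalar, f.source_id),
    )
    return best, closure_deviation(structure, seg.id, best)


# ---------------------------------------------------------------------------
# JSON round trip

def library_to_json(lib: FragmentLibrary) -> str:
    payload = {
        "seed": lib.seed,
        "provenance": lib.provenance,
        "entries": {
            signature_to_str(sig): [
                {
                    "rotation": [float(x) for x in frag.rotation.ravel()],
                    "translation": [float(x) for x in frag.translation],
                    "source_id": frag.source_id,
                }
                for frag in frags
            ]
            for sig, frags in lib.entries.items()
        },
    }
    return json.dumps(payload, indent=1)


def library_from_json(text: str) -> FragmentLibrary:
    payload = json.loads(text)
    lib = FragmentLibrary(seed=payload.get("seed"), provenance=payload.get("provenance", ""))
    for sig_str, frags in payload["entries"].items():
        sig = signature_from_str(sig_str)
        for f in frags:
            lib.add(
                FragmentTransform(
                    rotation=np.array(f["rotation"], dtype=float).reshape(3, 3),
                    translation=np.array(f["translation"], dtype=float),
                    signature=sig,
                    source_id=f.get("source_id", ""),
                )
            )
    return lib


def save_library(path, lib: FragmentLibrary) -> None:
    with open(path, "w") as fh:
        fh.write(library_to_json(lib))


def load_library(path) -> FragmentLibrary:
    with open(path) as fh:
        return library_from_json(fh.read())
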