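"""Metropolis fragment-assembly sampling.

States are fragment assignments over the loop elements of one element
graph; every state deterministically assembles into a rigid 3D structure.
Proposals exchange one fragment, two or three connected segments of the
same junction jointly, or one fragment followed by a constraint-driven
relaxation of its junction neighbors.  Structures with steric clashes, a
junction closure deviation above threshold, or pairwise distances beyond
the target curve's support are infeasible (infinite energy) and always
rejected; feasible structures are scored by the chosen PDD pseudo-energy
plus a harmonic penalty on the junction closure deviations, and accepted
with the Metropolis criterion min(1, exp(-dE/T)).

After every accepted move the broken segment of each junction is re-fitted
to the best-closing library fragment.  In reference-ratio mode the running
ensemble histogram is updated each step with the retained state's PDD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import pdist

from .cg_model import (
    CGStructure,
    assemble_structure,
    closure_deviation,
    detect_clashes,
    element_signature,
)
from .fragments import FragmentLibrary, assign_broken_fragment, lookup_fragments
from .pdd import (
    EnsembleHistogram,
    PDDCurve,
    area_energy,
    extract_points,
    reference_ratio_energy,
    update_ensemble,
)

__all__ = [
    "SamplerConfig",
    "TrajectoryRecord",
    "SamplingResult",
    "MoveInapplicable",
    "propose_move",
    "total_energy",
    "metropolis_accept",
    "relax_after_exchange",
    "run_sampling",
    "write_trajectory_tsv",
]

MOVE_KINDS = ("single", "pair", "triple", "exchange_relax")


class MoveInapplicable(Exception):
    """The drawn move kind cannot apply to this structure (e.g. a pair move
    on a graph without junctions); the sampler redraws the kind."""


class InitializationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SamplerConfig:
    steps: int = 1000
    seed: int = 0
    temperature: float | tuple[float, float] = 1.0  # constant, or (start, end) linear
    move_probabilities: dict = field(
        default_factory=lambda: {
            "single": 0.4, "pair": 0.2, "triple": 0.2, "exchange_relax": 0.2,
        }
    )
    energy: str = "area"  # "area" | "ref_ratio"
    k_pdd: float = 30.0
    k_ml: float = 1.0
    clash_cutoff: float = 4.0
    closure_threshold: float = 6.0
    point_mode: str = "three_points"
    ensemble_decay: float = 0.99
    save_every: int = 0
    max_init_retries: int = 10_000
    relax_budget: int = 20

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        probs = self.move_probabilities
        if any(p < 0 for p in probs.values()) or abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("move probabilities must be >= 0 and sum to 1")
        if self.energy not in ("area", "ref_ratio"):
            raise ValueError(f"unknown energy {self.energy!r}")

    def temperature_at(self, step: int) -> float:
        if isinstance(self.temperature, (tuple, list)):
            t0, t1 = self.temperature
            frac = step / max(1, self.steps - 1)
            temp = t0 + (t1 - t0) * frac
        else:
            temp = float(self.temperature)
        if temp <= 0:
            raise ValueError("temperature must be positive")
        return temp


@dataclass(frozen=True)
class TrajectoryRecord:
    step: int
    energy: float
    e_pdd: float
    e_ml: float
    accepted: bool
    closure: float  # largest junction closure scalar of the retained state
    clashes: int    # clash count of the proposed candidate
    snapshot: str | None = None


@dataclass
class SamplingResult:
    trajectory: list[TrajectoryRecord]
    best: CGStructure
    best_energy: float
    final: CGStructure
    ensemble: EnsembleHistogram | None


# ---------------------------------------------------------------------------
# State helpers

def _movable_elements(graph) -> list:
    return [e for e in graph.elements if e.kind != "stem" and not e.broken]


def _stem_params(graph) -> dict[str, int]:
    return {s.id: len(s.strands[0]) for s in graph.stems}


def _reassemble(structure: CGStructure, assignment) -> CGStructure:
    new = assemble_structure(
        structure.graph,
        assignment,
        _stem_params(structure.graph),
        root_stem=structure.graph.stems[0].id,
        params=structure.params,
        closure_weight=structure.closure_weight,
    )
    return new


def _fit_broken(structure: CGStructure, lib: FragmentLibrary) -> CGStructure:
    """Re-fit every junction's broken segment to the best-closing fragment
    and store it in the assignment (it does not affect the geometry)."""
    assignment = dict(structure.fragment_assignment)
    for junction in structure.graph.junctions:
        seg = next(
            s for s in junction.segments if structure.graph.element(s).broken
        )
        frag, _dev = assign_broken_fragment(structure, lib, seg)
        assignment[seg] = frag
    return replace(structure, fragment_assignment=assignment)


def _closure_scalars(structure: CGStructure) -> list[float]:
    out = []
    for junction in structure.graph.junctions:
        seg = next(
            s for s in junction.segments if structure.graph.element(s).broken
        )
        frag = structure.fragment_assignment.get(seg)
        if frag is None:
            raise KeyError(f"broken segment {seg} has no fitted fragment")
        out.append(closure_deviation(structure, seg, frag).scalar)
    return out


def _structure_pdd(structure: CGStructure, target: PDDCurve, mode: str) -> PDDCurve | None:
    """Structure PDD on the target's grid, or None when the structure's
    extent exceeds the target support (infeasible)."""
    pts = extract_points(structure, mode)
    dists = pdist(pts)
    n_bins = len(target.mass)
    top = n_bins * target.bin_width
    if dists.max() >= top:
        return None
    counts, _ = np.histogram(dists, bins=n_bins, range=(0.0, top))
    return PDDCurve(target.bin_width, counts / counts.sum(), target.d_max)


# ---------------------------------------------------------------------------
# Moves

def _junction_run(graph, rng, run_len: int) -> list[str]:
    """Pick run_len consecutive non-broken segments of one junction cycle."""
    candidates = []
    for junction in graph.junctions:
        segs = list(junction.segments)
        k = len(segs)
        for i in range(k):
            run = [segs[(i + d) % k] for d in range(run_len)]
            if len(set(run)) == run_len and not any(
                graph.element(s).broken for s in run
            ):
                candidates.append(run)
    if not candidates:
        raise MoveInapplicable(f"no junction run of length {run_len}")
    return candidates[rng.integers(len(candidates))]


def propose_move(
    state: CGStructure,
    kind: str,
    lib: FragmentLibrary,
    rng: np.random.Generator,
) -> CGStructure:
    """Draw one move of the given kind; returns the assembled candidate.

    The candidate differs from the state only in the exchanged fragment
    assignments (plus, for ``exchange_relax``, the relaxed neighbors).
    Raises :class:`MoveInapplicable` when the structure cannot support the
    kind (pair/triple without a junction).
    """
    graph = state.graph
    movable = _movable_elements(graph)
    if not movable:
        raise MoveInapplicable("no movable elements")
    assignment = dict(state.fragment_assignment)

    if kind in ("single", "exchange_relax"):
        element = movable[rng.integers(len(movable))]
        pool = lookup_fragments(lib, element_signature(element))
        assignment[element.id] = pool[rng.integers(len(pool))]
        candidate = _reassemble(state, assignment)
        if kind == "exchange_relax":
            candidate = relax_after_exchange(
                candidate, lib, budget=20, exchanged_id=element.id
            )
        return candidate
    if kind in ("pair", "triple"):
        run = _junction_run(graph, rng, 2 if kind == "pair" else 3)
        for seg_id in run:
            element = graph.element(seg_id)
            pool = lookup_fragments(lib, element_signature(element))
            assignment[seg_id] = pool[rng.integers(len(pool))]
        return _reassemble(state, assignment)
    raise ValueError(f"unknown move kind {kind!r}")


# ---------------------------------------------------------------------------
# Energy

def _evaluate(
    structure: CGStructure,
    target: PDDCurve,
    ensemble: EnsembleHistogram | None,
    config: SamplerConfig,
):
    """Return (e_total, e_pdd, e_ml, p, clash_count, max_closure).

    ``e_total`` is +inf for infeasible structures (clash, closure deviation
    above threshold, or extent beyond the target support).
    """
    clashes = detect_clashes(structure, config.clash_cutoff, config.point_mode)
    n_clash = len(clashes)
    scalars = _closure_scalars(structure)
    max_scalar = max(scalars, default=0.0)
    if n_clash > 0 or max_scalar > config.closure_threshold:
        return math.inf, math.nan, math.nan, None, n_clash, max_scalar
    p = _structure_pdd(structure, target, config.point_mode)
    if p is None:
        return math.inf, math.nan, math.nan, None, n_clash, max_scalar
    if config.energy == "area":
        e_pdd = area_energy(p, target, config.k_pdd)
    else:
        e_pdd = reference_ratio_energy(p, ensemble, target, config.k_pdd)
    e_ml = config.k_ml * sum(s * s for s in scalars)
    return e_pdd + e_ml, e_pdd, e_ml, p, n_clash, max_scalar


def total_energy(
    structure: CGStructure,
    target: PDDCurve,
    ensemble: EnsembleHistogram | None,
    config: SamplerConfig,
) -> float:
    """Total pseudo-energy of a structure; +inf when infeasible."""
    return _evaluate(structure, target, ensemble, config)[0]


def metropolis_accept(
    delta_e: float, temperature: float, rng: np.random.Generator
) -> bool:
    """Metropolis criterion: accept with probability min(1, exp(-dE/T)).

    ``delta_e = +inf`` (infeasible candidate) is always rejected.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if math.isinf(delta_e) and delta_e > 0:
        return False
    if delta_e <= 0:
        return True
    return rng.random() < math.exp(-delta_e / temperature)


# ---------------------------------------------------------------------------
# Relaxation

def _constraint_objective(structure: CGStructure, config_cutoff: float = 4.0):
    n_clash = len(detect_clashes(structure, config_cutoff))
    return (n_clash, sum(_closure_scalars(structure)))


def relax_after_exchange(
    structure: CGStructure,
    lib: FragmentLibrary,
    budget: int = 20,
    exchanged_id: str | None = None,
    clash_cutoff: float = 4.0,
) -> CGStructure:
    """Greedy constraint relaxation after a fragment exchange.

    Passes over the junction neighbors of the exchanged element (all
    movable elements when ``exchanged_id`` is None), re-selecting each
    fragment to lexicographically minimize (clash count, summed closure
    scalar).  The objective never increases; stops at a local minimum or
    after ``budget`` re-selections.
    """
    graph = structure.graph
    if exchanged_id is None:
        targets = [e.id for e in _movable_elements(graph)]
    else:
        # elements sharing a stem with the exchanged element
        stems = set(graph.adjacency[exchanged_id])
        targets = [
            e.id
            for e in _movable_elements(graph)
            if e.id != exchanged_id and stems & set(graph.adjacency[e.id])
        ]
        if not targets:
            targets = [exchanged_id]

    current = _fit_broken(structure, lib) if graph.junctions else structure
    best_obj = _constraint_objective(current, clash_cutoff)
    spent = 0
    improved = True
    while improved and spent < budget:
        improved = False
        for elem_id in targets:
            if spent >= budget:
                break
            element = graph.element(elem_id)
            pool = lookup_fragments(lib, element_signature(element))
            for frag in pool:
                if frag is current.fragment_assignment.get(elem_id):
                    continue
                assignment = dict(current.fragment_assignment)
                assignment[elem_id] = frag
                trial = _reassemble(current, assignment)
                if graph.junctions:
                    trial = _fit_broken(trial, lib)
                obj = _constraint_objective(trial, clash_cutoff)
                if obj < best_obj:
                    current, best_obj = trial, obj
                    improved = True
            spent += 1
    return current


# ---------------------------------------------------------------------------
# Main loop

def _random_assignment(graph, lib, rng) -> dict:
    assignment = {}
    for element in _movable_elements(graph):
        pool = lookup_fragments(lib, element_signature(element))
        assignment[element.id] = pool[rng.integers(len(pool))]
    return assignment


def initialize_state(graph, lib, config: SamplerConfig, target: PDDCurve,
                     rng: np.random.Generator) -> CGStructure:
    """Rejection-sample a feasible initial assignment."""
    stem_params = _stem_params(graph)
    for _ in range(config.max_init_retries):
        assignment = _random_assignment(graph, lib, rng)
        structure = assemble_structure(
            graph, assignment, stem_params, root_stem=graph.stems[0].id
        )
        if graph.junctions:
            structure = _fit_broken(structure, lib)
        e, *_ = _evaluate(structure, target, None, replace(config, energy="area"))
        if math.isfinite(e):
            return structure
    raise InitializationError(
        f"no feasible initial state in {config.max_init_retries} retries"
    )


def run_sampling(
    graph,
    lib: FragmentLibrary,
    target: PDDCurve,
    config: SamplerConfig,
    snapshot_dir=None,
) -> SamplingResult:
    """Seeded Metropolis run; returns the trajectory, the lowest-energy
    structure seen, the final state and (ref_ratio mode) the ensemble."""
    rng = np.random.default_rng(config.seed)
    state = initialize_state(graph, lib, config, target, rng)

    ensemble = None
    if config.energy == "ref_ratio":
        ensemble = EnsembleHistogram.empty_like(target, lam=config.ensemble_decay)
        p0 = _structure_pdd(state, target, config.point_mode)
        ensemble = update_ensemble(ensemble, p0)

    kinds = list(config.move_probabilities)
    probs = np.array([config.move_probabilities[k] for k in kinds])

    trajectory: list[TrajectoryRecord] = []
    best, best_e = state, math.inf
    for step in range(config.steps):
        temp = config.temperature_at(step)
        # state energy under the *current* ensemble (it evolves every step)
        e_state, *_ = _evaluate(state, target, ensemble, config)
        candidate = None
        for _ in range(20):  # redraw inapplicable kinds
            kind = kinds[rng.choice(len(kinds), p=probs)]
            try:
                candidate = propose_move(state, kind, lib, rng)
                break
            except MoveInapplicable:
                continue
        if candidate is None:
            raise RuntimeError("no applicable move kind")
        if graph.junctions:
            candidate = _fit_broken(candidate, lib)
        e_cand, e_pdd, e_ml, _p, n_clash, closure = _evaluate(
            candidate, target, ensemble, config
        )
        accepted = metropolis_accept(e_cand - e_state, temp, rng)
        if accepted:
            state = candidate
            e_state, e_pdd_s, e_ml_s = e_cand, e_pdd, e_ml
        else:
            _e, e_pdd_s, e_ml_s, *_rest = _evaluate(state, target, ensemble, config)
        if ensemble is not None:
            p_now = _structure_pdd(state, target, config.point_mode)
            ensemble = update_ensemble(ensemble, p_now)
        snap = None
        if snapshot_dir and config.save_every and (step + 1) % config.save_every == 0:
            from .cg_model import write_cg_pdb
            import os

            snap = os.path.join(str(snapshot_dir), f"snapshot_{step + 1:06d}.pdb")
            write_cg_pdb(snap, state, config.point_mode)
        trajectory.append(
            TrajectoryRecord(
                step=step,
                energy=e_state,
                e_pdd=e_pdd_s,
                e_ml=e_ml_s,
                accepted=accepted,
                closure=max(_closure_scalars(state), default=0.0),
                clashes=n_clash,
                snapshot=snap,
            )
        )
        if e_state < best_e:
            best, best_e = state, e_state
    return SamplingResult(
        trajectory=trajectory,
        best=best,
        best_energy=best_e,
        final=state,
        ensemble=ensemble,
    )


def write_trajectory_tsv(path, trajectory: list[TrajectoryRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("step\tE_total\tE_pdd\tE_ml\taccepted\tclashes\tclosure\n")
        for rec in trajectory:
            fh.write(
                f"{rec.step}\t{rec.energy:.6g}\t{rec.e_pdd:.6g}\t{rec.e_ml:.6g}\t"
                f"{int(rec.accepted)}\t{rec.clashes}\t{rec.closure:.6g}\n"
            )
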