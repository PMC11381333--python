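"""Pair distance distributions (PDD) and SAXS-fitting pseudo-energies.

The PDD ``P(r)`` is the distribution of pairwise distances between
scattering centers; experimentally it is obtained from the SAXS intensity
``I(q)`` by indirect Fourier transform (e.g. with GNOM) and read here as a
two/three-column text curve.  Model PDDs are computed directly from the
coarse-grained virtual points, interpreting the curve as a distribution of
distances between atomic centers (the hydration shell is neglected).

Two pseudo-energies drive sampling towards a target curve:

* ``area_energy`` — total variation between the structure's own PDD and
  the target (a potential on the area between the two curves);
* ``reference_ratio_energy`` — the reference ratio method applied per
  histogram bin: the sampled *ensemble*'s bin occupancies are compared to
  the target's, and a structure is (dis)favored according to the bins it
  populates.  At convergence (ensemble == target) the energy vanishes for
  every structure — no residual force.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "PDDCurve",
    "EnsembleHistogram",
    "GridError",
    "extract_points",
    "compute_pdd",
    "load_target_pdd",
    "write_pdd",
    "area_energy",
    "reference_ratio_energy",
    "update_ensemble",
    "total_variation",
]

DEFAULT_BIN_WIDTH = 1.0  # Angstrom
DEFAULT_EPS = 1e-6
DEFAULT_DECAY = 0.99


class GridError(ValueError):
    """Two curves do not share the same binning."""


@dataclass(frozen=True)
class PDDCurve:
    """Binned pair distance distribution.

    ``mass`` is a probability vector (sums to 1); bin ``i`` covers
    ``[i*bin_width, (i+1)*bin_width)`` with center ``(i+1/2)*bin_width``;
    support lies within ``[0, d_max]``.
    """

    bin_width: float
    mass: np.ndarray
    d_max: float

    def __post_init__(self):
        mass = np.asarray(self.mass, dtype=float)
        object.__setattr__(self, "mass", mass)
        if np.any(mass < -1e-12):
            raise ValueError("PDD mass must be non-negative")
        if abs(mass.sum() - 1.0) > 1e-9:
            raise ValueError(f"PDD mass must sum to 1 (got {mass.sum()!r})")

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(len(self.mass)) + 0.5) * self.bin_width

    def same_grid(self, other: "PDDCurve | EnsembleHistogram") -> bool:
        return (
            abs(self.bin_width - other.bin_width) < 1e-12
            and len(self.mass) == len(other.mass)
        )


@dataclass(frozen=True)
class EnsembleHistogram:
    """Decaying accumulator of accepted-structure PDDs (same binning as the
    target).  ``mass`` is unnormalized; ``normalized()`` yields a PDDCurve.
    The decay ``lam`` in (0, 1] makes old contributions fade (burn-in
    forgetting); ``lam = 1`` is a plain running sum."""

    bin_width: float
    mass: np.ndarray
    d_max: float
    lam: float = DEFAULT_DECAY
    n_contributions: int = 0

    def __post_init__(self):
        object.__setattr__(self, "mass", np.asarray(self.mass, dtype=float))
        if not (0.0 < self.lam <= 1.0):
            raise ValueError("decay factor must be in (0, 1]")

    @classmethod
    def empty_like(cls, target: PDDCurve, lam: float = DEFAULT_DECAY) -> "EnsembleHistogram":
        return cls(
            bin_width=target.bin_width,
            mass=np.zeros_like(target.mass),
            d_max=target.d_max,
            lam=lam,
        )

    def normalized(self) -> PDDCurve:
        if self.n_contributions < 1:
            raise ValueError("ensemble has no contributions yet")
        total = self.mass.sum()
        return PDDCurve(self.bin_width, self.mass / total, self.d_max)


def _require_same_grid(a, b) -> None:
    if abs(a.bin_width - b.bin_width) > 1e-12 or len(a.mass) != len(b.mass):
        raise GridError(
            f"binning mismatch: {len(a.mass)} bins @ {a.bin_width} vs "
            f"{len(b.mass)} bins @ {b.bin_width}"
        )


def extract_points(structure, mode: str = "three_points") -> np.ndarray:
    """Scattering-center cloud of a structure.

    ``one_point`` uses one center per residue (the C1'-proxy sugar point);
    ``three_points`` uses base, sugar and backbone points, i.e. exactly
    three centers per residue.
    """
    return structure.point_array(mode)


def compute_pdd(points: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH,
                d_max: float | None = None) -> PDDCurve:
    """Normalized histogram of all pairwise distances of a point cloud.

    ``d_max`` defaults to 1.1x the cloud's own maximal distance.  Any
    distance beyond an explicit ``d_max`` raises a range error (the target
    support cannot accommodate the structure).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    dists = pdist(points)
    max_dist = float(dists.max())
    if d_max is None:
        d_max = 1.1 * max_dist
    elif max_dist > d_max:
        raise ValueError(
            f"pairwise distance {max_dist:.3f} A exceeds d_max {d_max:.3f} A"
        )
    n_bins = int(np.ceil(d_max / bin_width - 1e-9))
    counts, _ = np.histogram(dists, bins=n_bins, range=(0.0, n_bins * bin_width))
    return PDDCurve(bin_width, counts / counts.sum(), float(d_max))


def load_target_pdd(path, bin_width: float = DEFAULT_BIN_WIDTH) -> PDDCurve:
    """Read an ``r  P(r)  [err]`` text curve (GNOM-style re-export).

    '#' lines are comments.  The curve is linearly interpolated onto the
    internal equal-width grid and renormalized to unit mass; ``d_max`` is
    the last radius with nonzero mass.
    """
    rs, ps = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            rs.append(float(cols[0]))
            ps.append(float(cols[1]))
    if not rs:
        raise ValueError(f"{path}: no data rows")
    r = np.array(rs)
    p = np.array(ps)
    if np.any(np.diff(r) <= 0):
        raise ValueError(f"{path}: r column must be strictly increasing")
    if np.any(p < -1e-12):
        raise ValueError(f"{path}: negative P(r) values")
    p = np.clip(p, 0.0, None)
    nonzero = np.nonzero(p > 0)[0]
    if len(nonzero) == 0:
        raise ValueError(f"{path}: curve is identically zero")
    d_max = float(r[nonzero[-1]])
    n_bins = max(1, int(np.ceil(d_max / bin_width - 1e-9)))
    centers = (np.arange(n_bins) + 0.5) * bin_width
    mass = np.interp(centers, r, p, left=0.0, right=0.0)
    if mass.sum() <= 0:  # single-row curves: put the mass in its bin
        mass = np.zeros(n_bins)
        for ri, pi in zip(r, p):
            if pi > 0:
                mass[min(n_bins - 1, int(ri / bin_width))] += pi
    return PDDCurve(bin_width, mass / mass.sum(), d_max)


def write_pdd(path, curve: PDDCurve, comment: str = "") -> None:
    """Write a curve as '#'-commented two-column text (6 significant digits)."""
    with open(path, "w") as fh:
        fh.write("# pair distance distribution\n")
        if comment:
            fh.write(f"# {comment}\n")
        fh.write(f"# bin_width {curve.bin_width:.6g}  d_max {curve.d_max:.6g}\n")
        for r, p in zip(curve.bin_centers, curve.mass):
            fh.write(f"{r:.6g} {p:.6g}\n")


def total_variation(a: PDDCurve, b: PDDCurve) -> float:
    """Half the L1 distance between two curves on the same grid."""
    _require_same_grid(a, b)
    return float(0.5 * np.abs(a.mass - b.mass).sum())


def area_energy(p: PDDCurve, target: PDDCurve, k: float = 1.0) -> float:
    """Potential on the area between the structure's PDD and the target:
    ``k`` times the total variation distance, in [0, k]."""
    return k * total_variation(p, target)


def reference_ratio_energy(
    p_structure: PDDCurve,
    ensemble: EnsembleHistogram,
    target: PDDCurve,
    k: float = 1.0,
    eps: float = DEFAULT_EPS,
) -> float:
    """Per-bin reference-ratio pseudo-energy.

    ``E = -k * sum_b p(b) * ln[(target(b)+eps) / (q(b)+eps)]`` where ``q``
    is the normalized ensemble histogram.  Bins the sampled ensemble
    underpopulates relative to the target are favored (negative
    contribution) for structures that occupy them, and vice versa; when the
    ensemble matches the target the energy is identically zero.
    """
    _require_same_grid(p_structure, target)
    q = ensemble.normalized()
    _require_same_grid(p_structure, q)
    ratio = (target.mass + eps) / (q.mass + eps)
    return float(-k * np.sum(p_structure.mass * np.log(ratio)))


def update_ensemble(ensemble: EnsembleHistogram, p_accepted: PDDCurve) -> EnsembleHistogram:
    """Fold an accepted structure's PDD into the decaying ensemble."""
    _require_same_grid(ensemble, p_accepted)
    return replace(
        ensemble,
        mass=ensemble.lam * ensemble.mass + p_accepted.mass,
        n_contributions=ensemble.n_contributions + 1,
    )
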