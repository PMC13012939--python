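"""Per-subject similarity networks from ROI morphometric distributions.

Each ROI's sample vector becomes a probability-mass profile on a grid shared
across all ROIs of the subject; pairs of profiles are compared with a
symmetric Kullback-Leibler divergence and mapped through exp(-d) into a
similarity in (0, 1], giving an N x N matrix per subject and metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlases import atlas_for_metric, atlas_labels, atlas_size
from .cohort import MIN_SAMPLES, RoiSampleSet
from .kde import gaussian_kde_on_grid, select_bandwidth

#: floor added to every density value before mass renormalization
EPSILON_FLOOR = 2.2e-16

#: default number of shared grid points
DEFAULT_GRID_SIZE = 256


@dataclass(frozen=True)
class DensityProfile:
    """Probability-mass profile of one ROI on a shared uniform grid."""

    grid: np.ndarray
    mass: np.ndarray
    roi_label: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        mass = np.asarray(self.mass, dtype=float)
        if grid.ndim != 1 or grid.size < 2:
            raise ValueError("grid must be a 1-D vector of >= 2 points")
        steps = np.diff(grid)
        if not np.all(steps > 0):
            raise ValueError("grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=0):
            raise ValueError("grid must be uniformly spaced")
        if mass.shape != grid.shape:
            raise ValueError("mass and grid shapes differ")
        if not np.all(mass > 0):
            raise ValueError("every mass element must be > 0 (post-floor)")
        if abs(mass.sum() - 1.0) > 1e-12:
            raise ValueError(f"mass sums to {mass.sum()!r}, not 1")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "mass", mass)


@dataclass
class SimilarityMatrix:
    """Symmetric per-subject KLS matrix with unit diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray
    metric: str = ""
    atlas: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.array_equal(v, v.T):
            i, j = np.argwhere(v != v.T)[0]
            raise ValueError(f"matrix not symmetric at cell ({i}, {j})")
        if not np.all(np.diag(v) == 1.0):
            i = int(np.argwhere(np.diag(v) != 1.0)[0][0])
            raise ValueError(f"diagonal element ({i}, {i}) is {v[i, i]!r}, expected 1")
        off = v[~np.eye(n, dtype=bool)]
        if off.size and (off.min() <= 0 or off.max() > 1):
            raise ValueError("off-diagonal values must lie in (0, 1]")
        self.labels = tuple(self.labels)
        self.values = v

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def offdiag_values(self) -> np.ndarray:
        """Strictly-upper-triangular entries in row-major order."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.values[iu]


def build_common_grid(sample_set: RoiSampleSet, m: int = DEFAULT_GRID_SIZE) -> np.ndarray:
    """Uniform m-point grid spanning the global min..max over all ROIs."""
    if m < 2:
        raise ValueError("grid size m must be >= 2")
    lo = min(float(v.min()) for v in sample_set.samples.values())
    hi = max(float(v.max()) for v in sample_set.samples.values())
    if hi <= lo:
        raise ValueError(
            "degenerate input: all sample values identical across the set"
        )
    return np.linspace(lo, hi, m)


def estimate_density(
    samples: np.ndarray,
    grid: np.ndarray,
    bandwidth_rule: str = "botev",
    roi_label: str = "",
    epsilon: float = EPSILON_FLOOR,
) -> DensityProfile:
    """Gaussian-kernel KDE on *grid*, floored and renormalized to a
    probability-mass vector."""
    x = np.asarray(samples, dtype=float)
    if x.size < MIN_SAMPLES:
        raise ValueError(f"need >= {MIN_SAMPLES} samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite sample values")
    if x.std(ddof=1) <= 0:
        raise ValueError("degenerate input: zero-variance samples")
    h = select_bandwidth(x, bandwidth_rule)
    dens = gaussian_kde_on_grid(x, grid, h)
    dx = float(grid[1] - grid[0])
    # floor in probability-mass units: keeps the floor invariant under
    # affine rescaling of the samples (density units would not be)
    mass = dens * dx + epsilon
    mass = mass / mass.sum()
    return DensityProfile(grid=np.asarray(grid, float), mass=mass, roi_label=roi_label)


def symmetric_kl(p: DensityProfile, q: DensityProfile) -> float:
    """Symmetric KL divergence sum_i [P_i log(P_i/Q_i) + Q_i log(Q_i/P_i)]
    over probability masses, natural log, canonical ascending-index order."""
    if not np.array_equal(p.grid, q.grid):
        raise ValueError("density profiles are on different grids")
    pm, qm = p.mass, q.mass
    if np.any(pm <= 0) or np.any(qm <= 0):
        raise ValueError("zero mass encountered; epsilon floor missing")
    # (P-Q)(logP - logQ) is the two-term sum, symmetric element-wise so the
    # result is bit-identical under argument swap
    terms = (pm - qm) * (np.log(pm) - np.log(qm))
    return float(np.sum(terms))


def kls_similarity(d: float) -> float:
    """exp(-d): 1 for identical distributions, decreasing toward 0."""
    if not np.isfinite(d) or d < 0:
        raise ValueError(f"divergence must be finite and >= 0, got {d!r}")
    return float(np.exp(-d))


def _mass_matrix(
    sample_set: RoiSampleSet, m: int, bandwidth_rule: str, epsilon: float
) -> tuple[np.ndarray, np.ndarray]:
    grid = build_common_grid(sample_set, m)
    labels = sample_set.labels
    masses = np.empty((len(labels), m))
    for i, lab in enumerate(labels):
        try:
            prof = estimate_density(
                sample_set.samples[lab], grid, bandwidth_rule, lab, epsilon
            )
        except ValueError as exc:
            raise ValueError(f"ROI {lab!r}: {exc}") from exc
        masses[i] = prof.mass
    return grid, masses


def build_similarity_matrix(
    sample_set: RoiSampleSet,
    m: int = DEFAULT_GRID_SIZE,
    bandwidth_rule: str = "botev",
    epsilon: float = EPSILON_FLOOR,
) -> SimilarityMatrix:
    """Pairwise KLS over all ROI pairs of one subject x metric.

    116 x 116 for (GMV, AAL116); 68 x 68 for surface metrics on DK68.
    """
    _, masses = _mass_matrix(sample_set, m, bandwidth_rule, epsilon)
    logm = np.log(masses)
    # symmetric KL for all pairs: D_jk = u_j + u_k - (M L^T)_jk - (M L^T)_kj
    w = masses @ logm.T
    # diag(w) as u makes identical rows give exactly zero divergence
    u = np.diag(w).copy()
    # w + w.T and u_j + u_k are exactly symmetric, so d is bit-symmetric
    d = (u[:, None] + u[None, :]) - (w + w.T)
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)  # guard tiny negative rounding
    values = np.exp(-d)
    np.fill_diagonal(values, 1.0)
    mat = SimilarityMatrix(
        labels=sample_set.labels,
        values=values,
        metric=sample_set.metric,
        atlas=sample_set.atlas,
        subject_id=sample_set.subject_id,
    )
    expected = atlas_size(sample_set.atlas)
    assert mat.n_nodes == expected
    return mat
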