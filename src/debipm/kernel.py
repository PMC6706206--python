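"""DEB-IPM projection kernel on a discretised length domain.

The population state is a density over body length L on a closed domain
discretised into equal cells.  One time step is governed by four fundamental
functions:

* survival  ``S(L) = exp(-mu)`` for ``L <= L_m E(Y)/kappa``, else 0
  (starvation: maintenance exceeds assimilated energy);
* growth    ``G(L', L)`` — Gaussian around the von Bertalanffy mean
  ``E[L'] = L e^{-rB} + (1 - e^{-rB}) L_m E(Y)`` with standard deviation
  ``(1 - e^{-rB}) L_m sigma(Y)``, independent of L;
* reproduction  ``R(L) = E(Y) R_m L^2 / L_m^2`` for mature, non-starved
  lengths, else 0;
* offspring size  ``D(L')`` — Gaussian around a fixed offspring mean.

The discretised operator is ``A[i, j] = G[i, j] S(L_j) + D[i] R(L_j)``.
Survival discounts the growth term; offspring produced between t and t+1
are censused before background mortality acts, and starved adults never
reproduce because the fertile window of R closes at the same starvation
cutoff as S.

All Gaussian terms are integrated over destination cells as differences of
normal CDFs at the cell edges rather than evaluated at midpoints: the
offspring-size spread (and the growth spread when sigma(Y) = 0) can be far
narrower than one cell, where a midpoint rule fails badly, and the CDF rule
degrades gracefully to a point mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.stats import norm

from .life_history import DEBParams

__all__ = [
    "SizeMesh",
    "Kernel",
    "build_mesh",
    "survival_probability",
    "survival_cell_average",
    "reproduction_cell_average",
    "growth_mean",
    "growth_sd",
    "growth_transition",
    "reproduction_rate",
    "offspring_distribution",
    "assemble_kernel",
    "dominant_eigenpair",
    "mean_body_size",
    "export_kernel",
]

#: Interior growth columns should integrate to 1 within this tolerance; a
#: larger loss of probability mass ("eviction") indicates the mesh is too
#: narrow and triggers a warning.
EVICTION_TOLERANCE = 1e-3
EVICTION_WARN_FRACTION = 0.01
#: Mesh bounds are padded by this many growth standard deviations.
MESH_PADDING_SDS = 5.0


@dataclass(frozen=True)
class SizeMesh:
    """Equal-width discretisation of the body-length domain."""

    lower: float
    upper: float
    n_cells: int

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError(f"n_cells must be >= 2, got {self.n_cells}")
        if not self.lower < self.upper:
            raise ValueError(
                f"mesh bounds must satisfy lower < upper, got "
                f"[{self.lower}, {self.upper}]"
            )

    @property
    def cell_width(self) -> float:
        return (self.upper - self.lower) / self.n_cells

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.lower, self.upper, self.n_cells + 1)

    @property
    def midpoints(self) -> np.ndarray:
        w = self.cell_width
        return self.lower + (np.arange(self.n_cells) + 0.5) * w

    def cell_containing(self, length: float) -> int:
        """Index of the cell containing ``length`` (lower edge inclusive)."""
        if not (self.lower <= length <= self.upper):
            raise ValueError(f"length {length} outside mesh [{self.lower}, {self.upper}]")
        idx = int(np.floor((length - self.lower) / self.cell_width))
        return min(idx, self.n_cells - 1)


@dataclass(frozen=True)
class Kernel:
    """Discretised projection operator for one feeding level."""

    matrix: np.ndarray
    feeding_level: float
    sigma_Y: float
    mesh: SizeMesh
    params: DEBParams

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.shape != (self.mesh.n_cells, self.mesh.n_cells):
            raise ValueError("kernel matrix shape does not match mesh")
        if np.any(m < 0):
            raise ValueError("kernel matrix has negative entries")


def _check_feeding_level(feeding_level: float) -> float:
    y = float(feeding_level)
    if not (0.0 <= y <= 1.0):
        raise ValueError(f"feeding level E(Y) must lie in [0, 1], got {y}")
    return y


def build_mesh(params: DEBParams, sigma_Y: float, n_cells: int = 200) -> SizeMesh:
    """Mesh spanning every reachable length for the given noise level.

    The lower bound sits ``MESH_PADDING_SDS`` growth standard deviations
    below the offspring length (floored at zero); the upper bound covers
    both the full-feeding starvation cutoff ``L_m / kappa`` and the largest
    growth excursion above ``L_m``.
    """
    if sigma_Y < 0:
        raise ValueError("sigma_Y must be >= 0")
    sd = growth_sd(params, sigma_Y)
    pad = MESH_PADDING_SDS * sd
    lower = float(max(0.0, params.L_b - pad))
    upper = float(max(params.L_m / params.kappa, params.L_m + pad))
    return SizeMesh(lower=lower, upper=upper, n_cells=int(n_cells))


def survival_probability(L, params: DEBParams, feeding_level: float):
    """Per-step survival: exp(-mu) below the starvation cutoff, else 0."""
    y = _check_feeding_level(feeding_level)
    L_arr = np.asarray(L, dtype=float)
    out = np.where(L_arr <= params.starvation_cutoff(y), np.exp(-params.mu), 0.0)
    return float(out) if np.ndim(L) == 0 else out


def growth_mean(L, params: DEBParams, feeding_level: float):
    """Expected length next step: von Bertalanffy approach to L_m * E(Y)."""
    y = _check_feeding_level(feeding_level)
    L_arr = np.asarray(L, dtype=float)
    decay = np.exp(-params.rB)
    out = L_arr * decay + (1.0 - decay) * params.L_m * y
    return float(out) if np.ndim(L) == 0 else out


def growth_sd(params: DEBParams, sigma_Y: float) -> float:
    """Growth standard deviation ``(1 - e^{-rB}) L_m sigma(Y)`` (length-free)."""
    if sigma_Y < 0:
        raise ValueError("sigma_Y must be >= 0")
    return float((1.0 - np.exp(-params.rB)) * params.L_m * sigma_Y)


def growth_transition(
    mesh: SizeMesh,
    params: DEBParams,
    feeding_level: float,
    sigma_Y: float,
    shrink_allowed: bool | None = None,
) -> np.ndarray:
    """Cell-to-cell growth probabilities, column per source cell.

    Column ``j`` integrates a normal distribution centred on the von
    Bertalanffy mean for source midpoint ``L_j`` over each destination cell.
    When shrinking is forbidden, mass in cells strictly below the source cell
    is truncated and the column rescaled back to its pre-truncation total, so
    survival mass is conserved.  With ``sigma_Y = 0`` each column collapses
    to a point mass in the cell containing the deterministic mean.
    """
    y = _check_feeding_level(feeding_level)
    if shrink_allowed is None:
        shrink_allowed = params.shrink_allowed
    mids = mesh.midpoints
    means = growth_mean(mids, params, y)
    sd = growth_sd(params, sigma_Y)
    n = mesh.n_cells

    mean_outside = (means < mesh.lower) | (means > mesh.upper)
    if sd == 0.0:
        G = np.zeros((n, n))
        for j, m in enumerate(means):
            if mesh.lower <= m <= mesh.upper:
                G[mesh.cell_containing(m), j] = 1.0
    else:
        # edges x sources -> CDF differences down each column
        cdf = norm.cdf(mesh.edges[:, None], loc=means[None, :], scale=sd)
        G = np.diff(cdf, axis=0)
    # Eviction guard: a mesh from build_mesh keeps every growth mean inside
    # (the von Bertalanffy map is a contraction onto the domain) and pads by
    # MESH_PADDING_SDS growth SDs, so well-padded interior columns keep
    # their mass.  Warn on user-supplied meshes that break either property.
    interior = (means - MESH_PADDING_SDS * sd >= mesh.lower) & (
        means + MESH_PADDING_SDS * sd <= mesh.upper
    )
    col_sums = G.sum(axis=0)
    lost = mean_outside | (interior & (col_sums < 1.0 - EVICTION_WARN_FRACTION))
    if np.any(lost):
        warnings.warn(
            f"{int(lost.sum())} growth column(s) lose > "
            f"{EVICTION_WARN_FRACTION:.0%} probability mass to eviction "
            "(growth mean outside or too close to the mesh bounds); "
            "consider widening the mesh",
            RuntimeWarning,
            stacklevel=2,
        )

    if not shrink_allowed:
        totals = G.sum(axis=0)
        G *= np.tril(np.ones((n, n)))  # zero destinations strictly below source (i < j)
        kept = G.sum(axis=0)
        scale = np.divide(totals, kept, out=np.zeros_like(kept), where=kept > 0)
        G *= scale[None, :]
    return G


def survival_cell_average(mesh: SizeMesh, params: DEBParams, feeding_level: float) -> np.ndarray:
    """Cell-averaged survival: exp(-mu) times the fraction of each cell
    below the starvation cutoff.

    The pointwise survival function is a step; averaging it over each cell
    makes the discretised kernel vary smoothly when the cutoff (hence L_m or
    E(Y)) is perturbed, instead of jumping cell by cell.
    """
    y = _check_feeding_level(feeding_level)
    cutoff = params.starvation_cutoff(y)
    left = mesh.edges[:-1]
    frac = np.clip((cutoff - left) / mesh.cell_width, 0.0, 1.0)
    return np.exp(-params.mu) * frac


def reproduction_cell_average(mesh: SizeMesh, params: DEBParams, feeding_level: float) -> np.ndarray:
    """Cell-averaged reproduction rate over the fertile window.

    Integrates ``E(Y) R_m L^2 / L_m^2`` exactly over the part of each cell
    inside ``[L_p, L_m E(Y)/kappa]`` and divides by the cell width, so the
    discretised fecundity responds smoothly to sub-cell shifts of the
    puberty length or the starvation cutoff under perturbation.
    """
    y = _check_feeding_level(feeding_level)
    cutoff = params.starvation_cutoff(y)
    a = np.maximum(mesh.edges[:-1], params.L_p)
    b = np.minimum(mesh.edges[1:], cutoff)
    span = np.clip(b - a, 0.0, None)
    # integral of L^2 over [a, b] = (b^3 - a^3) / 3
    integral = np.where(span > 0, (b**3 - a**3) / 3.0, 0.0)
    return y * params.R_m / params.L_m**2 * integral / mesh.cell_width


def reproduction_rate(L, params: DEBParams, feeding_level: float):
    """Offspring per step: ``E(Y) R_m L^2 / L_m^2`` for mature, fed lengths.

    Zero below puberty length L_p and above the starvation cutoff.
    """
    y = _check_feeding_level(feeding_level)
    L_arr = np.asarray(L, dtype=float)
    fertile = (L_arr >= params.L_p) & (L_arr <= params.starvation_cutoff(y))
    out = np.where(fertile, y * params.R_m * L_arr**2 / params.L_m**2, 0.0)
    return float(out) if np.ndim(L) == 0 else out


def offspring_distribution(mesh: SizeMesh, params: DEBParams) -> np.ndarray:
    """Probability vector of offspring lengths over destination cells.

    Normal with mean ``offspring_mean`` and variance ``offspring_variance``,
    cell-integrated and renormalised; a point mass when the variance is zero.
    Parent-independent, since the offspring mean is held constant.
    """
    if params.offspring_variance == 0.0:
        # mean-preserving deposition on the two cells whose midpoints
        # bracket the offspring length, so the discretised distribution
        # responds smoothly to sub-cell perturbations of L_b
        D = np.zeros(mesh.n_cells)
        mids = mesh.midpoints
        x = params.offspring_mean
        if x <= mids[0]:
            D[0] = 1.0
        elif x >= mids[-1]:
            D[-1] = 1.0
        else:
            k = int(np.searchsorted(mids, x)) - 1
            w = (x - mids[k]) / (mids[k + 1] - mids[k])
            D[k] = 1.0 - w
            D[k + 1] = w
        return D
    sd = float(np.sqrt(params.offspring_variance))
    cdf = norm.cdf(mesh.edges, loc=params.offspring_mean, scale=sd)
    D = np.diff(cdf)
    total = D.sum()
    if total <= 0:
        raise ValueError("offspring distribution has no mass on the mesh")
    return D / total


def assemble_kernel(
    mesh: SizeMesh, params: DEBParams, feeding_level: float, sigma_Y: float
) -> Kernel:
    """Assemble ``A[i, j] = G[i, j] S(L_j) + D[i] R(L_j)``.

    Survival multiplies the growth term; reproduction ``between t and t+1``
    is censused before the background mortality acts (a post-breeding
    convention).  Starved adults never reproduce regardless, because the
    fertile window of ``R`` closes at the same starvation cutoff as ``S``,
    so columns for starved source lengths are identically zero.
    """
    y = _check_feeding_level(feeding_level)
    S = survival_cell_average(mesh, params, y)
    G = growth_transition(mesh, params, y, sigma_Y)
    R = reproduction_cell_average(mesh, params, y)
    D = offspring_distribution(mesh, params)
    A = G * S[None, :] + np.outer(D, R)
    return Kernel(matrix=A, feeding_level=y, sigma_Y=float(sigma_Y), mesh=mesh, params=params)


def dominant_eigenpair(
    kernel: Kernel | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> tuple[float, np.ndarray]:
    """Dominant eigenvalue and stable size distribution by power iteration.

    Iterates ``v <- A v / ||A v||_1`` until successive eigenvalue estimates
    differ by less than ``tol``.  Returns ``(lambda, w)`` with ``w``
    normalised to sum 1.  For a nonnegative primitive kernel this converges
    to the Perron root and stable structure.
    """
    A = kernel.matrix if isinstance(kernel, Kernel) else np.asarray(kernel, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("kernel must be a square matrix")
    if np.any(A < 0):
        raise ValueError("kernel must be nonnegative")
    n = A.shape[0]
    v = np.full(n, 1.0 / n)
    lam_prev = np.inf
    for iteration in range(1, max_iter + 1):
        w = A @ v
        lam = w.sum()  # v sums to 1, so ||Av||_1 is the Rayleigh-like estimate
        if lam == 0.0:
            raise ValueError(
                f"kernel annihilated the population vector at iteration {iteration} "
                "(no non-starved, surviving sources)"
            )
        v = w / lam
        if abs(lam - lam_prev) < tol:
            return float(lam), v
        lam_prev = lam
    raise RuntimeError(
        f"power iteration failed to converge within {max_iter} iterations; "
        f"last eigenvalue estimate {lam_prev:.6g}, last change "
        f"{abs(lam - lam_prev):.3g} > tol {tol:g}"
    )


def mean_body_size(distribution: np.ndarray, mesh: SizeMesh) -> float:
    """Mean length of a (renormalised) distribution over mesh cells."""
    w = np.asarray(distribution, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("cannot take the mean of an all-zero size distribution")
    return float(np.dot(mesh.midpoints, w) / total)


def export_kernel(kernel: Kernel, path) -> None:
    """Write the kernel matrix as TSV plus a YAML sidecar of its provenance."""
    path = str(path)
    np.savetxt(path, kernel.matrix, delimiter="\t")
    sidecar = {
        "feeding_level": kernel.feeding_level,
        "sigma_Y": kernel.sigma_Y,
        "mesh": {
            "lower": kernel.mesh.lower,
            "upper": kernel.mesh.upper,
            "n_cells": kernel.mesh.n_cells,
        },
        "params": kernel.params.to_dict(),
    }
    with open(path + ".meta.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)
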