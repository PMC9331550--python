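"""Gaussian Markov random field precision structures.

Three GMRFs drive the spatial models:

* **Intrinsic CAR (ICAR)** — prior for the structured region effect s.  Its
  precision is ``tau_str * (D - W)`` where ``D`` is the diagonal of neighbour
  counts and ``W`` the adjacency indicator.  Each region's full conditional is
  Gaussian with mean equal to the average of its neighbours and variance
  ``1 / (tau_str * d_j)``.  The precision is rank-deficient (null space =
  per-component constants), so effects carry a sum-to-zero constraint.

* **Proper CAR** — prior for spatially varying coefficient vectors.  Written
  in conditional (G/H) form: ``G`` holds scaled neighbour weights
  ``g_ik = rho * a_ik / d_i`` and ``H = diag(tau_i^2)`` the conditional
  variances, with the symmetry condition ``g_ik tau_k^2 = g_ki tau_i^2``.
  The joint precision is ``B = H^{-1} (I - G) = (1/sigma2) (D - rho W)``,
  positive definite for ``rho`` in [0, 1).

* **RW2** — second-order random-walk smoothness prior for the non-linear age
  effect on an ordered bin grid; precision ``tau_age * D2' D2`` with ``D2``
  the second-difference operator.  Null space = affine functions of the grid.

All structures are parameterized by a *precision* scalar (tau = 1/variance);
conversion to the variance convention happens only at reporting boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import RegionGraph


@dataclass(frozen=True)
class IcarPrecision:
    """Intrinsic CAR precision Q = tau_str * (D - W) with sum-to-zero
    constraint per connected component."""

    Q: np.ndarray
    tau_str: float
    graph: RegionGraph
    sum_to_zero: bool = True

    @property
    def structure(self) -> np.ndarray:
        """The scale-free structure matrix D - W."""
        return self.Q / self.tau_str


@dataclass(frozen=True)
class CarStructure:
    """Proper CAR in conditional (G/H) form with joint precision B."""

    G: np.ndarray
    H: np.ndarray
    B: np.ndarray
    rho: float
    graph: RegionGraph

    @property
    def k(self) -> int:
        return self.B.shape[0]


@dataclass(frozen=True)
class Rw2Precision:
    """RW2 precision K = tau_age * D2' D2 over an ordered bin grid."""

    K: np.ndarray
    tau_age: float
    bin_grid: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.K.shape[0]

    @property
    def structure(self) -> np.ndarray:
        return self.K / self.tau_age


def icar_precision(graph: RegionGraph, tau_str: float) -> IcarPrecision:
    """Build the intrinsic CAR precision for a region graph.

    Raises if ``tau_str <= 0`` or if the graph has an isolated region (its
    conditional mean — the neighbour average — would be undefined).
    """
    if tau_str <= 0:
        raise ValueError(f"tau_str must be > 0, got {tau_str}")
    d = graph.degrees
    if np.any(d == 0):
        bad = [graph.region_ids[j] for j in np.flatnonzero(d == 0)]
        raise ValueError(f"isolated regions (degree 0) not allowed for ICAR: {bad}")
    Q = tau_str * (np.diag(d.astype(float)) - graph.adjacency())
    return IcarPrecision(Q=Q, tau_str=float(tau_str), graph=graph)


def icar_conditional(prec: IcarPrecision, j: int, values: np.ndarray):
    """Full conditional of region ``j`` given the other regions' values.

    ``values`` may have length n_regions (entry ``j`` ignored) or
    n_regions - 1 (other regions in region order).  Returns ``(mean, var)``
    with mean the neighbour average and var ``1 / (tau_str * d_j)``.
    """
    g = prec.graph
    n = g.n_regions
    values = np.asarray(values, dtype=float)
    if values.shape == (n,):
        full = values
    elif values.shape == (n - 1,):
        full = np.empty(n)
        full[:j] = values[:j]
        full[j] = np.nan
        full[j + 1:] = values[j:]
    else:
        raise ValueError(f"values must have length {n} or {n - 1}")
    nbrs = g.neighbors(j)
    if not nbrs:
        raise ValueError(f"region {g.region_ids[j]!r} is isolated; conditional undefined")
    mean = float(np.mean(full[nbrs]))
    var = 1.0 / (prec.tau_str * len(nbrs))
    return mean, var


def car_structure(
    graph: RegionGraph, tau_vec: np.ndarray, rho: float = 0.9
) -> CarStructure:
    """Build a proper CAR structure from per-region conditional variances.

    Weights follow the convention ``g_ik = rho * a_ik / d_i`` with
    ``tau_i^2 = sigma2 / d_i``; ``tau_vec`` must therefore be proportional to
    ``1/degrees`` (this is exactly the symmetry condition
    ``g_ik tau_k^2 = g_ki tau_i^2`` for this weight scheme).  The implied
    joint precision is ``B = (1/sigma2) (D - rho W)``.
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    tau_vec = np.asarray(tau_vec, dtype=float)
    if tau_vec.shape != (graph.n_regions,):
        raise ValueError("tau_vec length must equal number of regions")
    if np.any(tau_vec <= 0):
        raise ValueError("all conditional variances must be > 0")
    d = graph.degrees.astype(float)
    if np.any(d == 0):
        raise ValueError("isolated regions not allowed in a CAR structure")
    sigma2_each = tau_vec * d
    sigma2 = float(np.mean(sigma2_each))
    if np.max(np.abs(sigma2_each - sigma2)) > 1e-8 * sigma2:
        raise ValueError(
            "tau_vec incompatible with the g_ik = rho*a_ik/d_i weight scheme: "
            "conditional variances must be proportional to 1/degree"
        )
    W = graph.adjacency()
    G = rho * W / d[:, None]
    H = np.diag(tau_vec)
    B = (np.diag(d) - rho * W) / sigma2
    asym = np.max(np.abs(B - B.T)) / max(np.max(np.abs(B)), 1e-300)
    if asym > 1e-10:
        raise RuntimeError(f"CAR precision not symmetric (relative error {asym:.2e})")
    B = 0.5 * (B + B.T)
    return CarStructure(G=G, H=H, B=B, rho=float(rho), graph=graph)


def car_structure_from_scale(
    graph: RegionGraph, sigma2: float, rho: float = 0.9
) -> CarStructure:
    """Convenience: proper CAR with conditional variances sigma2 / d_i."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    return car_structure(graph, sigma2 / graph.degrees, rho=rho)


def car_logdensity(phi: np.ndarray, car: CarStructure) -> float:
    """Log density of the zero-mean proper-CAR Gaussian at ``phi``:
    -(k/2) log(2 pi) + (1/2) log|B| - (1/2) phi' B phi.
    """
    phi = np.asarray(phi, dtype=float)
    k = car.k
    if phi.shape != (k,):
        raise ValueError(f"phi must have length {k}, got shape {phi.shape}")
    sign, logdet = np.linalg.slogdet(car.B)
    if sign <= 0:
        raise ValueError("CAR precision is not positive definite")
    return float(-0.5 * k * np.log(2 * np.pi) + 0.5 * logdet - 0.5 * phi @ car.B @ phi)


def rw2_structure_matrix(n_bins: int) -> np.ndarray:
    """Scale-free RW2 structure D2' D2 (rank n_bins - 2)."""
    if n_bins < 3:
        raise ValueError(f"RW2 needs at least 3 bins, got {n_bins}")
    D2 = np.zeros((n_bins - 2, n_bins))
    for t in range(n_bins - 2):
        D2[t, t] = 1.0
        D2[t, t + 1] = -2.0
        D2[t, t + 2] = 1.0
    return D2.T @ D2


def rw2_precision(
    n_bins: int, tau_age: float, bin_grid: np.ndarray | None = None
) -> Rw2Precision:
    """RW2 precision over ``n_bins`` equally spaced ordered bins.

    The quadratic form is ``tau_age * sum_t (f_{t-1} - 2 f_t + f_{t+1})^2``;
    adding any affine function of the grid leaves it unchanged.
    """
    if tau_age <= 0:
        raise ValueError(f"tau_age must be > 0, got {tau_age}")
    K = tau_age * rw2_structure_matrix(n_bins)
    if bin_grid is None:
        bin_grid = np.arange(n_bins, dtype=float)
    bin_grid = np.asarray(bin_grid, dtype=float)
    if bin_grid.shape != (n_bins,):
        raise ValueError("bin_grid length must equal n_bins")
    if np.any(np.diff(bin_grid) <= 0):
        raise ValueError("bin_grid must be strictly increasing")
    return Rw2Precision(K=K, tau_age=float(tau_age), bin_grid=bin_grid)
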