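"""Model specifications and design assembly for the eight-model grid.

The stationary models progressively add region effects to a logistic
regression:

* Model 1 — fixed effects only
* Model 2 — + unstructured iid region effect nu
* Model 3 — + structured (ICAR) region effect s
* Model 4 — + both nu and s

The spatially-varying-coefficient (SVC) models repeat the progression on
top of region-indexed coefficients with a proper-CAR prior and a non-linear
(RW2) age effect:

* Model 5 — SVC + RW2 age
* Model 6 — Model 5 + nu
* Model 7 — Model 5 + s
* Model 8 — Model 5 + nu + s

When a covariate column is spatially varying it leaves the fixed block; its
overall mean effect mu_pi is sampled with a diffuse normal prior and the
per-region deviations get the CAR prior.  Models 1-4 include a linear
(standardized) age term instead of the RW2 smooth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .graph import RegionGraph
from .survey import SurveyDataset

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HyperPriors:
    """Hyperprior settings (weakly informative disease-mapping defaults).

    All precision scalars (structured, unstructured, RW2, CAR scale) get
    Gamma(shape, rate) priors; fixed effects and SVC means get
    N(0, beta_var) priors.
    """

    tau_shape: float = 1.0
    tau_rate: float = 5e-4
    beta_var: float = 1000.0
    car_rho: float = 0.9


@dataclass(frozen=True)
class ModelSpec:
    """Which effects a model includes (the Model 1-8 grid)."""

    model_id: int
    include_unstructured: bool
    include_structured: bool
    svc_covariates: tuple[str, ...] = ()
    include_rw2_age: bool = False
    svc_intercept: bool = False
    hyper: HyperPriors = field(default_factory=HyperPriors)

    def __post_init__(self) -> None:
        if self.model_id in (1, 2, 3, 4) and self.svc_covariates:
            raise ValueError("Models 1-4 are stationary: svc_covariates must be empty")
        if self.model_id in (5, 6, 7, 8) and not self.include_rw2_age:
            raise ValueError("Models 5-8 include the RW2 age effect")

    @classmethod
    def from_id(
        cls,
        model_id: int,
        svc_covariates: Sequence[str] = (),
        svc_intercept: bool = False,
        hyper: HyperPriors | None = None,
    ) -> "ModelSpec":
        if model_id not in range(1, 9):
            raise ValueError(f"model_id must be 1..8, got {model_id}")
        svc = model_id >= 5
        if svc and not (svc_covariates or svc_intercept):
            raise ValueError(f"Model {model_id} needs a non-empty svc covariate list")
        return cls(
            model_id=model_id,
            include_unstructured=model_id in (2, 4, 6, 8),
            include_structured=model_id in (3, 4, 7, 8),
            svc_covariates=tuple(svc_covariates) if svc else (),
            include_rw2_age=svc,
            svc_intercept=svc_intercept and svc,
            hyper=hyper or HyperPriors(),
        )


@dataclass
class ModelDesign:
    """Assembled design for one fitted model."""

    y: np.ndarray
    X_fixed: np.ndarray
    fixed_names: tuple[str, ...]
    X_svc: np.ndarray
    svc_names: tuple[str, ...]
    region_idx: np.ndarray
    age_bin: np.ndarray
    bin_grid: np.ndarray
    graph: RegionGraph
    spec: ModelSpec
    outcome: str = "outcome"

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_regions(self) -> int:
        return self.graph.n_regions


@dataclass
class ParamState:
    """One full parameter state of the sampler."""

    beta0: float
    beta: np.ndarray                  # fixed-effect coefficients
    mu_svc: np.ndarray                # SVC mean effects (one per svc column)
    phi: np.ndarray                   # (n_svc, n_regions) SVC deviations, row-mean 0
    nu: np.ndarray
    s: np.ndarray
    f_age: np.ndarray
    tau_str: float
    tau_unstr: float
    tau_age: float
    lambda_svc: np.ndarray            # CAR precision scale per svc column
    omega: np.ndarray | None = None

    def constraint_residuals(self, graph: RegionGraph) -> dict[str, float]:
        res = {}
        if self.s.size:
            res.update({
                f"s_comp{ci}": float(abs(self.s[np.asarray(comp)].sum()))
                for ci, comp in enumerate(graph.components())
            })
        if self.f_age.size:
            res["f_age_sum"] = float(abs(self.f_age.sum()))
        for c in range(self.phi.shape[0]):
            res[f"phi{c}_sum"] = float(abs(self.phi[c].sum()))
        return res


def build_design(
    dataset: SurveyDataset, spec: ModelSpec, graph: RegionGraph | None = None
) -> ModelDesign:
    """Split the encoded covariate matrix into fixed and varying blocks.

    Column ordering follows declaration order.  Zero-variance columns are
    dropped with a warning.  For stationary models a standardized linear age
    column ``age_lin`` (per 10 years, centred) joins the fixed block; for
    SVC models age enters through the RW2 smooth instead.
    """
    if graph is None:
        from .graph import south_africa_graph
        graph = south_africa_graph()
    if tuple(graph.region_ids) != tuple(dataset.region_ids):
        raise ValueError("graph region_ids must match dataset region_ids")
    unknown = set(spec.svc_covariates) - set(dataset.X.columns)
    if unknown:
        raise ValueError(f"svc covariates not in dataset: {sorted(unknown)}")

    fixed_cols, svc_cols = [], []
    for c in dataset.X.columns:
        col = dataset.X[c].to_numpy(float)
        if np.ptp(col) == 0.0:
            log.warning("dropping zero-variance column %r", c)
            continue
        (svc_cols if c in spec.svc_covariates else fixed_cols).append(c)

    X_fixed = dataset.X[fixed_cols].to_numpy(float) if fixed_cols else np.empty((dataset.n, 0))
    fixed_names = list(fixed_cols)
    if not spec.include_rw2_age:
        age_lin = (dataset.age - dataset.age.mean()) / 10.0
        X_fixed = np.column_stack([X_fixed, age_lin])
        fixed_names.append("age_lin")

    svc_names = list(svc_cols)
    X_svc = dataset.X[svc_cols].to_numpy(float) if svc_cols else np.empty((dataset.n, 0))
    if spec.svc_intercept:
        X_svc = np.column_stack([np.ones(dataset.n), X_svc])
        svc_names = ["(intercept)", *svc_names]

    design = ModelDesign(
        y=dataset.y.astype(float),
        X_fixed=X_fixed, fixed_names=tuple(fixed_names),
        X_svc=X_svc, svc_names=tuple(svc_names),
        region_idx=dataset.region_idx, age_bin=dataset.age_bin,
        bin_grid=dataset.bin_grid, graph=graph, spec=spec,
        outcome=dataset.outcome,
    )
    log.info(
        "design: n=%d, %d fixed, %d svc, regions=%d, bins=%d (model %d)",
        design.n, X_fixed.shape[1], X_svc.shape[1], graph.n_regions,
        len(dataset.bin_grid), spec.model_id,
    )
    return design


def initial_state(design: ModelDesign) -> ParamState:
    J = design.n_regions
    nb = design.bin_grid.shape[0]
    k = design.X_svc.shape[1]
    return ParamState(
        beta0=0.0,
        beta=np.zeros(design.X_fixed.shape[1]),
        mu_svc=np.zeros(k),
        phi=np.zeros((k, J)),
        nu=np.zeros(J),
        s=np.zeros(J),
        f_age=np.zeros(nb if design.spec.include_rw2_age else 0),
        tau_str=1.0, tau_unstr=1.0, tau_age=1.0,
        lambda_svc=np.ones(k),
    )


def linear_predictor(design: ModelDesign, state: ParamState) -> np.ndarray:
    """eta_i = beta0 + X_fixed beta + sum_c X_svc[:,c] (mu_c + phi_c[region])
    + nu_region + s_region + f_age[bin]; absent components contribute 0."""
    if state.beta.shape[0] != design.X_fixed.shape[1]:
        raise ValueError("beta length does not match fixed design")
    if state.phi.shape[0] != design.X_svc.shape[1]:
        raise ValueError("phi rows do not match svc design")
    eta = state.beta0 + (design.X_fixed @ state.beta if state.beta.size else 0.0)
    eta = np.full(design.n, state.beta0) if np.isscalar(eta) else eta
    j = design.region_idx
    for c in range(design.X_svc.shape[1]):
        eta = eta + design.X_svc[:, c] * (state.mu_svc[c] + state.phi[c, j])
    if design.spec.include_unstructured:
        eta = eta + state.nu[j]
    if design.spec.include_structured:
        eta = eta + state.s[j]
    if design.spec.include_rw2_age and state.f_age.size:
        eta = eta + state.f_age[design.age_bin]
    return np.asarray(eta, dtype=float)


def bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    """Sum of y*eta - log(1 + exp(eta)), overflow-safe."""
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if y.shape != eta.shape:
        raise ValueError("y and eta must have equal length")
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))
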