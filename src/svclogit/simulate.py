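"""Synthetic survey generator with known ground truth.

Generates individual-level data under exactly the generative structure the
models assume — the richest (Model 8) structure with every component
switchable off by zeroing its scale:

    logit p_i = beta0 + x_i' beta + sum_c x_ic * pi[c, region_i]
                + nu_region + s_region + f_age[bin_i]

with s ~ constrained intrinsic CAR, nu ~ iid Normal, pi columns ~ proper
CAR around their mean, and f_age a smooth curve on integer age bins.

Defaults emulate a 9-region national household survey of respondents aged
35+: ~5,500 records split across regions roughly proportional to the
provincial shares of such a survey, categorical covariate frequencies from
its descriptive table, and a binary outcome anchored at ~10% prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence
import json
import warnings

import numpy as np
import pandas as pd

from .gmrf import CarStructure, car_structure_from_scale, icar_precision
from .graph import RegionGraph, south_africa_graph
from .survey import (
    DEFAULT_COVARIATES,
    LEVELS,
    REFERENCES,
    RawSurveyTable,
    SurveyDataset,
    encode_covariates,
)


def logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


#: covariate level frequencies of the default scenario (aged-35+ household
#: survey shares; rural share corrected to the complement of urban)
DEFAULT_FREQS: dict[str, dict[str, float]] = {
    "sex": {"Male": 0.504, "Female": 0.496},
    "race": {"African": 0.847, "Colored": 0.089, "Indian/Asian": 0.010, "White": 0.054},
    "education": {"No primary": 0.040, "Primary": 0.178, "Secondary": 0.630, "Tertiary": 0.152},
    "marital": {"Single": 0.305, "Married": 0.575, "Divorced/Separated/Widowed": 0.120},
    "wage_work": {"Yes": 0.816, "No": 0.184},
    "residence": {"Urban": 0.693, "Rural": 0.307},
}

#: per-region record counts of the default 9-region scenario (total 5571)
DEFAULT_N_PER_REGION: dict[str, int] = {
    "EC": 700, "FS": 398, "Gau": 1557, "KN": 548, "Lim": 512,
    "Mp": 600, "NC": 380, "NW": 387, "WC": 489,
}

#: modest fixed-effect sizes (log-odds) for the default scenario
DEFAULT_EFFECTS: dict[str, float] = {
    "sex=Female": -0.25,
    "race=Colored": 0.20,
    "race=Indian/Asian": 0.40,
    "race=White": 0.15,
    "education=Primary": -0.10,
    "education=Secondary": -0.25,
    "education=Tertiary": -0.40,
    "marital=Married": 0.15,
    "marital=Divorced/Separated/Widowed": 0.25,
    "wage_work=No": 0.20,
    "residence=Rural": -0.15,
}


@dataclass
class TruthRecord:
    """Ground truth used to generate one synthetic dataset."""

    beta0: float
    beta: dict[str, float]
    nu: np.ndarray
    s: np.ndarray
    pi: dict[str, np.ndarray]          # column name -> per-region coefficients
    mu_pi: dict[str, float]
    f_age: np.ndarray
    bin_grid: np.ndarray
    tau_params: dict[str, float]
    seed: int

    def to_json(self) -> str:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            return v
        return json.dumps({k: conv(v) for k, v in asdict(self).items()}, indent=2)


@dataclass
class SimConfig:
    """Scenario description for :func:`simulate_survey`.

    Scales of the spatial pieces are on the log-odds scale: ``tau_str`` is
    the ICAR precision of s, ``sigma2_unstr`` the variance of nu,
    ``svc_scale`` the proper-CAR conditional-variance scale of the varying
    coefficient deviations (0 turns the SVC off), ``age_amplitude`` the
    range of the age curve.
    """

    graph: RegionGraph = field(default_factory=south_africa_graph)
    n_per_region: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_N_PER_REGION))
    freqs: Mapping[str, Mapping[str, float]] = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FREQS.items()})
    covariates: Sequence[str] = DEFAULT_COVARIATES
    beta0: float = logit(0.10)
    effects: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    svc_columns: Sequence[str] = ("sex=Female", "wage_work=No", "residence=Rural")
    svc_scale: float = 0.09            # conditional-variance scale; marginal sd ~0.2
    svc_rho: float = 0.9
    tau_str: float = 10.0              # structured-effect marginal sd ~0.25
    sigma2_unstr: float = 0.01         # unstructured-effect sd 0.1
    age_shape: str = "logarithmic"
    age_amplitude: float = 1.0
    age_range: tuple[int, int] = (35, 80)
    seed: int = 0

    def validate(self) -> None:
        for var, fr in self.freqs.items():
            tot = sum(fr.values())
            if abs(tot - 1.0) > 1e-6:
                raise ValueError(f"frequencies for {var!r} sum to {tot}, not 1")
        if any(n <= 0 for n in self.n_per_region.values()):
            raise ValueError("n_per_region entries must be positive")


def draw_spatial_effects(
    graph: RegionGraph,
    tau_str: float,
    sigma2_unstr: float,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (s, nu): constrained ICAR structured effects and iid noise.

    s is drawn exactly from the intrinsic CAR restricted to the sum-to-zero
    subspace of each connected component, via the eigendecomposition of the
    pseudo-inverse of Q (no MCMC).  nu ~ N(0, sigma2_unstr) iid.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    prec = icar_precision(graph, tau_str)  # also rejects isolated nodes
    n = graph.n_regions
    s = np.zeros(n)
    for comp in graph.components():
        idx = np.asarray(comp)
        Qc = prec.Q[np.ix_(idx, idx)]
        lam, V = np.linalg.eigh(Qc)
        keep = lam > 1e-10 * lam.max()
        z = rng.standard_normal(int(keep.sum()))
        s[idx] = V[:, keep] @ (z / np.sqrt(lam[keep]))
        s[idx] -= s[idx].mean()  # numerical tidy-up; already in constraint subspace
    nu = (
        np.sqrt(sigma2_unstr) * rng.standard_normal(n)
        if sigma2_unstr > 0 else np.zeros(n)
    )
    return s, nu


def draw_varying_coefficients(
    graph: RegionGraph,
    mu_pi: np.ndarray,
    car: CarStructure,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw a (coefficients x regions) matrix of spatially varying
    coefficients: row c ~ MVN(mu_pi[c] * 1, B^{-1}) independently."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if car.k != graph.n_regions:
        raise ValueError("CAR dimension must equal the number of regions")
    if car.rho >= 1.0:
        raise ValueError("simulation requires a proper CAR (rho < 1)")
    mu_pi = np.atleast_1d(np.asarray(mu_pi, dtype=float))
    L = np.linalg.cholesky(car.B)
    pi = np.empty((mu_pi.shape[0], car.k))
    for c in range(mu_pi.shape[0]):
        z = rng.standard_normal(car.k)
        # x = L^{-T} z  has covariance B^{-1}
        pi[c] = mu_pi[c] + np.linalg.solve(L.T, z)
    return pi


def make_age_effect(
    bin_grid: np.ndarray,
    shape: str = "logarithmic",
    amplitude: float = 1.0,
    custom: np.ndarray | None = None,
) -> np.ndarray:
    """Smooth true age-effect curve on the bin grid.

    "logarithmic": log(age - min + 1), increasing, emulating a risk curve
    that rises steeply through middle age then flattens.  "quadratic": a
    centred parabola.  "custom": caller-supplied vector, centred and with
    its linear trend removed (so it lies in the RW2-identified subspace).
    All shapes are centred to mean zero and scaled so max - min equals
    ``amplitude``.
    """
    g = np.asarray(bin_grid, dtype=float)
    if g.shape[0] < 3:
        raise ValueError("need at least 3 age bins")
    if shape == "logarithmic":
        f = np.log(g - g.min() + 1.0)
    elif shape == "quadratic":
        t = (g - g.mean()) / (g.max() - g.min())
        f = t ** 2
    elif shape == "custom":
        if custom is None:
            raise ValueError("custom shape requires a vector")
        f = np.asarray(custom, dtype=float).copy()
        if f.shape != g.shape:
            raise ValueError("custom vector length must match bin_grid")
        # project out the affine (RW2 null-space) component
        A = np.column_stack([np.ones_like(g), g - g.mean()])
        f = f - A @ np.linalg.lstsq(A, f, rcond=None)[0]
    else:
        raise ValueError(f"unknown age-effect shape {shape!r}")
    if amplitude == 0:
        return np.zeros_like(g)
    f = f - f.mean()
    rng_ = f.max() - f.min()
    if rng_ > 0:
        f = f * (amplitude / rng_)
    return f - f.mean()


def simulate_survey(config: SimConfig) -> tuple[SurveyDataset, TruthRecord]:
    """Generate one synthetic survey dataset plus its ground truth.

    Deterministic for a given config (all randomness flows from
    ``config.seed``).  Warns and redraws (new substream) if the outcome
    collapses to a single class.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    graph = config.graph
    region_ids = graph.region_ids

    # --- region-level truth -------------------------------------------------
    s, nu = draw_spatial_effects(graph, config.tau_str, config.sigma2_unstr, rng)
    svc_cols = tuple(config.svc_columns)
    mu_pi = np.array([config.effects.get(c, 0.0) for c in svc_cols])
    if svc_cols and config.svc_scale > 0:
        car = car_structure_from_scale(graph, config.svc_scale, rho=config.svc_rho)
        pi = draw_varying_coefficients(graph, mu_pi, car, rng)
    else:
        pi = np.tile(mu_pi[:, None], (1, graph.n_regions)) if svc_cols else np.zeros((0, graph.n_regions))

    lo, hi = config.age_range
    bin_grid = np.arange(lo, hi + 1, dtype=float)
    f_age = make_age_effect(bin_grid, config.age_shape, config.age_amplitude)

    # --- individual records -------------------------------------------------
    regions = np.concatenate([
        np.full(int(config.n_per_region[lab]), k)
        for k, lab in enumerate(region_ids)
    ])
    n = regions.shape[0]
    age = rng.integers(lo, hi + 1, size=n).astype(float)
    data = {"age": age, "region": np.asarray(region_ids, dtype=object)[regions]}
    for var in config.covariates:
        fr = config.freqs[var]
        levels = list(fr.keys())
        data[var] = rng.choice(levels, size=n, p=list(fr.values()))
    df = pd.DataFrame(data)
    df["person_id"] = np.arange(n)

    # encode through the same path real data takes
    df["_tmp_outcome"] = 0
    table = RawSurveyTable(df=df.rename(columns={"_tmp_outcome": "diabetes"}))
    ds = encode_covariates(
        table, region_ids, outcome="diabetes",
        covariates=config.covariates, bin_grid=bin_grid,
    )

    # --- linear predictor and outcome ----------------------------------------
    beta = {c: config.effects.get(c, 0.0) for c in ds.X.columns if c not in svc_cols}
    eta = np.full(n, config.beta0)
    Xnp = ds.X.to_numpy(float)
    for k, c in enumerate(ds.X.columns):
        if c in svc_cols:
            ci = svc_cols.index(c)
            eta += Xnp[:, k] * pi[ci, regions]
        else:
            eta += Xnp[:, k] * beta[c]
    eta += nu[regions] + s[regions] + f_age[ds.age_bin]
    y = (rng.random(n) < expit(eta)).astype(int)
    if y.min() == y.max():
        warnings.warn("simulated outcome collapsed to a single class; redrawing")
        y = (rng.random(n) < expit(eta)).astype(int)

    ds.y = y
    ds.validate()
    truth = TruthRecord(
        beta0=config.beta0, beta=beta, nu=nu, s=s,
        pi={c: pi[i] for i, c in enumerate(svc_cols)},
        mu_pi={c: float(mu_pi[i]) for i, c in enumerate(svc_cols)},
        f_age=f_age, bin_grid=bin_grid,
        tau_params={
            "tau_str": config.tau_str, "sigma2_unstr": config.sigma2_unstr,
            "svc_scale": config.svc_scale, "svc_rho": config.svc_rho,
        },
        seed=config.seed,
    )
    return ds, truth


def dataset_to_frame(ds: SurveyDataset) -> pd.DataFrame:
    """Raw-format table (CSV-writable) for a simulated dataset."""
    from .survey import decode_covariates

    df = decode_covariates(ds)
    df.insert(0, "person_id", np.arange(ds.n))
    df.insert(1, "age", ds.age.astype(int))
    df["region"] = np.asarray(ds.region_ids, dtype=object)[ds.region_idx]
    df[ds.outcome] = ds.y
    return df
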