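"""Polya-Gamma-augmented Gibbs sampler for the spatial logistic models.

Each sweep augments the Bernoulli-logit likelihood with omega_i ~ PG(1,
eta_i), after which every Gaussian block (fixed effects + SVC means, SVC
deviations, unstructured and structured region effects, RW2 age effect) has
a conjugate multivariate-normal full conditional under the working response
z_i = (y_i - 1/2) / omega_i with weight omega_i.  Each GMRF precision is
slice-sampled from its conditional with the corresponding Gaussian block
integrated out of the working likelihood, then the block is redrawn — a
joint blocked draw that sidesteps the precision/block funnel a plain
conjugate Gamma step falls into with few regions.  Constrained blocks (s per graph component, f_age,
SVC deviations) are re-centred after each sweep, with the removed mean
transferred into the intercept / SVC mean so the linear predictor is
unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .models import (
    ModelDesign,
    ModelSpec,
    ParamState,
    bernoulli_loglik,
    initial_state,
    linear_predictor,
)
from .pg import pg_draw

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class McmcSettings:
    """Chain length controls; ``seed`` is mandatory for reproducibility."""

    iters: int = 12000
    burnin: int = 2000
    thin: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iters <= self.burnin:
            raise ValueError("iters must exceed burnin")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.iters - self.burnin) // self.thin


@dataclass
class PosteriorDraws:
    """Retained posterior samples plus running linear-predictor summaries.

    ``params`` maps parameter-block name to an array with the retained-draw
    axis first.  ``eta_mean`` is the posterior mean linear predictor per
    record; ``deviance`` the per-draw model deviance (both are what DIC
    needs, without storing eta for every draw).
    """

    params: dict[str, np.ndarray]
    eta_mean: np.ndarray
    deviance: np.ndarray
    design: ModelDesign
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.deviance.shape[0]


def _draw_gaussian(P: np.ndarray, m: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw from N(P^{-1} m, P^{-1}) via Cholesky of the precision."""
    c, low = cho_factor(P, lower=True)
    mean = cho_solve((c, low), m)
    z = rng.standard_normal(m.shape[0])
    return mean + solve_triangular(c, z, lower=True, trans="T")


def _slice_sample_1d(logpost, x0: float, rng: np.random.Generator,
                     w: float = 1.0, max_steps: int = 30) -> float:
    """Neal's stepping-out/shrinkage slice sampler for one scalar."""
    f0 = logpost(x0)
    logy = f0 - rng.exponential(1.0)
    lo = x0 - w * rng.random()
    hi = lo + w
    for _ in range(max_steps):
        if logpost(lo) <= logy:
            break
        lo -= w
    for _ in range(max_steps):
        if logpost(hi) <= logy:
            break
        hi += w
    while True:
        x1 = lo + (hi - lo) * rng.random()
        if logpost(x1) > logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


def _precision_update(
    B0: np.ndarray, rank: int, A_diag: np.ndarray, m: np.ndarray,
    lam0: float, a_tau: float, b_tau: float, rng: np.random.Generator,
) -> float:
    """Partially collapsed update of a GMRF precision scalar.

    Samples lambda from p(lambda | working data) with the Gaussian block
    integrated out of the omega-weighted pseudo-likelihood — the caller then
    redraws the block given the new lambda, making the pair a joint blocked
    draw.  This avoids the funnel pathology of the plain conjugate Gamma
    step, where a block shrunk to zero pins its precision at the prior mode
    (and vice versa).  ``B0`` is the scale-free structure matrix (may be
    rank-deficient with the given generalized rank), ``A_diag``/``m`` the
    data precision diagonal and information vector.
    """

    def logpost(theta: float) -> float:
        lam = np.exp(theta)
        P = lam * B0 + np.diag(A_diag)
        try:
            c, low = cho_factor(P, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        quad = float(m @ cho_solve((c, low), m))
        return (a_tau * theta - b_tau * lam
                + 0.5 * rank * theta - 0.5 * logdet + 0.5 * quad)

    theta = _slice_sample_1d(logpost, float(np.log(lam0)), rng)
    return float(np.exp(theta))


def gibbs_fit(
    design: ModelDesign,
    spec: ModelSpec | None = None,
    mcmc: McmcSettings = McmcSettings(),
    keep_omega: bool = False,
) -> PosteriorDraws:
    """Run the Gibbs sampler and return retained draws.

    ``spec`` defaults to ``design.spec``.  Raises on non-finite linear
    predictors with a diagnostic state dump in the exception message.
    """
    spec = spec or design.spec
    hyper = spec.hyper
    rng = np.random.default_rng(mcmc.seed)

    y = design.y
    n = design.n
    J = design.n_regions
    j = design.region_idx
    kappa = y - 0.5
    Xf, Xs = design.X_fixed, design.X_svc
    pf, k = Xf.shape[1], Xs.shape[1]
    nb = design.bin_grid.shape[0] if spec.include_rw2_age else 0
    b = design.age_bin

    # fixed block: intercept + fixed effects + SVC mean effects
    A = np.column_stack([np.ones(n), Xf, Xs]) if (pf or k) else np.ones((n, 1))
    p0 = A.shape[1]
    prior_prec_theta = np.eye(p0) / hyper.beta_var

    W = design.graph.adjacency()
    Dg = np.diag(design.graph.degrees.astype(float))
    icar_struct = Dg - W                       # scale-free ICAR structure
    car_struct = Dg - hyper.car_rho * W        # scale-free proper-CAR structure
    comps = design.graph.components()
    icar_rank = J - len(comps)
    if spec.include_structured and np.any(design.graph.degrees == 0):
        raise ValueError("isolated regions: structured effect undefined")
    if nb:
        from .gmrf import rw2_structure_matrix
        K0 = rw2_structure_matrix(nb)

    state = initial_state(design)
    eta = linear_predictor(design, state)

    nd = mcmc.n_retained
    out: dict[str, np.ndarray] = {"beta0": np.empty(nd)}
    if pf:
        out["beta"] = np.empty((nd, pf))
    if k:
        out["mu_svc"] = np.empty((nd, k))
        out["phi"] = np.empty((nd, k, J))
        out["lambda_svc"] = np.empty((nd, k))
    if spec.include_unstructured:
        out["nu"] = np.empty((nd, J))
        out["tau_unstr"] = np.empty(nd)
    if spec.include_structured:
        out["s"] = np.empty((nd, J))
        out["tau_str"] = np.empty(nd)
    if nb:
        out["f_age"] = np.empty((nd, nb))
        out["tau_age"] = np.empty(nd)
    if keep_omega:
        out["omega"] = np.empty((nd, n))
    deviance = np.empty(nd)
    eta_sum = np.zeros(n)

    a_tau, b_tau = hyper.tau_shape, hyper.tau_rate
    kept = 0
    for it in range(mcmc.iters):
        if not np.all(np.isfinite(eta)):
            bad = int(np.flatnonzero(~np.isfinite(eta))[0])
            raise FloatingPointError(
                f"non-finite linear predictor at sweep {it}, record {bad}; "
                f"state: beta0={state.beta0:.3g}, "
                f"tau=({state.tau_str:.3g},{state.tau_unstr:.3g},{state.tau_age:.3g})"
            )
        omega = pg_draw(eta, rng.integers(2**31 - 1))
        z = kappa / omega

        # --- fixed block (intercept, fixed betas, SVC means) ---------------
        theta = np.concatenate([[state.beta0], state.beta, state.mu_svc])
        eta_rest = eta - A @ theta
        r = z - eta_rest
        Aw = A * omega[:, None]
        P = Aw.T @ A + prior_prec_theta
        theta = _draw_gaussian(P, Aw.T @ r, rng)
        state.beta0 = float(theta[0])
        state.beta = theta[1:1 + pf]
        state.mu_svc = theta[1 + pf:]
        eta = eta_rest + A @ theta

        # --- SVC deviations (proper CAR prior, one 9-dim block per column) -
        for c in range(k):
            xc = Xs[:, c]
            contrib = xc * state.phi[c, j]
            r = z - (eta - contrib)
            wxx = np.bincount(j, weights=omega * xc * xc, minlength=J)
            m = np.bincount(j, weights=omega * xc * r, minlength=J)
            state.lambda_svc[c] = _precision_update(
                car_struct, J, wxx, m, state.lambda_svc[c], a_tau, b_tau, rng)
            P = state.lambda_svc[c] * car_struct + np.diag(wxx)
            phi_new = _draw_gaussian(P, m, rng)
            eta = eta - contrib + xc * phi_new[j]
            shift = phi_new.mean()        # transfer mean into mu_svc[c];
            state.mu_svc[c] += shift      # (mu + phi) and hence eta unchanged
            state.phi[c] = phi_new - shift

        # --- unstructured region effect ------------------------------------
        if spec.include_unstructured:
            contrib = state.nu[j]
            r = z - (eta - contrib)
            wsum = np.bincount(j, weights=omega, minlength=J)
            m = np.bincount(j, weights=omega * r, minlength=J)
            state.tau_unstr = _precision_update(
                np.eye(J), J, wsum, m, state.tau_unstr, a_tau, b_tau, rng)
            prec = state.tau_unstr + wsum
            state.nu = m / prec + rng.standard_normal(J) / np.sqrt(prec)
            eta = eta - contrib + state.nu[j]

        # --- structured (ICAR) region effect -------------------------------
        if spec.include_structured:
            contrib = state.s[j]
            r = z - (eta - contrib)
            wsum = np.bincount(j, weights=omega, minlength=J)
            m = np.bincount(j, weights=omega * r, minlength=J)
            state.tau_str = _precision_update(
                icar_struct, icar_rank, wsum, m, state.tau_str, a_tau, b_tau, rng)
            P = state.tau_str * icar_struct + np.diag(wsum)
            s_new = _draw_gaussian(P, m, rng)
            eta = eta - contrib + s_new[j]
            if len(comps) == 1:           # sum-to-zero; mean into intercept
                mshift = s_new.mean()
                s_new -= mshift
                state.beta0 += mshift
            else:                         # per-component centring; intercept
                for comp in comps:        # absorbs the size-weighted mean
                    idx = np.asarray(comp)
                    mshift = s_new[idx].mean()
                    s_new[idx] -= mshift
                    state.beta0 += mshift * idx.size / J
            state.s = s_new
            if len(comps) > 1:            # eta drifts slightly; rebuild
                eta = linear_predictor(design, state)

        # --- RW2 age effect -------------------------------------------------
        if nb:
            contrib = state.f_age[b]
            r = z - (eta - contrib)
            wsum = np.bincount(b, weights=omega, minlength=nb)
            m = np.bincount(b, weights=omega * r, minlength=nb)
            state.tau_age = _precision_update(
                K0, nb - 2, wsum, m, state.tau_age, a_tau, b_tau, rng)
            P = state.tau_age * K0 + np.diag(wsum)
            f_new = _draw_gaussian(P, m, rng)
            eta = eta - contrib + f_new[b]
            shift = f_new.mean()
            state.beta0 += shift
            state.f_age = f_new - shift

        # --- retain ----------------------------------------------------------
        if it >= mcmc.burnin and (it - mcmc.burnin) % mcmc.thin == 0 and kept < nd:
            out["beta0"][kept] = state.beta0
            if pf:
                out["beta"][kept] = state.beta
            if k:
                out["mu_svc"][kept] = state.mu_svc
                out["phi"][kept] = state.phi
                out["lambda_svc"][kept] = state.lambda_svc
            if spec.include_unstructured:
                out["nu"][kept] = state.nu
                out["tau_unstr"][kept] = state.tau_unstr
            if spec.include_structured:
                out["s"][kept] = state.s
                out["tau_str"][kept] = state.tau_str
            if nb:
                out["f_age"][kept] = state.f_age
                out["tau_age"][kept] = state.tau_age
            if keep_omega:
                out["omega"][kept] = omega
            deviance[kept] = -2.0 * bernoulli_loglik(y, eta)
            eta_sum += eta
            kept += 1

    if kept < 100:
        warnings.warn(f"only {kept} retained draws; summaries will be noisy")
    return PosteriorDraws(
        params={k_: v[:kept] for k_, v in out.items()},
        eta_mean=eta_sum / max(kept, 1),
        deviance=deviance[:kept],
        design=design,
        meta={
            "seed": mcmc.seed, "iters": mcmc.iters, "burnin": mcmc.burnin,
            "thin": mcmc.thin, "model_id": spec.model_id, "outcome": design.outcome,
        },
    )


def scalar_draws(draws: PosteriorDraws) -> dict[str, np.ndarray]:
    """Flatten parameter blocks to named scalar chains."""
    d = draws.design
    labels = {
        "beta": list(d.fixed_names),
        "mu_svc": list(d.svc_names),
        "nu": [f"nu[{r}]" for r in d.graph.region_ids],
        "s": [f"s[{r}]" for r in d.graph.region_ids],
        "f_age": [f"f_age[{int(g)}]" for g in d.bin_grid],
        "lambda_svc": [f"lambda_svc[{c}]" for c in d.svc_names],
    }
    out: dict[str, np.ndarray] = {}
    for name, arr in draws.params.items():
        if name == "omega":
            continue
        if arr.ndim == 1:
            out[name] = arr
        elif arr.ndim == 2:
            labs = labels.get(name, [f"{name}[{i}]" for i in range(arr.shape[1])])
            for i in range(arr.shape[1]):
                key = labs[i] if name in ("nu", "s", "f_age", "lambda_svc") else f"{name}[{labs[i]}]"
                out[key] = arr[:, i]
        elif arr.ndim == 3 and name == "phi":
            for c, cname in enumerate(d.svc_names):
                for r, reg in enumerate(d.graph.region_ids):
                    out[f"phi[{cname},{reg}]"] = arr[:, c, r]
    return out


def posterior_summary(draws: PosteriorDraws, levels=(0.80, 0.95)):
    """Posterior mean, SD and equal-tailed credible intervals per scalar.

    Returns a DataFrame indexed by parameter name with columns ``mean``,
    ``sd`` and ``lo{level}`` / ``hi{level}`` for each requested level.
    """
    import pandas as pd

    chains = scalar_draws(draws)
    rows = {}
    for name, x in chains.items():
        row = {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0}
        for lev in levels:
            alpha = (1.0 - lev) / 2.0
            lo, hi = np.quantile(x, [alpha, 1.0 - alpha])
            pct = int(round(100 * lev))
            row[f"lo{pct}"] = float(lo)
            row[f"hi{pct}"] = float(hi)
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index")
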