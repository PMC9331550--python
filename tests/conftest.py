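import numpy as np
import pytest

from svclogit.graph import RegionGraph, build_region_graph, south_africa_graph


@pytest.fixture(scope="session")
def sa_graph() -> RegionGraph:
    return south_africa_graph()


@pytest.fixture
def path_graph() -> RegionGraph:
    """Three regions in a line: A - B - C."""
    return build_region_graph([("A", "B"), ("B", "C")], ["A", "B", "C"])


def random_connected_graph(n: int, rng: np.random.Generator) -> RegionGraph:
    """Random spanning tree plus extra edges (always connected, no isolates)."""
    labels = [f"R{i}" for i in range(n)]
    edges = []
    for i in range(1, n):
        j = int(rng.integers(0, i))
        edges.append((labels[j], labels[i]))
    for _ in range(n):
        a, b = rng.integers(0, n, size=2)
        if a != b:
            edges.append((labels[int(a)], labels[int(b)]))
    return build_region_graph(edges, labels)


def grid_posterior_1d(y, prior_var=1000.0, lo=-10.0, hi=10.0, num=4001):
    """Dense-grid posterior for an intercept-only Bernoulli-logit model.

    Returns (grid, normalized density) — the independent oracle for the
    sampler's beta0 marginal.
    """
    y = np.asarray(y, dtype=float)
    grid = np.linspace(lo, hi, num)
    logpost = y.sum() * grid - y.size * np.logaddexp(0.0, grid) \
        - grid**2 / (2 * prior_var)
    dens = np.exp(logpost - logpost.max())
    dens /= np.trapezoid(dens, grid)
    return grid, dens


def grid_posterior_2d(y, x, prior_var=1000.0, half_width=6.0, num=241):
    """Dense-grid posterior for a one-covariate Bernoulli-logit model.

    Grid is centred on the MLE +/- half_width; returns (g0, g1, density)
    with density normalized over the grid.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    mle = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    g0 = np.linspace(mle.params[0] - half_width, mle.params[0] + half_width, num)
    g1 = np.linspace(mle.params[1] - half_width, mle.params[1] + half_width, num)
    B0, B1 = np.meshgrid(g0, g1, indexing="ij")
    eta = B0[..., None] + B1[..., None] * x          # (num, num, n)
    logpost = (y * eta - np.logaddexp(0.0, eta)).sum(axis=-1) \
        - (B0**2 + B1**2) / (2 * prior_var)
    dens = np.exp(logpost - logpost.max())
    dens /= dens.sum() * (g0[1] - g0[0]) * (g1[1] - g1[0])
    return g0, g1, dens


def ks_vs_grid(draws, grid, dens) -> float:
    """Kolmogorov-Smirnov distance between sample draws and a grid density."""
    # trapezoidal cumulative: a plain cumsum carries a half-bin bias that
    # would dominate the KS distance at coarse grid spacings
    cdf = np.concatenate([[0.0],
                          np.cumsum((dens[1:] + dens[:-1]) * 0.5 * np.diff(grid))])
    cdf /= cdf[-1]
    F = np.interp(np.sort(draws), grid, cdf)
    n = len(draws)
    emp_hi = np.arange(1, n + 1) / n
    emp_lo = np.arange(0, n) / n
    return float(max(np.max(np.abs(F - emp_hi)), np.max(np.abs(F - emp_lo))))


def intercept_only_design(y, graph=None):
    """Minimal ModelDesign with no covariates (oracle test harness)."""
    from svclogit.models import ModelDesign, ModelSpec

    if graph is None:
        graph = build_region_graph([("A", "B")], ["A", "B"])
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    spec = ModelSpec(model_id=1, include_unstructured=False, include_structured=False)
    return ModelDesign(
        y=y, X_fixed=np.empty((n, 0)), fixed_names=(),
        X_svc=np.empty((n, 0)), svc_names=(),
        region_idx=np.zeros(n, dtype=int), age_bin=np.zeros(n, dtype=int),
        bin_grid=np.array([35.0]), graph=graph, spec=spec,
    )


def one_covariate_design(y, x, graph=None):
    from svclogit.models import ModelDesign, ModelSpec

    if graph is None:
        graph = build_region_graph([("A", "B")], ["A", "B"])
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    spec = ModelSpec(model_id=1, include_unstructured=False, include_structured=False)
    return ModelDesign(
        y=y, X_fixed=np.asarray(x, dtype=float).reshape(n, 1), fixed_names=("x",),
        X_svc=np.empty((n, 0)), svc_names=(),
        region_idx=np.zeros(n, dtype=int), age_bin=np.zeros(n, dtype=int),
        bin_grid=np.array([35.0]), graph=graph, spec=spec,
    )
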