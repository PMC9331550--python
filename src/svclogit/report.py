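"""Posterior reporting: choropleth layers, significance maps, age curves.

Turns posterior draws into the deliverables of a disease-mapping analysis:
per-region posterior means of spatially varying coefficients and spatial
effects (with posterior tail probabilities as a significance measure), the
non-linear age-effect curve with credible bands, and GeoJSON export of
region layers (label-joined, never order-joined).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gibbs import PosteriorDraws

#: two-sided 95% rule: a region is flagged when P(effect > 0) is outside
#: [0.025, 0.975]
SIG_HI = 0.975
SIG_LO = 0.025


@dataclass
class RegionValueLayer:
    """One scalar per region plus an optional posterior probability."""

    region_ids: tuple[str, ...]
    values: np.ndarray
    name: str
    significance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.region_ids),):
            raise ValueError("one value per region required")
        if self.significance is not None:
            self.significance = np.asarray(self.significance, dtype=float)
            if self.significance.shape != self.values.shape:
                raise ValueError("significance shape mismatch")
            if np.any((self.significance < 0) | (self.significance > 1)):
                raise ValueError("significance must be probabilities")

    def significant(self) -> np.ndarray:
        """Boolean flags under the 0.975 / 0.025 tail rule."""
        if self.significance is None:
            raise ValueError("layer has no significance probabilities")
        return (self.significance >= SIG_HI) | (self.significance <= SIG_LO)


@dataclass
class AgeCurve:
    """Posterior mean age effect with equal-tailed credible bands."""

    bin_grid: np.ndarray
    mean: np.ndarray
    lo80: np.ndarray
    hi80: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray

    def __post_init__(self) -> None:
        m = self.mean
        for nm in ("lo80", "hi80", "lo95", "hi95"):
            if getattr(self, nm).shape != m.shape:
                raise ValueError("band length mismatch")
        if np.any(self.lo80 > m) or np.any(self.hi80 < m):
            raise ValueError("80% band must contain the mean")
        if np.any(self.lo95 > self.lo80) or np.any(self.hi95 < self.hi80):
            raise ValueError("95% band must contain the 80% band")


def svc_effect_layers(draws: PosteriorDraws) -> list[RegionValueLayer]:
    """One layer per spatially varying covariate.

    Layer value = posterior mean of the region coefficient pi[c, j] =
    mu_c + phi_c[j]; significance = posterior P(pi[c, j] > 0).
    """
    if "phi" not in draws.params:
        raise ValueError("model has no spatially varying coefficients (Models 1-4)")
    d = draws.design
    phi = draws.params["phi"]                     # (nd, k, J)
    mu = draws.params["mu_svc"][:, :, None]       # (nd, k, 1)
    pi = phi + mu
    layers = []
    for c, cname in enumerate(d.svc_names):
        layers.append(RegionValueLayer(
            region_ids=d.graph.region_ids,
            values=pi[:, c, :].mean(axis=0),
            name=f"svc:{cname}",
            significance=(pi[:, c, :] > 0).mean(axis=0),
        ))
    return layers


def spatial_effect_layer(draws: PosteriorDraws, which: str = "s") -> RegionValueLayer:
    """Posterior mean structured spatial effect (log-odds scale) per region
    with P(effect > 0) as significance."""
    if which not in draws.params:
        raise ValueError(f"model has no {which!r} effect")
    arr = draws.params[which]
    return RegionValueLayer(
        region_ids=draws.design.graph.region_ids,
        values=arr.mean(axis=0),
        name=f"spatial:{which}",
        significance=(arr > 0).mean(axis=0),
    )


def age_curve(draws: PosteriorDraws) -> AgeCurve:
    """Posterior mean and 80%/95% bands of the RW2 age effect."""
    if "f_age" not in draws.params:
        raise ValueError("model has no RW2 age effect")
    f = draws.params["f_age"]
    lo80, hi80 = np.quantile(f, [0.10, 0.90], axis=0)
    lo95, hi95 = np.quantile(f, [0.025, 0.975], axis=0)
    return AgeCurve(
        bin_grid=draws.design.bin_grid, mean=f.mean(axis=0),
        lo80=lo80, hi80=hi80, lo95=lo95, hi95=hi95,
    )


def export_choropleth(
    layer: RegionValueLayer,
    polygons: dict | str | Path,
    out_path: str | Path | None = None,
    label_property: str = "name",
    png_path: str | Path | None = None,
) -> dict:
    """Join a region layer onto polygons and write a GeoJSON choropleth.

    Features are matched by region *label*, never by order.  Output feature
    properties are ``{label_property, layer, value, significance}`` in that
    order.  Optionally renders a PNG with a diverging blue-white-orange
    scale centred at zero (negative effects blue, positive orange).
    """
    if not isinstance(polygons, dict):
        polygons = json.loads(Path(polygons).read_text())
    by_label = {}
    for f in polygons.get("features", []):
        props = f.get("properties") or {}
        if label_property in props:
            by_label[str(props[label_property])] = f
    missing = [r for r in layer.region_ids if r not in by_label]
    if missing:
        raise ValueError(f"no polygon for region(s): {missing}")
    feats = []
    for i, r in enumerate(layer.region_ids):
        src = by_label[r]
        props = {label_property: r, "layer": layer.name, "value": float(layer.values[i])}
        if layer.significance is not None:
            props["significance"] = float(layer.significance[i])
        feats.append({"type": "Feature", "properties": props, "geometry": src["geometry"]})
    fc = {"type": "FeatureCollection", "features": feats}
    if out_path is not None:
        Path(out_path).write_text(json.dumps(fc, indent=1, sort_keys=False))
    if png_path is not None:
        _render_choropleth_png(fc, layer, Path(png_path), label_property)
    return fc


def _render_choropleth_png(fc: dict, layer: RegionValueLayer, path: Path,
                           label_property: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import TwoSlopeNorm
    from shapely.geometry import shape

    vmax = float(np.max(np.abs(layer.values))) or 1.0
    norm = TwoSlopeNorm(vmin=-vmax, vcenter=0.0, vmax=vmax)
    cmap = plt.get_cmap("coolwarm")
    fig, ax = plt.subplots(figsize=(6, 6))
    for f in fc["features"]:
        geom = shape(f["geometry"])
        polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
        color = cmap(norm(f["properties"]["value"]))
        for p in polys:
            xs, ys = p.exterior.xy
            ax.fill(xs, ys, facecolor=color, edgecolor="black", linewidth=0.5)
        c = geom.representative_point()
        ax.annotate(f["properties"][label_property], (c.x, c.y),
                    ha="center", fontsize=7)
    ax.set_title(layer.name)
    ax.set_aspect("equal")
    fig.colorbar(plt.cm.ScalarMappable(norm=norm, cmap=cmap), ax=ax, shrink=0.7)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_age_curve(curve: AgeCurve, path: str | Path, title: str = "Age effect") -> None:
    """Line plot of the posterior mean age effect with 80/95% bands."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    g = curve.bin_grid
    ax.fill_between(g, curve.lo95, curve.hi95, color="0.85", label="95% CI")
    ax.fill_between(g, curve.lo80, curve.hi80, color="0.7", label="80% CI")
    ax.plot(g, curve.mean, "k-", lw=1.5, label="posterior mean")
    ax.axhline(0, color="k", lw=0.5, ls=":")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("effect on log-odds")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
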