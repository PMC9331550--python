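"""Deviance summaries and DIC-based model comparison.

DIC = D̄ + pD, where D̄ is the posterior mean of the model deviance
(-2 log-likelihood) and pD = D̄ - D(θ̄) is the effective number of
parameters, with D(θ̄) the deviance at the plug-in posterior-mean linear
predictor.  Lower DIC is better; differences under 3 do not distinguish
models, differences of 3-7 distinguish them weakly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gibbs import PosteriorDraws
from .models import ModelDesign, bernoulli_loglik


def deviance(y: np.ndarray, eta: np.ndarray) -> float:
    """Model deviance -2 * Bernoulli log-likelihood at linear predictor eta."""
    return -2.0 * bernoulli_loglik(y, eta)


@dataclass(frozen=True)
class DicReport:
    """DIC decomposition for one fitted model."""

    d_bar: float
    d_hat: float
    p_d: float
    dic: float
    model_id: int | None = None
    outcome: str | None = None
    negative_pd: bool = False

    @classmethod
    def from_components(
        cls, d_bar: float, p_d: float,
        model_id: int | None = None, outcome: str | None = None,
    ) -> "DicReport":
        """Aggregate a (D̄, pD) pair into a DIC report via DIC = D̄ + pD."""
        return cls(
            d_bar=float(d_bar), d_hat=float(d_bar) - float(p_d), p_d=float(p_d),
            dic=float(d_bar) + float(p_d), model_id=model_id, outcome=outcome,
            negative_pd=p_d < 0,
        )


def dic(draws: PosteriorDraws, design: ModelDesign | None = None) -> DicReport:
    """Compute the DIC report from posterior draws.

    D̄ averages the per-draw deviances; D(θ̄) plugs in the posterior-mean
    linear predictor.  A negative pD is reported with a flag, not clamped.
    """
    design = design or draws.design
    if draws.n_draws < 100:
        import warnings
        warnings.warn(f"DIC from only {draws.n_draws} draws is noisy")
    d_bar = float(np.mean(draws.deviance))
    d_hat = deviance(design.y, draws.eta_mean)
    p_d = d_bar - d_hat
    return DicReport(
        d_bar=d_bar, d_hat=d_hat, p_d=p_d, dic=d_bar + p_d,
        model_id=draws.meta.get("model_id"), outcome=draws.meta.get("outcome"),
        negative_pd=p_d < 0,
    )


def _label(delta: float) -> str:
    if delta == 0:
        return "best"
    if delta < 3:
        return "indistinguishable"
    if delta <= 7:
        return "weakly distinguishable"
    return "distinguishable"


def compare_models(reports: list[DicReport]) -> pd.DataFrame:
    """Rank DIC reports (same outcome) ascending and label the gaps.

    Labels follow the <3 / 3-7 / >7 discrimination rule relative to the
    best model.
    """
    if len(reports) < 2:
        raise ValueError("need at least two models to compare")
    outcomes = {r.outcome for r in reports}
    if len(outcomes) > 1:
        raise ValueError(f"mixed outcomes in comparison: {sorted(map(str, outcomes))}")
    rows = sorted(reports, key=lambda r: r.dic)
    best = rows[0].dic
    return pd.DataFrame(
        [
            {
                "model_id": r.model_id, "outcome": r.outcome,
                "pD": r.p_d, "D_bar": r.d_bar, "DIC": r.dic,
                "delta_DIC": r.dic - best, "label": _label(r.dic - best),
                "negative_pd": r.negative_pd,
            }
            for r in rows
        ]
    )


def render_comparison(table: pd.DataFrame, digits: int = 2) -> str:
    """Aligned-text layout: rows pD / D̄ / DIC, one column per model."""
    cols = [f"Model {int(m)}" for m in table["model_id"]]
    lines = [" " * 8 + "".join(f"{c:>12s}" for c in cols)]
    for row_name, key in (("pD", "pD"), ("D_bar", "D_bar"), ("DIC", "DIC")):
        vals = "".join(f"{v:>12.{digits}f}" for v in table[key])
        lines.append(f"{row_name:<8s}{vals}")
    return "\n".join(lines)
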