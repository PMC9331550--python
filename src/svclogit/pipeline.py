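"""End-to-end pipeline: simulate/load -> fit model set -> compare -> map.

Driven by a single config mapping (YAML/JSON); every source of randomness
flows from the config seed, and a manifest (inputs, seeds, versions, SHA-256
hashes of outputs) makes reruns verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .dic import compare_models, dic, render_comparison
from .gibbs import McmcSettings, gibbs_fit, posterior_summary
from .graph import build_region_graph, read_edge_list, south_africa_graph
from .models import HyperPriors, ModelSpec, build_design
from .report import age_curve, spatial_effect_layer, svc_effect_layers
from .simulate import SimConfig, dataset_to_frame, simulate_survey
from .survey import apply_eligibility, encode_covariates, load_survey

log = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_graph(cfg: dict):
    if "graph" in cfg:
        edges = read_edge_list(cfg["graph"])
        ids = cfg.get("region_ids") or sorted({lab for e in edges for lab in e})
        return build_region_graph(edges, ids)
    return south_africa_graph()


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the configured analysis and return the manifest dict.

    Config keys: ``seed`` (required); either ``simulate`` (SimConfig field
    overrides) or ``data`` (path/outcome/covariates for a CSV); ``models``
    (list of model ids, default [1..8]); ``svc_covariates``; ``mcmc``
    (iters/burnin/thin); optional ``graph`` edge-list path + ``region_ids``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    rng = np.random.default_rng(seed)
    graph = _load_graph(config)
    manifest: dict = {
        "version": __version__, "seed": seed, "config": config,
        "outputs": {}, "status": "running",
    }

    try:
        # --- data ------------------------------------------------------------
        truth = None
        if "data" in config:
            dcfg = config["data"]
            table = load_survey(dcfg["path"], schema=dcfg.get("schema"))
            covs = tuple(dcfg.get("covariates") or ())
            kwargs = {"covariates": covs} if covs else {}
            table = apply_eligibility(table, dcfg["outcome"], **kwargs)
            dataset = encode_covariates(
                table, graph.region_ids, outcome=dcfg["outcome"], **kwargs
            )
            manifest["data"] = {"path": str(dcfg["path"]), "sha256": _sha256(Path(dcfg["path"]))}
        else:
            scfg = dict(config.get("simulate") or {})
            scfg.setdefault("seed", seed)
            sim = SimConfig(graph=graph, **scfg)
            dataset, truth = simulate_survey(sim)
            data_path = out / "simulated_data.csv"
            dataset_to_frame(dataset).to_csv(data_path, index=False)
            (out / "truth.json").write_text(truth.to_json())
            manifest["outputs"]["data"] = _sha256(data_path)
            manifest["outputs"]["truth"] = _sha256(out / "truth.json")

        # --- fits ------------------------------------------------------------
        model_ids = list(config.get("models") or range(1, 9))
        svc_covs = tuple(config.get("svc_covariates") or
                         (truth.pi.keys() if truth else ()))
        mcfg = dict(config.get("mcmc") or {})
        hyper = HyperPriors(**(config.get("hyperpriors") or {}))
        reports, fits = [], {}
        for mid in model_ids:
            spec = ModelSpec.from_id(mid, svc_covariates=svc_covs if mid >= 5 else (),
                                     hyper=hyper)
            design = build_design(dataset, spec, graph)
            mc = McmcSettings(seed=int(rng.integers(2**31 - 1)), **mcfg)
            draws = gibbs_fit(design, spec, mc)
            fits[mid] = draws
            reports.append(dic(draws))
            posterior_summary(draws).to_csv(out / f"summary_model{mid}.csv")
            manifest["outputs"][f"summary_model{mid}"] = _sha256(out / f"summary_model{mid}.csv")

        # --- comparison -------------------------------------------------------
        table = compare_models(reports)
        table.to_csv(out / "comparison.csv", index=False)
        (out / "comparison.txt").write_text(render_comparison(table))
        manifest["outputs"]["comparison"] = _sha256(out / "comparison.csv")
        best_id = int(table.iloc[0]["model_id"])
        manifest["best_model"] = best_id

        # --- maps / curves ----------------------------------------------------
        layer_dicts = []
        best = fits[best_id]
        if "phi" in best.params:
            layer_dicts += [_layer_dict(l) for l in svc_effect_layers(best)]
        for which in ("s", "nu"):
            if which in best.params:
                layer_dicts.append(_layer_dict(spatial_effect_layer(best, which)))
        if layer_dicts:
            (out / "layers.json").write_text(json.dumps(layer_dicts, indent=1))
            manifest["outputs"]["layers"] = _sha256(out / "layers.json")
        if "f_age" in best.params:
            curve = age_curve(best)
            import pandas as pd
            pd.DataFrame({
                "age": curve.bin_grid, "mean": curve.mean,
                "lo80": curve.lo80, "hi80": curve.hi80,
                "lo95": curve.lo95, "hi95": curve.hi95,
            }).to_csv(out / "age_curve.csv", index=False)
            manifest["outputs"]["age_curve"] = _sha256(out / "age_curve.csv")
        manifest["status"] = "ok"
    except Exception as exc:  # keep partial outputs, mark failure
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _layer_dict(layer) -> dict:
    d = {"name": layer.name, "region_ids": list(layer.region_ids),
         "values": layer.values.tolist()}
    if layer.significance is not None:
        d["significance"] = layer.significance.tolist()
    return d
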