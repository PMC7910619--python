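"""Three-step coarse-to-fine pipeline orchestration.

Step 1 fits the model on a deliberately small node set (K < N) by Gibbs
sampling; step 2 refines the node set (K >= N) and transfers the latent
fields by GP interpolation; step 3 fine-tunes under the one-to-one
constraint and emits the final table.  `run_pipeline` drives the three
steps from a config mapping and, when given an output directory, writes
the table, the log-density trace, timings and a manifest.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .assignment import ElementTable, fine_tune
from .errors import ParameterError
from .expansion import interpolate_state
from .layouts import NodeLayout, expand_layout, layout_from_spec
from .mcmc import PosteriorEnsemble, estimate, run_gibbs
from .model import FeatureMatrix, Hyperparams, ModelState
from .synthetic import element_fixture

__all__ = ["PipelineResult", "run_pipeline", "square_preset", "cone_preset", "smoke_preset"]

REQUIRED_ARTIFACTS = (
    "config_echo.json",
    "table.csv",
    "table.json",
    "trace.csv",
    "timings.json",
)


@dataclass
class PipelineResult:
    table: ElementTable
    coarse_ensemble: PosteriorEnsemble
    final_state: ModelState
    coarse_layout: NodeLayout
    fine_layout: NodeLayout
    timings: dict
    outdir: Path | None = None


def square_preset(**overrides) -> dict:
    """Standard-operating-point config for the 5x5 -> 9x9 square table."""
    cfg = {
        "layout": {"kind": "grid", "sides": [5, 5]},
        "hyper": {"nu_g": 1 / 3, "l_g": 3.0, "nu_r": 1 / 3, "l_r": 3.0},
        "mcmc": {"n_sweeps": 10_000, "burn_in": 5_000, "thin": 1},
        "fine_tune": {"n_iter": 10},
        "seed": 0,
    }
    cfg.update(overrides)
    return cfg


def cone_preset(**overrides) -> dict:
    """Conical layout: 25 nodes on 4 slices refined to 85 on 7 slices."""
    cfg = square_preset(**overrides)
    cfg["layout"] = {"kind": "cone", "slice_counts": [1, 4, 8, 12]}
    return cfg


def smoke_preset(**overrides) -> dict:
    """Short run for end-to-end checks (fixture data, few sweeps)."""
    cfg = square_preset(**overrides)
    cfg["mcmc"] = {"n_sweeps": 200, "burn_in": 100, "thin": 1}
    return cfg


def _load_data(config, data: FeatureMatrix | None) -> FeatureMatrix:
    if data is not None:
        return data
    spec = config.get("data", {})
    if "csv" in spec:
        return FeatureMatrix.from_csv(
            spec["csv"], standardize=spec.get("standardize", True)
        )
    if spec.get("fixture", False) or not spec:
        return element_fixture(seed=spec.get("seed", 0))
    raise ParameterError("config.data must give 'csv' or 'fixture'")


def run_pipeline(
    config: dict,
    data: FeatureMatrix | None = None,
    outdir=None,
) -> PipelineResult:
    """Execute the full coarse-to-fine pipeline described by ``config``.

    ``config`` keys: layout (spec mapping), hyper, mcmc {n_sweeps, burn_in,
    thin}, fine_tune {n_iter}, seed, and optionally data {csv | fixture}.
    ``data`` overrides the config's data source.  Schema problems are
    reported before any compute; stage failures carry the stage name.
    """
    hyper = Hyperparams(**config.get("hyper", {}))
    coarse = layout_from_spec(config["layout"])
    fine = expand_layout(coarse)
    X = _load_data(config, data)
    if fine.K < X.N:
        raise ParameterError(
            f"expanded layout has K={fine.K} < N={X.N} items; "
            "one-to-one assignment is infeasible"
        )
    mcmc_cfg = config.get("mcmc", {})
    n_sweeps = int(mcmc_cfg.get("n_sweeps", 10_000))
    burn_in = int(mcmc_cfg.get("burn_in", n_sweeps // 2))
    thin = int(mcmc_cfg.get("thin", 1))
    n_ft = int(config.get("fine_tune", {}).get("n_iter", 10))
    seed = int(config.get("seed", 0))
    rng = np.random.default_rng(seed)

    timings = {}
    t0 = time.perf_counter()
    ensemble = run_gibbs(X, coarse, hyper, n_sweeps, burn_in, rng, thin)
    coarse_state = estimate(ensemble, X)
    timings["step1_gibbs_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fine_state = interpolate_state(coarse_state, coarse, fine, hyper)
    timings["step2_expand_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    table, final_state = fine_tune(X, fine_state, fine, hyper, n_ft, rng)
    timings["step3_finetune_s"] = time.perf_counter() - t0

    table.provenance.update(
        {"seed": seed, "config": _jsonable(config), "coarse_K": coarse.K, "fine_K": fine.K}
    )
    result = PipelineResult(
        table, ensemble, final_state, coarse, fine, timings, None
    )
    if outdir is not None:
        result.outdir = _write_artifacts(result, config, seed)
    return result


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=str))


def _write_artifacts(result: PipelineResult, config: dict, seed: int) -> Path:
    outdir = Path(result.outdir) if result.outdir else None
    outdir = Path(config.get("outdir", "ptg_run")) if outdir is None else outdir
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config_echo.json", "w") as fh:
        json.dump({"config": _jsonable(config), "seed": seed}, fh, indent=2)
    result.table.to_csv(outdir / "table.csv")
    result.table.to_json(outdir / "table.json")
    result.coarse_ensemble.trace_frame().to_csv(outdir / "trace.csv", index=False)
    with open(outdir / "timings.json", "w") as fh:
        json.dump(result.timings, fh, indent=2)
    manifest = {
        "artifacts": sorted(p.name for p in outdir.iterdir()),
        "required": list(REQUIRED_ARTIFACTS),
        "complete": all((outdir / a).exists() for a in REQUIRED_ARTIFACTS),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir
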