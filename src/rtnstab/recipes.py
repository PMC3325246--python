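"""Named experiment recipes and the config-driven runner.

Each recipe reproduces one figure-style analysis at desk scale: a sweep,
an enumeration, or an attractor census, parameterized through a flat
config mapping.  ``run_experiment`` validates a config file, executes
the recipe under a master seed, and writes TSV tables, a JSON manifest
and a plain-text log into the output directory.  Re-running the same
config and seed reproduces the tables byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import pathlib
import sys
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from . import __version__, attractor_stats, netgen, stability
from .dynamics import DynamicsSpec, RunLimits
from .errors import ConfigError
from .netgen import EnsembleSpec


def _base_specs(params: dict) -> tuple[EnsembleSpec, DynamicsSpec]:
    ens = EnsembleSpec(
        n_genes=int(params.get("n_genes", 10)),
        k=params.get("k"),
        density=params.get("density", 1.0 if params.get("k") is None else None),
        topology=params.get("topology", "regular"),
        weight_scheme=params.get("weight_scheme", "binary_pm1"),
        allow_self_loops=bool(params.get("allow_self_loops", True)),
    )
    limits = RunLimits(t_max=params.get("t_max"))
    dyn = DynamicsSpec(
        map=params.get("map", "pm1"),
        norm=params.get("norm", "step"),
        steepness=float(params.get("steepness", 10.0)),
        zero_convention=params.get("zero_convention", "minus"),
        limits=limits,
    )
    return ens, dyn


def _sweep_recipe(axis: str, grid_key: str, default_grid: list):
    def run(params: dict, seed: int, n_trials: int) -> dict[str, pd.DataFrame]:
        ens, dyn = _base_specs(params)
        grid = params.get(grid_key, default_grid)
        table = stability.sweep(axis, grid, ens, dyn, n_trials, seed)
        return {"stability": table}

    return run


def _recipe_period_distribution(params, seed, n_trials):
    ens, dyn = _base_specs(params)
    rng = np.random.Generator(np.random.PCG64(seed))
    dist = attractor_stats.period_distribution(ens, dyn, n_trials, rng)
    rows = [{"period": p, "count": c, "freq": c / dist.total}
            for p, c in sorted(dist.counts.items())]
    tables = {"periods": pd.DataFrame(rows)}
    ratios = [{"even_period": L, "ratio": dist.even_odd_ratio(L)}
              for L in (2, 4, 6)]
    tables["even_odd_ratios"] = pd.DataFrame(ratios)
    try:
        fits = attractor_stats.fit_decay(dist)
        tables["decay_fits"] = pd.DataFrame(
            [{"branch": b, **vals} for b, vals in fits.items()])
    except Exception:
        pass  # thin support at small n_trials is not an error for the recipe
    return tables


def _recipe_transient_scaling(params, seed, n_trials):
    ens, dyn = _base_specs(params)
    grid = params.get("n_grid", [4, 8, 16])
    ens_grid = [ens.replace(n_genes=int(n)) for n in grid]
    table = attractor_stats.transient_summary(ens_grid, dyn, n_trials, seed)
    return {"transients": table}


def _recipe_discovery(params, seed, n_trials):
    ens, dyn = _base_specs(params)
    rng = np.random.Generator(np.random.PCG64(seed))
    curve = attractor_stats.discovery_curve(
        ens, dyn, rng,
        target_count=params.get("target_count"),
        max_samples=int(params.get("max_samples", n_trials)))
    rows = [{"discovery": i + 1, "sample": s}
            for i, s in enumerate(curve.discovery_samples)]
    return {"discoveries": pd.DataFrame(rows, columns=["discovery", "sample"]),
            "summary": pd.DataFrame([{
                "n_discovered": curve.n_discovered,
                "n_samples": curve.n_samples,
                "censored": curve.censored}])}


def _recipe_bimodality(params, seed, n_trials):
    n = int(params.get("n_genes", 3))
    k = int(params.get("k", n))
    _, dyn = _base_specs({**params, "n_genes": n, "k": k, "density": None})
    est, fractions = stability.exact_stability(n, k, dyn)
    values, counts = np.unique(fractions, return_counts=True)
    hist = pd.DataFrame({"stability": values, "n_matrices": counts})
    summary = pd.DataFrame([{
        "S_exact": est.s, "omega": est.omega, "f": est.f,
        "n_matrices": len(fractions),
        "n_never_stable": int((fractions == 0).sum()),
        "n_always_stable": int((fractions == 1).sum())}])
    return {"per_matrix_histogram": hist, "summary": summary}


@dataclasses.dataclass(frozen=True)
class Recipe:
    name: str
    figure: str
    run: Callable[[dict, int, int], dict]


RECIPES: dict[str, Recipe] = {r.name: r for r in [
    Recipe("stability_vs_N", "stability against network size at fixed density",
           _sweep_recipe("N", "n_grid", [4, 8, 16])),
    Recipe("stability_vs_density", "stability against connectivity K at fixed size",
           _sweep_recipe("K", "k_grid", [2, 5, 10, 20])),
    Recipe("map_comparison", "+/-1 map versus 0/1 map",
           _sweep_recipe("map", "map_grid", ["zero_one", "pm1"])),
    Recipe("weight_comparison", "binary versus real-valued weights",
           _sweep_recipe("weight_scheme", "weight_grid",
                         ["binary_pm1", "real_gaussian"])),
    Recipe("steepness_sweep", "sigmoid steepness versus the sign function",
           _sweep_recipe("steepness", "a_grid", [0.5, 2.0, 10.0, 100.0])),
    Recipe("topology_comparison", "regular / Poisson / exp-in power-out topologies",
           _sweep_recipe("topology", "topology_grid",
                         ["regular", "poisson", "bio_exp_in_pow_out"])),
    Recipe("zero_convention_comparison", "conventions for zero net input",
           _sweep_recipe("zero_convention", "zc_grid",
                         ["minus", "plus", "quenched_random", "keep_previous"])),
    Recipe("period_distribution", "attractor period distribution, even/odd split",
           _recipe_period_distribution),
    Recipe("transient_scaling", "mean fixed-point transient against size",
           _recipe_transient_scaling),
    Recipe("discovery_curve", "samples needed to discover fixed-point phenotypes",
           _recipe_discovery),
    Recipe("bimodality_enumeration", "exact per-matrix stability distribution",
           _recipe_bimodality),
]}


def list_recipes() -> pd.DataFrame:
    """Catalogue of recipe names and the analysis each emulates."""
    return pd.DataFrame(
        [{"recipe": r.name, "analysis": r.figure} for r in RECIPES.values()])


def _load_config(config) -> dict:
    if isinstance(config, (str, pathlib.Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    return config


def validate_config(config: dict) -> dict:
    name = config.get("recipe")
    if name not in RECIPES:
        raise ConfigError(
            f"unknown recipe {name!r} (field 'recipe'); known: {sorted(RECIPES)}")
    if not isinstance(config.get("seed", 0), int):
        raise ConfigError("field 'seed' must be an integer")
    n_trials = config.get("n_trials", 10_000)
    if not isinstance(n_trials, int) or n_trials < 1:
        raise ConfigError("field 'n_trials' must be a positive integer")
    params = config.get("params", {})
    if not isinstance(params, dict):
        raise ConfigError("field 'params' must be a mapping")
    if RECIPES[name].run is not _recipe_bimodality:
        _base_specs(params)  # raises ParameterError naming the offending field
    return config


def run_experiment(config, out_dir: str | pathlib.Path | None = None,
                   log_stream=None) -> pathlib.Path:
    """Execute a recipe config; returns the output directory.

    Writes one TSV per output table, ``manifest.json`` (config snapshot,
    seed, version, timestamps, output paths) and ``run.log``.
    """
    config = validate_config(_load_config(config))
    name = config["recipe"]
    seed = config.get("seed", 0)
    n_trials = config.get("n_trials", 10_000)
    params = config.get("params", {})
    out = pathlib.Path(out_dir or config.get("out_dir", f"results/{name}"))
    out.mkdir(parents=True, exist_ok=True)
    started = datetime.datetime.now(datetime.timezone.utc).isoformat()
    tables = RECIPES[name].run(params, seed, n_trials)
    paths = {}
    for key, df in tables.items():
        p = out / f"{key}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[key] = str(p)
    manifest = {
        "recipe": name, "seed": seed, "n_trials": n_trials, "params": params,
        "version": __version__, "started": started,
        "finished": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": paths,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    log = log_stream or sys.stderr
    lines = [f"recipe={name} seed={seed} n_trials={n_trials}"]
    for key, df in tables.items():
        if "unresolved" in df.columns:
            frac = df["unresolved"].sum() / max(1, df.get("omega", df["unresolved"] + 1).sum())
            lines.append(f"{key}: unresolved fraction {frac:.4g}")
    text = "\n".join(lines) + "\n"
    (out / "run.log").write_text(text)
    print(text, file=log, end="")
    return out
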