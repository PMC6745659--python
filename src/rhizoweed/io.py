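"""Configuration files, run manifests, result writers, and fixture generation.

Configs are hierarchical key-value (YAML) files mirroring the
``ScenarioConfig`` field names; every output file round-trips through its
reader. All dates are serialized as DASS (days after the start of a
season). The run manifest -- written before the simulation starts --
snapshots the full config, the root seed, and the package version, and is
sufficient to reproduce the run exactly.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genetics import FitnessCost, QuantTraitModel, SingleGeneModel
from .lifecycle import EmergenceDistribution, FecundityParams, HerbicideSpec
from .scenarios import ScenarioConfig

_NESTED_TYPES = {
    "seedling_emergence": EmergenceDistribution,
    "tiller_emergence": EmergenceDistribution,
    "fecundity": FecundityParams,
    "single_gene": SingleGeneModel,
    "quant_trait": QuantTraitModel,
    "fitness_cost": FitnessCost,
}


def config_to_dict(cfg: ScenarioConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["herbicides"] = [dataclasses.asdict(h) for h in cfg.herbicides]
    return d


def config_from_dict(d: dict) -> ScenarioConfig:
    kwargs = dict(d)
    for key, typ in _NESTED_TYPES.items():
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = typ(**kwargs[key])
    if "herbicides" in kwargs:
        kwargs["herbicides"] = tuple(
            HerbicideSpec(**h) if isinstance(h, dict) else h
            for h in kwargs["herbicides"]
        )
    return ScenarioConfig(**kwargs)


def save_config(cfg: ScenarioConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def load_config(path) -> ScenarioConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def apply_overrides(cfg: ScenarioConfig, overrides: list[str]) -> ScenarioConfig:
    """Apply ``key=value`` (dotted keys for nested fields) onto a config.

    Values are parsed with YAML semantics, so ``true``, ``0.5``, and quoted
    strings all behave as expected.
    """
    d = config_to_dict(cfg)
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override {item!r} is not of the form key=value")
        key, raw = item.split("=", 1)
        value = yaml.safe_load(raw)
        if isinstance(value, str):
            # YAML 1.1 reads bare scientific notation like 1e-7 as a string
            try:
                value = int(value)
            except ValueError:
                try:
                    value = float(value)
                except ValueError:
                    pass
        node = d
        parts = key.strip().split(".")
        for p in parts[:-1]:
            if p not in node or not isinstance(node[p], dict):
                raise KeyError(f"unknown config key {key!r}")
            node = node[p]
        if parts[-1] not in node:
            raise KeyError(f"unknown config key {key!r}")
        node[parts[-1]] = value
    return config_from_dict(d)


# ---------------------------------------------------------------------------
# run manifest and result writers
# ---------------------------------------------------------------------------

def write_manifest(
    path,
    cfg: ScenarioConfig,
    seed: int,
    n_replicates: int,
    overrides: list[str] | None = None,
) -> dict:
    from . import __version__

    manifest = {
        "package": "rhizoweed",
        "version": __version__,
        "created_unix_time": time.time(),
        "root_seed": int(seed),
        "n_replicates": int(n_replicates),
        "rng": "numpy PCG64; per-replicate streams spawned from SeedSequence(root_seed)",
        "overrides": list(overrides or []),
        # the two knobs calibrated within their documented open ranges
        "calibrated_knobs": {
            "tertiary_rate": cfg.tertiary_rate,
            "classification_threshold": cfg.classification_threshold,
        },
        "config": config_to_dict(cfg),
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
    return manifest


def replicates_frame(results) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(results):
        rows.append(
            dict(
                replicate=i,
                years_run=r.n_years_run,
                failure_year=r.failure_year,
                accase_resistance_year=r.accase_resistance_year,
                glyphosate_resistance_year=r.glyphosate_resistance_year,
            )
        )
    return pd.DataFrame(rows)


def trajectories_frame(results, field_area: float) -> pd.DataFrame:
    """One row per (replicate, year) with counts and per-m^2 densities."""
    rows = []
    for i, r in enumerate(results):
        for s in r.seasons:
            rows.append(
                dict(
                    replicate=i,
                    year=s.year,
                    seedbank_start=s.seedbank_start,
                    seedbank_start_per_m2=s.seedbank_start / field_area,
                    adults=s.adults,
                    density_per_m2=s.density,
                    accase_resistant_fraction=s.accase_resistant_fraction,
                    glyphosate_resistant_fraction=s.glyphosate_resistant_fraction,
                    allele_frequency=s.allele_frequency,
                    median_pz=s.median_pz,
                    new_seeds=s.new_seeds,
                    new_seeds_per_m2=s.new_seeds / field_area,
                    tertiary_rhizomes=s.tertiary_rhizomes,
                    tertiary_rhizomes_per_m2=s.tertiary_rhizomes / field_area,
                    failed=s.failed,
                )
            )
    return pd.DataFrame(rows)


def summary_dict(stats) -> dict:
    return {
        "n_replicates": stats.n_replicates,
        "accase_r_probability": stats.accase_r_probability,
        "glyphosate_r_probability": stats.glyphosate_r_probability,
        "failure_probability": stats.failure_probability,
        "mean_failure_year": stats.mean_failure_year,
        "seedbank_rhizome_ratio": stats.seedbank_rhizome_ratio,
        "mean_accase_onset_year": stats.mean_accase_onset_year,
        "mean_glyphosate_onset_year": stats.mean_glyphosate_onset_year,
    }


def write_summary(path, stats) -> None:
    Path(path).write_text(json.dumps(summary_dict(stats), indent=2))


# ---------------------------------------------------------------------------
# synthetic fixtures for the parameterization module
# ---------------------------------------------------------------------------

def generate_emergence_fixture(
    shape_k: float,
    scale_lambda: float,
    n_plants: int,
    eval_dates: list[float] | None = None,
    cohort: str = "seedling",
    site: str = "synthetic",
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Quadrat-style emergence counts from a known Weibull ground truth.

    ``n_plants`` individual emergence dates are sampled and binned at the
    evaluation dates (per-interval counts, plants emerging after the last
    evaluation are dropped, as in a real survey). Returns the table and a
    side-car dict recording the ground truth.
    """
    rng = np.random.default_rng(seed)
    dist = EmergenceDistribution(shape_k, scale_lambda)
    if eval_dates is None:
        eval_dates = [100.0, 130.0, 155.0, 175.0, 200.0, 240.0]
    dates = np.sort(np.asarray(eval_dates, dtype=float))
    samples = dist.sample(n_plants, rng)
    edges = np.concatenate([[0.0], dates])
    counts, _ = np.histogram(samples, bins=edges)
    df = pd.DataFrame(
        {"date": dates, "count": counts, "cohort": cohort, "site": site}
    )
    truth = {
        "kind": "emergence",
        "shape_k": shape_k,
        "scale_lambda": scale_lambda,
        "n_plants": n_plants,
        "seed": seed,
    }
    return df, truth


def generate_fecundity_fixture(
    a: float,
    b: float,
    n_points: int = 20,
    x_range: tuple[float, float] = (100.0, 220.0),
    noise_sd_log: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Plant-level fecundity observations from ``a*exp(b*x)`` with optional
    multiplicative log-normal noise."""
    rng = np.random.default_rng(seed)
    x = np.linspace(*x_range, n_points)
    y = a * np.exp(b * x)
    if noise_sd_log > 0:
        y = y * np.exp(rng.normal(0.0, noise_sd_log, n_points))
    df = pd.DataFrame({"date": x, "count": y})
    truth = {
        "kind": "fecundity",
        "a": a,
        "b": b,
        "noise_sd_log": noise_sd_log,
        "seed": seed,
    }
    return df, truth


def generate_fixtures(
    kind: str, out_dir, seed: int = 0, noise: float = 0.0, n: int = 10_000, **params
) -> tuple[Path, Path]:
    """Write a synthetic dataset plus its ground-truth side-car JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if kind == "emergence":
        df, truth = generate_emergence_fixture(
            params.get("shape_k", 10.5),
            params.get("scale_lambda", 169.0),
            n_plants=n,
            seed=seed,
        )
    elif kind == "fecundity":
        df, truth = generate_fecundity_fixture(
            params.get("a", 4098.5),
            params.get("b", -0.066),
            noise_sd_log=noise,
            seed=seed,
        )
    else:
        raise ValueError("kind must be 'emergence' or 'fecundity'")
    csv_path = out / f"{kind}_fixture.csv"
    truth_path = out / f"{kind}_fixture.truth.json"
    df.to_csv(csv_path, index=False)
    truth_path.write_text(json.dumps(truth, indent=2))
    return csv_path, truth_path
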