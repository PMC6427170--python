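"""End-to-end orchestration: simulate -> extract -> stats -> monte carlo.

One YAML-serializable :class:`RunConfig` and one integer seed reproduce the
whole study byte-for-byte.  Stages write UTF-8 CSV files plus a JSON manifest
(config echo, seeds, package versions, per-stage shapes); progress goes to a
logger, data only ever to files.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exposure import (
    DEFAULT_RADII,
    build_exposure_matrix,
    exposure_to_csv,
)
from .geotiff import write_geotiff
from .montecarlo import sensitivity_from_exposures
from .raster import NdviStack, filter_water
from .scene import AddressSet, SceneConfig, generate_stack, sample_addresses
from . import stats as ustats

log = logging.getLogger("greenexposure")


@dataclass
class RunConfig:
    """Full study configuration.

    ``n_addresses`` is the initial exposure sample; ``pool_size`` addresses
    are drawn separately (excluding the initial set) as the Monte Carlo
    resampling pool.
    """

    scene: SceneConfig = field(default_factory=SceneConfig)
    n_addresses: int = 500
    pool_size: int = 2000
    radii: tuple[float, ...] = DEFAULT_RADII
    pairwise_family: str = "radius"  # or "global"
    paired_tests: bool = False
    mc_replicates: int = 50
    mc_sample_size: int = 100
    output_dir: str = "greenexposure_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        try:
            self.radii = tuple(float(r) for r in self.radii)
        except (TypeError, ValueError):
            pass  # left as-is; validate_config reports it
        # keep the scene and the run on one seed unless the user split them
        if isinstance(self.scene, dict):
            self.scene = SceneConfig.from_dict(self.scene)

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["scene"] = self.scene.to_dict()
        d["radii"] = list(self.radii)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)


def validate_config(config: RunConfig) -> list[str]:
    """Every violated invariant as a human-readable message; never raises."""
    problems: list[str] = []
    try:
        radii = [float(r) for r in config.radii]
        if not radii:
            problems.append("radii list is empty")
        elif any(r <= 0 for r in radii):
            problems.append(f"radii must be positive, got {radii}")
        elif any(b <= a for a, b in zip(radii, radii[1:])):
            problems.append(f"radii must be strictly increasing, got {radii}")
    except (TypeError, ValueError):
        problems.append(f"radii not numeric: {config.radii!r}")
    if not isinstance(config.scene, SceneConfig):
        try:
            SceneConfig.from_dict(config.scene)
        except Exception as exc:
            problems.append(f"scene config invalid: {exc}")
    if config.n_addresses < 1:
        problems.append("n_addresses must be >= 1")
    if config.pool_size < config.mc_sample_size:
        problems.append(
            f"Monte Carlo draw size m={config.mc_sample_size} exceeds pool_size={config.pool_size}"
        )
    if config.mc_replicates < 2:
        problems.append("mc_replicates must be >= 2 for a reference SD")
    if config.pairwise_family not in ("radius", "global"):
        problems.append(f"pairwise_family must be 'radius' or 'global', got {config.pairwise_family!r}")
    out = config.output_dir
    parent = os.path.dirname(os.path.abspath(out))
    if os.path.exists(out) and not os.path.isdir(out):
        problems.append(f"output path {out} exists and is not a directory")
    elif not os.path.exists(out) and not os.access(parent, os.W_OK):
        problems.append(f"cannot create output directory under {parent}")
    elif os.path.isdir(out) and not os.access(out, os.W_OK):
        problems.append(f"output directory {out} is not writable")
    return problems


def _mc_seed(base_seed: int, year: int, radius: float) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(year), int(radius)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_all(config: RunConfig, write_rasters: bool = True) -> dict:
    """Execute every stage in order; returns the manifest dict.

    Outputs in ``config.output_dir``: ndvi_<year>.tif, addresses.csv,
    pool.csv, exposure.csv, summary.csv, correlation_{rho,p_raw,p_adj}.csv,
    pairwise_<radius>.csv, fligner.csv, trend.csv, montecarlo.csv,
    montecarlo_ref_means.csv, config.yaml, manifest.json.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(problems))
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    scene = config.scene
    if scene.seed != config.seed:
        scene = SceneConfig.from_dict({**scene.to_dict(), "seed": config.seed})

    # -- simulate ----------------------------------------------------------
    log.info("stage simulate: %d years on %s native cells", len(scene.years), scene.native_shape)
    stack = generate_stack(scene)
    initial = sample_addresses(config.n_addresses, scene, stream=0)
    pool = sample_addresses(config.pool_size, scene, exclude=initial, stream=1)
    if write_rasters:
        for year in stack.years:
            write_geotiff(stack.layer(year), os.path.join(out, f"ndvi_{year}.tif"))
    addresses_to_csv(initial, os.path.join(out, "addresses.csv"))
    addresses_to_csv(pool, os.path.join(out, "pool.csv"))
    manifest["stages"]["simulate"] = {
        "years": list(stack.years),
        "grid": [stack.layers[0].n_rows, stack.layers[0].n_cols],
        "n_addresses": len(initial),
        "pool_size": len(pool),
    }

    # -- extract -----------------------------------------------------------
    log.info("stage extract: %d addresses x %d years x %d radii",
             len(initial), len(stack), len(config.radii))
    clean = stack.map(filter_water)
    exposures = build_exposure_matrix(clean, initial, config.radii)
    exposure_to_csv(exposures, os.path.join(out, "exposure.csv"))
    manifest["stages"]["extract"] = {
        "rows": int(exposures.shape[0]),
        "columns": int(exposures.shape[1]),
        "missing": int(exposures.isna().to_numpy().sum()),
    }

    # -- stats -------------------------------------------------------------
    log.info("stage stats")
    summary = ustats.summary_table(exposures)
    summary.to_csv(os.path.join(out, "summary.csv"), index=False, float_format="%.10g")
    corr = ustats.spearman_matrix(exposures)
    for name, frame in corr.to_frames().items():
        frame.to_csv(os.path.join(out, f"correlation_{name}.csv"), float_format="%.10g")
    pairwise = ustats.pairwise_all_radii(
        exposures, paired=config.paired_tests, family=config.pairwise_family
    )
    for radius, tests in pairwise.items():
        tests.to_frame().to_csv(
            os.path.join(out, f"pairwise_{int(radius)}.csv"), index=False, float_format="%.10g"
        )
    flg = ustats.fligner_by_year(exposures)
    flg.to_csv(os.path.join(out, "fligner.csv"), index=False, float_format="%.10g")
    trend = ustats.trend_table(exposures)
    trend.to_csv(os.path.join(out, "trend.csv"), index=False, float_format="%.10g")
    manifest["stages"]["stats"] = {
        "summary_rows": int(summary.shape[0]),
        "correlation_dim": len(corr.labels),
        "pairwise_entries_per_radius": {
            str(int(r)): len(t.pairs) for r, t in pairwise.items()
        },
        "fligner_rows": int(flg.shape[0]),
    }

    # -- monte carlo -------------------------------------------------------
    log.info("stage montecarlo: R=%d m=%d over %d cells",
             config.mc_replicates, config.mc_sample_size,
             len(stack.years) * len(config.radii))
    pool_exposures = build_exposure_matrix(clean, pool, config.radii)
    mc_rows = []
    ref_rows = []
    for year in stack.years:
        for radius in config.radii:
            res = sensitivity_from_exposures(
                exposures[(year, radius)].to_numpy(),
                pool_exposures[(year, radius)].dropna().to_numpy(),
                R=config.mc_replicates,
                m=config.mc_sample_size,
                seed=_mc_seed(config.seed, year, radius),
                year=year,
                radius=radius,
            )
            mc_rows.append(
                {
                    "year": res.year,
                    "radius_m": res.radius,
                    "initial_mean": res.initial_mean,
                    "ref_mean": res.ref_mean,
                    "ref_sd": res.ref_sd,
                    "z": res.z,
                    "percentile": res.percentile,
                    "consistent": res.consistent,
                }
            )
            for k, v in enumerate(res.ref_means):
                ref_rows.append({"year": res.year, "radius_m": res.radius, "replicate": k, "mean": v})
    mc = pd.DataFrame(mc_rows)
    mc.to_csv(os.path.join(out, "montecarlo.csv"), index=False, float_format="%.10g")
    pd.DataFrame(ref_rows).to_csv(
        os.path.join(out, "montecarlo_ref_means.csv"), index=False, float_format="%.10g"
    )
    manifest["stages"]["montecarlo"] = {
        "cells": int(mc.shape[0]),
        "replicates": config.mc_replicates,
        "consistent_fraction": float(mc["consistent"].mean()),
    }

    config.to_yaml(os.path.join(out, "config.yaml"))
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("run complete: %s", out)
    return manifest


def addresses_to_csv(addresses: AddressSet, path: str) -> None:
    pd.DataFrame({"id": addresses.ids, "x": addresses.x, "y": addresses.y}).to_csv(
        path, index=False, float_format="%.10g"
    )


def addresses_from_csv(path: str) -> AddressSet:
    df = pd.read_csv(path)
    return AddressSet(ids=tuple(df["id"]), x=df["x"].to_numpy(), y=df["y"].to_numpy())
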