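"""Monte Carlo sensitivity check of the initial address sample.

Because a single random address sample could be an unlucky draw, the study
design is stress-tested by re-drawing many alternative samples from the
remaining address pool (the initial addresses are excluded) and situating the
initial sample's mean exposure within the resulting reference distribution of
sample means.  The verdict follows a plus/minus one standard deviation band
around the reference mean; a z-score and an empirical percentile are reported
alongside for users who prefer conventional scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exposure import buffer_mean
from .raster import NdviStack
from .scene import AddressSet


@dataclass(frozen=True)
class MonteCarloResult:
    year: int
    radius: float
    initial_mean: float
    ref_means: np.ndarray  # one mean per replicate draw
    ref_mean: float
    ref_sd: float
    consistent: bool  # initial mean within ref_mean +/- ref_sd
    z: float  # (initial_mean - ref_mean) / ref_sd
    percentile: float  # fraction of ref_means <= initial_mean


def sensitivity_from_exposures(
    initial_values,
    pool_values,
    R: int = 100,
    m: int = 1000,
    seed: int | None = 0,
    year: int = 0,
    radius: float = 0.0,
) -> MonteCarloResult:
    """Core resampling step on precomputed exposure vectors.

    ``R`` samples of ``m`` values are drawn without replacement from
    ``pool_values`` (draws are independent of each other, so they may overlap
    one another — only the initial sample is excluded, which the caller
    guarantees by construction of the pool).  Missing exposures are dropped
    before any mean.
    """
    if R < 2:
        raise ValueError("need R >= 2 replicates for a reference SD")
    if m < 1:
        raise ValueError("need m >= 1 addresses per draw")
    init = np.asarray(initial_values, dtype=float)
    init = init[~np.isnan(init)]
    pool = np.asarray(pool_values, dtype=float)
    if init.size == 0:
        raise ValueError("initial sample has no non-missing exposures")
    if pool.size < m:
        raise ValueError(f"pool of {pool.size} addresses too small for draws of {m}")
    rng = np.random.default_rng(seed)
    ref_means = np.empty(R)
    for k in range(R):
        idx = rng.choice(pool.size, size=m, replace=False)
        draw = pool[idx]
        draw = draw[~np.isnan(draw)]
        if draw.size == 0:
            raise ValueError("a replicate draw contained no non-missing exposures")
        ref_means[k] = draw.mean()
    ref_mean = float(ref_means.mean())
    ref_sd = float(ref_means.std(ddof=1))
    initial_mean = float(init.mean())
    consistent = bool(ref_mean - ref_sd <= initial_mean <= ref_mean + ref_sd)
    z = float((initial_mean - ref_mean) / ref_sd) if ref_sd > 0 else float("inf")
    return MonteCarloResult(
        year=int(year),
        radius=float(radius),
        initial_mean=initial_mean,
        ref_means=ref_means,
        ref_mean=ref_mean,
        ref_sd=ref_sd,
        consistent=consistent,
        z=z,
        percentile=float(np.mean(ref_means <= initial_mean)),
    )


def run_sensitivity(
    stack: NdviStack,
    pool: AddressSet,
    initial: AddressSet,
    radius: float,
    year: int,
    R: int = 100,
    m: int = 1000,
    seed: int | None = 0,
) -> MonteCarloResult:
    """Full sensitivity run for one (year, radius) combination.

    ``pool`` must already exclude every initial address; buffer exposures for
    both sets are extracted here on the given layer.
    """
    initial_pts = set(zip(initial.x.tolist(), initial.y.tolist()))
    overlap = [
        (px, py) for px, py in zip(pool.x.tolist(), pool.y.tolist()) if (px, py) in initial_pts
    ]
    if overlap:
        raise ValueError(
            f"pool overlaps initial sample at {len(overlap)} locations; exclude them first"
        )
    if len(pool) < m:
        raise ValueError(f"pool of {len(pool)} addresses too small for draws of {m}")
    grid = stack.layer(year)
    init_vals = np.array([buffer_mean(grid, px, py, radius) for px, py in zip(initial.x, initial.y)])
    pool_vals = np.array([buffer_mean(grid, px, py, radius) for px, py in zip(pool.x, pool.y)])
    return sensitivity_from_exposures(
        init_vals, pool_vals, R=R, m=m, seed=seed, year=year, radius=radius
    )
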