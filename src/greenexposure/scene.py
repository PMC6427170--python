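"""Seeded synthetic NDVI scenes and address samples.

Real inputs for this kind of analysis are satellite vegetation-index
composites (250 m cells, annual snapshots) joined to a cadastral address
register.  Neither ships with the package, so this module fabricates stand-ins
carrying the statistical structure the downstream analysis actually relies
on:

* spatial autocorrelation with a controllable correlation length
  (kernel-smoothed Gaussian white noise, standardized to unit variance);
* year-to-year dependence via a stationary order-1 autoregression on the
  latent field, so consecutive layers correlate at ``temporal_rho``;
* a small linear temporal trend in the mean;
* spatially coherent negative "water" patches, placed by thresholding a fixed
  auxiliary smooth field (lakes and canals, not salt-and-pepper);
* native 250 m cells refined to 100 m by bilinear interpolation, as one would
  do to densify buffer zonal statistics.

Everything is driven by one integer seed; sub-streams for the field, the
water mask and address sampling are spawned deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .raster import NdviStack, RasterGrid, bilinear_downscale

#: NDVI assigned inside water patches: low enough to be unambiguous water,
#: within the physical [-1, 0) range.
WATER_VALUE = -0.3


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic study scene.

    Defaults emulate a temperate, partly urbanized study region observed by a
    moderate-resolution sensor: mean summer NDVI around 0.55 with a
    cross-location spread of roughly 0.11, a faint greening trend, strong but
    imperfect persistence between consecutive summers, and ~6% open water.
    """

    extent: tuple[float, float, float, float] = (0.0, 0.0, 20_000.0, 20_000.0)
    native_cell: float = 250.0
    target_cell: float = 100.0
    years: tuple[int, ...] = tuple(range(2006, 2018))
    base_mean: float = 0.55
    spatial_range: float = 500.0
    marginal_sd: float = 0.11
    temporal_rho: float = 0.8
    trend_per_year: float = 0.002
    water_fraction: float = 0.06
    seed: int = 0

    def __post_init__(self):
        xmin, ymin, xmax, ymax = self.extent
        if not (xmax > xmin and ymax > ymin):
            raise ValueError(f"degenerate extent {self.extent}")
        if not 0 < self.target_cell <= self.native_cell:
            raise ValueError(
                f"need native_cell >= target_cell > 0, got {self.native_cell}, {self.target_cell}"
            )
        years = tuple(int(y) for y in self.years)
        if len(years) < 2 or any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("years must be >= 2 strictly increasing integers")
        if not self.marginal_sd > 0:
            raise ValueError("marginal_sd must be positive")
        if not 0 <= self.temporal_rho < 1:
            raise ValueError("temporal_rho must lie in [0, 1)")
        if not 0 <= self.water_fraction < 1:
            raise ValueError("water_fraction must lie in [0, 1)")
        if not self.spatial_range > 0:
            raise ValueError("spatial_range must be positive")
        object.__setattr__(self, "extent", tuple(float(v) for v in self.extent))
        object.__setattr__(self, "years", years)

    @property
    def native_shape(self) -> tuple[int, int]:
        xmin, ymin, xmax, ymax = self.extent
        return (
            max(1, int(round((ymax - ymin) / self.native_cell))),
            max(1, int(round((xmax - xmin) / self.native_cell))),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["extent"] = list(self.extent)
        d["years"] = list(self.years)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        if "extent" in d:
            d["extent"] = tuple(d["extent"])
        if "years" in d:
            d["years"] = tuple(d["years"])
        return cls(**d)


@dataclass(frozen=True)
class AddressSet:
    """Point locations (projected meters) with unique ids."""

    ids: tuple
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        ids = tuple(self.ids)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if len(ids) != len(set(ids)):
            raise ValueError("address ids must be unique")
        if not (len(ids) == x.size == y.size):
            raise ValueError("ids, x, y must have equal length")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.ids)


def _smooth_unit_field(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    """Kernel-smoothed white noise, standardized to mean 0 / sd 1."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma_cells, mode="reflect")
    return (f - f.mean()) / f.std()


def generate_stack(config: SceneConfig) -> NdviStack:
    """Simulate the annual NDVI stack described by ``config``.

    The latent field evolves as ``f_t = rho * f_{t-1} + sqrt(1 - rho^2) e_t``
    with independent standardized smooth innovations ``e_t``, so it is
    stationary with unit variance and lag-1 correlation ``rho``.  The observed
    layer is ``base_mean + trend * (year - year0) + marginal_sd * f_t``
    clamped to the NDVI domain [-1, 1]; water cells are then overwritten with
    a negative constant, and the native stack is refined to ``target_cell``.
    """
    root = np.random.SeedSequence(config.seed)
    field_seq, water_seq, _addr_seq = root.spawn(3)
    rng = np.random.default_rng(field_seq)
    shape = config.native_shape
    sigma = config.spatial_range / config.native_cell

    water_field = _smooth_unit_field(np.random.default_rng(water_seq), shape, sigma)
    if config.water_fraction > 0:
        thresh = np.quantile(water_field, config.water_fraction)
        water = water_field <= thresh
    else:
        water = np.zeros(shape, dtype=bool)

    xmin, _ymin, _xmax, ymax = config.extent
    rho = config.temporal_rho
    y0 = config.years[0]
    layers = []
    f = _smooth_unit_field(rng, shape, sigma)
    for i, year in enumerate(config.years):
        if i > 0:
            f = rho * f + np.sqrt(1.0 - rho * rho) * _smooth_unit_field(rng, shape, sigma)
        obs = config.base_mean + config.trend_per_year * (year - y0) + config.marginal_sd * f
        obs = np.clip(obs, -1.0, 1.0)
        obs[water] = WATER_VALUE
        native = RasterGrid(
            values=obs, origin_x=xmin, origin_y=ymax, cell_size=config.native_cell
        )
        layers.append(bilinear_downscale(native, config.target_cell))
    return NdviStack(years=config.years, layers=tuple(layers))


def sample_addresses(
    n: int,
    config: SceneConfig,
    exclude: AddressSet | None = None,
    stream: int = 0,
    candidates: AddressSet | None = None,
) -> AddressSet:
    """Draw ``n`` address points with equal selection probability.

    By default points are uniform over the scene extent; when ``candidates``
    is given (a discrete register, like a cadastral address list), the draw
    is a uniform subset of it instead.  Points never coincide with any point
    of ``exclude``.  ``stream`` distinguishes independent draws under the
    same scene seed (e.g. the initial sample vs the resampling pool); ids are
    prefixed accordingly.
    """
    if n < 1:
        raise ValueError("need n >= 1 addresses")
    root = np.random.SeedSequence(config.seed)
    _field_seq, _water_seq, addr_seq = root.spawn(3)
    rng = np.random.default_rng(addr_seq.spawn(stream + 1)[-1])
    if candidates is not None:
        excluded_ids = set() if exclude is None else set(exclude.ids)
        keep = [i for i, cid in enumerate(candidates.ids) if cid not in excluded_ids]
        if len(keep) < n:
            raise ValueError(
                f"candidate pool has only {len(keep)} addresses after exclusion, need {n}"
            )
        pick = rng.choice(len(keep), size=n, replace=False)
        idx = [keep[int(i)] for i in pick]
        return AddressSet(
            ids=tuple(candidates.ids[i] for i in idx),
            x=candidates.x[idx],
            y=candidates.y[idx],
        )
    xmin, ymin, xmax, ymax = config.extent
    taken = set()
    if exclude is not None:
        taken = {(float(px), float(py)) for px, py in zip(exclude.x, exclude.y)}
    xs, ys = [], []
    attempts = 0
    while len(xs) < n:
        attempts += 1
        if attempts > 100 * n + 1000:
            raise RuntimeError("could not place addresses without collision")
        px = float(rng.uniform(xmin, xmax))
        py = float(rng.uniform(ymin, ymax))
        if (px, py) in taken:
            continue
        taken.add((px, py))
        xs.append(px)
        ys.append(py)
    ids = tuple(f"A{stream}-{i:06d}" for i in range(n))
    return AddressSet(ids=ids, x=np.array(xs), y=np.array(ys))
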