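"""Synthetic landscapes with known suitability truth.

Every downstream stage of the pipeline — occurrence cleaning and thinning,
predictor selection, boosted-tree fitting, threshold binarization and
range-change mapping — is exercisable on landscapes produced here, with
the generating truth available for parameter-recovery checks.

The generator emulates the structure of a real study region:

* spatially autocorrelated environmental layers (white noise smoothed by a
  Gaussian kernel whose sigma, in cells, is the autocorrelation range);
* a block correlation structure among layers: layers within a block share
  a latent field and reach a target pairwise correlation, while blocks are
  independent by construction (between-block |r| stays well below 0.2), so
  a correlation-clustering step at cutoff 0.5 has an unambiguous truth;
* a known suitability surface: a logistic of summed threshold-shaped
  (sigmoid ramp) responses to a small subset of driver layers, mimicking
  the steep nonlinear responses species show to climate limits;
* presence-only sampling biased by an optional effort layer, as records
  aggregated from public biodiversity databases are;
* future scenarios derived by additive temperature/precipitation deltas,
  so the climate change signal attributed downstream is exactly known.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import EnvGrid
from .occurrences import OccurrenceSet

__all__ = [
    "ResponseRamp",
    "TruthSpec",
    "ScenarioKey",
    "make_env_grid",
    "make_true_suitability",
    "sample_occurrences",
    "apply_climate_deltas",
]


@dataclass(frozen=True)
class ResponseRamp:
    """A threshold-shaped partial response on the logit scale.

    Contributes ``amplitude / (1 + exp(-steepness * (x - location)))``:
    flat below the threshold ``location``, rising steeply through it, and
    saturating at ``amplitude`` (negative amplitudes give declining
    responses).
    """

    location: float
    steepness: float = 1.0
    amplitude: float = 1.0

    def __call__(self, x: np.ndarray) -> np.ndarray:
        z = np.clip(self.steepness * (np.asarray(x, dtype=float) - self.location),
                    -500, 500)
        return self.amplitude / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class TruthSpec:
    """The known data-generating suitability model of a synthetic landscape."""

    response_functions: dict[str, ResponseRamp]
    intercept: float = 0.0
    noise_sd: float = 0.0

    @property
    def driver_layers(self) -> list[str]:
        return list(self.response_functions)


@dataclass(frozen=True)
class ScenarioKey:
    """Identifies one projection scenario: a GCM × RCP × period triple.

    The present has no GCM or RCP attached.
    """

    period: str = "present"
    gcm: str | None = None
    rcp: float | None = None

    def __post_init__(self) -> None:
        if self.period == "present" and (self.gcm is not None or self.rcp is not None):
            raise ValueError("the present scenario carries no gcm/rcp")
        if self.rcp is not None and self.rcp not in (2.6, 4.5, 6.0, 8.5):
            raise ValueError(f"unknown RCP {self.rcp}")

    def __str__(self) -> str:
        if self.period == "present":
            return "present"
        return f"{self.gcm}:rcp{self.rcp}:{self.period}"


def _smooth_field(rng: np.ndarray, sigma: float) -> np.ndarray:
    """Standardize a smoothed white-noise field to zero mean, unit sd."""
    f = gaussian_filter(rng, sigma=sigma, mode="reflect") if sigma > 0 else rng
    sd = f.std()
    if sd == 0:
        raise ValueError("degenerate (constant) random field")
    return (f - f.mean()) / sd


def make_env_grid(
    n_rows: int,
    n_cols: int,
    block_spec: list[tuple[int, float]],
    autocorr_range: float = 3.0,
    seed: int = 0,
    *,
    layer_names: list[str] | None = None,
    origin_x: float = 0.0,
    origin_y: float | None = None,
    cell_size: float = 1.0,
    crs_label: str = "synthetic",
) -> EnvGrid:
    """Generate a correlated, autocorrelated stack of environmental layers.

    ``block_spec`` is a list of ``(n_layers, target_abs_r)`` pairs. Layers
    inside a block are built as ``sqrt(r) * shared + sqrt(1-r) * own`` from
    independent standardized fields, so their pairwise correlation
    approaches ``target_abs_r`` as the grid grows; distinct blocks use
    independent shared fields and are uncorrelated by construction.

    Layers are standardized (zero mean, unit sd up to smoothing edge
    effects). Deterministic for a fixed seed.
    """
    if n_rows < 8 or n_cols < 8:
        raise ValueError("grid must be at least 8 x 8")
    for size, r in block_spec:
        if size < 1:
            raise ValueError("block size must be >= 1")
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"target |r| must lie in [0, 1], got {r}")
    rng = np.random.default_rng(seed)
    n_layers = sum(size for size, _ in block_spec)
    if layer_names is None:
        layer_names = [
            f"b{bi}v{vi}"
            for bi, (size, _) in enumerate(block_spec)
            for vi in range(size)
        ]
    if len(layer_names) != n_layers:
        raise ValueError("layer_names length does not match block_spec")

    layers: dict[str, np.ndarray] = {}
    names = iter(layer_names)
    for size, r in block_spec:
        shared = _smooth_field(rng.standard_normal((n_rows, n_cols)), autocorr_range)
        a, b = np.sqrt(r), np.sqrt(1.0 - r)
        for _ in range(size):
            own = _smooth_field(rng.standard_normal((n_rows, n_cols)), autocorr_range)
            layers[next(names)] = a * shared + b * own
    if origin_y is None:
        origin_y = n_rows * cell_size
    return EnvGrid(
        layers=layers,
        origin_x=origin_x,
        origin_y=origin_y,
        cell_size=cell_size,
        crs_label=crs_label,
    )


def make_true_suitability(env: EnvGrid, truth: TruthSpec, seed: int = 0) -> np.ndarray:
    """Evaluate the known suitability surface of a landscape.

    Per cell, the logit is the intercept plus the summed driver responses
    (plus optional Gaussian noise of sd ``truth.noise_sd``); suitability is
    its logistic, hence strictly inside (0, 1). Nodata cells propagate as
    NaN.
    """
    missing = [n for n in truth.driver_layers if n not in env.layers]
    if missing:
        raise KeyError(f"driver layers not in grid: {missing}")
    logit = np.full((env.n_rows, env.n_cols), float(truth.intercept))
    for name, resp in truth.response_functions.items():
        logit = logit + resp(env.layers[name])
    if truth.noise_sd > 0:
        rng = np.random.default_rng(seed)
        logit = logit + rng.normal(0.0, truth.noise_sd, size=logit.shape)
    suit = 1.0 / (1.0 + np.exp(-np.clip(logit, -500, 500)))
    suit[env.nodata_mask] = np.nan
    return suit


def sample_occurrences(
    env: EnvGrid,
    suitability: np.ndarray,
    n: int,
    bias: np.ndarray | None = None,
    seed: int = 0,
    source: str = "synthetic",
) -> OccurrenceSet:
    """Draw presence records from a suitability surface.

    Cells are drawn independently (with replacement, as repeat visits in
    aggregated occurrence databases) with probability proportional to
    ``suitability × bias``; coordinates are cell centers.
    """
    if n < 1:
        raise ValueError("need n >= 1 presences")
    w = np.asarray(suitability, dtype=float).copy()
    w[env.nodata_mask] = 0.0
    w = np.nan_to_num(w, nan=0.0)
    if bias is not None:
        w = w * np.asarray(bias, dtype=float)
    if (w < 0).any():
        raise ValueError("negative sampling weights")
    total = w.sum()
    if total <= 0:
        raise ValueError("all sampling weights are zero")
    rng = np.random.default_rng(seed)
    flat = rng.choice(w.size, size=n, replace=True, p=(w / total).ravel())
    rows, cols = np.unravel_index(flat, w.shape)
    x, y = env.cell_center(rows, cols)
    return OccurrenceSet.from_arrays(
        lon=x, lat=y, label=np.ones(n, dtype=int), source=source, extent=env.extent
    )


def apply_climate_deltas(
    env: EnvGrid, deltas: dict[str, float | np.ndarray], key: ScenarioKey
) -> EnvGrid:
    """Derive a future-scenario stack by additive layer shifts.

    Layers named in ``deltas`` are shifted by the given amount (°C for
    temperature-like, mm for precipitation-like layers) — a scalar for a
    uniform shift or an array for a spatially varying one; all other
    layers are shared unchanged. The applied delta is thereafter the
    exactly known future − present difference for attribution checks.
    """
    unknown = [n for n in deltas if n not in env.layers]
    if unknown:
        raise KeyError(f"delta names not in grid: {unknown}")
    layers = {
        name: (arr + deltas[name]) if name in deltas else arr
        for name, arr in env.layers.items()
    }
    return EnvGrid(
        layers=layers,
        origin_x=env.origin_x,
        origin_y=env.origin_y,
        cell_size=env.cell_size,
        nodata_mask=env.nodata_mask.copy(),
        crs_label=env.crs_label,
    )
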