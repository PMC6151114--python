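"""Occurrence-record preparation.

Takes raw point records (presences from biodiversity databases plus, later,
generated pseudo-absences) through the standard presence/background
preparation chain: coordinate cleaning, spatial thinning on a regular grid
at a target distance, pseudo-absence generation, stratified train/test
splitting, and extraction of predictor values at record locations.

Target distances are expressed in map units. For geographic (degree)
coordinates, kilometre distances are converted with the documented
constant 1 km = 1/111.32 degrees (:data:`KM_PER_DEGREE`), appropriate for
study regions at ~1 km working resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import EnvGrid

__all__ = [
    "OccurrenceSet",
    "SplitSpec",
    "KM_PER_DEGREE",
    "km_to_degrees",
    "clean_occurrences",
    "thin_by_grid",
    "generate_pseudo_absences",
    "stratified_split",
    "extract_features",
]

KM_PER_DEGREE = 111.32

PRESENCE = 1
ABSENCE = 0


def km_to_degrees(km: float) -> float:
    """Convert a kilometre target distance to degrees (1 km = 1/111.32 deg)."""
    return km / KM_PER_DEGREE


@dataclass
class OccurrenceSet:
    """Labelled point records: presences (label 1) and pseudo-absences (0)."""

    records: pd.DataFrame  # columns lon, lat, label, source
    extent: tuple[float, float, float, float]  # (xmin, ymin, xmax, ymax)

    COLUMNS = ("lon", "lat", "label", "source")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"occurrence table missing columns {missing}")
        self.records = self.records.loc[:, list(self.COLUMNS)].reset_index(drop=True)

    @classmethod
    def from_arrays(cls, lon, lat, label, source="unknown", extent=None) -> "OccurrenceSet":
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        label = np.asarray(label, dtype=int)
        if np.isscalar(source) or isinstance(source, str):
            source = np.full(lon.shape, source, dtype=object)
        df = pd.DataFrame({"lon": lon, "lat": lat, "label": label, "source": source})
        if extent is None:
            extent = (lon.min(), lat.min(), lon.max(), lat.max())
        return cls(df, tuple(extent))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return self.records["label"].to_numpy()

    def subset(self, mask) -> "OccurrenceSet":
        return OccurrenceSet(self.records.loc[mask].reset_index(drop=True), self.extent)

    def concat(self, other: "OccurrenceSet") -> "OccurrenceSet":
        df = pd.concat([self.records, other.records], ignore_index=True)
        return OccurrenceSet(df, self.extent)

    def to_csv(self, path: str) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str, extent=None) -> "OccurrenceSet":
        df = pd.read_csv(path)
        if "source" not in df.columns:
            df["source"] = "unknown"
        if extent is None:
            extent = (df["lon"].min(), df["lat"].min(), df["lon"].max(), df["lat"].max())
        return cls(df, tuple(extent))


@dataclass(frozen=True)
class SplitSpec:
    """Stratified-split configuration (default 30% of each class to train)."""

    train_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def clean_occurrences(
    raw: pd.DataFrame,
    extent: tuple[float, float, float, float],
    geographic: bool = True,
) -> tuple[OccurrenceSet, dict[str, int]]:
    """Remove malformed, out-of-extent and duplicated records.

    Rules apply in a fixed order and the report counts removals per rule:

    1. ``invalid`` — non-finite coordinates and, for geographic
       coordinates (the default), |lat| > 90 or |lon| > 180 (e.g. records
       placed in the ocean by sign errors); pass ``geographic=False`` for
       projected map units, where only finiteness applies;
    2. ``outside`` — coordinates outside the study extent;
    3. ``duplicate`` — exact repeats of a (lon, lat, label) triple.
    """
    df = raw.copy()
    if "label" not in df.columns:
        df["label"] = PRESENCE
    if "source" not in df.columns:
        df["source"] = "unknown"
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")

    n0 = len(df)
    valid = np.isfinite(df["lon"]) & np.isfinite(df["lat"])
    if geographic:
        valid &= (df["lat"].abs() <= 90) & (df["lon"].abs() <= 180)
    df = df[valid]
    n_invalid = n0 - len(df)

    xmin, ymin, xmax, ymax = extent
    inside = (
        (df["lon"] >= xmin) & (df["lon"] <= xmax)
        & (df["lat"] >= ymin) & (df["lat"] <= ymax)
    )
    n_outside = len(df) - int(inside.sum())
    df = df[inside]

    deduped = df.drop_duplicates(subset=["lon", "lat", "label"], keep="first")
    n_dup = len(df) - len(deduped)

    report = {
        "input": n0,
        "invalid": n_invalid,
        "outside": n_outside,
        "duplicate": n_dup,
        "retained": len(deduped),
    }
    if len(deduped) == 0:
        raise ValueError("no records survived cleaning")
    return OccurrenceSet(deduped.reset_index(drop=True), extent), report


def _thin_one_class(df: pd.DataFrame, extent, cell_size: float, rng) -> pd.DataFrame:
    xmin, _, _, ymax = extent
    col = np.floor((df["lon"].to_numpy() - xmin) / cell_size).astype(int)
    row = np.floor((ymax - df["lat"].to_numpy()) / cell_size).astype(int)
    keep_idx = []
    cells = pd.Series(np.arange(len(df))).groupby([row, col], sort=True)
    for _, idx in cells.groups.items():
        idx = np.asarray(idx)
        keep_idx.append(idx[rng.integers(len(idx))])
    return df.iloc[sorted(keep_idx)]


def thin_by_grid(occ: OccurrenceSet, cell_size: float, seed: int = 0) -> OccurrenceSet:
    """Thin records to at most one per cell of a regular sampling grid.

    A grid of the target cell size is anchored at the extent's upper-left
    corner; within each occupied cell exactly one record survives, chosen
    uniformly at random under the seed. Presences and pseudo-absences are
    thinned independently on the same grid; where a cell holds both, the
    presence wins and the pseudo-absence is dropped.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    rng = np.random.default_rng(seed)
    df = occ.records
    parts = []
    pres_cells: set[tuple[int, int]] = set()
    for label in (PRESENCE, ABSENCE):  # presences first so they win shared cells
        sub = df[df["label"] == label]
        if sub.empty:
            continue
        kept = _thin_one_class(sub, occ.extent, cell_size, rng)
        xmin, _, _, ymax = occ.extent
        col = np.floor((kept["lon"].to_numpy() - xmin) / cell_size).astype(int)
        row = np.floor((ymax - kept["lat"].to_numpy()) / cell_size).astype(int)
        if label == PRESENCE:
            pres_cells = set(zip(row, col))
        else:
            free = [rc not in pres_cells for rc in zip(row, col)]
            kept = kept[np.asarray(free, dtype=bool)]
        parts.append(kept)
    out = pd.concat(parts).sort_index().reset_index(drop=True)
    return OccurrenceSet(out, occ.extent)


def generate_pseudo_absences(
    env: EnvGrid, presences: OccurrenceSet, n: int = 2000, seed: int = 0
) -> OccurrenceSet:
    """Place random background points on valid cells free of presences.

    Draws ``n`` distinct cells without replacement from the valid cells of
    the raster that contain no presence record, and returns their centers
    labelled 0. The default of 2,000 background points is the conventional
    calibration set size for presence/pseudo-absence modelling at this
    scale.
    """
    pr, pc = env.point_to_cell(
        presences.records["lon"].to_numpy(), presences.records["lat"].to_numpy()
    )
    occupied = np.zeros((env.n_rows, env.n_cols), dtype=bool)
    inb = env.in_bounds(pr, pc)
    occupied[pr[inb], pc[inb]] = True
    free = env.valid_mask & ~occupied
    free_idx = np.flatnonzero(free.ravel())
    if len(free_idx) < n:
        raise ValueError(
            f"only {len(free_idx)} free cells available for {n} pseudo-absences"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(free_idx, size=n, replace=False)
    rows, cols = np.unravel_index(chosen, free.shape)
    x, y = env.cell_center(rows, cols)
    return OccurrenceSet.from_arrays(
        lon=x, lat=y, label=np.zeros(n, dtype=int), source="pseudo-absence",
        extent=env.extent,
    )


def stratified_split(
    occ: OccurrenceSet, spec: SplitSpec = SplitSpec()
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Split records into train/test with per-class proportions.

    Within each label class, ``round(train_fraction * count)`` records
    (round half up) are drawn uniformly at random into the training set and
    the remainder into the test set; the two are disjoint and exhaustive.
    """
    labels = occ.labels
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both presence and absence records are required for a split")
    rng = np.random.default_rng(spec.seed)
    train_mask = np.zeros(len(occ), dtype=bool)
    for c in classes:
        idx = np.flatnonzero(labels == c)
        n_train = int(math.floor(spec.train_fraction * len(idx) + 0.5))
        chosen = rng.choice(idx, size=n_train, replace=False)
        train_mask[chosen] = True
    return occ.subset(train_mask), occ.subset(~train_mask)


def extract_features(
    occ: OccurrenceSet, env: EnvGrid, variables: list[str] | None = None
) -> tuple[pd.DataFrame, int]:
    """Look up predictor values at each record's raster cell.

    Returns the feature table (one row per record: ``record_id``, one
    column per predictor, and ``label``) and the count of records dropped
    for landing on nodata cells. Records outside the raster extent are an
    error — inputs are expected to be cleaned first.
    """
    if variables is None:
        variables = env.layer_names
    missing = [v for v in variables if v not in env.layers]
    if missing:
        raise KeyError(f"variables not in grid: {missing}")
    lon = occ.records["lon"].to_numpy()
    lat = occ.records["lat"].to_numpy()
    row, col = env.point_to_cell(lon, lat)
    inb = env.in_bounds(row, col)
    if not inb.all():
        raise ValueError(f"{int((~inb).sum())} records fall outside the raster extent")
    valid = env.valid_mask[row, col]
    n_dropped = int((~valid).sum())
    row, col = row[valid], col[valid]
    data = {"record_id": np.flatnonzero(valid)}
    for v in variables:
        data[v] = env.layers[v][row, col]
    data["label"] = occ.labels[valid]
    return pd.DataFrame(data), n_dropped
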