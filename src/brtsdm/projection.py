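"""Projection, maxSSS binarization, GCM composites and range change.

The selected ensemble is projected onto the present predictor stack and
onto each future stack (one per GCM × RCP × period). Suitability maps are
binarized at the threshold maximizing sensitivity + specificity (maxSSS),
computed on an evaluation split. For each RCP × period the binary maps of
the participating GCMs are summed cellwise into a composite (0 = both
absent, 2 = both present for two GCMs); comparing the composite with the
present binary map classifies every cell as absent, contraction,
refugium or expansion, from which percentage range change and the
distribution of climate deltas per change class are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .brt import BRTModel, predict_brt
from .grids import EnvGrid
from .synthetic import ScenarioKey

__all__ = [
    "SuitabilityMap",
    "ThresholdResult",
    "ChangeMap",
    "CATEGORIES",
    "project_suitability",
    "max_sss_threshold",
    "binarize",
    "composite_gcm",
    "change_map",
    "range_change_stats",
    "delta_by_class",
]

ABSENT, CONTRACTION, REFUGIUM, EXPANSION = 0, 1, 2, 3
CATEGORIES = {
    ABSENT: "absent",
    CONTRACTION: "contraction",
    REFUGIUM: "refugium",
    EXPANSION: "expansion",
}


@dataclass
class SuitabilityMap:
    values: np.ndarray  # probabilities, NaN on nodata
    nodata_mask: np.ndarray
    scenario: ScenarioKey

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    sensitivity: float
    specificity: float
    degenerate: bool = False

    @property
    def sss(self) -> float:
        return self.sensitivity + self.specificity


@dataclass
class ChangeMap:
    categories: np.ndarray  # int map of ABSENT/CONTRACTION/REFUGIUM/EXPANSION
    nodata_mask: np.ndarray
    rcp: float | None = None
    period: str | None = None

    def count(self, category: int) -> int:
        return int(((self.categories == category) & ~self.nodata_mask).sum())


def project_suitability(
    model: BRTModel, env: EnvGrid, key: ScenarioKey = ScenarioKey()
) -> SuitabilityMap:
    """Per-cell probability prediction of the ensemble on a raster stack."""
    missing = [v for v in model.variables if v not in env.layers]
    if missing:
        raise KeyError(f"scenario stack missing model layers: {missing}")
    valid = env.valid_mask
    X = np.column_stack([env.layers[v][valid] for v in model.variables])
    out = np.full((env.n_rows, env.n_cols), np.nan)
    out[valid] = predict_brt(model, X, scale="probability")
    return SuitabilityMap(values=out, nodata_mask=env.nodata_mask.copy(), scenario=key)


def max_sss_threshold(labels: np.ndarray, scores: np.ndarray) -> ThresholdResult:
    """Threshold maximizing sensitivity + specificity.

    Candidate thresholds are the midpoints between consecutive sorted
    unique scores, plus a below-minimum and an above-maximum sentinel;
    presence is predicted where score ≥ threshold. Among maximizers the
    smallest threshold is returned. If all scores are equal every cut
    gives sensitivity + specificity = 1 and the result is flagged
    degenerate.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required to compute maxSSS")
    uniq = np.unique(s)
    candidates = np.concatenate((
        [uniq[0] - 1.0],
        (uniq[:-1] + uniq[1:]) / 2.0,
        [uniq[-1] + 1.0],
    ))
    # vectorized sweep: sens/spec at every candidate
    pred = s[None, :] >= candidates[:, None]
    sens = (pred & (y == 1)).sum(axis=1) / n1
    spec = ((~pred) & (y == 0)).sum(axis=1) / n0
    sss = sens + spec
    best = sss.max()
    # ties (incl. last-ulp float noise on equal rational sums) resolve to
    # the smallest threshold; candidates are ascending
    i = int(np.flatnonzero(sss >= best - 1e-12)[0])
    return ThresholdResult(
        threshold=float(candidates[i]),
        sensitivity=float(sens[i]),
        specificity=float(spec[i]),
        degenerate=bool(uniq.size == 1),
    )


def binarize(suit: SuitabilityMap, threshold: float) -> np.ndarray:
    """Binary range map: 1 where probability ≥ threshold; NaN on nodata."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    out = np.where(suit.values >= threshold, 1.0, 0.0)
    out[suit.nodata_mask] = np.nan
    return out


def composite_gcm(binary_maps: list[np.ndarray]) -> np.ndarray:
    """Cellwise sum of per-GCM binary maps (0..k for k GCMs)."""
    if not binary_maps:
        raise ValueError("no maps to composite")
    shape = binary_maps[0].shape
    for m in binary_maps[1:]:
        if m.shape != shape:
            raise ValueError("binary maps are not aligned")
    stack = np.stack(binary_maps)
    out = stack.sum(axis=0)
    out[np.isnan(stack).any(axis=0)] = np.nan
    return out


def change_map(
    present_binary: np.ndarray,
    future_composite: np.ndarray,
    consensus: str = "all",
    rcp: float | None = None,
    period: str | None = None,
    n_gcms: int = 2,
) -> ChangeMap:
    """Classify each cell by present vs. future suitability.

    A cell counts as future-suitable when the GCM composite reaches
    ``n_gcms`` (consensus="all", the default strict agreement) or is at
    least 1 (consensus="any"). Categories: suitable now and in the future
    → refugium; suitable now only → contraction; future only → expansion;
    neither → absent.
    """
    if present_binary.shape != future_composite.shape:
        raise ValueError("present and future maps are not aligned")
    if consensus == "all":
        fut = future_composite >= n_gcms
    elif consensus == "any":
        fut = future_composite >= 1
    else:
        raise ValueError("consensus must be 'all' or 'any'")
    pres = present_binary == 1
    nodata = np.isnan(present_binary) | np.isnan(future_composite)
    cats = np.full(present_binary.shape, ABSENT, dtype=int)
    cats[pres & fut] = REFUGIUM
    cats[pres & ~fut] = CONTRACTION
    cats[~pres & fut] = EXPANSION
    return ChangeMap(categories=cats, nodata_mask=nodata, rcp=rcp, period=period)


def range_change_stats(change: ChangeMap) -> dict:
    """Percent contraction/expansion relative to the present suitable range.

    Contraction % = 100 · contraction cells / present-suitable cells,
    where present-suitable = contraction + refugium; expansion is reported
    on the same denominator, so net change = expansion − contraction.
    """
    counts = {name: change.count(code) for code, name in CATEGORIES.items()}
    present_suitable = counts["contraction"] + counts["refugium"]
    if present_suitable == 0:
        raise ValueError("no present-suitable cells; change percentages undefined")
    return {
        "counts": counts,
        "present_suitable": present_suitable,
        "pct_contraction": 100.0 * counts["contraction"] / present_suitable,
        "pct_expansion": 100.0 * counts["expansion"] / present_suitable,
        "pct_refugium": 100.0 * counts["refugium"] / present_suitable,
    }


def mean_change_stats(stats: list[dict]) -> dict:
    """Average the percentage change statistics across several maps
    (e.g. across RCPs within a period)."""
    if not stats:
        raise ValueError("no statistics to average")
    return {
        key: float(np.mean([s[key] for s in stats]))
        for key in ("pct_contraction", "pct_expansion", "pct_refugium")
    }


def delta_by_class(change: ChangeMap, delta: np.ndarray) -> pd.DataFrame:
    """Distribution of a climate delta within each change class.

    For each class, reports n, median, first and third quartiles (linear
    interpolation between order statistics) and box-plot whiskers — the
    most extreme values lying within 1.5 × IQR of the hinges. Empty
    classes are reported with n = 0.
    """
    if delta.shape != change.categories.shape:
        raise ValueError("delta layer is not aligned with the change map")
    rows = []
    for code, name in CATEGORIES.items():
        mask = (change.categories == code) & ~change.nodata_mask & np.isfinite(delta)
        vals = delta[mask]
        if vals.size == 0:
            rows.append({"class": name, "n": 0, "q1": np.nan, "median": np.nan,
                         "q3": np.nan, "whisker_low": np.nan,
                         "whisker_high": np.nan})
            continue
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        rows.append({
            "class": name, "n": int(vals.size),
            "q1": float(q1), "median": float(med), "q3": float(q3),
            "whisker_low": float(inside.min()),
            "whisker_high": float(inside.max()),
        })
    return pd.DataFrame(rows)
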