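"""Predictor reduction: correlation clustering, label correlation, VIF.

The candidate predictor set is reduced in three stages. First, predictors
are grouped by hierarchical (default complete-linkage) clustering on the
distance 1 − |r|, with the tree cut so that groups correspond to mutual
Pearson correlation above a cutoff (default 0.5). Second, each group
contributes its single member whose point-biserial correlation with the
presence/absence label is strongest in absolute value. Third, the
surviving set is screened for residual multicollinearity by iteratively
removing the predictor with the largest variance inflation factor until
all VIFs fall at or below a ceiling (default 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "PredictorCluster",
    "SelectionConfig",
    "correlation_matrix",
    "cluster_predictors",
    "point_biserial",
    "select_representatives",
    "vif",
    "vif_filter",
    "select_variables",
]


@dataclass
class PredictorCluster:
    cluster_id: int
    members: list[str]
    representative: str | None = None
    member_scores: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SelectionConfig:
    correlation_cutoff: float = 0.5
    vif_threshold: float = 5.0
    linkage: str = "complete"

    def __post_init__(self) -> None:
        if not 0.0 < self.correlation_cutoff < 1.0:
            raise ValueError("correlation cutoff must lie in (0, 1)")
        if self.vif_threshold <= 1.0:
            raise ValueError("VIF threshold must exceed 1")


def correlation_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the predictor columns."""
    X = features.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = [c for c, s in zip(features.columns, sd) if s == 0]
        raise ValueError(f"constant columns have undefined correlation: {bad}")
    r = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=features.columns, columns=features.columns)


def cluster_predictors(
    corr: pd.DataFrame, cutoff: float = 0.5, method: str = "complete"
) -> list[PredictorCluster]:
    """Group predictors by agglomerative clustering on d = 1 − |r|.

    The dendrogram is cut at height 1 − cutoff, so (under complete
    linkage) no two variables merged into one group are farther apart than
    that; variables whose mutual |r| never reaches the cutoff end up in
    singleton groups.
    """
    names = list(corr.columns)
    if len(names) == 1:
        return [PredictorCluster(1, names)]
    d = 1.0 - np.abs(corr.to_numpy(dtype=float))
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # symmetrize away float noise
    Z = linkage(squareform(d, checks=False), method=method)
    assignment = fcluster(Z, t=1.0 - cutoff, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for name, cid in zip(names, assignment):
        clusters.setdefault(int(cid), []).append(name)
    return [PredictorCluster(cid, members) for cid, members in sorted(clusters.items())]


def point_biserial(x: np.ndarray, y: np.ndarray) -> float:
    """Correlation between a continuous variable and a 0/1 label.

    Computed in the classical form r = (M1 − M0) / s_x · sqrt(p q) with
    the population standard deviation of x, which is identical to the
    Pearson correlation of x with the label coded 0/1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask1 = y == 1
    n1, n0 = int(mask1.sum()), int((~mask1).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both labels must be present")
    s = x.std()  # population sd
    if s == 0:
        raise ValueError("x is constant")
    p = n1 / x.size
    return float((x[mask1].mean() - x[~mask1].mean()) / s * np.sqrt(p * (1.0 - p)))


def select_representatives(
    clusters: list[PredictorCluster], features: pd.DataFrame, labels: np.ndarray
) -> list[str]:
    """Pick per cluster the member most correlated with the label.

    Maximizes |point-biserial r|; exact ties break to the
    lexicographically first layer name. Fills in each cluster's
    ``representative`` and ``member_scores`` in place.
    """
    chosen = []
    for cl in clusters:
        scores = {
            m: point_biserial(features[m].to_numpy(), labels) for m in cl.members
        }
        cl.member_scores = scores
        best = min(scores, key=lambda m: (-abs(scores[m]), m))
        cl.representative = best
        chosen.append(best)
    return chosen


def vif(features: pd.DataFrame, variables: list[str] | None = None) -> pd.Series:
    """Variance inflation factor 1/(1 − R²) per variable.

    R²_j comes from the least-squares regression (with intercept) of
    variable j on the remaining variables. Perfect collinearity is
    reported as ``inf`` rather than raised.
    """
    if variables is None:
        variables = list(features.columns)
    if len(variables) < 2:
        raise ValueError("VIF needs at least 2 variables")
    X = features.loc[:, variables].to_numpy(dtype=float)
    n = X.shape[0]
    if n <= len(variables):
        raise ValueError("need more rows than variables")
    out = {}
    for j, name in enumerate(variables):
        yj = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        tss = ((yj - yj.mean()) ** 2).sum()
        if tss == 0:
            raise ValueError(f"variable {name!r} is constant")
        r2 = 1.0 - (resid**2).sum() / tss
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def vif_filter(
    features: pd.DataFrame,
    variables: list[str] | None = None,
    threshold: float = 5.0,
) -> tuple[list[str], list[dict]]:
    """Iteratively drop the worst-VIF variable until all VIFs ≤ threshold.

    Returns the retained variable list and a removal trace (one entry per
    step with the dropped variable, its VIF, and the VIFs seen). Ties on
    the maximum break to the lexicographically first name.
    """
    if variables is None:
        variables = list(features.columns)
    current = list(variables)
    trace: list[dict] = []
    while len(current) >= 2:
        v = vif(features, current)
        if (v <= threshold).all():
            break
        worst = min(v.index, key=lambda m: (-v[m], m))
        trace.append({"removed": worst, "vif": float(v[worst]),
                      "vifs": {k: float(x) for k, x in v.items()}})
        current.remove(worst)
    return current, trace


def select_variables(
    features: pd.DataFrame,
    labels: np.ndarray,
    config: SelectionConfig = SelectionConfig(),
) -> dict:
    """Run the full three-stage reduction; returns clusters, picks and trace."""
    corr = correlation_matrix(features)
    clusters = cluster_predictors(corr, config.correlation_cutoff, config.linkage)
    reps = select_representatives(clusters, features, labels)
    if len(reps) >= 2:
        selected, trace = vif_filter(features, reps, config.vif_threshold)
    else:
        selected, trace = reps, []
    return {
        "clusters": clusters,
        "representatives": reps,
        "selected": selected,
        "vif_trace": trace,
    }
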