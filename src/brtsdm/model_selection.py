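"""Cross-validated evaluation, the parameter-grid search, and model choice.

Candidate models span a grid of thinning target distances and boosting
hyper-parameters (bag fraction, learning rate, tree complexity, step
size); each candidate is scored by k-fold cross-validated AUC and
deviance explained, and the best model is the one with the highest AUC,
ties resolved toward higher deviance explained and then toward the
smallest learning rate (slower learning shrinks each tree's contribution
and estimates the response more reliably).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .brt import BRTParams, bernoulli_deviance, fit_brt

__all__ = [
    "EvalMetrics",
    "auc",
    "cross_validate",
    "grid_search",
    "select_best",
    "GRID_COLUMNS",
]

GRID_COLUMNS = [
    "target_distance", "bf", "lr", "tc", "ss",
    "nt", "cv_auc", "deviance_explained", "cv_deviance", "null_deviance",
    "seed", "status",
]


@dataclass(frozen=True)
class EvalMetrics:
    auc: float
    cv_deviance: float
    null_deviance: float
    nt: int

    @property
    def deviance_explained(self) -> float:
        return 1.0 - self.cv_deviance / self.null_deviance


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the rank (Mann–Whitney) statistic.

    Equals the probability that a randomly drawn presence outscores a
    randomly drawn absence, ties counted one half.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def cross_validate(
    data: pd.DataFrame, params: BRTParams, k: int = 10, seed: int | None = None
) -> EvalMetrics:
    """k-fold cross-validated AUC and deviance explained for one candidate.

    Folds are stratified (per-class sizes within one record of equal) and
    grown stagewise alongside the full model: each fold model is fitted on
    the other k−1 folds and scores its held-out fold, and the pooled
    held-out predictions at the selected tree count give the AUC and CV
    deviance. Null deviance comes from the intercept-only model, so an
    ensemble no better than the prevalence has deviance explained 0.
    """
    p = replace(params, n_folds=k)
    if seed is not None:
        p = replace(p, seed=seed)
    model = fit_brt(data, p)
    if model.cv_predictions is None:  # intercept-only (max_trees = 0)
        y = data["label"].to_numpy(dtype=float)
        probs = np.full(len(y), y.mean())
    else:
        y = model.cv_labels
        probs = model.cv_predictions
    null_probs = np.full(len(y), y.mean())
    return EvalMetrics(
        auc=auc(y, probs),
        cv_deviance=bernoulli_deviance(y, probs),
        null_deviance=bernoulli_deviance(y, null_probs),
        nt=model.nt,
    )


def grid_search(
    datasets: dict[float, pd.DataFrame],
    bf_grid=(0.1, 0.5, 0.75),
    lr_grid=(0.01, 0.005, 0.001),
    tc_grid=(1, 2, 3, 4),
    ss_grid=(25, 50),
    k: int = 10,
    seed: int = 0,
    base_params: BRTParams | None = None,
    existing: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Evaluate every (target distance, bf, lr, tc, ss) combination.

    ``datasets`` maps each thinning target distance to its prepared
    feature table (the distances produce different sample sizes, so they
    are part of the grid). One row is emitted per combination; fitting
    failures are recorded in the row's ``status`` rather than raised.
    Passing a previous result as ``existing`` resumes the search, skipping
    combinations already evaluated. Deterministic for a fixed seed.
    """
    if not datasets:
        raise ValueError("no datasets supplied")
    base = base_params if base_params is not None else BRTParams()
    done = set()
    rows = []
    if existing is not None and len(existing):
        rows = existing.to_dict("records")
        done = {
            (r["target_distance"], r["bf"], r["lr"], r["tc"], r["ss"])
            for r in rows
        }
    for dist, table in datasets.items():
        for bf in bf_grid:
            for lr in lr_grid:
                for tc in tc_grid:
                    for ss in ss_grid:
                        key = (dist, bf, lr, tc, ss)
                        if key in done:
                            continue
                        params = replace(base, bf=bf, lr=lr, tc=tc, ss=ss, seed=seed)
                        row = dict(target_distance=dist, bf=bf, lr=lr, tc=tc,
                                   ss=ss, seed=seed)
                        try:
                            m = cross_validate(table, params, k=k, seed=seed)
                            row.update(
                                nt=m.nt, cv_auc=m.auc,
                                deviance_explained=m.deviance_explained,
                                cv_deviance=m.cv_deviance,
                                null_deviance=m.null_deviance, status="ok",
                            )
                        except Exception as exc:  # recorded, not fatal
                            row.update(nt=np.nan, cv_auc=np.nan,
                                       deviance_explained=np.nan,
                                       cv_deviance=np.nan, null_deviance=np.nan,
                                       status=f"error: {exc}")
                        rows.append(row)
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


def select_best(results: pd.DataFrame) -> pd.Series:
    """The grid row chosen by the model-selection rule.

    Order by cross-validated AUC (descending), then deviance explained
    (descending), then learning rate (ascending — the smallest lr wins
    among otherwise equal candidates), then tc, bf, ss and target distance
    ascending as documented final tie-breaks.
    """
    ok = results[results["status"] == "ok"] if "status" in results else results
    if len(ok) == 0:
        raise ValueError("no successful grid rows to select from")
    ordered = ok.sort_values(
        by=["cv_auc", "deviance_explained", "lr", "tc", "bf", "ss",
            "target_distance"],
        ascending=[False, False, True, True, True, True, True],
        kind="mergesort",
    )
    return ordered.iloc[0]
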