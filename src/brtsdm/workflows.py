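"""End-to-end synthetic study workflows.

These functions wire the pipeline stages together on a synthetic
landscape with a known truth, the configuration every recovery check in
the package uses:

* a square grid with three correlated predictor blocks (eight layers,
  within-block |r| ≈ 0.8, blocks mutually independent);
* a suitability truth driven by one temperature-like and one
  precipitation-like layer through steep threshold-shaped responses;
* presence-only sampling of the truth (800 draws, echoing the scale of a
  real occurrence compilation), grid thinning at one cell, 2,000
  pseudo-absences, and a 30% stratified training split.

Because the truth is known, each run can report the Bayes AUC — the AUC
the true suitability surface itself attains on the sampled records — as
the ceiling against which the fitted ensemble's cross-validated AUC is
judged, and future scenarios built from known climate deltas let range-
change attribution be checked against the construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .brt import BRTParams, bernoulli_deviance, fit_brt, relative_influence
from .model_selection import auc
from .occurrences import (
    SplitSpec,
    extract_features,
    generate_pseudo_absences,
    stratified_split,
    thin_by_grid,
)
from .projection import (
    binarize,
    change_map,
    composite_gcm,
    delta_by_class,
    max_sss_threshold,
    project_suitability,
    range_change_stats,
)
from .synthetic import (
    ResponseRamp,
    ScenarioKey,
    TruthSpec,
    make_env_grid,
    make_true_suitability,
    sample_occurrences,
)
from .brt import predict_brt

__all__ = ["StudyConfig", "simulate_study", "recovery_run", "change_run"]

# layers: block 0 = temperature-like, block 1 = precipitation-like,
# block 2 = topographic-index-like; truth drives one layer of each
# climate block with a steep threshold response
DEFAULT_BLOCKS = [(3, 0.8), (3, 0.8), (2, 0.8)]
DEFAULT_LAYER_NAMES = [
    "temp_mean", "temp_max_warmest", "temp_wettest_q",
    "precip_annual", "precip_seasonality", "precip_warmest_q",
    "topo_wetness", "topo_openness",
]
# a two-requirement species: suitability needs BOTH a warm-enough summer
# and enough annual rain (each ramp alone leaves the logit deep below 0),
# giving the sharp threshold responses and strong discrimination typical
# of climate-limited desert plants
DEFAULT_TRUTH = TruthSpec(
    response_functions={
        "temp_max_warmest": ResponseRamp(location=0.5, steepness=6.0, amplitude=6.0),
        "precip_annual": ResponseRamp(location=-0.3, steepness=6.0, amplitude=6.0),
    },
    intercept=-9.0,
)


@dataclass(frozen=True)
class StudyConfig:
    """The synthetic study conditions (generator defaults, not dials)."""

    n_rows: int = 200
    n_cols: int = 200
    blocks: list[tuple[int, float]] = field(default_factory=lambda: DEFAULT_BLOCKS)
    layer_names: list[str] = field(default_factory=lambda: DEFAULT_LAYER_NAMES)
    truth: TruthSpec = DEFAULT_TRUTH
    autocorr_range: float = 3.0
    n_presences: int = 800
    thin_cell: float = 1.0
    n_pseudo_absences: int = 2000
    train_fraction: float = 0.30


# analysis defaults for the worked synthetic runs: a moderate learning
# rate and 5 internal folds keep the stagewise selection well inside an
# interactive budget at these sample sizes
RECOVERY_PARAMS = BRTParams(bf=0.75, lr=0.05, tc=3, ss=25, max_trees=500,
                            n_folds=5, patience=2)


def simulate_study(seed: int, config: StudyConfig = StudyConfig()) -> dict:
    """Generate one landscape and its prepared modelling dataset."""
    ss = np.random.SeedSequence(seed)
    s_env, s_noise, s_occ, s_thin, s_abs, s_split = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)
    )
    env = make_env_grid(config.n_rows, config.n_cols, config.blocks,
                        config.autocorr_range, seed=s_env,
                        layer_names=config.layer_names)
    suit = make_true_suitability(env, config.truth, seed=s_noise)
    presences = sample_occurrences(env, suit, config.n_presences, seed=s_occ)
    thinned = thin_by_grid(presences, config.thin_cell, seed=s_thin)
    absences = generate_pseudo_absences(env, thinned,
                                        n=config.n_pseudo_absences, seed=s_abs)
    occ = thinned.concat(absences)
    train, test = stratified_split(occ, SplitSpec(config.train_fraction,
                                                  seed=s_split))
    features, _ = extract_features(occ, env)
    train_features, _ = extract_features(train, env)
    test_features, _ = extract_features(test, env)
    return {
        "env": env,
        "truth": config.truth,
        "suitability": suit,
        "presences": presences,
        "thinned": thinned,
        "occurrences": occ,
        "train": train,
        "test": test,
        "features": features,
        "train_features": train_features,
        "test_features": test_features,
    }


def bayes_auc(study: dict) -> float:
    """AUC of the true suitability surface on the study's records."""
    env = study["env"]
    occ = study["occurrences"]
    row, col = env.point_to_cell(occ.records["lon"].to_numpy(),
                                 occ.records["lat"].to_numpy())
    return auc(occ.labels, study["suitability"][row, col])


def recovery_run(
    seed: int,
    config: StudyConfig = StudyConfig(),
    params: BRTParams = RECOVERY_PARAMS,
    cv_folds: int = 5,
) -> dict:
    """Variable selection + BRT fit on one simulated study.

    Returns the selected variables (one expected per correlated block),
    the relative-influence ranking, the cross-validated AUC of the fit and
    the Bayes AUC of the generating truth.
    """
    from .variable_selection import select_variables

    study = simulate_study(seed, config)
    features = study["features"]
    predictors = features.drop(columns=["record_id", "label"])
    selection = select_variables(predictors, features["label"].to_numpy())
    cols = selection["selected"] + ["label"]
    fit_params = replace(params, n_folds=cv_folds, seed=seed % (2**31))
    model = fit_brt(features[cols], fit_params)
    y, probs = model.cv_labels, model.cv_predictions
    cv_dev = bernoulli_deviance(y, probs)
    null_dev = bernoulli_deviance(y, np.full(len(y), y.mean()))
    influence = relative_influence(model)
    return {
        "study": study,
        "selection": selection,
        "model": model,
        "influence": influence,
        "cv_auc": auc(y, probs),
        "deviance_explained": 1.0 - cv_dev / null_dev,
        "bayes_auc": bayes_auc(study),
    }


def change_run(
    seed: int,
    config: StudyConfig = StudyConfig(n_rows=100, n_cols=100,
                                      n_pseudo_absences=1000),
    params: BRTParams = RECOVERY_PARAMS,
    temp_delta: float = 1.5,
    precip_delta: float = -1.0,
    half_region: bool = True,
    gcm_jitter: float = 0.1,
) -> dict:
    """Fit, project, binarize and map range change under a known delta.

    A warming delta is applied to the temperature driver and a drying
    delta to the precipitation driver — over the western half of the grid
    only when ``half_region`` is set (full strength at the west edge,
    tapering linearly to zero at the centerline), so contraction should
    concentrate there and the per-class delta distributions should
    separate. Two pseudo-GCM stacks (the delta, jittered oppositely by
    ``gcm_jitter``) are composited with strict agreement.
    """
    from .synthetic import apply_climate_deltas

    study = simulate_study(seed, config)
    env = study["env"]
    features = study["train_features"]
    drivers = list(config.truth.response_functions)
    cols = drivers + ["label"]
    model = fit_brt(features[cols], replace(params, seed=seed % (2**31)))

    test_features = study["test_features"]
    scores = predict_brt(model, test_features[drivers])
    thr = max_sss_threshold(test_features["label"].to_numpy(), scores)

    present_map = project_suitability(model, env)
    present_binary = binarize(present_map, thr.threshold)

    if half_region:
        taper = np.clip(1.0 - np.arange(env.n_cols) / (env.n_cols / 2.0), 0.0, 1.0)
        mask = np.broadcast_to(taper, (env.n_rows, env.n_cols)).copy()
    else:
        mask = np.ones((env.n_rows, env.n_cols))
    temp_layer, precip_layer = drivers[0], drivers[1]
    deltas = {temp_layer: temp_delta * mask, precip_layer: precip_delta * mask}
    futures = []
    for sign in (+1.0, -1.0):
        jittered = {k: v * (1.0 + sign * gcm_jitter) for k, v in deltas.items()}
        key = ScenarioKey("2070", "GCM-A" if sign > 0 else "GCM-B", 4.5)
        fut_env = apply_climate_deltas(env, jittered, key)
        fmap = project_suitability(model, fut_env, key)
        futures.append((fut_env, binarize(fmap, thr.threshold)))
    composite = composite_gcm([b for _, b in futures])
    cm = change_map(present_binary, composite, rcp=4.5, period="2070")
    stats = range_change_stats(cm)
    # attribute change to the mean (across GCMs) known precipitation delta
    precip_delta_map = np.mean(
        [fe.layers[precip_layer] - env.layers[precip_layer] for fe, _ in futures],
        axis=0,
    )
    summary = delta_by_class(cm, precip_delta_map)
    return {
        "study": study,
        "model": model,
        "threshold": thr,
        "present_binary": present_binary,
        "composite": composite,
        "change_map": cm,
        "stats": stats,
        "delta_summary": summary,
        "affected_mask": mask.astype(bool),
    }
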