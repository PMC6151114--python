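"""Occurrence preparation: clean, thin, add pseudo-absences, split.

Starts from raw presence records (including a few deliberately corrupted
rows), then runs the standard presence/background preparation chain.
"""

import numpy as np
import pandas as pd

from brtsdm import (
    SplitSpec,
    clean_occurrences,
    generate_pseudo_absences,
    make_env_grid,
    make_true_suitability,
    sample_occurrences,
    stratified_split,
    thin_by_grid,
)
from brtsdm.workflows import DEFAULT_BLOCKS, DEFAULT_LAYER_NAMES, DEFAULT_TRUTH

env = make_env_grid(120, 120, DEFAULT_BLOCKS, autocorr_range=3.0, seed=7,
                    layer_names=DEFAULT_LAYER_NAMES)
suit = make_true_suitability(env, DEFAULT_TRUTH)
presences = sample_occurrences(env, suit, n=500, seed=8)

# corrupt a few rows the way aggregated databases are: a non-finite
# coordinate, a point far outside the study region, a duplicated record
raw = pd.concat([
    presences.records,
    pd.DataFrame({"lon": [np.nan, 4000.0, presences.records["lon"].iloc[0]],
                  "lat": [5.0, 5.0, presences.records["lat"].iloc[0]],
                  "label": [1, 1, 1], "source": ["bad"] * 3}),
], ignore_index=True)

# the landscape is in projected map units, so only finiteness and the
# extent apply (geographic lat/lon bounds are for degree coordinates)
occ, report = clean_occurrences(raw, env.extent, geographic=False)
print("cleaning report:", report)

thinned = thin_by_grid(occ, cell_size=2.0, seed=9)
print(f"thinning at 2 map units: {len(occ)} -> {len(thinned)} records "
      f"(one per occupied grid cell)")

absences = generate_pseudo_absences(env, thinned, n=2000, seed=10)
print(f"pseudo-absences: {len(absences)} background points on "
      f"presence-free valid cells")

both = thinned.concat(absences)
train, test = stratified_split(both, SplitSpec(train_fraction=0.30, seed=11))
print(f"stratified split: {len(train)} train / {len(test)} test "
      f"({(train.labels == 1).sum()} presences in train, i.e. 30% of each class)")
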