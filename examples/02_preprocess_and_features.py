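"""Preprocess a small session and extract FBCSP feature maps.

Fits the z-score normalizer on the training runs only, applies common
average referencing and the 60/120/180/240 Hz notch cascade, windows the
trials (9 windows of 600 samples per 5 s trial), and fits a 12-component
CSP with the 6-band rhythm filter bank for one finger pair.
"""

import numpy as np

from scbam import BandSpec, FBCSPModel, SimSpec, make_grid_montage, simulate_session
from scbam.pipeline import FoldPlan, split_by_runs
from scbam.preprocess import WindowSet, fit_normalizer, preprocess_run, window_trials

montage = make_grid_montage(6, 6, 8.6)
spec = SimSpec(n_runs=3, trials_per_run=15, seed=2, effect_size=1.5)
session = simulate_session(spec, montage)

stats = fit_normalizer([rec for rec, _ in session[:2]])  # training runs only
wsets = [window_trials(preprocess_run(rec, stats), ev) for rec, ev in session]
windows = WindowSet(
    np.concatenate([w.data for w in wsets]),
    np.concatenate([w.labels for w in wsets]),
    np.concatenate([w.trial_ids for w in wsets]),
    np.concatenate([w.run_ids for w in wsets]), 600, 300)
print(f"windows: {windows.n_windows} of shape "
      f"{windows.data.shape[1]} channels x {windows.window_len} samples")

train_w, _, test_w = split_by_runs(windows, FoldPlan((1, 2), (3,)), 0.0)
pair = (1, 2)
pair_train = train_w.subset(np.isin(train_w.labels, pair))
model = FBCSPModel(BandSpec(), 600.0, n_components=12).fit(pair_train, pair)
features = model.transform(pair_train)
print(f"feature map: {features.values.shape} "
      "(windows x CSP components x rhythm bands)")
print(f"rhythm bands: {features.band_names}")
print("CSP eigenvalues (6 largest then 6 smallest): "
      + np.array2string(model.csp.eigenvalues, precision=3))

# Eigenvalues near 1 mark spatial filters whose variance favours the first
# finger of the pair; near 0 the second. The 12 x 6 log-power map per
# window is what the attention classifier consumes.
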