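"""Classify single tiles as inflamed vs excluded from Ripley's L curves.

Simulates labeled tiles (co-clustered vs spatially segregated tumor/immune
patterns), computes each tile's L(r) - r feature curve with isotropic edge
correction, selects the fused-lasso penalties by 5-fold cross-validation and
reports the cross-validated accuracy.  Under independence L(r) - r is about
zero; positive values mean immune cells aggregate around tumor cells,
negative values mean segregation.
"""

import numpy as np

from tipmap import Config, cv_select, fit_fused_lasso
from tipmap.validation import featurize_synthetic_tile

config = Config()
n_per_class = 25

features, labels = [], []
for k in range(n_per_class):
    features.append(featurize_synthetic_tile("inflamed", 100 + k, config)[1])
    labels.append(1.0)
    features.append(featurize_synthetic_tile("excluded", 200 + k, config)[1])
    labels.append(0.0)

X = np.array([f.x for f in features])
y = np.array(labels)

r50 = int(np.argmin(np.abs(config.r_grid - 50)))
print(f"mean L(50um) - 50um | inflamed: {X[y == 1, r50].mean():+.1f} um")
print(f"mean L(50um) - 50um | excluded: {X[y == 0, r50].mean():+.1f} um")

l1, l2, table = cv_select(X, y, [0.001, 0.01, 0.1], [0.0005, 0.005], seed=0)
acc = max(row[2] for row in table if (row[0], row[1]) == (l1, l2))
print(f"selected penalties: fusion lambda1={l1}, sparsity lambda2={l2}")
print(f"5-fold cross-validated accuracy: {acc:.2f}")

model = fit_fused_lasso(X, y, l1, l2, r_grid=config.r_grid)
nonzero = np.flatnonzero(np.abs(model.beta) > 1e-8)
print(f"coefficient curve: {len(nonzero)}/{len(model.beta)} non-zero radii; "
      f"positive weights at small r favour the inflamed call")
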