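"""Left-censored (MNAR) train/test partitioning of a quantification matrix.

Calibrates the Bernoulli probability so that 20% of observed entries are
held out, then shows the held-out test set is left shifted — lower mean
intensity — relative to the training set, mimicking how low-abundance
proteins go missing in real mass-spectrometry data.
"""

import numpy as np

from lupine import QuantMatrix, calibrate_bernoulli_p, mnar_partition

rng = np.random.default_rng(1)
X = QuantMatrix(
    rng.normal(12, 1.3, (400, 60)),
    [f"P{i}" for i in range(400)],
    [f"S{j}" for j in range(60)],
)

p = calibrate_bernoulli_p(X, target_test_frac=0.2)
print(f"calibrated Bernoulli success probability: {p:.3f}")

mask = mnar_partition(X, bernoulli_p=p, val_frac=0.1, seed=7)
vals = X.values.ravel()
print("entry counts:", mask.counts())
print(f"test fraction: {mask.test_indices.size / vals.size:.3f}")
print(
    f"mean intensity  train {vals[mask.train_indices].mean():.3f}  "
    f"test {vals[mask.test_indices].mean():.3f}"
)
# The test mean sits well below the train mean: low-intensity entries
# fall below their Gaussian threshold more often and are preferentially
# withheld, which is exactly the regime an imputation method faces.
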