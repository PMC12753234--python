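"""Within-complex vs. random protein-pair correlations.

Subunits of a protein complex are co-regulated, so their abundances
should correlate across samples — and a good imputation method must not
destroy (or fabricate) such correlations. This example builds a
synthetic matrix in which three 4-subunit complexes share latent
abundance factors, then compares within-complex to random-pair Spearman
correlations.
"""

import numpy as np
import pandas as pd

from lupine import QuantMatrix, complex_correlations

rng = np.random.default_rng(8)
n_bg, n_samples = 80, 50
values = [rng.normal(12, 1, (n_bg, n_samples))]
membership_rows = []
pids = [f"BG{i}" for i in range(n_bg)]
for c in range(3):
    latent = rng.normal(0, 1, n_samples)
    for s in range(4):
        pid = f"CPLX{c}_SUB{s}"
        pids.append(pid)
        membership_rows.append((f"complex_{c}", pid))
        values.append(12 + latent + rng.normal(0, 0.5, n_samples))

X = QuantMatrix(
    np.vstack([values[0]] + [v[None, :] for v in values[1:]]),
    pids,
    [f"S{j}" for j in range(n_samples)],
)
membership = pd.DataFrame(membership_rows, columns=["complex_id", "protein_id"])

report = complex_correlations(X, membership, seed=1)
print(f"within-complex pairs: {len(report.within_correlations)}")
print(f"mean within-complex Spearman rho: {report.mean_within:.3f}")
print(f"mean random-pair Spearman rho:    {report.mean_random:.3f}")
print(f"paired t-test p-value:            {report.paired_test_p:.2e}")
# Shared latent factors drive within-complex correlations toward ~0.8
# while random pairs hover near zero — the signature expected of real
# co-complex proteins in (well-imputed) quantification data.
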