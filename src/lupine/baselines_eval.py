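"""Baseline imputation methods and held-out evaluation metrics.

Two reference baselines are provided: k-nearest-neighbor imputation
(samples as observations, proteins as features, NaN-aware Euclidean
distance) and Perseus-style Gaussian random sampling, which draws each
missing value from a down-shifted, narrowed Gaussian fitted to the
observed values of its sample — the classic left-censoring assumption
made explicit.

Evaluation compares predictions to the observed values held out in the
test partition: global test-set MSE, per-protein mean absolute
residuals, and the fraction of proteins one method predicts more
accurately than another (restricted to proteins where either method's
residual exceeds a floor, so near-perfect proteins don't dilute the
comparison).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.impute import KNNImputer

from .quantio import QuantMatrix
from .partition import PartitionMask


@dataclass
class EvalReport:
    test_mse: float
    n_test_entries: int
    per_protein_residuals: dict


def knn_impute(X: QuantMatrix, k: int = 5) -> np.ndarray:
    """Impute by averaging the k nearest samples' values.

    Observations are samples (columns), features are proteins (rows);
    distances are NaN-aware Euclidean over mutually present proteins,
    scaled by the shared-feature count. For a missing (protein i,
    sample j), the k nearest samples that do quantify protein i donate
    their mean (uniform weights); if no sample quantifies it, the
    protein's overall mean is used.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not np.isnan(X.values).any():
        return X.values.copy()
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    return imputer.fit_transform(X.values.T).T


def gaussian_downshift_impute(
    X: QuantMatrix,
    width: float = 0.3,
    shift: float = 1.8,
    per_sample: bool = True,
    seed: int = 0,
) -> np.ndarray:
    """Perseus-style Gaussian random sampling imputation.

    For each sample column with observed mean mu and standard deviation
    sigma, missing entries are drawn i.i.d. from
    N(mu - shift * sigma, (width * sigma)^2) — a distribution shifted
    toward the detection limit, emulating left-censored dropout. With
    ``per_sample=False`` the global mean and sd are used instead.
    Observed entries are never altered.
    """
    rng = np.random.default_rng(seed)
    out = X.values.copy()
    present = X.present
    all_vals = X.values[present]
    if all_vals.size < 2:
        raise ValueError("need >= 2 present values")
    g_mu = float(all_vals.mean())
    g_sd = float(all_vals.std(ddof=1))

    if not per_sample:
        miss = ~present
        out[miss] = rng.normal(
            g_mu - shift * g_sd, width * g_sd, size=int(miss.sum())
        )
        return out

    for j in range(X.n_samples):
        col = X.values[:, j]
        obs = col[~np.isnan(col)]
        miss_idx = np.flatnonzero(np.isnan(col))
        if miss_idx.size == 0:
            continue
        if obs.size < 2:
            raise ValueError(
                f"sample {X.sample_ids[j]!r} has fewer than 2 present values"
            )
        mu = float(obs.mean())
        sd = float(obs.std(ddof=1))
        if sd == 0.0:
            warnings.warn(
                f"sample {X.sample_ids[j]!r} has zero variance; "
                "falling back to the global sd",
                stacklevel=2,
            )
            sd = g_sd
        out[miss_idx, j] = rng.normal(
            mu - shift * sd, width * sd, size=miss_idx.size
        )
    return out


def test_mse(
    pred: np.ndarray, X: QuantMatrix, mask: PartitionMask
) -> EvalReport:
    """MSE between predictions and observed values over test entries."""
    test = mask.labels == PartitionMask.TEST
    n_test = int(test.sum())
    if n_test == 0:
        raise ValueError("mask has no test entries")
    resid = pred[test] - X.values[test]
    mse = float(np.mean(resid**2))
    per_protein: dict = {}
    abs_resid = np.abs(pred - X.values)
    for i, pid in enumerate(X.protein_ids):
        row_test = test[i]
        if row_test.any():
            per_protein[pid] = float(abs_resid[i, row_test].mean())
    return EvalReport(mse, n_test, per_protein)


# not a pytest case, despite the conventional metric name
test_mse.__test__ = False


def frac_more_accurate(
    residA: dict, residB: dict, min_resid: float = 0.25
) -> float:
    """Fraction of proteins method A predicts more accurately than B.

    Only proteins where either method's residual exceeds ``min_resid``
    are compared (both-accurate proteins are uninformative); ties count
    as half.
    """
    shared = sorted(set(residA) & set(residB))
    wins = 0.0
    eligible = 0
    for pid in shared:
        a, b = residA[pid], residB[pid]
        if max(a, b) > min_resid:
            eligible += 1
            if a < b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    if eligible == 0:
        warnings.warn("no proteins above the residual floor", stacklevel=2)
        return float("nan")
    return wins / eligible
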