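"""Two-condition simulation with known differential abundance.

The generator emulates a log-scale protein quantification study: protein
means are Gaussian around 12 (sd 1.0) — typical of log2 TMT or LFQ
intensities — and per-protein standard deviations are themselves drawn
from a Gaussian (mean 1.0, sd 1.0), truncated away from zero by redraw.
Condition A samples each protein around its mean; condition B shifts the
means of a randomly chosen 10% of proteins up and a disjoint 10% down by
a fixed fraction ``delta_pct`` of the mean. Missingness is then injected
with the same left-censoring (thresholds + Bernoulli) machinery used for
partitioning, topping up with MCAR dropout when the requested fraction
exceeds what pure left-censoring can reach.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quantio import QuantMatrix
from .partition import censoring_probabilities


@dataclass
class SimulatedStudy:
    """Two-condition matrices with ground-truth DA labels."""

    A: np.ndarray  # (n_proteins, n_samples), condition 1
    B: np.ndarray  # same shape, condition 2
    true_da_up: np.ndarray  # protein indices shifted up in B
    true_da_down: np.ndarray  # protein indices shifted down in B
    protein_means: np.ndarray
    protein_sds: np.ndarray
    delta_pct: float
    seed: int

    @property
    def n_proteins(self) -> int:
        return self.A.shape[0]

    @property
    def truth(self) -> np.ndarray:
        """Boolean per-protein DA indicator (up or down)."""
        t = np.zeros(self.n_proteins, dtype=bool)
        t[self.true_da_up] = True
        t[self.true_da_down] = True
        return t

    def to_quant_matrix(self) -> QuantMatrix:
        """Concatenate [A | B] into one matrix with labeled sample IDs."""
        n, s = self.A.shape
        width = max(4, len(str(s)))
        ids = [f"A_{j:0{width}d}" for j in range(s)] + [
            f"B_{j:0{width}d}" for j in range(s)
        ]
        pw = max(4, len(str(n)))
        pids = [f"P{i:0{pw}d}" for i in range(n)]
        ds = ["condA"] * s + ["condB"] * s
        return QuantMatrix(np.hstack([self.A, self.B]), pids, ids, ds)

    def sample_pairs(self) -> list[tuple[int, int]]:
        """Column pairs (A_k, B_k) of the concatenated matrix."""
        s = self.A.shape[1]
        return [(k, s + k) for k in range(s)]


def simulate_da(
    n_proteins: int = 10000,
    n_samples: int = 128,
    mean_center: float = 12.0,
    mean_sd: float = 1.0,
    sd_center: float = 1.0,
    sd_sd: float = 1.0,
    da_frac_each: float = 0.10,
    delta_pct: float = 0.075,
    min_sd: float = 0.05,
    seed: int = 0,
) -> SimulatedStudy:
    """Generate the two-condition study.

    ``delta_pct`` is the spike-in effect size as a fraction of each DA
    protein's mean: an up-shifted protein with mean m gets mean
    m * (1 + delta_pct) in condition B. Per-protein sds below ``min_sd``
    are redrawn (the N(1,1) law has mass at and below zero).
    """
    if delta_pct < 0:
        raise ValueError("delta_pct must be non-negative")
    n_da = int(round(da_frac_each * n_proteins))
    if 2 * n_da > n_proteins:
        raise ValueError("da_frac_each too large: up and down sets overlap")
    rng = np.random.default_rng(seed)

    means = rng.normal(mean_center, mean_sd, size=n_proteins)
    sds = rng.normal(sd_center, sd_sd, size=n_proteins)
    bad = sds <= min_sd
    while bad.any():
        sds[bad] = rng.normal(sd_center, sd_sd, size=int(bad.sum()))
        bad = sds <= min_sd

    da = rng.choice(n_proteins, size=2 * n_da, replace=False)
    up, down = np.sort(da[:n_da]), np.sort(da[n_da:])

    A = rng.normal(
        means[:, None], sds[:, None], size=(n_proteins, n_samples)
    )
    means_b = means.copy()
    means_b[up] = means[up] + means[up] * delta_pct
    means_b[down] = means[down] - means[down] * delta_pct
    B = rng.normal(
        means_b[:, None], sds[:, None], size=(n_proteins, n_samples)
    )
    return SimulatedStudy(A, B, up, down, means, sds, delta_pct, seed)


def inject_missingness(
    M: np.ndarray,
    target_frac: float,
    seed: int = 0,
    percentile: float = 25.0,
    sd_scale: float = 1.1,
) -> np.ndarray:
    """Mask a target fraction of entries, MNAR-first.

    The Bernoulli success probability of the left-censoring procedure is
    calibrated so the expected masked fraction hits ``target_frac``; when
    the target exceeds what censoring can reach even at probability one
    (high targets), the shortfall is removed MCAR from the remaining
    entries. Retained entries are bit-identical to the input.
    """
    if not 0 <= target_frac < 1:
        raise ValueError("target_frac must be in [0, 1)")
    M = np.asarray(M, dtype=float)
    out = M.copy()
    if target_frac == 0:
        return out
    rng = np.random.default_rng(seed)

    qm = QuantMatrix(
        M,
        [f"r{i}" for i in range(M.shape[0])],
        [f"c{j}" for j in range(M.shape[1])],
    )
    sf = censoring_probabilities(qm, percentile, sd_scale)
    mean_sf = float(sf.mean())
    p = min(1.0, target_frac / mean_sf)

    # One thresholds comparison per entry, realized through its
    # censoring probability: entry masked with prob p * P(T >= X_ij).
    mask_prob = (p * sf).reshape(M.shape)
    masked = rng.random(M.shape) < mask_prob

    total = M.size
    want = int(round(target_frac * total))
    n_masked = int(masked.sum())
    if n_masked < want:
        remaining = np.flatnonzero(~masked.ravel())
        extra = rng.choice(remaining, size=want - n_masked, replace=False)
        masked.ravel()[extra] = True
    elif n_masked > want:
        # Over-draw from Bernoulli noise; un-mask a random excess so the
        # achieved fraction stays within tolerance of the target.
        chosen = np.flatnonzero(masked.ravel())
        release = rng.choice(chosen, size=n_masked - want, replace=False)
        masked.ravel()[release] = False
    out[masked] = np.nan
    return out
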