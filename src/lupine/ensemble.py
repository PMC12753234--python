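"""Hyperparameter-ensemble imputation.

A single embedding+MLP model is sensitive to its architecture and
initialization; averaging predictions over several models trained with
different hyperparameters, seeds and validation splits is markedly more
accurate than any single member. Configurations are drawn uniformly
without replacement from a fixed grid; each member trains on the same
training entries but holds out its own MCAR 10% validation split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .quantio import QuantMatrix
from .partition import PartitionMask
from .model import HyperParams, TrainingTrace, train_model, predict_all

#: Full search grid: 5 x 5 x 3 x 3 = 225 combinations.
DEFAULT_GRID = {
    "n_protein_factors": [64, 128, 256, 512, 1024],
    "n_sample_factors": [64, 128, 256, 512, 1024],
    "n_hidden_layers": [1, 2, 4],
    "nodes_per_layer": [512, 1024, 2048],
}

#: Small-matrix grid for desk-scale runs (factor sizes <= 32, <= 128 nodes).
REDUCED_GRID = {
    "n_protein_factors": [8, 16, 32],
    "n_sample_factors": [8, 16, 32],
    "n_hidden_layers": [1, 2],
    "nodes_per_layer": [32, 64, 128],
}


@dataclass
class EnsembleConfig:
    """Grid, ensemble size, seeding and validation fraction.

    ``hp_overrides`` supplies non-grid hyperparameters (batch size,
    epoch cap, learning rate ...) applied to every member.
    """

    grid: dict = field(default_factory=lambda: dict(DEFAULT_GRID))
    n_models: int = 10
    base_seed: int = 0
    val_frac: float = 0.10
    hp_overrides: dict = field(default_factory=dict)
    p_bg: float = 0.35


@dataclass
class ImputationResult:
    """Ensemble output.

    ``reconstructed`` is the element-wise mean of member predictions at
    every position; ``imputed`` keeps the original observed values and
    fills only the missing entries from the reconstruction.
    """

    reconstructed: np.ndarray
    imputed: QuantMatrix
    member_traces: list[TrainingTrace]
    member_hyperparams: list[HyperParams]
    member_predictions: list[np.ndarray] | None = None


def grid_combinations(grid: dict) -> list[dict]:
    """All grid points, in deterministic (sorted-key, product) order."""
    keys = sorted(grid)
    return [dict(zip(keys, combo)) for combo in product(*(grid[k] for k in keys))]


def sample_hyperparams(cfg: EnsembleConfig) -> list[HyperParams]:
    """Draw ``n_models`` distinct grid combinations, uniformly.

    Deterministic given ``base_seed``; independent of matrix contents.
    """
    combos = grid_combinations(cfg.grid)
    if cfg.n_models > len(combos):
        raise ValueError(
            f"n_models={cfg.n_models} exceeds grid size {len(combos)}"
        )
    rng = np.random.default_rng(cfg.base_seed)
    picks = rng.choice(len(combos), size=cfg.n_models, replace=False)
    return [HyperParams(**combos[k], **cfg.hp_overrides) for k in picks]


def _pairwise_mean(mats: list[np.ndarray]) -> np.ndarray:
    """Mean with a fixed pairwise summation order (bit-reproducible)."""
    level = [m.astype(float) for m in mats]
    n = len(level)
    while len(level) > 1:
        nxt = [
            level[k] + level[k + 1] if k + 1 < len(level) else level[k]
            for k in range(0, len(level), 2)
        ]
        level = nxt
    return level[0] / n


def ensemble_impute(
    X: QuantMatrix,
    mask: PartitionMask | None = None,
    cfg: EnsembleConfig | None = None,
    keep_member_predictions: bool = False,
    rollback_best: bool = False,
) -> ImputationResult:
    """Train the ensemble and average its predictions.

    Member k trains with seed ``base_seed + k`` and its own MCAR
    ``val_frac`` validation split of the train entries. When ``mask`` is
    omitted every present entry is a train candidate (the imputation
    use-case); supply a mask with test entries for benchmarking. A
    failing member aborts the run — members are never silently dropped.
    """
    cfg = cfg or EnsembleConfig()
    hps = sample_hyperparams(cfg)

    if mask is None:
        labels = np.zeros(X.values.shape, dtype=np.int8)
        labels[X.present] = PartitionMask.TRAIN
        base_mask = PartitionMask(labels, cfg.base_seed, {"scheme": "all-train"})
    else:
        base_mask = mask

    candidates = np.concatenate(
        [base_mask.train_indices, base_mask.val_indices]
    )

    predictions: list[np.ndarray] = []
    traces: list[TrainingTrace] = []
    for k, hp in enumerate(hps):
        member_seed = cfg.base_seed + k
        rng = np.random.default_rng(member_seed)
        labels = base_mask.labels.copy()
        labels.ravel()[candidates] = PartitionMask.TRAIN
        n_val = max(1, int(round(cfg.val_frac * candidates.size)))
        val_sel = rng.choice(candidates, size=n_val, replace=False)
        labels.ravel()[val_sel] = PartitionMask.VAL
        member_mask = PartitionMask(labels, member_seed, dict(base_mask.params))

        state, trace = train_model(
            X, member_mask, hp, seed=member_seed, p_bg=cfg.p_bg,
            rollback_best=rollback_best,
        )
        predictions.append(predict_all(state))
        traces.append(trace)

    reconstructed = _pairwise_mean(predictions)
    imputed_values = np.where(X.present, X.values, reconstructed)
    imputed = QuantMatrix(
        imputed_values,
        list(X.protein_ids),
        list(X.sample_ids),
        list(X.dataset_of_sample) if X.dataset_of_sample else None,
    )
    return ImputationResult(
        reconstructed,
        imputed,
        traces,
        hps,
        predictions if keep_member_predictions else None,
    )
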