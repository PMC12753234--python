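"""The imputation model: protein/sample embeddings feeding an MLP.

Each protein i carries a learned factor vector ``W_i`` (length p) and
each sample j a factor vector ``H_j`` (length q). To predict the
quantification of protein i in sample j, the two factors are
concatenated and passed through a fully connected multilayer perceptron
with leaky-ReLU activations (negative slope 0.1) after every hidden
layer and a single linear output unit. All parameters — the embedding
matrices W (n x p) and H (q x m) and the MLP weights and biases — are
trained jointly by minimizing the mean squared error over observed
training entries, using Adam (learning rate 0.001) on left-skewed
batches of 128 entries sampled with replacement (see
:mod:`lupine.partition`).

Convergence is monitored on an MCAR-held-out validation split of the
training entries; training stops when the relative improvement in
validation MSE stays below a tolerance for a run of epochs, or when a
one-sided Wilcoxon rank-sum test indicates the validation error has
started rising.

The implementation is plain NumPy with hand-written backpropagation:
the network is small and dense, and CPU correctness, determinism and
zero heavyweight dependencies are the contract here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .quantio import QuantMatrix
from .partition import PartitionMask, biased_batches

logger = logging.getLogger(__name__)


@dataclass
class HyperParams:
    """Architecture and optimization settings for one model."""

    n_protein_factors: int = 32
    n_sample_factors: int = 32
    n_hidden_layers: int = 1
    nodes_per_layer: int = 128
    learning_rate: float = 0.001
    batch_size: int = 128
    leaky_slope: float = 0.1
    tol: float = 0.001
    patience: int = 10
    max_epochs: int = 500

    def __post_init__(self) -> None:
        for name in (
            "n_protein_factors",
            "n_sample_factors",
            "n_hidden_layers",
            "nodes_per_layer",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class ModelState:
    """All learned parameters of one model.

    ``mlp`` is an ordered list of (weight, bias) pairs; weight shapes
    chain from input width p+q down to a single output unit. W and H
    never contain missing values.
    """

    W: np.ndarray  # (n, p)
    H: np.ndarray  # (q, m)
    mlp: list[tuple[np.ndarray, np.ndarray]]
    rng_seed: int = 0
    leaky_slope: float = 0.1

    @property
    def n_proteins(self) -> int:
        return self.W.shape[0]

    @property
    def n_samples(self) -> int:
        return self.H.shape[1]


@dataclass
class TrainingTrace:
    """Per-epoch validation MSE and the reason training stopped."""

    val_mse_by_epoch: list[float] = field(default_factory=list)
    stop_reason: str = "max_epochs"
    epochs_run: int = 0


def init_model(n: int, m: int, hp: HyperParams, seed: int = 0) -> ModelState:
    """Randomly initialize embeddings and MLP weights.

    Every array uses the standard linear-layer law: uniform in
    ±1/sqrt(fan_in), i.e. ±1/sqrt(p) for protein factors, ±1/sqrt(q)
    for sample factors, and ±1/sqrt(input width) for each MLP layer.
    Deterministic given the seed.
    """
    if n <= 0 or m <= 0:
        raise ValueError("matrix dimensions must be positive")
    rng = np.random.default_rng(seed)
    p, q = hp.n_protein_factors, hp.n_sample_factors
    W = rng.uniform(-1, 1, size=(n, p)) / np.sqrt(p)
    H = rng.uniform(-1, 1, size=(q, m)) / np.sqrt(q)
    mlp = []
    widths = [p + q] + [hp.nodes_per_layer] * hp.n_hidden_layers + [1]
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        weight = rng.uniform(-bound, bound, size=(fan_out, fan_in))
        bias = rng.uniform(-bound, bound, size=fan_out)
        mlp.append((weight, bias))
    return ModelState(W, H, mlp, rng_seed=seed, leaky_slope=hp.leaky_slope)


def _forward_batch(
    state: ModelState, i: np.ndarray, j: np.ndarray, keep_cache: bool = False
):
    """Vectorized forward pass over entry index arrays."""
    x = np.concatenate([state.W[i], state.H[:, j].T], axis=1)
    slope = state.leaky_slope
    cache = [x] if keep_cache else None
    pre_acts = [] if keep_cache else None
    for layer, (weight, bias) in enumerate(state.mlp):
        a = x @ weight.T + bias
        if layer < len(state.mlp) - 1:
            x = np.where(a > 0, a, slope * a)
        else:
            x = a  # linear output
        if keep_cache:
            pre_acts.append(a)
            cache.append(x)
    out = x[:, 0]
    if keep_cache:
        return out, cache, pre_acts
    return out


def forward(state: ModelState, i: int, j: int) -> float:
    """Predicted quantification for protein i in sample j."""
    if not (0 <= i < state.n_proteins and 0 <= j < state.n_samples):
        raise IndexError(f"entry ({i}, {j}) out of range")
    return float(
        _forward_batch(state, np.array([i]), np.array([j]))[0]
    )


def predict_all(state: ModelState, chunk: int = 1 << 16) -> np.ndarray:
    """Dense n x m prediction matrix (one forward pass per entry)."""
    n, m = state.n_proteins, state.n_samples
    out = np.empty((n, m))
    flat = np.arange(n * m)
    for start in range(0, flat.size, chunk):
        idx = flat[start : start + chunk]
        out.ravel()[idx] = _forward_batch(state, idx // m, idx % m)
    return out


def convergence_check(
    trace, tol: float = 0.001, patience: int = 10
) -> tuple[bool, str | None]:
    """Decide whether validation MSEs indicate training has converged.

    Two criteria, checked in order:

    1. *Tolerance plateau* — at each epoch compute the relative
       improvement over the best validation MSE seen in earlier epochs,
       (best - current) / best. If this ratio has been below ``tol``
       (negative ratios included: the loss got worse) for ``patience``
       successive epochs, stop.
    2. *Rising error* (needs >= 15 epochs) — one-sided Wilcoxon rank-sum
       test comparing the MSEs of epochs n-15..n-11 (older window)
       against the previous five epochs (recent window), with the
       alternative that the older window is stochastically smaller,
       i.e. the error has started to increase. Stop at p < 0.05.
    """
    trace = list(trace)
    n = len(trace)
    if n >= patience + 1:
        ratios = []
        for e in range(n - patience, n):
            best_before = min(trace[:e])
            ratios.append((best_before - trace[e]) / best_before)
        if all(r < tol for r in ratios):
            return True, "tolerance"
    if n >= 15:
        recent = np.asarray(trace[-5:])
        older = np.asarray(trace[-10:-5])
        res = stats.mannwhitneyu(older, recent, alternative="less",
                                 method="auto")
        if res.pvalue < 0.05:
            return True, "wilcoxon"
    return False, None


class _Adam:
    """Adam over a flat list of parameter arrays (dense updates)."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def _backward_batch(state: ModelState, i, j, targets):
    """MSE loss gradient w.r.t. every parameter, for one batch."""
    pred, cache, pre_acts = _forward_batch(state, i, j, keep_cache=True)
    B = pred.size
    slope = state.leaky_slope
    d = (2.0 / B) * (pred - targets)[:, None]  # (B, 1)

    grads_mlp = [None] * len(state.mlp)
    for layer in range(len(state.mlp) - 1, -1, -1):
        weight, _ = state.mlp[layer]
        if layer < len(state.mlp) - 1:
            a = pre_acts[layer]
            d = d * np.where(a > 0, 1.0, slope)
        z_in = cache[layer]
        grads_mlp[layer] = (d.T @ z_in, d.sum(axis=0))
        d = d @ weight

    p = state.W.shape[1]
    gW = np.zeros_like(state.W)
    np.add.at(gW, i, d[:, :p])
    gHT = np.zeros((state.H.shape[1], state.H.shape[0]))
    np.add.at(gHT, j, d[:, p:])
    loss = float(np.mean((pred - targets) ** 2))
    return gW, gHT.T, grads_mlp, loss


def _mse_at(state: ModelState, X: QuantMatrix, flat_idx: np.ndarray) -> float:
    m = X.n_samples
    pred = _forward_batch(state, flat_idx // m, flat_idx % m)
    truth = X.values.ravel()[flat_idx]
    return float(np.mean((pred - truth) ** 2))


def train_model(
    X: QuantMatrix,
    mask: PartitionMask,
    hp: HyperParams,
    seed: int = 0,
    p_bg: float = 0.35,
    rollback_best: bool = False,
) -> tuple[ModelState, TrainingTrace]:
    """Fit one model to the train entries of ``X``.

    Each epoch draws ceil(|train| / batch_size) left-skewed batches with
    replacement and takes one Adam step per batch; validation MSE over
    the mask's validation entries is recorded at epoch end and drives
    the stopping criteria. Validation and test entries never contribute
    gradient. With ``rollback_best`` the returned state is the epoch
    with the lowest validation MSE rather than the final one.
    """
    train_flat = mask.train_indices
    val_flat = mask.val_indices
    if train_flat.size == 0:
        raise ValueError("mask has no train entries")
    if val_flat.size == 0:
        raise ValueError("mask has no validation entries: convergence "
                         "would be undefined")
    n, m = X.values.shape
    rng = np.random.default_rng(seed)
    init_seed = int(rng.integers(2**31))
    state = init_model(n, m, hp, seed=init_seed)

    params = [state.W, state.H]
    for weight, bias in state.mlp:
        params.extend([weight, bias])
    opt = _Adam(params, lr=hp.learning_rate)

    n_batches = int(np.ceil(train_flat.size / hp.batch_size))
    trace = TrainingTrace()
    best_mse = np.inf
    best_snapshot = None
    vals_flat = X.values.ravel()

    for epoch in range(hp.max_epochs):
        epoch_seed = int(rng.integers(2**31))
        stream = biased_batches(
            X, mask, batch_size=hp.batch_size, n_batches=n_batches,
            seed=epoch_seed, p_bg=p_bg,
        )
        for batch in stream.batches:
            i, j = batch // m, batch % m
            gW, gH, grads_mlp, _ = _backward_batch(
                state, i, j, vals_flat[batch]
            )
            flat_grads = [gW, gH]
            for gw, gb in grads_mlp:
                flat_grads.extend([gw, gb])
            opt.step(flat_grads)

        val_mse = _mse_at(state, X, val_flat)
        trace.val_mse_by_epoch.append(val_mse)
        trace.epochs_run = epoch + 1
        logger.info("epoch %d: validation MSE %.6f", epoch + 1, val_mse)
        if rollback_best and val_mse < best_mse:
            best_mse = val_mse
            best_snapshot = _snapshot(state)
        stop, reason = convergence_check(
            trace.val_mse_by_epoch, tol=hp.tol, patience=hp.patience
        )
        if stop:
            trace.stop_reason = reason
            break
    else:
        trace.stop_reason = "max_epochs"

    if rollback_best and best_snapshot is not None:
        state = best_snapshot
    return state, trace


def _snapshot(state: ModelState) -> ModelState:
    return ModelState(
        state.W.copy(),
        state.H.copy(),
        [(w.copy(), b.copy()) for w, b in state.mlp],
        state.rng_seed,
        state.leaky_slope,
    )


def save_checkpoint(state: ModelState, hp: HyperParams, path) -> None:
    """Write all model arrays plus hyperparameters to one .npz archive."""
    arrays = {"W": state.W, "H": state.H}
    for k, (w, b) in enumerate(state.mlp):
        arrays[f"mlp_w{k}"] = w
        arrays[f"mlp_b{k}"] = b
    arrays["meta_rng_seed"] = np.array(state.rng_seed)
    arrays["meta_leaky_slope"] = np.array(state.leaky_slope)
    for name, val in asdict(hp).items():
        arrays[f"hp_{name}"] = np.array(val)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[ModelState, HyperParams]:
    """Exact round-trip of :func:`save_checkpoint`."""
    with np.load(path) as data:
        hp_kwargs = {}
        for key in data.files:
            if key.startswith("hp_"):
                val = data[key].item()
                hp_kwargs[key[3:]] = val
        hp = HyperParams(**hp_kwargs)
        mlp = []
        k = 0
        while f"mlp_w{k}" in data.files:
            mlp.append((data[f"mlp_w{k}"], data[f"mlp_b{k}"]))
            k += 1
        state = ModelState(
            data["W"],
            data["H"],
            mlp,
            int(data["meta_rng_seed"]),
            float(data["meta_leaky_slope"]),
        )
    return state, hp
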