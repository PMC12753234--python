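# Methods

## Data model and input conventions

The package operates on wide protein-by-sample matrices of log-scale,
reference-normalized quantifications (`QuantMatrix`). Missing entries
are NaN and only NaN; zeros are ordinary values. No transform is
applied on input — upstream pipelines (e.g. TMT reporter-ion
normalization and protein rollup) are assumed to have produced
log-scale values already, and fold changes downstream are therefore
computed as plain differences of means.

Joint matrices are built by outer join over protein IDs: rows are the
union of proteins (sorted lexicographically for run-to-run
determinism), columns the concatenation of samples, entries absent
from a contributing dataset are NaN. Two filters reflect common
practice: sample IDs containing reference/QC keywords
(`RefInt, QC, pool, pooled, reference, NCI, NX, ref`; case-sensitive
substring match, configurable) are dropped, and proteins observed in
fewer than 18 samples (3 for small single-cohort subsets) are removed —
too few observations make for unusable imputations. When a partition
mask is supplied, the min-present filter counts only training entries,
so the filter cannot leak test information.

## MNAR partitioning

To evaluate imputation under left-censored dropout, held-out entries
must be drawn preferentially from the low-intensity end. For each
entry `X_ij` a threshold `T_ij` is drawn from a Gaussian centered on
the 25th percentile of the observed values with standard deviation
`1.1 × sd(X)`. Entries above their threshold always train; entries at
or below it enter the test set with Bernoulli probability `p`. The
expected test fraction is exactly linear in `p`,

    E[test fraction] = p · mean_ij P(T >= X_ij),

with `P(T >= X_ij)` a Gaussian tail probability, so `calibrate_bernoulli_p`
solves for `p` in closed form rather than by search; the historical
default `p = 0.61` (appropriate for large multi-cohort TMT matrices,
and recovered to two decimals on Gaussian log-intensity data by the
calibration) is kept as the default for `mnar_partition`. Validation
entries, used only for early stopping, are drawn MCAR from the training
set after the test split. On degenerate inputs (e.g. constant
matrices) the left-shift guarantee can fail; this produces a warning,
not an error.

Training batches are sampled with replacement from the training
entries through the same machinery with the acceptance direction
inverted: a candidate with value `v` is accepted outright when a fresh
threshold draw `t` satisfies `t >= v`, otherwise with background
probability `p_bg = 0.35`; rejected candidates are redrawn. Low values
are thus over-represented and the pooled batch distribution is left
skewed relative to the training set. `p_bg` is exposed; 0.35 makes the
skew clearly visible (pooled batch mean more than 0.1 sd below the
train mean on Gaussian data) without starving the batches of
high-intensity context, and `p_bg = 1` recovers unbiased sampling.

## Model and training

Each protein i carries a factor vector `W_i` (length p), each sample j
a factor vector `H_j` (length q). The prediction for entry (i, j) is
`MLP([W_i; H_j])` with leaky-ReLU (negative slope 0.1) after every
hidden layer and a linear scalar output; no output clipping is applied.
All arrays initialize uniformly in ±1/√fan_in (±1/√p and ±1/√q for the
embeddings). Training minimizes MSE over batch entries with Adam
(lr 0.001, β = 0.9/0.999, ε = 1e−8, dense moment updates for all
parameters including the embeddings); one optimizer step per batch,
ceil(|train| / batch_size) batches per epoch, batch size 128 by
default.

Early stopping is evaluated on the validation MSE at each epoch end:

1. **Tolerance plateau.** Relative improvement over the best previous
   epoch, `(best − current) / best`, below `tol = 1e−3` for
   `patience = 10` successive epochs (negative ratios — the loss got
   worse — count as below tolerance).
2. **Rising error** (active from epoch 15). One-sided Wilcoxon
   rank-sum test of the previous-five-epoch window against the five
   epochs before it, alternative "the older window is smaller"; stop at
   p < 0.05. The published description of the window offsets is
   internally inconsistent (its worked example uses adjacent windows
   while its formula implies a gap); we use adjacent windows, which
   match the example and the stated intent. The test uses the exact
   rank-sum distribution for untied 5-vs-5 windows and the normal
   approximation otherwise.

A hard cap `max_epochs = 500` bounds runtime; it is rarely binding.
The returned model is the final-epoch state by default, with an
optional `rollback_best` flag to return the best-validation epoch
instead. The implementation is plain NumPy with hand-written
backpropagation: the networks are small and dense, and CPU determinism
given seeds is part of the contract (identical seeds give bit-identical
traces).

## Ensembling

Hyperparameter configurations (p, q, hidden layers, nodes per layer)
are drawn uniformly without replacement from the grid; member k trains
with seed `base_seed + k` and its own MCAR 10% validation split. The
reconstruction is the element-wise mean of member predictions with a
fixed pairwise summation order (bit-reproducible); the imputed matrix
keeps observed values and fills only missing entries. Both are exposed,
since held-out benchmarking evaluates predictions at *observed*
positions while downstream analysis wants the observed-preserving
matrix. A failing member aborts the run — members are never silently
dropped. The default ensemble size is 10, past which returns diminish.

## Baselines and evaluation

- **kNN**: scikit-learn's `KNNImputer` on the transposed matrix, so
  observations are samples and features proteins, with NaN-aware
  Euclidean distances; k = 5.
- **Gaussian downshift**: per sample column with observed mean μ and sd
  σ, missing values are drawn from N(μ − 1.8σ, (0.3σ)²) — the standard
  width/shift defaults for this procedure. Zero-variance columns fall
  back to the global sd with a warning.
- **Metrics**: test-set MSE over test-labeled entries; per-protein mean
  absolute residuals; and the fraction of proteins one method predicts
  better than another, restricted to proteins where either residual
  exceeds 0.25 (ties count ½) so that uniformly well-predicted proteins
  do not dilute the comparison.

## Differential abundance

Per-protein paired t-tests between matched sample groups; pairs with a
missing member are dropped per protein in the no-imputation mode;
proteins with fewer than two usable pairs or zero difference variance
are flagged excluded rather than aborting. P-values are adjusted with
Benjamini–Hochberg step-up (implemented directly; verified against a
brute-force definition and statsmodels). Calls use adj-p < 0.01 and
|log2 FC| > 0.5, both strict. Proteins with more than half their
values missing before imputation are conventionally excluded from DA
analysis (`exclude_high_missingness`; strict >0.5).

Ranking quality against known spike-ins is scored by non-interpolated
average precision: proteins ranked by ascending p-value (ties broken by
descending |log2 FC|, unusable proteins last), AP = mean precision at
each newly recalled positive.

## Simulation

The spike-in generator emulates a log2-scale two-condition study:
protein means ~ N(12, 1), per-protein sds ~ N(1, 1) redrawn while
≤ 0.05 (the law has mass below zero; the floor is exposed), condition A
rows ~ N(m_i, s_i²). A randomly chosen 10% of proteins is shifted up
and a disjoint 10% down by `delta_pct × m_i` in condition B — so 20% of
proteins are differentially abundant with known labels. Missingness is
injected with the same thresholds/Bernoulli law, with the Bernoulli
probability calibrated to the target fraction; pure left-censoring
saturates near 33% on Gaussian data, so higher targets (40%, 60%) are
topped up MCAR. DA testing pairs column k of A with column k of B.

What the generator does *not* emulate: TMT plex/batch structure,
correlated proteins, condition-specific variance changes, or any
relationship between abundance and biological function — proteins are
i.i.d. given their mean and sd. Passing the simulation benchmarks
therefore demonstrates that the pipeline preserves per-protein
between-condition signal under left-censored dropout, not that it
captures real co-regulation structure (the protein-complex analysis
addresses that question on real data).

## Benchmark scales and observed behavior

The end-to-end DA-recovery benchmarks (tests and
`scripts/acceptance.py`) run the full 10,000 × 128-per-condition
simulation for the no-imputation case, and a reduced configuration for
the imputation sweeps — 1,000–1,200 proteins, 2–3 ensemble members,
factor sizes ≤ 32, ≤ 128 nodes, batch 1024, ≤ 25 epochs, averaged over
3 replicate seeds — chosen so each sweep completes in minutes on one
CPU. The simulated study is essentially additive (protein mean plus a
condition shift), so small models impute it close to optimally; with
heavily overparameterized members (millions of parameters against
~10⁶ training entries), imputations at high missingness become
noticeably noisier and downstream DA recovery degrades further than
the small-model configurations reproduce. Reported PR-AUCs at high
missingness should be read with that in mind: they characterize this
configuration, and larger ensembles on larger matrices can score lower.

## Numerical and design choices

- Entry indexing is (protein row, sample column), 0-based internally;
  all file interfaces use IDs, never indices.
- All randomness flows through `numpy.random.default_rng` seeds; every
  stochastic operation takes an explicit seed and is reproducible.
- Masks serialize as three-column TSV (protein_id, sample_id, label);
  matrices as wide TSV with full-precision `repr` values that
  round-trip bit-identically; model checkpoints as a single `.npz`
  archive holding W, H, MLP arrays, hyperparameters and seed.
- Degenerate inputs: constant matrices give point-mass thresholds
  (handled without error); all-NaN matrices are rejected; empty
  validation sets are an error for training (convergence undefined).

## Known limitations

- The imputer treats entries independently given the factors; it does
  not model plex/batch covariance or sample pairing.
- Embeddings are not identifiable across ensemble members (no
  alignment is attempted); exported factors are per-member.
- The Gaussian-downshift baseline follows the standard per-sample
  downshift procedure; descriptions of this method vary across tools,
  and other width/shift conventions exist.
- CPU-only by design; very large matrices (10⁴ × 10³ and beyond) are
  out of scope for the default configuration and would benefit from an
  accelerator port.
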