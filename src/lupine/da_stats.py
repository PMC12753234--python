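"""Differential-abundance calling and downstream evaluation.

DA calling follows the standard clinical-proteomics recipe: per-protein
paired t-tests between matched sample groups (tumor/non-tumor, or the
matched columns of two simulated conditions), Benjamini–Hochberg
adjustment, and a dual threshold — adjusted p below 0.01 and absolute
log2 fold change above 0.5. Proteins with more than 50% missingness
before imputation are conventionally excluded.

For simulation benchmarks with known spiked-in DA proteins, the p-value
ranking is scored with the area under the precision-recall curve
(average precision). The protein-complex analysis checks that imputation
does not fabricate or destroy co-abundance: subunits of the same complex
should correlate across samples, random protein pairs should not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantio import QuantMatrix


@dataclass
class DAResult:
    """Per-protein DA statistics and calls.

    ``call`` is one of "up", "down", "not_da", "excluded"; excluded
    proteins (too few usable pairs, zero-variance differences, or
    missingness above the pre-imputation cutoff) carry NaN statistics.
    """

    protein_ids: list[str]
    t_statistic: np.ndarray
    p_value: np.ndarray
    adj_p: np.ndarray
    log2_fc: np.ndarray
    call: np.ndarray  # dtype object / str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_statistic": self.t_statistic,
                "p_value": self.p_value,
                "adj_p": self.adj_p,
                "log2_fc": self.log2_fc,
                "call": self.call,
            },
            index=self.protein_ids,
        )


@dataclass
class ComplexCorrReport:
    within_correlations: np.ndarray
    random_correlations: np.ndarray
    mean_within: float
    mean_random: float
    paired_test_p: float


def exclude_high_missingness(
    X_preimpute: QuantMatrix, max_frac: float = 0.5
) -> np.ndarray:
    """Indices of proteins with pre-imputation missingness <= max_frac.

    The cutoff is strict on the excluded side: a protein missing in
    exactly half the samples is kept.
    """
    miss = np.isnan(X_preimpute.values).mean(axis=1)
    return np.flatnonzero(miss <= max_frac)


def paired_t_tests(
    M: np.ndarray, pairs: list[tuple[int, int]]
) -> pd.DataFrame:
    """Classical paired t-test per protein over matched column pairs.

    ``pairs`` lists (reference column, condition-of-interest column);
    the log2 fold change is the mean per-pair difference (values are
    assumed already log2 scale). Pairs where either member is missing
    are dropped per protein; proteins left with fewer than two usable
    pairs, or with zero difference variance, are flagged excluded
    rather than aborting the analysis.
    """
    M = np.asarray(M, dtype=float)
    a_cols = np.array([a for a, _ in pairs], dtype=int)
    b_cols = np.array([b for _, b in pairs], dtype=int)
    D = M[:, b_cols] - M[:, a_cols]  # NaN where either member missing

    n_used = (~np.isnan(D)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_d = np.nanmean(D, axis=1)
        sd_d = np.nanstd(D, axis=1, ddof=1)

    usable = (n_used >= 2) & (sd_d > 0)
    t = np.full(M.shape[0], np.nan)
    p = np.full(M.shape[0], np.nan)
    se = sd_d[usable] / np.sqrt(n_used[usable])
    t[usable] = mean_d[usable] / se
    p[usable] = 2 * stats.t.sf(np.abs(t[usable]), df=n_used[usable] - 1)
    log2_fc = np.where(n_used >= 1, mean_d, np.nan)
    return pd.DataFrame(
        {
            "t_statistic": t,
            "p_value": p,
            "log2_fc": log2_fc,
            "n_pairs": n_used,
            "usable": usable,
        }
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(n)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def call_da(
    stats_df: pd.DataFrame, alpha: float = 0.01, lfc: float = 0.5
) -> DAResult:
    """Apply the dual DA threshold to per-protein statistics.

    A protein is called up when adj_p < alpha and log2_fc > lfc, down
    when adj_p < alpha and log2_fc < -lfc (both thresholds strict);
    otherwise not_da. Unusable proteins stay excluded.
    """
    usable = stats_df["usable"].to_numpy()
    p = stats_df["p_value"].to_numpy(dtype=float)
    adj = np.full(p.size, np.nan)
    if usable.any():
        adj[usable] = bh_adjust(p[usable])
    lfc_vals = stats_df["log2_fc"].to_numpy(dtype=float)
    call = np.full(p.size, "not_da", dtype=object)
    call[~usable] = "excluded"
    sig = usable & (adj < alpha)
    call[sig & (lfc_vals > lfc)] = "up"
    call[sig & (lfc_vals < -lfc)] = "down"
    ids = (
        list(stats_df.index.astype(str))
        if stats_df.index.dtype == object
        else [str(i) for i in stats_df.index]
    )
    return DAResult(
        ids,
        stats_df["t_statistic"].to_numpy(dtype=float),
        p,
        adj,
        lfc_vals,
        call,
    )


def pr_auc(p_values, truth, lfc=None) -> float:
    """Average precision of a p-value ranking against binary truth.

    Proteins are ranked by ascending p-value, ties broken by descending
    absolute log2 fold change when supplied (stable otherwise); unusable
    proteins (NaN p) rank last. The AUC is non-interpolated average
    precision: the mean, over true positives in rank order, of the
    precision at each newly recalled positive.
    """
    truth = np.asarray(truth, dtype=bool)
    n_pos = int(truth.sum())
    if n_pos == 0:
        raise ValueError("truth has no positives")
    p = np.asarray(p_values, dtype=float)
    p = np.where(np.isnan(p), np.inf, p)
    if lfc is not None:
        keys = np.lexsort((-np.abs(np.asarray(lfc, dtype=float)), p))
    else:
        keys = np.argsort(p, kind="stable")
    hits = truth[keys]
    ranks = np.flatnonzero(hits) + 1  # 1-based ranks of positives
    precision_at_hits = np.arange(1, ranks.size + 1) / ranks
    return float(precision_at_hits.sum() / n_pos)


def complex_correlations(
    X: QuantMatrix,
    membership: pd.DataFrame,
    X_preimpute: QuantMatrix | None = None,
    max_missing: float = 0.5,
    seed: int = 0,
) -> ComplexCorrReport:
    """Within-complex vs. random protein-pair Spearman correlations.

    ``membership`` has two columns (complex_id, protein_id). Proteins
    with pre-imputation missingness above ``max_missing`` are removed
    (using ``X_preimpute`` when given, else ``X`` itself). Every
    within-complex pair contributes one Spearman correlation across
    samples; an equal number of random pairs (excluding within-complex
    pairs) is drawn for comparison, and the two matched lists are
    summarized with a paired t-test.
    """
    ref = X_preimpute if X_preimpute is not None else X
    keep = exclude_high_missingness(ref, max_missing)
    Xk = X.subset_rows(keep)
    row_of = {p: i for i, p in enumerate(Xk.protein_ids)}

    membership = membership.iloc[:, :2]
    membership.columns = ["complex_id", "protein_id"]
    within_pairs: list[tuple[int, int]] = []
    within_set: set[tuple[int, int]] = set()
    for _, group in membership.groupby("complex_id"):
        members = sorted(
            {row_of[p] for p in group["protein_id"] if p in row_of}
        )
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                pair = (members[a], members[b])
                within_pairs.append(pair)
                within_set.add(pair)
    if not within_pairs:
        raise ValueError("no complex with >= 2 member proteins present")

    rng = np.random.default_rng(seed)
    n = Xk.n_proteins
    random_pairs: list[tuple[int, int]] = []
    while len(random_pairs) < len(within_pairs):
        a, b = rng.choice(n, size=2, replace=False)
        pair = (min(a, b), max(a, b))
        if pair in within_set:
            continue
        random_pairs.append(pair)

    def _rho(pairs):
        out = np.empty(len(pairs))
        for k, (a, b) in enumerate(pairs):
            va, vb = Xk.values[a], Xk.values[b]
            ok = ~(np.isnan(va) | np.isnan(vb))
            if ok.sum() < 3:
                out[k] = np.nan
                continue
            out[k] = stats.spearmanr(va[ok], vb[ok]).statistic
        return out

    within = _rho(within_pairs)
    rand = _rho(random_pairs)
    ok = ~(np.isnan(within) | np.isnan(rand))
    t_res = stats.ttest_rel(within[ok], rand[ok])
    return ComplexCorrReport(
        within,
        rand,
        float(np.nanmean(within)),
        float(np.nanmean(rand)),
        float(t_res.pvalue),
    )
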