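"""Read, write, assemble and filter protein-by-sample quantification matrices.

The on-disk format is a wide tab-separated table: first column holds
protein IDs, the header row holds sample IDs, and empty cells, ``NA`` or
``NaN`` denote missing quantifications. Values are taken as-is — they
are assumed to be log-scale, reference-normalized protein quantities as
produced by an upstream pipeline (e.g. TMT reporter-ion ratios rolled up
to protein level); no transform is applied here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sample-ID substrings that mark reference channels, QC runs and pools.
DEFAULT_EXCLUDE_KEYWORDS = [
    "RefInt",
    "QC",
    "pool",
    "pooled",
    "reference",
    "NCI",
    "NX",
    "ref",
]

_NA_STRINGS = {"", "NA", "NaN", "nan"}


@dataclass
class QuantMatrix:
    """A protein-by-sample matrix of (log-scale) quantifications.

    Missing entries are coded as NaN and only as NaN; zeros are ordinary
    observed values.

    Attributes
    ----------
    values : ndarray of shape (n_proteins, n_samples)
    protein_ids : list of unique row identifiers
    sample_ids : list of unique column identifiers
    dataset_of_sample : optional per-sample source label (cohort name)
    """

    values: np.ndarray
    protein_ids: list[str]
    sample_ids: list[str]
    dataset_of_sample: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.protein_ids = [str(p) for p in self.protein_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, m = self.values.shape
        if n != len(self.protein_ids):
            raise ValueError(
                f"{n} rows but {len(self.protein_ids)} protein IDs"
            )
        if m != len(self.sample_ids):
            raise ValueError(
                f"{m} columns but {len(self.sample_ids)} sample IDs"
            )
        if len(set(self.protein_ids)) != n:
            raise ValueError("duplicate protein IDs")
        if len(set(self.sample_ids)) != m:
            raise ValueError("duplicate sample IDs")
        if self.dataset_of_sample is not None and len(self.dataset_of_sample) != m:
            raise ValueError("dataset_of_sample length mismatch")

    # -- convenience -------------------------------------------------

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def present(self) -> np.ndarray:
        """Boolean mask of observed entries."""
        return ~np.isnan(self.values)

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.values).mean()) if self.values.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.protein_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, dataset_of_sample: list[str] | None = None
    ) -> "QuantMatrix":
        return cls(
            df.to_numpy(dtype=float),
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            dataset_of_sample,
        )

    def copy(self) -> "QuantMatrix":
        ds = list(self.dataset_of_sample) if self.dataset_of_sample else None
        return QuantMatrix(
            self.values.copy(), list(self.protein_ids), list(self.sample_ids), ds
        )

    def subset_rows(self, row_idx: np.ndarray) -> "QuantMatrix":
        ds = list(self.dataset_of_sample) if self.dataset_of_sample else None
        return QuantMatrix(
            self.values[row_idx],
            [self.protein_ids[i] for i in np.atleast_1d(row_idx)],
            list(self.sample_ids),
            ds,
        )

    def subset_cols(self, col_idx: np.ndarray) -> "QuantMatrix":
        col_idx = np.atleast_1d(col_idx)
        ds = (
            [self.dataset_of_sample[j] for j in col_idx]
            if self.dataset_of_sample
            else None
        )
        return QuantMatrix(
            self.values[:, col_idx],
            list(self.protein_ids),
            [self.sample_ids[j] for j in col_idx],
            ds,
        )


def read_quant_matrix(path, dataset_label: str | None = None) -> QuantMatrix:
    """Parse a wide TSV into a :class:`QuantMatrix`.

    Empty cells, ``NA`` and ``NaN`` parse to missing. Row and column
    order are preserved. Duplicate protein IDs and ragged rows raise
    with the offending ID / line number.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    n_fields = len(header)
    sample_ids = header[1:]
    protein_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if line == "" and lineno == len(lines) + 1:
            continue
        cells = line.split("\t")
        if len(cells) != n_fields:
            raise ValueError(
                f"{path}: line {lineno} has {len(cells)} fields, "
                f"expected {n_fields}"
            )
        pid = cells[0]
        if pid in seen:
            raise ValueError(f"{path}: duplicate protein ID {pid!r}")
        seen.add(pid)
        protein_ids.append(pid)
        rows.append(
            [np.nan if c in _NA_STRINGS else float(c) for c in cells[1:]]
        )
    values = (
        np.array(rows, dtype=float)
        if rows
        else np.empty((0, len(sample_ids)))
    )
    ds = [dataset_label] * len(sample_ids) if dataset_label is not None else None
    return QuantMatrix(values, protein_ids, sample_ids, ds)


def write_quant_matrix(X: QuantMatrix, path) -> None:
    """Write a wide TSV that round-trips through :func:`read_quant_matrix`.

    Values are written with full ``repr`` precision; NaN becomes an
    empty cell.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\t" + "\t".join(X.sample_ids) + "\n")
        for i, pid in enumerate(X.protein_ids):
            cells = [
                "" if np.isnan(v) else repr(float(v)) for v in X.values[i]
            ]
            fh.write(pid + "\t" + "\t".join(cells) + "\n")


def exclude_samples_by_keyword(
    X: QuantMatrix,
    keywords: list[str] | None = None,
    case_sensitive: bool = True,
) -> QuantMatrix:
    """Drop samples whose ID contains any keyword as a substring.

    The default keyword list targets reference channels, QC runs and
    pooled samples, which carry no biological signal of their own.
    Matching is plain (case-sensitive) substring containment.
    """
    if keywords is None:
        keywords = DEFAULT_EXCLUDE_KEYWORDS
    if case_sensitive:
        keep = [
            j
            for j, s in enumerate(X.sample_ids)
            if not any(k in s for k in keywords)
        ]
    else:
        low = [k.lower() for k in keywords]
        keep = [
            j
            for j, s in enumerate(X.sample_ids)
            if not any(k in s.lower() for k in low)
        ]
    return X.subset_cols(np.array(keep, dtype=int))


def build_joint_matrix(
    datasets: list[QuantMatrix], min_present: int = 18
) -> QuantMatrix:
    """Outer-join several matrices into one joint quantifications matrix.

    Rows are the union of all protein IDs (sorted lexicographically for
    determinism); columns are the concatenation of all samples in input
    order. A protein absent from a contributing dataset is NaN in that
    dataset's columns. Proteins observed in fewer than ``min_present``
    samples of the joint matrix are removed: too few observations make
    for low-quality imputations.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    all_samples: list[str] = []
    for d in datasets:
        all_samples.extend(d.sample_ids)
    if len(set(all_samples)) != len(all_samples):
        dupes = sorted(
            {s for s in all_samples if all_samples.count(s) > 1}
        )
        raise ValueError(f"duplicate sample IDs across datasets: {dupes}")

    proteins = sorted(set().union(*(d.protein_ids for d in datasets)))
    row_of = {p: i for i, p in enumerate(proteins)}
    n, m = len(proteins), len(all_samples)
    values = np.full((n, m), np.nan)
    dataset_of_sample: list[str] = []
    col = 0
    for k, d in enumerate(datasets):
        rows = np.array([row_of[p] for p in d.protein_ids], dtype=int)
        values[rows, col : col + d.n_samples] = d.values
        if d.dataset_of_sample is not None:
            dataset_of_sample.extend(d.dataset_of_sample)
        else:
            dataset_of_sample.extend([f"dataset_{k}"] * d.n_samples)
        col += d.n_samples
    joint = QuantMatrix(values, proteins, all_samples, dataset_of_sample)
    if min_present > 0:
        keep = np.flatnonzero(joint.present.sum(axis=1) >= min_present)
        joint = joint.subset_rows(keep)
    return joint


def filter_min_present(X: QuantMatrix, k: int, mask=None):
    """Remove proteins with fewer than ``k`` counted present values.

    If a partition mask is supplied, only train-assigned entries count,
    so proteins whose observations fall almost entirely in the test set
    are dropped from both views. Returns the filtered matrix, and the
    consistently row-subset mask when one was supplied.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if mask is not None:
        counts = (mask.labels == mask.TRAIN).sum(axis=1)
    else:
        counts = X.present.sum(axis=1)
    keep = np.flatnonzero(counts >= k)
    Xf = X.subset_rows(keep)
    if mask is not None:
        return Xf, mask.subset_rows(keep)
    return Xf
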