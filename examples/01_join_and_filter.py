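"""Assemble a joint quantifications matrix from two small cohorts.

Builds two tiny synthetic cohort matrices with partially overlapping
protein sets (plus a reference-channel sample that must be dropped),
outer-joins them, and applies the minimum-observations filter.
"""

import numpy as np

from lupine import (
    QuantMatrix,
    exclude_samples_by_keyword,
    build_joint_matrix,
)

rng = np.random.default_rng(0)

cohort_a = QuantMatrix(
    rng.normal(12, 1, (6, 4)),
    [f"PROT{i}" for i in range(6)],
    ["A_s1", "A_s2", "A_s3", "A_RefInt_pool"],
    ["cohortA"] * 4,
)
cohort_b = QuantMatrix(
    rng.normal(12, 1, (6, 3)),
    [f"PROT{i}" for i in range(3, 9)],  # proteins 3-5 shared with A
    ["B_s1", "B_s2", "B_s3"],
    ["cohortB"] * 3,
)

cohort_a = exclude_samples_by_keyword(cohort_a)
print(f"cohort A after reference/QC exclusion: {cohort_a.n_samples} samples")

joint = build_joint_matrix([cohort_a, cohort_b], min_present=3)
print(
    f"joint matrix: {joint.n_proteins} proteins x {joint.n_samples} samples, "
    f"{100 * joint.missing_fraction:.1f}% missing"
)
# Proteins private to one cohort are NaN in the other cohort's columns;
# the min_present=3 filter keeps only proteins observed in >= 3 samples,
# so cohort-B-only proteins (3 samples) survive while anything sparser
# would not.
print("proteins retained:", ", ".join(joint.protein_ids))
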