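"""Log transform, variation filter, row normalization and matrix stacking.

The canonical order is: log2 the linear (microarray) rows, drop rows whose
maximum fold change across samples falls below a linear-scale threshold,
normalize each surviving row, then stack the mRNA and miRNA matrices into a
single joint table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix

UNIT_INTERVAL = "unit_interval"
MEAN_ANCHORED = "mean_anchored"
NORMALIZATION_MODES = (UNIT_INTERVAL, MEAN_ANCHORED)


@dataclass
class PreprocessConfig:
    fold_change_threshold: float = 2.5
    normalization_mode: str = UNIT_INTERVAL
    log_transform_mrna: bool = True

    def __post_init__(self) -> None:
        if self.fold_change_threshold <= 1:
            raise ValueError("fold_change_threshold must exceed 1")
        if self.normalization_mode not in NORMALIZATION_MODES:
            raise ValueError(f"unknown normalization mode {self.normalization_mode!r}")


def log2_transform(mat: ExpressionMatrix) -> ExpressionMatrix:
    """log2 the rows of every kind flagged linear; log2 rows pass through."""
    linear_kinds = [k for k, s in mat.scales.items() if s == "linear"]
    if not linear_kinds:
        return mat
    values = mat.values.copy()
    for kind in linear_kinds:
        mask = mat.kind_mask(kind)
        block = values[mask]
        if np.any(block <= 0):
            i, j = np.argwhere(block <= 0)[0]
            rid = [r for r, keep in zip(mat.row_ids, mask) if keep][i]
            raise ValueError(
                f"non-positive value at row {rid!r}, sample {mat.sample_ids[j]!r}: "
                "cannot log2-transform"
            )
        values[mask] = np.log2(block)
    return mat.with_values(values, scales={k: "log2" for k in mat.scales})


def max_fold_change_filter(
    mat: ExpressionMatrix, threshold: float = 2.5
) -> tuple[ExpressionMatrix, int]:
    """Keep rows whose max−min (log2) is at least log2(threshold).

    Rows strictly below the threshold ratio are removed; the removal count
    is returned alongside the filtered matrix.
    """
    if any(s != "log2" for s in mat.scales.values()):
        raise ValueError("fold-change filter expects log2-scale data")
    span = mat.values.max(axis=1) - mat.values.min(axis=1)
    keep = span >= np.log2(threshold)
    removed = int((~keep).sum())
    if not keep.any():
        warnings.warn("fold-change filter removed every row", stacklevel=2)
    return mat.subset_rows(keep), removed


def normalize_rows(mat: ExpressionMatrix, mode: str = UNIT_INTERVAL) -> ExpressionMatrix:
    """Affinely map each row to [0, 1] (unit_interval) or [μ_i, μ_i+1].

    unit_interval:  y_ij = (x_ij − m_i) / (M_i − m_i)
    mean_anchored:  y_ij = μ_i + (x_ij − m_i) / (M_i − m_i)
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization mode {mode!r}")
    x = mat.values
    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    flat = (hi - lo).ravel() == 0
    if flat.any():
        rid = mat.row_ids[int(np.argmax(flat))]
        raise ValueError(
            f"constant row {rid!r}: apply the fold-change filter before normalizing"
        )
    y = (x - lo) / (hi - lo)
    if mode == MEAN_ANCHORED:
        y = y + x.mean(axis=1, keepdims=True)
    return mat.with_values(y)


def stack_joint_matrix(
    mrna: ExpressionMatrix, mirna: ExpressionMatrix
) -> ExpressionMatrix:
    """Concatenate the two matrices row-wise over an identical sample set."""
    if set(mrna.sample_ids) != set(mirna.sample_ids):
        only_mrna = sorted(set(mrna.sample_ids) - set(mirna.sample_ids))
        only_mirna = sorted(set(mirna.sample_ids) - set(mrna.sample_ids))
        raise ValueError(
            f"sample sets differ: only in mRNA {only_mrna}, only in miRNA {only_mirna}"
        )
    if mirna.sample_ids != mrna.sample_ids:
        mirna = mirna.reorder_samples(mrna.sample_ids)
    scales = dict(mrna.scales)
    for k, s in mirna.scales.items():
        if scales.setdefault(k, s) != s:
            raise ValueError(f"conflicting scale for kind {k!r}")
    return ExpressionMatrix(
        row_ids=mrna.row_ids + mirna.row_ids,
        row_kinds=mrna.row_kinds + mirna.row_kinds,
        sample_ids=list(mrna.sample_ids),
        values=np.vstack([mrna.values, mirna.values]),
        scales=scales,
    )


def preprocess(
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    config: PreprocessConfig | None = None,
) -> tuple[ExpressionMatrix, dict]:
    """Full chain: log2 → stack → fold-change filter → normalize.

    Returns the normalized joint matrix and a stage-by-stage row-count log.
    """
    config = config or PreprocessConfig()
    if config.log_transform_mrna:
        mrna = log2_transform(mrna)
    mirna = log2_transform(mirna)
    joint = stack_joint_matrix(mrna, mirna)
    rows_in = joint.n_features
    joint, removed = max_fold_change_filter(joint, config.fold_change_threshold)
    joint = normalize_rows(joint, config.normalization_mode)
    log = {
        "rows_in": rows_in,
        "rows_removed_by_fold_change": removed,
        "rows_out": joint.n_features,
        "fold_change_threshold": config.fold_change_threshold,
        "normalization_mode": config.normalization_mode,
        "mrna_rows_out": int(joint.kind_mask("mRNA").sum()),
        "mirna_rows_out": int(joint.kind_mask("miRNA").sum()),
    }
    return joint, log
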