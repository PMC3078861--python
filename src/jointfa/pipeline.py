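"""Orchestration helpers chaining preprocessing, factor extraction, rotation,
scoring and gene selection into one call."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .factor_analysis import (
    FactorGeneSet,
    FactorModel,
    kaiser_count,
    principal_axes_fa,
    regression_scores,
    rotate_model,
    sample_correlation,
    select_factor_genes,
)
from .io import ExpressionMatrix
from .preprocess import NORMALIZATION_MODES, normalize_rows
from .synthetic_data import match_factors


@dataclass
class PipelineResult:
    model: FactorModel
    gene_sets: list[FactorGeneSet]
    kaiser_suggested: int


def fit_joint_model(
    joint: ExpressionMatrix,
    n_factors: int | None = None,
    kaiser_t: float = 1.0,
    rotation: str = "promax",
    promax_power: int = 4,
    score_multiplier: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> PipelineResult:
    """Fit the factor model on an already-normalized joint matrix.

    When ``n_factors`` is omitted the Kaiser criterion on the unreduced
    correlation matrix decides, floored at one factor.
    """
    r = sample_correlation(joint)
    eigenvalues = np.sort(np.linalg.eigvalsh(r))[::-1]
    suggested = kaiser_count(eigenvalues, kaiser_t)
    if n_factors is None:
        n_factors = suggested
        if n_factors == 0:
            warnings.warn("no eigenvalue above the Kaiser threshold; using 1 factor",
                          stacklevel=2)
            n_factors = 1
    model = principal_axes_fa(
        r, n_factors, tol=tol, max_iter=max_iter, sample_ids=joint.sample_ids
    )
    model = rotate_model(model, method=rotation, power=promax_power)
    scores = regression_scores(joint, model, r=r)
    model.scores = scores
    model.gene_ids = list(joint.row_ids)
    gene_sets = select_factor_genes(scores, joint.row_ids, multiplier=score_multiplier)
    return PipelineResult(model=model, gene_sets=gene_sets, kaiser_suggested=suggested)


def normalization_discrepancy(
    joint_log2: ExpressionMatrix,
    n_factors: int,
    rotation: str = "promax",
) -> float:
    """Fit both normalizations and report the maximum absolute difference in
    |loadings| after factor matching (measured, not asserted)."""
    fits = []
    for mode in NORMALIZATION_MODES:
        normed = normalize_rows(joint_log2, mode)
        fits.append(fit_joint_model(normed, n_factors=n_factors, rotation=rotation))
    a, b = fits[0].model.loadings, fits[1].model.loadings
    perm, signs, _ = match_factors(b, a)
    matched = b[:, perm] * np.asarray(signs)[None, :]
    return float(np.max(np.abs(np.abs(a) - np.abs(matched))))
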