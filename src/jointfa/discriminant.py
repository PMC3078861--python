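"""Leave-one-out LDA on factor loadings, Fisher exact scoring of the
resulting 2×2 tables, greedy factor-subset search, and model selection.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np

from .factor_analysis import FactorModel
from .io import SampleMetadata


@dataclass
class ConfusionTable:
    """2×2 leave-one-out counts: rows = true class/complement, columns =
    predicted class/complement."""

    a: int  # true class, predicted class
    b: int  # true class, predicted complement
    c: int  # complement, predicted class
    d: int  # complement, predicted complement
    class_name: str = ""
    factor_subset: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("confusion counts must be non-negative integers")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def counts(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def accuracy(table: ConfusionTable) -> float:
    """Fraction of correctly classified samples, (a+d)/n."""
    if table.n == 0:
        raise ValueError("empty confusion table")
    return (table.a + table.d) / table.n


def fisher_exact_two_sided(table: ConfusionTable) -> float:
    """Two-sided Fisher exact p: sum of point hypergeometric probabilities
    over all margin-compatible tables no more probable than the observed one.

    Point probabilities share the denominator C(n, c1), so the comparison is
    done on exact integer numerators, with the conventional 1e-7 relative
    slack on the "no more probable" side.
    """
    a, b, c, d = table.counts()
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    lo = max(0, c1 - (c + d))
    hi = min(r1, c1)
    r2 = c + d
    weight = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    w_obs = weight[a]
    # integer-safe form of w <= w_obs * (1 + 1e-7)
    scale = 10**7
    numer = sum(w for w in weight.values() if w * scale <= w_obs * (scale + 1))
    return min(1.0, numer / comb(n, c1))


# ---------------------------------------------------------------------------
# leave-one-out LDA


def _lda_predict(train_x, train_y, test_x, ridge=1e-8):
    """Gaussian LDA with pooled covariance and training-frequency priors."""
    classes = np.array([False, True])
    means = np.stack([train_x[train_y == cl].mean(axis=0) for cl in classes])
    priors = np.array([(train_y == cl).mean() for cl in classes])
    centered = train_x - means[train_y.astype(int)]
    dof = max(train_x.shape[0] - 2, 1)
    cov = centered.T @ centered / dof
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn("singular pooled covariance; ridge regularization applied",
                      stacklevel=3)
        cov = cov + ridge * np.eye(cov.shape[0])
    inv = np.linalg.inv(cov)
    scores = [
        test_x @ inv @ mu - 0.5 * mu @ inv @ mu + np.log(pi)
        for mu, pi in zip(means, priors)
    ]
    return bool(classes[int(np.argmax(scores))])


def loo_lda_confusion(
    loadings: np.ndarray,
    labels: np.ndarray,
    subset: tuple[int, ...] | None = None,
    class_name: str = "",
) -> ConfusionTable:
    """Jack-knife (leave-one-out) LDA classification of every sample.

    ``labels`` is boolean with True marking the class of interest; ``subset``
    selects factor columns (all factors when omitted).
    """
    loadings = np.asarray(loadings, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if loadings.shape[0] != labels.shape[0]:
        raise ValueError("loadings and labels disagree on sample count")
    subset = tuple(range(loadings.shape[1])) if subset is None else tuple(subset)
    x = loadings[:, list(subset)]
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos < 2 or n_neg < 2:
        small = class_name or ("class" if n_pos < 2 else "complement")
        raise ValueError(
            f"{small!r} side has fewer than 2 members; leave-one-out LDA needs ≥ 2"
        )
    a = b = c = d = 0
    for i in range(x.shape[0]):
        mask = np.ones(x.shape[0], dtype=bool)
        mask[i] = False
        pred = _lda_predict(x[mask], labels[mask], x[i])
        if labels[i]:
            a, b = (a + 1, b) if pred else (a, b + 1)
        else:
            c, d = (c + 1, d) if pred else (c, d + 1)
    return ConfusionTable(a, b, c, d, class_name=class_name, factor_subset=subset)


# ---------------------------------------------------------------------------
# factor-subset search


def _evaluate(loadings, labels, subset, class_name):
    t = loo_lda_confusion(loadings, labels, subset=subset, class_name=class_name)
    return t, accuracy(t), fisher_exact_two_sided(t)


def greedy_factor_search(
    loadings: np.ndarray,
    labels: np.ndarray,
    class_name: str = "",
) -> tuple[tuple[int, ...], ConfusionTable, float]:
    """Step-wise greedy subset search: start from the best single factor and
    add the factor with the largest accuracy gain until none improves.

    Ties are broken by lower Fisher p, then lexicographic factor order.
    """
    l = np.asarray(loadings).shape[1]
    best = None
    for f in range(l):
        t, acc, p = _evaluate(loadings, labels, (f,), class_name)
        key = (-acc, p, (f,))
        if best is None or key < best[0]:
            best = (key, (f,), t, p, acc)
    _, subset, table, p, acc = best
    while len(subset) < l:
        candidate = None
        for f in range(l):
            if f in subset:
                continue
            trial = tuple(sorted(subset + (f,)))
            t, a2, p2 = _evaluate(loadings, labels, trial, class_name)
            key = (-a2, p2, trial)
            if candidate is None or key < candidate[0]:
                candidate = (key, trial, t, p2, a2)
        if candidate is None or candidate[4] <= acc:
            break
        _, subset, table, p, acc = candidate
    return subset, table, p


def exhaustive_factor_search(
    loadings: np.ndarray,
    labels: np.ndarray,
    class_name: str = "",
) -> tuple[tuple[int, ...], ConfusionTable, float]:
    """Audit mode: evaluate every non-empty factor subset.

    Best accuracy wins; ties go to the smallest subset, then lower p, then
    lexicographic order.
    """
    l = np.asarray(loadings).shape[1]
    best = None
    for size in range(1, l + 1):
        for subset in itertools.combinations(range(l), size):
            t, acc, p = _evaluate(loadings, labels, subset, class_name)
            key = (-acc, len(subset), p, subset)
            if best is None or key < best[0]:
                best = (key, subset, t, p)
    _, subset, table, p = best
    return subset, table, p


# ---------------------------------------------------------------------------
# model selection


@dataclass
class ContrastResult:
    contrast: str
    subset: tuple[int, ...]
    table: ConfusionTable
    accuracy: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass
class ModelSelectionReport:
    """Per-model, per-contrast search results and the chosen model."""

    results: dict[int, dict[str, ContrastResult]]
    retained: dict[int, bool]
    chosen: int | None
    alpha: float = 0.05
    warnings: list[str] = field(default_factory=list)


def select_model(
    models: list[FactorModel],
    metadata: SampleMetadata,
    alpha: float = 0.05,
    exhaustive: bool = False,
) -> ModelSelectionReport:
    """Run the subset search for every model × contrast; keep models with at
    least one contrast significant at ``alpha``; among models with identical
    (accuracy, significance) profiles choose the one with fewest factors.
    """
    if not models:
        raise ValueError("no models supplied")
    search = exhaustive_factor_search if exhaustive else greedy_factor_search
    results: dict[int, dict[str, ContrastResult]] = {}
    retained: dict[int, bool] = {}
    notes: list[str] = []
    for model in sorted(models, key=lambda m: m.n_factors):
        if not model.sample_ids:
            raise ValueError("models must carry sample_ids for label alignment")
        dichotomies = metadata.dichotomies(model.sample_ids)
        if not dichotomies:
            raise ValueError("no valid dichotomy available")
        per_contrast: dict[str, ContrastResult] = {}
        for name, labels_map in dichotomies.items():
            labels = np.array([labels_map[s] for s in model.sample_ids])
            try:
                subset, table, p = search(model.loadings, labels, class_name=name)
            except ValueError as exc:
                notes.append(f"model {model.n_factors}, contrast {name}: {exc}")
                continue
            per_contrast[name] = ContrastResult(
                contrast=name,
                subset=subset,
                table=table,
                accuracy=accuracy(table),
                p_value=p,
            )
        results[model.n_factors] = per_contrast
        retained[model.n_factors] = any(r.significant for r in per_contrast.values())

    candidates = [l for l, keep in retained.items() if keep]
    if not candidates:
        warnings.warn("no model reaches significance in any contrast", stacklevel=2)
        chosen = None
    else:
        def profile(l: int):
            per = results[l]
            n_sig = sum(r.significant for r in per.values())
            total_acc = round(sum(r.accuracy for r in per.values()), 12)
            return (n_sig, total_acc)

        best = max(profile(l) for l in candidates)
        chosen = min(l for l in candidates if profile(l) == best)
    return ModelSelectionReport(
        results=results, retained=retained, chosen=chosen, alpha=alpha,
        warnings=notes,
    )
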