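"""Common-factor model fit by iterated principal axes, oblique rotation and
per-gene regression scores.

Orientation: the analysis treats *samples* as variables and *genes* as
observations, so the correlation matrix is m×m (samples), loadings are
samples×factors, and scores place every gene in the factor space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class FactorModel:
    """Fitted common-factor model for samples-as-variables data."""

    n_factors: int
    loadings: np.ndarray                 # m × l
    communalities: np.ndarray            # m
    uniqueness: np.ndarray               # m
    eigenvalues: np.ndarray              # of the unreduced correlation matrix, desc
    factor_correlation: np.ndarray       # l × l
    rotation: str = "none"               # none | varimax | promax
    converged: bool = True
    iterations: int = 0
    sample_ids: list[str] = field(default_factory=list)
    scores: np.ndarray | None = None     # l × n_genes
    gene_ids: list[str] | None = None

    @property
    def structure(self) -> np.ndarray:
        """Structure matrix: loadings post-multiplied by factor correlations."""
        return self.loadings @ self.factor_correlation


@dataclass
class FactorGeneSet:
    """Genes whose score on one factor lies outside μ ± multiplier·σ."""

    factor: int
    positive_set: dict[str, float]
    negative_set: dict[str, float]
    score_mean: float
    score_sd: float
    multiplier: float = 2.0

    @property
    def selected_ids(self) -> set[str]:
        return set(self.positive_set) | set(self.negative_set)


# ---------------------------------------------------------------------------
# correlation and extraction


def sample_correlation(joint: ExpressionMatrix) -> np.ndarray:
    """Pearson correlation between sample columns, computed across genes."""
    x = joint.values
    if x.shape[0] < 3:
        raise ValueError("need at least 3 genes to correlate samples")
    if np.any(x.std(axis=0) == 0):
        j = int(np.argmax(x.std(axis=0) == 0))
        raise ValueError(f"sample {joint.sample_ids[j]!r} is constant across genes")
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return r


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def smc_communalities(r: np.ndarray) -> np.ndarray:
    """Squared multiple correlations, 1 − 1/(R⁻¹)ᵢᵢ; falls back on singular R."""
    try:
        rinv = np.linalg.inv(r)
        diag = np.diag(rinv)
        if np.any(diag <= 0):
            raise np.linalg.LinAlgError("non-positive inverse diagonal")
        return np.clip(1.0 - 1.0 / diag, 0.0, 1.0)
    except np.linalg.LinAlgError:
        warnings.warn(
            "correlation matrix is singular; using 1 - 1/diag(R) initial communalities",
            stacklevel=2,
        )
        return np.clip(1.0 - 1.0 / np.diag(r), 0.0, 1.0)


def principal_axes_fa(
    r: np.ndarray,
    n_factors: int,
    tol: float = 1e-6,
    max_iter: int = 100,
    sample_ids: list[str] | None = None,
) -> FactorModel:
    """Iterated principal-axis extraction of ``n_factors`` common factors.

    Communalities start at the squared multiple correlation, are placed on
    the diagonal of R, and are refreshed from the row sums of squared
    loadings of the top eigenpairs until they stabilise.
    """
    r = np.asarray(r, dtype=float)
    m = r.shape[0]
    if r.shape != (m, m) or not np.allclose(r, r.T, atol=1e-10):
        raise ValueError("R must be a symmetric square matrix")
    if not np.allclose(np.diag(r), 1.0, atol=1e-8):
        raise ValueError("R must have a unit diagonal")
    if not 1 <= n_factors < m:
        raise ValueError(f"factor count must be in [1, {m - 1}]")

    eigenvalues = np.sort(np.linalg.eigvalsh(r))[::-1]
    comm = smc_communalities(r)
    loadings = np.zeros((m, n_factors))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        reduced = r.copy()
        np.fill_diagonal(reduced, comm)
        vals, vecs = np.linalg.eigh(reduced)
        order = np.argsort(vals)[::-1][:n_factors]
        top = np.clip(vals[order], 0.0, None)
        loadings = vecs[:, order] * np.sqrt(top)
        new_comm = np.sum(loadings**2, axis=1)
        if np.any(new_comm > 1.0):
            logger.info("Heywood case: clipping %d communalities to 1", int((new_comm > 1).sum()))
        new_comm = np.clip(new_comm, 0.0, 1.0)
        delta = np.max(np.abs(new_comm - comm))
        comm = new_comm
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"principal-axes iteration did not converge in {max_iter} steps",
            stacklevel=2,
        )
    return FactorModel(
        n_factors=n_factors,
        loadings=_fix_signs(loadings),
        communalities=comm,
        uniqueness=1.0 - comm,
        eigenvalues=eigenvalues,
        factor_correlation=np.eye(n_factors),
        rotation="none",
        converged=converged,
        iterations=it,
        sample_ids=list(sample_ids) if sample_ids else [],
    )


def kaiser_count(eigenvalues: np.ndarray, t: float = 1.0) -> int:
    """Number of eigenvalues strictly greater than the threshold ``t``."""
    ev = np.asarray(eigenvalues, dtype=float)
    if np.any(np.diff(ev) > 1e-12):
        raise ValueError("eigenvalues must be sorted descending")
    return int(np.sum(ev > t))


# ---------------------------------------------------------------------------
# rotation


def varimax(
    loadings: np.ndarray,
    normalize: bool = True,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation (Kaiser row normalization by default).

    Returns (rotated loadings, rotation matrix T) with rotated = Λ·T.
    """
    x = np.asarray(loadings, dtype=float).copy()
    m, l = x.shape
    if l < 2:
        return x.copy(), np.eye(l)
    h = np.ones(m)
    if normalize:
        h = np.sqrt(np.sum(x**2, axis=1))
        h[h == 0] = 1.0
        x = x / h[:, None]
    rot = np.eye(l)
    var_old = 0.0
    for _ in range(max_iter):
        lam = x @ rot
        grad = x.T @ (lam**3 - lam * (np.sum(lam**2, axis=0) / m))
        u, s, vt = np.linalg.svd(grad)
        rot = u @ vt
        var_new = float(np.sum(s))
        if var_new - var_old < tol * max(var_new, 1.0):
            break
        var_old = var_new
    rotated = (x @ rot) * h[:, None]
    return rotated, rot


def promax_rotate(
    loadings: np.ndarray, power: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Oblique Promax rotation: varimax, then least-squares fit to the
    sign-preserving ``power``-th moment target with column rescaling.

    Returns (rotated loadings, factor correlation matrix).  A single factor
    is returned unchanged with a 1×1 identity correlation.
    """
    lam = np.asarray(loadings, dtype=float)
    m, l = lam.shape
    if l == 1:
        return lam.copy(), np.eye(1)
    if np.linalg.matrix_rank(lam) < l:
        raise ValueError("loadings are rank-deficient; cannot rotate")
    x, _ = varimax(lam, normalize=True)
    target = np.sign(x) * np.abs(x) ** power
    u, *_ = np.linalg.lstsq(x, target, rcond=None)
    d = np.diag(np.linalg.inv(u.T @ u))
    u = u * np.sqrt(d)[None, :]
    rotated = x @ u
    phi = np.linalg.inv(u.T @ u)
    # symmetrize and pin the unit diagonal against round-off
    phi = (phi + phi.T) / 2.0
    np.fill_diagonal(phi, 1.0)
    return _fix_signs(rotated), phi


def rotate_model(model: FactorModel, method: str = "promax", power: int = 4) -> FactorModel:
    if method == "none" or model.n_factors == 1:
        return replace(model, rotation=model.rotation if method == "none" else "none")
    if method == "varimax":
        rotated, _ = varimax(model.loadings)
        return replace(model, loadings=_fix_signs(rotated), rotation="varimax",
                       factor_correlation=np.eye(model.n_factors))
    if method == "promax":
        rotated, phi = promax_rotate(model.loadings, power=power)
        return replace(model, loadings=rotated, factor_correlation=phi, rotation="promax")
    raise ValueError(f"unknown rotation {method!r}")


# ---------------------------------------------------------------------------
# scores and gene selection


def regression_scores(
    joint: ExpressionMatrix, model: FactorModel, r: np.ndarray | None = None
) -> np.ndarray:
    """Thomson regression estimator of per-gene factor scores (l × genes).

    Genes are standardized within each sample; weights solve R·W = S with
    S the structure matrix.  A tiny ridge is applied if R is singular.
    """
    x = joint.values  # genes × samples
    if model.loadings.shape[0] != x.shape[1]:
        raise ValueError("model fitted on a different number of samples")
    if r is None:
        r = sample_correlation(joint)
    z = (x - x.mean(axis=0)) / x.std(axis=0)
    s = model.structure
    try:
        w = np.linalg.solve(r, s)
    except np.linalg.LinAlgError:
        warnings.warn("singular correlation matrix; ridge fallback", stacklevel=2)
        w = np.linalg.solve(r + 1e-8 * np.eye(r.shape[0]), s)
    return (z @ w).T


def select_factor_genes(
    scores: np.ndarray,
    gene_ids: list[str],
    multiplier: float = 2.0,
) -> list[FactorGeneSet]:
    """Per factor, split genes scoring outside μ ± multiplier·σ by sign."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores contain non-finite values")
    out = []
    for f in range(scores.shape[0]):
        row = scores[f]
        mu = float(row.mean())
        sd = float(row.std())
        if sd == 0:
            warnings.warn(f"factor {f}: zero score variance, nothing selected",
                          stacklevel=2)
            out.append(FactorGeneSet(f, {}, {}, mu, sd, multiplier))
            continue
        hi = row > mu + multiplier * sd
        lo = row < mu - multiplier * sd
        out.append(
            FactorGeneSet(
                factor=f,
                positive_set={gene_ids[i]: float(row[i]) for i in np.flatnonzero(hi)},
                negative_set={gene_ids[i]: float(row[i]) for i in np.flatnonzero(lo)},
                score_mean=mu,
                score_sd=sd,
                multiplier=multiplier,
            )
        )
    return out


def simple_structure_diagnostic(model: FactorModel, near_zero: float = 0.1) -> dict:
    """Descriptive count of near-zero loadings per factor and per sample."""
    small = np.abs(model.loadings) < near_zero
    return {
        "near_zero_per_factor": small.sum(axis=0).tolist(),
        "near_zero_per_sample": small.sum(axis=1).tolist(),
        "threshold": near_zero,
    }
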