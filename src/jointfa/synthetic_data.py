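"""Seeded generator of joint mRNA+miRNA datasets with planted factor
structure, class-separating sample loadings and co-regulated genomic miRNA
clusters, plus factor-matching and recovery-evaluation utilities.

The generative model mirrors the analysis model: D = L·F + E with D the
samples×genes matrix, so the written expression table is Dᵀ plus a per-gene
baseline (the baseline is removed again by row normalization).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import (
    ExpressionMatrix,
    GenomicCluster,
    SampleMetadata,
    write_expression_table,
    write_mirna_clusters_bed,
    write_sample_metadata,
)


@dataclass
class PlantedCluster:
    size: int
    factor: int
    sign: int = 1          # tail the members load on: +1 or -1
    name: str = ""
    chromosome: str = "chr13"


@dataclass
class SyntheticSpec:
    """Fully determines a dataset: same spec + seed ⇒ identical output."""

    n_samples: int = 12
    n_mrna: int = 4966
    n_mirna: int = 93
    n_factors: int = 3
    #: dichotomy name -> (separating factor, loading offset between classes)
    class_design: dict[str, tuple[int, float]] = field(
        default_factory=lambda: {
            "gliosarcoma": (0, 1.0),
            "anaplastic": (1, 1.2),
        }
    )
    #: factor -> (sample indices, loading offset) for latent factors that are
    #: not tied to a class; the default plants the cluster-carrying factor on
    #: a subset of the glioblastomas, so the glioblastoma contrast is only
    #: separable by a combination of factors
    latent_design: dict[int, tuple[tuple[int, ...], float]] = field(
        default_factory=lambda: {2: ((0, 1, 2), 1.2)}
    )
    #: factor -> (sample indices, offset) loaded with the *negative* sign;
    #: counterweights keep every sample loaded on some factor, without which
    #: the row normalization couples all never-loaded samples into a spurious
    #: extra structure
    counterweights: dict[int, tuple[tuple[int, ...], float]] = field(
        default_factory=lambda: {0: ((3, 4, 5), 1.0), 1: ((11,), 1.2)}
    )
    signal_genes_per_factor: int = 60
    signal_score: float = 6.0
    score_sd: float = 0.75
    #: fraction of background genes carrying factor scores at all; the rest
    #: are idiosyncratic, keeping the score distribution peaked at zero with
    #: identifiable ±2σ tails
    background_active_fraction: float = 0.25
    clusters: list[PlantedCluster] = field(
        default_factory=lambda: [
            PlantedCluster(size=4, factor=2, sign=1, name="mir-c17", chromosome="chr13"),
            PlantedCluster(size=3, factor=2, sign=1, name="mir-c106", chromosome="chrX"),
        ]
    )
    base_loading_sd: float = 0.1
    #: scale of per-gene idiosyncratic variation (most genes are noise-shaped,
    #: which is what makes the ±2σ score tails identifiable after row
    #: normalization flattens amplitudes)
    unique_sd: float = 0.8
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_mrna, self.n_mirna, self.n_factors) < 1:
            raise ValueError("all counts must be positive")
        if self.signal_genes_per_factor < 1:
            raise ValueError("need at least one signal gene per factor")
        if self.n_factors * self.signal_genes_per_factor > self.n_mrna:
            raise ValueError("more signal genes than mRNA rows")
        if sum(c.size for c in self.clusters) > self.n_mirna:
            raise ValueError("cluster members exceed miRNA rows")
        for c in self.clusters:
            if not 0 <= c.factor < self.n_factors:
                raise ValueError(f"cluster factor {c.factor} out of range")
        for name, (f, _) in self.class_design.items():
            if not 0 <= f < self.n_factors:
                raise ValueError(f"dichotomy {name!r} targets unknown factor {f}")
        for design in (self.latent_design, self.counterweights):
            for f, (support, _) in design.items():
                if not 0 <= f < self.n_factors:
                    raise ValueError(f"planted design targets unknown factor {f}")
                if any(not 0 <= i < self.n_samples for i in support):
                    raise ValueError(f"factor {f} support out of sample range")


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    expression: ExpressionMatrix          # joint genes×samples, log2 scale
    metadata: SampleMetadata
    clusters: list[GenomicCluster]
    loadings: np.ndarray                  # planted, samples×factors
    scores: np.ndarray                    # planted, factors×genes
    signal_genes: dict[int, dict[str, set[str]]]  # factor -> {"positive","negative"}


def _default_histotypes(n_samples: int) -> list[str]:
    """Histotype layout mimicking the study composition, cycled as needed."""
    base = (
        ["glioblastoma"] * 6 + ["gliosarcoma"] * 3 + ["anaplastic"] * 2
        + ["oligodendroglioma"]
    )
    return [base[i % len(base)] for i in range(n_samples)]


def simulate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a dataset with planted loadings, scores and clusters."""
    rng = np.random.default_rng(spec.seed)
    m, l = spec.n_samples, spec.n_factors
    n = spec.n_mrna + spec.n_mirna

    sample_ids = [f"s{i + 1:02d}" for i in range(m)]
    histotype = _default_histotypes(m)
    grade = ["low" if h == "anaplastic" else "high" for h in histotype]
    metadata = SampleMetadata(
        sample_ids=sample_ids,
        grade=dict(zip(sample_ids, grade)),
        histotype=dict(zip(sample_ids, histotype)),
    )

    # --- planted loadings: simple structure (each factor loads on the samples
    # of one class only), which keeps the columns near-orthogonal and the
    # oblique rotation identifiable
    loadings = rng.normal(0.0, spec.base_loading_sd, size=(m, l))
    dichotomies = metadata.dichotomies()
    for name, (f, offset) in spec.class_design.items():
        if name not in dichotomies:
            continue
        in_class = np.array([dichotomies[name][s] for s in sample_ids])
        loadings[in_class, f] += offset
    for f, (support, offset) in spec.latent_design.items():
        loadings[list(support), f] += offset
    for f, (support, offset) in spec.counterweights.items():
        loadings[list(support), f] -= offset

    # --- planted scores: heavy background plus explicit signal genes
    gene_ids = [f"gene{i + 1:05d}" for i in range(spec.n_mrna)] + [
        f"mir{i + 1:03d}" for i in range(spec.n_mirna)
    ]
    kinds = ["mRNA"] * spec.n_mrna + ["miRNA"] * spec.n_mirna
    active = rng.random(n) < spec.background_active_fraction
    scores = rng.normal(0.0, spec.score_sd, size=(l, n)) * active[None, :]

    signal_genes: dict[int, dict[str, set[str]]] = {
        f: {"positive": set(), "negative": set()} for f in range(l)
    }
    perm = rng.permutation(spec.n_mrna)
    cursor = 0
    for f in range(l):
        idx = perm[cursor : cursor + spec.signal_genes_per_factor]
        cursor += spec.signal_genes_per_factor
        half = len(idx) // 2
        for j, gi in enumerate(idx):
            sign = 1.0 if j < half or len(idx) == 1 else -1.0
            scores[f, gi] = sign * spec.signal_score + rng.normal(0.0, 0.05)
            key = "positive" if sign > 0 else "negative"
            signal_genes[f][key].add(gene_ids[gi])

    # --- cluster miRNAs: near-identical scores in one factor's tail
    clusters: list[GenomicCluster] = []
    mir_cursor = 0
    for c in spec.clusters:
        rows = np.arange(spec.n_mrna + mir_cursor, spec.n_mrna + mir_cursor + c.size)
        mir_cursor += c.size
        common = c.sign * spec.signal_score
        scores[c.factor, rows] = common + rng.normal(0.0, 0.05, size=c.size)
        key = "positive" if c.sign > 0 else "negative"
        members = [gene_ids[r] for r in rows]
        for mid in members:
            signal_genes[c.factor][key].add(mid)
        start = 1000
        spans = {
            mid: (start + 200 * j, start + 200 * j + 80) for j, mid in enumerate(members)
        }
        clusters.append(
            GenomicCluster(
                cluster_name=c.name or f"cluster{len(clusters) + 1}",
                chromosome=c.chromosome,
                member_ids=members,
                span=(min(s for s, _ in spans.values()), max(e for _, e in spans.values())),
                member_spans=spans,
            )
        )

    # --- observed data: shared-factor part plus measurement noise plus
    # per-gene idiosyncratic variation (unique variance)
    unique = np.abs(rng.normal(0.0, spec.unique_sd, size=n))
    cell_sd = np.sqrt(spec.noise_sd**2 + unique**2)
    noise = rng.normal(0.0, 1.0, size=(m, n)) * cell_sd[None, :]
    d = loadings @ scores + noise
    baseline = rng.normal(8.0, 1.0, size=n)
    values = d.T + baseline[:, None]
    expression = ExpressionMatrix(
        row_ids=gene_ids,
        row_kinds=kinds,
        sample_ids=sample_ids,
        values=values,
        scales={"mRNA": "log2", "miRNA": "log2"},
    )
    return SyntheticDataset(
        spec=spec,
        expression=expression,
        metadata=metadata,
        clusters=clusters,
        loadings=loadings,
        scores=scores,
        signal_genes=signal_genes,
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write the dataset in the pipeline's own input formats plus ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr = dataset.expression
    mrna = expr.subset_rows(expr.kind_mask("mRNA"))
    mirna = expr.subset_rows(expr.kind_mask("miRNA"))
    paths = {
        "mrna": str(outdir / "mrna.tsv"),
        "mirna": str(outdir / "mirna.tsv"),
        "metadata": str(outdir / "metadata.tsv"),
        "clusters": str(outdir / "clusters.bed"),
        "truth": str(outdir / "truth.json"),
    }
    write_expression_table(mrna, paths["mrna"])
    write_expression_table(mirna, paths["mirna"])
    write_sample_metadata(dataset.metadata, paths["metadata"])
    write_mirna_clusters_bed(dataset.clusters, paths["clusters"])
    truth = {
        "spec": {
            **{k: v for k, v in asdict(dataset.spec).items() if k not in ("clusters", "class_design")},
            "class_design": {k: list(v) for k, v in dataset.spec.class_design.items()},
            "clusters": [asdict(c) for c in dataset.spec.clusters],
        },
        "loadings": dataset.loadings.tolist(),
        "scores_sd": float(dataset.scores.std()),
        "signal_genes": {
            str(f): {k: sorted(v) for k, v in sides.items()}
            for f, sides in dataset.signal_genes.items()
        },
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths


# ---------------------------------------------------------------------------
# evaluation utilities


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two loading columns."""
    a, b = np.ravel(a), np.ravel(b)
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def match_factors(
    recovered: np.ndarray, planted: np.ndarray
) -> tuple[list[int], list[int], list[float]]:
    """Assign recovered columns to planted columns maximizing total |congruence|.

    Returns (permutation, signs, congruences): ``permutation[j]`` is the
    recovered column matched to planted column j, ``signs[j]`` aligns its
    orientation, and ``congruences[j]`` is the absolute Tucker congruence.
    Extra recovered columns are left unmatched.
    """
    recovered = np.asarray(recovered, dtype=float)
    planted = np.asarray(planted, dtype=float)
    if recovered.shape[0] != planted.shape[0]:
        raise ValueError("sample dimensions differ")
    if recovered.shape[1] < planted.shape[1]:
        raise ValueError("fewer recovered factors than planted")
    lp, lr = planted.shape[1], recovered.shape[1]
    c = np.zeros((lp, lr))
    for i in range(lp):
        for j in range(lr):
            c[i, j] = tucker_congruence(planted[:, i], recovered[:, j])
    rows, cols = linear_sum_assignment(-np.abs(c))
    perm = [0] * lp
    signs = [1] * lp
    cong = [0.0] * lp
    for i, j in zip(rows, cols):
        perm[i] = int(j)
        signs[i] = 1 if c[i, j] >= 0 else -1
        cong[i] = float(abs(c[i, j]))
    return perm, signs, cong


def evaluate_recovery(
    dataset: SyntheticDataset,
    model,
    gene_sets,
    enrichment_results=None,
) -> dict:
    """Score a pipeline run against the planted ground truth.

    Reports matched factor congruences, precision/recall of the ±2σ gene
    selection per planted factor, cluster-enrichment adjusted p-values and
    LOO-LDA accuracy for every designed dichotomy on its planted factor.
    """
    from .discriminant import accuracy, loo_lda_confusion

    # column means of loading patterns are unidentifiable after per-row
    # normalization (only contrasts between samples survive), so matching is
    # done on mean-centered columns
    recovered_c = model.loadings - model.loadings.mean(axis=0, keepdims=True)
    planted_c = dataset.loadings - dataset.loadings.mean(axis=0, keepdims=True)
    perm, _, congruences = match_factors(recovered_c, planted_c)

    selection: dict[int, dict[str, float]] = {}
    for f in range(dataset.spec.n_factors):
        truth = (
            dataset.signal_genes[f]["positive"] | dataset.signal_genes[f]["negative"]
        )
        got = gene_sets[perm[f]].selected_ids
        tp = len(truth & got)
        selection[f] = {
            "recall": tp / len(truth) if truth else 1.0,
            "precision": tp / len(got) if got else 0.0,
            "n_selected": len(got),
            "n_planted": len(truth),
        }

    dichotomy_acc: dict[str, float] = {}
    dichotomies = dataset.metadata.dichotomies(dataset.expression.sample_ids)
    for name, (f, _) in dataset.spec.class_design.items():
        if name not in dichotomies:
            continue
        labels = np.array(
            [dichotomies[name][s] for s in dataset.expression.sample_ids]
        )
        table = loo_lda_confusion(
            model.loadings, labels, subset=(perm[f],), class_name=name
        )
        dichotomy_acc[name] = accuracy(table)

    report = {
        "congruences": congruences,
        "mean_congruence": float(np.mean(congruences)),
        "selection": selection,
        "dichotomy_accuracy": dichotomy_acc,
    }
    if enrichment_results is not None:
        report["cluster_p_adj"] = {
            r.unit: r.p_adj for r in enrichment_results
        }
    return report
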