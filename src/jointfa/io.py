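"""Readers/writers for the tabular formats the pipeline touches.

Expression tables are plain TSV/CSV with features in rows and samples in
columns.  Genomic loci come in as BED6+1 (seventh column = cluster tag) or
GFF3; both are normalised to 0-based half-open intervals internally.  Gene
sets use the GMT convention; miRNA→target maps are two-column tables.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

KIND_MRNA = "mRNA"
KIND_MIRNA = "miRNA"
VALID_KINDS = (KIND_MRNA, KIND_MIRNA)
VALID_SCALES = ("linear", "log2")

GRADES = ("high", "low")
HISTOTYPES = ("anaplastic", "glioblastoma", "gliosarcoma", "oligodendroglioma")

#: dichotomy name -> function of (grade, histotype) returning membership
DICHOTOMY_NAMES = ("grade", "anaplastic", "glioblastoma", "gliosarcoma")


@dataclass
class ExpressionMatrix:
    """Features × samples expression values with per-row molecule kind.

    ``values[i, j]`` is the expression of feature ``row_ids[i]`` in sample
    ``sample_ids[j]``.  ``scales`` maps each molecule kind present to the
    scale its rows are on (``linear`` or ``log2``).
    """

    row_ids: list[str]
    row_kinds: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scales: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape if self.values.ndim == 2 else (len(self.values), 0)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if len(self.row_ids) != n or len(self.row_kinds) != n:
            raise ValueError(
                f"row dimension mismatch: {len(self.row_ids)} ids, "
                f"{len(self.row_kinds)} kinds, {n} value rows"
            )
        if len(self.sample_ids) != m:
            raise ValueError(
                f"sample dimension mismatch: {len(self.sample_ids)} ids, {m} columns"
            )
        dup = _first_duplicate(self.row_ids)
        if dup is not None:
            raise ValueError(f"duplicate feature id: {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValueError(f"duplicate sample id: {dup!r}")
        for k in self.row_kinds:
            if k not in VALID_KINDS:
                raise ValueError(f"unknown molecule kind: {k!r}")
        for k, s in self.scales.items():
            if k not in VALID_KINDS or s not in VALID_SCALES:
                raise ValueError(f"invalid scale entry: {k!r} -> {s!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def kind_mask(self, kind: str) -> np.ndarray:
        return np.array([k == kind for k in self.row_kinds], dtype=bool)

    def subset_rows(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask, dtype=bool)
        ids = [r for r, keep in zip(self.row_ids, mask) if keep]
        kinds = [k for k, keep in zip(self.row_kinds, mask) if keep]
        kinds_present = set(kinds)
        return ExpressionMatrix(
            row_ids=ids,
            row_kinds=kinds,
            sample_ids=list(self.sample_ids),
            values=self.values[mask],
            scales={k: s for k, s in self.scales.items() if k in kinds_present},
        )

    def reorder_samples(self, order: list[str]) -> "ExpressionMatrix":
        if set(order) != set(self.sample_ids) or len(order) != len(self.sample_ids):
            raise ValueError("sample reorder must be a permutation of sample_ids")
        idx = [self.sample_ids.index(s) for s in order]
        return replace(self, sample_ids=list(order), values=self.values[:, idx])

    def with_values(self, values: np.ndarray, scales: dict[str, str] | None = None) -> "ExpressionMatrix":
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            scales=dict(scales) if scales is not None else dict(self.scales),
        )


@dataclass
class SampleMetadata:
    """Per-sample tumor grade and histotype with the four derived contrasts."""

    sample_ids: list[str]
    grade: dict[str, str]
    histotype: dict[str, str]

    def __post_init__(self) -> None:
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValueError(f"duplicate sample id in metadata: {dup!r}")
        for s in self.sample_ids:
            g = self.grade.get(s)
            h = self.histotype.get(s)
            if g not in GRADES:
                raise ValueError(f"unknown grade {g!r} for sample {s!r}")
            if h not in HISTOTYPES:
                raise ValueError(f"unknown histotype {h!r} for sample {s!r}")

    def check_covers(self, expression_samples: list[str]) -> None:
        missing = [s for s in expression_samples if s not in self.grade]
        if missing:
            raise ValueError(f"metadata missing samples: {missing}")

    def dichotomies(self, samples: list[str] | None = None) -> dict[str, dict[str, bool]]:
        """Return dichotomy name → {sample_id: in-class} for valid contrasts.

        A contrast whose two sides are not both non-empty is skipped with a
        warning.
        """
        samples = list(samples) if samples is not None else list(self.sample_ids)
        self.check_covers(samples)
        out: dict[str, dict[str, bool]] = {}
        candidates = {
            "grade": {s: self.grade[s] == "high" for s in samples},
            "anaplastic": {s: self.histotype[s] == "anaplastic" for s in samples},
            "glioblastoma": {s: self.histotype[s] == "glioblastoma" for s in samples},
            "gliosarcoma": {s: self.histotype[s] == "gliosarcoma" for s in samples},
        }
        for name, labels in candidates.items():
            k = sum(labels.values())
            if k == 0 or k == len(samples):
                warnings.warn(
                    f"contrast {name!r} does not split the samples; skipped",
                    stacklevel=2,
                )
                continue
            out[name] = labels
        return out


@dataclass
class GenomicCluster:
    """A set of co-located miRNAs on one chromosome (0-based half-open span)."""

    cluster_name: str
    chromosome: str
    member_ids: list[str]
    span: tuple[int, int]
    member_spans: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError(f"cluster {self.cluster_name!r} has no members")
        dup = _first_duplicate(self.member_ids)
        if dup is not None:
            raise ValueError(
                f"member {dup!r} listed twice in cluster {self.cluster_name!r}"
            )
        start, end = self.span
        if start >= end:
            raise ValueError(
                f"cluster {self.cluster_name!r} span {self.span} is empty"
            )
        for mid, (s, e) in self.member_spans.items():
            if s < start or e > end:
                raise ValueError(
                    f"member {mid!r} interval [{s}, {e}) outside cluster span {self.span}"
                )


@dataclass
class TermMap:
    """term_id → gene-id set, with optional human-readable descriptions."""

    terms: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene set")

    def terms_for_gene(self, gene: str) -> list[str]:
        return sorted(t for t, genes in self.terms.items() if gene in genes)


# ---------------------------------------------------------------------------
# expression tables


def _first_duplicate(items) -> str | None:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_expression_table(path, kind: str, scale: str) -> ExpressionMatrix:
    """Parse a delimited expression table (first column = feature id).

    Rows containing empty cells are dropped with a logged count; non-numeric
    cells and ragged rows raise with the offending location named.
    """
    if kind not in VALID_KINDS:
        raise ValueError(f"unknown molecule kind: {kind!r}")
    if scale not in VALID_SCALES:
        raise ValueError(f"unknown scale: {scale!r}")
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise ValueError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        header = next(csv.reader([first], delimiter=delim))
        sample_ids = [c.strip() for c in header[1:]]
        ncol = len(header)
        row_ids: list[str] = []
        rows: list[list[float]] = []
        dropped = 0
        for lineno, rec in enumerate(csv.reader(fh, delimiter=delim), start=2):
            if not rec or (len(rec) == 1 and not rec[0].strip()):
                continue
            rid = rec[0].strip()
            if len(rec) != ncol:
                raise ValueError(
                    f"{path}: row {rid!r} (line {lineno}) has {len(rec) - 1} "
                    f"values, expected {ncol - 1}"
                )
            cells = [c.strip() for c in rec[1:]]
            if any(c == "" or c.upper() in ("NA", "NAN") for c in cells):
                dropped += 1
                continue
            parsed = []
            for sample, c in zip(sample_ids, cells):
                try:
                    parsed.append(float(c))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {c!r} at row {rid!r}, "
                        f"sample {sample!r}"
                    ) from None
            row_ids.append(rid)
            rows.append(parsed)
    if dropped:
        logger.info("%s: dropped %d rows with missing values", path, dropped)
    return ExpressionMatrix(
        row_ids=row_ids,
        row_kinds=[kind] * len(row_ids),
        sample_ids=sample_ids,
        values=np.array(rows, dtype=float).reshape(len(rows), len(sample_ids)),
        scales={kind: scale},
    )


def write_expression_table(mat: ExpressionMatrix, path, sep: str = "\t") -> None:
    """Write a table that round-trips to the same floats (repr precision)."""
    with open(path, "w", newline="") as fh:
        fh.write(sep.join(["feature_id", *mat.sample_ids]) + "\n")
        for rid, row in zip(mat.row_ids, mat.values):
            fh.write(sep.join([rid, *(repr(float(v)) for v in row)]) + "\n")


# ---------------------------------------------------------------------------
# sample metadata


def read_sample_metadata(path) -> SampleMetadata:
    with open(path, newline="") as fh:
        first = fh.readline()
        delim = _sniff_delimiter(first)
        header = [c.strip() for c in next(csv.reader([first], delimiter=delim))]
        for col in ("sample_id", "grade", "histotype"):
            if col not in header:
                raise ValueError(f"{path}: missing required column {col!r}")
        idx = {c: header.index(c) for c in ("sample_id", "grade", "histotype")}
        sample_ids, grade, histotype = [], {}, {}
        for rec in csv.reader(fh, delimiter=delim):
            if not rec or (len(rec) == 1 and not rec[0].strip()):
                continue
            sid = rec[idx["sample_id"]].strip()
            g = rec[idx["grade"]].strip().lower()
            h = rec[idx["histotype"]].strip().lower()
            if g not in GRADES:
                raise ValueError(f"{path}: unknown grade {g!r} for sample {sid!r}")
            if h not in HISTOTYPES:
                raise ValueError(f"{path}: unknown histotype {h!r} for sample {sid!r}")
            sample_ids.append(sid)
            grade[sid] = g
            histotype[sid] = h
    return SampleMetadata(sample_ids=sample_ids, grade=grade, histotype=histotype)


def write_sample_metadata(meta: SampleMetadata, path, sep: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        fh.write(sep.join(["sample_id", "grade", "histotype"]) + "\n")
        for sid in meta.sample_ids:
            fh.write(sep.join([sid, meta.grade[sid], meta.histotype[sid]]) + "\n")


# ---------------------------------------------------------------------------
# genomic clusters (BED6+1 / GFF3)


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_mirna_clusters(path, cluster_key: str = "cluster") -> list[GenomicCluster]:
    """Read miRNA loci grouped into clusters from BED6+1 or GFF3.

    BED: columns chrom/start/end/name/score/strand plus a seventh column
    carrying the cluster tag (coordinates are 0-based half-open already).
    GFF3: 1-based inclusive coordinates converted on read; the member id is
    the ``ID`` (or ``Name``) attribute and the cluster tag is the attribute
    named by ``cluster_key``.
    """
    text = open(path).read()
    is_gff = str(path).endswith((".gff", ".gff3")) or text.lstrip().startswith("##gff")
    features: list[tuple[str, str, str, int, int]] = []  # (cluster, member, chrom, s, e)
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if is_gff:
            if len(cols) < 9:
                raise ValueError(f"{path}: line {lineno}: GFF3 needs 9 columns")
            chrom, start1, end1 = cols[0], int(cols[3]), int(cols[4])
            start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
            attrs = _parse_gff_attributes(cols[8])
            member = attrs.get("ID") or attrs.get("Name")
            if not member:
                raise ValueError(f"{path}: line {lineno}: feature lacks ID/Name")
            cluster = attrs.get(cluster_key)
            if not cluster:
                raise ValueError(
                    f"{path}: line {lineno}: feature lacks attribute {cluster_key!r}"
                )
        else:
            if len(cols) < 7:
                raise ValueError(
                    f"{path}: line {lineno}: BED needs 7 columns "
                    "(chrom start end name score strand cluster)"
                )
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            member, cluster = cols[3], cols[6]
        if start >= end:
            raise ValueError(
                f"{path}: line {lineno}: empty interval [{start}, {end}) for {member!r}"
            )
        features.append((cluster, member, chrom, start, end))

    by_cluster: dict[str, list[tuple[str, str, int, int]]] = {}
    member_home: dict[str, str] = {}
    for cluster, member, chrom, start, end in features:
        if member in member_home and member_home[member] != cluster:
            warnings.warn(
                f"miRNA {member!r} listed in clusters {member_home[member]!r} "
                f"and {cluster!r}; kept in both",
                stacklevel=2,
            )
        member_home.setdefault(member, cluster)
        by_cluster.setdefault(cluster, []).append((member, chrom, start, end))

    clusters = []
    for name, members in by_cluster.items():
        chroms = {chrom for _, chrom, _, _ in members}
        if len(chroms) > 1:
            raise ValueError(f"cluster {name!r} spans chromosomes {sorted(chroms)}")
        clusters.append(
            GenomicCluster(
                cluster_name=name,
                chromosome=next(iter(chroms)),
                member_ids=[m for m, _, _, _ in members],
                span=(min(s for _, _, s, _ in members), max(e for _, _, _, e in members)),
                member_spans={m: (s, e) for m, _, s, e in members},
            )
        )
    return clusters


def write_mirna_clusters_bed(clusters: list[GenomicCluster], path) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            for m in c.member_ids:
                s, e = c.member_spans.get(m, c.span)
                fh.write(f"{c.chromosome}\t{s}\t{e}\t{m}\t0\t+\t{c.cluster_name}\n")


# ---------------------------------------------------------------------------
# gene sets and target maps


def read_gmt(path) -> TermMap:
    terms: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT needs term, description, genes")
            term, desc, genes = cols[0], cols[1], [g for g in cols[2:] if g.strip()]
            if not genes:
                raise ValueError(f"{path}: line {lineno}: term {term!r} has no genes")
            terms[term] = set(genes)
            descriptions[term] = desc
    return TermMap(terms=terms, descriptions=descriptions)


def read_target_map(path) -> dict[str, set[str]]:
    """Two-column miRNA→target-gene table (no header, '#' comments)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t") if "\t" in line else line.split(",")
            if len(cols) != 2:
                raise ValueError(f"{path}: line {lineno}: expected two columns")
            out.setdefault(cols[0].strip(), set()).add(cols[1].strip())
    return out
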