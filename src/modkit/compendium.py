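"""Reading, merging, quality control and reference-centering of expression compendia.

The objects here carry gene-by-sample log-TPM matrices (as pandas DataFrames,
genes on the index, samples on the columns) together with a sample metadata
table describing the experimental design: project, condition, sampling time in
minutes, replicate label, and which samples serve as the normalization
reference. Downstream decomposition operates on *centered* matrices — per-gene
deviations from the mean of the reference samples — so that component
activities are expressed relative to an unperturbed baseline condition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleTable",
    "QCReport",
    "CenteredMatrix",
    "read_expression",
    "write_expression",
    "read_sample_table",
    "merge_datasets",
    "qc_replicates",
    "center_to_reference",
]

META_COLUMNS = ("sample_id", "project", "condition", "time_min", "replicate_id", "is_reference")


class ValidationError(ValueError):
    """Raised when an input matrix or metadata table violates its invariants."""


@dataclass
class ExpressionMatrix:
    """Gene × sample log-scale expression values.

    ``data`` has unique gene identifiers on the index and unique sample
    identifiers on the columns; every value is finite. Row/column order is
    significant and preserved by I/O round trips.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        dup_genes = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup_genes:
            raise ValidationError(f"duplicate gene identifiers: {dup_genes}")
        dup_samples = self.data.columns[self.data.columns.duplicated()].unique().tolist()
        if dup_samples:
            raise ValidationError(f"duplicate sample identifiers: {dup_samples}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def restrict(self, genes=None, samples=None) -> "ExpressionMatrix":
        """Sub-matrix in the given gene/sample order (defaults keep all)."""
        d = self.data
        if genes is not None:
            d = d.loc[list(genes)]
        if samples is not None:
            d = d[list(samples)]
        return ExpressionMatrix(d.copy())


@dataclass
class SampleTable:
    """Per-sample experimental design metadata.

    Required columns: sample_id, project, condition, time_min, replicate_id,
    is_reference. ``mapped_reads`` is optional. ``time_min`` may be missing
    (NaN) for samples outside a time course.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"sample table missing columns: {missing}")
        self.data = self.data.copy()
        self.data["sample_id"] = self.data["sample_id"].astype(str)
        dup = self.data["sample_id"][self.data["sample_id"].duplicated()].unique().tolist()
        if dup:
            raise ValidationError(f"duplicate sample_id entries: {dup}")
        self.data["is_reference"] = self.data["is_reference"].map(_parse_bool)
        triples = self.data[["project", "condition", "time_min", "replicate_id"]]
        if triples.duplicated().any():
            bad = triples[triples.duplicated()].iloc[0].tolist()
            raise ValidationError(
                f"(condition, time_min, replicate_id) not unique within project: {bad}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    def reference_samples(self) -> list[str]:
        return self.data.loc[self.data["is_reference"], "sample_id"].tolist()

    def replicate_groups(self) -> dict[tuple, list[str]]:
        """Samples grouped by (project, condition, time_min)."""
        groups: dict[tuple, list[str]] = {}
        for _, row in self.data.iterrows():
            key = (row["project"], row["condition"], row["time_min"])
            groups.setdefault(key, []).append(row["sample_id"])
        return groups

    def subset(self, sample_ids) -> "SampleTable":
        keep = self.data["sample_id"].isin(set(map(str, sample_ids)))
        return SampleTable(self.data[keep].reset_index(drop=True))


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, (int, np.integer, float)):
        return bool(v)
    s = str(v).strip().lower()
    if s in {"true", "t", "1", "yes"}:
        return True
    if s in {"false", "f", "0", "no", ""}:
        return False
    raise ValidationError(f"cannot interpret is_reference value {v!r} as boolean")


@dataclass
class QCReport:
    """Outcome of replicate-correlation / mapped-read quality control."""

    replicate_correlation: dict[str, float]  # best within-group Pearson r, NaN if none
    reads_pass: dict[str, bool]
    removed_samples: list[tuple[str, list[str]]]  # (sample_id, reasons)
    uncheckable: list[str] = field(default_factory=list)

    @property
    def removed_ids(self) -> list[str]:
        return [s for s, _ in self.removed_samples]

    def retained(self, all_samples) -> list[str]:
        removed = set(self.removed_ids)
        return [s for s in all_samples if s not in removed]


@dataclass
class CenteredMatrix:
    """Gene × sample deviations from the mean of the reference samples.

    Shares gene/sample ordering with its source ExpressionMatrix; per gene,
    the mean over ``reference_samples`` columns is zero.
    """

    data: pd.DataFrame
    reference_samples: list[str]

    @property
    def genes(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy()


def read_expression(path, fmt: str = "tsv") -> ExpressionMatrix:
    """Read a gene × sample expression TSV (first column gene IDs, header samples)."""
    sep = {"tsv": "\t", "csv": ","}[fmt]
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.index.name = "gene_id"
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad.to_numpy().argmax()]
            raise ValidationError(
                f"non-numeric value {raw.loc[gene, col]!r} at gene {gene!r}, sample {col!r}"
            )
        numeric[col] = converted
    return ExpressionMatrix(numeric)


def write_expression(x: ExpressionMatrix | CenteredMatrix, path, fmt: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[fmt]
    df = x.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep=sep)


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t")
    return SampleTable(df)


def write_sample_table(meta: SampleTable, path) -> None:
    meta.data.to_csv(path, sep="\t", index=False)


def merge_datasets(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    policy: str = "union",
    fill_value: float = 0.0,
    names: tuple[str, str] = ("a", "b"),
) -> tuple[ExpressionMatrix, dict[str, set[str]]]:
    """Merge two compendia with partially disjoint gene universes.

    ``union`` keeps every gene, filling genes absent from one dataset with
    ``fill_value`` (0 on the log scale, applied before centering) for that
    dataset's samples; ``intersection`` keeps only shared genes. The returned
    ``dataset_gene_sets`` maps each dataset name to its native gene universe so
    that artifact screening can test dataset exclusivity of component members.
    """
    collisions = sorted(set(a.samples) & set(b.samples))
    if collisions:
        raise ValidationError(f"overlapping sample IDs between datasets: {collisions}")
    genes_a, genes_b = set(a.genes), set(b.genes)
    if policy == "union":
        # keep A's gene order, then B-only genes in B's order
        merged_genes = list(a.genes) + [g for g in b.genes if g not in genes_a]
        da = a.data.reindex(merged_genes).fillna(fill_value)
        db = b.data.reindex(merged_genes).fillna(fill_value)
    elif policy == "intersection":
        merged_genes = [g for g in a.genes if g in genes_b]
        da = a.data.loc[merged_genes]
        db = b.data.loc[merged_genes]
    else:
        raise ValueError(f"unknown merge policy {policy!r}")
    merged = ExpressionMatrix(pd.concat([da, db], axis=1))
    return merged, {names[0]: genes_a, names[1]: genes_b}


def _pairwise_pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson r over positions finite in both vectors."""
    ok = np.isfinite(u) & np.isfinite(v)
    if ok.sum() < 2:
        return np.nan
    uu, vv = u[ok], v[ok]
    if uu.std() == 0 or vv.std() == 0:
        return np.nan
    return float(np.corrcoef(uu, vv)[0, 1])


def qc_replicates(
    x: ExpressionMatrix,
    meta: SampleTable,
    min_corr: float = 0.95,
    min_reads: float = 500_000,
) -> QCReport:
    """Flag samples with low mapped reads or poor replicate correlation.

    Two-stage: samples failing the mapped-read check (when ``mapped_reads`` is
    present in the metadata) are removed first; replicate correlation is then
    assessed among the survivors of each (project, condition, time_min) group.
    A surviving sample fails if its best Pearson correlation against any
    same-group survivor is below ``min_corr``. Groups reduced to a single
    sample are reported as "uncheckable" and retained.
    """
    if x.data.size == 0:
        raise ValidationError("empty expression matrix")
    orphans = sorted(set(x.samples) ^ set(meta.sample_ids))
    if orphans:
        raise ValidationError(f"samples present in only one of matrix/metadata: {orphans}")

    reads_pass: dict[str, bool] = {}
    removed: dict[str, list[str]] = {}
    has_reads = "mapped_reads" in meta.data.columns
    for _, row in meta.data.iterrows():
        sid = row["sample_id"]
        if has_reads and pd.notna(row["mapped_reads"]):
            ok = float(row["mapped_reads"]) >= min_reads
        else:
            ok = True
        reads_pass[sid] = ok
        if not ok:
            removed.setdefault(sid, []).append("low mapped reads")

    best_corr: dict[str, float] = {}
    uncheckable: list[str] = []
    values = x.data
    for _, members in sorted(meta.replicate_groups().items(), key=lambda kv: repr(kv[0])):
        survivors = [s for s in members if s not in removed]
        if len(survivors) == 1:
            uncheckable.append(survivors[0])
            best_corr[survivors[0]] = np.nan
            continue
        cols = {s: values[s].to_numpy() for s in survivors}
        for s in survivors:
            rs = [_pairwise_pearson(cols[s], cols[t]) for t in survivors if t != s]
            rs = [r for r in rs if np.isfinite(r)]
            best = max(rs) if rs else np.nan
            best_corr[s] = best
            if np.isfinite(best) and best < min_corr:
                removed.setdefault(s, []).append("replicate correlation")

    removed_list = [(s, removed[s]) for s in meta.sample_ids if s in removed]
    return QCReport(
        replicate_correlation=best_corr,
        reads_pass=reads_pass,
        removed_samples=removed_list,
        uncheckable=sorted(uncheckable),
    )


def center_to_reference(
    x: ExpressionMatrix | CenteredMatrix,
    meta: SampleTable | None = None,
    reference_samples: list[str] | None = None,
) -> CenteredMatrix:
    """Subtract, per gene, the mean over reference samples from every column.

    The reference set comes from an explicit ``reference_samples`` list or the
    metadata ``is_reference`` flags. Centering an already-centered matrix with
    the same reference set is a no-op.
    """
    if reference_samples is None:
        if meta is None:
            raise ValidationError("provide a SampleTable or an explicit reference list")
        reference_samples = meta.reference_samples()
    reference_samples = [str(s) for s in reference_samples]
    if not reference_samples:
        raise ValidationError(
            "no reference samples: set is_reference in the metadata or pass "
            "an explicit reference_samples list"
        )
    missing = [s for s in reference_samples if s not in x.data.columns]
    if missing:
        raise ValidationError(f"reference samples absent from matrix: {missing}")
    ref_mean = x.data[reference_samples].mean(axis=1)
    centered = x.data.sub(ref_mean, axis=0)
    return CenteredMatrix(centered, reference_samples=list(reference_samples))
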