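"""From components to iModulons: membership, explained variance, enrichment, artifacts.

An iModulon is one column of the M matrix promoted to an annotated gene set:
member genes are those whose weights stand out from the near-Gaussian bulk of
the weight distribution (membership is sign-blind — strongly negative weights
are members too), the component is named after the transcriptional regulator
whose regulon it is most enriched in, and its contribution to expression
variation is quantified as the fraction of the (optionally sample-restricted)
centered matrix's squared Frobenius norm removed by its rank-one
reconstruction. Components whose members are exclusively genes present in only
one of two merged datasets are flagged as merge artifacts rather than biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .compendium import CenteredMatrix
from .decomposition import IcaResults

__all__ = [
    "IModulon",
    "TrnTable",
    "EnrichmentRecord",
    "threshold_genes",
    "explained_variance",
    "enrich_regulons",
    "detect_artifacts",
    "build_catalog",
]


@dataclass
class TrnTable:
    """Regulator → gene annotation pairs (one row per pair, no duplicates)."""

    pairs: pd.DataFrame  # columns: regulator, gene_id

    def __post_init__(self) -> None:
        missing = [c for c in ("regulator", "gene_id") if c not in self.pairs.columns]
        if missing:
            raise ValueError(f"TRN table missing columns: {missing}")
        self.pairs = self.pairs.drop_duplicates(["regulator", "gene_id"]).reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "TrnTable":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_regulons(cls, regulons: dict[str, set[str]]) -> "TrnTable":
        rows = [(r, g) for r, genes in regulons.items() for g in sorted(genes)]
        return cls(pd.DataFrame(rows, columns=["regulator", "gene_id"]))

    def regulons(self) -> dict[str, set[str]]:
        return {r: set(sub["gene_id"]) for r, sub in self.pairs.groupby("regulator")}


@dataclass
class EnrichmentRecord:
    regulator: str
    overlap: int
    p_value: float
    q_value: float
    precision: float
    recall: float
    f1: float


@dataclass
class IModulon:
    """One annotated component of the decomposition."""

    component_id: str
    gene_weights: pd.Series
    members: set[str]
    threshold: float
    name: str = ""
    category: str = "uncharacterized"
    enrichments: list[EnrichmentRecord] = field(default_factory=list)
    explained_variance_global: float = np.nan
    explained_variance_subset: dict[str, float] = field(default_factory=dict)
    artifact_flag: bool = False
    artifact_reason: str = ""

    @property
    def n_members(self) -> int:
        return len(self.members)


def threshold_genes(
    weights: pd.Series,
    cutoff_stat: float = 100.0,
) -> tuple[set[str], float]:
    """Sign-blind member selection by iterative outlier removal.

    Weights are median-centered, then the gene with the largest absolute
    weight is peeled off repeatedly until the D'Agostino K² normality
    statistic of the remaining weights drops below ``cutoff_stat``; the peeled
    genes are the members. The returned threshold is the largest absolute
    weight among non-members, so members are exactly the genes with
    |weight − median| above it. Equal-|weight| ties are broken toward the gene
    that comes first in the input order.
    """
    if len(weights) < 20:
        raise ValueError("need at least 20 genes for the K² normality statistic")
    w = weights - weights.median()
    order = np.lexsort((np.arange(len(w)), -np.abs(w.to_numpy())))  # |w| desc, stable
    abs_sorted = np.abs(w.to_numpy())[order]
    members: list[str] = []
    remaining = w.to_numpy()[order]
    for i in range(len(order)):
        tail = remaining[i:]
        if len(tail) < 8:  # normaltest needs n >= 8; everything removed
            members = list(weights.index[order])
            import warnings

            warnings.warn("thresholding removed (nearly) all genes; returning all as members")
            return set(members), 0.0
        stat, _ = stats.normaltest(tail)
        if stat < cutoff_stat:
            threshold = abs_sorted[i] if i < len(order) else 0.0
            return set(weights.index[order[:i]]), float(threshold)
    return set(weights.index[order]), 0.0


def explained_variance(
    x: CenteredMatrix,
    results: IcaResults,
    component_id: str,
    sample_subset: list[str] | None = None,
) -> float:
    """Fraction of ‖x_S‖² removed by the component's rank-one reconstruction.

    Returns 1 − ‖x_S − m·a_S‖²_F / ‖x_S‖²_F over sample subset S (default all
    samples), clipped at 0 when the rank-one term increases the residual.
    """
    if component_id not in results.component_ids:
        raise KeyError(f"unknown component {component_id!r}")
    cols = list(sample_subset) if sample_subset is not None else x.samples
    xs = x.data[cols].to_numpy()
    denom = float((xs**2).sum())
    if denom == 0:
        raise ValueError("subset has zero variance; explained fraction undefined")
    m = results.M[component_id].to_numpy()[:, None]
    a = results.A.loc[component_id, cols].to_numpy()[None, :]
    resid = xs - m @ a
    return max(0.0, 1.0 - float((resid**2).sum()) / denom)


def explained_variance_joint(
    x: CenteredMatrix,
    results: IcaResults,
    component_ids: list[str] | None = None,
    sample_subset: list[str] | None = None,
) -> float:
    """Joint explained variance of several components via least-squares fit."""
    ids = component_ids if component_ids is not None else results.component_ids
    cols = list(sample_subset) if sample_subset is not None else x.samples
    xs = x.data[cols].to_numpy()
    denom = float((xs**2).sum())
    if denom == 0:
        raise ValueError("subset has zero variance; explained fraction undefined")
    M = results.M[ids].to_numpy()
    A, *_ = np.linalg.lstsq(M, xs, rcond=None)
    resid = xs - M @ A
    return max(0.0, 1.0 - float((resid**2).sum()) / denom)


def enrich_regulons(
    members: set[str],
    trn: TrnTable,
    universe: set[str],
) -> list[EnrichmentRecord]:
    """One-sided Fisher's exact enrichment of members against each regulon.

    Each regulon is intersected with the gene universe; the 2×2 table is
    (member∩regulon, member\\regulon, regulon\\member, rest). P-values are
    BH-corrected across the tested regulators; records come back sorted by
    descending F1 (ties by ascending p).
    """
    members = set(members)
    if not members:
        return []
    stray = members - set(universe)
    if stray:
        raise ValueError(f"members outside the gene universe: {sorted(stray)[:5]}")
    n_universe = len(universe)
    records = []
    for regulator, regulon in sorted(trn.regulons().items()):
        regulon = regulon & set(universe)
        if not regulon:
            continue
        overlap = len(members & regulon)
        table = [
            [overlap, len(members) - overlap],
            [len(regulon) - overlap, n_universe - len(members) - len(regulon) + overlap],
        ]
        _, p = stats.fisher_exact(table, alternative="greater")
        precision = overlap / len(members)
        recall = overlap / len(regulon)
        f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
        records.append((regulator, overlap, float(p), precision, recall, f1))
    if not records:
        return []
    qs = multipletests([r[2] for r in records], method="fdr_bh")[1]
    out = [
        EnrichmentRecord(reg, ov, p, float(q), prec, rec, f1)
        for (reg, ov, p, prec, rec, f1), q in zip(records, qs)
    ]
    out.sort(key=lambda r: (-r.f1, r.p_value, r.regulator))
    return out


def detect_artifacts(
    imodulons: list[IModulon],
    dataset_gene_sets: dict[str, set[str]],
) -> list[IModulon]:
    """Flag components whose members are exclusively dataset-exclusive genes.

    With two merged gene universes, a component whose (non-empty) member set
    lies entirely in the symmetric difference of the universes reflects the
    merge, not biology; it is flagged and retained, to be excluded by default
    downstream.
    """
    names = sorted(dataset_gene_sets)
    if len(names) != 2:
        raise ValueError("artifact screening needs exactly two dataset gene sets")
    sym_diff = dataset_gene_sets[names[0]] ^ dataset_gene_sets[names[1]]
    for im in imodulons:
        if im.members and im.members <= sym_diff:
            im.artifact_flag = True
            im.artifact_reason = "dataset-exclusive genes"
    return imodulons


def _assign_names(imodulons: list[IModulon], q_cutoff: float = 0.05) -> None:
    counts: dict[str, int] = {}
    unchar = 0
    for im in imodulons:
        best = next((e for e in im.enrichments if e.q_value < q_cutoff and e.overlap > 0), None)
        if best is None:
            unchar += 1
            im.name = f"Unchar_{unchar}"
        else:
            counts[best.regulator] = counts.get(best.regulator, 0) + 1
            n = counts[best.regulator]
            im.name = best.regulator if n == 1 else f"{best.regulator}-{n}"


def build_catalog(
    x: CenteredMatrix,
    results: IcaResults,
    trn: TrnTable | None = None,
    dataset_gene_sets: dict[str, set[str]] | None = None,
    sample_subsets: dict[str, list[str]] | None = None,
    cutoff_stat: float = 100.0,
    categories: dict[str, str] | None = None,
) -> list[IModulon]:
    """Threshold, annotate and screen every component of a fitted decomposition."""
    universe = set(x.genes)
    imodulons = []
    for cid in results.component_ids:
        weights = results.M[cid]
        members, threshold = threshold_genes(weights, cutoff_stat=cutoff_stat)
        im = IModulon(component_id=cid, gene_weights=weights, members=members, threshold=threshold)
        if trn is not None and members:
            im.enrichments = enrich_regulons(members, trn, universe)
        im.explained_variance_global = explained_variance(x, results, cid)
        for label, cols in (sample_subsets or {}).items():
            im.explained_variance_subset[label] = explained_variance(x, results, cid, cols)
        imodulons.append(im)
    _assign_names(imodulons)
    if categories:
        for im in imodulons:
            im.category = categories.get(im.name, categories.get(im.component_id, im.category))
    if dataset_gene_sets is not None:
        detect_artifacts(imodulons, dataset_gene_sets)
    return imodulons


def catalog_table(imodulons: list[IModulon]) -> pd.DataFrame:
    """Flat per-iModulon summary table (one row per component)."""
    rows = []
    for im in imodulons:
        row = {
            "component_id": im.component_id,
            "name": im.name,
            "category": im.category,
            "n_members": im.n_members,
            "threshold": im.threshold,
            "EV_global": im.explained_variance_global,
            "artifact_flag": im.artifact_flag,
        }
        for label, ev in im.explained_variance_subset.items():
            row[f"EV_{label}"] = ev
        rows.append(row)
    return pd.DataFrame(rows)
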