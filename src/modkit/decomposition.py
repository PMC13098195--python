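"""Robust independent component analysis of a centered expression matrix.

The centered matrix X (gene × sample) is factored as X ≈ M · A, where the
columns of M are gene-weight vectors of independently modulated gene sets and
the rows of A are their activities across samples. A single FastICA run is not
reproducible across random restarts, so the robust procedure pools components
from many seeded restarts, clusters them by the correlation of their gene
weights, and keeps only clusters reproduced in a sufficient fraction of runs.
The retained M columns are sign-aligned cluster centroids, re-normalized to
unit L2 norm; A is recomputed by least squares so that M·A is the best
reconstruction of X in the retained subspace.

Conventions: every M column has unit L2 norm (all magnitude lives in A, in
log-TPM deviation units) and non-negative weight skewness; when skewness is
numerically zero the largest-magnitude weight is made positive.

Usage follows the model/results pattern::

    model = RobustICA(xc, k=15, n_runs=50)
    res = model.fit(seed=42)
    res.M, res.A, res.cluster_support
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import DBSCAN
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .compendium import CenteredMatrix

__all__ = ["RobustICA", "IcaResults", "DimensionScan", "run_ica_once", "select_dimension"]


def _orient_and_normalize(components: np.ndarray, mixing: np.ndarray | None = None):
    """Unit-norm columns, skew-positive orientation; rescale mixing to match."""
    comps = components.copy()
    mix = None if mixing is None else mixing.copy()
    for j in range(comps.shape[1]):
        norm = np.linalg.norm(comps[:, j])
        if norm == 0:
            continue
        comps[:, j] /= norm
        if mix is not None:
            mix[j, :] *= norm
        skew = stats.skew(comps[:, j])
        if abs(skew) < 1e-6:
            flip = comps[np.argmax(np.abs(comps[:, j])), j] < 0
        else:
            flip = skew < 0
        if flip:
            comps[:, j] *= -1
            if mix is not None:
                mix[j, :] *= -1
    return comps, mix


def run_ica_once(
    x: CenteredMatrix,
    k: int,
    seed: int,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """One FastICA run: returns (components gene × k, mixing k × sample, converged).

    Components are column-normalized and sign-oriented; components @ mixing
    approximates x. Deterministic for a given seed. Non-convergence yields a
    warning but the run still contributes components.
    """
    values = x.values()
    n_genes, n_samples = values.shape
    if k >= min(n_genes, n_samples):
        raise ValueError(f"k={k} must be < min(genes, samples) = {min(n_genes, n_samples)}")
    if not np.isfinite(values).all():
        raise ValueError("centered matrix contains non-finite values")
    ica = FastICA(
        n_components=k,
        whiten="unit-variance",
        fun="logcosh",
        max_iter=max_iter,
        tol=tol,
        random_state=int(seed),
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(values)  # genes × k
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
    mixing = ica.mixing_.T  # k × samples
    comps, mix = _orient_and_normalize(sources, mixing)
    return comps, mix, converged


@dataclass
class IcaResults:
    """Fitted robust decomposition X ≈ M·A.

    M: gene × component weights (unit-norm, skew-positive columns);
    A: component × sample activities; cluster_support: fraction of restarts
    in which each retained component appeared.
    """

    M: pd.DataFrame
    A: pd.DataFrame
    k: int
    n_runs: int
    support_frac: float
    cluster_support: pd.Series
    seeds: list[int]
    n_converged: int
    model: "RobustICA"

    @property
    def component_ids(self) -> list[str]:
        return self.M.columns.tolist()

    @property
    def n_components(self) -> int:
        return self.M.shape[1]

    def reconstruction(self) -> pd.DataFrame:
        return self.M @ self.A

    def explained_variance_total(self) -> float:
        x = self.model.x.values()
        resid = x - self.M.to_numpy() @ self.A.to_numpy()
        denom = float((x**2).sum())
        return max(0.0, 1.0 - float((resid**2).sum()) / denom) if denom else 0.0

    def summary(self) -> str:
        lines = [
            "Robust ICA decomposition",
            "=" * 60,
            f"genes: {self.M.shape[0]}   samples: {self.A.shape[1]}",
            f"requested k: {self.k}   retained components: {self.n_components}",
            f"restarts: {self.n_runs} ({self.n_converged} converged)   "
            f"support threshold: {self.support_frac}",
            f"total explained variance: {self.explained_variance_total():.3f}",
            "-" * 60,
            f"{'component':<12}{'support':>8}{'|A| max':>10}",
        ]
        amax = self.A.abs().max(axis=1)
        for cid in self.component_ids:
            lines.append(f"{cid:<12}{self.cluster_support[cid]:>8.2f}{amax[cid]:>10.2f}")
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        m = self.M.copy()
        m.index.name = "gene_id"
        m.to_csv(out / "M.tsv", sep="\t")
        a = self.A.copy()
        a.index.name = "component_id"
        a.to_csv(out / "A.tsv", sep="\t")
        meta = {
            "k": self.k,
            "n_runs": self.n_runs,
            "support_frac": self.support_frac,
            "seeds": self.seeds,
            "n_converged": self.n_converged,
            "cluster_support": self.cluster_support.to_dict(),
        }
        (out / "model.json").write_text(json.dumps(meta, indent=2))


@dataclass
class DimensionScan:
    """Grid search over candidate dimensionalities."""

    grid: list[int]
    robust_counts: list[int]
    single_gene_counts: list[int]
    chosen_k: int

    def summary(self) -> str:
        lines = [f"{'k':>6}{'robust':>8}{'single-gene':>13}{'score':>8}"]
        for k, r, s in zip(self.grid, self.robust_counts, self.single_gene_counts):
            mark = "  <- chosen" if k == self.chosen_k else ""
            lines.append(f"{k:>6}{r:>8}{s:>13}{r - s:>8}{mark}")
        return "\n".join(lines)


class RobustICA:
    """Consensus ICA model over many seeded restarts.

    Parameters
    ----------
    x : CenteredMatrix
        Reference-centered log-TPM deviations, genes × samples.
    k : int
        Number of components requested per restart; must be below
        min(n_genes, n_samples).
    n_runs : int
        Number of FastICA restarts pooled into the consensus (>= 2).
    support_frac : float
        Minimum fraction of restarts a component cluster must appear in to be
        retained.
    eps : float
        DBSCAN radius on the 1 - |Pearson r| gene-weight distance.
    """

    def __init__(
        self,
        x: CenteredMatrix,
        k: int,
        n_runs: int = 50,
        support_frac: float = 0.5,
        eps: float = 0.1,
        max_iter: int = 1000,
        tol: float = 1e-6,
    ) -> None:
        if n_runs < 2:
            raise ValueError("n_runs must be >= 2 for a robust consensus")
        if not 0 < support_frac <= 1:
            raise ValueError("support_frac must lie in (0, 1]")
        self.x = x
        self.k = int(k)
        self.n_runs = int(n_runs)
        self.support_frac = float(support_frac)
        self.eps = float(eps)
        self.max_iter = max_iter
        self.tol = tol

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, reference_samples=None, **kwargs) -> "RobustICA":
        """Build from an already-centered genes × samples DataFrame."""
        return cls(CenteredMatrix(df, reference_samples=list(reference_samples or [])), **kwargs)

    def fit(self, seed: int = 0) -> IcaResults:
        rng = np.random.default_rng(seed)
        seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=self.n_runs)]
        values = self.x.values()

        pooled: list[np.ndarray] = []
        run_of: list[int] = []
        n_converged = 0
        for run_idx, s in enumerate(seeds):
            comps, _, converged = run_ica_once(
                self.x, self.k, s, max_iter=self.max_iter, tol=self.tol
            )
            n_converged += converged
            for j in range(comps.shape[1]):
                pooled.append(comps[:, j])
                run_of.append(run_idx)
        P = np.column_stack(pooled)  # genes × (n_runs * k)
        run_of_arr = np.asarray(run_of)

        # distance 1 - |r| between pooled gene-weight vectors
        corr = np.corrcoef(P.T)
        dist = np.clip(1.0 - np.abs(corr), 0.0, None)
        np.fill_diagonal(dist, 0.0)
        min_size = int(np.ceil(self.support_frac * self.n_runs))
        labels = DBSCAN(eps=self.eps, min_samples=min_size, metric="precomputed").fit_predict(dist)

        centroids: list[np.ndarray] = []
        supports: list[float] = []
        for lab in sorted(set(labels) - {-1}):
            idx = np.flatnonzero(labels == lab)
            support = len(set(run_of_arr[idx])) / self.n_runs
            if support < self.support_frac:
                continue
            ref = P[:, idx[0]]
            aligned = [P[:, i] * np.sign(np.dot(P[:, i], ref) or 1.0) for i in idx]
            centroid = np.mean(aligned, axis=0)
            centroids.append(centroid)
            supports.append(support)
        if not centroids:
            raise ValueError(
                "no component cluster reached the support threshold; "
                "lower k or support_frac"
            )
        M, _ = _orient_and_normalize(np.column_stack(centroids))
        # one alternating-least-squares sweep: FastICA's internal per-sample
        # centering leaves centroids offset from the data's row space, so
        # refit the weights against their own activities before the final
        # activity projection; X ≈ M·A is then exact in the retained subspace
        A, *_ = np.linalg.lstsq(M, values, rcond=None)
        M_ref, *_ = np.linalg.lstsq(A.T, values.T, rcond=None)
        M, _ = _orient_and_normalize(M_ref.T)
        A, *_ = np.linalg.lstsq(M, values, rcond=None)

        # deterministic ordering: explained magnitude, descending
        order = np.argsort(-(A**2).sum(axis=1), kind="stable")
        M = M[:, order]
        A = A[order]
        supports = [supports[i] for i in order]

        ids = [f"IC_{i + 1:03d}" for i in range(M.shape[1])]
        M_df = pd.DataFrame(M, index=self.x.genes, columns=ids)
        A_df = pd.DataFrame(A, index=ids, columns=self.x.samples)
        return IcaResults(
            M=M_df,
            A=A_df,
            k=self.k,
            n_runs=self.n_runs,
            support_frac=self.support_frac,
            cluster_support=pd.Series(supports, index=ids),
            seeds=seeds,
            n_converged=n_converged,
            model=self,
        )


def _is_single_gene(weights: np.ndarray, dominance_frac: float = 0.3) -> bool:
    w2 = weights**2
    return bool(w2.max() > dominance_frac * w2.sum())


def select_dimension(
    x: CenteredMatrix,
    grid: list[int],
    n_runs: int = 10,
    seed: int = 0,
    support_frac: float = 0.5,
    dominance_frac: float = 0.3,
) -> DimensionScan:
    """Pick a dimensionality from a candidate grid.

    For each k the robust decomposition is fitted and two counts taken: the
    number of retained (robust) components, and how many of those are
    "single-gene" components in which one gene carries more than
    ``dominance_frac`` of the squared weight. The chosen k maximizes
    robust − single-gene, ties resolved toward the smallest k.
    """
    if not grid:
        raise ValueError("empty dimensionality grid")
    grid = sorted(int(k) for k in grid)
    robust_counts, single_counts = [], []
    for k in grid:
        try:
            res = RobustICA(x, k=k, n_runs=n_runs, support_frac=support_frac).fit(seed=seed)
        except ValueError:
            robust_counts.append(0)
            single_counts.append(0)
            continue
        robust_counts.append(res.n_components)
        M = res.M.to_numpy()
        single_counts.append(
            sum(_is_single_gene(M[:, j], dominance_frac) for j in range(M.shape[1]))
        )
    scores = [r - s for r, s in zip(robust_counts, single_counts)]
    chosen = grid[int(np.argmax(scores))]  # argmax takes the first (smallest k) on ties
    return DimensionScan(grid, robust_counts, single_counts, chosen)
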