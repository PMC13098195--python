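"""Differential iModulon activity and temporal phase classification.

The differential test (DiMA) compares the mean activity of each component
between two conditions against a component-specific null distribution fitted
to the spread of activities between biological replicates: absolute
replicate-to-replicate activity differences, pooled over all replicate groups,
are fitted with a log-normal law by maximum likelihood, and the p-value of an
observed absolute mean difference is that law's survival function. P-values
are Benjamini-Hochberg corrected across components, and a component is called
significant only under the dual rule: absolute difference above ``diff_threshold``
(default 5 activity units) AND FDR-adjusted p below ``fdr_threshold``
(default 0.01).

Time-course activity profiles are additionally classified into a three-phase
vocabulary by correlation against unit templates on the sampling grid:

* primary   — immediate step up at the first post-exposure point, sustained;
* secondary — transient pulse peaking mid-course, mostly back to baseline by
  the end of the course;
* tertiary  — late monotone ramp beginning mid-course and maximal at the final
  time point.

A profile is assigned the best-correlating template when that correlation
reaches ``corr_threshold`` (default 0.7), else it stays unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .compendium import SampleTable

__all__ = [
    "ReplicateNull",
    "DimaRecord",
    "PhaseAssignment",
    "fit_replicate_null",
    "dima_test",
    "condition_profiles",
    "cluster_profiles",
    "phase_templates",
    "classify_phase",
]

PHASES = ("primary", "secondary", "tertiary")


@dataclass
class ReplicateNull:
    """Log-normal null for one component's replicate-to-replicate |Δactivity|."""

    component_id: str
    mu: float
    sigma: float
    n_pairs: int
    degenerate: bool = False

    def sf(self, abs_diff: float) -> float:
        """Survival function of the null at an observed absolute difference."""
        if self.degenerate:
            return 1.0
        if abs_diff <= 0:
            return 1.0
        return float(stats.lognorm.sf(abs_diff, s=self.sigma, scale=np.exp(self.mu)))


@dataclass
class DimaRecord:
    component_id: str
    mean_a: float
    mean_b: float
    abs_diff: float
    p_value: float
    q_value: float
    significant: bool


@dataclass
class PhaseAssignment:
    component_id: str
    profile: pd.Series  # activity indexed by time (minutes)
    phase: str  # primary | secondary | tertiary | unclassified
    template_correlation: float
    cluster_id: int = -1


def _replicate_pairs(meta: SampleTable) -> list[tuple[str, str]]:
    pairs = []
    for _, members in sorted(meta.replicate_groups().items(), key=lambda kv: repr(kv[0])):
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.append((members[i], members[j]))
    return pairs


def fit_replicate_null(
    a: pd.DataFrame,
    meta: SampleTable,
    min_diff: float = 1e-8,
) -> list[ReplicateNull]:
    """Fit each component's log-normal replicate null by maximum likelihood.

    ``a`` is the component × sample activity matrix. Absolute within-group
    activity differences are pooled over every replicate group (all pairwise
    combinations within a group of size n contribute n(n-1)/2 values);
    differences below ``min_diff`` are dropped before fitting. A component
    whose usable differences are too few or essentially constant gets a
    degenerate null whose tests return p = 1.
    """
    pairs = [(s, t) for s, t in _replicate_pairs(meta) if s in a.columns and t in a.columns]
    if not pairs:
        raise ValueError("no replicate groups of size >= 2 in the metadata")
    nulls = []
    for cid in a.index:
        diffs = np.abs([a.loc[cid, s] - a.loc[cid, t] for s, t in pairs])
        usable = diffs[diffs >= min_diff]
        if len(usable) < 2:
            nulls.append(ReplicateNull(cid, mu=0.0, sigma=0.0, n_pairs=len(diffs), degenerate=True))
            continue
        logs = np.log(usable)
        mu = float(logs.mean())
        sigma = float(logs.std(ddof=0))  # MLE
        degenerate = sigma < 1e-6
        nulls.append(
            ReplicateNull(cid, mu=mu, sigma=sigma, n_pairs=len(diffs), degenerate=degenerate)
        )
    return nulls


def dima_test(
    a: pd.DataFrame,
    meta: SampleTable,
    cond_a: str,
    cond_b: str,
    nulls: list[ReplicateNull],
    diff_threshold: float = 5.0,
    fdr_threshold: float = 0.01,
) -> list[DimaRecord]:
    """Differential activity of every component between two conditions.

    Condition means are taken over all samples carrying each condition label;
    the absolute difference of means is scored against the component's
    replicate null; BH correction runs across the components of this
    comparison; significance requires both |Δ| > diff_threshold and
    q < fdr_threshold.
    """
    null_by_id = {n.component_id: n for n in nulls}
    missing = [cid for cid in a.index if cid not in null_by_id]
    if missing:
        raise ValueError(f"components without a fitted replicate null: {missing}")
    samples_a = meta.data.loc[meta.data["condition"] == cond_a, "sample_id"].tolist()
    samples_b = meta.data.loc[meta.data["condition"] == cond_b, "sample_id"].tolist()
    for cond, cols in ((cond_a, samples_a), (cond_b, samples_b)):
        if not cols:
            raise ValueError(f"condition {cond!r} has no samples in the metadata")
    records = []
    for cid in a.index:
        mean_a = float(a.loc[cid, samples_a].mean())
        mean_b = float(a.loc[cid, samples_b].mean())
        abs_diff = abs(mean_a - mean_b)
        p = null_by_id[cid].sf(abs_diff)
        records.append([cid, mean_a, mean_b, abs_diff, p])
    qs = multipletests([r[4] for r in records], method="fdr_bh")[1]
    return [
        DimaRecord(
            component_id=cid,
            mean_a=ma,
            mean_b=mb,
            abs_diff=d,
            p_value=p,
            q_value=float(q),
            significant=bool(d > diff_threshold and q < fdr_threshold),
        )
        for (cid, ma, mb, d, p), q in zip(records, qs)
    ]


def dima_table(records: list[DimaRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "component_id": r.component_id,
                "mean_a": r.mean_a,
                "mean_b": r.mean_b,
                "abs_diff": r.abs_diff,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "significant": r.significant,
            }
            for r in records
        ]
    )


def condition_profiles(
    a: pd.DataFrame,
    meta: SampleTable,
    condition: str | None = None,
) -> dict[str, pd.Series]:
    """Replicate-averaged activity-versus-time profile per component.

    With ``condition`` given, only that condition's samples are used;
    otherwise time-matched samples of every non-reference condition are
    averaged together. Returns {component_id: Series indexed by time_min}.
    """
    md = meta.data
    mask = md["time_min"].notna() & ~md["is_reference"]
    if condition is not None:
        mask &= md["condition"] == condition
    md = md[mask]
    if md.empty:
        raise ValueError("no time-annotated samples to build profiles from")
    times = sorted(md["time_min"].unique())
    if len(times) < 2:
        raise ValueError("need at least two time points for a profile")
    profiles = {}
    for cid in a.index:
        vals = [a.loc[cid, md.loc[md["time_min"] == t, "sample_id"]].mean() for t in times]
        profiles[cid] = pd.Series(vals, index=pd.Index(times, name="time_min"), name=cid)
    return profiles


def cluster_profiles(
    a: pd.DataFrame,
    meta: SampleTable,
    corr_threshold: float = 0.7,
    condition: str | None = None,
) -> dict[str, int]:
    """Group components by the similarity of their temporal activity profiles.

    Average-linkage hierarchical clustering on the distance 1 − Pearson r
    between replicate-averaged profiles, with the tree cut at
    1 − corr_threshold. Returns {component_id: cluster_id}.
    """
    profiles = condition_profiles(a, meta, condition=condition)
    ids = list(profiles)
    mat = np.array([profiles[c].to_numpy() for c in ids])
    sd = mat.std(axis=1)
    safe = np.where(sd == 0, 1.0, sd)
    z = (mat - mat.mean(axis=1, keepdims=True)) / safe[:, None]
    corr = (z @ z.T) / mat.shape[1]
    corr[sd == 0, :] = 0.0
    corr[:, sd == 0] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, None)
    if len(ids) == 1:
        return {ids[0]: 1}
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=1.0 - corr_threshold, criterion="distance")
    return dict(zip(ids, (int(v) for v in labels)))


def phase_templates(timepoints) -> dict[str, np.ndarray]:
    """Unit response templates on a sampling grid (first point is baseline).

    primary: 0 at baseline, 1 at every later point. secondary: linear rise to
    a peak of 1 at the second-to-last point, dropping to 0.2 at the last.
    tertiary: flat 0 through mid-course, then linear ramp to 1 at the final
    point.
    """
    t = np.asarray(sorted(timepoints), dtype=float)
    n = len(t)
    if n < 4:
        raise ValueError("need at least 4 time points for phase templates")
    primary = np.ones(n)
    primary[0] = 0.0
    secondary = np.zeros(n)
    secondary[: n - 1] = np.linspace(0.0, 1.0, n - 1)
    secondary[n - 1] = 0.2
    tertiary = np.zeros(n)
    start = (n - 1) // 2
    tertiary[start:] = np.linspace(0.0, 1.0, n - start)
    return {"primary": primary, "secondary": secondary, "tertiary": tertiary}


def classify_phase(
    profile: pd.Series,
    corr_threshold: float = 0.7,
    component_id: str = "",
) -> PhaseAssignment:
    """Assign a time-course profile to the three-phase vocabulary.

    The profile (activity indexed by minutes, covering >= 4 points including
    t = 0) is baseline-subtracted, taken in absolute value so that repression
    and activation classify alike, and correlated against the three templates;
    the best template wins if its correlation reaches ``corr_threshold``.
    Constant profiles are unclassified with correlation reported as 0.
    """
    profile = profile.sort_index()
    times = profile.index.to_numpy(dtype=float)
    if len(times) < 4 or times[0] != 0:
        raise ValueError("profile must cover >= 4 time points including t = 0")
    shape = np.abs(profile.to_numpy(dtype=float) - profile.iloc[0])
    if np.ptp(shape) == 0:
        return PhaseAssignment(component_id, profile, "unclassified", 0.0)
    templates = phase_templates(times)
    best_phase, best_r = "unclassified", -np.inf
    for phase in PHASES:
        r = float(np.corrcoef(shape, templates[phase])[0, 1])
        if r > best_r:
            best_phase, best_r = phase, r
    if best_r < corr_threshold:
        return PhaseAssignment(component_id, profile, "unclassified", best_r)
    return PhaseAssignment(component_id, profile, best_phase, best_r)


def classify_phases(
    a: pd.DataFrame,
    meta: SampleTable,
    corr_threshold: float = 0.7,
    condition: str | None = None,
) -> list[PhaseAssignment]:
    """Cluster and classify every component's replicate-averaged profile."""
    profiles = condition_profiles(a, meta, condition=condition)
    clusters = cluster_profiles(a, meta, corr_threshold=corr_threshold, condition=condition)
    out = []
    for cid, prof in profiles.items():
        pa = classify_phase(prof, corr_threshold=corr_threshold, component_id=cid)
        pa.cluster_id = clusters[cid]
        out.append(pa)
    return out


def phase_table(assignments: list[PhaseAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "component_id": p.component_id,
                "phase": p.phase,
                "template_correlation": p.template_correlation,
                "cluster_id": p.cluster_id,
            }
            for p in assignments
        ]
    )
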