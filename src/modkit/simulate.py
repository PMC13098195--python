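"""Synthetic expression compendia with planted ground truth.

The generator emulates the structure of a large bacterial RNA-seq compendium
augmented with a small antibiotic-exposure time series: a background set of
diverse samples, a block of reference/control samples used for centering, and
a 3-condition × 6-time-point × 2-replicate treatment series. Ground truth is
planted as a sparse gene-weight matrix M* (disjoint member blocks, one module
with all-negative member weights) and an activity matrix A* built from the
three phase templates (immediate-sustained step, transient mid-course pulse,
late monotone ramp), plus condition-specific and background-only modules.
Observed expression is per-gene baseline + M*·A* + Gaussian log-scale noise;
replicate variability enters through that same noise, so the downstream
replicate-null test is exercised end to end.

Everything is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .activity import phase_templates
from .compendium import CenteredMatrix, ExpressionMatrix, SampleTable
from .decomposition import IcaResults

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "generate_truth",
    "generate_expression",
    "split_two_datasets",
    "recovery_score",
    "member_jaccard",
    "simulate_dima_panel",
    "simulate_phase_profiles",
    "simulate_qc_design",
]

PHASE_CYCLE = ("primary", "secondary", "tertiary")


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic compendium.

    Defaults mirror the default study conditions: 1,000 genes; 15 modules of
    20 member genes; 120 background samples; a 3-condition time series on the
    grid (0, 1.5, 3.5, 7.5, 15, 30) min in duplicate; 10 reference samples;
    observation noise sd 0.25 log-TPM; 48 genes private to the time-series
    dataset. ``phase_assignments`` gives each module's planted behaviour;
    by default 4 primary, 4 secondary, 4 tertiary, 2 condition-specific and
    1 background-only module.
    """

    n_genes: int = 1000
    n_modules: int = 15
    members_per_module: int = 20
    weight_scale: float = 1.0
    n_background_samples: int = 120
    timepoints: tuple[float, ...] = (0.0, 1.5, 3.5, 7.5, 15.0, 30.0)
    conditions: tuple[str, ...] = ("amp_quarter", "amp_sixteenth", "cipro")
    phase_assignments: tuple[str, ...] | None = None
    n_replicates: int = 2
    noise_sd: float = 0.25
    n_reference_samples: int = 10
    dataset_b_extra_genes: int = 48
    amplitude_range: tuple[float, float] = (8.0, 15.0)
    seed: int = 0

    def resolved_phases(self) -> list[str]:
        if self.phase_assignments is not None:
            if len(self.phase_assignments) != self.n_modules:
                raise ValueError("phase_assignments length must equal n_modules")
            return list(self.phase_assignments)
        labels = [PHASE_CYCLE[i % 3] for i in range(max(0, self.n_modules - 3))]
        extras = ["condition_specific", "condition_specific", "background"]
        labels += extras[: self.n_modules - len(labels)]
        return labels[: self.n_modules]

    def validate(self) -> None:
        if self.n_modules * self.members_per_module > self.n_genes:
            raise ValueError("members_per_module * n_modules exceeds n_genes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name in ("n_genes", "members_per_module", "n_background_samples",
                     "n_replicates", "n_reference_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SyntheticTruth:
    """Planted factors of a synthetic compendium."""

    M_star: pd.DataFrame  # gene × module, unit-norm columns
    A_star: pd.DataFrame  # module × sample
    phase_labels: dict[str, str]
    member_sets: dict[str, set[str]]
    specific_condition: dict[str, str]  # condition_specific module -> its condition
    noise_sd: float
    config: SimConfig
    meta: SampleTable | None = None
    dataset_gene_sets: dict[str, set[str]] = field(default_factory=dict)

    @property
    def module_ids(self) -> list[str]:
        return self.M_star.columns.tolist()


def _sample_frame(config: SimConfig) -> pd.DataFrame:
    rows = []
    for i in range(config.n_background_samples):
        rows.append(("bg_%03d" % (i + 1), "background", "bg_%03d" % (i + 1),
                     np.nan, "r1", False))
    for i in range(config.n_reference_samples):
        rows.append(("ref_%02d" % (i + 1), "control", "control",
                     0.0, "r%d" % (i + 1), True))
    for cond in config.conditions:
        for t in config.timepoints:
            for r in range(1, config.n_replicates + 1):
                rows.append((f"{cond}_t{t:g}_r{r}", "antibiotic", cond, float(t),
                             f"r{r}", False))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "project", "condition", "time_min", "replicate_id", "is_reference"],
    )


def generate_truth(config: SimConfig) -> SyntheticTruth:
    """Plant M*, A* and phase labels for a configuration; deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    phases = config.resolved_phases()
    genes = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    module_ids = [f"mod_{j + 1:02d}" for j in range(config.n_modules)]
    meta_df = _sample_frame(config)
    samples = meta_df["sample_id"].tolist()

    M = np.zeros((config.n_genes, config.n_modules))
    member_sets: dict[str, set[str]] = {}
    negative_module = next(
        (j for j, ph in enumerate(phases) if ph in PHASE_CYCLE), None
    )
    for j in range(config.n_modules):
        start = j * config.members_per_module
        idx = np.arange(start, start + config.members_per_module)
        mags = np.abs(rng.normal(config.weight_scale, 0.25 * config.weight_scale, size=len(idx)))
        mags = np.maximum(mags, 0.2 * config.weight_scale)
        if j == negative_module:
            signs = -np.ones(len(idx))  # all-negative member weights
        else:
            signs = rng.choice([-1.0, 1.0], size=len(idx), p=[0.25, 0.75])
        M[idx, j] = mags * signs
        M[:, j] /= np.linalg.norm(M[:, j])
        # orient skew-positive except the mandated all-negative module
        if j != negative_module and _skew(M[:, j]) < 0:
            M[:, j] *= -1
        member_sets[module_ids[j]] = {genes[i] for i in idx}

    templates = phase_templates(config.timepoints)
    A = np.zeros((config.n_modules, len(samples)))
    col_of = {s: i for i, s in enumerate(samples)}
    lo, hi = config.amplitude_range

    specific_condition: dict[str, str] = {}
    spec_count = 0
    # one planted module-condition amplitude below the five-unit differential
    # rule (3 activity units) so both arms of the dual threshold are exercised
    straddle = None
    phase_mod_conds = [
        (j, c) for j, ph in enumerate(phases) if ph in PHASE_CYCLE
        for c in config.conditions
    ]
    if phase_mod_conds:
        straddle = phase_mod_conds[-1]

    for j, phase in enumerate(phases):
        if phase in PHASE_CYCLE:
            tpl = templates[phase]
            for cond in config.conditions:
                # responses go either way (activation or repression), which also
                # keeps same-template modules from having collinear activities
                amp = float(rng.uniform(lo, hi)) * float(rng.choice([-1.0, 1.0]))
                if straddle == (j, cond):
                    amp = 3.0
                for ti, t in enumerate(config.timepoints):
                    for r in range(1, config.n_replicates + 1):
                        A[j, col_of[f"{cond}_t{t:g}_r{r}"]] = amp * tpl[ti]
        elif phase == "condition_specific":
            cond = config.conditions[spec_count % len(config.conditions)]
            spec_count += 1
            specific_condition[module_ids[j]] = cond
            tpl = templates["tertiary"] if spec_count % 2 else templates["primary"]
            amp = 20.0
            for ti, t in enumerate(config.timepoints):
                for r in range(1, config.n_replicates + 1):
                    A[j, col_of[f"{cond}_t{t:g}_r{r}"]] = amp * tpl[ti]
        # background-only modules get no time-series activity

    # compendium diversity: sparse random activity in background samples for
    # every module, so module activities are mutually independent across the
    # compendium even when their treatment profiles share a template
    for j in range(config.n_modules):
        active = rng.random(config.n_background_samples) < 0.5
        amps = rng.normal(0.0, 10.0, size=config.n_background_samples)
        for i in range(config.n_background_samples):
            if active[i]:
                A[j, col_of[f"bg_{i + 1:03d}"]] = amps[i]
    # reference samples keep zero activity in every module

    truth = SyntheticTruth(
        M_star=pd.DataFrame(M, index=genes, columns=module_ids),
        A_star=pd.DataFrame(A, index=module_ids, columns=samples),
        phase_labels=dict(zip(module_ids, phases)),
        member_sets=member_sets,
        specific_condition=specific_condition,
        noise_sd=config.noise_sd,
        config=config,
        meta=SampleTable(meta_df),
    )
    return truth


def _skew(v: np.ndarray) -> float:
    m = v.mean()
    s = v.std()
    return 0.0 if s == 0 else float(((v - m) ** 3).mean() / s**3)


def generate_expression(
    truth: SyntheticTruth, config: SimConfig | None = None
) -> tuple[ExpressionMatrix, SampleTable]:
    """Observed log-TPM matrix: baseline + M*·A* + Gaussian noise, with metadata."""
    config = config or truth.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    baseline = rng.normal(8.0, 2.0, size=truth.M_star.shape[0])
    signal = truth.M_star.to_numpy() @ truth.A_star.to_numpy()
    noise = rng.normal(0.0, config.noise_sd, size=signal.shape) if config.noise_sd else 0.0
    values = baseline[:, None] + signal + noise
    x = ExpressionMatrix(
        pd.DataFrame(values, index=truth.M_star.index, columns=truth.A_star.columns)
    )
    meta_df = truth.meta.data.copy()
    meta_df["mapped_reads"] = rng.integers(1_500_000, 4_000_000, size=len(meta_df))
    return x, SampleTable(meta_df)


def split_two_datasets(
    x: ExpressionMatrix,
    meta: SampleTable,
    config: SimConfig,
    truth: SyntheticTruth | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Split the compendium into two datasets with partially disjoint genes.

    Dataset A holds the background and reference samples without the last
    ``dataset_b_extra_genes`` non-member genes; dataset B holds the
    time-series samples with the full gene universe, so the extra genes carry
    baseline-only signal. Re-merging with the union policy reproduces the
    condition that yields a dataset-exclusive artifact component.
    """
    if config.dataset_b_extra_genes <= 0:
        raise ValueError("dataset_b_extra_genes must be positive for a two-dataset split")
    n_member_genes = config.n_modules * config.members_per_module
    pool = config.n_genes - n_member_genes
    if config.dataset_b_extra_genes > pool:
        raise ValueError(
            f"dataset_b_extra_genes={config.dataset_b_extra_genes} exceeds the "
            f"{pool} non-member genes available"
        )
    genes = x.genes
    extra = genes[config.n_genes - config.dataset_b_extra_genes:]
    a_genes = [g for g in genes if g not in set(extra)]
    md = meta.data
    a_samples = md.loc[md["project"].isin(["background", "control"]), "sample_id"].tolist()
    b_samples = md.loc[md["project"] == "antibiotic", "sample_id"].tolist()
    return x.restrict(a_genes, a_samples), x.restrict(genes, b_samples)


def _weight_correlations(M_true: np.ndarray, M_est: np.ndarray) -> np.ndarray:
    zt = (M_true - M_true.mean(axis=0)) / M_true.std(axis=0)
    ze = (M_est - M_est.mean(axis=0)) / M_est.std(axis=0)
    return np.abs(zt.T @ ze) / M_true.shape[0]


def recovery_score(
    model: IcaResults | pd.DataFrame,
    truth: SyntheticTruth,
    r_threshold: float = 0.9,
) -> tuple[dict[str, str], list[float], int]:
    """Match planted modules to fitted components and score the recovery.

    Uses the optimal one-to-one assignment maximizing total |Pearson r|
    between M* and M columns (permutation- and sign-invariant). Returns the
    matching, the per-pair |r| list (module order), and the number of modules
    recovered at |r| >= ``r_threshold``.
    """
    M_est_df = model.M if isinstance(model, IcaResults) else model
    if set(M_est_df.index) != set(truth.M_star.index):
        raise ValueError("model and truth gene universes differ")
    M_est = M_est_df.loc[truth.M_star.index].to_numpy()
    M_true = truth.M_star.to_numpy()
    if M_true.shape[1] == 0:
        return {}, [], 0
    sim = _weight_correlations(M_true, M_est)
    rows, cols = linear_sum_assignment(-sim)
    matching = {
        truth.module_ids[i]: M_est_df.columns[j] for i, j in zip(rows, cols)
    }
    per_pair = [float(sim[i, j]) for i, j in zip(rows, cols)]
    return matching, per_pair, int(sum(r >= r_threshold for r in per_pair))


def member_jaccard(
    members_by_component: dict[str, set[str]],
    truth: SyntheticTruth,
    matching: dict[str, str],
) -> dict[str, float]:
    """Jaccard index between each planted member set and its matched component's."""
    out = {}
    for module_id, comp_id in matching.items():
        a = truth.member_sets[module_id]
        b = members_by_component.get(comp_id, set())
        union = a | b
        out[module_id] = len(a & b) / len(union) if union else 1.0
    return out


def simulate_dima_panel(
    n_components: int = 1000,
    delta: float = 0.0,
    diff_sd: float = 2.0,
    log_sigma: float = 0.5,
    jitter_sd: float = 0.05,
    n_fit_groups: int = 30,
    seed: int = 0,
) -> tuple[pd.DataFrame, SampleTable]:
    """Activity panel for calibrating the differential-activity test.

    Each component gets ``n_fit_groups`` duplicate groups for null fitting
    plus one duplicate group per test condition; condition B's mean is shifted
    by ``delta`` activity units. Replicate noise is injected at the pair
    level: within-pair absolute differences follow a log-normal law
    (log-scale sd ``log_sigma``) scaled so their standard deviation equals
    ``diff_sd``, matching the distributional family the test fits, plus a
    small independent Gaussian jitter per sample.
    """
    rng = np.random.default_rng(seed)
    s2 = log_sigma**2
    scale = diff_sd / np.sqrt((np.exp(s2) - 1.0) * np.exp(s2))
    mu = np.log(scale)

    groups = [(f"fit_{i + 1:03d}", 0.0) for i in range(n_fit_groups)]
    groups += [("cond_a", 0.0), ("cond_b", float(delta))]
    rows, col_ids = [], []
    for gname, _ in groups:
        for r in (1, 2):
            col_ids.append(f"{gname}_r{r}")
            rows.append((f"{gname}_r{r}", "panel", gname, 0.0, f"r{r}", False))
    meta = SampleTable(
        pd.DataFrame(
            rows,
            columns=["sample_id", "project", "condition", "time_min",
                     "replicate_id", "is_reference"],
        )
    )
    n_groups = len(groups)
    d = rng.lognormal(mean=mu, sigma=log_sigma, size=(n_components, n_groups))
    signs = rng.choice([-1.0, 1.0], size=(n_components, n_groups))
    jitter = rng.normal(0.0, jitter_sd, size=(n_components, 2 * n_groups))
    a = np.empty((n_components, 2 * n_groups))
    for gi, (_, center) in enumerate(groups):
        half = signs[:, gi] * d[:, gi] / 2.0
        a[:, 2 * gi] = center + half + jitter[:, 2 * gi]
        a[:, 2 * gi + 1] = center - half + jitter[:, 2 * gi + 1]
    ids = [f"IC_{i + 1:04d}" for i in range(n_components)]
    return pd.DataFrame(a, index=ids, columns=col_ids), meta


def simulate_phase_profiles(
    n_per_phase: int = 50,
    noise_sd: float = 0.1,
    timepoints: tuple[float, ...] = (0.0, 1.5, 3.5, 7.5, 15.0, 30.0),
    seed: int = 0,
) -> list[tuple[str, pd.Series]]:
    """Noisy unit-template profiles labelled with their generating phase."""
    rng = np.random.default_rng(seed)
    templates = phase_templates(timepoints)
    out = []
    for phase in ("primary", "secondary", "tertiary"):
        for _ in range(n_per_phase):
            vals = templates[phase] + rng.normal(0.0, noise_sd, size=len(timepoints))
            out.append((phase, pd.Series(vals, index=list(timepoints))))
    return out


def simulate_qc_design(
    n_genes: int = 300,
    corrupt_index: int = 7,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SampleTable, str]:
    """A 3-condition × 6-time × duplicate design (36 samples) with one corrupt sample.

    The corrupt sample's expression values are shuffled across genes (breaking
    replicate correlation) and its mapped-read count is set below any sensible
    threshold, mirroring a sample that fails both quality criteria. Returns
    (expression, metadata, corrupt_sample_id).
    """
    rng = np.random.default_rng(seed)
    conditions = ("amp_quarter", "amp_sixteenth", "cipro")
    times = (0.0, 1.5, 3.5, 7.5, 15.0, 30.0)
    baseline = rng.normal(8.0, 2.0, size=n_genes)
    cols, rows = {}, []
    i = 0
    corrupt_id = ""
    for cond in conditions:
        shift_gene = rng.normal(0.0, 1.0, size=n_genes)
        for t in times:
            signal = baseline + shift_gene * np.log1p(t)
            for r in (1, 2):
                sid = f"{cond}_t{t:g}_r{r}"
                vals = signal + rng.normal(0.0, noise_sd, size=n_genes)
                reads = int(rng.integers(1_500_000, 4_000_000))
                if i == corrupt_index:
                    vals = rng.permutation(vals)
                    reads = 100_000
                    corrupt_id = sid
                cols[sid] = vals
                rows.append((sid, "antibiotic", cond, t, f"r{r}", False, reads))
                i += 1
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    x = ExpressionMatrix(pd.DataFrame(cols, index=genes))
    meta = SampleTable(
        pd.DataFrame(
            rows,
            columns=["sample_id", "project", "condition", "time_min",
                     "replicate_id", "is_reference", "mapped_reads"],
        )
    )
    return x, meta, corrupt_id


def centered_from_truth(truth: SyntheticTruth) -> CenteredMatrix:
    """Noise-free centered matrix M*·A* (a convenience for closed-loop tests)."""
    values = truth.M_star.to_numpy() @ truth.A_star.to_numpy()
    return CenteredMatrix(
        pd.DataFrame(values, index=truth.M_star.index, columns=truth.A_star.columns),
        reference_samples=truth.meta.reference_samples() if truth.meta else [],
    )
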