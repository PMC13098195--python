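# Methods

## Model

The package factors a reference-centered log-TPM expression matrix
X (genes × samples) as X ≈ M·A. Columns of M (gene weights) are unit L2
norm and carry the gene composition of each independently modulated gene set
(iModulon); rows of A carry all magnitude, in log-TPM deviation units
relative to the reference condition. Two conventions remove the scale and
sign indeterminacy of ICA: ‖M column‖₂ = 1, and each column is oriented so
that the skewness of its weights is non-negative (when skewness is
numerically zero, |skew| < 1e-6, the largest-magnitude weight is made
positive). With these conventions, rescaling X by c rescales A by c and
leaves M unchanged. Note that sign-blind membership means a component's
member genes can all carry negative weights after orientation — increased
activity then means coordinated *repression* of those genes.

Underlying assumptions, inherited from ICA: gene expression deviations are
(approximately) linear mixtures of statistically independent, non-Gaussian
source processes; the compendium is diverse enough that distinct regulatory
programs are activated independently across samples. Modules whose
activities are strongly correlated across the whole compendium cannot be
separated, whatever the restart budget.

## Robust consensus decomposition

A single FastICA run depends on its random initialization. The consensus
procedure:

1. run FastICA (`fun="logcosh"`, unit-variance whitening, tol 1e-6, max 1000
   iterations) `n_runs` times with seeds spawned deterministically from one
   master seed; non-convergent runs contribute components but are counted in
   the results object;
2. pool all gene-weight columns and cluster them with DBSCAN on the distance
   1 − |Pearson r|, eps = 0.1, minimum cluster size ⌈support_frac · n_runs⌉;
3. keep clusters whose members span ≥ support_frac of the runs
   (default 0.5 of 50 runs); the component is the sign-aligned cluster mean;
4. one alternating-least-squares sweep: activities A by least squares
   against the centroids, weights refitted against those activities, then
   re-normalized, re-oriented and projected once more. FastICA internally
   removes the per-sample mean across genes, so raw centroids sit slightly
   outside the data's row space; the sweep removes that offset and makes
   X ≈ M·A exact in the retained subspace (a noiseless rank-1 matrix is
   reconstructed perfectly).

Components are ordered by descending activity energy and labelled
`IC_001…`. The fit is bit-for-bit deterministic given (X, k, n_runs,
support_frac, seed).

### Dimensionality selection

`select_dimension` fits the consensus at each candidate k and counts (a)
retained robust components and (b) "single-gene" components in which one
gene carries more than `dominance_frac` of the squared weight; the chosen k
maximizes (a) − (b), ties resolved toward the smaller k. The single-gene
count is the over-specification signal: when k exceeds the number of real
modules, the surplus components collapse onto individually noisy genes.
`dominance_frac` defaults to 0.3 — measured max-weight shares are strongly
bimodal (genuine 20-gene modules stay below ~0.16, single-gene components
sit above ~0.43), so 0.3 lies in the gap with margin on both sides. This
criterion is a documented stand-in for dimensionality selection on real
compendia; both tunables are exposed.

## Membership thresholding

Weights are median-centered (guarding against offset components), then the
largest-|weight| gene is removed iteratively until the D'Agostino K²
normality statistic of the remaining weights falls below `cutoff_stat`;
removed genes are the members, and the reported threshold is the largest
absolute weight among non-members. Ties in |weight| break toward the gene
earlier in input order, making the loop deterministic. The default cutoff is
100: the K² transform saturates for extreme outliers, so while true members
remain the statistic stays in the hundreds-to-thousands, and once the weight
distribution is Gaussian it collapses below ~20 (its null distribution is
χ² with 2 df); 100 sits in that wide gap. The statistic needs ≥ 20 genes;
degenerate loops that would remove everything return all genes with a
warning.

## Enrichment, naming, explained variance, artifacts

Member sets are tested against each regulator's regulon (intersected with
the gene universe) with a one-sided Fisher's exact test on the 2×2 table
(member∩regulon, member\regulon, regulon\member, rest), BH-corrected across
regulators; precision, recall and F1 accompany each record. The best-F1
regulator with q < 0.05 names the iModulon (repeats get `-2`, `-3`, …);
otherwise `Unchar_n`. Functional categories are user-supplied annotations.

Explained variance of a component over sample subset S is
1 − ‖X_S − m·a_S‖²_F / ‖X_S‖²_F, clipped at zero. Single-component fractions
do not sum to the joint fraction because components are not orthogonal; the
joint fraction (least-squares reconstruction on all retained components) is
also provided and always at least the best single fraction.

When two datasets with partially disjoint gene universes are union-merged,
genes absent from one dataset are filled with 0 on the log scale *before*
centering. If the reference samples belong to the dataset lacking those
genes, the filled genes acquire a spurious offset that ICA isolates as its
own component. `detect_artifacts` flags any component whose (non-empty)
member set lies entirely in the symmetric difference of the two gene
universes; flagged components are kept but marked for exclusion downstream.

## Quality control

Samples are grouped by (project, condition, time_min). QC is two-stage:
samples failing the mapped-read floor (default 500,000, when counts are
available) are removed first; Pearson correlation over all genes is then
computed among each group's survivors, and a sample fails when its best
correlation against any same-group survivor is below `min_corr` (default
0.95). Groups reduced to one sample are reported "uncheckable" and retained.
The two-stage order matters for duplicate designs: correlation alone cannot
say *which* member of a failing pair is bad, but a sample that also fails
the read floor identifies itself, and its partner is then uncheckable rather
than guilty by association. Both thresholds are declared defaults, not
values inferred from any particular dataset.

## Differential activity (DiMA)

For each component, absolute activity differences between replicates are
pooled over every replicate group, differences below 1e-8 are dropped
(rather than jittered), and a log-normal law is fitted by maximum likelihood
(μ̂, σ̂ = mean and population sd of the log differences). Components with
fewer than two usable differences or σ̂ < 1e-6 get a degenerate null whose
tests conservatively return p = 1. The p-value of an observed absolute
difference of condition means is the fitted survival function; BH correction
runs across the components of one comparison; significance requires both
|Δ| > 5 activity units and q < 0.01. Signed activities are averaged within
conditions; the absolute value is taken of the difference only. Pooling
across conditions assumes replicate spread is condition-independent — with
two replicates per condition, per-condition fits would be hopeless.

## Phase classification

Profiles are replicate-averaged activity versus time. The classifier
baseline-subtracts (value at t = 0), takes absolute values so repression and
activation classify alike, and correlates against three unit templates on
the sampling grid (n points): *primary* — 0 then 1 at every post-exposure
point; *secondary* — linear rise to a peak at the second-to-last point,
falling to 0.2 at the last; *tertiary* — flat zero through mid-course, then
a linear ramp to 1 at the final point. The best-correlated template is
assigned when r ≥ 0.7, else the profile is unclassified (constant profiles
are unclassified with correlation reported as 0). Classification is
invariant to positive scaling of the profile. The templates and the 0.7 gate
are explicit, configurable stand-ins for what is, on real data, a mixture of
statistics and biological judgment; profile clustering (average-linkage on
1 − Pearson r, tree cut at 1 − corr_threshold) is provided alongside for
grouping before interpretation.

## Synthetic compendium

The generator emulates a large diverse compendium plus a small treatment
time series. Defaults: 1,000 genes; 15 modules × 20 member genes (disjoint
blocks); 120 background samples; 10 reference samples with zero activity in
every module; 3 treatment conditions × 6 time points (0, 1.5, 3.5, 7.5, 15,
30 min) × 2 replicates; observation noise sd 0.25 log-TPM; per-gene
baselines N(8, 2²).

Planted structure: member weight magnitudes ~|N(1, 0.25²)| (floored at 0.2)
with random signs, one module all-negative; columns unit-normalized,
skew-oriented except the all-negative module (whose orientation cannot be
made skew-positive — that module exists precisely to exercise sign-blind
membership). Twelve modules follow the three phase templates (four each),
with per-(module, condition) peak amplitudes drawn U(8, 15) and a random
sign, so responses go both ways; one module-condition amplitude is fixed at
3 to put planted effects on both sides of the 5-unit differential rule. Two
modules are condition-specific (amplitude 20 in one condition, silent in the
other treatments), one is background-only. Every module also receives sparse
random activity in background samples (Bernoulli(0.5) × N(0, 10²)): this is
the compendium diversity that makes planted sources near-independent — the
assumption ICA itself needs. With weaker or absent background activity,
same-template modules have strongly correlated activities and the
decomposition genuinely cannot separate them.

Replicate variability enters only through the observation noise, so the
replicate-null test is exercised end to end on the compendium. The
two-dataset split assigns the background + reference samples to dataset A
without the last 48 non-member genes, and the time series to dataset B with
all genes, reproducing the merge-artifact condition.

The DiMA calibration panel is separate and noise-model-consistent: within
each replicate pair, the absolute activity difference is drawn from a
log-normal law (log-sd 0.5) scaled so the difference sd is 2, split
symmetrically across the pair, plus per-sample Gaussian jitter (sd 0.05).
A log-normal fitted to absolute *Gaussian* differences always has log-sd
≈ 1.11, a tail so heavy that a 15-unit shift would be undetectable at
FDR 0.01; the panel instead matches the distributional family the test
fits, which is also what "noise matching the fitted null" means for the
type-I arm.

What the generator does not emulate: count overdispersion and
mean-variance coupling of real RNA-seq, batch effects beyond the gene-universe
split, correlated regulatory programs (modules sharing genes), and compositional
effects of TPM normalization. Passing recovery tests therefore show the
pipeline is correct under its own model assumptions, not that real
compendia satisfy them.

## Problem sizes and numerical choices

The validation suite runs the full consensus (50 restarts, k = 15–16) on the
1,000 × 166 default compendium, 1,000-component DiMA panels, and 300
phase profiles; this keeps a complete run in seconds on one CPU while
leaving every statistic in its asymptotic regime (the K² statistic, BH over
1,000 tests, hypergeometric tails). Tolerances: component unit-norm to
1e-8; skew tie-break at |skew| < 1e-6; degenerate null at σ < 1e-6;
replicate differences below 1e-8 treated as zero. All randomness flows from
`numpy.random.default_rng` seeded explicitly; derived seeds stay below 2³¹.

## Known limitations

* Restart-based robustness cannot reject components that reflect
  reproducible structure of the *realized* noise; on small matrices with
  homoscedastic noise, over-specified decompositions can return more robust
  components than true modules. The single-gene arm of the dimensionality
  criterion addresses the common real-data failure mode (idiosyncratically
  variable genes), not this one.
* The explained-variance accounting is single-component rank-one (or joint
  least-squares); leave-one-out accounting is not implemented.
* The QC correlation check needs replicate groups; fully unreplicated
  designs pass through as "uncheckable".
* Phase templates are tied to a sampling grid with a baseline at t = 0 and
  at least four points.
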