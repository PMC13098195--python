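# modkit

iModulon analysis of bacterial expression compendia: robust independent
component analysis (ICA) of log-TPM expression, differential module-activity
testing against a replicate-derived log-normal null, and three-phase temporal
classification of activity profiles.

## The problem

Time-resolved RNA-seq of a perturbation (for example, *E. coli* sampled
minutes after antibiotic exposure) produces thousands of gene-level changes
that are hard to interpret individually. ICA of a large expression compendium
decomposes the centered log-expression matrix

```
X ≈ M · A
```

where **X** (genes × samples) holds log-TPM deviations from a reference
condition, the columns of **M** are *iModulons* — independently modulated
gene sets with a weight per gene — and the rows of **A** are each iModulon's
*activity* across samples, in log-TPM units. Gene membership of an iModulon
is obtained by thresholding its weight distribution (membership is
sign-blind: strongly negative weights are members too); each iModulon is
named for the transcriptional regulator whose regulon it is most enriched in
(one-sided Fisher's exact test, BH-corrected); and its contribution to
expression variation is the fraction of ‖X‖²_F removed by its rank-one
reconstruction, optionally restricted to a sample subset.

On top of the decomposition, modkit provides:

* **Robust consensus ICA** — components pooled from many seeded FastICA
  restarts, clustered by gene-weight correlation, retained only when
  reproduced in a sufficient fraction of runs (`RobustICA(...).fit(seed)`
  returns an `IcaResults` with `M`, `A`, cluster support and a `summary()`).
* **Compendium handling** — TSV I/O, quality control by mapped reads and
  replicate Pearson correlation, union/intersection merging of datasets with
  partially disjoint gene universes, and reference centering.
* **Artifact screening** — components whose members are exclusively genes
  private to one of two merged datasets are flagged as merge artifacts.
* **DiMA** (differential iModulon activity) — per-component log-normal null
  fitted to replicate-to-replicate activity differences; a component is
  significantly differential between two conditions only when |Δmean| > 5
  activity units *and* the BH-adjusted p-value is below 0.01.
* **Phase classification** — activity-versus-time profiles correlated with
  three templates: an immediate sustained step (*primary*), a transient
  mid-course pulse (*secondary*), and a late monotone ramp (*tertiary*).
* **Synthetic compendia** — a generator that plants known M*, A*, phase
  labels, replicate noise and dataset splits, so every stage is testable
  with ground truth.

## Worked example

Generate the default synthetic compendium (1,000 genes; 15 planted modules of
20 genes; 120 background, 10 reference and 36 time-series samples across
three treatments sampled at 0, 1.5, 3.5, 7.5, 15 and 30 min in duplicate),
decompose it, and test for differential activity:

```python
import modkit as mk
from modkit.activity import fit_replicate_null, dima_test

cfg = mk.SimConfig(seed=0)
truth = mk.generate_truth(cfg)
x, meta = mk.generate_expression(truth, cfg)
xc = mk.center_to_reference(x, meta)

res = mk.RobustICA(xc, k=15, n_runs=50).fit(seed=42)
print(res.summary())
```

```
Robust ICA decomposition
============================================================
genes: 1000   samples: 166
requested k: 15   retained components: 15
restarts: 50 (50 converged)   support threshold: 0.5
total explained variance: 0.926
------------------------------------------------------------
component    support   |A| max
IC_001          1.00     26.25
IC_002          1.00     26.87
...
```

Every retained component appeared in all 50 restarts (support 1.00), and the
15 components jointly account for 92.6% of the squared Frobenius norm of the
centered matrix. Comparing against the planted truth and testing one
treatment against the reference condition:

```python
matching, per_r, n_rec = mk.recovery_score(res, truth)
print(f"recovered {n_rec}/15 planted modules, min |r| = {min(per_r):.3f}")

nulls = fit_replicate_null(res.A, meta)
records = dima_test(res.A, meta, "cipro", "control", nulls)
print([(r.component_id, round(r.abs_diff, 1)) for r in records if r.significant])
```

```
recovered 15/15 planted modules, min |r| = 0.989
[('IC_001', 12.5), ('IC_002', 8.3), ('IC_003', 12.2), ('IC_007', 11.0),
 ('IC_009', 5.1), ('IC_013', 6.0)]
```

All 15 planted gene-weight vectors are matched one-to-one by fitted
components at |Pearson r| ≥ 0.989, and the components significantly
differential under ciprofloxacin-like treatment are exactly those whose
planted activities respond in that condition — including `IC_003`, the
module planted as condition-specific to it.

The same pipeline is available from the shell:

```sh
modkit simulate --seed 7 --out-dir sim/
modkit qc        --expr sim/expression.tsv --meta sim/meta.tsv --out qc.json
modkit center    --expr sim/expression.tsv --meta sim/meta.tsv --out Xc.tsv
modkit decompose --expr Xc.tsv --k 15 --runs 50 --seed 42 --out-dir ica/
modkit extract   --expr Xc.tsv --model ica/ --trn trn.tsv --out catalog/
modkit dima      --act ica/A.tsv --meta sim/meta.tsv \
                 --cond-a amp_quarter --cond-b control --out dima.tsv
modkit phases    --act ica/A.tsv --meta sim/meta.tsv --out phases.tsv
```

## Documentation

`docs/methods.md` describes the model, the defaults and their rationale, the
synthetic-data design, and known limitations.
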