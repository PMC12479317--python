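# aiekit

Semiparametric efficient, double-robust estimation of average treatment
effects (ATEs) and *k*-point average interaction effects (AIEs) of
categorical exposures — genotypes, discretized environments — on continuous
or binary outcomes under confounding.

The estimand is an alternating signed sum of covariate-adjusted
counterfactual outcome means over the `2**k` vertices of a per-treatment
(baseline, target) contrast hypercube; the ATE is the `k = 1` case.
Estimators are built from a pluggable outcome regression and propensity
score (GLM, ridge, gradient-boosted trees, saturated cell fits, or a
cross-validated stacked ensemble) and include:

- **plugin** — the substitution estimator over the empirical covariate
  distribution;
- **ose** — one-step estimator (plugin + first-order bias; the AIPW
  estimator for `k = 1`);
- **tmle / wtmle** — targeted maximum-likelihood with the canonical
  inverse-propensity clever covariate, or the weighted fluctuation that
  moves the propensity into the loss (better behaved near positivity
  violations);
- **cv_ose / cv_tmle / cv_wtmle** — cross-fitted versions (each individual
  scored by out-of-fold nuisance models, one pooled fluctuation).

Inference is based on the efficient influence function (EIF): Wald
intervals and p-values, joint Hotelling *t²* tests across contrast
components, delta-method functionals (e.g. the allelic-effect difference
`psi(1->2) - psi(0->1)`), marginal vertex-frequency positivity pruning, and
Benjamini–Hochberg FDR adjustment across a batch.  For cohorts with
related individuals, a sieve-plateau variance estimator built on a genetic
relationship matrix (GRM) replaces the iid EIF variance by the most
conservative value of a dissimilarity-thresholded variance curve.

A simulation module generates null and confounded synthetic cohorts with
known ground truth (by Monte Carlo integration of the declared mean
function) and provides a coverage/bias/variance/power evaluation harness.

## Library quick start

```python
import pandas as pd
from aiekit import Contrast, EstimandSpec, LearnerSpec, estimate

data = pd.read_csv("cohort.tsv", sep="\t")
spec = EstimandSpec(
    kind="ate", outcome="bmi", treatments=("rs123",),
    contrast=Contrast(pairs=((0, 1),)),
    confounders=("PC1", "PC2"), covariates=("age", "sex"),
)
rec = estimate(data, spec, estimator="wtmle",
               q_learner=LearnerSpec("glmnet"), g_learner=LearnerSpec("glm"))
print(rec.psi, rec.ci, rec.pvalue)
```

## Command line

```sh
aiekit simulate --n 5000 --maf 0.3 --seed 1 --out cohort.tsv
aiekit estimate run.yaml --out results.tsv
aiekit phewas phewas.yaml --out results.tsv
aiekit grm dosages.tsv --out-prefix mygrm
aiekit svp eif.txt --grm-prefix mygrm --out curve.tsv
```

A run configuration looks like:

```yaml
cohort: cohort.tsv
outcome: {name: Y, family: gaussian}
treatments: {A1: {levels: [0, 1, 2]}}
confounders: [PC1, PC2]
study: {template: gwas_lite, variants: [A1]}   # or phewas / custom
estimator: wtmle
learners: {q: {name: glm}, g: {name: glm}}
positivity_threshold: 0.01
joint_tests: true
allelic_difference: true
sieve: {enabled: false}
seed: 1
```

`run_study` expands the template into per-transition contrast components
(e.g. `0->1` and `1->2` for a three-level genotype), prunes components
whose vertex frequencies fall below the positivity threshold, estimates
the survivors on shared nuisance fits, optionally adds the joint Hotelling
and allelic-difference rows, BH-adjusts p-values, and (when enabled)
applies the sieve-plateau correction to rows under the configured p-value
trigger.

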