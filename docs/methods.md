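# Methods

`mucosig` implements a statistical pipeline for multi-cohort mucosal 16S
microbiota case–control studies with repeated anatomical sampling per
patient: genus-level filtering and compositional transforms, alpha and
beta diversity with cohort-aware models, two-method consensus
differential abundance with cross-cohort consistency rules, a disease
signature, patient-grouped bootstrap classification, a clr-based
microbial dysbiosis index (MDI), and a resampled clinical-correlation
procedure. A synthetic-cohort generator with fully known ground truth
makes every stage testable end to end.

## Synthetic cohort model

Samples are drawn from a hierarchical log-linear model. For taxon $t$ in
a sample from patient $p$ (cohort $c$, group $g$, one row per gut
segment),

$$\log a_{pt} = \mu_t + s_t\,\delta\,u_p\,[g \neq \mathrm{HC}] + b_{ct} + r_{pt} + \varepsilon,$$

where $\mu_t \sim N(0, 2)$ gives a heavy-tailed rank-abundance curve,
$s_t \in \{+1, -1, 0\}$ marks the planted signature (disjoint increased /
decreased sets), $\delta$ is the log-scale effect size,
$u_p \sim N(1, 0.35)$ is the patient's latent dysbiosis severity
(0-centred in controls), $b_{ct} \sim N(0, 0.3)$ is a cohort-wide batch
effect on every taxon, $r_{pt} \sim N(0, 0.3)$ is a patient random
effect shared across that patient's segments, and
$\varepsilon \sim N(0, 0.3)$ is per-sample noise. Compositions
$\mathrm{softmax}(\log a)$ are converted to counts by a multinomial draw
at the sample's library size (optionally Dirichlet-multinomial via an
overdispersion parameter). Library sizes are log-uniform on
(12,000, 60,000); 5% of samples are forced below 10,000 reads to
exercise the depth filter. Clinical covariates are linear in $u_p$ with
fixed loadings: positive for ALP, GGT, AST, APRI and FIB-4, negative for
albumin, and exactly zero for fecal calprotectin (intestinal
inflammation is deliberately uncoupled from the planted liver-disease
axis). One cohort's healthy controls carry missing laboratory values, as
happens when controls are endoscopy volunteers without blood sampling.

Defaults are the study conditions used throughout the tests: two
cohorts, four groups (HC, pre_LTx, post-transplant without/with
recurrence), 40 patients per group per cohort, 126 genera with 7
increased and 15 decreased planted taxa at effect size 1.0, ileum plus
two colonic sites per patient in cohort A and ileum plus three in
cohort B.

What the generator does **not** emulate: read-level artefacts (chimeras,
primer bias, contamination), taxon–taxon ecological interactions,
zero inflation beyond the multinomial sampling zeros, non-Gaussian
covariate distributions, and age/sex confounding. Passing tests
therefore demonstrate that the procedures are correctly implemented and
calibrated under a realistic compositional repeated-measures model, not
that they are robust to every artefact of real amplicon data.

## Preprocessing

Samples under 10,000 reads are removed (strictly below; a 10,000-read
sample is retained). Features are aggregated to genus by summing columns
that share a `g__` label; genus-unassigned features are pooled at their
deepest named rank. Low-information taxa are dropped by the
near-zero-variance rule (frequency ratio of the two most common values
> 19 **and** percent-distinct values < 10; both conditions required);
this filter is applied to all analyses except alpha diversity.
Rarefaction subsamples without replacement (multivariate hypergeometric)
to exactly 10,000 reads with a recorded seed. The clr transform adds a
pseudocount of 0.5 to every count (the standard half-count correction
for sampling zeros; configurable) and centres each row by its
mean log; rows sum to zero by construction. The clr for the classifier
is computed after taxon filtering; computing it before filtering would
change values only through the removed columns' contribution to the row
mean.

## Diversity models

Richness is the count of observed features and Shannon uses natural log
(base configurable), both on rarefied data. Group comparisons fit
`metric ~ Group + Cohort + Group×Cohort` with cohort effect-coded
(±1/2), so group coefficients are cohort-averaged. The terminal ileum
(one sample per patient) uses OLS; the colon adds a patient random
intercept estimated by REML (statsmodels MixedLM), degenerating to the
fixed model with a warning when every patient has a single sample.
Pairwise group contrasts are BH-corrected within each segment × metric
family. A contrast whose interaction term has unadjusted p < 0.05
triggers per-cohort post hoc fits, reported alongside (never
suppressing) the pooled contrast, with a consistency flag (both cohorts
p < 0.05, same sign). Group×cohort cells that are empty drop their
interaction column with a warning, and affected pairs report an
undefined interaction p.

## Beta diversity

The robust Aitchison distance applies the rclr transform per sample —
log of nonzero counts centred by the mean log over that sample's nonzero
entries, zeros left at zero — followed by Euclidean distance; on
zero-free tables this is exactly the classical Aitchison distance
(asserted against a hand computation). PCoA is classical MDS with
explained variance normalised by the sum of positive eigenvalues.

PERMANOVA partitions the Gower-centred inner-product matrix sequentially
(type-I, Group entered first) via hat-matrix traces, giving each term a
pseudo-F. P-values come from label permutations: free permutation of
samples for single-sample designs, and whole-patient block permutation
(each patient's samples keep their design attributes together) for
repeated colonic measures; free permutation remains available for
designs where that restriction is not wanted. 999 permutations by
default; exact enumeration of all distinct labelings is available for
small inputs and is verified against brute-force enumeration. A
significant interaction (p < 0.05) triggers the two post hoc families
(Group within each cohort; Cohort within each group), BH-corrected
within family.

## Consensus differential abundance

Two independent procedures run per contrast, both as per-taxon linear
models on `Group + Cohort + Group×Cohort` (vectorised OLS):

1. **clr linear model with mode bias correction.** Under the assumption
   that most taxa are not differential, the shared compositional bias of
   clr coefficients is estimated as the mode of the across-taxa
   coefficient distribution (Gaussian KDE, Silverman bandwidth, 512-point
   grid) and subtracted before t-tests.
2. **log-TSS linear model.** Counts are total-sum scaled to proportions,
   log-transformed after adding half the smallest nonzero proportion,
   and fit per taxon without bias correction.

BH correction runs across taxa within each method. Differentially
abundant taxa are the **intersection**: q < 0.05 in both methods with
agreeing effect direction. Taxa with a significant Group×Cohort
interaction (unadjusted p < 0.05, screening use) must additionally be
significant (within-cohort BH q < 0.05, keeping the global
significance convention) with the same sign in
each cohort's separate fit; others pass through. The disease signature
is the direction-consistent intersection of the pre-transplant-vs-HC and
post-transplant-vs-HC hit sets; direction conflicts are excluded with a
warning. Signature difference (e.g. against an alcohol-related-disease
signature) removes taxa shared with the other signature in the same
direction. The recurrence-subset analysis reuses the same operations on
the signature taxa only, reporting unadjusted p alongside q; IBD and
calprotectin (cut-off 250 µg/g) contrasts reuse them with different
group columns. The design matrix is Group + Cohort (+ interaction) only;
additional covariates (age, sex) are out of scope for the defaults.

## Classification harness

Elastic-net logistic regression (scikit-learn saga) on standardised clr
features. Hyperparameters — mixing grid {0.0, 0.1, …, 1.0} × a 6-point
log-spaced penalty grid — are chosen by five-fold cross-validation,
stratified by class and grouped by patient, minimising CV binomial
deviance; the grid search uses lighter convergence settings
(max_iter 1000, tol 1e-3) and the chosen pair is refit at full
precision. Tuning happens once on the full data and is then fixed across
bootstrap iterations — tune first, then train/validate; per-iteration
retuning (nested validation) is a deliberate non-default because it
answers a different question (performance of the tuning procedure rather
than of the tuned model).

Validation bootstraps **patients**: each of 500 iterations resamples
patients with replacement for training (duplicated patients contribute
their samples multiply); all samples of out-of-bag patients form the
validation set, so no patient ever appears on both sides. The
optimism-corrected AUC is the mean validation AUC (Mann–Whitney, ties
half-counted); the 95% CI is the 2.5/97.5 bootstrap percentiles; the
p-value is the proportion of bootstrap AUCs ≤ 0.5, floored at
1/(n_boot+1) — a one-sided test against chance that reuses the
already-computed bootstrap distribution (a DeLong-style test against
0.5 would be the conventional alternative). Iterations with a
single-class validation set are redrawn
and counted. With one sample per patient the grouped bootstrap is an
ordinary sample-level bootstrap. The standard null check shuffles group
labels at the patient level and re-runs the harness; because a single
shuffle's mean OOB AUC has appreciable draw-to-draw variance (chance
correlation of the shuffled labels with cohort or patient structure),
the null check averages the harness over three independent shuffles.
Random forest, gradient boosting and K-nearest-neighbour learners run
through the identical harness as consistency checks.

## Dysbiosis index and clinical correlations

The MDI is the log-ratio of total abundance of disease-increased over
disease-decreased signature taxa; on clr values this is the difference
of sums: $\mathrm{MDI} = \sum_{t \in \mathrm{inc}} \mathrm{clr}_t -
\sum_{t \in \mathrm{dec}} \mathrm{clr}_t$, computed per segment from
that segment's signature. It is exactly antisymmetric under swapping the
two sets, and adding a constant $c$ to a sample's clr row shifts it by
$c(|\mathrm{inc}| - |\mathrm{dec}|)$. Signature taxa absent from a
dataset's columns are dropped with a warning (mismatched use, not
imputable data). Group comparisons reuse the fixed/mixed models above.
The original ratio-of-relative-abundance index is deliberately not the
default (the clr formulation replaces it) and is not provided.

Clinical correlations on colonic data use the resampled Spearman
procedure: 100 iterations, each drawing exactly one sample per patient
uniformly at random; the reported correlation is the mean rho and a
correlation is significant only if ≥ 90 of 100 iterations reach
p < 0.05 — a deliberately conservative rule (null final-significance
rate ≪ 0.05 in calibration tests). Ileal correlations (one sample per
patient) are computed once; the procedure provably reduces to a plain
Spearman test there. Spearman p-values use the t-approximation with
midranks; for n ≤ 8 an exact enumeration over all rank permutations is
used instead (full enumeration beyond that is combinatorially
impractical inside the 100-iteration loop, and the t-approximation is
adequate from n = 9). Missing covariates are handled by
pairwise-complete deletion per covariate, and correlations pool all
samples with available covariates (controls with missing labs drop out
naturally). The per-taxon clinical heatmap applies the same procedure to
every signature-taxon × covariate pair, using the median across-iteration
p per cell for BH correction across the family.

## Numerical choices and degenerate inputs

- Degenerate contrasts (constant response) report p = 1 rather than NaN.
- Aliased DA designs (empty group, collinear columns) raise immediately
  with the offending contrast named.
- PERMANOVA factor levels need ≥ 2 samples; fewer than 99 permutations
  warns about p resolution.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); reports are bit-for-bit reproducible
  under a fixed seed, and pseudo-F statistics are permutation-seed
  invariant by construction.

## Problem sizes

The bundled analyses and tests run at the default design (40 patients
per group per cohort, 126 genera) for recovery and null-harness checks,
20 independent seeds for signature recovery, and 200 null replicates at
30 patients per arm and 100 taxa for calibration of the DA methods and
PERMANOVA — sizes chosen so the full evaluation completes on a single
CPU in minutes while keeping Monte-Carlo error small relative to the
tolerances tested.

## Known limitations

- The two DA procedures are re-implementations of their published model
  classes, not wrappers of the original packages; option-for-option
  parity with those packages is a non-goal.
- The clr-with-mode-correction method shows mild FDR inflation at small
  n (empirically ≈ 0.06–0.08 at nominal 0.05 here), inherent to
  estimating the bias term from the coefficient distribution.
- MixedLM occasionally converges at the variance boundary for
  near-degenerate random effects; coefficients remain valid and warnings
  are suppressed only inside the comparison helpers.
- PERMANOVA's block permutation treats the patient as the exchangeable
  unit; designs where cohort or group vary within a patient are not
  supported.
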