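# Methods

This note documents the models, conventions and numerical choices behind
`cohortjuxt`, and what the synthetic experiments do and do not establish.

## Data model and conventions

A cohort is a set of patient records (center, gender ∈ {f, m, NA}, age,
item-level responses per questionnaire and time point) coded against a
catalog that assigns each questionnaire an item count, a topical category
and the centers that administer it.  The shared questionnaire set S and
shared category set V are always recomputed as intersections over
centers, never stored.

Two conventions matter throughout:

- **Missingness is explicit.**  An unanswered item is `None` in memory and
  an empty field on disk, never a sentinel number: adherence must
  distinguish "answered 0" from "not answered".  A wholly absent response
  block counts as 0% adherence rather than being dropped from averages —
  an unanswered questionnaire is the strongest non-adherence signal, and
  excluding it would bias center-wide averages upward.
- **Scores require completeness.**  The total score is the item sum and is
  only defined when every item is answered; analysis cohorts are filtered
  to patients with a computable score at the required time points.
  Prorated scores for partially answered questionnaires are a conceivable
  alternative and are deliberately not implemented.

## Synthetic cohort generator

The generator emulates a two-center questionnaire study:

- Ages: truncated normal per center (defaults 53.7 ± 12.9 and 50.3 ± 12.2
  years on [18, 95], matching the published descriptive statistics of the
  two tinnitus centers the defaults model).  An optional second mixture
  component exists to produce the non-normal age shapes of real referral
  populations, so both branches of the normality gate can be exercised.
- Gender: multinomial f/m/NA with center-specific male fractions (the
  defaults are the exact published cohort ratios 473/733 and 1,994/3,822)
  and a small unknown-gender fraction at one center.
- Admission score TQ_t0: truncated normal on the score bounds [0, 84].
  The real cohorts' TQ moments are unpublished; the defaults
  (mean 42/46, SD 17) are package choices, not literature values.
- Outcome model: TQ_t1 = β0 + β1·TQ_t0 + β2·age + γ·1[male] + ε with
  Gaussian noise, clipped to the score bounds.  This linear-Gaussian form
  is a deliberate design choice: it makes the regression stage
  well-specified, so the attainable R² equals signal variance over total
  variance (computable in closed form from the truncated-normal moments)
  and coefficient recovery can be verified to numerical precision.
  Default β = (2–4, 0.75, 0.05), γ = 1, σ_ε = 7, giving a within-center
  signal fraction near 0.75.
- Adherence: per questionnaire, a block is present with probability
  `present_prob`; a present block is fully answered with probability
  `complete_prob`, otherwise the patient's answer propensity is drawn
  from Beta(a, b) and items are answered independently.  The two-part
  (point mass + Beta) form reproduces the "mostly complete, long lower
  tail" shape of real adherence summaries with interpretable parameters.
- Dropout: with center-specific probability the final visit is missed
  entirely (defaults 0.90 and 0.55, matching the published completeness
  cascade from admission to final visit).

Scores are integers by default; items are generated by distributing the
drawn total uniformly over item slots (each item capped at 2).  With
`round_scores=False` the generator keeps continuous scores (items carry
equal fractional values), which is what the exact parameter-recovery
experiments use — integer rounding would otherwise floor the achievable
recovery error around 1e-2.  One global seed is split into per-purpose
substreams (ages, genders, scores, missingness, item content) so changing
one configuration block leaves the other draws untouched.

What the generator does **not** emulate: item-content realism (non-TQ
answers are unstructured small integers), correlation between adherence
and demographics or severity, informative dropout, and the genuine
non-normality of real age distributions (available only through the
mixture option).  Passing tests therefore demonstrate correctness of the
machinery and calibration under a known model, not robustness to real
clinical data pathologies.

## Distribution juxtaposition

Each two-sample comparison is gated by Shapiro–Wilk at α on both samples:
both pass → two-sided t test on the means, otherwise two-sided
Mann–Whitney U.  Choices:

- The t branch uses the Welch (unequal-variance) form — the safe default
  when center sizes and variances differ.
- Mann–Whitney uses exact null enumeration when both groups have ≤ 8
  observations and no ties, and the tie- and continuity-corrected normal
  approximation otherwise.  The reported U is U of the first sample
  (U(s1) + U(s2) = n1·n2); the orientation is a convention and is fixed
  and documented rather than inferred.
- A family of m comparisons shares one Bonferroni-corrected critical
  value α/m; significance means p < α/m.  The default family for a
  two-center cohort is the standard six-fold design: f-vs-f and m-vs-m
  across centers, m-vs-f within each center, and the two mixed
  cross-center pairs.
- KDE uses a Gaussian kernel with Scott's-rule bandwidth (overridable) on
  a 512-point grid spanning the sample range padded by three bandwidths.
- The bundled reference-population table (gender and 10-year age-band
  proportions) contains rounded illustrative values for Germany, editable
  by replacing the CSV; it is not an official census extract.

## Similarity networks and the heat-trace descriptor

Scores are standardized per center (the statistics are indexed by center,
and pooling genders within a center is the closest reading of that
convention; per-stratum standardization is the alternative).  Within a
stratum, every patient pair is connected with weight
w = 1/max(|Δs′|, ε), ε = 1e-6 by default.  The ε floor exists because
integer questionnaire scores tie routinely and 1/x is undefined at 0;
capping preserves the weight ranking and keeps the Laplacian finite.

**Pruning.**  "Delete non-significant edges" is implemented as a
score-permutation null: shuffle the standardized scores across patients,
recompute all pairwise weights, pool over permutations (default 1,000,
seeded), and retain edges at or above the (1−α) null quantile.  A
structural fact worth recording: permuting scores across patients leaves
the *multiset* of pairwise differences unchanged, so this null is exactly
the graph's own weight distribution and the rule coincides with the also
exposed `keep-top-q` quantile threshold.  Both are shipped; the
permutation form is the default because it states the inferential intent.
For large graphs the pooled null is subsampled to a bounded number of
pairs to cap memory; small graphs are pooled exactly, which is what the
brute-force oracle test checks.

**Descriptor.**  h(t) = Σ exp(−tλ_k) over the eigenvalues of the
symmetric-normalized weighted Laplacian L = D^{+1/2}(D − W)D^{+1/2}
(isolated nodes contribute a zero eigenvalue), on a default grid of 250
log-spaced points in [1e-2, 1e2].  Limits: h(0⁺) = node count,
h(∞) = number of connected components; h is non-increasing in t.
Normalization modes: `none`; `empty-graph` (divide by n); and the default
`complete-graph`, dividing by the closed form 1 + (n−1)e^{−tn/(n−1)} of
K_n under the normalized Laplacian — required here because the two
centers (and hence their stratum graphs) differ in size.  Eigenvalues are
computed by dense symmetric eigendecomposition up to 2,000 nodes; above
that a truncated spectrum (150 extreme eigenvalues each end, linear
interpolation between) is used and flagged in the signature.  The network
distance is the L2 norm between signatures on identical grids.

**What the descriptor can and cannot see.**  Edge weights depend only on
within-stratum pairwise score differences, so a pure location shift of a
stratum's score law produces an identically distributed graph; a uniform
scale factor additionally cancels in the normalized Laplacian.  What
distinguishes strata is the *shape* of the score distribution — with
integer scores, concretely the tie-cluster structure (the score
histogram).  The validation experiment
(`simnet.same_law_ranking_experiment`) therefore draws four integer-score
strata — two from one discretized normal law, one narrow-normal, one
uniform — and checks that the same-law pair ranks most similar among the
six pairs.  At 150 patients per stratum this recovery is essentially
deterministic (rate 1.0 over 50 replicates across several seed bases);
at 50–80 patients with continuous scores the spectrum is dominated by
extreme-gap sampling noise and the experiment is not informative, which
is why the shipped experiment fixes integer scores and n = 150.  The
experiment uses unpruned graphs; the pruned variant also recovers the
pair (~0.96) but is left out of the headline check for robustness.

## Adherence

adh_I(x) = 100 · (items of I answered by x)/|I| at admission only —
later-visit adherence would leak information about the post-treatment
target.  Set 1 averages over all of the center's questionnaires; set 2
keeps one value per questionnaire shared by all centers; set 3 averages
within each shared category over the center's own questionnaires of that
category; set 4 is the unweighted mean of the set-3 values (a vector
variant returning the set-3 mapping itself is available behind
`mode="vector"` for the alternative reading of set 4).  Values are exact
rationals internally, so set 4 equals the mean of set 3 identically and
brute-force recounts can assert equality, not approximation.  Summaries
report mean ± SD per center × gender (the unknown-gender column appears
only where such patients exist); the "all" column is recomputed over the
pooled patients, never averaged over subgroup means.

## Prediction

Features: age, gender (male = 1, female = 0), TQ_t0, optionally one
adherence set (restricted to shared questionnaires/categories so the same
columns exist in both cohorts — the precondition for transfer).  Patients
with unknown gender or an incomplete TQ at either time point are
excluded, and each report carries its row counts so the exclusion cascade
is auditable.  Model families: ordinary least squares, lasso, ridge, SVR
(RBF).  Hyperparameters by 10-fold CV grid search minimizing MSE within
the training data only; grids are conventional wide defaults (penalty
10⁻³…10³, 13 log-spaced points; SVR C ∈ {0.1, 1, 10, 100}, γ ∈ {scale,
10⁻³…1}) and overridable.  Penalized and kernel models are fit on
standardized features (training statistics); plain least squares is not,
so its coefficients stay on the generative scale and can be compared to
the generator's β directly.  Within-center experiments use a seeded 80/20
held-out split (the split ratio is a package choice); cross-center
experiments select and fit on the full training cohort and only score on
the other center.  All families are reported with MAE, MSE and R²; the
best family is flagged by held-out R².

## Pipeline

`cohortjuxt run-all --config pipeline.yaml` chains
simulate/load → juxtapose → simnet → adherence → predict, writing each
stage's outputs plus a consolidated JSON report keyed by seed and config
hash; omitting a stage block skips that stage and everything in the
report stays traceable to (stage, seed, config).  Errors abort with the
stage name.

## Validation experiment sizes

The default test and acceptance runs use deliberately scaled problem
sizes, chosen to make the statistical assertions sharp at interactive
runtimes: heat-trace oracle on 200 random graphs of ≤ 12 nodes against
dense `expm`; standardization identity at n = 1,000; adherence recount on
500 patients; noise-free recovery at n = 400 and signal-fraction recovery
(target R² 0.8 ± 0.05) at n = 2,500; same-law network ranking over 50
replicates of 4 × 150 patients; family-wise error over 500 replicates of
four 80-patient strata, asserted below the 99% binomial band around the
nominal 0.05.

## Known limitations

- The permutation pruning null degenerates to the weight-quantile rule
  (see above); a null that broke the equivalence (e.g. parametric score
  resampling) would be a genuine extension.
- Heat-trace distances between small strata (≲ 100 patients) with
  continuous scores are noise-dominated; rankings should be interpreted
  only for larger strata or integer scores.
- The generator's independence assumptions (adherence ⟂ severity,
  dropout ⟂ outcome) are optimistic; transfer-performance conclusions on
  synthetic data are best-case.
- Only sum scoring is implemented; instruments with reverse-coded or
  weighted items need score-level preprocessing before import.
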