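# Methods

## Severity measures

All five measures are phenotype-level: a patient-level quantity is
computed for every *carrier* of a phenotype (any patient with ≥ 1
condition event of that code) and averaged across carriers.

| measure | per-carrier quantity | unit | notes |
|---|---|---|---|
| `treatment_time` | span between first and last event of the code | days | single event → 0; aggregation configurable (`mean`/`median`/`max`, default mean) |
| `n_comorbidities` | distinct *other* condition codes on the whole record | count | distinct-code semantics |
| `n_medications` | distinct drug codes on the whole record | count | carriers with no drug rows contribute 0 |
| `n_procedures` | procedure events on the whole record | count | events, not distinct codes: repetitions are informative |
| `cost` | Σ over HCPCS events of rate/min × typical minutes | currency | ICD-9 procedure events carry no fee; codes missing from the fee schedule contribute 0 with a warning |

Counts use the whole patient record with no time window and no
visit-level linkage; episode segmentation is an explicit non-goal.
Prevalence is per-patient (distinct carriers / distinct patients in the
condition table); the denominator can be overridden with an external
patient count.  The retention filter keeps codes with prevalence ≥ the
threshold (inclusive), default 0.0001.

## E-PSI

Each measure is max-normalised within the analysed table
(`proportion = value / column max`; an identically-zero column yields
proportion 0 for everyone rather than 0/0) and E-PSI is the mean of the
five proportions, so it lies in [0, 1] and is invariant to each
measure's unit.  A flag returns the raw sum (range [0, 5]) instead of
the mean.  E-PSI is monotone in every measure and the phenotype
attaining a measure's maximum has that proportion exactly 1.

## Unsupervised forest and proximity

The feature matrix is the five measures plus E-PSI (six columns, fixed
order, raw scale — trees are scale-equivariant).  A synthetic contrast
class of equal size is drawn by resampling each column independently
with replacement: marginals are preserved exactly, inter-measure
dependence is destroyed.  1000 CART trees (scikit-learn
`DecisionTreeClassifier`, `max_features="sqrt"`) are each grown on a
bootstrap of the stacked real+synthetic data to discriminate the two
classes; bootstrap draws, the contrast sample and tree seeds all derive
from one master seed, so a fixed seed reproduces every artifact
byte-for-byte.

* **Proximity** of two observed rows = fraction of *all* trees in which
  they share a terminal node.  (One common variant counts only trees
  where both rows are out of bag; the all-trees form is simpler and
  deterministic at fixed seed, and the diagonal is exactly 1.)
* **Importance** = mean decrease in Gini impurity per feature, averaged
  over trees and expressed on the training-sample count scale.
* **OOB error curve** = cumulative-majority out-of-bag error of the
  real-vs-synthetic vote after each tree; a tied vote counts as an
  error (conservative).  Rows not yet out of bag are excluded from the
  denominator, so the first few entries may be NaN.

## Classical scaling

The dissimilarity D = 1 − proximity is embedded by Torgerson scaling:
double-centre −½D², eigendecompose, keep the top-2 eigenvectors scaled
by √eigenvalue.  D need not be Euclidean, so negative eigenvalues are
clipped at zero and their mass logged; dimensions beyond the
configuration's rank come back as zero columns.  Sign convention: each
dimension's largest-magnitude coordinate is made positive.  On exactly
Euclidean input the pairwise distances are recovered to < 1e-6
(tested).

## Mild/severe calls

Reference-standard phenotypes act as anchors.  Each phenotype takes its
k = 15 highest-proximity anchors (itself excluded, so anchors are scored
leave-one-out automatically) and the anchors vote with their proximity
as weight.  Ties go to *severe* — when in doubt, flagging a phenotype
severe is the safer error for downstream prioritisation.
`neighbor_support` is the winning share of summed neighbour proximity
(0.5 on a tie).  Neighbour ties at the k-th proximity are resolved by
the partition order, which is deterministic for identical inputs.  The
severe/mild error-versus-trees curves re-run this read-out at every
cumulative tree count using the stored terminal-node memberships.

Evaluation reports confusion counts and sensitivity/specificity in both
positive-class orientations, Cohen's kappa (pairwise) and Fleiss' kappa
(multi-rater) for evaluation ratings, and two-sided Wilcoxon rank-sum
class contrasts with quartiles (the measures are far from normal).
Kappas return 1 when expected agreement is 1 (unanimous single-category
data) instead of NaN.  The rank-sum test enumerates the exact null when
both groups have ≤ 10 tie-free observations, otherwise it uses the
normal approximation with tie and continuity corrections.  Two-sided
p-values throughout; no multiple-testing correction is applied across
the six measure contrasts.

## Synthetic cohort generator

The generator emulates the *structure* the method assumes, not clinical
realism.  Defaults: 2000 patients, 500 phenotypes, 30% severe,
multiplicative effect size 3 on every measure for severe phenotypes, 10%
of mild phenotypes "chronic", reference standard covering 25% of
phenotypes at the 372:144 mild:severe ratio, severe prevalence boost
1.5×.

Mechanics, all driven by one seed:

* carriers per phenotype ~ 2 + Poisson(6) (×1.5 for severe), so every
  phenotype has ≥ 2 carriers and no retry logic is needed;
* per-carrier comorbidity/medication/procedure counts are negative
  binomial (dispersion 2; overdispersed as real utilisation data are),
  with means = baseline × phenotype-level log-normal multiplier
  (σ = 0.3) × class effect;
* treatment spans are log-normal (σ = 0.8, mild median 60 days),
  scaled by the effect size for severe phenotypes **and** for the
  chronic-mild subgroup — the confounder that makes treatment time
  alone misleading, which the multi-measure design is meant to defeat;
* comorbidity events draw codes from a filler pool distinct from the
  analysed phenotypes; procedure events are 20% ICD-9 (no fee) and 80%
  HCPCS from a 60-code pool of which 10 codes are absent from the fee
  schedule, and severe carriers tilt toward pricier codes — so cost
  tracks procedure volume only imperfectly, as observed in real claims;
* **severity-assortative carrier pools**: a seeded permutation splits
  patients into a severe-carrier pool and a mild-carrier pool sized by
  each class's expected carrier demand.  Sick patients accumulate severe
  diagnoses in real inpatient data (Berkson-type enrichment); without
  this, multi-phenotype records would average mild and severe
  contributions and the whole-record measures would no longer reflect
  the configured effect sizes.  With it, the null configuration (all
  effects 1, no chronic subgroup) remains class-symmetric, which the
  tests check.

What the generator does *not* emulate: real vocabularies, visit
structure, demographics, coding noise, care-seeking behaviour, or
correlated measurement artifacts.  Passing tests on this cohort show
the pipeline recovers planted structure under the stated noise model;
they do not certify performance on real EHR data.

## Problem sizes and numerical choices

The test suite runs the full study configuration (500 phenotypes, 1000
trees) once and otherwise uses scaled-down cohorts (80 phenotypes, 200
trees) and a 4-patient hand-checkable fixture whose profile table is
committed as a golden file.  Eigenvalues are clipped at 0 in scaling;
proximity invariants (symmetry, unit diagonal, [0, 1] range) are
asserted on every fit; CSV floats are written with `%.10g` so repeated
runs are byte-identical.

## Limitations

* The mild/severe decision rule (proximity-weighted k-NN over anchors)
  is one reproducible formalisation of cluster-based labelling; other
  demarcations of the proximity space are possible and k is exposed as
  a flag.
* Proximity counts all trees rather than OOB-only pairs; values are
  slightly optimistic for rows that share bootstrap draws, though the
  read-out only uses proximity *ranks* and weights.
* Binary labels only; the proximity matrix supports finer severity
  grading, but nothing beyond the binary call plus neighbour support is
  produced.
* Cost covers priced procedures only — phenotypes treated without
  procedures appear cheap regardless of drug or inpatient costs.
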