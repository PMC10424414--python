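# Methods

## Problem setting

A fecal microbiota transplant moves a donor's gut community into a
recipient. `fmtforge` asks what can be predicted about the recipient's
post-transplant microbiome — Shannon diversity, per-taxon abundance and
presence, clinical success — from the donor sample alone, with no access to
the recipient's baseline. Donor-only prediction is what permits banked,
off-the-shelf transplants and in-silico design of synthetic communities.

## Preprocessing

Feature tables are samples × taxa with QIIME-style taxonomy strings
(`k__...;p__...;...;s__...`). Unprefixed labels are accepted and ranked
positionally; missing intermediate ranks are filled with
`<parent>__unclassified` so every leaf has a complete 7-rank path (the
image builder requires it). Tables whose rows sum to 1 within 1e-6 are
treated as relative abundance, otherwise as counts closed on demand.

The model-space pipeline follows the MIPMLP conventions: merge leaf taxa to
a chosen rank ("sum" adds member leaves and conserves row totals; "mean"
averages them — the default for model input at the species level), close
each sample to the simplex, then x → log10(x + ε) with ε = 1e-4. ε keeps
zero cells finite (log10 ε = −4) and well below any observed abundance; the
exact constant is exposed in `PrepRecipe`. An optional per-taxon z-score
uses statistics learned on the training split only and frozen into the
trained model, as is the covariate standardization (mean/sd of days
post-FMT, donor age/sex/weight). Shannon diversity is computed in nats
(H = −Σ pᵢ ln pᵢ, after closure); the log base is configurable.

## The microbiome image and the convolutional predictor

For a fixed training taxonomy, leaves are ordered by a depth-first
traversal whose children are sorted by descending mean training abundance
of their subtree (ties lexicographic). The image of a sample is a
7 × n_leaves matrix: row r, column c holds the mean abundance over the
leaves sharing leaf c's rank-r ancestor. The bottom row is the leaf vector
itself; each higher row is exactly a blockwise re-expanded mean-merge of
the leaf vector at that rank (this equivalence is the test oracle for the
builder). Internal tree nodes are therefore valued as means over their
descendant leaves — equivalently a leaf-count-weighted mean of their
children — so that every image row coincides with the corresponding
taxonomic merge.

The convolutional predictor is implemented in numpy: two valid-padding
convolutions (8 then 16 channels, 2×3 kernels, ReLU), a 1×2 max-pool, and
a dense head (32 units, dropout 0.2) that also receives the standardized
covariates. Training uses Adam (lr 1e-3, batch 32, ≤150 epochs), early
stopping (patience 20) on an internal validation split that groups by
recipient subject, and input/target standardization with statistics frozen
at fit time. All sizes are configurable; the defaults are the smallest
configuration that reliably recovers the synthetic transfer signal on one
CPU. Fits are deterministic per seed.

Two numerical guards matter in practice:

- **Input standardization.** Log-space images concentrate around −4 for
  absent taxa; training on raw log values stalls the network, so images
  and covariates are standardized per pixel at fit time.
- **Label-range bounding.** Regression predictions are clipped to the
  training label range. A donor-only model has no evidence for outcomes
  outside the labels it saw, and an optimizer run against the predictor
  must not be rewarded for pushing it into extrapolation. With the bound
  in place the genetic algorithm's best predicted diversity saturates at
  the maximum realized in the training cohort, matching how such
  optimizers should behave against a trustworthy surrogate.

The baseline bank (ridge/logistic, kNN, SVR/SVC, random forest, gradient
boosting via xgboost, dense net via scikit-learn) consumes the same
flattened design matrix (preprocessed donor vector + covariates), so model
comparisons are not confounded by preprocessing differences. One model is
fitted per prediction task; binary tasks return probabilities.

## Evaluation protocol

Cross-validation partitions recipient *subjects* (not samples) into k
near-equal folds, so repeated samples of one recipient never straddle the
train/test boundary. Per-fold R² (coefficient of determination on held-out
data; may be negative), Spearman correlation and AUC are reported as mean ±
standard error over folds. Constant predictions are scored SCC = 0 (no
monotone association). Folds with constant held-out labels are skipped and
recorded. Leave-one-dataset-out trains on all cohorts except a named
holdout. Model comparison runs a one-way ANOVA over per-fold metrics and,
when significant at 0.05, paired one-sided t-tests of each model against
the best on average (paired, because folds are shared across models).
Time-stratified accuracy pools held-out predictions from one grouped CV and
scores Spearman correlations within days-post-FMT bins.

Note that grouping is by recipient: when one donor feeds several
recipients, different recipients of that donor can land in different
folds. Pooled CV therefore measures a donor-familiar setting, while LODO
measures strict cross-cohort transfer; the package treats them as distinct
questions rather than forcing one number.

## Distance hierarchy

Recipient samples are compared by Euclidean distance between order-level
relative-abundance vectors (no log — order "frequencies"), or by absolute
Shannon difference. Groups: SDSR (same recipient across timepoints, defined
post-FMT only), SDDR (different recipients, same donor, matched timepoint),
DDDR (different donors, matched timepoint). Timepoint matching is exact by
default with an optional ± tolerance for ragged schedules. One-sided
t-tests check SDSR < SDDR, SDDR < DDDR, SDSR < DDDR with star-coded
p-values. Pre-FMT (day 0) samples are donor-independent by construction in
the generator, so the pre-FMT SDDR vs DDDR test is the negative control.

## Genetic algorithm

Candidates are compositions on the simplex; the support mask is re-derived
from the abundances after every operator, so padding zero taxa never
changes fitness. Per generation: predict each candidate's 7-day outcome,
score fitness_max(s, b) = s − nnz(b)·γ (minimization negates s), keep the
top 30 of 100 (ties: fewer taxa, then lineage id), and refill with
offspring bred from elites only — uniform crossover with probability 0.3,
then a toggling mutation with probability 0.3 that flips k ~ Poisson(3)+1
taxa (a switched-on taxon draws its abundance from the pool's empirical
nonzero distribution for that taxon; a switched-off taxon is zeroed; the
vector is re-closed). Elites pass unchanged, making the best fitness
non-decreasing and convergence well-defined. The default budget is 25
generations with an optional plateau rule. A run reports the best-fitness
trajectory, elite profiles and community sizes, the dominant orders among
the elites, and a triviality check: the Spearman correlation between each
elite donor's own target property and its predicted recipient property
(low values mean the GA did not simply breed donors that already exhibit
the target).

The donor pool is expanded to the working size by mixing real donors: each
synthetic profile takes the support of one random parent and, on it, a
convex mixture (weight ~ U(0,1)) of that parent and a second donor, times
lognormal jitter (sd 0.3), re-closed. Restricting to the first parent's
support preserves per-taxon prevalence, which a union-support mixture would
systematically inflate.

## Synthetic cohorts

Donor communities are sparse lognormal compositions: per-taxon log-mean ~
N(0, 1.2), prevalence ~ U(0.3, 1), per-sample lognormal noise (sd 0.8),
closed to the simplex. A recipient sampled t days post-FMT is

    r(t) = close( δ·e^(−τt) · close(engraftability ⊙ donor)
                  + ρ · host_background + (1 − δ·e^(−τt) − ρ) · noise )

with donor effect δ, recipient background ρ (δ + ρ ≤ 1), decay τ, and a
fixed engraftability vector ~ U(0.2, 1). Host backgrounds and noise are
fresh draws from the same community family; pre-FMT baselines (day 0) come
from the host background alone. Clinical outcomes are Bernoulli draws from
a sigmoid of the realized recipient Shannon (slope 3 around the cohort
median), or fully donor-determined in a degenerate mode used for testing.
A `world_seed` separates population-level structure (taxonomy, log-means,
prevalences, engraftability) from sampling, so several cohorts can share
one underlying population — the setting LODO assumes.

The four recipient regimes are presets ordered by increasing background:
germ-free (ρ = 0, δ = 0.85), antibiotic-treated mouse (0.1, 0.7),
antibiotic-treated human (0.25, 0.5), untreated human (0.45, 0.3). δ
shrinks as ρ grows because the transplant competes with the resident
community.

This linear-in-composition transfer model reproduces the qualitative
phenomena the package is built around — donor effect exceeding background
(SDDR < DDDR), a nonlinear donor↔recipient property relation after
closure, time decay, and prediction accuracy that degrades with ρ — while
remaining analytically transparent. It does *not* emulate ecological
interactions (no cross-feeding or competition dynamics), strain-level
engraftment, compositional overdispersion beyond lognormal noise, or
covariate effects on transfer. Tests passing on it show the pipeline
recovers a known signal under realistic sparsity and noise; they do not
certify accuracy on real cohorts.

## Problem sizes and determinism

Default study sizes are chosen for single-CPU work: reference cohort 100
donors × 4 recipients (400 pairs, ~80 taxa over 8 orders), donor pool 2083
profiles, GA population 100 for 25–60 generations, 10-fold grouped CV.
Every stochastic component takes an explicit seed (numpy Generator
end-to-end); repeated runs with one seed are bit-identical, including CNN
training and the GA.

## Known limitations

- The image uses a single fixed leaf ordering learned from training
  abundances; alternative orderings (e.g. dendrogram-based) are pluggable
  but not implemented.
- One convolutional architecture is provided; a second structural variant
  is reserved in configuration but identical by default.
- Per-species presence tasks with fewer than 5 positives or negatives in
  an evaluation split are skipped (AUC unstable).
- The clinical-outcome link in the generator is deliberately simple
  (sigmoid of realized diversity); real cohort outcome definitions vary by
  disease and are taken as input labels, never computed.
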