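# Methods

## Problem and data model

The data are a binary bipartite association matrix **A** ∈ {0,1}^(ns×nm)
between small molecules (rows) and miRNAs (columns), read from a
two-column TSV edge list, optionally against explicit universe files so
that zero-degree entities (compounds with no known miRNA partner, and
vice versa) keep their rows and columns.  Row/column order follows first
appearance in the universe (or edge) file; all downstream matrices
inherit that order, which makes every output diff-able.  Duplicate edges
collapse silently to a single 1 and are counted in the log, since
curated edge lists commonly contain duplicates.
`restrict_to_connected` derives the dense core of such a dataset — the
submatrix of entities with at least one known association — conserving
the number of 1 entries.

Similarity matrices are square, symmetric, in [0,1].  On load, small
asymmetries are repaired as (S+Sᵀ)/2 and out-of-range values clipped,
both with warnings; the diagonal is forced to 1 (an entity is maximally
similar to itself).  Forcing the diagonal cannot leak labels because
neighborhood scoring always excludes the self entity.

Integrated similarities are entrywise weighted means of component
matrices (chemical structure, disease phenotype, side effect and
target-gene functional consistency on the SM side; disease phenotype
and functional consistency on the miRNA side), with all weights
defaulting to 1.  Component matrices a dataset lacks are dropped and
the remaining weights renormalized.  The weighted mean is emitted as-is,
without renormalization, so outputs stay inside the convex hull of the
components.  A Jaccard utility builds profile-based components from
binary annotation matrices; a pair of empty profiles scores 0 rather
than NaN, reading absence of evidence as no neighbor signal.

## Neighborhood-based inference

The NI score of (sᵢ, mⱼ) on the SM side is the similarity-weighted mean
of A(d, j) over neighbors d with ISMS(d,i) ≥ σ, d ≠ i; the miRNA side is
the mirror image.  Conventions, all exercised by tests:

* **Threshold comparison is ≥** — ties at the threshold count as
  neighbors.  A single threshold governs numerator and denominator.
* **Empty neighborhoods score 0.**  The 0/0 cell of an isolated entity
  is defined as "no evidence", keeping scores finite and conservative.
* **Self is never a neighbor**, so known labels of the focal entity
  cannot reach its own score.

One cutoff is arbitrary, so basic models over the fixed grid
0.05:0.05:0.50 are averaged; `sigma_upper` selects which grid values
participate ({σ ∈ grid : σ ≤ σ_upper}).  The SM-side and miRNA-side
grid averages are finally averaged with equal weight.  All NI scores
are convex combinations of 0/1 entries and therefore lie in [0,1].

## Restricted Boltzmann machine

A Bernoulli–Bernoulli RBM with nm visible units (one per miRNA) and s
hidden units is trained on the ns row-observations of **A**.  The
training algorithm is CD-k with defaults chosen as ordinary practice
for small binary RBMs, all exposed in `RBMConfig`:

| parameter      | default | rationale                                        |
|----------------|---------|--------------------------------------------------|
| hidden_units s | 40      | middle of the 20–120 selection grid              |
| learning_rate  | 0.05    | stable for 0/1 data at these scales              |
| epochs         | 100     | reconstruction error plateaus well before this   |
| batch_size     | 10      | minibatch SGD, no momentum or weight decay       |
| cd_steps k     | 1       | CD-1; longer chains gave no benefit at this size |
| init           | W ~ N(0, 0.01²), b = c = 0 | standard small-weight start   |

Hidden samples drive the Gibbs chain, while the gradient statistics use
probabilities for both layers (the visible reconstruction is never
binarized in the statistics); this is the usual variance-reduced CD
estimator.  Training is deterministic given the config seed: one
generator is created from it and threaded through initialization,
shuffling and sampling.

Prediction is deterministic mean-field, with no sampling: hidden
probabilities P = σ(Aᵢ·W + c) from the observed row, then visible
probabilities σ(W·P + b) as the scores, strictly inside (0,1).  A toy
machine small enough for exhaustive enumeration (3 visible, 2 hidden,
2⁵ states) verifies that the implemented conditionals match the
partition-function-normalized joint distribution.

## Ensemble

Each base predictor's matrix is z-scored over all ns×nm cells —
population standard deviation; the n vs n−1 choice is immaterial
because the subsequent map is rank-preserving — and squashed as
(tanh(0.1·z)+1)/2, then the two are averaged with weight 0.5.  The
normalization is invariant to positive affine transforms of the raw
scores, so each predictor contributes only its ranking and its shape,
not its scale.  A constant matrix (σ = 0) maps uniformly to 0.5 instead
of erroring, which keeps cross-validation loops robust on degenerate
folds.

## Evaluation protocols

Candidate samples are the cells that are 0 in the **full** association
matrix; held-in positives are never treated as negatives.  Four
protocols are provided:

* **Global LOOCV** — each known pair is zeroed in turn, the full
  pipeline retrained, and the pair's score ranked against all
  candidates.
* **miRNA-fixed / SM-fixed local LOOCV** — same loop with candidates
  restricted to pairs sharing the test pair's miRNA (resp. SM); test
  pairs whose restricted candidate set is empty are skipped with a
  logged notice.
* **Repeated k-fold CV** — positives partitioned into k folds with
  sizes differing by at most one (664 positives at k=5 give
  133/133/133/133/132), each fold masked in turn; the per-repetition
  AUC's mean and standard deviation are reported.

Because candidate sets differ between iterations in the local
protocols, each test score is converted to its normalized mid-rank
within its own iteration's candidate set, and the pooled AUC compares
those normalized ranks against the candidates' uniform quantiles via
the Mann–Whitney statistic (ties count ½ everywhere).  A perfect
predictor attains exactly 1.0 and a constant predictor exactly 0.5
under this convention, and the tie-grouped ROC curve integrates back to
the same AUC by the trapezoid rule.  ROC curves are plotted with FPR on
the x axis.  LOOCV retrains the model from scratch in every iteration —
the faithful default (`eval.rbm_retrain: full`); a warm-start mode is
reserved in the config for large-matrix runs but not implemented.

Hyperparameters are selected on training positives only:
`tune_hyperparameters` evaluates each σ_upper candidate
(0.05:0.05:0.50) with the NI base model and each hidden-unit candidate
(20:10:120) with the RBM base model over a shared inner k-fold split
(default k=5), scoring by mean AUPR — the right criterion under the
extreme class imbalance of this problem — and breaking ties toward the
smaller value.  Tuning each knob against its own base predictor rather
than the full ensemble keeps the inner loop linear instead of
quadratic in the grid sizes; the ensemble weights themselves are fixed,
not tuned.  AUPR uses step-wise interpolation (average precision).

## Synthetic data generator

`generate_fixture` emulates the one statistical assumption the method
relies on — similar entities share association partners — with a
planted-block design: SMs and miRNAs are assigned round-robin to
blocks; A(i,j) is Bernoulli(within_density) when the pair co-blocks and
Bernoulli(between_density) otherwise; similarities are two-level
(sim_within/sim_between) plus symmetrized truncated Gaussian noise,
clipped to [0,1] with unit diagonal.  The standard fixture is 20 SMs ×
30 miRNAs, 2 blocks, densities 0.4/0.02, similarities 0.8/0.2, noise
sd 0.05 — sized so that a LOOCV loop retraining the full ensemble per
iteration completes in seconds, and placed so the default threshold
grid straddles the two similarity levels.

What it does *not* emulate: the heavy-tailed degree distribution of
curated association databases (95% of compounds there have no known
partner at all), realistic similarity marginals, or correlated noise
between the similarity views.  Tests passing on the fixture therefore
demonstrate correctness of the machinery and sane ranking behavior
under the block assumption, not expected performance on real curated
data.

Two regimes serve as analytic anchors.  With within_density 1,
between_density 0 and noiseless similarities, any threshold strictly
between sim_between and sim_within isolates exactly the co-block
neighbors, every held-out pair scores 1 and every candidate 0, so NI
must reach LOOCV AUC exactly 1.0.  On the standard noisy fixture the
full ensemble is compared against a score-permutation null (each test
rank placed uniformly among its candidates, 100 permutations); the
observed AUC exceeds the null mean by several null standard deviations.

## Numerical choices and degenerate inputs

* Empty neighbor set → score 0 (NI); constant matrix → 0.5 (ensemble);
  empty profiles → similarity 0 (Jaccard); all mid-rank ties in metrics.
* All-zero association matrix → validation error at the connected-core
  filter; a single known pair → validation error in LOOCV (nothing to
  rank against in rotation).
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; repeated-CV repetitions use seed +
  repetition index.  Re-running any workflow with the same config is
  bit-identical.

## Known limitations

* Full retraining inside LOOCV makes the harness O(positives) model
  fits; at curated-database scale (hundreds of positives, 831×541
  matrix) a run is minutes-to-hours, and the reserved warm-start path
  would be needed for interactive use.
* The RBM's CD training details (epochs, learning rate, batch size, CD
  order) are package defaults, not values fixed by the method itself;
  different choices move the RBM's contribution within a few AUC
  points while NI is fully deterministic.
* The ensemble is a fixed 0.5/0.5 average after rank-preserving
  normalization; no stacking or learned fusion is attempted.
* Component similarities are consumed as precomputed matrices; the
  package computes only Jaccard profile similarities itself.
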