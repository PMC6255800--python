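# Methods

This note documents the models, the estimation and evaluation choices, the
synthetic-data generator, and the numerical conventions of `odortransfer`,
including the places where the design was genuinely open and what was
decided.

## Transfer models

The object of study is a pair of perceptual datasets rating (partly
overlapping) molecule sets on two different descriptor lexicons: a
*source* lexicon of `D_S` broad descriptors on a 0–100 scale and a
*target* lexicon of `D_T` fine-grained descriptors on a 0–5 scale. Each
descriptor also carries a fixed word-embedding vector (conventionally
300-dimensional), giving embedding matrices `Σ_S (D_S × dim)` and
`Σ_T (D_T × dim)`.

* **Baseline.** The per-descriptor mean target rating over the training
  molecules, `p̄_T`; the zero vector when no training molecules exist.
  Because odor profiles share much structure across molecules, this
  baseline correlates substantially with any molecule's true profile and
  is the reference every model must beat.
* **Semantic (zero-shot) model.** A linear map `S (D_T × D_S)` is fit so
  that `Σ_T ≈ S Σ_S` — each target descriptor's embedding, regressed on
  the source descriptors' embeddings across embedding dimensions. The same
  `S` is then applied to *ratings*: `p̂_T = S p_S + p̄_T`. No molecule and
  no target rating enters the fit of `S`; the fitter's signature does not
  even accept ratings tables, which makes the zero-shot property
  structural. `S` is fit without an intercept: the map is applied to
  ratings exactly as estimated, and an embedding-space offset would have
  no meaning on the ratings side.
* **Ratings (supervised) model.** `R (D_T × D_S)` is an elastic-net fit
  from source ratings to target ratings over molecules rated in both
  studies. `R` is trained on *baseline residuals* `p_T − p̄_T` so that the
  `+ p̄_T` added at predict time does not double-count the mean; a
  `residualize=False` flag fits raw targets for sensitivity analysis.
* **Imputed variants.** A chemistry-to-perception map
  `C (D_S × n_features)` predicts source ratings from molecular features
  (elastic net; NaN features imputed with training-molecule medians).
  Composing `S∘C` or `R∘C` scores molecules never rated in the source
  study. The imputed ratings model trains `R` on *imputed* source ratings
  paired with real target ratings, matching how it will be used at
  predict time.
* **Mixed model.** The elementwise mean of the semantic and ratings
  predictions — algebraically `½(S + R) p_S + p̄_T`. This identity is
  exact and tested to machine precision.

## Elastic-net engine

All maps minimize, independently per output,
`Σ_i ‖Y_i − A X_i‖² + λ₁‖A‖₁ + λ₂‖A‖₂²` with the intercept fit by
column-centering and never penalized. One `(λ₁, λ₂)` pair is shared by all
outputs and selected by inner k-fold cross-validation (10 folds by
default, reduced with a logged warning when there are fewer samples)
minimizing pooled held-out squared error; exact ties go to the larger
total penalty. Default grids are `{0} ∪ 7 log-spaced points in [1e-3, 10]`
for both strengths. Pooled (rather than per-output) tuning reflects the
framework's premise of *one* transformation per model rather than
per-descriptor models.

Numerics: both penalties zero → minimum-norm least squares (`lstsq`);
`λ₁ = 0` → closed-form ridge; otherwise scikit-learn coordinate descent
with the raw-objective `(λ₁, λ₂)` mapped onto `alpha`/`l1_ratio`. The
limiting cases are verified against the closed forms to 1e-6. An optional
`standardize` flag z-scores the design columns before fitting (weights
are reported on the original scale); it is off by default — columns of a
ratings or embedding matrix are already commensurate — but it is what
makes a fixed λ-grid meaningful across input scales, so the
cross-validation harness and CLI enable it.

## Evaluation

Per molecule, performance is the Pearson correlation across the `D_T`
target descriptors between predicted and observed profiles; per-molecule
correlations with zero variance are NaN, logged, and excluded from
medians (with counts reported). Model-vs-baseline significance uses the
dependent-correlation statistic for two correlations sharing a variable
(the truth): `Z = √(N−3)·(z(r_GM) − z(r_GB)) / √(2(1−s))`, with `s` the
Pearson–Filon/Steiger covariance term driven by `r_MB` and `N = D_T`.
One printed variant of this formula circulating in the application
literature is internally inconsistent (its numerator compares the wrong
pair); an `as_printed=True` flag reproduces that literal form for
comparison, while the default is the standard statistic, whose null
calibration (5% ± 2% at |Z| > 1.96 under equal population correlations,
N = 131) is verified by simulation in the acceptance suite. With no
training molecules the baseline correlation is identically zero and `Z`
reduces to the Fisher transform of `r`. Infinite values at `|r| = 1` are
capped at ±38 (the double-precision `atanh` overflow guard) and logged.

**Cross-validation harness.** `cv_curves` repeats seeded k-fold splits of
the shared molecules (default 10 folds); within each repetition the train
side is subsampled without replacement to each requested `n_train`, the
baseline and `R` are refit, and all models are scored on the fold's test
molecules. `S` is fit once — it involves no molecules. Medians are taken
across molecules within a repetition (tidy output: one row per model ×
`n_train` × repetition) and across repetitions for curve points.
`n_train = 0` is valid only for the semantic and baseline models and
scores them against the zero baseline.

One harness convention deserves emphasis: `harmonize_scales=True`
multiplies the source ratings by the single scalar gain mapping the
source scale width onto the target's (5/100 for the default scales). A
common positive gain leaves every individual model's per-molecule
correlation *exactly* unchanged, but it is essential for the mixed model:
without it, the semantic stream `S·p_S` inherits the 0–100 source scale
and numerically swamps the ratings stream (which learns the 0–5 target
scale), reducing the plain average to a copy of the semantic model. A
per-descriptor z-scoring was considered and rejected — unequal descriptor
variances make it a non-uniform transformation that distorts the
semantic map's predictions.

**Descriptor-count sweep.** Given a priority order of the source
descriptors (typically the prototype-selection order), the semantic map
is refit on each prefix `k = 1…D_S` and scored by leave-one-out
cross-validation over molecules (the left-out molecule's baseline is the
mean of the others). `k = 1` is permitted here even though a standalone
semantic fit requires `D_S ≥ 2`.

**Paradigm-odor scoring.** Rank-based ROC AUC with midrank ties
(satisfying `AUC(s) + AUC(−s) = 1` exactly), a one-sided two-sample
t-test per molecule for "paradigm descriptors score higher", and an exact
Kolmogorov–Smirnov test of the resulting p-values against Uniform(0, 1).

## Prototype selection

Ranking source descriptors uses greedy MMD prototype selection: with
kernel matrix `K` on candidates and `μ_p` the mean kernel evaluation
against the data set, maximize `l(w) = w'μ_p − ½w'Kw` over non-negative
weights supported on the selected set. Each step adds the candidate with
the largest gradient `μ_p − Kw` (ties to the lowest index) and refits the
weights by an active-set NNLS reformulation of the non-negative QP
(Cholesky with a ~1e-10-scaled jitter ladder). Applied to ratings,
candidates are descriptor columns of the raw (unstandardized) molecule ×
descriptor matrix with the data set equal to the candidate set.

Kernel default: Gaussian with the median pairwise-distance bandwidth on
the candidates; a linear kernel is available for exact small-case
algebra. The greedy scheme carries an approximation guarantee, not
optimality: on small *low-coherence* instances (well-separated points,
near-diagonal `K`) it provably coincides with exhaustive subset search
and the acceptance suite verifies agreement to 1e-8 on 50 such seeded
instances across both kernels; on highly coherent clouds it is an
approximation by design (verified to reach ≥ 0.7 of the brute-force
optimum in the module tests). Reported invariants — non-negative
weights, non-decreasing objective trace, MMD non-increasing in the
number of prototypes — are asserted unconditionally.

## Structure analyses

The ratings-basis cross-correlation matrix correlates each target
descriptor's rating profile (across shared molecules) with each source
descriptor's; the semantic-basis matrix does the same with embedding
vectors. Correspondence tests:

* **Procrustes permutation test** — observed Procrustes dissimilarity
  (translation + scaling + orthogonal rotation) versus row-permuted
  surrogates of the second matrix; permuting rows destroys exactly the
  descriptor correspondence under test. Both the add-one permutation
  p-value and a one-sided Wilcoxon on surrogate-minus-observed are
  reported, since the choice between them is ambiguous in the original
  description.
* **Maxima-Spearman** — for each descriptor on the chosen axis, the
  maximum correlation it attains in each matrix; Spearman correlation
  between the two maxima sequences.
* **Smoothness tests** — nearest-neighbor correlation of a per-descriptor
  performance vector over the semantic space, and leave-self-out
  1/distance-weighted k-NN regression MSE, each against a null that
  relabels descriptors before the neighbor lookup. All permutation
  p-values use the add-one estimator, so the smallest reportable p is
  `1/(n_perm+1)`.

Organization tools: average-linkage agglomerative clustering on cosine
distances (with Newick export) and 2-D metric MDS by stress majorization
on cosine distances, seeded random initialization with best-of-8
restarts.

## Synthetic-data generator

`make_scenario` plants one ground-truth map `true_S (D_T × D_S)` with
dense, signed, ℓ2-normalized Gaussian rows and threads it through *both*
views:

* target embeddings = `true_S ·` source embeddings + semantic noise
  (`noise_semantic`, in units of a unit-norm embedding row);
* latent molecule loadings = sparse non-negative features `×` non-negative
  coefficients `true_C` (+ `noise_chem`), with each source descriptor
  reading its own disjoint feature block so loading columns are
  independent with no common molecule-activity factor;
* source ratings = loadings scaled by a pure gain onto [0, 100]
  (+ `noise_ratings`, in scale-width units, clipped with a logged
  fraction);
* target ratings = `true_S ·` loadings mapped affinely onto [0, 5]
  (+ noise, clipped). The affine offset is benign because per-molecule
  Pearson evaluation is affine-invariant, which is also why the
  zero-noise scenario is *exactly* identifiable: an unpenalized semantic
  fit recovers `true_S` and achieves per-molecule r = 1.

Design rationale. Dense signed map rows make every cross-correlation
entry carry a continuous value, so the ratings-basis and semantic-basis
matrices agree up to monotone distortion (entrywise rank correlation
≈ 0.96 at large scale; at the default 58 shared molecules the
finite-sample correlation noise alone caps the agreement near 0.84 — a
measurement limit, not a generator defect). Disjoint chemistry blocks
with non-negative terms give the loadings the positive skew of real odor
profiles and keep their covariance near-diagonal, which is what lets the
correlation structure of the ratings read off `true_S`.

Noise defaults (`noise_semantic = 2.0`, `noise_ratings = 0.02`,
`noise_chem = 0.1`) encode the regime the method addresses: word use is a
real but rough proxy of perception, so the zero-shot model plateaus at a
median Z around 3–4 — clearly above baseline, clearly below what a
supervised ratings map achieves once enough co-rated molecules exist —
while averaged ratings themselves are comparatively clean. Under these
defaults the learning curves reproduce the qualitative shape the
framework predicts: a flat zero-shot curve, a supervised curve rising
from the baseline and overtaking it, and a mixed curve never below the
supervised one. Sizes default to the motivating datasets (19/131
descriptors, 300 dimensions, 58 + 70 molecules) with `n_features = 500`
standing in for a full physicochemical block to keep runs in seconds; the
learning-curve analyses in the tests and acceptance script use a reduced
scale (60 target descriptors, 150 embedding dimensions, 160 shared
molecules) chosen so the supervised model can approach its asymptote
within the molecule budget.

What the generator does *not* emulate: real chemistry (features are
abstract sparse non-negatives), subject-level rating noise and response
styles, non-linear semantic–perceptual relations, and the heavy-tailed
marginal distributions of real panels. Passing tests therefore
demonstrate correctness and calibration of the machinery and
recoverability under the planted model — not real-data effect sizes,
which require the external ratings, embedding and chemoinformatic files.

## Numerical conventions and edge cases

* Descriptors are lowercased and whitespace-normalized; exact-match
  embedding lookup drops multiword descriptors into the `missing` list
  (logged, never silent); an optional `subword_mean` policy averages
  constituent-word vectors instead.
* CSV round-trips are exact (full-precision float repr).
* Molecule alignment takes the intersection in the first table's order
  and is idempotent; empty intersections raise.
* Degenerate correlation triples in the dependent-Z (non-PSD, `s ≥ 1`)
  raise in the scalar API and become logged NaNs inside bulk evaluation.
* Zero cosine distances in the k-NN weighting fall back to 1/rank
  weights; nearest-neighbor ties resolve to lexicon order.
* All stochastic procedures (fold assignment, subsampling, permutations,
  MDS restarts, generators) are driven by explicit integer seeds and are
  bit-reproducible.

## Known limitations

* The greedy prototype selection is exact only in low-coherence regimes;
  on strongly correlated descriptor sets the selection order is an
  approximation (with refitted weights still optimal for the selected
  support).
* Pooled `(λ₁, λ₂)` selection can under-regularize a minority of outputs
  whose noise level differs strongly from the pool.
* The mixed model's plain average is scale-sensitive by construction; the
  harness's scalar gain harmonization addresses the default scales but a
  principled stacked combination is out of scope.
* Per-subject (non-averaged) ratings, odor mixtures, and richer lexical
  structure (synonymy/antonymy) are outside the package's scope.
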