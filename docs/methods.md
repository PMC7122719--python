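# Methods

## Model and procedure

The package scores ordinal self-report questionnaires in a semantic word
vector space. Its core assumptions are:

* **Distributional semantics.** Item wording carries clinical information
  beyond the ordinal code, and that information is recoverable from word
  embeddings trained on a large biomedical/psychiatric corpus: related
  items land near each other in the vector space even when they share no
  vocabulary.
* **Linear response weighting.** A patient's survey representation is the
  sum of item vectors multiplied by the integer ordinal answer on each
  item's native printed scale. The construction is linear and homogeneous
  in the answers; an answer of 0 contributes nothing. This asymmetry is
  inherited from the construction itself — items are not recoded or
  centered — and is documented rather than "fixed", because reverse-scored
  item detection is out of scope.
* **Low-dimensional symptom structure.** The leading principal components
  of each patients × d survey matrix capture severity axes; the first
  canonical correlation variable (CCV) against a 13-column self-rated
  symptom-domain matrix extracts the component of the survey matrix that
  is about symptoms rather than generic wording variance; cosine
  similarity to seed-word domain vectors yields bounded [-1, 1] RDoC-style
  domain scores.

### Pipeline stages

1. **Corpus.** `preprocess_text` lowercases, strips punctuation and splits
   on whitespace; an optional fixed-suffix stemmer stands in for
   heavyweight lexical normalization, trading linguistic coverage for
   exact reproducibility. IDF uses the classic `ln(N/df)` (a smoothed
   variant `ln((1+N)/(1+df)) + 1` is available behind a flag). One
   preprocessed input record counts as one document for `df` and `N`.
   `train_embeddings` implements skip-gram with negative sampling in
   numpy — single-threaded, seeded, bit-reproducible — suitable for
   desk-scale corpora; pretrained vectors in word2vec text format can be
   read instead for production use.
2. **Embedding.** Tokens missing from either the embedding vocabulary or
   the IDF table are skipped (they contribute the zero vector), matching
   a minimum-frequency vocabulary cut. Question vectors are not length
   normalized before summation (the raw construction), with unit
   normalization available for sensitivity analysis. IDF weights are not
   renormalized within a question.
3. **Scores.** PCA is computed by SVD of the column-centered matrix; CCA
   z-scores both blocks and solves the whitened cross-covariance SVD with
   a ridge of 1e-9 on each block covariance for rank safety (small enough
   that a shared column still yields a canonical correlation of 1 within
   1e-8). The number of PCs fed to CCA is the smallest count explaining
   80% of variance, capped at 10. PC and canonical directions have their
   largest-|loading| coordinate made positive so bootstrap replicates are
   comparable. RDoC patient vectors pool questions across all surveys
   (per-survey pooling would tie every domain score to one instrument's
   vocabulary); because the question-domain cosine weights can be
   negative, the weighted average normalizes by the sum of |weights|. The
   cosine of a zero vector is defined as 0 throughout, so all-zero
   responders propagate zeros rather than NaNs.
4. **Evaluation.** The bootstrap unit is the patient, resampled with
   replacement within each diagnostic group so both classes survive every
   replicate. GMM: two components, full covariance, k-means++
   initialization, 5 restarts, tolerance 1e-6, max 500 EM iterations;
   metrics are in-sample on the replicate by default, with an out-of-bag
   mode that scores the replicate-fitted, replicate-oriented model on the
   patients left out of the resample. Logistic regression uses a large-C
   (near-unpenalized) L2 model with 10-fold stratified CV inside each
   replicate; features are z-scored with training-fold statistics only.
   Confidence intervals are percentile (2.5, 97.5). The permutation test
   treats bootstrap replicate metrics as exchangeable samples; replicate
   values are positively correlated across resamples, so its p-values are
   calibrated for comparing procedures on the same replicates rather than
   as strict independent-sample tests.
5. **Associations.** Spearman correlations use midranks and pairwise
   deletion (cells with fewer than 3 complete pairs or a constant column
   are marked missing); regressions use listwise deletion. Outcomes with
   sample skewness |g1| > 1 are replaced by `ln(x - min(x) + 1)`; the
   shift guards nonpositive values, and constant columns (skewness taken
   as 0) are left alone. LASSO penalties are chosen on a 100-point
   log-spaced path from the smallest all-zero penalty down to 1e-4 of it,
   minimizing `AIC = n·ln(RSS/n) + 2·df` with `df` the nonzero-coefficient
   count (the standard LARS-style estimate); ties break toward the larger
   penalty, and RSS is floored at 1e-12 so the log never diverges.

## Numerical choices worth knowing

* **Posterior orientation.** Mixture posteriors saturate to 0/1 at double
  precision, and the float map `p -> 1-p` is not exactly order-reversing
  (distinct near-1 values collapse into ties). `align_clusters` therefore
  quantizes posteriors to a 1e-12 grid before orienting, which makes the
  flip exactly tie-preserving and guarantees the oriented in-sample AUC is
  ≥ 0.5. Consequence: under the null the in-sample GMM AUC distribution
  sits at 0.5 from above; use the out-of-bag mode when a null-calibrated
  GMM AUC is needed.
* **Fold assignment.** Cross-validation folds are dealt over a canonical
  (label, feature) lexicographic ordering of rows, so out-of-fold metrics
  are exactly invariant to patient order at a fixed fold seed.
* **Threshold convention.** Hard assignments use `p >= 0.5`. AUC is the
  tie-averaged Mann-Whitney rank statistic and equals brute-force pair
  enumeration exactly.
* **Embedding file I/O** prints 9 significant digits, which keeps a
  write/read round trip within 1e-6 per component.
* **Missing answers** default to per-question median imputation rounded to
  the nearest in-range integer; "zero" and "drop" policies are available.
  Median imputation keeps the matrix complete without inventing severity.

## The synthetic study

`simdata` emulates the structure the method assumes, not real language or
real instruments:

* a vocabulary of 500 synthetic tokens partitioned into 5 orthogonal
  topics (one per latent symptom domain), token vectors = topic centroid
  plus isotropic noise, IDF drawn log-uniform on [0.5, 5], and per-domain
  seed words taken nearest each centroid;
* a cohort of 310 patients in three a-priori groups — 64% cases (matching
  the motivating cohort's 198/310), with the remaining split 13% control /
  23% supercontrol as the package's choice — with latent severities
  `z ~ N(mu_group, I)` per domain, `mu = 2, 1, 0` SD for case, control,
  supercontrol by default;
* nine surveys of 10 ordinal items each (0–4), item text sampled from the
  item's domain topic, answers produced by a graded-threshold
  (cumulative-probit-style) model on `z + noise` — chosen because the
  scoring construction multiplies by ordinal level, so a monotone
  severity-response link is the structure being presumed;
* a 13-column symptom matrix and outcome measures linear in `z` plus
  noise, including one pure-noise outcome as a negative control.

Passing tests on this generator show that the pipeline recovers planted
linear, monotone, topic-aligned structure and is calibrated when no
structure exists. They do not show robustness to real-world features the
generator omits: polysemous natural language, reverse-scored or skip-logic
items, instrument-specific response styles, missingness that is not at
random, or correlated latent domains.

Default problem sizes (d = 50, vocabulary 500, n = 310, 50–100 bootstrap
replicates in tests and the acceptance script) are chosen so the whole
suite runs in well under an hour on one CPU; full scale (d = 500, B = 500)
is reachable through `SimConfig` and the `B`/`n_alphas` arguments.

## Known limitations

* AIC-based LASSO selection is liberal: on pure-noise outcomes with
  n = 300 and 18 features it returns supports of 3–8 variables in roughly
  40% of draws (sklearn's `LassoLarsIC` behaves identically). Treat small
  nonzero coefficients under AIC as exploratory; a BIC-style criterion
  would select more conservatively but is not what the procedure
  specifies.
* The skip-gram trainer is desk-scale: it is exact and reproducible but
  makes no attempt at the throughput needed for hundreds of thousands of
  documents; use pretrained embeddings for corpora of that size.
* In-sample GMM metrics are optimistic by construction (orientation and
  fit use the same replicate); the out-of-bag flag exists precisely for
  null calibration.
* Only ordinal-response items are supported; free-text and categorical
  items are out of scope, as is factor-analytic or IRT scoring.
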