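# Methods

## Problem and model

The package predicts continuous drug–target binding affinities (DTBA) from
a weighted heterogeneous graph rather than from 3-D structures. The inputs
are a drug × target affinity matrix Y (possibly sparse), drug–drug and
target–target similarity matrices, and the entities' raw representations
(SMILES strings, amino-acid sequences). Three node/edge classes make up
the graph G(V, E): drug–drug similarity edges, target–target similarity
edges, and drug–target affinity edges. All edge weights live in [0, 1]
and larger weight always means a stronger relationship.

The pipeline has four stages:

1. **Graph construction.** Each similarity matrix is min–max normalized
   and thresholded (entries below the cutoff become 0; the diagonal is
   forced to 0 so that no meta-path can re-enter the node it is standing
   on). Raw affinities are first re-oriented to a *distance-like*
   quantity (smaller = stronger binding): raw values are used directly on
   lower-is-stronger scales (Kd in nM, raw KIBA score), and `max − value`
   on higher-is-stronger scales (pKd). The distance z is then mapped to
   an edge weight by `exp(−α·z)` (default) or by a softmax of −z rescaled
   so its largest edge is 1. The transform only ever sees *training*
   affinities — held-out edges contribute nothing, not even to the
   softmax normalizer.
2. **Meta-path score features.** For each drug–target pair and each of
   the six drug-to-target path structures with at most three edges
   (D-D-T, D-T-T, D-D-D-T, D-T-T-T, D-D-T-T, D-T-D-T), the score of a
   path is the product of its edge weights; the features are the sum and
   the maximum of those products over all *simple* paths of that
   structure — 12 features per source graph, 24 when two graphs (one
   from provided similarities, one from embedding cosines) are combined.
3. **Sequence embeddings.** Proteins are embedded ProtVec-style: a
   skip-gram model is trained on three lists of shifted non-overlapping
   3-grams per sequence, and a protein's vector is the sum of the
   vectors of all of its overlapping 3-grams (averaging is available by
   flag). Drugs are embedded by a pluggable encoder contract; the default
   is a deterministic hashed token-n-gram encoder with a seeded Gaussian
   projection, and a GRU sequence-autoencoder whose bottleneck is the
   fingerprint can be trained instead.
4. **Regression.** Gradient-boosted trees (XGBoost, squared-error
   objective) on one of three feature variants: PSCORE (meta-path scores
   only), EMBED (concatenated drug ∥ protein embeddings), HYBRID
   (PSCORE then EMBED columns).

## Walks vs. simple paths

The sum scores are computed as commuting-matrix products (C1: DD·A,
C2: A·TT, C3: DD²·A, C4: A·TT², C5: DD·A·TT, C6: A·Aᵀ·A) and the max
scores as the analogous (max, ×) semiring products. Matrix products count
*walks*; the path definition requires each node to appear only once. With
zero diagonals on DD and TT the only offending walks are:

* C3: d_i → d_k → d_i → t_j, contributing `diag(DD²)_i · A_ij`;
* C4: d_i → t_j → t_l → t_j, contributing `A_ij · diag(TT²)_j`;
* C6: walks revisiting d_i or t_j, contributing
  `A_ij·diag(AAᵀ)_i + A_ij·diag(AᵀA)_j − A_ij³` by inclusion–exclusion.

Simple-path semantics subtracts these closed forms (sums) or excludes the
offending candidates via zeroed semiring diagonals and a top-2 fallback
for C6 (maxima). Both semantics are selectable (`semantics="simple"` is
the default, `"walk"` matches plain matrix products); matrix results are
verified against a brute-force simple-path enumeration oracle on hundreds
of random graphs to < 1e-10.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `alpha` | 1.0 | decay rate of `exp(−α·z)` on the distance-like affinity; selected from the grid {0.1, 0.5, 1.0} by validation on the synthetic reference conditions |
| `drug_threshold` | 0.3 | similarity cutoff for drug–drug edges (Davis-style 2-D-structure similarity setting) |
| `target_threshold` | 0.04 | similarity cutoff for target–target edges (Davis-style normalized alignment-score setting) |
| protein k-mer dim | 100 | ProtVec-style embedding width |
| drug encoder dim | 128 | fingerprint width (search space {128, 256, 512, 1024}) |
| boosting | 500 trees, depth 6, lr 0.05, subsample 0.8 | tuned per run via `tune()` when a grid is supplied |

## Evaluation

* **MSE / RMSE** on the continuous predictions.
* **Concordance index**: over all pairs with distinct actual affinities,
  the average of h(Δpred) with h = 1 / 0.5 / 0 for positive / zero /
  negative differences; an O(n log n) Fenwick-tree implementation is
  checked for exact equality against the O(n²) definition.
* **rm²** = r²·(1 − √(r² − r0²)), r² the squared Pearson correlation and
  r0² the determination coefficient of the least-squares fit through the
  origin of actual on predicted (the axis convention is a flag; the
  radicand is floored at 0 against float cancellation).
* **Thresholded AUPR**: affinities binarized at one or more thresholds
  (≥ t positive on pKd-style scales, ≤ t selectable for raw scales),
  average-precision computed with scores oriented so larger = more likely
  positive, and averaged over thresholds that contain both classes.
* **Y-randomization**: the model is refit on label-shuffled training data
  (default 100 iterations); the observed test r² is located in the
  permuted r² distribution both parametrically (normal fit) and by
  empirical rank (count + 1)/(n_iter + 1).

## Experimental protocols

**Nested CV (setting 1).** Labelled pairs are randomly partitioned into
six near-equal sets; one is the hold-out, the other five are inner folds.
For every inner fold the graph is rebuilt with that fold's *and* the
hold-out's affinity edges removed (asserted programmatically), the model
is trained on the remaining pairs, and the hold-out is scored. Hold-out
metrics are computed on the average of the five models' prediction
vectors (a bagging reading of "the five models' averages on the hold-out";
averaging the five metric values instead is available via
`aggregate_predictions=False` — the two differ by ensemble variance
reduction only).

**Time split (setting 2).** With a per-pair year map: train on years
≤ 2011, validate on 2012, test on ≥ 2013 (boundaries configurable).

**Feature normalization.** `normalize_train_test` offers INDEPENDENT
(each block scaled by its own column min/max — its literal default) and
FIT_ON_TRAIN (train min/max applied to both, test clipped to [0, 1]).
The pipeline (`RunConfig`) defaults to FIT_ON_TRAIN: it is leakage-safe
and keeps tree split thresholds on one scale; INDEPENDENT rescaling of
differently-sized blocks measurably distorted tree models in our runs.

## Synthetic data generator

The generator emulates the guilt-by-association premise directly: drug
latents u_i and target latents w_j are i.i.d. standard normal in
`latent_dim` dimensions, the noise-free affinity is an affine map of
u_i·w_j onto the affinity range, observation noise is Gaussian, and the
similarity matrices are min–max-normalized cosine similarities of the
latents. The affine map sends mean ± 3 sd of the latent products to the
range endpoints, so the signal's standard deviation is range/6 — the
spread of a dense kinase-panel pKd dataset (≈ 0.9 over a 5.0–10.8
range) — rather than the much flatter signal a strict min/max map would
produce. Defaults are a 60 × 50 fully observed panel, 5 latent factors,
and noise at 10% of the affinity range; `density=0.244` emulates the
sparse KIBA-style regime.

What the generator does *not* emulate: real chemistry (SMILES-like
strings are random token strings), heavy-tailed or truncated affinity
distributions (the Davis floor at pKd 5.0), systematic missingness, and
assay noise correlated by drug or target. Passing recovery tests
therefore demonstrate that the pipeline's machinery extracts
guilt-by-association signal without leakage — not benchmark-level
performance on real data.

## Numerical choices and degenerate inputs

* Constant columns under min–max normalization map to zero; an empty
  softmax input, all-tied actuals in the concordance index, and
  zero-variance rm² inputs raise errors.
* All-zero embedding rows get cosine similarity 0 with a warning.
* Simple-path corrections can leave tiny negative residues by float
  cancellation; sum scores are clipped at 0.
* Tie-breaks in hyperparameter tuning go to fewer trees, then shallower
  depth. XGBoost runs single-threaded (`n_jobs=1`) with a fixed seed, so
  reports are byte-reproducible.
* A single global seed fans out to split/encoder/regressor seeds via
  `numpy.random.SeedSequence`, all below 2³¹.

## Design choices where the design was open

* **Affinity orientation.** Whether a dataset's raw scale is
  higher-is-stronger (pKd) or lower-is-stronger (Kd nM, raw KIBA) is an
  explicit flag on the dataset, and the edge transform is always applied
  to the distance-like quantity so larger edge weight = stronger binding
  regardless of the input scale.
* **Softmax edge weights** are computed over all observed training
  affinities at once (one probability vector, not per drug row), applied
  to the negated distance, and rescaled so the strongest edge has weight
  1 to stay commensurate with similarity edges.
* **Skip-gram trainer.** The 3-gram embedding model is a compact
  numpy implementation of skip-gram with negative sampling (window 5,
  min_count 1, 10 epochs, unigram^0.75 negatives), single-threaded and
  deterministic by seed; pretrained vectors can be loaded from word2vec
  text format instead.
* **GRU autoencoder.** Written directly in numpy with manual
  backprop-through-time and Adam (the contract only requires
  `fit_corpus`/`encode`, so any stronger external encoder can be slotted
  in); it is intended for small corpora and desk-scale verification.
* **Early stopping** is off by default in the boosted-tree wrapper: on
  12-feature inputs with noisy labels a 10% validation carve-out
  systematically underfit. It remains available for wide feature sets.

## Problem sizes used in the shipped checks

Oracle equivalence uses 200 random graphs with at most 8 drugs/targets;
metric oracles use 500 random instances (concordance) and 10,000 points
(AUPR null); signal recovery uses twenty 60 × 50 replicates under nested
CV; Y-randomization uses 100 shuffles of a 30 × 25 panel with a reduced
(40-tree) model. These sizes make every check reproducible on a single
CPU in about a minute each.

## Known limitations

* Transductive by construction: a drug or target absent from the graph
  at fit time has no meta-path features (cold-start is out of scope).
* The default drug encoder is untrained (hashed n-grams); its cosine
  similarities are lexical, not chemical.
* SIMCOMP / Smith–Waterman similarity computation is out of scope; the
  package accepts precomputed matrices and offers a hashed-n-gram
  Tanimoto fallback for testing.
* Paths are limited to three edges; longer structures would require
  further revisit corrections.
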