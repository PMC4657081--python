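# Methods

## Problem and model

Real pre-miRNA hairpins are vastly outnumbered by hairpin-shaped decoys
(pseudo hairpins from protein-coding regions).  A classifier trained
naively on such data maximizes accuracy by calling almost everything
negative, which is useless for discovery: the quantity that matters is
sensitivity on the rare positives, without giving up specificity.  The
package addresses this with a cost-sensitive boosting ensemble over
balanced undersamples:

1. **Representation.**  Each hairpin is a 139-dimensional vector of
   sequence composition, secondary-structure topology and folding-energy
   features (full formula table in `features.md`).  The classifier is
   representation-agnostic: it accepts any labeled numeric table, which
   is how the synthetic benchmark exercises it.
2. **Initial weights.**  With |V| samples, every positive starts at
   C_P/|V| and every negative at C_N/|V|, C_P ≥ C_N > 0 (defaults 1 and
   0.6).  Misclassifying a real pre-miRNA is deemed costlier than
   misclassifying a decoy.
3. **Iteration 1.**  All negatives are clustered into k groups (k =
   number of positives) by K-means under the Rogers–Tanimoto distance

       dis(v_x, v_y) = 1 − (v_x·v_y)/(v_x·v_x + v_y·v_y − v_x·v_y),

   and the member closest to each center joins the first balanced
   training set A₁ (k positives + k representative negatives).  M₁ is an
   RBF-kernel SVM fit on A₁.
4. **Boosting loop (t = 1 … T).**  M_t classifies all of V; its error is
   φ_t = 1 − G_m(M_t), with G_m = √(SE·SP), clamped into (0, 0.5).  With
   θ_t = φ_t/(1 − φ_t) ∈ (0, 1), every correctly classified sample's
   weight is multiplied by θ_t while misclassified samples keep theirs;
   weights are then renormalized to constant total mass.  The next
   balanced subset takes all k positives plus k negatives drawn without
   replacement with probability proportional to current weights, and
   M_{t+1} is fit with the current weights as per-sample importance.
5. **Prediction.**  Instance t votes with weight log(1/θ_t); a sample is
   called positive when the positive vote mass reaches half the total
   (ties resolve positive, consistent with the cost asymmetry).  A
   normalized vote score in [0, 1] is returned alongside the label.

Evaluation uses SE = TP/(TP+FN), SP = TN/(TN+FP), Acc and G_m.  Under
heavy imbalance Acc ≈ SP, so G_m is the headline statistic.

## Parameters

| Parameter | Default | Meaning / rationale |
|---|---|---|
| `C_P`, `C_N` | 1.0, 0.6 | misclassification costs; C_N = 0.6 is the published optimum of a 0.1-step grid on the original data |
| `T` | 300 | boosting iterations; tests and the synthetic benchmark use T = 30, which is enough for vote weights to stabilize there |
| `phi_epsilon` | 1e−6 | clamp for φ_t; a perfect instance gets a large but finite vote weight, a degenerate one (G_m ≤ 0.5) a vanishing positive weight |
| base learner | SVC(C=1, RBF, gamma="scale") | see numerical choices |
| `use_sample_weights` | True | weights enter the fit as per-sample importance; set False to let weights drive selection only |
| `seed` | 0 | master seed; iteration t uses seed + t, so traces are reproducible and iterations order-independent |

## Numerical and design choices

* **Feature scaling.**  All features are min-max scaled to [0, 1]
  per column (parameters learned on training data, stored in the model,
  out-of-range values clipped at transform time).  This keeps vectors
  nonnegative, which bounds the Rogers–Tanimoto distance in [0, 1] and
  makes K-means assignments well behaved; signed features such as dG are
  handled by the same scaling.
* **K-means details.**  k-means++-style seeding, Lloyd iterations with
  Rogers–Tanimoto assignment and arithmetic-mean centroids, at most 100
  iterations or relative inertia change < 1e−4; an emptied cluster is
  reseeded with the point farthest from its center.  Written in-package
  because library K-means implementations fix the Euclidean metric.
* **Weighted sampling without replacement** uses the exponential-race
  scheme (keys Exp(1)/w_i, keep the k smallest), distributionally
  identical to sequential draws proportional to remaining weight.
* **RBF width.**  In min-max-scaled space, pairwise squared distances
  are far below the dimension n, so the classical 1/n width leaves the
  kernel nearly constant and the base SVM degenerates into a one-class
  voter (measured G_m 0.67 vs 0.90 on a small benchmark).  The default
  is therefore the variance-aware width 1/(n·Var(X)); both are
  selectable through `base_learner_params`.
* **Fit-weight normalization.**  Boosting weights sum to 1 over all |V|
  samples; passed raw into an SVM fit they would multiply into the
  effective regularization C and cripple the learner.  Weights are
  rescaled to mean 1 over each balanced subset — relative importance is
  preserved, absolute scale is neutralized.
* **Weight renormalization** after each update keeps total mass
  constant.  Selection probabilities are scale-free, so this is purely a
  guard against underflow of θ^t products over hundreds of iterations.
* **Stems and loops.**  A stem is a maximal run of ≥ 3 stacked pairs; a
  hairpin loop is an innermost pair enclosing only unpaired bases.
  Structures with pairs but no ≥ 3 run have n_stems = 0 and fall under
  the zero-denominator conventions of `features.md`.
* **`|X−Y|%/n_stems` reading.**  Interpreted as the stem-region fraction
  of each pair class (stem pairs of that class / total pairs) divided by
  n_stems.  The alternative reading (all pairs, not stem-restricted)
  differs only for structures with isolated pairs.
* **Folding backend.**  `fold_hairpin` uses the ViennaRNA bindings for
  the MFE structure, ensemble free energy, MFE-structure frequency,
  ensemble diversity and pairing-probability entropies.  Melting
  quantities are not equilibrium-folding outputs, so dH is accumulated
  from nearest-neighbor stack enthalpies over the MFE structure,
  dS = (dH − dG)/T at 310.15 K, and Tm = dH/dS; each fold records its
  provenance (`viennarna` / `file` / `synthetic`).  Classifier behavior
  never depends on these surrogates — fold files and the synthetic
  generator supply scalars directly.
* **Tie-breaks.**  An exact vote tie is called positive.  Duplicate
  points that leave a K-means cluster without a free representative fall
  back to the nearest unclaimed point.

## Synthetic data: what it emulates and what it does not

`gen_gaussian_bench` emulates the *imbalance regime*, not RNA biology: a
single positive Gaussian mode against several negative modes placed at a
controlled separation (in shared-SD units).  Cluster geometry is a fixed
function of (dim, neg_clusters, separation), so draws with different
seeds sample one population and an honest holdout exists.  The default
benchmark — 100 positives vs 5,000 negatives, 20 dimensions, separation
2.5, 3 negative clusters, seeds 1–20, T = 30 — makes an unweighted SVM
collapse to the majority class (SE ≈ 0, SP ≈ 1), the failure mode the
ensemble is designed to fix.  Passing these tests shows the *mechanism*
works (balanced instances recover sensitivity at bounded specificity
cost); it does not show field-realistic accuracy, because real hairpin
features are non-Gaussian, correlated and informative in ways this
generator does not model.

`gen_hairpins` produces designed stem-loops (random arm + loop +
reverse-complement arm, optional point mutations) whose dot-bracket
structure is known by construction, with clearly flagged surrogate
thermodynamic scalars, so feature extraction is testable without any
folding backend.  It does not sample realistic thermodynamics or
miRBase-like composition.

## Observed training dynamics and limitations

* The cost asymmetry acts mechanically at the instance level: with
  C_N = 0.6, M₁ recovers more holdout positives than with C_N = 1.0
  (higher relative positive fit weight; positive difference on 12/12
  benchmark seeds).  Over many iterations, however, the *ensemble-level*
  effect of lowering C_N depends on the weight dynamics of the data:
  instances biased toward positives classify them correctly, so positive
  weights decay faster (×θ_t per iteration), and later instances can
  swing toward specificity.  On the Gaussian benchmark the net
  ensemble-level SE at C_N = 0.6 is actually below C_N = 1.0; the
  published optimum of C_N was established on real hairpin data, and
  users should treat C_N as a dataset-specific knob rather than a
  monotone sensitivity dial.
* Each base instance sees only 2k samples; when k is small relative to
  the feature dimension, base SVMs underfit and φ_t hovers near 0.5,
  contributing near-zero vote weight.  Increasing T compensates only
  partially.
* φ_t is measured on the full training set V (as specified by the
  procedure), so it is an optimistic, partially in-sample estimate;
  model selection should rely on held-out G_m.
* Problem sizes in the test suite (benchmarks of 30/300 up to 100/5,000
  samples, T between 1 and 30) were chosen as the smallest scales at
  which the imbalance phenomena are clearly expressed.
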