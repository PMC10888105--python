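# Methods

## The weighted-ensemble model

Given M classifiers emitting row-stochastic probability matrices
P_1 … P_M over C classes for the same N samples, the ensemble is the convex
combination y_pred = Σ β_i P_i with β on the probability simplex
(β_i ≥ 0, Σ β_i = 1). Because the combination is convex, every output row
is again a probability vector, and the ensemble log loss at a simplex
corner equals that single model's loss exactly.

The fitting objective is the categorical cross-entropy
−(1/N) Σ_n log p_n[y_n]. The binary cross-entropy form, written with
one-hot labels, reduces to exactly this expression, and the categorical
form is the one that applies to the C = 3 and C = 4 softmax outputs this
toolkit targets. True-class probabilities are clipped to
[eps, 1 − eps] with eps = 1e-15 (configurable) so the objective stays
finite when a model assigns numerical zero to the truth.

A caution on protocol: the weights are fit on whatever split the caller
provides (`--fit-on` semantics are explicit in the CLI inputs). Fitting
weights on the same split used to report performance is optimistic; the
tool is split-agnostic and leaves the choice to the user.

## The PSO weight search

Classic global-best PSO over the simplex:

* velocity: v' = ω·v + c₁·r₁·(pbest − x) + c₂·r₂·(gbest − x), with r₁, r₂
  drawn fresh per dimension per update from U(0, 1) (per-dimension draws
  explore better than a single scalar draw per particle);
* position: x' = x + v', then repaired onto the simplex.

Defaults: 100 particles, 1000 iterations, ω = 0.7, c₁ = c₂ = 1.5. These are
the standard settings for this problem size and are deliberately not
adaptive; no constriction-factor or annealed-inertia variants are offered.

Choices the classic recipe leaves open, and how they are resolved here:

* **Simplex repair.** Negatives are clipped to zero and the vector is
  L1-normalized. This is cheap, idempotent on feasible points, and keeps
  every particle feasible after every iteration; the degenerate all-zero
  vector maps to uniform. Alternatives (Euclidean projection, softmax
  reparameterization) change the search geometry without a clear benefit
  at M ≤ 10.
* **Velocity clamp.** v_max = 0.2 per dimension. Weights live in [0, 1];
  without a clamp the social/cognitive terms can slingshot particles far
  off the simplex and the repair step then collapses them to corners,
  hurting exploration.
* **Deterministic seeding.** Particles 0…M−1 start at the simplex corners
  e_1 … e_M, particle M at the uniform vector, the rest from a flat
  Dirichlet; velocities start at zero. Corner seeding turns "the ensemble
  is at least as good as the best single model" from an empirical hope
  into an exact guarantee at zero cost, because the global best is
  initialized from evaluated corners and never increases.
* **Intra-iteration order.** Each sweep evaluates all particles, updates
  personal/global bests, then moves and repairs. With this order the
  returned global best is always an evaluated, feasible position and the
  best-loss trace is non-increasing by construction.
* **Stopping.** The full iteration budget runs by default. An optional
  `patience` window stops early after that many sweeps without global-best
  improvement; it is off by default so runs are schedule-deterministic.
* **Determinism.** All randomness flows from one `numpy` Generator seeded
  by the config; identical config + seed reproduces weights, loss and
  trace bit-for-bit, down to the serialized JSON artifacts.

Implementation note: the swarm is stored as (P, M) arrays and the
objective is evaluated for the whole swarm as one matrix product — the
ensemble's true-class probability is linear in the weights, so per-model
true-class probabilities (M × N) are precomputed once. A full
100-particle × 1000-iteration run on a 500-sample fixture takes well under
a second on one CPU.

The test-side verifier, `grid_oracle`, exhaustively enumerates simplex
lattice points (step 1e-3 for M = 2, 0.01 for M = 3) and shares no code
path with the swarm beyond the loss definition.

## Evaluation metrics

Confusion matrices use rows = actual, columns = predicted. Per-class
counts in the one-vs-rest view: tp = diagonal cell, fn = rest of the row,
fp = rest of the column, tn = remainder. Accuracy is trace/N. Precision,
recall and F1 follow the standard formulas; 0/0 cases return 0 with a
logged warning rather than NaN, so macro means stay defined.

Multiclass summaries are **macro** averages (unweighted class means). The
averaging scheme is embedded in every report because macro and weighted
averages silently diverge on imbalanced data.

AUC is one-vs-rest per class on the corresponding probability column,
computed as the tie-corrected Mann–Whitney statistic
U/(n₊·n₋), macro-averaged over classes that have both positives and
negatives (others are skipped with a warning). This is the only multiclass
AUC computable from softmax columns alone without pairwise class
restrictions.

## Brain-region cropping

Pipeline: grayscale (BT.601 luma for RGB) → Gaussian blur with a fixed
9×9 kernel → Otsu binarization → tight box over the extreme points of the
largest 8-connected foreground component → crop the *original* image.

* **Blur sigma.** The kernel size is the stated parameter; sigma derives
  from it as σ = 0.3·((k−1)/2 − 1) + 0.8 (σ = 1.7 at k = 9), the de-facto
  standard mapping in mainstream imaging toolchains, with reflect padding
  so no artificial dark frame biases the threshold.
* **Otsu.** Explicit 256-level search maximizing between-class variance;
  foreground is *strictly above* the threshold; ties take the lowest
  level. A constant image has no valid split and raises. On an inverted
  image (bright background) the "foreground" is the background — the
  caller must not pre-invert; this is documented behavior, not a repair.
* **Largest contour.** Interpreted as the largest 8-connected component by
  pixel area; its extreme top/bottom/left/right pixels define the
  half-open crop box. Area ties go to the component seen first in
  row-major scan order. Extreme points of a filled component and of its
  boundary contour coincide, and components are simpler to verify against
  a flood-fill oracle.
* The box is applied to the original, unblurred image (the deliverable is
  a sharp crop); an optional margin grows the box, clamped to the image.
  Resizing for a downstream CNN is left to the consumer.

Coordinates are row-major, origin top-left, boxes half-open — everywhere.

## Synthetic data generators

**Prediction fixtures.** Labels are uniform over C classes. For each model
and sample, a Bernoulli with the model's target accuracy decides whether
the model's winning class is the truth or a uniformly drawn wrong class;
the probability row is then a Dirichlet draw peaked on the winner
(α = concentration on the winner, 1 elsewhere), with the row maximum
swapped into the winning position so the argmax is the winner even at low
concentration. Consequences: each model's empirical argmax accuracy
converges to its target (±0.03 at n = 10,000 in the test suite), and rows
are smooth rather than one-hot.

Error correlation between models uses comonotone coupling: with
probability `pair_correlation` a sample's Bernoulli uses a single uniform
draw shared by all models, otherwise an independent draw. A shared draw
makes every model with accuracy below the draw fail *together*, so weaker
models fail on a superset of the stronger models' shared failures, while
each model's marginal accuracy stays exactly its target. One knob, exact
marginals. (A mechanism that flips all models' outcomes together would
distort the marginal accuracies the rest of the suite relies on, which is
why the coupling form was chosen.)

Defaults — five models with accuracies 0.95/0.93/0.91/0.89/0.87,
C = 3, N = 500, concentration 8, pair_correlation 0.3 — emulate the
realistic regime for this tool: a handful of comparably strong,
partially correlated classifiers. In that regime the loss-optimal ensemble
also improves argmax accuracy in ≥ 18 of 20 seeded runs (monitored
empirically in the suite). With one dominant model and much weaker,
correlated partners, the loss guarantee still holds but the accuracy gain
does not reliably appear — mixing in weak correlated models mostly adds
argmax noise. The suite's degraded 3-model fixture (0.9/0.7/0.5) is used
to stress the optimizer against the grid oracle, not to claim accuracy
gains.

What the generator does **not** model: calibrated confidence (wrong
predictions are as confident as right ones), class imbalance, and any
structure between samples. Passing tests therefore show the optimizer,
metrics and plumbing are correct — not that a weighted ensemble will
improve any particular real model stack.

**Phantom images.** A bright axis-aligned ellipse (default intensity 200)
on a dark background (10), with small bright discs ("noise specks",
default ≤ 3 px radius, 5 per image) rejection-sampled until every speck
pixel lies strictly outside the ellipse. Ground truth is the tight
half-open bounding box of the rendered ellipse pixels. The cropper
recovers that box within ±6 px per edge (tolerance reflecting the 9×9
blur spread) on ≥ 49/50 seeded phantoms; in practice the deviation is
0–1 px. Not modeled: skull anatomy, intensity inhomogeneity, scanner
noise spectra, 3-D volumes.

## File formats and pipeline

One strict CSV dialect (comma, UTF-8, required header, `.` decimals).
Probability files: `sample_id,class_0,…`; labels: `sample_id,label` with
integer indices or names mapped through a *declared* class list — class
order is never inferred from data. Cross-file alignment is by `sample_id`;
set mismatches and duplicates are errors, never silent reorders. Rows
whose probabilities sum within 1e-6 of 1 are renormalized; anything
further off is rejected with its row number.

`run` executes read → optimize → combine → evaluate. All inputs are read
and validated before any artifact is written, and JSON artifacts are
written atomically with sorted keys, so failed runs leave nothing partial
and identical runs produce byte-identical files. The weight artifact
echoes the seed, the full PSO config and a config hash for exact replay.

## Problem sizes in the test and acceptance suites

Fixtures use N = 120–500 samples, C = 3–4 classes and M = 1–5 models;
oracle comparisons run 20 seeds per condition at the full
100 × 1000 swarm schedule; crop recovery uses 50 seeded 200×200 phantoms;
metric-oracle equivalence uses 100 random 25-sample score sets. These
sizes make every brute-force oracle exact and keep the whole suite in the
tens of seconds on one CPU.

## Known limitations

* Weight fitting on the evaluation split inflates reported metrics; the
  tool does not enforce a held-out protocol.
* PSO is a metaheuristic: on multimodal loss surfaces with M ≫ 4 the
  global optimum is not guaranteed (the oracle-agreement evidence covers
  M ≤ 3; corner seeding bounds the result by the best single model
  regardless).
* The preprocessor assumes one bright dominant region on a darker
  background; bright-background images binarize inverted by design.
* Metrics assume single-label multiclass problems; no calibration
  metrics, confidence intervals, or multilabel support.
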