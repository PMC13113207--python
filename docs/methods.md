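# Methods

`mortexplain` is an interpretability toolkit for classifiers that select the
underlying cause of death (UCOD) from ICD-10-coded death certificates. It
implements four analyses — post-hoc confidence calibration, instance
difficulty by Variance of Gradients (VoG), Integrated Gradients (IG) word
attribution, and chapter/category-stratified reporting — together with a
synthetic certificate generator and a small differentiable text classifier
so that the whole stack can be exercised, tested and benchmarked end to end
without access to restricted national mortality files or a large pretrained
transformer.

This note records the models, the default parameters and why they were
chosen, the numerical conventions, and what the synthetic setting does and
does not establish about real data.

## 1. Synthetic certificates and ground truth

### Data model

A coded certificate holds sex, age, up to four ordered Part 1 lines of
ICD-10-style codes (the causal chain, read top to bottom; the last code of
the last used line is the *originating condition*), an optional Part 2 list
of contributing conditions, and the true UCOD. Codes follow the NCHS style
`letter + two digits + optional decimal` (e.g. `I21.9`), and map to the 22
ICD-10 chapters through the standard letter-range table (`A00–B99 → I`, …,
`U00–U99 → XXII`), hard-coded as a versioned constant (2016 boundaries).

### Ground-truth UCOD rule

The generator labels each certificate with a simplified, deterministic
cascade of WHO-style selection principles:

* **R1 — external-cause precedence.** If any chapter XX code is stated
  anywhere (Part 1 or Part 2), the first one in reading order is the UCOD.
* **R2 — originating condition with exclusions.** Otherwise, walk backwards
  through the flattened Part 1 chain starting at the originating condition
  and select the first code that is selectable, not ill-defined
  (chapter XVIII) and not an injury (chapter XIX).
* **R3 — fallback.** If every candidate is excluded, the originating
  condition is selected regardless of flags. Part 2 is never selected.

This is intentionally a small subset of the WHO selection and modification
tables: it keeps the ground truth unambiguous and machine-checkable. One
consequence is that chains that real mortality coders would modify (e.g.
recoding combinations into more specific categories) are labelled by the
plain cascade here. Because real certificates that state an injury
virtually always state the external cause that produced it, the generator
guarantees an external-cause code on any certificate that states an injury;
this is what keeps chapter XIX codes out of the UCOD column, mirroring
national statistics where injuries are never selected.

### Distributional defaults

* **Chapter mix** of stated conditions follows the chapter imbalance of US
  multiple-cause-of-death files (circulatory ≈ 31 %, neoplasms ≈ 22 %,
  eye/ear chapters near zero, chapters XXI/XXII absent).
* **Condition count** per certificate: 1 + Poisson(mean_conditions − 1),
  clipped to [1, 15]; `mean_conditions = 3` by default.
* **Code frequencies** are long-tailed: within each chapter codes get Zipf
  weights `rank^(−imbalance_exponent)` with exponent 2.0 by default. The
  exponent was set so that a desk-scale sample (thousands of certificates)
  still exhibits the full frequency spectrum — including codes stated only
  a handful of times — rather than a truncated tail; at lighter exponents
  the rare-occurrence strata of the difficulty analysis are simply empty at
  this scale.
* **Titles** are pseudo-medical: adjective + disease noun built from two
  medical morphemes (optionally a third as a subtype qualifier) + site,
  ~2,600 noun combinations. Real ICD concept titles are term-dense and
  rarely share their distinctive terms across categories; building titles
  this way means the reverse-coded sentence of a code never seen in
  training contains genuinely novel words, which is the mechanism that
  makes "unseen code" a meaningful out-of-distribution condition for a text
  model. A `title_collision` switch forces duplicate titles to reproduce
  the known failure mode where two distinct codes become indistinguishable
  after reverse coding.
* **Part 2** is populated with probability 0.3 per certificate (1–2 codes
  moved from the sampled conditions). National files do not publish this
  rate, so it is exposed as a parameter rather than fixed.
* **Splits** are stratified by UCOD with a largest-remainder transportation
  rounding: global split sizes are exact and every class is within one
  member of its proportional share; classes smaller than the number of
  splits are effectively assigned at random (logged). Certificates stating
  a held-out code are moved from train to test after splitting, so held-out
  codes are never seen in training but appear at evaluation.

### Synthetic miscalibrated predictions

`generate_calibrated_logits(n, k, T*, seed)` draws logit vectors with
i.i.d. N(0, 2²) components (the spread puts raw confidences in every bin)
and samples labels from `softmax(z/T*)`. By construction, probabilities
computed at the true temperature are perfectly calibrated in expectation,
so the fitted temperature should recover T* — the basis of the
parameter-recovery tests — and raw probabilities at T* ≠ 1 are known-
miscalibrated inputs for the ECE-improvement checks.

## 2. Classifier surrogate

The classifier is deliberately small and written directly in numpy:
token embeddings (width d = 32) → mean pool over non-padding tokens →
one tanh hidden layer (64 units) → affine map to k logits (`arch="linear"`
drops the hidden layer). Hand-derived backpropagation makes training
bit-reproducible on one CPU and gives closed forms for every gradient the
analyses need:

* linear head: ∂z_p/∂e_i = w_p / n for every token i;
* mlp head: ∂z_p/∂e_i = W₁ᵀ[(1 − tanh²a) ⊙ W₂ₚ] / n.

The mlp head is the default: a purely linear mean-pool model has the same
logit gradient at every input, so input-dependent difficulty and
attribution analyses would be vacuous on it. The linear head is kept as the
exact oracle for gradient and IG tests.

Training is cross-entropy with Adam (lr 0.01, batch 64, 30 epochs) plus
L2 weight decay 1e-3 applied *sparsely* to embedding rows — only rows that
occur in the current batch decay, as in sparse optimizers. Two properties
motivate this: (i) unregularised Adam inflates trained embedding norms far
above their initialisation, and (ii) vocabulary rows never seen in training
(the unknown token) stay exactly at initialisation. With sparse decay and
`init_scale = 0.25`, trained and never-trained rows live at a comparable
scale — the analogue of how layer-normalised transformers keep unseen-token
representations on the same scale as trained ones — so unseen words are
neither invisible nor wildly dominant in the pooled representation.

K = 5 checkpoints are captured at evenly spaced epochs, the last always
being the final model. Checkpoints serialize to per-parameter `.npy` files
plus a JSON manifest with SHA-256 hashes (plain `.npy` is timestamp-free,
so a rerun reproduces the directory byte for byte).

The tokenizer is a lowercased word/punctuation splitter with character
offsets and a word map (word → contiguous token range). Words are built per
whitespace chunk: edge punctuation stands alone, interior punctuation
(hyphens, commas in numbers) stays inside the word. Out-of-vocabulary words
map to a reserved unknown id; id 0 is padding. A subword tokenizer was
deliberately not reimplemented; hyphenated words already exercise
multi-token word aggregation.

### What the surrogate does not model

Reverse-coded sentences are fed as a bag of words: the mean pool discards
token order, while the ground-truth rule cascade is order-sensitive
(originating condition, first external cause). Certificates whose label
depends on the order of otherwise identical condition sets are therefore
irreducibly ambiguous to this model, which caps desk-scale accuracy near
0.5 on the default generator — far below the ≈0.99 a fine-tuned
domain transformer reaches on national data. All calibration, difficulty
and attribution analyses are well-defined at any accuracy level; the
benchmark configuration (single-condition certificates, 20 classes)
verifies the trainer itself reaches ≥ 0.95 held-out accuracy when the task
is separable.

## 3. Calibration

Predictions are grouped into M equal-width half-open confidence bins
((m−1)/M, m/M]; confidence 0 joins the first bin. ECE is the count-weighted
mean absolute gap between per-bin accuracy and mean confidence; MCE the
maximum gap. Conventions (the source analyses leave them unstated): M
defaults to 10; empty bins contribute zero weight to ECE and are excluded
from the MCE maximum; results are reported on the percent scale with all
internal arithmetic on [0, 1]; argmax ties break toward the lowest class
index.

Temperature scaling divides logits by a single scalar T before the
softmax, leaving predicted labels unchanged. T is fitted on held-out
predictions by bounded scalar minimisation of the mean negative log
likelihood on T ∈ [0.05, 20] (tolerance 1e-4); a fit that lands on a bound
is flagged (degenerate likelihoods, e.g. an all-correct validation set,
push T to a boundary). Minimising binned ECE over a dense grid is available
as an option (`objective="ece"`; grid search because binned ECE is
piecewise-constant in T).

At desk scale the pipeline fits T on a validation split of ≈100 records
(the 40:10:1 train:test:validation proportions of the national-scale study
design applied to 5,000 certificates); with so small a split, the fitted
temperature is noisy and test-set ECE can worsen after rescaling. The
controlled recovery experiments (50,000 synthetic predictions) are the
calibrated-measurement path; the pipeline numbers show realistic
small-validation behaviour.

## 4. Variance of Gradients

For a record with token embeddings e₁…e_n and class p, each checkpoint k
yields a gradient matrix S_k (tokens × components) of the class-p logit.
The raw VoG is the population variance (denominator K) of every
(token, component) cell across the K checkpoints, averaged over all cells.
Gradients are taken on pre-softmax logits; K ≥ 2 is required.

**Token gradient scale.** By default the cells hold the gradient with
respect to each token's *pooled contribution* (e_i/n), i.e. n·∂z_p/∂e_i.
Under mean pooling the raw embedding gradient carries a structural 1/n
factor, so the per-embedding-cell variance scales as 1/n² and difficulty
comparisons across certificates would otherwise be dominated by certificate
length (short certificates would all look hard). The contribution gradient
removes exactly that attenuation and nothing else; the raw embedding scale
is retained as `token_scale="embedding"` for sensitivity analysis. The
original image formulation does not face this choice because pixel inputs
have no pooling weight.

**Class.** Gradients are taken at the true label for labeled analysis and
at the predicted label for unlabeled scoring (`class_of`).

**Modes.** `mode="checkpoint"` (default) is the across-checkpoint variance
described above; `mode="final"` computes the per-token variance across
embedding components at the final checkpoint only, for the single-snapshot
reading of token-level VoG.

**Normalisation.** Raw scores are first class-centred (subtract the mean
raw score of the record's class, so per-class means are exactly zero —
this removes class-frequency effects), then globally standardised
(z-score of the centred score) and clipped to [−1, 1] for reporting.
Both clipped and unclipped values are retained; ranking and the
quantile-based flag use the unclipped score, because clipping piles the
upper tail onto exactly 1.0 and would make "exceeds the 95 % quantile"
vacuous there. Subtraction (not division) was chosen for class
normalisation, and centring precedes the global z-score; neither
composition is dictated by the method's description.

**OOD flagging.** A record is flagged when it states any code with zero
training occurrences, or when its score exceeds the `flag_quantile`
(default 0.95) of the score distribution.

**Frequency stratification.** Each record is assigned by the minimum
training occurrence among its stated codes. The full-scale default ranges
are {0}, {1–2}, {3–1000}, {1001–5000}, {5001–20000}, {>20000}; the pipeline
default uses the same stratification compressed to desk scale
({0}, {1–2}, {3–10}, {11–50}, {51–200}, {>200}), since a 5,000-certificate
sample has no code with 20,000 occurrences. A log₂(min occurrence + 1)
binned-means table is produced for the trend view (binned means, not a
LOESS smoother). Class-level difficulty is correlated (Pearson, Kendall)
with the class's mean number of stated conditions and of used lines.

On the default synthetic conditions, pooled over five independent runs,
records containing never-seen codes have the highest mean normalized VoG,
the range means decrease with increasing frequency, and the class-level
correlation with condition count is weakly positive — the qualitative
pattern expected of a difficulty score, reproduced by the test suite. The
correlation is weak (≈0 to 0.1 by seed) and its per-seed sign can flip;
only the pooled direction is asserted.

## 5. Integrated Gradients

For F = pre-softmax logit of the target class (pre-softmax avoids
saturation), attributions follow the straight-line path from a baseline to
the input embeddings:

IG_i = (x_i − x'_i) · ∫₀¹ ∂F(x' + α(x − x'))/∂x_i dα,

approximated by Gauss–Legendre quadrature (default, 50 steps) or a left
Riemann sum. The default baseline is the padding-token embedding repeated
to input length (an actual "empty input" for this model, untouched by
training); a zero baseline is available. The completeness identity
Σ IG = F(x) − F(baseline) is computed per record and its residual reported.
For the linear head, attributions are exact at any step count; for the mlp
head the integrand is a polynomial-free smooth function and Gauss–Legendre
at 128 steps leaves residuals near machine precision.

Per-token scalars are component sums (sign preserved — the red/white/green
rendering needs signed values, so no norms), words sum their tokens'
scalars, and display values are scaled by the record's maximum absolute
word attribution (display only; the numeric TSV carries unscaled values).
The report renders one row per record with true/predicted codes and titles,
colour-scaled word importances and the attribution score (sum of word
attributions); the target class is the predicted label by default, so
failure cases are explained in terms of what the model chose.

## 6. Stratified reporting

* Chapter table: input frequency counts every stated condition by chapter,
  target frequency counts true UCODs, accuracy@1 is computed among records
  whose true UCOD lies in the chapter and is null where a chapter never
  occurs as a target. Percent columns share one denominator each (total
  stated conditions, total certificates) and sum to 100.
* Top-k tables report count, percent (exact; formatted to 3 decimals) and
  cumulative coverage, ordered by count with ties broken by code.
* Confidence summaries per chapter or class: five-number summary (linear
  interpolation for quartiles, stated in the output metadata), error rate,
  and the group's training-sample count for confidence-vs-support scatter
  analyses.

## 7. Pipeline and problem sizes

`mortexplain run --config cfg.yaml --out DIR` executes
generate → reverse-code → train → calibrate → vog → saliency → report,
with every stage re-runnable in isolation from the serialized
intermediates. The manifest records the configuration and its hash, stage
statuses, every paper-gap flag in force (bin count, fit objective, VoG
mode/scale, IG baseline/method/target) and SHA-256 hashes of all outputs;
two runs under the same seed produce identical manifests. A stage failure
aborts the run with a stage-named error, keeps partial outputs and leaves a
`FAILED` marker.

Default desk scale: 5,000 certificates over a 60-code codebook (≈50
distinct UCOD classes), splits 0.784/0.196/0.02, three held-out rare codes,
d = 32 / 64 hidden units, 30 epochs, K = 5 checkpoints, 10 calibration
bins, 50 IG steps, six saliency examples. A full run takes well under a
minute on one CPU; the sizes were chosen as the largest round numbers at
which the whole analysis suite, repeated over several seeds, remains
comfortable on a laptop.

## 8. Known limitations

* The rule cascade omits WHO modification rules; synthetic ground truth
  diverges from real coding practice on chains coders would recode.
* The bag-of-words surrogate cannot express order-dependent selection, so
  desk-scale accuracy is structurally capped; accuracy-dependent artefacts
  of real systems (e.g. extreme confidence concentration near 1.0) appear
  only in attenuated form.
* The unseen-code mechanism operates through novel title words; real OOD
  certificates can also be novel combinations of known conditions, to which
  a mean-pooling model is blind by construction.
* Temperature scaling at desk scale inherits the variance of a ≈100-record
  validation split; conclusions about calibration improvements should rest
  on the controlled synthetic-recovery path.
* Passing the qualitative difficulty checks here shows the scoring
  machinery behaves as designed under known conditions; it is not evidence
  about any particular real model or dataset.
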