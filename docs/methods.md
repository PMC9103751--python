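# Methods

## Problem and model

Clinical records in traditional Chinese medicine (TCM) are unsegmented
Chinese character sequences annotated with a binary syndrome label (Yang
deficiency = 0, Yin deficiency = 1). Two tasks are solved jointly:

1. **Chinese word segmentation (CWS)**, cast as per-character sequence
   tagging over {B, I, O}: B opens a multi-character word, I continues
   one, O marks a single-character word. Words are recovered from a tag
   sequence by reverse matching tags to character positions.
2. **Syndrome differentiation**, binary text classification of the whole
   record.

The network is a multi-task architecture with hard parameter sharing:

* **Shared trunk** — a character-embedding lookup table. The padding row
  is frozen at zero.
* **Segmentation head** — a bidirectional LSTM; per position the forward
  and backward hidden states are concatenated and mapped linearly to
  three tag scores. No CRF layer: tags are taken by per-position argmax.
* **Classification head** — a TextCNN: 1-D convolutions with kernel
  widths 3 and 5 (100 channels each by default) over the embedded
  characters, ReLU, max-pooling over valid windows, and a linear map to
  two class scores.

The joint objective is `Loss = r0 * L0 + r1 * L1` with `L0` a masked
cross-entropy over tag scores (padding positions contribute exactly
zero) and `L1` a cross-entropy over class scores. One backward pass per
mini-batch optimizes both heads and the trunk together.

The whole network, and the reverse-mode automatic differentiation it
runs on, are implemented in this package on numpy (`jointcws._autodiff`).
Everything is float64 and single-threaded, so fixed seeds give
bit-identical runs on a fixed platform.

## Loss-weighting strategies

* **fixed** — constant `(r0, r1)`; the default (0.4, 0.4) is the optimum
  of an exhaustive grid search over {0.1,…,0.5}² selected by validation
  classification accuracy (`grid_search_weights`).
* **gradnorm** — per step, each task's gradient norm on the shared
  embedding `G_i = r_i‖∇L_i‖` is pulled toward `mean(G)·ρ_i^α`, where
  `ρ_i` is the task's relative inverse training rate (`α = 1.5`). The
  weight step is the damped proportional form
  `Δr_i = −lr_w (G_i − target_i)‖∇L_i‖ / mean(G)` with `lr_w = 0.025`;
  the step length vanishes as each norm reaches its target, so the
  weights settle monotonically instead of oscillating around the
  fixed point (a sign-gradient step with a constant length does
  oscillate). Weights are clamped at 1e-4 and renormalized to sum to
  the task count after every step.
* **dwa** — dynamic weight averaging:
  `w_i = L_i(t−1)/L_i(t−2)`, `r_i = 2·exp(w_i/T)/Σ_j exp(w_j/T)` with
  `T = 2`; the first two epochs use uniform weights.
* **uncertainty** — learnable log-noise scales `s_i`, objective
  `Σ_i exp(−2 s_i) L_i + s_i`, with both tasks in the same
  (classification) form since both losses are cross-entropies. The
  `s_i` are ordinary scalars stepped by the same Adam optimizer as the
  network; `+ s_i` prevents collapse to zero weight.

## Optimization protocol

Adam with learning rate 0.001, mini-batches of 32, up to 50 epochs,
gradient clipping at global norm 5. After every epoch the validation
objective is computed; the weights finally restored are those of the
epoch with the minimum validation loss. Training aborts with a
diagnostic if any loss becomes non-finite. An optional early stop
(`TrainConfig.stop_at_val_accuracy`) halts once validation accuracies
clear given thresholds; the stopping epoch's weights are then kept.

"Seven-fold cross-validation" combined with a fixed 60/10/30 split is
not a standard fold scheme; `run_cross_validation` therefore repeats the
stratified 60/10/30 split with k distinct logged seeds and averages the
metrics, and the fold count stays configurable.

## Two-stage (non-joint) baseline

Stage 1 trains the Bi-LSTM tagger alone (checkpoint on validation tag
loss). Stage 2 trains the TextCNN classifier on sentences
re-represented as character embeddings concatenated with an 8-dim
learned embedding of the stage-1 *predicted* boundary tag at each
position — predicted, not gold, on train/validation/test alike, and with
no gradient into stage 1. This coupling keeps the classifier
architecture identical across modes, so joint-vs-non-joint comparisons
isolate the shared-training effect; a word-level coupling (classifying
over predicted words) is a possible alternative that is deliberately not
implemented. The baseline embeds every sentence twice (once per stage),
surfaced as `feature_extraction_passes_per_sentence = 2` against the
joint model's 1.

## Synthetic corpus generator

The real 1209-record clinical corpus is private, so the generator
reproduces its statistical skeleton, not its content:

* **Scale** — defaults: 1209 records, balanced Bernoulli class labels,
  5–30 words per sentence, word lengths 1–4 with probabilities
  (0.3, 0.45, 0.15, 0.1), a 200-word lexicon over 400 CJK characters.
* **Prefix-free lexicon** — no word is a prefix of another, so every
  concatenation of lexicon words has a unique parse (the prefix-code
  argument). The gold segmentation is therefore unambiguous and a greedy
  lookup segmenter (`oracle_segment`) attains tag accuracy 1.0 — perfect
  segmentation is an achievable ceiling, which makes trainability
  testable.
* **Class signal** — 12 symptom words per class (disjoint sets). Each
  word slot is informative with probability 0.2 (at least one per
  sentence); an informative slot draws from the true class's symptom
  words with probability `class_word_strength` (default 0.9) and from
  the *other* class's otherwise, so strength 0.5 carries no signal and
  the spec of the generator requires strength > 0.5. After composing
  the sentence the label is flipped with probability `label_noise`.
  With strength 1 and no noise a symptom-word majority vote
  (`oracle_classify`) is exact.

What the generator does **not** emulate: real TCM vocabulary, character
frequency distributions, segmentation ambiguity, discourse structure, or
correlated symptom mentions. Tests passing on synthetic corpora
demonstrate that the machinery learns the intended statistical structure,
not that the reported clinical-level accuracies transfer to real records.

## Statistical comparison machinery

Two models evaluated on the same test items are compared by:

* **Bootstrap** — 1000 with-replacement resamples of the per-item
  correctness vector; mean resampled accuracy and percentile 2.5/97.5
  interval, for each model and for the accuracy difference.
* **Paired sign-flip permutation test** — statistic `t = acc_B − acc_A`;
  under the null each item's correctness pair is exchangeable, so each
  pair is swapped independently with probability 1/2 (10,000 draws by
  default). Two-sided p-value with the add-one (Phipson–Smyth)
  correction, hence never exactly zero.

## Numerical and design choices

* The architecture sizes are not dictated by the task; the defaults
  (embedding 128, hidden 128, 100 channels/width) land near 0.47 M
  parameters at a realistic vocabulary (~800 characters), matching the
  intended "small model, minutes on a CPU" operating point. An analytic
  parameter-count formula is implemented and checked against the actual
  count.
* Max-pooling is restricted to windows lying fully inside the real
  sequence (−∞ fill elsewhere), which makes the pooled features exactly
  invariant to appended padding; a sentence shorter than the widest
  kernel keeps its single right-padded window, and a fully padded row is
  scored from padding-only windows with a logged warning.
* BIO decoding repairs ill-formed transitions (a leading I opens a word,
  as if it were B) rather than dropping characters, so every prediction
  is a total segmentation.
* Dataset splits are stratified by class label (largest-remainder
  apportionment, exact global 60/10/30 sizes) because at ~1200 records
  an unstratified 10% validation split can become degenerate.
* Weight initialization is Glorot-uniform from the run seed; the LSTM
  forget-gate bias starts at +1; the padding embedding row is zero and
  excluded from updates via a gradient mask.
* Tie-breaks: argmax takes the first maximum; ROC thresholds sweep
  unique scores so tied scores move as a block (AUC then equals the
  tie-averaged rank statistic).

## Problem sizes used in the test suite

The packaged acceptance checks run on deliberately small instances
chosen as this package's own benchmark conditions: the joint-vs-two-stage
direction uses 300-record corpora with label noise 0.1 over 10 seeds at
a reduced epoch budget and a compact architecture (embedding 32, hidden
32, 16 channels/width); the trainability ceiling uses a 2000-record
noise-free corpus with an early stop once validation accuracy clears the
targets; the calibration studies use 500 replications with 1000
permutations/resamples inside the loops. User-facing defaults stay at
the full protocol (50 epochs, 10,000 permutations, 1000 resamples).

## Known limitations

* The tagger has no CRF transition layer, so nothing forbids an
  ill-formed tag sequence; the decoder's repair policy absorbs them.
* GradNorm computes per-task gradients on the embedding only (the only
  trunk both heads share), the usual last-shared-layer convention.
* The two-task implementation of the weighting strategies is not tested
  beyond two tasks.
* Training is pure-Python over numpy; it is deliberately CPU-sized and
  does not scale to large corpora or transformer-scale models.
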