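# Methods

`ehrformer` implements a tokenization and modeling pipeline for estimating
ICU patient acuity — operationalized as six readmission/mortality outcomes —
directly from irregular electronic-health-record event streams, together
with the sequential and tree-based baselines such a study is compared
against, and a synthetic cohort generator that makes the whole pipeline
runnable and testable without access to protected clinical data.

## Event tokenization

Raw input is a long-format event table: one row per clinical measurement
(stay id, variable name, elapsed hours from ICU admission, numeric value),
with each variable tagged as a vital sign, laboratory test, medication
administration, or bedside assessment component. Each retained event becomes
a 12-entry token

```
x_t = (p, f, t, v)   with   v in R^9
```

where `p` is the *dense rank* of the event's timestamp within the stay
(simultaneous events share a position index; each new unique time increments
the index by exactly one, so `[0.1, 0.2, 0.2, 0.3, 0.3]` maps to
`[0, 1, 1, 2, 2]`), `f` is an integer variable id, `t` is elapsed time, and
`v` holds the current value plus eight running statistics of the same
variable's history within the stay: mean, median, count, minimum, maximum,
standard deviation, first value, and the gap since the variable's previous
measurement.

Conventions the data definition leaves open, fixed here:

* Running statistics are **inclusive** of the current measurement; the gap
  is 0 for a variable's first event.
* Standard deviation is the population (divide-by-n) form; a singleton
  history has std 0.
* Events are stably sorted by (time, variable name). Tie order cannot
  affect position indices, which depend only on timestamps.
* Out-of-vocabulary events are dropped by default; an unknown-token mode is
  available on the vocabulary.

The vocabulary is fitted on training stays only. Laboratory tests and
medications are retained when they appear in at least 1% of training stays
(boundary inclusive); vitals and assessment components are always retained.
Ids 0 and 1 are reserved for padding and the static slot, the next ids for
the per-task tokens, then variables in sorted-name order.

All nine value columns are standardized per (variable, column) with
training-set means and scales; elapsed time is standardized with a single
global transform; zero-variance columns are flagged and given scale 1.
Static records become `[one-hot categorical blocks | standardized numerics |
missingness masks]`, with missing numerics imputed by training medians and
unseen categorical levels encoded as all-zero blocks.

Stays with length of stay outside [1 h, 240 h] or more than 12,000 tokens
are excluded, with a per-stay reason log.

## Model

Sequence layout per stay: `[static slot][7 task tokens][event tokens]`.
Task tokens carry reserved ids, time equal to the standardized length of
stay, and exactly-zero value features. The embedding of each token is the
sum of three parts: a single linear projection of `[t, v]` (10 inputs; just
`[t]` in the discrete-only variant), a lookup embedding of `f`, and a
parameter-free interleaved sin/cos encoding of `p`. Special tokens receive a
zero positional component — their temporality is carried by the time
feature — and the static slot's embedding is produced by a two-layer
fully-connected network over the static vector.

The encoder is a stack of pre-norm transformer layers with GELU feedforward
and a Longformer-style attention pattern: non-global tokens attend within a
window (total width `w`, `w // 2` on each side of the sequence index) plus
all global tokens; the static slot and the task tokens are global and attend
everywhere. At desk scale the pattern is computed as dense attention under a
boolean mask, which is exactly equivalent to a banded kernel and is verified
against an independent dense oracle in the tests. Each task head is a linear
layer over the concatenation of its task token's representation from every
encoder layer (8 x 128 = 1,024 wide at the full-scale configuration). The
seventh (auxiliary long-term readmission) head is symmetric with the others
but is excluded from the acuity metric.

The reference configuration is 8 layers, hidden 128, feedforward 512,
8 heads, window 128, dropout 0.1, batch size 21. The loss is the unweighted
mean of per-task binary cross-entropy on logits (auxiliary weight 1.0).
Training uses adaptive-moment optimization (default lr 1e-4 — a package
choice, as the optimizer is not pinned down by the problem definition) and
early stopping on the validation mean AUROC over the six acuity outcomes
with patience 4, restoring the best checkpoint.

Because no deep-learning framework is assumed, the package ships its own
minimal reverse-mode autograd on NumPy (`ehrformer.nn`): broadcast
arithmetic, batched matmul, softmax, layer norm, GELU (sigmoid
approximation), gather/concatenate, and a numerically stable binary
cross-entropy, each gradient-checked against central finite differences.

## Splitting and evaluation

The cohort is split chronologically by admission time: earliest 80% to
development, latest 20% held out, and any held-out stay whose patient also
appears in development is pulled into development so no patient spans the
boundary. A seeded patient-grouped 10% of the development set serves as the
within-training validation split (whether this split should itself be
chronological is not specified; a seeded random grouped sample is used).
AUROC is the rank-based Mann-Whitney statistic with midrank ties; tasks
with a single observed class report NaN and are excluded from the mean with
a warning.

## Baselines

* **GRU (resampled)** — per-variable 1-hour bins (half-open `[k, k+1)`,
  within-bin mean, forward fill, training-median imputation for leading
  gaps, per-variable standardization), final hidden state concatenated with
  the static vector into an MLP. The imputation scheme is a package choice;
  resampling conventions vary across the literature.
* **GRU + attention (resampled)** — additive alignment scores over hidden
  states, softmax-normalized, weighted sum replacing the final-state
  readout.
* **GRU + attention (tokenized)** — the same attentional GRU consuming the
  transformer's own token embeddings (bit-identical embedding module).
* **XGBoost / LightGBM** — one independent booster per outcome over a
  fixed-width vector: static block, then per vocabulary variable the final
  cumulative 8-vector + last value + presence flag (how variable-length
  event streams become a fixed-width tree input is not specified anywhere;
  this block construction is the package's documented stand-in). LightGBM
  is the second gradient-boosted family alongside XGBoost.

All families emit the same seven-logit schema and run through the same
split/train/evaluate code path; the `benchmark` subcommand prints a
model-by-task AUROC grid (mean + six outcome columns).

## Synthetic cohort generator

Each stay draws a latent acuity `a ~ N(0, 1.75^2)`. The generator plants
this signal in three places:

* **Values**: variable `f` at time `t` is
  `base_f + coef_f * a * acuity_effect * (t / LOS) + noise_f`, a time trend
  whose slope is proportional to acuity (`acuity_effect` default 2.0).
* **Event frequency**: one designated rescue medication's event rate is
  multiplied by `exp(discrete_effect * a)` (default 0.3, so the dominant
  planted signal lives in the continuous values, matching the regime the
  model-ordering experiment probes).
* **Survival**: death time follows a proportional-hazards Weibull draw
  `T = hazard_scale * (E * exp(-a))^(1/k)`, `E ~ Exp(1)`, shape `k = 0.35`.
  The heavy tail (decreasing hazard) is what lets 7-day and 1-year mortality
  rates both be non-trivial, mirroring real ICU cohorts; `k = 1` recovers a
  plain exponential hazard. With the defaults, ranking stays by latent
  acuity against the 1-year label yields AUROC ~ 0.88 over ~2,000 stays —
  the ceiling any model faces.

Event streams are per-variable homogeneous Poisson processes (per-category
rates), with a configurable fraction of vital signs arriving as simultaneous
panels (shared timestamps across the stay's vitals) to exercise the
non-unique position rule. Each stay samples a subset of the variable
catalog. Death during the ICU stay truncates the event stream and sets LOS
to the death time; hospital discharge is ICU discharge plus an exponential
tail so inpatient mortality differs from the ICU-horizon labels. Mortality
horizons (7/30/90/365 days) are measured from ICU admission — the anchor is
configurable since the outcome definition does not state it — which makes
the four horizon labels nested by construction. The ICU-readmission outcome
and the auxiliary long-term readmission target are Bernoulli draws with
acuity-linked logits. Static records carry a mix of acuity-correlated
numerics (age, a comorbidity index), uninformative numerics, small
categorical level sets, and 10% injected missingness.

What the generator deliberately does **not** emulate: physiological
plausibility or units, inter-variable correlation structure, care-process
feedback (treatment responding to measurements), informative-sampling
missingness, or real cohort summary statistics. Passing benchmarks on this
cohort therefore demonstrate that the pipeline recovers a planted signal of
known strength and that model orderings behave as expected — not clinical
performance; printed AUROCs on any real cohort are site-specific and are
not reproduced here.

## Reduced-scale benchmark

The standing benchmark trains the full and discrete-only transformer
variants on ~2,000 stays with hidden 32, 2 layers, 4 heads, window 32,
sequences capped at 256 tokens, batch size 21, lr 1e-3 (scaled up from the
full-scale default to suit the smaller model and cohort), at most 18 epochs
with patience-4 early stopping. These problem sizes are the package's
chosen desk-scale experiment; the full-scale configuration above remains
available through the config objects. Typical results (seeds 0-3): full
model validation mean AUROC 0.83-0.89, discrete-only 0.74-0.83, ordering
gap 0.06-0.09.

## Numerical choices and degenerate inputs

* Masked attention logits use an additive -1e9 bias; fully-masked rows
  (padding) softmax to uniform and are never read out.
* Zero-variance standardization scales are set to 1 and flagged.
* A stay with no in-vocabulary events tokenizes to an empty matrix with a
  warning and assembles to a specials-only sequence.
* Gradient clipping at global norm 5 guards the small-batch training loop;
  a non-finite loss aborts with diagnostics rather than continuing.
* Checkpoints are a flat named-parameter `.npz` plus a JSON config;
  identical seeds and data reproduce identical training histories on one
  device.

## Known limitations

The NumPy autograd is single-threaded and dense; it is sized for the
desk-scale benchmark, not for 12,000-token sequences at hidden 128 (the
full-scale configuration is functional but slow). The banded-attention
computation is realized by dense masking, so memory is O(L^2). Tree
baselines use fixed mild hyperparameters; no hyperparameter search is
performed anywhere, deliberately.
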