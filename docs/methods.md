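# Methods

## The PU problem and the bin-ensemble estimator

Curated CPI resources for bacteria record positives only. Treating every
non-positive pair as negative biases a classifier, because an unknown
fraction of those pairs are undiscovered positives. The bin-ensemble
strategy mitigates this in two ways: (i) each of the K per-bin
classifiers sees only |Du|/K unlabeled pairs as negatives, so the hidden
positives contaminating any single training set are diluted; (ii)
averaging the K posteriors smooths out bin-specific noise, and only pairs
whose mean score clears a confident margin (Pr̄ > θu or Pr̄ < θl) receive
a pseudo label at all — the ambiguous middle is discarded rather than
mislabeled.

Spy positives hidden in the pool give an internal yardstick (SCR, the
fraction of spies the ensemble scores above a capture threshold). SCR can
be inflated by a scorer that calls everything positive; the confident
double-threshold labeling is what keeps that failure mode from
propagating into training data.

## Contracts and conventions

- Every bin's training set contains the *entire* training-positive set
  `Dp_tr` (the union `D_k = Dp_tr ∪ Du_k` is taken literally); only the
  unlabeled pool is partitioned.
- Spies stay inside the pool during partitioning and train as negatives
  inside their bins; they are excluded from the emitted pseudo labels.
- Thresholding uses strict inequalities; a score exactly equal to θu or
  θl stays unlabeled. In percentile mode ties are broken by the
  deterministic lexicographic (compound_id, protein_id) order.
- Scoring scope: by default every bin's model scores the whole pool and
  Pr̄ averages all K scores. A `held-out` scope (each model never scores
  its own bin's members, leaving K−1 scores per pair) is available for
  leakage-sensitive use; it removes the small downward bias on a pair
  that was a training negative of one model, at the cost of one fewer
  vote.
- One master seed; stage s uses seed master + s (mod 2³¹), so each stage
  is independently reproducible and reruns are byte-identical.
- SCR with zero spies raises an error rather than returning NaN.

## The composite loss

L = L_BCE + λ·L_WP with natural logarithms (a base change only rescales
both terms by a constant). Predictions are clipped to [ε, 1−ε], ε = 1e−7,
before any logarithm, since BCE is unbounded at {0, 1}; the
weighted-positive term is finite on [0, 1] and is not clipped. The WP
normalizer 1/|Dp| is interpreted batch-locally (the count of curated
positives in the current mini-batch), which is what mini-batch descent
requires; a `global_dp_size` option restores a fixed global normalizer.
The analytic gradient is

    dL/dŷᵢ = −(yᵢ/ŷᵢ − (1−yᵢ)/(1−ŷᵢ))/N
             + [i ∈ Dp] · λ · 2(ln(ŷᵢ+1) − ln 2) / ((ŷᵢ+1)·|Dp|),

verified against central finite differences to 1e−5 relative error in the
tests and in the acceptance script.

## Reference backbone

The framework is backbone-agnostic; the shipped reference backbone is a
deliberately small, fully deterministic stand-in suitable for CPU-scale
runs:

- **Features.** Overlapping protein k-mers and SMILES character n-grams,
  signed-hashed (blake2b keyed by `hash_seed`, sign bit from the hash)
  into `hash_dim` buckets, L2-normalized per entity, pair feature =
  concatenation. Defaults k = n = 3, hash_dim = 1024, hash_seed = 17.
  Signed hashing makes collision noise cancel in expectation.
- **Model.** One tanh hidden layer into a sigmoid output, trained by
  plain mini-batch gradient descent on the composite loss with decoupled
  weight decay. No adaptive optimizer: determinism and exact
  reproducibility are worth more here than convergence speed.
- **Defaults.** learning rate 1e−4 and weight decay 1e−5 mirror the
  hyperparameters typical of the deep CPI backbones this model stands in
  for. A plain-gradient-descent numpy network needs a much larger step to
  converge in a few hundred epochs, so the synthetic benchmark and the
  CLI examples pass their own training configuration (see below); the
  defaults are kept as the package-level reference point.

`check_backbone_contract` validates any third-party backbone (score
range, post-fit determinism, row independence, factory freshness) before
it is trusted inside the pipeline.

## Synthetic worlds

`generate_world` draws latent vectors z ~ N(0, I_d) per entity; the
propensity of pair (c, p) is logistic(a·⟨z_c, z_p⟩ + b). The bias b is
calibrated to the target prevalence — exactly, by order statistics, for
deterministic (thresholded) labels; by bisection to ±1e−4 in expectation
for Bernoulli labels. Deterministic labels are the default because they
make parameter-recovery tests clean; a = 0 requires stochastic labels
(with constant propensity, thresholding cannot produce an intermediate
prevalence, and the generator says so in its error).

Entities are rendered into strings by drawing characters independently
per position from softmax(P·z), with one fixed random projection P per
alphabet per world. Consequences worth knowing:

- Rendering is position-iid, so *unigram frequencies are a sufficient
  statistic* for the latent. Hashed 1-gram features recover it cleanly;
  longer k-mers only add estimation noise on top.
- The SMILES-like strings use a 12-character alphabet (C, N, O, c, n, o,
  =, #, 1, 2, parentheses) and are syntactically plausible but not
  chemically valid; the pipeline treats SMILES as opaque tokens
  throughout, so nothing downstream depends on validity.
- What the generator does **not** emulate: motif/domain structure,
  positional dependence along the sequence, chemistry-aware similarity,
  family structure among enzymes, and dataset-level biases of curated
  databases. Passing the synthetic benchmark therefore demonstrates that
  the PU machinery recovers a planted signal through string features —
  not that any particular real dataset is predictable.

## Benchmark study conditions

The end-to-end benchmark (`eval_metrics.benchmark_world`, used by the
acceptance script and tests) runs on 50 proteins × 40 compounds with
latent dimension 2, signal strength a = 5, 10% true prevalence, 30% of
true positives observed, sequences of length 600 and SMILES of length
100. Lengths were set so that per-entity character-frequency estimates
are tight (standard error ≈ √(p(1−p)/L)); latent dimension 2 keeps the
bilinear interaction surface learnable by a small network from ~50
positives.

Benchmark-specific configuration, chosen once from this analysis:

- Featurizer k = n = 1, hash_dim = 64 (sufficient statistic, see above).
- Training: learning rate 1.0, weight decay 1e−4, 400 epochs, batch 32,
  hidden 64; each ensemble member gets a distinct derived init seed so
  bins differ in their random starts as well as their data.
- K = 10 bins. The package default is K = 20, appropriate when the
  unlabeled pool is tens of thousands of pairs; at 2,000 pairs K = 10
  keeps each bin's negative set a few times larger than the positive set,
  the same regime as the large-scale configuration (bin ≈ 3,500 vs ≈ 400
  positives).
- Final-model λ = 1.0; baseline positive weight w = 10.

Both arms (bin ensemble and the unlabeled-as-negative baseline) tune
their discriminant threshold on their own validation data and are
evaluated against the generator's ground truth on the same pool (every
pair except the observed positives), making the comparison paired. The
zero-signal null uses percentile-mode labeling (top/bottom 20%) so the
pseudo-positive set has a fixed nonzero size and its precision is a
well-defined quantity to compare with prevalence.

## Numerical and degenerate-input choices

- Bin partition: sizes differ by at most one (the first |Du| mod K bins
  get the extra element of a seeded permutation).
- Spy count = round(fraction · |Dp|); fraction 0 is allowed (no spies, no
  SCR), fraction 1 is not (nothing left to train on).
- Threshold grid 0.00–1.00 in steps of 0.01, ties to the smallest θ;
  λ grid default {0.1, 0.5, 1, 2, 5}.
- Empty worlds, single-class training data, unscored spies, zero spies,
  out-of-range backbone scores and conflicting duplicate labels all raise
  typed errors; nothing degenerates silently.
- Multi-seed pseudo-label precision is reported pooled across seeds
  (total hits / total pseudo-positives), which stays defined even if one
  seed emits an empty pseudo-positive set in score mode.

## Known limitations

- The reference backbone's concatenated entity features force the hidden
  layer to learn all compound–protein interaction structure; it is a
  yardstick for the PU machinery, not a competitive CPI model.
- Entity deduplication is exact-string; two SMILES differing only in
  atom ordering are distinct entities unless canonicalized upstream.
- The spy mechanism assumes spies are exchangeable with the hidden
  positives; if curated positives are biased toward well-studied
  chemistry, SCR overstates recovery of the truly novel positives.
- Percentile-mode labeling fixes |Ψpos| by fiat; with weak signal this
  manufactures confident-looking labels with precision near prevalence —
  the zero-signal null quantifies exactly this behavior.
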