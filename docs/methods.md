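# Methods

This note documents the models implemented in `emodrop`, the defaults and the
reasoning behind them, the synthetic data the pipeline is validated on, and
the limitations of both.

## Text cleaning

Five steps in a fixed order: lowercase → punctuation stripping → whitespace
tokenization → stop-word removal → common-term removal → rare-term removal.

- Punctuation (any character neither alphanumeric nor whitespace) is replaced
  by a space rather than deleted, so `"end.start"` yields two tokens.
- Stop words come from a packaged plain-text English list (~160 entries);
  user-supplied lists override it.
- *Common* terms are those whose document frequency strictly exceeds
  `common_df_threshold` (default 0.90, a standard corpus-linguistics cut);
  *rare* terms are those whose total corpus count falls below
  `rare_min_count` (default 3, i.e. tokens occurring once or twice are
  dropped). Both filters are computed on the stop-word-free token streams,
  which makes the whole chain idempotent on its own output.
- Documents that lose every token are kept as empty token sequences: labels
  and document order are invariants of cleaning.
- Corpus-level frequency filters before/after stop-word removal is a genuine
  ordering choice; we run them after, so the document-frequency estimates are
  not distorted by function words.

Corpus descriptive statistics (word, character, numeric-token counts; unique
uni/bi/trigram inventories) are deliberately computed on the *raw* text with
plain whitespace tokenization — they describe the dataset, not the features.
"Characters" counts every character including spaces, and "numerics" means
digits-only tokens; both are declared conventions, exposed as such.

## Vectorization, resampling, splitting

The vocabulary is the lexicographically sorted set of n-grams (orders ⊆
{1,2,3}, default unigrams) occurring at least once; sorting makes feature
matrices bit-identical across runs. Feature values are raw occurrence counts
by default — counts make the wrapper fitness and the network's behavior easy
to verify — with smoothed TF-IDF (tf × (1 + ln(N/(1+df)))) behind a flag.

The stratified split allocates round(count × test_fraction) test rows per
class (half-up), floored at 1 and capped at count − 1. Resampling balances
classes exactly: oversampling keeps every row and draws extras with
replacement up to the majority count; undersampling draws without
replacement down to the minority count.

Ordering matters twice and both choices are deliberate:

1. **Resampling happens after the split, on training rows only.** Balancing
   first would copy duplicated rows into the test set and inflate every
   reported metric.
2. **Feature selection sees the un-resampled training rows.** Oversampled
   duplicates straddle the wrapper's CV folds, which lets uninformative
   features recognize near-copies of fold-mates and look predictive
   (measured on the benchmark corpus: random 30-feature subsets score 0.61
   pooled CV accuracy on oversampled rows vs 0.56 without, while the
   planted-keyword subset *drops* from 0.96 to 0.84). The oversampled rows
   are used only to train the network, where exact class balance is what we
   want.

## IWD feature selection

Drops tour a complete graph over feature nodes plus a virtual start node;
a tour of m moves defines a candidate subset. Per move from i to j:

    vel ← vel + a_v/(b_v + c_v·soil(i,j)²)
    time = HUD(j)/vel;  Δ = a_s/(b_s + c_s·time²)
    soil(i,j) ← (1−ρ_n)·soil(i,j) − ρ_n·Δ      (drop carries Δ)

Transition probabilities use soil only: p(j) ∝ 1/(ε + g(soil)), g shifting
so the minimum candidate soil is never negative. Per iteration, the best of
`n_drops` tours (by fitness) receives the global update
soil ← (1+ρ_iwd)·soil − ρ_iwd·carried/(m−1) on each of its edges, and an
elitist archive keeps the best subset ever scored (strict improvement only,
so ties keep the incumbent).

**HUD.** The heuristic undesirability of feature j is
1 − |r_j|/max_k |r_k|, where r_j is the largest absolute point-biserial
correlation between column j and any one-vs-rest class indicator.
Label-informative features are "easy riverbed": drops traversing them erode
more soil, nudging later drops toward them.

**Fitness.** Pooled stratified 3-fold accuracy of a nearest-centroid
classifier on the subset's columns, minus `lambda_penalty · m / d` (default
penalty 0 — the subset size is fixed per run, so the penalty is a constant
unless configured otherwise). Nearest-centroid rather than the BPNN keeps
the wrapper ~10³× cheaper; the network is trained once, on the final subset.
Fold assignment is seeded and fitness values are memoized, so the search is
fully deterministic given its seed.

**Default constants** are a_v = a_s = 1, b_v = b_s = 1, c_v = c_s = 1,
ρ_n = ρ_iwd = 0.1, init_soil = 1, init_vel = 1, ε = 1. These are chosen to be
*scale-consistent* with HUD ∈ [0, 1] and near-unit soils: early in the run
soil spreads are small relative to ε, so transition probabilities stay
smooth and the drops explore; as traversal and reinforcement push soils
apart (and reinforced soils negative), 1/(ε + g(·)) sharpens and the search
exploits. The constants often quoted for travelling-salesman IWD
(b = 0.01, ρ = 0.9, init_soil = 10⁴, init_vel = 200, ε = 0.01) assume
heuristic values on the scale of Euclidean city distances; with a [0, 1]
heuristic they make the soil delta constant to 0.25 % and the transition
rule winner-take-all after a single tour, freezing the search on its first
random subset. All constants remain configurable.

**Budget.** Defaults are 10 drops × 100 iterations (≈10³ tours); subset size
defaults to 10 % of the features (minimum 5). On an enumerable landscape
(10 features, unique optimal 3-subset, deterministic fitness) the search
recovers the exhaustive optimum in 20/20 seeded runs.

## BPNN

Three layers: inputs (the selected features), one logistic hidden layer, one
logistic output unit per class with one-hot targets. Training descends
½Σ(o−t)² — same minimizer as the RMSE that is logged, monitored, and used
for model selection — per sample with momentum, order reshuffled every epoch.
Weights initialize uniformly in ±scale/√fan_in (seeded). A stratified
`validation_fraction` (default 0.15) of the training rows is held out for
early stopping (patience 25) and for the snapshot rule: the returned model
is the one with the best validation RMSE, not the last. Hidden-size
selection trains one model per grid entry (default grid {4, 8, 16, 32, 64})
on a single fixed stratified split and keeps the size with minimum
validation RMSE, ties to the smaller. The 20 % test split is touched exactly
once, at final evaluation.

Defaults: learning rate 0.1, momentum 0.9, max 500 epochs. The central
correctness oracle is a finite-difference gradient check (relative 1e-6),
run over randomized small architectures in the suite.

## Evaluation

One-vs-rest per class: TP = cm(c,c), FN = row − TP, FP = column − TP,
TN = rest; sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision
TP/(TP+FP), F the harmonic mean of precision and sensitivity. Macro numbers
are unweighted class means (matching how single summary bars are usually
reported); overall accuracy is trace/total. Ratios 0/0 are reported as 0
and *flagged*, so degenerate classes (no true and no predicted documents)
surface instead of silently inflating averages. The implementation agrees
with scikit-learn to 1e-12 on randomized confusion matrices (test-only
cross-check).

## Synthetic corpus

The generator emulates the statistical structure of a six-class imbalanced
patient-emotion corpus whose reference distribution is 1343/358/742/1215/22/
522 (≈4200 documents, ≈1.63 M words, ≈65 k numeric tokens, i.e. ≈390 words
per document with ≈4 % numerics — these two ratios set `doc_length_mean=390`
and `numeric_token_rate=0.04`). Each document draws tokens i.i.d.: with
probability `keyword_rate` (default 0.35) from its class's disjoint pool of
`keywords_per_class` (default 5) synthetic keywords, with probability
`numeric_token_rate` a random digit string, otherwise from a shared
Zipf-weighted background vocabulary (`background_vocab_size=400`, a
desk-scale stand-in for the ~92 k unique unigrams of a full-size corpus —
chosen so the common/rare filters and the feature search are exercised
without quadratic soil tables becoming the bottleneck). Document lengths are
Poisson with a floor; labels are reassigned uniformly with probability
`label_noise_rate` (default 0.05). Everything is reproducible from one seed.

What the generator does **not** emulate: grammar, discourse, topical
correlation between tokens, class overlap in vocabulary (keyword pools are
disjoint by design, to give feature selection an unambiguous ground truth).
Passing benchmarks on this corpus therefore demonstrates that the machinery
works end to end under realistic imbalance, noise, and nuisance vocabulary —
not that these accuracy levels transfer to real clinical text, which is
harder in exactly the dimensions the generator idealizes.

## Pipeline and reproducibility

Stage order: load → (optional minority-class drop) → clean → vectorize →
split → IWD select → resample(train) → BPNN size-select + train → evaluate.
One global seed derives a per-stage seed by hashing the stage name, so any
stage can be rerun in isolation with identical results; two runs with the
same config and seed produce byte-identical artifact files. Every number in
the final report is recomputable from the persisted intermediates.

The benchmark configuration (tenth-scale corpus, 30 selected features,
hidden grid {8, 16, 32}) was sized to run in well under a minute on one CPU;
the suite's heavier property tests use the same scale.

## Known limitations

- **Redundant-keyword recovery.** With 5 interchangeable keywords per class
  at keyword rate 0.35, one selected keyword per class already saturates the
  wrapper fitness (measured: 0.958 for all 30 planted keywords vs 0.955 for
  a 6-keyword subset — a one-document difference at n=336). No wrapper
  objective can prefer redundant planted features over fitness-neutral
  background features, so "fraction of planted keywords recovered" is not a
  meaningful score here; the suite instead verifies class *coverage* and
  near-oracle fitness of the selected subset.
- **Tiny classes.** A 2-document class (the tenth-scale `Bored`) cannot be
  learned or reliably evaluated; its flagged 0/0 metrics are the honest
  report. The `drop_minority_class` flag exists for exactly this analysis.
- **Wrapper/classifier mismatch.** The subset is chosen for nearest-centroid
  accuracy but consumed by the BPNN; a BPNN-in-the-loop wrapper (supported
  via the custom fitness hook) removes the mismatch at ~10³× the cost.
- **Dense soil table.** The (d+1)² soil matrix limits the search to
  vocabularies of a few thousand features; larger corpora should raise the
  rare-term threshold or restrict n-gram orders before selection.
- **Selection bias of the wrapper.** The reported best-subset fitness is an
  optimistic estimate (maximum over ~10³ evaluated subsets); only the final
  test-split report is unbiased.
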