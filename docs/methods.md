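# Methods

## Normalization

Every reaction is reduced to a 40-value feature vector before any modelling.
The raw reporter signal (FAM or VIC) is divided cycle-by-cycle by the ROX
passive reference dye, cancelling well-to-well optical variation, and the
standardized curve is shifted so its own minimum equals exactly 1:
`Fnorm_c = Fstand_c − (Fmin − 1)`. `Fmin` is computed per trace over that
trace's cycles only — no pooling across wells — and no smoothing, baseline
regression, outlier rejection, or curve-feature extraction is applied. Two
consequences worth noting: the vector is invariant to any joint rescaling of
reporter and ROX, and its shape (all pairwise differences between cycles) is
exactly that of the standardized curve.

## The two-stage caller

Stage one is an XGBoost classifier with binary logistic loss mapping the 40
normalized values to an amplification probability; a reaction is called
amplified only when the probability is **strictly** greater than 0.5 (a
probability of exactly 0.5 is a negative call). Stage two is an XGBoost
regressor with squared-error loss predicting the Ct; it is trained only on
reactions the gold standard marks amplified and applied only to reactions
stage one calls positive, so a Ct exists exactly for positive calls. Calls
with probability in the closed interval [0.1, 0.9] are flagged for manual
review; closed endpoints are the conservative (more-flagging) reading.

Training objectives, cross-validation selection metrics, and round counts
are this package's choices: the classifier is selected on mean CV log-loss,
the regressor on mean CV MAE (the reported Ct metric), and the boosting
round count is not a grid axis but chosen by early stopping within 5-fold
CV (patience 20, cap 500), after which the final booster is refit on all of
that stage's training rows — keeping the contract that the classifier sees
every training row and the regressor exactly the gold-amplified rows.

The full tuning grid spans eta {0.1, 0.3, 0.5, 0.7}, max_depth 10–18,
min_child_weight {1, 5, 10}, subsample {0.5, 0.7, 1}, gamma {0, 0.1, 0.2},
colsample_bytree {0.5, 0.7, 1} (2,916 points per stage). The optima
published for the original 165k-reaction TAC corpus ship as
`CLASSIFIER_PRESET` / `REGRESSOR_PRESET`; they are provenance, not
defaults — tuning on other data, including the synthetic corpus, is
expected to select different points. The untuned defaults
(`eta 0.3, depth 6` classifier; `eta 0.1, depth 6, min_child_weight 5`
regressor) are deliberately moderate: the feature space is only 40 smooth,
monotone-ish columns, and deep trees buy nothing on desk-scale data.

All boosters run single-threaded with a fixed seed, so identical data,
parameters, and seed reproduce identical probabilities byte-for-byte;
multi-thread training is possible through xgboost directly but is not the
reproducible default.

## Evaluation conventions

Amplification is the positive class everywhere: Se = TP/(TP+FN),
Sp = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN); a metric with a zero
denominator is reported as absent, never as 0. MAE is computed over the
reactions the model *called* amplified: true positives contribute
|predicted − gold| and false positives contribute |predicted − 40|, the
no-amplification-within-40-cycles convention. The
`mae_excluding_misclassified` variant drops the false positives. False
negatives carry no predicted Ct and are excluded from the default MAE
denominator; an optional symmetric mode (`include_false_negatives=True`)
counts them with a predicted Ct of 40. Note that the excluding variant is
usually, but not provably always, the smaller of the two: it is smaller
exactly when the false positives' |predicted − 40| penalties exceed the
true positives' mean error, which holds whenever the regressor is accurate
and false positives are called well before cycle 40.

The analyst comparison scores any number of call tables against the same
gold labels with the same accuracy/MAE conventions and orders them worst to
best (ascending accuracy, ties broken by lower MAE first), optionally
ranking the automated model alongside.

## The synthetic generator

Each reaction is drawn on the standardized (reporter/ROX) scale as

    signal(c) = B0 + B1·c + A/(1 + exp(−k(c − m))) + ε_c,   ε_c ~ N(0, σ²)

with the logistic term present with probability equal to the prevalence
(default 0.25, the amplification rate typical of enteric stool-metagenome
panels). The reporter trace is the signal times the nominal ROX level
(default 1.5 instrument units); the ROX channel itself gets independent
N(0, σ_R²) jitter, so the division step is genuinely exercised. Defaults:
amplitude A ~ U(1.5, 6) in normalized units, midpoint m ~ U(12, 42) cycles
(the upper tail produces late amplifiers crossing only near cycle 40),
slope k ~ U(0.4, 1.2) per cycle, baseline B0 ~ U(0.5, 1.5), drift
B1 ~ U(−0.005, 0.005) per cycle, σ = 0.05, σ_R = 0.01. A 10% random subset
of amplified curves gets a hook effect: linear decay at rate `0.01·A` per
cycle once the logistic passes ~95% of plateau (`c > m + 3/k`). Dye
identity is FAM with probability 0.702, and 12.6% of reactions are emitted
as FAM+VIC duplex pairs sharing a well id — the composition of the large
TAC corpora this generator emulates. Negative-curve morphology (flat with
drift and noise) is this package's own choice; no published quantitative
description of it exists.

Ground truth is analytic: Ct = m + ln(q/(1−q))/k with q = 0.05, the cycle
where the noiseless logistic reaches 5% of its plateau, and a reaction is
labelled amplified exactly when that crossing falls within the run. Because
the label comes from latent parameters rather than from the observed trace,
a marginal late amplifier can be labelled positive while its noisy observed
rise is indistinguishable from baseline — a configuration where a model can
be *confidently* wrong. Real gold standards (human analysts reading the
same trace) cannot produce this case, which is why flag-enrichment
behaviour on synthetic data is assessed at noise levels where errors are
plentiful rather than from the handful of errors a near-perfect run yields.
More generally, the generator does not emulate inter-well spatial effects,
amplification-efficiency kinetics, heavy-tailed instrument noise, or
between-card drift, so passing synthetic benchmarks demonstrates the
pipeline's mechanics and contracts, not clinical performance on instrument
data.

## Numerical choices

- **Fractional-Ct crossing oracle.** The simulator's self-check compares the
  first crossing of `1 + q·A` by the noiseless normalized trace with the
  closed form. Crossings are located by monotone cubic (PCHIP) root
  finding on the per-cycle samples: a linear chord between adjacent cycles
  systematically leads the true crossing in the convex early-exponential
  region (worst case ~0.1–0.4 cycles at steep slopes), while PCHIP stays
  within ~0.05 cycles. The check draws midpoints m ≥ 18 so the curve has a
  resolvable baseline phase: for crossings much before cycle ~10 the trace
  minimum already sits on the rising curve, and min-anchored normalization
  itself biases the observable crossing late — an identifiability limit of
  very early amplifiers, not an interpolation artifact.
- **Split.** Train size is exactly `floor(fraction · N)` (reproducing
  132,171/33,043 from 165,214 at 0.8), drawn uniformly at random by seed at
  the reaction level. Grouped splitting (e.g. by well, keeping duplex pairs
  together) is available for leakage-sensitive uses; with groups the floor
  target is met as closely as whole groups allow, never exceeded.
- **Ties and degenerate inputs.** Probability exactly 0.5 → negative call;
  flag endpoints inclusive; constant traces normalize to all-ones; an
  all-negative training set is an error (the regressor has nothing to learn
  from); an empty amplified subset in scoring yields absent MAE rather than
  0; metrics with empty denominators are absent, with a note.
- **Persistence.** Model bundles are a directory of two xgboost JSON
  boosters plus a JSON manifest (cycle count, threshold, flag interval,
  training sizes, hyperparameters, seed); calls round-trip through CSV at
  full float precision.

## Problem sizes

The test suite and the acceptance script run the full pipeline at 10,000
simulated reactions (8,000 train / 2,000 test), the normalization and
oracle property checks at 1,000 traces/curves each, and auxiliary checks at
1,200–6,000 reactions — sizes at which the synthetic task's accuracy and
MAE have comfortably converged while a complete run stays in the tens of
seconds on one core.

## Known limitations

Probabilities are not calibrated (the flag interval is used as published,
not refit); the simulator's Gaussian noise understates heavy-tailed
artifacts like bubbles or lifted baselines; tuning the full 2,916-point
grid per stage is supported but impractical on a laptop for large corpora —
the small grid or the presets are the intended entry points; and concordance
with the original study's archived instrument data is out of scope here, as
those curves and trained models are external artifacts.
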