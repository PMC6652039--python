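# Methods

## The model

`phenostack` builds, per injury phenotype, a two-level classifier over
compound records that carry a continuous 2D-descriptor vector and a binary
fingerprint.

**Level 1 — four single classifiers.**  AdaBoost (50 rounds of depth-1
stumps), kNN (inverse-distance-weighted vote on z-scored descriptors,
K chosen in 1–10 by pooled out-of-fold MCC over 5 stratified folds),
a classification tree (entropy splits, Laplace-smoothed leaf probabilities
(a+1)/(n+2)), and a random forest (100 trees).  All four are fit on the
descriptors that survive selection and export `p_positive`, `p_negative`
(summing to 1) and a hard label (`p_positive ≥ 0.5`).

**Level 2 — Laplacian-corrected naive Bayes.**  Each training compound is
represented by 12 meta-features (the 8 probabilities + 4 labels) plus,
optionally, its fingerprint bits.  Continuous meta-features are cut into at
most `n_bins` (default 10) quantile intervals estimated on the training
distribution; each interval becomes a Boolean indicator (exactly one per
group fires per compound; out-of-range values clamp into the edge bins;
a constant feature collapses to a single always-on indicator).  For every
Boolean feature F with total count N_F and active count A_F the model
stores

    p_F = (A_F + P_base·K) / (N_F + K),  K = 1/P_base,  W_F = ln(p_F/P_base)

which is the standard Laplacian-corrected estimator of commercial Bayesian
categorizers: the correction adds one virtual active among 1/P_base virtual
compounds, so an unseen feature relaxes to the prior (W=0) and — a pleasant
algebraic consequence — a feature present in *every* compound also gets
exactly W=0.  A compound's score is the sum of its present features'
weights; `EstPGood = logistic(logit(P_base) + score)` maps it to [0, 1].

**Out-of-fold stacking.**  Meta-features for training the Bayes layer come
from base models fit on the other 4 of 5 stratified folds, so no base model
ever scores a compound it was trained on; resubstitution stacking would
leak the base models' overfit (near-0/1 probabilities) into the
meta-model's bins.  The deployed base models are then refit on the full
training partition.

## Decision thresholds

EstPGood saturates to exactly 1.0 in float64 once the score exceeds ~37,
which is routine when a few hundred fingerprint features are informative;
distinct compounds become indistinguishable on the probability scale.  The
model therefore stores its decision cutoff in raw-score space.

Two defaults serve two purposes, both configurable:

* **Classification reporting** uses the best-split rule: the raw-score
  cutoff that maximises MCC on the out-of-fold training scores (midpoints
  of adjacent distinct scores as candidates, first maximiser wins).  This
  is the analogue of the best-split threshold that screening platforms
  attach to a Bayesian categorizer, and it is why a compound can be called
  active at an EstPGood far from 0.5.
* **Screening** uses the posterior-majority rule EstPGood ≥ 0.5 per model.
  Hit nomination favours recall: the dual-phenotype consensus already
  multiplies two filters, and clustering plus manual triage absorb false
  positives, whereas a precision-oriented cutoff silently drops borderline
  dual actives whose support under one model is mostly fingerprint-borne.

## Descriptor selection

Three rules, strictly in order, fit on the training partition only:
(1) drop a descriptor whose modal value covers more than 50% of compounds
(strict inequality — a binary descriptor balanced 50/50 survives);
(2) drop descriptors with |Pearson r(descriptor, 0/1 label)| < 0.1
(point-biserial); (3) visit pairs with |r| > 0.9 in descending |r| and drop
the member with the lower |activity correlation| (ties: the
lexicographically later name).  Correlation with a constant vector is
defined as 0.  Columns containing missing values are dropped before rule 1
with a warning.  Selection is idempotent, and the report's four lists
partition the input names.

## Synthetic study conditions

The generator emulates what the method needs from a curated
active/decoy benchmark, with defaults frozen at design time:

| parameter | default | meaning |
|---|---|---|
| `n_actives` | 116 | actives (263 for the hypoxia set in the demo) |
| `decoy_ratio` | 4 | inactives per active |
| `split_ratio` | 3:1 | train:test, stratified; test count = ⌊n/4 + 0.5⌋ per class |
| `n_chemotypes` | 5 | active clusters |
| `n_fp_bits` / `signal_bits_per_chemotype` | 256 / 8 | fingerprint length; enriched block per chemotype |
| `enrichment` / `background_rate` | 0.9 / 0.05 | P(signal bit set in own cluster) / P(any bit set) |
| `n_descriptors` / `matched_fraction` | 20 / 0.5 | descriptor count; fraction property-matched in decoys |
| `mean_scale` / `noise_sd` | 2.5 / 0.5 | chemotype centroid spread / within-cluster noise (unitless descriptor surrogates) |
| `seed` | 20190710 | master seed (a memorable constant) |

Actives cluster at chemotype centroids in descriptor space and carry their
chemotype's fingerprint block at the enrichment rate.  Decoys copy a random
active on the matched half of the descriptors (plus matching noise) — those
dimensions are class-uninformative by construction, as property matching
intends — and draw the other half from the background distribution, which
is where the descriptor-level class signal lives.  A fully matched decoy
set (`matched_fraction=1.0`, available for experiments) makes every
descriptor's activity correlation ≈ 0, so rule 2 removes the entire matrix
and no descriptor-based classifier can work; partial matching is what lets
the selection step and the base classifiers behave as they do on real
benchmarks.  Decoy fingerprints are pure background.

For screening experiments, two phenotype configs share their
chemotype-centroid pool (same `mean_seed`) but own disjoint fingerprint
signal blocks (`signal_bit_offset`), so a library compound can plausibly
carry one or both activity signals; the library generator plants known
dual-, single- and no-signal compounds with per-herb tags.

What the generator does **not** emulate: real descriptor distributions
(correlated, heavy-tailed, mixed discrete/continuous), fingerprint bit
collisions and substructure correlation, activity cliffs, assay noise in
labels, and chemotype imbalance.  Passing tests therefore demonstrate that
the pipeline's machinery is correct and that stacking behaves as designed
when its assumptions hold — not that the reported performance transfers to
any particular real dataset.

## Evaluation conventions

SE = TP/(TP+FN), SP = TN/(TN+FP), PPV = TP/(TP+FP),
accuracy = (TP+TN)/total, MCC by the usual four-factor formula; any metric
with a zero denominator is reported as 0 ("undefined/uninformative") so
tabular reports stay total.  Screening-domain tables conventionally label
overall accuracy "PPV"; the report writer follows that convention in its
`PPV` column and keeps the true positive predictive value under `ppv_eq3`.
ROC curves come from descending-score thresholds with trapezoidal AUC,
which equals the Mann–Whitney concordance statistic under ties.
Cross-validation refits the *entire* pipeline (selection, base models,
stacking) inside each of 5 stratified folds and reports per-metric mean
and sd.

## Screening procedure

Both phenotype models score the library; the consensus is the intersection
of per-model active calls.  Consensus hits are clustered on Tanimoto
(jaccard) distance by average-linkage agglomeration cut at k=5 clusters
(hits visited in compound-ID order, making the result independent of input
order), and the top 2 hits per cluster by EstPGood sum are nominated as
representatives — scaffold-novelty judgment is deliberately left to the
user.  Each hit reports its maximum Dice similarity to the union of both
models' training actives as an applicability-domain indicator.

## Problem sizes

The demo pipeline uses the study-scale datasets (263- and 116-active
phenotypes, 1315 and 580 compounds) and a 200-compound screening library;
a full run takes ~40 s on one CPU and is byte-reproducible under a fixed
seed.  The test suite regenerates everything programmatically; no data
files ship with the package.

## Known limitations

* The naive Bayes layer treats base-model outputs as independent evidence;
  four classifiers voting on the same descriptors are highly correlated,
  so their agreement is over-counted.  Out-of-fold stacking and the
  fingerprint replenishment mitigate but do not remove this; hard decoys
  that fool two or three base models remain the dominant error mode.
* The classification tree uses information gain, not C4.5's gain ratio,
  and AdaBoost uses SAMME stumps; hyperparameter semantics, not
  bit-for-bit behavior of any proprietary platform, are the contract.
* `select_k` optimises pooled out-of-fold MCC; with small training sets
  the selected K can vary between seeds.
* Dice-to-nearest-active is computed against training actives only; it is
  an applicability indicator, not a novelty score.
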