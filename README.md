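# oxygrad

Compositional analysis of how deep-sea sediment microbial communities
respond to declining oxygen.

Oxygen is one of the strongest controls on microbial community
composition in marine sediments, but most surveys only resolve the
oxic/anoxic dichotomy. `oxygrad` implements a reusable inference chain
for multi-core 16S surveys sampled along an oxygen penetration
gradient:

1. **Oxygen model** — per-core nonlinear fit of an exponential decay
   `O2(z) = a·e^(−kz)` to discrete optode measurements, interpolation at
   the microbial sampling horizons, zeroing of untrusted values below an
   anoxic threshold (default 5 µM), and assignment to seven
   concentration categories (>150, 150–100, 100–50, 50–25, 25–10, 10–5,
   <5 µM) with binary/ternary/quaternary groupings.
2. **Filtering** — singleton removal, <1,000-read sample removal,
   <100-read OTU removal, and per-core retention of the uppermost three
   anoxic samples.
3. **CoDA preprocessing** — count-zero-multiplicative zero imputation
   (δ = 0.65/N per sample) and centred log-ratio (CLR) transform, so all
   statistics respect the relative nature of read counts.
4. **Classification** — per-taxon RBF-kernel SVMs predicting the oxygen
   group from CLR features: 128 random 75/25 train/test iterations with
   per-iteration 10-fold CV tuning of (C, γ), matched shuffled-label
   null runs, a >60% dominance guard, per-sample accuracies, Spearman
   correlations and incremental-OTU overfitting scans.
5. **Differential proportionality** — for every OTU pair and category
   pair, the disjointed proportionality

   θ_d = SS_within / SS_total = 1 − R²

   of the log-ratio ln(x_i/x_j) in a two-group one-way layout; a pair is
   differentially abundant when θ_d < 0.50 (between-group log-ratio
   variance at least twice the within-group variance), survives a
   label-permutation FDR ≤ 0.0005, and sits in the lowest 25% of
   surviving θ_d. OTUs in no retained pair are "never differentially
   abundant" and are binned to class level by read fraction.
6. **Interpretation** — each taxon lands in a quadrant of
   (classification skill vs null) × (never-DA read fraction):
   oxygen-dependent, covariate-suspected, weak signal, or ambiguous.

A synthetic multi-core generator with known ground truth (threshold
responders, gradual responders, high-variance non-responders,
nitrate-tracking OTUs, noise; logistic-normal compositions; multinomial
reads at heterogeneous depths) makes every stage testable end to end.

## Worked example

Run the full pipeline on the default synthetic survey (11 cores × 17
horizons, 500 OTUs in five 100-OTU classes) with two grouping schemes
and 32 classifier iterations:

```sh
cat > config.yaml <<EOF
groupings: [binary, quaternary]
classifier:
  n_iterations: 32
diffabund:
  n_perm: 100
seed: 11
EOF
oxygrad run --config config.yaml --out-dir out
```

Output (abridged):

```
samples per category: {1: 11, 2: 4, 3: 7, 4: 10, 5: 10, 6: 10, 7: 33}
       taxon   grouping  n_otus  median_accuracy  null_median  null_iqr
  Gradientia     binary      30         0.904762     0.476190  0.142857
  Stochastia     binary      30         0.571429     0.428571  0.142857
 Thresholdia     binary      30         0.880952     0.476190  0.154762
 Thresholdia quaternary      30         0.714286     0.357143  0.107143
never-DA OTUs: 145 (24.6% of reads)
```

Reading the numbers: the threshold-responder class (`Thresholdia`)
classifies binary oxygen state in 88% of test draws against a 48%
shuffled-label null, and none of its reads are never-DA — the
oxygen-dependent quadrant. The deliberately noisy non-responder class
(`Stochastia`) barely beats its null (57% vs 43%) and carries 100%
never-DA reads (see `out/never_da_per_class.tsv`): its OTUs vary too
much *within* oxygen categories for any pairwise log-ratio to flag
them, exactly the behaviour that makes abundant taxa look
oxygen-indifferent at the OTU level. `out/interpretation.tsv` holds the
quadrant labels, `out/sample_oxygen.tsv` the interpolated per-sample
concentrations and categories, and `out/da_pairs_1v6.tsv` /
`out/da_pairs_1v7.tsv` the retained differentially abundant pairs.

The same stages are available piecemeal (`oxygrad simulate`, `oxygen`,
`filter`, `transform`, `classify`, `diffabund`, `verify`) and as a
library (`oxygrad.theta_d`, `oxygrad.run_classification`, ...).

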