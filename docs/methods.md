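# Methods

This note documents the models, defaults and numerical choices behind
`oxygrad`, and what the synthetic benchmark does and does not show.

## Oxygen model

Each core's discrete oxygen measurements are summarised by a
two-parameter exponential decay `O2(z) = a·exp(−k·z)` (a in µM, k per
cm, both > 0). A third (asymptote) parameter was deliberately not
included: near the optode detection limit the tail is censored, so an
asymptote is unidentifiable, and the zeroing rule below absorbs tail
behaviour. The fit is initialised from an ordinary least-squares
regression of ln(O2) on depth and refined by nonlinear least squares on
the linear scale (`scipy.optimize.curve_fit`, positivity bounds).
Only measurements at or above the detection limit (default 3 µM) enter
the fit; censored readings carry no quantitative information and
treating them as zeros would bias k. Cores with fewer than three usable
points are rejected (`InsufficientOxygenDataError`) and dropped by the
pipeline with a logged warning.

Interpolated concentrations below the **anoxic threshold** (default
5 µM) are set to exactly 0: downcore extrapolation beyond the last
measurement fluctuates between small positive and negative values, so
the model tail is not trusted. Categories 1–7 partition [0, ∞) µM with
lower-closed/upper-open boundaries at 150/100/50/25/10/threshold; a
concentration of exactly 25 µM is category 4. The category-6/7 boundary
follows the anoxic threshold so that the 3 µM sensitivity variant
relabels borderline (3–5 µM) samples from anoxic to low-oxic rather
than leaving the partition fixed; at the default threshold this is the
standard interval set. Groupings: binary = {1–5 | 6–7}, ternary =
{1–5 | 6 | 7}, quaternary = {1–4 | 5 | 6 | 7}.

## Filters

Order is fixed and order-sensitive: singletons (dataset-wide total of
exactly 1) → samples with fewer than 1,000 reads → OTUs with fewer than
100 reads, recomputed after the sample removal (text order of the
protocol; the alternative recount-before order is a one-line change) →
per core, only the three shallowest anoxic samples are kept (ties in
depth broken lexicographically by sample id). Boundary values (exactly
1,000 reads, exactly 100 reads) are retained. Filters are pure
subsetting; each emits a `FilterReport` and reports chain exactly.

## Compositional machinery

Zeros are replaced count-zero-multiplicatively: for a sample with total
N, each zero becomes δ = 0.65/N (65% of the per-sample detection limit
1/N — the conventional default of multiplicative-replacement routines;
the factor is exposed as `delta_factor`) and non-zero proportions are
multiplied by (1 − n_zeros·δ), preserving closure exactly. The scheme is
only well defined while n_zeros·δ < 1; `impute_zeros` raises beyond
that. Under the default pipeline (≥1,000-read samples, ≥100-read OTUs,
500 OTUs) the replaced mass stays ≤ ~0.33.

CLR uses natural logarithms throughout; VLR and θ_d are log-base
invariant, and CLR features differ between bases only by a constant
factor that the SVM's tuned γ absorbs. VLR is the ddof = 1 sample
variance of ln(x_i/x_j); it is closure-invariant and invariant to
subsetting to any superset of the pair (subcompositional coherence),
both asserted by exact tests.

## Differential proportionality

For a pair (i, j) and two sample groups, the disjointed proportionality
is θ_d = SS_within/SS_total of the per-sample log-ratio — the 1 − R² of
a one-way two-group ANOVA, in [0, 1], with SS_total = 0 defined as
θ_d = 1. θ_d < 0.50 means the total log-ratio variance is at least
twice the pooled within-group variance. The all-pairs screen is
vectorised through per-group Gram matrices
(SS_ij = q_i + q_j − 2G_ij − (r_i − r_j)²/n), so a 500-OTU screen is a
handful of 500×500 matmuls; a soft cap (`max_otus`, default 2,000)
guards the O(p²) memory and is an explicit opt-in beyond that.

The FDR attached to each pair is permutation-based (default 100 label
permutations preserving group sizes): FDR(t) = mean permutation count
of θ* ≤ t divided by the observed count of θ ≤ t, clipped to [0, 1] and
made monotone non-decreasing in θ. SS_total is permutation-invariant,
so only within-group sums are recomputed per permutation. Retention is
three filters in sequence — θ_d < 0.50, FDR ≤ 0.0005, then the
⌈25%⌉ of surviving pairs with lowest θ_d — applied **per category-pair
comparison** (the unit at which θ_d is defined); a pooled-across-
comparisons variant would only require concatenating the scored tables
first. "Never differentially abundant" OTUs appear in no retained pair
across the designated comparisons (default categories 1–6 and 1–7);
the report gives per-class never-DA read fractions and dataset-level
OTU/read shares. The same pathway runs against any covariate via
user-supplied breakpoints (`covariate_screen`); nitrate-like category
boundaries are deliberately an input, not a constant.

## Classification protocol

Features are CLR values of one taxon's OTUs (samples × OTUs), OTUs
ordered by decreasing dataset-wide read count; `top_k` truncates
(default 30 in the pipeline; `None` uses all). The response is the
binary/ternary/quaternary oxygen group. A guard refuses problems where
one group exceeds 60% of samples. Each analysis runs 128 iterations of:
random 25% test split; 10-fold CV grid search on the training set over
C ∈ {0.25, 1, 4, 16, 64} and γ = median-heuristic × {0.1, 1, 10}
(median heuristic: inverse median squared Euclidean distance between
training samples; ties resolve to smallest C then smallest γ via
first-best-wins in that order); RBF-SVM fit (one-vs-one for >2 groups);
test accuracy and per-sample correctness recorded. Null runs permute
the full label vector once per iteration *before* splitting, so train
and test share the same broken labelling; under it, mean accuracy sits
between the proportional-chance bound Σg² and the majority-class bound
max g of the group frequencies. One master seed spawns per-iteration
child seeds, so iteration results are independent of execution order.
Degenerate single-group training splits are redrawn (up to 100 times).

The overfitting scan evaluates k = 10, 30, 50, … up to all of the
taxon's OTUs; the optimum is the smallest k achieving the maximum
median accuracy. Per-sample accuracy is times-correct/times-tested;
its Spearman correlations against category and depth use mid-ranked
ties and asymptotic p-values, with constant inputs reported as NaN.

## Synthetic generator

The generator emulates the structure of a post-processed multi-core
survey; defaults are desk scale and were fixed once:

- 11 cores, 17 horizons each over 0–190 cmbsf; true profiles
  O2(z) = a·e^(−λz) with a ~ U(150, 300) µM and λ solved so the 5 µM
  crossing is U(10, 116) cmbsf; measurements every 4 cm with N(0, 2 µM)
  noise, truncated at the first reading below 3 µM (shipboard practice).
- 500 OTUs in five 100-OTU classes, one archetype each. Per OTU and
  sample, log abundance = baseline + effect·response(O2) + N(0, σ_w),
  exponentiated and closed per sample (logistic-normal). Baselines are
  N(0, 1) per OTU. Responses in [0, 1]: logistic step at 25 µM (width
  5 µM) for threshold responders; ln(1+O2)/ln(1+300) for gradual
  responders; 0 for non-responders and noise; nitrate/30 for covariate
  trackers. Default effect 2 log-units, σ_w = 0.5 — except
  non-responders, which carry σ_w = 1.5 and no oxygen effect: the large
  *within-category* spread is precisely the mechanism by which abundant
  taxa escape the pairwise screen, so the benchmark encodes it as the
  non-responder's defining property rather than as an optional knob.
- The nitrate-like covariate is peaked: baseline 2 µM above 50 µM O2,
  rising linearly to 30 µM at the anoxic threshold, then decaying with
  depth below the crossing (e-folding 30 cm), plus N(0, 2 µM) noise. It
  is a minimal stand-in for a real porewater profile — enough to give
  trackers a gradient that covaries with, but is not, oxygen.
- Reads: per-sample totals log-normal (median 15,000, σ_log = 0.6,
  clipped at ≥1,000), multinomial draws from the latent composition; 5%
  of samples forced to U{100..999} reads (so the low-depth fraction is
  exact by construction); 2% singleton OTUs injected with one read in a
  random sample. All randomness flows from one integer seed through
  spawned `numpy` Generator streams; output is bit-reproducible.

What the generator does **not** emulate: sequencing error, chimeras,
contamination lineages, phylogenetic correlation between OTUs, spatial
autocorrelation between cores, or bioturbation. Passing recovery tests
therefore shows the chain is correct and sensitive under idealised
log-linear responses, not that any real survey meets those conditions.

An observation worth keeping in mind: because CLR centres each sample
by its geometric mean, OTU blocks with no oxygen effect of their own
can still classify above null when other blocks shift — the
compositional coupling the log-ratio framework is designed to make
explicit. The pairwise θ_d screen is the instrument that separates
intrinsic responders from such passengers.

## Pipeline and reproducibility

`run_pipeline` executes simulate/load → oxygen → filter → transform →
classify → differential abundance → interpretation with one master
seed; stage logs are JSON lines; every report count is re-derivable
from emitted files (`oxygrad verify`). The interpretation matrix calls
a taxon's accuracy "high" when the real median exceeds the null median
by 2× the null IQR and its never-DA read fraction "high" above 0.5;
both cuts are configuration, since no principled constants exist for
these qualitative quadrants. Default problem sizes (500 OTUs, ~130
filtered samples, 128 iterations, 100 permutations) keep a full run in
minutes on a single CPU; tests use smaller designs chosen to exercise
the same code paths.

## Known limitations

- The 25% retention rule is interpreted per category-pair comparison;
  pooled retention across comparisons would retain a different set near
  the θ_d cutoff.
- The permutation FDR is the screen's native estimator but is grainy at
  small n_perm; with 100 permutations the smallest non-zero FDR
  resolution per pair scale is limited by the permutation count.
- Exact zeros are imputed, not modelled; heavy zero inflation beyond
  the guard's range requires stronger filtering, not a smaller δ.
- The oxygen model is phenomenological; it is an interpolator, not a
  reactive-transport model, and extrapolation below the last
  measurement is deliberately refused (zeroing rule).
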