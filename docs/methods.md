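# Methods

`ehgselect` implements a preterm-labor prediction pipeline for
electrohysterogram (EHG) recordings under severe class imbalance: signal
conditioning and windowing, a 227-dimensional feature representation,
genetic-algorithm (GA) wrapper feature selection with resampling embedded
in the selection loop, and threshold-independent evaluation over repeated
stratified holdout partitions. This note records the model, the
parameters that matter, and the design decisions taken where the design
was genuinely open.

## Signal model and preprocessing

Records are 3 bipolar abdominal channels sampled at 20 Hz. Uterine
electrical activity concentrates below 1 Hz (fast wave low 0.2–0.34 Hz,
fast wave high 0.34–4 Hz), so signals are band-pass filtered to
0.1–4 Hz with a 5th-order Butterworth filter applied forward and
backward (zero phase; the effective magnitude response is 10th order).
Edge transients of the slow 0.1 Hz edge settle over roughly `1/f_low`
seconds, so the forward–backward pass uses reflective padding of
`3 fs / f_low` samples — without it, refiltering passband content changes
it by ~2 % RMS purely through endpoint transients; with it, well below
1 %.

Expert-style artifact annotations are taken as input (the synthetic
generator produces ground-truth masks). Analysis windows are 120 s with
50 % overlap; a window is used only if it lies entirely inside a clean
interval, and the window grid restarts at the start of every maximal
clean segment, giving `floor((T_clean − 120)/60) + 1` windows per
segment. Windows partially overlapping an artifact are dropped entirely —
the conservative reading of "corrupted segments were removed". Filtering
happens before windowing. Window-level features are summarised per record
by the sample median, which is robust to the occasional pathological
window.

## Feature set

Per channel: peak-to-peak amplitude (App) in 0.1–4, 0.2–0.34, 0.34–4 and
0.34–1 Hz (4 temporal); mean frequency, dominant frequencies DF1
(0.2–1 Hz) and DF2 (0.34–1 Hz), three normalised sub-band energies
(0.2–0.34, 0.34–0.6, 0.6–1 Hz), the high/low energy ratio
(0.34–1)/(0.2–0.34), spectrum deciles D1–D9, Teager energy and the
spectral moment ratio, all over 0.2–1 Hz (18 spectral); and 13 non-linear
measures — binary and 6-state Lempel–Ziv, time reversibility, Katz
fractal dimension, Poincaré SD1/SD2/SDRR/SD1:SD2, and sample, fuzzy,
spectral, dispersion and bubble entropy — each computed after refiltering
to the same four bands as App (52 non-linear). That is 74 per channel,
222 over 3 channels, plus 5 obstetric covariates (maternal age, parity,
abortions, weight, gestational week at recording) = 227 classifier
inputs.

Numerical choices where the measures' literature leaves room:

* **Spectrum estimator** — Welch averaged modified periodogram, Hann
  window, 600-sample (30 s) segments with 50 % overlap inside each 120 s
  window; bin width 1/30 Hz. Welch trades frequency resolution for
  variance, which matters on 2 400-sample windows. Deciles are linearly
  interpolated on bin edges (each bin's energy attributed up to its right
  edge), which removes the half-bin bias a bin-centre interpolation
  introduces. Sub-band masks are half-open so the three NormEn bands tile
  0.2–1 Hz without double-counting boundary bins.
* **SpMR** — the dimensionless moment ratio `m0 m2 / m1^2` over
  0.2–1 Hz (moments of the PSD in frequency).
* **Teager energy** — mean of `x²(n) − x(n−1) x(n+1)` on the 0.2–1 Hz
  filtered window.
* **Entropies** — SampEn/FuzEn: m = 2, r = 0.15 × window SD, Chebyshev
  distance, FuzEn membership `exp(−(d/r)²)` with locally centred
  templates; DispEn: 6 classes via normal-CDF mapping, m = 2, delay 1,
  normalised by `log(6²)`; BubbEn: Rényi-2 entropy growth of inversion
  counts between embedding dimensions 10 and 11; SpEn: Shannon entropy of
  the normalised Welch spectrum over the band, normalised by the log bin
  count. SampEn with zero matches returns the upper-bound sentinel
  `log(#pairs)` rather than infinity.
* **Lempel–Ziv** — LZ76 exhaustive production parsing; binary
  quantisation at the window median, 6-state via equal-probability bins
  from order statistics; the phrase count is normalised by
  `n log(states)/log(n)`. A constant window parses to the 2-phrase
  minimum, not an error.
* **Time reversibility** — third moment of lag-1 differences (the most
  common form); odd under time reversal by construction.
* **KFD** — ordinate-only curve length (`L = Σ|Δx|`), which makes the
  measure scale-invariant and exactly 1 for straight lines.

Missing obstetric covariates are median-imputed from training rows only;
signal features are never imputed.

## Classifier

LDA as a pooled-covariance Gaussian discriminant, written in closed form
(`w = Σ⁻¹(μ₁−μ₀)` plus a bias from the class means and empirical priors;
the preterm posterior is the logistic of the linear score). A ridge term
`1e-9 · trace(Σ)/p` keeps Σ invertible under collinearity; in that limit
the discriminant matches the minimum-norm solution, so duplicated
columns give the same posteriors as dropping them. Features with zero
pooled variance are dropped with a warning. The closed form exists
because the GA fitness loop fits ~10⁵ small LDAs per run; the
implementation is cross-checked against scikit-learn's
`LinearDiscriminantAnalysis` in the tests.

## Partitioning and resampling

The holdout scheme draws stratified train (64 %) / validation (16 %) /
test (20 %) index triples; repeat *i* is a deterministic function of
(seed, *i*). All steps reuse one scheme, so strategy comparisons are
paired across partitions. For the 51:275 study composition each test set
holds 65 rows with 10 preterm.

Resampling families (all with a target minority:majority ratio, default
1:1, minority = preterm by definition): SMOTE (k = 5) interpolates
synthetic minority rows between a minority row and one of its k nearest
minority neighbours; NCL removes majority rows via Wilson's edited
nearest-neighbour rule (k = 3) plus the majority neighbours of
misclassified minority rows; the hybrid applies SMOTE then NCL (the
reverse order is a flag). NCL alone cannot hit an arbitrary ratio, so
the undersampling family follows NCL with seeded random majority removal
down to the target — this keeps NCL's boundary cleaning while making the
ratio sweep well defined. Distances are Euclidean on z-scored features
(training-fold statistics). Invariants: no minority row is ever deleted,
no majority row fabricated.

## GA feature selection

Binary masks over all 227 candidate features by default (a helper
restricts the genome to the 222 signal features with covariates always
included, covering the alternative configuration). Fitness =
mean over partitions of `F1 × (NFeat − NCFeat)` with F1 the preterm-class
F1 of LDA(train fold) on the validation fold, after resampling either the
training fold (FS_TO/TU/TH) or the validation fold (FS_VO/VU/VH) inside
the loop. The all-ones mask scores exactly 0 and, at equal F1, smaller
masks score higher — the size term is the only parsimony pressure. F1
uses the posterior-argmax decision (0.5 threshold), since no operative
threshold exists during selection. The same partitions are reused for
every chromosome, so fitness is a deterministic function of the mask
and is cached by mask bytes.

The GA is generational: i.i.d. Bernoulli(0.5) initial masks, tournament
selection of size 2, arithmetic crossover (p = 0.8) with *per-gene*
weights re-binarised at 0.5 — a single shared weight would thresh to
pure parent cloning on binary genomes, so per-gene weights are required
for any gene mixing; exact 0.5 ties fall back to the respective parent's
bit — uniform bit-flip mutation (p = 0.01), 2 elites, all-zero children
repaired by activating one random gene. Termination: 500 generations or
best-fitness improvement below 1e-6 for 150 consecutive generations.
Defaults are the full-scale configuration (population 222); tests and the
acceptance script run the scaled configuration (population 40,
60 generations, 20 partitions) so a selection run takes seconds rather
than hours — the full-scale settings remain available through
`GAConfig`.

## Evaluation and statistics

Threshold-independent: AUC (rank/Mann–Whitney equivalent) and average
precision (step-summed precision-recall area), via scikit-learn, both
checked against brute-force oracles in the tests; the summary score is
(AUC + AP)/2. Threshold-dependent metrics (recall, specificity,
precision, F1, G-mean) are evaluated at operative points maximising F1
or G-mean over the observed scores, ties resolving to the lowest
threshold (favouring recall — false negatives are the costly error in
obstetrics). Strategy comparisons: per-method D'Agostino K² normality
check, one-way repeated-measures ANOVA with partitions as subjects (no
sphericity correction), and Tukey's studentized-range test on the RANOVA
error term; homogeneous groups are the connected components of the
"not significantly different at α = 0.05" graph. The RANOVA is
implemented directly (the common Tukey implementations use the
between-subject error term) and cross-checked against pingouin.

## Synthetic data: what it emulates and what it does not

The cohort generator produces pink-noise baselines band-limited to
0.1–4 Hz (10 µV RMS) with Poisson-placed contraction-like bursts
(Gaussian envelope, 0.2–0.8 Hz carrier with integrated phase jitter,
~40 µV, shared timing across channels), annotated high-amplitude
artifact segments covering a controllable fraction of the record, and
obstetric covariates drawn from plausible ranges with *no* class effect —
so any discriminative power in tests comes from the signals. Class
effects are multiplicative: preterm records scale the whole signal by
`amplitude_shift`, burst carriers by `frequency_shift`, and divide the
phase jitter by `regularity_shift` (defaults 1.3 / 1.15 / 1.3 — moderate
shifts chosen so the classes overlap, as they do in recordings taken far
from delivery). The default composition is 51 preterm : 275 term.

The generator reproduces the *statistical structure* the pipeline
assumes (imbalance, class-dependent amplitude/frequency/regularity
shifts, artifacts, covariates), not uterine electrophysiology: no
tocogram, no electrode geometry, no gestational-age dynamics, and
burst waveforms are stylised. Passing tests therefore demonstrate the
machinery — leakage-free resampling, selection behaviour, metric
correctness — not clinical performance on real EHG databases, whose
headline numbers require the real recordings.

Gaussian feature tables (`generate_feature_table`) provide a second,
fully controlled test bed: informative columns shift the minority mean
by `separation/√n_informative` each (total Mahalanobis distance =
`separation`), noise columns are identically distributed in both
classes, and the theoretical LDA ceiling is `AUC = Φ(separation/√2)`.

## Experiment defaults and problem sizes

The acceptance script and test suite run: planted-subset recovery (20
runs, 5 informative + 45 noise columns at separation 3, 51:275 rows,
scaled GA); the leakage contrast (separation 0.5, 30:170, 50 paired
repeats — SMOTE before the split inflates test AUC because interpolated
minority rows land on both sides of it); and the ratio sweep. The sweep
runs in the heavy-overlap regime (227 columns, 30 weakly informative at
total separation 1.0, 51:275 rows), chosen because its all-features LDA
baseline sits near chance — the regime the method targets; two
independent replicates of the whole sweep are run and the trend is
summarised as the Spearman correlation between ratio and test
(AUC+AP)/2 over all points. These sizes keep a full run in minutes
while leaving every qualitative contrast measurable.

## Known limitations

* On i.i.d. Gaussian feature tables the final test performance after
  selection shows no measurable dependence on the validation target
  ratio: the GA reaches comparable masks at any balance, and the
  per-ratio differences sit inside Monte-Carlo noise in every regime
  tried (separable, moderate and heavy overlap). A monotone
  ratio-performance trend appears to require data structure —
  correlated, heterogeneous, clustered features — that the independent-
  Gaussian table generator deliberately does not model; the sweep
  experiment reports the measured correlation either way.
* Real-database loaders cover the package's own plain-text layout;
  native WFDB reading is not included.
* The GA fitness is noisy at 20 partitions; at the scaled configuration
  the planted-recovery rate sits near the 80 % mark rather than
  comfortably above it. The full-scale configuration (200 partitions)
  averages the noise down but costs hours.
* Only LDA is wrapped; the design isolates the classifier behind
  `lda_fit`/`lda_posterior`, but no other classifier is provided.
* RANOVA applies no sphericity correction; with 200 paired partitions
  and 4–7 methods the F test is used as a gate for Tukey grouping, not
  as a precise p-value.
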