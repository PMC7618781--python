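# Methods

This note documents the models, conventions and numerical choices behind
`msnorm`, in the order data flows through the toolkit.

## Raw-data handling

Centroided peak lists are binned to a unit-mass axis by adding each
peak's intensity to its nearest-integer m/z bin, with halves rounding
away from zero; peaks outside the configured range are dropped and every
integer bin in the range is present (zero-filled). The default axis is
10–999 Th inclusive (990 features), chosen to match the feature count of
the plasma data sets this design targets; it is configurable everywhere.

Background subtraction is a per-bin difference clamped below at zero:
negative intensities have no physical meaning here and every downstream
operator assumes non-negative raw data. Replicate averaging takes the
arithmetic per-bin mean within a grouping key (usually the patient) and
requires the class label to be constant within each group.

mzML support is deliberately minimal: read-only parsing of centroided
spectra (64/32-bit little-endian floats, optionally zlib-compressed)
with a total-ion-current threshold selector standing in for
probe-in-source segment extraction. Profile-mode peak picking is out of
scope.

## Normalisation operators

Row-wise operators divide each spectrum by its own sum (AUC), mean,
median, or Euclidean norm. All four are exactly invariant to
multiplication of a spectrum by any positive constant — the loading
factor — which is their purpose.

**Minimised-vector** rescales each spectrum I_S by the k_S that minimises
‖Ī − k_S·I_S‖², where Ī is the centroid (column-mean) spectrum of the
set. The minimiser has the closed form k_S = (Ī·I_S)/(I_S·I_S); a grid
search over k confirms it in the tests.

**Quantile** normalisation forces all spectra to share one intensity
distribution: sort each row, average across rows at each rank, write the
averages back at each row's sorted positions, restore the original
order. Ties are broken by stable sort order, so ranks are positional
(no mid-rank averaging).

**Histogram** normalisations build, per spectrum, a histogram of that
spectrum's intensity values over five unequal segments: one bin
[0, q(P₁)), three runs of n₁/n₂/n₃ equal-width bins spanning
[q(P₁), q(P₂)), [q(P₂), q(P₃)), [q(P₃), q(P₄)), and one final bin
[q(P₄), max], where q(·) are linear-interpolation percentiles of the
spectrum's own intensities (defaults P = 20/40/60/80, n = 30/30/30 —
the segments' published starting values, with the unstated P₂..P₄
spaced evenly between P₁ and 100). The total bin count is
2 + n₁ + n₂ + n₃: the first and last segments are single bins. Bins are
left-closed right-open except the final bin, which is right-closed so
the maximum is always assigned. A spectrum whose P₁ and P₄ percentiles
coincide (e.g. constant intensities) is degenerate and raises an error.
Three representations are derived:

* *bin*: each intensity is replaced by its 0-based histogram bin index
  (because indices are 0-based, the lowest-intensity bin maps to 0;
  a 1-based convention would shift the *function* variant by 1/I);
* *intensity*: each spectrum is replaced by its histogram's counts
  vector, so the feature axis becomes histogram-bin indices of dimension
  2 + n₁ + n₂ + n₃ and downstream scaling operates on those columns;
* *function*: each intensity I is replaced by bin[I]/I, with 0 kept at
  I = 0 so absent peaks stay absent.

Because the histogram is built per spectrum, these operators involve no
cross-spectrum statistics and cannot leak between train and test
partitions.

## Scaling and transformation

Column statistics (mean, median, sample standard deviation with n−1
denominator, min, max) are computed from a designated reference matrix
and applied separately, so a training partition's statistics can scale a
test partition.

The scaling operators follow their printed division-based definitions:
mean-centre N = I/Ī_m, median-centre N = I/Ĩ_m, auto N = (I/Ī_m)/σ_m,
Pareto N = (I/Ī_m)/√σ_m, range N = (I/Ī_m)/(max−min). The conventional
subtractive forms ((I−Ī_m), (I−Ī_m)/σ_m, …) are available behind
`conventional=True` for comparison but are not the defaults. Auto and
Pareto differ only in the exponent of the standard deviation in the
divisor (σ vs √σ).

Transformations are element-wise: natural log, exp, x², x³, √x, ∛x. The
log of data containing zeros adds a pseudo-offset of one tenth of the
smallest strictly positive value (fitted on the reference matrix in
pipelines); values still non-positive after the offset are an error, as
are negative inputs to √x. The cube root of a negative value is the real
root, so transforms compose after subtractive scaling.

## The pipeline and the C_R grid

Combinations are applied in the fixed order normalisation → scaling →
transformation. `apply_combo(matrix, combo, fit_matrix)` sources every
set-level quantity (quantile rank-means, minimised-vector centroid,
column statistics, log offset) from `fit_matrix`, which defaults to the
matrix itself; the ML protocol passes the training rows. The 420
combinations are enumerated in deterministic normalisation-major order.

`run_grid` scores all 420 combinations by the clustering ratio

C_R = ‖x̄₁ − x̄₂‖ / (s₁ + s₂),

where x̄_c is the class-c centroid and s_c the *sample* (n−1) standard
deviation of the class members' Euclidean distances from x̄_c. C_R is
computed in the full feature space of the processed matrix — no
dimensionality reduction. If both cluster sizes are zero while the
centroids differ, C_R is +∞ with a warning; a combination that errors
(degenerate histogram, zero scaling denominator, non-finite values from
overflow) is recorded as failed with its reason so the grid always
completes. In practice many histogram × scaling combinations fail on
sparse data because histogram binning produces constant-zero columns,
whose division-based scaling is undefined; this is reported, not hidden.

## Classification evaluation

Partitions are drawn at the patient level: within each class a fraction
(default 20%, at least one patient) is held out per split, so all
replicate spectra of a patient fall wholly on one side and both classes
appear in every test set. Stratification is a deliberate choice — with
cohorts of a few dozen patients, unstratified splits can produce
single-class test sets, for which κ is undefined.

Per split, the preprocessing combination is fitted on the training rows
and applied to both sides, an off-the-shelf scikit-learn classifier
(KNN, SVC, LDA, Gaussian naive Bayes, or random forest) is trained and
predicts the test rows, and the split's binary confusion table yields one
κ. Reported are the mean and (n−1) standard deviation of κ over the
partitions, plus the accuracy of the summed confusion table. κ is
computed from the algebraic closed form
2(TP·TN − FN·FP)/((TP+FP)(FP+TN) + (TP+FN)(FN+TN)); its equivalence to
(P₀−P_e)/(1−P_e) is asserted in the tests. Degenerate tables (zero
denominator) and classifier failures skip the split and are counted.
Mean-κ agreement bands (none/minimal/weak/moderate/strong/almost
perfect) follow McHugh's published cut-offs.

Classifier hyperparameters default to the library defaults. A small grid
(KNN n_neighbors ∈ {3,5,7}; SVC C ∈ {0.1,1,10}; naive-Bayes
var_smoothing ∈ {1e-9,1e-7}; random-forest max_features ∈ {√p, p})
searched by 5-fold cross-validation on the training split is available
via `tune=True`; it is off by default because it multiplies runtime
roughly 15-fold and, on the synthetic cohorts, does not change the
qualitative ranking of preprocessing methods.

## Genetic-algorithm histogram optimisation

The GA optimises the seven-gene genome (P₁..P₄, n₁..n₃) with C_R of the
histogram-normalised matrix as fitness. Defaults: population 40,
50 generations, tournament size 3, uniform crossover rate 0.8, per-gene
mutation rate 0.1 (Gaussian σ = 5 percentile points for P genes, ±5 for
n genes, both clipped to bounds), elitism 2. These are design choices —
no published values exist for them. Constraint handling is by −∞
penalty: genomes with out-of-order percentiles, or valid genomes whose
histogram is degenerate on the data, simply lose every tournament; this
keeps the encoding simple at the cost of some wasted evaluations. The
initial population is the default layout, a quarter of jittered copies
of it, and random genomes. Elitism makes the best-so-far fitness
non-decreasing, which the tests assert, and a coarse exhaustive sweep
serves as an optimality oracle on a reduced search space. The number of
segments is fixed at five; a variable segment count is a known
limitation, not implemented because the five-segment layout is the one
with published starting values.

## Synthetic cohorts

The generator emulates, from a single seed, the structure the toolkit is
designed to cope with. Defaults state a 20-patients-per-class cohort
with 10 replicate spectra per patient and 990 bins — the design of the
plasma study this package abstracts. Each measurement is

base × class-effect × patient-peak-noise × dominant-instability ×
loading × batch + truncated baseline noise,

with: a log-normal base profile (median ≈ e³ ≈ 20 counts, σ_log = 1,
heavy right tail); a 2-fold class effect on 50 signal bins (defaults);
per-patient per-peak log-normal noise at CV 0.2 (drawn once per patient,
so replicates stay correlated and patient-level hold-out is meaningful);
5 dominant unstable peaks at 10× the largest stable peak with σ_log = 1
run-to-run instability (the scenario in which a dominant peak distorts
AUC normalisation); a log-normal loading factor with σ = 0.5; additive
Gaussian baseline noise (sd 1.0 ≈ 5% of the median base peak) truncated
at zero. Log-normal noise models reflect that intensity errors in this
kind of data are asymmetric. Where no published value existed
(signal-bin count, peak CV, dominant-peak magnitudes, baseline scale)
the defaults were chosen once as plausible for plasma ASAP spectra and
are not tuned.

What the generator does *not* emulate: real metabolite identities or
isotope patterns, m/z-dependent noise, calibration drift, correlated
peak groups from shared compounds, and non-self-averaging concentration
changes beyond the simple fold-change effect. A green test on synthetic
cohorts therefore establishes that the algorithms behave as specified
under the stated variation structure, not that any particular method is
best for real plasma data.

A fixed two-spectrum fixture illustrates the dominant-peak problem
directly: 19 stable peaks with identical intensities in both spectra
plus one peak at 10× the largest stable peak in spectrum 1 only. AUC
normalisation suppresses the stable peaks of spectrum 1 relative to
spectrum 2, while median normalisation keeps them within 10% — the
fixture is constructed, so these assertions are directional, not
numeric-exact.

## Numerical conventions

* Sample (n−1) standard deviations throughout (column stats, cluster
  sizes, κ spread).
* Linear-interpolation percentiles (`numpy.percentile` default).
* CSV round trips use 17-significant-digit output and round-trip float
  parsing, so write→read reproduces values bit-exactly.
* Randomness is confined to the generator, partition drawing, the GA and
  classifier internals, all seeded; grid evaluation and fitness are
  deterministic.
* Seeds derived from user seeds stay below 2³¹.
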