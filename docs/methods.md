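# Methods

## Pipeline

A labelled single-channel EEG record (µV) is cut into fixed-length epochs
(default 2 s, 50 % overlap; epochs never straddle a segment boundary and
inherit their segment's state label), screened by a ±500 µV amplitude
guardrail, and mapped to a feature matrix of 20 named characteristics.
Classification into the four anesthesia states (awake, light, deep,
isoelectric) uses Gaussian class-conditional densities; feature-subset
search uses a generational GA with an exhaustive oracle for verification.

Epoch length is a compromise: 2 s at 128 Hz gives 256 samples — enough for
stable ApEn/LZ estimates and 1 Hz Welch resolution — while remaining short
against state-transition time scales. The sampling default of 128 Hz
places Nyquist safely above the 47 Hz analysis ceiling used by all
spectral features (high-pass 0.5 Hz).

## Characteristics

* **Welch PSD**: 1 s Hann segments, 50 % overlap, constant detrend;
  Parseval-consistent within 5 %.
* **SEF95 / MF**: smallest grid frequency whose cumulative power reaches
  95 % / 50 % of the 0.5–47 Hz total; ties resolve to the first bin
  reaching the threshold. Undefined (NaN sentinel) for zero-power epochs.
* **Band powers**: delta 0.5–4, theta 4–8, alpha 8–12, beta 12–30 Hz
  (textbook edges; the era's monitors do not publish theirs). Ratio
  features divide by total 0.5–47 Hz power.
* **Beta ratio**: log₁₀(P[30–47]/P[11–20]), the BIS-literature form.
* **Burst suppression**: a sample is suppressed when |x| ≤ 5 µV throughout
  a run of ≥ 0.5 s (both config keys); BS% is the flagged-sample
  percentage per epoch. Optional 15-epoch smoothing is available but off
  by default — monitors average over ~1 min, which would blur the epoch
  labels used here.
* **Bispectrum**: direct FFT estimator, mean over Hann-windowed 0.25 s
  segments of X(f1)X(f2)X*(f1+f2) on the principal domain
  f1 ≥ f2 ≥ 0, f1+f2 ≤ 47 Hz. SynchFastSlow sums |B| over bifrequency
  points with f1+f2 in 0.5–47 Hz versus 40–47 Hz and takes log₁₀.
  Magnitude (not real-part) summation is used; with the estimator
  unpublished for the commercial index, this is the documented convention
  adopted here. The coarse 4 Hz grid trades bifrequency resolution for 15
  averaged segments inside a single 2 s epoch.
* **Histogram entropies** (Shannon, Rényi −1 and 3): 64 equal-width bins
  spanning a fixed ±200 µV dynamic range (configurable). Binning against
  the instrument range rather than the epoch min–max is deliberate: it
  makes these entropies sensitive to amplitude structure (a 60 µV delta
  trace occupies many more bins than a 2 µV isoelectric one), which is
  what renders them informative about depth. Zero-count bins are excluded
  before exponentiation — for order −1 the summand p⁻¹ diverges on empty
  bins — and probabilities are floored at 1e−12.
* **Spectral entropy**: normalized Shannon entropy of the PSD over
  0.5–47 Hz, in [0, 1].
* **SVD entropy**: delay embedding with dimension 10, lag 1; Shannon
  entropy of normalized singular values over log 10.
* **ApEn**: Pincus convention, m = 2, r = 0.2 × epoch SD, self-matches
  included; a vectorized O(n²) implementation verified against a literal
  double-loop oracle to 1e−10.
* **Lempel–Ziv**: binarize at the median, LZ76 exhaustive-history phrase
  count c(n), normalized by n / log₂ n.
* **Wavelet characteristic**: Shannon entropy of relative energies across
  a 4-level db4 decomposition (5 sub-bands).

## Classifier

Quadratic discriminant (per-class mean and full covariance on z-scored
features, ridge 1e−3 against within-class-constant features such as BS%
in awake epochs). A generative Gaussian rule is the minimal family in the
discriminant-analysis lineage of the commercial indices; it is pluggable
behind the `fit/predict` surface. Evaluation is stratified 5-fold
cross-validation with fold-internal z-scoring (no leakage); held-out
predictions pool into one confusion matrix from which per-class
sensitivity TP/(TP+FN), specificity TN/(TN+FP) and total accuracy derive.
Posterior ties break toward the shallower state via the fixed class order.

## Genetic algorithm

Chromosomes are sorted k-index subsets (k fixed in 2–5 — the vector
dimension is a design constraint, not a search variable). Defaults:
population 40, 60 generations, tournament size 3, crossover 0.8 (uniform
draw from the parent union, refilled if short), per-gene mutation 0.1
(swap for an unused index), elitism 2. Fitness is the cross-validated
error, cached per subset within a run; elitism makes the per-generation
best monotone non-increasing. Ties break lexicographically on sorted
indices everywhere, making runs reproducible under a seed. On pools ≤ 12
features with k ≤ 3 the GA provably (by test, over 10 seeds) returns the
exhaustive-enumeration optimum; `rank_vectors` ranks the subsets the GA
evaluated rather than re-enumerating, since full enumeration at pool 20,
k = 5 would cost ~15k cross-validated fits.

## Synthetic reference data

The generator emulates the four reference classes with transparent
ingredients:

* **Spectral shaping**: per-class mixtures of band-pass-filtered white
  noise (Butterworth order 4, zero-phase), one filter per band — delta,
  theta, alpha, beta, plus a fast 30–47 Hz band that carries the
  beta/gamma and frontalis-EMG energy characteristic of awake frontal
  recordings. Gains weight band power; the sum is scaled to the class RMS.
* **Defaults**: AWAKE 10 µV RMS, beta/gamma-dominant; LIGHT 20 µV,
  alpha/theta; DEEP 60 µV, delta with 5 % burst suppression; ISOELECTRIC
  2 µV nominal, fully suppressed slow residual at the 0.5 µV noise floor.
  Chosen to realize the classical qualitative picture — amplitude grows
  and spectral content slows with depth, complexity falls monotonically —
  with clear margins between adjacent states.
* **Burst suppression**: exponential cycle lengths (clipped to 1–8 s) with
  the leading `suppression_fraction` share of each cycle suppressed; the
  realized fraction therefore tracks the requested one even on 60 s
  records, and single suppression episodes are bounded by the cycle
  length. During suppression the shaped signal is attenuated to the noise
  floor — residual low-amplitude cortical activity, not silence.
* **Recording chain**: a small white instrument-noise term (1 % of the
  noise floor) and rounding to the ADC resolution (0.01 µV default, a
  modern 24-bit amplifier; EDF output additionally quantizes to 16 bits
  over the record range).

What the generator does *not* model: drug pharmacokinetics, state
transitions within a segment, eye-blink/EMG artifacts beyond the
stationary gamma band, electrode impedance drift, mains interference, or
inter-patient variability. Passing tests therefore establish that the
implementation computes each characteristic correctly and that the
pipeline separates *well-specified* spectral/dynamical state prototypes —
not that the same accuracies would be obtained on clinical recordings,
where class overlap is substantially larger.

## Default study and problem sizes

The study replica runs 60 s per class at 128 Hz (236 two-second epochs at
50 % overlap), seed 0, stratified 5-fold CV — small enough that the full
suite (including the 10-seed GA-versus-oracle comparison) completes in
about a minute on one core, while 59 epochs per class keep the 5-fold
per-class test counts near 12. A 15-minute-per-class session
(`duration_s_per_class=900`) runs through the same code path.

On this default study the entropy quadruple {AE, L-Z V, RE(3), SE} and the
triple {AE, ShE, BS%} reach 100 % cross-validated accuracy (the values the
acceptance script recomputes), entropy vectors dominate the CSI-style and
BIS-style presets, and median ApEn/spectral entropy fall strictly and BS%
rises strictly with depth. Across other generator seeds the two saturating
vectors stay within half an epoch-percent of saturation (≥ 99.5 %,
occasionally one ambiguous deep epoch).

## Degenerate inputs and numerical conventions

Zero-power epochs yield NaN sentinels for spectral quantile, ratio and
spectral-entropy features; sentinel rows are excluded (and logged) before
fitting or prediction. Constant epochs give zero Shannon/Rényi/ApEn by
convention. Segments are half-open [start, end); sample indexing is
0-based; all amplitudes are µV and all rates Hz.
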