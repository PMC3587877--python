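# anesdepth

Quantitative-EEG analysis of the depth of anesthesia: feature extraction,
four-state classification, and genetic-algorithm feature-subset selection.

## The problem

During general anesthesia the EEG shifts from low-amplitude, fast,
irregular activity (awake) through alpha/theta-weighted rhythms (light
anesthesia) to high-amplitude slow delta waves with burst suppression
(deep anesthesia), and ultimately to a near-flat isoelectric trace.
Commercial monitors condense this into a single index — BIS combines the
burst-suppression ratio, a spectral beta ratio and the bispectral
SynchFastSlow; CSI feeds band ratios and BSR into an ANFIS system — but no
single characteristic tracks all four depth states well. This package asks
the combinatorial question instead: of 19 classical quantitative EEG
characteristics, *which small vector (2–5 features) classifies the four
anesthesia states best?*

The toolkit provides:

* **Characteristics** (per 2 s epoch, single frontal channel):
  spectral edge frequency SEF95 (smallest f with
  ∫₀ᶠ P(ν)dν ≥ 0.95 ∫ P(ν)dν over 0.5–47 Hz), median frequency,
  absolute and relative delta/theta/alpha/beta band powers,
  the BIS beta ratio log₁₀(P₃₀₋₄₇/P₁₁₋₂₀), bispectral SynchFastSlow
  log₁₀(Σ|B| ₀.₅₋₄₇ / Σ|B| ₄₀₋₄₇), burst-suppression percentage, and seven
  entropy/complexity measures — Shannon, spectral, Rényi (orders −1, 3),
  SVD entropy, approximate entropy ApEn(m=2, r=0.2·SD), Lempel–Ziv (LZ76)
  complexity — plus a wavelet-energy entropy (db4 × 4 levels).
* **Classifier**: Gaussian class-conditional (quadratic discriminant) on
  z-scored features, evaluated by stratified 5-fold cross-validation with
  per-class sensitivity/specificity and total accuracy.
* **GA selection**: a generational genetic algorithm over fixed-dimension
  feature subsets (tournament selection, uniform subset crossover with
  repair, index-swap mutation, elitism), with an exhaustive-enumeration
  oracle for small pools.
* **Synthetic reference data**: a generator emulating the four reference
  classes (band-pass-filtered noise mixtures, multiplicative
  burst-suppression envelopes, ADC quantization), so the entire pipeline
  is testable without patient recordings. Real EDF/CSV recordings travel
  through the identical path.

## Worked example

Simulate a 60 s-per-class study, extract features, and classify with the
four-dimensional entropy vector:

```sh
$ anesdepth simulate --duration-per-class 60 --seed 0 --out demo
wrote demo.csv and demo_labels.csv (240 s)
$ anesdepth extract --signal demo.csv --labels demo_labels.csv --out demo_features.csv
wrote 236 epochs x 20 features to demo_features.csv
$ anesdepth classify --features demo_features.csv --subset "AE,L-Z V,RE(3),SE" --seed 0
total accuracy: 100.00%
  AWAKE        sensitivity 1.000  specificity 1.000
  LIGHT        sensitivity 1.000  specificity 1.000
  DEEP         sensitivity 1.000  specificity 1.000
  ISOELECTRIC  sensitivity 1.000  specificity 1.000
```

The entropy quadruple {ApEn, Lempel–Ziv, Rényi(3), spectral entropy}
separates all four states perfectly: cross-validated accuracy is 100 %,
and every state is recognized with sensitivity and specificity 1. The full
study replica compares the named composite vectors in one shot:

```sh
$ anesdepth study --duration-per-class 60 --seed 0 --skip-ga --out report.json
vector                        dim  accuracy(%)
CSI_QUAD                        4      100.00
BIS_TRIPLE                      3       96.61
ENTROPY_QUAD                    4      100.00
ENTROPY_PENT                    5      100.00
BEST_TRIPLE                     3      100.00
AE_SHE_BS                       3      100.00
```

On the synthetic study the entropy-based vectors saturate while the
BIS-style triple {BS%, BetaRatioBIS, BSFSR} trails — the bispectral and
beta-ratio features overlap between the intermediate states. Drop
`--skip-ga` to add the GA-selected best vector per dimension k ∈ {2..5};
`anesdepth select --k 3 --pool entropy` searches a specific pool.

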