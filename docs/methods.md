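# Methods

`lipidfinger` implements a whole-cell MALDI-TOF lipid fingerprinting
analysis: profile spectra of intact cells are preprocessed into a
TIC-normalized feature matrix, recalibrated internally on phospholipid lock
masses, tested for group-dependent intensity differences under FDR control,
and the differential features are identified by accurate-mass adduct
matching, rule-based MS/MS fragment evidence, and ion-mobility collisional
cross sections. A synthetic-spectrum generator with known ground truth
provides the validation substrate.

## Preprocessing chain

Each spectrum passes through a fixed chain, in this order:

1. **Resampling** onto a uniform grid (default step 0.01 Th) by linear
   interpolation. All downstream window operators assume a uniform grid.
2. **Savitzky–Golay smoothing**, polynomial order 2, window 0.1 m/z
   (11 points at the default step), 1 cycle. Order 2 is the conventional
   choice that preserves peak apex height for locally quadratic peak tops.
3. **TopHat baseline subtraction**: morphological opening (erosion then
   dilation) with a flat structuring element spanning 10% of the m/z range,
   rounded to an odd size; boundary handling replicates the edge value. The
   residual is clipped at zero.
4. **TIC normalization** to unit total ion current. Zero-TIC (null) spectra
   are dropped before normalization.

Peak picking operates on the total average spectrum of all retained
(normalized) spectra. Noise is estimated per 20-Th window as
1.4826 × median absolute deviation, with the per-window **median kept as the
local background floor**: after a morphological opening the residual still
carries the DC offset of the noise, and an apex/noise ratio alone would
classify essentially every noise extremum as a peak. SNR is therefore
defined as (apex − floor)/noise, thresholded at 3. Apexes are refined by
3-point parabolic interpolation and peaks closer than m/(2·R), R = 10,000,
are merged keeping the higher apex.

Feature values are per-sample window maxima around each picked peak
(half-window m/R, i.e. the m/(2·R) cluster half-width times a width
multiplier of 2); apex-intensity fingerprinting rather than peak areas,
configurable. Sample-level QC drops zero-TIC columns and columns whose
Pearson correlation to their group-average fingerprint falls below 0.5, and
reports per-group mean ± sd pairwise correlations between replicates.

## Mass recalibration

TOF spectra are recalibrated internally on four positive-mode phospholipid
lock masses — LysoPC(16:0) [M+H]⁺ 496.3398 and PC(34:1) [M+H]⁺ 760.5851,
[M+Na]⁺ 782.5670, [M+K]⁺ 798.5410 (full-precision theoretical values from
the annotation module) — by least squares on the quadratic correction
m′ = c0 + c1·m + c2·m². Four locks over three parameters leave one degree
of freedom as a residual sanity check; the fit is performed in the m/z
domain (the TOF time domain is not accessible downstream of vendor export).
The lock-match window defaults to 200 ppm for TOF peak lists (the
pre-calibration error scale) and 5 ppm for the ultra-high-resolution
single-point scale correction c1 = m_ref/m_obs. For any drift inside the
quadratic family up to ~100 ppm, post-fit lock residuals are below 0.5 ppm.
Calibrated objects carry a provenance flag; re-applying a calibration warns.

## Differential analysis

Technical replicates are collapsed to their biological-replicate means, so
n equals the number of biological replicates (6 in the emulated design).
Testing uses Welch's unequal-variance t statistic with Satterthwaite degrees
of freedom on **log2-transformed intensities**: feature intensities are
multiplicative (group effects act as fold changes and replicate noise is
lognormal), so the log transform stabilizes variance and roughly doubles
sensitivity at n = 6 relative to testing raw intensities. Fold changes are
reported as log2 of the ratio of raw group means with a floor of half the
smallest positive feature value against zero means. Benjamini–Hochberg
step-up adjustment controls the FDR; a feature is called significant when
adjusted p ≤ 0.01 and |log2FC| ≥ 0.3 (the volcano thresholds). Overlap of
significant sets across treatment conditions is reported as exact Venn
region counts with the shared fraction |∩|/|∪| as a percentage rounded
half-even to one decimal. Three-group modulation comparisons use one-way
ANOVA with Tukey's HSD post hoc test (studentized-range distribution) at
α = 0.05.

## Lipid annotation

Monoisotopic masses use IUPAC element masses (C 12 exactly, H 1.00782503,
N 14.00307400, O 15.99491462, P 30.97376163, Na 22.98976928, K 38.96370649)
and adduct deltas that include the electron mass (proton 1.00727646;
Na⁺ +22.98922070; K⁺ +38.96315791; [M+H−H₂O]⁺ −17.00328822) — required to
reproduce literature theoretical m/z at the fourth decimal. The bundled
reference table carries the 21 assigned microglia inflammation markers
(LysoPC, PC, SM, Cer/HexCer, DG, TG species with their formulas, published
theoretical/observed m/z, ppm errors, 1/K₀ and CCS values) plus the PC(34:1)
calibrant adducts; a user CSV with the same columns extends it. One
published row, [LPC 18:0 + K]⁺ at 562.3278, disagrees with its own formula
arithmetic (C26H54NO7P + K − e⁻ = 562.3269, 1.5 ppm) while the +H and +Na
rows of the same neutral agree exactly; the bundled table keeps the printed
value in the `mz_printed` column and the computed value everywhere m/z
arithmetic is used. Matching reports every candidate within tolerance ranked
by |ppm| (1 ppm for ultra-high-resolution identification, 50 ppm for
TOF-stage matching); coinciding formulas under distinct names are all
reported, since positional isomers are not distinguishable at this level.

## MS/MS fragment rules

Positive-mode diagnostic fragments for choline- and sphingoid-containing
classes, from exact-mass arithmetic shared with the annotation module:

- **PC / LysoPC** — neutral loss of trimethylamine (59.0735) and of choline
  phosphate (183.0660); the protonated phosphocholine headgroup at 184.0733
  for protonated precursors, or the cyclophosphane–alkali ion (146.9818 with
  Na, 162.9557 with K) for alkali adducts. Confirmation requires the NL-59
  evidence and one headgroup-type evidence (headgroup ion, NL-183 product,
  or the adduct-specific cyclophosphane ion).
- **SM** — requires 184.0733; water loss, NL-59/183 and the d18:1 base ion
  are corroborating.
- **Cer** — requires the water-loss ion [M+H−18]⁺; sphingoid d18:1 base
  ions at 264.2686 and 282.2791 are corroborating.
- **DG / TG / HexCer** — no MS/MS rules (identified at the MS1 level);
  prediction returns an empty list.

Acyl-chain-informative fragments (losses of each fatty acid as free acid
and as ketene, from the precursor and from the NL-183 product) are predicted
for chain-resolved names only and are never required for confirmation. The
match tolerance is absolute (0.05 Th high-resolution, 0.3 Th TOF), which
also absorbs literature values printed at lower precision.

## Ion mobility

Reduced inverse mobilities (1/K₀, V·s/cm²) convert to CCS (Å²) through the
Mason–Schamp relation with reduced mass μ = m·M/(m+M) against N₂
(28.0134 Da) and the Loschmidt number N₀ = 2.6867811 × 10²⁵ m⁻³. The
effective drift-gas temperature is not part of vendor output; a
one-parameter least-squares fit of T against the bundled 21 (m/z, 1/K₀, CCS)
triples lands at 305 K (closed form, since CCS ∝ T^(−1/2)), which is the
package default; all 21 bundled CCS values are then reproduced within 0.1%.
The linear TIMS calibration maps raw instrument mobility readings to 1/K₀
through reference ions of the standard ESI tuning mix (m/z 118.0862 /
322.0481 / 622.0289 / 922.0097 with CCS 120.8 / 152.8 / 201.6 / 241.8 Å²),
inverting Mason–Schamp for the reference 1/K₀ values. Any systematic
vendor-side correction beyond Mason–Schamp would be absorbed into the
fitted temperature.

## Synthetic-data generator

The generator emulates positive-mode whole-cell profile spectra in
m/z 300–1800 at resolving power 10,000 (Gaussian peaks, FWHM = m/R), with:

- **Isotope envelopes** from a binomial C-13/H-2/N-15 convolution truncated
  at 3 peaks on the +1.003355 Da lattice — adequate where fine structure is
  unresolved.
- **Baseline** b(m) = A·exp(−(m−m₀)/τ), defaults A = 2, τ = 300 Th.
- **Noise** half-normal per grid point (σ = 0.05), keeping intensities
  non-negative without clipping artifacts.
- **Mass miscalibration** as a quadratic ppm warp
  m′ = m·(1 + (a₀ + a₁m + a₂m²)·10⁻⁶) applied to peak positions.
- **Replicate structure**: one spectrum per (group, biological, technical)
  replicate — default 6 biological × 4 technical per group. Biological
  replicates share a per-lipid lognormal effect (σ = 0.3 in log2 units),
  technical replicates add smaller jitter (σ = 0.1), chosen so technical
  replicates correlate at r ≈ 0.9–0.96, the repeatability regime of
  automated whole-cell fingerprinting. Per-spectrum TIC factors are
  lognormal with CV = 0.15.
- **Panel**: the bundled marker and calibrant ions plus 60 unannotated
  background lipid ions (deterministic positions ≥ 3.5 Da from any reference
  ion, lognormal abundances, averagine-like lipid compositions for their
  envelopes). Without a background, TIC normalization would couple the
  spiked markers to the normalizer and attenuate their fold changes; with
  it, default runs yield ~300–400 picked features, the size of a real
  positive-mode whole-cell fingerprint. The background is part of the panel
  definition (fixed internal seed), not of the per-experiment randomness.
- **Group effects**: defaults spike |log2FC| = 2 on every other marker ion
  in each non-control group — the strong-marker regime the workflow is
  designed to flag, chosen by power analysis: under the σ = 0.3/0.1 variance
  split and n = 6, a 2× effect is detected by Welch+BH at adjusted p ≤ 0.01
  only ~65–70% of the time, whereas a 4× effect is detected essentially
  always. Calibrant and background ions never receive effects.

Everything is deterministic given the experiment seed.

What the generator does **not** emulate: matrix cluster chemical noise,
detector saturation, peak-shape asymmetry (EMG tails), correlated baseline
structure, and real biological covariance between lipids. Passing tests on
synthetic data therefore demonstrate correctness of the computational chain
under the stated noise model, not performance on any particular instrument.

## Validation simulations and problem sizes

The FDR/power validation simulates 200 independent 500-feature experiments
with 50 spiked features at |log2FC| = 1 and n = 6 vs 6 biological
replicates, with lognormal feature noise of σ(log2) = 0.2 — the
between-biological-replicate variability of technical-quadruplicate-averaged
features on a well-controlled platform, a regime chosen so the sensitivity
bound is informative about implementation correctness (at σ = 0.3 the
design itself lacks power for 2× effects, as noted above). Empirical FDR at
nominal BH 0.01 stays below 0.05 (it is in fact ≈ 0.01) and sensitivity
exceeds 0.8. End-to-end validation uses the full default generator (48
spectra, 150,001-point grids) plus a null run with no effects, asserting
≥ 90% recovery with correct annotation of spiked lipids and ≤ 1% flagged
features under the null.

## Numerical choices and degenerate inputs

- Duplicate m/z values on load are merged by summing (logged); unsorted
  axes are sorted with a warning; negative raw intensities are clipped at 0.
- Zero variance in both Welch groups: t = 0, p = 1 for equal means; p → 0
  with a warning for unequal means.
- Zero-TIC spectra are excluded as null before normalization; all-zero
  noise windows floor at a tiny positive value so SNR stays defined.
- BH adjustment is the exact step-up (p_adj(i) = min_{j≥i} (m/j)p_(j),
  capped at 1), validated against brute-force enumeration.
- Calibration refuses rank-deficient designs and non-monotone corrected
  axes; fewer than 3 lock matches downgrades to no recalibration with a
  warning in the pipeline.
- Display roundings (4-decimal m/z, 1-decimal ppm and CCS) use round-half-even.

## Known limitations

- The quadratic calibration acts in the m/z domain; true TOF miscalibration
  is quadratic in flight time, so very large drifts are only approximately
  representable.
- The ClinProTools-style "resolution 10,000" peak-cluster parameter is
  interpreted as the m/(2·R) bin half-width; vendor semantics are not
  public.
- MS/MS scoring is evidence counting against rule-based predictions, not
  spectral-library matching; it cannot distinguish isobaric candidates that
  share fragment rules.
- Negative-ion mode is routed through the same pipeline with the [M−H]⁻
  adduct only; no negative-mode-specific fragment rules are implemented.
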