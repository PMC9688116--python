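# Methods

This note documents the models, numerical choices and limitations of the
package; it states nothing the test suite does not itself compute.

## Preprocessing

Reflectance is computed per wavelength as
R = (1/ρ_ref) · (I_tissue − I_bg) / (I_ref − I_bg).  The reference
standard's reflectivity ρ_ref defaults to 0.99 (configurable as a scalar
or spectrum); a non-positive (I_ref − I_bg) raises an error naming the
offending wavelengths; negative reflectance values (detector noise below
background) are clipped to 0 with a warning, since downstream scaling
tolerates them but physical reflectance cannot be negative.

The VIS (350–1140 nm) and NIR (1090–1920 nm) arms are merged across the
1090–1140 nm overlap.  The weighted sum with index i = 0..100 is
realized on 101 evenly spaced wavelengths across the overlap — both arms
are linearly interpolated onto those points, combined with weights
(100−i)/100 and i/100, and interpolated onto the output grid.  This
makes the merge exactly continuous at both overlap endpoints and keeps
the blended values pointwise between the two inputs.  The default output
grid is 1 nm from 350 to 1920 nm; native spectrometer pixel grids are
unknown, so a uniform grid is assumed throughout.

## Chromophore library

The bundled absorption curves for Hb, HbO₂, water and lipid are smooth
parametric approximations: Gaussian bands on gently decaying baselines,
with band centers fixed at the canonical peak wavelengths (HbO₂
414/542/576 nm; Hb 433/556/757 nm; the lipid doublet at ~1728/1765 nm
within 1700–1800 nm; the water edge rising toward 1940 nm) and
magnitudes at literature scale: hemoglobin curves are per unit blood
volume fraction (whole blood), water and lipid per unit volume fraction,
all in mm⁻¹.  Only the peak *positions* are treated as contractual
(verified on a 1-nm grid, ±3 nm); absolute magnitudes are plausible but
not calibrated against any extinction compilation, which is out of
scope.  Methemoglobin, bile, β-carotene, bilirubin, ceroid, collagen and
melanin are omitted from the default library — they can be added through
the same `ChromophoreLibrary` interface — and the MetHb column of the
attribution matrix is retained for layout fidelity but is always False
by default.

Tissue optics: μa(λ) is the linear mixture
tHb·[StO₂·εHbO₂ + (1−StO₂)·εHb] + f_w·μa,water + f_l·μa,lipid, and
reduced scattering follows the power law μs′(λ) = a·(λ/λ₀)^(−b) with
λ₀ = 500 nm.

## Synthetic cohort generator

The generator emulates the statistical structure of an ex-vivo
colorectal study, not its radiometry:

- **Design.** 47 patients, 15 mucosa + 15 tumor sites each, per probe
  (630 µm and 2500 µm source–detector separation); each stored spectrum
  is the average of 3 noisy acquisitions.
- **Class means.** Mucosa: blood volume fraction 0.01, StO₂ 0.75, water
  0.65, lipid 0.10, a = 2.0 mm⁻¹, b = 1.2.  Tumor: blood ×2.0, StO₂
  0.60, water 0.70, lipid 0.05, a ×1.2.  These magnitudes are the
  generator's stated scenario — directionally consistent with reported
  tumor biology (hypervascular, hypoxic, edematous, lipid-poor, more
  scattering) — and are not fitted to any dataset.
- **Hierarchy.** Each varying parameter is multiplied by a log-normal
  patient effect (CV 0.2, one draw per patient, shared by both classes
  within the patient — a physiological baseline) and an independent
  log-normal site effect (CV 0.1); fractions are truncated to [0, 1].
  Sharing the patient effect across classes makes the spectrum-wise
  two-sample test conservative under the null, and gives the
  within-patient-SD < 2× pooled-SD property by construction.
- **Noise.** Multiplicative Gaussian (σ 1%) plus additive (σ 10⁻⁴),
  both tripled above 1850 nm to mimic falling detector sensitivity.
- **Forward model.** Farrell-type steady-state diffusion approximation
  of a semi-infinite homogeneous medium evaluated at the probe's
  source–detector separation (refractive index 1.4, Groenhuis boundary
  parameter), scaled by a fixed effective collection area (0.283 mm²,
  i.e. a 600-µm fiber core) and clipped to (0, 1].  A Beer–Lambert-like
  `exp_attenuation` fallback exists for degenerate regimes.  The
  diffusion approximation is knowingly inaccurate where absorption is
  strong (the Soret band): it compresses the 380–450 nm contrast, which
  is acceptable for the generator's purpose but means a green test
  establishes statistical behavior, not radiometric truth.  Layered
  tissue, probe-depth estimation and non-tumor pathology classes are
  not modeled.
- **Determinism.** One seed fans out through a numpy `SeedSequence` to
  patient, site and noise streams; identical specs give bit-identical
  datasets.

## Band selection

Normality gating uses Anderson–Darling (scipy, interpolated p-value)
and Lilliefors (statsmodels) at α_norm = 0.05 per class; a wavelength
is tested with the pooled-variance Student t-test when all four checks
pass, otherwise with the Wilcoxon rank-sum test (exact for samples of
≤ 20 without ties, normal approximation with tie correction otherwise).
Pooled variance (not Welch) is the default to match the protocol being
replicated; Welch is a flag away in scipy if needed.  The per-wavelength
threshold is p < 0.001 with no multiple-testing correction — the
selection rule *is* the per-wavelength threshold (a Bonferroni option
exists, off by default).  Bands are maximal runs of significant grid
points: runs separated by gaps ≤ max_gap points (default 0) are merged,
then runs shorter than min_run points (default 3) are dropped.  Printed
sub-splits of a long significant region are not algorithmically
derivable; user-specified band lists are accepted wherever bands are,
so arbitrary range combinations can be benchmarked.

## PLS-KNN protocol

Per-wavelength scaling maps the observed column range to [−1, +1]
(constant columns map to 0).  PLS is single-response NIPALS
(scikit-learn, `scale=False`) with labels coded mucosa = −1,
tumor = +1; the first weight vector is proportional to the covariance
of centered X with the coded response, scores are mutually orthogonal,
and loadings are exposed per component for interpretation.  The
component count is fixed at 4 by default; an accuracy-increment rule
(stop when the next component adds < 2 percentage points of
cross-validated accuracy) is provided but bypassed by default.

Cross-validation replicates the protocol under study: scaling and PLS
are fitted once on the **full** dataset, then 20 random stratified
equal-half splits are drawn; KNN (k = 10, squared-inverse-distance
weights, Euclidean distance in score space) is trained on each half's
scores and evaluated on the other, fold metrics are averaged per
iteration, and the report is mean ± SD over iterations.  This protocol
deliberately leaks the test fold into the feature extraction — the
package also provides a leakage-free mode (refit per training fold) for
honest generalization estimates.  The permutation null of the default
protocol is slightly above 0.5 AUC at small n and approaches chance at
the default cohort size; this is a property of the replicated protocol,
not a bug.

KNN details: a zero-distance neighbor dominates (posterior = tumor
fraction among zero-distance neighbors); posterior ties at 0.5 break
toward tumor (favoring sensitivity in a screening context).  Stratified
splits are used — plain random equal halves risk degenerate folds.
AUC is computed rank-based from the KNN tumor posterior (equivalent to
the Mann–Whitney statistic with tie correction).

## Loading interpretation

The reference analysis compares loading shapes to chromophore spectra
visually; here that comparison is operationalized, with every threshold
declared and config-exposed:

- **Amplitude profile:** mean |loading| per named region, ranked
  descending (ties break toward the lower wavelength).
- **Chromophore attribution:** within each chromophore's characteristic
  bands (Hb/HbO₂ 380–450, 530–590, 740–780 nm; water 950–1000,
  1150–1250, 1380–1500, 1850–1920 nm; lipid 740–780, 1150–1250,
  1700–1800 nm), the absolute Pearson correlation between loading and
  absorption; marked if max |r| ≥ 0.6 in a band whose mean |loading|
  also exceeds the component's median amplitude over the coarse regions
  350–600 / 600–1350 / 1350–1900 nm.  The gate discards shape matches
  in bands where the component carries negligible weight; computing the
  median over the coarse amplitude regions (rather than over the
  attribution bands themselves) avoids mechanically rejecting half the
  bands when amplitudes are nearly uniform.  In the shared 740–780 nm
  band (Hb peak 757 nm vs lipid 761 nm) a lipid mark is suppressed when
  a hemoglobin correlation there is at least as strong, since Hb
  dominates tissue absorption at those wavelengths.
- **Scattering attribution:** within the 600–1000 nm (VIS) and
  1000–1350 nm (NIR) low-absorption windows, a loading is attributed to
  scattering when its normalized total variation Σ|Δ| / range ≤ 1.5
  (a strictly monotone segment scores exactly 1) and ≥ 80% of its
  first differences share one sign after 5-point smoothing.

All metrics use |r| and |Δ|, so attribution is invariant to the global
sign indeterminacy of PLS components.  Every positive cell in the
attribution matrix carries an evidence record (band, metric value,
threshold).

## Known limitations

- With the default contrast scenario the discriminative absorption
  difference is a deoxy-weighted blood mixture
  (Δμa ∝ 0.45·εHbO₂ + 0.55·εHb); its Q-band shape is single-humped, so
  the first component reliably carries *blood* signatures (one or both
  hemoglobins in every seeded run tested) but the specific pair
  (Hb *and* HbO₂ simultaneously) appears in roughly 14 of 20 seeded
  full-scale runs rather than nearly always.  The corresponding
  acceptance test is intentionally left failing with this analysis
  rather than loosening thresholds post hoc.
- The synthetic generator's class contrast magnitudes are stated, not
  estimated; classification performance on synthetic data says nothing
  quantitative about clinical performance.
- The chromophore curves are shape-faithful approximations; any
  analysis that depends on absolute extinction magnitudes needs a
  calibrated compilation instead.
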