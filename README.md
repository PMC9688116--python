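# drspipe

Analysis pipeline for broadband diffuse reflectance spectroscopy (DRS) of
colorectal tissue: given reflectance spectra of mucosa and tumor sites
measured between 350 and 1920 nm with two fiber probes (source–detector
separations 630 µm and 2500 µm), the package selects the wavelength bands
that discriminate the two tissue classes, classifies sites with a
PLS-KNN model, and attributes the discriminative spectral features to
tissue chromophores (Hb, HbO₂, water, lipid) and scattering.

Because clinical DRS datasets of this kind are rarely deposited, the
package ships a physics-based synthetic generator (diffusion-approximation
forward model with hierarchical patient/site variability and detector
noise) so that every stage of the analysis is testable end to end.

## Method

1. **Preprocessing.** Raw detector counts become reflectance via
   R(λ) = (1/ρ_ref) · (I_tissue − I_bg) / (I_ref − I_bg), and the
   visible (350–1140 nm) and NIR (1090–1920 nm) spectrometer arms are
   blended across their 1090–1140 nm overlap with linear weights
   (100−i)/100 and i/100 on 101 evenly spaced points.
2. **Band selection.** Per wavelength, both class distributions are
   screened with Anderson–Darling and Lilliefors normality tests; a
   pooled-variance two-sample t-test (Wilcoxon rank-sum where normality
   is rejected) is applied, and maximal contiguous runs with p < 0.001
   become the selected bands.
3. **Classification.** Spectra restricted to the bands are rescaled per
   wavelength to [−1, +1], reduced to 4 partial-least-squares components
   (labels coded mucosa = −1, tumor = +1), and classified by weighted
   KNN (10 neighbors, squared-inverse-distance votes) under a 2-fold ×
   20-iteration cross-validation; sensitivity, specificity, accuracy and
   rank-based AUC are reported as mean ± SD over iterations.  Matching
   the protocol it replicates, scaling and PLS are fitted once on the
   full dataset before cross-validation; a `leakage_free=True` mode
   refits them per training fold.
4. **Interpretation.** PLS loadings are ranked by mean absolute
   amplitude per wavelength region and shape-matched (banded absolute
   Pearson correlation, with an amplitude gate) against the chromophore
   absorption library; flat, monotone loadings in the 600–1350 nm
   low-absorption window are attributed to scattering.

## Worked example

```python
import numpy as np
from drspipe import (PopulationSpec, ForwardModelConfig, SHORT_SDD,
                     simulate_dataset, screen_wavelengths, select_bands,
                     cross_validate)

spec = PopulationSpec(seed=1)          # 47 patients x 15 sites x 2 classes
cfg = ForwardModelConfig(grid=np.arange(350.0, 1921.0, 5.0))
ds = simulate_dataset(spec, SHORT_SDD, cfg)

bands = select_bands(screen_wavelengths(ds), alpha=0.001)
print(bands.to_json())
report = cross_validate(ds, bands, n_components=4, k_nn=10,
                        iterations=20, seed=1)
print(f"accuracy ({report.accuracy[0]:.1f} ± {report.accuracy[1]:.1f})%  "
      f"AUC {report.auc[0]:.3f} ± {report.auc[1]:.3f}")
```

Output:

```
[[350.0, 470.0], [480.0, 585.0], [595.0, 1380.0], [1520.0, 1790.0], [1825.0, 1835.0]]
accuracy (97.5 ± 0.3)%  AUC 0.996 ± 0.001
```

The selected bands cover the hemoglobin Soret/Q-band region, the optical
window and the SWIR water/lipid features; the accuracy is the
cross-validated performance of the 4-component PLS-KNN model on those
bands for the planted tumor contrast (total hemoglobin ×2, StO₂
0.75→0.60, water 0.65→0.70, lipid 0.10→0.05, scattering ×1.2).

The same run is available from the shell:

```sh
drspipe simulate --probe short --seed 1 --out spectra.csv
drspipe select-bands --in spectra.csv --out bands.json
drspipe classify --in spectra.csv --bands bands.json --seed 1 --out report.csv
drspipe interpret --in spectra.csv --out attribution.csv
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole pipeline from scratch for both probes at the default
cohort design (simulation → band selection → PLS-KNN cross-validation →
loading attribution), prints per-probe summaries, leaves the full
artifacts under `scratch/acceptance_run/`, and writes the results JSON
to the given path.

## Layout

- `drspipe.spectra` — spectrum containers, reflectance computation, VIS/NIR merging, tabular I/O
- `drspipe.chromophores` — absorption library, μa/μs′ tissue model, attribution bands
- `drspipe.simulate` — synthetic cohort generator and diffusion forward model
- `drspipe.band_selection` — normality gating, per-wavelength tests, band extraction
- `drspipe.pls_knn` — scaling, PLS, weighted KNN, cross-validation protocol, metrics
- `drspipe.interpretation` — loading amplitude profiles and chromophore/scattering attribution
- `drspipe.pipeline`, `drspipe.cli` — orchestrated runs, YAML config, manifest, `drspipe` CLI

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
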