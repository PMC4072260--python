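# fibroquant

Quantifying myocardial fibrosis — the collagen area fraction of heart tissue —
on Masson's-trichrome–stained biopsy images, and measuring how well different
quantification methods agree.

Cardiac fibrosis is excess extracellular collagen in the myocardium; its
extent predicts heart function and survival, so pathology labs need a number,
not an impression. On a trichrome slide collagen stains blue, muscle red, and
the surrounding glass stays near-white, which makes the fibrosis fraction a
planar image-analysis problem. This package implements three independent
estimators of that fraction and the statistical battery for comparing them:

* **Colocalization** — per-pixel color deconvolution. Stains mix additively in
  optical density (Beer–Lambert): `OD_c = -log10(I_c / I0_c)` and
  `OD = amounts · V` for a matrix `V` of unit stain OD vectors, so
  `amounts = OD · V⁻¹` recovers per-stain amounts (Ruifrok–Johnston). Each
  pixel is classified by which stains exceed their thresholds (patterns 1, 2,
  3, 1+2, 1+3, 2+3, 1+2+3, none) and fibrosis is the tissue share of the
  collagen-carrying patterns 3, 2+3, 1+3.
* **Trainable pixel classifier** ("Genie-style" pattern recognition) — a
  supervised per-pixel model trained on user-marked myocardium / fibrosis /
  glass regions using color plus local spatial statistics (9 features: OD
  triple, local means, local SDs); fibrosis % is taken over tissue, ignoring
  glass.
* **Point-grid stereology** — the criterion standard. A systematic lattice of
  test points (default: 200 px sampling interval, 20 px marker) is labeled
  glass / fibrosis / myocardium / other; the area fraction is
  `p = n_fibrosis / n_effective` ignoring glass and other, with Weibel's
  point-counting uncertainty `RSE = sqrt((1-p)/(p·n))`.

Agreement is assessed the way method-comparison studies do it: summary
statistics, Pearson correlations, Friedman's test with Wilcoxon signed-rank
post-hocs under Bonferroni correction, raw and ln-transformed regression, and
Bland–Altman plots with the stereology reference on the X axis and limits of
agreement at mean ± 2 SD.

Because real annotated slides are rarely shareable, the package ships a
synthetic-histology generator: trichrome-like tiles composed through the same
Beer–Lambert forward model from phantoms with exactly known per-pixel labels,
plus simulated pathologist visual scores (noisy, rounded to 5%). Every
estimator can therefore be scored against ground truth.

## Worked example

```python
import fibroquant as fq
from fibroquant.stain_deconvolution import StainMatrix

sm = fq.default_stain_model()
phantom = fq.generate_phantom(256, 256, target_fibrosis_fraction=0.30, seed=7)
tile = fq.render_trichrome(phantom, sm, noise_sd=0.02, seed=1)

res = fq.quantify_tile(tile, StainMatrix(sm.od_vectors), sm.background_intensity)
print(f"truth  {100 * phantom.fibrosis_fraction_of_tissue:.2f}%")
print(f"coloc  {res.fibrosis_pct:.2f}%  over {res.tissue_pixel_count} tissue px")

stereo = fq.stereology.point_count_on_phantom(phantom, sampling_interval=8,
                                              offset="random", seed=5)
print(f"grid   {stereo.pct:.2f}%  (RSE {stereo.uncertainty:.3f}, "
      f"{stereo.n_effective} effective points)")
```

prints

```
truth  30.00%
coloc  30.00%  over 49143 tissue px
grid   31.47%  (RSE 0.054, 753 effective points)
```

The colocalization route recovers the truth to well under a percentage point
(its errors are quantization-limited); the 753-point grid lands within its own
predicted sampling error (RSE 0.054 → ±1.6 pp at 30%).

The full study is the `analysis/` sequence — `01_simulate_cohort.py` (116
synthetic slides spanning 0–90% fibrosis), `02_quantify_fibrosis.py` (all
three routes plus simulated pathologist readings), `03_compare_methods.py`
(the agreement battery and plots), `04_method_calibration.py` (round-trip,
grid-calibration and classifier-recovery experiments) — writing its tables
under `results/`. The same pipeline is available as a CLI:
`fibroquant run --config study.yaml`, or per-route `fibroquant coloc`,
`fibroquant stereology`, `fibroquant genie-train`, `fibroquant genie-classify`,
`fibroquant compare`.

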