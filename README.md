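# synct — synthetic contrast-enhanced CT generation and validation

Cardiac substructures (chambers and coronary arteries) are nearly
invisible on the non-contrast planning CT (NCT) used for breast
radiotherapy, yet their absorbed dose drives the risk of
radiation-induced heart disease. `synct` implements a conditional-GAN
pipeline that translates NCT toward contrast-enhanced appearance
(SCECT), so that substructures can be delineated without injecting a
contrast agent, together with the three-stage validation used to judge
whether a synthetic volume is good enough:

1. **Image quality** — slice-wise MAE, PSNR and SSIM between SCECT and
   real CECT, compared against the NCT baseline with a two-sample
   t-test.
2. **Contour geometry** — Dice similarity coefficient
   `DSC = 2|X∩Y| / (|X|+|Y|)` and symmetric mean surface distance
   `MSD = (Σ_p d(p,S') + Σ_p' d(p',S)) / (n_S + n_S')` between
   structure sets, with a 5 mm expansion of the LAD and RCA vessels on
   both sides before comparison.
3. **Dosimetry** — cumulative DVHs and the clinical dose-volume metrics
   (D_max, D_mean, V5–V40 Gy) per substructure under a transferred
   tangential-field dose, reported as absolute differences.

The model is the pix2pix objective

```
G* = arg min_G max_D  E[log D(x,y)] + E[log(1 − D(G(x)))] + λ ‖y − G(x)‖₁ ,   λ = 100
```

with a 2-D fully convolutional DenseNet generator (five transition-down
and five transition-up stages with dense blocks and skip
concatenations; 5.4 M parameters) and a PatchGAN discriminator judging
two-channel (NCT, candidate) pairs through four strided
down-transitions (1.6 M parameters). Preprocessing windows intensities
to the [−150, 500] HU contrast range, resamples to 0.9 × 0.9 × 1.0 mm,
crops a 384 × 384 × 150 box near the heart and feeds randomly cropped
352 × 352 axial slices during training. The networks run on a compact
NumPy reverse-mode autodiff engine (`synct.nn`) with Adam/SGD
optimizers, so the whole pipeline is a pure scientific-Python stack.

Because paired clinical data cannot ship with the package, a
procedural phantom generator (`synct.phantom`) builds co-registered
NCT/CECT chest phantoms with a four-chamber heart, surface LAD/RCA
vessels, ground-truth masks, known blood-pool enhancement and a
tangential-wedge dose field — every downstream stage is exercised
end-to-end against known truth.

## Worked example

Run the full workflow (simulate 8 phantoms, train a small model for 30
epochs on CPU, infer on the held-out test phantoms, evaluate all three
stages — about 90 seconds):

```bash
synct run-all --out run/ --seed 0
```

or in Python:

```python
from synct.pipeline import run_all, default_demo_config
manifest, results = run_all(default_demo_config(), out_dir="run")
print(results["cohort"].summary.round(3))
```

which prints (stage 1, per-slice means ± SD over the test phantoms):

```
               mae_mean  mae_sd  psnr_mean  psnr_sd  ssim_mean  ssim_sd
arm
nct_vs_cect      18.231   8.716     24.667    6.104      0.578    0.181
scect_vs_cect     8.387   1.359     32.267    1.990      0.897    0.037
```

The synthetic volumes sit much closer to the real contrast volumes
than the input does: less than half the MAE, ~7.6 dB more PSNR and a
substantially higher SSIM (all three differences significant at
p ≪ 0.05). Stage 2 (`results["contour_summary"]`) shows the
size-dependence familiar from inter-observer studies — large chambers
near DSC 0.95, the thin coronary vessels much lower — and stage 3
(`results["dose_table"]`) reports sub-Gray mean-dose differences with
non-significant t-tests, i.e. contours drawn on the synthetic volume
would support the same dosimetric conclusions.

Clinical DICOM data can be substituted for phantoms through
`synct.ct_io` (CT series, RTSTRUCT, RTDOSE, NIfTI).

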