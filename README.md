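# dmistroke

Diffusion microstructure imaging (DMI) for acute ischemic stroke, as a
reusable Python pipeline.

Conventional stroke DWI compresses the diffusion signal into a single
apparent diffusion coefficient (ADC), and the infarct core is convention-
ally delineated at ADC < 0.620 µm²/ms. DMI instead fits the three-
compartment *standard model* of white matter — an intra-axonal stick, an
extra-axonal zeppelin and a free-water ball with fixed D_csf = 3 µm²/ms —
yielding six parameter maps: the volume fractions V_intra, V_extra, V_CSF
(summing to 1) and the diffusivities D_ax_intra, D_ax_extra, D_rad_extra.
In acute ischemia the intra-axonal axial diffusivity D_ax_intra drops
sharply (axonal beading) while V_intra rises, making D_ax_intra a more
discriminative infarct-core contrast than ADC, with an operating threshold
near 2 µm²/ms.

The package is aimed at diffusion-MRI methods researchers who want to
reproduce or extend this analysis chain without patient data: a digital
stroke phantom stands in for the clinical cohort.

## Method

For a fiber population along **n**, gradient direction **g** and b-value
*b* (ms/µm²), the normalized signal is

```
S(b, g) = V_intra · exp(−b·D_ax_intra·(g·n)²)
        + V_extra · exp(−b·D_rad_extra − b·(D_ax_extra − D_rad_extra)·(g·n)²)
        + V_CSF   · exp(−3b)
```

subject to `D_ax_intra > D_ax_extra + 2·D_rad_extra` (degeneracy
constraint). Rather than fitting this per voxel, each voxel is reduced to
three rotation-invariant order-≤2 spherical-harmonic features
(spherical means of the two radial bins, plus the order-2 power `p2 =
sqrt(Σ c_2m²)` of the outer bin), and a supervised Bayesian estimator —
an order-3 polynomial regressor trained on signals simulated from a broad
biophysical prior with Rician noise — maps features to the posterior-mean
parameters. ROC analysis (AUC, Youden's J = sens + spec − 1, optimal
threshold) evaluates threshold segmentation of the lesion against four
ground-truth variants (two raters, their union, their intersection), and
descriptive statistics compare the lesion with its mirrored contralateral
region.

## Worked example

```python
import dmistroke as dm

scheme = dm.preset_scheme("two_shell")          # b = 1.0/2.0 ms/µm², 30 dirs each
config = dm.PhantomConfig(seed=11)              # 48³ stroke phantom, SNR 30
volume, phantom = dm.make_phantom_volume(config)

est = dm.train_estimator(scheme, dm.PriorConfig(seed=5))
maps = dm.predict_maps(est, volume, phantom.brain_mask)
adc, _ = dm.compute_adc(volume, phantom.brain_mask)

roc = dm.pooled_roc([maps.d_ax_intra], [phantom.lesion_mask], [phantom.brain_mask])
print(f"D_ax_intra: AUC={roc.auc:.3f} Jmax={roc.j_max:.3f} "
      f"threshold={roc.optimal_threshold:.2f} µm²/ms")
roca = dm.pooled_roc([adc], [phantom.lesion_mask], [phantom.brain_mask])
print(f"ADC:        AUC={roca.auc:.3f} threshold={roca.optimal_threshold:.3f} µm²/ms")
```

prints

```
D_ax_intra: AUC=0.993 Jmax=0.908 threshold=2.26 µm²/ms
ADC:        AUC=1.000 threshold=0.630 µm²/ms
```

i.e. on the phantom both contrasts separate the lesion from the rest of
the brain; the Youden-optimal D_ax_intra threshold falls between the
configured lesion (1.4) and healthy white-matter (2.4) diffusivities, and
the ADC threshold lands at the conventional ≈0.62 µm²/ms infarct-core
boundary.

The same pipeline is scriptable from the shell:

```
dmistroke phantom --seed 11 --out-dir data/
dmistroke train --scheme two_shell --seed 5 --out est.json
dmistroke fit --dwi data/dwi.nii.gz --bval data/dwi.bval --bvec data/dwi.bvec \
              --mask data/brain_mask.nii.gz --estimator est.json --out-dir maps/
dmistroke evaluate --dax-map maps/d_ax_intra.nii.gz --adc-map maps/adc.nii.gz \
                   --brain-mask data/brain_mask.nii.gz \
                   --dwi-truth data/lesion_truth.nii.gz \
                   --dmi-truth data/lesion_truth.nii.gz --out roc.csv
```

## Layout

- `dmistroke.io` — NIfTI / FSL bval-bvec I/O, acquisition-scheme presets
- `dmistroke.model` — standard-model signal generation, Watson dispersion
- `dmistroke.features` — rotation-invariant SH features
- `dmistroke.estimator` — prior sampling, training, prediction, oracle
- `dmistroke.adc` — ADC and mean high-b DWI maps
- `dmistroke.lesion` — thresholding, pooled ROC, mirroring, statistics
- `dmistroke.phantom` — the digital stroke phantom and Rician noise
- `dmistroke.cli` — the `dmistroke` command

See `docs/methods.md` for modelling assumptions, parameter conventions and
known limitations.
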