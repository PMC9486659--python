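# Methods

## The signal model

Each voxel is a convex mixture of three non-exchanging compartments:

* **intra-axonal stick** — 1-D diffusion along the fiber axis with axial
  diffusivity `d_ax_intra`;
* **extra-axonal zeppelin** — axially symmetric tensor with axial
  diffusivity `d_ax_extra` and radial diffusivity `d_rad_extra`;
* **free-fluid ball** — isotropic diffusion fixed at `D_csf = 3 µm²/ms`
  (body-temperature free water), absorbing CSF and perivascular space.

Assumptions: negligible inter-compartment exchange (myelinated white
matter; weaker in gray matter), no diffusion-time dependence, no
compartmental T1/T2 weighting. Internal units put b in ms/µm² and D in
µm²/ms so that b·D is dimensionless; conversion from s/mm² happens only at
gradient-table I/O, and b ≤ 50 s/mm² counts as b = 0 (vendor rounding).

For single pulsed-field-gradient data the model is degenerate unless
`d_ax_intra > d_ax_extra + 2·d_rad_extra`; this inequality defines the
admissible prior region and is linear in the parameters (which is why the
phantom's partial-volume mixing cannot violate it).

## Mesostructure and the orientation average

Macroscopic fiber architecture is a nuisance. It is modelled as a Watson
distribution (concentration κ; 0 = uniform, ∞ = parallel), the simplest
axially symmetric family with a dispersion knob — any spanning family
would do, since the features are built to be insensitive to it. The
orientation average is computed on a fixed deterministic Lebedev sphere
grid, default precision order 47 (770 points): the relative error of the
Watson average stays below 1e-4 across the trained dispersion range
(κ ≤ 64), which a 194-point grid does not achieve (≈4e-2 at κ = 64).
Watson weights are renormalized on the grid itself, making the l = 0
moment exact by construction. Above κ = 1e4 a delta-ODF branch evaluates
the single-fiber kernel directly; the true Watson-vs-delta deviation there
is O(|S''|/κ) ≲ 1e-4. The grid order is configurable and covered by an
accuracy test against a much denser grid.

## Invariant features

Signals are normalized per voxel by the arithmetic mean of all interleaved
b = 0 frames. Weightings with 0 < b ≤ 1.0 ms/µm² form the inner radial
bin and b > 1.0 the outer bin — exactly the two shells of the two-shell
protocol, and a half-radius² split of the hexagonal q-ball scheme (whose
original continuous radial basis is not reproduced here; the two-bin
projection is a documented stand-in that yields the same three order-≤2
invariants). Features per voxel:

| feature | definition | default range |
|---|---|---|
| `f0_inner` | spherical mean (c00/√4π of the order-≤2 LS fit) on the inner bin | (0, 1] |
| `f0_outer` | same on the outer bin | (0, 1] |
| `p2` | √(Σ_m c_2m²) of the outer-bin fit | ≥ 0 |

The real orthonormal SH basis at orders {0, 2} is used; p2 uses only the
outer bin, where anisotropy encoding is strongest. Under a *joint rotation
of the gradient table* (fixed signal values) the LS design transforms by
an orthogonal block-Wigner matrix, so c00 and ‖c2‖ — hence all three
features — are invariant to machine precision; this is the patient-
rotation invariance that matters for the estimator. Rotating the *tissue*
against a fixed 30-direction set leaves a small residual through order-≥4
aliasing of the equal-weight LS fit (≈1–2 % of f0 at bD ≈ 5, measured);
this is a property of any such acquisition, enters the training set as
extra feature noise, and is marginalized by the regressor.

## Prior, training and the estimator

Training samples are drawn i.i.d. from:

| quantity | law | default |
|---|---|---|
| (V_intra, V_extra, V_CSF) | flat Dirichlet(1,1,1) on the simplex | — |
| d_ax_intra, d_ax_extra | uniform | [0, 3] µm²/ms |
| d_rad_extra | uniform | [0, 1.5] µm²/ms |
| constraint | rejection on d_ai > d_ae + 2·d_re | accepts 1/6 of draws |
| κ (Watson) | log-uniform | [0.5, 64] |
| fiber direction | uniform on the sphere | — |
| SNR at b = 0 | uniform | [15, 60] |

`n_samples` defaults to 20 000 (≥ 10× the 20 polynomial terms, and enough
that training noise is far below the posterior spread). Rician noise
(`sqrt((S+n₁)² + n₂²)`, σ = 1/SNR on the normalized signal) is applied to
all frames including the b = 0s, and the features are computed by the
identical code path used at inference. The regressor is the full cubic
expansion of the three standardized features (20 terms including
intercept) fitted to all six parameters by ridge-regularized normal
equations (ridge 1e-6 on standardized terms, conditioning safeguard only,
intercept unpenalized). The fit is written in plain numpy so the trained
estimator serializes to a versioned JSON containing the coefficients,
standardization constants and the scheme fingerprint; prediction refuses a
volume whose gradient table hashes differently.

Predicted fractions are clipped to [0, 1] and renormalized to sum to 1;
diffusivities are clipped to [0, 3]. With three features against five free
parameters the inverse problem is under-determined: maps inherit
prior-induced correlations, and the correctness criterion is agreement
with the Bayesian posterior mean, not unbiased truth recovery. The
reference is an importance-sampling posterior mean over noiseless
prior-predictive features with per-feature Gaussian noise scales estimated
empirically at the working SNR; when regressor and oracle are compared,
both are evaluated under the same fixed-SNR condition (SNR 30) so they
estimate the same posterior. On 100 held-out SNR-30 voxels the mean
absolute disagreement is ≈0.02 on fractions and ≈0.07 µm²/ms on
diffusivities (recomputed by `scripts/acceptance.py` and asserted by the
test suite at 0.05 / 0.15 bounds).

## ADC and mean DWI

ADC = −(1/b)·ln(mean over b = 1.0 directions / mean over b = 0 frames),
directional mean before the log (trace-weighted convention; the
alternative per-direction average differs at second order for the phantom
tests). The mean DWI image averages all frames with b above a caller-
chosen floor (conventionally ≈1.8 ms/µm²).

## ROC and lesion statistics

Lesion-positive means score **below** threshold (ischemia lowers both
contrasts). The pooled ROC sweeps all unique observed values plus ±∞ —
the exact empirical curve, avoiding any discretization choice — and AUC by
trapezoid then equals the Mann–Whitney concordance probability with
half-credit for ties (asserted exactly against a brute-force pairwise
count). Youden ties break toward the lower threshold (the more specific
segmentation). Four ground-truth variants mirror the cross-validation
design of rater-based studies: two rater masks, their union and their
intersection; for the phantom, "raters" are emulated by one-voxel erosion
and dilation of the true lesion. Contralateral sampling reflects the
lesion across the mid-sagittal grid plane (the phantom grid is
midline-aligned by construction, so no registration is needed) and clips
CSF via the brain/CSF mask. Percentiles use linear interpolation (NumPy's
default convention).

## The phantom

A sphere (radius 21 voxels on a 48³ grid, centered on the x mid-plane so
x-flips are exact) with a 2-voxel CSF rim, a central ventricle, a 3-voxel
gray-matter ribbon and a white-matter core; fiber directions follow a
smooth azimuthal field. A spherical lesion (radius 6, offset 9.5 voxels
into one hemisphere) carries the acute-ischemia contrast pattern:

| tissue | V_intra/V_extra/V_CSF | d_ax_intra/d_ax_extra/d_rad_extra | κ |
|---|---|---|---|
| CSF | 0 / 0 / 1 | (free water) | — |
| GM | 0.35 / 0.50 / 0.15 | 2.0 / 1.2 / 0.30 | 2 |
| WM | 0.45 / 0.45 / 0.10 | 2.4 / 1.6 / 0.35 | 16 |
| lesion | 0.65 / 0.30 / 0.05 | 1.4 / 0.8 / 0.20 | 16 |

These are modelling conventions, not measured patient values: every
diffusivity drops in the lesion with d_ax_intra dropping most, V_intra
rises while V_extra and V_CSF fall, and the healthy/lesion d_ax_intra
midpoint sits near the ≈2 µm²/ms operating threshold reported for this
contrast; the implied mean diffusivities put lesion ADC ≈ 0.57 and healthy
WM ≈ 1.0 µm²/ms, bracketing the 0.620 clinical guide value. A one-voxel
partial-volume layer linearly mixes adjacent tissues so ROC analyses face
non-separable boundary voxels. Rician noise at SNR 30 (b = 0 scale) is
seed-controlled and independent of the (deterministic) ground truth.

What the phantom does *not* emulate: real anatomy and registration error,
leukoencephalopathy and artifact confounds, spatially varying coil noise,
partial Fourier/Gibbs effects, or rater behavior beyond morphological
perturbation. Passing the end-to-end tests therefore demonstrates
pipeline correctness and internal consistency — not clinical performance
on patients.

## Problem sizes and numerical choices

Default working sizes — 48³ phantom (~39 000 brain voxels), 20 000
training samples, 50 000–100 000 oracle reference samples, 100 held-out
test voxels — keep a full pipeline run in the minutes range on one CPU
while leaving Monte-Carlo error well below the asserted tolerances.
Degenerate inputs are handled explicitly: voxels with non-positive b = 0
mean are flagged invalid and excluded from masks; an SH fit with fewer
than six directions (or a degenerate direction set, condition > 1e8)
raises a conditioning error; an all-underflowing oracle weight vector
widens its noise scale with a warning; empty ROC classes raise.

## Known limitations

* The hexagonal scheme's two-bin radial projection is a self-consistent
  convention, not the original continuous radial basis.
* Feature aliasing from 30-direction shells bounds the achievable
  tissue-rotation insensitivity at the percent level (acquisition
  property, marginalized in training).
* The oracle's Gaussian feature-noise model ignores the small Rician bias
  of p2 at low SNR; at SNR ≥ 15 this is well below the comparison bounds.
* No spatial regularization, no T2-compartment weighting, no exchange —
  gray-matter parameter interpretation is correspondingly loose.
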