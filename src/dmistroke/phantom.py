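"""Digital stroke phantom — the stand-in for unavailable patient data.

A spherical "brain" on a midline-aligned grid carries concentric tissue
classes (CSF rim, a central ventricle, a gray-matter ribbon, a white-matter
core) with literature-plausible microstructure, plus a spherical ischemic
lesion inserted into the white matter of one hemisphere.  The lesion
parameter contrast follows the qualitative pattern seen in acute stroke:
diffusivities reduced in every compartment with the intra-axonal axial
diffusivity dropping most (2.4 → 1.4 µm²/ms, so that a decision boundary
near 2 µm²/ms separates the classes), V-intra increased (axonal swelling /
beading), V-extra and V-CSF decreased.  These defaults are modelling
conventions chosen to respect that pattern, not measured patient values.

A one-voxel partial-volume layer linearly mixes the parameters of adjacent
tissues, so threshold/ROC analyses face non-separable boundary voxels, and
magnitude (Rician) noise is added at a configurable b=0 SNR.  All
randomness is seed-controlled; ground-truth masks never depend on the
noise seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .exceptions import ConfigError
from .io import (AcquisitionScheme, DwiVolume, ParameterMaps, VoxelMask,
                 preset_scheme, write_dwi, write_mask)
from .model import DEFAULT_GRID_ORDER, MicrostructureParams, TissueField, simulate_volume

#: Tissue labels in the label map.
LABELS = {"background": 0, "csf": 1, "gm": 2, "wm": 3, "lesion": 4}

#: Default per-tissue microstructure (conventions; diffusivities in µm²/ms).
DEFAULT_TISSUES = {
    "csf": MicrostructureParams(0.0, 0.0, 1.0, 2.0, 1.0, 0.4),
    "gm": MicrostructureParams(0.35, 0.50, 0.15, 2.0, 1.2, 0.30),
    "wm": MicrostructureParams(0.45, 0.45, 0.10, 2.4, 1.6, 0.35),
    "lesion": MicrostructureParams(0.65, 0.30, 0.05, 1.4, 0.8, 0.20),
}

#: Watson concentration per tissue (CSF value is irrelevant: v_csf = 1).
DEFAULT_KAPPA = {"csf": 1.0, "gm": 2.0, "wm": 16.0, "lesion": 16.0}


@dataclass
class PhantomConfig:
    """Geometry, tissue parameters, lesion placement, noise and scheme choice.

    The grid is midline-aligned: the brain center sits on the x mid-plane
    ((W−1)/2), so an exact x-flip maps each hemisphere onto the other.
    Radii are in voxels.
    """

    seed: int
    shape: tuple = (48, 48, 48)
    scheme_name: str = "two_shell"
    snr: float = 30.0
    s0: float = 1000.0
    brain_radius: float = 21.0
    csf_rim_thickness: float = 2.0
    gm_thickness: float = 3.0
    ventricle_radius: float = 2.5
    lesion_offset_x: float = 9.5
    lesion_radius: float = 6.0
    tissues: dict = field(default_factory=lambda: dict(DEFAULT_TISSUES))
    kappa: dict = field(default_factory=lambda: dict(DEFAULT_KAPPA))
    partial_volume: bool = True
    grid_order: int = DEFAULT_GRID_ORDER
    voxel_size: tuple = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("a seed is mandatory")
        if self.snr <= 0:
            raise ConfigError("snr must be positive (use np.inf for noiseless)")
        if self.brain_radius > min((s - 1) / 2.0 for s in self.shape):
            raise ConfigError("brain sphere does not fit inside the grid")
        if self.lesion_offset_x + self.lesion_radius >= self.brain_radius - \
                self.csf_rim_thickness - self.gm_thickness:
            raise ConfigError("lesion must lie inside the white-matter core")
        if self.lesion_offset_x - self.lesion_radius <= self.ventricle_radius:
            raise ConfigError("lesion must not touch the ventricle")
        for name, p in self.tissues.items():
            if not isinstance(p, MicrostructureParams):
                raise ConfigError(f"tissue {name!r} is not a MicrostructureParams")
            if name != "csf" and not p.is_admissible():
                raise ConfigError(
                    f"tissue {name!r} violates d_ax_intra > d_ax_extra + 2·d_rad_extra"
                )

    def replace(self, **kw) -> "PhantomConfig":
        return replace(self, **kw)


@dataclass
class Phantom:
    """Ground truth: parameter fields, tissue labels and the truth masks."""

    field: TissueField
    labels: np.ndarray
    lesion_mask: VoxelMask
    brain_mask: VoxelMask
    csf_mask: VoxelMask
    config: PhantomConfig

    def truth_maps(self) -> ParameterMaps:
        f = self.field
        return ParameterMaps(v_intra=f.v_intra, v_extra=f.v_extra, v_csf=f.v_csf,
                             d_ax_intra=f.d_ax_intra, d_ax_extra=f.d_ax_extra,
                             d_rad_extra=f.d_rad_extra, mask=self.brain_mask.data,
                             voxel_size=self.config.voxel_size)


def _radius_grid(shape):
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    ii = np.indices(shape).astype(float)
    d = ii - center.reshape(3, 1, 1, 1)
    return np.sqrt((d ** 2).sum(axis=0)), ii, center


def generate_phantom(config: PhantomConfig) -> Phantom:
    """Build the deterministic ground-truth phantom (no noise involved)."""
    shape = tuple(config.shape)
    r, ii, center = _radius_grid(shape)

    labels = np.zeros(shape, dtype=np.int8)
    brain = r <= config.brain_radius
    r_gm_out = config.brain_radius - config.csf_rim_thickness
    r_wm_out = r_gm_out - config.gm_thickness
    labels[brain] = LABELS["csf"]
    labels[r <= r_gm_out] = LABELS["gm"]
    labels[r <= r_wm_out] = LABELS["wm"]
    labels[r <= config.ventricle_radius] = LABELS["csf"]

    lesion_center = center + np.array([config.lesion_offset_x, 0.0, 0.0])
    d = ii - lesion_center.reshape(3, 1, 1, 1)
    lesion = np.sqrt((d ** 2).sum(axis=0)) <= config.lesion_radius
    labels[lesion] = LABELS["lesion"]

    fields = {nm: np.zeros(shape) for nm in
              ("v_intra", "v_extra", "v_csf", "d_ax_intra", "d_ax_extra",
               "d_rad_extra", "kappa")}
    for tissue, lab in LABELS.items():
        if tissue == "background":
            continue
        sel = labels == lab
        p = config.tissues[tissue]
        for nm in ("v_intra", "v_extra", "v_csf", "d_ax_intra", "d_ax_extra",
                   "d_rad_extra"):
            fields[nm][sel] = getattr(p, nm)
        fields["kappa"][sel] = config.kappa[tissue]

    if config.partial_volume:
        _mix_boundaries(fields, labels, brain)

    # smooth, deterministic fiber-direction field: azimuthal circulation
    # around the z axis with a constant through-plane component
    dx = ii[0] - center[0]
    dy = ii[1] - center[1]
    direction = np.stack([-dy, dx, 6.0 * np.ones(shape)], axis=-1)
    nrm = np.linalg.norm(direction, axis=-1, keepdims=True)
    direction = direction / np.where(nrm > 0, nrm, 1.0)

    tissue_field = TissueField(direction=direction, **fields)
    csf = brain & (fields["v_csf"] > 0.5)
    return Phantom(field=tissue_field, labels=labels,
                   lesion_mask=VoxelMask(lesion), brain_mask=VoxelMask(brain),
                   csf_mask=VoxelMask(csf), config=config)


def _mix_boundaries(fields: dict, labels: np.ndarray, brain: np.ndarray) -> None:
    """Linearly mix parameters in the one-voxel layer around tissue interfaces.

    The degeneracy constraint is a linear inequality in the parameters, so
    convex mixtures of admissible tissues stay admissible, and the fraction
    simplex is preserved because all three fractions share the same weights.
    """
    lab_max = ndimage.maximum_filter(labels, size=3)
    lab_min = ndimage.minimum_filter(np.where(brain, labels, np.int8(127)), size=3)
    boundary = brain & (lab_max != lab_min)
    w = ndimage.uniform_filter(brain.astype(float), size=3)
    for nm, arr in fields.items():
        sm = ndimage.uniform_filter(arr * brain, size=3)
        arr[boundary] = sm[boundary] / w[boundary]


def add_rician_noise(volume: DwiVolume, snr: float, seed: int) -> DwiVolume:
    """Magnitude noise: S' = sqrt((S + n₁)² + n₂²), n ~ N(0, s0/snr).

    SNR is defined at the b=0 intensity scale (taken as the volume's maximal
    mean b=0 signal).  ``snr = inf`` returns the volume unchanged.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    if not np.isfinite(snr):
        return DwiVolume(data=volume.data.copy(), scheme=volume.scheme,
                         voxel_size=volume.voxel_size, affine=volume.affine)
    b0 = volume.data[..., volume.scheme.b0_mask].mean(axis=-1)
    sigma = float(b0.max()) / snr
    rng = np.random.default_rng(seed)
    n1 = rng.standard_normal(volume.data.shape)
    n2 = rng.standard_normal(volume.data.shape)
    noisy = np.sqrt((volume.data + sigma * n1) ** 2 + (sigma * n2) ** 2)
    return DwiVolume(data=noisy, scheme=volume.scheme,
                     voxel_size=volume.voxel_size, affine=volume.affine)


def make_phantom_volume(config: PhantomConfig,
                        scheme: AcquisitionScheme | None = None
                        ) -> tuple[DwiVolume, Phantom]:
    """Phantom ground truth plus its noisy DWI volume in one call."""
    phantom = generate_phantom(config)
    scheme = scheme or preset_scheme(config.scheme_name)
    clean = simulate_volume(phantom.field, scheme, s0=config.s0,
                            mask=phantom.brain_mask.data,
                            grid_order=config.grid_order,
                            voxel_size=config.voxel_size)
    noisy = add_rician_noise(clean, config.snr, seed=config.seed)
    return noisy, phantom


def make_fixture(config: PhantomConfig, out_dir) -> dict:
    """Write a complete end-to-end input set (NIfTI + bval/bvec + truths).

    Emits ``dwi.nii.gz``, ``dwi.bval``, ``dwi.bvec``, ``brain_mask.nii.gz``,
    ``lesion_truth.nii.gz``, ``labels.nii.gz`` and a ``config.json`` echo;
    returns the path mapping.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    volume, phantom = make_phantom_volume(config)
    paths = {
        "dwi": out_dir / "dwi.nii.gz",
        "bval": out_dir / "dwi.bval",
        "bvec": out_dir / "dwi.bvec",
        "brain_mask": out_dir / "brain_mask.nii.gz",
        "lesion_truth": out_dir / "lesion_truth.nii.gz",
        "labels": out_dir / "labels.nii.gz",
        "config": out_dir / "config.json",
    }
    write_dwi(volume, paths["dwi"], paths["bval"], paths["bvec"])
    aff = volume.get_affine()
    write_mask(phantom.brain_mask, paths["brain_mask"], affine=aff)
    write_mask(phantom.lesion_mask, paths["lesion_truth"], affine=aff)
    import nibabel as nib
    nib.save(nib.Nifti1Image(phantom.labels.astype(np.uint8), aff),
             str(paths["labels"]))
    echo = {
        "seed": config.seed, "shape": list(config.shape),
        "scheme_name": config.scheme_name, "snr": config.snr, "s0": config.s0,
        "brain_radius": config.brain_radius,
        "lesion_offset_x": config.lesion_offset_x,
        "lesion_radius": config.lesion_radius,
        "tissues": {k: v.as_array().tolist() for k, v in config.tissues.items()},
        "kappa": config.kappa,
    }
    paths["config"].write_text(json.dumps(echo, indent=1, sort_keys=True))
    return paths
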