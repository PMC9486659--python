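"""Conventional single-shell diffusion maps: ADC and mean high-b DWI.

The apparent diffusion coefficient is the single-exponential decay rate
between the unweighted signal and the b = 1000 s/mm² shell,

    ADC = −(1/b) · ln( mean_dirs(S_b) / mean(S_b0) )   [µm²/ms],

with the directional arithmetic mean taken *before* the logarithm
(trace-weighted convention).  The clinical infarct-core guide threshold for
this map is ADC < 0.620 µm²/ms.
"""

from __future__ import annotations

import numpy as np

from .exceptions import SchemeError
from .io import B0_THRESHOLD, DwiVolume, VoxelMask


def compute_adc(volume: DwiVolume, mask: VoxelMask, b_shell: float = 1.0,
                b_tol: float = 0.1) -> tuple[np.ndarray, VoxelMask]:
    """ADC map (µm²/ms) from the b=0 frames and the shell at ``b_shell``.

    Returns ``(adc, valid_mask)``; voxels with a non-positive signal ratio
    are excluded from the valid mask (NaN in the map).  Raises
    :class:`SchemeError` when the scheme lacks b=0 frames or the shell.
    """
    if volume.spatial_shape != mask.data.shape:
        raise ValueError("mask shape does not match volume shape")
    bvals = volume.scheme.bvals
    b0_idx = np.flatnonzero(bvals <= B0_THRESHOLD)
    sh_idx = np.flatnonzero(np.abs(bvals - b_shell) <= b_tol)
    if b0_idx.size == 0:
        raise SchemeError("scheme has no b=0 frame")
    if sh_idx.size == 0:
        raise SchemeError(f"scheme has no shell at b = {b_shell} ms/µm²")
    b_eff = float(bvals[sh_idx].mean())

    adc = np.full(volume.spatial_shape, np.nan)
    valid = np.zeros(volume.spatial_shape, dtype=bool)
    m = mask.data
    s0 = volume.data[m][:, b0_idx].mean(axis=1)
    sb = volume.data[m][:, sh_idx].mean(axis=1)
    ok = (s0 > 0) & (sb > 0)
    vals = np.full(len(s0), np.nan)
    vals[ok] = -np.log(sb[ok] / s0[ok]) / b_eff
    adc[m] = vals
    valid[m] = ok
    return adc, VoxelMask(valid)


def mean_dwi(volume: DwiVolume, b_min: float) -> np.ndarray:
    """Arithmetic mean image over all weightings with b ≥ ``b_min`` (ms/µm²)."""
    idx = np.flatnonzero(volume.scheme.bvals >= b_min)
    if idx.size == 0:
        raise ValueError(f"no weighting with b ≥ {b_min} ms/µm²")
    return volume.data[..., idx].mean(axis=-1)
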