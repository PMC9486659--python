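"""Rotation-invariant signal features (spherical-harmonic order ≤ 2).

The estimator never sees raw signals.  Each voxel is reduced to three
numbers that are invariant under joint rotation of the gradient set and
carry only microstructural information:

* ``f0_inner`` — normalized spherical-mean signal on the inner radial bin,
* ``f0_outer`` — normalized spherical-mean signal on the outer radial bin,
* ``p2``       — the rotation-invariant order-2 power ``sqrt(Σ_m c_2m²)``
  of the real-SH fit on the outer bin.

Radial bins: weightings with 0 < b ≤ 1.0 ms/µm² are "inner" and b > 1.0
"outer", so for the two-shell protocol the bins are exactly the b = 1 and
b = 2 shells, and the hexagonal q-ball scheme splits at half its maximal
radius².  Signals are normalized per voxel by the arithmetic mean of all
interleaved b=0 frames.

Invariance under a joint rotation of the gradient directions is exact by
construction: the order-≤2 least-squares design transforms by an orthogonal
(block Wigner) matrix, which leaves ``c_00`` and ``‖c_2‖`` unchanged.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ConditioningError, SchemeError
from .io import AcquisitionScheme, DwiVolume, VoxelMask

#: b-value (ms/µm²) splitting the inner and outer radial bins.
RADIAL_SPLIT_B = 1.0

#: Number of real SH coefficients at orders {0, 2}.
N_SH_COEFF = 6

_SQRT_4PI = float(np.sqrt(4.0 * np.pi))


def real_sh_order2(directions: np.ndarray) -> np.ndarray:
    """Real orthonormal spherical harmonics at orders {0, 2}.

    Coefficient order: (0,0), (2,−2), (2,−1), (2,0), (2,1), (2,2).  With this
    normalization ``∫ Y_i Y_j dΩ = δ_ij`` and the spherical mean of a function
    equals ``c_00 / sqrt(4π)``.
    """
    d = np.asarray(directions, dtype=float)
    x, y, z = d[..., 0], d[..., 1], d[..., 2]
    c15 = 0.5 * np.sqrt(15.0 / np.pi)
    return np.stack([
        np.full_like(x, 0.5 / np.sqrt(np.pi)),
        c15 * x * y,
        c15 * y * z,
        0.25 * np.sqrt(5.0 / np.pi) * (3.0 * z * z - 1.0),
        c15 * x * z,
        0.5 * c15 * (x * x - y * y),
    ], axis=-1)


def fit_sh(signals: np.ndarray, directions: np.ndarray,
           max_order: int = 2) -> np.ndarray:
    """Least-squares real-SH coefficients (orders {0, 2}) of directional data.

    ``signals`` may be (..., N) for batched voxels over N directions.
    Raises :class:`ConditioningError` for < 6 directions or a numerically
    degenerate direction set.
    """
    if max_order != 2:
        raise ValueError("only max_order=2 is supported")
    directions = np.asarray(directions, dtype=float)
    signals = np.asarray(signals, dtype=float)
    if directions.shape[0] < N_SH_COEFF:
        raise ConditioningError(
            f"need ≥ {N_SH_COEFF} directions for an order-2 fit, "
            f"got {directions.shape[0]}"
        )
    basis = real_sh_order2(directions)
    if np.linalg.cond(basis) > 1e8:
        raise ConditioningError("direction set is degenerate for an order-2 fit")
    coeffs, *_ = np.linalg.lstsq(basis, signals.reshape(-1, signals.shape[-1]).T,
                                 rcond=None)
    return coeffs.T.reshape(signals.shape[:-1] + (N_SH_COEFF,))


def spherical_mean_from_sh(coeffs: np.ndarray) -> np.ndarray:
    """Spherical mean implied by an SH coefficient set: c_00/sqrt(4π)."""
    return np.asarray(coeffs)[..., 0] / _SQRT_4PI


def radial_bins(scheme: AcquisitionScheme) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frame indices of (b0, inner-bin, outer-bin) weightings.

    Raises :class:`SchemeError` if the scheme has no b=0 frame or either bin
    is too small for an order-2 SH fit.
    """
    from .io import B0_THRESHOLD
    bvals = scheme.bvals
    b0 = np.flatnonzero(bvals <= B0_THRESHOLD)
    inner = np.flatnonzero((bvals > B0_THRESHOLD) & (bvals <= RADIAL_SPLIT_B))
    outer = np.flatnonzero(bvals > RADIAL_SPLIT_B)
    if b0.size == 0:
        raise SchemeError("scheme has no b=0 frame; cannot normalize signals")
    if inner.size < N_SH_COEFF or outer.size < N_SH_COEFF:
        raise SchemeError(
            "scheme needs ≥ 6 directions in each radial bin "
            f"(inner: {inner.size}, outer: {outer.size})"
        )
    return b0, inner, outer


def signal_features(signals: np.ndarray,
                    scheme: AcquisitionScheme) -> tuple[np.ndarray, np.ndarray]:
    """Feature vectors (f0_inner, f0_outer, p2) for (..., n_frames) signals.

    Returns ``(features (..., 3), valid (...))``; voxels whose mean b=0
    signal is non-positive are flagged invalid (their features are NaN).
    """
    signals = np.asarray(signals, dtype=float)
    if signals.shape[-1] != len(scheme):
        raise SchemeError(
            f"signal vector length {signals.shape[-1]} does not match "
            f"scheme length {len(scheme)}"
        )
    b0_idx, inner_idx, outer_idx = radial_bins(scheme)
    s0 = signals[..., b0_idx].mean(axis=-1)
    valid = s0 > 0
    s0_safe = np.where(valid, s0, 1.0)
    norm = signals / s0_safe[..., None]

    c_inner = fit_sh(norm[..., inner_idx], scheme.bvecs[inner_idx])
    c_outer = fit_sh(norm[..., outer_idx], scheme.bvecs[outer_idx])
    f0_inner = spherical_mean_from_sh(c_inner)
    f0_outer = spherical_mean_from_sh(c_outer)
    p2 = np.linalg.norm(c_outer[..., 1:], axis=-1)
    feats = np.stack([f0_inner, f0_outer, p2], axis=-1)
    feats = np.where(valid[..., None], feats, np.nan)
    return feats, valid


def compute_features(volume: DwiVolume,
                     mask: VoxelMask) -> tuple[np.ndarray, VoxelMask]:
    """Per-voxel feature field for the masked voxels of a DWI volume.

    Returns ``(features (X, Y, Z, 3), valid_mask)``: NaN outside the valid
    mask, which excludes input-mask voxels with non-positive b=0 signal.
    """
    if volume.spatial_shape != mask.data.shape:
        raise ValueError("mask shape does not match volume shape")
    feats = np.full(volume.spatial_shape + (3,), np.nan)
    valid = np.zeros(volume.spatial_shape, dtype=bool)
    voxels = volume.data[mask.data]
    if voxels.size:
        f, ok = signal_features(voxels, volume.scheme)
        feats[mask.data] = f
        valid[mask.data] = ok
    return feats, VoxelMask(valid)
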