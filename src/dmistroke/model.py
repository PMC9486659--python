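"""Three-compartment "standard model" signal generation.

The voxel signal is a convex combination of three non-exchanging
compartments (Fig.-1-style picture of white matter):

* an intra-axonal *stick* — water diffuses along the axon only, with axial
  diffusivity ``d_ax_intra``;
* an extra-axonal *zeppelin* — an axially symmetric tensor with axial
  diffusivity ``d_ax_extra`` and a slight radial component ``d_rad_extra``;
* a free-fluid *ball* — isotropic diffusion at the fixed CSF diffusivity
  of 3 µm²/ms.

For a fiber population along unit vector ``n`` probed with gradient
direction ``g`` at b-value ``b`` (ms/µm²), the normalized signal is::

    S = v_intra · exp(−b·d_ax_intra·(g·n)²)
      + v_extra · exp(−b·d_rad_extra − b·(d_ax_extra − d_rad_extra)·(g·n)²)
      + v_csf   · exp(−b·d_csf)

Macroscopic fiber configurations (the mesostructure the invariant features
must not depend on) are modelled by numerically averaging the single-fiber
kernel over a Watson orientation distribution on a fixed Lebedev sphere
grid.  Diffusion-time dependence and inter-compartment exchange are
deliberately absent — low-permeability compartments and long diffusion
times are the model's standing assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.integrate import lebedev_rule

from .exceptions import ConfigError
from .io import AcquisitionScheme, DwiVolume

#: Fixed free-fluid (CSF) diffusivity, µm²/ms.
D_CSF = 3.0

#: Watson concentrations at or above this are treated as a single fiber
#: (delta ODF).  The true Watson average deviates from the delta limit by
#: O(|S''|/kappa) ≲ 1e-4 here, below the quadrature resolution.
KAPPA_DELTA_LIMIT = 1.0e4

#: Default Lebedev precision order (770 grid points): relative quadrature
#: error of the Watson average stays below 1e-4 for kappa ≤ 64.
DEFAULT_GRID_ORDER = 47


@dataclass
class MicrostructureParams:
    """One voxel's six model parameters.

    Fractions are unitless and sum to 1; diffusivities are in µm²/ms and
    bounded by the free-water value 3.  A parameter set is *prior-admissible*
    when additionally ``d_ax_intra > d_ax_extra + 2·d_rad_extra`` — the
    degeneracy-breaking constraint of the standard model for single
    pulsed-field-gradient data.
    """

    v_intra: float
    v_extra: float
    v_csf: float
    d_ax_intra: float
    d_ax_extra: float
    d_rad_extra: float

    def __post_init__(self) -> None:
        fr = (self.v_intra, self.v_extra, self.v_csf)
        if min(fr) < -1e-9:
            raise ValueError("volume fractions must be non-negative")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"volume fractions must sum to 1, got {sum(fr)}")
        for nm in ("d_ax_intra", "d_ax_extra", "d_rad_extra"):
            d = getattr(self, nm)
            if not 0.0 <= d <= D_CSF:
                raise ValueError(f"{nm}={d} outside [0, {D_CSF}] µm²/ms")

    @property
    def d_csf(self) -> float:
        return D_CSF

    def is_admissible(self) -> bool:
        return self.d_ax_intra > self.d_ax_extra + 2.0 * self.d_rad_extra

    def as_array(self) -> np.ndarray:
        return np.array([self.v_intra, self.v_extra, self.v_csf,
                         self.d_ax_intra, self.d_ax_extra, self.d_rad_extra])

    def replace(self, **kw) -> "MicrostructureParams":
        return replace(self, **kw)


@dataclass
class FiberGeometry:
    """Mesostructure nuisance: Watson-distributed fiber orientations.

    ``dispersion_kappa`` is the Watson concentration (0 = uniform ODF,
    ∞ = perfectly parallel fibers).
    """

    mean_direction: np.ndarray
    dispersion_kappa: float

    def __post_init__(self) -> None:
        mu = np.asarray(self.mean_direction, dtype=float)
        if mu.shape != (3,) or abs(np.linalg.norm(mu) - 1.0) > 1e-6:
            raise ValueError("mean_direction must be a 3D unit vector")
        self.mean_direction = mu
        if self.dispersion_kappa < 0:
            raise ValueError("dispersion_kappa must be ≥ 0")


@lru_cache(maxsize=8)
def sphere_grid(order: int = DEFAULT_GRID_ORDER) -> tuple[np.ndarray, np.ndarray]:
    """Fixed deterministic Lebedev grid: (points (Q, 3), weights summing to 4π)."""
    pts, w = lebedev_rule(order)
    return pts.T.copy(), w.copy()


def _check_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if np.any(np.abs(np.linalg.norm(v, axis=-1) - 1.0) > 1e-6):
        raise ValueError(f"{name} must be a unit vector")
    return v


def single_fiber_signal(params: MicrostructureParams, b, g, n) -> np.ndarray:
    """Normalized signal of a single coherent fiber population.

    ``b`` may be scalar or an array broadcasting against the dot products of
    gradient direction(s) ``g`` with the fiber direction ``n``.  At b=0 the
    signal is exactly 1 (the model is normalized to the unweighted frame).
    """
    scalar = np.isscalar(b) and np.asarray(g).ndim == 1
    b = np.asarray(b, dtype=float)
    g = _check_unit(g, "gradient direction g")
    n = _check_unit(n, "fiber direction n")
    t2 = np.sum(g * n, axis=-1) ** 2
    s = (params.v_intra * np.exp(-b * params.d_ax_intra * t2)
         + params.v_extra * np.exp(-b * params.d_rad_extra
                                   - b * (params.d_ax_extra - params.d_rad_extra) * t2)
         + params.v_csf * np.exp(-b * D_CSF))
    return float(s) if scalar else s


def _watson_weights(kappa, mu, grid_points, grid_weights) -> np.ndarray:
    """Discrete Watson ODF on the grid, normalized to sum to 1.

    Normalizing on the same grid that evaluates the orientation average makes
    the l=0 moment exact by construction.
    """
    t2 = (grid_points @ np.asarray(mu)) ** 2
    w = grid_weights * np.exp(kappa * (t2 - 1.0))
    return w / w.sum()


def dispersed_signal(params: MicrostructureParams, geometry: FiberGeometry,
                     b, g, grid_order: int = DEFAULT_GRID_ORDER) -> np.ndarray:
    """Orientation average of the single-fiber kernel over the Watson ODF.

    Reduces to :func:`single_fiber_signal` as kappa → ∞ (a delta-ODF branch
    engages above :data:`KAPPA_DELTA_LIMIT`) and to the spherical-mean signal
    at kappa = 0.
    """
    if geometry.dispersion_kappa >= KAPPA_DELTA_LIMIT:
        return single_fiber_signal(params, b, g, geometry.mean_direction)
    pts, lw = sphere_grid(grid_order)
    w = _watson_weights(geometry.dispersion_kappa, geometry.mean_direction, pts, lw)
    b = np.atleast_1d(np.asarray(b, dtype=float))
    g = np.atleast_2d(_check_unit(g, "gradient direction g"))
    t2 = (pts @ g.T) ** 2                                   # (Q, G)
    s = (params.v_intra * (w @ np.exp(-b * params.d_ax_intra * t2))
         + params.v_extra * (w @ np.exp(-b * params.d_rad_extra
                                        - b * (params.d_ax_extra
                                               - params.d_rad_extra) * t2))
         + params.v_csf * np.exp(-b * D_CSF))
    return s if s.size > 1 else float(s[0])


# ---------------------------------------------------------------------------
# batched evaluation (training sets, phantom synthesis)
# ---------------------------------------------------------------------------

def batch_dispersed_signals(theta: np.ndarray, kappa: np.ndarray, mu: np.ndarray,
                            scheme: AcquisitionScheme,
                            grid_order: int = DEFAULT_GRID_ORDER,
                            chunk: int = 512) -> np.ndarray:
    """Dispersed signals for many parameter sets against one scheme.

    Parameters
    ----------
    theta : (M, 6) array
        Columns in :data:`dmistroke.io.PARAMETER_NAMES` order.
    kappa, mu : (M,), (M, 3)
        Watson concentration and mean direction per sample.
    Returns
    -------
    (M, len(scheme)) normalized signals; b=0 frames are exactly 1.
    """
    theta = np.asarray(theta, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    mu = np.asarray(mu, dtype=float)
    m = len(theta)
    if kappa.shape != (m,) or mu.shape != (m, 3):
        raise ValueError("theta, kappa and mu lengths disagree")
    pts, lw = sphere_grid(grid_order)
    dw = scheme.dw_mask
    b = scheme.bvals[dw][None, None, :]                     # (1, 1, G)
    cos2 = ((pts @ scheme.bvecs[dw].T) ** 2)[None, :, :]    # (1, Q, G)
    out = np.ones((m, len(scheme)), dtype=float)

    delta = kappa >= KAPPA_DELTA_LIMIT
    for sel, use_delta in ((~delta, False), (delta, True)):
        idx = np.flatnonzero(sel)
        for lo in range(0, len(idx), chunk):
            ii = idx[lo:lo + chunk]
            v_i, v_e, v_c = theta[ii, 0], theta[ii, 1], theta[ii, 2]
            d_ai, d_ae, d_re = theta[ii, 3], theta[ii, 4], theta[ii, 5]
            if use_delta:
                c2 = ((mu[ii] @ scheme.bvecs[dw].T) ** 2)[:, None, :]
                w = np.ones((len(ii), 1))
            else:
                t2 = (pts @ mu[ii].T) ** 2                  # (Q, chunk)
                w = np.exp(kappa[ii] * (t2 - 1.0)) * lw[:, None]
                w = (w / w.sum(axis=0)).T                   # (chunk, Q)
                c2 = cos2
            e_i = np.exp(-d_ai[:, None, None] * (b * c2))
            e_x = np.exp(-d_re[:, None, None] * b
                         - (d_ae - d_re)[:, None, None] * (b * c2))
            s_dw = (v_i[:, None] * np.einsum("cq,cqg->cg", w, e_i, optimize=True)
                    + v_e[:, None] * np.einsum("cq,cqg->cg", w, e_x, optimize=True)
                    + v_c[:, None] * np.exp(-D_CSF * b[0]))
            out[np.ix_(ii, np.flatnonzero(dw))] = s_dw
    return out


@dataclass
class TissueField:
    """Per-voxel microstructure parameters plus fiber geometry on a 3D grid."""

    v_intra: np.ndarray
    v_extra: np.ndarray
    v_csf: np.ndarray
    d_ax_intra: np.ndarray
    d_ax_extra: np.ndarray
    d_rad_extra: np.ndarray
    kappa: np.ndarray
    direction: np.ndarray  # (..., 3), unit vectors where kappa matters

    def __post_init__(self) -> None:
        shp = np.asarray(self.v_intra).shape
        for nm in ("v_extra", "v_csf", "d_ax_intra", "d_ax_extra",
                   "d_rad_extra", "kappa"):
            if np.asarray(getattr(self, nm)).shape != shp:
                raise ValueError(f"field {nm} shape mismatch")
        if np.asarray(self.direction).shape != shp + (3,):
            raise ValueError("direction field must have trailing axis 3")

    @property
    def spatial_shape(self) -> tuple:
        return np.asarray(self.v_intra).shape

    def theta_flat(self, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        theta = np.stack([self.v_intra[mask], self.v_extra[mask], self.v_csf[mask],
                          self.d_ax_intra[mask], self.d_ax_extra[mask],
                          self.d_rad_extra[mask]], axis=1)
        return theta, self.kappa[mask], self.direction[mask]


def simulate_volume(field: TissueField, scheme: AcquisitionScheme,
                    s0: float = 1000.0,
                    mask: np.ndarray | None = None,
                    grid_order: int = DEFAULT_GRID_ORDER,
                    voxel_size: tuple = (2.0, 2.0, 2.0)) -> DwiVolume:
    """Noiseless DWI volume: per-voxel dispersed signals scaled by ``s0``.

    Voxels outside ``mask`` (default: everywhere) are zero.
    """
    shp = field.spatial_shape
    if mask is None:
        mask = np.ones(shp, dtype=bool)
    if mask.shape != shp:
        raise ValueError("mask shape does not match field shape")
    theta, kappa, mu = field.theta_flat(mask)
    nrm = np.linalg.norm(mu, axis=1)
    nrm[nrm == 0] = 1.0
    mu = mu / nrm[:, None]
    signals = batch_dispersed_signals(theta, kappa, mu, scheme, grid_order)
    data = np.zeros(shp + (len(scheme),), dtype=float)
    data[mask] = s0 * signals
    return DwiVolume(data=data, scheme=scheme, voxel_size=voxel_size)
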