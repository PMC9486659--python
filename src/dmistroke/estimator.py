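"""Simulation-trained Bayesian estimator of microstructure parameters.

Instead of fitting the standard model voxel by voxel, the posterior-mean
map from invariant signal features to model parameters is *learned* from a
simulated training set:

1. draw parameters from a broad biophysical prior — flat Dirichlet on the
   volume-fraction simplex, uniform diffusivities on [0, 3] µm²/ms
   (d_rad_extra on [0, 1.5]) rejected against the degeneracy constraint
   ``d_ax_intra > d_ax_extra + 2·d_rad_extra`` — together with nuisance
   fiber geometry (Watson dispersion, random orientation) and an SNR level;
2. simulate the scheme's signals, corrupt them with Rician noise, and
   compute the same three invariant features used at inference time;
3. fit an order-3 polynomial regressor (full cubic expansion of the three
   standardized features, 20 terms, tiny ridge) from features to the six
   parameters.

A trained regressor approximates the Bayesian posterior-mean estimator
under the simulated prior; :func:`posterior_mean_oracle` is the slow
importance-sampling reference it is validated against.  Prediction is a
single polynomial evaluation per voxel, fast enough for an acute-stroke
workflow.  With only three features for five free parameters the problem is
under-determined, so parameter maps carry prior-induced correlations; the
contract is agreement with the posterior mean, not zero bias.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path

import numpy as np

from .exceptions import ConditioningError, ConfigError, SchemeError
from .features import compute_features, signal_features
from .io import PARAMETER_NAMES, AcquisitionScheme, DwiVolume, ParameterMaps, VoxelMask
from .model import DEFAULT_GRID_ORDER, batch_dispersed_signals

_ESTIMATOR_FORMAT_VERSION = 1

#: Exponent tuples of the full cubic expansion of 3 features (20 terms).
_POLY_EXPONENTS = tuple(
    tuple(comb.count(k) for k in range(3))
    for deg in range(4)
    for comb in combinations_with_replacement(range(3), deg)
)


@dataclass
class PriorConfig:
    """Sampling configuration for the simulated training prior.

    Diffusivity ranges are in µm²/ms and bounded by the free-water value 3;
    ``d_rad_extra`` is capped at 1.5 so the constraint region stays
    non-degenerate.  ``kappa_range`` (Watson concentration, log-uniform) and
    ``snr_range`` (uniform, SNR at b=0) are nuisance dimensions the
    estimator marginalizes over.
    """

    n_samples: int = 20000
    seed: int = 0
    d_ax_intra_range: tuple = (0.0, 3.0)
    d_ax_extra_range: tuple = (0.0, 3.0)
    d_rad_extra_range: tuple = (0.0, 1.5)
    kappa_range: tuple = (0.5, 64.0)
    snr_range: tuple = (15.0, 60.0)
    grid_order: int = DEFAULT_GRID_ORDER

    def __post_init__(self) -> None:
        for nm in ("d_ax_intra_range", "d_ax_extra_range", "d_rad_extra_range"):
            lo, hi = getattr(self, nm)
            if not (0.0 <= lo < hi <= 3.0):
                raise ConfigError(f"{nm}=({lo}, {hi}) must satisfy 0 ≤ lo < hi ≤ 3")
        if self.d_ax_intra_range[1] <= self.d_ax_extra_range[0] + 2 * self.d_rad_extra_range[0]:
            raise ConfigError("admissible region is empty under the constraint")
        if not (0 < self.kappa_range[0] <= self.kappa_range[1]):
            raise ConfigError("kappa_range must be positive and ordered")
        if self.snr_range is not None and not (0 < self.snr_range[0] <= self.snr_range[1]):
            raise ConfigError("snr_range must be positive and ordered")
        if self.n_samples < 10 * len(_POLY_EXPONENTS):
            raise ConfigError(
                f"n_samples must be ≥ {10 * len(_POLY_EXPONENTS)} "
                f"(10× the number of polynomial terms)"
            )


@dataclass
class PriorSamples:
    """A draw from the prior: (M, 6) parameters plus nuisance dimensions."""

    theta: np.ndarray            # columns in PARAMETER_NAMES order
    kappa: np.ndarray
    direction: np.ndarray        # (M, 3) unit vectors
    snr: np.ndarray              # inf when noiseless
    acceptance_fraction: float   # of the diffusivity rejection step

    def __len__(self) -> int:
        return len(self.theta)


def sample_prior(config: PriorConfig, n_samples: int | None = None,
                 seed: int | None = None) -> PriorSamples:
    """Draw admissible parameter/geometry/SNR samples; deterministic per seed."""
    n = n_samples if n_samples is not None else config.n_samples
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fractions = rng.dirichlet(np.ones(3), size=n)

    diffs = np.empty((n, 3))
    filled, proposed, accepted = 0, 0, 0
    while filled < n:
        m = max(4 * (n - filled), 1024)
        d_ai = rng.uniform(*config.d_ax_intra_range, size=m)
        d_ae = rng.uniform(*config.d_ax_extra_range, size=m)
        d_re = rng.uniform(*config.d_rad_extra_range, size=m)
        ok = d_ai > d_ae + 2.0 * d_re
        proposed += m
        accepted += int(ok.sum())
        take = min(int(ok.sum()), n - filled)
        sel = np.flatnonzero(ok)[:take]
        diffs[filled:filled + take] = np.stack([d_ai[sel], d_ae[sel], d_re[sel]], 1)
        filled += take
        if proposed > 1000 * n + 10000 and accepted == 0:
            raise ConfigError("empty admissible region: rejection never accepts")

    log_k = rng.uniform(np.log(config.kappa_range[0]),
                        np.log(config.kappa_range[1]), size=n)
    mu = rng.normal(size=(n, 3))
    mu /= np.linalg.norm(mu, axis=1, keepdims=True)
    if config.snr_range is None:
        snr = np.full(n, np.inf)
    else:
        snr = rng.uniform(*config.snr_range, size=n)
    return PriorSamples(theta=np.concatenate([fractions, diffs], axis=1),
                        kappa=np.exp(log_k), direction=mu, snr=snr,
                        acceptance_fraction=accepted / proposed)


def _apply_rician(signals: np.ndarray, snr: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Magnitude (Rician) noise at per-sample SNR defined on the b=0 signal."""
    sigma = np.where(np.isfinite(snr), 1.0 / np.maximum(snr, 1e-12), 0.0)[:, None]
    n1 = rng.standard_normal(signals.shape)
    n2 = rng.standard_normal(signals.shape)
    return np.sqrt((signals + sigma * n1) ** 2 + (sigma * n2) ** 2)


def build_training_set(samples: PriorSamples, scheme: AcquisitionScheme,
                       grid_order: int = DEFAULT_GRID_ORDER,
                       noise_seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Simulate per-sample signals → Rician noise → invariant features.

    Returns ``(X (M, 3) features, Y (M, 6) parameters)`` with rows aligned to
    ``samples``; the feature computation is byte-identical to the
    inference-time path, so train and test distributions match.
    """
    signals = batch_dispersed_signals(samples.theta, samples.kappa,
                                      samples.direction, scheme, grid_order)
    rng = np.random.default_rng(noise_seed)
    noisy = _apply_rician(signals, samples.snr, rng)
    feats, valid = signal_features(noisy, scheme)
    if not np.all(valid):  # pragma: no cover - needs pathological SNR
        raise ValueError("training sample produced a non-positive b=0 mean")
    return feats, samples.theta.copy()


def polynomial_design(features_std: np.ndarray) -> np.ndarray:
    """Full cubic monomial expansion (incl. intercept) of standardized features."""
    f = np.asarray(features_std, dtype=float)
    cols = [np.prod([f[..., k] ** e for k, e in enumerate(exps)], axis=0)
            for exps in _POLY_EXPONENTS]
    return np.stack(cols, axis=-1)


@dataclass
class TrainedEstimator:
    """Order-3 polynomial posterior-mean regressor for one acquisition scheme."""

    degree: int
    feature_mean: np.ndarray        # (3,)
    feature_std: np.ndarray         # (3,)
    coefficients: np.ndarray        # (20, 6), target order PARAMETER_NAMES
    scheme_fingerprint: str
    scheme: AcquisitionScheme | None = None
    training_rmse: dict = field(default_factory=dict)

    def predict_features(self, features: np.ndarray) -> np.ndarray:
        """Raw regressor outputs (..., 6) for feature vectors (..., 3)."""
        z = (np.asarray(features) - self.feature_mean) / self.feature_std
        return polynomial_design(z) @ self.coefficients

    # -- serialization: versioned JSON with the scheme embedded --------------
    def save(self, path) -> None:
        doc = {
            "format": "dmistroke-estimator",
            "version": _ESTIMATOR_FORMAT_VERSION,
            "degree": self.degree,
            "feature_mean": self.feature_mean.tolist(),
            "feature_std": self.feature_std.tolist(),
            "coefficients": self.coefficients.tolist(),
            "scheme_fingerprint": self.scheme_fingerprint,
            "training_rmse": self.training_rmse,
            "scheme": self.scheme.to_dict() if self.scheme is not None else None,
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "TrainedEstimator":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "dmistroke-estimator":
            raise ValueError(f"{path} is not a dmistroke estimator file")
        if doc["version"] != _ESTIMATOR_FORMAT_VERSION:
            raise ValueError(f"unsupported estimator format version {doc['version']}")
        scheme = (AcquisitionScheme.from_dict(doc["scheme"])
                  if doc.get("scheme") else None)
        return cls(degree=doc["degree"],
                   feature_mean=np.asarray(doc["feature_mean"]),
                   feature_std=np.asarray(doc["feature_std"]),
                   coefficients=np.asarray(doc["coefficients"]),
                   scheme_fingerprint=doc["scheme_fingerprint"],
                   scheme=scheme,
                   training_rmse=doc.get("training_rmse", {}))


def fit_regressor(features: np.ndarray, targets: np.ndarray, degree: int = 3,
                  ridge: float = 1e-6,
                  scheme_fingerprint: str = "") -> TrainedEstimator:
    """Ridge-regularized cubic polynomial fit from features to parameters.

    Features are standardized; the ridge penalty (on all terms but the
    intercept) is a conditioning safeguard only.
    """
    if degree != 3:
        raise ValueError("only degree=3 is supported")
    X = np.asarray(features, dtype=float)
    Y = np.asarray(targets, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("features must be (M, 3)")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    if np.any(std <= 0):
        if ridge <= 0:
            raise ConditioningError("degenerate feature column without ridge")
        std = np.where(std > 0, std, 1.0)
    D = polynomial_design((X - mean) / std)
    gram = D.T @ D
    if ridge > 0:
        pen = np.eye(D.shape[1])
        pen[0, 0] = 0.0
        gram = gram + ridge * pen
    elif np.linalg.matrix_rank(gram) < D.shape[1]:
        raise ConditioningError("rank-deficient polynomial design without ridge")
    coef = np.linalg.solve(gram, D.T @ Y)
    resid = D @ coef - Y
    rmse = {nm: float(v) for nm, v in
            zip(PARAMETER_NAMES, np.sqrt((resid ** 2).mean(axis=0)))}
    return TrainedEstimator(degree=3, feature_mean=mean, feature_std=std,
                            coefficients=coef, scheme_fingerprint=scheme_fingerprint,
                            training_rmse=rmse)


def train_estimator(scheme: AcquisitionScheme,
                    config: PriorConfig) -> TrainedEstimator:
    """Sample the prior, simulate features, fit the regressor — one call.

    Deterministic: the noise stream is derived from ``config.seed``.
    """
    samples = sample_prior(config)
    X, Y = build_training_set(samples, scheme, grid_order=config.grid_order,
                              noise_seed=config.seed + 1)
    est = fit_regressor(X, Y, scheme_fingerprint=scheme.fingerprint())
    est.scheme = scheme
    return est


def postprocess_predictions(raw: np.ndarray) -> np.ndarray:
    """Map raw regressor outputs onto the physical domain.

    Fractions are clipped to [0, 1] and renormalized to sum to 1 (equal
    thirds if all clip to zero); diffusivities are clipped to [0, 3].
    """
    out = np.asarray(raw, dtype=float).copy()
    fr = np.clip(out[..., :3], 0.0, 1.0)
    tot = fr.sum(axis=-1, keepdims=True)
    fr = np.where(tot > 0, fr / np.where(tot > 0, tot, 1.0), 1.0 / 3.0)
    out[..., :3] = fr
    out[..., 3:] = np.clip(out[..., 3:], 0.0, 3.0)
    return out


def predict_maps(estimator: TrainedEstimator, volume: DwiVolume,
                 mask: VoxelMask) -> ParameterMaps:
    """Apply a trained estimator voxelwise; refuses cross-protocol use."""
    if estimator.scheme_fingerprint != volume.scheme.fingerprint():
        raise SchemeError(
            "estimator was trained for a different acquisition scheme "
            f"({estimator.scheme_fingerprint} != {volume.scheme.fingerprint()})"
        )
    feats, valid = compute_features(volume, mask)
    arrays = {nm: np.zeros(volume.spatial_shape) for nm in PARAMETER_NAMES}
    vm = valid.data
    if vm.any():
        pred = postprocess_predictions(estimator.predict_features(feats[vm]))
        for j, nm in enumerate(PARAMETER_NAMES):
            arrays[nm][vm] = pred[:, j]
    return ParameterMaps(mask=vm, voxel_size=volume.voxel_size,
                         affine=volume.affine, **arrays)


# ---------------------------------------------------------------------------
# slow Bayesian reference
# ---------------------------------------------------------------------------

def estimate_feature_noise_sigma(scheme: AcquisitionScheme, snr: float,
                                 config: PriorConfig | None = None,
                                 n: int = 2000, seed: int = 12345) -> np.ndarray:
    """Empirical per-feature noise std at a given SNR.

    Simulates prior voxels with and without Rician noise and returns the
    std of the feature differences — the Gaussian feature-noise scale the
    posterior-mean oracle needs.
    """
    cfg = config or PriorConfig(seed=seed)
    samples = sample_prior(cfg, n_samples=n, seed=seed)
    signals = batch_dispersed_signals(samples.theta, samples.kappa,
                                      samples.direction, scheme, cfg.grid_order)
    clean, _ = signal_features(signals, scheme)
    rng = np.random.default_rng(seed + 1)
    noisy_signals = _apply_rician(signals, np.full(n, float(snr)), rng)
    noisy, valid = signal_features(noisy_signals, scheme)
    return np.std(noisy[valid] - clean[valid], axis=0)


def posterior_mean_oracle(feature: np.ndarray, config: PriorConfig,
                          noise_sigma, n_mc: int = 100000,
                          scheme: AcquisitionScheme | None = None,
                          reference: tuple | None = None) -> np.ndarray:
    """Importance-sampling posterior mean — the slow Bayesian reference.

    ``E[θ | f] ≈ Σ_i θ_i w_i / Σ_i w_i`` with Gaussian feature-noise weights
    ``w_i = exp(−Σ_k (f_k − f_k(θ_i))²/(2σ_k²))`` over ``n_mc`` prior samples
    with noiseless simulated features.  ``noise_sigma`` may be scalar or
    per-feature.  Pass ``reference=(features_i, theta_i)`` to reuse a
    precomputed prior sample set across calls; otherwise ``scheme`` is
    required and the set is built from ``config``.

    If all weights underflow for a query, sigma is widened (doubled, with a
    warning) until they do not.  Intended for validation, not production.
    """
    single = np.asarray(feature).ndim == 1
    feature = np.atleast_2d(np.asarray(feature, dtype=float))
    if reference is None:
        if scheme is None:
            raise ValueError("either reference or scheme must be provided")
        samples = sample_prior(config, n_samples=n_mc)
        signals = batch_dispersed_signals(samples.theta, samples.kappa,
                                          samples.direction, scheme,
                                          config.grid_order)
        ref_feats, _ = signal_features(signals, scheme)
        ref_theta = samples.theta
    else:
        ref_feats, ref_theta = reference
    sigma = np.broadcast_to(np.asarray(noise_sigma, dtype=float), (3,))
    out = np.empty((len(feature), 6))
    for i, f in enumerate(feature):
        s = sigma.copy()
        while True:
            log_w = -0.5 * (((f - ref_feats) / s) ** 2).sum(axis=1)
            peak = log_w.max()
            if peak > -700.0:  # representable without underflowing every weight
                break
            warnings.warn("posterior_mean_oracle: weights underflow; widening sigma")
            s = 2.0 * s
        w = np.exp(log_w - peak)
        out[i] = (w[:, None] * ref_theta).sum(axis=0) / w.sum()
    return out[0] if single else out
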