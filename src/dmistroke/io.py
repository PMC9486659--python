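"""Data containers and NIfTI / gradient-table I/O.

Internal units are fixed so that the diffusion exponent ``b * D`` is
dimensionless: b-values in ms/µm² and diffusivities in µm²/ms
(1000 s/mm² == 1.0 ms/µm²).  Conversion from the scanner convention
(s/mm²) happens only when reading or writing FSL-style gradient tables.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .exceptions import FormatError

#: b-values at or below this (ms/µm², i.e. 50 s/mm²) count as b=0 acquisitions.
B0_THRESHOLD = 0.05

#: Canonical parameter-map names, in storage order.
PARAMETER_NAMES = (
    "v_intra",
    "v_extra",
    "v_csf",
    "d_ax_intra",
    "d_ax_extra",
    "d_rad_extra",
)

_SCHEME_PRESETS = ("two_shell", "hex_ball")


def _golden_spiral_hemisphere(n: int) -> np.ndarray:
    """``n`` unit vectors quasi-uniform on the upper hemisphere (golden-angle
    spiral).  Deterministic; adequate angular coverage for order-2 spherical
    harmonic fits from ~15 directions upward."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


@dataclass
class AcquisitionScheme:
    """One diffusion protocol: b-values (ms/µm²), unit gradient directions and
    integer shell labels (−1 for b=0 frames)."""

    bvals: np.ndarray
    bvecs: np.ndarray
    shell_ids: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        self.shell_ids = np.asarray(self.shell_ids, dtype=int)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise FormatError(f"bvecs must be (N, 3), got {self.bvecs.shape}")
        if len(self.bvals) != len(self.bvecs) or len(self.bvals) != len(self.shell_ids):
            raise FormatError(
                "bvals, bvecs and shell_ids must have equal length "
                f"({len(self.bvals)}, {len(self.bvecs)}, {len(self.shell_ids)})"
            )
        if np.any(self.bvals < 0):
            raise FormatError("negative b-value in scheme")
        norms = np.linalg.norm(self.bvecs[~self.b0_mask], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise FormatError("non-b0 gradient directions must be unit vectors")

    @classmethod
    def from_bvals_bvecs(
        cls, bvals, bvecs, name: str = "", shell_decimals: int = 2
    ) -> "AcquisitionScheme":
        """Build a scheme, assigning shell ids by grouping rounded b-values.

        b-values ≤ 50 s/mm² (0.05 ms/µm²) are classed as b=0 (shell id −1),
        a tolerance for vendor rounding of the nominally unweighted frames.
        """
        bvals = np.asarray(bvals, dtype=float)
        bvecs = np.asarray(bvecs, dtype=float)
        b0 = bvals <= B0_THRESHOLD
        shell_ids = np.full(len(bvals), -1, dtype=int)
        rounded = np.round(bvals[~b0], shell_decimals)
        for sid, b in enumerate(np.unique(rounded)):
            shell_ids[np.flatnonzero(~b0)[rounded == b]] = sid
        # normalize direction vectors defensively; zero them on b=0 frames
        bvecs = bvecs.copy()
        bvecs[b0] = 0.0
        nrm = np.linalg.norm(bvecs[~b0], axis=1)
        if np.any(nrm <= 0):
            raise FormatError("zero gradient vector on a diffusion-weighted frame")
        bvecs[~b0] /= nrm[:, None]
        return cls(bvals=bvals, bvecs=bvecs, shell_ids=shell_ids, name=name)

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= B0_THRESHOLD

    @property
    def dw_mask(self) -> np.ndarray:
        return ~self.b0_mask

    @property
    def shells(self) -> np.ndarray:
        """Unique non-zero shell b-values, ascending."""
        return np.unique(np.round(self.bvals[self.dw_mask], 6))

    def fingerprint(self) -> str:
        """Stable hash of the gradient table; embedded in trained estimators to
        prevent silent cross-protocol use."""
        h = hashlib.sha256()
        h.update(np.round(self.bvals, 6).tobytes())
        h.update(np.round(self.bvecs, 6).tobytes())
        return h.hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "bvals": self.bvals.tolist(),
            "bvecs": self.bvecs.tolist(),
            "shell_ids": self.shell_ids.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionScheme":
        return cls(
            bvals=np.asarray(d["bvals"]),
            bvecs=np.asarray(d["bvecs"]),
            shell_ids=np.asarray(d["shell_ids"]),
            name=d.get("name", ""),
        )


@dataclass
class DwiVolume:
    """4D diffusion-weighted volume (x, y, z, weighting) with its scheme."""

    data: np.ndarray
    scheme: AcquisitionScheme
    voxel_size: tuple = (2.0, 2.0, 2.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise FormatError(f"DWI data must be 4D, got {self.data.ndim}D")
        if self.data.shape[3] != len(self.scheme):
            raise FormatError(
                f"volume has {self.data.shape[3]} frames but scheme has "
                f"{len(self.scheme)} weightings"
            )
        if np.any(self.data < 0):
            raise FormatError("negative signal intensities")

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]

    def get_affine(self) -> np.ndarray:
        if self.affine is not None:
            return self.affine
        return np.diag(list(self.voxel_size) + [1.0])


@dataclass
class VoxelMask:
    """Binary 3D mask on the same grid as an associated volume."""

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise FormatError(f"mask must be 3D, got {arr.ndim}D")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise FormatError("mask values must be 0/1")
        self.data = arr.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def __and__(self, other: "VoxelMask") -> "VoxelMask":
        return VoxelMask(self.data & other.data)

    def __or__(self, other: "VoxelMask") -> "VoxelMask":
        return VoxelMask(self.data | other.data)


@dataclass
class ParameterMaps:
    """3D fields of the six microstructure parameters, optionally plus ADC.

    Fractions live in [0, 1] and sum to 1 inside the processing mask;
    diffusivities in [0, 3] µm²/ms.
    """

    v_intra: np.ndarray
    v_extra: np.ndarray
    v_csf: np.ndarray
    d_ax_intra: np.ndarray
    d_ax_extra: np.ndarray
    d_rad_extra: np.ndarray
    adc: np.ndarray | None = None
    mask: np.ndarray | None = None
    voxel_size: tuple = (2.0, 2.0, 2.0)
    affine: np.ndarray | None = field(default=None, repr=False)

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in PARAMETER_NAMES + ("adc",):
            raise KeyError(name)
        return getattr(self, name)

    def items(self):
        for name in PARAMETER_NAMES:
            yield name, getattr(self, name)
        if self.adc is not None:
            yield "adc", self.adc

    def validate(self, mask: np.ndarray | None = None, atol: float = 1e-6) -> None:
        m = mask if mask is not None else (self.mask if self.mask is not None else
                                           np.ones(self.v_intra.shape, bool))
        fr = np.stack([self.v_intra[m], self.v_extra[m], self.v_csf[m]])
        if fr.size and (fr.min() < -atol or fr.max() > 1 + atol):
            raise ValueError("volume fractions outside [0, 1]")
        if fr.size and np.max(np.abs(fr.sum(axis=0) - 1.0)) > atol:
            raise ValueError("volume fractions do not sum to 1 inside the mask")
        for name in ("d_ax_intra", "d_ax_extra", "d_rad_extra"):
            d = getattr(self, name)[m]
            if d.size and (d.min() < -atol or d.max() > 3 + atol):
                raise ValueError(f"{name} outside [0, 3] µm²/ms")

    def get_affine(self) -> np.ndarray:
        if self.affine is not None:
            return self.affine
        return np.diag(list(self.voxel_size) + [1.0])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_gradient_table(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    """Read FSL-dialect bval (1×N) / bvec (3×N) text files.

    Returns b-values converted to ms/µm² and direction vectors as (N, 3).
    """
    bvals = np.loadtxt(bval_path, ndmin=1).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # FSL stores 3 rows of N entries
    if bvecs.shape[1] != 3:
        raise FormatError(f"bvec file must be 3×N, got shape {bvecs.shape}")
    if len(bvals) != len(bvecs):
        raise FormatError(
            f"bval has {len(bvals)} entries but bvec has {len(bvecs)}"
        )
    if np.any(bvals < 0):
        raise FormatError("negative b-value in bval file")
    return bvals / 1000.0, bvecs


def write_gradient_table(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    """Write FSL-dialect gradient files (b back-converted to s/mm²)."""
    np.savetxt(bval_path, (scheme.bvals * 1000.0)[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.10g")


def read_dwi(image_path, bval_path, bvec_path) -> DwiVolume:
    """Load a 4D NIfTI with its FSL gradient table into a :class:`DwiVolume`."""
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"expected a 4D image, got {data.ndim}D")
    bvals, bvecs = read_gradient_table(bval_path, bvec_path)
    if data.shape[3] != len(bvals):
        raise FormatError(
            f"image has {data.shape[3]} volumes but gradient table has {len(bvals)}"
        )
    scheme = AcquisitionScheme.from_bvals_bvecs(bvals, bvecs)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DwiVolume(data=data, scheme=scheme, voxel_size=voxel_size,
                     affine=np.asarray(img.affine))


def write_dwi(volume: DwiVolume, image_path, bval_path=None, bvec_path=None) -> None:
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), volume.get_affine()),
             str(image_path))
    if bval_path is not None and bvec_path is not None:
        write_gradient_table(volume.scheme, bval_path, bvec_path)


def read_mask(path) -> VoxelMask:
    img = nib.load(str(path))
    return VoxelMask(np.asarray(img.dataobj) > 0.5)


def write_mask(mask: VoxelMask, path, affine: np.ndarray | None = None) -> None:
    aff = affine if affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), aff), str(path))


def write_parameter_maps(maps: ParameterMaps, out_dir) -> list[Path]:
    """Write one ``<name>.nii.gz`` per parameter (plus ``adc.nii.gz`` if set)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = maps.get_affine()
    written = []
    for name, arr in maps.items():
        p = out_dir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), aff), str(p))
        written.append(p)
    return written


def read_parameter_maps(out_dir) -> ParameterMaps:
    out_dir = Path(out_dir)
    arrays = {}
    affine = None
    for name in PARAMETER_NAMES:
        img = nib.load(str(out_dir / f"{name}.nii.gz"))
        arrays[name] = np.asarray(img.dataobj, dtype=float)
        affine = np.asarray(img.affine)
    adc_path = out_dir / "adc.nii.gz"
    adc = np.asarray(nib.load(str(adc_path)).dataobj, dtype=float) if adc_path.exists() else None
    vz = tuple(float(abs(affine[i, i])) for i in range(3))
    return ParameterMaps(adc=adc, affine=affine, voxel_size=vz, **arrays)


def read_scalar_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


# ---------------------------------------------------------------------------
# scheme presets
# ---------------------------------------------------------------------------

def _interleave_b0(bvals, bvecs, every: int = 6):
    """Leading b=0 plus one inserted after every ``every``-th weighting."""
    out_b, out_v = [0.0], [np.zeros(3)]
    for i, (b, v) in enumerate(zip(bvals, bvecs), start=1):
        out_b.append(b)
        out_v.append(v)
        if i % every == 0:
            out_b.append(0.0)
            out_v.append(np.zeros(3))
    return np.asarray(out_b), np.asarray(out_v)


def _hex_ball_qvectors(n_points: int = 28) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic hexagonal (FCC) packing of q-space truncated to
    ``n_points`` non-zero points inside the unit ball.

    Lattice points (i, j, k) with even coordinate sum are enumerated out to
    the third shell, sorted by (radius², i, j, k) and the first ``n_points``
    kept; radii are then scaled so the outermost point sits at |q| = 1.
    Returns (unit directions, |q|² in units of the maximal radius²), from
    which b = b_max·|q|² since b ∝ q².
    """
    rng = range(-3, 4)
    pts = np.array([(i, j, k) for i in rng for j in rng for k in rng
                    if (i + j + k) % 2 == 0 and (i, j, k) != (0, 0, 0)],
                   dtype=float)
    r2 = (pts ** 2).sum(axis=1)
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], r2))
    pts = pts[order][:n_points]
    r2 = (pts ** 2).sum(axis=1)
    dirs = pts / np.sqrt(r2)[:, None]
    return dirs, r2 / r2.max()


def preset_scheme(name: str) -> AcquisitionScheme:
    """Return one of the two built-in acquisition protocols.

    ``"two_shell"``
        30 directions per shell at b = 1.0 and 2.0 ms/µm² (golden-spiral
        hemisphere sets), a leading b=0 and one b=0 inserted after every
        6th weighting — the interleaving used on two-shell stroke protocols.
    ``"hex_ball"``
        28 weightings whose q-vectors form a deterministic hexagonal
        close-packing truncated to the ball of radius b = 2.0 ms/µm²
        (b ∝ |q|², giving sub-shells at b ≈ 0.67, 1.33 and 2.0), with the
        same interleaved b=0 convention.
    """
    if name == "two_shell":
        dirs = _golden_spiral_hemisphere(30)
        bvals = np.concatenate([np.full(30, 1.0), np.full(30, 2.0)])
        bvecs = np.concatenate([dirs, dirs])
    elif name == "hex_ball":
        dirs, rel_b = _hex_ball_qvectors(28)
        bvals = 2.0 * rel_b
        bvecs = dirs
    else:
        raise ValueError(
            f"unknown scheme preset {name!r}; choose from {_SCHEME_PRESETS}"
        )
    bvals, bvecs = _interleave_b0(bvals, bvecs)
    return AcquisitionScheme.from_bvals_bvecs(bvals, bvecs, name=name)
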