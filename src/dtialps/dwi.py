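"""Diffusion-weighted volumes, gradient schemes and per-voxel tensor fitting.

The diffusion tensor model relates the measured signal to the b-matrix of
each acquisition::

    S(g, b) = S0 * exp(-b * g^T D g)

with ``D`` the symmetric 3x3 diffusion tensor in the scanner frame
(x = right-left, y = anterior-posterior, z = superior-inferior).  Fitting is
plain log-linear least squares on ``ln S``, which is exact on noiseless data
for any positive-semi-definite generating tensor.

The axis diffusivities used downstream by the ALPS index are the *diagonal
elements* Dxx, Dyy, Dzz of the tensor in the scanner frame — not eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "GradientScheme",
    "DWIVolume",
    "TensorField",
    "DWIFormatError",
    "fibonacci_scheme",
    "read_dwi",
    "write_dwi",
    "fit_tensor",
    "axis_diffusivities",
    "fractional_anisotropy",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))
_UNIT_TOL = 1e-6


class DWIFormatError(ValueError):
    """Inconsistent or malformed DWI data / gradient table."""


@dataclass(frozen=True)
class GradientScheme:
    """Per-volume b-values (s/mm^2) and unit gradient directions.

    Directions are given in the scanner frame; rows with ``b == 0`` may carry
    a zero vector.  FSL dialect on disk: ``bval`` one row, ``bvec`` three rows.
    """

    bvals: np.ndarray
    bvecs: np.ndarray  # shape (n, 3)

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise DWIFormatError(f"bvecs must be (n, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise DWIFormatError(
                f"{bvals.shape[0]} b-values vs {bvecs.shape[0]} directions"
            )
        if np.any(bvals < 0) or not np.all(np.isfinite(bvals)):
            raise DWIFormatError("b-values must be finite and non-negative")
        norms = np.linalg.norm(bvecs, axis=1)
        bad = (bvals > 0) & (np.abs(norms - 1.0) > _UNIT_TOL)
        if np.any(bad):
            raise DWIFormatError(
                f"non-unit gradient direction(s) at b>0: volumes {np.where(bad)[0].tolist()}"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def n_dwi(self) -> int:
        return int(np.sum(~self.b0_mask))

    def validate_for_fit(self) -> None:
        if self.n_dwi < 6:
            raise DWIFormatError(
                f"tensor fit needs >=6 diffusion-weighted directions, got {self.n_dwi}"
            )
        if not np.any(self.b0_mask):
            raise DWIFormatError("tensor fit needs at least one b=0 volume")


def fibonacci_scheme(
    n_directions: int = 32, bvalue: float = 1000.0, n_b0: int = 1
) -> GradientScheme:
    """Deterministic spherical-Fibonacci gradient scheme.

    Near-uniform coverage of the sphere; the default matches a 32-direction
    b=1000 s/mm^2 acquisition with one leading b=0 volume.
    """
    i = np.arange(n_directions)
    z = 1.0 - (2.0 * i + 1.0) / n_directions
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = i * _GOLDEN_ANGLE
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(bvalue))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientScheme(bvals=bvals, bvecs=bvecs)


@dataclass(frozen=True)
class DWIVolume:
    """4-D diffusion signal grid (x, y, z, volume) with affine and scheme."""

    signal: np.ndarray
    affine: np.ndarray
    scheme: GradientScheme

    def __post_init__(self) -> None:
        signal = np.asarray(self.signal, dtype=float)
        affine = np.asarray(self.affine, dtype=float)
        if signal.ndim != 4:
            raise DWIFormatError(f"signal must be 4-D, got shape {signal.shape}")
        if affine.shape != (4, 4):
            raise DWIFormatError("affine must be 4x4")
        if signal.shape[3] != len(self.scheme):
            raise DWIFormatError(
                f"{signal.shape[3]} volumes vs {len(self.scheme)} scheme entries"
            )
        if np.any(signal < 0):
            raise DWIFormatError("signal must be non-negative")
        object.__setattr__(self, "signal", signal)
        object.__setattr__(self, "affine", affine)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


def write_dwi(volume: DWIVolume, nifti_path, bval_path, bvec_path) -> None:
    """Write a DWI volume as NIfTI-1 plus FSL-dialect bval/bvec text files."""
    img = nib.Nifti1Image(volume.signal, volume.affine)
    nib.save(img, str(nifti_path))
    np.savetxt(bval_path, volume.scheme.bvals[None, :], fmt="%.17g")
    np.savetxt(bvec_path, volume.scheme.bvecs.T, fmt="%.17g")


def read_dwi(nifti_path, bval_path, bvec_path) -> DWIVolume:
    """Read NIfTI + bval/bvec into a :class:`DWIVolume` (lossless roundtrip)."""
    img = nib.load(str(nifti_path))
    signal = np.asarray(img.get_fdata(), dtype=float)
    bvals = np.loadtxt(bval_path, ndmin=2)
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] != 3:
        raise DWIFormatError(f"bvec file must have 3 rows, got {bvecs.shape[0]}")
    scheme = GradientScheme(bvals=bvals.ravel(), bvecs=bvecs.T)
    if signal.ndim != 4 or signal.shape[3] != len(scheme):
        raise DWIFormatError(
            f"image has {signal.shape[3] if signal.ndim == 4 else 'non-4D'} volumes "
            f"but gradient table has {len(scheme)} entries"
        )
    return DWIVolume(signal=signal, affine=np.asarray(img.affine), scheme=scheme)


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor in the scanner frame.

    ``tensor`` has shape grid + (3, 3); ``s0`` is the fitted b0 signal;
    ``fit_ok`` flags voxels where the fit succeeded; ``clamped`` flags voxels
    where negative eigenvalues were clamped to zero.
    """

    tensor: np.ndarray
    s0: np.ndarray
    fit_ok: np.ndarray
    clamped: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.clamped is None:
            self.clamped = np.zeros(self.fit_ok.shape, dtype=bool)

    @property
    def dxx(self) -> np.ndarray:
        return self.tensor[..., 0, 0]

    @property
    def dyy(self) -> np.ndarray:
        return self.tensor[..., 1, 1]

    @property
    def dzz(self) -> np.ndarray:
        return self.tensor[..., 2, 2]


def _design_matrix(scheme: GradientScheme) -> np.ndarray:
    b = scheme.bvals
    g = scheme.bvecs
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx * gx,
            -b * gy * gy,
            -b * gz * gz,
            -2.0 * b * gx * gy,
            -2.0 * b * gx * gz,
            -2.0 * b * gy * gz,
        ]
    )


_LOG_FLOOR_FRAC = 1e-8  # signals clipped at this fraction of S0 before log


def fit_tensor(dwi: DWIVolume) -> TensorField:
    """Log-linear least-squares tensor fit, vectorized over voxels.

    Signals at or below zero are clipped to ``1e-8 * S0`` (per-voxel mean b0)
    before the log.  Negative eigenvalues of the fitted tensor are clamped to
    zero and flagged; voxels with no usable b0 signal get ``fit_ok = False``.
    """
    dwi.scheme.validate_for_fit()
    grid = dwi.grid_shape
    nvol = len(dwi.scheme)
    sig = dwi.signal.reshape(-1, nvol)  # (nvox, nvol)

    b0_mean = sig[:, dwi.scheme.b0_mask].mean(axis=1)
    ok = b0_mean > 0

    floor = np.where(ok, b0_mean, 1.0) * _LOG_FLOOR_FRAC
    logs = np.log(np.maximum(sig, floor[:, None]))

    A = _design_matrix(dwi.scheme)
    coef = np.linalg.pinv(A) @ logs.T  # (7, nvox)

    nvox = sig.shape[0]
    D = np.zeros((nvox, 3, 3))
    D[:, 0, 0] = coef[1]
    D[:, 1, 1] = coef[2]
    D[:, 2, 2] = coef[3]
    D[:, 0, 1] = D[:, 1, 0] = coef[4]
    D[:, 0, 2] = D[:, 2, 0] = coef[5]
    D[:, 1, 2] = D[:, 2, 1] = coef[6]
    s0 = np.exp(coef[0])

    D[~ok] = 0.0
    s0[~ok] = 0.0

    evals, evecs = np.linalg.eigh(D)
    clamped = np.any(evals < 0, axis=1) & ok
    if np.any(clamped):
        ev = np.clip(evals[clamped], 0.0, None)
        V = evecs[clamped]
        D[clamped] = np.einsum("nij,nj,nkj->nik", V, ev, V)

    return TensorField(
        tensor=D.reshape(grid + (3, 3)),
        s0=s0.reshape(grid),
        fit_ok=ok.reshape(grid),
        clamped=clamped.reshape(grid),
    )


def axis_diffusivities(field: TensorField) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scanner-frame diagonal diffusivities (Dxx, Dyy, Dzz) in mm^2/s.

    These are tensor diagonal elements, not eigenvalues: in a fiber not
    aligned with a scanner axis the two differ, and the ALPS index is defined
    on the axis components.
    """
    return field.dxx.copy(), field.dyy.copy(), field.dzz.copy()


def fractional_anisotropy(field: TensorField) -> np.ndarray:
    """FA in [0, 1] from the tensor eigenvalues; 0 for the zero tensor."""
    evals = np.linalg.eigvalsh(field.tensor)
    mean = evals.mean(axis=-1, keepdims=True)
    num = np.sum((evals - mean) ** 2, axis=-1)
    den = np.sum(evals**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)
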