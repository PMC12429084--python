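"""DTI-ALPS index: ROI placement and the perivascular diffusivity ratio.

At the level of the lateral-ventricle body, perivascular spaces run along the
scanner x-axis (right-left), perpendicular both to projection fibers (mainly
z) and association fibers (mainly y).  Diffusivity along x in those two fiber
regions therefore partly reflects water movement along the perivascular
space, and the index is

    ALPS = mean(Dx_proj, Dx_assoc) / mean(Dy_proj, Dz_assoc)

where the four terms are ROI means of the scanner-frame tensor diagonal
elements.  An index of 1 means no preferential perivascular diffusivity;
healthy adult white matter typically sits well above 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dwi import DWIVolume, TensorField, axis_diffusivities, fit_tensor

__all__ = [
    "ROISpec",
    "ALPSResult",
    "ROIError",
    "roi_voxels",
    "roi_mean",
    "alps_index",
    "compute_subject_alps",
]

ROI_LABELS = ("projection", "association", "subcortical")


class ROIError(ValueError):
    """Invalid ROI placement or degenerate ROI contents."""


@dataclass(frozen=True)
class ROISpec:
    """A spherical ROI: 5 mm diameter, 12 voxels by default on a 2.5 mm grid."""

    label: str
    center: tuple[int, int, int]
    diameter: float = 5.0
    target_voxel_count: int = 12

    def __post_init__(self) -> None:
        if self.label not in ROI_LABELS:
            raise ROIError(f"label must be one of {ROI_LABELS}, got {self.label!r}")
        if self.diameter <= 0:
            raise ROIError("diameter must be positive")
        if self.target_voxel_count < 1:
            raise ROIError("target_voxel_count must be >= 1")


@dataclass(frozen=True)
class ALPSResult:
    """Four ROI diffusivities (mm^2/s), the index, and per-ROI voxel counts."""

    dx_proj: float
    dy_proj: float
    dx_assoc: float
    dz_assoc: float
    alps: float
    voxel_counts: dict = field(default_factory=dict)


def roi_voxels(
    roi: ROISpec, grid_shape: tuple[int, int, int], voxel_size
) -> np.ndarray:
    """The ``target_voxel_count`` voxels nearest the ROI center.

    Distances are Euclidean in mm; ties are broken by lexicographic voxel
    index.  Raises :class:`ROIError` if the center is outside the grid or the
    ROI sphere would extend past the grid boundary.
    """
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float).ravel(), (3,))
    shape = tuple(int(s) for s in grid_shape)
    center = np.asarray(roi.center, dtype=int)
    if np.any(center < 0) or np.any(center >= np.asarray(shape)):
        raise ROIError(f"ROI center {tuple(center)} outside grid {shape}")
    k = roi.target_voxel_count
    if k > np.prod(shape):
        raise ROIError("ROI larger than the whole grid")

    idx = np.indices(shape).reshape(3, -1).T  # (nvox, 3) lexicographic order
    d = np.linalg.norm((idx - center) * vs, axis=1)
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], d))
    chosen = order[:k]
    max_d = d[chosen].max()

    # nearest voxel center outside the grid, per axis
    outside = np.min(np.minimum(center + 1, np.asarray(shape) - center) * vs)
    if outside <= max_d:
        raise ROIError(
            f"ROI of {k} voxels at {tuple(center)} extends outside the grid"
        )
    return idx[chosen]


def roi_mean(scalar_map: np.ndarray, voxels: np.ndarray, fit_ok=None) -> float:
    """Arithmetic mean of a scalar map over ROI voxels with a valid fit."""
    voxels = np.asarray(voxels, dtype=int)
    if voxels.size == 0:
        raise ROIError("empty ROI")
    vals = scalar_map[voxels[:, 0], voxels[:, 1], voxels[:, 2]]
    if fit_ok is not None:
        good = fit_ok[voxels[:, 0], voxels[:, 1], voxels[:, 2]]
        if not np.any(good):
            raise ROIError("all ROI voxels flagged as failed fits")
        vals = vals[good]
    return float(np.mean(vals))


def alps_index(dx_proj: float, dy_proj: float, dx_assoc: float, dz_assoc: float) -> float:
    """mean(Dx_proj, Dx_assoc) / mean(Dy_proj, Dz_assoc); scale-invariant."""
    denom = 0.5 * (dy_proj + dz_assoc)
    if not denom > 0:
        raise ValueError(f"non-positive denominator mean ({denom})")
    return float(0.5 * (dx_proj + dx_assoc) / denom)


def compute_subject_alps(dwi: DWIVolume, rois) -> ALPSResult:
    """Full chain: tensor fit -> axis maps -> ROI means -> ALPS index.

    ``rois`` must include a projection- and an association-fiber ROI; a
    subcortical ROI, if present, is carried in the voxel counts but does not
    enter the index.
    """
    by_label = {r.label: r for r in rois}
    for needed in ("projection", "association"):
        if needed not in by_label:
            raise ROIError(f"missing required ROI label {needed!r}")

    field = fit_tensor(dwi)
    return alps_from_tensor_field(field, rois, dwi.grid_shape, dwi.voxel_size)


def alps_from_tensor_field(
    tensor_field: TensorField, rois, grid_shape, voxel_size
) -> ALPSResult:
    """ALPS from an already-fitted tensor field (shared by fit and oracle paths)."""
    by_label = {r.label: r for r in rois}
    dxx, dyy, dzz = axis_diffusivities(tensor_field)
    ok = tensor_field.fit_ok

    counts = {}
    vox = {}
    for label, roi in by_label.items():
        vox[label] = roi_voxels(roi, grid_shape, voxel_size)
        counts[label] = int(vox[label].shape[0])

    dx_proj = roi_mean(dxx, vox["projection"], ok)
    dy_proj = roi_mean(dyy, vox["projection"], ok)
    dx_assoc = roi_mean(dxx, vox["association"], ok)
    dz_assoc = roi_mean(dzz, vox["association"], ok)
    return ALPSResult(
        dx_proj=dx_proj,
        dy_proj=dy_proj,
        dx_assoc=dx_assoc,
        dz_assoc=dz_assoc,
        alps=alps_index(dx_proj, dy_proj, dx_assoc, dz_assoc),
        voxel_counts=counts,
    )
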