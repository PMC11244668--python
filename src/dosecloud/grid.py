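"""Dose grids and rigid setup-error transforms (static dose cloud).

A 3D dose distribution lives on a regular lattice in patient millimetre
coordinates.  A patient setup error — a small translation of the patient or a
small rotation about the plan isocenter — is modelled by the *static dose
cloud* approximation: the dose field is assumed frozen in room coordinates,
so the dose seen by the (displaced) anatomy is the original field re-sampled
through the rigid map.  Structures stay fixed on the lattice; only the dose
moves.  This stands in for a full dose recomputation with unchanged monitor
units, which is accurate for small rigid cranial displacements where tissue
heterogeneity changes are negligible.

Axes are fixed as ``x`` = left-right, ``y`` = anterior-posterior,
``z`` = superior-inferior.  Coordinates are millimetres, voxel-center
convention, 0-based indices.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

AXES = ("x", "y", "z")

#: If True (default), a scenario describes the PATIENT's displacement and the
#: dose seen by the fixed structures is the original field *pulled back*
#: through the patient map: out(x) = D(T_patient(x)).  Set False to flip the
#: convention (dose cloud moves with the scenario instead).
PATIENT_MOVES = True

#: Fraction of resampled voxels allowed to fall outside the source lattice
#: before a warning is logged.
_EXTRAPOLATION_WARN_FRACTION = 1e-3


class GridError(ValueError):
    """Invalid dose-grid construction or use."""


@dataclass(frozen=True)
class DoseGrid:
    """A 3D absorbed-dose field on a regular lattice.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Absorbed dose in Gy; finite and non-negative.
    spacing : array-like of 3 floats
        Voxel pitch per axis in mm, strictly positive.
    origin : array-like of 3 floats
        Patient-space coordinate (mm) of the *center* of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if values.ndim != 3:
            raise GridError(f"dose values must be 3D, got ndim={values.ndim}")
        if any(n < 2 for n in values.shape):
            raise GridError(f"grid needs >= 2 voxels per axis, got {values.shape}")
        if not np.all(np.isfinite(values)):
            raise GridError("dose values contain non-finite entries")
        if np.any(values < 0):
            raise GridError("dose values contain negative entries")
        if not np.all(np.isfinite(spacing)) or np.any(spacing <= 0):
            raise GridError(f"spacing must be positive and finite, got {spacing}")
        if not np.all(np.isfinite(origin)):
            raise GridError("origin must be finite")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Voxel-center bounding box (lower, upper) in mm."""
        upper = self.origin + (np.array(self.shape) - 1) * self.spacing
        return self.origin.copy(), upper

    def contains_point(self, point) -> bool:
        lo, hi = self.bounds()
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= lo - 1e-9) and np.all(p <= hi + 1e-9))

    def same_lattice(self, other: "DoseGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def point_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map patient coordinates (mm) to fractional voxel indices."""
        return (np.atleast_2d(points) - self.origin) / self.spacing

    def index_to_point(self, indices: np.ndarray) -> np.ndarray:
        return self.origin + np.atleast_2d(indices) * self.spacing

    def replace_values(self, values: np.ndarray) -> "DoseGrid":
        return DoseGrid(values, self.spacing.copy(), self.origin.copy())


@dataclass(frozen=True)
class RigidTransform:
    """A rigid map of patient space: rotation about ``center`` then translation.

    Angles are (pitch, roll, yaw) in degrees about the (x, y, z) axes, applied
    in the fixed intrinsic order yaw -> pitch -> roll.  The full map is
    ``p -> R (p - center) + center + translation``.
    """

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    angles: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        for name in ("translation", "angles", "center"):
            v = np.asarray(getattr(self, name), dtype=np.float64).reshape(3)
            if not np.all(np.isfinite(v)):
                raise GridError(f"{name} must be finite, got {v}")
            object.__setattr__(self, name, v)

    @property
    def is_identity(self) -> bool:
        return bool(
            np.all(self.translation == 0.0) and np.all(self.angles == 0.0)
        )


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    """Right-handed rotation matrix, intrinsic yaw(z) -> pitch(x) -> roll(y)."""
    pitch, roll, yaw = np.deg2rad(angles_deg)

    def rot(axis: int, a: float) -> np.ndarray:
        c, s = np.cos(a), np.sin(a)
        m = np.eye(3)
        i, j = [k for k in range(3) if k != axis]
        m[i, i] = c
        m[j, j] = c
        m[i, j] = -s if (j - i) % 3 == 1 else s
        m[j, i] = -m[i, j]
        return m

    # intrinsic composition: successive rotations right-multiply
    return rot(2, yaw) @ rot(0, pitch) @ rot(1, roll)


def compose_matrix(transform: RigidTransform) -> np.ndarray:
    """4x4 homogeneous matrix of a rigid transform in patient coordinates.

    Rotation acts about ``transform.center``; translation is applied after
    the rotation.  The rotation block is orthonormal with determinant +1.
    """
    r = _rotation_matrix(transform.angles)
    m = np.eye(4)
    m[:3, :3] = r
    m[:3, 3] = transform.center + transform.translation - r @ transform.center
    return m


def invert_matrix(matrix: np.ndarray) -> np.ndarray:
    """Exact inverse of a rigid homogeneous matrix (transpose of R block)."""
    r = matrix[:3, :3]
    inv = np.eye(4)
    inv[:3, :3] = r.T
    inv[:3, 3] = -r.T @ matrix[:3, 3]
    return inv


@dataclass(frozen=True)
class ErrorScenario:
    """One hypothetical setup error.

    ``kind`` is ``"translation"`` (magnitude in mm) or ``"rotation"``
    (magnitude in degrees).  By default the magnitude is applied
    simultaneously to all three axes, mirroring a worst-case simultaneous
    setup deviation; ``applied_axes`` restricts it to a subset.
    """

    kind: str
    magnitude: float
    applied_axes: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self) -> None:
        if self.kind not in ("translation", "rotation"):
            raise GridError(f"unknown scenario kind {self.kind!r}")
        if not np.isfinite(self.magnitude) or self.magnitude < 0:
            raise GridError(f"magnitude must be >= 0, got {self.magnitude}")
        axes = tuple(sorted(set(int(a) for a in self.applied_axes)))
        if not axes or any(a not in (0, 1, 2) for a in axes):
            raise GridError(f"applied_axes must be a subset of (0,1,2), got {axes}")
        object.__setattr__(self, "applied_axes", axes)

    @property
    def label(self) -> str:
        unit = "mm" if self.kind == "translation" else "deg"
        return f"{self.kind}+{self.magnitude:g}{unit}"

    def to_transform(self, isocenter) -> RigidTransform:
        """Rigid transform of the patient for this scenario."""
        vec = np.zeros(3)
        for a in self.applied_axes:
            vec[a] = self.magnitude
        if self.kind == "translation":
            return RigidTransform(translation=vec, center=np.asarray(isocenter))
        return RigidTransform(angles=vec, center=np.asarray(isocenter))


def trilinear_sample(
    grid: DoseGrid, points, outside_policy: str = "zero"
) -> np.ndarray:
    """Trilinear interpolation of the dose field at patient coordinates.

    ``outside_policy``: ``"zero"`` returns 0 Gy outside the voxel-center
    bounding box; ``"mark-invalid"`` returns NaN there instead.
    """
    if outside_policy not in ("zero", "mark-invalid"):
        raise GridError(f"unknown outside_policy {outside_policy!r}")
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if not np.all(np.isfinite(pts)):
        raise GridError("sample points must be finite")
    idx = grid.point_to_index(pts)
    out = ndimage.map_coordinates(
        grid.values, idx.T, order=1, mode="constant", cval=0.0
    )
    if outside_policy == "mark-invalid":
        hi = np.array(grid.shape) - 1
        invalid = np.any((idx < -1e-12) | (idx > hi + 1e-12), axis=1)
        out = out.astype(float)
        out[invalid] = np.nan
    return out


def resample_through(
    dose: DoseGrid, matrix: np.ndarray, within: np.ndarray | None = None
) -> DoseGrid:
    """Re-sample a dose field through a rigid map: out(x) = D(M x).

    The output lattice is identical to the input's.  Samples falling outside
    the source voxel-center box are set to 0 Gy; if more than 0.1% of the
    voxels of interest (the ``within`` mask when given, e.g. the brain,
    otherwise the whole grid) are extrapolated this way, a warning is
    logged.
    """
    idx = np.indices(dose.shape, dtype=np.float64).reshape(3, -1)
    pts = dose.origin[:, None] + idx * dose.spacing[:, None]
    src = matrix[:3, :3] @ pts + matrix[:3, 3:4]
    src_idx = (src - dose.origin[:, None]) / dose.spacing[:, None]
    hi = (np.array(dose.shape, dtype=float) - 1)[:, None]
    outside = np.any((src_idx < 0) | (src_idx > hi), axis=0)
    if within is not None:
        outside = outside & np.asarray(within, dtype=bool).reshape(-1)
        denom = max(1, int(np.count_nonzero(within)))
    else:
        denom = outside.size
    frac_outside = float(np.count_nonzero(outside)) / denom
    if frac_outside > _EXTRAPOLATION_WARN_FRACTION:
        log.warning(
            "resample: %.2f%% of voxels of interest sampled outside the "
            "dose grid (set to 0 Gy)", 100 * frac_outside,
        )
    vals = ndimage.map_coordinates(
        dose.values, src_idx, order=1, mode="constant", cval=0.0
    )
    vals = np.clip(vals, 0.0, None)  # guard tiny negative round-off
    return dose.replace_values(vals.reshape(dose.shape))


def apply_setup_error(
    dose: DoseGrid,
    scenario: ErrorScenario,
    isocenter,
    patient_moves: bool | None = None,
    within: np.ndarray | None = None,
) -> DoseGrid:
    """Dose delivered to fixed structures after a rigid setup error.

    With the default convention (:data:`PATIENT_MOVES`), the scenario
    describes the patient's displacement ``T`` about the isocenter and the
    returned grid is the original field pulled back through it,
    ``out(x) = D(T x)``.  A zero-magnitude scenario returns a bit-for-bit
    copy of the input.
    """
    iso = np.asarray(isocenter, dtype=float).reshape(3)
    if not dose.contains_point(iso):
        raise GridError(f"isocenter {iso} lies outside the dose grid")
    if scenario.magnitude == 0:
        return dose.replace_values(dose.values.copy())
    if patient_moves is None:
        patient_moves = PATIENT_MOVES
    m = compose_matrix(scenario.to_transform(iso))
    if not patient_moves:
        m = invert_matrix(m)
    return resample_through(dose, m, within=within)
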