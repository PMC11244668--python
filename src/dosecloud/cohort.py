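"""Synthetic virtual-patient cohort with analytic dose distributions.

Real multi-metastasis treatment plans (CT, contours, TPS dose) are not
portable, so this module generates virtual patients whose geometry and dose
statistics carry the structure the robustness analysis needs: several
spherical gross tumor volumes (GTVs) scattered inside an ellipsoidal brain,
a single isocenter at the mean of the GTV centroids, an isotropic GTV->PTV
margin, geometric organs at risk, and an analytic dose kernel per target
with a tunable penumbra steepness.

Two planning "techniques" are emulated purely through the penumbra:
couch-rotated (non-coplanar) arc geometries achieve steeper dose fall-off
than coplanar ones, so the non-coplanar-like technique gets a narrower
penumbra and hence a lower gradient index.  No arc, MLC or fluence modelling
is attempted.

The per-target kernel is prescription dose inside the PTV sphere with a
radial Gaussian-tail penumbra reaching 50% of the prescription at
``penumbra_width`` mm beyond the PTV surface; targets combine by voxelwise
maximum, and a brain-wide Gaussian low-dose bath (scatter surrogate) is
added so whole-brain V4/V12 are nonzero.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .grid import DoseGrid, GridError
from .metrics import StructureMask, normalize_plan

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d2 = np.sum((pts - np.asarray(self.center)) ** 2, axis=-1)
        return d2 <= self.radius**2

    @property
    def volume_mm3(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius**3


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def contains(self, pts: np.ndarray) -> np.ndarray:
        u = (pts - np.asarray(self.center)) / np.asarray(self.semi_axes)
        return np.sum(u**2, axis=-1) <= 1.0

    def contains_sphere(self, s: Sphere, clearance: float = 0.0) -> bool:
        # conservative test: shrink every semi-axis by radius + clearance
        shrink = np.asarray(self.semi_axes) - (s.radius + clearance)
        if np.any(shrink <= 0):
            return False
        u = (np.asarray(s.center) - np.asarray(self.center)) / shrink
        return bool(np.sum(u**2) <= 1.0)


@dataclass(frozen=True)
class Capsule:
    """All points within ``radius`` of the segment from ``a`` to ``b``."""

    a: tuple[float, float, float]
    b: tuple[float, float, float]
    radius: float

    def contains(self, pts: np.ndarray) -> np.ndarray:
        a = np.asarray(self.a, dtype=float)
        ab = np.asarray(self.b, dtype=float) - a
        denom = float(ab @ ab)
        t = np.clip((pts - a) @ ab / denom, 0.0, 1.0) if denom > 0 else 0.0
        closest = a + np.multiply.outer(t, ab)
        return np.sum((pts - closest) ** 2, axis=-1) <= self.radius**2


Shape = Sphere | Ellipsoid | Capsule


# ---------------------------------------------------------------------------
# configuration and patient model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Distributional knobs of the virtual cohort (all lengths in mm)."""

    brain_semi_axes: tuple[float, float, float] = (70.0, 85.0, 60.0)
    gtv_count_range: tuple[int, int] = (1, 6)
    gtv_radius_range: tuple[float, float] = (5.0, 15.0)
    margin_mm: float = 2.0
    min_surface_separation: float = 5.0
    brain_clearance: float = 3.0          # PTV-to-brain-surface clearance
    rx_few: tuple[float, int] = (40.0, 5)  # <= rx_cutoff GTVs
    rx_many: tuple[float, int] = (42.0, 7)
    rx_cutoff: int = 3
    max_attempts: int = 2000

    def to_dict(self) -> dict:
        return {
            "brain_semi_axes": list(self.brain_semi_axes),
            "gtv_count_range": list(self.gtv_count_range),
            "gtv_radius_range": list(self.gtv_radius_range),
            "margin_mm": self.margin_mm,
            "min_surface_separation": self.min_surface_separation,
            "brain_clearance": self.brain_clearance,
            "rx_few": list(self.rx_few),
            "rx_many": list(self.rx_many),
            "rx_cutoff": self.rx_cutoff,
            "max_attempts": self.max_attempts,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        kw = {}
        for key, value in d.items():
            if key in ("brain_semi_axes", "gtv_count_range", "gtv_radius_range",
                       "rx_few", "rx_many"):
                kw[key] = tuple(value)
            else:
                kw[key] = value
        return cls(**kw)


@dataclass(frozen=True)
class VirtualPatient:
    """Geometry + prescription of one synthetic case."""

    patient_id: str
    brain: Ellipsoid
    gtvs: tuple[Sphere, ...]
    oars: dict[str, Shape]
    prescription: tuple[float, int]  # (total dose Gy, fractions)
    isocenter: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not 1 <= len(self.gtvs) <= 10:
            raise GridError(f"patient needs 1..10 GTVs, got {len(self.gtvs)}")
        centroid = np.mean([g.center for g in self.gtvs], axis=0)
        if not np.allclose(centroid, self.isocenter, atol=1e-6):
            raise GridError(
                f"isocenter {self.isocenter} is not the GTV centroid mean {centroid}"
            )
        for g in self.gtvs:
            if not self.brain.contains_sphere(g):
                raise GridError(f"GTV at {g.center} not strictly inside the brain")

    @property
    def rx(self) -> float:
        return self.prescription[0]


def expand_margin(gtv: Sphere, margin: float) -> Sphere:
    """Isotropic GTV -> PTV expansion: same center, radius + margin."""
    if margin < 0:
        raise GridError(f"margin must be >= 0, got {margin}")
    return Sphere(gtv.center, gtv.radius + margin)


def default_oars(brain: Ellipsoid) -> dict[str, Shape]:
    """Anatomically plausible geometric OARs, fixed relative to the brain.

    y is anterior-negative; z is inferior-negative.  Eyes and lenses sit
    anterior-inferior (partly outside the brain ellipsoid, as in anatomy);
    the optic pathway runs as two thin capsules from the eyes to the chiasm.
    """
    cx, cy, cz = brain.center
    ax, ay, az = brain.semi_axes
    eye_y = cy - ay * 0.92
    eye_z = cz - az * 0.45
    eyes = {
        "eye_l": Sphere((cx - ax * 0.40, eye_y, eye_z), 12.0),
        "eye_r": Sphere((cx + ax * 0.40, eye_y, eye_z), 12.0),
    }
    chiasm = Sphere((cx, cy - ay * 0.25, cz - az * 0.30), 5.0)
    nerves = tuple(
        Capsule(
            (eye.center[0], eye.center[1] + eye.radius, eye_z),
            chiasm.center,
            2.5,
        )
        for eye in eyes.values()
    )
    return {
        **eyes,
        "lens_l": Sphere((cx - ax * 0.40, eye_y - 9.0, eye_z), 2.5),
        "lens_r": Sphere((cx + ax * 0.40, eye_y - 9.0, eye_z), 2.5),
        "chiasm": chiasm,
        "brainstem": Capsule(
            (cx, cy - ay * 0.10, cz - az * 0.95),
            (cx, cy - ay * 0.10, cz - az * 0.25),
            10.0,
        ),
        "optic_pathway": _ShapeUnion(nerves),
    }


@dataclass(frozen=True)
class _ShapeUnion:
    parts: tuple[Shape, ...]

    def contains(self, pts: np.ndarray) -> np.ndarray:
        out = self.parts[0].contains(pts)
        for p in self.parts[1:]:
            out = out | p.contains(pts)
        return out


def generate_cohort(
    n_patients: int, seed: int, config: CohortConfig | None = None
) -> list[VirtualPatient]:
    """Draw a reproducible cohort of virtual patients.

    GTV count is uniform on ``gtv_count_range``, radii uniform on
    ``gtv_radius_range``; centers are rejection-sampled so each PTV clears
    the brain surface and GTV surfaces are mutually separated.  The isocenter
    is the mean of the GTV centroids.  Deterministic given (seed, config).
    """
    if n_patients < 1:
        raise GridError(f"n_patients must be >= 1, got {n_patients}")
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    brain = Ellipsoid((0.0, 0.0, 0.0), cfg.brain_semi_axes)
    oars = default_oars(brain)
    patients = []
    for i in range(n_patients):
        k = int(rng.integers(cfg.gtv_count_range[0], cfg.gtv_count_range[1] + 1))
        gtvs = _place_gtvs(rng, brain, k, cfg)
        rx = cfg.rx_few if len(gtvs) <= cfg.rx_cutoff else cfg.rx_many
        iso = tuple(np.mean([g.center for g in gtvs], axis=0))
        patients.append(
            VirtualPatient(
                patient_id=f"vp{i + 1:03d}",
                brain=brain,
                gtvs=tuple(gtvs),
                oars=oars,
                prescription=rx,
                isocenter=iso,
            )
        )
    return patients


def _place_gtvs(
    rng: np.random.Generator, brain: Ellipsoid, k: int, cfg: CohortConfig
) -> list[Sphere]:
    gtvs: list[Sphere] = []
    attempts = 0
    lo, hi = cfg.gtv_radius_range
    semi = np.asarray(brain.semi_axes)
    while len(gtvs) < k:
        if attempts >= cfg.max_attempts:
            raise GridError(
                f"could not place {k} GTVs after {cfg.max_attempts} attempts: "
                f"the surface-separation constraint "
                f"({cfg.min_surface_separation} mm) is infeasible"
            )
        attempts += 1
        r = float(rng.uniform(lo, hi))
        # sample inside the unit ball, stretch to the feasible ellipsoid
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        rad = rng.uniform() ** (1.0 / 3.0)
        shrink = semi - (r + cfg.margin_mm + cfg.brain_clearance)
        if np.any(shrink <= 0):
            continue
        center = np.asarray(brain.center) + u * rad * shrink
        cand = Sphere(tuple(center), r)
        sep = cfg.min_surface_separation
        ok = all(
            np.linalg.norm(np.asarray(cand.center) - np.asarray(g.center))
            >= cand.radius + g.radius + sep
            for g in gtvs
        )
        if ok:
            gtvs.append(cand)
    return gtvs


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Lattice definition: spacing (mm), origin (mm), shape (voxels)."""

    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    shape: tuple[int, int, int]

    @classmethod
    def covering(
        cls,
        patient: VirtualPatient,
        spacing: float = 2.0,
        padding: float = 5.0,
    ) -> "GridSpec":
        """Lattice covering the brain and every OAR with ``padding`` mm."""
        lo = np.full(3, np.inf)
        hi = np.full(3, -np.inf)

        def grow(center, extent) -> None:
            nonlocal lo, hi
            c = np.asarray(center, dtype=float)
            e = np.asarray(extent, dtype=float)
            lo = np.minimum(lo, c - e)
            hi = np.maximum(hi, c + e)

        grow(patient.brain.center, patient.brain.semi_axes)
        for shape in patient.oars.values():
            for part in getattr(shape, "parts", (shape,)):
                if isinstance(part, Sphere):
                    grow(part.center, part.radius)
                elif isinstance(part, Capsule):
                    grow(part.a, part.radius)
                    grow(part.b, part.radius)
        lo -= padding
        hi += padding
        n = np.ceil((hi - lo) / spacing).astype(int) + 1
        return cls(
            spacing=(spacing,) * 3,
            origin=tuple(lo),
            shape=tuple(int(v) for v in n),
        )

    def voxel_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-center coordinates in mm."""
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def to_dict(self) -> dict:
        return {
            "spacing": list(self.spacing),
            "origin": list(self.origin),
            "shape": list(self.shape),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(
            spacing=tuple(d["spacing"]),
            origin=tuple(d["origin"]),
            shape=tuple(int(v) for v in d["shape"]),
        )


def rasterize(
    patient: VirtualPatient,
    grid_spec: GridSpec,
    margin: float = 2.0,
    rois: list[str] | None = None,
) -> dict[str, StructureMask]:
    """Voxel-center-in-shape masks for brain, GTVs, PTV and OARs.

    The PTV is the union of all margin-expanded GTVs.  ``rois`` restricts the
    output (e.g. ``["brain", "ptv"]``); GTV masks are named ``gtv_01`` ...
    """
    pts = grid_spec.voxel_centers()
    spacing = np.asarray(grid_spec.spacing)
    shapes: dict[str, object] = {"brain": patient.brain}
    ptv_parts = []
    for i, g in enumerate(patient.gtvs, start=1):
        shapes[f"gtv_{i:02d}"] = g
        ptv_parts.append(expand_margin(g, margin))
    shapes["ptv"] = _ShapeUnion(tuple(ptv_parts))
    shapes.update(patient.oars)
    if rois is not None:
        shapes = {k: v for k, v in shapes.items() if k in rois}
    masks: dict[str, StructureMask] = {}
    for name, shape in shapes.items():
        vox = shape.contains(pts)
        if name == "brain" and (
            vox[0].any() or vox[-1].any()
            or vox[:, 0].any() or vox[:, -1].any()
            or vox[:, :, 0].any() or vox[:, :, -1].any()
        ):
            raise GridError("grid does not cover the brain ellipsoid")
        if not vox.any():
            log.warning("ROI %r rasterizes to an empty mask on this grid", name)
        masks[name] = StructureMask(name=name, voxels=vox, spacing=spacing)
    return masks


# ---------------------------------------------------------------------------
# dose synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlanTechnique:
    """Penumbra regime emulating an arc geometry class.

    ``penumbra_width`` is the distance (mm) from the PTV surface to the 50%
    isodose; ``bath_level`` is the low-dose bath amplitude at the isocenter
    as a fraction of the prescription.
    """

    label: str
    penumbra_width: float
    bath_level: float
    bath_sigma: float = 60.0  # mm, Gaussian decay length of the bath
    hotspot: float = 0.15     # central dose excess as a fraction of Rx

    def __post_init__(self) -> None:
        if self.penumbra_width <= 0:
            raise GridError("penumbra_width must be positive")
        if not 0 <= self.bath_level < 0.5:
            raise GridError("bath_level must be in [0, 0.5)")
        if not 0 <= self.hotspot < 1:
            raise GridError("hotspot must be in [0, 1)")


#: Default techniques.  The non-coplanar-like regime has the narrower
#: penumbra (steeper gradient, lower GI) and a slightly lighter bath.
COPLANAR = PlanTechnique(label="coplanar", penumbra_width=6.0, bath_level=0.12)
NONCOPLANAR = PlanTechnique(label="noncoplanar", penumbra_width=4.5, bath_level=0.10)

TECHNIQUES = {"coplanar": COPLANAR, "noncoplanar": NONCOPLANAR}

_LN2 = math.log(2.0)


def synth_dose(
    patient: VirtualPatient,
    technique: PlanTechnique,
    grid_spec: GridSpec,
    margin: float = 2.0,
) -> DoseGrid:
    """Analytic pre-normalization dose field for a virtual patient.

    Per target, radially from the GTV center: a flat hot center at
    ``Rx * (1 + hotspot)`` inside the GTV, a linear ramp down to exactly Rx
    at the PTV surface, then a Gaussian-tail penumbra
    ``Rx * exp(-ln2 ((r - R) / w)^2)`` whose 50% point lies ``w`` beyond the
    PTV surface.  The hot center mirrors real stereotactic plans (maximum
    dose well above prescription at the lesion center) and keeps the 5% of
    the PTV left uncovered by the 95% normalization in the margin rim rather
    than inside a GTV.  Targets combine by voxelwise maximum; a brain-wide
    Gaussian bath centered at the isocenter is added on top.
    """
    pts = grid_spec.voxel_centers()
    rx = patient.rx
    kernel = np.zeros(pts.shape[:3])
    w = technique.penumbra_width
    for g in patient.gtvs:
        ptv = expand_margin(g, margin)
        r = np.sqrt(np.sum((pts - np.asarray(ptv.center)) ** 2, axis=-1))
        excess = np.clip(r - ptv.radius, 0.0, None)
        target = np.exp(-_LN2 * (excess / w) ** 2)
        if technique.hotspot > 0 and margin > 0:
            ramp = np.clip((ptv.radius - r) / margin, 0.0, 1.0)
            target += technique.hotspot * ramp * (r <= ptv.radius)
        elif technique.hotspot > 0:
            target += technique.hotspot * (r <= g.radius)
        np.maximum(kernel, target, out=kernel)
    if technique.bath_level > 0:
        d2 = np.sum((pts - np.asarray(patient.isocenter)) ** 2, axis=-1)
        kernel = kernel + technique.bath_level * np.exp(
            -d2 / (2.0 * technique.bath_sigma**2)
        )
    return DoseGrid(
        values=rx * kernel,
        spacing=np.asarray(grid_spec.spacing),
        origin=np.asarray(grid_spec.origin),
    )


# ---------------------------------------------------------------------------
# plan bundles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlanBundle:
    """One analysable unit: patient + technique + normalized dose + masks."""

    patient: VirtualPatient
    technique: PlanTechnique
    dose: DoseGrid
    masks: dict[str, StructureMask]
    grid_spec: GridSpec
    seed: int | None = None

    @property
    def rx(self) -> float:
        return self.patient.rx

    @property
    def plan_id(self) -> str:
        return f"{self.patient.patient_id}-{self.technique.label}"


def build_plan(
    patient: VirtualPatient,
    technique: PlanTechnique,
    spacing: float = 2.0,
    margin: float = 2.0,
    seed: int | None = None,
) -> PlanBundle:
    """Rasterize, synthesize and normalize one plan bundle."""
    spec = GridSpec.covering(patient, spacing=spacing)
    masks = rasterize(patient, spec, margin=margin)
    raw = synth_dose(patient, technique, spec, margin=margin)
    dose = normalize_plan(raw, masks["ptv"], patient.rx)
    return PlanBundle(
        patient=patient,
        technique=technique,
        dose=dose,
        masks=masks,
        grid_spec=spec,
        seed=seed,
    )
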