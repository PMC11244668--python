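"""Plan-quality metrics: DVH statistics, normalization, Paddick CI and GI.

Conventions, written out because coverage contracts depend on them:

* All volumes are voxel counts times the voxel volume; no partial-volume or
  surface estimation.  At 2 mm spacing this limits volume accuracy for the
  smallest targets; geometry-sensitive checks use a 1 mm lattice.
* ``Vx`` counts voxels with dose >= the threshold (inclusive).
* ``D95`` (dose received by 95% of the structure volume) is the 5th
  percentile of the voxel doses with linear interpolation between sorted
  values (``numpy.percentile`` linear rule).
* ``Dmax`` is the voxel-point maximum, not a D0.03cc near-max; this is the
  conservative choice.
* Plan normalization rescales so that 95% of the PTV receives the
  prescription.  The scale factor uses the exact discrete quantile (the
  round(0.95 n)-th highest voxel dose) rather than the interpolated D95, so
  the post-normalization V100%(PTV) = 95% contract holds to within half a
  voxel-count step by construction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import DoseGrid, GridError


class UndefinedMetricError(ValueError):
    """A metric was requested on an empty structure or degenerate input."""


@dataclass(frozen=True)
class StructureMask:
    """A binary region of interest on a dose-grid lattice."""

    name: str
    voxels: np.ndarray  # bool, same shape as the dose grid
    spacing: np.ndarray  # mm, inherited from the grid

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=bool)
        spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        if vox.ndim != 3:
            raise GridError(f"mask {self.name!r} must be 3D")
        if np.any(spacing <= 0):
            raise GridError(f"mask {self.name!r} spacing must be positive")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", spacing)

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_cc(self) -> float:
        return self.voxel_count * float(np.prod(self.spacing)) / 1000.0

    def doses(self, dose: DoseGrid) -> np.ndarray:
        if dose.shape != self.voxels.shape:
            raise GridError(
                f"mask {self.name!r} shape {self.voxels.shape} does not match "
                f"dose grid {dose.shape}"
            )
        return dose.values[self.voxels]


def v_dose(dose: DoseGrid, mask: StructureMask, threshold: float) -> float:
    """Percent of the structure volume receiving >= ``threshold`` Gy."""
    d = mask.doses(dose)
    if d.size == 0:
        raise UndefinedMetricError(f"V{threshold:g}Gy undefined: mask {mask.name!r} is empty")
    return 100.0 * float(np.count_nonzero(d >= threshold)) / d.size


def d_stats(dose: DoseGrid, mask: StructureMask) -> tuple[float, float, float]:
    """(Dmax, Dmean, D95) in Gy over the structure."""
    d = mask.doses(dose)
    if d.size == 0:
        raise UndefinedMetricError(f"dose statistics undefined: mask {mask.name!r} is empty")
    d95 = float(np.percentile(d, 5.0))  # dose received by 95% of the volume
    return float(d.max()), float(d.mean()), d95


def normalization_factor(dose: DoseGrid, ptv_mask: StructureMask, rx: float) -> float:
    """Scale making the prescription cover 95% of the PTV voxels.

    Uses the m-th highest PTV voxel dose with m = round(0.95 n), nudged by
    one ulp so the defining voxel stays on the covered side of the >=
    comparison after the floating-point rescale.
    """
    if rx <= 0:
        raise UndefinedMetricError(f"prescription must be positive, got {rx}")
    d = ptv_mask.doses(dose)
    if d.size == 0:
        raise UndefinedMetricError("normalization undefined: PTV mask is empty")
    m = min(d.size, max(1, int(round(0.95 * d.size))))
    ref = float(np.sort(d)[::-1][m - 1])
    if ref <= 0:
        raise UndefinedMetricError("normalization undefined: D95(PTV) is not positive")
    return rx / ref * (1.0 + 1e-12)


def normalize_plan(dose: DoseGrid, ptv_mask: StructureMask, rx: float) -> DoseGrid:
    """Rescale the dose so 95% of the PTV receives the prescription ``rx``."""
    return dose.replace_values(dose.values * normalization_factor(dose, ptv_mask, rx))


@dataclass(frozen=True)
class IsodoseVolumes:
    """Volumes (cm^3) entering the Paddick conformity and gradient indices."""

    tv: float       # target volume
    piv: float      # prescription isodose volume
    tv_piv: float   # their intersection
    pv50: float     # 50%-prescription isodose volume

    def __post_init__(self) -> None:
        if self.tv_piv > min(self.tv, self.piv) + 1e-9:
            raise UndefinedMetricError(
                f"intersection {self.tv_piv} exceeds min(TV, PIV) = "
                f"{min(self.tv, self.piv)}"
            )
        if self.pv50 + 1e-9 < self.piv:
            raise UndefinedMetricError(
                f"PV50 {self.pv50} smaller than PIV {self.piv}: isodose "
                "volumes must nest"
            )


def isodose_volumes(dose: DoseGrid, ptv_mask: StructureMask, rx: float) -> IsodoseVolumes:
    """Voxel-counted TV / PIV / TV∩PIV / PV50 for a normalized plan."""
    if ptv_mask.voxel_count == 0:
        raise UndefinedMetricError("isodose volumes undefined: PTV mask is empty")
    vcc = dose.voxel_volume_cc
    piv_vox = dose.values >= rx
    pv50_vox = dose.values >= 0.5 * rx
    return IsodoseVolumes(
        tv=ptv_mask.voxel_count * vcc,
        piv=float(np.count_nonzero(piv_vox)) * vcc,
        tv_piv=float(np.count_nonzero(piv_vox & ptv_mask.voxels)) * vcc,
        pv50=float(np.count_nonzero(pv50_vox)) * vcc,
    )


def paddick_ci(volumes: IsodoseVolumes) -> float:
    """Paddick conformity index, TV_PIV^2 / (TV * PIV); ideal coverage = 1."""
    if volumes.tv <= 0 or volumes.piv <= 0:
        raise UndefinedMetricError("CI undefined for zero TV or PIV")
    return volumes.tv_piv**2 / (volumes.tv * volumes.piv)


def paddick_gi(volumes: IsodoseVolumes) -> float:
    """Paddick gradient index, PV50% / PIV; smaller means a steeper fall-off."""
    if volumes.piv <= 0:
        raise UndefinedMetricError("GI undefined for zero PIV")
    return volumes.pv50 / volumes.piv


@dataclass(frozen=True)
class PlanMetrics:
    """The per-plan evaluation record."""

    ci: float
    gi: float
    v100_ptv: float                  # % of PTV at >= Rx
    v100_gtv: dict[str, float]       # % per GTV at >= Rx
    brain_v4: float                  # % of brain at >= 4 Gy
    brain_v12: float                 # % of brain at >= 12 Gy
    brain_v4_cc: float
    brain_v12_cc: float
    brain_mean: float                # Gy
    oar_dmax: dict[str, float]       # Gy per OAR
    d95_ptv: float                   # Gy

    def oar_record(self) -> dict[str, float]:
        """OAR-side metrics as a flat name -> value map (for deltas/tables)."""
        rec = {
            "brain_v4": self.brain_v4,
            "brain_v12": self.brain_v12,
            "brain_mean": self.brain_mean,
        }
        for name, dmax in sorted(self.oar_dmax.items()):
            rec[f"dmax_{name}"] = dmax
        return rec


#: ROI names treated as organs at risk when assembling metrics.
OAR_NAMES = (
    "brainstem",
    "eye_l",
    "eye_r",
    "lens_l",
    "lens_r",
    "optic_pathway",
    "chiasm",
)


def plan_metrics(
    dose: DoseGrid, masks: dict[str, StructureMask], rx: float
) -> PlanMetrics:
    """Assemble all plan-quality metrics for a (normalized) dose grid.

    ``masks`` must contain ``ptv`` and ``brain``; GTVs are the keys starting
    with ``gtv``; OARs are taken from :data:`OAR_NAMES` when present.
    """
    ptv = masks["ptv"]
    brain = masks["brain"]
    vols = isodose_volumes(dose, ptv, rx)
    dmax_b, dmean_b, _ = d_stats(dose, brain)
    _, _, d95_ptv = d_stats(dose, ptv)
    vcc = dose.voxel_volume_cc
    v4 = v_dose(dose, brain, 4.0)
    v12 = v_dose(dose, brain, 12.0)
    return PlanMetrics(
        ci=paddick_ci(vols),
        gi=paddick_gi(vols),
        v100_ptv=v_dose(dose, ptv, rx),
        v100_gtv={
            name: v_dose(dose, masks[name], rx)
            for name in sorted(masks)
            if name.startswith("gtv")
        },
        brain_v4=v4,
        brain_v12=v12,
        brain_v4_cc=v4 / 100.0 * brain.voxel_count * vcc,
        brain_v12_cc=v12 / 100.0 * brain.voxel_count * vcc,
        brain_mean=dmean_b,
        oar_dmax={
            name: d_stats(dose, masks[name])[0]
            for name in OAR_NAMES
            if name in masks and masks[name].voxel_count > 0
        },
        d95_ptv=d95_ptv,
    )
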