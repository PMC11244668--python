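"""Cohort robustness experiment: scenarios, metric deltas, statistics.

The experiment mirrors a paired design: for each virtual patient, one
coplanar-like and one non-coplanar-like plan are built on the same geometry;
four setup-error scenarios (+1 mm, +2 mm translation; +1 deg, +2 deg
rotation, each applied simultaneously on all three axes) are simulated with
the static dose cloud, target-coverage and OAR metrics are recomputed
against the fixed structures, and the variations (modified minus original)
are summarized per technique with a paired t-test across techniques.
Gamma analysis is run only for the largest translation and rotation by
default; the gamma pass rate serves as an additional robustness metric.

Target-level pooling: PTV metrics contribute one observation per patient;
per-GTV coverage is pooled across patients with each GTV as one observation
(deliberate pseudo-replication, matching common practice in multi-target
plan evaluation).  No multiple-testing correction is applied; p-values are
reported raw at the conventional 0.05 threshold.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    COPLANAR,
    NONCOPLANAR,
    CohortConfig,
    PlanBundle,
    build_plan,
    generate_cohort,
)
from .gamma import GammaParams, GammaResult, gamma_map
from .grid import DoseGrid, ErrorScenario, GridError, apply_setup_error
from .metrics import UndefinedMetricError, plan_metrics

log = logging.getLogger(__name__)


def default_scenarios() -> list[ErrorScenario]:
    """+1 / +2 mm translations and +1 / +2 deg rotations, all axes at once."""
    return [
        ErrorScenario("translation", 1.0),
        ErrorScenario("translation", 2.0),
        ErrorScenario("rotation", 1.0),
        ErrorScenario("rotation", 2.0),
    ]


def default_gamma_scenarios(scenarios: list[ErrorScenario]) -> set[str]:
    """Labels of the largest translation and largest rotation."""
    out = set()
    for kind in ("translation", "rotation"):
        of_kind = [s for s in scenarios if s.kind == kind and s.magnitude > 0]
        if of_kind:
            out.add(max(of_kind, key=lambda s: s.magnitude).label)
    return out


@dataclass(frozen=True)
class ScenarioResult:
    """Metric variations of one plan under one setup-error scenario."""

    patient_id: str
    technique: str
    scenario: ErrorScenario
    delta_v100_ptv: float                 # percentage points
    delta_v100_gtv: dict[str, float]      # pp per GTV
    oar_deltas: dict[str, float]          # native units (Gy or pp)
    gamma_pass: float | None = None       # %, only for flagged scenarios

    def __post_init__(self) -> None:
        vals = [self.delta_v100_ptv, *self.delta_v100_gtv.values(),
                *self.oar_deltas.values()]
        if not np.all(np.isfinite(vals)):
            raise GridError("scenario deltas must be finite")


def run_patient(
    bundle: PlanBundle,
    scenarios: list[ErrorScenario] | None = None,
    gamma_params: GammaParams | None = None,
    gamma_for: set[str] | None = None,
) -> list[ScenarioResult]:
    """Evaluate every scenario against one normalized plan bundle.

    Deltas are modified minus original against the *fixed* structure masks.
    ``gamma_for`` is the set of scenario labels to run gamma analysis on
    (default: the largest translation and rotation).  A failure in one
    scenario is logged and skips that scenario only.
    """
    scenarios = scenarios if scenarios is not None else default_scenarios()
    if gamma_for is None:
        gamma_for = default_gamma_scenarios(scenarios)
    gamma_params = gamma_params or GammaParams()
    original = plan_metrics(bundle.dose, bundle.masks, bundle.rx)
    iso = np.asarray(bundle.patient.isocenter)
    results: list[ScenarioResult] = []
    brain = bundle.masks.get("brain")
    for scenario in scenarios:
        try:
            moved = apply_setup_error(
                bundle.dose, scenario, iso,
                within=brain.voxels if brain is not None else None,
            )
            modified = plan_metrics(moved, bundle.masks, bundle.rx)
            gamma_pass = None
            if scenario.label in gamma_for:
                gamma_pass = gamma_map(bundle.dose, moved, gamma_params).pass_rate
            oar_deltas = {
                k: modified.oar_record()[k] - v
                for k, v in original.oar_record().items()
            }
            results.append(
                ScenarioResult(
                    patient_id=bundle.patient.patient_id,
                    technique=bundle.technique.label,
                    scenario=scenario,
                    delta_v100_ptv=modified.v100_ptv - original.v100_ptv,
                    delta_v100_gtv={
                        k: modified.v100_gtv[k] - v
                        for k, v in original.v100_gtv.items()
                    },
                    oar_deltas=oar_deltas,
                    gamma_pass=gamma_pass,
                )
            )
        except (GridError, UndefinedMetricError) as exc:
            log.error(
                "scenario %s failed for %s/%s: %s",
                scenario.label, bundle.patient.patient_id,
                bundle.technique.label, exc,
            )
    return results


def paired_t_test(x, y) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p).

    ``t = mean(d) / (sd(d) / sqrt(n))`` with the n-1 sample SD of the
    differences ``d = x - y``.  All-zero differences give (0, n-1, 1) by
    convention rather than a 0/0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise GridError("paired samples must be 1D and equal length")
    n = x.size
    if n < 2:
        raise GridError(f"paired t-test needs n >= 2, got n={n}")
    d = x - y
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        if np.all(d == 0):
            return 0.0, df, 1.0
        # constant nonzero difference: infinitely significant
        return float(np.sign(d.mean()) * np.inf), df, 0.0
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, df, p


def iqr_outliers(values) -> np.ndarray:
    """Tukey-fence outlier flags: outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation.  With fewer than 4 values no flags
    are raised (a warning is logged).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise GridError("iqr_outliers expects a 1D sample")
    if v.size < 4:
        log.warning("iqr_outliers: n=%d < 4, no outliers flagged", v.size)
        return np.zeros(v.size, dtype=bool)
    q1, q3 = np.percentile(v, [25.0, 75.0])
    iqr = q3 - q1
    return (v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)


@dataclass(frozen=True)
class CohortSummary:
    """Per (scenario, metric) cohort cells plus paired-technique tests.

    ``table`` columns: scenario, metric, level, n, mean/sd per technique,
    t, df, p, and outlier counts per technique.
    """

    table: pd.DataFrame
    techniques: tuple[str, str]

    def cell(self, scenario: str, metric: str) -> pd.Series:
        m = self.table[(self.table.scenario == scenario)
                       & (self.table.metric == metric)]
        if m.empty:
            raise KeyError(f"no summary cell for ({scenario}, {metric})")
        return m.iloc[0]


def _collect(results: list[ScenarioResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            dict(patient_id=r.patient_id, technique=r.technique,
                 scenario=r.scenario.label, metric="delta_v100_ptv",
                 level="ptv", key=r.patient_id, value=r.delta_v100_ptv)
        )
        for gtv, v in r.delta_v100_gtv.items():
            rows.append(
                dict(patient_id=r.patient_id, technique=r.technique,
                     scenario=r.scenario.label, metric="delta_v100_gtv",
                     level="gtv", key=f"{r.patient_id}/{gtv}", value=v)
            )
        for k, v in r.oar_deltas.items():
            rows.append(
                dict(patient_id=r.patient_id, technique=r.technique,
                     scenario=r.scenario.label, metric=f"delta_{k}",
                     level="oar", key=r.patient_id, value=v)
            )
        if r.gamma_pass is not None:
            rows.append(
                dict(patient_id=r.patient_id, technique=r.technique,
                     scenario=r.scenario.label, metric="gamma_pass",
                     level="gamma", key=r.patient_id, value=r.gamma_pass)
            )
    return pd.DataFrame(rows)


def summarize_cohort(results: list[ScenarioResult]) -> CohortSummary:
    """Mean +/- SD per technique and paired t-test across techniques.

    Every (scenario, metric) observation must be present for both techniques
    (paired design); unpaired observations are rejected.  GTV-level rows
    pool one observation per GTV across all patients.
    """
    long = _collect(results)
    if long.empty:
        raise GridError("no scenario results to summarize")
    techniques = tuple(sorted(long.technique.unique()))
    if len(techniques) != 2:
        raise GridError(
            f"paired summary needs exactly two techniques, got {techniques}"
        )
    a, b = techniques
    rows = []
    for (scenario, metric, level), grp in long.groupby(
        ["scenario", "metric", "level"], sort=True
    ):
        wide = grp.pivot_table(index="key", columns="technique",
                               values="value", aggfunc="first")
        if wide[[a, b]].isna().any().any():
            missing = wide.index[wide[[a, b]].isna().any(axis=1)].tolist()
            raise GridError(
                f"unpaired observations for ({scenario}, {metric}): {missing}"
            )
        xa = wide[a].to_numpy()
        xb = wide[b].to_numpy()
        t, df, p = paired_t_test(xa, xb)
        rows.append({
            "scenario": scenario, "metric": metric, "level": level,
            "n": int(xa.size),
            f"mean_{a}": xa.mean(), f"sd_{a}": xa.std(ddof=1) if xa.size > 1 else 0.0,
            f"mean_{b}": xb.mean(), f"sd_{b}": xb.std(ddof=1) if xb.size > 1 else 0.0,
            "t": t, "df": df, "p": p,
            f"outliers_{a}": int(iqr_outliers(xa).sum()),
            f"outliers_{b}": int(iqr_outliers(xb).sum()),
        })
    return CohortSummary(table=pd.DataFrame(rows), techniques=(a, b))


@dataclass(frozen=True)
class CohortRun:
    """Everything produced by one end-to-end cohort experiment."""

    bundles: list[PlanBundle]
    results: list[ScenarioResult]
    summary: CohortSummary
    plan_table: pd.DataFrame  # original-plan metrics per bundle


def plan_table(bundles: list[PlanBundle]) -> pd.DataFrame:
    """Original-plan quality metrics (CI, GI, coverage, OARs) per bundle."""
    rows = []
    for bundle in bundles:
        m = plan_metrics(bundle.dose, bundle.masks, bundle.rx)
        row = {
            "patient_id": bundle.patient.patient_id,
            "technique": bundle.technique.label,
            "rx": bundle.rx,
            "n_gtvs": len(bundle.patient.gtvs),
            "ci": m.ci, "gi": m.gi,
            "v100_ptv": m.v100_ptv,
            "brain_v4": m.brain_v4, "brain_v12": m.brain_v12,
            "brain_mean": m.brain_mean,
        }
        for k, v in sorted(m.oar_dmax.items()):
            row[f"dmax_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def run_cohort(
    n_patients: int = 15,
    seed: int = 0,
    config: CohortConfig | None = None,
    spacing: float = 2.0,
    scenarios: list[ErrorScenario] | None = None,
    gamma_params: GammaParams | None = None,
    gamma_for: set[str] | None = None,
    techniques=(COPLANAR, NONCOPLANAR),
) -> CohortRun:
    """Generate, plan, perturb and summarize a full two-technique cohort."""
    patients = generate_cohort(n_patients, seed=seed, config=config)
    bundles = [
        build_plan(p, tech, spacing=spacing, seed=seed)
        for p in patients
        for tech in techniques
    ]
    results: list[ScenarioResult] = []
    for bundle in bundles:
        results.extend(
            run_patient(bundle, scenarios=scenarios,
                        gamma_params=gamma_params, gamma_for=gamma_for)
        )
    return CohortRun(
        bundles=bundles,
        results=results,
        summary=summarize_cohort(results),
        plan_table=plan_table(bundles),
    )
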