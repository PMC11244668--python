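"""DVH statistics, plan normalization, and the Paddick indices."""
import numpy as np
import pytest

import dosecloud as dc
from dosecloud.metrics import UndefinedMetricError


def make_grid(values, spacing=2.0):
    values = np.asarray(values, dtype=float)
    return dc.DoseGrid(values, (spacing,) * 3, (0.0, 0.0, 0.0))


def make_mask(voxels, spacing=2.0, name="roi"):
    return dc.StructureMask(name=name, voxels=np.asarray(voxels, dtype=bool),
                            spacing=(spacing,) * 3)


def brute_force_v_dose(dose, mask, threshold):
    """Independent voxel-loop recount of Vx."""
    n = hit = 0
    for i in range(dose.shape[0]):
        for j in range(dose.shape[1]):
            for k in range(dose.shape[2]):
                if mask.voxels[i, j, k]:
                    n += 1
                    if dose.values[i, j, k] >= threshold:
                        hit += 1
    return 100.0 * hit / n


class TestVDose:
    def test_uniform_dose_at_threshold_gives_full_coverage(self):
        g = make_grid(np.full((4, 4, 4), 40.0))
        m = make_mask(np.ones((4, 4, 4)))
        assert dc.v_dose(g, m, 40.0) == 100.0

    def test_half_above_half_below(self):
        vals = np.full((4, 4, 4), 10.0)
        vals[:2] = 50.0
        g = make_grid(vals)
        m = make_mask(np.ones((4, 4, 4)))
        assert dc.v_dose(g, m, 40.0) == 50.0

    def test_matches_voxel_loop_recount(self):
        rng = np.random.default_rng(10)
        g = make_grid(rng.random((20, 20, 20)) * 50)
        m = make_mask(rng.random((20, 20, 20)) > 0.4)
        for thr in (5.0, 20.0, 45.0):
            assert dc.v_dose(g, m, thr) == brute_force_v_dose(g, m, thr)

    def test_monotone_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(11)
        g = make_grid(rng.random((10, 10, 10)) * 50)
        m = make_mask(np.ones((10, 10, 10)))
        vs = [dc.v_dose(g, m, t) for t in np.linspace(0, 55, 23)]
        assert all(a >= b for a, b in zip(vs, vs[1:]))

    def test_empty_mask_is_undefined_not_zero(self):
        g = make_grid(np.ones((4, 4, 4)))
        m = make_mask(np.zeros((4, 4, 4)))
        with pytest.raises(UndefinedMetricError):
            dc.v_dose(g, m, 1.0)


class TestDStats:
    def test_constant_field(self):
        g = make_grid(np.full((4, 4, 4), 7.5))
        m = make_mask(np.ones((4, 4, 4)))
        assert dc.d_stats(g, m) == (7.5, 7.5, 7.5)

    def test_d95_linear_interpolation_rule(self):
        # 20 voxels at 1..20 Gy: position 0.05*(20-1)=0.95 between the two
        # lowest -> D95 = 1 + 0.95*(2-1) = 1.95 Gy (hand computation)
        vals = np.zeros((20, 2, 2))
        vals[:, 0, 0] = np.arange(1, 21)
        g = dc.DoseGrid(vals, (1, 1, 1), (0, 0, 0))
        mask = np.zeros((20, 2, 2), dtype=bool)
        mask[:, 0, 0] = True
        m = make_mask(mask, spacing=1.0)
        dmax, dmean, d95 = dc.d_stats(g, m)
        assert (dmax, dmean) == (20.0, 10.5)
        assert d95 == pytest.approx(1.95, abs=1e-12)
        # cross-check against the reference percentile routine
        assert d95 == pytest.approx(np.percentile(np.arange(1, 21), 5))

    def test_shift_equivariance(self):
        rng = np.random.default_rng(12)
        vals = rng.random((6, 6, 6)) * 20
        m = make_mask(rng.random((6, 6, 6)) > 0.3)
        base = dc.d_stats(make_grid(vals), m)
        shifted = dc.d_stats(make_grid(vals + 1.0), m)
        assert np.allclose(np.array(shifted) - np.array(base), 1.0)


class TestNormalizePlan:
    def _plan(self, seed=13, n=16):
        rng = np.random.default_rng(seed)
        vals = rng.random((n, n, n)) * 30 + 10
        mask = np.zeros((n, n, n), dtype=bool)
        mask[4:12, 4:12, 4:12] = True
        return make_grid(vals), make_mask(mask, name="ptv")

    def test_coverage_contract_within_half_voxel_step(self):
        g, m = self._plan()
        out = dc.normalize_plan(g, m, 40.0)
        v100 = dc.v_dose(out, m, 40.0)
        assert abs(v100 - 95.0) <= 100.0 * 0.5 / m.voxel_count

    def test_idempotent_to_1e12(self):
        g, m = self._plan()
        once = dc.normalize_plan(g, m, 40.0)
        scale_again = dc.normalization_factor(once, m, 40.0)
        assert scale_again == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self):
        g, m = self._plan()
        halved = g.replace_values(g.values * 0.5)
        a = dc.normalize_plan(g, m, 40.0)
        b = dc.normalize_plan(halved, m, 40.0)
        assert np.allclose(a.values, b.values, rtol=1e-12)

    def test_zero_dose_rejected(self):
        g = make_grid(np.zeros((6, 6, 6)) + 1e-30)
        m = make_mask(np.ones((6, 6, 6)), name="ptv")
        g = g.replace_values(np.zeros((6, 6, 6)))
        with pytest.raises(UndefinedMetricError):
            dc.normalize_plan(g, m, 40.0)


class TestPaddickIndices:
    def test_perfect_conformity(self):
        v = dc.IsodoseVolumes(tv=12.0, piv=12.0, tv_piv=12.0, pv50=30.0)
        assert dc.paddick_ci(v) == 1.0

    def test_ci_formula_arithmetic(self):
        v = dc.IsodoseVolumes(tv=10.0, piv=10.0, tv_piv=8.0, pv50=20.0)
        assert dc.paddick_ci(v) == pytest.approx(0.64)

    def test_disjoint_volumes_give_zero_ci(self):
        v = dc.IsodoseVolumes(tv=10.0, piv=5.0, tv_piv=0.0, pv50=5.0)
        assert dc.paddick_ci(v) == 0.0

    def test_gi_degenerate_and_arithmetic(self):
        assert dc.paddick_gi(
            dc.IsodoseVolumes(tv=1, piv=10.0, tv_piv=1, pv50=10.0)
        ) == 1.0
        assert dc.paddick_gi(
            dc.IsodoseVolumes(tv=1, piv=10.0, tv_piv=1, pv50=50.0)
        ) == 5.0

    def test_nesting_violation_rejected(self):
        with pytest.raises(UndefinedMetricError):
            dc.IsodoseVolumes(tv=10, piv=10, tv_piv=11, pv50=10)
        with pytest.raises(UndefinedMetricError):
            dc.IsodoseVolumes(tv=10, piv=10, tv_piv=5, pv50=5)

    def test_ci_bounded_and_gi_at_least_one_on_random_plans(self):
        rng = np.random.default_rng(14)
        for _ in range(50):
            vals = rng.random((12, 12, 12)) * 50
            g = make_grid(vals)
            mask = rng.random((12, 12, 12)) > 0.5
            m = make_mask(mask, name="ptv")
            vols = dc.isodose_volumes(g, m, rx=30.0)
            assert 0.0 <= dc.paddick_ci(vols) <= 1.0
            assert dc.paddick_gi(vols) >= 1.0

    def test_gi_of_analytic_spherical_plan(self):
        # flat Rx inside R, linear falloff to 0.5 Rx at R+w:
        # PIV = sphere(R), PV50 = sphere(R+w) -> GI = ((R+w)/R)^3
        R, w, rx = 12.0, 6.0, 40.0
        n, h = 72, 1.0
        ax = (np.arange(n) - (n - 1) / 2) * h
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        r = np.sqrt(x**2 + y**2 + z**2)
        vals = np.where(r <= R, rx, rx * np.clip(1 - 0.5 * (r - R) / w, 0, None))
        g = dc.DoseGrid(vals, (h,) * 3, (ax[0],) * 3)
        m = make_mask(r <= R, spacing=h, name="ptv")
        gi = dc.paddick_gi(dc.isodose_volumes(g, m, rx))
        assert gi == pytest.approx(((R + w) / R) ** 3, rel=0.02)


def test_plan_metrics_assembles_consistent_record(single_patient_bundle):
    b = single_patient_bundle
    m = dc.plan_metrics(b.dose, b.masks, b.rx)
    assert abs(m.v100_ptv - 95.0) <= 100.0 * 0.5 / b.masks["ptv"].voxel_count
    assert 0.0 <= m.ci <= 1.0
    assert m.gi >= 1.0
    assert set(m.v100_gtv) == {k for k in b.masks if k.startswith("gtv")}
    assert set(m.oar_dmax) <= set(dc.metrics.OAR_NAMES)
    again = dc.plan_metrics(b.dose, b.masks, b.rx)
    assert again == m  # deterministic recomputation


def test_plan_metrics_matches_voxel_loop_oracle():
    """All assembled DVH quantities agree with a brute-force recount."""
    rng = np.random.default_rng(15)
    shape = (20, 20, 20)
    vals = rng.random(shape) * 50
    g = make_grid(vals)
    ptv = make_mask(rng.random(shape) > 0.7, name="ptv")
    brain = make_mask(np.ones(shape), name="brain")
    masks = {"ptv": ptv, "brain": brain,
             "gtv_01": make_mask(rng.random(shape) > 0.9, name="gtv_01")}
    rx = 35.0
    m = dc.plan_metrics(g, masks, rx)
    assert m.v100_ptv == brute_force_v_dose(g, ptv, rx)
    assert m.brain_v4 == brute_force_v_dose(g, brain, 4.0)
    assert m.brain_v12 == brute_force_v_dose(g, brain, 12.0)
    assert m.v100_gtv["gtv_01"] == brute_force_v_dose(g, masks["gtv_01"], rx)
    # isodose volumes recounted by hand
    vcc = g.voxel_volume_cc
    piv = (vals >= rx).sum() * vcc
    pv50 = (vals >= rx / 2).sum() * vcc
    tvpiv = ((vals >= rx) & ptv.voxels).sum() * vcc
    tv = ptv.voxel_count * vcc
    assert m.ci == pytest.approx(tvpiv**2 / (tv * piv), rel=1e-12)
    assert m.gi == pytest.approx(pv50 / piv, rel=1e-12)
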