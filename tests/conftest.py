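import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy import ndimage

import dosecloud as dc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


COHORT_SEED = 1  # the seeded default cohort used throughout the suite


@pytest.fixture(scope="session")
def default_cohort_run():
    """Full two-technique 15-patient experiment at the 2 mm grid.

    Expensive (a few minutes); session-scoped and shared by the pipeline
    invariants and the acceptance checks.
    """
    return dc.run_cohort(n_patients=15, seed=COHORT_SEED, spacing=2.0)


@pytest.fixture(scope="session")
def single_patient_bundle():
    """One multi-target patient planned with the coplanar-like technique."""
    patient = dc.generate_cohort(3, seed=COHORT_SEED)[0]
    return dc.build_plan(patient, dc.COPLANAR, spacing=2.0)


@pytest.fixture(scope="session")
def smooth_pair_16():
    """A smooth, plan-like (reference, evaluated) pair on a 16^3 lattice.

    The evaluated field is the reference shifted by ~1 mm with a 2% output
    rescale — the kind of disagreement a small setup error produces.
    """
    rng = np.random.default_rng(7)
    ref = ndimage.gaussian_filter(rng.random((16, 16, 16)), 4.0)
    ref = 50.0 * ref / ref.max()
    ev = ndimage.shift(ref, (0.5, 0.3, -0.4), order=1, mode="nearest") * 1.02
    spacing = (2.0, 2.0, 2.0)
    return (
        dc.DoseGrid(ref, spacing, (0.0, 0.0, 0.0)),
        dc.DoseGrid(np.clip(ev, 0.0, None), spacing, (0.0, 0.0, 0.0)),
    )


@pytest.fixture(scope="session")
def gamma_oracle_comparison(smooth_pair_16):
    """Fast gamma and the brute-force dense-search oracle on the same pair.

    The lower threshold is raised so the exhaustive oracle (quartic cost)
    stays tractable; both implementations see identical parameters.
    """
    ref, ev = smooth_pair_16
    params = dc.GammaParams(interp_step=0.4, lower_threshold=55.0)
    fast = dc.gamma_map(ref, ev, params)
    brute = dc.brute_force_gamma(ref, ev, params)
    return fast, brute


def gaussian_blob_grid(shape=(40, 40, 40), spacing=2.0, sigma=12.0, amp=40.0):
    """Compactly supported smooth dose field centered in the grid."""
    ax = [np.arange(n) * spacing for n in shape]
    x, y, z = np.meshgrid(*ax, indexing="ij")
    c = [(n - 1) * spacing / 2.0 for n in shape]
    r2 = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
    vals = amp * np.exp(-r2 / (2.0 * sigma**2))
    vals[vals < 1e-9] = 0.0
    return dc.DoseGrid(vals, (spacing,) * 3, (0.0, 0.0, 0.0))


@pytest.fixture
def gaussian_blob():
    return gaussian_blob_grid()
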