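import numpy as np
import pytest

import arrayqa as aq


@pytest.fixture(scope="session")
def grid():
    return aq.DetectorGrid()


@pytest.fixture(scope="session")
def cf_table_6mv():
    """CF table derived from a noiseless synthetic 6 MV calibration run."""
    model = aq.default_response_model("6MV")
    meas = aq.calibration_measurement("6MV", model)
    ref = aq.reference_at_detectors("6MV")
    return aq.derive_cf(meas, ref, "6MV")


@pytest.fixture(scope="session")
def cf_table_10mv():
    model = aq.default_response_model("10MV")
    meas = aq.calibration_measurement("10MV", model)
    ref = aq.reference_at_detectors("10MV")
    return aq.derive_cf(meas, ref, "10MV")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_plane(rng, n=20, spacing=3.0, lo=50.0, hi=100.0, smooth=True):
    """Random smooth-ish positive dose plane for gamma tests."""
    v = rng.uniform(lo, hi, size=(n, n))
    if smooth:
        # mild smoothing so dose gradients are finite but non-trivial
        k = np.array([0.25, 0.5, 0.25])
        v = np.apply_along_axis(lambda r: np.convolve(r, k, mode="same"), 0, v)
        v = np.apply_along_axis(lambda r: np.convolve(r, k, mode="same"), 1, v)
    return aq.DosePlane(values=np.abs(v), spacing=spacing, origin=(0.0, 0.0))


def brute_force_gamma(reference, evaluated, criteria):
    """Exhaustive pixel-centre gamma oracle: all-pairs search, no radius cap.

    Independent of the implementation's search strategy; used to pin the
    vectorised/sub-sampled path on small instances.
    """
    ref = reference.values
    ev = evaluated.values
    s = reference.spacing
    ny, nx = ref.shape
    ys, xs = np.mgrid[0:ny, 0:nx]
    pos = np.column_stack([ys.ravel() * s, xs.ravel() * s])
    evf = ev.ravel()
    ref_max = ref.max()
    mask = ref >= criteria.threshold / 100.0 * ref_max
    if criteria.normalization == "global_max":
        dd = criteria.dose_tol / 100.0 * ref_max
    gamma = np.full(ref.shape, np.nan)
    argmin_dist = np.full(ref.shape, np.nan)
    for iy in range(ny):
        for ix in range(nx):
            if not mask[iy, ix]:
                continue
            d2 = ((pos - np.array([iy * s, ix * s])) ** 2).sum(axis=1)
            g2 = (evf - ref[iy, ix]) ** 2 / dd**2 + d2 / criteria.dta**2
            k = int(np.argmin(g2))
            gamma[iy, ix] = np.sqrt(g2[k])
            argmin_dist[iy, ix] = np.sqrt(d2[k])
    return gamma, mask, argmin_dist
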