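"""Shared Monte Carlo fixtures.

The expensive white runs are session-scoped and sized for a desk-scale
budget; statistical quality is tracked via the effective sample size of
the weighted records (docs/methods.md gives the variance analysis behind
the sizes).  Round-trip fixtures share one band run between the LUT and
the measurement side (same white-MC family, the forward model's stated
contract); independent-seed runs exist separately for the estimator
cross-checks.
"""

import numpy as np
import pytest

import wmcfit as wf
from wmcfit.transport import scale_white_run

BASE_SEED = 20260922


@pytest.fixture(scope="session")
def tissue_band_run():
    """Wide-band white run at mus' = 2.3 (g=0.9, n=1.4), similarity-
    rescalable to every tissue mus' in [1.2, 2.3]."""
    probe = wf.ProbeGeometry()
    props = wf.OpticalProperties.from_musp(0.0, 2.3)
    k_max = 2.3 / 1.2
    band = ((probe.separation - probe.detector_radius) / k_max,
            probe.separation + probe.detector_radius)
    cfg = wf.SimConfig(n_detected_target=1_100_000, seed=BASE_SEED,
                       max_launch=10**9)
    return wf.run_white_mc(props, probe, cfg, band=band)


def _lut_from_band(band_run, musp_range, mua_range, g, n, musp_step=0.1):
    grid = wf.LUTGrid.reduced(musp_range, mua_range, musp_step=musp_step,
                              g=g, n=n)
    runs = {float(m): scale_white_run(band_run, float(m))
            for m in grid.musp_values}
    return wf.build_lut(runs, grid)


@pytest.fixture(scope="session")
def tissue_lut(tissue_band_run):
    """Reduced LUT bracketing the rat gray-matter example: mus' 1.2-2.2,
    mua 0.03-0.07."""
    return _lut_from_band(tissue_band_run, (1.2, 2.2), (0.03, 0.07),
                          g=0.9, n=1.4)


@pytest.fixture(scope="session")
def tissue_lut_high_mua(tissue_band_run):
    """Reduced LUT bracketing the monkey example: mus' 1.3-2.3,
    mua 0.06-0.10."""
    return _lut_from_band(tissue_band_run, (1.3, 2.3), (0.06, 0.10),
                          g=0.9, n=1.4)


@pytest.fixture(scope="session")
def fig3a_white(tissue_band_run):
    """Measurement-side white run at the rat example scattering
    (mus' = 1.70), from the same white-MC family as the LUT."""
    return scale_white_run(tissue_band_run, 1.70)


@pytest.fixture(scope="session")
def fig3b_white(tissue_band_run):
    """Measurement-side white run at the monkey example scattering
    (mus' = 1.8), same family as the LUT."""
    return scale_white_run(tissue_band_run, 1.8)


@pytest.fixture(scope="session")
def direct_17_run():
    """Direct annulus run at mus' = 1.7, independent seed — used for the
    similarity cross-check and the independent-noise round trip."""
    props = wf.OpticalProperties.from_musp(0.0, 1.7)
    cfg = wf.SimConfig(n_detected_target=40_000, seed=BASE_SEED + 1,
                       max_launch=10**9)
    return wf.run_white_mc(props, wf.ProbeGeometry(), cfg)


@pytest.fixture(scope="session")
def phantom_probe():
    return wf.ProbeGeometry(immersion_depth=0.5)


@pytest.fixture(scope="session")
def phantom_band_run(phantom_probe):
    """Wide-band immersed-fiber run at mus' = 2.8 (g=0.836, n=1.33)
    covering the phantom neighborhood 2.46-2.8."""
    props = wf.OpticalProperties.from_musp(0.0, 2.8, g=0.836, n=1.33)
    k_max = 2.8 / 2.46
    band = ((phantom_probe.separation - phantom_probe.detector_radius) / k_max,
            phantom_probe.separation + phantom_probe.detector_radius)
    cfg = wf.SimConfig(n_detected_target=250_000, seed=BASE_SEED + 3,
                       max_launch=10**9)
    return wf.run_white_mc(props, phantom_probe, cfg, band=band)


@pytest.fixture(scope="session")
def phantom_lut(phantom_band_run):
    """Phantom-neighborhood LUT: fine mus' step (0.02) because the
    phantom's true mus' sits between 0.1-step grid lines."""
    return _lut_from_band(phantom_band_run, (2.46, 2.66), (0.015, 0.035),
                          g=0.836, n=1.33, musp_step=0.02)


@pytest.fixture(scope="session")
def phantom_white(phantom_band_run):
    """Measurement-side white run at the phantom's tabulated scattering
    (mus = 15.6, g = 0.836 -> mus' = 2.5584), same family as the LUT."""
    return scale_white_run(phantom_band_run, 15.6 * (1.0 - 0.836))


@pytest.fixture(scope="session")
def gaussian_irf():
    return wf.synthesize_irf(3.44)


@pytest.fixture(scope="session")
def analog_ring_run():
    """Analog (unit-weight, probabilistic Fresnel) annulus run at
    mus' = 1.7 — reference oracle for the production estimator."""
    props = wf.OpticalProperties.from_musp(0.0, 1.7)
    cfg = wf.SimConfig(n_detected_target=1500, seed=BASE_SEED + 5,
                       ring_detector=False, max_launch=2 * 10**7)
    return wf.run_white_mc(props, wf.ProbeGeometry(), cfg, analog_ring=True)
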