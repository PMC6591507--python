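"""Synthetic IRFs, forward measurements and scenario presets.

This module emulates the measurement side of a femtosecond time-resolved
reflectance experiment so the full estimation chain can be exercised
without hardware: a Gaussian instrument response (optionally with a
falling-edge reflection hump, as seen with some streak-camera optics), a
forward model composing white-MC transport, Beer-Lambert absorption and
IRF convolution, plus tabulated scenario presets for a liquid phantom and
for rat/monkey gray and white matter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import IRF, CurveTrace, convolve_irf, _shifted
from .lut import rescale_to_mua, smooth_tpsf
from .model import OpticalProperties, ProbeGeometry, SimConfig, WhiteRunResult
from .transport import run_white_mc

__all__ = [
    "ScenarioPreset", "NoiseModel",
    "synthesize_irf", "impulse_irf", "forward_measurement", "preset",
]


@dataclass(frozen=True)
class ScenarioPreset:
    """Named measurement scenario with known ground-truth properties."""

    name: str
    props: OpticalProperties
    probe: ProbeGeometry
    expected_mua: float
    expected_musp: float


@dataclass(frozen=True)
class NoiseModel:
    """Detection-noise description for synthetic measurements.

    ``shot`` mode treats the curve as a photon-count histogram with
    ``scale`` total counts and draws Poisson variates per bin; ``gaussian``
    adds zero-mean noise with standard deviation ``scale`` relative to the
    peak.  Curves are clipped at zero and re-normalized afterwards.
    """

    mode: str = "none"
    scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "shot", "gaussian"):
            raise ValueError(f"unknown noise mode {self.mode!r}")
        if self.mode != "none" and self.scale <= 0:
            raise ValueError("noise scale must be > 0")


def synthesize_irf(fwhm: float, bin_width: float = 0.3125,
                   hump: tuple[float, float, float] | None = None) -> IRF:
    """Gaussian IRF of the requested FWHM sampled on the bin grid.

    ``hump``, if given, is ``(delay_ps, relative_amplitude, fwhm_ps)`` for
    a secondary Gaussian on the falling edge (amplitude relative to the
    main peak, must be < 1).  The curve is peak-normalized.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be > 0")
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    center = max(1, int(np.ceil(5.0 * sigma / bin_width)))
    n = 2 * center + 1
    if hump is not None:
        delay, amp, hump_fwhm = hump
        if amp >= 1:
            raise ValueError("hump amplitude must be < 1 (secondary feature)")
        if amp <= 0 or delay <= 0 or hump_fwhm <= 0:
            raise ValueError("hump delay, amplitude and width must be > 0")
        hsig = hump_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        n = center + int(np.ceil((delay + 5.0 * hsig) / bin_width)) + 1
    t = np.arange(n) * bin_width
    t0 = center * bin_width
    y = np.exp(-0.5 * ((t - t0) / sigma) ** 2)
    if hump is not None:
        y = y + amp * np.exp(-0.5 * ((t - t0 - delay) / hsig) ** 2)
    y = y / y.max()
    return IRF(times=t, intensities=y, fwhm=fwhm)


def impulse_irf(bin_width: float = 0.3125) -> IRF:
    """A single-bin unit impulse (identity element of the convolution)."""
    return IRF(times=np.array([0.0, bin_width]),
               intensities=np.array([1.0, 0.0]), fwhm=0.0)


def _apply_noise(y: np.ndarray, noise: NoiseModel) -> np.ndarray:
    if noise.mode == "none":
        return y
    rng = np.random.default_rng(noise.seed)
    if noise.mode == "shot":
        counts = y * (noise.scale / y.sum())
        y = rng.poisson(counts).astype(float)
    else:
        y = y + rng.normal(0.0, noise.scale * y.max(), y.size)
    return np.clip(y, 0.0, None)


def forward_measurement(props: OpticalProperties, probe: ProbeGeometry,
                        irf: IRF, noise: NoiseModel = NoiseModel(),
                        shift_bins: int = 0,
                        config: SimConfig = SimConfig(),
                        white: WhiteRunResult | None = None,
                        smooth: float | None = 0.05) -> CurveTrace:
    """Emulate a measured TPSF at the given medium properties.

    Runs (or reuses) a white MC simulation, imposes ``props.mua`` by
    Beer-Lambert reweighting, convolves with the IRF, embeds a known
    trigger offset of ``shift_bins`` bins, applies the noise model and
    peak-normalizes.  Passing a cached ``white`` run (same mus, g, n,
    probe) skips the simulation.

    ``smooth`` suppresses the emulator's own Monte Carlo sampling noise
    (:func:`wmcfit.lut.smooth_tpsf`, relative window 0.05 by default)
    before the noise model is applied: the instrument being emulated has
    shot noise but no transport-sampling noise, so the injected noise
    model — not the simulation's record statistics — should set the
    curve's noise floor.  ``None`` keeps the raw histogram.
    """
    if white is None:
        white = run_white_mc(props.with_mua(0.0), probe, config)
    else:
        for name in ("mus", "g", "n"):
            if abs(getattr(white.props, name) - getattr(props, name)) > 1e-9:
                raise ValueError(f"cached white run {name} does not match")
    tpsf = rescale_to_mua(white, props.mua, white.config)
    if smooth is not None:
        tpsf = type(tpsf)(
            values=smooth_tpsf(tpsf.values, smooth),
            bin_width=tpsf.bin_width, t_max=tpsf.t_max,
            provenance=dict(tpsf.provenance))
    curve = convolve_irf(tpsf, irf)
    y = _shifted(curve.intensities, shift_bins)
    y = _apply_noise(y, noise)
    if y.max() <= 0:
        raise ValueError("noise model produced an all-zero curve")
    return CurveTrace(
        times=curve.times,
        intensities=y / y.max(),
        meta={
            "mua": props.mua, "musp": props.musp, "g": props.g, "n": props.n,
            "shift_bins": shift_bins, "noise": noise.mode,
            "noise_scale": noise.scale, "noise_seed": noise.seed,
            "mc_seed": white.config.seed,
        },
    )


_TISSUE_PROBE = ProbeGeometry()
_PHANTOM_PROBE = ProbeGeometry(immersion_depth=0.5)

# (mua mm^-1, musp mm^-1) ground truths; tissue values use the model
# constants g = 0.9, n = 1.4.  The phantom liquid's index is not tabulated;
# 1.33 (water-like) is assumed and recorded here.
_PRESETS: dict[str, ScenarioPreset] = {}


def _add_preset(name, mua, musp=None, mus=None, g=0.9, n=1.4, probe=_TISSUE_PROBE):
    if mus is None:
        props = OpticalProperties.from_musp(mua, musp, g=g, n=n)
    else:
        props = OpticalProperties(mua=mua, mus=mus, g=g, n=n)
    _PRESETS[name] = ScenarioPreset(
        name=name, props=props, probe=probe,
        expected_mua=mua, expected_musp=props.musp)


_add_preset("phantom", 0.0231, mus=15.6, g=0.836, n=1.33, probe=_PHANTOM_PROBE)
_add_preset("rat_gray", 0.054, musp=1.67)
_add_preset("rat_white", 0.029, musp=2.13)
_add_preset("monkey_gray", 0.084, musp=1.97)
_add_preset("monkey_white", 0.021, musp=2.40)
_add_preset("fig3a_rat", 0.052, musp=1.70)
_add_preset("fig3b_monkey", 0.081, musp=1.8)


def preset(name: str) -> ScenarioPreset:
    """Tabulated scenario by name.

    Available: ``phantom`` (latex-microsphere liquid phantom, immersed
    fibers), ``rat_gray``/``rat_white``/``monkey_gray``/``monkey_white``
    (cohort-mean brain tissue values) and ``fig3a_rat``/``fig3b_monkey``
    (single-measurement curve-fitting examples).
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
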