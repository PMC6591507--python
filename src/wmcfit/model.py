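"""Domain types for time-resolved photon-transport simulation.

The physical setting is reflectance-mode time-resolved spectroscopy of a
semi-infinite turbid medium: an ultrashort pulse is launched from a small
source fiber, and photons returning to a closely spaced detector fiber are
histogrammed by arrival time into a temporal point spread function (TPSF).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np

#: Speed of light in vacuum, mm/ps.
C_MM_PER_PS = 0.299792458


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of a homogeneous medium.

    Parameters
    ----------
    mua : float
        Absorption coefficient, mm^-1.
    mus : float
        Scattering coefficient, mm^-1.
    g : float
        Scattering anisotropy (mean cosine of the single-scattering
        polar angle), dimensionless, in (-1, 1).
    n : float
        Refractive index of the medium.
    """

    mua: float
    mus: float
    g: float = 0.9
    n: float = 1.4

    def __post_init__(self) -> None:
        if self.mua < 0:
            raise ValueError(f"mua must be >= 0, got {self.mua}")
        if self.mus <= 0:
            raise ValueError(f"mus must be > 0, got {self.mus}")
        if not -1 < self.g < 1:
            raise ValueError(f"g must be in (-1, 1), got {self.g}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")

    @property
    def musp(self) -> float:
        """Reduced scattering coefficient mus' = mus * (1 - g), mm^-1."""
        return self.mus * (1.0 - self.g)

    @classmethod
    def from_musp(cls, mua: float, musp: float, g: float = 0.9,
                  n: float = 1.4) -> "OpticalProperties":
        """Construct from the reduced scattering coefficient."""
        return cls(mua=mua, mus=musp / (1.0 - g), g=g, n=n)

    def with_mua(self, mua: float) -> "OpticalProperties":
        return OpticalProperties(mua=mua, mus=self.mus, g=self.g, n=self.n)


@dataclass(frozen=True)
class ProbeGeometry:
    """Source/detector fiber arrangement on (or in) the medium.

    Coordinates: the fiber-tip plane is z = 0 with the medium at z > 0
    (z is depth below the tips).  In surface-contact mode
    (``immersion_depth == 0``) the medium boundary coincides with the tip
    plane.  With ``immersion_depth > 0`` the fibers sit that far below a
    liquid-air interface at z = -immersion_depth (liquid phantom mode).

    Lengths in mm, angles in degrees.
    """

    source_radius: float = 0.025
    source_half_angle: float = 11.5
    detector_radius: float = 0.025
    detector_na: float = 0.2
    separation: float = 1.25
    immersion_depth: float = 0.0
    n_outside: float = 1.0

    def __post_init__(self) -> None:
        for name in ("source_radius", "detector_radius", "separation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.immersion_depth < 0:
            raise ValueError("immersion_depth must be >= 0")
        if not 0 < self.detector_na < 1:
            raise ValueError("detector_na must be in (0, 1)")
        if not 0 < self.source_half_angle < 90:
            raise ValueError("source_half_angle must be in (0, 90) degrees")
        if self.separation <= self.source_radius + self.detector_radius:
            raise ValueError("separation must exceed the sum of fiber radii")
        if self.n_outside < 1:
            raise ValueError("n_outside must be >= 1")


@dataclass(frozen=True)
class SimConfig:
    """Run-control parameters for a Monte Carlo simulation.

    ``bin_width`` and ``t_max`` are in ps; the defaults (0.3125 ps bins,
    300 ps span) give 960 time bins, matching a streak camera with
    312.5 fs resolution.  ``n_detected_target`` stops the run once that
    many packets have been detected; ``max_launch`` is a safety cap on
    launched packets.

    ``ring_detector`` selects the variance-reduced estimator (azimuthal
    ring detection with deterministic Fresnel splitting and roulette);
    with ``False`` the analog reference estimator (physical detector
    spot, probabilistic reflection, unit weights) is used.
    ``depth_roulette_start`` (mm below the fiber tips, variance-reduced
    estimator only) is where depth roulette begins thinning packets that
    dive deep — they contribute only to the late tail of the TPSF;
    ``None`` disables it.
    """

    bin_width: float = 0.3125
    t_max: float = 300.0
    n_detected_target: int = 500_000
    max_launch: int | None = None
    seed: int = 1
    ring_detector: bool = True
    depth_roulette_start: float | None = 3.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        n = self.t_max / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("t_max must be an integer multiple of bin_width")
        if self.n_detected_target <= 0:
            raise ValueError("n_detected_target must be > 0")
        if self.max_launch is not None and self.max_launch <= 0:
            raise ValueError("max_launch must be > 0")
        if self.depth_roulette_start is not None and self.depth_roulette_start <= 0:
            raise ValueError("depth_roulette_start must be > 0 or None")

    @property
    def n_bins(self) -> int:
        return int(round(self.t_max / self.bin_width))


@dataclass
class WhiteRunResult:
    """Per-detected-photon records from a zero-absorption (white) MC run.

    The medium is simulated with mua = 0, so every detected packet carries
    its launch weight; any absorption level can be imposed afterwards by
    Beer-Lambert reweighting of the stored path lengths
    (``wmcfit.lut.rescale_to_mua``).

    Attributes
    ----------
    weight, path_length, n_scatter, max_depth, arrival_bin, exit_radius : ndarray
        One entry per detected packet: packet weight, total optical path
        length L (mm), number of scattering events, deepest z reached
        below the fiber tips (mm), time-bin index floor(t / bin_width),
        and radial exit distance from the source axis (mm).
    band : tuple or None
        Radial collection band (mm) when the run collected a wide annular
        band for later slicing/similarity rescaling; ``None`` when the
        physical detector annulus/spot was used directly.
    launched_weight, escaped_weight, truncated_weight : float
        Weight bookkeeping over all launched packets; at mua = 0 the
        detected + escaped + truncated weights equal the launched weight.
    area_correction : float
        Spot-to-annulus area ratio applied when binning ring-detector
        records so that curves are on the spot-detector scale.  1.0 for
        spot detection.  Record weights themselves are kept unscaled so
        the conservation identity stays exact.
    """

    weight: np.ndarray
    path_length: np.ndarray
    n_scatter: np.ndarray
    max_depth: np.ndarray
    arrival_bin: np.ndarray
    exit_radius: np.ndarray
    launched_weight: float
    escaped_weight: float
    truncated_weight: float
    area_correction: float
    props: OpticalProperties
    probe: ProbeGeometry
    config: SimConfig
    band: tuple[float, float] | None = None

    @property
    def n_detected(self) -> int:
        return self.weight.size

    @property
    def detected_weight(self) -> float:
        return float(self.weight.sum())

    @property
    def n_effective(self) -> float:
        """Effective sample size (sum w)^2 / sum w^2 of the records."""
        if self.weight.size == 0:
            return 0.0
        s = self.weight.sum()
        return float(s * s / np.square(self.weight).sum())

    @property
    def config_fingerprint(self) -> str:
        """Stable hash of medium, probe and run-control provenance."""
        blob = json.dumps(
            {
                "props": asdict(self.props),
                "probe": asdict(self.probe),
                "config": asdict(self.config),
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
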