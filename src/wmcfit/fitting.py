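"""IRF-convolved grid-search fitting of (mua, mus') to a measured TPSF.

Each candidate LUT curve is convolved with the instrument response
function (IRF), peak-normalized, registered to the measurement by an
integer-bin shift search, and scored by the root-mean-square error over
the segment of the measured curve between its leading- and falling-edge
fraction-of-peak crossings (the "10/10" or "40/40" range).  The grid
argmin is returned; no interpolation between grid cells is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .lut import LUT, TPSF

__all__ = [
    "CurveTrace", "IRF", "FitConfig", "FitResult",
    "convolve_irf", "fit_range", "rmse_in_range", "fit_optical_properties",
    "read_curve", "write_curve",
]


@dataclass
class CurveTrace:
    """A time/intensity trace on a uniform time grid (ps, arbitrary units)."""

    times: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape or self.times.ndim != 1:
            raise ValueError("times and intensities must be equal-length 1-D")
        if self.times.size < 2:
            raise ValueError("need at least two samples")
        dt = np.diff(self.times)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time grid must be uniform")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def bin_width(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class IRF(CurveTrace):
    """Instrument response function; ``fwhm`` (ps) is descriptive."""

    fwhm: float = 0.0


@dataclass(frozen=True)
class FitConfig:
    """Fit-range fractions, acceptance threshold and registration search.

    ``leading_fraction``/``falling_fraction`` select the fraction-of-peak
    crossings bounding the fitted segment (0.1/0.1 by default; 0.4/0.4
    avoids falling-edge artifacts such as a humped IRF).  A fit is
    ``accepted`` when the minimum RMSE is below ``rmse_threshold``
    (default 0.025).  Candidate curves are shifted by up to
    ``shift_search_halfwidth`` bins each way to absorb the arbitrary
    trigger offset of a measured curve.

    ``amplitude`` controls the residual model: both curves are always
    peak-normalized, and with ``"free"`` (the default) each candidate is
    additionally rescaled by the least-squares amplitude over the fit
    range before the RMSE is taken, so that the comparison is purely of
    shape and the single noisy peak bin does not set the overall level;
    ``"peak"`` compares the peak-normalized curves as they are.
    """

    leading_fraction: float = 0.1
    falling_fraction: float = 0.1
    rmse_threshold: float = 0.025
    shift_search_halfwidth: int = 16
    amplitude: str = "free"

    def __post_init__(self) -> None:
        for f in (self.leading_fraction, self.falling_fraction):
            if not 0 < f < 1:
                raise ValueError("fractions must be in (0, 1)")
        if self.rmse_threshold <= 0:
            raise ValueError("rmse_threshold must be > 0")
        if self.shift_search_halfwidth < 0:
            raise ValueError("shift_search_halfwidth must be >= 0")
        if self.amplitude not in ("free", "peak"):
            raise ValueError("amplitude must be 'free' or 'peak'")


@dataclass
class FitResult:
    """Outcome of the LUT grid search."""

    best_mua: float
    best_musp: float
    rmse: float
    fit_range: tuple[int, int]
    accepted: bool
    shift_bins: int


def convolve_irf(tpsf: TPSF | CurveTrace, irf: IRF) -> CurveTrace:
    """Convolve a simulated TPSF with the IRF and peak-normalize.

    Discrete linear convolution truncated to the TPSF's own time axis.
    A unit-impulse IRF returns the peak-normalized input.
    """
    if isinstance(tpsf, TPSF):
        values = tpsf.values
        bw = tpsf.bin_width
        times = tpsf.times
    else:
        values = tpsf.intensities
        bw = tpsf.bin_width
        times = tpsf.times
    if abs(bw - irf.bin_width) > 1e-9:
        raise ValueError(
            f"bin width mismatch: curve {bw} ps vs IRF {irf.bin_width} ps")
    out = fftconvolve(values, irf.intensities)[: values.size]
    out = np.clip(out, 0.0, None)
    peak = out.max()
    if peak <= 0:
        raise ValueError("convolution produced an all-zero curve")
    return CurveTrace(times=times.copy(), intensities=out / peak)


def fit_range(curve: CurveTrace | np.ndarray, leading_fraction: float,
              falling_fraction: float) -> tuple[int, int]:
    """Bin range between the fraction-of-peak edge crossings.

    On a peak-normalized curve, returns ``(first, last)`` where ``first``
    is the earliest bin at or before the peak with value >=
    ``leading_fraction`` and ``last`` the latest bin at or after the peak
    with value >= ``falling_fraction`` (threshold crossings at bin
    resolution, closed range containing the peak).
    """
    y = curve.intensities if isinstance(curve, CurveTrace) else np.asarray(curve, float)
    for f in (leading_fraction, falling_fraction):
        if not 0 < f < 1:
            raise ValueError("fractions must be in (0, 1)")
    peak = int(np.argmax(y))
    if y[peak] <= 0:
        raise ValueError("curve has no positive peak")
    yn = y / y[peak]
    lead = np.nonzero(yn[: peak + 1] >= leading_fraction)[0]
    first = int(lead[0])
    above = np.nonzero(yn[peak:] >= falling_fraction)[0]
    last = peak + int(above[-1])
    return first, last


def rmse_in_range(measured, simulated, rng: tuple[int, int]) -> float:
    """Root-mean-square difference over the closed bin range ``rng``."""
    a = measured.intensities if isinstance(measured, CurveTrace) else np.asarray(measured, float)
    b = simulated.intensities if isinstance(simulated, CurveTrace) else np.asarray(simulated, float)
    first, last = rng
    if last < first:
        raise ValueError("empty fit range")
    if first < 0 or last >= min(a.size, b.size):
        raise ValueError("fit range exceeds curve support")
    d = a[first:last + 1] - b[first:last + 1]
    return float(np.sqrt(np.mean(d * d)))


def _shifted(arr: np.ndarray, shift: int) -> np.ndarray:
    """Delay a curve by ``shift`` bins (zero-filled; negative advances)."""
    out = np.zeros_like(arr)
    if shift >= 0:
        out[..., shift:] = arr[..., : arr.shape[-1] - shift] if shift else arr
    else:
        out[..., :shift] = arr[..., -shift:]
    return out


def fit_optical_properties(measured: CurveTrace, irf: IRF, lut: LUT,
                           config: FitConfig = FitConfig()) -> FitResult:
    """Exhaustive LUT grid search for the best-fitting (mua, mus').

    Every LUT cell is convolved with the IRF and peak-normalized; for each
    integer bin shift within the registration window the RMSE against the
    peak-normalized measurement is computed over the fit range derived
    from the measured curve.  Returns the global argmin; exact RMSE ties
    are broken toward smaller mua, then smaller mus', then smaller |shift|.
    """
    if lut.tpsf.size == 0:
        raise ValueError("empty LUT")
    n_bins = lut.n_bins
    if measured.intensities.size < n_bins:
        raise ValueError("measured curve shorter than the LUT time axis")
    if abs(measured.bin_width - lut.bin_width) > 1e-9:
        raise ValueError("measured curve binning does not match the LUT")

    meas = measured.intensities[:n_bins]
    peak = meas.max()
    if peak <= 0:
        raise ValueError("measured curve has no positive peak")
    meas = meas / peak
    first, last = fit_range(meas, config.leading_fraction,
                            config.falling_fraction)
    if last - first + 1 < 4:
        raise ValueError("fit range is degenerate (fewer than 4 bins)")

    n_musp = lut.grid.musp_values.size
    n_mua = lut.grid.mua_values.size
    flat = lut.tpsf.reshape(n_musp * n_mua, n_bins)
    conv = fftconvolve(flat, irf.intensities[None, :], axes=1)[:, :n_bins]
    conv = np.clip(conv, 0.0, None)
    conv /= conv.max(axis=1, keepdims=True)

    h = config.shift_search_halfwidth
    shifts = np.arange(-h, h + 1)
    target = meas[first:last + 1]
    # rmse[s, cell]
    rmse = np.empty((shifts.size, flat.shape[0]))
    for k, s in enumerate(shifts):
        seg = _shifted(conv, int(s))[:, first:last + 1]
        if config.amplitude == "free":
            denom = np.einsum("ij,ij->i", seg, seg)
            denom[denom == 0] = 1.0
            a = (seg @ target) / denom
            seg = seg * a[:, None]
        d = seg - target[None, :]
        rmse[k] = np.sqrt(np.mean(d * d, axis=1))

    best = rmse.min()
    # tie-break: smaller mua, then smaller musp, then smaller |shift|
    ks, cells = np.nonzero(rmse == best)
    i = cells // n_mua
    j = cells % n_mua
    order = np.lexsort((np.abs(shifts[ks]), i, j))
    pick = order[0]
    return FitResult(
        best_mua=float(lut.grid.mua_values[j[pick]]),
        best_musp=float(lut.grid.musp_values[i[pick]]),
        rmse=float(best),
        fit_range=(first, last),
        accepted=bool(best < config.rmse_threshold),
        shift_bins=int(shifts[ks[pick]]),
    )


def write_curve(curve: CurveTrace, path, **meta) -> None:
    """Write a two-column (time_ps, intensity) delimited-text curve file."""
    header = dict(curve.meta)
    header.update(meta)
    header.setdefault("bin_width_ps", curve.bin_width)
    with open(path, "w") as f:
        for k, v in header.items():
            f.write(f"# {k}: {v}\n")
        f.write("# time_ps\tintensity\n")
        for t, y in zip(curve.times, curve.intensities):
            f.write(f"{t:.6f}\t{y:.9e}\n")


def read_curve(path, cls=CurveTrace) -> CurveTrace:
    """Read a curve file written by :func:`write_curve` (validates the grid)."""
    meta: dict = {}
    times, vals = [], []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, _, v = body.partition(":")
                    meta[k.strip()] = v.strip()
                continue
            t, y = line.split()
            times.append(float(t))
            vals.append(float(y))
    if cls is IRF:
        return IRF(times=np.array(times), intensities=np.array(vals),
                   meta=meta, fwhm=float(meta.get("fwhm_ps", 0.0)))
    return cls(times=np.array(times), intensities=np.array(vals), meta=meta)
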