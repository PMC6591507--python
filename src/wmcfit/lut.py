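"""Look-up-table construction from white Monte Carlo runs.

A single zero-absorption run per mus' value is expanded across the whole
absorption axis analytically: each detected packet's ultimate weight at
absorption mua is W = W0 * exp(-mua * L), where L is its stored total
path length (Beer-Lambert over the random walk).  The absorption axis of
the look-up table is therefore free — simulation cost scales only with
the number of scattering grid points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .model import SimConfig, WhiteRunResult

_SCHEMA_VERSION = 1

__all__ = [
    "TPSF", "LUTGrid", "LUT",
    "rescale_to_mua", "peak_normalize", "smooth_tpsf", "build_lut",
    "lut_save", "lut_load",
]


@dataclass
class TPSF:
    """A time-binned detected-weight curve (temporal point spread function).

    ``values[k]`` is the weight detected in the half-open time bin
    [k * bin_width, (k+1) * bin_width) ps.
    """

    values: np.ndarray
    bin_width: float
    t_max: float
    normalized: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.t_max / self.bin_width
        if self.values.size != round(n):
            raise ValueError(
                f"length {self.values.size} != t_max/bin_width = {n:g}")
        if np.any(self.values < 0):
            raise ValueError("TPSF values must be >= 0")

    @property
    def times(self) -> np.ndarray:
        """Left edges of the time bins, ps."""
        return np.arange(self.values.size) * self.bin_width


def rescale_to_mua(white: WhiteRunResult, mua: float,
                   config: SimConfig | None = None) -> TPSF:
    """Impose absorption ``mua`` on a white run and bin by arrival time.

    Each detected packet contributes W0 * exp(-mua * L) to its arrival
    bin.  With mua = 0 this reproduces the raw white-MC accumulation.
    Returns an unnormalized TPSF.
    """
    if mua < 0:
        raise ValueError(f"mua must be >= 0, got {mua}")
    cfg = config if config is not None else white.config
    w = white.weight * np.exp(-mua * white.path_length) * white.area_correction
    values = np.bincount(white.arrival_bin, weights=w, minlength=cfg.n_bins)
    return TPSF(
        values=values[: cfg.n_bins],
        bin_width=cfg.bin_width,
        t_max=cfg.t_max,
        normalized=False,
        provenance={
            "musp": white.props.musp,
            "mua": mua,
            "g": white.props.g,
            "n": white.props.n,
            "probe": white.config_fingerprint,
        },
    )


def peak_normalize(tpsf: TPSF) -> TPSF:
    """Divide all bins by the maximum so the peak is exactly 1."""
    peak = tpsf.values.max() if tpsf.values.size else 0.0
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero curve")
    return TPSF(
        values=tpsf.values / peak,
        bin_width=tpsf.bin_width,
        t_max=tpsf.t_max,
        normalized=True,
        provenance=dict(tpsf.provenance),
    )


def _grid_axis(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    return np.round(lo + step * np.arange(n), 10)


@dataclass
class LUTGrid:
    """The (mus', mua) grid of the look-up table, mm^-1.

    Defaults reproduce the full table: mus' from 0.6 to 4.0 in steps of
    0.1 (35 values) and mua from 0 to 0.1 in steps of 0.001 (101 values),
    at fixed anisotropy g and index n.
    """

    musp_values: np.ndarray = field(
        default_factory=lambda: _grid_axis(0.6, 4.0, 0.1))
    mua_values: np.ndarray = field(
        default_factory=lambda: _grid_axis(0.0, 0.1, 0.001))
    g: float = 0.9
    n: float = 1.4

    def __post_init__(self) -> None:
        self.musp_values = np.asarray(self.musp_values, dtype=float)
        self.mua_values = np.asarray(self.mua_values, dtype=float)
        for name, ax in (("musp", self.musp_values), ("mua", self.mua_values)):
            if ax.ndim != 1 or ax.size == 0:
                raise ValueError(f"{name}_values must be a non-empty 1-D axis")
            if np.any(np.diff(ax) <= 0):
                raise ValueError(f"{name}_values must be strictly increasing")
        if self.musp_values[0] <= 0:
            raise ValueError("all musp values must be > 0")
        if self.mua_values[0] < 0:
            raise ValueError("all mua values must be >= 0")

    @classmethod
    def reduced(cls, musp_range: tuple[float, float],
                mua_range: tuple[float, float],
                musp_step: float = 0.1, mua_step: float = 0.001,
                g: float = 0.9, n: float = 1.4) -> "LUTGrid":
        """A sub-range grid (same default steps) for desk-scale builds."""
        return cls(_grid_axis(*musp_range, musp_step),
                   _grid_axis(*mua_range, mua_step), g=g, n=n)


@dataclass
class LUT:
    """Grid of peak-normalized TPSFs indexed by (mus', mua).

    ``tpsf[i, j, :]`` is the curve for ``grid.musp_values[i]``,
    ``grid.mua_values[j]``.
    """

    grid: LUTGrid
    tpsf: np.ndarray
    bin_width: float
    t_max: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tpsf = np.asarray(self.tpsf, dtype=float)
        expect = (self.grid.musp_values.size, self.grid.mua_values.size,
                  int(round(self.t_max / self.bin_width)))
        if self.tpsf.shape != expect:
            raise ValueError(f"tpsf shape {self.tpsf.shape} != {expect}")

    @property
    def n_bins(self) -> int:
        return self.tpsf.shape[2]

    def curve(self, musp: float, mua: float) -> np.ndarray:
        """The stored curve at the grid point nearest (musp, mua)."""
        i = int(np.argmin(np.abs(self.grid.musp_values - musp)))
        j = int(np.argmin(np.abs(self.grid.mua_values - mua)))
        return self.tpsf[i, j]


def smooth_tpsf(values: np.ndarray, rel_width: float = 0.05,
                min_sigma: float = 1.0) -> np.ndarray:
    """Variance-reduce a binned TPSF with a time-proportional Gaussian window.

    The underlying curve is a smooth function whose features scale with
    time (sharp rise near the peak, slowly decaying tail), so each bin k
    is averaged with a Gaussian window of width
    sigma = max(min_sigma, rel_width * k) bins (k counted from the first
    occupied bin, so the sharp onset region keeps the narrowest window).
    Tail bins are averaged over ~2*rel_width of their own time, trading
    a sub-percent smoothing bias for a several-fold Monte Carlo noise
    reduction.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    out = values.copy()
    occupied = np.nonzero(values > 0)[0]
    if occupied.size == 0:
        return out
    k0 = occupied[0]
    k = np.arange(n)
    for i in range(k0, n):
        sigma = max(min_sigma, rel_width * (i - k0))
        half = int(np.ceil(3.0 * sigma))
        lo, hi = max(0, i - half), min(n, i + half + 1)
        w = np.exp(-0.5 * ((k[lo:hi] - i) / sigma) ** 2)
        out[i] = np.dot(w, values[lo:hi]) / w.sum()
    return out


def build_lut(white_runs, grid: LUTGrid, config: SimConfig | None = None,
              smooth: float | None = 0.05) -> LUT:
    """Expand one white run per mus' grid value into the full LUT.

    ``white_runs`` maps mus' (to grid precision) to a
    :class:`WhiteRunResult` simulated at that reduced scattering
    coefficient (mus = mus'/(1-g)) with zero absorption, all with
    identical probe and binning.  A sequence ordered like
    ``grid.musp_values`` is also accepted.

    ``smooth`` applies :func:`smooth_tpsf` with the given relative
    window to each cell's binned curve before normalization (the LUT is
    the model side of the fit, so denoising it is a numerical choice,
    not data manipulation); ``None`` stores the raw histograms.
    """
    if not isinstance(white_runs, dict):
        white_runs = {round(float(w.props.musp), 6): w for w in white_runs}
    else:
        white_runs = {round(float(k), 6): v for k, v in white_runs.items()}

    runs = []
    for musp in grid.musp_values:
        key = round(float(musp), 6)
        if key not in white_runs:
            raise ValueError(f"missing white run for musp = {musp:g}")
        runs.append(white_runs[key])

    cfg = config if config is not None else runs[0].config
    for w in runs:
        if (w.config.bin_width != cfg.bin_width
                or w.config.t_max != cfg.t_max):
            raise ValueError("white runs have inconsistent binning")
        if abs(w.props.g - grid.g) > 1e-9 or abs(w.props.n - grid.n) > 1e-9:
            raise ValueError("white run g/n do not match the grid")

    n_bins = cfg.n_bins
    out = np.empty((grid.musp_values.size, grid.mua_values.size, n_bins))
    for i, w in enumerate(runs):
        for j, mua in enumerate(grid.mua_values):
            values = rescale_to_mua(w, float(mua), cfg).values
            if smooth is not None:
                values = smooth_tpsf(values, smooth)
            peak = values.max()
            if peak <= 0:
                raise ValueError(
                    f"all-zero TPSF at musp={grid.musp_values[i]:g}, "
                    f"mua={mua:g}")
            out[i, j] = values / peak
    meta = {
        "bin_width_ps": cfg.bin_width,
        "t_max_ps": cfg.t_max,
        "g": grid.g,
        "n": grid.n,
        "n_runs": len(runs),
        "smooth_rel_width": -1.0 if smooth is None else float(smooth),
        "run_fingerprints": ",".join(w.config_fingerprint for w in runs),
    }
    return LUT(grid=grid, tpsf=out, bin_width=cfg.bin_width, t_max=cfg.t_max,
               meta=meta)


def lut_save(lut: LUT, path) -> None:
    """Persist a LUT to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = _SCHEMA_VERSION
        f.attrs["bin_width_ps"] = lut.bin_width
        f.attrs["t_max_ps"] = lut.t_max
        g = f.create_group("grid")
        g.create_dataset("musp", data=lut.grid.musp_values)
        g.create_dataset("mua", data=lut.grid.mua_values)
        g.attrs["g"] = lut.grid.g
        g.attrs["n"] = lut.grid.n
        f.create_dataset("tpsf", data=lut.tpsf)
        m = f.create_group("meta")
        for k, v in lut.meta.items():
            m.attrs[k] = v


def lut_load(path) -> LUT:
    """Load a LUT saved by :func:`lut_save`; bit-exact round trip."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != _SCHEMA_VERSION:
            raise ValueError(
                f"unsupported LUT schema_version {version!r}, "
                f"expected {_SCHEMA_VERSION}")
        bin_width = float(f.attrs["bin_width_ps"])
        t_max = float(f.attrs["t_max_ps"])
        grid = LUTGrid(
            musp_values=f["grid/musp"][...],
            mua_values=f["grid/mua"][...],
            g=float(f["grid"].attrs["g"]),
            n=float(f["grid"].attrs["n"]),
        )
        tpsf = f["tpsf"][...]
        meta = dict(f["meta"].attrs)
        meta_bw = meta.get("bin_width_ps")
        if meta_bw is not None and float(meta_bw) != bin_width:
            raise ValueError(
                f"metadata bin_width_ps {meta_bw!r} contradicts root "
                f"attribute {bin_width!r}")
    return LUT(grid=grid, tpsf=tpsf, bin_width=bin_width, t_max=t_max,
               meta=meta)
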