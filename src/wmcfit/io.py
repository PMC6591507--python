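"""Persistence of white-run records and structured-text configuration."""

from __future__ import annotations

from dataclasses import asdict

import h5py
import numpy as np
import yaml

from .model import OpticalProperties, ProbeGeometry, SimConfig, WhiteRunResult

_SCHEMA_VERSION = 1

__all__ = ["save_white_run", "load_white_run", "load_config"]


def save_white_run(run: WhiteRunResult, path) -> None:
    """Persist per-detected-photon records plus full provenance to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = _SCHEMA_VERSION
        rec = f.create_group("records")
        rec.create_dataset("weight", data=run.weight)
        rec.create_dataset("path_length", data=run.path_length)
        rec.create_dataset("n_scatter", data=run.n_scatter)
        rec.create_dataset("max_depth", data=run.max_depth)
        rec.create_dataset("arrival_bin", data=run.arrival_bin)
        rec.create_dataset("exit_radius", data=run.exit_radius)
        meta = f.create_group("meta")
        if run.band is not None:
            meta.attrs["band"] = list(run.band)
        meta.attrs["launched_weight"] = run.launched_weight
        meta.attrs["escaped_weight"] = run.escaped_weight
        meta.attrs["truncated_weight"] = run.truncated_weight
        meta.attrs["area_correction"] = run.area_correction
        meta.attrs["config_fingerprint"] = run.config_fingerprint
        for group, obj in (("props", run.props), ("probe", run.probe),
                           ("config", run.config)):
            g = meta.create_group(group)
            for k, v in asdict(obj).items():
                g.attrs[k] = "__none__" if v is None else v


def load_white_run(path) -> WhiteRunResult:
    """Inverse of :func:`save_white_run`."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != _SCHEMA_VERSION:
            raise ValueError(f"unsupported white-run schema_version {version!r}")

        def attrs(name):
            out = {}
            for k, v in f[f"meta/{name}"].attrs.items():
                if isinstance(v, bytes):
                    v = v.decode()
                if isinstance(v, str) and v == "__none__":
                    v = None
                elif isinstance(v, np.generic):
                    v = v.item()
                out[k] = v
            return out

        run = WhiteRunResult(
            weight=f["records/weight"][...],
            path_length=f["records/path_length"][...],
            n_scatter=f["records/n_scatter"][...],
            max_depth=f["records/max_depth"][...],
            arrival_bin=f["records/arrival_bin"][...],
            exit_radius=f["records/exit_radius"][...],
            band=(tuple(float(x) for x in f["meta"].attrs["band"])
                  if "band" in f["meta"].attrs else None),
            launched_weight=float(f["meta"].attrs["launched_weight"]),
            escaped_weight=float(f["meta"].attrs["escaped_weight"]),
            truncated_weight=float(f["meta"].attrs["truncated_weight"]),
            area_correction=float(f["meta"].attrs["area_correction"]),
            props=OpticalProperties(**attrs("props")),
            probe=ProbeGeometry(**attrs("probe")),
            config=SimConfig(**attrs("config")),
        )
    return run


def load_config(path) -> tuple[OpticalProperties, ProbeGeometry, SimConfig]:
    """Read a YAML config with ``medium``, ``probe`` and ``sim`` blocks.

    The medium block takes either ``mus`` or ``musp`` (plus ``g``, ``n``);
    ``mua`` defaults to 0 (white run).  Probe and sim keys mirror the
    dataclass fields.
    """
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    med = dict(cfg.get("medium", {}))
    mua = float(med.pop("mua", 0.0))
    g = float(med.pop("g", 0.9))
    n = float(med.pop("n", 1.4))
    if "musp" in med and "mus" in med:
        raise ValueError("specify either mus or musp, not both")
    if "musp" in med:
        props = OpticalProperties.from_musp(mua, float(med.pop("musp")), g=g, n=n)
    elif "mus" in med:
        props = OpticalProperties(mua=mua, mus=float(med.pop("mus")), g=g, n=n)
    else:
        raise ValueError("medium block needs mus or musp")
    if med:
        raise ValueError(f"unknown medium keys: {sorted(med)}")
    probe = ProbeGeometry(**cfg.get("probe", {}))
    sim = dict(cfg.get("sim", {}))
    # accept the _ps-suffixed spellings used in config files
    for src, dst in (("bin_width_ps", "bin_width"), ("t_max_ps", "t_max"),
                     ("budget", "n_detected_target")):
        if src in sim:
            sim[dst] = sim.pop(src)
    config = SimConfig(**sim)
    return props, probe, config
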