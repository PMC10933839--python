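"""Reading and writing the package's standard on-disk formats.

Velocity-field series travel as TIFF stacks of shape (frames, 2, ny, nx)
(page pair per frame: u_x then u_y) with a JSON metadata sidecar holding
pixel size and frame interval, or as paired CSV grids for single frames.
Curves and time series travel as plain CSV tables; lattice snapshots as HDF5.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .flow import VelocityFieldSeries
from .motor_kinetics import MicroscopicCurves
from .scaling import HydroCurves

__all__ = [
    "write_velocity_fields", "load_velocity_fields", "sidecar_path",
    "curves_to_csv", "curves_from_csv", "hydro_to_csv", "load_config",
    "save_lb_state",
]


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_velocity_fields(path, series: VelocityFieldSeries) -> Path:
    """Write a TIFF stack plus JSON sidecar; returns the TIFF path."""
    path = Path(path)
    data = np.stack([series.u_x, series.u_y], axis=1)  # (frames, 2, ny, nx)
    tifffile.imwrite(path, data.astype(np.float64))
    meta = {"pixel_size_um": series.pixel_size,
            "frame_interval_s": series.frame_interval,
            "n_frames": series.n_frames}
    sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def load_velocity_fields(path, pixel_size: float | None = None,
                         frame_interval: float | None = None
                         ) -> VelocityFieldSeries:
    """Load a velocity-field series.

    ``path`` may be a TIFF stack written by :func:`write_velocity_fields`
    (metadata read from the sidecar unless overridden) or a pair of CSV
    paths ``(ux_csv, uy_csv)`` holding one frame each.
    """
    if isinstance(path, (tuple, list)):
        ux = np.loadtxt(path[0], delimiter=",", ndmin=2)
        uy = np.loadtxt(path[1], delimiter=",", ndmin=2)
        if ux.shape != uy.shape:
            raise ValueError(f"component grids have mismatched shapes "
                             f"{ux.shape} vs {uy.shape}")
        return VelocityFieldSeries(ux, uy, pixel_size or 1.0,
                                   frame_interval or 1.0)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim == 3:          # single frame stored as (2, ny, nx)
        data = data[None]
    if data.ndim != 4 or data.shape[1] != 2:
        raise ValueError(
            f"expected a (frames, 2, ny, nx) stack, got shape {data.shape}")
    meta = {}
    sc = sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_um", 1.0)
    dt = frame_interval if frame_interval is not None \
        else meta.get("frame_interval_s", 1.0)
    return VelocityFieldSeries(data[:, 0], data[:, 1], px, dt)


def curves_to_csv(curves: MicroscopicCurves, path) -> Path:
    path = Path(path)
    cols = {"atp_uM": curves.atp, "epsilon": curves.epsilon,
            "p_cl": curves.p_cl}
    if curves.se_epsilon is not None:
        cols["se_epsilon"] = curves.se_epsilon
    if curves.se_p_cl is not None:
        cols["se_p_cl"] = curves.se_p_cl
    pd.DataFrame(cols).to_csv(path, index=False)
    return path


def curves_from_csv(path) -> MicroscopicCurves:
    df = pd.read_csv(path)
    for col in ("atp_uM", "epsilon", "p_cl"):
        if col not in df:
            raise ValueError(f"curves file missing column {col!r}")
    return MicroscopicCurves(
        atp=df["atp_uM"].to_numpy(), epsilon=df["epsilon"].to_numpy(),
        p_cl=df["p_cl"].to_numpy(),
        se_epsilon=df["se_epsilon"].to_numpy() if "se_epsilon" in df else None,
        se_p_cl=df["se_p_cl"].to_numpy() if "se_p_cl" in df else None)


def hydro_to_csv(curves: HydroCurves, path) -> Path:
    path = Path(path)
    pd.DataFrame({"atp_uM": curves.atp, "alpha": curves.alpha,
                  "K": curves.k_elastic, "v": curves.v,
                  "ell": curves.ell}).to_csv(path, index=False)
    return path


def load_config(path) -> dict:
    """YAML or JSON configuration file as a plain dict."""
    text = Path(path).read_text()
    return yaml.safe_load(text)


def save_lb_state(path, state) -> Path:
    """Lattice snapshot to HDF5 (datasets rho, ux, uy, Qxx, Qyy, Qxy)."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        for name, arr in (("rho", state.rho), ("ux", state.ux),
                          ("uy", state.uy), ("Qxx", state.qxx),
                          ("Qyy", state.qyy), ("Qxy", state.qxy)):
            h5.create_dataset(name, data=arr)
        h5.attrs["step"] = state.step
    return path
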