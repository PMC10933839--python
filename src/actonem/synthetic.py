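"""Synthetic inputs with known ground truth for estimator validation.

Two generators: steady vortex-structured velocity-field series (Rankine or
Lamb-Oseen profiles, single vortex or an alternating-sign lattice, optional
additive Gaussian noise) whose core radius is known exactly, and microscopic
epsilon/P_cl curves with the rising/falling Michaelis-Menten structure the
scaling analysis assumes, with optional multiplicative noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flow import VelocityFieldSeries
from .motor_kinetics import MicroscopicCurves, default_atp_grid
from .scaling import MMParams, mm_microscopic_curves

__all__ = ["VortexFieldParams", "SyntheticCurveParams", "synth_vortex_field",
           "synth_microscopic_curves", "lamb_oseen_peak_radius"]


@dataclass(frozen=True)
class VortexFieldParams:
    shape: tuple = (128, 128)        # (ny, nx)
    core_radius: float = 10.0        # px
    n_vortices: int = 1
    profile: str = "rankine"         # or "lamb_oseen"
    peak_speed: float = 1.0          # um/s
    sign_pattern: str = "alternating"  # or "random"
    noise_sigma: float = 0.0         # fraction of peak speed
    placement: str = "lattice"       # or "random" (centers >= 3R apart)
    pixel_size: float = 1.0          # um
    frame_interval: float = 1.0      # s
    n_frames: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.core_radius < 2:
            raise ValueError("core_radius must be at least 2 px")
        if self.profile not in ("rankine", "lamb_oseen"):
            raise ValueError("profile must be 'rankine' or 'lamb_oseen'")
        if self.n_vortices < 0:
            raise ValueError("n_vortices must be non-negative")


@dataclass(frozen=True)
class SyntheticCurveParams:
    atp_grid: np.ndarray = field(default_factory=default_atp_grid)
    mm: MMParams = field(default_factory=MMParams)
    noise_sigma: float = 0.0         # multiplicative, fraction of the value
    seed: int = 0


def _azimuthal_speed(r: np.ndarray, R: float, profile: str) -> np.ndarray:
    """u_theta(r), normalized to peak speed 1 at its maximum."""
    with np.errstate(divide="ignore", invalid="ignore"):
        if profile == "rankine":
            # solid-body core, 1/r tail; maximum exactly at r = R
            u = np.where(r <= R, r / R, R / r)
        else:
            # Lamb-Oseen: u ~ (1 - exp(-r^2/R^2)) / r, rescaled to peak 1
            rp = lamb_oseen_peak_radius(R)
            up = (1.0 - np.exp(-(rp / R) ** 2)) / rp
            u = np.where(r > 0, (1.0 - np.exp(-(r / R) ** 2)) / (r * up), 0.0)
    return np.where(r > 0, u, 0.0)


def lamb_oseen_peak_radius(core_radius: float) -> float:
    """Radius of maximum azimuthal speed of the Lamb-Oseen profile.

    Computed numerically from u(r) ~ (1 - exp(-r^2/R^2))/r; approximately
    1.1209 * R.  Never assumed in tests.
    """
    r = np.linspace(1e-6, 5 * core_radius, 200001)
    u = (1.0 - np.exp(-(r / core_radius) ** 2)) / r
    return float(r[np.argmax(u)])


def synth_vortex_field(params: VortexFieldParams) -> VelocityFieldSeries:
    """Superpose azimuthal-profile vortices on a periodic grid, add noise."""
    ny, nx = params.shape
    rng = np.random.default_rng(int(params.seed))
    ux = np.zeros((ny, nx))
    uy = np.zeros((ny, nx))
    R = params.core_radius

    centers, signs = [], []
    n = params.n_vortices
    if n > 0 and params.placement == "lattice":
        m = int(np.ceil(np.sqrt(n)))
        cell_y, cell_x = ny / m, nx / m
        if min(cell_x, cell_y) < 2 * R:
            raise ValueError("vortex lattice cells smaller than 2R; "
                             "reduce n_vortices or core_radius")
        k = 0
        for i in range(m):
            for j in range(m):
                if k >= n:
                    break
                centers.append(((i + 0.5) * cell_y, (j + 0.5) * cell_x))
                if params.sign_pattern == "alternating":
                    signs.append(1.0 if (i + j) % 2 == 0 else -1.0)
                else:
                    signs.append(rng.choice([-1.0, 1.0]))
                k += 1
    elif n > 0:
        min_sep = 3.0 * R
        for _ in range(n):
            for attempt in range(10000):
                cy, cx = rng.uniform(0, ny), rng.uniform(0, nx)
                ok = True
                for (py, px) in centers:
                    ddy = min(abs(cy - py), ny - abs(cy - py))
                    ddx = min(abs(cx - px), nx - abs(cx - px))
                    if np.hypot(ddy, ddx) < min_sep:
                        ok = False
                        break
                if ok:
                    centers.append((cy, cx))
                    signs.append(rng.choice([-1.0, 1.0])
                                 if params.sign_pattern == "random" else
                                 (1.0 if len(signs) % 2 == 0 else -1.0))
                    break
            else:
                raise ValueError("could not place vortices >= 3R apart")

    yy = np.arange(ny)[:, None]
    xx = np.arange(nx)[None, :]
    for (cy, cx), sgn in zip(centers, signs):
        dy = yy - cy
        dy = dy - ny * np.round(dy / ny)     # nearest periodic image
        dx = xx - cx
        dx = dx - nx * np.round(dx / nx)
        r = np.hypot(dy, dx)
        u_t = params.peak_speed * _azimuthal_speed(r, R, params.profile)
        with np.errstate(invalid="ignore"):
            ux += sgn * u_t * np.where(r > 0, -dy / r, 0.0)
            uy += sgn * u_t * np.where(r > 0, dx / r, 0.0)

    frames_x = np.repeat(ux[None], params.n_frames, axis=0)
    frames_y = np.repeat(uy[None], params.n_frames, axis=0)
    if params.noise_sigma > 0:
        sd = params.noise_sigma * params.peak_speed
        frames_x = frames_x + rng.normal(0.0, sd, frames_x.shape)
        frames_y = frames_y + rng.normal(0.0, sd, frames_y.shape)
    return VelocityFieldSeries(frames_x, frames_y, params.pixel_size,
                               params.frame_interval)


def synth_microscopic_curves(params: SyntheticCurveParams) -> MicroscopicCurves:
    """Michaelis-Menten backbones with optional multiplicative noise."""
    curves = mm_microscopic_curves(np.asarray(params.atp_grid, float),
                                   params.mm)
    if params.noise_sigma > 0:
        rng = np.random.default_rng(int(params.seed))
        eps = curves.epsilon * np.clip(
            1.0 + rng.normal(0.0, params.noise_sigma, curves.epsilon.shape),
            1e-6, None)
        pcl = np.clip(curves.p_cl * np.clip(
            1.0 + rng.normal(0.0, params.noise_sigma, curves.p_cl.shape),
            1e-6, None), None, 1.0)
        curves = MicroscopicCurves(atp=curves.atp, epsilon=eps, p_cl=pcl)
    return curves
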