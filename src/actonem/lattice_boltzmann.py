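"""Hybrid lattice-Boltzmann simulator of 2-D active nematic hydrodynamics.

Momentum is evolved on a periodic D2Q9 lattice with BGK collisions (lattice
viscosity eta = (tau - 1/2)/3) and Guo forcing; the nematic order parameter
is evolved by finite-difference Beris-Edwards dynamics with flow alignment
xi, rotational mobility Gamma and a Landau-de Gennes bulk free energy

    f = (A0/2)(1 - U/3) Tr Q^2 - (A0 U/3) Tr Q^3 + (A0 U/4) (Tr Q^2)^2
        + (K/2) |grad Q|^2.

The tensor convention is the three-dimensionally embedded one, Q = q(nn - I/3)
for a uniaxial state, with the director confined to the plane: the evolved
fields are Qxx, Qyy, Qxy and Qzz = -(Qxx + Qyy), which the 2-D flow preserves.
In this convention the ordered bulk minimum is q = 1/4 + (3/4)sqrt(1 - 8/(3U))
(0.616 at U = 3.5); an isotropic state is the minimum for U < 8/3.  The
momentum equation is forced by the divergence of the elastic and active
stresses, the latter -alpha*Q with alpha > 0 extensile.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar

from .motor_kinetics import derive_seeds

__all__ = [
    "LBConfig", "LBState", "LBTimeSeries", "equilibrium_order",
    "bulk_free_energy_uniaxial", "lb_init", "lb_step", "lb_run",
    "kinetic_energy", "mean_order", "measure_viscosity",
]

# D2Q9 velocity set and weights
_CX = np.array([0, 1, 0, -1, 0, 1, -1, -1, 1])
_CY = np.array([0, 0, 1, 0, -1, 1, 1, -1, -1])
_W = np.array([4 / 9] + [1 / 9] * 4 + [1 / 36] * 4)


@dataclass(frozen=True)
class LBConfig:
    """Simulation parameters, all in lattice units."""
    nx: int = 64
    ny: int = 64
    tau: float = 1.5             # BGK collision time; eta = (tau - 1/2)/3
    xi: float = 0.7              # flow-alignment parameter
    gamma_rot: float = 0.13      # rotational mobility Gamma
    a0: float = 0.1              # free-energy scale A0
    u_lc: float = 3.5            # free-energy coefficient U
    k_elastic: float = 0.01      # one-constant elastic constant K
    alpha: float = 0.0           # activity (> 0 extensile)
    n_steps: int = 5000          # sampled phase length
    burn_in: int = 5000
    sample_every: int = 50
    perturbation: float = 0.1    # director-angle noise amplitude, rad
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 0.5:
            raise ValueError("tau must exceed 1/2")
        if self.nx < 16 or self.ny < 16:
            raise ValueError("lattice must be at least 16x16")
        if self.k_elastic < 0 or self.alpha < 0:
            raise ValueError("K and alpha must be non-negative")


@dataclass
class LBState:
    f: np.ndarray                # (9, ny, nx) distributions
    rho: np.ndarray
    ux: np.ndarray
    uy: np.ndarray
    qxx: np.ndarray
    qyy: np.ndarray
    qxy: np.ndarray
    step: int = 0

    @property
    def qzz(self) -> np.ndarray:
        return -(self.qxx + self.qyy)


@dataclass
class LBTimeSeries:
    steps: np.ndarray
    kinetic_energy: np.ndarray
    mean_speed: np.ndarray
    mean_q: np.ndarray

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({"step": self.steps,
                             "kinetic_energy": self.kinetic_energy,
                             "mean_speed": self.mean_speed,
                             "mean_q": self.mean_q})


def bulk_free_energy_uniaxial(q, a0: float = 0.1, u_lc: float = 3.5):
    """Bulk free-energy density of the uniaxial state Q = q(nn - I/3)."""
    q = np.asarray(q, dtype=float)
    tr2 = 2.0 * q ** 2 / 3.0
    tr3 = 2.0 * q ** 3 / 9.0
    f = (a0 / 2.0) * (1 - u_lc / 3.0) * tr2 - (a0 * u_lc / 3.0) * tr3 \
        + (a0 * u_lc / 4.0) * tr2 ** 2
    return f if f.ndim else float(f)


def equilibrium_order(u_lc: float, a0: float = 0.1,
                      check_numeric: bool = False) -> float:
    """Ordered minimum of the bulk free energy: q = 1/4 + (3/4)sqrt(1-8/(3U)).

    Below the spinodal U = 8/3 the isotropic state is returned (q = 0).
    With ``check_numeric`` the closed form is verified against a bounded
    numerical minimisation of :func:`bulk_free_energy_uniaxial`.
    """
    if u_lc < 8.0 / 3.0:
        return 0.0
    q = 0.25 + 0.75 * np.sqrt(max(1.0 - 8.0 / (3.0 * u_lc), 0.0))
    if check_numeric:
        res = minimize_scalar(lambda s: bulk_free_energy_uniaxial(s, a0, u_lc),
                              bounds=(1e-6, 1.5), method="bounded",
                              options={"xatol": 1e-12})
        if abs(res.x - q) > 1e-5:
            raise RuntimeError(
                f"closed form ({q:.6f}) and numerical minimum ({res.x:.6f}) "
                "of the bulk free energy disagree")
    return float(q)


def _feq(rho, ux, uy):
    cu = _CX[:, None, None] * ux[None] + _CY[:, None, None] * uy[None]
    usq = ux ** 2 + uy ** 2
    return _W[:, None, None] * rho[None] * \
        (1.0 + 3.0 * cu + 4.5 * cu ** 2 - 1.5 * usq[None])


def lb_init(config: LBConfig, seed: int | None = None) -> LBState:
    """Uniform ordered state with seeded director-angle perturbations."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(int(seed))
    ny, nx = config.ny, config.nx
    q0 = equilibrium_order(config.u_lc, config.a0)
    theta = np.zeros((ny, nx))
    if config.perturbation > 0:
        theta = theta + rng.normal(0.0, config.perturbation, size=(ny, nx))
    c, s = np.cos(theta), np.sin(theta)
    qxx = q0 * (c * c - 1.0 / 3.0)
    qyy = q0 * (s * s - 1.0 / 3.0)
    qxy = q0 * c * s
    rho = np.ones((ny, nx))
    ux = np.zeros((ny, nx))
    uy = np.zeros((ny, nx))
    return LBState(f=_feq(rho, ux, uy), rho=rho, ux=ux, uy=uy,
                   qxx=qxx, qyy=qyy, qxy=qxy, step=0)


def _dx(a):
    return 0.5 * (np.roll(a, -1, axis=1) - np.roll(a, 1, axis=1))


def _dy(a):
    return 0.5 * (np.roll(a, -1, axis=0) - np.roll(a, 1, axis=0))


def _lap(a):
    return (np.roll(a, -1, axis=0) + np.roll(a, 1, axis=0) +
            np.roll(a, -1, axis=1) + np.roll(a, 1, axis=1) - 4.0 * a)


def _molecular_field(qxx, qyy, qxy, cfg: LBConfig):
    """H = -dF/dQ (traceless by construction since Tr Q = 0)."""
    a0, u = cfg.a0, cfg.u_lc
    qzz = -(qxx + qyy)
    tr2 = qxx ** 2 + qyy ** 2 + qzz ** 2 + 2.0 * qxy ** 2
    sq_xx = qxx ** 2 + qxy ** 2
    sq_yy = qyy ** 2 + qxy ** 2
    sq_xy = qxy * (qxx + qyy)
    lin = a0 * (1.0 - u / 3.0)
    hxx = -lin * qxx + a0 * u * (sq_xx - tr2 / 3.0) - a0 * u * qxx * tr2 \
        + cfg.k_elastic * _lap(qxx)
    hyy = -lin * qyy + a0 * u * (sq_yy - tr2 / 3.0) - a0 * u * qyy * tr2 \
        + cfg.k_elastic * _lap(qyy)
    hxy = -lin * qxy + a0 * u * sq_xy - a0 * u * qxy * tr2 \
        + cfg.k_elastic * _lap(qxy)
    return hxx, hyy, hxy


def _stress_force(state: LBState, cfg: LBConfig, hxx, hyy, hxy):
    """F = div(sigma) with sigma the elastic + active stress."""
    qxx, qyy, qxy = state.qxx, state.qyy, state.qxy
    qzz = -(qxx + qyy)
    hzz = -(hxx + hyy)
    xi = cfg.xi
    axx, ayy, axy = qxx + 1.0 / 3.0, qyy + 1.0 / 3.0, qxy
    tr_qh = qxx * hxx + qyy * hyy + qzz * hzz + 2.0 * qxy * hxy
    # symmetric flow-alignment part: -xi(HA + AH) + 2 xi A Tr(QH)
    ha_xx = hxx * axx + hxy * axy
    ha_yy = hxy * axy + hyy * ayy
    ha_xy = hxx * axy + hxy * ayy
    ah_xy = axx * hxy + axy * hyy
    s_xx = -2.0 * xi * ha_xx + 2.0 * xi * axx * tr_qh
    s_yy = -2.0 * xi * ha_yy + 2.0 * xi * ayy * tr_qh
    s_xy_sym = -xi * (ha_xy + ah_xy) + 2.0 * xi * axy * tr_qh
    # antisymmetric part: (QH - HQ)_xy = Qxx Hxy + Qxy Hyy - Hxx Qxy - Hxy Qyy
    anti = qxx * hxy + qxy * hyy - hxx * qxy - hxy * qyy
    # Ericksen distortion stress: -K d_i Q_kl d_j Q_kl
    k = cfg.k_elastic
    gx = (_dx(qxx), _dx(qyy), _dx(qzz), _dx(qxy))
    gy = (_dy(qxx), _dy(qyy), _dy(qzz), _dy(qxy))
    def dot(a, b):
        return a[0] * b[0] + a[1] * b[1] + a[2] * b[2] + 2.0 * a[3] * b[3]
    e_xx = -k * dot(gx, gx)
    e_yy = -k * dot(gy, gy)
    e_xy = -k * dot(gx, gy)
    # total stress (sigma_ij, i = force component); active part -alpha Q
    sig_xx = s_xx + e_xx - cfg.alpha * qxx
    sig_yy = s_yy + e_yy - cfg.alpha * qyy
    sig_xy = s_xy_sym + e_xy + anti - cfg.alpha * qxy
    sig_yx = s_xy_sym + e_xy - anti - cfg.alpha * qxy
    fx = _dx(sig_xx) + _dy(sig_xy)
    fy = _dx(sig_yx) + _dy(sig_yy)
    return fx, fy


def _beris_edwards_update(state: LBState, cfg: LBConfig, hxx, hyy, hxy):
    qxx, qyy, qxy = state.qxx, state.qyy, state.qxy
    ux, uy = state.ux, state.uy
    xi = cfg.xi
    wxx = _dx(ux)
    wxy = _dy(ux)     # W_ij = d_j u_i
    wyx = _dx(uy)
    wyy = _dy(uy)
    dxx, dyy = wxx, wyy
    dxy = 0.5 * (wxy + wyx)
    oxy = 0.5 * (wxy - wyx)   # Omega_xy
    axx, ayy, axy = qxx + 1.0 / 3.0, qyy + 1.0 / 3.0, qxy
    tr_qw = qxx * dxx + qyy * dyy + 2.0 * qxy * dxy
    sxx = 2.0 * xi * dxx * axx + 2.0 * (xi * dxy + oxy) * axy \
        - 2.0 * xi * axx * tr_qw
    syy = 2.0 * xi * dyy * ayy + 2.0 * (xi * dxy - oxy) * axy \
        - 2.0 * xi * ayy * tr_qw
    sxy = xi * dxy * (axx + ayy) + oxy * (ayy - axx) \
        + xi * axy * (dxx + dyy) - 2.0 * xi * axy * tr_qw
    adv_xx = ux * _dx(qxx) + uy * _dy(qxx)
    adv_yy = ux * _dx(qyy) + uy * _dy(qyy)
    adv_xy = ux * _dx(qxy) + uy * _dy(qxy)
    g = cfg.gamma_rot
    state.qxx = qxx + (-adv_xx + sxx + g * hxx)
    state.qyy = qyy + (-adv_yy + syy + g * hyy)
    state.qxy = qxy + (-adv_xy + sxy + g * hxy)


def lb_step(state: LBState, config: LBConfig) -> LBState:
    """One hybrid update: Q-tensor finite-difference step, then BGK LB step."""
    hxx, hyy, hxy = _molecular_field(state.qxx, state.qyy, state.qxy, config)
    fx, fy = _stress_force(state, config, hxx, hyy, hxy)
    # macroscopic fields including the Guo half-force shift
    rho = state.f.sum(axis=0)
    ux = (np.einsum("i,ijk->jk", _CX.astype(float), state.f) + 0.5 * fx) / rho
    uy = (np.einsum("i,ijk->jk", _CY.astype(float), state.f) + 0.5 * fy) / rho
    state.rho, state.ux, state.uy = rho, ux, uy
    # order-parameter dynamics use the current velocity field
    _beris_edwards_update(state, config, hxx, hyy, hxy)
    # BGK collision with Guo forcing, then streaming
    feq = _feq(rho, ux, uy)
    cu = _CX[:, None, None] * ux[None] + _CY[:, None, None] * uy[None]
    cf = _CX[:, None, None] * fx[None] + _CY[:, None, None] * fy[None]
    uf = ux * fx + uy * fy
    source = (1.0 - 0.5 / config.tau) * _W[:, None, None] * \
        (3.0 * (cf - uf[None]) + 9.0 * cu * cf)
    f_post = state.f - (state.f - feq) / config.tau + source
    for i in range(9):
        f_post[i] = np.roll(np.roll(f_post[i], _CY[i], axis=0),
                            _CX[i], axis=1)
    state.f = f_post
    state.step += 1
    if not (np.isfinite(state.f).all() and np.isfinite(state.qxx).all()):
        raise FloatingPointError(
            f"lattice-Boltzmann fields diverged at step {state.step}")
    return state


def kinetic_energy(state: LBState) -> float:
    """Mean over sites of rho |u|^2 / 2."""
    return float(np.mean(0.5 * state.rho * (state.ux ** 2 + state.uy ** 2)))


def mean_order(state: LBState) -> float:
    """Mean scalar order parameter q = (3/2) * max in-plane eigenvalue."""
    half_tr = 0.5 * (state.qxx + state.qyy)
    disc = np.sqrt(0.25 * (state.qxx - state.qyy) ** 2 + state.qxy ** 2)
    return float(np.mean(1.5 * (half_tr + disc)))


def lb_run(config: LBConfig, seed: int | None = None) -> LBTimeSeries:
    """Burn in, then sample kinetic energy, mean speed and mean q."""
    state = lb_init(config, seed=seed)
    for _ in range(config.burn_in):
        lb_step(state, config)
    n_samples = config.n_steps // config.sample_every
    steps = np.empty(n_samples, dtype=int)
    ke = np.empty(n_samples)
    speed = np.empty(n_samples)
    mq = np.empty(n_samples)
    k = 0
    for t in range(1, config.n_steps + 1):
        lb_step(state, config)
        if t % config.sample_every == 0:
            steps[k] = state.step
            ke[k] = kinetic_energy(state)
            speed[k] = float(np.mean(np.hypot(state.ux, state.uy)))
            mq[k] = mean_order(state)
            k += 1
    return LBTimeSeries(steps=steps, kinetic_energy=ke, mean_speed=speed,
                        mean_q=mq)


def energy_vs_elasticity(k_values, alpha: float = 0.01, n_seeds: int = 3,
                         master_seed: int = 0,
                         config: LBConfig | None = None) -> "np.ndarray":
    """Time-averaged kinetic energy for each K, for each seed.

    Returns an array of shape (len(k_values), n_seeds).
    """
    base = config or LBConfig(alpha=alpha, burn_in=3000, n_steps=2000)
    out = np.empty((len(k_values), n_seeds))
    for i, k in enumerate(k_values):
        cfg = replace(base, k_elastic=float(k), alpha=alpha)
        seeds = derive_seeds(master_seed, n_seeds, stream=7000 + i)
        for j in range(n_seeds):
            series = lb_run(cfg, seed=int(seeds[j]))
            out[i, j] = series.kinetic_energy.mean()
    return out


def measure_viscosity(tau: float = 1.5, nx: int = 64, ny: int = 64,
                      n_steps: int = 600, amplitude: float = 1e-3
                      ) -> tuple[float, float]:
    """Kinematic viscosity from the decay of a seeded shear wave.

    Runs the pure fluid (isotropic Q = 0, xi = 0, K = 0, alpha = 0) with a
    transverse wave ux ~ sin(2 pi y / ny) and fits the exponential decay rate
    gamma = nu k^2.  Returns (measured eta, analytic eta = (tau - 1/2)/3).
    """
    cfg = LBConfig(nx=nx, ny=ny, tau=tau, xi=0.0, k_elastic=0.0, alpha=0.0,
                   perturbation=0.0)
    state = lb_init(cfg, seed=0)
    state.qxx[:] = 0.0
    state.qyy[:] = 0.0
    state.qxy[:] = 0.0
    y = np.arange(ny)
    kwave = 2.0 * np.pi / ny
    state.ux = amplitude * np.sin(kwave * y)[:, None] * np.ones((ny, nx))
    state.f = _feq(state.rho, state.ux, state.uy)
    mode = np.sin(kwave * y)[:, None]
    amps = []
    for _ in range(n_steps):
        lb_step(state, cfg)
        amps.append(2.0 * np.mean(state.ux * mode))
    amps = np.asarray(amps)
    t = np.arange(1, n_steps + 1, dtype=float)
    keep = amps > amplitude * 1e-3
    slope = np.polyfit(t[keep], np.log(amps[keep]), 1)[0]
    nu = -slope / kwave ** 2
    return float(nu), (tau - 0.5) / 3.0
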