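"""Hydrodynamic scaling: from microscopic motor curves to nematic flow.

Active-nematic turbulence is governed by a single length scale set by the
balance of elastic stress K/l^2 with the active stress scale alpha, so that
l = sqrt(K/alpha), and by force balance the mean flow speed is
v = l*alpha/eta = sqrt(K*alpha)/eta with eta the solvent viscosity.

The microscopic input enters twice.  The activity follows the interfilament
strain rate, alpha = alpha0 * epsilon**beta, and the elastic constant is
augmented by crosslinking,

    K = K0 + kappa * c_e,      c_e = c_m * P_cl + c_p,

where K0 is the excluded-volume baseline, kappa the energetic penalty per
unit crosslinker concentration, c_m the (dimensionless) motor concentration
and c_p an optional passive-crosslinker concentration.  Because P_cl falls
and epsilon rises with [ATP], v = sqrt(K*alpha)/eta can peak at intermediate
[ATP]: at the peak K'*alpha + K*alpha' = 0, with primes denoting [ATP]
derivatives.  A Michaelis-Menten alternative parameterisation of the
microscopic curves is provided for robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .motor_kinetics import MicroscopicCurves, default_atp_grid

__all__ = [
    "ScalingParams", "HydroCurves", "PeakResult", "MMParams",
    "activity_from_strain", "elastic_constant", "hydrodynamic_prediction",
    "predict_curves", "find_speed_peak", "mm_microscopic_curves",
]


@dataclass(frozen=True)
class ScalingParams:
    """Parameters of the activity/elasticity scaling map (model units)."""
    k0: float = 0.001        # baseline elastic constant K0
    kappa: float = 0.01      # crosslink elasticity coefficient (10*K0)
    beta: float = 0.1        # activity exponent in alpha ~ epsilon**beta
    eta: float = 1.0         # solvent viscosity
    c_m: float = 1.0         # dimensionless motor concentration
    c_p: float = 0.0         # passive crosslinker concentration
    alpha0: float = 1.0      # activity prefactor

    def __post_init__(self):
        if self.k0 <= 0 or self.eta <= 0 or self.alpha0 <= 0:
            raise ValueError("k0, eta and alpha0 must be positive")
        if self.kappa < 0 or self.c_p < 0:
            raise ValueError("kappa and c_p must be non-negative")
        if not 0.0 <= self.beta <= 2.0:
            raise ValueError("beta must lie in [0, 2]")


@dataclass
class HydroCurves:
    """Activity, elasticity and predicted flow curves on an [ATP] grid."""
    atp: np.ndarray
    alpha: np.ndarray
    k_elastic: np.ndarray
    v: np.ndarray
    ell: np.ndarray
    normalized: bool = False
    v_scale: float = 1.0
    ell_scale: float = 1.0


@dataclass
class PeakResult:
    atp_peak: float          # grid argmax of v
    alpha_peak: float
    residual: float          # |K'a + Ka'| / max(|K'a| + |Ka'|), at the peak
    boundary_flag: bool
    k_prime_at_peak: float
    flat: bool = False
    atp_peak_refined: float | None = None   # local quadratic vertex in log[ATP]


def activity_from_strain(epsilon, beta: float = 0.1, alpha0: float = 1.0):
    """alpha = alpha0 * epsilon**beta (normalized strain-rate input)."""
    epsilon = np.asarray(epsilon, dtype=float)
    if np.any(epsilon < 0):
        raise ValueError("strain rate must be non-negative")
    with np.errstate(divide="ignore"):
        alpha = alpha0 * np.power(epsilon, beta)
    if beta == 0:
        alpha = np.full_like(epsilon, alpha0)
    return alpha if alpha.ndim else float(alpha)


def elastic_constant(p_cl, params: ScalingParams):
    """K = K0 + kappa * (c_m * P_cl + c_p); never below K0."""
    p_cl = np.asarray(p_cl, dtype=float)
    if np.any(p_cl < 0) or np.any(p_cl > 1):
        raise ValueError("P_cl must lie in [0, 1]")
    k = params.k0 + params.kappa * (params.c_m * p_cl + params.c_p)
    return k if k.ndim else float(k)


def hydrodynamic_prediction(k_elastic, alpha, eta: float = 1.0):
    """(v, l) from stress balance: l = sqrt(K/alpha), v = sqrt(K*alpha)/eta.

    alpha = 0 yields l = inf (no active length selected) and v = 0.
    """
    k_elastic = np.asarray(k_elastic, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(k_elastic <= 0) or eta <= 0:
        raise ValueError("K and eta must be positive")
    if np.any(alpha < 0):
        raise ValueError("alpha must be non-negative")
    with np.errstate(divide="ignore"):
        ell = np.sqrt(k_elastic / alpha)
    v = np.sqrt(k_elastic * alpha) / eta
    if ell.ndim:
        return v, ell
    return float(v), float(ell)


def predict_curves(micro: MicroscopicCurves,
                   params: ScalingParams | None = None) -> HydroCurves:
    """Compose the scaling map pointwise and normalize v, l to maximum 1.

    The strain rate enters only through the power law alpha ~ epsilon**beta,
    so it is normalized to its grid maximum first (the activity scale is
    absorbed by alpha0); P_cl is used as given, since it enters the elastic
    constant as a physical concentration.
    """
    params = params or ScalingParams()
    eps = np.asarray(micro.epsilon, dtype=float)
    e_max = float(np.max(eps))
    if e_max <= 0:
        raise ValueError("strain-rate curve is identically zero")
    alpha = activity_from_strain(eps / e_max, params.beta, params.alpha0)
    k = elastic_constant(micro.p_cl, params)
    v, ell = hydrodynamic_prediction(k, alpha, params.eta)
    finite = np.isfinite(ell)
    v_max = float(np.max(v))
    ell_max = float(np.max(ell[finite])) if np.any(finite) else 1.0
    if v_max <= 0:
        raise ValueError("predicted speed is identically zero")
    return HydroCurves(atp=np.asarray(micro.atp, float), alpha=alpha,
                       k_elastic=k, v=v / v_max, ell=ell / ell_max,
                       normalized=True, v_scale=v_max, ell_scale=ell_max)


def find_speed_peak(curves: HydroCurves, refine: int = 0) -> PeakResult:
    """Locate the speed maximum and check the stationarity condition there.

    The residual reports |K'*alpha + K*alpha'| at the peak (central finite
    differences on the [ATP] grid), normalized by the largest magnitude of
    the two competing terms anywhere on the grid; for an interior peak of a
    smooth curve it vanishes as the grid is refined.

    ``refine`` > 0 additionally fits a quadratic in log[ATP] over that many
    grid points on each side of the argmax and reports its vertex as
    ``atp_peak_refined``.  Because v([ATP]) is very flat near its maximum
    for small beta, the broad vertex fit localises the peak of noisy curves
    far better than the raw argmax.
    """
    v = np.asarray(curves.v, float)
    atp = np.asarray(curves.atp, float)
    if v.size < 3:
        raise ValueError("need at least 3 grid points")
    i = int(np.argmax(v))
    flat = bool(np.allclose(v, v[0]))
    boundary = i in (0, v.size - 1) or flat
    kp = np.gradient(curves.k_elastic, atp)
    ap = np.gradient(curves.alpha, atp)
    stat = kp * curves.alpha + curves.k_elastic * ap
    scale = float(np.max(np.abs(kp * curves.alpha)) +
                  np.max(np.abs(curves.k_elastic * ap)))
    residual = float(np.abs(stat[i]) / scale) if scale > 0 else 0.0
    refined = None
    if refine > 0 and not flat:
        x = np.log(atp)
        lo, hi = max(0, i - refine), min(v.size, i + refine + 1)
        c2, c1, _ = np.polyfit(x[lo:hi], v[lo:hi], 2)
        if c2 < 0:
            refined = float(np.exp(np.clip(-c1 / (2 * c2), x[lo], x[hi - 1])))
        else:
            refined = float(atp[i])
    return PeakResult(atp_peak=float(atp[i]),
                      alpha_peak=float(curves.alpha[i]),
                      residual=residual, boundary_flag=boundary,
                      k_prime_at_peak=float(kp[i]), flat=flat,
                      atp_peak_refined=refined)


@dataclass(frozen=True)
class MMParams:
    """Michaelis-Menten parameterisation of the microscopic curves."""
    v_max: float = 1.0       # saturating motor speed
    km_v: float = 50.0       # half-saturation for speed, uM
    p_max: float = 1.0       # crosslink probability at [ATP] -> 0
    p_floor: float = 0.05    # residual crosslink probability at high [ATP]
    km_p: float = 50.0       # half-saturation for unbinding, uM

    def __post_init__(self):
        if min(self.v_max, self.km_v, self.p_max, self.p_floor, self.km_p) <= 0:
            raise ValueError("Michaelis-Menten parameters must be positive")
        if not self.p_floor < self.p_max <= 1.0:
            raise ValueError("need p_floor < p_max <= 1")


def mm_microscopic_curves(atp_grid: np.ndarray | None = None,
                          params: MMParams | None = None) -> MicroscopicCurves:
    """Closed-form curves: rising v_m(A), falling P_cl(A), epsilon = v_m*P_cl."""
    params = params or MMParams()
    atp = default_atp_grid() if atp_grid is None else np.asarray(atp_grid, float)
    v_m = params.v_max * atp / (params.km_v + atp)
    p_cl = params.p_floor + (params.p_max - params.p_floor) * \
        params.km_p / (params.km_p + atp)
    return MicroscopicCurves(atp=atp, epsilon=v_m * p_cl, p_cl=p_cl)
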