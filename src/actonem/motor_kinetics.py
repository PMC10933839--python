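"""Stochastic kinetics of synthetic motor clusters on one or two filaments.

A cluster carries ``n_heads`` independent enzymatic heads, each cycling
through three states (unbound/ATP -> bound/ADP -> bound/apo -> unbound) with
irreversible rates k12, k23 and k31 = k31_per_atp * [ATP].  The joint between
lever arm and multimerisation domain is flexible, so a binding head draws its
position from N(x(t) + s/2, sd = s/2), where x(t) sits a distance s/2 ahead
of the rearmost bound head on that filament and s is the motor step size.
With two filaments the binding target is chosen uniformly at random.

From ensembles of such trajectories the module computes single-filament
velocity and run length, and — for filament pairs — the strain rate epsilon
(anchor motion accrued while the cluster crosslinks both filaments, per unit
time) and the crosslink probability P_cl (fraction of time both filaments
carry at least one bound head).  Closed-form renewal/combinatorial oracles
for the stationary bound fraction and P_cl are provided for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _gillespie
from ._gillespie import TRANS_BIND, TRANS_RELEASE, TRANS_UNBIND

__all__ = [
    "RateConstants", "ClusterConfig", "MotorTrajectory",
    "SingleFilamentStats", "TwoFilamentStats", "MicroscopicCurves",
    "CalibrationResult", "gillespie_trajectory", "single_filament_summary",
    "two_filament_summary", "stationary_bound_fraction",
    "crosslink_probability_closed_form", "calibrate_rates", "sweep_atp",
    "derive_seeds", "default_atp_grid",
]

_TRANS_LABELS = {TRANS_BIND: "1->2", TRANS_RELEASE: "2->3",
                 TRANS_UNBIND: "3->1"}


def derive_seeds(master_seed: int, n: int, stream: int = 0) -> np.ndarray:
    """Derive ``n`` independent 31-bit seeds from a master seed.

    Uses :class:`numpy.random.SeedSequence` with ``(master_seed, stream)`` as
    entropy, so distinct streams (e.g. grid points of a sweep) never collide.
    """
    ss = np.random.SeedSequence([int(master_seed), int(stream)])
    return (ss.generate_state(n, dtype=np.uint64) % (2 ** 31)).astype(np.int64)


@dataclass(frozen=True)
class RateConstants:
    """Catalytic rates of a single head.

    k12, k23 in 1/s; k31_per_atp in 1/(s*uM), so k31 = k31_per_atp * [ATP].
    """
    k12: float
    k23: float
    k31_per_atp: float

    def __post_init__(self):
        if not (self.k12 > 0 and self.k23 > 0 and self.k31_per_atp > 0):
            raise ValueError("rate constants must be strictly positive")

    def k31(self, atp: float) -> float:
        if atp < 0:
            raise ValueError("[ATP] must be non-negative")
        return self.k31_per_atp * atp


@dataclass(frozen=True)
class ClusterConfig:
    """Geometry and composition of a motor cluster."""
    n_heads: int = 4
    step_size: float = 0.036      # um; actin pseudo-helical repeat
    n_filaments: int = 1
    c_m: float = 1.0              # dimensionless motor concentration
    bind_sd: float | None = None  # binding-position spread; default s/2

    def __post_init__(self):
        if not 1 <= self.n_heads <= 16:
            raise ValueError("n_heads must be in 1..16")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.n_filaments not in (1, 2):
            raise ValueError("n_filaments must be 1 or 2")
        if self.bind_sd is not None and self.bind_sd <= 0:
            raise ValueError("bind_sd must be positive")

    @property
    def binding_sd(self) -> float:
        """Standard deviation of the binding-position draw N(x + s/2, sd)."""
        return self.bind_sd if self.bind_sd is not None else 0.5 * self.step_size


@dataclass
class MotorTrajectory:
    """Event-resolved history of one cluster simulation.

    Events are ordered by time; ``anchors[i]`` is the per-filament anchor
    x(t) immediately after event ``i`` (anchors start at 0).
    """
    times: np.ndarray
    heads: np.ndarray
    transitions: np.ndarray      # codes: 0 = 1->2, 1 = 2->3, 2 = 3->1
    filaments: np.ndarray
    positions: np.ndarray        # binding positions (valid for 1->2 events)
    anchors: np.ndarray          # (n_events, 2)
    t_final: float
    seed: int
    cluster: ClusterConfig
    rates: RateConstants
    atp: float

    @property
    def n_events(self) -> int:
        return len(self.times)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.times,
            "head": self.heads,
            "transition": [_TRANS_LABELS[c] for c in self.transitions],
            "filament": self.filaments,
            "position": self.positions,
        })

    def holding_times(self, state: int, head: int | None = None) -> np.ndarray:
        """Sojourn times spent in ``state`` (1, 2 or 3), completed only."""
        enter = {1: TRANS_UNBIND, 2: TRANS_BIND, 3: TRANS_RELEASE}[state]
        leave = {1: TRANS_BIND, 2: TRANS_RELEASE, 3: TRANS_UNBIND}[state]
        out = []
        heads = range(self.cluster.n_heads) if head is None else [head]
        for h in heads:
            mask = self.heads == h
            t = self.times[mask]
            tr = self.transitions[mask]
            # state 1 is the initial state: its first sojourn starts at t = 0
            t_enter = 0.0 if state == 1 else None
            for ti, ci in zip(t, tr):
                if ci == leave and t_enter is not None:
                    out.append(ti - t_enter)
                    t_enter = None
                elif ci == enter:
                    t_enter = ti
        return np.asarray(out)


@dataclass
class SingleFilamentStats:
    velocity: float              # um/s, signed ensemble mean
    run_length: float            # um, mean over runs
    n_runs: int
    se_velocity: float
    se_run_length: float
    no_runs: bool = False


@dataclass
class TwoFilamentStats:
    epsilon: float               # um/s
    p_cl: float                  # dimensionless
    se_epsilon: float
    se_p_cl: float


@dataclass
class MicroscopicCurves:
    """epsilon([ATP]) and P_cl([ATP]) on an ascending [ATP] grid."""
    atp: np.ndarray              # uM
    epsilon: np.ndarray
    p_cl: np.ndarray
    se_epsilon: np.ndarray | None = None
    se_p_cl: np.ndarray | None = None
    normalized: bool = False
    epsilon_scale: float = 1.0   # multiply back to recover raw curves
    p_cl_scale: float = 1.0

    def __post_init__(self):
        self.atp = np.asarray(self.atp, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        self.p_cl = np.asarray(self.p_cl, dtype=float)
        if np.any(np.diff(self.atp) <= 0):
            raise ValueError("[ATP] grid must be sorted strictly ascending")

    def normalize(self) -> "MicroscopicCurves":
        """Return a copy with each curve scaled to maximum exactly 1."""
        e_max = float(np.max(self.epsilon))
        p_max = float(np.max(self.p_cl))
        if e_max <= 0 or p_max <= 0:
            raise ValueError("cannot normalize an identically zero curve")
        return replace(
            self,
            epsilon=self.epsilon / e_max,
            p_cl=self.p_cl / p_max,
            se_epsilon=None if self.se_epsilon is None else self.se_epsilon / e_max,
            se_p_cl=None if self.se_p_cl is None else self.se_p_cl / p_max,
            normalized=True, epsilon_scale=e_max, p_cl_scale=p_max,
        )


def default_atp_grid(n: int = 40, lo: float = 1.0, hi: float = 1000.0) -> np.ndarray:
    """Log-spaced [ATP] grid in uM."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


# ---------------------------------------------------------------------------
# simulation


def _event_capacity(cluster: ClusterConfig, rates: RateConstants, atp: float,
                    t_max: float) -> int:
    k31 = rates.k31(atp)
    if k31 <= 0:
        return 4 * cluster.n_heads + 64
    cycle = 1.0 / rates.k12 + 1.0 / rates.k23 + 1.0 / k31
    mean_events = 3.0 * cluster.n_heads * t_max / cycle
    return int(mean_events + 6.0 * np.sqrt(mean_events + 1.0)) + 256


def gillespie_trajectory(cluster: ClusterConfig, rates: RateConstants,
                         atp: float, t_max: float, seed: int) -> MotorTrajectory:
    """Exact stochastic simulation of one cluster, with full event log."""
    if atp < 0:
        raise ValueError("[ATP] must be non-negative")
    if t_max < 0:
        raise ValueError("t_max must be non-negative")
    k31 = rates.k31(atp)
    cap = _event_capacity(cluster, rates, atp, t_max)
    while True:
        out = _gillespie.simulate_cluster(
            cluster.n_heads, cluster.n_filaments, rates.k12, rates.k23, k31,
            cluster.step_size, cluster.binding_sd, t_max, int(seed), cap)
        if not out[10]:
            break
        cap *= 2  # overflowed the event log: rerun with more room
    (_, _, _, _, _, _, _, _, _, _, _,
     ev_t, ev_head, ev_trans, ev_fil, ev_pos, ev_x) = out
    positions = np.where(ev_trans == TRANS_BIND, ev_pos, np.nan)
    return MotorTrajectory(
        times=ev_t.copy(), heads=ev_head.copy(), transitions=ev_trans.copy(),
        filaments=ev_fil.copy(), positions=positions, anchors=ev_x.copy(),
        t_final=t_max, seed=int(seed), cluster=cluster, rates=rates, atp=atp)


def _trajectory_accumulators(traj: MotorTrajectory):
    """Recompute kernel accumulators from an event log (numpy reduction)."""
    tr = traj.transitions
    fil = traj.filaments
    t = traj.times
    n_ev = len(t)
    # bound-head counts per filament, after each event
    delta = np.zeros((n_ev, 2))
    for f in (0, 1):
        delta[(tr == TRANS_BIND) & (fil == f), f] = 1
        delta[(tr == TRANS_UNBIND) & (fil == f), f] = -1
    counts = np.cumsum(delta, axis=0)
    pre = np.vstack([np.zeros(2), counts[:-1]]) if n_ev else np.zeros((0, 2))
    anchors = traj.anchors
    prev_anchor = np.vstack([np.zeros(2), anchors[:-1]]) if n_ev else np.zeros((0, 2))
    jumps = anchors - prev_anchor
    disp = jumps.sum(axis=0) if n_ev else np.zeros(2)
    cross_pre = (pre[:, 0] > 0) & (pre[:, 1] > 0)
    strain = float(jumps[cross_pre].sum()) if n_ev else 0.0
    # time-weighted occupancy of the crosslinked / bound states
    edges = np.concatenate([[0.0], t, [traj.t_final]])
    dt = np.diff(edges)                      # interval i follows event i-1
    state = np.vstack([np.zeros(2), counts]) if n_ev else np.zeros((1, 2))
    crossed = (state[:, 0] > 0) & (state[:, 1] > 0)
    bound = state.sum(axis=1) > 0
    t_cross = float(dt[crossed].sum())
    t_bound = float(dt[bound].sum())
    # runs: maximal intervals with >= 1 bound head
    run_lengths = []
    x_tot = anchors.sum(axis=1)
    start_x = None
    for i in range(n_ev):
        if not bound[i] and bound[i + 1]:
            start_x = x_tot[i]
        elif start_x is not None and bound[i] and not bound[i + 1]:
            run_lengths.append(x_tot[i] - start_x)
            start_x = None
    if start_x is not None and n_ev and bound[-1]:
        run_lengths.append(x_tot[-1] - start_x)
    return disp, strain, t_cross, t_bound, np.asarray(run_lengths)


def single_filament_summary(trajectories: Sequence[MotorTrajectory],
                            cluster: ClusterConfig) -> SingleFilamentStats:
    """Velocity and run length from an ensemble of single-filament runs.

    Velocity is total anchor displacement over total simulated time; a run is
    a maximal interval with at least one head bound, and its length is the
    anchor displacement between the first and last bound instants.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("empty trajectory ensemble")
    if any(tr.cluster.n_filaments != 1 for tr in trajectories):
        raise ValueError("single_filament_summary requires n_filaments = 1")
    velocities, runs = [], []
    total_disp = total_time = 0.0
    for tr in trajectories:
        disp, _, _, _, run_lengths = _trajectory_accumulators(tr)
        total_disp += disp[0]
        total_time += tr.t_final
        velocities.append(disp[0] / tr.t_final if tr.t_final > 0 else 0.0)
        runs.extend(run_lengths)
    if total_time <= 0:
        raise ValueError("zero total simulated time")
    runs = np.asarray(runs)
    n_runs = len(runs)
    velocity = total_disp / total_time
    se_v = float(np.std(velocities, ddof=1) / np.sqrt(len(velocities))) \
        if len(velocities) > 1 else np.nan
    if n_runs == 0:
        return SingleFilamentStats(velocity=velocity, run_length=0.0,
                                   n_runs=0, se_velocity=se_v,
                                   se_run_length=np.nan, no_runs=True)
    se_rl = float(np.std(runs, ddof=1) / np.sqrt(n_runs)) if n_runs > 1 else np.nan
    return SingleFilamentStats(velocity=velocity,
                               run_length=float(np.mean(runs)),
                               n_runs=n_runs, se_velocity=se_v,
                               se_run_length=se_rl)


def two_filament_summary(trajectories: Sequence[MotorTrajectory],
                         cluster: ClusterConfig) -> TwoFilamentStats:
    """Strain rate epsilon and crosslink probability P_cl for filament pairs."""
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("empty trajectory ensemble")
    if any(tr.cluster.n_filaments != 2 for tr in trajectories):
        raise ValueError("two_filament_summary requires n_filaments = 2")
    eps_i, pcl_i = [], []
    tot_strain = tot_cross = tot_time = 0.0
    for tr in trajectories:
        _, strain, t_cross, _, _ = _trajectory_accumulators(tr)
        tot_strain += strain
        tot_cross += t_cross
        tot_time += tr.t_final
        if tr.t_final > 0:
            eps_i.append(strain / tr.t_final)
            pcl_i.append(t_cross / tr.t_final)
    if tot_time <= 0:
        raise ValueError("zero total simulated time")
    n = len(eps_i)
    se = lambda v: float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    return TwoFilamentStats(epsilon=tot_strain / tot_time,
                            p_cl=tot_cross / tot_time,
                            se_epsilon=se(eps_i), se_p_cl=se(pcl_i))


def _ensemble_stats(cluster: ClusterConfig, rates: RateConstants, atp: float,
                    t_max: float, reps: int, seed: int, stream: int = 0):
    """Kernel-side ensemble summaries (no event logs); used by sweeps/scans."""
    seeds = derive_seeds(seed, reps, stream=stream)
    return _gillespie.ensemble_stats(
        cluster.n_heads, cluster.n_filaments, rates.k12, rates.k23,
        rates.k31(atp), cluster.step_size, cluster.binding_sd, t_max, seeds)


def _single_filament_point(cluster, rates, atp, t_max, reps, seed, stream=0):
    disp0, _, _, _, _, n_runs, run_sum, _ = _ensemble_stats(
        replace(cluster, n_filaments=1), rates, atp, t_max, reps, seed, stream)
    velocity = float(disp0.sum()) / (t_max * reps)
    total_runs = int(n_runs.sum())
    run_length = float(run_sum.sum()) / total_runs if total_runs else 0.0
    return velocity, run_length, total_runs


def _two_filament_point(cluster, rates, atp, t_max, reps, seed, stream=0):
    _, _, strain, t_cross, _, _, _, _ = _ensemble_stats(
        replace(cluster, n_filaments=2), rates, atp, t_max, reps, seed, stream)
    total = t_max * reps
    eps = strain / t_max
    pcl = t_cross / t_max
    se = lambda v: float(np.std(v, ddof=1) / np.sqrt(reps)) if reps > 1 else np.nan
    return (float(strain.sum()) / total, float(t_cross.sum()) / total,
            se(eps), se(pcl))


# ---------------------------------------------------------------------------
# closed-form oracles


def stationary_bound_fraction(rates: RateConstants, atp: float) -> float:
    """Stationary probability that a head is bound (states 2 or 3).

    Renewal argument: the cycle spends mean times 1/k12, 1/k23, 1/k31 in the
    three states, of which states 2 and 3 are bound.  At [ATP] = 0 state 3 is
    absorbing and the bound fraction tends to 1.
    """
    if atp < 0:
        raise ValueError("[ATP] must be non-negative")
    if atp == 0:
        return 1.0
    k31 = rates.k31(atp)
    bound = 1.0 / rates.k23 + 1.0 / k31
    return bound / (1.0 / rates.k12 + bound)


def crosslink_probability_closed_form(p_bound: float, n_heads: int) -> float:
    """P_cl for n independent heads with bound fraction p and random filament.

    Each head is on filament A with probability p/2, on B with p/2, unbound
    otherwise; inclusion-exclusion over "A empty" / "B empty" gives
    ``1 - 2(1 - p/2)**n + (1 - p)**n``.
    """
    if not 0.0 <= p_bound <= 1.0:
        raise ValueError("p_bound must be a probability")
    if n_heads < 1:
        raise ValueError("n_heads must be >= 1")
    if n_heads == 1:
        return 0.0   # a single head can never bridge two filaments
    p = p_bound
    val = 1.0 - 2.0 * (1.0 - p / 2.0) ** n_heads + (1.0 - p) ** n_heads
    return min(max(val, 0.0), 1.0)


# ---------------------------------------------------------------------------
# calibration and sweeps


@dataclass
class CalibrationResult:
    rates: RateConstants
    loss: float
    achieved: list            # [(atp, velocity, run_length), ...]
    targets: list             # [(atp, velocity, run_length), ...]
    within_tolerance: bool
    max_rel_error: float
    seed: int


def _calibration_loss(cluster, rates, targets, t_max, reps, seed):
    loss = 0.0
    for i, (atp, v_t, rl_t) in enumerate(targets):
        v, rl, _ = _single_filament_point(cluster, rates, atp, t_max, reps,
                                          seed, stream=1000 + i)
        for sim, tgt in ((v, v_t), (rl, rl_t)):
            if sim <= 1e-9 * tgt:
                loss += 100.0
            else:
                loss += np.log(sim / tgt) ** 2
    return loss


def default_calibration_grid(n: int = 12) -> dict:
    """Logarithmic scan grids: k12, k23 over [0.1, 1e3] 1/s and
    k31_per_atp over [1e-3, 10] 1/(s*uM)."""
    return {
        "k12": np.logspace(-1, 3, n),
        "k23": np.logspace(-1, 3, n),
        "k31_per_atp": np.logspace(-3, 1, n),
    }


def calibrate_rates(targets: Iterable[tuple], scan_grid: dict | None = None,
                    cluster: ClusterConfig | None = None, seed: int = 0,
                    t_max: float = 8.0, coarse_reps: int = 3,
                    fine_reps: int = 16, n_fine: int = 32,
                    refine_rounds: int = 2, final_reps: int = 150,
                    rel_tolerance: float = 0.2) -> CalibrationResult:
    """Scan rate constants for single-filament velocity / run-length targets.

    ``targets`` is a list of (atp_uM, velocity_um_s, run_length_um).  The
    scan minimises the summed squared log-error of simulated versus target
    velocity and run length.  A coarse pass over the full grid ranks points
    cheaply; the best ``n_fine`` are re-simulated with more replicates; one
    or more local log-grid refinements then shrink the spacing around the
    running best.

    ``t_max`` is the observation window of each simulated engagement.  Like
    the finite observation time of a motility experiment, it bounds the
    measurable run length: at low [ATP] a processive cluster stays engaged
    throughout the window, and the reported run length is then
    window-limited (about velocity times window).  The default 8 s window
    matches the few-second engagements seen for low-duty myosin clusters.
    """
    targets = [tuple(t) for t in targets]
    if not targets:
        raise ValueError("no calibration targets given")
    cluster = cluster or ClusterConfig(n_heads=4, n_filaments=1)
    grid = scan_grid or default_calibration_grid()
    for key in ("k12", "k23", "k31_per_atp"):
        if key not in grid or len(np.atleast_1d(grid[key])) == 0:
            raise ValueError(f"scan grid missing values for {key}")
    points = [RateConstants(a, b, c)
              for a in np.atleast_1d(grid["k12"])
              for b in np.atleast_1d(grid["k23"])
              for c in np.atleast_1d(grid["k31_per_atp"])]

    if len(points) == 1:
        best = points[0]
    else:
        coarse = [_calibration_loss(cluster, r, targets, t_max,
                                    coarse_reps, seed) for r in points]
        order = np.argsort(coarse)
        shortlist = [points[i] for i in order[:n_fine]]
        fine = [_calibration_loss(cluster, r, targets, t_max, fine_reps,
                                  seed + 1) for r in shortlist]
        best = shortlist[int(np.argmin(fine))]
        # local refinement: 5-point log grids spanning one coarse spacing
        spacings = {}
        for key in ("k12", "k23", "k31_per_atp"):
            vals = np.sort(np.atleast_1d(grid[key]))
            spacings[key] = (vals[-1] / vals[0]) ** (1 / max(len(vals) - 1, 1)) \
                if len(vals) > 1 else 1.0
        for round_ in range(refine_rounds):
            span = {k: max(s ** (0.5 ** round_), 1.0 + 1e-9)
                    for k, s in spacings.items()}
            local = [RateConstants(a, b, c)
                     for a in np.geomspace(best.k12 / span["k12"],
                                           best.k12 * span["k12"], 5)
                     for b in np.geomspace(best.k23 / span["k23"],
                                           best.k23 * span["k23"], 5)
                     for c in np.geomspace(best.k31_per_atp / span["k31_per_atp"],
                                           best.k31_per_atp * span["k31_per_atp"], 5)]
            losses = [_calibration_loss(cluster, r, targets, t_max,
                                        fine_reps, seed + 2 + round_)
                      for r in local]
            best = local[int(np.argmin(losses))]

    achieved, rel_errs = [], []
    loss = 0.0
    for i, (atp, v_t, rl_t) in enumerate(targets):
        v, rl, _ = _single_filament_point(cluster, best, atp, t_max,
                                          final_reps, seed + 97, stream=i)
        achieved.append((atp, v, rl))
        rel_errs += [abs(v - v_t) / v_t, abs(rl - rl_t) / rl_t]
        for sim, tgt in ((v, v_t), (rl, rl_t)):
            loss += np.log(max(sim, 1e-30) / tgt) ** 2
    max_rel = float(max(rel_errs))
    return CalibrationResult(rates=best, loss=float(loss), achieved=achieved,
                             targets=targets,
                             within_tolerance=max_rel <= rel_tolerance,
                             max_rel_error=max_rel, seed=seed)


def sweep_atp(cluster: ClusterConfig, rates: RateConstants,
              atp_grid: np.ndarray | None = None, reps: int = 100,
              seed: int = 0, t_max: float = 100.0,
              normalize: bool = False) -> MicroscopicCurves:
    """Two-filament epsilon([ATP]) and P_cl([ATP]) over an ascending grid."""
    atp_grid = default_atp_grid() if atp_grid is None else np.asarray(atp_grid, float)
    if atp_grid.size == 0:
        raise ValueError("empty [ATP] grid")
    if np.any(atp_grid <= 0) or np.any(np.diff(atp_grid) <= 0):
        raise ValueError("[ATP] grid must be positive and strictly ascending")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    eps = np.empty(atp_grid.size)
    pcl = np.empty(atp_grid.size)
    se_e = np.empty(atp_grid.size)
    se_p = np.empty(atp_grid.size)
    for i, atp in enumerate(atp_grid):
        eps[i], pcl[i], se_e[i], se_p[i] = _two_filament_point(
            cluster, rates, atp, t_max, reps, seed, stream=i)
    curves = MicroscopicCurves(atp=atp_grid, epsilon=eps, p_cl=pcl,
                               se_epsilon=se_e, se_p_cl=se_p)
    return curves.normalize() if normalize else curves
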