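"""Motor-cluster stochastic kinetics: oracles, invariants, summaries."""

import itertools

import numpy as np
import pytest
from scipy import stats

from actonem.motor_kinetics import (
    ClusterConfig, RateConstants, calibrate_rates,
    crosslink_probability_closed_form, gillespie_trajectory,
    single_filament_summary, stationary_bound_fraction, sweep_atp,
    two_filament_summary,
)
from actonem._gillespie import TRANS_BIND, TRANS_RELEASE, TRANS_UNBIND


def test_rate_constants_validation():
    with pytest.raises(ValueError):
        RateConstants(0.0, 1.0, 1.0)
    with pytest.raises(ValueError):
        RateConstants(1.0, -1.0, 1.0)
    r = RateConstants(1.0, 2.0, 3.0)
    assert r.k31(0.0) == 0.0
    assert r.k31(2.0) == 6.0
    with pytest.raises(ValueError):
        r.k31(-1.0)


def test_zero_time_gives_empty_trajectory():
    traj = gillespie_trajectory(ClusterConfig(n_heads=4),
                                RateConstants(10, 10, 1), atp=50.0,
                                t_max=0.0, seed=1)
    assert traj.n_events == 0
    assert traj.t_final == 0.0


def test_rigor_at_zero_atp_is_absorbing():
    """Without ATP the 3->1 exit is closed: no unbinding events ever occur
    and every head ends bound (nucleotide-free), i.e. rigor."""
    cluster = ClusterConfig(n_heads=4)
    traj = gillespie_trajectory(cluster, RateConstants(5, 5, 1), atp=0.0,
                                t_max=200.0, seed=7)
    assert not np.any(traj.transitions == TRANS_UNBIND)
    # each head performs exactly its 1->2 and 2->3 transitions, then stalls
    assert traj.n_events == 2 * cluster.n_heads
    assert stationary_bound_fraction(RateConstants(5, 5, 1), 0.0) == 1.0


def test_completed_cycle_count_matches_renewal_theory():
    """Single head, unit rates: mean cycle time 3 s, so ~333 cycles in
    1000 s; renewal CLT gives SD sqrt(T*var/mu^3) = 10.5."""
    traj = gillespie_trajectory(ClusterConfig(n_heads=1),
                                RateConstants(1, 1, 1), atp=1.0,
                                t_max=1000.0, seed=42)
    cycles = int(np.sum(traj.transitions == TRANS_UNBIND))
    assert abs(cycles - 1000.0 / 3.0) < 3 * np.sqrt(1000.0 * 3.0 / 27.0)


def test_holding_times_are_exponential():
    """Kolmogorov-Smirnov test of per-state sojourn times against the
    exponential law with the configured rate, >= 1e4 samples."""
    rates = RateConstants(50.0, 80.0, 120.0)
    traj = gillespie_trajectory(ClusterConfig(n_heads=1), rates, atp=1.0,
                                t_max=450.0, seed=3)
    for state, k in ((1, 50.0), (2, 80.0), (3, 120.0)):
        ht = traj.holding_times(state)
        assert len(ht) >= 10_000
        p = stats.kstest(ht, "expon", args=(0, 1.0 / k)).pvalue
        assert p > 0.01, f"state {state}: KS p = {p}"


def test_identical_seeds_give_bit_identical_trajectories():
    cluster = ClusterConfig(n_heads=4, n_filaments=2)
    rates = RateConstants(20, 30, 2)
    a = gillespie_trajectory(cluster, rates, 50.0, 20.0, seed=9)
    b = gillespie_trajectory(cluster, rates, 50.0, 20.0, seed=9)
    c = gillespie_trajectory(cluster, rates, 50.0, 20.0, seed=10)
    assert np.array_equal(a.times, b.times)
    assert np.array_equal(a.anchors, b.anchors)
    assert np.array_equal(a.positions, b.positions, equal_nan=True)
    assert not np.array_equal(a.times, c.times)


def test_event_log_invariants():
    """Times strictly increase; each head cycles 1->2->3->1 in order;
    binding positions appear only on 1->2 events."""
    cluster = ClusterConfig(n_heads=4, n_filaments=2)
    traj = gillespie_trajectory(cluster, RateConstants(30, 40, 3), 30.0,
                                30.0, seed=5)
    assert np.all(np.diff(traj.times) > 0)
    expected = {TRANS_BIND: TRANS_RELEASE, TRANS_RELEASE: TRANS_UNBIND,
                TRANS_UNBIND: TRANS_BIND}
    for h in range(cluster.n_heads):
        tr = traj.transitions[traj.heads == h]
        assert tr[0] == TRANS_BIND          # state 1 is the initial state
        for a, b in zip(tr[:-1], tr[1:]):
            assert b == expected[a]
    assert np.all(np.isnan(traj.positions[traj.transitions != TRANS_BIND]))
    assert np.all(~np.isnan(traj.positions[traj.transitions == TRANS_BIND]))


def test_stationary_bound_fraction_closed_form():
    assert stationary_bound_fraction(RateConstants(1, 1, 1), 1.0) == \
        pytest.approx(2.0 / 3.0)
    assert stationary_bound_fraction(RateConstants(2, 4, 0.5), 1.0) == \
        pytest.approx(2.25 / 2.75)
    # unbound time vanishes as k12 -> infinity
    assert stationary_bound_fraction(RateConstants(1e12, 1, 1), 1.0) == \
        pytest.approx(1.0, abs=1e-10)


def test_crosslink_closed_form_against_enumeration():
    """Brute-force enumeration over 3^n head placements with weights
    (1-p, p/2, p/2) reproduces the inclusion-exclusion formula."""
    for p, n in [(0.5, 4), (0.3, 3), (0.8, 8), (1.0, 2)]:
        total = 0.0
        for combo in itertools.product((0, 1, 2), repeat=n):
            w = 1.0
            for c in combo:
                w *= (1.0 - p) if c == 0 else p / 2.0
            if 1 in combo and 2 in combo:
                total += w
        assert crosslink_probability_closed_form(p, n) == pytest.approx(total)
    assert crosslink_probability_closed_form(0.5, 4) == pytest.approx(0.4297,
                                                                      abs=1e-4)
    assert crosslink_probability_closed_form(1.0, 2) == pytest.approx(0.5)
    for p in (0.0, 0.2, 0.9, 1.0):
        assert crosslink_probability_closed_form(p, 1) == 0.0


def test_single_head_cannot_crosslink():
    cluster = ClusterConfig(n_heads=1, n_filaments=2)
    trajs = [gillespie_trajectory(cluster, RateConstants(10, 10, 1), 20.0,
                                  50.0, seed=s) for s in range(5)]
    st = two_filament_summary(trajs, cluster)
    assert st.p_cl == 0.0
    assert st.epsilon == 0.0


def test_simulated_crosslink_probability_matches_oracle():
    """p = 0.5 stationary bound fraction, tetramer: P_cl = 0.4297."""
    rates = RateConstants(2, 4, 4)    # at atp = 1: p = (1/4+1/4)/(1/2+1/2)
    assert stationary_bound_fraction(rates, 1.0) == pytest.approx(0.5)
    cluster = ClusterConfig(n_heads=4, n_filaments=2)
    trajs = [gillespie_trajectory(cluster, rates, 1.0, 200.0, seed=s)
             for s in range(30)]
    st = two_filament_summary(trajs, cluster)
    expected = crosslink_probability_closed_form(0.5, 4)
    assert abs(st.p_cl - expected) < 3 * st.se_p_cl


def test_summaries_require_matching_geometry():
    cluster1 = ClusterConfig(n_heads=2, n_filaments=1)
    cluster2 = ClusterConfig(n_heads=2, n_filaments=2)
    t1 = gillespie_trajectory(cluster1, RateConstants(5, 5, 1), 10.0, 5.0, 1)
    t2 = gillespie_trajectory(cluster2, RateConstants(5, 5, 1), 10.0, 5.0, 1)
    with pytest.raises(ValueError):
        single_filament_summary([], cluster1)
    with pytest.raises(ValueError):
        two_filament_summary([], cluster2)
    with pytest.raises(ValueError):
        single_filament_summary([t2], cluster2)
    with pytest.raises(ValueError):
        two_filament_summary([t1], cluster1)


def test_no_binding_ensemble_reports_zero_with_flag():
    cluster = ClusterConfig(n_heads=2, n_filaments=1)
    rates = RateConstants(1e-9, 10.0, 1.0)   # binding essentially never
    trajs = [gillespie_trajectory(cluster, rates, 10.0, 1.0, seed=s)
             for s in range(3)]
    st = single_filament_summary(trajs, cluster)
    assert st.velocity == 0.0
    assert st.n_runs == 0
    assert st.run_length == 0.0
    assert st.no_runs


def test_event_log_summary_matches_kernel_accumulators():
    """The numpy event-log reduction and the kernel's online accumulators
    describe the same realisation (same seeds) and must agree."""
    from actonem.motor_kinetics import _two_filament_point, derive_seeds
    cluster = ClusterConfig(n_heads=4, n_filaments=2)
    rates = RateConstants(20, 30, 2)
    seeds = derive_seeds(17, 6, stream=0)
    trajs = [gillespie_trajectory(cluster, rates, 40.0, 30.0, seed=int(s))
             for s in seeds]
    st = two_filament_summary(trajs, cluster)
    eps, pcl, _, _ = _two_filament_point(cluster, rates, 40.0, 30.0, 6,
                                         seed=17, stream=0)
    assert st.epsilon == pytest.approx(eps, rel=1e-10)
    assert st.p_cl == pytest.approx(pcl, rel=1e-10)


def test_sweep_normalization_and_errors():
    cluster = ClusterConfig(n_heads=4, n_filaments=2)
    rates = RateConstants(50, 50, 1)
    grid = np.array([5.0, 50.0, 500.0])
    curves = sweep_atp(cluster, rates, grid, reps=4, seed=2, t_max=10.0,
                       normalize=True)
    assert curves.epsilon.max() == 1.0
    assert curves.p_cl.max() == 1.0
    assert curves.normalized
    with pytest.raises(ValueError):
        sweep_atp(cluster, rates, np.array([]), reps=2, seed=0)
    with pytest.raises(ValueError):
        sweep_atp(cluster, rates, np.array([10.0, 5.0]), reps=2, seed=0)


def test_valency_raises_crosslinking_and_processivity():
    """More heads: higher P_cl at every [ATP]; on single filaments, lower
    speed and longer runs."""
    from actonem.motor_kinetics import _single_filament_point
    rates = RateConstants(1000.0, 433.0, 2.85)
    grid = np.logspace(0, 3, 6)
    pcl = {}
    for n in (3, 8):
        cl = ClusterConfig(n_heads=n, n_filaments=2)
        pcl[n] = sweep_atp(cl, rates, grid, reps=12, seed=4, t_max=10.0).p_cl
    assert np.all(pcl[8] >= pcl[3])
    v, rl = {}, {}
    for n in (3, 4, 8):
        cl = ClusterConfig(n_heads=n, n_filaments=1)
        v[n], rl[n], nr = _single_filament_point(cl, rates, 500.0, 20.0, 40,
                                                 seed=11, stream=0)
        assert nr > 50
    assert v[3] > v[4] > v[8]
    assert rl[3] < rl[4] < rl[8]


def test_single_point_scan_returns_that_point():
    grid = {"k12": [100.0], "k23": [200.0], "k31_per_atp": [1.0]}
    res = calibrate_rates([(100.0, 1.0, 1.0)], scan_grid=grid, seed=0,
                          final_reps=4)
    assert res.rates == RateConstants(100.0, 200.0, 1.0)


def test_scan_grid_validation():
    with pytest.raises(ValueError):
        calibrate_rates([], seed=0)
    with pytest.raises(ValueError):
        calibrate_rates([(10.0, 1.0, 1.0)], scan_grid={"k12": [1.0]}, seed=0)
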