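"""Numba kernel for exact stochastic simulation of motor-cluster stepping.

Each head of a cluster cycles irreversibly through three chemical states:

    1 (unbound, ATP) --k12--> 2 (bound, ADP) --k23--> 3 (bound, apo) --k31--> 1

with k31 proportional to [ATP].  Heads are independent, so at any instant
there are exactly ``n_heads`` allowed transitions and the Gillespie algorithm
reduces to drawing an exponential waiting time at the summed rate and picking
one head with probability proportional to its rate.

The kernel tracks, per filament, the anchor position x(t) of the cluster's
multimerisation domain (rearmost bound head + s/2) and accumulates the summary
statistics needed by the higher-level operations (anchor displacement, strain
accrued while crosslinking, crosslink time, run bookkeeping), optionally
recording the full event log.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# transition codes stored in event logs
TRANS_BIND = 0      # 1 -> 2, head binds a filament
TRANS_RELEASE = 1   # 2 -> 3, ADP release (no spatial change)
TRANS_UNBIND = 2    # 3 -> 1, ATP exchange, head leaves the filament


@njit(cache=True)
def simulate_cluster(n_heads, n_filaments, k12, k23, k31, step, bind_sd,
                     t_max, seed, ev_cap):
    """Simulate one cluster; return summary accumulators and the event log.

    ``ev_cap`` is the event-log capacity; pass 0 to skip recording.  The RNG
    consumption is identical whether or not events are recorded, so summaries
    and trajectories produced from the same seed describe the same realisation.
    """
    np.random.seed(seed)
    state = np.ones(n_heads, np.int64)
    fil = np.full(n_heads, -1, np.int64)
    pos = np.zeros(n_heads)
    x = np.zeros(2)            # per-filament anchor, retained when unbound
    nbound = np.zeros(2, np.int64)

    t = 0.0
    disp = np.zeros(2)         # signed anchor displacement per filament
    strain = 0.0               # anchor motion accrued while crosslinked
    t_cross = 0.0              # time with >=1 head bound on each filament
    t_bound = 0.0              # time with >=1 head bound anywhere
    n_runs = 0
    run_sum = 0.0
    run_sumsq = 0.0
    run_start_x = 0.0
    in_run = False

    n_ev = 0
    overflow = False
    ev_t = np.empty(ev_cap)
    ev_head = np.empty(ev_cap, np.int64)
    ev_trans = np.empty(ev_cap, np.int64)
    ev_fil = np.empty(ev_cap, np.int64)
    ev_pos = np.empty(ev_cap)
    ev_x = np.empty((ev_cap, 2))

    rates = np.empty(n_heads)
    while t < t_max:
        total = 0.0
        for h in range(n_heads):
            s_h = state[h]
            if s_h == 1:
                r = k12
            elif s_h == 2:
                r = k23
            else:
                r = k31
            rates[h] = r
            total += r
        crosslinked = nbound[0] > 0 and nbound[1] > 0
        bound_any = nbound[0] + nbound[1] > 0
        if total <= 0.0:
            # all heads absorbed (rigor at [ATP] = 0): run out the clock
            if bound_any:
                t_bound += t_max - t
            if crosslinked:
                t_cross += t_max - t
            t = t_max
            break
        dt = -np.log(np.random.random()) / total
        if t + dt >= t_max:
            if bound_any:
                t_bound += t_max - t
            if crosslinked:
                t_cross += t_max - t
            t = t_max
            break
        if bound_any:
            t_bound += dt
        if crosslinked:
            t_cross += dt
        t += dt

        u = np.random.random() * total
        acc = 0.0
        h = n_heads - 1
        for i in range(n_heads):
            acc += rates[i]
            if u < acc:
                h = i
                break

        s_h = state[h]
        if s_h == 1:
            f = 0
            if n_filaments == 2 and np.random.random() < 0.5:
                f = 1
            p_new = np.random.normal(x[f] + 0.5 * step, bind_sd)
            state[h] = 2
            fil[h] = f
            pos[h] = p_new
            nbound[f] += 1
            trans = TRANS_BIND
        elif s_h == 2:
            state[h] = 3
            f = fil[h]
            p_new = pos[h]
            trans = TRANS_RELEASE
        else:
            state[h] = 1
            f = fil[h]
            p_new = pos[h]
            fil[h] = -1
            nbound[f] -= 1
            trans = TRANS_UNBIND

        # re-evaluate the anchor of the affected filament after the transition
        if trans != TRANS_RELEASE:
            if nbound[f] > 0:
                rear = 1.0e300
                for i in range(n_heads):
                    if fil[i] == f and pos[i] < rear:
                        rear = pos[i]
                old = x[f]
                x[f] = rear + 0.5 * step
                dx = x[f] - old
                disp[f] += dx
                if crosslinked:
                    strain += dx
            # filament emptied: anchor retains its last value

        now_bound = nbound[0] + nbound[1] > 0
        if not in_run and now_bound:
            in_run = True
            run_start_x = x[0] + x[1]
        elif in_run and not now_bound:
            in_run = False
            rl = (x[0] + x[1]) - run_start_x
            n_runs += 1
            run_sum += rl
            run_sumsq += rl * rl

        if n_ev < ev_cap:
            ev_t[n_ev] = t
            ev_head[n_ev] = h
            ev_trans[n_ev] = trans
            ev_fil[n_ev] = f
            ev_pos[n_ev] = p_new
            ev_x[n_ev, 0] = x[0]
            ev_x[n_ev, 1] = x[1]
            n_ev += 1
        elif ev_cap > 0:
            overflow = True

    if in_run:  # truncated run at t_max still counts as a run
        rl = (x[0] + x[1]) - run_start_x
        n_runs += 1
        run_sum += rl
        run_sumsq += rl * rl

    return (t, disp[0], disp[1], strain, t_cross, t_bound,
            n_runs, run_sum, run_sumsq,
            n_ev, overflow,
            ev_t[:n_ev], ev_head[:n_ev], ev_trans[:n_ev],
            ev_fil[:n_ev], ev_pos[:n_ev], ev_x[:n_ev])


@njit(cache=True)
def ensemble_stats(n_heads, n_filaments, k12, k23, k31, step, bind_sd,
                   t_max, seeds):
    """Per-replicate summary statistics for an ensemble of clusters.

    Returns arrays (reps,) of: displacement on filament 0, displacement on
    filament 1, strain, crosslink time, bound time, run count, run-length sum.
    """
    reps = seeds.shape[0]
    disp0 = np.empty(reps)
    disp1 = np.empty(reps)
    strain = np.empty(reps)
    t_cross = np.empty(reps)
    t_bound = np.empty(reps)
    n_runs = np.empty(reps, np.int64)
    run_sum = np.empty(reps)
    run_sumsq = np.empty(reps)
    for r in range(reps):
        out = simulate_cluster(n_heads, n_filaments, k12, k23, k31, step,
                               bind_sd, t_max, seeds[r], 0)
        disp0[r] = out[1]
        disp1[r] = out[2]
        strain[r] = out[3]
        t_cross[r] = out[4]
        t_bound[r] = out[5]
        n_runs[r] = out[6]
        run_sum[r] = out[7]
        run_sumsq[r] = out[8]
    return disp0, disp1, strain, t_cross, t_bound, n_runs, run_sum, run_sumsq
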