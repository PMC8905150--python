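"""Numba-compiled core loop of the excitable-agent simulation.

The kernel advances the whole colony one second at a time with a fixed
synchronous schedule (clock tick -> spontaneous activation -> movement ->
stimulation -> deactivation) and records the proportion of active agents on a
regular stride.  It is deliberately free of Python objects so a 100 001-step
colony runs in well under a second; the readable per-step reference
implementation lives in :mod:`antsync.model` and is cross-checked against
this kernel by the test suite.

Randomness comes from numba's internal RNG seeded once at kernel entry, so a
given (parameters, seed) pair reproduces bit-identical output.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# distribution kind codes (shared with antsync.distributions.DistributionSpec.encode)
KIND_FIXED = 0
KIND_EXPONENTIAL = 1
KIND_UNIFORM_RANGE = 2

# event codes
EV_SPONTANEOUS = 0
EV_STIMULATED = 1
EV_DEACTIVATION = 2
EV_IGNORED = 3

MAX_WALL_TRIES = 64


@njit(cache=True)
def _draw(kind, p1, p2):
    if kind == KIND_EXPONENTIAL:
        return np.random.exponential(p1)
    if kind == KIND_UNIFORM_RANGE:
        return float(np.random.randint(int(p1), int(p2) + 1))
    return p1  # fixed


@njit(cache=True)
def _in_bounds(x, y, side):
    return 0.0 <= x <= side and 0.0 <= y <= side


@njit(cache=True)
def simulate(
    seed,
    n_ants,
    grid_side,
    n_steps,
    active_duration,
    r_kind,
    r_p1,
    r_p2,
    s_kind,
    s_p1,
    s_p2,
    walk_jitter,
    stim_radius,
    n_initial_active,
    record_stride,
    every_step,
    log_events,
    event_capacity,
):
    """Run the colony and return (recorded proportions, events, n_events, overflow).

    ``events`` rows are (step, ant_id, code); rows beyond ``n_events`` are
    garbage.  ``overflow`` is True when the event buffer filled up (the caller
    should retry with a larger capacity).
    """
    np.random.seed(seed)
    side = float(grid_side)

    x = np.empty(n_ants)
    y = np.empty(n_ants)
    heading = np.empty(n_ants)
    clock = np.zeros(n_ants)
    r_cur = np.empty(n_ants)
    s_cur = np.empty(n_ants)
    active = np.zeros(n_ants, np.bool_)

    for i in range(n_ants):
        x[i] = np.random.uniform(0.0, side)
        y[i] = np.random.uniform(0.0, side)
        heading[i] = np.random.uniform(0.0, 360.0)
        if i < n_initial_active:
            active[i] = True
            r_cur[i] = 0.0
            s_cur[i] = 0.0
        else:
            r_cur[i] = _draw(r_kind, r_p1, r_p2)
            s_cur[i] = _draw(s_kind, s_p1, s_p2)

    # pair (i, j) currently inside an unbroken proximity episode
    contact = np.zeros((n_ants, n_ants), np.bool_)
    stim_flag = np.zeros(n_ants, np.bool_)

    n_rec = (n_steps - 1) // record_stride + 1
    rec = np.empty(n_rec)
    rec[0] = n_initial_active / n_ants
    rec_i = 1

    events = np.empty((event_capacity if log_events else 1, 3), np.int64)
    n_events = 0
    overflow = False

    r2 = stim_radius * stim_radius

    for t in range(1, n_steps):
        # (1) personal clocks advance one second
        for i in range(n_ants):
            clock[i] += 1.0

        # (2) spontaneous activation of matured inactive ants
        for i in range(n_ants):
            if not active[i] and clock[i] >= s_cur[i]:
                active[i] = True
                clock[i] = 0.0
                for j in range(n_ants):
                    contact[i, j] = False
                    contact[j, i] = False
                if log_events:
                    if n_events < event_capacity:
                        events[n_events, 0] = t
                        events[n_events, 1] = i
                        events[n_events, 2] = EV_SPONTANEOUS
                        n_events += 1
                    else:
                        overflow = True

        # (3) every active ant takes a unit step of the correlated random walk
        for i in range(n_ants):
            if not active[i]:
                continue
            if walk_jitter >= 360.0:
                h = np.random.uniform(0.0, 360.0)
            else:
                h = (heading[i] + np.random.uniform(-walk_jitter, walk_jitter)) % 360.0
            rad = h * np.pi / 180.0
            nx = x[i] + np.cos(rad)
            ny = y[i] + np.sin(rad)
            if not _in_bounds(nx, ny, side):
                ok = False
                for _ in range(MAX_WALL_TRIES):
                    h = (h + np.random.randint(0, 180)) % 360.0
                    rad = h * np.pi / 180.0
                    nx = x[i] + np.cos(rad)
                    ny = y[i] + np.sin(rad)
                    if _in_bounds(nx, ny, side):
                        ok = True
                        break
                if not ok:
                    h = (h + 180.0) % 360.0
                    rad = h * np.pi / 180.0
                    nx = min(max(x[i] + np.cos(rad), 0.0), side)
                    ny = min(max(y[i] + np.sin(rad), 0.0), side)
            heading[i] = h
            x[i] = nx
            y[i] = ny

        # (4) stimulation at proximity-episode onsets, applied synchronously
        if r2 > 0.0 or stim_radius > 0.0:
            for i in range(n_ants):
                stim_flag[i] = False
            for i in range(n_ants):
                if not active[i]:
                    continue
                for j in range(n_ants):
                    if active[j]:
                        continue
                    dx = x[i] - x[j]
                    dy = y[i] - y[j]
                    if dx * dx + dy * dy <= r2:
                        onset = not contact[i, j]
                        contact[i, j] = True
                        contact[j, i] = True
                        if clock[j] >= r_cur[j]:
                            # every-step mode keeps testing while in range;
                            # episode mode tests only when a pair first meets
                            if every_step or onset:
                                stim_flag[j] = True
                        elif onset and log_events:
                            if n_events < event_capacity:
                                events[n_events, 0] = t
                                events[n_events, 1] = j
                                events[n_events, 2] = EV_IGNORED
                                n_events += 1
                            else:
                                overflow = True
                    else:
                        contact[i, j] = False
                        contact[j, i] = False
            for j in range(n_ants):
                if stim_flag[j]:
                    active[j] = True
                    clock[j] = 0.0
                    for k in range(n_ants):
                        contact[j, k] = False
                        contact[k, j] = False
                    if log_events:
                        if n_events < event_capacity:
                            events[n_events, 0] = t
                            events[n_events, 1] = j
                            events[n_events, 2] = EV_STIMULATED
                            n_events += 1
                        else:
                            overflow = True

        # (5) active bouts of length A end; fresh (R, S) drawn for the rest bout
        for i in range(n_ants):
            if active[i] and clock[i] >= active_duration:
                active[i] = False
                clock[i] = 0.0
                r_cur[i] = _draw(r_kind, r_p1, r_p2)
                s_cur[i] = _draw(s_kind, s_p1, s_p2)
                for j in range(n_ants):
                    contact[i, j] = False
                    contact[j, i] = False
                if log_events:
                    if n_events < event_capacity:
                        events[n_events, 0] = t
                        events[n_events, 1] = i
                        events[n_events, 2] = EV_DEACTIVATION
                        n_events += 1
                    else:
                        overflow = True

        if t % record_stride == 0:
            n_act = 0
            for i in range(n_ants):
                if active[i]:
                    n_act += 1
            rec[rec_i] = n_act / n_ants
            rec_i += 1

    return rec, events, n_events, overflow
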