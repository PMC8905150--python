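"""Two-state excitable-agent model of ant colony activity cycles.

Each agent is either *active* or *inactive* and carries a personal clock ``T``
(seconds since its last state switch).  An active agent walks a correlated
random walk through a bounded square arena for a fixed duration ``A`` and can
stimulate inactive agents it passes within one body length.  An inactive agent
wakes on its own once ``T`` reaches its spontaneous-activation draw ``S``, or
earlier through contact — but only after its refractory draw ``R`` has
elapsed; both ``R`` and ``S`` are re-drawn at every active-to-inactive
transition.  Collective activity cycles emerge from this interplay of
spontaneous excitation, contact-mediated recruitment and refractoriness
without any external pacemaker.

The per-step update is a fixed synchronous schedule:

1. every clock advances one second;
2. inactive agents with ``T >= S`` activate spontaneously;
3. every active agent takes a unit step (heading jittered uniformly within
   ``+/- walk_jitter`` degrees; at walls an integer rotation in [0, 180) deg
   is added until the step stays inside);
4. an inactive agent within ``stim_radius`` of an active one activates iff
   its refractory draw has elapsed (``T >= R``); by default this test runs
   every step the pair stays in range (``stimulation_mode="every_step"``, so
   an agent maturing while a neighbour lingers wakes immediately), while
   ``"episode_onset"`` evaluates it only when a pair first comes within
   range; ignored contacts are logged once per proximity episode either way;
5. active agents with ``T >= A`` deactivate and draw a fresh ``(R, S)``.

Two equivalent implementations exist: :func:`run_simulation` drives the
compiled kernel in :mod:`antsync._kernel` (fast path, used by all campaigns),
while :func:`step` advances an explicit :class:`SimState` one update at a
time (reference path, used as an oracle by the tests).  Both follow the
schedule above; their random streams differ, so cross-checks are exact only
where randomness is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _kernel
from .distributions import DistributionSpec
from .trace import ActivityTrace

__all__ = [
    "ModelParams",
    "Ant",
    "SimState",
    "EventLog",
    "EventType",
    "sample_bout_params",
    "propose_heading",
    "move_agent",
    "find_stimulation_pairs",
    "step",
    "init_state",
    "run_simulation",
    "run_reference",
]


class EventType(str, Enum):
    SPONTANEOUS_ACTIVATION = "spontaneous_activation"
    STIMULATED_ACTIVATION = "stimulated_activation"
    DEACTIVATION = "deactivation"
    STIMULATION_IGNORED = "stimulation_ignored"


_EVENT_BY_CODE = {
    _kernel.EV_SPONTANEOUS: EventType.SPONTANEOUS_ACTIVATION,
    _kernel.EV_STIMULATED: EventType.STIMULATED_ACTIVATION,
    _kernel.EV_DEACTIVATION: EventType.DEACTIVATION,
    _kernel.EV_IGNORED: EventType.STIMULATION_IGNORED,
}
_CODE_BY_EVENT = {v: k for k, v in _EVENT_BY_CODE.items()}


@dataclass(frozen=True)
class ModelParams:
    """Full configuration of one colony simulation.

    Times are in seconds (1 time step = 1 s), lengths in patch units
    (1 patch = 1 unit; an agent step has length 1).
    """

    refractory_spec: DistributionSpec
    spontaneous_spec: DistributionSpec
    active_duration: float
    n_ants: int = 50
    grid_side: float = 32.0
    n_steps: int = 100_001
    walk_jitter: float = 45.0
    stim_radius: float = 1.0
    n_initial_active: Optional[int] = None
    seed: int = 0
    record_stride: int = 1
    stimulation_mode: str = "every_step"  # or "episode_onset"

    def __post_init__(self) -> None:
        if self.n_ants < 1:
            raise ValueError("n_ants must be >= 1")
        if self.grid_side < 2:
            raise ValueError("grid_side must be >= 2")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.active_duration < 1:
            raise ValueError("active_duration A must be >= 1 s")
        if self.stim_radius < 0:
            raise ValueError("stim_radius must be >= 0")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        if self.stimulation_mode not in ("every_step", "episode_onset"):
            raise ValueError("stimulation_mode must be 'every_step' or 'episode_onset'")
        if self.n_initial_active is None:
            object.__setattr__(self, "n_initial_active", self.n_ants // 2)
        if not 0 <= self.n_initial_active <= self.n_ants:
            raise ValueError("n_initial_active must be in [0, n_ants]")

    def with_seed(self, seed: int) -> "ModelParams":
        return replace(self, seed=int(seed))


@dataclass
class Ant:
    """One agent: state, continuous position, heading and bout draws."""

    state: str  # "active" | "inactive"
    x: float
    y: float
    heading: float
    T: float = 0.0
    R_current: float = 0.0
    S_current: float = 0.0

    @property
    def active(self) -> bool:
        return self.state == "active"


@dataclass
class SimState:
    """Mutable simulation state for the per-step reference path."""

    ants: List[Ant]
    t: int
    rng: np.random.Generator
    # unordered pairs (i, j), i < j, currently inside a proximity episode
    contacts: set = field(default_factory=set)

    @property
    def n_active(self) -> int:
        return sum(a.active for a in self.ants)


@dataclass
class EventLog:
    """Time-ordered record of state transitions and ignored contacts."""

    steps: np.ndarray
    ant_ids: np.ndarray
    events: List[EventType]

    def __len__(self) -> int:
        return len(self.events)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"step": self.steps, "ant_id": self.ant_ids, "event": [e.value for e in self.events]}
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def for_ant(self, ant_id: int) -> "EventLog":
        m = self.ant_ids == ant_id
        return EventLog(self.steps[m], self.ant_ids[m], [e for e, k in zip(self.events, m) if k])


# ---------------------------------------------------------------------------
# reference operations (readable path; semantics identical to the kernel)
# ---------------------------------------------------------------------------

def sample_bout_params(
    refractory_spec: DistributionSpec,
    spontaneous_spec: DistributionSpec,
    rng: np.random.Generator,
) -> Tuple[float, float]:
    """Draw the (R, S) pair consumed at an active-to-inactive transition."""
    return float(refractory_spec.sample(rng)), float(spontaneous_spec.sample(rng))


def propose_heading(heading: float, walk_jitter: float, rng: np.random.Generator) -> float:
    """Jitter a heading by a uniform angle in ``+/- [0, walk_jitter)`` degrees.

    ``walk_jitter = 360`` is the fully random walk: the new heading is
    uniform on [0, 360) regardless of the old one.
    """
    if walk_jitter >= 360.0:
        return float(rng.uniform(0.0, 360.0))
    return float((heading + rng.uniform(-walk_jitter, walk_jitter)) % 360.0)


def _unit_step(x: float, y: float, heading_deg: float) -> Tuple[float, float]:
    rad = np.deg2rad(heading_deg)
    return x + np.cos(rad), y + np.sin(rad)


def move_agent(ant: Ant, grid_side: float, walk_jitter: float, rng: np.random.Generator) -> Ant:
    """Advance an active agent one unit step, bouncing off arena walls.

    A step that would leave the arena gets an integer rotation in [0, 180)
    degrees added and is re-proposed; after 64 failed tries the heading is
    reversed (and the position clipped, which can only matter in degenerate
    sub-unit arenas).
    """
    h = propose_heading(ant.heading, walk_jitter, rng)
    nx, ny = _unit_step(ant.x, ant.y, h)
    if not (0.0 <= nx <= grid_side and 0.0 <= ny <= grid_side):
        for _ in range(_kernel.MAX_WALL_TRIES):
            h = (h + float(rng.integers(0, 180))) % 360.0
            nx, ny = _unit_step(ant.x, ant.y, h)
            if 0.0 <= nx <= grid_side and 0.0 <= ny <= grid_side:
                break
        else:
            h = (h + 180.0) % 360.0
            nx, ny = _unit_step(ant.x, ant.y, h)
            nx = min(max(nx, 0.0), grid_side)
            ny = min(max(ny, 0.0), grid_side)
    ant.heading = h
    ant.x, ant.y = float(nx), float(ny)
    return ant


def find_stimulation_pairs(
    ants: Sequence[Ant], stim_radius: float = 1.0
) -> List[Tuple[int, int]]:
    """All (active_id, inactive_id) pairs within ``stim_radius`` of each other."""
    pairs = []
    for i, a in enumerate(ants):
        if not a.active:
            continue
        for j, b in enumerate(ants):
            if b.active:
                continue
            if (a.x - b.x) ** 2 + (a.y - b.y) ** 2 <= stim_radius**2:
                pairs.append((i, j))
    return pairs


def init_state(params: ModelParams, rng: Optional[np.random.Generator] = None) -> SimState:
    """Initial colony: uniform positions/headings, first half active with T=0."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    ants = []
    for i in range(params.n_ants):
        ant = Ant(
            state="active" if i < params.n_initial_active else "inactive",
            x=float(rng.uniform(0, params.grid_side)),
            y=float(rng.uniform(0, params.grid_side)),
            heading=float(rng.uniform(0, 360)),
        )
        if not ant.active:
            ant.R_current, ant.S_current = sample_bout_params(
                params.refractory_spec, params.spontaneous_spec, rng
            )
        ants.append(ant)
    return SimState(ants=ants, t=0, rng=rng)


def step(state: SimState, params: ModelParams, log: Optional[list] = None) -> SimState:
    """Advance the colony one second (reference path; mutates ``state``).

    ``log``, if given, collects ``(step, ant_id, EventType)`` tuples.
    """
    ants = state.ants
    state.t += 1
    t = state.t

    def _record(i, ev):
        if log is not None:
            log.append((t, i, ev))

    def _break_contacts(i):
        state.contacts = {p for p in state.contacts if i not in p}

    # (1) clocks
    for ant in ants:
        ant.T += 1.0

    # (2) spontaneous activation
    for i, ant in enumerate(ants):
        if not ant.active and ant.T >= ant.S_current:
            ant.state = "active"
            ant.T = 0.0
            _break_contacts(i)
            _record(i, EventType.SPONTANEOUS_ACTIVATION)

    # (3) movement
    for ant in ants:
        if ant.active:
            move_agent(ant, params.grid_side, params.walk_jitter, state.rng)

    # (4) stimulation, applied synchronously
    if params.stim_radius > 0:
        every_step = params.stimulation_mode == "every_step"
        to_activate = set()
        in_range = set()
        for i, j in find_stimulation_pairs(ants, params.stim_radius):
            key = (min(i, j), max(i, j))
            in_range.add(key)
            onset = key not in state.contacts
            state.contacts.add(key)
            if ants[j].T >= ants[j].R_current:
                if every_step or onset:
                    to_activate.add(j)
            elif onset:
                _record(j, EventType.STIMULATION_IGNORED)
        # an episode ends when the pair separates beyond the radius
        state.contacts = {p for p in state.contacts if p in in_range}
        for j in sorted(to_activate):
            ants[j].state = "active"
            ants[j].T = 0.0
            _break_contacts(j)
            _record(j, EventType.STIMULATED_ACTIVATION)

    # (5) deactivation and fresh bout draws
    for i, ant in enumerate(ants):
        if ant.active and ant.T >= params.active_duration:
            ant.state = "inactive"
            ant.T = 0.0
            ant.R_current, ant.S_current = sample_bout_params(
                params.refractory_spec, params.spontaneous_spec, state.rng
            )
            _break_contacts(i)
            _record(i, EventType.DEACTIVATION)

    return state


def run_reference(params: ModelParams) -> Tuple[ActivityTrace, EventLog]:
    """Run the whole simulation on the per-step reference path (slow).

    Intended for small ``n_steps``; the campaigns use :func:`run_simulation`.
    """
    state = init_state(params)
    log: list = []
    rec = [state.n_active / params.n_ants]
    for t in range(1, params.n_steps):
        step(state, params, log)
        if t % params.record_stride == 0:
            rec.append(state.n_active / params.n_ants)
    trace = ActivityTrace(np.array(rec), dt=float(params.record_stride))
    if log:
        steps = np.array([e[0] for e in log], dtype=np.int64)
        ids = np.array([e[1] for e in log], dtype=np.int64)
        evs = [e[2] for e in log]
    else:
        steps = np.empty(0, np.int64)
        ids = np.empty(0, np.int64)
        evs = []
    return trace, EventLog(steps, ids, evs)


# ---------------------------------------------------------------------------
# fast path
# ---------------------------------------------------------------------------

def run_simulation(
    params: ModelParams,
    log_events: bool = True,
    event_capacity: int = 200_000,
) -> Tuple[ActivityTrace, EventLog]:
    """Run one colony on the compiled kernel.

    Returns the proportion-active trace (sampled every ``record_stride``
    steps, i.e. every ``record_stride`` seconds) and the event log.  The same
    ``(params, seed)`` always reproduces bit-identical output.  Set
    ``log_events=False`` in large replicate campaigns to skip event storage.
    """
    r_kind, r_p1, r_p2 = params.refractory_spec.encode()
    s_kind, s_p1, s_p2 = params.spontaneous_spec.encode()
    capacity = int(event_capacity)
    while True:
        rec, events, n_events, overflow = _kernel.simulate(
            int(params.seed) & 0x7FFFFFFF,
            int(params.n_ants),
            float(params.grid_side),
            int(params.n_steps),
            float(params.active_duration),
            r_kind, r_p1, r_p2,
            s_kind, s_p1, s_p2,
            float(params.walk_jitter),
            float(params.stim_radius),
            int(params.n_initial_active),
            int(params.record_stride),
            params.stimulation_mode == "every_step",
            bool(log_events),
            capacity,
        )
        if not overflow:
            break
        capacity *= 4  # re-run with room; the kernel is deterministic per seed

    trace = ActivityTrace(rec, dt=float(params.record_stride))
    if log_events and n_events:
        ev = events[:n_events]
        log = EventLog(
            steps=ev[:, 0].copy(),
            ant_ids=ev[:, 1].copy(),
            events=[_EVENT_BY_CODE[int(c)] for c in ev[:, 2]],
        )
    else:
        log = EventLog(np.empty(0, np.int64), np.empty(0, np.int64), [])
    return trace, log
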