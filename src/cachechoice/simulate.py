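"""Generative simulators for the two task protocols and a model-driven agent.

The agent's *site choice* (where it caches, where it checks) is drawn from
the package's own choice model — the same baseline-times-scaling-factors
probability that the likelihood evaluates — at a configurable true
parameter vector. Everything else (when the bird eats versus caches versus
checks, how fast events arrive) is a simple stochastic policy whose rates
are configurable; those rates shape data volume, not the object under
test.

Protocol details follow the apparatus: the Caching task runs 1 hr sessions
with a feeder state machine (state 0 = all closed with probability 1/4,
each of states 1-4 with probability 3/16; dwell times 60 s plus an
exponential tail of 15 s truncated at 90 s; after three state-0 draws in a
row, states 1-4 are drawn with probability 1/4 each). Retrieval-task
trials have a feeder-open phase (eating timers 30-60 s with a 15 s
exponential tail; a feeder re-draw on each newly occupied site; the phase
ends 15 s after a post-cache feeder visit or at three occupied sites), a
2 min lights-off delay, and a feeder-closed phase that ends 15 s after the
last cache is removed or after 10 min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arena import ArenaGeometry
from .choice import BiasDistribution, site_probabilities
from .events import BirdDataset
from .params import ParameterVector


@dataclass
class AgentPolicy:
    """True parameters and event-timing policy of a simulated bird.

    ``pbias`` is the bird's generative spatial bias over all S sites (zero
    at feeders: the model's baseline concerns cache sites; feeder visits
    are dictated by the feeder schedule).
    """

    theta: ParameterVector = field(default_factory=ParameterVector)
    pbias: np.ndarray | None = None  # (S,), defaults to uniform over cache sites
    event_interval_s: float = 10.0   # mean gap between interactions
    p_cache_given_seed: float = 0.35  # cache (vs eat) a carried seed
    p_check: float = 0.75            # check when idle (vs seek food)
    p_retrieve_own: float = 0.04     # retrieve an own cache when idle
    p_transient: float = 0.0         # immediately retrieve a fresh cache
    p_retrieve_on_find: float = 0.9  # retrieval task: retrieve a found cache
    p_recache: float = 0.4           # retrieval task: recache a retrieved seed

    def __post_init__(self):
        for name in (
            "event_interval_s", "p_cache_given_seed", "p_check",
            "p_retrieve_own", "p_transient", "p_retrieve_on_find", "p_recache",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def bias(self, arena: ArenaGeometry) -> BiasDistribution:
        if self.pbias is None:
            p = arena.is_cache_site.astype(float)
            return BiasDistribution(p / p.sum())
        return BiasDistribution(np.asarray(self.pbias, dtype=float))


def dirichlet_bias(
    arena: ArenaGeometry, concentration: float, rng: np.random.Generator
) -> np.ndarray:
    """A random per-bird spatial bias over cache sites (Dirichlet draw).

    Smaller concentration gives stronger idiosyncratic bias; the reference
    birds spread caches over most of the arena but far from uniformly.
    """
    p = np.zeros(arena.n_sites)
    cs = arena.cache_sites
    p[cs] = rng.dirichlet(np.full(len(cs), concentration))
    return p


class _ArenaState:
    """Incremental bookkeeping mirroring the state-derivation rules."""

    def __init__(self, arena: ArenaGeometry):
        self.arena = arena
        S = arena.n_sites
        self.count = np.zeros(S, dtype=int)
        self.checked = np.zeros(S, dtype=bool)
        self.last_time = np.full(S, np.nan)
        self.last_cache_recache = np.zeros(S, dtype=bool)
        self.prev_site = -1

    def new_trial(self):
        self.count[:] = 0
        self.checked[:] = False
        self.last_time[:] = np.nan
        self.last_cache_recache[:] = False

    def event_state(self, t: float):
        from .choice import EventState

        occ = (self.count > 0).astype(float)
        ce = (
            self.checked & (self.count == 0) & self.arena.is_cache_site
        ).astype(float)
        with np.errstate(invalid="ignore"):
            tsince = np.where(np.isnan(self.last_time), np.inf, t - self.last_time)
        rec = occ * self.last_cache_recache
        return EventState(
            prev_site=self.prev_site,
            occupancy=occ,
            checked_empty=ce,
            recache=rec,
            time_since=tsince,
            total_occupancy=float(occ[self.arena.is_cache_site].sum()),
            total_checked_empty=float(ce.sum()),
        )

    def apply(self, site: int, delta: int, t: float, phase: int):
        if self.arena.is_cache_site[site]:
            if delta > 0:
                self.count[site] += delta
                self.last_cache_recache[site] = phase == 2
            elif delta < 0:
                self.count[site] = max(self.count[site] + delta, 0)
            self.checked[site] = True
        self.last_time[site] = t
        self.prev_site = site


def _feeder_dwell(rng, lo=60.0, hi=90.0, decay=15.0) -> float:
    """Dwell time: lo plus an exponential(decay) tail truncated at hi."""
    u = rng.random()
    span = hi - lo
    # inverse CDF of an exponential truncated to [0, span]
    return lo - decay * np.log1p(-u * (1.0 - np.exp(-span / decay)))


class _FeederSchedule:
    """The Caching-task feeder state machine."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.zero_streak = 0
        self.state = self._draw()
        self.until = _feeder_dwell(rng)

    def _draw(self) -> int:
        if self.zero_streak >= 3:
            state = int(self.rng.integers(1, 5))
        else:
            state = int(
                self.rng.choice(5, p=[1 / 4, 3 / 16, 3 / 16, 3 / 16, 3 / 16])
            )
        self.zero_streak = self.zero_streak + 1 if state == 0 else 0
        return state

    def advance_to(self, t: float):
        while t >= self.until:
            self.state = self._draw()
            self.until += _feeder_dwell(self.rng)

    @property
    def open_feeder(self) -> int | None:
        """Index (0-3) of the open feeder, or None if all closed."""
        return None if self.state == 0 else self.state - 1


def _choose_site(bookkeeping, t, policy, pbias, arena, rng):
    dist = site_probabilities(
        bookkeeping.event_state(t), policy.theta, pbias, arena
    )
    return int(rng.choice(arena.n_sites, p=dist.p_hat))


def simulate_caching_task(
    policy: AgentPolicy,
    arena: ArenaGeometry,
    duration: float = 3600.0,
    seed: int | None = 0,
    bird: str = "sim",
    session: int = 0,
) -> BirdDataset:
    """One Caching-task session: free caching for ``duration`` seconds.

    The whole session is a single trial (phase 0). Returns the event log;
    a zero-rate policy yields an empty session.
    """
    seq = np.random.SeedSequence(seed)
    rng_protocol, rng_agent = [np.random.default_rng(s) for s in seq.spawn(2)]
    feeders = _FeederSchedule(rng_protocol)
    pbias = policy.bias(arena)
    book = _ArenaState(arena)
    book.new_trial()
    rows = []
    feeder_sites = arena.feeders
    carrying = False
    t = 0.0
    if policy.event_interval_s <= 0:
        import warnings

        warnings.warn("zero event rate: empty session")
        return BirdDataset(bird, pd.DataFrame(columns=[
            "session", "trial", "phase", "time", "site", "delta"]))

    def emit(site, delta):
        rows.append((session, 0, 0, t, site, delta))
        book.apply(site, delta, t, 0)

    while True:
        t += rng_agent.exponential(policy.event_interval_s)
        if t >= duration:
            break
        feeders.advance_to(t)
        if carrying:
            if rng_agent.random() < policy.p_cache_given_seed:
                s = _choose_site(book, t, policy, pbias, arena, rng_agent)
                emit(s, +1)
                carrying = False
                if rng_agent.random() < policy.p_transient:
                    t += rng_agent.uniform(1.0, 3.0)
                    if t >= duration:
                        break
                    emit(s, -1)
                    carrying = True
            else:
                carrying = False  # seed eaten, no site interaction
            continue
        occupied = np.flatnonzero(book.count > 0)
        if len(occupied) and rng_agent.random() < policy.p_retrieve_own:
            s = int(rng_agent.choice(occupied))
            emit(s, -1)
            carrying = True
        elif feeders.open_feeder is not None and (
            rng_agent.random() >= policy.p_check
        ):
            emit(int(feeder_sites[feeders.open_feeder]), -1)
            carrying = True
        else:
            s = _choose_site(book, t, policy, pbias, arena, rng_agent)
            emit(s, 0)

    frame = pd.DataFrame(
        rows, columns=["session", "trial", "phase", "time", "site", "delta"]
    )
    return BirdDataset(bird, frame)


def simulate_retrieval_task(
    policy: AgentPolicy,
    arena: ArenaGeometry,
    n_trials: int = 10,
    seed: int | None = 0,
    bird: str = "sim",
    session: int = 0,
) -> BirdDataset:
    """One Retrieval-task session of ``n_trials`` trials.

    Each trial: feeder-open phase (phase 1, 1-3 caches), 2 min delay with
    no interactions, feeder-closed phase (phase 2) in which site checks are
    drawn from the choice model and found caches may be retrieved and
    recached.
    """
    seq = np.random.SeedSequence(seed)
    rng_protocol, rng_agent = [np.random.default_rng(s) for s in seq.spawn(2)]
    pbias = policy.bias(arena)
    feeder_sites = arena.feeders
    rows = []
    t = 0.0
    for trial in range(n_trials):
        book = _ArenaState(arena)
        book.new_trial()

        def emit(site, delta, phase):
            rows.append((session, trial, phase, t, site, delta))
            book.apply(site, delta, t, phase)

        # --- feeder-open phase ---
        open_feeder = int(rng_protocol.integers(4))
        feeder_until = t + _feeder_dwell(rng_protocol, 30.0, 60.0)
        carrying = False
        n_caches = 0
        close_at = np.inf  # 15 s timer after a post-cache feeder visit
        while True:
            t += rng_agent.exponential(policy.event_interval_s)
            if t >= close_at or n_caches >= 3:
                break
            while n_caches == 0 and t >= feeder_until:
                open_feeder = int(rng_protocol.integers(4))
                feeder_until += _feeder_dwell(rng_protocol, 30.0, 60.0)
            if carrying:
                if rng_agent.random() < policy.p_cache_given_seed:
                    s = _choose_site(book, t, policy, pbias, arena, rng_agent)
                    newly_occupied = book.count[s] == 0
                    emit(s, +1, 1)
                    n_caches += 1
                    if newly_occupied:  # feeder re-draw on new occupied site
                        open_feeder = int(rng_protocol.integers(4))
                carrying = False
            else:
                emit(int(feeder_sites[open_feeder]), -1, 1)
                carrying = True
                if n_caches > 0:
                    close_at = min(close_at, t + 15.0)

        # --- delay phase: 2 min, no interactions ---
        t = max(t, close_at if np.isfinite(close_at) else t) + 120.0

        # --- feeder-closed phase ---
        phase_end = t + 600.0
        empty_since = np.inf
        carrying = False
        while True:
            t += rng_agent.exponential(policy.event_interval_s)
            if t >= phase_end or t >= empty_since + 15.0:
                t = min(t, max(phase_end, 0.0))
                break
            if carrying:
                if rng_agent.random() < policy.p_recache:
                    s = _choose_site(book, t, policy, pbias, arena, rng_agent)
                    emit(s, +1, 2)
                    empty_since = np.inf
                carrying = False
                continue
            s = _choose_site(book, t, policy, pbias, arena, rng_agent)
            found = book.count[s] > 0
            if found and rng_agent.random() < policy.p_retrieve_on_find:
                emit(s, -1, 2)
                carrying = True
                if book.count.sum() == 0:
                    empty_since = t
            else:
                emit(s, 0, 2)
        t += rng_protocol.uniform(5.0, 15.0)  # inter-trial gap

    frame = pd.DataFrame(
        rows, columns=["session", "trial", "phase", "time", "site", "delta"]
    )
    return BirdDataset(bird, frame)


def simulate_bird(
    policy: AgentPolicy,
    arena: ArenaGeometry,
    n_sessions: int = 5,
    task: str = "caching",
    seed: int | None = 0,
    bird: str = "sim",
    **kwargs,
) -> BirdDataset:
    """Multiple sessions for one bird, concatenated into one dataset."""
    seq = np.random.SeedSequence(seed)
    parts = []
    t_offset = 0.0
    for k, child in enumerate(seq.spawn(n_sessions)):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        if task == "caching":
            ds = simulate_caching_task(
                policy, arena, seed=sub_seed, bird=bird, session=k, **kwargs
            )
        elif task == "retrieval":
            ds = simulate_retrieval_task(
                policy, arena, seed=sub_seed, bird=bird, session=k, **kwargs
            )
        else:
            raise ValueError(f"unknown task {task!r}")
        block = ds.events.drop(columns=["trial_label", "event"]).copy()
        block["time"] += t_offset
        t_offset = block["time"].iloc[-1] + 60.0 if len(block) else t_offset
        parts.append(block)
    return BirdDataset(bird, pd.concat(parts, ignore_index=True))


# ---------------------------------------------------------------------------
# synthetic ROI frame stacks
# ---------------------------------------------------------------------------

@dataclass
class RoiSchedule:
    """Ground-truth event schedule for one synthetic site ROI."""

    n_frames: int
    deposits: tuple[int, ...] = ()
    removals: tuple[int, ...] = ()
    checks: tuple[int, ...] = ()  # transient flap openings


def simulate_roi_stack(
    schedule: RoiSchedule,
    noise_sd: float = 0.05,
    seed: int | None = 0,
    shape: tuple[int, int] = (12, 12),
    seed_amplitude: float = 1.0,
    check_amplitude: float = 1.0,
    check_duration: int = 3,
):
    """Synthetic per-site ROI video with known cache/retrieval/check times.

    The empty site is a fixed spatial pattern; a deposited seed adds a
    persistent blob (contrast ``seed_amplitude``); every interaction —
    check, deposit, or removal — additionally perturbs the image for
    ``check_duration`` frames (the flap opening and the bird's beak).
    Gaussian pixel noise of standard deviation ``noise_sd`` is added
    throughout. Returns the (T, H, W) stack; the schedule itself is the
    ground truth.

    Raises if deposits/removals contradict each other (removal while
    empty, deposit while occupied).
    """
    rng = np.random.default_rng(seed)
    T = schedule.n_frames
    H, W = shape
    base = rng.uniform(0.2, 0.8, size=(H, W))
    yy, xx = np.mgrid[0:H, 0:W]
    blob = np.exp(-(((yy - H / 2) ** 2 + (xx - W / 2) ** 2) / (2 * (H / 6) ** 2)))

    transitions = sorted(
        [(f, +1) for f in schedule.deposits] + [(f, -1) for f in schedule.removals]
    )
    occupied = np.zeros(T, dtype=bool)
    state = 0
    ptr = 0
    for f in range(T):
        while ptr < len(transitions) and transitions[ptr][0] == f:
            state += transitions[ptr][1]
            if state not in (0, 1):
                raise ValueError(
                    f"contradictory schedule at frame {f}: occupancy {state}"
                )
            ptr += 1
        occupied[f] = state > 0

    frames = np.tile(base, (T, 1, 1))
    frames[occupied] -= seed_amplitude * blob
    flaps = set(schedule.checks) | set(schedule.deposits) | set(schedule.removals)
    for f in sorted(flaps):
        stop = min(f + check_duration, T)
        frames[f:stop] += check_amplitude * rng.uniform(
            -1.0, 1.0, size=(H, W)
        )
    frames += rng.normal(0.0, noise_sd, size=frames.shape)
    return frames
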