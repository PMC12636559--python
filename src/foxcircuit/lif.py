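"""Leaky integrate-and-fire network simulation on a connectome graph.

Each neuron follows

    tau_mem * dv/dt = (v_rest - v) + g
    tau_syn * dg/dt = -g

where ``g`` (mV) is an exponentially decaying synaptic drive.  A presynaptic
spike of neuron j at time t increments g_i by
``sign(j->i) * w_syn * synapse_count(j->i)`` at time ``t + spike_delay``.
When v reaches threshold the neuron spikes, resets to ``v_reset`` and is
clamped there for the refractory period.  Stimulated neurons are force-spiked
with Poisson trains (their intrinsic dynamics are bypassed); silenced neurons
stay in the graph but can never spike.

The production engine integrates with fixed-step exponential Euler
(default dt = 0.2 ms) and a ring buffer for delayed deliveries.
:func:`oracle_simulate` is a deliberately independent re-implementation —
scalar forward-Euler at dt/10 with a heap-queued event list — used to
cross-check the engine on micro-circuits.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .connectome import ConnectomeGraph

__all__ = [
    "LifParams",
    "StimulusSpec",
    "SilenceSpec",
    "SpikeTrainSet",
    "TrialSummary",
    "SimulationError",
    "simulate_trial",
    "run_trials",
    "oracle_simulate",
    "poisson_train",
]


class SimulationError(Exception):
    pass


@dataclass(frozen=True)
class LifParams:
    """Physiological constants plus the free synaptic weight ``w_syn``.

    Voltages in mV, times in ms.  ``tau_mem`` is not constrained by the
    sweep protocol this package reproduces; 20 ms is the conventional value
    for this class of whole-brain models and is freely configurable.
    """

    v_rest: float = -52.0
    v_reset: float = -52.0
    v_thresh: float = -45.0
    t_refractory: float = 2.2
    tau_syn: float = 5.0
    spike_delay: float = 1.8
    tau_mem: float = 20.0
    w_syn: float = 0.39
    dt: float = 0.2
    trial_duration: float = 1000.0

    def __post_init__(self):
        if not self.v_reset <= self.v_rest < self.v_thresh:
            raise ValueError("need v_reset <= v_rest < v_thresh")
        if min(self.tau_syn, self.tau_mem, self.t_refractory,
               self.spike_delay, self.dt, self.trial_duration) <= 0:
            raise ValueError("time constants, dt and duration must be > 0")
        if self.dt > self.spike_delay:
            raise ValueError("dt must not exceed spike_delay")

    @property
    def n_steps(self) -> int:
        return int(round(self.trial_duration / self.dt))

    @property
    def delay_steps(self) -> int:
        return max(1, int(round(self.spike_delay / self.dt)))

    @property
    def refractory_steps(self) -> int:
        return int(math.ceil(self.t_refractory / self.dt))


@dataclass(frozen=True)
class StimulusSpec:
    """Which neurons are driven, at what Poisson rate, in which window.

    ``window`` is (start, end) in ms within the trial; None means the full
    trial.  ``explicit_trains`` (id -> spike times, ms) overrides the Poisson
    generator with fixed trains, for deterministic verification runs.
    """

    neurons: frozenset = frozenset()
    rate: float = 0.0
    window: tuple | None = None
    explicit_trains: Mapping[str, Sequence[float]] | None = None

    def __post_init__(self):
        object.__setattr__(self, "neurons", frozenset(self.neurons))
        if self.rate < 0:
            raise ValueError("stimulation rate must be >= 0")

    def resolved_window(self, params: LifParams) -> tuple:
        win = self.window or (0.0, params.trial_duration)
        if not 0.0 <= win[0] < win[1] <= params.trial_duration:
            raise ValueError(f"stimulus window {win} outside the trial")
        return win


@dataclass(frozen=True)
class SilenceSpec:
    """Neurons whose spiking is disabled (threshold effectively infinite)."""

    neurons: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "neurons", frozenset(self.neurons))


@dataclass(frozen=True)
class SpikeTrainSet:
    """Per-neuron ordered spike times (ms) for a single trial."""

    spikes: Mapping[str, np.ndarray]
    meta: Mapping[str, object] = field(default_factory=dict)

    def count(self, neuron_id: str, window: tuple | None = None) -> int:
        t = self.spikes[neuron_id]
        if window is None:
            return len(t)
        return int(np.count_nonzero((t >= window[0]) & (t < window[1])))


@dataclass(frozen=True)
class TrialSummary:
    """Per-neuron mean firing rate (Hz) over the stimulation window."""

    rates: Mapping[str, float]
    trial_index: int = 0
    seed: int | None = None


def poisson_train(rng: np.random.Generator, rate: float, window: tuple,
                  t_refractory: float) -> np.ndarray:
    """Homogeneous Poisson spike times (ms) thinned to respect refractoriness.

    Candidate events closer than ``t_refractory`` to the last accepted spike
    are dropped, so the realized rate is slightly below the nominal one at
    high rates (expected factor 1 / (1 + rate * t_ref)).
    """
    if rate <= 0:
        return np.array([], dtype=float)
    start, end = window
    mean_gap = 1000.0 / rate
    times = []
    t = start + rng.exponential(mean_gap)
    last = -np.inf
    while t < end:
        if t - last >= t_refractory:
            times.append(t)
            last = t
        t += rng.exponential(mean_gap)
    return np.asarray(times, dtype=float)


def _check_specs(graph: ConnectomeGraph, stimulus: StimulusSpec,
                 silenced: SilenceSpec) -> None:
    known = set(graph.neuron_ids)
    for name, ids in (("stimulated", stimulus.neurons),
                      ("silenced", silenced.neurons)):
        unknown = ids - known
        if unknown:
            raise SimulationError(f"{name} set contains unknown neurons "
                                  f"{sorted(unknown)}")
    overlap = stimulus.neurons & silenced.neurons
    if overlap:
        raise SimulationError(
            f"neurons cannot be stimulated and silenced at once: "
            f"{sorted(overlap)}")


def _adjacency(graph: ConnectomeGraph, index: Mapping[str, int],
               w_syn: float):
    """Per presynaptic neuron: (postsynaptic index array, weight array)."""
    adj: list = [None] * len(index)
    for pre in graph.neuron_ids:
        posts, weights = [], []
        for e in graph.out_edges(pre):
            posts.append(index[e.post_id])
            weights.append(e.sign * e.synapse_count * w_syn)
        if posts:
            adj[index[pre]] = (np.asarray(posts, dtype=np.intp),
                               np.asarray(weights, dtype=float))
    return adj


def _forced_steps(graph, params, stimulus, rng) -> dict:
    """Map neuron index -> sorted array of forced spike steps."""
    ids = graph.neuron_ids
    index = {nid: i for i, nid in enumerate(ids)}
    out = {}
    if stimulus.explicit_trains is not None:
        for nid, times in stimulus.explicit_trains.items():
            if nid not in index:
                raise SimulationError(f"explicit train for unknown neuron {nid!r}")
            steps = np.unique(np.floor(np.asarray(times, float)
                                       / params.dt).astype(int))
            out[index[nid]] = steps[(steps >= 0) & (steps < params.n_steps)]
        return out
    window = stimulus.resolved_window(params)
    for nid in sorted(stimulus.neurons):
        times = poisson_train(rng, stimulus.rate, window, params.t_refractory)
        steps = np.floor(times / params.dt).astype(int)
        out[index[nid]] = steps[steps < params.n_steps]
    return out


def simulate_trial(graph: ConnectomeGraph, params: LifParams,
                   stimulus: StimulusSpec,
                   silenced: SilenceSpec = SilenceSpec(),
                   seed: int = 0) -> SpikeTrainSet:
    """Run one trial; identical inputs and seed give identical output."""
    _check_specs(graph, stimulus, silenced)
    ids = graph.neuron_ids
    n = len(ids)
    index = {nid: i for i, nid in enumerate(ids)}
    rng = np.random.default_rng(seed)

    adj = _adjacency(graph, index, params.w_syn)
    forced = _forced_steps(graph, params, stimulus, rng)

    # forced spikes as (n_steps-long) lists of index arrays, sparse by step
    forced_by_step: dict[int, list] = {}
    for i, steps in forced.items():
        for s in steps:
            forced_by_step.setdefault(int(s), []).append(i)

    stim_mask = np.zeros(n, dtype=bool)
    for i in forced:
        stim_mask[i] = True
    for nid in stimulus.neurons:
        stim_mask[index[nid]] = True
    sil_mask = np.zeros(n, dtype=bool)
    for nid in silenced.neurons:
        sil_mask[index[nid]] = True

    alpha = math.exp(-params.dt / params.tau_mem)
    beta = math.exp(-params.dt / params.tau_syn)
    # exact step response of v to an exponentially decaying g (arrivals are
    # quantized to step boundaries, so the pair of linear ODEs is solvable
    # in closed form over one step)
    if params.tau_mem == params.tau_syn:
        c_g = alpha * params.dt / params.tau_mem
    else:
        k = 1.0 / params.tau_mem - 1.0 / params.tau_syn
        c_g = alpha * (math.exp(k * params.dt) - 1.0) / (k * params.tau_mem)
    n_steps = params.n_steps
    d_steps = params.delay_steps
    ref_steps = params.refractory_steps
    ring = np.zeros((d_steps + 1, n))
    v = np.full(n, params.v_rest)
    g = np.zeros(n)
    ref = np.zeros(n, dtype=int)
    eligible_base = ~(stim_mask | sil_mask)

    spike_steps: list[list[int]] = [[] for _ in range(n)]
    for t in range(n_steps):
        slot = t % (d_steps + 1)
        g += ring[slot]
        ring[slot] = 0.0
        v = params.v_rest + (v - params.v_rest) * alpha + g * c_g
        g *= beta
        refractory = ref > 0
        v[refractory] = params.v_reset   # membrane held during refractoriness
        crossing = eligible_base & ~refractory & (v >= params.v_thresh)
        spikers = np.nonzero(crossing)[0]
        if spikers.size:
            v[spikers] = params.v_reset
            ref[spikers] = ref_steps
        forced_now = forced_by_step.get(t)
        if forced_now:
            spikers = np.concatenate([spikers, np.asarray(forced_now)]) \
                if spikers.size else np.asarray(forced_now)
        if spikers.size:
            target = ring[(t + d_steps) % (d_steps + 1)]
            for i in spikers:
                spike_steps[i].append(t)
                a = adj[i]
                if a is not None:
                    target[a[0]] += a[1]   # post indices unique per pre
        ref[refractory] -= 1

    spikes = {nid: np.asarray(spike_steps[index[nid]], dtype=float) * params.dt
              for nid in ids}
    return SpikeTrainSet(spikes=spikes,
                         meta={"seed": seed, "w_syn": params.w_syn,
                               "dt": params.dt})


def run_trials(graph: ConnectomeGraph, params: LifParams,
               stimulus: StimulusSpec, silenced: SilenceSpec = SilenceSpec(),
               n_trials: int = 30, base_seed: int = 0) -> list:
    """Repeat :func:`simulate_trial`; trial k uses seed ``base_seed + k``.

    Each summary holds per-neuron mean firing rates over the stimulation
    window (spike count / window length).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    window = stimulus.resolved_window(params)
    win_s = (window[1] - window[0]) / 1000.0
    out = []
    for k in range(n_trials):
        seed = base_seed + k
        trains = simulate_trial(graph, params, stimulus, silenced, seed=seed)
        rates = {nid: trains.count(nid, window) / win_s
                 for nid in graph.neuron_ids}
        out.append(TrialSummary(rates=rates, trial_index=k, seed=seed))
    return out


def oracle_simulate(graph: ConnectomeGraph, params: LifParams,
                    explicit_input_trains: Mapping[str, Sequence[float]],
                    silenced: SilenceSpec = SilenceSpec()) -> SpikeTrainSet:
    """Independent fine-step reference integrator (tests only).

    Scalar forward-Euler at ``dt/10`` with a heap-based event queue for
    delayed deliveries.  Refuses graphs larger than 50 neurons: this is a
    verification oracle, not a production path.
    """
    if graph.n_neurons > 50:
        raise SimulationError("oracle_simulate is restricted to graphs with "
                              "<= 50 neurons")
    stimulus = StimulusSpec(neurons=frozenset(explicit_input_trains),
                            explicit_trains=dict(explicit_input_trains))
    _check_specs(graph, stimulus, silenced)

    ids = graph.neuron_ids
    index = {nid: i for i, nid in enumerate(ids)}
    n = len(ids)
    dtf = params.dt / 10.0
    n_steps = int(round(params.trial_duration / dtf))
    delay_steps = int(round(params.spike_delay / dtf))
    ref_steps = int(math.ceil(params.t_refractory / dtf))

    adj = _adjacency(graph, index, params.w_syn)
    forced: dict[int, set] = {}
    for nid, times in explicit_input_trains.items():
        steps = {int(math.floor(t / dtf)) for t in times
                 if 0 <= t < params.trial_duration}
        forced[index[nid]] = steps
    stim = set(forced)
    sil = {index[nid] for nid in silenced.neurons}

    v = [params.v_rest] * n
    g = [0.0] * n
    ref_until = [-1] * n
    events: list = []   # (arrival_step, order, neuron, weight)
    order = 0
    spikes: list[list[float]] = [[] for _ in range(n)]

    for t in range(n_steps):
        while events and events[0][0] <= t:
            _, _, i, w = heapq.heappop(events)
            g[i] += w
        spikers = []
        for i in range(n):
            if i in stim:
                if t in forced[i]:
                    spikers.append(i)
                continue
            # Heun (explicit trapezoid) on the two linear ODEs
            gi = g[i]
            k1g = -gi / params.tau_syn
            g1 = gi + dtf * k1g
            if t <= ref_until[i]:
                v[i] = params.v_reset
            else:
                vi = v[i]
                k1v = ((params.v_rest - vi) + gi) / params.tau_mem
                k2v = ((params.v_rest - (vi + dtf * k1v)) + g1) / params.tau_mem
                v[i] = vi + 0.5 * dtf * (k1v + k2v)
            k2g = -g1 / params.tau_syn
            g[i] = gi + 0.5 * dtf * (k1g + k2g)
            if i in sil or t <= ref_until[i]:
                continue
            if v[i] >= params.v_thresh:
                spikers.append(i)
                v[i] = params.v_reset
                ref_until[i] = t + ref_steps
        for i in spikers:
            spikes[i].append(t * dtf)
            a = adj[i]
            if a is not None:
                for j, w in zip(a[0], a[1]):
                    heapq.heappush(events, (t + delay_steps, order, int(j), w))
                    order += 1
        # keep g decaying for stimulated neurons too (their g is unused)

    return SpikeTrainSet(
        spikes={nid: np.asarray(spikes[index[nid]]) for nid in ids},
        meta={"oracle": True, "dt": dtf})
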