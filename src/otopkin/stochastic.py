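"""Exact stochastic simulation of channel ensembles (Gillespie SSA).

Channels are independent and identical, so the ensemble occupancy is itself
a Markov jump process on per-state counts whose transition propensities are
``count[s] * Q[s, t]``.  Simulating that aggregated process with exact
exponential waiting times is statistically identical to simulating every
channel separately, at a fraction of the cost.  This module is the
brute-force oracle for the deterministic propagator and the channel-noise
source for synthetic recordings.

At an epoch boundary the pending waiting time is discarded and rates are
re-drawn under the new generator; by memorylessness of the exponential
distribution this truncation is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .model import ChannelModel
from .protocol import Protocol, _initial_vector, sample_grid
from .ratematrix import StateSpace, build_rate_matrix, conducting_mask, enumerate_states

_BUF = 1 << 14  # uniforms pre-drawn per batch


@dataclass(frozen=True)
class EnsembleOccupancy:
    """Per-state channel counts sampled along a protocol."""

    time_s: np.ndarray
    counts: np.ndarray  # rows = times, columns = states, sums to n_channels
    n_channels: int
    seed: int
    space: StateSpace
    model: ChannelModel
    protocol: Protocol
    epoch_index: np.ndarray
    driving_mV: np.ndarray

    @property
    def conducting_counts(self) -> np.ndarray:
        return self.counts[:, conducting_mask(self.model)].sum(axis=1)

    @property
    def conducting_fraction(self) -> np.ndarray:
        return self.conducting_counts / self.n_channels


class _UniformStream:
    """Batched uniform variates from one named generator."""

    def __init__(self, rng: np.random.Generator) -> None:
        self.rng = rng
        self._buf = rng.random(_BUF)
        self._i = 0

    def next(self) -> float:
        if self._i == _BUF:
            self._buf = self.rng.random(_BUF)
            self._i = 0
        u = self._buf[self._i]
        self._i += 1
        return u


def _simulate_epoch(Q, counts, duration, sample_times, stream, log):
    """Advance the aggregated jump process through one epoch.

    ``counts`` (list of ints) is modified in place; state snapshots are
    appended to ``log`` for each requested local sample time.
    """
    N = len(counts)
    targets = []  # per state: list of target indices
    rates = []  # per state: list of per-channel rates
    exit_rate = []
    for s in range(N):
        tg, rt = [], []
        for t in range(N):
            if t != s and Q[s][t] > 0.0:
                tg.append(t)
                rt.append(Q[s][t])
        targets.append(tg)
        rates.append(rt)
        exit_rate.append(sum(rt))
    w = [counts[s] * exit_rate[s] for s in range(N)]
    total = sum(w)
    t = 0.0
    k = 0  # next sample index
    n_samples = len(sample_times)
    events_since_resum = 0
    from math import log as _ln

    while True:
        if total <= 0.0:
            t_next = duration
        else:
            t_next = t - _ln(1.0 - stream.next()) / total
        while k < n_samples and sample_times[k] <= t_next:
            log.append(list(counts))
            k += 1
        if t_next >= duration:
            break
        t = t_next
        # pick the source state proportionally to counts[s]*exit_rate[s]
        r = stream.next() * total
        acc = 0.0
        s = N - 1
        for i in range(N):
            acc += w[i]
            if r < acc:
                s = i
                break
        # leftover uniform picks the transition within the state
        leftover = (r - (acc - w[s])) / max(counts[s], 1)
        tg, rt = targets[s], rates[s]
        acc2 = 0.0
        j = len(rt) - 1
        for i in range(len(rt)):
            acc2 += rt[i]
            if leftover < acc2:
                j = i
                break
        d = tg[j]
        counts[s] -= 1
        counts[d] += 1
        total += (counts[s] * exit_rate[s] - w[s]) + (
            counts[d] * exit_rate[d] - w[d]
        )
        w[s] = counts[s] * exit_rate[s]
        w[d] = counts[d] * exit_rate[d]
        events_since_resum += 1
        if events_since_resum == 4096:  # control float drift in the running sum
            total = sum(w)
            events_since_resum = 0
    while k < n_samples:  # samples at/after the epoch end
        log.append(list(counts))
        k += 1


def gillespie_protocol(
    model: ChannelModel,
    protocol: Protocol,
    n_channels: int,
    seed: int,
) -> EnsembleOccupancy:
    """Exact stochastic simulation of ``n_channels`` independent channels
    along a protocol; deterministic for a given seed.

    The initial counts are a multinomial draw from the protocol's initial
    distribution; occupancy is recorded on the protocol's sample grid.
    """
    if n_channels < 1:
        raise InvalidParameterError("n_channels must be >= 1")
    rng = np.random.default_rng(seed)
    stream = _UniformStream(rng)
    p0 = _initial_vector(model, protocol)
    counts = list(rng.multinomial(n_channels, p0 / p0.sum()))
    locals_, time_s, epoch_index, driving_mV = sample_grid(protocol)
    log: list[list[int]] = []
    for epoch, local in zip(protocol.epochs, locals_):
        Q = build_rate_matrix(model, epoch.conditions).Q.tolist()
        _simulate_epoch(Q, counts, epoch.duration_s, list(local), stream, log)
    return EnsembleOccupancy(
        time_s=time_s,
        counts=np.asarray(log, dtype=np.int64),
        n_channels=n_channels,
        seed=seed,
        space=enumerate_states(model),
        model=model,
        protocol=protocol,
        epoch_index=epoch_index,
        driving_mV=driving_mV,
    )


def occupancy_to_current(
    occ: EnsembleOccupancy, conductance_pS: float = 1.0
) -> np.ndarray:
    """Ensemble current (pA): conducting count times the per-channel Ohmic
    current ``gamma * driving * 1e-3``."""
    return occ.conducting_counts * conductance_pS * occ.driving_mV * 1e-3
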