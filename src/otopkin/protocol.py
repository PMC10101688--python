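"""Deterministic simulation of solution-exchange protocols.

A protocol is a sequence of epochs, each with a fixed extracellular pH,
Zn2+ concentration and electrochemical driving force.  Within an epoch the
generator Q is constant and the state-probability row vector evolves as
dp/dt = pQ; epochs are chained by carrying the final vector of one epoch
into the next (solution exchange is instantaneous by default).

Per-channel current is Ohmic: I = gamma * (V - E_rev) * P(conducting),
with gamma in pS, driving force in mV and current in pA (1 pS * 1 mV =
1e-3 pA); inward current at negative driving force is negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .errors import ConfigurationError, InvalidParameterError
from .model import ChannelModel, Conditions
from .ratematrix import (
    RateMatrix,
    StateSpace,
    build_rate_matrix,
    conducting_mask,
    enumerate_states,
    equilibrium_distribution,
    open_mask,
)

#: Driving forces (V - E_rev, mV) estimated from ramp experiments for the
#: two solutions used throughout: 0 mV at pH 7.4 and -80 mV at pH 5.5.
DRIVING_MV_BY_PH = {7.4: 0.0, 5.5: -80.0}


def driving_for_ph(pH: float) -> float:
    """Known driving force for a pH; other pH values must be set explicitly
    in the epoch (no interpolation)."""
    try:
        return DRIVING_MV_BY_PH[pH]
    except KeyError:
        raise ConfigurationError(
            f"no driving force known for pH {pH}; set driving_mV explicitly"
        ) from None


@dataclass(frozen=True)
class Epoch:
    """One piecewise-constant segment of a solution-exchange protocol."""

    duration_s: float
    pH: float
    zn_molar: float = 0.0
    driving_mV: float | None = None

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise InvalidParameterError("epoch duration must be positive")
        if self.zn_molar < 0:
            raise InvalidParameterError("[Zn2+] must be >= 0")

    @property
    def conditions(self) -> Conditions:
        return Conditions.from_ph_zn(self.pH, self.zn_molar)

    def resolved_driving(self) -> float:
        if self.driving_mV is not None:
            return self.driving_mV
        return driving_for_ph(self.pH)


@dataclass(frozen=True)
class Protocol:
    """Ordered epochs plus sampling/initial-condition rules.

    The initial state defaults to the equilibrium distribution at the first
    epoch's conditions (cells rest in the first solution before recording);
    pass ``initial`` as a probability vector to override.  ``marks`` carries
    optional named annotation times (stimulus onset, Zn on/off) used by the
    metrics stage.
    """

    epochs: tuple[Epoch, ...]
    sample_interval_s: float = 1e-3
    initial: tuple[float, ...] | str = "equilibrium"
    marks: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "epochs", tuple(self.epochs))
        if len(self.epochs) == 0:
            raise ConfigurationError("protocol needs at least one epoch")
        shortest = min(e.duration_s for e in self.epochs)
        if not (0 < self.sample_interval_s <= shortest):
            raise ConfigurationError(
                "sample interval must be positive and no longer than the "
                "shortest epoch"
            )

    @property
    def total_duration_s(self) -> float:
        return sum(e.duration_s for e in self.epochs)

    def epoch_starts(self) -> np.ndarray:
        return np.concatenate(
            [[0.0], np.cumsum([e.duration_s for e in self.epochs])]
        )


@dataclass(frozen=True)
class SimulationResult:
    """Time-resolved state probabilities under a protocol."""

    time_s: np.ndarray
    probabilities: np.ndarray  # rows = times, columns = states
    space: StateSpace
    model: ChannelModel
    protocol: Protocol
    epoch_index: np.ndarray
    driving_mV: np.ndarray

    @property
    def p_open(self) -> np.ndarray:
        return self.probabilities[:, open_mask(self.model)].sum(axis=1)

    @property
    def p_conducting(self) -> np.ndarray:
        return self.probabilities[:, conducting_mask(self.model)].sum(axis=1)


class _PropagatorCache:
    """expm(Q*dt) cached per distinct step size within one epoch."""

    def __init__(self, Q: np.ndarray) -> None:
        self.Q = Q
        self._cache: dict[float, np.ndarray] = {}

    def step(self, dt: float) -> np.ndarray:
        P = self._cache.get(dt)
        if P is None:
            P = expm(self.Q * dt)
            self._cache[dt] = P
        return P


def propagate_epoch(rm: RateMatrix | np.ndarray, p0, times) -> np.ndarray:
    """Solve dp/dt = pQ at the requested times (s, non-decreasing, from the
    epoch start) via matrix exponentials; returns one probability row per
    requested time."""
    Q = rm.Q if isinstance(rm, RateMatrix) else np.asarray(rm, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    if abs(p0.sum() - 1.0) > 1e-8 or (p0 < -1e-12).any():
        raise ConfigurationError("initial vector must be a probability vector")
    rowsums = np.abs(Q.sum(axis=1))
    if rowsums.max() > 1e-8 * max(1.0, np.abs(Q).max()):
        raise ConfigurationError("Q rows must sum to zero (generator matrix)")
    times = np.asarray(times, dtype=float)
    if times.size and (times[0] < 0 or np.any(np.diff(times) < 0)):
        raise ConfigurationError("times must be non-negative and non-decreasing")
    cache = _PropagatorCache(Q)
    out = np.empty((times.size, p0.size))
    p = p0
    t_prev = 0.0
    for k, t in enumerate(times):
        dt = t - t_prev
        if dt > 0:
            p = p @ cache.step(round(dt, 15))
        out[k] = p
        t_prev = t
    return out


def _initial_vector(model: ChannelModel, protocol: Protocol) -> np.ndarray:
    if isinstance(protocol.initial, str):
        if protocol.initial != "equilibrium":
            raise ConfigurationError(
                f"unknown initial-state rule {protocol.initial!r}"
            )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero [Zn] support reduction is fine
            return equilibrium_distribution(
                model, protocol.epochs[0].conditions, check=False
            )
    p0 = np.asarray(protocol.initial, dtype=float)
    if abs(p0.sum() - 1.0) > 1e-8:
        raise ConfigurationError("initial vector must sum to 1")
    return p0


def sample_grid(protocol: Protocol):
    """Uniform output grid of a protocol.

    Returns ``(locals_, time_s, epoch_index, driving_mV)`` where ``locals_``
    is the list of per-epoch sample times relative to each epoch start (the
    protocol endpoint is appended to the last epoch) and the other three are
    the concatenated global arrays.  Samples at an epoch boundary belong to
    the incoming epoch.
    """
    dt = protocol.sample_interval_s
    locals_, times, idx, driving = [], [], [], []
    t0 = 0.0
    for i, epoch in enumerate(protocol.epochs):
        n_steps = math.ceil(epoch.duration_s / dt - 1e-9)
        local = np.arange(n_steps) * dt
        if i == len(protocol.epochs) - 1:
            local = np.append(local, epoch.duration_s)
        locals_.append(local)
        times.append(t0 + local)
        idx.append(np.full(local.size, i, dtype=int))
        driving.append(np.full(local.size, epoch.resolved_driving()))
        t0 += epoch.duration_s
    return (
        locals_,
        np.concatenate(times),
        np.concatenate(idx),
        np.concatenate(driving),
    )


def run_protocol(model: ChannelModel, protocol: Protocol) -> SimulationResult:
    """Simulate state probabilities along a protocol.

    Q is rebuilt for each epoch; the final probability vector of one epoch
    (propagated over the exact epoch duration) seeds the next.  Output is
    sampled on a uniform grid of the protocol's sample interval, with the
    protocol endpoint appended.
    """
    locals_, time_s, epoch_index, driving_mV = sample_grid(protocol)
    p = _initial_vector(model, protocol)
    rows = []
    for epoch, local in zip(protocol.epochs, locals_):
        rm = build_rate_matrix(model, epoch.conditions)
        grid = np.append(local, epoch.duration_s)  # endpoint for chaining
        rowblock = propagate_epoch(rm, p, grid)
        p = rowblock[-1]
        rows.append(rowblock[: local.size])
    return SimulationResult(
        time_s=time_s,
        probabilities=np.vstack(rows),
        space=enumerate_states(model),
        model=model,
        protocol=protocol,
        epoch_index=epoch_index,
        driving_mV=driving_mV,
    )


def current_trace(
    result: SimulationResult,
    conductance_pS: float = 1.0,
    n_channels: int = 1,
) -> np.ndarray:
    """Macroscopic current (pA): ``n * gamma * driving * P(conducting) * 1e-3``.

    Inward current at negative driving force is negative; blocked states
    contribute nothing because only conducting states enter P(conducting).
    """
    return (
        n_channels
        * conductance_pS
        * result.driving_mV
        * result.p_conducting
        * 1e-3
    )


# ---------------------------------------------------------------------------
# Protocol presets mirroring the experimental designs
# ---------------------------------------------------------------------------

def pre_exposure_protocol(
    zn_molar: float,
    exposure_s: float,
    *,
    hold_s: float = 2.0,
    stim_s: float = 8.0,
    ph_rest: float = 7.4,
    ph_stim: float = 5.5,
    sample_interval_s: float = 1e-3,
) -> Protocol:
    """Zn2+ applied at resting pH before the acid stimulus: rest -> Zn at
    pH 7.4 for ``exposure_s`` -> acid stimulus.  ``zn_molar = 0`` gives the
    paired no-Zn control with identical epoch structure."""
    epochs = (
        Epoch(hold_s, ph_rest, 0.0),
        Epoch(exposure_s, ph_rest, zn_molar),
        Epoch(stim_s, ph_stim, 0.0),
    )
    marks = {
        "zn_on_s": hold_s,
        "zn_off_s": hold_s + exposure_s,
        "stimulus_onset_s": hold_s + exposure_s,
    }
    return Protocol(epochs, sample_interval_s, marks=marks)


def wash_off_protocol(
    wash_s: float,
    *,
    zn_molar: float = 1e-3,
    exposure_s: float = 16.0,
    hold_s: float = 2.0,
    stim_s: float = 8.0,
    ph_rest: float = 7.4,
    ph_stim: float = 5.5,
    sample_interval_s: float = 1e-3,
) -> Protocol:
    """Zn2+ pre-exposure followed by a Zn2+-free wash at resting pH before
    the acid stimulus; ``wash_s = 0`` reduces to the pre-exposure design."""
    epochs = [
        Epoch(hold_s, ph_rest, 0.0),
        Epoch(exposure_s, ph_rest, zn_molar),
    ]
    if wash_s > 0:
        epochs.append(Epoch(wash_s, ph_rest, 0.0))
    epochs.append(Epoch(stim_s, ph_stim, 0.0))
    marks = {
        "zn_on_s": hold_s,
        "zn_off_s": hold_s + exposure_s,
        "stimulus_onset_s": hold_s + exposure_s + wash_s,
    }
    return Protocol(tuple(epochs), sample_interval_s, marks=marks)


def block_rebound_protocol(
    *,
    zn_molar: float = 1e-3,
    hold_s: float = 2.0,
    pre_s: float = 8.0,
    zn_s: float = 8.0,
    post_s: float = 8.0,
    ph_rest: float = 7.4,
    ph_stim: float = 5.5,
    sample_interval_s: float = 1e-3,
) -> Protocol:
    """Zn2+ applied and removed during a sustained acid stimulus: the
    design that exposes fast block followed by rebound potentiation."""
    epochs = (
        Epoch(hold_s, ph_rest, 0.0),
        Epoch(pre_s, ph_stim, 0.0),
        Epoch(zn_s, ph_stim, zn_molar),
        Epoch(post_s, ph_stim, 0.0),
    )
    marks = {
        "stimulus_onset_s": hold_s,
        "zn_on_s": hold_s + pre_s,
        "zn_off_s": hold_s + pre_s + zn_s,
    }
    return Protocol(epochs, sample_interval_s, marks=marks)


def with_exchange_tau(protocol: Protocol, tau_s: float,
                      step_s: float | None = None) -> Protocol:
    """Approximate a finite solution-exchange time constant.

    Concentrations relax exponentially toward each epoch's target with time
    constant ``tau_s``, discretized into sub-epochs of ``step_s`` (default
    tau/5) holding piecewise-constant concentrations.  Driving force still
    switches at the nominal epoch boundary.  ``tau_s = 0`` returns the
    protocol unchanged (instantaneous exchange, the default model)."""
    if tau_s == 0:
        return protocol
    if tau_s < 0:
        raise InvalidParameterError("exchange tau must be >= 0")
    step = step_s if step_s is not None else tau_s / 5.0
    h = 10.0 ** (-protocol.epochs[0].pH)
    zn = protocol.epochs[0].zn_molar
    out: list[Epoch] = []
    for epoch in protocol.epochs:
        h_target = 10.0 ** (-epoch.pH)
        zn_target = epoch.zn_molar
        t = 0.0
        while t < epoch.duration_s - 1e-12:
            d = min(step, epoch.duration_s - t)
            mid = t + d / 2.0
            decay = math.exp(-mid / tau_s)
            h_mid = h_target + (h - h_target) * decay
            zn_mid = zn_target + (zn - zn_target) * decay
            out.append(
                Epoch(d, -math.log10(h_mid), zn_mid, epoch.resolved_driving())
            )
            t += d
        end_decay = math.exp(-epoch.duration_s / tau_s)
        h = h_target + (h - h_target) * end_decay
        zn = zn_target + (zn - zn_target) * end_decay
    return Protocol(
        tuple(out),
        min(protocol.sample_interval_s, step),
        protocol.initial,
        dict(protocol.marks),
    )
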