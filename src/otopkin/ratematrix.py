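"""State-space enumeration, generator matrices, and equilibria.

A model with n binary elements has 2**n configuration states.  State index
``s`` encodes element ``i``'s configuration in bit ``i`` (``(s >> i) & 1``);
transitions connect states differing in exactly one bit, so the sparsity
pattern of the generator is the n-cube adjacency.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InvalidParameterError
from .model import OFF_TO_ON, ON_TO_OFF, ChannelModel, Conditions


@dataclass(frozen=True)
class StateSpace:
    """Enumeration of the 2**n configuration states of a model."""

    element_names: tuple[str, ...]

    @property
    def n_elements(self) -> int:
        return len(self.element_names)

    @property
    def n_states(self) -> int:
        return 2 ** self.n_elements

    def bits(self, index: int) -> tuple[int, ...]:
        """Configuration vector (bit per element) of a state index."""
        return tuple((index >> i) & 1 for i in range(self.n_elements))

    def index(self, bits) -> int:
        return sum(int(b) << i for i, b in enumerate(bits))

    def label(self, index: int) -> str:
        """Human-readable configuration string, e.g. ``pore+.H-.ZnA+.ZnB-``."""
        b = self.bits(index)
        return ".".join(
            f"{name}{'+' if bit else '-'}"
            for name, bit in zip(self.element_names, b)
        )

    def labels(self) -> list[str]:
        return [self.label(s) for s in range(self.n_states)]

    def mask(self, **configs: bool) -> np.ndarray:
        """Boolean mask over states where each named element has the given
        configuration (True = on)."""
        m = np.ones(self.n_states, dtype=bool)
        for name, on in configs.items():
            i = self.element_names.index(name)
            has = (np.arange(self.n_states) >> i) & 1 == 1
            m &= has if on else ~has
        return m


def enumerate_states(model: ChannelModel) -> StateSpace:
    """Deterministic state enumeration: bit i of the index is element i."""
    return StateSpace(tuple(e.name for e in model.elements))


def effective_rate(base: float, barrier_changes, RT: float) -> float:
    """Rate after applying barrier changes: ``base * exp(-sum(ddG)/RT)``."""
    if not base > 0:
        raise InvalidParameterError("base rate must be positive")
    if not RT > 0:
        raise InvalidParameterError("RT must be positive")
    return base * math.exp(-sum(barrier_changes) / RT)


@dataclass(frozen=True)
class RateMatrix:
    """Generator matrix Q (s^-1) over a model's state space at fixed
    ligand conditions.  Rows sum to zero; off-diagonals are flip rates."""

    Q: np.ndarray
    space: StateSpace
    conditions: Conditions

    @property
    def n_states(self) -> int:
        return self.space.n_states


def _condition_holds(bits, model: ChannelModel, condition) -> bool:
    return all(
        bits[model.index_of(name)] == (cfg == "on") for name, cfg in condition
    )


def build_rate_matrix(model: ChannelModel, conditions: Conditions) -> RateMatrix:
    """Assemble Q from intrinsic rates, ligand concentrations, barrier
    couplings and destabilization partitions.

    For each state and element, the flip rate is the intrinsic rate (times
    the ligand concentration for binding steps), times ``exp(-ddG/RT)`` for
    every coupling whose source condition holds in the current state and
    whose target matches the flip, times the destabilization factors for
    flips that enter or leave a destabilized state set.
    """
    space = enumerate_states(model)
    for e in model.elements:
        if e.ligand is not None and e.ligand not in conditions:
            raise ConfigurationError(
                f"no concentration given for ligand {e.ligand!r} "
                f"(element {e.name!r})"
            )
    n = model.n_elements
    N = space.n_states
    RT = model.RT
    Q = np.zeros((N, N))
    for s in range(N):
        bits = space.bits(s)
        for i, el in enumerate(model.elements):
            turning_on = bits[i] == 0
            if turning_on:
                base = el.k_fwd
                if el.ligand is not None:
                    base *= conditions[el.ligand]
                direction = OFF_TO_ON
            else:
                base = el.k_bwd
                direction = ON_TO_OFF
            if base == 0.0:
                continue
            ddG = 0.0
            for c in model.couplings:
                if (
                    c.target_element == el.name
                    and c.direction == direction
                    and bits[model.index_of(c.source_element)]
                    == (c.source_config == "on")
                ):
                    ddG += c.ddG
            t = s ^ (1 << i)
            tbits = space.bits(t)
            factor = math.exp(-ddG / RT)
            for d in model.destabilizations:
                in_s = _condition_holds(bits, model, d.condition)
                in_t = _condition_holds(tbits, model, d.condition)
                if in_s and not in_t:
                    factor *= math.exp(+d.partition * d.dG / RT)
                elif in_t and not in_s:
                    factor *= math.exp(-(1.0 - d.partition) * d.dG / RT)
            Q[s, t] = base * factor
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return RateMatrix(Q, space, conditions)


def _pair_energy_terms(model: ChannelModel):
    """Equilibrium coupling energies, one per interacting element pair.

    Couplings tagged by :func:`otopkin.model.pair_coupling` are grouped by
    tag; for each group the energy ``ddG(off->on) - ddG(on->off)`` of the
    primary direction is added to states where the source condition holds
    and the target is on (by closure the reciprocal direction reports the
    same energy).  Untagged couplings contribute individually.
    """
    terms = []  # (source_name, source_cfg, target_name, energy)
    groups: dict[str, list] = {}
    for c in model.couplings:
        if c.pair is not None:
            groups.setdefault(c.pair, []).append(c)
        else:
            sign = 1.0 if c.direction == OFF_TO_ON else -1.0
            terms.append((c.source_element, c.source_config, c.target_element,
                          sign * c.ddG))
    for tag, cs in groups.items():
        primary_source = tag.split("~")[0].split(":")[0]
        fwd = sum(c.ddG for c in cs
                  if c.source_element == primary_source and c.direction == OFF_TO_ON)
        bwd = sum(c.ddG for c in cs
                  if c.source_element == primary_source and c.direction == ON_TO_OFF)
        cfg = next(c.source_config for c in cs if c.source_element == primary_source)
        target = next(c.target_element for c in cs
                      if c.source_element == primary_source)
        terms.append((primary_source, cfg, target, fwd - bwd))
    return terms


def state_free_energies(model: ChannelModel, conditions: Conditions) -> np.ndarray:
    """Free energy of every state (kcal/mol, all-off state as reference).

    Per-element contribution for an 'on' element: ``-RT*ln(k_fwd*[L]/k_bwd)``
    (ligand factor omitted for gates); plus the equilibrium coupling energy
    of each interacting pair whose condition holds; plus destabilization
    energies.  States unreachable at zero ligand concentration get +inf.
    """
    space = enumerate_states(model)
    RT = model.RT
    N = space.n_states
    G = np.zeros(N)
    pair_terms = _pair_energy_terms(model)
    for s in range(N):
        bits = space.bits(s)
        g = 0.0
        for i, el in enumerate(model.elements):
            if bits[i]:
                k_on = el.k_fwd
                if el.ligand is not None:
                    k_on *= conditions[el.ligand]
                g += math.inf if k_on == 0.0 else -RT * math.log(k_on / el.k_bwd)
        for src, cfg, tgt, energy in pair_terms:
            if (
                bits[model.index_of(src)] == (cfg == "on")
                and bits[model.index_of(tgt)] == 1
            ):
                g += energy
        for d in model.destabilizations:
            if _condition_holds(bits, model, d.condition):
                g += d.dG
        G[s] = g
    return G


def boltzmann_distribution(model: ChannelModel, conditions: Conditions) -> np.ndarray:
    """Equilibrium distribution from state free energies (energy route)."""
    G = state_free_energies(model, conditions)
    finite = np.isfinite(G)
    if not finite.all():
        warnings.warn(
            "zero ligand concentration leaves some states unreachable; "
            "equilibrium support is reduced",
            stacklevel=2,
        )
    w = np.zeros_like(G)
    g0 = G[finite].min()
    w[finite] = np.exp(-(G[finite] - g0) / model.RT)
    return w / w.sum()


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution as the null vector of Q^T (kernel route)."""
    evals, evecs = np.linalg.eig(Q.T)
    k = int(np.argmin(np.abs(evals)))
    pi = np.real(evecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def equilibrium_distribution(
    model: ChannelModel, conditions: Conditions, *, check: bool = True,
    atol: float = 1e-9,
) -> np.ndarray:
    """Equilibrium state probabilities at fixed conditions.

    Computed by two independent routes — Boltzmann weights from state free
    energies and the null space of Q^T — which must agree to ``atol``
    (max absolute difference) when ``check`` is set.
    """
    p_energy = boltzmann_distribution(model, conditions)
    if check:
        Q = build_rate_matrix(model, conditions).Q
        p_kernel = stationary_distribution(Q)
        gap = float(np.max(np.abs(p_energy - p_kernel)))
        if gap > atol:
            raise RuntimeError(
                f"Boltzmann and null-space equilibria disagree (max |diff| = "
                f"{gap:.3e}); the model is not thermodynamically consistent"
            )
    return p_energy


def _path_stationary(Q: np.ndarray) -> np.ndarray | None:
    """Candidate stationary distribution from edge-rate path products along
    the hypercube (exact when detailed balance holds; None if an edge on a
    canonical path carries zero rate).

    log pi_s is accumulated as sum(ln(Q[u,v]/Q[v,u])) walking from the
    all-off state by flipping set bits in index order.  For a reversible
    chain this is path-independent; for a broken cycle the resulting vector
    leaves some edge visibly unbalanced, which is what the detailed-balance
    check is after.
    """
    N = Q.shape[0]
    logpi = np.zeros(N)
    for s in range(1, N):
        u = s & (s - 1)  # clear the top set bit: the parent differs in one bit
        if Q[u, s] <= 0 or Q[s, u] <= 0:
            return None
        logpi[s] = logpi[u] + math.log(Q[u, s] / Q[s, u])
    w = np.exp(logpi - logpi.max())
    return w / w.sum()


def detailed_balance_violation(Q: np.ndarray, pi: np.ndarray | None = None,
                               eps: float = 1e-300) -> float:
    """Max relative imbalance of equilibrium fluxes:
    ``max_ij |pi_i Q_ij - pi_j Q_ji| / max(pi_i Q_ij, pi_j Q_ji, eps)``.

    Unless ``pi`` is supplied, the equilibrium candidate comes from exact
    edge-rate path products (Kolmogorov-criterion route), falling back to
    the eigenvector route when some edge rate is zero.
    """
    if pi is None:
        pi = _path_stationary(Q)
        if pi is None:
            pi = stationary_distribution(Q)
    F = pi[:, None] * Q
    np.fill_diagonal(F, 0.0)
    num = np.abs(F - F.T)
    den = np.maximum(np.maximum(F, F.T), eps)
    mask = (F > 0) | (F.T > 0)
    if not mask.any():
        return 0.0
    return float((num[mask] / den[mask]).max())


def verify_cycles(model: ChannelModel, conditions: Conditions) -> float:
    """Numerical detailed-balance check of the built generator; returns the
    max relative flux imbalance (0 for a thermodynamically closed model)."""
    Q = build_rate_matrix(model, conditions).Q
    return detailed_balance_violation(Q)


def conducting_mask(model: ChannelModel) -> np.ndarray:
    """States that carry current: pore on and every blocking site off."""
    space = enumerate_states(model)
    configs = {}
    for e in model.elements:
        if e.conducts_when_on:
            configs[e.name] = True
        elif e.blocks_when_on:
            configs[e.name] = False
    return space.mask(**configs)


def open_mask(model: ChannelModel) -> np.ndarray:
    """States with the pore gate on (conducting or blocked)."""
    space = enumerate_states(model)
    pore = next(e.name for e in model.elements if e.conducts_when_on)
    return space.mask(**{pore: True})
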