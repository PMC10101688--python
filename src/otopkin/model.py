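"""Coupled binary-element channel models.

A channel is described as a set of two-configuration elements — a pore gate
(closed/open) and ligand binding sites (unbound/bound) — with intrinsic
transition rates, plus state-dependent interaction energies that raise or
lower the activation barriers of other elements' transitions, plus optional
destabilization energies applied to whole sets of states (used to implement
competition between ligands for a shared physical site).

Energies are in kcal/mol throughout; a barrier change ``ddG`` multiplies the
affected rate by ``exp(-ddG / RT)``.  The thermal energy ``RT`` defaults to
0.593 kcal/mol (room temperature).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

from .errors import InvalidParameterError, ModelError

#: Thermal energy RT at room temperature (298 K), kcal/mol.
RT_ROOM = 0.593

OFF_TO_ON = "off_to_on"
ON_TO_OFF = "on_to_off"

_DIRECTIONS = (OFF_TO_ON, ON_TO_OFF)
_CONFIGS = ("on", "off")


@dataclass(frozen=True)
class BinaryElement:
    """One two-configuration element of a channel model.

    Parameters
    ----------
    name :
        Unique identifier within the model.
    kind :
        ``"gate"`` (conformational, rates in s^-1) or ``"site"`` (ligand
        binding site; the forward rate is a second-order association rate in
        M^-1 s^-1 and is multiplied by the ligand concentration).
    k_fwd, k_bwd :
        Intrinsic forward (off->on) and backward (on->off) rates.
    ligand :
        Ligand species name; required for sites, forbidden for gates.
    conducts_when_on :
        True for the pore gate: the channel conducts only in states where
        this element is on.
    blocks_when_on :
        True for a blocking site: any state with this element on carries no
        current regardless of the pore.
    """

    name: str
    kind: str
    k_fwd: float
    k_bwd: float
    ligand: str | None = None
    conducts_when_on: bool = False
    blocks_when_on: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("gate", "site"):
            raise ModelError(f"element {self.name!r}: kind must be 'gate' or 'site'")
        if not (self.k_fwd > 0 and self.k_bwd > 0):
            raise InvalidParameterError(
                f"element {self.name!r}: rates must be positive"
            )
        if self.conducts_when_on and self.blocks_when_on:
            raise ModelError(
                f"element {self.name!r}: cannot both conduct and block when on"
            )
        if (self.ligand is not None) != (self.kind == "site"):
            raise ModelError(
                f"element {self.name!r}: ligand must be given iff kind is 'site'"
            )


@dataclass(frozen=True)
class BarrierCoupling:
    """State-dependent change of one transition's activation barrier.

    When element ``source_element`` is in configuration ``source_config``,
    the ``direction`` transition of ``target_element`` has its barrier
    changed by ``ddG`` kcal/mol (negative = faster, rate multiplied by
    ``exp(-ddG/RT)``).

    ``derived`` marks values implied by thermodynamic-cycle closure rather
    than stated independently; they are excluded from the free-parameter
    count.  ``pair`` tags the four directional couplings generated together
    by :func:`pair_coupling` so equilibrium energies are counted once per
    element pair.
    """

    source_element: str
    source_config: str
    target_element: str
    direction: str
    ddG: float
    derived: bool = False
    pair: str | None = None

    def __post_init__(self) -> None:
        if self.source_element == self.target_element:
            raise ModelError("coupling source and target must differ")
        if self.source_config not in _CONFIGS:
            raise ModelError("source_config must be 'on' or 'off'")
        if self.direction not in _DIRECTIONS:
            raise ModelError(f"direction must be one of {_DIRECTIONS}")
        if not math.isfinite(self.ddG):
            raise InvalidParameterError("coupling ddG must be finite")


def pair_coupling(
    source: str,
    target: str,
    *,
    ddG_fwd: float,
    ddG_bwd: float = 0.0,
    recip_fwd: float | None = None,
    recip_bwd: float | None = None,
    source_config: str = "on",
) -> list[BarrierCoupling]:
    """Build the four directional couplings of one interacting element pair.

    ``ddG_fwd``/``ddG_bwd`` modify the target's off->on / on->off barriers
    when the source is in ``source_config``.  The reciprocal effect of the
    target (when on) on the source's transitions is given by ``recip_fwd``
    and ``recip_bwd``; exactly one of the two may be omitted, in which case
    it is derived from thermodynamic-cycle closure,

        ddG_fwd - ddG_bwd  ==  recip_fwd - recip_bwd,

    i.e. both elements must report the same equilibrium coupling energy.
    A barrier change that shifts an equilibrium constant cannot be
    one-sided, which is why a reciprocal pair is always produced.
    """
    net = ddG_fwd - ddG_bwd
    if recip_fwd is None and recip_bwd is None:
        if abs(net) > 1e-12:
            raise ModelError(
                "an equilibrium-shifting coupling requires a reciprocal "
                "barrier change; give recip_fwd or recip_bwd"
            )
        recip_fwd, recip_bwd = 0.0, 0.0
        derived_fwd = derived_bwd = False
    elif recip_bwd is None:
        recip_bwd = recip_fwd - net
        derived_fwd, derived_bwd = False, True
    elif recip_fwd is None:
        recip_fwd = recip_bwd + net
        derived_fwd, derived_bwd = True, False
    else:
        if abs((recip_fwd - recip_bwd) - net) > 1e-9:
            raise ModelError(
                f"cycle closure violated for pair ({source}, {target}): "
                f"{net} != {recip_fwd - recip_bwd}"
            )
        derived_fwd = derived_bwd = False
    tag = f"{source}:{source_config}~{target}"
    return [
        BarrierCoupling(source, source_config, target, OFF_TO_ON, ddG_fwd, pair=tag),
        BarrierCoupling(source, source_config, target, ON_TO_OFF, ddG_bwd, pair=tag),
        BarrierCoupling(target, "on", source, OFF_TO_ON, recip_fwd,
                        derived=derived_fwd, pair=tag),
        BarrierCoupling(target, "on", source, ON_TO_OFF, recip_bwd,
                        derived=derived_bwd, pair=tag),
    ]


@dataclass(frozen=True)
class Destabilization:
    """Free-energy penalty applied to every state satisfying a condition.

    ``condition`` is a tuple of (element name, 'on'|'off') requirements that
    must all hold.  ``dG`` (kcal/mol, positive = destabilizing) raises the
    free energy of those states.  The penalty is partitioned onto rates with
    coefficient ``partition`` (default 1, "exit-only"): transitions leaving
    the destabilized set are multiplied by ``exp(+partition*dG/RT)`` and
    transitions entering it by ``exp(-(1-partition)*dG/RT)``; transitions
    between two destabilized states are unmodified.  Any partition preserves
    detailed balance; exit-only leaves transition-state energies untouched.
    """

    condition: tuple[tuple[str, str], ...]
    dG: float
    partition: float = 1.0

    def __post_init__(self) -> None:
        cond = tuple((str(n), str(c)) for n, c in self.condition)
        object.__setattr__(self, "condition", cond)
        if not math.isfinite(self.dG):
            raise InvalidParameterError("destabilization dG must be finite")
        names = {n for n, _ in cond}
        if len(names) < 2:
            raise ModelError("destabilization condition must reference >=2 elements")
        for _, c in cond:
            if c not in _CONFIGS:
                raise ModelError("condition configurations must be 'on' or 'off'")


@dataclass(frozen=True)
class Conditions:
    """Ligand concentrations (molar) at which a rate matrix is evaluated."""

    concentrations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for species, c in self.concentrations.items():
            if c < 0:
                raise InvalidParameterError(f"[{species}] must be >= 0")

    @classmethod
    def from_ph_zn(cls, pH: float, zn_molar: float = 0.0) -> "Conditions":
        """Conditions from a pH ([H+] = 10**-pH exactly) and [Zn2+] in M."""
        return cls({"H": 10.0 ** (-pH), "Zn": float(zn_molar)})

    def __getitem__(self, species: str) -> float:
        return self.concentrations[species]

    def __contains__(self, species: str) -> bool:
        return species in self.concentrations


@dataclass(frozen=True)
class ChannelModel:
    """A complete coupled binary-element channel model."""

    elements: tuple[BinaryElement, ...]
    couplings: tuple[BarrierCoupling, ...] = ()
    destabilizations: tuple[Destabilization, ...] = ()
    RT: float = RT_ROOM

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(self.elements))
        object.__setattr__(self, "couplings", tuple(self.couplings))
        object.__setattr__(self, "destabilizations", tuple(self.destabilizations))
        if self.RT <= 0:
            raise InvalidParameterError("RT must be positive")
        names = [e.name for e in self.elements]
        if len(set(names)) != len(names):
            raise ModelError("element names must be unique")
        if sum(e.conducts_when_on for e in self.elements) != 1:
            raise ModelError("exactly one element must have conducts_when_on")
        known = set(names)
        for c in self.couplings:
            if c.source_element not in known or c.target_element not in known:
                raise ModelError(f"coupling references unknown element: {c}")
        for d in self.destabilizations:
            for n, _ in d.condition:
                if n not in known:
                    raise ModelError(f"destabilization references unknown element {n!r}")

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def index_of(self, name: str) -> int:
        for i, e in enumerate(self.elements):
            if e.name == name:
                return i
        raise KeyError(name)

    def element(self, name: str) -> BinaryElement:
        return self.elements[self.index_of(name)]

    @property
    def ligand_species(self) -> set[str]:
        return {e.ligand for e in self.elements if e.ligand is not None}

    @property
    def n_free_parameters(self) -> int:
        """Independent parameters: two intrinsic rates per element, each
        stated (non-derived, nonzero) interaction energy, and each
        destabilization energy."""
        n_rates = 2 * len(self.elements)
        n_energies = sum(
            1 for c in self.couplings if not c.derived and c.ddG != 0.0
        )
        n_energies += len(self.destabilizations)
        return n_rates + n_energies

    def with_partition(self, partition: float) -> "ChannelModel":
        """Copy of the model with all destabilization partitions replaced
        (sensitivity handle for the exit-only convention)."""
        return replace(
            self,
            destabilizations=tuple(
                replace(d, partition=partition) for d in self.destabilizations
            ),
        )


def otop3_zn_model() -> ChannelModel:
    """The published four-element model of Zn2+ potentiation and block of
    the murine OTOP3 proton channel.

    Elements: a pore gate (k_o = 0.02 s^-1, k_c = 25 s^-1), a proton
    activating site (5e4 M^-1 s^-1 on, 1 s^-1 off), a Zn2+ activating site
    (35 M^-1 s^-1 on, 1 s^-1 off) and a fast, independent Zn2+ blocking
    site (5e4 M^-1 s^-1 on, 20 s^-1 off) that abolishes current when
    occupied.

    Interactions (kcal/mol): proton binding lowers the pore-opening barrier
    by 4 (closing untouched) and pore opening lowers the proton-binding
    barrier by 1 (the implied +3 on unbinding is derived); Zn2+ binding at
    the activating site lowers the opening barrier by 3 and raises the
    closing barrier by 3, and pore opening lowers Zn2+ binding by 5 (the
    implied +1 on unbinding is derived).  States with both activating sites
    occupied are destabilized by +6 kcal/mol, implementing H+/Zn2+
    competition for a shared physical site.  14 free parameters in total:
    8 intrinsic rates and 6 stated interaction energies.
    """
    elements = (
        BinaryElement("pore", "gate", k_fwd=0.02, k_bwd=25.0, conducts_when_on=True),
        BinaryElement("H", "site", k_fwd=5e4, k_bwd=1.0, ligand="H"),
        BinaryElement("ZnA", "site", k_fwd=35.0, k_bwd=1.0, ligand="Zn"),
        BinaryElement("ZnB", "site", k_fwd=5e4, k_bwd=20.0, ligand="Zn",
                      blocks_when_on=True),
    )
    couplings = tuple(
        itertools.chain(
            pair_coupling("H", "pore", ddG_fwd=-4.0, ddG_bwd=0.0, recip_fwd=-1.0),
            pair_coupling("ZnA", "pore", ddG_fwd=-3.0, ddG_bwd=3.0, recip_fwd=-5.0),
        )
    )
    destab = (Destabilization((("H", "on"), ("ZnA", "on")), dG=6.0),)
    return ChannelModel(elements, couplings, destab, RT=RT_ROOM)


#: Registry of built-in model presets, loadable by name from configs/CLI.
PRESETS = {"otop3-zn": otop3_zn_model}
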