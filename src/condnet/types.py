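"""Parameter presets for neurons, ion channels and connections.

Units follow the package-wide convention: current in nA, voltage in mV,
conductance in uS, capacitance in nF, time in ms.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "Gate",
    "ChannelType",
    "NeuronType",
    "ConnectionType",
    "nonspiking_neuron",
    "spiking_neuron",
    "channel_neuron",
    "sodium_channel",
    "nonspiking_synapse",
    "spiking_synapse",
    "electrical_synapse",
]

CHEMICAL_NONSPIKING = "chemical_nonspiking"
CHEMICAL_SPIKING = "chemical_spiking"
ELECTRICAL = "electrical"


@dataclass(frozen=True)
class Gate:
    """One gating term of a voltage-gated channel.

    The steady state is ``z_inf(V) = 1 / (1 + K * exp(S * (E - V)))`` and the
    voltage-dependent time constant (dynamic gates only) is
    ``tau(V) = tau_max * z_inf(V) * K * exp(S * (E - V))``.

    ``p`` is the exponent applied to the gate in the channel current; ``p = 0``
    disables the gate (its factor is 1).
    """

    p: float = 0.0
    K: float = 1.0
    S: float = 0.0
    E: float = 0.0  # mV
    tau_max: float = 1.0  # ms; only meaningful for dynamic gates

    def __post_init__(self) -> None:
        if self.p < 0:
            raise ValueError("gate exponent p must be >= 0")


@dataclass(frozen=True)
class ChannelType:
    """A voltage-gated ion channel.

    The channel current into its neuron is
    ``Gion * a_inf(V)^pa * b^pb * c^pc * (Eion - V)``
    where gate ``a`` is instantaneous (always at steady state) and gates
    ``b`` and ``c`` are first-order state variables.
    """

    name: str
    Gion: float  # uS, maximal conductance
    Eion: float  # mV, reversal potential
    gate_a: Gate = field(default_factory=Gate)
    gate_b: Gate = field(default_factory=Gate)
    gate_c: Gate = field(default_factory=Gate)

    def __post_init__(self) -> None:
        if self.Gion < 0:
            raise ValueError(f"channel {self.name!r}: Gion must be >= 0")
        for label in ("b", "c"):
            g: Gate = getattr(self, f"gate_{label}")
            if g.p > 0 and g.tau_max <= 0:
                raise ValueError(
                    f"channel {self.name!r}: dynamic gate {label} needs tau_max > 0"
                )


@dataclass(frozen=True)
class NeuronType:
    """Membrane (and, for spiking neurons, threshold) parameters.

    Non-spiking neurons are leaky integrators; spiking neurons add an
    adaptive firing threshold ``theta`` with time constant ``tau_theta``,
    initial value ``theta0`` and voltage proportionality ``m``.  Ion channels
    may only be attached to non-spiking neurons.
    """

    name: str
    Cm: float = 5.0  # nF
    Gm: float = 1.0  # uS
    Vrest: float = 0.0  # mV
    Ibias: float = 0.0  # nA
    spiking: bool = False
    theta0: float = 1.0  # mV
    tau_theta: float = 1.0  # ms
    m: float = 0.0
    channels: tuple[ChannelType, ...] = ()

    def __post_init__(self) -> None:
        if self.Cm <= 0:
            raise ValueError(f"neuron type {self.name!r}: Cm must be > 0")
        if self.Gm <= 0:
            raise ValueError(f"neuron type {self.name!r}: Gm must be > 0")
        if self.spiking:
            if self.tau_theta <= 0:
                raise ValueError(
                    f"neuron type {self.name!r}: tau_theta must be > 0"
                )
            if self.channels:
                raise ValueError(
                    f"neuron type {self.name!r}: spiking neurons may not carry "
                    "ion channels"
                )
        object.__setattr__(self, "channels", tuple(self.channels))


@dataclass(frozen=True)
class ConnectionType:
    """Synapse preset.

    ``kind`` is one of ``chemical_nonspiking`` (graded conductance, linear in
    presynaptic voltage between ``Elo`` and ``Ehi``), ``chemical_spiking``
    (conductance jumps to ``Gmax`` on a delayed presynaptic spike then decays
    with ``tau_syn``) or ``electrical`` (gap junction, optionally rectified).
    ``delay`` is an integer number of timesteps.
    """

    name: str
    kind: str
    Gmax: float  # uS
    Esyn: float = 0.0  # mV (chemical only)
    Elo: float = 0.0  # mV (non-spiking chemical)
    Ehi: float = 1.0  # mV (non-spiking chemical)
    tau_syn: float = 1.0  # ms (spiking chemical)
    delay: int = 0  # timesteps (spiking chemical)
    rectified: bool = False  # electrical only

    def __post_init__(self) -> None:
        if self.kind not in (CHEMICAL_NONSPIKING, CHEMICAL_SPIKING, ELECTRICAL):
            raise ValueError(f"unknown connection kind {self.kind!r}")
        if self.Gmax < 0:
            raise ValueError(f"connection type {self.name!r}: Gmax must be >= 0")
        if self.kind == CHEMICAL_NONSPIKING and not self.Ehi > self.Elo:
            raise ValueError(
                f"connection type {self.name!r}: requires Ehi > Elo"
            )
        if self.kind == CHEMICAL_SPIKING:
            if self.tau_syn <= 0:
                raise ValueError(
                    f"connection type {self.name!r}: tau_syn must be > 0"
                )
            if not isinstance(self.delay, (int,)) or isinstance(self.delay, bool):
                raise ValueError(
                    f"connection type {self.name!r}: delay must be an integer "
                    "number of timesteps"
                )
            if self.delay < 0:
                raise ValueError(
                    f"connection type {self.name!r}: delay must be >= 0"
                )

    def with_(self, **changes) -> "ConnectionType":
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# Convenience factories


def nonspiking_neuron(name: str = "nonspiking", **kw) -> NeuronType:
    return NeuronType(name=name, spiking=False, **kw)


def spiking_neuron(
    name: str = "spiking",
    theta0: float = 1.0,
    tau_theta: float = 5.0,
    m: float = 0.0,
    **kw,
) -> NeuronType:
    return NeuronType(
        name=name, spiking=True, theta0=theta0, tau_theta=tau_theta, m=m, **kw
    )


def channel_neuron(
    name: str, channels: tuple[ChannelType, ...], **kw
) -> NeuronType:
    return NeuronType(name=name, spiking=False, channels=tuple(channels), **kw)


def sodium_channel(
    name: str = "NaP",
    Gna: float = 1.5,
    Ena: float = 50.0,
    Km: float = 1.0,
    Sm: float = 0.05,
    Em: float = -40.0,
    Kh: float = 0.5,
    Sh: float = -0.05,
    Eh: float = -60.0,
    tau_h_max: float = 300.0,
) -> ChannelType:
    """Persistent sodium channel: instantaneous activation ``m``, slow
    inactivation ``h``; current ``Gna * m_inf(V) * h * (Ena - V)``."""
    return ChannelType(
        name=name,
        Gion=Gna,
        Eion=Ena,
        gate_a=Gate(p=1.0, K=Km, S=Sm, E=Em),
        gate_b=Gate(p=1.0, K=Kh, S=Sh, E=Eh, tau_max=tau_h_max),
        gate_c=Gate(p=0.0),
    )


def nonspiking_synapse(
    name: str = "chem",
    Gmax: float = 1.0,
    Esyn: float = 20.0,
    Elo: float = 0.0,
    Ehi: float = 1.0,
) -> ConnectionType:
    return ConnectionType(
        name=name, kind=CHEMICAL_NONSPIKING, Gmax=Gmax, Esyn=Esyn, Elo=Elo, Ehi=Ehi
    )


def spiking_synapse(
    name: str = "spike",
    Gmax: float = 1.0,
    Esyn: float = 20.0,
    tau_syn: float = 1.0,
    delay: int = 0,
) -> ConnectionType:
    return ConnectionType(
        name=name,
        kind=CHEMICAL_SPIKING,
        Gmax=Gmax,
        Esyn=Esyn,
        tau_syn=tau_syn,
        delay=delay,
    )


def electrical_synapse(
    name: str = "gap", Gmax: float = 1.0, rectified: bool = False
) -> ConnectionType:
    return ConnectionType(name=name, kind=ELECTRICAL, Gmax=Gmax, rectified=rectified)
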