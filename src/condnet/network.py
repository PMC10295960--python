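"""Author-facing network data model.

A :class:`Network` is an editable, ordered container of named neuron
populations plus the connections, input sources and output monitors between
them.  Nothing here is executable; the compiler flattens a network into the
vector/matrix form the simulation engine consumes.

Populations may be declared with a 1-D length or a 2-D ``(rows, cols)``
shape; 2-D populations are flattened row-major, so neuron ``(r, c)`` of an
``R x C`` population sits at flat offset ``r * C + c`` within it.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .types import (
    CHEMICAL_NONSPIKING,
    CHEMICAL_SPIKING,
    ELECTRICAL,
    ConnectionType,
    NeuronType,
)

__all__ = ["Population", "ConnectionSpec", "InputSpec", "OutputSpec", "Network"]

#: payload keys accepted for matrix / pattern schemes, per connection kind
_PAYLOAD_KEYS = {
    CHEMICAL_NONSPIKING: {"Gmax", "Esyn", "Elo", "Ehi"},
    CHEMICAL_SPIKING: {"Gmax", "Esyn", "tau_syn", "delay"},
    ELECTRICAL: {"Gmax"},
}

SCHEMES = ("direct", "one_to_one", "matrix", "pattern")


@dataclass
class Population:
    name: str
    shape: tuple[int, ...]  # (n,) or (rows, cols)
    neuron_type: NeuronType
    initial_voltage: np.ndarray | None = None  # mV, flat, length == size

    @property
    def size(self) -> int:
        return int(np.prod(self.shape))

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in np.atleast_1d(self.shape))
        if len(shape) not in (1, 2) or any(s < 1 for s in shape):
            raise ValueError(
                f"population {self.name!r}: shape must be a positive length "
                f"or (rows, cols), got {self.shape!r}"
            )
        self.shape = shape
        if self.initial_voltage is not None:
            v0 = np.asarray(self.initial_voltage, dtype=float).ravel()
            if v0.size != self.size:
                raise ValueError(
                    f"population {self.name!r}: initial_voltage has "
                    f"{v0.size} entries, expected {self.size}"
                )
            self.initial_voltage = v0

    def flat_index(self, r: int, c: int = 0) -> int:
        """Row-major flat index of neuron ``(r, c)`` within this population."""
        if len(self.shape) == 1:
            return int(r)
        return int(r * self.shape[1] + c)


@dataclass
class ConnectionSpec:
    """A (possibly population-level) connection.

    Schemes:

    ``direct``
        single synapse between single neurons, or a scaled all-to-all fan
        between populations (per-synapse conductance ``Gmax / n_src``).
    ``one_to_one``
        equal-size populations, neuron ``k`` to neuron ``k``, shared preset.
    ``matrix``
        explicit per-parameter ``(dest_size, src_size)`` matrices in
        ``payload`` (``Gmax`` required; zero entries mean "no synapse").
    ``pattern``
        per-parameter odd-dimension kernels replicated at every spatial
        offset between equal-shape 2-D populations.
    """

    source: str
    destination: str
    connection_type: ConnectionType
    scheme: str = "direct"
    payload: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown connection scheme {self.scheme!r}")
        self.payload = {
            k: np.asarray(v, dtype=float) for k, v in self.payload.items()
        }
        if self.scheme in ("matrix", "pattern"):
            allowed = _PAYLOAD_KEYS[self.connection_type.kind]
            bad = set(self.payload) - allowed
            if bad:
                raise ValueError(
                    f"payload keys {sorted(bad)} not valid for kind "
                    f"{self.connection_type.kind!r}"
                )
            if "Gmax" not in self.payload:
                raise ValueError(f"{self.scheme} scheme requires a 'Gmax' payload")
            if np.any(self.payload["Gmax"] < 0):
                raise ValueError("payload Gmax entries must be >= 0")
        elif self.payload:
            raise ValueError(f"scheme {self.scheme!r} takes no payload")


@dataclass
class InputSpec:
    """External-current source feeding a population.

    ``width`` is 1 (a single current routed to the population's first
    neuron) or the population size (one current element per neuron).
    """

    target: str
    width: int = 1


@dataclass
class OutputSpec:
    """Monitor on a population; one output record per source neuron."""

    source: str
    mode: str = "voltage"  # or "spike"

    def __post_init__(self) -> None:
        if self.mode not in ("voltage", "spike"):
            raise ValueError(f"output mode must be 'voltage' or 'spike', got {self.mode!r}")


class Network:
    """Ordered, named collection of populations, connections, inputs, outputs."""

    def __init__(self, name: str = "network"):
        self.name = name
        self.populations: list[Population] = []
        self.connections: list[ConnectionSpec] = []
        self.inputs: list[InputSpec] = []
        self.outputs: list[OutputSpec] = []

    # -- lookups ----------------------------------------------------------
    def population(self, name: str) -> Population:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(f"no population named {name!r}")

    def offset(self, name: str) -> int:
        """Flat index of the first neuron of the named population."""
        off = 0
        for p in self.populations:
            if p.name == name:
                return off
            off += p.size
        raise KeyError(f"no population named {name!r}")

    @property
    def num_neurons(self) -> int:
        return sum(p.size for p in self.populations)

    @property
    def input_width(self) -> int:
        return sum(i.width for i in self.inputs)

    @property
    def num_outputs(self) -> int:
        return sum(self.population(o.source).size for o in self.outputs)

    # -- construction -----------------------------------------------------
    def add_population(
        self,
        neuron_type: NeuronType,
        shape,
        name: str,
        initial_voltage=None,
    ) -> "Network":
        if any(p.name == name for p in self.populations):
            raise ValueError(f"duplicate population name {name!r}")
        self.populations.append(
            Population(
                name=name,
                shape=tuple(np.atleast_1d(shape)),
                neuron_type=neuron_type,
                initial_voltage=initial_voltage,
            )
        )
        return self

    def add_connection(
        self,
        source: str,
        destination: str,
        connection_type: ConnectionType,
        scheme: str = "direct",
        payload: dict | None = None,
    ) -> "Network":
        spec = ConnectionSpec(
            source=source,
            destination=destination,
            connection_type=connection_type,
            scheme=scheme,
            payload=payload or {},
        )
        self._validate_connection(spec)
        self.connections.append(spec)
        return self

    def add_connection_spec(self, spec: ConnectionSpec) -> "Network":
        self._validate_connection(spec)
        self.connections.append(spec)
        return self

    def _validate_connection(self, spec: ConnectionSpec) -> None:
        src = self.population(spec.source)
        dst = self.population(spec.destination)
        if spec.scheme == "one_to_one" and src.size != dst.size:
            raise ValueError(
                f"one_to_one requires equal sizes, got {src.size} -> {dst.size}"
            )
        if spec.scheme == "matrix":
            for key, mat in spec.payload.items():
                if mat.shape != (dst.size, src.size):
                    raise ValueError(
                        f"matrix payload {key!r} has shape {mat.shape}, "
                        f"expected ({dst.size}, {src.size})"
                    )
        if spec.scheme == "pattern":
            if len(src.shape) != 2 or len(dst.shape) != 2:
                raise ValueError("pattern connections require 2-D populations")
            if src.shape != dst.shape:
                raise ValueError(
                    f"pattern requires equal shapes, got {src.shape} vs {dst.shape}"
                )
            for key, ker in spec.payload.items():
                if ker.ndim != 2 or ker.shape[0] % 2 == 0 or ker.shape[1] % 2 == 0:
                    raise ValueError(
                        f"pattern kernel {key!r} must be 2-D with odd dimensions, "
                        f"got {ker.shape}"
                    )
                if ker.shape != spec.payload["Gmax"].shape:
                    raise ValueError("pattern kernels must share one shape")

    def add_input(self, target: str, width: int = 1) -> "Network":
        pop = self.population(target)
        if width not in (1, pop.size):
            raise ValueError(
                f"input width must be 1 or the population size ({pop.size}), "
                f"got {width}"
            )
        self.inputs.append(InputSpec(target=target, width=int(width)))
        return self

    def add_output(self, source: str, mode: str = "voltage") -> "Network":
        pop = self.population(source)
        spec = OutputSpec(source=source, mode=mode)
        if mode == "spike" and not pop.neuron_type.spiking:
            raise ValueError(
                f"spike output on non-spiking population {source!r}"
            )
        self.outputs.append(spec)
        return self

    def include_network(self, sub: "Network", prefix: str) -> "Network":
        """Copy ``sub`` into this network with every name prefixed.

        The prefix is prepended verbatim (include a separator yourself,
        e.g. ``"L."``).  Collides loudly rather than silently merging.
        """
        existing = {p.name for p in self.populations}
        for p in sub.populations:
            if prefix + p.name in existing:
                raise ValueError(
                    f"include_network: name {prefix + p.name!r} already exists"
                )
        for p in sub.populations:
            self.populations.append(
                Population(
                    name=prefix + p.name,
                    shape=p.shape,
                    neuron_type=p.neuron_type,
                    initial_voltage=None
                    if p.initial_voltage is None
                    else p.initial_voltage.copy(),
                )
            )
        for c in sub.connections:
            self.connections.append(
                ConnectionSpec(
                    source=prefix + c.source,
                    destination=prefix + c.destination,
                    connection_type=c.connection_type,
                    scheme=c.scheme,
                    payload={k: v.copy() for k, v in c.payload.items()},
                )
            )
        for i in sub.inputs:
            self.inputs.append(InputSpec(target=prefix + i.target, width=i.width))
        for o in sub.outputs:
            self.outputs.append(OutputSpec(source=prefix + o.source, mode=o.mode))
        return self

    def copy(self) -> "Network":
        return copy.deepcopy(self)

    def validate(self) -> None:
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        for c in self.connections:
            self._validate_connection(c)
        for i in self.inputs:
            pop = self.population(i.target)
            if i.width not in (1, pop.size):
                raise ValueError(f"bad input width {i.width} on {i.target!r}")
        for o in self.outputs:
            pop = self.population(o.source)
            if o.mode == "spike" and not pop.neuron_type.spiking:
                raise ValueError(f"spike output on non-spiking {o.source!r}")

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Network({self.name!r}: {len(self.populations)} populations, "
            f"{self.num_neurons} neurons, {len(self.connections)} connections)"
        )
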