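"""Serialization: JSON network documents and CSV time series.

Network documents are versioned JSON with presets (neuron, channel and
connection types) stored once by name and referenced from populations and
connections.  Units are fixed to nA / mV / uS / nF / ms.  Spike states are
written to files as 0/1, converting from the internal 0/-1 representation.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import ConnectionSpec, Network
from .types import ChannelType, ConnectionType, Gate, NeuronType

__all__ = [
    "save_network",
    "load_network",
    "network_to_dict",
    "network_from_dict",
    "read_input_series",
    "write_output_series",
]

FORMAT_VERSION = 1


class DocumentError(ValueError):
    """Malformed or unsupported network document."""


# --------------------------------------------------------------------------
# dict <-> objects

_GATE_FIELDS = ("p", "K", "S", "E", "tau_max")
_NEURON_FIELDS = (
    "Cm", "Gm", "Vrest", "Ibias", "spiking", "theta0", "tau_theta", "m",
)
_CONN_FIELDS = (
    "kind", "Gmax", "Esyn", "Elo", "Ehi", "tau_syn", "delay", "rectified",
)


def _check_fields(obj: dict, allowed: set[str], context: str) -> None:
    unknown = set(obj) - allowed
    if unknown:
        raise DocumentError(
            f"unknown field(s) {sorted(unknown)} in {context} "
            f"(document version {FORMAT_VERSION})"
        )


def _gate_to_dict(g: Gate) -> dict:
    return {f: getattr(g, f) for f in _GATE_FIELDS}


def _channel_to_dict(c: ChannelType) -> dict:
    return {
        "name": c.name,
        "Gion": c.Gion,
        "Eion": c.Eion,
        "gate_a": _gate_to_dict(c.gate_a),
        "gate_b": _gate_to_dict(c.gate_b),
        "gate_c": _gate_to_dict(c.gate_c),
    }


def _channel_from_dict(d: dict) -> ChannelType:
    _check_fields(d, {"name", "Gion", "Eion", "gate_a", "gate_b", "gate_c"}, "channel type")
    gates = {}
    for g in ("gate_a", "gate_b", "gate_c"):
        gd = d.get(g, {})
        _check_fields(gd, set(_GATE_FIELDS), f"channel gate {g}")
        gates[g] = Gate(**gd)
    return ChannelType(name=d["name"], Gion=d["Gion"], Eion=d["Eion"], **gates)


def network_to_dict(net: Network) -> dict:
    neuron_types: dict[str, dict] = {}
    connection_types: dict[str, dict] = {}
    for pop in net.populations:
        nt = pop.neuron_type
        doc = {f: getattr(nt, f) for f in _NEURON_FIELDS}
        doc["channels"] = [_channel_to_dict(c) for c in nt.channels]
        neuron_types.setdefault(nt.name, doc)
    for con in net.connections:
        ct = con.connection_type
        connection_types.setdefault(
            ct.name, {f: getattr(ct, f) for f in _CONN_FIELDS}
        )
    return {
        "format": "condnet-network",
        "version": FORMAT_VERSION,
        "name": net.name,
        "units": {
            "current": "nA", "voltage": "mV", "conductance": "uS",
            "capacitance": "nF", "time": "ms",
        },
        "neuron_types": neuron_types,
        "connection_types": connection_types,
        "populations": [
            {
                "name": p.name,
                "shape": list(p.shape),
                "neuron_type": p.neuron_type.name,
                "initial_voltage": None
                if p.initial_voltage is None
                else p.initial_voltage.tolist(),
            }
            for p in net.populations
        ],
        "connections": [
            {
                "source": c.source,
                "destination": c.destination,
                "connection_type": c.connection_type.name,
                "scheme": c.scheme,
                "payload": {k: v.tolist() for k, v in c.payload.items()},
            }
            for c in net.connections
        ],
        "inputs": [{"target": i.target, "width": i.width} for i in net.inputs],
        "outputs": [{"source": o.source, "mode": o.mode} for o in net.outputs],
    }


def network_from_dict(doc: dict) -> Network:
    if not isinstance(doc, dict) or doc.get("format") != "condnet-network":
        raise DocumentError("not a condnet network document")
    if doc.get("version") != FORMAT_VERSION:
        raise DocumentError(
            f"unsupported document version {doc.get('version')!r}; "
            f"this build reads version {FORMAT_VERSION}"
        )
    _check_fields(
        doc,
        {
            "format", "version", "name", "units", "neuron_types",
            "connection_types", "populations", "connections", "inputs", "outputs",
        },
        "network document",
    )
    neuron_types: dict[str, NeuronType] = {}
    for name, d in doc.get("neuron_types", {}).items():
        _check_fields(d, set(_NEURON_FIELDS) | {"channels"}, f"neuron type {name!r}")
        channels = tuple(_channel_from_dict(c) for c in d.get("channels", []))
        kw = {f: d[f] for f in _NEURON_FIELDS if f in d}
        neuron_types[name] = NeuronType(name=name, channels=channels, **kw)
    connection_types: dict[str, ConnectionType] = {}
    for name, d in doc.get("connection_types", {}).items():
        _check_fields(d, set(_CONN_FIELDS), f"connection type {name!r}")
        connection_types[name] = ConnectionType(name=name, **d)
    net = Network(name=doc.get("name", "network"))
    for p in doc.get("populations", []):
        _check_fields(
            p, {"name", "shape", "neuron_type", "initial_voltage"}, "population"
        )
        try:
            nt = neuron_types[p["neuron_type"]]
        except KeyError:
            raise DocumentError(
                f"population {p['name']!r} references unknown neuron type "
                f"{p['neuron_type']!r}"
            ) from None
        net.add_population(
            nt, tuple(p["shape"]), p["name"], initial_voltage=p.get("initial_voltage")
        )
    for c in doc.get("connections", []):
        _check_fields(
            c,
            {"source", "destination", "connection_type", "scheme", "payload"},
            "connection",
        )
        try:
            ct = connection_types[c["connection_type"]]
        except KeyError:
            raise DocumentError(
                f"connection references unknown connection type "
                f"{c['connection_type']!r}"
            ) from None
        net.add_connection_spec(
            ConnectionSpec(
                source=c["source"],
                destination=c["destination"],
                connection_type=ct,
                scheme=c.get("scheme", "direct"),
                payload={
                    k: np.asarray(v, dtype=float)
                    for k, v in c.get("payload", {}).items()
                },
            )
        )
    for i in doc.get("inputs", []):
        _check_fields(i, {"target", "width"}, "input")
        net.add_input(i["target"], i.get("width", 1))
    for o in doc.get("outputs", []):
        _check_fields(o, {"source", "mode"}, "output")
        net.add_output(o["source"], o.get("mode", "voltage"))
    net.validate()
    return net


def save_network(net: Network, path) -> None:
    doc = network_to_dict(net)
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def load_network(path) -> Network:
    text = Path(path).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise DocumentError(f"malformed network document {path}: {e}") from None
    return network_from_dict(doc)


# --------------------------------------------------------------------------
# CSV time series


def read_input_series(path) -> tuple[list[str], np.ndarray]:
    """Read an input CSV (header row naming inputs, one row per timestep,
    currents in nA).  Returns (names, array of shape (steps, L))."""
    df = pd.read_csv(path)
    arr = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-numeric or non-finite cells in input series {path}")
    return list(df.columns), arr


def write_output_series(path, matrix: np.ndarray, names, spike_mask=None) -> None:
    """Write an output CSV.  Columns flagged in ``spike_mask`` hold spike
    states and are converted from the internal 0/-1 encoding to 0/1."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("output matrix must be 2-D (steps x outputs)")
    data = matrix.copy()
    if spike_mask is not None:
        spike_mask = np.asarray(spike_mask, dtype=bool)
        data[:, spike_mask] = -data[:, spike_mask]
    pd.DataFrame(data, columns=list(names)).to_csv(path, index=False)
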