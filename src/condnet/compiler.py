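"""Flatten a :class:`~condnet.network.Network` into executable arrays.

Compilation proceeds in a fixed order: neuron parameters, input mapping,
synaptic parameter matrices, time factors, delay-buffer geometry, output
mapping.  It is pure — the same network and timestep always produce an
identical model.

Matrix convention: synaptic parameter matrices are ``N x N`` with columns
indexing the presynaptic neuron and rows the postsynaptic neuron.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import ConnectionSpec, Network
from .types import (
    CHEMICAL_NONSPIKING,
    CHEMICAL_SPIKING,
    ELECTRICAL,
    ChannelType,
    ConnectionType,
)

__all__ = [
    "CompiledModel",
    "ChannelArrays",
    "compile_network",
    "expand_all_to_all",
    "expand_one_to_one",
    "expand_pattern",
]

_GATES = ("a", "b", "c")


@dataclass
class ChannelArrays:
    """Per-channel-instance parameter arrays (one entry per attached channel)."""

    neuron: np.ndarray  # int, target neuron index
    Gion: np.ndarray
    Eion: np.ndarray
    # per gate g in (a, b, c): exponent p, K, S, E; tau_max for b and c
    p: dict[str, np.ndarray] = field(default_factory=dict)
    K: dict[str, np.ndarray] = field(default_factory=dict)
    S: dict[str, np.ndarray] = field(default_factory=dict)
    E: dict[str, np.ndarray] = field(default_factory=dict)
    tau_max: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.neuron.size


@dataclass
class CompiledModel:
    dt: float  # ms
    N: int
    L: int  # external input width
    # per-neuron vectors
    Cm: np.ndarray
    Gm: np.ndarray
    Vrest: np.ndarray
    Ibias: np.ndarray
    spiking: np.ndarray  # bool mask
    theta0: np.ndarray
    T_theta: np.ndarray  # dt / tau_theta (0 for non-spiking)
    m: np.ndarray
    T_m: np.ndarray  # dt / Cm, membrane step factor
    V0: np.ndarray  # initial voltages
    # N x N synaptic parameter matrices
    Gmax_non: np.ndarray
    Gmax_spike: np.ndarray
    Esyn: np.ndarray
    Elo: np.ndarray
    Ehi: np.ndarray
    T_syn: np.ndarray  # dt / tau_syn (1 where unused)
    delay: np.ndarray  # int timesteps
    G_elec: np.ndarray  # symmetric, bidirectional gap junctions
    G_rec: np.ndarray  # rectified gap junctions, (dst, src)
    buffer_depth: int  # max delay + 1
    channels: ChannelArrays
    # input / output maps
    Cin: np.ndarray  # N x L, each column one-hot
    Cout_voltage: np.ndarray  # n_out x N
    Cout_spike: np.ndarray  # n_out x N
    output_is_spike: np.ndarray  # bool per output row
    output_names: list[str]
    input_names: list[str]

    @property
    def n_outputs(self) -> int:
        return self.Cout_voltage.shape[0]


def expand_all_to_all(n_src: int, n_dst: int, Gmax: float) -> np.ndarray:
    """All-to-all conductance block, scaled so each postsynaptic row sums to
    ``Gmax`` (per-synapse conductance ``Gmax / n_src``)."""
    if n_src < 1 or n_dst < 1:
        raise ValueError("population sizes must be >= 1")
    return np.full((n_dst, n_src), Gmax / n_src)


def expand_one_to_one(n: int, value: float) -> np.ndarray:
    """Diagonal parameter block sharing one preset value."""
    return np.eye(n) * value


def expand_pattern(kernel: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Expand a ``(2u+1) x (2v+1)`` kernel into an ``RC x RC`` parameter
    matrix between two equal ``(R, C)`` populations (row-major flattening).

    Entry ``P[p, q]`` (postsynaptic flat index ``p``, presynaptic ``q``) is
    ``kernel[u + (q_r - p_r), v + (q_c - p_c)]`` when the offset falls inside
    the kernel, else 0 (zero padding, stride 1).
    """
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 2 or kernel.shape[0] % 2 == 0 or kernel.shape[1] % 2 == 0:
        raise ValueError(f"kernel must be 2-D with odd dimensions, got {kernel.shape}")
    R, C = shape
    u = kernel.shape[0] // 2
    v = kernel.shape[1] // 2
    P = np.zeros((R * C, R * C))
    rows = np.arange(R)
    cols = np.arange(C)
    # offsets between presynaptic (q) and postsynaptic (p) grid coordinates
    dr = rows[None, :] - rows[:, None] + u  # (p_r, q_r)
    dc = cols[None, :] - cols[:, None] + v  # (p_c, q_c)
    ok_r = (dr >= 0) & (dr < kernel.shape[0])
    ok_c = (dc >= 0) & (dc < kernel.shape[1])
    for pr in range(R):
        for qr in range(R):
            if not ok_r[pr, qr]:
                continue
            krow = kernel[dr[pr, qr]]
            block = np.zeros((C, C))
            mask = ok_c
            block[mask] = krow[dc[mask]]
            P[pr * C:(pr + 1) * C, qr * C:(qr + 1) * C] = block
    return P


def _pair_blocks(spec: ConnectionSpec, src_size: int, dst_size: int):
    """Return per-parameter (dst_size x src_size) blocks for a connection.

    The returned dict always has a ``Gmax`` block; other parameters are
    present only when they differ per-pair (matrix/pattern payload), and the
    connection-type defaults apply elsewhere.
    """
    ct = spec.connection_type
    if spec.scheme == "direct":
        if src_size == 1 and dst_size == 1:
            blocks = {"Gmax": np.array([[ct.Gmax]])}
        else:
            blocks = {"Gmax": expand_all_to_all(src_size, dst_size, ct.Gmax)}
    elif spec.scheme == "one_to_one":
        blocks = {"Gmax": expand_one_to_one(src_size, ct.Gmax)}
    elif spec.scheme == "matrix":
        blocks = {k: v.copy() for k, v in spec.payload.items()}
    else:  # pattern
        shape = None  # filled by caller
        raise AssertionError("pattern handled separately")
    return blocks


def _accumulate_chemical(
    model: "CompiledModel",
    occupied: np.ndarray,
    spec: ConnectionSpec,
    blocks: dict[str, np.ndarray],
    r0: int,
    c0: int,
    dt: float,
) -> None:
    ct = spec.connection_type
    G = blocks["Gmax"]
    nz = G > 0
    if not nz.any():
        return
    rows, cols = np.nonzero(nz)
    rows = rows + r0
    cols = cols + c0
    if occupied[rows, cols].any():
        raise ValueError(
            f"multiple chemical synapses onto the same ordered neuron pair "
            f"({spec.source!r} -> {spec.destination!r}); dense parameter "
            "matrices cannot superpose two reversal potentials"
        )
    occupied[rows, cols] = True

    def block_or_default(key: str, default: float) -> np.ndarray:
        if key in blocks:
            return blocks[key][nz]
        return np.full(rows.size, default)

    if ct.kind == CHEMICAL_NONSPIKING:
        model.Gmax_non[rows, cols] = G[nz]
        model.Esyn[rows, cols] = block_or_default("Esyn", ct.Esyn)
        elo = block_or_default("Elo", ct.Elo)
        ehi = block_or_default("Ehi", ct.Ehi)
        if np.any(ehi <= elo):
            raise ValueError(
                f"connection {spec.source!r} -> {spec.destination!r}: "
                "requires Ehi > Elo"
            )
        model.Elo[rows, cols] = elo
        model.Ehi[rows, cols] = ehi
    else:  # spiking
        model.Gmax_spike[rows, cols] = G[nz]
        model.Esyn[rows, cols] = block_or_default("Esyn", ct.Esyn)
        tau = block_or_default("tau_syn", ct.tau_syn)
        if np.any(tau <= 0):
            raise ValueError("tau_syn must be > 0")
        if np.any(dt >= tau):
            warnings.warn(
                f"timestep {dt} ms >= tau_syn on connection "
                f"{spec.source!r} -> {spec.destination!r}; spiking "
                "conductance decay will be inaccurate",
                stacklevel=2,
            )
        model.T_syn[rows, cols] = dt / tau
        d = block_or_default("delay", float(ct.delay))
        if np.any(d != np.round(d)) or np.any(d < 0):
            raise ValueError("delays must be non-negative integers (timesteps)")
        model.delay[rows, cols] = d.astype(np.int64)


def _accumulate_electrical(
    model: "CompiledModel",
    spec: ConnectionSpec,
    blocks: dict[str, np.ndarray],
    r0: int,
    c0: int,
) -> None:
    ct = spec.connection_type
    G = blocks["Gmax"]
    rows, cols = np.nonzero(G > 0)
    for r, c in zip(rows + r0, cols + c0):
        if r == c:
            continue  # electrical self-coupling carries no current; drop it
        g = G[r - r0, c - c0]
        if ct.rectified:
            model.G_rec[r, c] += g
        else:
            model.G_elec[r, c] += g
            model.G_elec[c, r] += g


def _build_channels(net: Network) -> ChannelArrays:
    neuron_idx: list[int] = []
    chans: list[ChannelType] = []
    off = 0
    for pop in net.populations:
        for ch in pop.neuron_type.channels:
            for k in range(pop.size):
                neuron_idx.append(off + k)
                chans.append(ch)
        off += pop.size
    n = len(chans)
    arr = ChannelArrays(
        neuron=np.array(neuron_idx, dtype=np.int64),
        Gion=np.array([c.Gion for c in chans], dtype=float),
        Eion=np.array([c.Eion for c in chans], dtype=float),
    )
    for g in _GATES:
        gates = [getattr(c, f"gate_{g}") for c in chans]
        arr.p[g] = np.array([x.p for x in gates], dtype=float)
        arr.K[g] = np.array([x.K for x in gates], dtype=float)
        arr.S[g] = np.array([x.S for x in gates], dtype=float)
        arr.E[g] = np.array([x.E for x in gates], dtype=float)
        if g in ("b", "c"):
            arr.tau_max[g] = np.array([x.tau_max for x in gates], dtype=float)
    if n == 0:
        for g in _GATES:
            arr.p[g] = np.zeros(0)
            arr.K[g] = np.zeros(0)
            arr.S[g] = np.zeros(0)
            arr.E[g] = np.zeros(0)
        arr.tau_max["b"] = np.zeros(0)
        arr.tau_max["c"] = np.zeros(0)
    return arr


def compile_network(net: Network, dt: float) -> CompiledModel:
    """Compile ``net`` for simulation at timestep ``dt`` (ms)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    net.validate()
    N = net.num_neurons

    # --- per-neuron parameters ------------------------------------------
    Cm = np.empty(N)
    Gm = np.empty(N)
    Vrest = np.empty(N)
    Ibias = np.empty(N)
    spiking = np.zeros(N, dtype=bool)
    theta0 = np.zeros(N)
    T_theta = np.zeros(N)
    m = np.zeros(N)
    V0 = np.empty(N)
    off = 0
    offsets: dict[str, int] = {}
    for pop in net.populations:
        sl = slice(off, off + pop.size)
        offsets[pop.name] = off
        nt = pop.neuron_type
        Cm[sl] = nt.Cm
        Gm[sl] = nt.Gm
        Vrest[sl] = nt.Vrest
        Ibias[sl] = nt.Ibias
        if nt.spiking:
            spiking[sl] = True
            theta0[sl] = nt.theta0
            T_theta[sl] = dt / nt.tau_theta
            m[sl] = nt.m
        V0[sl] = nt.Vrest if pop.initial_voltage is None else pop.initial_voltage
        off += pop.size

    # --- input mapping ---------------------------------------------------
    L = net.input_width
    Cin = np.zeros((N, L))
    input_names: list[str] = []
    col = 0
    for inp in net.inputs:
        base = offsets[inp.target]
        if inp.width == 1:
            Cin[base, col] = 1.0
            input_names.append(inp.target)
            col += 1
        else:
            for k in range(inp.width):
                Cin[base + k, col] = 1.0
                input_names.append(f"{inp.target}[{k}]")
                col += 1

    # --- synaptic parameter matrices ------------------------------------
    model = CompiledModel(
        dt=dt,
        N=N,
        L=L,
        Cm=Cm,
        Gm=Gm,
        Vrest=Vrest,
        Ibias=Ibias,
        spiking=spiking,
        theta0=theta0,
        T_theta=T_theta,
        m=m,
        T_m=dt / Cm,
        V0=V0,
        Gmax_non=np.zeros((N, N)),
        Gmax_spike=np.zeros((N, N)),
        Esyn=np.zeros((N, N)),
        Elo=np.zeros((N, N)),
        Ehi=np.ones((N, N)),
        T_syn=np.ones((N, N)),
        delay=np.zeros((N, N), dtype=np.int64),
        G_elec=np.zeros((N, N)),
        G_rec=np.zeros((N, N)),
        buffer_depth=1,
        channels=_build_channels(net),
        Cin=Cin,
        Cout_voltage=np.zeros((0, N)),
        Cout_spike=np.zeros((0, N)),
        output_is_spike=np.zeros(0, dtype=bool),
        output_names=[],
        input_names=input_names,
    )
    occupied = np.zeros((N, N), dtype=bool)  # chemical pair bookkeeping
    for spec in net.connections:
        src = net.population(spec.source)
        dst = net.population(spec.destination)
        r0 = offsets[spec.destination]
        c0 = offsets[spec.source]
        if spec.scheme == "pattern":
            shape = src.shape  # validated equal to dst.shape, 2-D
            blocks = {
                k: expand_pattern(v, shape) for k, v in spec.payload.items()
            }
        else:
            blocks = _pair_blocks(spec, src.size, dst.size)
        if spec.connection_type.kind == ELECTRICAL:
            _accumulate_electrical(model, spec, blocks, r0, c0)
        else:
            _accumulate_chemical(model, occupied, spec, blocks, r0, c0, dt)

    np.fill_diagonal(model.G_elec, 0.0)
    np.fill_diagonal(model.G_rec, 0.0)

    # --- time factors / delay buffer geometry ---------------------------
    model.buffer_depth = int(model.delay.max()) + 1 if N else 1

    # --- output mapping --------------------------------------------------
    n_out = net.num_outputs
    Cout_v = np.zeros((n_out, N))
    Cout_s = np.zeros((n_out, N))
    is_spike = np.zeros(n_out, dtype=bool)
    names: list[str] = []
    row = 0
    for out in net.outputs:
        base = offsets[out.source]
        size = net.population(out.source).size
        for k in range(size):
            if out.mode == "spike":
                Cout_s[row, base + k] = 1.0
                is_spike[row] = True
            else:
                Cout_v[row, base + k] = 1.0
            suffix = f"[{k}]" if size > 1 else ""
            names.append(f"{out.source}{suffix}:{out.mode}")
            row += 1
    model.Cout_voltage = Cout_v
    model.Cout_spike = Cout_s
    model.output_is_spike = is_spike
    model.output_names = names
    return model
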