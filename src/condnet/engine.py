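"""Discrete-time simulation of a compiled model.

Two interchangeable backends are provided: a dense, vectorized NumPy
backend and an element-iterating backend that walks explicit per-synapse
lists.  Both advance the state with the same forward-Euler schedule, and a
test suite asserts their traces agree.

Step schedule (every quantity a neuron sees comes from the previous step):

1. route external currents,
2. graded synaptic conductances from the previous voltages,
3. decay spiking conductances and trigger resets from the delay buffer,
4. chemical, electrical and ionic currents from the previous voltages,
5. integrate the membrane,
6. advance gating variables,
7. update thresholds, detect spikes, reset spiked membranes,
8. push the new spike vector into the delay buffer,
9. assemble outputs.

A spike therefore reaches a postsynaptic conductance with a base latency of
one timestep plus the synapse's configured delay.

Spikes are represented internally as impulses of magnitude -1.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .compiler import CompiledModel

__all__ = [
    "SimulationState",
    "DenseBackend",
    "IterativeBackend",
    "get_backend",
    "BACKENDS",
    "initialize",
    "run",
]

log = logging.getLogger(__name__)


def gate_steady_state(V, K, S, E):
    """Voltage-dependent gate steady state ``1 / (1 + K * exp(S * (E - V)))``."""
    return 1.0 / (1.0 + K * np.exp(S * (E - V)))


def gate_time_constant(V, K, S, E, tau_max):
    """Voltage-dependent gate time constant ``tau_max * z_inf * K * exp(S*(E-V))``."""
    return tau_max * gate_steady_state(V, K, S, E) * K * np.exp(S * (E - V))


@dataclass
class SimulationState:
    V: np.ndarray  # mV
    V_last: np.ndarray  # mV, previous step
    theta: np.ndarray  # mV, firing thresholds
    delta: np.ndarray  # spike states in {0, -1}
    G_spike: np.ndarray  # N x N instantaneous spiking conductances
    buffer: np.ndarray  # D x N spike history, row 0 newest
    gate_b: np.ndarray  # per channel instance
    gate_c: np.ndarray
    step: int = 0

    def copy(self) -> "SimulationState":
        return SimulationState(
            V=self.V.copy(),
            V_last=self.V_last.copy(),
            theta=self.theta.copy(),
            delta=self.delta.copy(),
            G_spike=self.G_spike.copy(),
            buffer=self.buffer.copy(),
            gate_b=self.gate_b.copy(),
            gate_c=self.gate_c.copy(),
            step=self.step,
        )


def initialize(model: CompiledModel) -> SimulationState:
    """Fresh state: voltages at their initial values, thresholds at theta0,
    no spikes, zero spiking conductances, dynamic gates at steady state."""
    V0 = model.V0.copy()
    ch = model.channels
    gb = np.zeros(ch.n)
    gc = np.zeros(ch.n)
    if ch.n:
        v = V0[ch.neuron]
        for g, arr in (("b", gb), ("c", gc)):
            dyn = ch.p[g] > 0
            arr[dyn] = gate_steady_state(
                v[dyn], ch.K[g][dyn], ch.S[g][dyn], ch.E[g][dyn]
            )
    return SimulationState(
        V=V0.copy(),
        V_last=V0.copy(),
        theta=model.theta0.copy(),
        delta=np.zeros(model.N),
        G_spike=np.zeros((model.N, model.N)),
        buffer=np.zeros((model.buffer_depth, model.N)),
        gate_b=gb,
        gate_c=gc,
    )


def _check_finite(model: CompiledModel, V: np.ndarray) -> None:
    if not np.all(np.isfinite(V)):
        bad = int(np.argmax(~np.isfinite(V)))
        raise FloatingPointError(
            f"non-finite membrane potential at neuron {bad} "
            f"(dt={model.dt} ms is likely too large for this network)"
        )


# ---------------------------------------------------------------------------
# Dense backend: each sub-operation is a standalone, testable function.


def apply_inputs(model: CompiledModel, Iext: np.ndarray) -> np.ndarray:
    Iext = np.asarray(Iext, dtype=float).ravel()
    if Iext.size != model.L:
        raise ValueError(f"expected {model.L} external currents, got {Iext.size}")
    if model.L == 0:
        return np.zeros(model.N)
    return model.Cin @ Iext


def update_nonspiking_conductances(model: CompiledModel, V_last: np.ndarray) -> np.ndarray:
    ramp = model.Gmax_non * (V_last[None, :] - model.Elo) / (model.Ehi - model.Elo)
    lo = np.minimum(model.Gmax_non, 0.0)  # Gmax >= 0, so lower bound is 0
    return np.clip(ramp, lo, np.maximum(model.Gmax_non, 0.0))


def decay_and_trigger_spiking_conductances(
    model: CompiledModel, state: SimulationState
) -> np.ndarray:
    G = state.G_spike * (1.0 - model.T_syn)
    delayed = state.buffer[model.delay, np.arange(model.N)[None, :]]
    return np.maximum(G, -delayed * model.Gmax_spike)


def compute_chemical_currents(
    model: CompiledModel, G_non: np.ndarray, G_spike: np.ndarray, V_last: np.ndarray
) -> np.ndarray:
    G = G_non + G_spike
    return (G * model.Esyn).sum(axis=1) - V_last * G.sum(axis=1)


def compute_electrical_currents(model: CompiledModel, V_last: np.ndarray) -> np.ndarray:
    I = model.G_elec @ V_last - V_last * model.G_elec.sum(axis=1)
    if model.G_rec.any():
        # current permitted only from the higher-voltage presynaptic side
        M = (V_last[None, :] > V_last[:, None]).astype(float)
        MG = M * model.G_rec
        MD = MG + MG.T - np.diag(np.diag(MG))
        I += MD @ V_last - V_last * MD.sum(axis=1)
    return I


def compute_ionic_currents(
    model: CompiledModel, V_last: np.ndarray, gate_b: np.ndarray, gate_c: np.ndarray
) -> np.ndarray:
    Iion = np.zeros(model.N)
    ch = model.channels
    if ch.n == 0:
        return Iion
    v = V_last[ch.neuron]
    factor = np.ones(ch.n)
    pa = ch.p["a"]
    has_a = pa > 0
    if has_a.any():
        a = gate_steady_state(v[has_a], ch.K["a"][has_a], ch.S["a"][has_a], ch.E["a"][has_a])
        factor[has_a] *= a ** pa[has_a]
    for g, z in (("b", gate_b), ("c", gate_c)):
        p = ch.p[g]
        dyn = p > 0
        if dyn.any():
            factor[dyn] *= z[dyn] ** p[dyn]
    contrib = ch.Gion * factor * (ch.Eion - v)
    np.add.at(Iion, ch.neuron, contrib)
    return Iion


_clamp_warned = False


def update_gating(
    model: CompiledModel, V_last: np.ndarray, gate_b: np.ndarray, gate_c: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    global _clamp_warned
    ch = model.channels
    out = []
    for g, z in (("b", gate_b), ("c", gate_c)):
        z = z.copy()
        dyn = ch.p[g] > 0
        if dyn.any():
            v = V_last[ch.neuron][dyn]
            K, S, E = ch.K[g][dyn], ch.S[g][dyn], ch.E[g][dyn]
            zinf = gate_steady_state(v, K, S, E)
            tau = gate_time_constant(v, K, S, E, ch.tau_max[g][dyn])
            znew = z[dyn] + model.dt * (zinf - z[dyn]) / tau
            clipped = np.clip(znew, 0.0, 1.0)
            if not _clamp_warned and np.any(clipped != znew):
                log.warning(
                    "gating variable clamped to [0, 1]; dt=%g ms may be too "
                    "large for the gate time constants", model.dt,
                )
                _clamp_warned = True
            z[dyn] = clipped
        out.append(z)
    return out[0], out[1]


def integrate_membrane(
    model: CompiledModel,
    V_last: np.ndarray,
    Isyn_total: np.ndarray,
    Iion: np.ndarray,
    Iapp: np.ndarray,
) -> np.ndarray:
    V = V_last + model.T_m * (
        -model.Gm * (V_last - model.Vrest) + model.Ibias + Isyn_total + Iapp + Iion
    )
    _check_finite(model, V)
    return V


def update_thresholds_and_spikes(
    model: CompiledModel, state: SimulationState, V: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    theta = state.theta.copy()
    spk = model.spiking
    if spk.any():
        theta[spk] = theta[spk] + model.T_theta[spk] * (
            -theta[spk]
            + model.theta0[spk]
            + model.m[spk] * (state.V_last[spk] - model.Vrest[spk])
        )
    delta = np.zeros(model.N)
    delta[spk] = np.where(V[spk] > theta[spk], -1.0, 0.0)
    V = (V - model.Vrest) * (delta + 1.0) + model.Vrest
    return theta, delta, V


def advance_buffer(buffer: np.ndarray, delta: np.ndarray) -> np.ndarray:
    buffer = np.roll(buffer, 1, axis=0)
    buffer[0] = delta
    return buffer


class DenseBackend:
    """Vectorized NumPy backend."""

    name = "dense"

    def __init__(self, model: CompiledModel):
        self.model = model

    def initialize(self) -> SimulationState:
        return initialize(self.model)

    def step(self, state: SimulationState, Iext=None) -> tuple[SimulationState, np.ndarray]:
        model = self.model
        if Iext is None:
            Iext = np.zeros(model.L)
        Iapp = apply_inputs(model, Iext)
        V_last = state.V_last
        G_non = update_nonspiking_conductances(model, V_last)
        G_spike = decay_and_trigger_spiking_conductances(model, state)
        Isyn = compute_chemical_currents(model, G_non, G_spike, V_last)
        Isyn = Isyn + compute_electrical_currents(model, V_last)
        Iion = compute_ionic_currents(model, V_last, state.gate_b, state.gate_c)
        V = integrate_membrane(model, V_last, Isyn, Iion, Iapp)
        gate_b, gate_c = update_gating(model, V_last, state.gate_b, state.gate_c)
        theta, delta, V = update_thresholds_and_spikes(model, state, V)
        buffer = advance_buffer(state.buffer.copy(), delta)
        out = model.Cout_voltage @ V + model.Cout_spike @ delta
        new = SimulationState(
            V=V,
            V_last=V.copy(),
            theta=theta,
            delta=delta,
            G_spike=G_spike,
            buffer=buffer,
            gate_b=gate_b,
            gate_c=gate_c,
            step=state.step + 1,
        )
        return new, out


class IterativeBackend:
    """Element-iterating backend; walks explicit per-neuron / per-synapse
    lists instead of doing matrix algebra.  Slow, but structurally
    independent of the dense backend."""

    name = "iterative"

    def __init__(self, model: CompiledModel):
        self.model = model
        m = model
        self.chem_non = [
            (i, j, m.Gmax_non[i, j], m.Esyn[i, j], m.Elo[i, j], m.Ehi[i, j])
            for i in range(m.N)
            for j in range(m.N)
            if m.Gmax_non[i, j] > 0
        ]
        self.chem_spike = [
            (i, j, m.Gmax_spike[i, j], m.Esyn[i, j], m.T_syn[i, j], int(m.delay[i, j]))
            for i in range(m.N)
            for j in range(m.N)
            if m.Gmax_spike[i, j] > 0
        ]
        self.elec = [
            (i, j, m.G_elec[i, j])
            for i in range(m.N)
            for j in range(m.N)
            if m.G_elec[i, j] > 0
        ]
        self.rec = [
            (i, j, m.G_rec[i, j])
            for i in range(m.N)
            for j in range(m.N)
            if m.G_rec[i, j] > 0
        ]

    def initialize(self) -> SimulationState:
        return initialize(self.model)

    def step(self, state: SimulationState, Iext=None) -> tuple[SimulationState, np.ndarray]:
        m = self.model
        N = m.N
        if Iext is None:
            Iext = np.zeros(m.L)
        Iext = np.asarray(Iext, dtype=float).ravel()
        if Iext.size != m.L:
            raise ValueError(f"expected {m.L} external currents, got {Iext.size}")
        V_last = state.V_last
        Iapp = np.zeros(N)
        for ell in range(m.L):
            for i in range(N):
                if m.Cin[i, ell]:
                    Iapp[i] += Iext[ell]
        Isyn = np.zeros(N)
        # graded chemical synapses
        for i, j, gmax, esyn, elo, ehi in self.chem_non:
            g = gmax * (V_last[j] - elo) / (ehi - elo)
            g = min(max(g, 0.0), gmax)
            Isyn[i] += g * (esyn - V_last[i])
        # spiking chemical synapses: decay then delayed trigger
        G_spike = state.G_spike.copy()
        for i, j, gmax, esyn, tsyn, d in self.chem_spike:
            g = G_spike[i, j] * (1.0 - tsyn)
            if state.buffer[d, j] == -1.0:
                g = max(g, gmax)
            G_spike[i, j] = g
            Isyn[i] += g * (esyn - V_last[i])
        # electrical synapses
        for i, j, g in self.elec:
            Isyn[i] += g * (V_last[j] - V_last[i])
        for i, j, g in self.rec:
            if V_last[j] > V_last[i]:
                Isyn[i] += g * (V_last[j] - V_last[i])
                Isyn[j] += g * (V_last[i] - V_last[j])
        # ionic currents
        ch = m.channels
        Iion = np.zeros(N)
        gate_b = state.gate_b.copy()
        gate_c = state.gate_c.copy()
        for k in range(ch.n):
            i = ch.neuron[k]
            v = V_last[i]
            factor = 1.0
            if ch.p["a"][k] > 0:
                a = gate_steady_state(v, ch.K["a"][k], ch.S["a"][k], ch.E["a"][k])
                factor *= a ** ch.p["a"][k]
            if ch.p["b"][k] > 0:
                factor *= state.gate_b[k] ** ch.p["b"][k]
            if ch.p["c"][k] > 0:
                factor *= state.gate_c[k] ** ch.p["c"][k]
            Iion[i] += ch.Gion[k] * factor * (ch.Eion[k] - v)
        # membrane integration
        V = np.empty(N)
        for i in range(N):
            V[i] = V_last[i] + m.T_m[i] * (
                -m.Gm[i] * (V_last[i] - m.Vrest[i])
                + m.Ibias[i]
                + Isyn[i]
                + Iapp[i]
                + Iion[i]
            )
        _check_finite(m, V)
        # gating update
        for k in range(ch.n):
            i = ch.neuron[k]
            v = V_last[i]
            for g, arr in (("b", gate_b), ("c", gate_c)):
                if ch.p[g][k] > 0:
                    zinf = gate_steady_state(v, ch.K[g][k], ch.S[g][k], ch.E[g][k])
                    tau = gate_time_constant(
                        v, ch.K[g][k], ch.S[g][k], ch.E[g][k], ch.tau_max[g][k]
                    )
                    z = arr[k] + m.dt * (zinf - arr[k]) / tau
                    arr[k] = min(max(z, 0.0), 1.0)
        # thresholds and spikes
        theta = state.theta.copy()
        delta = np.zeros(N)
        for i in range(N):
            if m.spiking[i]:
                theta[i] = theta[i] + m.T_theta[i] * (
                    -theta[i] + m.theta0[i] + m.m[i] * (V_last[i] - m.Vrest[i])
                )
                if V[i] > theta[i]:
                    delta[i] = -1.0
                    V[i] = m.Vrest[i]
        buffer = np.roll(state.buffer, 1, axis=0)
        buffer[0] = delta
        out = np.zeros(m.n_outputs)
        for r in range(m.n_outputs):
            for i in range(N):
                if m.Cout_voltage[r, i]:
                    out[r] += V[i]
                if m.Cout_spike[r, i]:
                    out[r] += delta[i]
        new = SimulationState(
            V=V,
            V_last=V.copy(),
            theta=theta,
            delta=delta,
            G_spike=G_spike,
            buffer=buffer,
            gate_b=gate_b,
            gate_c=gate_c,
            step=state.step + 1,
        )
        return new, out


BACKENDS = {"dense": DenseBackend, "iterative": IterativeBackend}


def get_backend(model: CompiledModel, name: str = "dense"):
    try:
        return BACKENDS[name](model)
    except KeyError:
        raise ValueError(
            f"unknown backend {name!r}; available: {sorted(BACKENDS)}"
        ) from None


def run(
    model: CompiledModel,
    inputs=None,
    n_steps: int | None = None,
    backend: str = "dense",
    record_voltage: bool = False,
):
    """Simulate ``n_steps`` steps and return the output matrix.

    ``inputs`` may be None (no external current), a length-L vector applied
    at every step, or an ``(n_steps, L)`` array.  With ``record_voltage``
    the full membrane-potential trace is returned as a second array.
    """
    series = None
    if inputs is not None:
        inputs = np.asarray(inputs, dtype=float)
        if inputs.ndim == 1:
            const = inputs
        else:
            series = inputs
            const = None
            if n_steps is None:
                n_steps = series.shape[0]
            if series.shape[0] < n_steps:
                raise ValueError(
                    f"input series has {series.shape[0]} rows, need {n_steps}"
                )
            if series.shape[1] != model.L:
                raise ValueError(
                    f"input series has {series.shape[1]} columns, model expects {model.L}"
                )
    else:
        const = np.zeros(model.L)
    if n_steps is None:
        raise ValueError("n_steps is required unless a 2-D input series is given")
    be = get_backend(model, backend)
    state = be.initialize()
    out = np.zeros((n_steps, model.n_outputs))
    volts = np.zeros((n_steps, model.N)) if record_voltage else None
    for t in range(n_steps):
        Iext = series[t] if series is not None else const
        state, out[t] = be.step(state, Iext)
        if record_voltage:
            volts[t] = state.V
    if record_voltage:
        return out, volts
    return out
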