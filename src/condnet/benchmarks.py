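"""Synthetic benchmark network generator and a step-timing harness.

Sparse benchmark networks follow a fixed structural recipe: 8% of neurons
receive external input, 12% are recorded for output, and the number of
synapses equals the number of neurons (distinct ordered pairs, no
self-synapses).  Dense networks connect every ordered pair of distinct
neurons.  Timing numbers are reported, never asserted — they are
hardware-dependent.
"""
from __future__ import annotations

import math
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compiler import compile_network
from .engine import get_backend
from .network import Network
from .types import nonspiking_neuron, nonspiking_synapse, spiking_neuron, spiking_synapse

__all__ = ["BenchmarkSpec", "generate_benchmark", "time_backends"]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class BenchmarkSpec:
    n_neurons: int
    connectivity: str = "sparse"  # or "dense"
    kind: str = "nonspiking"  # or "spiking"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.connectivity not in ("sparse", "dense"):
            raise ValueError("connectivity must be 'sparse' or 'dense'")
        if self.kind not in ("nonspiking", "spiking"):
            raise ValueError("kind must be 'nonspiking' or 'spiking'")


def generate_benchmark(spec: BenchmarkSpec) -> Network:
    """Build a benchmark network, reproducible per seed.

    Neurons are declared as size-1 populations so inputs and outputs can
    target individual neurons.
    """
    rng = np.random.default_rng(spec.seed)
    N = spec.n_neurons
    if spec.kind == "spiking":
        ntype = spiking_neuron("bench_spiking", theta0=1.0, tau_theta=5.0, m=0.0)
        ctype = spiking_synapse("bench_syn", Gmax=0.5, Esyn=5.0, tau_syn=2.0)
    else:
        ntype = nonspiking_neuron("bench_nonspiking")
        ctype = nonspiking_synapse("bench_syn", Gmax=0.5, Esyn=5.0, Elo=0.0, Ehi=1.0)
    net = Network(name=f"benchmark_{spec.connectivity}_{spec.kind}_{N}")
    for k in range(N):
        net.add_population(ntype, 1, f"n{k}")

    if spec.connectivity == "dense":
        pairs = [(j, i) for j in range(N) for i in range(N) if i != j]
    else:
        n_pairs = N * (N - 1)
        n_syn = min(N, n_pairs) if N > 1 else 0
        chosen = rng.choice(n_pairs, size=n_syn, replace=False)
        pairs = []
        for code in np.sort(chosen):
            j, r = divmod(int(code), N - 1)
            i = r if r < j else r + 1  # skip the diagonal
            pairs.append((j, i))
    for j, i in pairs:
        net.add_connection(f"n{j}", f"n{i}", ctype)

    n_in = _round_half_away(0.08 * N)
    n_out = _round_half_away(0.12 * N)
    in_idx = np.sort(rng.choice(N, size=n_in, replace=False))
    out_idx = np.sort(rng.choice(N, size=n_out, replace=False))
    for k in in_idx:
        net.add_input(f"n{k}", width=1)
    for k in out_idx:
        net.add_output(f"n{k}", mode="voltage")
    return net


def time_backends(
    sizes,
    connectivity: str = "sparse",
    kind: str = "nonspiking",
    n_steps: int = 100,
    dt: float = 0.1,
    backends=("dense", "iterative"),
    seed: int = 0,
) -> pd.DataFrame:
    """Measure per-step wall-clock time.  Returns one row per (size, backend)
    with the mean and the 5th/95th percentiles across steps, in ms."""
    rows = []
    for n in sizes:
        spec = BenchmarkSpec(n_neurons=n, connectivity=connectivity, kind=kind, seed=seed)
        net = generate_benchmark(spec)
        model = compile_network(net, dt)
        rng = np.random.default_rng(seed + 1)
        Iext = rng.uniform(0.0, 2.0, size=model.L)
        for name in backends:
            be = get_backend(model, name)
            state = be.initialize()
            times = np.empty(n_steps)
            for t in range(n_steps):
                t0 = time.perf_counter()
                state, _ = be.step(state, Iext)
                times[t] = time.perf_counter() - t0
            times *= 1e3  # ms
            rows.append(
                {
                    "n_neurons": n,
                    "connectivity": connectivity,
                    "kind": kind,
                    "backend": name,
                    "n_steps": n_steps,
                    "mean_ms": float(times.mean()),
                    "p5_ms": float(np.percentile(times, 5)),
                    "p95_ms": float(np.percentile(times, 95)),
                }
            )
    return pd.DataFrame(rows)
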