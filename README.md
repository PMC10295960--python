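# condnet

Design, compile and simulate heterogeneous networks of conductance-based
neurons in discrete time. Supported building blocks:

- **Neurons** — non-spiking leaky integrators; leaky integrate-and-fire
  neurons with an adaptive firing threshold (spike-frequency adaptation or
  facilitation); non-spiking neurons with Hodgkin–Huxley-style voltage-gated
  ion channels (a persistent-sodium preset is included).
- **Connections** — graded (non-spiking) chemical synapses with a linear
  conductance ramp; spiking chemical synapses with exponential decay and
  integer-timestep propagation delays; electrical synapses (gap junctions),
  bidirectional or rectified. Population-level schemes: scaled all-to-all,
  one-to-one, explicit per-parameter matrices, and convolution-style kernel
  patterns between equal-shape 2-D populations.
- **I/O** — external current sources routed by a binary input map; voltage
  and spike output monitors (one record per neuron).

Networks are authored programmatically (or loaded from JSON), compiled into
flat parameter vectors/matrices plus a spike delay buffer, and stepped one
timestep at a time by one of two interchangeable backends: a vectorized
dense NumPy backend and an element-iterating reference backend. The step
schedule unfolds the recurrent network in time — every neuron sees only
previous-step state, so a spike reaches a postsynaptic conductance after a
base latency of one step plus the configured delay.

Units throughout: current nA, voltage mV, conductance µS, capacitance nF,
time ms. Spikes are internally impulses of magnitude −1; files show 0/1.

## Library quick start

```python
import numpy as np
from condnet import (Network, nonspiking_neuron, nonspiking_synapse,
                     compile_network, run)

nt = nonspiking_neuron("cell", Cm=5.0, Gm=1.0, Vrest=0.0)
net = Network("demo")
net.add_population(nt, 1, "a").add_population(nt, 1, "b")
net.add_connection("a", "b", nonspiking_synapse(Gmax=0.5, Esyn=20.0,
                                                Elo=0.0, Ehi=1.0))
net.add_input("a")
net.add_output("b", "voltage")

model = compile_network(net, dt=0.1)          # ms
out = run(model, np.array([1.0]), n_steps=1000)  # (steps, outputs)
```

Backends can also be driven one step at a time for closed-loop use
(`get_backend(model, "dense").step(state, Iext)`).

## Command line

```sh
condnet compile network.json --dt 0.1
condnet run --network network.json --inputs currents.csv --out trace.csv \
            --backend dense
condnet benchmark --sizes 10,100,1000 --connectivity sparse --out report.csv
condnet demo steering --out commands.csv
condnet demo hco --out traces.csv --duration 5000
```

`benchmark` generates synthetic networks (sparse recipe: 8% input neurons,
12% output neurons, synapse count equal to neuron count; dense: all ordered
pairs) and reports mean and 5th/95th-percentile per-step wall-clock times —
reported only, never asserted.

The demos are self-contained re-implementations of two application
networks: a LiDAR steering controller (beam distances → currents → two
heading neurons and an inhibited speed neuron → angular/linear velocity
commands) and a persistent-sodium half-center oscillator that produces
sustained antiphase bursting (~300 ms period at the documented parameters).
A motoneuron-to-muscle-activation sigmoid is available as
`condnet.examples.motoneuron_to_activation`.

## Layout

```
src/condnet/
  types.py       neuron / channel / connection parameter presets
  network.py     author-facing network container and validation
  compiler.py    flattening into parameter matrices, maps, delay geometry
  engine.py      dense and iterative simulation backends
  io.py          JSON network documents, CSV time series
  benchmarks.py  benchmark generator + timing harness
  examples.py    steering, muscle-activation and oscillator examples
  cli.py         click-based command line
tests/           unit, property and acceptance suites
scripts/acceptance.py
```
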