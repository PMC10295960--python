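import numpy as np
import pytest

from condnet.network import Network
from condnet.types import (
    electrical_synapse,
    nonspiking_neuron,
    nonspiking_synapse,
    sodium_channel,
    spiking_neuron,
    spiking_synapse,
    channel_neuron,
)


@pytest.fixture
def ns_type():
    return nonspiking_neuron("ns", Cm=5.0, Gm=1.0, Vrest=0.0)


@pytest.fixture
def spk_type():
    return spiking_neuron("spk", Cm=5.0, Gm=1.0, Vrest=0.0, theta0=1.0, tau_theta=5.0)


@pytest.fixture
def two_neuron_net(ns_type):
    net = Network("two")
    net.add_population(ns_type, 1, "a")
    net.add_population(ns_type, 1, "b")
    return net


def random_network(seed: int, n_neurons: int = 20) -> tuple[Network, np.ndarray]:
    """Random mixed network (size-1 populations) plus a constant input vector.

    Mixes non-spiking, spiking and channel-bearing neurons and all three
    synapse kinds (incl. delays and rectified gap junctions).
    """
    rng = np.random.default_rng(seed)
    nap = sodium_channel("NaP", Gna=0.5, Sm=0.05, Sh=-0.1, tau_h_max=50.0)
    kinds = []
    net = Network(f"random_{seed}")
    for k in range(n_neurons):
        u = rng.random()
        if u < 0.4:
            nt = spiking_neuron(
                f"spk{k}",
                Cm=rng.uniform(1, 10),
                Gm=rng.uniform(0.5, 2),
                Vrest=rng.uniform(-70, 0),
                theta0=rng.uniform(0.5, 5),
                tau_theta=rng.uniform(1, 20),
                m=rng.uniform(-0.5, 1.0),
                Ibias=rng.uniform(0, 1),
            )
        elif u < 0.55:
            nt = channel_neuron(
                f"chan{k}",
                channels=(nap,),
                Cm=rng.uniform(1, 10),
                Gm=rng.uniform(0.5, 2),
                Vrest=-60.0,
            )
        else:
            nt = nonspiking_neuron(
                f"ns{k}",
                Cm=rng.uniform(1, 10),
                Gm=rng.uniform(0.5, 2),
                Vrest=rng.uniform(-70, 0),
                Ibias=rng.uniform(-0.5, 1),
            )
        kinds.append(nt.spiking)
        net.add_population(nt, 1, f"n{k}")
    # chemical synapses on distinct ordered pairs
    n_pairs = n_neurons * (n_neurons - 1)
    chosen = rng.choice(n_pairs, size=min(2 * n_neurons, n_pairs), replace=False)
    for code in chosen:
        j, r = divmod(int(code), n_neurons - 1)
        i = r if r < j else r + 1
        vr = net.population(f"n{j}").neuron_type.Vrest
        if kinds[j]:
            ct = spiking_synapse(
                f"s{code}",
                Gmax=rng.uniform(0.05, 0.5),
                Esyn=rng.uniform(-80, 20),
                tau_syn=rng.uniform(1, 10),
                delay=int(rng.integers(0, 6)),
            )
        else:
            ct = nonspiking_synapse(
                f"c{code}",
                Gmax=rng.uniform(0.05, 0.5),
                Esyn=rng.uniform(-80, 20),
                Elo=vr,
                Ehi=vr + rng.uniform(5, 30),
            )
        net.add_connection(f"n{j}", f"n{i}", ct)
    # a few gap junctions
    for _ in range(max(2, n_neurons // 5)):
        j, i = rng.choice(n_neurons, size=2, replace=False)
        ct = electrical_synapse(
            f"e{j}_{i}",
            Gmax=rng.uniform(0.05, 0.3),
            rectified=bool(rng.random() < 0.5),
        )
        net.add_connection(f"n{j}", f"n{i}", ct)
    n_in = max(1, n_neurons // 4)
    for k in rng.choice(n_neurons, size=n_in, replace=False):
        net.add_input(f"n{k}", width=1)
    for k in range(n_neurons):
        net.add_output(f"n{k}", mode="voltage")
    Iext = rng.uniform(0.0, 3.0, size=n_in)
    return net, Iext
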