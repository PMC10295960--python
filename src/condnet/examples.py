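"""Self-contained application networks.

* A LiDAR-driven steering controller: a ring of sensory neurons maps beam
  distances to currents, two heading neurons integrate the left/right half
  of the array, and a speed neuron is inhibited by all beams.
* A motoneuron-voltage to muscle-activation sigmoid.
* A half-center oscillator built from two persistent-sodium neurons that
  mutually inhibit each other through two interneurons.

No robotics or physics middleware is involved; scans are synthetic.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compiler import compile_network
from .engine import get_backend, run
from .network import Network
from .types import (
    channel_neuron,
    nonspiking_neuron,
    nonspiking_synapse,
    sodium_channel,
)

__all__ = [
    "LidarMap",
    "SteeringParams",
    "MuscleActivationParams",
    "distance_to_current",
    "build_steering_network",
    "command_velocities",
    "corridor_scan",
    "run_steering_demo",
    "motoneuron_to_activation",
    "build_hco_network",
    "run_hco_demo",
    "HCO_GMAX_INHIB",
]


@dataclass(frozen=True)
class LidarMap:
    """Distance-to-current mapping for a planar range scanner."""

    Dmin: float = 0.5  # m
    Dmax: float = 10.0  # m
    n_beams: int = 720  # beams across the scan arc

    def __post_init__(self) -> None:
        if not 0 < self.Dmin < self.Dmax:
            raise ValueError("requires 0 < Dmin < Dmax")


@dataclass(frozen=True)
class SteeringParams:
    Kang: float = 0.1  # (rad/s) per mV
    v_lin_max: float = 0.5  # m/s
    speed_bias: float = 1.0  # nA tonic drive to the speed neuron

    def __post_init__(self) -> None:
        if self.Kang < 0 or self.v_lin_max < 0:
            raise ValueError("gains must be >= 0")


@dataclass(frozen=True)
class MuscleActivationParams:
    s: float = 1.0  # 1/mV sigmoid steepness
    x_offset: float = 0.0  # mV, half-activation motoneuron potential
    y_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("s must be > 0")


def distance_to_current(D, lidar: LidarMap) -> np.ndarray:
    """Map distance (m) to applied current (nA).

    ``I(D) = (1/D - 1/Dmax) / (1/Dmin - 1/Dmax)``: 1 nA at the minimum
    range, 0 nA at the maximum, strictly decreasing in between.  Distances
    outside [Dmin, Dmax] are clamped into range first.
    """
    D = np.asarray(D, dtype=float)
    if np.any(D <= 0):
        raise ValueError("distances must be positive")
    D = np.clip(D, lidar.Dmin, lidar.Dmax)
    return (1.0 / D - 1.0 / lidar.Dmax) / (1.0 / lidar.Dmin - 1.0 / lidar.Dmax)


def build_steering_network(
    lidar: LidarMap, params: SteeringParams | None = None
) -> Network:
    """Sensory array plus three command neurons (CW, CCW, speed).

    Sensory neurons use a unit membrane conductance (1 uS), zero rest and
    zero bias, so each settles at a voltage (mV) numerically equal to its
    applied current (nA): 0 at Dmax and 1 at Dmin.  The left half of the
    array excites the clockwise neuron, the right half the counter-clockwise
    neuron, with one shared conductance; every beam inhibits the speed
    neuron, which carries a tonic bias current.
    """
    params = params or SteeringParams()
    n = lidar.n_beams
    if n % 2:
        raise ValueError("n_beams must be even")
    sensory = nonspiking_neuron("steer_sensory", Cm=5.0, Gm=1.0, Vrest=0.0, Ibias=0.0)
    command = nonspiking_neuron("steer_command", Cm=5.0, Gm=1.0, Vrest=0.0, Ibias=0.0)
    speed = nonspiking_neuron(
        "steer_speed", Cm=5.0, Gm=1.0, Vrest=0.0, Ibias=params.speed_bias
    )
    net = Network(name="steering")
    net.add_population(sensory, n, "sensors")
    net.add_population(command, 1, "cw")
    net.add_population(command, 1, "ccw")
    net.add_population(speed, 1, "speed")
    net.add_input("sensors", width=n)

    g_heading = 0.02  # uS, shared by every sensory->heading synapse
    excite = nonspiking_synapse("steer_excite", Gmax=1.0, Esyn=20.0, Elo=0.0, Ehi=1.0)
    half = n // 2
    left = np.zeros((1, n))
    left[0, :half] = g_heading
    right = np.zeros((1, n))
    right[0, half:] = g_heading
    net.add_connection("sensors", "cw", excite, scheme="matrix", payload={"Gmax": left})
    net.add_connection("sensors", "ccw", excite, scheme="matrix", payload={"Gmax": right})

    inhibit = nonspiking_synapse("steer_inhibit", Gmax=1.0, Esyn=-1.0, Elo=0.0, Ehi=1.0)
    all_g = np.full((1, n), 0.01)
    net.add_connection(
        "sensors", "speed", inhibit, scheme="matrix", payload={"Gmax": all_g}
    )
    net.add_output("cw", "voltage")
    net.add_output("ccw", "voltage")
    net.add_output("speed", "voltage")
    return net


def command_velocities(V_cw, V_ccw, V_speed, params: SteeringParams):
    """Angular velocity ``Kang * (Vcw - Vccw)`` (rad/s) and linear velocity
    ``v_lin_max * Vspeed`` (m/s) from the command-neuron voltages (mV)."""
    v_ang = params.Kang * (np.asarray(V_cw) - np.asarray(V_ccw))
    v_lin = params.v_lin_max * np.asarray(V_speed)
    return v_ang, v_lin


def corridor_scan(
    lidar: LidarMap, left_wall: float, right_wall: float
) -> np.ndarray:
    """Synthetic scan of a straight corridor: the left half of the beams sees
    the left wall, the right half the right wall (distances in m)."""
    half = lidar.n_beams // 2
    scan = np.empty(lidar.n_beams)
    scan[:half] = left_wall
    scan[half:] = right_wall
    return scan


def run_steering_demo(
    scans: np.ndarray,
    lidar: LidarMap | None = None,
    params: SteeringParams | None = None,
    dt: float = 0.1,
    settle_steps: int = 500,
):
    """Feed a sequence of scans through the steering network.

    Each scan row is held for ``settle_steps`` timesteps; the command
    velocities after settling are recorded.  Returns an array with columns
    (v_ang, v_lin, V_cw, V_ccw, V_speed), one row per scan.
    """
    lidar = lidar or LidarMap()
    params = params or SteeringParams()
    net = build_steering_network(lidar, params)
    model = compile_network(net, dt)
    backend = get_backend(model, "dense")
    state = backend.initialize()
    scans = np.atleast_2d(np.asarray(scans, dtype=float))
    rows = np.empty((scans.shape[0], 5))
    for k, scan in enumerate(scans):
        Iext = distance_to_current(scan, lidar)
        for _ in range(settle_steps):
            state, out = backend.step(state, Iext)
        v_cw, v_ccw, v_speed = out
        v_ang, v_lin = command_velocities(v_cw, v_ccw, v_speed, params)
        rows[k] = (v_ang, v_lin, v_cw, v_ccw, v_speed)
    return rows


def motoneuron_to_activation(stim, params: MuscleActivationParams) -> np.ndarray:
    """Sigmoidal mapping from motoneuron potential (mV) to muscle activation,
    ``1 / (1 + exp(s * (x_offset - stim))) + y_offset``, clamped to [0, 1]."""
    stim = np.asarray(stim, dtype=float)
    with np.errstate(over="ignore"):  # exp overflow saturates correctly to 0
        act = 1.0 / (1.0 + np.exp(params.s * (params.x_offset - stim))) + params.y_offset
    return np.clip(act, 0.0, 1.0)


# --------------------------------------------------------------------------
# Half-center oscillator demo

#: mutual-inhibition conductance of the demo oscillator (uS)
HCO_GMAX_INHIB = 0.5

_HCO_REST = -60.0  # mV
_HCO_RANGE = 20.0  # mV operating range of the interneurons


def build_hco_network(g_inhib: float = HCO_GMAX_INHIB) -> Network:
    """Two persistent-sodium half-center neurons that inhibit one another
    through two plain non-spiking interneurons.

    Parameters are tuned (and documented here) for slow, sustained antiphase
    bursting: the sodium channel's instantaneous activation regenerates
    depolarization, its slow inactivation (tau up to 300 ms) terminates each
    burst, and crossed inhibition enforces alternation.  The excitatory
    conductance (0.25 uS against a +100 mV reversal over a 20 mV ramp) keeps
    the interneurons inside their linear range so the loop gain never
    saturates.  The two half-centers start at slightly different voltages to
    break symmetry.  At dt = 0.1 ms this oscillates with ~300 ms period and
    ~37 mV amplitude; with ``g_inhib = 0`` both cells settle to a fixed
    point.
    """
    nap = sodium_channel(
        "NaP",
        Gna=1.5,
        Ena=50.0,
        Km=1.0,
        Sm=0.05,
        Em=-40.0,
        Kh=0.5,
        Sh=-0.1,
        Eh=-60.0,
        tau_h_max=300.0,
    )
    hc = channel_neuron(
        "hco_hc", channels=(nap,), Cm=5.0, Gm=1.0, Vrest=_HCO_REST
    )
    inter = nonspiking_neuron("hco_inter", Cm=5.0, Gm=1.0, Vrest=_HCO_REST)
    excite = nonspiking_synapse(
        "hco_excite",
        Gmax=0.25,
        Esyn=_HCO_REST + 100.0,
        Elo=_HCO_REST,
        Ehi=_HCO_REST + _HCO_RANGE,
    )
    inhibit = nonspiking_synapse(
        "hco_inhibit",
        Gmax=g_inhib,
        Esyn=_HCO_REST - 40.0,
        Elo=_HCO_REST,
        Ehi=_HCO_REST + _HCO_RANGE,
    )
    net = Network(name="half_center_oscillator")
    net.add_population(hc, 1, "hc_l", initial_voltage=[_HCO_REST + 10.0])
    net.add_population(hc, 1, "hc_r", initial_voltage=[_HCO_REST - 10.0])
    net.add_population(inter, 1, "in_l")
    net.add_population(inter, 1, "in_r")
    net.add_connection("hc_l", "in_l", excite)
    net.add_connection("hc_r", "in_r", excite)
    net.add_connection("in_l", "hc_r", inhibit)
    net.add_connection("in_r", "hc_l", inhibit)
    net.add_output("hc_l", "voltage")
    net.add_output("hc_r", "voltage")
    return net


def run_hco_demo(
    duration_ms: float = 5000.0, dt: float = 0.1, g_inhib: float = HCO_GMAX_INHIB
):
    """Simulate the half-center oscillator; returns (time_ms, traces) where
    ``traces`` has one column per half-center voltage (mV)."""
    net = build_hco_network(g_inhib=g_inhib)
    model = compile_network(net, dt)
    n_steps = int(round(duration_ms / dt))
    out = run(model, None, n_steps=n_steps)
    t = np.arange(1, n_steps + 1) * dt
    return t, out
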