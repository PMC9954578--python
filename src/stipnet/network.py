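"""Clock-driven simulation of fully connected feedforward LIF networks.

Each neuron integrates a single membrane state V with exponential leak.
Per time step (duration dt): the membrane decays by exp(−dt/τ), weighted
presynaptic spikes of the current step are added (delta synapses, no
synaptic filter state), and if V reaches the threshold the neuron emits a
spike at the step's grid time and V is hard-reset.  There is no refractory
period and no bias current.  Layers are evaluated front to back; a spike
travels one layer per step with zero conduction delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .spiketrains import SpikeTrainSet, ValidationError, _n_steps

__all__ = ["LIFParams", "NetworkConfig", "init_weights", "lif_forward",
           "lif_forward_counts"]


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire neuron constants.

    Defaults follow the reference parameterisation: membrane time constant
    τ = 5 ms, firing threshold 5.0, reset potential 0.0, simulated on a
    dt = 1 ms grid.
    """

    tau: float = 5.0
    threshold: float = 5.0
    reset: float = 0.0
    dt: float = 1.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValidationError(f"tau must be positive, got {self.tau}")
        if self.threshold <= self.reset:
            raise ValidationError("threshold must exceed the reset potential")
        if self.dt <= 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")

    @property
    def decay(self) -> float:
        """Per-step membrane decay factor exp(−dt/τ)."""
        return float(np.exp(-self.dt / self.tau))


@dataclass
class NetworkConfig:
    """Layer sizes H_0..H_L, weight matrices W_l (H_l × H_{l−1}), and the
    shared LIF parameters.  Layer 0 is the input layer; layer L the output."""

    layer_sizes: tuple
    weights: list
    lif: LIFParams = field(default_factory=LIFParams)

    def __post_init__(self):
        sizes = tuple(int(s) for s in self.layer_sizes)
        if len(sizes) < 3:
            raise ValidationError("need at least one hidden layer "
                                  "(three layers including input and output)")
        if len(self.weights) != len(sizes) - 1:
            raise ValidationError(
                f"expected {len(sizes) - 1} weight matrices, got {len(self.weights)}")
        for l, w in enumerate(self.weights, start=1):
            w = np.asarray(w, dtype=float)
            if w.shape != (sizes[l], sizes[l - 1]):
                raise ValidationError(
                    f"W_{l} has shape {w.shape}, expected {(sizes[l], sizes[l - 1])}")
            self.weights[l - 1] = w
        self.layer_sizes = sizes

    @property
    def n_layers(self) -> int:
        """Number of weighted layers L (hidden layers plus output)."""
        return len(self.weights)

    def copy(self) -> "NetworkConfig":
        return NetworkConfig(self.layer_sizes, [w.copy() for w in self.weights],
                             self.lif)


def init_weights(layer_sizes: Sequence[int], seed: int, scale: float = 1.0,
                 lif: LIFParams | None = None) -> NetworkConfig:
    """Draw every synaptic weight i.i.d. from N(0, scale²).

    The reference setting is scale = 1.0 (standard normal initialisation).
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    sizes = tuple(int(s) for s in layer_sizes)
    weights = [scale * rng.standard_normal((sizes[l], sizes[l - 1]))
               for l in range(1, len(sizes))]
    return NetworkConfig(sizes, weights, lif or LIFParams())


def lif_forward_counts(x0: np.ndarray, net: NetworkConfig,
                       record_potentials: bool = False):
    """Simulate the network on spike-count input, batched.

    Parameters
    ----------
    x0:
        Input spike counts, shape (..., H_0, n_steps); leading batch
        dimensions are simulated in parallel.
    net:
        Network configuration.
    record_potentials:
        Also return the membrane potential of every neuron at every step,
        sampled after integration and before the reset.

    Returns
    -------
    list of arrays, one per layer 1..L, each of shape (..., H_l, n_steps)
    with 0/1 spike indicators; if ``record_potentials``, a second list of
    equally shaped potential traces as well.
    """
    lif = net.lif
    decay = lif.decay
    n_steps = x0.shape[-1]
    pre = np.asarray(x0, dtype=float)
    out: list[np.ndarray] = []
    traces: list[np.ndarray] = []
    for w in net.weights:
        drive = np.einsum("ij,...jk->...ik", w, pre, optimize=True)
        spikes = np.zeros(drive.shape)
        vtrace = np.zeros(drive.shape) if record_potentials else None
        v = np.full(drive.shape[:-1], lif.reset, dtype=float)
        for k in range(n_steps):
            v = v * decay + drive[..., k]
            if record_potentials:
                vtrace[..., k] = v
            fired = v >= lif.threshold
            spikes[..., k] = fired
            v = np.where(fired, lif.reset, v)
        out.append(spikes)
        if record_potentials:
            traces.append(vtrace)
        pre = spikes
    return (out, traces) if record_potentials else out


def lif_forward(inputs: SpikeTrainSet, net: NetworkConfig) -> list[SpikeTrainSet]:
    """Map input spike trains to the spike trains of every layer 1..L.

    Input spikes must lie on the dt grid (clock-driven simulation).  The
    hidden-layer trains are returned as well because the learning rules
    consume presynaptic activity at every depth.
    """
    if inputs.layer_size != net.layer_sizes[0]:
        raise ValidationError(
            f"input has {inputs.layer_size} neurons, network expects "
            f"{net.layer_sizes[0]}")
    dt = net.lif.dt
    _n_steps(inputs.interval_end, dt)  # validates divisibility
    x0 = inputs.to_counts(dt)          # validates grid alignment
    layer_counts = lif_forward_counts(x0, net)
    return [SpikeTrainSet.from_counts(c, dt, inputs.interval_end)
            for c in layer_counts]
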