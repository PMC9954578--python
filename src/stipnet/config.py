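"""Run configuration: one flat document resolving every knob of a run.

Defaults reproduce the reference parameterisation (learning rate 8e−5,
batch 64, 150 epochs, τ = 5 ms, threshold 5.0, reset 0.0, a 10 ms interval
on a 1 ms grid, N(0, 1) weight and feedback initialisation, gaussian
kernel σ = 40 ms).  A config can be serialised to YAML next to a run's
outputs and reloaded to reproduce it exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .kernels import DEFAULT_KERNEL_PARAMS, KernelSpec
from .learning import FeedbackConfig, TrainConfig
from .network import LIFParams, NetworkConfig, init_weights
from .spiketrains import ValidationError

__all__ = ["RunConfig", "KERNEL_ALIASES"]

#: Short CLI aliases for kernel family names.
KERNEL_ALIASES = {
    "gaussian": "gaussian",
    "laplacian": "laplacian",
    "invmq": "inverse_multiquadratic",
    "inverse_multiquadratic": "inverse_multiquadratic",
    "alpha": "alpha",
}


@dataclass
class RunConfig:
    """Flat, serialisable description of a training run."""

    mode: str = "FA"
    kernel_family: str = "gaussian"
    kernel_param: float | None = None       # None → family default
    imq_form: str = "sqrt"
    input_dim: int = 784
    hidden_sizes: tuple = (800, 800)
    n_classes: int = 10
    learning_rate: float = 8e-5
    batch_size: int = 64
    epochs: int = 150
    tau: float = 5.0
    threshold: float = 5.0
    reset: float = 0.0
    dt: float = 1.0
    interval_end: float = 10.0
    weight_scale: float = 1.0
    frozen_encoding: bool = False
    data: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        self.mode = self.mode.upper()
        self.kernel_family = KERNEL_ALIASES.get(self.kernel_family,
                                                self.kernel_family)
        if self.kernel_param is None:
            self.kernel_param = DEFAULT_KERNEL_PARAMS.get(self.kernel_family)
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if not self.hidden_sizes:
            raise ValidationError("at least one hidden layer is required")

    # -- resolved objects ---------------------------------------------------

    @property
    def layer_sizes(self) -> tuple:
        return (self.input_dim, *self.hidden_sizes, self.n_classes)

    def kernel_spec(self) -> KernelSpec:
        return KernelSpec(self.kernel_family, self.kernel_param, self.imq_form)

    def lif_params(self) -> LIFParams:
        return LIFParams(self.tau, self.threshold, self.reset, self.dt)

    def build_network(self) -> NetworkConfig:
        return init_weights(self.layer_sizes, seed=self.seed,
                            scale=self.weight_scale, lif=self.lif_params())

    def build_feedback(self) -> FeedbackConfig:
        # distinct stream from the weight init, still derived from the seed
        return FeedbackConfig.create(self.mode, self.layer_sizes,
                                     seed=self.seed + 1)

    def train_config(self) -> TrainConfig:
        return TrainConfig(learning_rate=self.learning_rate,
                           batch_size=self.batch_size, epochs=self.epochs,
                           kernel=self.kernel_spec(),
                           interval_end=self.interval_end, seed=self.seed,
                           frozen_encoding=self.frozen_encoding)

    # -- serialisation ------------------------------------------------------

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["hidden_sizes"] = tuple(d["hidden_sizes"])
        return RunConfig(**d)
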