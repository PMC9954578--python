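"""Self-contained synthetic classification tasks.

Each class gets a fixed binary intensity prototype: a random subset of
input components at a high "on" intensity, the rest at a low "off"
intensity — the same statistical shape (normalised intensities in [0, 1],
sparse informative components) that a normalised pixel vector feeds into
the Poisson encoder, without any external data.  Samples are the class
prototype with independent component flips at a small noise rate, and
splits are class-balanced.  Prototypes are guaranteed pairwise distinct
with a minimum Hamming separation so the task is learnable by design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .encoding import IntensityVector, LabelCode
from .spiketrains import SpikeTrain, SpikeTrainSet, ValidationError

__all__ = ["SyntheticTaskSpec", "make_task", "worked_example_fixture",
           "WorkedExample", "save_task", "load_task"]


@dataclass(frozen=True)
class SyntheticTaskSpec:
    """Parameters of the prototype-plus-flip-noise task.

    Defaults give a 3-class, 20-input task (300 train / 90 test samples)
    sized so that a full training run takes seconds on one CPU: half the
    components are "on" per prototype at intensity 0.8, the rest at 0.05,
    and each sample flips each component with probability 0.05.
    """

    n_classes: int = 3
    input_dim: int = 20
    prototype_on_fraction: float = 0.5
    on_intensity: float = 0.8
    off_intensity: float = 0.05
    flip_noise: float = 0.05
    n_train: int = 300
    n_test: int = 90
    seed: int = 0
    min_hamming_fraction: float = 0.25

    def __post_init__(self):
        for name in ("prototype_on_fraction", "on_intensity", "off_intensity",
                     "flip_noise", "min_hamming_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_classes < 2 or self.input_dim < 1:
            raise ValidationError("need at least 2 classes and 1 input")
        if self.n_train % self.n_classes or self.n_test % self.n_classes:
            raise ValidationError(
                "n_train and n_test must be multiples of n_classes "
                "(balanced splits)")


def _draw_prototypes(spec: SyntheticTaskSpec, rng: np.random.Generator
                     ) -> np.ndarray:
    """Binary on/off masks per class with enforced Hamming separation."""
    n_on = max(1, int(round(spec.prototype_on_fraction * spec.input_dim)))
    min_dist = int(np.ceil(spec.min_hamming_fraction * spec.input_dim))
    for attempt in range(200):
        masks = np.zeros((spec.n_classes, spec.input_dim), dtype=bool)
        for c in range(spec.n_classes):
            masks[c, rng.choice(spec.input_dim, size=n_on, replace=False)] = True
        dists = [(masks[i] != masks[j]).sum()
                 for i in range(spec.n_classes)
                 for j in range(i + 1, spec.n_classes)]
        if min(dists) >= min_dist:
            return masks
    raise ValidationError(
        f"could not draw {spec.n_classes} prototypes with pairwise Hamming "
        f"distance >= {min_dist} over {spec.input_dim} components after 200 "
        f"attempts; loosen the spec")


def _sample_split(masks: np.ndarray, spec: SyntheticTaskSpec, n: int,
                  rng: np.random.Generator):
    per_class = n // spec.n_classes
    pairs = []
    for c in range(spec.n_classes):
        flips = rng.random((per_class, spec.input_dim)) < spec.flip_noise
        on = masks[c][None, :] ^ flips
        values = np.where(on, spec.on_intensity, spec.off_intensity)
        for row in values:
            pairs.append((IntensityVector(row), LabelCode(c, spec.n_classes)))
    return pairs


def make_task(spec: SyntheticTaskSpec = SyntheticTaskSpec()):
    """Generate (train split, test split) of (IntensityVector, LabelCode)
    pairs; balanced classes, deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    masks = _draw_prototypes(spec, rng)
    train = _sample_split(masks, spec, spec.n_train, rng)
    test = _sample_split(masks, spec, spec.n_test, rng)
    return train, test


# ---------------------------------------------------------------------------
# On-disk fixture format: plain TSV, label followed by the intensities.

def save_task(path, pairs) -> None:
    with open(path, "w") as fh:
        for x, y in pairs:
            vals = "\t".join(f"{v:.6g}" for v in x.values)
            fh.write(f"{y.label}\t{y.n_classes}\t{vals}\n")


def load_task(path):
    pairs = []
    with open(path) as fh:
        for line in fh:
            parts = line.split("\t")
            label, n_classes = int(parts[0]), int(parts[1])
            values = np.array([float(v) for v in parts[2:]])
            pairs.append((IntensityVector(values), LabelCode(label, n_classes)))
    return pairs


# ---------------------------------------------------------------------------
# Worked example: a 3-4-2 network instance small enough to check by hand.

@dataclass(frozen=True)
class WorkedExample:
    """Fixed spike trains, weights and feedback matrices for a 3-4-2 net,
    with golden Gram and update matrices.

    The golden values were produced by an explicit double loop over spike
    pairs (pure-Python, independent of the vectorised implementation) with
    the gaussian kernel, σ = 40 ms, η = 0.1, and are committed alongside
    the package.  FA feedback uses an independent fixed B chain; the BP/FA
    coincidence case (B = W) is exercised separately in the tests.
    """

    interval_end: float
    kernel_sigma: float
    eta: float
    inputs: SpikeTrainSet            # s_0, 3 neurons
    hidden: SpikeTrainSet            # s_1, 4 neurons
    actual: SpikeTrainSet            # s_oa, 2 neurons
    desired: SpikeTrainSet           # s_od, 2 neurons
    w1: np.ndarray                   # 4 × 3
    w2: np.ndarray                   # 2 × 4
    b1: np.ndarray                   # FA feedback, 4 × 3
    b2: np.ndarray                   # FA feedback, 2 × 4
    ba1: np.ndarray                  # BA broadcast matrix B′_1, 2 × 4
    golden: dict                     # name → matrix (lists of lists)


def worked_example_fixture() -> WorkedExample:
    """Load the committed hand-checkable 3-4-2 instance."""
    text = resources.files("stipnet.data").joinpath(
        "worked_example.json").read_text()
    d = json.loads(text)
    T = d["interval_end"]
    mk = lambda key: SpikeTrainSet(
        [SpikeTrain(ts, T) for ts in d[key]])
    arr = lambda key: np.asarray(d[key], dtype=float)
    return WorkedExample(
        interval_end=T,
        kernel_sigma=d["kernel_sigma"],
        eta=d["eta"],
        inputs=mk("inputs"),
        hidden=mk("hidden"),
        actual=mk("actual"),
        desired=mk("desired"),
        w1=arr("w1"), w2=arr("w2"),
        b1=arr("b1"), b2=arr("b2"), ba1=arr("ba1"),
        golden={k: np.asarray(v, dtype=float)
                for k, v in d["golden"].items()},
    )
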