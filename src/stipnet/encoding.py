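"""Encoders and decoder: intensities → spike trains, labels → target
trains, output trains → class predictions.

Input encoding is clock-driven Poisson (rate) coding: at every grid step a
component of intensity x ∈ [0, 1] emits a spike with independent Bernoulli
probability x, so x is the per-step firing probability and x = 1 means one
spike per step.  Targets use linear one-hot extension: the labelled class's
output neuron fires at every step of the interval while all other output
neurons stay silent.  Decoding is nearest-template in RKHS distance, with
softmax(−distance) reported as a class-score vector (softmax-like scoring:
the argmax of the scores and the argmin of the distances coincide).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kernels import KernelSpec, rkhs_error
from .spiketrains import SpikeTrain, SpikeTrainSet, ValidationError, _n_steps

__all__ = ["IntensityVector", "LabelCode", "poisson_encode", "encode_label",
           "classify", "poisson_encode_counts", "label_counts",
           "label_templates"]


@dataclass(frozen=True)
class IntensityVector:
    """Normalised input intensities, one value in [0, 1] per input neuron."""

    values: np.ndarray

    def __init__(self, values):
        v = np.asarray(values, dtype=float).ravel()
        if v.size == 0:
            raise ValidationError("intensity vector must be non-empty")
        if np.any(v < 0) or np.any(v > 1):
            raise ValidationError("intensities must lie in [0, 1]")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def length(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class LabelCode:
    """Integer class label with its number of classes."""

    label: int
    n_classes: int

    def __post_init__(self):
        if not 0 <= self.label < self.n_classes:
            raise ValidationError(
                f"label {self.label} outside [0, {self.n_classes})")


def poisson_encode_counts(values: np.ndarray, n_steps: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Bernoulli-per-step spike counts, shape values.shape + (n_steps,)."""
    v = np.asarray(values, dtype=float)
    return (rng.random(v.shape + (n_steps,)) < v[..., None]).astype(float)


def poisson_encode(x: IntensityVector, interval_end: float, dt: float,
                   seed: int) -> SpikeTrainSet:
    """Poisson (Bernoulli-per-step) encoding of an intensity vector.

    Component i spikes at grid time k·dt with probability values[i],
    independently across components and steps.  Deterministic given seed.
    """
    n_steps = _n_steps(interval_end, dt)
    rng = np.random.default_rng(seed)
    counts = poisson_encode_counts(x.values, n_steps, rng)
    return SpikeTrainSet.from_counts(counts, dt, interval_end)


def label_counts(labels: np.ndarray, n_classes: int, n_steps: int) -> np.ndarray:
    """One-hot target spike counts, shape labels.shape + (n_classes, n_steps)."""
    labels = np.asarray(labels, dtype=int)
    out = np.zeros(labels.shape + (n_classes, n_steps))
    idx = np.indices(labels.shape)
    out[(*idx, labels, slice(None))] = 1.0
    return out


def encode_label(y: LabelCode, interval_end: float, dt: float,
                 spikes_per_step: int = 1) -> SpikeTrainSet:
    """Target spike trains for a label: the class neuron fires evenly
    (every grid step), every other output neuron stays silent.

    ``spikes_per_step`` thins the target train: 1 keeps every step, k keeps
    every k-th step.  The default is the densest even activation.
    """
    n_steps = _n_steps(interval_end, dt)
    step_idx = np.arange(0, n_steps, spikes_per_step)
    trains = []
    for i in range(y.n_classes):
        if i == y.label:
            trains.append(SpikeTrain(step_idx * dt, interval_end))
        else:
            trains.append(SpikeTrain([], interval_end))
    return SpikeTrainSet(trains)


def label_templates(n_classes: int, interval_end: float, dt: float
                    ) -> list[SpikeTrainSet]:
    """Target train sets for every class, in class order."""
    return [encode_label(LabelCode(c, n_classes), interval_end, dt)
            for c in range(n_classes)]


def classify(output: SpikeTrainSet, templates: Sequence[SpikeTrainSet],
             spec: KernelSpec) -> tuple[int, np.ndarray]:
    """Nearest-template decoding in RKHS distance.

    Computes d_c = rkhs_error(output, template_c) for every class and
    predicts argmin d_c (ties broken towards the lowest class index).
    Returns the prediction together with softmax(−d) as a score vector
    that sums to one.
    """
    d = np.empty(len(templates))
    for c, tmpl in enumerate(templates):
        if tmpl.layer_size != output.layer_size:
            raise ValidationError(
                f"template {c} has {tmpl.layer_size} neurons, output has "
                f"{output.layer_size}")
        d[c] = rkhs_error(output, tmpl, spec)
    pred = int(np.argmin(d))  # np.argmin returns the first minimum: low-index tie rule
    z = -d + d.min()
    scores = np.exp(z)
    scores /= scores.sum()
    return pred, scores
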