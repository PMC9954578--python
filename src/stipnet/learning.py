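"""STIP-based weight updates (BP / FA / BA) and the mini-batch trainer.

All three learning rules share one building block: the error Gram matrix

    G_l = F(s_oa, s_{l−1}) − F(s_od, s_{l−1}),

the difference between the STIP Gram matrices of the actual and the desired
output trains against the presynaptic trains of layer l.  The rules differ
only in the pathway matrix that carries the output error down to layer l:

* BP  (error backpropagation):   ΔW_l = −η (W_L ⋯ W_{l+1})ᵀ G_l — the
  transposed forward weights, as in classical backprop.  Exact gradient of
  the RKHS error under the linear spike-train relation h_l = W_l h_{l−1}.
* FA  (feedback alignment):      ΔW_l = −η (B_L ⋯ B_{l+1})ᵀ G_l — fixed
  random matrices B_l, shaped like W_l, propagated layer by layer.  Avoids
  the weight-transport problem.
* BA  (broadcast alignment, a.k.a. direct feedback alignment):
  ΔW_l = −η (B′_l)ᵀ G_l — one fixed random matrix B′_l (H_L × H_l) per
  hidden layer; the output error is broadcast directly, a local
  three-factor rule.

For the output layer all three modes use ΔW_L = −η G_L.  Feedback matrices
are drawn once from N(0, 1) and never updated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .encoding import label_counts, poisson_encode_counts
from .kernels import (KernelSpec, grid_kernel_matrix, stip_matrix)
from .network import NetworkConfig, lif_forward_counts
from .spiketrains import SpikeTrainSet, ValidationError, _n_steps

__all__ = ["FeedbackConfig", "TrainConfig", "TrainRecord",
           "TrainingDiverged", "output_delta", "bp_hidden_delta",
           "fa_hidden_delta", "ba_hidden_delta", "output_delta_from_grams",
           "hidden_delta_from_grams", "backward_pathway", "train",
           "evaluate_counts"]

MODES = ("BP", "FA", "BA")


class TrainingDiverged(RuntimeError):
    """Weights became non-finite or exceeded the norm guard."""

    def __init__(self, epoch: int, layer: int, detail: str):
        self.epoch, self.layer = epoch, layer
        super().__init__(
            f"training diverged at epoch {epoch}, layer {layer}: {detail}")


@dataclass(frozen=True)
class FeedbackConfig:
    """Error-feedback mode plus its fixed random matrices.

    ``fa_matrices[l-1]`` is B_l with the shape of W_l (used by FA for
    l = 2..L); ``ba_matrices[l-1]`` is B′_l of shape (H_L, H_l) for the
    hidden layers l = 1..L−1 (used by BA).  Matrices are created once,
    marked read-only, and never updated during training.
    """

    mode: str
    fa_matrices: tuple = ()
    ba_matrices: tuple = ()
    seed: int | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        for m in (*self.fa_matrices, *self.ba_matrices):
            m.setflags(write=False)

    @staticmethod
    def create(mode: str, layer_sizes: Sequence[int], seed: int = 0
               ) -> "FeedbackConfig":
        """Draw N(0, 1) feedback matrices matching a network's layer sizes."""
        sizes = tuple(int(s) for s in layer_sizes)
        L = len(sizes) - 1
        rng = np.random.default_rng(seed)
        fa = ()
        ba = ()
        if mode == "FA":
            fa = tuple(rng.standard_normal((sizes[l], sizes[l - 1]))
                       for l in range(1, L + 1))
        elif mode == "BA":
            ba = tuple(rng.standard_normal((sizes[L], sizes[l]))
                       for l in range(1, L))
        return FeedbackConfig(mode, fa, ba, seed)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters.

    Defaults are the reference full-scale settings: learning rate 8e−5,
    batch size 64, 150 epochs, gaussian kernel with σ = 40 ms, a 10 ms
    simulation interval.  ``frozen_encoding`` disables the per-presentation
    Poisson re-draw (every epoch then sees identical input trains), which
    makes small deterministic experiments possible.
    """

    learning_rate: float = 8e-5
    batch_size: int = 64
    epochs: int = 150
    kernel: KernelSpec = field(default_factory=lambda: KernelSpec.default("gaussian"))
    interval_end: float = 10.0
    seed: int = 0
    frozen_encoding: bool = False
    weight_guard: float | None = 1e8

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValidationError("learning rate must be positive")
        if self.batch_size < 1:
            raise ValidationError("batch size must be at least 1")
        if self.epochs < 0:
            raise ValidationError("epochs must be non-negative")


@dataclass
class TrainRecord:
    """Per-epoch loss and accuracy traces."""

    train_loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    test_acc: list = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def rows(self):
        """(epoch, train_loss, train_acc, test_acc) tuples, 1-based epochs."""
        for e in range(self.n_epochs):
            yield (e + 1, self.train_loss[e], self.train_acc[e],
                   self.test_acc[e])

    def to_table(self) -> str:
        """Plain tab-separated metrics table, one row per epoch."""
        lines = ["epoch\ttrain_loss\ttrain_acc\ttest_acc"]
        for e, loss, tra, tea in self.rows():
            lines.append(f"{e}\t{loss:.6f}\t{tra:.6f}\t{tea:.6f}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Update rules: Gram-level cores ...

def output_delta_from_grams(gram_actual: np.ndarray, gram_desired: np.ndarray,
                            eta: float) -> np.ndarray:
    """ΔW_L = −η [F(s_oa, s_{L−1}) − F(s_od, s_{L−1})] from Gram matrices."""
    return -eta * (gram_actual - gram_desired)


def hidden_delta_from_grams(pathway: np.ndarray, gram_actual: np.ndarray,
                            gram_desired: np.ndarray, eta: float) -> np.ndarray:
    """ΔW_l = −η · pathwayᵀ · [F(s_oa, s_{l−1}) − F(s_od, s_{l−1})].

    ``pathway`` is the un-transposed product carrying the output error to
    layer l: (W_L ⋯ W_{l+1}) for BP, (B_L ⋯ B_{l+1}) for FA, B′_l for BA.
    """
    return -eta * (pathway.T @ (gram_actual - gram_desired))


def backward_pathway(matrices: Sequence[np.ndarray], l: int) -> np.ndarray:
    """Product M_L ⋯ M_{l+2} M_{l+1} for the layer-wise feedback modes.

    ``matrices`` is the full chain (M_1 .. M_L, index 0 holding M_1);
    the factors above layer l are accumulated right-to-left.
    """
    L = len(matrices)
    if not 1 <= l <= L - 1:
        raise ValidationError(f"hidden layer index l={l} outside [1, {L - 1}]")
    acc = matrices[l]  # M_{l+1}
    for m in matrices[l + 1:]:
        acc = m @ acc
    return acc


# ... and spike-train wrappers.

def _error_grams(actual: SpikeTrainSet, desired: SpikeTrainSet,
                 prev_layer: SpikeTrainSet, spec: KernelSpec):
    if actual.layer_size != desired.layer_size:
        raise ValidationError("actual and desired output sizes differ")
    return (stip_matrix(actual, prev_layer, spec),
            stip_matrix(desired, prev_layer, spec))


def output_delta(actual: SpikeTrainSet, desired: SpikeTrainSet,
                 last_hidden: SpikeTrainSet, spec: KernelSpec,
                 eta: float) -> np.ndarray:
    """Output-layer update ΔW_L (shape H_L × H_{L−1}); same for all modes."""
    ga, gd = _error_grams(actual, desired, last_hidden, spec)
    return output_delta_from_grams(ga, gd, eta)


def bp_hidden_delta(l: int, actual: SpikeTrainSet, desired: SpikeTrainSet,
                    prev_layer: SpikeTrainSet, weights: Sequence[np.ndarray],
                    spec: KernelSpec, eta: float) -> np.ndarray:
    """Backprop update for hidden layer l (1 ≤ l ≤ L−1)."""
    ga, gd = _error_grams(actual, desired, prev_layer, spec)
    return hidden_delta_from_grams(backward_pathway(weights, l), ga, gd, eta)


def fa_hidden_delta(l: int, actual: SpikeTrainSet, desired: SpikeTrainSet,
                    prev_layer: SpikeTrainSet, feedback: FeedbackConfig,
                    spec: KernelSpec, eta: float) -> np.ndarray:
    """Feedback-alignment update: BP with W replaced by the fixed B chain."""
    if feedback.mode != "FA":
        raise ValidationError(f"feedback mode is {feedback.mode}, expected FA")
    ga, gd = _error_grams(actual, desired, prev_layer, spec)
    return hidden_delta_from_grams(backward_pathway(feedback.fa_matrices, l),
                                   ga, gd, eta)


def ba_hidden_delta(l: int, actual: SpikeTrainSet, desired: SpikeTrainSet,
                    prev_layer: SpikeTrainSet, feedback: FeedbackConfig,
                    spec: KernelSpec, eta: float) -> np.ndarray:
    """Broadcast-alignment update: output error through one fixed B′_l.

    Local: depends on no weight matrix and on no layer other than the
    output error and the presynaptic trains of layer l.
    """
    if feedback.mode != "BA":
        raise ValidationError(f"feedback mode is {feedback.mode}, expected BA")
    if not 1 <= l <= len(feedback.ba_matrices):
        raise ValidationError(f"no broadcast matrix for layer {l}")
    ga, gd = _error_grams(actual, desired, prev_layer, spec)
    return hidden_delta_from_grams(feedback.ba_matrices[l - 1], ga, gd, eta)


# ---------------------------------------------------------------------------
# Training loop.

def _as_arrays(dataset):
    """(IntensityVector, LabelCode) pairs → (X float array, y int array)."""
    xs, ys = [], []
    n_classes = None
    for x, y in dataset:
        xs.append(np.asarray(x.values if hasattr(x, "values") else x, dtype=float))
        ys.append(int(y.label if hasattr(y, "label") else y))
        if hasattr(y, "n_classes"):
            n_classes = y.n_classes
    if not xs:
        raise ValidationError("dataset is empty")
    X = np.stack(xs)
    y = np.asarray(ys)
    return X, y, n_classes or int(y.max()) + 1


def evaluate_counts(out_counts: np.ndarray, labels: np.ndarray,
                    kgrid: np.ndarray) -> tuple[float, float]:
    """(mean RKHS loss, accuracy) of batched output spike counts.

    Nearest-template decoding against the even one-hot target trains; the
    predicted class is the argmin of the RKHS distances (first index on
    ties), exactly as in :func:`stipnet.encoding.classify`.
    """
    n, c, s = out_counts.shape
    target = label_counts(labels, c, s)
    self_aa = np.einsum("bis,st,bit->b", out_counts, kgrid, out_counts,
                        optimize=True)
    cross = np.einsum("bis,st,bit->b", out_counts, kgrid, target,
                      optimize=True)
    self_dd = np.einsum("bis,st,bit->b", target, kgrid, target, optimize=True)
    loss = float(np.mean(0.5 * (self_aa - 2.0 * cross + self_dd)))
    # distance to template c differs across c only through the cross term
    # −F(out_c, template-train); template self-terms are class-independent.
    cross_all = np.einsum("bcs,st,t->bc", out_counts, kgrid,
                          np.ones(s), optimize=True)
    pred = np.argmax(cross_all, axis=1)
    acc = float(np.mean(pred == labels))
    return loss, acc


def train(dataset, net: NetworkConfig, feedback: FeedbackConfig,
          cfg: TrainConfig, test_dataset=None
          ) -> tuple[NetworkConfig, TrainRecord]:
    """Mini-batch training of a LIF network under the configured rule.

    Per batch: inputs are Poisson-encoded (a fresh draw per presentation
    unless ``cfg.frozen_encoding``), the network is simulated, per-sample
    updates for every layer are computed from the same pre-update weights,
    averaged over the batch, and applied simultaneously.  After each epoch
    the record gains the mean RKHS loss and accuracy on the training split
    and the accuracy on the test split, both measured with a fixed
    evaluation encoding so that epochs are comparable.  Fully reproducible
    given ``cfg.seed``.
    """
    X, y, n_classes = _as_arrays(dataset)
    net = net.copy()
    L = net.n_layers
    if n_classes != net.layer_sizes[-1]:
        raise ValidationError(
            f"dataset has {n_classes} classes but the network outputs "
            f"{net.layer_sizes[-1]}")
    lif = net.lif
    n_steps = _n_steps(cfg.interval_end, lif.dt)
    kgrid = grid_kernel_matrix(cfg.kernel, lif.dt, n_steps)
    eta = cfg.learning_rate

    ss = np.random.SeedSequence(cfg.seed)
    shuffle_rng, enc_rng, eval_rng = (np.random.default_rng(s)
                                      for s in ss.spawn(3))

    # fixed evaluation encodings: one Poisson draw reused at every epoch
    X_eval = poisson_encode_counts(X, n_steps, eval_rng)
    if test_dataset is not None:
        Xt, yt, _ = _as_arrays(test_dataset)
        Xt_eval = poisson_encode_counts(Xt, n_steps, eval_rng)
    if cfg.frozen_encoding:
        X_frozen = poisson_encode_counts(X, n_steps, enc_rng)

    record = TrainRecord()
    n = X.shape[0]
    for epoch in range(1, cfg.epochs + 1):
        order = shuffle_rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if cfg.frozen_encoding:
                x0 = X_frozen[idx]
            else:
                x0 = poisson_encode_counts(X[idx], n_steps, enc_rng)
            counts = [x0] + lif_forward_counts(x0, net)
            out = counts[-1]
            target = label_counts(y[idx], n_classes, n_steps)
            b = x0.shape[0]
            deltas = []
            for l in range(1, L + 1):
                prev = counts[l - 1]
                # batch-mean error Gram; the update is linear in it
                ga = np.einsum("bis,st,bjt->ij", out, kgrid, prev,
                               optimize=True) / b
                gd = np.einsum("bis,st,bjt->ij", target, kgrid, prev,
                               optimize=True) / b
                if l == L:
                    deltas.append(output_delta_from_grams(ga, gd, eta))
                elif feedback.mode == "BP":
                    path = backward_pathway(net.weights, l)
                    deltas.append(hidden_delta_from_grams(path, ga, gd, eta))
                elif feedback.mode == "FA":
                    path = backward_pathway(feedback.fa_matrices, l)
                    deltas.append(hidden_delta_from_grams(path, ga, gd, eta))
                else:  # BA
                    deltas.append(hidden_delta_from_grams(
                        feedback.ba_matrices[l - 1], ga, gd, eta))
            for l, dw in enumerate(deltas, start=1):
                net.weights[l - 1] += dw
                w = net.weights[l - 1]
                if not np.all(np.isfinite(w)) or (
                        cfg.weight_guard is not None
                        and np.abs(w).max() > cfg.weight_guard):
                    raise TrainingDiverged(
                        epoch, l, f"max |W_{l}| = {np.abs(w).max():g}")

        out_eval = lif_forward_counts(X_eval, net)[-1]
        loss, acc = evaluate_counts(out_eval, y, kgrid)
        record.train_loss.append(loss)
        record.train_acc.append(acc)
        if test_dataset is not None:
            out_t = lif_forward_counts(Xt_eval, net)[-1]
            _, tacc = evaluate_counts(out_t, yt, kgrid)
            record.test_acc.append(tacc)
        else:
            record.test_acc.append(float("nan"))
    return net, record
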