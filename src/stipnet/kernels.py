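"""Spike-time kernels, spike-train inner products, and the RKHS error.

A shift-invariant kernel κ(|t_m − t_n|) defines an inner product between
individual spike times.  Summing κ over all pairs of spike times from two
trains yields the spike-train inner product (STIP)

    F(s_a, s_b) = Σ_m Σ_n κ(t_m, t_n),

the bilinear form on which every error and weight-update computation in
this package is built.  Conceptually each train is embedded in a
reproducing-kernel Hilbert space as a sum of smoothing filters centred on
its spike times; the STIP is the inner product of those embeddings, and it
is computed here in closed form without ever materialising the continuous
signals.

Four kernel families are supported (parameter in milliseconds):

========================  ===========================================  =======
family                    κ(x, y)                                      default
========================  ===========================================  =======
gaussian                  exp(−|x−y|² / 2σ²)                           σ = 40
laplacian                 exp(−|x−y| / σ)                              σ = 80
inverse_multiquadratic    1 / sqrt(|x−y|² + c²)                        c = 30
alpha                     (|x−y|/σ)·exp(−|x−y|/σ)                      σ = 5
========================  ===========================================  =======

gaussian, laplacian and inverse_multiquadratic are positive definite, so
self Gram matrices are positive semidefinite and the RKHS error is a true
squared distance.  The alpha kernel has κ(x, x) = 0 and is *not* positive
definite, so the
distance-like guarantees do not apply to it.  It is included because the
alignment-based rules need only Gram matrices, not a metric, and it is
commonly used with them in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spiketrains import SpikeTrain, SpikeTrainSet, ValidationError

__all__ = [
    "KernelSpec",
    "KERNEL_FAMILIES",
    "DEFAULT_KERNEL_PARAMS",
    "PSD_FAMILIES",
    "kernel_eval",
    "stip_pair",
    "stip_matrix",
    "rkhs_error",
    "grid_kernel_matrix",
    "grid_gram",
    "rkhs_error_from_grams",
    "ConfigurationError",
]

KERNEL_FAMILIES = ("gaussian", "laplacian", "inverse_multiquadratic", "alpha")

#: Kernel width/shape parameters (ms) used in the reference experiments.
DEFAULT_KERNEL_PARAMS = {
    "gaussian": 40.0,
    "laplacian": 80.0,
    "inverse_multiquadratic": 30.0,
    "alpha": 5.0,
}

#: Families whose kernel is positive definite (Gram matrices PSD).
PSD_FAMILIES = ("gaussian", "laplacian", "inverse_multiquadratic")


class ConfigurationError(ValueError):
    """Unknown kernel family or otherwise unresolvable configuration."""


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus its width/shape parameter.

    Parameters
    ----------
    family:
        One of :data:`KERNEL_FAMILIES`.
    parameter:
        σ for gaussian/laplacian/alpha, c for the inverse multiquadratic,
        in milliseconds.  Must be positive.
    imq_form:
        Form of the inverse multiquadratic: ``"sqrt"`` for the standard
        1/sqrt(|x−y|²+c²) (default) or ``"plain"`` for 1/(|x−y|²+c²).
    """

    family: str
    parameter: float
    imq_form: str = "sqrt"

    def __post_init__(self):
        if self.family not in KERNEL_FAMILIES:
            raise ConfigurationError(
                f"unknown kernel family {self.family!r}; "
                f"expected one of {KERNEL_FAMILIES}")
        if not self.parameter > 0:
            raise ValidationError(
                f"kernel parameter must be positive, got {self.parameter}")
        if self.imq_form not in ("sqrt", "plain"):
            raise ConfigurationError(
                f"imq_form must be 'sqrt' or 'plain', got {self.imq_form!r}")

    @staticmethod
    def default(family: str) -> "KernelSpec":
        """Spec with the reference parameter for the given family."""
        if family not in DEFAULT_KERNEL_PARAMS:
            raise ConfigurationError(f"unknown kernel family {family!r}")
        return KernelSpec(family, DEFAULT_KERNEL_PARAMS[family])


def _kappa(diff: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Vectorised kernel of absolute time differences."""
    d = np.abs(diff)
    p = spec.parameter
    if spec.family == "gaussian":
        return np.exp(-(d * d) / (2.0 * p * p))
    if spec.family == "laplacian":
        return np.exp(-d / p)
    if spec.family == "inverse_multiquadratic":
        q = d * d + p * p
        return 1.0 / np.sqrt(q) if spec.imq_form == "sqrt" else 1.0 / q
    if spec.family == "alpha":
        r = d / p
        return r * np.exp(-r)
    raise ConfigurationError(f"unknown kernel family {spec.family!r}")


def kernel_eval(tm: float, tn: float, spec: KernelSpec) -> float:
    """Inner product κ(t_m, t_n) between two spike times.

    Symmetric in its time arguments, finite and non-negative for every
    supported family.
    """
    return float(_kappa(np.asarray(tm, dtype=float) - tn, spec))


def stip_pair(a: SpikeTrain, b: SpikeTrain, spec: KernelSpec) -> float:
    """Spike-train inner product F(a, b): the double sum of κ over all
    spike-time pairs.

    O(N_a · N_b); symmetric; zero when either train is empty.
    """
    if a.interval_end != b.interval_end:
        raise ValidationError("trains must share the same interval")
    if a.n_spikes == 0 or b.n_spikes == 0:
        return 0.0
    return float(_kappa(a.times[:, None] - b.times[None, :], spec).sum())


def stip_matrix(p: SpikeTrainSet, q: SpikeTrainSet, spec: KernelSpec) -> np.ndarray:
    """Gram matrix F(s_p, s_q) of shape (p.layer_size, q.layer_size).

    Entry (i, j) is ``stip_pair(p[i], q[j], spec)``.  Satisfies
    ``stip_matrix(p, q) == stip_matrix(q, p).T``.  Computed by flattening
    all spike times of each set and folding the full time-pair kernel
    matrix back per neuron with one-hot membership matrices (BLAS-friendly
    at the spike counts this package works with).
    """
    if p.interval_end != q.interval_end:
        raise ValidationError("spike-train sets must share the same interval")
    F = np.zeros((p.layer_size, q.layer_size))
    tp, ip = _flatten(p)
    tq, iq = _flatten(q)
    if tp.size == 0 or tq.size == 0:
        return F
    K = _kappa(tp[:, None] - tq[None, :], spec)
    Ep = np.zeros((p.layer_size, tp.size))
    Ep[ip, np.arange(tp.size)] = 1.0
    Eq = np.zeros((q.layer_size, tq.size))
    Eq[iq, np.arange(tq.size)] = 1.0
    return Ep @ K @ Eq.T


def _flatten(s: SpikeTrainSet):
    times = [tr.times for tr in s]
    owners = [np.full(tr.n_spikes, i) for i, tr in enumerate(s)]
    if s.total_spikes == 0:
        return np.empty(0), np.empty(0, dtype=int)
    return np.concatenate(times), np.concatenate(owners)


def rkhs_error(actual: SpikeTrainSet, desired: SpikeTrainSet,
               spec: KernelSpec) -> float:
    """Network error E = ½ ∫ ‖h_a(t) − h_d(t)‖² dt in closed form.

    Expanding the squared RKHS distance neuron by neuron:

        E = ½ Σ_i [ F(a_i, a_i) − 2 F(a_i, d_i) + F(d_i, d_i) ].

    Non-negative for positive-definite kernels and exactly zero when the
    two sets are identical.  For the alpha kernel (not positive definite)
    the value can be negative and E = 0 does not imply equality.
    """
    if actual.layer_size != desired.layer_size:
        raise ValidationError(
            f"layer sizes differ: {actual.layer_size} vs {desired.layer_size}")
    if actual.interval_end != desired.interval_end:
        raise ValidationError("sets must share the same interval")
    e = 0.0
    for a_i, d_i in zip(actual, desired):
        if a_i.times.shape == d_i.times.shape and np.array_equal(a_i.times, d_i.times):
            continue  # identical trains contribute exactly zero
        e += (stip_pair(a_i, a_i, spec)
              - 2.0 * stip_pair(a_i, d_i, spec)
              + stip_pair(d_i, d_i, spec))
    return 0.5 * e


# ---------------------------------------------------------------------------
# Grid fast path.
#
# Clock-driven encoders and the LIF simulator emit spikes only at the grid
# times t_k = k*dt, so a layer's activity is a spike-count matrix
# C (H × n_steps) and every Gram matrix reduces to C_p @ K @ C_q.T with K
# the fixed kernel matrix of the grid times.  This is exact (not an
# approximation) for grid-aligned trains and is what the training loop uses.

def grid_kernel_matrix(spec: KernelSpec, dt: float, n_steps: int) -> np.ndarray:
    """Kernel matrix κ(|k·dt − m·dt|) of the simulation grid, (n_steps²)."""
    t = np.arange(n_steps) * dt
    return _kappa(t[:, None] - t[None, :], spec)


def grid_gram(counts_p: np.ndarray, counts_q: np.ndarray,
              kgrid: np.ndarray) -> np.ndarray:
    """Gram matrix between layers given as spike-count matrices.

    ``counts_p`` has shape (..., H_p, n_steps); leading batch dimensions
    broadcast.  Equals :func:`stip_matrix` on the corresponding trains.
    """
    return np.einsum("...is,st,...jt->...ij", counts_p, kgrid, counts_q,
                     optimize=True)


def rkhs_error_from_grams(gaa: np.ndarray, gad: np.ndarray,
                          gdd: np.ndarray) -> np.ndarray:
    """RKHS error from precomputed Gram matrices (batched).

    Arguments are the actual-actual, actual-desired and desired-desired
    Gram matrices of one output layer, shape (..., H, H).
    """
    tr = lambda g: np.trace(g, axis1=-2, axis2=-1)
    return 0.5 * (tr(gaa) - 2.0 * tr(gad) + tr(gdd))
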