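"""Independent oracles used across the test suite.

Everything here is deliberately written the slow, obvious way (explicit
Python loops, materialised continuous signals, numerical quadrature) so
that it shares no code path with the vectorised implementation it checks.
"""

import math

import numpy as np

# -- double-loop spike-train inner product ----------------------------------

def kernel_scalar(d, family, p, imq_form="sqrt"):
    d = abs(d)
    if family == "gaussian":
        return math.exp(-d * d / (2 * p * p))
    if family == "laplacian":
        return math.exp(-d / p)
    if family == "inverse_multiquadratic":
        q = d * d + p * p
        return 1.0 / math.sqrt(q) if imq_form == "sqrt" else 1.0 / q
    if family == "alpha":
        return (d / p) * math.exp(-d / p)
    raise ValueError(family)


def stip_double_loop(times_a, times_b, family, p):
    """F(a, b) as an explicit nested loop over spike pairs (exact sum)."""
    return math.fsum(kernel_scalar(tm - tn, family, p)
                     for tm in times_a for tn in times_b)


# -- continuous-signal quadrature for the gaussian family -------------------
#
# For the gaussian kernel κ(Δ) = exp(−Δ²/2σ²), the smoothing filter whose
# autocorrelation reproduces κ is itself gaussian with σ_φ = σ/√2 and
# amplitude (σ_φ√π)^{−1/2}.  Signals are evaluated on a fine grid padded
# well past the simulation interval so the filter tails are captured.

def phi_grid(sigma, interval_end, pad_sigmas=8.0, step=0.05):
    sigma_phi = sigma / math.sqrt(2.0)
    pad = pad_sigmas * sigma_phi
    return np.arange(-pad, interval_end + pad + step, step), sigma_phi


def smoothed_signal(times, grid, sigma_phi):
    """Σ_i φ(t − t_i) on the grid, φ the normalised gaussian filter."""
    amp = (sigma_phi * math.sqrt(math.pi)) ** -0.5
    out = np.zeros_like(grid)
    for ti in times:
        out += amp * np.exp(-((grid - ti) ** 2) / (2 * sigma_phi ** 2))
    return out


def quad_rkhs_error(actual_times, desired_times, sigma, interval_end):
    """½∫‖h_a(t) − h_d(t)‖²dt by trapezoidal quadrature, per-neuron lists."""
    grid, sigma_phi = phi_grid(sigma, interval_end)
    total = 0.0
    for ta, td in zip(actual_times, desired_times):
        diff = smoothed_signal(ta, grid, sigma_phi) - smoothed_signal(
            td, grid, sigma_phi)
        total += np.trapezoid(diff * diff, grid)
    return 0.5 * total


def quad_surrogate_error(weights, input_times, desired_times, sigma,
                         interval_end):
    """½∫‖(W_L⋯W_1)h_0(t) − h_od(t)‖²dt under the linear spike-train
    relation, by quadrature."""
    grid, sigma_phi = phi_grid(sigma, interval_end)
    h0 = np.stack([smoothed_signal(t, grid, sigma_phi) for t in input_times])
    hod = np.stack([smoothed_signal(t, grid, sigma_phi)
                    for t in desired_times])
    wtot = weights[-1]
    for w in reversed(weights[:-1]):
        wtot = wtot @ w
    diff = wtot @ h0 - hod
    return 0.5 * float(np.trapezoid((diff * diff).sum(axis=0), grid))


def fd_surrogate_gradient(weights, layer, input_times, desired_times, sigma,
                          interval_end, h=1e-3):
    """Central-difference gradient of the surrogate error w.r.t. W_layer
    (1-based).  The error is quadratic in the weights, so the central
    difference is exact up to quadrature and round-off error."""
    w = [np.array(m, dtype=float) for m in weights]
    grad = np.zeros_like(w[layer - 1])
    for i in range(grad.shape[0]):
        for j in range(grad.shape[1]):
            w[layer - 1][i, j] += h
            ep = quad_surrogate_error(w, input_times, desired_times, sigma,
                                      interval_end)
            w[layer - 1][i, j] -= 2 * h
            em = quad_surrogate_error(w, input_times, desired_times, sigma,
                                      interval_end)
            w[layer - 1][i, j] += h
            grad[i, j] = (ep - em) / (2 * h)
    return grad


# -- random spike trains -----------------------------------------------------

def random_times(rng, max_spikes, interval_end, min_n=0):
    n = int(rng.integers(min_n, max_spikes + 1))
    if n == 0:
        return np.empty(0)
    t = np.sort(rng.uniform(0, interval_end, size=n))
    while np.any(np.diff(t) <= 1e-9):  # enforce strict increase
        t = np.sort(rng.uniform(0, interval_end, size=n))
    return t
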