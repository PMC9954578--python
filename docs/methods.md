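# Methods

## Spike-train embeddings and kernels

A spike train is represented by its firing times only; all comparisons go
through the kernel. Conceptually each train is convolved with a smoothing
filter φ and compared in the resulting Hilbert space, but because the inner
product of two smoothed spikes is `κ(t_m, t_n) = ∫ φ(t−t_m)φ(t−t_n) dt`,
only the closed-form kernel κ is ever evaluated. The four kernels are
implemented exactly as closed forms (parameter in ms):

* gaussian `exp(−Δ²/2σ²)`, σ = 40 — the default throughout;
* laplacian `exp(−Δ/σ)`, σ = 80;
* inverse multiquadratic `1/√(Δ² + c²)`, c = 30;
* α-kernel `(Δ/σ)·exp(−Δ/σ)`, σ = 5.

The inverse multiquadratic appears in the literature both with and without
the square root; we implement the standard `1/√(Δ²+c²)` and expose the
variant `1/(Δ²+c²)` through `KernelSpec(imq_form="plain")`. The α-kernel
satisfies `κ(x, x) = 0`, so it is not positive definite: its Gram matrices
can be indefinite, the RKHS "error" can be negative, and `E = 0` does not
imply equal trains. It is provided because it is used in practice with the
FA/BA rules (which only need the Gram matrices, not a metric), but it is
excluded from every positive-semidefiniteness guarantee and from
distance-based reasoning.

STIP is computed densely in O(N_a·N_b) per train pair; at the spike counts
this package targets (≤ ~10 spikes per train over a 10 ms interval) this is
never the bottleneck. Trains produced by the clock-driven pipeline live on
the grid `t_k = k·dt`, where a layer's activity is equivalently a 0/1
count matrix `C (H × n_steps)` and every Gram matrix is exactly
`C_p K C_qᵀ` with `K` the fixed kernel matrix of grid times. The trainer
uses this identity (it is an algebraic rewrite, not an approximation); a
test pins it against the general implementation. Empty trains contribute
zero to every sum; the RKHS error of two identical sets is exactly 0.0 by
construction (identical neurons are skipped rather than cancelled in
floating point).

## LIF simulation

Single-state leaky integrate-and-fire neurons with delta synapses: per step,
`V ← V·exp(−dt/τ) + Σ_j w_j·[j spiked]`; if `V ≥ θ` the neuron spikes at
that step's grid time and V is hard-reset. Order within a step is decay →
integrate → threshold. Defaults: τ = 5 ms, θ = 5.0, reset 0.0, dt = 1 ms,
interval 10 ms (10 steps). dt = 1 ms is a choice, not a constraint — it
keeps per-train spike counts ≤ 10 and matches the common clock-driven
convention; it is configurable. There is no refractory period, bias
current, or synaptic filter state: the "postsynaptic potential decay" and
the membrane time constant are deliberately collapsed into the single
membrane leak, the simplest dynamics consistent with the model description.
Spikes propagate one layer per step with zero delay (layers are simulated
front to back over the whole interval).

Weight initialisation is i.i.d. N(0, scale²) with scale = 1.0 by default,
matching the reference setting. With hundreds of inputs an unscaled N(0, 1)
drive saturates LIF layers heavily; the `scale` parameter exists for
experiments that want to avoid this, but the default is kept faithful.

## Encoding and decoding

* **Input**: per-step Bernoulli ("Poisson") coding — component intensity
  x ∈ [0, 1] is the per-step spike probability, so the maximum rate is one
  spike per step. We chose the Bernoulli-per-step reading over count draws
  because it is the standard clock-driven encoder and bounds spikes at one
  per grid time.
* **Targets**: the labelled class's output neuron fires at every grid step
  ("evenly"); all others are silent. "Evenly" is unquantified in general;
  one spike per step is the maximal unambiguous choice, and a
  `spikes_per_step` thinning knob is provided.
* **Decoding**: distances `d_c = rkhs_error(output, template_c)` to each
  class's target train; prediction is argmin with ties broken toward the
  lowest class index (templates are permutations of one another, so an
  all-silent output ties every class). `softmax(−d)` is reported as a
  score vector; its argmax coincides with the argmin distance, which is
  what a softmax-like decoder needs to provide.

## Update rules and training loop

The three rules share the error Gram matrix
`G_l = F(s_oa, s_{l−1}) − F(s_od, s_{l−1})` and differ only in the pathway
matrix (see README table). Properties that follow directly and are enforced
by tests: exact zero update at zero error; FA ≡ BP bitwise when B = W; BA
locality (independence from all forward weights); linearity in η.

Training semantics, chosen where the reference description is silent:

* **Batch aggregation**: per-sample updates are averaged over the batch
  (standard mini-batch semantics). Because the update is linear in the Gram
  matrices, the implementation averages the Gram matrices and forms each
  delta once.
* **Synchronous updates**: all layers' deltas are computed from the same
  pre-update weights and applied together, matching the derivation and
  avoiding order dependence.
* **Re-encoding**: inputs are Poisson re-drawn at every presentation
  (seed-controlled); a `frozen_encoding` flag fixes one draw for
  deterministic experiments.
* **Metrics**: after each epoch, mean RKHS loss and accuracy are measured
  on a *fixed* evaluation encoding (one Poisson draw reused across epochs)
  so that epoch-to-epoch changes reflect the weights, not encoder noise.
* **Divergence guard**: training aborts with the offending epoch and layer
  if any weight becomes non-finite or exceeds a configurable magnitude
  (default 1e8) — BP in particular is known to be unstable in this family
  of rules, and a loud abort beats silent NaNs.
* **Epochs** mean full passes over the training set.

## Synthetic task generator

The generator emulates the statistical shape of the image pipeline —
normalised intensity vectors in [0, 1] with a sparse set of informative
components, rate-encoded — without any external data. Each class has a
fixed binary prototype (a random half of the 20 components at intensity
0.8, the rest at 0.05), samples flip each component independently with
probability 0.05, and splits are class-balanced (300 train / 90 test by
default). Prototypes are re-drawn (with a diagnostic after 200 attempts)
until every pair differs in at least 25% of components, so the task is
separable by construction. These defaults were chosen once as a realistic
small-scale rate-coding task whose full training run takes seconds on one
CPU.

What passing on this task shows: that the encoders, simulator, Gram
computations and all three update rules interact correctly end to end, and
that FA/BA credit assignment can drive a two-hidden-layer LIF network to
high accuracy. What it does not show: performance on real image data —
the prototypes have none of the correlated pixel geometry of digits, the
task is far easier than MNIST, and 100% accuracy here implies nothing
about full-scale accuracy figures.

A committed worked example (3-4-2 network, ≤3 spikes per train, gaussian
σ = 40, η = 0.1) carries golden Gram and update matrices for all three
rules, generated by an explicit pure-Python double loop, so every rule has
a hand-checkable reference.

## Numerical choices and test oracles

* Gram positive semidefiniteness is asserted with an eigenvalue floor of
  −1e−9 (accumulated round-off across ~400-entry matrices).
* The quadrature oracle used only in tests materialises the gaussian
  filter φ with σ_φ = σ/√2 and amplitude `(σ_φ√π)^(−1/2)` (so that
  φ⋆φ = κ), evaluates signals on a grid padded 8σ_φ past the interval and
  integrates by the trapezoidal rule; the closed-form kernel corresponds
  to the untruncated convolution, so the padding is what makes the two
  routes agree to the tested 1e−3/1e−4 tolerances.
* Gradient checks use the surrogate error `½∫‖(W_L⋯W_1)h_0 − h_od‖²dt`
  implied by the linear spike-train relation. Inner layers of that
  surrogate are linear combinations of filtered spikes rather than genuine
  spike trains, so the finite-difference comparison is run against the
  Gram-level update cores, with the surrogate's Gram matrices formed by
  bilinearity from `F(s_0, s_0)`; the spike-train-level wrappers are
  pinned separately against the double-loop golden example. The surrogate
  error is quadratic in the weights, so central differences are exact up
  to quadrature and round-off.
* Problem sizes in the test suite and acceptance script (3-4-2 oracle
  instances, 20-30-30-3 training runs, 100 epochs, 5 seeds) were chosen to
  make every check run comfortably on one CPU while keeping each property
  at its full stated strength.

## Known limitations

* The linear spike-train relation behind all three rules is a surrogate:
  LIF spike generation is not linear, so the updates are principled
  approximations, not exact gradients of the simulated network's error.
* No momentum, learning-rate schedules, or adaptive optimisers — plain
  delta-rule updates only, by design.
* Rate-based Poisson encoding discards precise-timing structure in inputs;
  temporal codes (latency, phase) are out of scope.
* The α-kernel caveats above: no PSD guarantees, error not a metric.
* Full-scale MNIST training (784-wide layers, 60k images, 150 epochs) is
  supported by the same code paths plus the IDX reader but is a
  long-running experiment, not part of the test surface, and MNIST is
  never downloaded automatically.
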