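# stipnet

Supervised learning for deep spiking neural networks (SNNs) built on
**spike-train inner products (STIP)** — with three interchangeable credit
assignment pathways: error **backpropagation (BP)**, **feedback alignment
(FA)**, and **broadcast alignment (BA**, also known as direct feedback
alignment). The package is aimed at computational-neuroscience and
neuromorphic-learning researchers who want a compact, fully inspectable
NumPy implementation of kernel-based spike-train learning: every update rule
is a few matrix products over closed-form Gram matrices, with no autodiff
framework underneath.

## The model

A spike train is a finite set of firing times `s = {t_i ∈ [0, T]}`. A
shift-invariant, positive-definite kernel `κ` defines an inner product
between spike times, and summing it over all spike pairs gives the
spike-train inner product

```
F(s_a, s_b) = Σ_m Σ_n κ(t_m, t_n)
```

which is the inner product of the trains' embeddings in a reproducing-kernel
Hilbert space (each train smoothed by a filter φ with autocorrelation κ).
Stacking it over two layers of neurons gives a Gram matrix `F(s_p, s_q)` of
shape `H_p × H_q`. Network error is the squared RKHS distance between the
actual and desired output trains,

```
E = ½ ∫ ‖h_oa(t) − h_od(t)‖² dt
  = ½ Σ_i [ F(a_i, a_i) − 2 F(a_i, d_i) + F(d_i, d_i) ],
```

computed in closed form — the continuous signals are never materialised.
Under the linear spike-train relation `h_l = W_l h_{l−1}`, gradient descent
on E yields weight updates that depend on spikes only through STIP Gram
matrices. For the output layer (all modes):

```
ΔW_L = −η [ F(s_oa, s_{L−1}) − F(s_od, s_{L−1}) ]
```

and for a hidden layer `l`, with `G_l = F(s_oa, s_{l−1}) − F(s_od, s_{l−1})`:

| mode | update | error pathway |
|------|--------|---------------|
| BP | `ΔW_l = −η (W_L ⋯ W_{l+1})ᵀ G_l` | transposed forward weights |
| FA | `ΔW_l = −η (B_L ⋯ B_{l+1})ᵀ G_l` | fixed random `B_l`, layer-wise |
| BA | `ΔW_l = −η (B′_l)ᵀ G_l` | one fixed random `B′_l` per layer, direct broadcast |

FA and BA sidestep the weight-transport problem: the feedback matrices are
drawn once from N(0, 1) and never updated. BA is a local three-factor rule.

Networks are fully connected leaky integrate-and-fire (LIF) layers simulated
clock-driven (default dt = 1 ms over a 10 ms interval; τ = 5 ms, threshold
5.0, hard reset to 0). Inputs are Poisson (Bernoulli-per-step) encodings of
intensity vectors in [0, 1]; targets are one-hot trains in which the
labelled class's neuron fires at every step; decoding is nearest-template in
RKHS distance. Four kernels are provided: gaussian (σ = 40 ms), laplacian
(σ = 80 ms), inverse multiquadratic (c = 30 ms), and the α-kernel (σ = 5 ms).

## Worked example

A self-contained 3-class synthetic task (20 inputs, Poisson-encoded binary
prototypes with 5% flip noise, 300 train / 90 test samples) trains in
seconds on one CPU with a 20-30-30-3 network:

```
$ stipnet demo --epochs 40 --seed 0
synthetic task: 3 classes, 20 inputs, 300 train / 90 test samples
mode  final_train_loss  train_acc  test_acc
BP              0.3095     1.0000    1.0000
FA              0.5804     1.0000    1.0000
BA              2.1081     1.0000    1.0000
```

All three pathways reach 100% test accuracy; the final column is the
fraction of test samples whose decoded class matches the label, and the loss
is the mean RKHS error between output and target trains (so BP, which
follows the exact gradient on this small, well-conditioned task, attains the
lowest final loss). `stipnet train --mode fa --out runs/fa ...` writes a
per-epoch metrics table, final weights, and the resolved run configuration;
`stipnet evaluate --run runs/fa` reloads and scores them. Reference
full-scale settings (784-800-800-10, learning rate 8e−5, batch 64, 150
epochs) are the CLI defaults; MNIST in IDX format can be supplied via
`--data idx:<images>,<labels>` but is never downloaded by the package.

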