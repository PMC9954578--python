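"""Weight-update rules (BP / FA / BA) and the training loop."""

import hashlib

import numpy as np
import pytest

from stipnet import (FeedbackConfig, KernelSpec, TrainConfig, TrainingDiverged,
                     ValidationError, ba_hidden_delta, bp_hidden_delta,
                     fa_hidden_delta, init_weights, output_delta, train)
from stipnet.kernels import stip_matrix
from stipnet.learning import (backward_pathway, hidden_delta_from_grams,
                              output_delta_from_grams)
from stipnet.synthetic import SyntheticTaskSpec, make_task

from conftest import T, make_set, random_set
from oracles import fd_surrogate_gradient


# -- worked example: every rule against the committed double-loop golden ----

def test_worked_example_stip_matrices(worked_example):
    ex = worked_example
    spec = KernelSpec("gaussian", ex.kernel_sigma)
    for sets, key in [((ex.actual, ex.hidden), "stip_actual_hidden"),
                      ((ex.desired, ex.hidden), "stip_desired_hidden"),
                      ((ex.actual, ex.inputs), "stip_actual_inputs"),
                      ((ex.desired, ex.inputs), "stip_desired_inputs")]:
        assert np.allclose(stip_matrix(*sets, spec), ex.golden[key],
                           atol=1e-12)


def test_worked_example_updates(worked_example):
    ex = worked_example
    spec = KernelSpec("gaussian", ex.kernel_sigma)
    dw2 = output_delta(ex.actual, ex.desired, ex.hidden, spec, ex.eta)
    assert np.allclose(dw2, ex.golden["delta_w2"], atol=1e-12)

    weights = [ex.w1, ex.w2]
    dw1_bp = bp_hidden_delta(1, ex.actual, ex.desired, ex.inputs, weights,
                             spec, ex.eta)
    assert np.allclose(dw1_bp, ex.golden["delta_w1_bp"], atol=1e-12)

    fa = FeedbackConfig("FA", fa_matrices=(ex.b1.copy(), ex.b2.copy()))
    dw1_fa = fa_hidden_delta(1, ex.actual, ex.desired, ex.inputs, fa, spec,
                             ex.eta)
    assert np.allclose(dw1_fa, ex.golden["delta_w1_fa"], atol=1e-12)

    ba = FeedbackConfig("BA", ba_matrices=(ex.ba1.copy(),))
    dw1_ba = ba_hidden_delta(1, ex.actual, ex.desired, ex.inputs, ba, spec,
                             ex.eta)
    assert np.allclose(dw1_ba, ex.golden["delta_w1_ba"], atol=1e-12)


# -- structural properties of the rules -------------------------------------

def _random_instance(rng, sizes=(3, 4, 2)):
    net = init_weights(sizes, seed=int(rng.integers(2**31)))
    prev = random_set(rng, sizes[0], max_spikes=3)
    actual = random_set(rng, sizes[-1], max_spikes=3)
    desired = random_set(rng, sizes[-1], max_spikes=3)
    return net, prev, actual, desired


def test_zero_update_when_actual_equals_desired(rng, gaussian40):
    """Every rule has the zero-error fixed point ΔW = 0 exactly."""
    net, prev, actual, _ = _random_instance(rng)
    hidden = random_set(rng, 4, max_spikes=3)
    fa = FeedbackConfig.create("FA", net.layer_sizes, seed=5)
    ba = FeedbackConfig.create("BA", net.layer_sizes, seed=6)
    assert np.all(output_delta(actual, actual, hidden, gaussian40, 0.1) == 0)
    assert np.all(bp_hidden_delta(1, actual, actual, prev, net.weights,
                                  gaussian40, 0.1) == 0)
    assert np.all(fa_hidden_delta(1, actual, actual, prev, fa,
                                  gaussian40, 0.1) == 0)
    assert np.all(ba_hidden_delta(1, actual, actual, prev, ba,
                                  gaussian40, 0.1) == 0)


def test_fa_with_b_equal_w_reproduces_bp_exactly(rng, gaussian40):
    net, prev, actual, desired = _random_instance(rng, (3, 5, 4, 2))
    fa = FeedbackConfig("FA",
                        fa_matrices=tuple(w.copy() for w in net.weights))
    prev_sets = {1: prev, 2: random_set(rng, 5, 3)}
    for l in (1, 2):
        bp = bp_hidden_delta(l, actual, desired, prev_sets[l], net.weights,
                             gaussian40, 0.1)
        fa_d = fa_hidden_delta(l, actual, desired, prev_sets[l], fa,
                               gaussian40, 0.1)
        assert np.array_equal(bp, fa_d)


def test_ba_update_is_local(rng, gaussian40):
    """Perturbing W_{l+1} does not change the BA update for layer l."""
    net, prev, actual, desired = _random_instance(rng)
    ba = FeedbackConfig.create("BA", net.layer_sizes, seed=9)
    before = ba_hidden_delta(1, actual, desired, prev, ba, gaussian40, 0.1)
    net.weights[1] += 100.0   # output-layer weights perturbed
    after = ba_hidden_delta(1, actual, desired, prev, ba, gaussian40, 0.1)
    assert np.array_equal(before, after)


def test_update_scales_linearly_in_eta(rng, gaussian40):
    net, prev, actual, desired = _random_instance(rng)
    hidden = random_set(rng, 4, 3)
    d1 = output_delta(actual, desired, hidden, gaussian40, 1.0)
    d3 = output_delta(actual, desired, hidden, gaussian40, 3.0)
    assert np.allclose(d3, 3.0 * d1, rtol=1e-12)


def test_output_delta_sign_single_pair(gaussian40):
    """Missing desired spike pulls the weight up: ΔW = −η(0 − 1) = +η."""
    actual = make_set([[]])
    desired = make_set([[5.0]])
    hidden = make_set([[5.0]])
    dw = output_delta(actual, desired, hidden, gaussian40, 0.1)
    assert dw.shape == (1, 1)
    assert dw[0, 0] == pytest.approx(0.1)


def test_backward_pathway_single_term_and_product(rng):
    ws = [rng.standard_normal(s) for s in [(4, 3), (5, 4), (2, 5)]]
    assert np.array_equal(backward_pathway(ws, 2), ws[2])
    assert np.allclose(backward_pathway(ws, 1), ws[2] @ ws[1])
    with pytest.raises(ValidationError):
        backward_pathway(ws, 3)
    with pytest.raises(ValidationError):
        backward_pathway(ws, 0)


def test_feedback_matrices_are_immutable():
    fb = FeedbackConfig.create("FA", (3, 4, 2), seed=1)
    with pytest.raises(ValueError):
        fb.fa_matrices[0][0, 0] = 1.0
    fb2 = FeedbackConfig.create("BA", (3, 4, 2), seed=1)
    with pytest.raises(ValueError):
        fb2.ba_matrices[0][0, 0] = 1.0


def test_feedback_shapes():
    fa = FeedbackConfig.create("FA", (3, 4, 5, 2), seed=0)
    assert [m.shape for m in fa.fa_matrices] == [(4, 3), (5, 4), (2, 5)]
    ba = FeedbackConfig.create("BA", (3, 4, 5, 2), seed=0)
    assert [m.shape for m in ba.ba_matrices] == [(2, 4), (2, 5)]


# -- gradient oracle ---------------------------------------------------------

def _surrogate_instance(rng):
    """3-4-2 instance: input and desired trains, weights drawn small."""
    sizes = (3, 4, 2)
    input_times = [np.sort(rng.uniform(0, T, rng.integers(1, 4)))
                   for _ in range(sizes[0])]
    desired_times = [np.sort(rng.uniform(0, T, rng.integers(1, 4)))
                     for _ in range(sizes[-1])]
    w1 = rng.standard_normal((4, 3))
    w2 = rng.standard_normal((2, 4))
    return input_times, desired_times, [w1, w2]


@pytest.mark.parametrize("seed", [11, 12, 13])
def test_updates_match_surrogate_gradient(seed):
    """Under the linear spike-train relation h_l = W_l h_{l−1}, the STIP
    update formulas are the exact gradient of the RKHS error; checked
    against central differences of the quadrature-evaluated error."""
    sigma = 40.0
    spec = KernelSpec("gaussian", sigma)
    rng = np.random.default_rng(seed)
    input_times, desired_times, (w1, w2) = _surrogate_instance(rng)
    s0 = make_set(input_times)
    sod = make_set(desired_times)

    # implementation-side Gram matrices of the surrogate:
    # ∫ h_oa h_l^T dt with h_oa = W2 W1 h_0 and h_l the linear responses
    g00 = stip_matrix(s0, s0, spec)
    gd0 = stip_matrix(sod, s0, spec)
    wtot = w2 @ w1
    eta = 1.0

    # output layer: ∇E_2 = ∫(h_oa − h_od) h_1^T dt
    ga = wtot @ g00 @ w1.T
    gd = gd0 @ w1.T
    impl_grad2 = -output_delta_from_grams(ga, gd, eta) / eta
    fd2 = fd_surrogate_gradient([w1, w2], 2, input_times, desired_times,
                                sigma, T)
    assert np.allclose(impl_grad2, fd2, rtol=1e-4,
                       atol=1e-4 * np.abs(fd2).max())

    # hidden layer: ∇E_1 = W_2ᵀ ∫(h_oa − h_od) h_0^T dt
    ga1 = wtot @ g00
    impl_grad1 = -hidden_delta_from_grams(backward_pathway([w1, w2], 1),
                                          ga1, gd0, eta) / eta
    fd1 = fd_surrogate_gradient([w1, w2], 1, input_times, desired_times,
                                sigma, T)
    assert np.allclose(impl_grad1, fd1, rtol=1e-4,
                       atol=1e-4 * np.abs(fd1).max())


# -- training loop -----------------------------------------------------------

def _tiny_task():
    spec = SyntheticTaskSpec(n_classes=3, input_dim=12, n_train=30, n_test=9,
                             seed=4)
    return make_task(spec)


def _tiny_cfg(**kw):
    defaults = dict(learning_rate=1e-3, batch_size=10, epochs=3, seed=2,
                    kernel=KernelSpec("gaussian", 40.0))
    defaults.update(kw)
    return TrainConfig(**defaults)


def test_train_zero_epochs_is_identity():
    tr, te = _tiny_task()
    net = init_weights((12, 8, 3), seed=0)
    before = [w.copy() for w in net.weights]
    trained, record = train(tr, net, FeedbackConfig.create("BA", (12, 8, 3)),
                            _tiny_cfg(epochs=0), test_dataset=te)
    assert record.n_epochs == 0
    assert all(np.array_equal(a, b)
               for a, b in zip(trained.weights, before))


def test_train_reproducible_given_seed():
    tr, te = _tiny_task()
    fb = FeedbackConfig.create("FA", (12, 8, 3), seed=1)
    runs = []
    for _ in range(2):
        net = init_weights((12, 8, 3), seed=0)
        trained, record = train(tr, net, fb, _tiny_cfg(), test_dataset=te)
        runs.append((trained, record))
    assert all(np.array_equal(a, b) for a, b in
               zip(runs[0][0].weights, runs[1][0].weights))
    assert runs[0][1].train_loss == runs[1][1].train_loss
    assert runs[0][1].test_acc == runs[1][1].test_acc


def test_train_leaves_feedback_matrices_untouched():
    tr, te = _tiny_task()
    fb = FeedbackConfig.create("BA", (12, 8, 3), seed=3)
    digest = lambda: hashlib.sha256(
        b"".join(m.tobytes() for m in fb.ba_matrices)).hexdigest()
    before = digest()
    net = init_weights((12, 8, 3), seed=0)
    train(tr, net, fb, _tiny_cfg(), test_dataset=te)
    assert digest() == before


def test_train_empty_dataset_rejected():
    net = init_weights((12, 8, 3), seed=0)
    with pytest.raises(ValidationError):
        train([], net, FeedbackConfig.create("BA", (12, 8, 3)), _tiny_cfg())


def test_train_divergence_guard_names_epoch_and_layer():
    tr, te = _tiny_task()
    net = init_weights((12, 8, 3), seed=0)
    cfg = _tiny_cfg(learning_rate=1e-3, weight_guard=1e-6, epochs=2)
    with pytest.raises(TrainingDiverged) as exc:
        train(tr, net, FeedbackConfig.create("BA", (12, 8, 3)), cfg)
    assert exc.value.epoch == 1
    assert 1 <= exc.value.layer <= 2


def test_train_record_table_format():
    tr, te = _tiny_task()
    net = init_weights((12, 8, 3), seed=0)
    _, record = train(tr, net, FeedbackConfig.create("BA", (12, 8, 3)),
                      _tiny_cfg(epochs=2), test_dataset=te)
    table = record.to_table()
    lines = table.strip().split("\n")
    assert lines[0] == "epoch\ttrain_loss\ttrain_acc\ttest_acc"
    assert len(lines) == 3
    assert lines[1].startswith("1\t")


def test_train_loss_decreases_on_synthetic_task():
    """FA and BA training reduces the RKHS loss from the first epoch to
    the best epoch (learning-stability property of the feedback modes)."""
    tr, te = _tiny_task()
    for mode in ("FA", "BA"):
        finals = []
        for seed in (0, 1, 2):
            net = init_weights((12, 8, 3), seed=seed)
            fb = FeedbackConfig.create(mode, (12, 8, 3), seed=seed + 10)
            _, rec = train(tr, net, fb, _tiny_cfg(epochs=15, seed=seed),
                           test_dataset=te)
            finals.append(min(rec.train_loss) < rec.train_loss[0])
        assert np.median(finals) == 1.0, f"{mode} loss did not decrease"
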