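"""Network forward-pass oracle equivalence, loss, integration and training."""

import numpy as np
import pytest

from tkebgc.data import WindowedSample
from tkebgc.model import (
    DimensionError,
    ModelConfig,
    TkeBgc,
    TrainingError,
    integrate,
    load_model,
    loss_mse,
    predict_sequence,
    save_model,
    train,
)

TOY = dict(P=4, n_emg=3, n_tactile=4, n_joint=5, d_E=6, d_k=8, d_q=5, d_a=8,
           h=2, mlp_hidden=(7,), dropout=0.0)


def toy_model(seed=0, **overrides):
    kw = dict(TOY)
    kw.update(overrides)
    cfg = ModelConfig(seed=seed, **kw)
    return TkeBgc(cfg, np.random.default_rng(seed))


# -- pure-loop reference implementation (no batched linear algebra) --------

def _loop_linear(x, W, b=None):
    n, d_in = x.shape
    d_out = W.shape[1]
    out = np.zeros((n, d_out))
    for i in range(n):
        for o in range(d_out):
            acc = 0.0
            for j in range(d_in):
                acc += x[i, j] * W[j, o]
            out[i, o] = acc + (b[o] if b is not None else 0.0)
    return out


def _loop_conv(x, W, b, kernel):
    P, c_in = x.shape
    pad = kernel // 2
    xp = np.zeros((P + 2 * pad, c_in))
    xp[pad : pad + P] = x
    c_out = W.shape[1]
    out = np.zeros((P, c_out))
    for t in range(P):
        for o in range(c_out):
            acc = b[o]
            for k in range(kernel):
                for c in range(c_in):
                    acc += xp[t + k, c] * W[k * c_in + c, o]
            out[t, o] = acc
    return out


def _loop_avgpool(x, kernel):
    P, C = x.shape
    pad = kernel // 2
    xp = np.zeros((P + 2 * pad, C))
    xp[pad : pad + P] = x
    out = np.zeros((P, C))
    for t in range(P):
        for c in range(C):
            out[t, c] = sum(xp[t + k, c] for k in range(kernel)) / kernel
    return out


def _loop_layernorm(x, gamma, beta, eps=1e-5):
    out = np.zeros_like(x)
    for i in range(x.shape[0]):
        mu = x[i].mean()
        var = ((x[i] - mu) ** 2).mean()
        out[i] = (x[i] - mu) / np.sqrt(var + eps) * gamma + beta
    return out


def _loop_softmax_row(v):
    e = np.exp(v - v.max())
    return e / e.sum()


def loop_forward(model, emg, tactile, joints):
    """Exhaustive per-position, per-head reference of the full forward pass."""
    cfg = model.config
    p = {k: t.data for k, t in model.named_params().items()}
    e = (emg - model.norm_emg.mean) / model.norm_emg.std
    f = (tactile - model.norm_tac.mean) / model.norm_tac.std
    j = (joints - model.norm_joint.mean) / model.norm_joint.std

    h1 = np.maximum(0.0, _loop_conv(e, p["conv1.W"], p["conv1.b"], 3))
    h2 = _loop_avgpool(_loop_conv(h1, p["conv2.W"], p["conv2.b"], 3), 3)
    e_r = _loop_linear(e, p["W_r.W"])
    e_prime = _loop_linear(np.concatenate([h2, e_r], axis=1), p["W_r2.W"])
    K = _loop_linear(e_prime, p["W_k.W"])
    V = _loop_linear(e_prime, p["W_v.W"])
    jp = _loop_linear(j, p["W_J.W"], p["W_J.b"])
    fp = _loop_linear(f, p["W_F.W"], p["W_F.b"])
    q = _loop_linear(np.concatenate([jp, fp], axis=1), p["W_Q.W"])

    z = q
    for b_i in range(cfg.n_blocks):
        pref = f"blocks.{b_i}."
        dh = cfg.d_head
        heads = np.zeros((cfg.P, cfg.d_a))
        for h_i in range(cfg.h):
            sl = slice(h_i * dh, (h_i + 1) * dh)
            for t in range(cfg.P):
                logits = np.array([
                    sum(z[t, sl][d] * K[s, sl][d] for d in range(dh)) / np.sqrt(dh)
                    for s in range(cfg.P)
                ])
                w = _loop_softmax_row(logits)
                for d in range(dh):
                    heads[t, h_i * dh + d] = sum(w[s] * V[s, sl][d] for s in range(cfg.P))
        x = _loop_layernorm(z + heads, p[pref + "ln1.gamma"], p[pref + "ln1.beta"])
        ff = _loop_linear(
            np.maximum(0.0, _loop_linear(x, p[pref + "ff1.W"], p[pref + "ff1.b"])),
            p[pref + "ff2.W"], p[pref + "ff2.b"],
        )
        z = _loop_layernorm(x + ff, p[pref + "ln2.gamma"], p[pref + "ln2.beta"])

    j0 = _loop_linear(j[-1:], p["W_J0.W"])[0]
    f0 = _loop_linear(f[-1:], p["W_F0.W"])[0]
    u = np.concatenate([z[-1], j0, f0])[None, :]
    n_layers = len(model.mlp)
    for li in range(n_layers - 1):
        u = np.maximum(0.0, _loop_linear(u, p[f"mlp.{li}.W"], p[f"mlp.{li}.b"]))
    return _loop_linear(u, p[f"mlp.{n_layers - 1}.W"], p[f"mlp.{n_layers - 1}.b"])[0]


class TestForwardOracle:
    def test_vectorized_forward_matches_loop_reference_on_seeded_instances(self):
        worst = 0.0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            model = toy_model(seed=seed)
            E = rng.normal(size=(TOY["P"], TOY["n_emg"]))
            F = rng.uniform(0, 10, size=(TOY["P"], TOY["n_tactile"]))
            J = rng.uniform(0, 90, size=(TOY["P"], TOY["n_joint"]))
            fast = model.predict(E[None], F[None], J[None])[0]
            slow = loop_forward(model, E, F, J)
            worst = max(worst, float(np.abs(fast - slow).max()))
        assert worst < 1e-6

    def test_oracle_holds_with_multiple_fusion_blocks(self):
        rng = np.random.default_rng(7)
        model = toy_model(seed=3, n_blocks=2)
        E = rng.normal(size=(TOY["P"], 3))
        F = rng.uniform(0, 10, (TOY["P"], 4))
        J = rng.uniform(0, 90, (TOY["P"], 5))
        np.testing.assert_allclose(
            model.predict(E[None], F[None], J[None])[0],
            loop_forward(model, E, F, J), atol=1e-8,
        )


class TestSubcomputations:
    def test_zero_weights_give_zero_outputs(self):
        model = toy_model()
        for t in model.named_params().values():
            t.data[:] = 0.0
        E = np.ones((1, TOY["P"], 3))
        out = model.encode_emg(E)
        assert np.abs(out.data).max() == 0.0
        assert np.abs(model.predict(E, np.ones((1, TOY["P"], 4)),
                                    np.ones((1, TOY["P"], 5)))).max() == 0.0

    def test_shapes_follow_the_dimension_algebra(self):
        model = toy_model()
        B = 3
        E = np.zeros((B, TOY["P"], 3))
        F = np.zeros((B, TOY["P"], 4))
        J = np.zeros((B, TOY["P"], 5))
        e_prime = model.encode_emg(E)
        assert e_prime.shape == (B, TOY["P"], TOY["d_k"])
        q = model.project_query(J, F)
        assert q.shape == (B, TOY["P"], TOY["d_a"])
        z = model.fuse(q, model.W_k(e_prime), model.W_v(e_prime))
        assert z.shape == (B, TOY["P"], TOY["d_a"])
        out = model.predict(E, F, J)
        assert out.shape == (B, 5)

    @pytest.mark.parametrize("seed", range(5))
    def test_dimension_algebra_for_random_valid_configs(self, seed):
        rng = np.random.default_rng(seed)
        h = int(rng.integers(1, 5))
        cfg = dict(P=int(rng.integers(2, 8)), n_emg=3,
                   n_tactile=int(rng.integers(2, 10)), n_joint=5,
                   d_E=int(rng.integers(2, 12)), d_k=int(rng.integers(2, 12)),
                   d_q=int(rng.integers(2, 10)), d_a=h * int(rng.integers(1, 6)),
                   h=h, mlp_hidden=(int(rng.integers(4, 16)),), dropout=0.0)
        model = TkeBgc(ModelConfig(seed=seed, **cfg), rng)
        out = model.predict(
            rng.normal(size=(2, cfg["P"], 3)),
            rng.uniform(0, 10, (2, cfg["P"], cfg["n_tactile"])),
            rng.uniform(0, 90, (2, cfg["P"], 5)),
        )
        assert out.shape == (2, 5)

    def test_indivisible_head_width_rejected(self):
        with pytest.raises(DimensionError):
            ModelConfig(d_a=10, h=3)

    def test_wrong_history_shape_names_the_expectation(self):
        model = toy_model()
        with pytest.raises(DimensionError, match="P=4"):
            model.encode_emg(np.zeros((1, 7, 3)))


class TestLossAndIntegration:
    def test_loss_examples(self, rng):
        zeros = np.zeros((4, 5))
        assert float(loss_mse(zeros, zeros).data) == 0.0
        ones_diff = np.ones((3, 5))
        assert float(loss_mse(ones_diff, np.zeros((3, 5))).data) == pytest.approx(5.0)
        pred = rng.normal(size=(6, 5))
        target = rng.normal(size=(6, 5))
        manual = np.mean([sum((pred[n, j] - target[n, j]) ** 2 for j in range(5))
                          for n in range(6)])
        assert float(loss_mse(pred, target).data) == pytest.approx(manual, rel=1e-12)

    def test_loss_shape_mismatch(self):
        with pytest.raises(DimensionError):
            loss_mse(np.zeros((2, 5)), np.zeros((3, 5)))

    def test_batch_permutation_leaves_mean_loss_invariant(self, rng):
        pred = rng.normal(size=(8, 5))
        target = rng.normal(size=(8, 5))
        perm = rng.permutation(8)
        assert float(loss_mse(pred, target).data) == pytest.approx(
            float(loss_mse(pred[perm], target[perm]).data), rel=1e-12)

    def test_integrate_clamps_and_telescopes(self, rng):
        j = np.array([89.0, 10.0, 0.0, 50.0, 45.0])
        np.testing.assert_array_equal(integrate(j, np.zeros(5)), j)
        stepped = integrate(j, np.array([5.0, 0.0, -5.0, 1.0, 20.0]))
        np.testing.assert_allclose(stepped, [90.0, 10.0, 0.0, 51.0, 50.0])
        # telescoping when no clamp binds
        j = np.full(5, 45.0)
        deltas = rng.uniform(-1, 1, (10, 5))
        for d in deltas:
            j = integrate(j, d)
        np.testing.assert_allclose(j, 45.0 + deltas.sum(axis=0), atol=1e-12)


def _linear_policy_samples(rng, n, P=6):
    """Targets are a fixed linear read-out of the last tactile row."""
    A = rng.normal(size=(4, 5)) * 0.3
    out = []
    for i in range(n):
        e = rng.normal(size=(P, 3)) * 0.2
        f = rng.uniform(0, 10, (P, 4))
        j = rng.uniform(0, 90, (P, 5))
        out.append(WindowedSample(e, f, j, f[-1] @ A, ("trial", i % 8)))
    return out


class TestTraining:
    CFG = dict(P=6, n_emg=3, n_tactile=4, n_joint=5, d_E=8, d_k=12, d_q=6,
               d_a=12, h=2, mlp_hidden=(16,), dropout=0.0, epochs=15,
               lr=3e-3, batch=32)

    def test_same_seed_reproduces_loss_curves(self, rng):
        samples = _linear_policy_samples(rng, 160)
        runs = [train(samples[:128], samples[128:], ModelConfig(seed=5, **self.CFG))
                for _ in range(2)]
        assert runs[0][1]["train_loss"] == runs[1][1]["train_loss"]
        assert runs[0][1]["val_loss"] == runs[1][1]["val_loss"]

    def test_learns_a_linear_policy_but_not_shuffled_targets(self, rng):
        samples = _linear_policy_samples(rng, 400)
        tr, va = samples[:320], samples[320:]
        _, hist = train(tr, va, ModelConfig(seed=0, epochs=30, **{
            k: v for k, v in self.CFG.items() if k != "epochs"}))
        targets = np.stack([s.target_delta for s in va])
        variance = ((targets - targets.mean(axis=0)) ** 2).sum(axis=1).mean()
        assert min(hist["val_loss"]) < 0.5 * variance
        # negative control: shuffled targets carry no signal
        shuffled = [WindowedSample(s.emg_hist, s.tactile_hist, s.joint_hist,
                                   tr[(i * 17 + 5) % len(tr)].target_delta,
                                   s.source_trial) for i, s in enumerate(tr)]
        _, hist_neg = train(shuffled, va, ModelConfig(seed=0, epochs=10, **{
            k: v for k, v in self.CFG.items() if k != "epochs"}))
        assert min(hist_neg["val_loss"]) > 0.5 * variance

    def test_empty_training_set_rejected(self):
        with pytest.raises(TrainingError):
            train([], [], ModelConfig())


class TestPredictSequenceAndSerialization:
    def test_sequence_length_and_determinism(self, rng, trial_factory):
        model = toy_model(n_tactile=9)
        trial = trial_factory(rng, n_ticks=30)
        a = predict_sequence(trial, model)
        b = predict_sequence(trial, model)
        assert a.shape == (30 - TOY["P"], 5)
        np.testing.assert_array_equal(a, b)

    def test_archive_round_trip_preserves_predictions(self, rng, tmp_path, trial_factory):
        model = toy_model(n_tactile=9, seed=4)
        model.norm_joint.mean[:] = 45.0  # non-trivial stats must survive
        trial = trial_factory(rng, n_ticks=20)
        path = save_model(model, tmp_path / "model.tkebgc")
        back = load_model(path)
        E, F, J = trial.emg[None, :4], trial.tactile[None, :4], trial.joints[None, :4]
        E = np.repeat(E, 1, axis=0)
        np.testing.assert_array_equal(model.predict(E, F, J), back.predict(E, F, J))
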