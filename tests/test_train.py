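"""Optimizer algebra, loss, augmentation, freeze schedules and the fit
loop."""

import numpy as np
import pytest

from helpers import scalar_adam_oracle
from pulmocad.netarch import (
    build_network,
    default_multiscale_table,
    reduced_multiscale_table,
)
from pulmocad.train import (
    AdamHyper,
    AdamState,
    TrainConfig,
    adam_step,
    augment_six,
    fit,
    masked_cross_entropy,
    over_ratio,
    resolve_freeze_group,
    train_acc,
)


class TestAdam:
    def test_zero_gradient_fixed_point(self):
        state, delta = adam_step(AdamState(), 0.0)
        assert delta == 0.0
        assert state.t == 1

    def test_closed_form_at_t1(self):
        """Bias correction at t=1 makes m_hat = g, n_hat = g^2, so the first
        step is -eta * sign(g) up to eps."""
        hyper = AdamHyper()
        _, delta = adam_step(AdamState(), 2.0, hyper)
        assert delta == pytest.approx(-hyper.eta * 2.0 / (2.0 + hyper.eps), abs=1e-12)
        assert delta == pytest.approx(-0.01, abs=1e-6)

    def test_matches_scalar_oracle_over_100_steps(self):
        rng = np.random.default_rng(5)
        gs = rng.normal(size=100)
        oracle = scalar_adam_oracle(gs)
        state = AdamState()
        for g, expected in zip(gs, oracle):
            state, delta = adam_step(state, g)
            assert delta == pytest.approx(expected, abs=1e-10)

    def test_two_constant_steps_match_recurrence(self):
        oracle = scalar_adam_oracle([3.0, 3.0])
        state = AdamState()
        for expected in oracle:
            state, delta = adam_step(state, 3.0)
            assert delta == pytest.approx(expected, abs=1e-12)

    def test_bias_correction_identity_constant_gradient(self):
        """For constant g the corrected first moment equals g at every t."""
        hyper = AdamHyper()
        state = AdamState()
        for _ in range(50):
            state, _ = adam_step(state, 1.7, hyper)
            m_hat = state.m / (1 - hyper.mu**state.t)
            assert m_hat == pytest.approx(1.7, abs=1e-9)

    def test_vector_state_and_nonneg_second_moment(self):
        state, delta = adam_step(AdamState(), np.array([1.0, -2.0, 0.0]))
        assert np.all(np.asarray(state.n) >= 0)
        assert delta.shape == (3,)

    def test_nonfinite_gradient_errors(self):
        with pytest.raises(FloatingPointError):
            adam_step(AdamState(), np.nan)

    def test_hyper_validation(self):
        with pytest.raises(ValueError):
            AdamHyper(mu=1.0)
        with pytest.raises(ValueError):
            AdamHyper(eta=0.0)


class TestMaskedCrossEntropy:
    def test_near_perfect_prediction(self):
        t = np.array([0.0, 1.0, 1.0, 0.0])
        p = np.where(t > 0.5, 0.9999, 0.0001)
        assert masked_cross_entropy(p, t) < 0.001

    def test_uniform_half_is_ln2(self):
        p = np.full((4, 4), 0.5)
        t = (np.arange(16).reshape(4, 4) % 2).astype(float)
        assert masked_cross_entropy(p, t) == pytest.approx(np.log(2), abs=1e-9)

    def test_ignore_mask_equals_loop_oracle(self, rng):
        p = rng.uniform(0.05, 0.95, size=(5, 6))
        t = (rng.random((5, 6)) > 0.5).astype(float)
        ignore = rng.random((5, 6)) > 0.5
        total, n = 0.0, 0
        for i in range(5):
            for j in range(6):
                if not ignore[i, j]:
                    total += -(t[i, j] * np.log(p[i, j]) + (1 - t[i, j]) * np.log(1 - p[i, j]))
                    n += 1
        assert masked_cross_entropy(p, t, ignore) == pytest.approx(total / n, rel=1e-9)

    def test_all_ignored_errors(self):
        with pytest.raises(ValueError):
            masked_cross_entropy(np.full((2, 2), 0.5), np.zeros((2, 2)), np.ones((2, 2), bool))

    def test_tensor_path_matches_array_path(self, rng):
        from pulmocad._autograd import Tensor

        p = rng.uniform(0.1, 0.9, size=(3, 4)).astype(np.float32)
        t = (rng.random((3, 4)) > 0.5).astype(np.float32)
        plain = masked_cross_entropy(p.astype(float), t.astype(float))
        tensor = masked_cross_entropy(Tensor(p), t)
        assert float(tensor.data) == pytest.approx(plain, rel=1e-5)


class TestAugmentation:
    def test_six_per_input(self, rng):
        items = [rng.normal(size=(3, 8, 8)) for _ in range(7)]
        assert len(augment_six(items)) == 42

    def test_asymmetric_image_gives_distinct_outputs(self):
        img = np.zeros((1, 4, 4))
        img[0, 0, 1] = 1.0
        img[0, 1, 3] = 2.0
        outs = augment_six([img])
        flat = {o.tobytes() for o in outs}
        assert len(flat) == 6

    def test_rot180_is_flip_composition(self, rng):
        img = rng.normal(size=(2, 6, 6))
        outs = augment_six([img])
        rot180 = outs[4]
        both_flips = outs[1][..., ::-1, :]  # vflip of the hflip
        assert np.array_equal(rot180, both_flips)

    def test_labels_transform_identically(self, rng):
        img = rng.normal(size=(2, 6, 6))
        lab = (rng.random((2, 6, 6)) > 0.7).astype(np.uint8)
        outs = augment_six([(img, lab)])
        for oi, ol in outs:
            assert ol.sum() == lab.sum()  # volume preserved
        # the transform applied to image and label is the same one
        assert np.array_equal(outs[3][0], np.rot90(img, 1, axes=(-2, -1)))
        assert np.array_equal(outs[3][1], np.rot90(lab, 1, axes=(-2, -1)))

    def test_non_square_rejected(self, rng):
        with pytest.raises(ValueError, match="square"):
            augment_six([rng.normal(size=(2, 4, 6))])


class TestMetricsAlgebra:
    def test_train_acc_cases(self):
        assert train_acc(850, 1000) == 0.85
        assert train_acc(0, 5) == 0.0
        assert train_acc(5, 5) == 1.0
        with pytest.raises(ValueError):
            train_acc(1, 0)
        with pytest.raises(ValueError):
            train_acc(6, 5)

    def test_over_ratio_reference_pair(self):
        """The 93.48% training accuracy with overfitting ratio 1.071 pair."""
        assert over_ratio(0.9348, 0.8728) == pytest.approx(1.0710, abs=0.0005)

    def test_over_ratio_directions(self):
        assert over_ratio(0.9, 0.9) == 1.0
        assert over_ratio(0.8, 0.9) == pytest.approx(0.889, abs=0.001)
        with pytest.raises(ValueError):
            over_ratio(0.5, 0.0)


class TestFreezeGroups:
    def test_up12_span_is_head_only(self):
        table = default_multiscale_table()
        names = resolve_freeze_group(table, "Up12")
        assert names == {"Up12pre", "Up12", "Out1", "Out"}

    def test_full_span_is_every_layer(self):
        table = default_multiscale_table()
        names = resolve_freeze_group(table, "convl-Up12")  # variant spelling
        assert names == {l.name for l in table.layers}

    def test_decoder_segment(self):
        table = default_multiscale_table()
        names = resolve_freeze_group(table, "Up6-Up8")
        assert "Up6pre" in names and "Conv6" in names and "Conv8" in names
        assert "Conv5" not in names and "Up9" not in names

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown freeze group"):
            resolve_freeze_group(default_multiscale_table(), "conv9")


def _tiny_dataset(rng, n=8, shape=(2, 16, 16)):
    """Blob-segmentation toy data for smoke training."""
    data = []
    for _ in range(n):
        lab = np.zeros(shape, dtype=np.float32)
        cy, cx = rng.integers(4, 12, size=2)
        lab[:, cy - 2 : cy + 2, cx - 2 : cx + 2] = 1.0
        img = lab * 2.0 + rng.normal(0, 0.1, size=shape).astype(np.float32)
        data.append((img, lab))
    return data


class TestFit:
    def test_loss_decreases_on_toy_problem(self, rng):
        net = build_network(reduced_multiscale_table(), mode="3d", seed=0)
        data = _tiny_dataset(rng)
        cfg = TrainConfig(lr=0.003, dropout=0.0, batch_size=2, max_steps=40,
                          eval_every=0, seed=0)
        _, m = fit(net, data, cfg, optimizer="adam")
        assert np.mean(m.loss_history[-5:]) < np.mean(m.loss_history[:5])

    def test_deterministic_given_seed(self, rng):
        data = _tiny_dataset(rng)
        hists = []
        for _ in range(2):
            net = build_network(reduced_multiscale_table(), mode="3d", seed=7)
            cfg = TrainConfig(lr=0.001, dropout=0.0, batch_size=2, max_steps=10,
                              eval_every=0, seed=7)
            _, m = fit(net, data, cfg, optimizer="adam")
            hists.append(m.loss_history)
        assert hists[0] == hists[1]

    def test_freeze_group_keeps_parameters_bit_identical(self, rng):
        net = build_network(reduced_multiscale_table(), mode="3d", seed=1)
        frozen_names = (
            {l.name for l in net.table.layers}
            - resolve_freeze_group(net.table, "Up12")
        )
        before = {
            i: p.data.copy()
            for i, (name, p) in enumerate(net.named_params())
            if name in frozen_names
        }
        data = _tiny_dataset(rng)
        cfg = TrainConfig(lr=0.01, dropout=0.0, batch_size=2, max_steps=8,
                          eval_every=0, freeze_group="Up12", seed=1)
        _, m = fit(net, data, cfg, optimizer="sgd")
        after = list(net.named_params())
        for i, original in before.items():
            assert np.array_equal(after[i][1].data, original)
        # trainable head did move
        head = [p for name, p in after if name == "Out1"][0]
        assert not np.allclose(head.data, 0.0) or m.loss_history[0] != m.loss_history[-1]

    def test_checkpoint_written_and_restorable(self, rng, tmp_path):
        net = build_network(reduced_multiscale_table(), mode="3d", seed=2)
        data = _tiny_dataset(rng, n=4)
        cfg = TrainConfig(lr=0.001, dropout=0.0, batch_size=2, max_steps=6,
                          checkpoint_every=3, eval_every=0, seed=2,
                          checkpoint_dir=str(tmp_path))
        _, m = fit(net, data, cfg)
        assert [s for s, _ in m.checkpoints] == [3, 6]
        assert (tmp_path / "step00000003.npz").exists()
        assert (tmp_path / "step00000006.json").exists()
        from pulmocad.train import load_checkpoint

        fresh = build_network(reduced_multiscale_table(), mode="3d", seed=99)
        load_checkpoint(fresh, str(tmp_path / "step00000006.npz"))
        for (_, a), (_, b) in zip(fresh.named_params(), net.named_params()):
            assert np.array_equal(a.data, b.data)

    def test_empty_dataset_rejected(self):
        net = build_network(reduced_multiscale_table(), mode="3d")
        with pytest.raises(ValueError):
            fit(net, [], TrainConfig(max_steps=1))

    def test_dropout_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(dropout=1.5)
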