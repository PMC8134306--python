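"""Architectures, training protocol and MC-dropout prediction."""

import numpy as np
import pytest

from seegbend import models as md
from seegbend import nn


class TestArchitectures:
    def test_hcf_output_shape_and_param_count(self):
        net = md.build_hcf_model(seed=0)
        out = net.forward({"features": np.zeros((7, 96))})
        assert out.shape == (7, 3)
        # dense 96->5 (485) + PReLU (1) + 3 x [dense 5->5 (30) + PReLU (1)]
        # + dense 5->3 (18)
        assert net.n_parameters() == 485 + 1 + 3 * 31 + 18

    def test_same_seed_identical_initialization(self):
        a, b = md.build_hcf_model(seed=4), md.build_hcf_model(seed=4)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)
        c = md.build_hcf_model(seed=5)
        assert any(
            not np.array_equal(pa.value, pc.value)
            for pa, pc in zip(a.params(), c.params())
        )

    def test_e2e_pooled_branch_size(self):
        net = md.build_e2e_model(conv_channels=8, seed=0)
        win = np.zeros((2, 1, 9, 9, 9))
        flat = net.img_branch.forward(win)
        assert flat.shape == (2, 8 * 4**3)

    def test_e2e_forward_on_zero_window_is_finite_3vector(self):
        net = md.build_e2e_model(seed=1)
        out = net.forward({"direction": np.array([[0.0, 0.0, 1.0]]),
                           "window": np.zeros((1, 9, 9, 9))})
        assert out.shape == (1, 3)
        assert np.all(np.isfinite(out))

    def test_e2e_final_layer_width_is_three(self):
        net = md.build_e2e_model(seed=0)
        assert net.head.layers[-1].W.value.shape[1] == 3

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            md.build_e2e_model(conv_channels=0)
        with pytest.raises(ValueError):
            md.TrainConfig(label_kind="gu")
        with pytest.raises(ValueError):
            md.MCConfig(n_passes=0)


class TestTraining:
    def test_memorizes_constant_labels(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((64, 96))
        y = np.tile([0.1, -0.2, 0.3], (64, 1))
        ds = {"inputs": {"features": X}, "y": y}
        net = md.build_hcf_model(seed=0)
        cfg = md.TrainConfig(epochs=200, seed=0, batch_size=16)
        net, hist = md.train_model(net, ds, ds, cfg)
        assert hist.attrs["best_val_loss"] <= 1e-4

    def test_learning_rate_drops_tenfold_on_plateau(self):
        # an immediately-solved problem: the loss reaches its floor and
        # stays there, so the plateau rule must fire
        ds = {"inputs": {"features": np.zeros((32, 96))},
              "y": np.zeros((32, 3))}
        net = md.build_hcf_model(seed=1)
        cfg = md.TrainConfig(epochs=120, seed=1)
        net, hist = md.train_model(net, ds, ds, cfg)
        drops = hist.attrs["lr_drop_epochs"]
        assert drops, "expected at least one plateau-triggered drop"
        first = drops[0]
        before = hist.loc[hist.epoch == first - 1, "lr"].iloc[0]
        after = hist.loc[hist.epoch == first, "lr"].iloc[0]
        assert after == pytest.approx(before / 10)

    def test_recovers_linear_map_within_noise_budget(self):
        # identifiable toy: low-rank linear map + noise; the held-out MSE
        # must come within a small factor of the injected noise floor
        # (predicting zero would score ~0.08, far above the budget)
        noise_sd = 0.05
        rng = np.random.default_rng(7)
        X_all = rng.standard_normal((500, 96))
        u = rng.standard_normal((96, 2)) / np.sqrt(96)
        v = rng.standard_normal((2, 3)) * 0.2
        y_all = X_all @ u @ v + rng.normal(0, noise_sd, (500, 3))
        train = {"inputs": {"features": X_all[:350]}, "y": y_all[:350]}
        val = {"inputs": {"features": X_all[350:420]}, "y": y_all[350:420]}
        held = {"inputs": {"features": X_all[420:]}, "y": y_all[420:]}
        net = md.build_hcf_model(seed=3)
        cfg = md.TrainConfig(epochs=200, seed=3, batch_size=16)
        net, _ = md.train_model(net, train, val, cfg)
        pred = net.forward(held["inputs"])
        mse = float(np.mean((pred - held["y"]) ** 2))
        assert mse <= 10 * noise_sd**2
        assert mse < float(np.mean(held["y"] ** 2))  # beats the zero map

    def test_empty_dataset_rejected(self):
        net = md.build_hcf_model(seed=0)
        empty = {"inputs": {"features": np.zeros((0, 96))},
                 "y": np.zeros((0, 3))}
        full = {"inputs": {"features": np.zeros((4, 96))},
                "y": np.zeros((4, 3))}
        with pytest.raises(ValueError):
            md.train_model(net, empty, full, md.TrainConfig())

    def test_loss_matches_hand_convention(self):
        rng = np.random.default_rng(4)
        pred = rng.standard_normal((10, 3))
        y = rng.standard_normal((10, 3))
        loss, _ = nn.mse_loss(pred, y)
        hand = np.sum(np.linalg.norm(pred - y, axis=1) ** 2) / (10 * 3)
        assert loss == pytest.approx(hand, abs=1e-12)


class TestPredict:
    def make_net(self):
        return md.build_e2e_model(seed=5)

    def inputs(self, n=1):
        rng = np.random.default_rng(6)
        return {"direction": np.tile([0.0, 0.0, 1.0], (n, 1)),
                "window": rng.random((n, 9, 9, 9))}

    def test_mc_with_p_zero_equals_direct_exactly(self):
        net = self.make_net()
        x = self.inputs()
        direct = md.predict(net, x, mode="direct")
        mc = md.predict(net, x, mode="mc",
                        mc_cfg=md.MCConfig(dropout_p=0.0, n_passes=5, seed=0))
        np.testing.assert_allclose(mc.mean, direct.mean, atol=1e-15)
        np.testing.assert_allclose(mc.variance, np.zeros(3), atol=1e-30)
        assert direct.variance is None

    def test_mc_reproducible_per_seed(self):
        net = self.make_net()
        x = self.inputs()
        cfg = md.MCConfig(n_passes=20, seed=3)
        a = md.predict(net, x, mode="mc", mc_cfg=cfg)
        b = md.predict(net, x, mode="mc", mc_cfg=cfg)
        np.testing.assert_array_equal(a.mean, b.mean)
        c = md.predict(net, x, mode="mc", mc_cfg=md.MCConfig(n_passes=20, seed=4))
        assert not np.array_equal(a.mean, c.mean)

    def test_mc_mean_sd_shrinks_like_inverse_sqrt_T(self):
        net = self.make_net()
        x = self.inputs()
        sds = {}
        for T in (10, 50, 200):
            means = [
                md.predict(net, x, mode="mc",
                           mc_cfg=md.MCConfig(n_passes=T, seed=s)).mean
                for s in range(30)
            ]
            sds[T] = np.linalg.norm(np.std(means, axis=0))
        assert sds[10] > sds[50] > sds[200]
        # expected ratios sqrt(5) ~ 2.24 and sqrt(20) ~ 4.47
        assert 1.4 < sds[10] / sds[50] < 3.6
        assert 2.8 < sds[10] / sds[200] < 7.2

    def test_dropout_restored_after_mc(self):
        net = self.make_net()
        p0 = net.dropout_p()
        md.predict(net, self.inputs(), mode="mc",
                   mc_cfg=md.MCConfig(dropout_p=0.42, n_passes=2, seed=0))
        assert net.dropout_p() == p0


class TestCheckpoint:
    @pytest.mark.parametrize("family", ["hcf", "e2e"])
    def test_save_load_reproduces_predictions(self, tmp_path, family):
        rng = np.random.default_rng(8)
        if family == "hcf":
            net = md.build_hcf_model(seed=9)
            x = {"features": rng.standard_normal((3, 96))}
        else:
            net = md.build_e2e_model(seed=9)
            x = {"direction": rng.standard_normal((3, 3)),
                 "window": rng.random((3, 9, 9, 9))}
        tm = md.TrainedModel(net=net, label_kind="lu", family=family,
                             source="tissue", train_config=md.TrainConfig())
        path = tmp_path / "model.npz"
        tm.save(path)
        clone = md.TrainedModel.load(path)
        np.testing.assert_allclose(clone.predict(x).mean, tm.predict(x).mean,
                                   atol=1e-12)
        assert clone.label_kind == "lu" and clone.family == family
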