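"""Network building, parameter accounting, training, and activation probes."""

import numpy as np
import pytest

import neuroplast as npl
from neuroplast._engine import (
    BatchNorm2d,
    Conv2d,
    Dense,
    MaxPool2d,
    softmax_cross_entropy,
)


class TestBuildAndCount:
    def test_vgg19_bn_parameter_total_matches_hand_accounting(self):
        """The 32x32 VGG19-BN variant totals 20.04M parameters."""
        net = npl.build_network(npl.NetworkSpec.vgg19_bn(), seed=0)
        acct = npl.count_parameters(net)
        assert acct.total == 20_040_522
        assert round(acct.total / 1e6, 2) == 20.04
        # conv weights alone, by the layer-wise product formula
        assert acct.total_eligible == 20_018_880 + 512 * 10

    def test_toy_conv_eligible_count(self):
        spec = npl.NetworkSpec(
            blocks=(npl.ConvBlock(4, kernel_size=3, batch_norm=False, pool=True),),
            hidden=(), n_classes=2, input_shape=(3, 4, 4),
        )
        net = npl.build_network(spec, seed=0)
        acct = npl.count_parameters(net)
        assert acct.eligible["conv1.W"] == 3 * 4 * 3 * 3 == 108
        assert acct.ineligible["conv1.b"] == 4

    def test_counts_agree_with_brute_force_enumeration(self, trained_tiny_net):
        acct = npl.count_parameters(trained_tiny_net)
        brute_eligible = sum(
            l.params["W"].size for l in trained_tiny_net.layers if l.has_weight
        )
        brute_total = sum(
            p.size for l in trained_tiny_net.layers for p in l.params.values()
        )
        assert acct.total_eligible == brute_eligible
        assert acct.total == brute_total
        assert npl.count_parameters(trained_tiny_net, policy="all").total_eligible \
            == brute_total

    def test_build_deterministic_given_seed(self, tiny_net_spec):
        a = npl.build_network(tiny_net_spec, seed=7)
        b = npl.build_network(tiny_net_spec, seed=7)
        c = npl.build_network(tiny_net_spec, seed=8)
        for la, lb, lc in zip(a.layers, b.layers, c.layers):
            for k in la.params:
                assert np.array_equal(la.params[k], lb.params[k])
        assert not np.array_equal(a["conv1"].params["W"], c["conv1"].params["W"])

    def test_shape_inconsistent_spec_rejected_with_layer_index(self):
        # 15x15 input cannot be pooled
        spec = npl.NetworkSpec(blocks=(npl.ConvBlock(4, pool=True),),
                               hidden=(), n_classes=2, input_shape=(3, 15, 15))
        with pytest.raises(ValueError, match=r"layer \d+"):
            npl.build_network(spec, seed=0)

    def test_spec_yaml_roundtrip(self, tmp_path, tiny_net_spec):
        path = tiny_net_spec.to_yaml(tmp_path / "spec.yaml")
        assert npl.NetworkSpec.from_yaml(path) == tiny_net_spec


class TestTraining:
    def test_zero_epochs_is_identity(self, tiny_net_spec, tiny_dataset):
        net = npl.build_network(tiny_net_spec, seed=1)
        before = net.state_dict()
        history = npl.train(net, tiny_dataset.train,
                            npl.TrainingConfig(epochs=0, seed=0))
        assert history == []
        for lname, lstate in net.state_dict().items():
            for k, v in lstate.items():
                assert np.array_equal(v, before[lname][k])

    def test_learnable_above_criterion(self, trained_tiny_net, tiny_dataset):
        acc = npl.evaluate_accuracy(trained_tiny_net, tiny_dataset.test)
        assert acc > 1 / 4  # above chance after a few epochs

    def test_full_mask_trains_to_chance(self, tiny_net_spec, tiny_dataset):
        net = npl.build_network(tiny_net_spec, seed=2)
        mask = npl.AblationMask.empty_for(net)
        for m in mask.masks.values():
            m[...] = True
        npl.apply_mask(net, mask)
        npl.train(net, tiny_dataset.train, npl.TrainingConfig(epochs=1, seed=0),
                  mask=mask)
        acc = npl.evaluate_accuracy(net, tiny_dataset.test)
        assert acc == pytest.approx(1 / 4)  # constant output on balanced classes

    def test_empty_dataset_rejected(self, trained_tiny_net):
        empty = npl.ImageSet(np.empty((0, 3, 16, 16), dtype=np.float32),
                             np.empty(0, dtype=np.int64), 4)
        with pytest.raises(ValueError):
            npl.train(trained_tiny_net.copy(), empty, npl.TrainingConfig(epochs=1))
        with pytest.raises(ValueError):
            npl.evaluate_accuracy(trained_tiny_net, empty)

    def test_untrained_accuracy_near_chance(self, tiny_net_spec, tiny_dataset):
        accs = [
            npl.evaluate_accuracy(npl.build_network(tiny_net_spec, seed=s),
                                  tiny_dataset.test)
            for s in range(6)
        ]
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 1 / 4) <= 3 * max(se, 0.02)


class TestEvaluateAccuracy:
    def test_label_out_of_range_rejected(self, trained_tiny_net, tiny_dataset):
        bad = npl.ImageSet(tiny_dataset.test.images[:4],
                           np.array([0, 1, 2, 7]), 4)
        with pytest.raises(ValueError, match="class range"):
            npl.evaluate_accuracy(trained_tiny_net, bad)

    def test_exact_fraction_by_enumeration(self, trained_tiny_net, tiny_dataset):
        """Accuracy equals the brute-force count of argmax matches."""
        images = tiny_dataset.test.images[:3]
        logits = trained_tiny_net.forward(images, training=False)
        preds = logits.argmax(axis=1)
        for forced in range(4):
            labels = np.full(3, forced)
            expected = float((preds == forced).sum()) / 3
            got = npl.evaluate_accuracy(trained_tiny_net, (images, labels))
            assert got == pytest.approx(expected)

    def test_perfect_oracle_labels_give_one(self, trained_tiny_net, tiny_dataset):
        images = tiny_dataset.test.images[:16]
        preds = trained_tiny_net.forward(images, training=False).argmax(axis=1)
        assert npl.evaluate_accuracy(trained_tiny_net, (images, preds)) == 1.0


class TestActivations:
    def test_duplicate_stimulus_rows_identical(self, trained_tiny_net, tiny_dataset):
        img = tiny_dataset.test.images[:1]
        batch = np.concatenate([img, img])
        acts = npl.extract_activations(trained_tiny_net, batch, "penultimate")
        assert np.array_equal(acts.values[0], acts.values[1])

    def test_unknown_layer_rejected_with_names(self, trained_tiny_net, tiny_dataset):
        with pytest.raises(ValueError, match="conv1"):
            npl.extract_activations(trained_tiny_net, tiny_dataset.test.images[:2],
                                    "nonexistent")

    def test_hand_convolution_oracle(self):
        """1-conv toy net on a 2x2 input matches a hand-computed convolution."""
        spec = npl.NetworkSpec(
            blocks=(npl.ConvBlock(1, kernel_size=2, padding=0, batch_norm=False),),
            hidden=(), n_classes=2, input_shape=(1, 2, 2),
        )
        net = npl.build_network(spec, seed=0)
        w = np.array([[[[1.0, -2.0], [0.5, 3.0]]]], dtype=np.float32)
        net["conv1"].params["W"][...] = w
        net["conv1"].params["b"][...] = 0.25
        x = np.array([[[[1.0, 2.0], [3.0, 4.0]]]], dtype=np.float32)
        acts = npl.extract_activations(net, x, "conv1")
        hand = 1 * 1 + 2 * -2 + 3 * 0.5 + 4 * 3 + 0.25
        assert acts.values[0, 0] == pytest.approx(hand)

    def test_zero_weight_network_gives_zero_preact(self, tiny_net_spec, tiny_dataset):
        net = npl.build_network(tiny_net_spec, seed=0)
        net["conv1"].params["W"][...] = 0.0
        net["conv1"].params["b"][...] = 0.0
        acts = npl.extract_activations(net, tiny_dataset.test.images[:3], "conv1")
        assert np.all(acts.values == 0.0)

    def test_hdf5_roundtrip(self, tmp_path, trained_tiny_net, tiny_dataset):
        acts = npl.extract_activations(trained_tiny_net, tiny_dataset.test.images[:5],
                                       "penultimate",
                                       labels=tiny_dataset.test.labels[:5])
        path = acts.to_hdf5(tmp_path / "acts.h5")
        loaded = npl.ActivationMatrix.from_hdf5(path)
        assert np.allclose(loaded.values, acts.values)
        assert loaded.layer_name == acts.layer_name
        assert np.array_equal(loaded.labels, acts.labels)


def _numerical_grad(f, x, eps=1e-5):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


class TestBackwardPasses:
    """Analytic gradients vs central finite differences (float64)."""

    @pytest.mark.parametrize("layer_factory,in_shape", [
        (lambda rng: Conv2d("c", 2, 3, kernel_size=3, padding=1, rng=rng,
                            dtype=np.float64), (2, 4, 4)),
        (lambda rng: Dense("d", 6, 4, rng=rng, dtype=np.float64), (6,)),
        (lambda rng: BatchNorm2d("b", 2, dtype=np.float64), (2, 4, 4)),
        (lambda rng: MaxPool2d("p"), (2, 4, 4)),
    ])
    def test_gradient_check(self, layer_factory, in_shape, rng):
        layer = layer_factory(rng)
        x = rng.normal(size=(3, *in_shape))
        target = rng.normal(size=(3, *layer.output_shape(in_shape)))

        def loss():
            return 0.5 * np.sum((layer.forward(x, training=True) - target) ** 2)

        out = layer.forward(x, training=True)
        dx = layer.backward(out - target)
        num_dx = _numerical_grad(loss, x)
        assert np.allclose(dx, num_dx, atol=1e-6), type(layer).__name__
        for key in layer.params:
            layer.forward(x, training=True)
            layer.backward(out - target)
            num = _numerical_grad(loss, layer.params[key])
            assert np.allclose(layer.grads[key], num, atol=1e-6), key

    def test_softmax_cross_entropy_gradient(self, rng):
        logits = rng.normal(size=(5, 4))
        labels = rng.integers(0, 4, size=5)

        def loss():
            return softmax_cross_entropy(logits, labels)[0]

        _, dlogits, _ = softmax_cross_entropy(logits, labels)
        num = _numerical_grad(loss, logits)
        assert np.allclose(dlogits, num, atol=1e-7)
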