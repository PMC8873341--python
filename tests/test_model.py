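"""Shape arithmetic, parameter counting, and the trainable network handle."""

import numpy as np
import pytest

from fnirs_transfer.exceptions import ShapeError, TrainingError, ValidationError
from fnirs_transfer.model import (
    CnnSpec,
    LayerSpec,
    build_network,
    conv_output_size,
    layer_param_count,
    validate_spec,
)
from fnirs_transfer._network import GROUPS, Network, examples_to_input


def sliding_positions(n, f, stride):
    """Brute-force oracle: count filter placements by enumeration."""
    count = 0
    pos = 0
    while pos + f <= n:
        count += 1
        pos += stride
    return count


class TestConvOutputSize:
    @pytest.mark.parametrize(
        "n,f,stride,expected", [(5, 3, 1, 3), (4, 4, 1, 1), (7, 3, 2, 3)]
    )
    def test_direct_evaluation(self, n, f, stride, expected):
        assert conv_output_size(n, f, stride) == expected

    def test_rejects_non_integer_tiling(self):
        with pytest.raises(ShapeError):
            conv_output_size(6, 3, 2)  # (6-3)/2 not integral

    def test_rejects_oversized_filter(self):
        with pytest.raises(ShapeError):
            conv_output_size(3, 5, 1)

    def test_matches_enumeration_oracle(self):
        """Exact agreement with brute-force placement counting, N <= 12."""
        for n in range(1, 13):
            for f in range(1, n + 1):
                for stride in range(1, 5):
                    if (n - f) % stride == 0:
                        assert conv_output_size(n, f, stride) == sliding_positions(n, f, stride)


class TestLayerParamCount:
    def test_depth_free_convention(self):
        assert layer_param_count(3, 3, 8, mode="paper") == 80

    def test_standard_convention_includes_depth(self):
        assert layer_param_count(3, 3, 8, input_depth=2, mode="standard") == 152

    def test_unit_filter_identity_case(self):
        assert layer_param_count(1, 1, 1, 1, "paper") == 2
        assert layer_param_count(1, 1, 1, 1, "standard") == 2

    def test_invalid_mode(self):
        with pytest.raises(ValidationError):
            layer_param_count(1, 1, 1, mode="other")


class TestValidateSpec:
    def test_default_spec_hand_propagated_shapes(self):
        """Sliding-filter arithmetic through the full-size architecture."""
        report = validate_spec(CnnSpec.default())
        shapes = {r["name"]: r["output_shape"] for r in report.rows}
        assert shapes["conv1"] == (34, 96, 16)  # (36-3)+1, (100-5)+1
        assert shapes["conv2"] == (32, 92, 32)
        assert shapes["maxpool"] == (16, 46, 32)
        assert shapes["flatten"] == (16 * 46 * 32,)
        assert shapes["dense"] == (64,)
        assert shapes["output"] == (3,)

    def test_totals_are_sums_of_rows(self):
        report = validate_spec(CnnSpec.reduced())
        assert report.total_params_standard == sum(r["params_standard"] for r in report.rows)
        assert report.total_params_paper == sum(r["params_paper"] for r in report.rows)
        # depth-free convention counts fewer parameters on conv layers
        assert report.total_params_paper < report.total_params_standard

    def test_shape_error_carries_layer_index(self):
        spec = CnnSpec(
            layers=(
                LayerSpec("conv", filters=4, size=(3, 4), stride=(1, 2)),
                LayerSpec("conv", filters=6, size=(30, 3), stride=(1, 1)),  # too tall
                LayerSpec("maxpool", size=(2, 2), stride=(2, 2)),
                LayerSpec("flatten"),
                LayerSpec("dense", units=8),
                LayerSpec("output", units=3),
            ),
            input_shape=(12, 2, 30),
        )
        with pytest.raises(ShapeError) as err:
            validate_spec(spec)
        assert err.value.layer_index == 1

    def test_topology_is_enforced(self):
        with pytest.raises(ValidationError):
            CnnSpec(
                layers=(LayerSpec("dense", units=4), LayerSpec("output", units=3)),
                input_shape=(12, 2, 30),
            )

    def test_json_round_trip(self, tiny_spec):
        again = CnnSpec.from_json(tiny_spec.to_json())
        assert again == tiny_spec


class TestNetwork:
    def test_seeded_initialization_reproducible(self, tiny_spec):
        a = build_network(tiny_spec, rng_seed=3)
        b = build_network(tiny_spec, rng_seed=3)
        assert a.param_hashes() == b.param_hashes()
        c = build_network(tiny_spec, rng_seed=4)
        assert c.param_hashes() != a.param_hashes()

    def test_forward_is_a_probability_vector(self, tiny_spec):
        net = build_network(tiny_spec, rng_seed=0)
        X = np.random.default_rng(0).normal(size=(5, 12, 2, 30))
        p = net.predict_proba(X)
        assert p.shape == (5, 3)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_handle_param_count_matches_standard_mode(self, tiny_spec):
        net = build_network(tiny_spec, rng_seed=0)
        assert net.count_params() == validate_spec(tiny_spec).total_params_standard

    def test_training_reduces_loss_on_separable_data(self, tiny_spec, toy_epochs):
        net = build_network(tiny_spec, rng_seed=0)
        log = net.train(toy_epochs.X, toy_epochs.y, epochs=25, seed=1, lr=1e-3)
        assert log[-1] < log[0] * 0.5
        acc = np.mean(net.predict(toy_epochs.X) == toy_epochs.y)
        assert acc > 0.9

    def test_training_is_deterministic(self, tiny_spec, toy_epochs):
        hashes = []
        for _ in range(2):
            net = build_network(tiny_spec, rng_seed=0)
            net.train(toy_epochs.X, toy_epochs.y, epochs=3, seed=5)
            hashes.append(net.param_hashes())
        assert hashes[0] == hashes[1]

    def test_zero_epochs_is_a_no_op(self, tiny_spec, toy_epochs):
        net = build_network(tiny_spec, rng_seed=0)
        before = net.param_hashes()
        log = net.train(toy_epochs.X, toy_epochs.y, epochs=0, seed=1)
        assert log == []
        assert net.param_hashes() == before

    def test_all_frozen_training_rejected(self, tiny_spec, toy_epochs):
        net = build_network(tiny_spec, rng_seed=0)
        for g in GROUPS:
            net.trainable[g] = False
        with pytest.raises(TrainingError):
            net.train(toy_epochs.X, toy_epochs.y, epochs=1, seed=1)

    def test_backprop_matches_numerical_gradients(self, tiny_spec):
        """Analytic gradients agree with central differences (float64)."""
        net = Network(tiny_spec, rng_seed=1, dtype=np.float64)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 12, 2, 30))
        y = rng.integers(0, 3, size=4)
        onehot = np.eye(3)[y]
        x = examples_to_input(X, dtype=np.float64)

        def loss():
            p = net._forward(x)
            return -np.mean(np.log(np.sum(p * onehot, axis=1) + 1e-12))

        probs, cache = net._forward(x, want_cache=True)
        grads = net._backward(x, onehot, cache, probs)
        eps = 1e-6
        for g in GROUPS:
            arr = net.params[g]["W"]
            flat = arr.ravel()
            for i in rng.choice(arr.size, size=min(6, arr.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss()
                flat[i] = orig - eps
                lm = loss()
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[g]["W"].ravel()[i]
                assert abs(num - ana) <= 1e-5 * max(1.0, abs(num)), f"group {g}"
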