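"""Architecture: shape-inference oracle vs. the published layer table,
conformance of the built network, parameter counting, forward contracts."""

import numpy as np
import pytest

from fus2net import (
    Fus2NetConfig,
    LayerSpec,
    TensorShape,
    build_fus2net,
    conformance_check,
    forward,
    infer_shape,
    reference_table,
)

S = TensorShape


@pytest.fixture(scope="module")
def table():
    return reference_table()


@pytest.fixture(scope="module")
def model299():
    return build_fus2net(Fus2NetConfig(seed=0))


@pytest.fixture(scope="module")
def small_model():
    return build_fus2net(Fus2NetConfig(input_size=48, seed=1))


# ------------------------------------------------------------ infer_shape


@pytest.mark.parametrize(
    "spec,ins,expected",
    [
        (LayerSpec("c", "conv", (3, 3), (2, 2), "valid", 32, ["i"]),
         [S(299, 299, 3)], S(149, 149, 32)),
        (LayerSpec("c", "conv", (3, 3), (1, 1), "valid", 96, ["i"]),
         [S(73, 73, 64)], S(71, 71, 96)),
        (LayerSpec("c", "conv", (1, 1), (1, 1), "same", 13, ["i"]),
         [S(50, 41, 7)], S(50, 41, 13)),
        (LayerSpec("p", "maxpool", (3, 3), (2, 2), "valid", None, ["i"]),
         [S(147, 147, 64)], S(73, 73, 64)),
        (LayerSpec("p", "avgpool", (3, 3), (2, 2), "valid", None, ["i"]),
         [S(71, 71, 192)], S(35, 35, 192)),
        (LayerSpec("k", "concat", inputs=["a", "b"]),
         [S(35, 35, 192), S(35, 35, 192)], S(35, 35, 384)),
        (LayerSpec("a", "add", inputs=["x", "y"]),
         [S(35, 35, 384), S(35, 35, 384)], S(35, 35, 384)),
    ],
)
def test_infer_shape_examples(spec, ins, expected):
    assert infer_shape(spec, ins) == expected


def test_infer_shape_rejects_inconsistent_fusion():
    with pytest.raises(ValueError):
        infer_shape(LayerSpec("k", "concat", inputs=["a", "b"]),
                    [S(35, 35, 192), S(36, 36, 192)])
    with pytest.raises(ValueError):
        infer_shape(LayerSpec("a", "add", inputs=["x", "y"]),
                    [S(35, 35, 384), S(35, 35, 128)])


def test_oracle_reproduces_every_table_row(table):
    """Propagating infer_shape along the table reproduces all 27 printed
    output shapes exactly."""
    assert len(table) == 27
    shapes = {}
    for row in table:
        if row.spec.kind == "input":
            shapes[row.spec.name] = row.expected_out
            continue
        out = infer_shape(row.spec, [shapes[s] for s in row.spec.inputs])
        assert out == row.expected_out, row.spec.name
        assert [shapes[s] for s in row.spec.inputs] == row.expected_in
        shapes[row.spec.name] = out


def test_table_key_rows(table):
    assert table.row("Conv2d_1").expected_out == S(149, 149, 32)
    assert table.row("Conv2d_1").spec.filter_size == (3, 3)
    assert table.row("Conv2d_1").spec.stride == (2, 2)
    assert table.row("Concatenate_3").expected_out.channels == 384
    add_row = table.row("Add")
    assert add_row.expected_out == S(35, 35, 384)
    assert all(s == add_row.expected_out for s in add_row.expected_in)


def test_concat_channels_conserved(table):
    for row in table:
        if row.spec.kind == "concat":
            assert row.expected_out.channels == sum(
                s.channels for s in row.expected_in
            )


# ------------------------------------------------------------ built model


def test_built_model_conforms_to_table(model299, table):
    report = conformance_check(model299, table)
    assert report.passed
    assert len(report.outcomes) == 27
    assert not report.mismatches


def test_stem_shapes_and_conv1_param_count(model299):
    reg = model299.registry
    assert reg["Conv2d_1"].get("out_shape") == S(149, 149, 32)
    assert reg["Conv2d_2"].get("out_shape") == S(147, 147, 32)
    assert reg["Conv2d_3"].get("out_shape") == S(147, 147, 64)
    # conv kernel parameters alone: 3*3*3*32 + 32 biases
    conv1 = model299.network._by_name["Conv2d_1"].layer
    assert sum(p.size for p in conv1.params.values()) == 3 * 3 * 3 * 32 + 32


def test_block_fusion_shapes(model299):
    reg = model299.registry
    assert reg["Concatenate_1"]["out_shape"] == S(73, 73, 160)
    assert reg["Concatenate_2"]["out_shape"] == S(71, 71, 192)
    assert reg["Concatenate_3"]["out_shape"] == S(35, 35, 384)
    assert reg["Concatenate_4"]["out_shape"] == S(35, 35, 128)
    assert reg["Add"]["out_shape"] == S(35, 35, 384)
    assert reg["Average_pooling2d_1"]["out_shape"] == S(4, 4, 384)


def test_altered_filter_count_flagged_as_mismatch(model299, table):
    """Corrupting the registry (as a mis-built Conv2d_4 would) must surface
    as a Concatenate_1 channel mismatch, not pass silently."""
    import copy

    broken = copy.copy(model299)
    broken.registry = copy.deepcopy(model299.registry)
    broken.registry["Conv2d_4"]["out_shape"] = S(73, 73, 64)
    broken.registry["Concatenate_1"]["in_shapes"] = [S(73, 73, 64), S(73, 73, 64)]
    broken.registry["Concatenate_1"]["out_shape"] = S(73, 73, 128)
    report = conformance_check(broken, table)
    assert not report.passed
    assert any(o.name == "Concatenate_1" for o in report.mismatches)


def test_missing_layer_reported_not_raised(model299, table):
    import copy

    broken = copy.copy(model299)
    broken.registry = {k: v for k, v in model299.registry.items() if k != "Add"}
    report = conformance_check(broken, table)
    assert any(o.name == "Add" and o.detail == "layer missing"
               for o in report.mismatches)


def _formula_param_count(model) -> int:
    """Brute-force per-layer parameter formulas: conv fh*fw*cin*cout + cout,
    dense nin*nout + nout, batch norm 4*c (scale, shift, two moving stats)."""
    import fus2net.nn as nn

    total = 0
    for node in model.network.nodes:
        layer = node.layer
        if isinstance(layer, nn.Conv2D):
            total += layer.fh * layer.fw * layer.cin * layer.cout + layer.cout
        elif isinstance(layer, nn.Dense):
            nin, nout = layer.params["W"].shape
            total += nin * nout + nout
        elif isinstance(layer, nn.BatchNorm):
            total += 4 * layer.params["gamma"].size
    return total


def test_total_param_count_matches_formula_oracle(model299):
    assert model299.param_count() == _formula_param_count(model299)


# ------------------------------------------------------------ forward


def test_forward_probabilities_sum_to_one(small_model, rng):
    x = rng.standard_normal((4, 48, 48, 3))
    p = forward(small_model, x)
    assert p.shape == (4, 2)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


def test_forward_batch_independence_in_inference(small_model, rng):
    x = rng.standard_normal((16, 48, 48, 3)).astype(np.float32)
    single = forward(small_model, x[:1])
    batched = forward(small_model, x)
    np.testing.assert_allclose(single[0], batched[0], atol=1e-5)


def test_forward_rejects_wrong_shape(small_model, rng):
    with pytest.raises(ValueError):
        forward(small_model, rng.standard_normal((2, 32, 32, 3)))


def test_fresh_model_predicts_near_half_on_average(small_model, rng):
    """Symmetric init with zero biases: mean malignant probability over 100
    random inputs stays near 0.5."""
    x = rng.standard_normal((100, 48, 48, 3))
    p = forward(small_model, x)
    assert abs(p[:, 1].mean() - 0.5) < 0.15


def test_residual_identity_limit():
    """With the three Block 2 branches zeroed, the block output reduces to
    BN+ReLU of its input regardless of the residual scale."""
    import fus2net.nn as nn

    model = build_fus2net(Fus2NetConfig(input_size=48, seed=3))
    net = model.network
    for name in ("Conv2d_18",):
        layer = net._by_name[name].layer
        layer.params["W"][...] = 0.0
        layer.params["b"][...] = 0.0
    x = np.random.default_rng(5).standard_normal((1, 48, 48, 3)).astype(np.float32)
    cache = {nn.INPUT: x}
    for node in net.nodes:
        cache[node.name] = node.layer.forward([cache[s] for s in node.inputs], False)
    trunk_in = cache["Concatenate_3"]
    post = cache["post_add_relu"]
    bn = net._by_name["post_add_bn"].layer
    expected = np.maximum(bn.forward([cache["Concatenate_3"]], False), 0)
    np.testing.assert_allclose(post, expected, atol=1e-5)
    np.testing.assert_array_equal(cache["Add"], trunk_in)


def test_gradient_reaches_every_parameter():
    """No dead branches: each parameter tensor receives a nonzero gradient
    on at least one random batch."""
    from fus2net.nn import softmax_cross_entropy

    model = build_fus2net(Fus2NetConfig(input_size=48, dropout_rate=0.0, seed=2))
    net = model.network
    rng = np.random.default_rng(0)
    nonzero = {}
    for trial in range(2):
        x = rng.standard_normal((4, 48, 48, 3)).astype(np.float32)
        y = rng.integers(0, 2, 4)
        logits = net.forward(x, training=True)
        _, d = softmax_cross_entropy(logits, y)
        net.backward(d)
        for name, key, _, grad in net.parameters():
            nonzero[(name, key)] = nonzero.get((name, key), False) or bool(
                np.any(grad != 0)
            )
    dead = [k for k, ok in nonzero.items() if not ok]
    assert not dead, f"parameters with zero gradient: {dead}"


def test_config_validation():
    with pytest.raises(ValueError):
        Fus2NetConfig(dropout_rate=1.5)
    with pytest.raises(ValueError):
        Fus2NetConfig(residual_scale=0.0)
    with pytest.raises(ValueError):
        Fus2NetConfig(channels=2)
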