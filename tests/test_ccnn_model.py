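"""Architecture construction, feature extraction and variants."""

import numpy as np
import pytest

from cceeg.ccnn_model import (
    ArchitectureSpec,
    build_model,
    default_architecture,
    extract_features,
    forward_probabilities,
    load_checkpoint,
    make_variant,
    save_checkpoint,
    spec_from_dict,
    spec_to_dict,
)
from cceeg.core_shapes import InvalidGeometryError


@pytest.fixture(scope="module")
def small_model():
    return build_model(default_architecture(), input_channels=8, input_length=512, seed=0)


def test_default_traces_reproduce_branch_tables():
    spec = default_architecture()
    traces = spec.shape_traces(input_channels=40, input_length=8064)
    assert traces[0].lengths == [8064, 8062, 4031, 100, 9]
    assert traces[1].lengths == [8064, 8062, 4031, 4029, 2015, 100, 9]
    assert traces[2].lengths == [8064, 8062, 4031, 4029, 2015, 2013, 1007, 100, 9]


def test_fused_feature_width_is_300(small_model, rng):
    x = rng.standard_normal((3, 8, 512))
    assert extract_features(small_model, x, "fused").shape == (3, 300)
    for level in ("bottom", "middle", "top"):
        assert extract_features(small_model, x, level).shape == (3, 100)


def test_fusion_is_columnwise_concatenation(small_model, rng):
    x = rng.standard_normal((2, 8, 512))
    fused = extract_features(small_model, x, "fused")
    parts = [extract_features(small_model, x, lvl) for lvl in ("bottom", "middle", "top")]
    assert np.array_equal(fused, np.concatenate(parts, axis=1))


def test_unknown_feature_level_rejected(small_model, rng):
    with pytest.raises(ValueError, match="unknown feature level"):
        extract_features(small_model, rng.standard_normal((1, 8, 512)), "penultimate")


def test_softmax_rows_sum_to_one(small_model, rng):
    probs = forward_probabilities(small_model, rng.standard_normal((5, 8, 512)))
    assert probs.shape == (5, 9)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)


def test_single_epoch_batch(small_model, rng):
    probs = forward_probabilities(small_model, rng.standard_normal((8, 512)))
    assert probs.shape == (1, 9)
    assert probs.sum() == pytest.approx(1.0, abs=1e-8)


def test_inference_is_deterministic(small_model, rng):
    x = rng.standard_normal((2, 8, 512))
    assert np.array_equal(
        forward_probabilities(small_model, x), forward_probabilities(small_model, x)
    )


def test_zero_final_layer_gives_uniform_ninths(small_model, rng):
    model = build_model(default_architecture(), 8, 512, seed=1)
    final_dense = model.network.head.layers[-1]
    final_dense.w.value[...] = 0.0
    final_dense.b.value[...] = 0.0
    probs = forward_probabilities(model, rng.standard_normal((4, 8, 512)))
    assert np.allclose(probs, 1.0 / 9.0, atol=1e-12)


def test_geometry_mismatch_rejected(small_model, rng):
    with pytest.raises(ValueError, match="does not match"):
        forward_probabilities(small_model, rng.standard_normal((2, 8, 100)))


def test_too_short_input_raises_with_branch_context():
    with pytest.raises(InvalidGeometryError, match="branch"):
        build_model(default_architecture(), input_channels=8, input_length=4)


def test_parameter_count_stable_across_builds():
    a = build_model(default_architecture(), 8, 512, seed=0)
    b = build_model(default_architecture(), 8, 512, seed=99)
    assert a.parameter_count == b.parameter_count > 0


def test_shared_stem_trace_and_geometry_match_parallel(rng):
    par = default_architecture(topology="parallel")
    shared = default_architecture(topology="shared_stem")
    assert [t.lengths for t in par.shape_traces(8, 512)] == [
        t.lengths for t in shared.shape_traces(8, 512)
    ]
    model = build_model(shared, 8, 512, seed=0)
    probs = forward_probabilities(model, rng.standard_normal((2, 8, 512)))
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-8)
    # the stem conv is built once: fewer parameters than three separate stems
    assert model.parameter_count < build_model(par, 8, 512, seed=0).parameter_count


def test_make_variant_widths():
    spec = default_architecture()
    assert make_variant(spec, 0) == spec
    assert make_variant(spec, 1).fused_width == 400
    assert make_variant(spec, 2).fused_width == 500


def test_variant_traces_succeed_at_full_length(rng):
    spec = make_variant(default_architecture(), 2)
    traces = spec.shape_traces(input_channels=40, input_length=8064)
    assert len(traces) == 5
    assert traces[3].lengths[-3] == 503   # one block past 1007
    assert traces[4].lengths[-3] == 251   # two blocks past 1007
    model = build_model(spec, 8, 512, seed=0)
    feats = extract_features(model, rng.standard_normal((2, 8, 512)), "fused")
    assert feats.shape == (2, 500)
    assert len(model.network.extra_convs) == 3  # one in the +1 tap, two in the +2 tap


def test_invalid_spec_rejected():
    with pytest.raises(ValueError):
        default_architecture(extra_layers=5)
    with pytest.raises(ValueError):
        default_architecture(dropout_rate=1.0)
    with pytest.raises(ValueError):
        ArchitectureSpec(branches=(tuple(), tuple(), tuple()))


def test_spec_dict_roundtrip():
    spec = default_architecture(topology="shared_stem", dropout_rate=0.25, extra_layers=1)
    assert spec_from_dict(spec_to_dict(spec)) == spec
    with pytest.raises(ValueError, match="unknown architecture keys"):
        spec_from_dict({"n_layers": 4})


def test_checkpoint_roundtrip(tmp_path, small_model, rng):
    x = rng.standard_normal((3, 8, 512))
    save_checkpoint(small_model, tmp_path / "model")
    restored = load_checkpoint(tmp_path / "model")
    assert np.allclose(
        forward_probabilities(small_model, x), forward_probabilities(restored, x)
    )
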